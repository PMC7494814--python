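"""Stranded genomic intervals and the genome-arithmetic vocabulary.

Coordinates are 1-based and fully closed: ``chr1:100-119`` spans 20 bases.
BED input (0-based, half-open) is converted at the I/O boundary
(:mod:`guideforge.genome`).

All arithmetic operations (:func:`extend`, :func:`up_flank`,
:func:`down_flank`, :func:`double_flank`, :func:`cutsite_to_spacer`) accept
and return lists of :class:`GenomeInterval` and are strand-aware on demand:
for a minus-strand interval a strand-aware operation applies its offsets in
the interval's own 5'->3' reading direction, which mirrors the arithmetic on
the genomic axis.  Offsets never merge intervals: each output keeps the
identity (``name``) of its parent target, which downstream target-set
specific filtering depends on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Sequence

if TYPE_CHECKING:  # pragma: no cover
    from .genome import Genome

logger = logging.getLogger("guideforge")

PLUS = "+"
MINUS = "-"
UNSTRANDED = "*"
_STRANDS = {PLUS, MINUS, UNSTRANDED}


class IntervalError(ValueError):
    """Base class for interval-arithmetic failures."""


class OutOfBoundsError(IntervalError):
    """Resulting coordinates leave ``[1, chromosome length]``."""


class DegenerateIntervalError(IntervalError):
    """Offsets would produce an interval of width < 1."""


@dataclass(frozen=True)
class GenomeInterval:
    """One stranded genomic range, 1-based, closed on both ends.

    The universal currency of the package: targets, spacers, PAMs and nick
    sites are all ``GenomeInterval`` instances.
    """

    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED
    name: str = ""

    def __post_init__(self) -> None:
        if self.start < 1:
            raise DegenerateIntervalError(
                f"start must be >= 1, got {self.start} ({self})"
            )
        if self.end < self.start:
            raise DegenerateIntervalError(
                f"end < start in {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in _STRANDS:
            raise IntervalError(f"strand must be one of +, -, *: {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.strand}"

    @classmethod
    def parse(cls, text: str, name: str = "") -> "GenomeInterval":
        """Parse ``chrom:start-end:strand`` (strand optional, defaults ``*``)."""
        parts = text.split(":")
        if len(parts) == 2:
            chrom, span = parts
            strand = UNSTRANDED
        elif len(parts) == 3:
            chrom, span, strand = parts
        else:
            raise IntervalError(f"cannot parse interval {text!r}")
        if "-" in span:
            start_s, end_s = span.split("-")
        else:
            start_s = end_s = span
        return cls(chrom, int(start_s), int(end_s), strand, name)

    def overlaps(self, other: "GenomeInterval") -> bool:
        """True when the two ranges share >= 1 base (strand ignored)."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )


@dataclass(frozen=True)
class ArithmeticPreset:
    """A named (start_offset, end_offset, mode) triple for one application."""

    name: str
    start_offset: int | None
    end_offset: int | None
    mode: str  # extend | up_flank | down_flank | double_flank
    strand_aware: bool = True
    description: str = ""


#: Built-in presets covering the standard CRISPR applications.
#:
#: - ``cut_within``:  strand-specific [-16, +5] extension so that the Cas9
#:   cut (after protospacer base 17) falls inside the original target.
#: - ``block``:       [-22, +22] extension so that every spacer/PAM word
#:   overlapping the search space still touches the target by >= 1 base.
#: - ``crispri``:     [-50, +300] strand-agnostic extension of a TSS for
#:   dCas9-repressor tiling.
#: - ``crispra``:     [-300, 0] strand-agnostic upstream flank of a TSS for
#:   dCas9-activator binding.
#: - ``excise``:      [-16, +x] downstream flank for a nickase pair in
#:   PAM-out orientation; ``x`` is application-specific and required.
#: - ``vicinity``:    double flank, searching both sides of the target.
PRESETS: dict[str, ArithmeticPreset] = {
    "cut_within": ArithmeticPreset("cut_within", -16, 5, "extend", True),
    "block": ArithmeticPreset("block", -22, 22, "extend", True),
    "crispri": ArithmeticPreset("crispri", -50, 300, "extend", False),
    "crispra": ArithmeticPreset("crispra", -300, 0, "up_flank", False),
    "excise": ArithmeticPreset("excise", -16, None, "down_flank", True),
    "vicinity": ArithmeticPreset("vicinity", None, None, "double_flank", True),
}


def _effective_strand(iv: GenomeInterval, strand_aware: bool) -> str:
    """Strand used for arithmetic; unstranded acts as plus (with a warning)."""
    if not strand_aware:
        return PLUS
    if iv.strand == UNSTRANDED:
        logger.warning(
            "strand-aware operation on unstranded interval %s: treating as '+'", iv
        )
        return PLUS
    return iv.strand


def _check_bounds(
    iv: GenomeInterval,
    start: int,
    end: int,
    genome: "Genome | None",
    clip: bool,
) -> tuple[int, int]:
    if end < start:
        raise DegenerateIntervalError(
            f"offsets collapse {iv} to width {end - start + 1}"
        )
    chrom_len = None
    if genome is not None:
        chrom_len = genome.chrom_length(iv.chrom)
    if start < 1 or (chrom_len is not None and end > chrom_len):
        if not clip:
            raise OutOfBoundsError(
                f"{iv.chrom}:{start}-{end} leaves [1, {chrom_len or 'inf'}] "
                f"(from {iv})"
            )
        new_start = max(start, 1)
        new_end = min(end, chrom_len) if chrom_len is not None else end
        logger.warning(
            "clipped %s:%d-%d to %s:%d-%d", iv.chrom, start, end, iv.chrom,
            new_start, new_end,
        )
        if new_end < new_start:
            raise DegenerateIntervalError(f"clipping {iv} left an empty interval")
        return new_start, new_end
    return start, end


def extend(
    intervals: Sequence[GenomeInterval],
    start_offset: int,
    end_offset: int,
    strand_aware: bool = True,
    genome: "Genome | None" = None,
    clip: bool = False,
) -> list[GenomeInterval]:
    """Grow (or shrink) each interval at both ends.

    On the plus strand (or with ``strand_aware=False``) the result is
    ``[start + start_offset, end + end_offset]``.  A strand-aware call on a
    minus-strand interval applies the offsets in 5'->3' reading direction,
    i.e. ``[start - end_offset, end - start_offset]``.
    """
    out = []
    for iv in intervals:
        if _effective_strand(iv, strand_aware) == MINUS:
            s, e = iv.start - end_offset, iv.end - start_offset
        else:
            s, e = iv.start + start_offset, iv.end + end_offset
        s, e = _check_bounds(iv, s, e, genome, clip)
        out.append(replace(iv, start=s, end=e))
    return out


def up_flank(
    intervals: Sequence[GenomeInterval],
    start_offset: int,
    end_offset: int,
    strand_aware: bool = True,
    genome: "Genome | None" = None,
    clip: bool = False,
) -> list[GenomeInterval]:
    """Flank anchored at the 5' end of each interval.

    Plus strand: ``[start + start_offset, start + end_offset]``; a
    strand-aware minus interval anchors at its own 5' end (genomic ``end``)
    with mirrored offsets.
    """
    if start_offset > end_offset:
        raise IntervalError("up_flank requires start_offset <= end_offset")
    out = []
    for iv in intervals:
        if _effective_strand(iv, strand_aware) == MINUS:
            s, e = iv.end - end_offset, iv.end - start_offset
        else:
            s, e = iv.start + start_offset, iv.start + end_offset
        s, e = _check_bounds(iv, s, e, genome, clip)
        out.append(replace(iv, start=s, end=e))
    return out


def down_flank(
    intervals: Sequence[GenomeInterval],
    start_offset: int,
    end_offset: int,
    strand_aware: bool = True,
    genome: "Genome | None" = None,
    clip: bool = False,
) -> list[GenomeInterval]:
    """Flank anchored at the 3' end of each interval (mirror of up_flank)."""
    if start_offset > end_offset:
        raise IntervalError("down_flank requires start_offset <= end_offset")
    out = []
    for iv in intervals:
        if _effective_strand(iv, strand_aware) == MINUS:
            s, e = iv.start - end_offset, iv.start - start_offset
        else:
            s, e = iv.end + start_offset, iv.end + end_offset
        s, e = _check_bounds(iv, s, e, genome, clip)
        out.append(replace(iv, start=s, end=e))
    return out


def double_flank(
    intervals: Sequence[GenomeInterval],
    up_offsets: tuple[int, int],
    down_offsets: tuple[int, int],
    strand_aware: bool = True,
    genome: "Genome | None" = None,
    clip: bool = False,
) -> list[GenomeInterval]:
    """Both flanks of each target, two output intervals per input.

    Each output keeps the parent target's name so hits found in either
    flank can be attributed back to it.
    """
    ups = up_flank(intervals, *up_offsets, strand_aware, genome, clip)
    downs = down_flank(intervals, *down_offsets, strand_aware, genome, clip)
    out = []
    for u, d in zip(ups, downs):
        out.append(u)
        out.append(d)
    return out


def cutsite_to_spacer(
    cut_positions: Sequence[GenomeInterval],
    genome: "Genome | None" = None,
    clip: bool = False,
) -> list[GenomeInterval]:
    """Expand width-1 cut-site coordinates to the full 20-nt spacer range.

    Cas9 cuts after protospacer base 17, so a recorded cut position expands
    with a [-17, +2] extension on the plus strand and [-16, +3] on the minus
    strand; every output has width exactly 20.
    """
    out = []
    for iv in cut_positions:
        if iv.width != 1:
            raise IntervalError(f"cut position must have width 1: {iv}")
        if iv.strand == MINUS:
            s, e = iv.start - 16, iv.start + 3
        else:
            s, e = iv.start - 17, iv.start + 2
        s, e = _check_bounds(iv, s, e, genome, clip)
        out.append(replace(iv, start=s, end=e))
    return out


def apply_preset(
    intervals: Sequence[GenomeInterval],
    preset: str | ArithmeticPreset,
    genome: "Genome | None" = None,
    clip: bool = False,
    excise_x: int | None = None,
    vicinity_offsets: tuple[tuple[int, int], tuple[int, int]] | None = None,
) -> list[GenomeInterval]:
    """Transform targets into spacer-search ranges with a named preset."""
    p = PRESETS[preset] if isinstance(preset, str) else preset
    if p.mode == "extend":
        return extend(intervals, p.start_offset, p.end_offset, p.strand_aware,
                      genome, clip)
    if p.mode == "up_flank":
        return up_flank(intervals, p.start_offset, p.end_offset, p.strand_aware,
                        genome, clip)
    if p.mode == "down_flank":
        end_offset = p.end_offset if p.end_offset is not None else excise_x
        if end_offset is None:
            raise IntervalError(
                f"preset {p.name!r} needs its downstream extent (excise_x)"
            )
        return down_flank(intervals, p.start_offset, end_offset, p.strand_aware,
                          genome, clip)
    if p.mode == "double_flank":
        if vicinity_offsets is None:
            raise IntervalError(
                f"preset {p.name!r} needs explicit (up, down) offset pairs"
            )
        return double_flank(intervals, *vicinity_offsets, p.strand_aware,
                            genome, clip)
    raise IntervalError(f"unknown preset mode {p.mode!r}")
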