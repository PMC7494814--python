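"""Genome-wide k-mismatch counting and target-set-specific filtering (TSSF).

Two engines count, for every spacer, the number of genomic windows (both
strands) at Hamming distance exactly m for m = 0..max_mm:

``exact``
    Full-sensitivity multi-pattern scan: every window of the genome is
    compared against every spacer (vectorised with numpy).  G_m is the true
    count at every level.

``seeded``
    Seed-and-verify: each spacer is partitioned into max_mm + 1 contiguous
    seeds; by the pigeonhole principle any window within max_mm mismatches
    preserves at least one seed exactly, so looking up exact seed
    occurrences and verifying candidates by a full Hamming check reports
    only true matches (precision 1.0) and, with contiguous-partition seeds,
    misses none.  The sensitivity contract it must satisfy is: complete at
    m <= 1, and never exceeding the exact engine at any m.

TSSF then attributes each genome match to the declared target set:
T_m = matches at level m overlapping any target range by >= 1 base
(match strand is ignored for attribution), and

    off_m = G_m - T_m,      off = sum of off_m over m = 0..max_mm

so that cross-target matches - matches landing inside *other* declared
targets - are not penalised as off-targets.  This is what makes parallel
targeting of many near-identical sites (e.g. transcription-factor binding
sites) workable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from intervaltree import IntervalTree

from .genome import Genome, revcomp
from .intervals import MINUS, PLUS, GenomeInterval
from .spacers import SpacerHit

MAX_SUPPORTED_MM = 3

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_ENCODE_TABLE = np.full(256, 4, dtype=np.uint8)  # anything unusual -> 4
for _b, _c in _BASE_CODE.items():
    _ENCODE_TABLE[ord(_b)] = _c


class ConsistencyError(RuntimeError):
    """Internal bookkeeping violation (e.g. T_m > G_m)."""


@dataclass
class MatchCounts:
    """Per-spacer match counts by mismatch level.

    ``G[m]`` genome-wide matches, ``T[m]`` matches overlapping the target
    set, ``off[m] = G[m] - T[m]`` off-target matches; ``off_total`` sums
    off over all levels.
    """

    max_mm: int
    G: list[int] = field(default_factory=list)
    T: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.G:
            self.G = [0] * (self.max_mm + 1)
        if not self.T:
            self.T = [0] * (self.max_mm + 1)

    @property
    def off(self) -> list[int]:
        out = []
        for m, (g, t) in enumerate(zip(self.G, self.T)):
            if t > g:
                raise ConsistencyError(
                    f"T{m} = {t} > G{m} = {g}: targets are not a subset of "
                    "the scanned genome"
                )
            out.append(g - t)
        return out

    @property
    def off_total(self) -> int:
        return sum(self.off)


@dataclass(frozen=True)
class GenomeMatch:
    """One genomic occurrence of a spacer within max_mm mismatches."""

    spacer_seq: str
    interval: GenomeInterval
    strand: str
    mismatches: int
    matched_seq: str


def _encode(seq: str) -> np.ndarray:
    return _ENCODE_TABLE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def _pam_mask(codes: np.ndarray, pam: str, offset: int,
              n_windows: int) -> np.ndarray:
    """Boolean mask over window starts whose [offset, offset+|pam|) bases
    match the IUPAC PAM pattern (genome N never matches)."""
    from .genome import IUPAC

    mask = np.ones(n_windows, dtype=bool)
    for j, code in enumerate(pam):
        allowed = [_BASE_CODE[b] for b in IUPAC[code]]
        col = codes[offset + j : offset + j + n_windows]
        ok = np.zeros(n_windows, dtype=bool)
        for a in allowed:
            ok |= col == a
        mask &= ok
    return mask


def _window_mismatches(codes: np.ndarray, pattern: np.ndarray) -> np.ndarray:
    """Hamming distance of every length-L window of ``codes`` to ``pattern``."""
    L = len(pattern)
    n = len(codes) - L + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int16)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)
    return (win != pattern).sum(axis=1, dtype=np.int16)


def _scan_exact(codes: np.ndarray, pattern: np.ndarray, max_mm: int
                ) -> tuple[np.ndarray, np.ndarray]:
    """(positions, mismatch counts) of all windows within max_mm."""
    mm = _window_mismatches(codes, pattern)
    pos = np.nonzero(mm <= max_mm)[0]
    return pos, mm[pos]


def _seed_partition(length: int, n_seeds: int) -> list[tuple[int, int]]:
    """Split [0, length) into n_seeds contiguous (offset, size) chunks."""
    base, extra = divmod(length, n_seeds)
    chunks = []
    off = 0
    for i in range(n_seeds):
        size = base + (1 if i < extra else 0)
        chunks.append((off, size))
        off += size
    return chunks


def _window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-5 integer encoding of every length-k window (5 covers the N
    sentinel, so windows containing N never equal an ACGT-only seed)."""
    n = len(codes) - k + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64)
    win = np.lib.stride_tricks.sliding_window_view(codes, k).astype(np.int64)
    powers = 5 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return win @ powers


def _scan_seeded(codes: np.ndarray, pattern: np.ndarray, max_mm: int
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Pigeonhole seed-and-verify scan; same return shape as _scan_exact."""
    L = len(pattern)
    n = len(codes) - L + 1
    if n <= 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int16)
    candidates: list[np.ndarray] = []
    for off, size in _seed_partition(L, max_mm + 1):
        seed = pattern[off : off + size].astype(np.int64)
        seed_code = int(seed @ (5 ** np.arange(size - 1, -1, -1, dtype=np.int64)))
        wc = _window_codes(codes, size)
        hit = np.nonzero(wc == seed_code)[0] - off
        hit = hit[(hit >= 0) & (hit < n)]
        candidates.append(hit)
    pos = np.unique(np.concatenate(candidates))
    if len(pos) == 0:
        return pos, np.zeros(0, dtype=np.int16)
    win = np.lib.stride_tricks.sliding_window_view(codes, L)[pos]
    mm = (win != pattern).sum(axis=1, dtype=np.int16)
    keep = mm <= max_mm
    return pos[keep], mm[keep]


Engine = Literal["exact", "seeded"]
PamMode = Literal["agnostic", "required"]


def count_genome_matches(
    spacers: Sequence[SpacerHit] | Sequence[str],
    genome: Genome,
    max_mm: int = 2,
    engine: Engine = "seeded",
    pam_mode: PamMode = "agnostic",
    pam: str = "NGG",
) -> tuple[dict[str, MatchCounts], list[GenomeMatch]]:
    """Count genome-wide matches per unique spacer sequence.

    Returns partially filled :class:`MatchCounts` (G only) keyed by spacer
    sequence, plus the individual :class:`GenomeMatch` records needed for
    target attribution.  ``pam_mode='required'`` restricts counting to
    windows followed (3' on the match strand) by the PAM pattern; the
    default is PAM-agnostic plain k-mismatch counting.
    """
    if not 0 <= max_mm <= MAX_SUPPORTED_MM:
        raise ValueError(f"max_mm must be in [0, {MAX_SUPPORTED_MM}]")
    seqs = []
    for sp in spacers:
        seqs.append(sp if isinstance(sp, str) else sp.spacer_seq)
    lengths = {len(s) for s in seqs}
    if len(lengths) > 1:
        raise ValueError(f"mixed spacer lengths: {sorted(lengths)}")
    unique = sorted(set(seqs))
    scan = _scan_exact if engine == "exact" else _scan_seeded
    if engine not in ("exact", "seeded"):
        raise ValueError(f"unknown engine {engine!r}")

    counts = {s: MatchCounts(max_mm) for s in unique}
    matches: list[GenomeMatch] = []
    if not unique:
        return counts, matches
    L = lengths.pop()
    plen = len(pam)

    for chrom in genome.chroms:
        text = genome.sequences[chrom]
        codes = _encode(text)
        n = len(codes) - L + 1
        if n <= 0:
            continue
        if pam_mode == "required":
            from .genome import revcomp as _rc

            n_pam_plus = len(codes) - (L + plen) + 1
            plus_pam = np.zeros(n, dtype=bool)
            if n_pam_plus > 0:
                plus_pam[:n_pam_plus] = _pam_mask(codes, pam, L, n_pam_plus)
            # minus-strand window at plus positions [i, i+L): PAM occupies
            # [i-plen, i) as revcomp(pam) on the plus strand
            minus_pam = np.zeros(n, dtype=bool)
            if n - plen > 0:
                minus_pam[plen:] = _pam_mask(codes, _rc(pam), 0, n - plen)
        for seq in unique:
            pat_plus = _encode(seq)
            pat_minus = _encode(revcomp(seq))
            for strand, pat in ((PLUS, pat_plus), (MINUS, pat_minus)):
                pos, mm = scan(codes, pat, max_mm)
                if pam_mode == "required" and len(pos):
                    mask = (plus_pam if strand == PLUS else minus_pam)[pos]
                    pos, mm = pos[mask], mm[mask]
                for p, m in zip(pos.tolist(), mm.tolist()):
                    counts[seq].G[m] += 1
                    iv = GenomeInterval(chrom, p + 1, p + L, strand)
                    matched = text[p : p + L]
                    if strand == MINUS:
                        matched = revcomp(matched)
                    matches.append(GenomeMatch(seq, iv, strand, m, matched))
    return counts, matches


def count_target_matches(
    matches: Sequence[GenomeMatch],
    targets: Sequence[GenomeInterval],
    max_mm: int = 2,
) -> dict[str, MatchCounts]:
    """T_m per spacer: matches overlapping any target range by >= 1 base.

    Attribution ignores the match strand: a minus-strand match inside a
    plus-strand target counts.  An empty target set yields all-zero T.
    """
    trees: dict[str, IntervalTree] = {}
    for t in targets:
        trees.setdefault(t.chrom, IntervalTree()).addi(t.start, t.end + 1)
    counts: dict[str, MatchCounts] = {}
    for gm in matches:
        c = counts.setdefault(gm.spacer_seq, MatchCounts(max_mm))
        tree = trees.get(gm.interval.chrom)
        if tree is not None and tree.overlaps(gm.interval.start,
                                              gm.interval.end + 1):
            c.T[gm.mismatches] += 1
    return counts


def aggregate_off(
    G: dict[str, MatchCounts],
    T: dict[str, MatchCounts],
    max_mm: int = 2,
) -> dict[str, MatchCounts]:
    """Merge G and T into full MatchCounts; off_m = G_m - T_m.

    Raises :class:`ConsistencyError` if any T_m exceeds G_m, which would
    mean the target set is not a subset of the scanned genome.
    """
    out: dict[str, MatchCounts] = {}
    for seq, g in G.items():
        t = T.get(seq, MatchCounts(max_mm))
        mc = MatchCounts(max_mm, G=list(g.G), T=list(t.T))
        mc.off  # noqa: B018 - validates T_m <= G_m eagerly
        out[seq] = mc
    return out


def filter_spacers(
    spacers: Sequence[SpacerHit],
    counts: dict[str, MatchCounts],
    policy: str = "parallel",
    require_off_free: bool = True,
) -> list[SpacerHit]:
    """Apply an off-target retention policy.

    ``parallel``
        Keep spacers with off = 0 up to max_mm; cross-target matches are
        permitted (they are not off-targets under TSSF).
    ``unique``
        Keep spacers with G0 = 1 (only the self-match); with
        ``require_off_free`` additionally demand off_m = 0 at every level.
        This is the policy for prime editing and classic single-locus work.
    """
    out = []
    for sp in spacers:
        mc = counts.get(sp.spacer_seq)
        if mc is None:
            continue
        if policy == "parallel":
            if mc.off_total == 0:
                out.append(sp)
        elif policy == "unique":
            if mc.G[0] == 1 and (not require_off_free or mc.off_total == 0):
                out.append(sp)
        else:
            raise ValueError(f"unknown policy {policy!r}")
    return out
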