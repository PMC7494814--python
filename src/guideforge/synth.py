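"""Seeded synthetic genomes with planted spacer matches.

Every other module is testable without downloading a reference genome:
:func:`make_genome` builds a random background of a chosen GC composition
and plants copies of given sequences at requested loci, each copy carrying
an exact number of mismatches.  The background is rejection-sampled so it
contains no *additional* occurrence of any planted core 20-mer within the
requested mismatch radius - verified with :func:`brute_force_matches`, the
deliberately naive all-windows Hamming scanner that also serves as the
independent oracle for the off-target engines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .genome import Genome, revcomp
from .intervals import MINUS, PLUS
from .offtargets import MatchCounts

logger = logging.getLogger("guideforge")

_BASES = "ACGT"


@dataclass(frozen=True)
class Placement:
    """One planted copy: where, which strand, how many mismatches."""

    chrom: str
    position: int  # 1-based start of the planted word
    strand: str = PLUS
    mismatches: int = 0
    mutate_pam: bool = False  # mismatches never land in a 3' NGG unless asked


@dataclass
class PlantSpec:
    """Plan for a synthetic genome.

    ``base_seq`` is the word to plant (typically spacer+PAM, 23 nt; the
    first ``core_len`` bases are the spacer whose neighbourhood must stay
    clean in the background).
    """

    base_seq: str
    placements: Sequence[Placement]
    chrom_lengths: Mapping[str, int]
    gc: float = 0.41
    core_len: int = 20
    max_mm: int = 2

    def __post_init__(self) -> None:
        self.base_seq = self.base_seq.upper()
        ends: dict[str, list[tuple[int, int]]] = {}
        for p in self.placements:
            if p.chrom not in self.chrom_lengths:
                raise ValueError(f"placement on unknown chrom {p.chrom!r}")
            span = (p.position, p.position + len(self.base_seq) - 1)
            if span[0] < 1 or span[1] > self.chrom_lengths[p.chrom]:
                raise ValueError(f"placement {p} outside chromosome")
            for s in ends.setdefault(p.chrom, []):
                if span[0] <= s[1] and s[0] <= span[1]:
                    raise ValueError(f"overlapping placements on {p.chrom}")
            ends[p.chrom].append(span)


def _mutate(word: str, n: int, rng: np.random.Generator,
            protect: range | None = None) -> str:
    """Exactly n substitutions, avoiding ``protect`` positions."""
    positions = [i for i in range(len(word)) if protect is None or i not in protect]
    if n > len(positions):
        raise ValueError("more mismatches requested than mutable positions")
    chosen = rng.choice(len(positions), size=n, replace=False)
    out = list(word)
    for idx in chosen:
        i = positions[int(idx)]
        out[i] = rng.choice([b for b in _BASES if b != out[i]])
    return "".join(out)


def make_genome(plan: PlantSpec, seed: int, max_retries: int = 50,
                fasta_path: str | None = None) -> Genome:
    """Reproducible synthetic genome honouring ``plan``.

    The background is redrawn (bounded by ``max_retries``) until no
    background window lies within ``plan.max_mm`` mismatches of the
    planted core on either strand; unsatisfiable plans raise.
    """
    rng = np.random.default_rng(seed)
    core = plan.base_seq[: plan.core_len]
    pam_protect = (range(plan.core_len, len(plan.base_seq))
                   if plan.placements and not any(p.mutate_pam
                                                  for p in plan.placements)
                   else None)

    expected = MatchCounts(plan.max_mm)
    words: dict[tuple[str, int], str] = {}
    for p in plan.placements:
        protect = None if p.mutate_pam else pam_protect
        word = (plan.base_seq if p.mismatches == 0
                else _mutate(plan.base_seq, p.mismatches, rng, protect))
        if p.strand == MINUS:
            word = revcomp(word)
        words[(p.chrom, p.position)] = word
        if p.mismatches <= plan.max_mm:
            expected.G[p.mismatches] += 1

    probs = np.array([(1 - plan.gc) / 2, plan.gc / 2, plan.gc / 2,
                      (1 - plan.gc) / 2])
    for attempt in range(max_retries):
        seqs = {}
        for chrom, length in plan.chrom_lengths.items():
            arr = rng.choice(list(_BASES), size=length, p=probs)
            seqs[chrom] = "".join(arr)
        for (chrom, pos), word in words.items():
            s = seqs[chrom]
            seqs[chrom] = s[: pos - 1] + word + s[pos - 1 + len(word):]
        genome = Genome(seqs, assembly_name=f"synthetic(seed={seed})")
        observed = brute_force_matches(core, genome, plan.max_mm)
        if observed.G == _expected_core_counts(plan, genome):
            if fasta_path:
                genome.to_fasta(fasta_path)
            return genome
        logger.info("background collision, redrawing (attempt %d)", attempt + 1)
    raise RuntimeError(
        f"could not satisfy plant constraints in {max_retries} attempts"
    )


def _expected_core_counts(plan: PlantSpec, genome: Genome) -> list[int]:
    """Core-20-mer counts implied by the placements alone.

    Recomputed against the actually planted words (a mutated copy's
    distance to the core can differ from the requested word distance when
    mutations fall in the PAM part, which is excluded from the core scan).
    """
    counts = [0] * (plan.max_mm + 1)
    for p in plan.placements:
        start = p.position if p.strand == PLUS else (
            p.position + len(plan.base_seq) - plan.core_len)
        seq = genome.sequences[p.chrom][start - 1 : start - 1 + plan.core_len]
        if p.strand == MINUS:
            seq = revcomp(seq)
        d = hamming(seq, plan.base_seq[: plan.core_len])
        if d <= plan.max_mm:
            counts[d] += 1
    return counts


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(x != y for x, y in zip(a, b))


def brute_force_matches(spacer: str, genome: Genome, max_mm: int
                        ) -> MatchCounts:
    """Literal scan of every window on both strands - the oracle.

    No indexing, no seeding, no vectorised tricks: per-window Hamming
    distance against the spacer (plus strand) and its reverse complement
    (minus strand).  A genome N never matches any spacer base.
    """
    spacer = spacer.upper()
    L = len(spacer)
    rc = revcomp(spacer)
    counts = MatchCounts(max_mm)
    for chrom, seq in genome.sequences.items():
        for i in range(len(seq) - L + 1):
            window = seq[i : i + L]
            d_plus = hamming(window, spacer)
            if d_plus <= max_mm:
                counts.G[d_plus] += 1
            d_minus = hamming(window, rc)
            if d_minus <= max_mm:
                counts.G[d_minus] += 1
    return counts


def brute_force_match_list(spacer: str, genome: Genome, max_mm: int
                           ) -> list[tuple[str, int, str, int]]:
    """(chrom, 1-based start, strand, mismatches) for every window within
    max_mm; the positional companion of :func:`brute_force_matches`."""
    spacer = spacer.upper()
    L = len(spacer)
    rc = revcomp(spacer)
    out = []
    for chrom, seq in genome.sequences.items():
        for i in range(len(seq) - L + 1):
            window = seq[i : i + L]
            d = hamming(window, spacer)
            if d <= max_mm:
                out.append((chrom, i + 1, PLUS, d))
            d = hamming(window, rc)
            if d <= max_mm:
                out.append((chrom, i + 1, MINUS, d))
    return out


def random_genome(chrom_lengths: Mapping[str, int], seed: int,
                  gc: float = 0.41) -> Genome:
    """Plain random background, no planting constraints."""
    rng = np.random.default_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seqs = {c: "".join(rng.choice(list(_BASES), size=n, p=probs))
            for c, n in chrom_lengths.items()}
    return Genome(seqs, assembly_name=f"random(seed={seed})")
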