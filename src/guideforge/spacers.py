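"""Spacer/PAM discovery inside (transformed) target ranges.

The default search pattern is the wild-type *S. pyogenes* N20-NGG
spacer/PAM word; both pattern and spacer length are configurable.  A hit is
any full spacer+PAM word lying entirely inside a target range, on either
strand.  Requiring full containment is what gives the arithmetic presets
their guarantees (e.g. a [-16, +5] extension forces the cut inside the
original target).

Hits are reported once per (location, strand, target): a spacer covered by
two overlapping targets yields two hits carrying different ``target_name``
values, because target-set-specific filtering needs per-target attribution.
Use :func:`dedupe_hits` for a location-unique view (library export).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .genome import IUPAC, Genome, revcomp
from .intervals import MINUS, PLUS, GenomeInterval

_ACGT = set("ACGT")


@dataclass(frozen=True)
class SpacerHit:
    """One spacer/PAM occurrence attributed to one target.

    ``cut_after`` is the genomic coordinate of the 17th protospacer base;
    Cas9 cleaves immediately 3' of it on the spacer strand, 3 bases 5' of
    the PAM.
    """

    spacer: GenomeInterval
    pam: GenomeInterval
    spacer_seq: str
    pam_seq: str
    cut_after: int
    target_name: str
    target: GenomeInterval | None = None

    @property
    def strand(self) -> str:
        return self.spacer.strand

    def sort_key(self) -> tuple:
        return (self.spacer.chrom, self.spacer.start, self.spacer.strand,
                self.target_name)


def _validate_pam(pam: str) -> str:
    pam = pam.upper()
    bad = set(pam) - set(IUPAC)
    if bad:
        raise ValueError(f"PAM pattern has non-IUPAC letters: {sorted(bad)}")
    return pam


def matches_iupac(seq: str, pattern: str) -> bool:
    """Genome-side IUPAC match: a genome ``N`` matches nothing."""
    if len(seq) != len(pattern):
        return False
    return all(base in IUPAC[code] for base, code in zip(seq, pattern))


def find_spacers(
    targets: Sequence[GenomeInterval],
    genome: Genome,
    pam: str = "NGG",
    spacer_len: int = 20,
) -> list[SpacerHit]:
    """All spacer/PAM words fully contained in the targets, both strands.

    Spacers overlapping any non-ACGT genome base are discarded (ambiguous
    spacers are experimentally unusable); PAM matching is IUPAC-aware on
    the pattern side only.  Output is sorted by (chrom, spacer start,
    strand, target) for determinism.
    """
    pam = _validate_pam(pam)
    plen, slen = len(pam), spacer_len
    word = slen + plen
    rc_pam = revcomp(pam)
    hits: list[SpacerHit] = []
    for ti, target in enumerate(targets):
        tname = target.name or f"T{ti:04d}"
        seq = genome.fetch(
            GenomeInterval(target.chrom, target.start, target.end, PLUS)
        )
        for i in range(0, len(seq) - word + 1):
            g = target.start + i  # genomic coordinate of window start
            # plus strand: [spacer][PAM]
            pam_seq = seq[i + slen : i + word]
            if matches_iupac(pam_seq, pam):
                spacer_seq = seq[i : i + slen]
                if _ACGT.issuperset(spacer_seq):
                    hits.append(SpacerHit(
                        spacer=GenomeInterval(target.chrom, g, g + slen - 1,
                                              PLUS, tname),
                        pam=GenomeInterval(target.chrom, g + slen,
                                           g + word - 1, PLUS),
                        spacer_seq=spacer_seq,
                        pam_seq=pam_seq,
                        cut_after=g + 16,
                        target_name=tname,
                        target=target,
                    ))
            # minus strand: revcomp(PAM) then revcomp(spacer) on plus text
            pam_fwd = seq[i : i + plen]
            if matches_iupac(pam_fwd, rc_pam):
                spacer_fwd = seq[i + plen : i + word]
                if _ACGT.issuperset(spacer_fwd):
                    sp_start, sp_end = g + plen, g + word - 1
                    hits.append(SpacerHit(
                        spacer=GenomeInterval(target.chrom, sp_start, sp_end,
                                              MINUS, tname),
                        pam=GenomeInterval(target.chrom, g, g + plen - 1,
                                           MINUS),
                        spacer_seq=revcomp(spacer_fwd),
                        pam_seq=revcomp(pam_fwd),
                        cut_after=sp_end - 16,
                        target_name=tname,
                        target=target,
                    ))
    hits.sort(key=SpacerHit.sort_key)
    return hits


def dedupe_hits(hits: Sequence[SpacerHit]) -> list[SpacerHit]:
    """Location-unique view: one hit per (chrom, start, strand)."""
    seen: set[tuple] = set()
    out = []
    for h in hits:
        key = (h.spacer.chrom, h.spacer.start, h.spacer.strand)
        if key not in seen:
            seen.add(key)
            out.append(h)
    return out
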