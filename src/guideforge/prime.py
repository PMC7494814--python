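"""PE2/PE3 prime-editing reagent design.

A prime editor is a Cas9 nickase fused to a reverse transcriptase, guided
by a pegRNA whose 3' extension carries a primer binding site (PBS) and a
reverse-transcription template (RT template) encoding the desired edit.
The nick falls between protospacer positions 17 and 18; the RT template
rewrites the sequence immediately 3' of the nick on the protospacer
strand.  An editing spacer is therefore admissible for a given edit only
if every edited base lies at protospacer-relative positions 18 through
17 + nrt (nrt = RT-template length in nt):

    plus-strand spacer starting at s, single-base edit at p:
        s + 17 <= p <= s + 16 + nrt   <=>   s in [p - (nrt + 16), p - 17]

with the minus strand mirrored.  With the default nrt = 16 this gives a
32..17-bases-upstream admissible window on each strand.  The PE3 variant
adds a nicking spacer on the opposite strand whose nick falls 40-90 nt
downstream (3' on the edited strand) of the prime-editing nick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from .genome import Genome, revcomp
from .intervals import MINUS, PLUS, GenomeInterval
from .spacers import SpacerHit, find_spacers

MAX_EDIT_LEN = 48  # longest rewrite a prime editor supports


class EditError(ValueError):
    pass


@dataclass(frozen=True)
class EditSpec:
    """One point edit on the plus strand: replace ``ref`` at ``position``
    (1-based, first edited base) by ``alt``.  Deletions (empty alt) and
    insertions are allowed."""

    chrom: str
    position: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "ref", self.ref.upper())
        object.__setattr__(self, "alt", self.alt.upper())
        if not self.ref:
            raise EditError("ref allele must be non-empty")
        if len(self.alt) > MAX_EDIT_LEN:
            raise EditError(f"alt longer than {MAX_EDIT_LEN} nt")
        for allele in (self.ref, self.alt):
            if set(allele) - set("ACGT"):
                raise EditError(f"allele {allele!r} is not plain DNA")

    def validate(self, genome: Genome) -> None:
        iv = GenomeInterval(self.chrom, self.position,
                            self.position + len(self.ref) - 1, PLUS)
        observed = genome.fetch(iv)
        if observed != self.ref:
            raise EditError(
                f"reference mismatch at {iv}: genome has {observed!r}, "
                f"edit claims {self.ref!r}"
            )


@dataclass(frozen=True)
class PrimeDesignParams:
    """Tunables of the pegRNA layout.

    ``nrt`` (default 16 nt) is the RT-template length; ``pbs_len``
    (default 13 nt) the primer-binding-site length; ``nick_window`` the
    admissible nick-to-nick distance range for the PE3 nicking spacer.
    """

    nrt: int = 16
    pbs_len: int = 13
    nick_window: tuple[int, int] = (40, 90)
    pam: str = "NGG"
    spacer_len: int = 20

    def __post_init__(self) -> None:
        if self.nrt < 1 or self.pbs_len < 1:
            raise EditError("nrt and pbs_len must be >= 1")
        lo, hi = self.nick_window
        if lo < 0 or hi < lo:
            raise EditError("nick_window must be ordered and non-negative")
        if self.pbs_len > 17:
            raise EditError("pbs_len > 17 would cross the protospacer 5' end")


@dataclass
class PrimeDesign:
    """One editing spacer with its pegRNA 3' extension and PE3 nicking
    candidates."""

    editing_spacer: SpacerHit
    pbs_seq: str
    rt_template_seq: str
    three_prime_extension: str
    nicking_spacers: list[SpacerHit] = field(default_factory=list)
    nick_distances: list[int] = field(default_factory=list)


def _edit_span(edit: EditSpec) -> tuple[int, int]:
    """Genomic span [first, last] that must sit inside the RT window.

    For a pure insertion (ref retained at its position) the span is the
    ref bases; the post-edit template-length check is handled separately.
    """
    return edit.position, edit.position + len(edit.ref) - 1


def find_prime_spacers(
    edit: EditSpec, genome: Genome, params: PrimeDesignParams = PrimeDesignParams()
) -> list[SpacerHit]:
    """Editing-spacer candidates on both strands.

    A candidate must place all edited bases at protospacer positions
    18..17+nrt (insertions: the post-edit alt must also fit inside the
    nrt-long template).  The search window is the strand-specific
    extension around the edit implied by that rule; candidates are then
    kept only if they satisfy it exactly.
    """
    edit.validate(genome)
    nrt, slen = params.nrt, params.spacer_len
    first, last = _edit_span(edit)
    lo = max(1, first - (nrt + 16) - 5)
    hi = min(genome.chrom_length(edit.chrom), last + (nrt + 16) + 5)
    window = GenomeInterval(edit.chrom, lo, hi, PLUS, "pe_window")
    hits = find_spacers([window], genome, pam=params.pam, spacer_len=slen)
    out = []
    growth = len(edit.alt) - len(edit.ref)
    template_len = nrt + growth
    if template_len < max(1, len(edit.alt)):
        return []  # edit cannot fit any admissible template
    for h in hits:
        if h.strand == PLUS:
            s = h.spacer.start
            rel_first = first - s + 1  # protospacer-relative position
            rel_last = last - s + 1
        else:
            e = h.spacer.end
            rel_first = e - last + 1
            rel_last = e - first + 1
        if rel_first < 18:
            continue
        # all edited bases inside the template; insertions measured against
        # the post-edit template length
        if rel_last + growth > 17 + nrt or rel_last > 17 + nrt:
            continue
        out.append(h)
    return out


def build_3prime_extension(
    spacer: SpacerHit, edit: EditSpec, genome: Genome,
    params: PrimeDesignParams = PrimeDesignParams(),
) -> tuple[str, str, str]:
    """(pbs_seq, rt_template_seq, three_prime_extension) for one spacer.

    PBS = revcomp of protospacer positions (17 - pbs_len + 1)..17 (the
    bases immediately 5' of the nick); RT template = revcomp of the edited
    protospacer-strand sequence from position 18 through 17 + nrt; the 3'
    extension is RT template followed by PBS, written 5'->3'.
    """
    nrt, pbs_len = params.nrt, params.pbs_len
    proto = spacer.spacer_seq  # 5'->3' on the protospacer strand
    pbs_seq = revcomp(proto[17 - pbs_len : 17])

    # wild-type protospacer-strand window covering positions 18..17+nrt
    if spacer.strand == PLUS:
        win = GenomeInterval(spacer.spacer.chrom, spacer.spacer.start + 17,
                             spacer.spacer.start + 16 + nrt, PLUS)
        wt = genome.fetch(win)
        rel_off = edit.position - win.start  # 0-based offset into wt
        ref, alt = edit.ref, edit.alt
    else:
        win = GenomeInterval(spacer.spacer.chrom, spacer.spacer.end - 16 - nrt,
                             spacer.spacer.end - 17, MINUS)
        wt = genome.fetch(win)  # already revcomp'd: protospacer-strand frame
        ref, alt = revcomp(edit.ref), revcomp(edit.alt)
        # offset of the (revcomp'd) ref within wt
        edit_last = edit.position + len(edit.ref) - 1
        rel_off = win.end - edit_last
    if not (0 <= rel_off and rel_off + len(ref) <= len(wt)):
        raise EditError(f"edit does not sit inside the RT window of {spacer}")
    if wt[rel_off : rel_off + len(ref)] != ref:
        raise EditError("RT window does not carry the reference allele")
    edited = wt[:rel_off] + alt + wt[rel_off + len(ref) :]
    rt_template_seq = revcomp(edited)
    return pbs_seq, rt_template_seq, rt_template_seq + pbs_seq


def _nick_boundary(spacer: SpacerHit) -> int:
    """Plus-strand boundary index of the nick: the cut lies between plus
    coordinates b and b + 1."""
    return spacer.cut_after if spacer.strand == PLUS else spacer.cut_after - 1


def find_nicking_spacers(
    edit: EditSpec,
    editing_spacer: SpacerHit,
    genome: Genome,
    params: PrimeDesignParams = PrimeDesignParams(),
) -> tuple[list[SpacerHit], list[int]]:
    """PE3 nicking candidates on the strand opposite the editing spacer.

    The nick-to-nick distance, measured downstream (3' on the edited
    strand) of the prime-editing nick, must fall inside
    ``params.nick_window``; each hit is annotated with its distance.
    """
    lo, hi = params.nick_window
    pe_nick = _nick_boundary(editing_spacer)
    want_strand = MINUS if editing_spacer.strand == PLUS else PLUS
    slen, plen = params.spacer_len, len(params.pam)
    reach = hi + slen + plen + 1
    w_lo = max(1, pe_nick - reach)
    w_hi = min(genome.chrom_length(edit.chrom), pe_nick + reach)
    window = GenomeInterval(edit.chrom, w_lo, w_hi, PLUS, "nick_window")
    hits = find_spacers([window], genome, pam=params.pam, spacer_len=slen)
    out, dists = [], []
    for h in hits:
        if h.strand != want_strand:
            continue
        d = _nick_boundary(h) - pe_nick
        if editing_spacer.strand == MINUS:
            d = -d  # downstream on a minus edited strand = decreasing coords
        if lo <= d <= hi and d > 0:
            out.append(h)
            dists.append(d)
    return out, dists


def design_prime_editing(
    edit: EditSpec,
    genome: Genome,
    params: PrimeDesignParams = PrimeDesignParams(),
    max_mm: int = 2,
    engine: str = "seeded",
) -> tuple[list[PrimeDesign], dict]:
    """Full PE3 design: editing spacers (unique-policy filtered on exact
    matches), 3' extensions, and nicking spacers with mismatch counts.

    Editing spacers must be genome-unique (G0 = 1; prime editing tolerates
    no mismatches, so only exact matches are considered and cross-target
    matches are rejected).  Nicking spacers are reported with full
    off0..off_max_mm counts (second element of the return value) rather
    than filtered: selecting a performant pair is left to the user.
    """
    from .offtargets import MatchCounts, count_genome_matches

    editing = find_prime_spacers(edit, genome, params)
    if not editing:
        return [], {}
    g_counts, _ = count_genome_matches(
        [h.spacer_seq for h in editing], genome, max_mm=0, engine=engine)
    editing = [h for h in editing if g_counts[h.spacer_seq].G[0] == 1]

    designs = []
    nick_seqs: set[str] = set()
    for h in editing:
        pbs, rt, ext = build_3prime_extension(h, edit, genome, params)
        nicks, dists = find_nicking_spacers(edit, h, genome, params)
        nick_seqs.update(n.spacer_seq for n in nicks)
        designs.append(PrimeDesign(h, pbs, rt, ext, nicks, dists))

    nick_counts: dict[str, MatchCounts] = {}
    if nick_seqs:
        nick_counts, _ = count_genome_matches(
            sorted(nick_seqs), genome, max_mm=max_mm, engine=engine)
    return designs, nick_counts
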