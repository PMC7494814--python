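"""Prime-editing design: admissible-window geometry, pegRNA extension
construction, and PE3 nicking placement."""

import numpy as np
import pytest

from guideforge import (
    EditSpec,
    Genome,
    GenomeInterval,
    PrimeDesignParams,
    build_3prime_extension,
    design_prime_editing,
    find_nicking_spacers,
    find_prime_spacers,
    revcomp,
)
from guideforge.prime import EditError


def gg_rich_locus(p=500, length=1200, seed=3):
    """Random genome with a known plus-strand spacer+PAM planted so the
    edit at ``p`` sits at protospacer position 21."""
    rng = np.random.default_rng(seed)
    seq = list("".join(rng.choice(list("ACGT"), size=length)))
    s = p - 20
    word = "ACGTACGTACGAACGTACGT"  # non-palindromic protospacer
    seq[s - 1 : s - 1 + 23] = list(word + "AGG")
    g = Genome({"chr1": "".join(seq)})
    ref = g.fetch(GenomeInterval("chr1", p, p))
    alt = "A" if ref != "A" else "C"
    return g, EditSpec("chr1", p, ref, alt), s, word


class TestEditSpec:
    def test_reference_allele_verified_against_genome(self):
        g = Genome({"chr1": "ACGTACGT"})
        EditSpec("chr1", 3, "G", "T").validate(g)
        with pytest.raises(EditError, match="reference mismatch"):
            EditSpec("chr1", 3, "A", "T").validate(g)

    def test_rewrites_capped_at_48nt(self):
        with pytest.raises(EditError):
            EditSpec("chr1", 1, "A", "C" * 49)

    def test_deletion_allowed(self):
        assert EditSpec("chr1", 5, "ACG", "").alt == ""


class TestAdmissibleWindow:
    def test_plus_strand_window_is_p_minus_32_to_p_minus_17(self):
        """With nrt = 16 the admissible plus-strand spacer starts span
        [p - 32, p - 17]; verified by brute-force application of the
        positional rule on a PAM-everywhere sequence."""
        p, nrt = 4699600, 16
        starts = [s for s in range(p - 60, p + 1)
                  if s + 17 <= p <= s + 16 + nrt]
        assert starts == list(range(p - 32, p - 16))
        assert starts[0] == 4699568  # leftmost admissible start

    def test_nrt_1_collapses_window_to_single_start(self):
        p, nrt = 500, 1
        starts = [s for s in range(p - 60, p + 1)
                  if s + 17 <= p <= s + 16 + nrt]
        assert starts == [p - 17]

    def test_found_spacers_obey_positional_rule(self):
        """Returned set equals independent enumeration of all PAM-bearing
        23-mers filtered by the positional rule."""
        g, edit, s, word = gg_rich_locus()
        p = edit.position
        nrt = 16
        got = {(h.spacer.start, h.strand)
               for h in find_prime_spacers(edit, g)}
        seq = g.sequences["chr1"]
        expected = set()
        for s0 in range(len(seq) - 22):
            start = s0 + 1
            if seq[s0 + 21 : s0 + 23] == "GG" and \
                    set(seq[s0 : s0 + 20]) <= set("ACGT"):
                if start + 17 <= p <= start + 16 + nrt:
                    expected.add((start, "+"))
            if seq[s0 : s0 + 2] == "CC":
                start_m, end_m = s0 + 4, s0 + 23  # spacer occupies [s0+4, s0+23]
                if set(seq[s0 + 3 : s0 + 23]) <= set("ACGT") and \
                        end_m - 16 - nrt <= p <= end_m - 17:
                    expected.add((start_m, "-"))
        assert got == expected and len(got) > 0

    def test_nrt1_only_admits_nick_adjacent_spacer(self):
        g, edit, s, word = gg_rich_locus()
        params = PrimeDesignParams(nrt=1)
        hits = find_prime_spacers(edit, g, params)
        for h in hits:
            if h.strand == "+":
                assert h.spacer.start == edit.position - 17
            else:
                assert h.spacer.end == edit.position + 17

    def test_revcomp_symmetry(self):
        """Mirroring genome and edit to the opposite strand mirrors the
        admissible design set exactly."""
        g, edit, s, word = gg_rich_locus()
        L = len(g.sequences["chr1"])
        g_rc = Genome({"chr1": revcomp(g.sequences["chr1"])})
        p_rc = L - (edit.position + len(edit.ref) - 1) + 1
        edit_rc = EditSpec("chr1", p_rc, revcomp(edit.ref), revcomp(edit.alt))
        fwd = {(h.spacer.start, h.spacer.end, h.strand)
               for h in find_prime_spacers(edit, g)}
        mirrored = {(L - e + 1, L - s0 + 1, "+" if st == "-" else "-")
                    for s0, e, st in
                    ((h.spacer.start, h.spacer.end, h.strand)
                     for h in find_prime_spacers(edit_rc, g_rc))}
        assert fwd == mirrored


class TestThreePrimeExtension:
    def test_manual_revcomp_oracle_plus_strand(self):
        g, edit, s, word = gg_rich_locus()
        h = next(h for h in find_prime_spacers(edit, g)
                 if h.spacer.start == s and h.strand == "+")
        pbs, rt, ext = build_3prime_extension(h, edit, g)
        # PBS: revcomp of protospacer positions 5..17
        assert pbs == revcomp(word[4:17])
        # RT: revcomp of edited genomic [s+17, s+32]
        seq = g.sequences["chr1"]
        wt = seq[s + 16 : s + 32]
        off = edit.position - (s + 17)
        edited = wt[:off] + edit.alt + wt[off + 1:]
        assert rt == revcomp(edited)
        assert edit.alt not in ("", edit.ref)  # the edit is really in there
        assert ext == rt + pbs

    def test_extension_length_bookkeeping(self):
        g, edit, s, word = gg_rich_locus()
        params = PrimeDesignParams(nrt=16, pbs_len=13)
        h = find_prime_spacers(edit, g, params)[0]
        pbs, rt, ext = build_3prime_extension(h, edit, g, params)
        assert len(pbs) == 13 and len(rt) == 16
        assert len(ext) == 16 + 13  # |alt| == |ref| == 1

    def test_null_edit_gives_wildtype_template(self):
        g, edit, s, word = gg_rich_locus()
        null = EditSpec(edit.chrom, edit.position, edit.ref, edit.ref)
        h = next(h for h in find_prime_spacers(null, g)
                 if h.spacer.start == s)
        _, rt, _ = build_3prime_extension(h, null, g)
        assert rt == revcomp(g.sequences["chr1"][s + 16 : s + 32])

    def test_minus_strand_extension_carries_edit(self):
        g, edit, s, word = gg_rich_locus()
        minus = [h for h in find_prime_spacers(edit, g) if h.strand == "-"]
        assert minus
        for h in minus:
            _, rt, _ = build_3prime_extension(h, edit, g)
            # the RT template, revcomp'd back to protospacer-strand frame,
            # must contain the minus-strand alt allele
            proto_frame = revcomp(rt)
            e = h.spacer.end
            off = e - 17 - edit.position
            assert proto_frame[off] == revcomp(edit.alt)

    def test_pbs_longer_than_17_rejected(self):
        with pytest.raises(EditError):
            PrimeDesignParams(pbs_len=18)


class TestNickingSpacers:
    def _locus_with_opposite_pam(self, nick_offset):
        """Editing spacer on plus; one minus-strand nicking site whose nick
        lands ``nick_offset`` nt downstream of the editing nick."""
        p = 300
        s = p - 20
        word = "ACGTACGTACGAACGTACGT"
        seq = ["T"] * 700
        seq[s - 1 : s - 1 + 23] = list(word + "AGG")
        # minus-strand spacer with nick boundary at pe_nick + nick_offset:
        # nick boundary of a minus spacer [sm, em] is em - 17
        pe_nick = s + 16
        em = pe_nick + nick_offset + 17
        sm = em - 19
        nick_word = "GTACGTAACGTACGTAACGT"
        seq[sm - 4 : sm - 1] = list("CCT")  # PAM (revcomp AGG) 5' of spacer
        seq[sm - 1 : em] = list(revcomp(nick_word))
        g = Genome({"chr1": "".join(seq)})
        ref = g.fetch(GenomeInterval("chr1", p, p))
        alt = "A" if ref != "A" else "C"
        edit = EditSpec("chr1", p, ref, alt)
        editing = next(h for h in find_prime_spacers(edit, g)
                       if h.spacer.start == s and h.strand == "+")
        return g, edit, editing

    def test_nick_at_60_found_at_95_not(self):
        g, edit, editing = self._locus_with_opposite_pam(60)
        nicks, dists = find_nicking_spacers(edit, editing, g)
        assert dists == [60]
        assert all(n.strand == "-" for n in nicks)

        g2, edit2, editing2 = self._locus_with_opposite_pam(95)
        nicks2, _ = find_nicking_spacers(edit2, editing2, g2)
        assert nicks2 == []

    def test_degenerate_window_is_empty(self):
        g, edit, editing = self._locus_with_opposite_pam(60)
        params = PrimeDesignParams(nick_window=(0, 0))
        nicks, _ = find_nicking_spacers(edit, editing, g, params)
        assert nicks == []


class TestDesignComposition:
    def test_full_design_on_synthetic_locus(self):
        g, edit, s, word = gg_rich_locus()
        designs, nick_counts = design_prime_editing(edit, g)
        assert designs
        for d in designs:
            assert len(d.three_prime_extension) == 16 + 13
            assert d.three_prime_extension == \
                d.rt_template_seq + d.pbs_seq
            assert len(d.nicking_spacers) == len(d.nick_distances)
            for dist in d.nick_distances:
                assert 40 <= dist <= 90

    def test_region_without_pams_yields_no_designs(self):
        g = Genome({"chr1": "AT" * 400})
        edit = EditSpec("chr1", 400, g.fetch(
            GenomeInterval("chr1", 400, 400)), "C")
        designs, _ = design_prime_editing(edit, g)
        assert designs == []

    def test_editing_spacers_are_genome_unique(self):
        # a revcomp-palindromic protospacer matches itself on both strands
        # (G0 = 2) and must be rejected by the unique policy
        rng = np.random.default_rng(8)
        seq = list("".join(rng.choice(list("ACGT"), size=800)))
        p = 400
        s = p - 20
        palindrome = "ACGTACGTACGTACGTACGT"
        assert revcomp(palindrome) == palindrome
        seq[s - 1 : s - 1 + 23] = list(palindrome + "AGG")
        g = Genome({"chr1": "".join(seq)})
        ref = g.fetch(GenomeInterval("chr1", p, p))
        edit = EditSpec("chr1", p, ref, "A" if ref != "A" else "C")
        designs, _ = design_prime_editing(edit, g)
        assert all(d.editing_spacer.spacer_seq != palindrome for d in designs)
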