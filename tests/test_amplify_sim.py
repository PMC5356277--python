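"""Double-primer PCR, single-primer linear amplification, strand annealing."""

import numpy as np
import pytest

from rfclone import (
    AmpliconDuplex,
    NucSeq,
    StrandProduct,
    anneal,
    linear_amplify,
    pcr_amplify,
    revcomp,
)
from rfclone.errors import (
    AmbiguousPrimingError,
    AnnealingError,
    AnnealingMismatchError,
    GeometryError,
    NoBindingError,
)
from rfclone.primer_design import Oligo

from conftest import random_dna


def oligo(body: str, tail: str = "", direction: str = "forward", name: str = "p") -> Oligo:
    return Oligo(name=name, role=1 if direction == "forward" else 2,
                 direction=direction, body=body, tail=tail)


def anneal_oracle(s1: str, s2: str, min_core: int):
    """Slide s2 (as the bottom strand) against s1 over every offset and keep
    the maximal perfect-complement overlap; ties go to the smaller shift."""
    top, r2 = s1, revcomp(s2)
    best, best_d = None, None
    for d in range(-(len(r2) - 1), len(top)):
        lo, hi = max(0, d), min(len(top), d + len(r2))
        ov = hi - lo
        if ov < min_core:
            continue
        if top[lo:hi] == r2[lo - d : hi - d]:
            key = (ov, -abs(d))
            if best is None or key > best:
                best, best_d = key, d
    if best_d is None:
        return None
    d = best_d
    left = ("top", top[:d]) if d > 0 else ("bottom", s2[len(s2) + d:]) if d < 0 else (None, "")
    r_exc = d + len(r2) - len(top)
    right = ("bottom", s2[:r_exc]) if r_exc > 0 else ("top", top[d + len(r2):]) if r_exc < 0 else (None, "")
    return left, right


class TestPcrAmplify:
    def test_identity_amplification_linear(self):
        rng = np.random.default_rng(1)
        t = NucSeq("t", random_dna(rng, 200), "linear")
        fwd = oligo(t.bases[:20])
        rev = oligo(revcomp(t.bases[-20:]), direction="reverse")
        product = pcr_amplify(t, fwd, rev)
        assert product.top == t.bases
        assert product.bottom == revcomp(t.bases)
        assert product.blunt

    def test_circular_template_wraps_origin(self, toy_vector):
        # amplicon from position 16 across the origin to position 10
        fwd = oligo(toy_vector.fetch(16, 5))  # GGGGG
        rev = oligo(revcomp(toy_vector.fetch(6, 5)), direction="reverse")  # vs TTTTT
        product = pcr_amplify(toy_vector, fwd, rev)
        assert product.top == "GGGGGAAAAATTTTT"

    def test_circular_agrees_with_doubled_string_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(30):
            n = int(rng.integers(80, 500))
            t = NucSeq("t", random_dna(rng, n), "circular")
            f = int(rng.integers(0, n))
            amp_len = int(rng.integers(45, n))
            doubled = t.bases * 2
            segment = doubled[f : f + amp_len]
            fwd = oligo(segment[:20])
            rev = oligo(revcomp(segment[-20:]), direction="reverse")
            try:
                product = pcr_amplify(t, fwd, rev)
            except AmbiguousPrimingError:
                continue  # a random 20-mer repeat; the oracle is void too
            assert product.top == segment

    def test_tails_append_to_both_ends(self):
        rng = np.random.default_rng(3)
        t = NucSeq("t", random_dna(rng, 120), "linear")
        fwd = oligo(t.bases[:20], tail="ACACAC")
        rev = oligo(revcomp(t.bases[-20:]), tail="GTGTGT", direction="reverse")
        product = pcr_amplify(t, fwd, rev)
        assert len(product) == 120 + 6 + 6
        assert product.top == "ACACAC" + t.bases + revcomp("GTGTGT")

    def test_no_binding_names_primer(self):
        t = NucSeq("t", "ACGT" * 30, "linear")
        with pytest.raises(NoBindingError, match="missing"):
            pcr_amplify(t, oligo("G" * 20, name="missing"),
                        oligo(revcomp(t.bases[-20:]), direction="reverse"))

    def test_ambiguous_binding_lists_sites(self):
        t = NucSeq("t", "TTTT" + "GACTGACTGACTGACT" + "CC" + "GACTGACTGACTGACT" + "AAGG", "linear")
        with pytest.raises(AmbiguousPrimingError) as exc:
            pcr_amplify(t, oligo("GACTGACTGACTGACT"),
                        oligo(revcomp(t.bases[-4:] ), direction="reverse"))
        assert len(exc.value.positions) == 2

    def test_divergent_primers_on_linear_template(self):
        rng = np.random.default_rng(4)
        t = NucSeq("t", random_dna(rng, 200), "linear")
        fwd = oligo(t.bases[150:170])
        rev = oligo(revcomp(t.bases[10:30]), direction="reverse")
        with pytest.raises(GeometryError):
            pcr_amplify(t, fwd, rev)

    def test_rotation_invariance_on_circular_template(self):
        rng = np.random.default_rng(21)
        t = NucSeq("t", random_dna(rng, 300), "circular")
        fwd = oligo(t.fetch(40, 22))
        rev = oligo(revcomp(t.fetch(200, 22)), direction="reverse")
        base_product = pcr_amplify(t, fwd, rev).top
        for shift in (2, 77, 150, 299):
            assert pcr_amplify(t.rotated(shift), fwd, rev).top == base_product


class TestLinearAmplify:
    def test_untailed_forward_primer_copies_top_strand(self):
        rng = np.random.default_rng(6)
        top = random_dna(rng, 150)
        duplex = AmpliconDuplex(top=top, bottom=revcomp(top))
        product = linear_amplify(duplex, oligo(top[:20]))
        assert product.bases == top

    def test_toy_tailed_products(self, toy_job, toy_config):
        from rfclone import design_primer_set

        ps = design_primer_set(toy_job, target_len=5, window=(5, 5))
        duplex = AmpliconDuplex(top="AACGT", bottom=revcomp("AACGT"), label="2")
        p3 = linear_amplify(duplex, ps.insert_fwd_tailed)
        p4 = linear_amplify(duplex, ps.insert_rev_tailed)
        assert p3.bases == "TTTTTAACGT"
        assert p4.bases == "CCCCCACGTT"

    def test_no_match_raises(self):
        duplex = AmpliconDuplex(top="ACGT" * 10, bottom=revcomp("ACGT" * 10))
        with pytest.raises(NoBindingError):
            linear_amplify(duplex, oligo("G" * 12))


class TestAnneal:
    def test_toy_cohesive_duplex(self):
        s1 = StrandProduct("TTTTTAACGT", origin="p3")
        s2 = StrandProduct("CCCCCACGTT", origin="p4")
        duplex = anneal(s1, s2, min_core=5)
        assert duplex.core == "AACGT"
        assert (duplex.left_overhang.strand, duplex.left_overhang.seq) == ("top", "TTTTT")
        assert (duplex.right_overhang.strand, duplex.right_overhang.seq) == ("bottom", "CCCCC")
        assert duplex.left_overhang.protrusion == "5p"
        assert duplex.right_overhang.protrusion == "5p"
        assert duplex.span == 15

    def test_perfect_complements_give_blunt_duplex(self):
        rng = np.random.default_rng(8)
        s = random_dna(rng, 60)
        duplex = anneal(StrandProduct(s, "a"), StrandProduct(revcomp(s), "b"))
        assert duplex.left_overhang.is_blunt
        assert duplex.right_overhang.is_blunt
        assert duplex.core == s

    def test_matches_offset_scan_oracle_on_random_tailed_pairs(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            core = random_dna(rng, int(rng.integers(20, 90)))
            t1 = random_dna(rng, int(rng.integers(0, 9)))
            t2 = random_dna(rng, int(rng.integers(0, 9)))
            s1 = t1 + core
            s2 = t2 + revcomp(core)
            expected = anneal_oracle(s1, s2, 15)
            assert expected is not None
            duplex = anneal(StrandProduct(s1, "a"), StrandProduct(s2, "b"))
            (ls, lseq), (rs, rseq) = expected
            assert (duplex.left_overhang.strand, duplex.left_overhang.seq) == (ls, lseq)
            assert (duplex.right_overhang.strand, duplex.right_overhang.seq) == (rs, rseq)

    def test_round_trip_reproduces_input_duplex(self):
        rng = np.random.default_rng(10)
        top = random_dna(rng, 200)
        duplex = AmpliconDuplex(top=top, bottom=revcomp(top))
        s1 = linear_amplify(duplex, oligo(top[:20]))
        s2 = linear_amplify(duplex, oligo(revcomp(top[-20:]), direction="reverse"))
        re_annealed = anneal(s1, s2)
        assert re_annealed.top == top
        assert re_annealed.bottom == revcomp(top)
        assert re_annealed.left_overhang.is_blunt and re_annealed.right_overhang.is_blunt

    def test_unrelated_strands_fail(self):
        rng = np.random.default_rng(11)
        with pytest.raises(AnnealingError):
            anneal(StrandProduct(random_dna(rng, 50), "a"),
                   StrandProduct(random_dna(rng, 50), "b"))

    def test_internal_mismatch_reported_with_positions(self):
        rng = np.random.default_rng(13)
        s = random_dna(rng, 60)
        mutated = list(s)
        mutated[30] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[30]]
        with pytest.raises(AnnealingMismatchError) as exc:
            anneal(StrandProduct(s, "a"), StrandProduct(revcomp("".join(mutated)), "b"))
        assert 31 in exc.value.positions
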