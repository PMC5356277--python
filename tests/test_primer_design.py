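"""Primer-body selection, melting temperature, the eight-primer set."""

import math

import numpy as np
import pytest

from rfclone import (
    NucSeq,
    Overhang,
    design_primer_set,
    melting_temp,
    revcomp,
    select_body,
    validate_overhangs,
)
from rfclone.primer_design import DesignWarning, Oligo

from conftest import random_dna

GC = set("GC")


def body_oracle(template: str, target: int, window: tuple[int, int]):
    """Exhaustively score all window lengths: 3' base must be G/C, closest
    to target wins, ties to the shorter length."""
    best = None
    for length in range(window[0], min(window[1], len(template)) + 1):
        body = template[:length]
        if body[-1] in GC:
            key = (abs(length - target), length)
            if best is None or key < best[0]:
                best = (key, body)
    return None if best is None else best[1]


class TestSelectBody:
    def test_extends_past_target_for_gc_end(self):
        # bases 1..25 end in T, bases 1..26 end in G
        template = NucSeq("t", "G" + "A" * 23 + "T" + "G" + "A" * 20, "linear")
        body, warnings = select_body(template, 1, "forward", 25, (20, 32))
        assert len(body) == 26
        assert body[-1] == "G"
        assert not any(w.code.startswith("GC_RULE") for w in warnings)

    def test_all_g_template_takes_target_length(self):
        template = NucSeq("t", "G" * 60, "linear")
        body, _ = select_body(template, 1, "forward", 25, (20, 32))
        assert len(body) == 25

    def test_no_qualifying_length_warns(self):
        template = NucSeq("t", "G" + "A" * 59, "linear")
        body, warnings = select_body(template, 1, "forward", 25, (20, 32))
        assert len(body) == 25
        assert any(w.code == "GC_RULE_3PRIME" for w in warnings)

    def test_matches_exhaustive_oracle_on_random_templates(self):
        rng = np.random.default_rng(31)
        for _ in range(50):
            bases = random_dna(rng, 80)
            template = NucSeq("t", bases, "linear")
            body, _ = select_body(template, 1, "forward", 25, (20, 32))
            expected = body_oracle(bases, 25, (20, 32))
            if expected is not None:
                assert body == expected
            else:
                assert len(body) == 25

    def test_reverse_body_is_revcomp_of_upstream_stretch(self):
        rng = np.random.default_rng(32)
        bases = random_dna(rng, 80)
        template = NucSeq("t", bases, "linear")
        body, _ = select_body(template, 80, "reverse", 25, (20, 32))
        expected = body_oracle(revcomp(bases), 25, (20, 32))
        if expected is not None:
            assert body == expected


class TestMeltingTemp:
    def test_pure_function(self):
        s = "ACGTACGTACGTACGTACGT"
        assert melting_temp(s) == melting_temp(s)

    def test_fallback_monotone_in_gc(self):
        low = melting_temp("ATATATATATATATATATAT", model="gc_fallback")
        mid = melting_temp("ATATATATATGTATATATAT", model="gc_fallback")
        high = melting_temp("GTATATATATGTATATATAG", model="gc_fallback")
        assert low < mid < high

    def test_nearest_neighbor_matches_independent_oracle(self):
        # independent reimplementation of the unified nearest-neighbor
        # parameters (Allawi & SantaLucia 1997) with the SantaLucia-1998
        # entropic salt correction at 50 mM Na+, 500 nM oligo
        nn = {
            "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
            "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
            "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
            "GG": (-8.0, -19.9),
        }

        def oracle(seq: str) -> float:
            dh = ds = 0.0
            for end in (seq[0], seq[-1]):
                if end in "AT":
                    dh += 2.3
                    ds += 4.1
                else:
                    dh += 0.1
                    ds += -2.8
            for i in range(len(seq) - 1):
                pair = seq[i : i + 2]
                dh_i, ds_i = nn[pair] if pair in nn else nn[revcomp(pair)]
                dh += dh_i
                ds += ds_i
            # no symmetry term: the model is oligo-to-template hybridization
            ds += 0.368 * (len(seq) - 1) * math.log(50.0 / 1000.0)
            k = 500e-9
            return dh * 1000.0 / (ds + 1.987 * math.log(k)) - 273.15

        rng = np.random.default_rng(7)
        seqs = ["ACGTACGTACGTACGTACGT"] + [random_dna(rng, 25) for _ in range(10)]
        for s in seqs:
            assert melting_temp(s, model="nn") == pytest.approx(oracle(s), abs=0.5)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            melting_temp("ACGTACG")


class TestValidateOverhangs:
    def test_palindromes_flagged(self):
        w = validate_overhangs(Overhang("GATC", "A"), Overhang("AATT", "B"))
        assert sum(x.code == "OVERHANG_PALINDROME" for x in w) == 2

    def test_homopolymers_flagged(self):
        w = validate_overhangs(Overhang("TTTTT", "A"), Overhang("GGGGG", "B"))
        codes = {x.code for x in w}
        assert codes == {"OVERHANG_HOMOPOLYMER"}

    def test_identical_overhangs_flagged(self):
        w = validate_overhangs(Overhang("CATGC", "A"), Overhang("CATGC", "B"))
        assert any(x.code == "OVERHANG_IDENTICAL" for x in w)


class TestDesignPrimerSet:
    def test_toy_tail_assignment(self, toy_job):
        ps = design_primer_set(toy_job, target_len=5, window=(5, 5))
        assert ps.insert_fwd_tailed.tail == "TTTTT"  # overhang A
        assert ps.insert_rev_tailed.tail == "CCCCC"  # revcomp(overhang B)
        assert ps.vector_fwd_tailed.tail == "GGGGG"  # overhang B
        assert ps.vector_rev_tailed.tail == "AAAAA"  # revcomp(overhang A)

    def test_structure_eight_oligos_four_plain(self, small_fixture):
        ps = design_primer_set(small_fixture.job)
        oligos = ps.all()
        assert len(oligos) == 8
        assert sorted(o.role for o in oligos) == list(range(1, 9))
        assert sum(o.tail == "" for o in oligos) == 4

    def test_tailed_share_bodies_with_plain(self, small_fixture):
        ps = design_primer_set(small_fixture.job)
        assert ps.insert_fwd_plain.body == ps.insert_fwd_tailed.body
        assert ps.insert_rev_plain.body == ps.insert_rev_tailed.body
        assert ps.vector_fwd_plain.body == ps.vector_fwd_tailed.body
        assert ps.vector_rev_plain.body == ps.vector_rev_tailed.body

    def test_tail_lengths_equal_k_and_bodies_on_template(self, small_fixture):
        job = small_fixture.job
        ps = design_primer_set(job)
        for o in (ps.insert_fwd_tailed, ps.insert_rev_tailed,
                  ps.vector_fwd_tailed, ps.vector_rev_tailed):
            assert len(o.tail) == job.k
        # bodies are template-homologous: forward on top, reverse on bottom
        assert job.insert.bases.startswith(ps.insert_fwd_plain.body)
        assert job.insert.bases.endswith(revcomp(ps.insert_rev_plain.body))
        assert job.backbone_core.startswith(ps.vector_fwd_plain.body)
        assert job.backbone_core.endswith(revcomp(ps.vector_rev_plain.body))

    def test_gc_rule_satisfied_or_warned(self, small_fixture):
        ps = design_primer_set(small_fixture.job)
        for o in ps.all():
            violations = {w.code for w in o.warnings}
            if o.seq[0] not in GC:
                assert "GC_RULE_5PRIME" in violations
            if o.seq[-1] not in GC:
                assert "GC_RULE_3PRIME" in violations

    def test_tm_attached_to_all_full_length_bodies(self, small_fixture):
        ps = design_primer_set(small_fixture.job)
        for o in ps.all():
            assert 40 < o.tm_body < 80


class TestOligo:
    def test_seq_is_tail_plus_body(self):
        o = Oligo(name="x", role=3, direction="forward", body="ACGTACGT", tail="TTT")
        assert o.seq == "TTTACGTACGT"
        assert len(o) == 11

    def test_n_rejected(self):
        with pytest.raises(Exception):
            Oligo(name="x", role=1, direction="forward", body="ACNGT")
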