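"""Repeat detection, RRPK and proteome-level repeat statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aarscan.repeatscan import (
    AAR,
    ProteinRecord,
    aar_residue_composition,
    classify_gc_rich,
    compute_rrpk,
    detect_aars,
    gc_content,
    regional_profile,
    species_summary,
    thirds_partition,
)
from conftest import brute_force_runs


def aars_of(seq, min_len=4):
    return detect_aars(ProteinRecord("p", seq), min_len=min_len)


class TestDetectAars:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("QQQQQSTWQQQQAAE", [("Q", 0, 5), ("Q", 8, 12)]),
            ("ACDEFGH", []),
            ("AAAA", [("A", 0, 4)]),
            ("AAA", []),  # below the 4-residue minimum
            ("WWWWW", [("W", 0, 5)]),
            ("XXXXX", []),  # ambiguous residues never seed a run
            ("AAXXAAAA", [("A", 4, 8)]),  # 'X' breaks the run
        ],
    )
    def test_examples(self, seq, expected):
        got = [(a.residue, a.start, a.end) for a in aars_of(seq)]
        assert got == expected

    def test_min_len_parameter(self):
        assert [(a.start, a.end) for a in aars_of("QQQWWAA", min_len=3)] == [(0, 3)]
        assert aars_of("QQQWW", min_len=4) == []

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            ProteinRecord("p", "")

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        st.text(alphabet="AQSGXLP", min_size=1, max_size=80),
        st.integers(min_value=2, max_value=6),
    )
    def test_matches_brute_force_oracle(self, seq, min_len):
        got = [(a.residue, a.start, a.end) for a in aars_of(seq, min_len=min_len)]
        assert got == brute_force_runs(seq, min_len=min_len)

    def test_thousand_random_sequences_match_oracle(self, rng):
        """Oracle equivalence over uniform and repeat-enriched alphabets."""
        alphabets = ["ACDEFGHIKLMNPQRSTVWY", "AAQQQSGX", "QA"]
        for k in range(1000):
            alpha = alphabets[k % len(alphabets)]
            n = int(rng.integers(50, 501))
            seq = "".join(alpha[i] for i in rng.integers(len(alpha), size=n))
            got = [(a.residue, a.start, a.end) for a in aars_of(seq)]
            assert got == brute_force_runs(seq)


class TestRrpk:
    def test_worked_example(self):
        aars = aars_of("QQQQQSTWQQQQAAE")
        assert sum(a.length for a in aars) == 9
        assert compute_rrpk(15, aars) == 600.0

    def test_bounds(self):
        assert compute_rrpk(100, []) == 0.0
        assert compute_rrpk(4, [AAR("p", "A", 0, 4)]) == 1000.0

    def test_out_of_range_aar_rejected(self):
        with pytest.raises(ValueError):
            compute_rrpk(3, [AAR("p", "A", 0, 4)])
        with pytest.raises(ValueError):
            compute_rrpk(0, [])


class TestGcContent:
    @pytest.mark.parametrize(
        "cds,expected", [("GCGC", 1.0), ("ATAT", 0.0), ("ATGCN", 0.5), ("acgt", 0.5)]
    )
    def test_examples(self, cds, expected):
        assert gc_content(cds) == expected

    def test_all_ambiguous_is_missing(self):
        assert gc_content("NNNN") is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gc_content("")

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGTN", min_size=1, max_size=60))
    def test_reversal_and_complement_invariance(self, cds):
        comp = cds[::-1].translate(str.maketrans("ACGT", "TGCA"))
        assert gc_content(cds) == gc_content(cds[::-1])
        got, want = gc_content(comp), gc_content(cds)
        if want is None:
            assert got is None
        else:
            assert got == pytest.approx(want)


class TestRegionalProfile:
    def test_thirds_remainder_goes_n_terminal(self):
        assert thirds_partition(15) == (5, 5, 5)
        assert thirds_partition(16) == (6, 5, 5)
        assert thirds_partition(17) == (6, 6, 5)

    def test_worked_partition(self):
        """Run Q8-Q11 straddles the mid/C boundary and splits 2/2."""
        p = ProteinRecord("p", "QQQQQSTWQQQQAAE")
        reg = regional_profile(p, detect_aars(p))
        assert reg.rrpk_n == 1000.0
        assert reg.rrpk_mid == pytest.approx(400.0)
        assert reg.rrpk_c == pytest.approx(400.0)

    def test_no_aars_all_zero(self):
        p = ProteinRecord("p", "ACDEFGHIK")
        reg = regional_profile(p, [])
        assert (reg.rrpk_n, reg.rrpk_mid, reg.rrpk_c) == (0.0, 0.0, 0.0)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            regional_profile(ProteinRecord("p", "AC"), [])

    def test_regional_identity_random(self, rng):
        """sum(segment_len * rrpk)/1000 recovers the total repeat residues."""
        for _ in range(50):
            n = int(rng.integers(5, 120))
            seq = "".join("AQSG"[i] for i in rng.integers(4, size=n))
            p = ProteinRecord("p", seq)
            aars = detect_aars(p)
            reg = regional_profile(p, aars)
            b0, b1, b2, b3 = reg.bounds
            total = (
                (b1 - b0) * reg.rrpk_n + (b2 - b1) * reg.rrpk_mid + (b3 - b2) * reg.rrpk_c
            ) / 1000.0
            assert total == pytest.approx(sum(a.length for a in aars))

    def test_regional_gc_projects_codons(self):
        cds = "GGG" * 5 + "ATC" * 5 + "GCA" * 5
        p = ProteinRecord("p", "G" * 5 + "I" * 5 + "A" * 5, cds=cds)
        reg = regional_profile(p, [])
        assert reg.gc_n == 1.0
        assert reg.gc_mid == pytest.approx(1 / 3)
        assert reg.gc_c == pytest.approx(2 / 3)


class TestComposition:
    def test_two_repeat_protein(self):
        p = ProteinRecord("p", "AAAACCCC")
        df = aar_residue_composition([p], {"p": detect_aars(p)})
        assert df.loc["A", "repeat_fraction"] == 0.5
        assert df.loc["C", "repeat_fraction"] == 0.5
        assert df.loc["A", "background_fraction"] == 0.5

    def test_background_covers_whole_set(self):
        p = ProteinRecord("p", "AAAAWY")
        df = aar_residue_composition([p], {"p": detect_aars(p)})
        assert df.loc["A", "repeat_fraction"] == 1.0
        assert df.loc["A", "background_fraction"] == pytest.approx(4 / 6)

    def test_fractions_sum_to_one_random(self, rng):
        prots = []
        aars = {}
        for i in range(30):
            seq = "".join("AQSGW"[j] for j in rng.integers(5, size=int(rng.integers(10, 80))))
            p = ProteinRecord(f"p{i}", seq)
            prots.append(p)
            aars[p.id] = detect_aars(p)
        df = aar_residue_composition(prots, aars)
        assert df["background_fraction"].sum() == pytest.approx(1.0, abs=1e-9)
        if df["repeat_fraction"].notna().all():
            assert df["repeat_fraction"].sum() == pytest.approx(1.0, abs=1e-9)
        # repeat tally equals a direct per-residue count inside detected runs
        for aa in "AQSGW":
            direct = sum(
                a.length for lst in aars.values() for a in lst if a.residue == aa
            )
            total = sum(a.length for lst in aars.values() for a in lst)
            if total:
                assert df.loc[aa, "repeat_fraction"] == pytest.approx(direct / total)

    def test_no_aars_flagged(self):
        p = ProteinRecord("p", "ACDEF")
        df = aar_residue_composition([p], {"p": []})
        assert df["repeat_fraction"].isna().all()


class TestGcRichAndSummary:
    @pytest.mark.parametrize(
        "residue,expected", [("A", True), ("G", True), ("P", True), ("Q", False), ("W", False)]
    )
    def test_gc_rich_classification(self, residue, expected):
        assert classify_gc_rich(AAR("p", residue, 0, 5)) is expected

    def test_species_summary_means(self):
        prots = [
            ProteinRecord("a", "QQQQQSTWQQQQAAE", species="sp1"),  # rrpk 600
            ProteinRecord("b", "ACDEFACDEFACDEF", species="sp1"),  # rrpk 0
        ]
        df = species_summary(prots)
        row = df[df["species"] == "sp1"].iloc[0]
        assert row["mean_rrpk"] == pytest.approx(300.0)
        assert row["aars_per_protein"] == pytest.approx(1.0)
        assert row["rcp_fraction"] == pytest.approx(0.5)

    def test_repeat_free_proteome(self):
        prots = [ProteinRecord(f"p{i}", "ACDEFGHIKL", species="s") for i in range(5)]
        df = species_summary(prots)
        assert df.iloc[0]["aars_per_protein"] == 0.0
        assert df.iloc[0]["mean_rrpk"] == 0.0
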