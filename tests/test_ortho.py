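"""Alignment mapping, conservation calls, flank extraction, dN/dS comparison."""

import numpy as np
import pytest

from aarscan.ortho import (
    conservation_status,
    extract_flanks,
    find_conserved_long_aars,
    flank_vs_whole_comparison,
    map_aar_to_columns,
    pair_codon_strings,
    project_to_codons,
    region_identity,
)
from aarscan.repeatscan import AAR, ProteinRecord, detect_aars
from conftest import make_group


class TestColumnMapping:
    def test_no_gap(self):
        g = make_group(["QQQQAAAA", "QQQQAAAA"])
        aligned = map_aar_to_columns(g, 0, AAR("g_m0", "Q", 0, 4))
        assert aligned.span == (0, 4)

    def test_leading_gap_shift(self):
        g = make_group(["-QQQQAA", "AQQQQAA"])
        aligned = map_aar_to_columns(g, 0, AAR("g_m0", "Q", 0, 4))
        assert aligned.span == (1, 5)

    def test_round_trip_property(self, rng):
        """Ungapping the span in the focal row recovers the repeat tract."""
        for _ in range(100):
            n = int(rng.integers(12, 60))
            row = "".join(
                "-" if rng.random() < 0.2 else "AQSG"[rng.integers(4)] for _ in range(n)
            )
            seq = row.replace("-", "")
            if len(seq) < 4:
                continue
            other = "A" * n
            g = make_group([row, other])
            for aar in detect_aars(g.members[0][1]):
                aligned = map_aar_to_columns(g, 0, aar)
                tract = row[aligned.col_start : aligned.col_end].replace("-", "")
                assert tract == seq[aar.start : aar.end]


class TestConservationStatus:
    def test_all_gaps_fails_to_align(self):
        g = make_group(["QQQQAA", "----AA", "----AA"])
        aligned = map_aar_to_columns(g, 0, AAR("g_m0", "Q", 0, 4))
        assert conservation_status(g, aligned) == "fails_to_align"

    def test_one_gap_free_other_row(self):
        g = make_group(["QQQQAA", "QQQQAA", "----AA"])
        aligned = map_aar_to_columns(g, 0, AAR("g_m0", "Q", 0, 4))
        assert conservation_status(g, aligned) == "partially_aligned"

    def test_half_gaps_at_threshold_is_partially_aligned(self):
        """Gap fraction must strictly exceed the threshold to fail."""
        g = make_group(["QQQQAA", "QQ--AA"])
        aligned = map_aar_to_columns(g, 0, AAR("g_m0", "Q", 0, 4))
        assert conservation_status(g, aligned, gap_frac_threshold=0.5) == "partially_aligned"
        assert conservation_status(g, aligned, gap_frac_threshold=0.49) == "fails_to_align"

    def test_brute_force_agreement_random(self, rng):
        for _ in range(60):
            width = 12
            rows = ["QQQQQQ" + "A" * (width - 6)]
            for _ in range(int(rng.integers(2, 5))):
                rows.append(
                    "".join("-" if rng.random() < 0.5 else "Q" for _ in range(width))
                )
            rows = [r if r.replace("-", "") else "Q" * width for r in rows]
            g = make_group(rows)
            aar = detect_aars(g.members[0][1])[0]
            aligned = map_aar_to_columns(g, 0, aar)
            lo, hi = aligned.span
            fails = all(
                sum(ch == "-" for ch in r[lo:hi]) / (hi - lo) > 0.5 for r in rows[1:]
            )
            expected = "fails_to_align" if fails else "partially_aligned"
            assert conservation_status(g, aligned) == expected


class TestConservedLongAars:
    def make_conserved_group(self, n_members=10, tract="Q" * 8, keep=None):
        keep = keep if keep is not None else [True] * n_members
        rows = []
        for k in range(n_members):
            mid = tract if keep[k] else "-" * len(tract)
            rows.append("ACDEF" + mid + "GHIKL")
        return make_group(rows)

    def test_fully_conserved_reported(self):
        g = self.make_conserved_group()
        found = find_conserved_long_aars(g)
        assert any(a.aar.length == 8 and a.member_index == 0 for a in found)

    def test_length_seven_not_reported(self):
        """'Longer than seven residues' is exclusive: 7 does not qualify."""
        g = self.make_conserved_group(tract="Q" * 7)
        assert find_conserved_long_aars(g) == []

    def test_support_count_threshold(self, rng):
        """Reported iff >= 8 *other* members carry the tract at >= 50%."""
        for k_support in (6, 7, 8, 9):
            keep = [True] + [i < k_support for i in range(9)]
            g = self.make_conserved_group(keep=keep)
            found = [a for a in find_conserved_long_aars(g) if a.member_index == 0]
            assert bool(found) == (k_support >= 8)

    def test_identity_recomputation_oracle(self, rng):
        for _ in range(20):
            keep = [True] + [bool(rng.integers(2)) for _ in range(9)]
            g = self.make_conserved_group(keep=keep)
            found = [a for a in find_conserved_long_aars(g) if a.member_index == 0]
            aar = detect_aars(g.members[0][1])[0]
            span = (5, 13)
            support = sum(
                1
                for i, row in enumerate(g.msa)
                if i != 0 and region_identity(row, span, aar.residue) >= 0.5
            )
            assert bool(found) == (support >= 8)

    def test_too_few_members_rejected(self):
        g = self.make_conserved_group(n_members=5)
        with pytest.raises(ValueError):
            find_conserved_long_aars(g)


class TestExtractFlanks:
    def test_interior_aar_both_flanks(self):
        p = ProteinRecord("p", "A" * 200)
        regions = extract_flanks(p, [AAR("p", "Q", 40, 48)])
        spans = {(r.side, r.start, r.end) for r in regions}
        assert spans == {("left", 7, 40), ("right", 48, 81)}

    def test_protein_start_truncation(self):
        p = ProteinRecord("p", "A" * 100)
        regions = extract_flanks(p, [AAR("p", "Q", 0, 5)])
        assert [(r.side, r.start, r.end) for r in regions] == [("right", 5, 38)]

    def test_neighboring_aars_share_between_region(self):
        p = ProteinRecord("p", "A" * 60)
        aars = [AAR("p", "Q", 10, 14), AAR("p", "S", 30, 34)]
        regions = extract_flanks(p, aars)
        spans = {(r.side, r.start, r.end) for r in regions}
        assert ("right", 14, 30) in spans
        assert ("left", 14, 30) in spans

    def test_flanks_disjoint_from_aars(self, rng):
        for _ in range(60):
            seq = "".join("AQSGW"[i] for i in rng.integers(5, size=int(rng.integers(20, 150))))
            p = ProteinRecord("p", seq)
            aars = detect_aars(p)
            for r in extract_flanks(p, aars):
                assert 0 <= r.start < r.end <= len(p)
                for a in aars:
                    assert r.end <= a.start or r.start >= a.end


class TestCodonProjection:
    def test_span_scaling(self):
        g = make_group(["QQQQAA", "QQQQAA"])
        assert project_to_codons(g, (2, 4)) == (6, 12)

    def test_gap_columns_excluded_per_pair(self):
        g = make_group(["QQQQAA", "QQ-QAA"])
        a, b = pair_codon_strings(g, 0, 1, [(0, 6)])
        assert len(a) == len(b) == 15  # 5 shared gap-free columns

    def test_translation_round_trip(self, rng):
        from aarscan.dnds import _translate

        for _ in range(30):
            n = int(rng.integers(6, 30))
            row1 = "".join("-" if rng.random() < 0.15 else "AQSG"[rng.integers(4)] for _ in range(n))
            row2 = "".join("-" if rng.random() < 0.15 else "AQSG"[rng.integers(4)] for _ in range(n))
            row1 = row1 if row1.replace("-", "") else "A" * n
            row2 = row2 if row2.replace("-", "") else "A" * n
            g = make_group([row1, row2])
            a, b = pair_codon_strings(g, 0, 1, [(0, n)])
            aa_a = "".join(_translate(a[i : i + 3]) for i in range(0, len(a), 3))
            aa_b = "".join(_translate(b[i : i + 3]) for i in range(0, len(b), 3))
            shared = [
                (x, y) for x, y in zip(row1, row2) if x != "-" and y != "-"
            ]
            assert aa_a == "".join(x for x, _ in shared)
            assert aa_b == "".join(y for _, y in shared)


class TestFlankVsWhole:
    def test_report_structure_on_synthetic_groups(self):
        from aarscan.synth import GeneratorConfig, generate_ortholog_groups

        cfg = GeneratorConfig(n_groups=8, group_size=4, seed=9)
        groups, _ = generate_ortholog_groups(cfg, np.random.default_rng(9))
        rep = flank_vs_whole_comparison(groups)
        assert "__pooled__" in set(rep["species"])
        pooled = rep[rep["species"] == "__pooled__"].iloc[0]
        assert pooled["n_proteins"] >= 1
        assert 0.0 <= pooled["frac_flank_gt1"] <= 1.0

    def test_relaxed_flanks_have_higher_ratio(self):
        from aarscan.synth import GeneratorConfig, generate_ortholog_groups

        cfg = GeneratorConfig(n_groups=25, group_size=6, seed=13, flank_relaxation=4.0)
        groups, _ = generate_ortholog_groups(cfg, np.random.default_rng(13))
        rep = flank_vs_whole_comparison(groups)
        pooled = rep[rep["species"] == "__pooled__"].iloc[0]
        assert pooled["median_flank_dnds"] > pooled["median_whole_dnds"]

    def test_single_protein_flagged_unreliable(self):
        from aarscan.synth import GeneratorConfig, generate_ortholog_groups

        cfg = GeneratorConfig(n_groups=1, group_size=2, seed=3, conserved_repeat_prob=0.0)
        groups, _ = generate_ortholog_groups(cfg, np.random.default_rng(3))
        rep = flank_vs_whole_comparison(groups)
        if len(rep):
            assert not rep.iloc[0]["reliable"] or rep.iloc[0]["n_proteins"] >= 2
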