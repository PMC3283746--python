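"""Expression normalization, TSI, half-lives, splice classes, hotspots."""

import numpy as np
import pandas as pd
import pytest

from aarscan.regulation import (
    ExpressionMatrix,
    GeneModelTable,
    aggregate_per_locus,
    classify_exons,
    compare_rcp_half_lives,
    exon_segment_rrpk,
    hotspot_neighbor_enrichment,
    normalize_expression,
    tissue_specificity_index,
)
from aarscan.repeatscan import AAR, ProteinRecord, detect_aars


class TestNormalization:
    def test_column_means_equal_grand_mean(self, rng):
        raw = pd.DataFrame(rng.lognormal(3, 1, size=(40, 5)))
        norm = normalize_expression(ExpressionMatrix(raw))
        col_means = norm.values.mean(axis=0)
        assert np.allclose(col_means, col_means.iloc[0], atol=1e-9)

    def test_doubled_tissue_restored(self, rng):
        """Doubling one tissue on the raw scale shifts its log values by 1;
        normalization removes the between-tissue difference (the overall
        level moves by the column's share of the grand mean)."""
        base = rng.lognormal(3, 1, size=(30, 4))
        raw = base.copy()
        raw[:, 2] *= 2.0
        norm = normalize_expression(ExpressionMatrix(pd.DataFrame(raw))).values.to_numpy()
        base_norm = normalize_expression(ExpressionMatrix(pd.DataFrame(base))).values.to_numpy()
        diff = norm - base_norm
        assert np.allclose(diff, diff.mean(), atol=1e-9)  # uniform shift only
        assert np.allclose(diff.mean(), 0.25, atol=1e-9)  # +1 log2 over 4 tissues

    def test_masked_entries_stay_masked(self, rng):
        raw = pd.DataFrame(rng.lognormal(3, 1, size=(10, 3)))
        raw.iloc[0, 0] = np.nan
        norm = normalize_expression(ExpressionMatrix(raw))
        assert np.isnan(norm.values.iloc[0, 0])

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            normalize_expression(ExpressionMatrix(pd.DataFrame([[1.0, -2.0], [3.0, 4.0]])))


class TestTsi:
    @pytest.mark.parametrize(
        "x,expected",
        [
            ((8.0, 8.0, 8.0, 8.0), 0.0),
            ((8.0, 0.0, 0.0, 0.0, 0.0), 1.0),
            ((4.0, 2.0), 0.5),
        ],
    )
    def test_analytic_cases(self, x, expected):
        res = tissue_specificity_index(np.array(x))
        assert res.defined
        assert abs(res.tsi - expected) < 1e-12

    def test_bounds_random(self, rng):
        for _ in range(200):
            x = rng.uniform(0, 10, size=int(rng.integers(2, 12)))
            res = tissue_specificity_index(x)
            assert 0.0 <= res.tsi <= 1.0

    def test_negative_values_floored_and_flagged(self):
        res = tissue_specificity_index(np.array([5.0, -1.0, 2.0]))
        assert res.floored
        manual = (0 + (1 - 0 / 5) + (1 - 2 / 5)) / 2
        assert res.tsi == pytest.approx(manual)

    def test_undefined_cases(self):
        assert not tissue_specificity_index(np.array([3.0])).defined
        assert not tissue_specificity_index(np.array([0.0, -2.0, -3.0])).defined
        assert not tissue_specificity_index(np.array([np.nan, 4.0])).defined

    def test_masked_tissues_dropped(self):
        res = tissue_specificity_index(np.array([4.0, np.nan, 2.0]))
        assert res.n_tissues_used == 2
        assert res.tsi == pytest.approx(0.5)


class TestAggregation:
    def test_single_probe_passthrough(self):
        v = pd.Series({"p1": 0.4})
        m = pd.Series({"p1": "g1"})
        assert aggregate_per_locus(v, m)["g1"] == 0.4

    def test_two_probe_mean(self):
        v = pd.Series({"p1": 0.2, "p2": 0.4})
        m = pd.Series({"p1": "g1", "p2": "g1"})
        assert aggregate_per_locus(v, m)["g1"] == pytest.approx(0.3)

    def test_groupby_oracle_random(self, rng):
        probes = [f"p{i}" for i in range(60)]
        loci = [f"g{rng.integers(10)}" for _ in probes]
        v = pd.Series(rng.normal(size=60), index=probes)
        m = pd.Series(loci, index=probes)
        got = aggregate_per_locus(v, m)
        for g in set(loci):
            members = [p for p, l in zip(probes, loci) if l == g]
            assert got[g] == pytest.approx(np.mean([v[p] for p in members]))


class TestHalfLives:
    def test_identical_distributions_null(self, rng):
        hl = pd.Series(rng.exponential(4, 200), index=[f"g{i}" for i in range(200)])
        flags = pd.Series([i % 2 == 0 for i in range(200)], index=hl.index)
        rep = compare_rcp_half_lives(hl, flags)
        assert rep.p_value > 0.001  # no systematic difference injected

    def test_shorter_rcp_half_lives_detected(self, rng):
        n = 2000
        idx = [f"g{i}" for i in range(2 * n)]
        hl = pd.Series(
            np.concatenate([rng.exponential(3.2, n), rng.exponential(4.0, n)]), index=idx
        )
        flags = pd.Series([i < n for i in range(2 * n)], index=idx)
        rep = compare_rcp_half_lives(hl, flags)
        assert rep.p_value < 0.01
        assert rep.extra["direction"] == "rcp_shorter"

    def test_degenerate_class_flagged(self):
        hl = pd.Series({"a": 1.0, "b": 2.0, "c": 3.0})
        flags = pd.Series({"a": True, "b": False, "c": False})
        rep = compare_rcp_half_lives(hl, flags)
        assert not rep.reliable


class TestExonClassification:
    def test_single_model_all_constitutive(self):
        m = GeneModelTable("g", {"m1": [(0, 90), (200, 290)]})
        assert set(classify_exons(m).values()) == {"constitutive"}

    def test_shared_and_private_exons(self):
        m = GeneModelTable(
            "g", {"m1": [(0, 90), (200, 290)], "m2": [(0, 90)]}
        )
        classes = classify_exons(m)
        assert classes[(0, 90)] == "constitutive"
        assert classes[(200, 290)] == "alternative"

    def test_intersection_oracle_random(self, rng):
        for _ in range(40):
            exon_pool = [(int(100 * i), int(100 * i + 50)) for i in range(6)]
            models = {}
            for mi in range(int(rng.integers(1, 4))):
                picks = sorted(
                    {exon_pool[j] for j in rng.choice(6, size=int(rng.integers(1, 6)), replace=False)}
                )
                models[f"m{mi}"] = picks
            gm = GeneModelTable("g", models)
            classes = classify_exons(gm)
            shared = set.intersection(*[set(e) for e in models.values()])
            for iv, cls in classes.items():
                assert (cls == "constitutive") == (iv in shared)


class TestExonSegmentRrpk:
    def test_single_exon_equals_protein_rrpk(self):
        p = ProteinRecord("p", "QQQQQSTWQQQQAAE")
        aars = detect_aars(p)
        segs = exon_segment_rrpk(p, aars, [(0, 45, "constitutive")])
        assert len(segs) == 1
        assert segs[0].rrpk == pytest.approx(600.0)

    def test_junction_codon_goes_upstream(self):
        # 10 residues; exon 1 covers 17 bases: codons 0..4 full + 2 bases of
        # codon 5 -> residue 5 belongs to the downstream exon, residues 0-5
        # split 6/4... codon 5 starts at base 15 < 17, so it is upstream.
        p = ProteinRecord("p", "QQQQQQWWWW")
        segs = exon_segment_rrpk(p, [], [(0, 17, "constitutive"), (17, 30, "alternative")])
        assert [(s.start, s.end) for s in segs] == [(0, 6), (6, 10)]

    def test_residue_conservation_identity_random(self, rng):
        for _ in range(40):
            n = int(rng.integers(6, 60))
            seq = "".join("AQSG"[i] for i in rng.integers(4, size=n))
            p = ProteinRecord("p", seq)
            aars = detect_aars(p)
            cds_len = 3 * n
            k = int(rng.integers(1, 5))
            cuts = sorted(rng.choice(np.arange(1, cds_len), size=k - 1, replace=False)) if k > 1 else []
            bounds = [0] + [int(c) for c in cuts] + [cds_len]
            exons = [
                (bounds[i], bounds[i + 1], "constitutive") for i in range(len(bounds) - 1)
            ]
            segs = exon_segment_rrpk(p, aars, exons)
            assert sum(s.end - s.start for s in segs) == n
            assert sum(s.repeat_residues for s in segs) == sum(a.length for a in aars)

    def test_length_mismatch_rejected(self):
        p = ProteinRecord("p", "QQQQ")
        with pytest.raises(ValueError):
            exon_segment_rrpk(p, [], [(0, 11, "constitutive")])


class TestHotspots:
    def make_genes(self, intervals):
        return pd.DataFrame(
            [{"chrom": "chr1", "start": s, "end": e, "name": f"g{i}"}
             for i, (s, e) in enumerate(intervals)]
        )

    def test_one_bp_overlap_counts(self):
        genes = self.make_genes([(100, 200), (300, 400)])
        hs = pd.DataFrame([{"chrom": "chr1", "start": 199, "end": 250}])
        flags = pd.Series({"g0": True, "g1": False})
        rep = hotspot_neighbor_enrichment(genes, hs, flags)
        assert rep.extra["table"][0][0] == 1  # g0 neighbouring
        assert rep.extra["table"][1][0] == 0

    def test_adjacent_half_open_does_not_overlap(self):
        genes = self.make_genes([(100, 200)])
        hs = pd.DataFrame([{"chrom": "chr1", "start": 200, "end": 250}])
        flags = pd.Series({"g0": True})
        rep = hotspot_neighbor_enrichment(genes, hs, flags)
        assert rep.extra["table"][0][0] == 0

    def test_no_hotspot_chrom_degenerate_flagged(self):
        genes = self.make_genes([(0, 10), (20, 30)])
        hs = pd.DataFrame([{"chrom": "chr9", "start": 0, "end": 5}])
        flags = pd.Series({"g0": True, "g1": False})
        rep = hotspot_neighbor_enrichment(genes, hs, flags)
        assert not rep.reliable

    def test_all_pairs_oracle_random(self, rng):
        for _ in range(20):
            genes = self.make_genes(
                [(int(s), int(s) + int(rng.integers(1, 50))) for s in rng.integers(0, 500, 12)]
            )
            hs = pd.DataFrame(
                [{"chrom": "chr1", "start": int(s), "end": int(s) + int(rng.integers(1, 40))}
                 for s in rng.integers(0, 500, 5)]
            )
            flags = pd.Series(rng.integers(2, size=12).astype(bool).tolist(),
                              index=genes["name"].tolist())
            rep = hotspot_neighbor_enrichment(genes, hs, flags)
            expected = {}
            for _, g in genes.iterrows():
                expected[g["name"]] = any(
                    h["start"] < g["end"] and h["end"] > g["start"] for _, h in hs.iterrows()
                )
            a = sum(1 for n, f in flags.items() if f and expected[n])
            assert rep.extra["table"][0][0] == a


def test_fisher_small_table_oracle(rng):
    """Pipeline 2x2 builder p matches the hypergeometric tail on n <= 60."""
    from scipy import stats as sps

    from aarscan.stats import fisher_exact_2x2

    for _ in range(100):
        t = rng.integers(0, 16, size=(2, 2))
        if t.sum() == 0 or t.sum() > 60:
            continue
        mine = fisher_exact_2x2(t).p_value
        _, p = sps.fisher_exact(t)
        assert mine == pytest.approx(p, abs=1e-10)
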