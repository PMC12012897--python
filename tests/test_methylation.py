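"""Methylation levels, in-silico methylome, DMR/DML calling, sRNA clusters."""

import numpy as np
import pandas as pd
import pytest

from allohybrid.intervals import GeneIndex, GeneModel, GenomicInterval
from allohybrid.methylation import (
    acr_methylation_status,
    bin_methylation,
    build_insilico_methylome,
    call_dmls,
    call_dmrs,
    classify_dmr_targets,
    cluster_srna,
    dmr_srna_enrichment,
    weighted_methylation,
)
from test_stats import fisher_enumeration_oracle


def cx(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "meth", "unmeth"])


class TestWeightedMethylation:
    def test_single_site(self):
        calls = cx([("A01", 10, "+", "CG", 17, 3)])
        assert weighted_methylation(calls, context="CG") == pytest.approx(0.85)

    def test_pooled_not_averaged(self):
        calls = cx([("A01", 10, "+", "CG", 3, 7), ("A01", 20, "+", "CG", 7, 3)])
        assert weighted_methylation(calls, context="CG") == pytest.approx(0.5)

    def test_count_weighting_differs_from_site_mean(self):
        # 1/10 and 9/18: pooled 10/28 = 0.357, site-mean trap would say 0.30
        calls = cx([("A01", 10, "+", "CG", 1, 9), ("A01", 20, "+", "CG", 9, 9)])
        assert weighted_methylation(calls, context="CG") == pytest.approx(10 / 28)

    def test_coverage_filter_yields_undefined(self):
        calls = cx([("A01", 10, "+", "CG", 2, 2)])
        assert weighted_methylation(calls, context="CG", min_coverage=5) is None

    def test_region_restriction(self):
        calls = cx([("A01", 10, "+", "CG", 10, 0), ("A01", 500, "+", "CG", 0, 10)])
        region = GenomicInterval("A01", 0, 100)
        assert weighted_methylation(calls, region, "CG") == pytest.approx(1.0)


class TestInsilicoMethylome:
    def test_equal_coverage_sums(self):
        m = cx([("A01", 10, "+", "CG", 8, 2)])
        p = cx([("A01", 10, "+", "CG", 2, 8)])
        mix = build_insilico_methylome(m, p)
        assert (mix.loc[0, "meth"], mix.loc[0, "unmeth"]) == (10, 10)

    def test_c_subgenome_passthrough(self):
        m = cx([("C01", 10, "+", "CG", 7, 3)])
        p = cx([("A01", 99, "+", "CG", 5, 5)])
        mix = build_insilico_methylome(m, p)
        row = mix[mix["chrom"] == "C01"].iloc[0]
        assert (row["meth"], row["unmeth"]) == (7, 3)

    def test_identical_parents_reproduce_levels(self):
        rng = np.random.default_rng(0)
        rows = [
            ("A01", int(i * 10), "+", "CG", int(m), int(20 - m))
            for i, m in enumerate(rng.integers(0, 21, 50))
        ]
        m = cx(rows)
        mix = build_insilico_methylome(m, m.copy())
        merged = m.merge(mix, on=["chrom", "pos", "strand", "context"], suffixes=("", "_mix"))
        lv = merged["meth"] / (merged["meth"] + merged["unmeth"])
        lv_mix = merged["meth_mix"] / (merged["meth_mix"] + merged["unmeth_mix"])
        assert lv.values == pytest.approx(lv_mix.values)

    def test_unequal_coverage_balanced_before_summing(self):
        # maternal 30x fully methylated, paternal 10x unmethylated: the 1:1
        # mixture must sit at level 0.5, not at the coverage-weighted 0.75
        m = cx([("A01", 10, "+", "CG", 30, 0)])
        p = cx([("A01", 10, "+", "CG", 0, 10)])
        mix = build_insilico_methylome(m, p)
        level = mix.loc[0, "meth"] / (mix.loc[0, "meth"] + mix.loc[0, "unmeth"])
        assert level == pytest.approx(0.5)


def make_bins(spec_rows):
    """spec_rows: (chrom, bin_start, context, meth, unmeth, n_sites)."""
    df = pd.DataFrame(
        spec_rows, columns=["chrom", "bin_start", "context", "meth", "unmeth", "n_sites"]
    )
    df["level"] = df["meth"] / (df["meth"] + df["unmeth"])
    df["bin_end"] = df["bin_start"] + 200
    return df


class TestCallDmrs:
    def test_cg_bin_needs_both_delta_and_p(self):
        b1 = make_bins([("A01", 0, "CG", 170, 30, 5)])  # level 0.85
        b2 = make_bins([("A01", 0, "CG", 100, 100, 5)])  # level 0.50
        out = call_dmrs(b1, b2)
        expected_p = fisher_enumeration_oracle(170, 30, 100, 100)
        assert out.loc[0, "p_value"] == pytest.approx(expected_p, abs=1e-12)
        assert out.loc[0, "delta"] == pytest.approx(0.35)
        assert bool(out.loc[0, "is_dmr"]) == (expected_p < 0.05)

    def test_chh_below_delta_never_dmr(self):
        b1 = make_bins([("A01", 0, "CHH", 180, 820, 5)])  # 0.18
        b2 = make_bins([("A01", 0, "CHH", 100, 900, 5)])  # 0.10, delta 0.08 < 0.1
        out = call_dmrs(b1, b2)
        assert out.loc[0, "p_value"] < 0.05 and not out.loc[0, "is_dmr"]

    def test_identical_bins_not_dmr(self):
        b = make_bins([("A01", 0, "CG", 50, 50, 5)])
        out = call_dmrs(b, b.copy())
        assert out.loc[0, "p_value"] == pytest.approx(1.0) and not out.loc[0, "is_dmr"]

    def test_min_sites_filter(self):
        b1 = make_bins([("A01", 0, "CG", 170, 30, 2)])
        b2 = make_bins([("A01", 0, "CG", 20, 180, 2)])
        assert len(call_dmrs(b1, b2)) == 0

    def test_unknown_context_rejected(self):
        b = make_bins([("A01", 0, "CNN", 10, 10, 5)])
        with pytest.raises(ValueError, match="CNN"):
            call_dmrs(b, b.copy())

    def test_swap_antisymmetry(self):
        rng = np.random.default_rng(5)
        rows1, rows2 = [], []
        for i in range(50):
            m1, m2 = int(rng.integers(0, 200)), int(rng.integers(0, 200))
            rows1.append(("A01", i * 200, "CG", m1, 200 - m1, 5))
            rows2.append(("A01", i * 200, "CG", m2, 200 - m2, 5))
        b1, b2 = make_bins(rows1), make_bins(rows2)
        fwd, rev = call_dmrs(b1, b2), call_dmrs(b2, b1)
        assert (fwd["is_dmr"].values == rev["is_dmr"].values).all()
        called = fwd["is_dmr"].values
        assert (
            (fwd.loc[called, "direction"] == "hyper").values
            == (rev.loc[called, "direction"] == "hypo").values
        ).all()


class TestBinning:
    def test_bins_tile_without_overlap(self):
        rng = np.random.default_rng(1)
        calls = cx(
            [
                ("A01", int(p), "+", "CG", 5, 5)
                for p in rng.choice(10000, size=300, replace=False)
            ]
        )
        bins = bin_methylation(calls, bin_size=200)
        assert bins.duplicated(subset=["chrom", "bin_start", "context"]).sum() == 0
        assert (bins["bin_start"] % 200 == 0).all()
        assert bins["n_sites"].sum() == 300  # every site in exactly one bin


class TestCallDmls:
    def test_extreme_site_is_hyper(self):
        c1 = cx([("A01", 10, "+", "CG", 20, 0)])
        c2 = cx([("A01", 10, "+", "CG", 0, 20)])
        out = call_dmls(c1, c2)
        expected = fisher_enumeration_oracle(20, 0, 0, 20)
        assert out.loc[0, "p_value"] == pytest.approx(expected, abs=1e-12)
        assert out.loc[0, "is_dml"] and out.loc[0, "direction"] == "hyper"

    def test_equal_site_not_dml(self):
        c = cx([("A01", 10, "+", "CG", 10, 10)])
        out = call_dmls(c, c.copy())
        assert not out.loc[0, "is_dml"]

    def test_low_coverage_excluded(self):
        c1 = cx([("A01", 10, "+", "CG", 5, 0)])
        c2 = cx([("A01", 10, "+", "CG", 0, 4)])  # coverage 4 < 5
        assert len(call_dmls(c1, c2)) == 0


class TestDmrTargets:
    def test_positional_assignment(self):
        gene_index = GeneIndex([GeneModel("g", GenomicInterval("A01", 5000, 8000))])
        dmrs = pd.DataFrame(
            {
                "chrom": ["A01"] * 3,
                "bin_start": [6000, 3400, 12000],
                "bin_end": [6200, 3600, 12200],
            }
        )
        out = classify_dmr_targets(dmrs, gene_index)
        assert list(out["positional"]) == ["genic", "proximal", "distal"]
        assert list(out["target_gene"]) == ["g", "g", ""]


class TestAcrMethylationStatus:
    def region(self):
        return GenomicInterval("A01", 0, 100)

    def calls(self, cg, chg, chh, cov=20):
        return cx(
            [
                ("A01", 10, "+", "CG", int(cg * cov), cov - int(cg * cov)),
                ("A01", 20, "+", "CHG", int(chg * cov), cov - int(chg * cov)),
                ("A01", 30, "+", "CHH", int(chh * cov), cov - int(chh * cov)),
            ]
        )

    def test_all_low_unmethylated(self):
        assert acr_methylation_status(self.region(), self.calls(0.02, 0.03, 0.01)) == "unmethylated"

    def test_any_high_methylated(self):
        assert acr_methylation_status(self.region(), self.calls(0.40, 0.05, 0.02)) == "methylated"

    def test_no_coverage_undefined(self):
        assert acr_methylation_status(self.region(), cx([])) == "undefined"


class TestSrnaClusters:
    def reads(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "length"])

    def test_nearby_reads_form_one_cluster(self):
        df = self.reads([("A01", 100, 121, 21), ("A01", 150, 171, 21), ("A01", 190, 211, 21)])
        out = cluster_srna(df, min_reads=1, total_reads=1_000_000)
        assert len(out) == 1
        assert out.loc[0, "rpm"] == pytest.approx(3.0)
        assert out.loc[0, "dominant_length"] == 21

    def test_length_filter(self):
        df = self.reads([("A01", 100, 135, 35)])
        assert len(cluster_srna(df, min_reads=1)) == 0

    def test_distant_reads_dropped_by_min_reads(self):
        df = self.reads([("A01", 100, 121, 21), ("A01", 800, 821, 21)])
        assert len(cluster_srna(df, min_reads=5)) == 0
        assert len(cluster_srna(df, min_reads=1)) == 2

    def test_cluster_count_threshold(self):
        rows = [("A01", 100 + 10 * i, 121 + 10 * i, 24) for i in range(5)]
        out = cluster_srna(self.reads(rows), min_reads=5)
        assert len(out) == 1 and out.loc[0, "read_count"] == 5


class TestDmrSrnaEnrichment:
    def dmrs(self, n, direction):
        return pd.DataFrame(
            {
                "chrom": ["A01"] * n,
                "bin_start": [i * 1000 for i in range(n)],
                "bin_end": [i * 1000 + 200 for i in range(n)],
                "direction": [direction] * n,
            }
        )

    def clusters(self, n, rpm):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "chrom": ["A01"] * n,
                "start": [i * 1000 + 50 for i in range(n)],
                "end": [i * 1000 + 150 for i in range(n)],
                "read_count": [10] * n,
                "rpm": rpm + rng.normal(0, rpm / 20, n),
                "dominant_length": [24] * n,
            }
        )

    def test_planted_shift_detected(self):
        dmrs = self.dmrs(30, "hyper")
        res = dmr_srna_enrichment(dmrs, self.clusters(30, 10.0), self.clusters(30, 20.0))
        assert res["hyper"]["p_value"] < 0.01
        assert res["hyper"]["higher_in"] == "insilico"

    def test_identical_distributions_not_significant(self):
        dmrs = self.dmrs(30, "hypo")
        cl = self.clusters(30, 10.0)
        res = dmr_srna_enrichment(dmrs, cl, cl.copy())
        assert res["hypo"]["p_value"] > 0.5

    def test_empty_direction_underpowered(self):
        dmrs = self.dmrs(5, "hyper")
        res = dmr_srna_enrichment(dmrs, self.clusters(5, 10.0), self.clusters(5, 10.0))
        assert res["hypo"]["underpowered"] and np.isnan(res["hypo"]["p_value"])
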