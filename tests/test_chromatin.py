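"""Region annotation, differential binding, concordance, metagene curves."""

import numpy as np
import pandas as pd
import pytest

from betrescue.chromatin import (
    RegionSignal,
    annotate_regions_to_genes,
    compensation_score,
    cross_model_concordance,
    differential_binding,
    metagene_profile,
    top_fraction_sites,
)


def regions_df(rows):
    return pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end"])


def tss_df(rows):
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "tss_position"])


class TestAnnotate:
    def test_midpoint_distance_assignment(self):
        regions = regions_df([("r1", "chr1", 900, 950)])
        tss = tss_df([("GENE1", "chr1", "+", 1000)])
        out = annotate_regions_to_genes(regions, tss)
        assert out.loc["r1", "linked_gene"] == "GENE1"
        assert out.loc["r1", "distance_to_tss"] == 75  # midpoint 925

    def test_equidistant_tie_breaks_lexicographically(self):
        regions = regions_df([("r1", "chr1", 990, 1010)])  # midpoint 1000
        tss = tss_df([("GENEB", "chr1", "+", 900), ("GENEA", "chr1", "+", 1100)])
        out = annotate_regions_to_genes(regions, tss)
        assert out.loc["r1", "linked_gene"] == "GENEA"

    def test_max_distance_cutoff_boundary(self):
        regions = regions_df([("r1", "chr1", 0, 2)])  # midpoint 1
        tss = tss_df([("G", "chr1", "+", 1_000_002)])
        out = annotate_regions_to_genes(regions, tss, max_distance_bp=1_000_000)
        assert out.loc["r1", "linked_gene"] is None
        out2 = annotate_regions_to_genes(regions, tss, max_distance_bp=1_000_001)
        assert out2.loc["r1", "linked_gene"] == "G"

    def test_missing_chromosome_warns_and_unassigns(self):
        regions = regions_df([("r1", "chrUn", 0, 100)])
        tss = tss_df([("G", "chr1", "+", 50)])
        with pytest.warns(UserWarning, match="absent from TSS table"):
            out = annotate_regions_to_genes(regions, tss)
        assert out.loc["r1", "linked_gene"] is None

    def test_duplicate_tss_rows_rejected(self):
        regions = regions_df([("r1", "chr1", 0, 100)])
        tss = tss_df([("G", "chr1", "+", 50), ("G", "chr1", "-", 50)])
        with pytest.raises(ValueError, match="duplicate"):
            annotate_regions_to_genes(regions, tss)


def make_region_signal(values_by_sample, n=None):
    """values_by_sample: {(factor, cond, rep): array}"""
    n = n or len(next(iter(values_by_sample.values())))
    regions = pd.DataFrame(
        {
            "region_id": [f"r{i}" for i in range(n)],
            "chrom": "chr1",
            "start": np.arange(n) * 1000,
            "end": np.arange(n) * 1000 + 500,
        }
    )
    signal = pd.DataFrame(
        {k: np.asarray(v, float) for k, v in values_by_sample.items()},
        index=pd.Index(regions["region_id"], name="region_id"),
    )
    signal.columns = pd.MultiIndex.from_tuples(
        signal.columns, names=["factor", "condition", "replicate"]
    )
    return RegionSignal(regions=regions, signal=signal)


class TestDifferentialBinding:
    def test_equal_conditions_give_zero(self, rng):
        v = rng.uniform(1, 100, 50)
        rs = make_region_signal({("F", "A", 1): v, ("F", "B", 1): v})
        out = differential_binding(rs, "F", "A", "B")
        np.testing.assert_allclose(out["log2fc"], 0.0, atol=1e-12)

    def test_doubling_with_tiny_pseudocount(self, rng):
        v = rng.uniform(10, 100, 50)
        rs = make_region_signal({("F", "A", 1): v, ("F", "B", 1): 2 * v})
        out = differential_binding(rs, "F", "A", "B", pseudocount=1e-9, scale="none")
        np.testing.assert_allclose(out["log2fc"], 1.0, atol=1e-6)

    def test_empty_region_stable_with_pseudocount(self):
        rs = make_region_signal({("F", "A", 1): [0.0, 5.0], ("F", "B", 1): [0.0, 5.0]})
        out = differential_binding(rs, "F", "A", "B", pseudocount=1.0, scale="none")
        assert out["log2fc"].iloc[0] == 0.0

    def test_missing_condition_rejected(self, rng):
        rs = make_region_signal({("F", "A", 1): rng.uniform(1, 10, 5)})
        with pytest.raises(ValueError, match="missing"):
            differential_binding(rs, "F", "A", "B")


class TestCompensation:
    def test_formula_and_null(self):
        idx = pd.Index(["r1", "r2"], name="region_id")
        lost = pd.DataFrame({"log2fc": [-1.0, 0.0]}, index=idx)
        gained = pd.DataFrame({"log2fc": [1.0, 0.0]}, index=idx)
        score = compensation_score(lost, gained)
        assert score.loc["r1"] == pytest.approx(2.0)
        assert score.loc["r2"] == 0.0

    def test_antisymmetric_under_factor_swap(self, rng):
        idx = pd.Index([f"r{i}" for i in range(30)], name="region_id")
        a = pd.DataFrame({"log2fc": rng.normal(0, 1, 30)}, index=idx)
        b = pd.DataFrame({"log2fc": rng.normal(0, 1, 30)}, index=idx)
        np.testing.assert_allclose(
            compensation_score(a, b), -compensation_score(b, a), atol=1e-12
        )

    def test_mismatched_regions_rejected(self):
        a = pd.DataFrame({"log2fc": [1.0]}, index=pd.Index(["r1"]))
        b = pd.DataFrame({"log2fc": [1.0]}, index=pd.Index(["r2"]))
        with pytest.raises(ValueError, match="same regions"):
            compensation_score(a, b)


class TestTopFraction:
    def test_count_is_ceil_of_fraction(self, rng):
        deltas = pd.DataFrame(
            {"log2fc": rng.uniform(0.1, 2, 1000)},
            index=pd.Index([f"r{i}" for i in range(1000)]),
        )
        assert len(top_fraction_sites(deltas, 0.05)) == 50

    def test_all_nonpositive_yields_empty_with_warning(self):
        deltas = pd.DataFrame(
            {"log2fc": [-1.0, 0.0, -0.5]}, index=pd.Index(["a", "b", "c"])
        )
        with pytest.warns(UserWarning, match="dropped"):
            out = top_fraction_sites(deltas, 0.5)
        assert len(out) == 0

    def test_matches_brute_force_sort(self, rng):
        vals = rng.normal(1, 1, 200)
        idx = [f"r{i:03d}" for i in range(200)]
        deltas = pd.DataFrame({"log2fc": vals}, index=pd.Index(idx))
        got = set(top_fraction_sites(deltas, 0.1))
        brute = sorted(zip(vals, idx), key=lambda t: (-t[0], t[1]))[:20]
        expected = {i for v, i in brute if v > 0}
        assert got == expected

    def test_nestedness_in_fraction(self, rng):
        deltas = pd.DataFrame(
            {"log2fc": rng.uniform(0.1, 2, 300)},
            index=pd.Index([f"r{i}" for i in range(300)]),
        )
        small = set(top_fraction_sites(deltas, 0.02))
        large = set(top_fraction_sites(deltas, 0.10))
        assert small <= large

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            top_fraction_sites(pd.DataFrame({"log2fc": []}), 0.05)


class TestConcordance:
    def test_toy_shift_statistic(self):
        deltas_b = pd.DataFrame(
            {"log2fc": [2.0, 2.0, 0.0, 0.0, 0.0, 0.0]},
            index=pd.Index([f"r{i}" for i in range(6)]),
        )
        stat, _ = cross_model_concordance(pd.Index(["r0", "r1"]), deltas_b, n_perm=99, seed=0)
        assert stat == pytest.approx(2.0)

    def test_self_concordance_attains_minimal_p(self, rng):
        vals = rng.normal(0, 1, 500)
        deltas = pd.DataFrame({"log2fc": vals}, index=pd.Index([f"r{i}" for i in range(500)]))
        top = top_fraction_sites(deltas, 0.05)
        stat, p = cross_model_concordance(top, deltas, n_perm=999, seed=1)
        assert stat > 0
        assert p == pytest.approx(1 / 1000)

    def test_no_shared_regions_rejected(self):
        deltas = pd.DataFrame({"log2fc": [1.0, 2.0]}, index=pd.Index(["a", "b"]))
        with pytest.raises(ValueError):
            cross_model_concordance(pd.Index(["zz"]), deltas, n_perm=10)


class TestMetagene:
    def test_constant_signal_gives_flat_curve(self):
        track = {"chr1": np.full(10_000, 2.0)}
        regions = regions_df([("r1", "chr1", 4000, 4500), ("r2", "chr1", 6000, 6100)])
        curve, skipped = metagene_profile(track, regions, flank_bp=1000, n_bins=20)
        assert skipped == 0
        np.testing.assert_allclose(curve, 2.0)

    def test_single_region_ramp_identity(self):
        track = {"chr1": np.arange(10_000, dtype=float)}
        regions = regions_df([("r1", "chr1", 4990, 5010)])  # midpoint 5000
        curve, _ = metagene_profile(track, regions, flank_bp=500, n_bins=10)
        # each 100-bp bin of a unit ramp averages to its midpoint value
        expected = 4500 + 100 * np.arange(10) + 49.5
        np.testing.assert_allclose(curve, expected)

    def test_curve_mean_conserves_window_mean(self, rng):
        track = {"chr1": rng.uniform(0, 5, 20_000)}
        regions = regions_df(
            [(f"r{i}", "chr1", 3000 + 1000 * i, 3400 + 1000 * i) for i in range(8)]
        )
        flank, nb = 1000, 20  # bins evenly divide the window
        curve, _ = metagene_profile(track, regions, flank_bp=flank, n_bins=nb)
        mids = ((regions["start"] + regions["end"]) // 2).to_numpy()
        window_means = [track["chr1"][m - flank : m + flank].mean() for m in mids]
        assert curve.mean() == pytest.approx(np.mean(window_means))

    def test_out_of_bounds_windows_skipped_and_counted(self):
        track = {"chr1": np.ones(3000)}
        regions = regions_df([("r1", "chr1", 0, 100), ("r2", "chr1", 1400, 1600)])
        curve, skipped = metagene_profile(track, regions, flank_bp=1000, n_bins=10)
        assert skipped == 1
        np.testing.assert_allclose(curve, 1.0)
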