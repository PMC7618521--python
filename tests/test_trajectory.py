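"""Variable-gene selection, clustering, archetypes, gene-set statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from betrescue.synthio import simulate_resistance_course
from betrescue.trajectory import (
    STAGES,
    assign_archetypes,
    geneset_delta,
    hierarchical_cluster,
    select_variable_genes,
    stage_response_summary,
)

PROPS5 = {a: 0.2 for a in ("evolution", "degression", "stress", "inflammation", "interferon")}


def profile_df(rows, genes=None):
    genes = genes or [f"g{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"), columns=list(STAGES))


class TestSelectVariableGenes:
    def test_returns_exactly_n(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, (500, 4)), columns=list(STAGES))
        assert len(select_variable_genes(m, 100)) == 100

    def test_clean_separation(self, rng):
        rows = np.zeros((300, 4))
        rows[:100] = rng.normal(0, 1, (100, 4))
        m = profile_df(rows)
        got = set(select_variable_genes(m, 100))
        assert got == {f"g{i}" for i in range(100)}

    def test_matches_brute_force_variance_sort(self, rng):
        m = pd.DataFrame(
            rng.normal(0, 1, (200, 4)),
            index=pd.Index([f"g{i:03d}" for i in range(200)], name="gene_id"),
            columns=list(STAGES),
        )
        got = list(select_variable_genes(m, 50))
        var = m.var(axis=1, ddof=0)
        brute = sorted(m.index, key=lambda g: (-var[g], g))[:50]
        assert got == brute

    def test_n_larger_than_matrix_rejected(self, rng):
        m = pd.DataFrame(rng.normal(0, 1, (10, 4)), columns=list(STAGES))
        with pytest.raises(ValueError):
            select_variable_genes(m, 11)


class TestHierarchicalCluster:
    def test_two_noise_free_archetypes_split_exactly(self):
        prof, truth = simulate_resistance_course(
            {"evolution": 0.5, "degression": 0.5}, n_genes=100, noise_sd=0.0, seed=1
        )
        ids = hierarchical_cluster(prof, 2)
        table = pd.crosstab(ids, truth["archetype"])
        # each cluster holds exactly one archetype
        assert (table.astype(bool).sum(axis=1) == 1).all()

    def test_k_equals_n_gives_singletons(self, rng):
        prof = profile_df(rng.normal(0, 1, (6, 4)))
        ids = hierarchical_cluster(prof, 6)
        assert ids.nunique() == 6

    def test_constant_profile_assigned_to_neighbor_with_warning(self):
        prof = profile_df([[0, 1, 2, 3], [0.1, 1.1, 2.1, 3.1], [3, 2, 1, 0],
                           [5, 5, 5, 5]])
        with pytest.warns(UserWarning, match="constant-profile"):
            ids = hierarchical_cluster(prof, 2)
        assert ids["g3"] in set(ids[:3])

    def test_five_archetype_recovery(self):
        from sklearn.metrics import adjusted_rand_score

        prof, truth = simulate_resistance_course(PROPS5, n_genes=600, noise_sd=0.25, seed=3)
        ids = hierarchical_cluster(prof, 5)
        assert adjusted_rand_score(truth["archetype"], ids) >= 0.9

    def test_deterministic_across_runs(self, rng):
        prof = profile_df(rng.normal(0, 1, (40, 4)))
        a = hierarchical_cluster(prof, 4)
        b = hierarchical_cluster(prof, 4)
        assert (a == b).all()


class TestArchetypes:
    @pytest.mark.parametrize(
        "profile,expected",
        [
            ((1, 2, 3, 4), "evolution"),
            ((9, 7, 5, 3), "degression"),
            ((5, 5, 9, 5), "inflammation"),
            ((0, 2, 0, 0), "stress"),
            ((1, 2, 2, 0), "interferon"),
        ],
    )
    def test_exact_templates_score_unity(self, profile, expected):
        out = assign_archetypes(profile_df([list(profile)]))
        assert out["archetype"].iloc[0] == expected
        assert out["template_correlation"].iloc[0] == pytest.approx(1.0)

    def test_low_correlation_falls_back_to_flat(self):
        out = assign_archetypes(profile_df([[0.0, 0.1, -0.1, 0.05]]), r_floor=0.99)
        assert out["archetype"].iloc[0] == "flat"

    def test_constant_profile_is_flat(self):
        out = assign_archetypes(profile_df([[2.0, 2.0, 2.0, 2.0]]))
        assert out["archetype"].iloc[0] == "flat"

    def test_wrong_stage_count_rejected(self):
        with pytest.raises(ValueError):
            assign_archetypes(pd.DataFrame([[1, 2, 3]], columns=["a", "b", "c"]))

    @given(scale=st.floats(0.1, 50), offset=st.floats(-100, 100))
    @settings(max_examples=30, deadline=None)
    def test_affine_invariance(self, scale, offset):
        prof = profile_df([[1, 2, 3, 4], [4, 3, 2, 1], [0, 0, 1, 0]],
                          genes=["a", "b", "c"])
        base = assign_archetypes(prof)
        moved = assign_archetypes(prof * scale + offset)
        assert (base["archetype"] == moved["archetype"]).all()

    def test_recovery_under_noise(self):
        prof, truth = simulate_resistance_course(PROPS5, n_genes=800, noise_sd=0.0, seed=5)
        assert (assign_archetypes(prof)["archetype"] == truth["archetype"]).all()
        prof, truth = simulate_resistance_course(PROPS5, n_genes=800, noise_sd=0.25, seed=6)
        acc = (assign_archetypes(prof)["archetype"] == truth["archetype"]).mean()
        assert acc >= 0.95


class TestStageResponse:
    def test_identical_arms_give_zero_ratio(self):
        prof, arm, truth = simulate_resistance_course(
            PROPS5, n_genes=100, noise_sd=0.0,
            p300i_log2_effect={a: np.zeros(4) for a in PROPS5}, seed=1,
        )
        out = stage_response_summary(prof, arm, truth["archetype"])
        np.testing.assert_allclose(out["p300i_log2_ratio"], 0.0, atol=1e-12)

    def test_planted_effect_localized_to_stage(self):
        prof, arm, truth = simulate_resistance_course(
            PROPS5, n_genes=200, noise_sd=0.0,
            p300i_log2_effect={"evolution": np.array([0, 0, 0, -1.0])}, seed=2,
        )
        out = stage_response_summary(prof, arm, truth["archetype"]).set_index(
            ["archetype", "stage"]
        )
        assert out.loc[("evolution", "IC90_r"), "p300i_log2_ratio"] == pytest.approx(-1.0)
        assert out.loc[("evolution", "DMSO"), "p300i_log2_ratio"] == pytest.approx(0.0)
        assert out.loc[("stress", "IC90_r"), "p300i_log2_ratio"] == pytest.approx(0.0)

    def test_means_match_brute_force_group_means(self):
        prof, arm, truth = simulate_resistance_course(
            PROPS5, n_genes=150, noise_sd=0.3,
            p300i_log2_effect={"stress": np.ones(4)}, seed=3,
        )
        out = stage_response_summary(prof, arm, truth["archetype"])
        row = out[(out["archetype"] == "stress") & (out["stage"] == "IC50_r")].iloc[0]
        members = truth.index[truth["archetype"] == "stress"]
        assert row["mean"] == pytest.approx(prof.loc[members, "IC50_r"].mean())
        assert row["p300i_mean"] == pytest.approx(arm.loc[members, "IC50_r"].mean())

    def test_unpaired_arm_rejected(self):
        prof, truth = simulate_resistance_course(PROPS5, n_genes=20, seed=4)
        with pytest.raises(ValueError, match="paired"):
            stage_response_summary(prof, prof.iloc[:10], truth["archetype"])


class TestGenesetDelta:
    def test_blunted_vs_deep_sets(self, rng):
        lfc = pd.Series(
            np.concatenate([rng.normal(-0.2, 0.3, 50), rng.normal(-1.0, 0.3, 50)]),
            index=[f"g{i}" for i in range(100)],
        )
        sets = {"blunted": [f"g{i}" for i in range(50)],
                "deep": [f"g{i}" for i in range(50, 100)]}
        summary, pairwise = geneset_delta(lfc, sets)
        row = pairwise.set_index(["set_a", "set_b"]).loc[("blunted", "deep")]
        assert row["mean_diff"] == pytest.approx(0.8, abs=0.2)
        assert row["p_value"] < 0.01

    def test_identical_sets_are_null(self, rng):
        vals = rng.normal(0, 1, 50)
        lfc = pd.Series(np.concatenate([vals, vals]), index=[f"g{i}" for i in range(100)])
        sets = {"a": [f"g{i}" for i in range(50)], "b": [f"g{i}" for i in range(50, 100)]}
        _, pairwise = geneset_delta(lfc, sets)
        assert pairwise["p_value"].iloc[0] == pytest.approx(0.5, abs=0.05)

    def test_small_set_excluded_with_warning(self, rng):
        lfc = pd.Series(rng.normal(0, 1, 60), index=[f"g{i}" for i in range(60)])
        sets = {"big": [f"g{i}" for i in range(50)], "tiny": ["g50", "g51"]}
        with pytest.warns(UserWarning, match="excluded"):
            summary, _ = geneset_delta(lfc, sets)
        assert list(summary["set"]) == ["big"]
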