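"""Density computation, decile scores, NMF meta-markers, state calls."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from dcisatlas.immune import (
    CellRecord,
    FEATURES,
    assign_immune_states,
    compartment_ratio,
    compute_density_matrix,
    decile_regularize,
    densities_frame,
    factorize_densities,
)


def cells_of(n, phenotype, ki67="negative", compartment="epithelium"):
    return [CellRecord(float(i), 0.0, phenotype, ki67, compartment) for i in range(n)]


AREAS = {"epithelium": 0.5, "stroma": 2.0}


class TestDensities:
    def test_density_is_count_over_area(self):
        regions = compute_density_matrix(
            {"R1": cells_of(10, "T-cell")}, {"R1": AREAS}
        )
        assert regions[0].densities["TC_np_Epi"] == pytest.approx(20.0)
        assert regions[0].densities["TC_t_Epi"] == pytest.approx(20.0)

    def test_absent_populations_are_zero_not_missing(self):
        regions = compute_density_matrix(
            {"R1": cells_of(5, "T-cell")}, {"R1": AREAS}
        )
        for f in FEATURES:
            if f.startswith("BC") or f.startswith("TREG"):
                assert regions[0].densities[f] == 0.0

    def test_total_is_sum_of_proliferative_states(self):
        cells = (
            cells_of(4, "B-cell", "positive", "stroma")
            + cells_of(7, "B-cell", "negative", "stroma")
            + cells_of(3, "T-reg", "positive", "epithelium")
        )
        (r,) = compute_density_matrix({"R1": cells}, {"R1": AREAS})
        for ct in ("BC", "TC", "TREG"):
            for comp in ("Epi", "Str"):
                assert r.densities[f"{ct}_t_{comp}"] == pytest.approx(
                    r.densities[f"{ct}_p_{comp}"] + r.densities[f"{ct}_np_{comp}"]
                )

    def test_tregs_disjoint_from_tcells_by_default(self):
        cells = cells_of(6, "T-reg")
        (r,) = compute_density_matrix({"R1": cells}, {"R1": AREAS})
        assert r.densities["TC_t_Epi"] == 0.0
        (r2,) = compute_density_matrix(
            {"R1": cells}, {"R1": AREAS}, include_tregs_in_tcells=True
        )
        assert r2.densities["TC_t_Epi"] == pytest.approx(12.0)

    def test_zero_area_raises(self):
        with pytest.raises(ValueError, match="area"):
            compute_density_matrix(
                {"R1": []}, {"R1": {"epithelium": 0.0, "stroma": 1.0}}
            )

    def test_frame_has_18_features(self):
        regions = compute_density_matrix({"R1": [], "R2": []}, {"R1": AREAS, "R2": AREAS})
        df = densities_frame(regions)
        assert df.shape == (2, 18)
        assert list(df.columns) == list(FEATURES)


class TestDeciles:
    def test_ten_distinct_values_get_scores_one_to_ten(self):
        m = pd.DataFrame({"f": np.arange(10.0)})
        assert list(decile_regularize(m)["f"]) == list(range(1, 11))

    def test_constant_feature_maps_to_single_decile(self):
        m = pd.DataFrame({"f": [3.0] * 12})
        assert decile_regularize(m)["f"].nunique() == 1

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(31)
        x = rng.uniform(0, 10, 25)
        m1 = pd.DataFrame({"f": x})
        m2 = pd.DataFrame({"f": np.exp(x / 3)})
        assert decile_regularize(m1).equals(decile_regularize(m2))

    def test_scores_within_bounds_and_near_uniform(self):
        rng = np.random.default_rng(32)
        m = pd.DataFrame(rng.uniform(size=(40, 5)), columns=list("abcde"))
        scores = decile_regularize(m)
        assert scores.min().min() >= 1 and scores.max().max() <= 10
        for col in scores:
            counts = scores[col].value_counts()
            assert counts.max() - counts.min() <= 1

    def test_too_few_regions_raises(self):
        with pytest.raises(ValueError):
            decile_regularize(pd.DataFrame({"f": [1.0]}))


def planted_separable(seed):
    """Exact rank-4 instance with anchor features and anchor regions.

    Anchors on both sides make the non-negative factorization unique up
    to permutation and scale, so factor recovery is well-posed.
    """
    rng = np.random.default_rng(seed)
    blocks = [range(0, 5), range(5, 10), range(10, 14), range(14, 18)]
    W0 = np.zeros((18, 4))
    for j, blk in enumerate(blocks):
        W0[list(blk), j] = rng.uniform(0.5, 1.0, len(list(blk)))
    H0 = np.zeros((4, 30))
    for j in range(4):
        H0[j, j * 4 : (j + 1) * 4] = rng.uniform(0.5, 2.0, 4)
    H0[:, 16:] = rng.uniform(0.1, 1.5, (4, 14))
    return W0, H0


class TestNmf:
    def test_recovers_planted_factors(self):
        W0, H0 = planted_separable(42)
        X = W0 @ H0
        scores = pd.DataFrame(X.T, columns=[f"f{i}" for i in range(18)])
        model = factorize_densities(
            scores, rank=4, seed=0, n_restarts=5, max_iter=20000, tol=0.0
        )
        Wh = model.W.to_numpy()
        assert model.loss < 1e-6
        cos = (W0 / np.linalg.norm(W0, axis=0)).T @ (Wh / np.linalg.norm(Wh, axis=0))
        rows, cols = linear_sum_assignment(-cos)
        assert cos[rows, cols].min() > 0.99

    def test_loss_history_non_increasing(self):
        rng = np.random.default_rng(33)
        scores = pd.DataFrame(rng.integers(1, 11, size=(20, 18)).astype(float))
        model = factorize_densities(scores, seed=1, n_restarts=2, max_iter=300)
        diffs = np.diff(model.loss_history)
        assert np.all(diffs <= 1e-8 * np.maximum(model.loss_history[:-1], 1.0))

    def test_same_seed_identical_output(self):
        rng = np.random.default_rng(34)
        scores = pd.DataFrame(rng.integers(1, 11, size=(15, 18)).astype(float))
        m1 = factorize_densities(scores, seed=7, n_restarts=3, max_iter=200)
        m2 = factorize_densities(scores, seed=7, n_restarts=3, max_iter=200)
        assert m1.W.equals(m2.W) and m1.H.equals(m2.H)

    def test_factors_non_negative(self):
        rng = np.random.default_rng(35)
        scores = pd.DataFrame(rng.integers(1, 11, size=(12, 18)).astype(float))
        model = factorize_densities(scores, seed=2, n_restarts=2, max_iter=200)
        assert (model.W.to_numpy() >= 0).all()
        assert (model.H.to_numpy() >= 0).all()

    def test_rank_exceeding_dimensions_raises(self):
        scores = pd.DataFrame(np.ones((3, 18)))
        with pytest.raises(ValueError, match="rank"):
            factorize_densities(scores, rank=5, seed=0)


def archetype_model(order=("A", "B", "C")):
    """Hand-built model whose H has three well-separated archetypes."""
    H = pd.DataFrame(
        0.1,
        index=["MM1", "MM2", "MM3", "MM4"],
        columns=[f"{g}{i}" for g in order for i in range(4)],
    )
    for col in H.columns:
        if col.startswith("A"):  # MM4-dominant -> Excluded
            H.loc["MM4", col] = 3.0
        elif col.startswith("B"):  # MM2-dominant -> Active
            H.loc["MM2", col] = 3.0
        else:  # MM3-dominant -> Suppressed
            H.loc["MM3", col] = 3.0
    W = pd.DataFrame(np.ones((18, 4)), index=list(FEATURES), columns=H.index)
    from dcisatlas.immune import MetaMarkerModel

    return MetaMarkerModel(W=W, H=H, loss=0.0, seed=0, n_iter=1,
                           loss_history=np.array([0.0]))


class TestStateAssignment:
    def test_planted_archetypes_named_correctly(self):
        states = assign_immune_states(archetype_model())
        for col, state in states.items():
            expected = {"A": "Excluded", "B": "Active", "C": "Suppressed"}[col[0]]
            assert state == expected

    def test_region_order_invariance(self):
        model = archetype_model()
        perm = archetype_model()
        order = list(model.H.columns)[::-1]
        perm.H = perm.H[order]
        s1 = assign_immune_states(model)
        s2 = assign_immune_states(perm)
        assert all(s1[c] == s2[c] for c in s1.index)

    def test_duplicating_regions_preserves_assignments(self):
        model = archetype_model()
        dup = archetype_model()
        doubled = pd.concat([dup.H, dup.H.add_suffix("_bis")], axis=1)
        dup.H = doubled
        s1 = assign_immune_states(model)
        s2 = assign_immune_states(dup)
        assert all(s2[c] == s1[c] for c in s1.index)

    def test_fewer_than_three_distinct_columns_raises(self):
        model = archetype_model()
        model.H = pd.DataFrame(
            np.ones((4, 5)), index=["MM1", "MM2", "MM3", "MM4"]
        )
        with pytest.raises(ValueError, match="distinct"):
            assign_immune_states(model)


class TestCompartmentRatio:
    def make_matrix(self, rows):
        df = pd.DataFrame(0.0, index=list(rows), columns=list(FEATURES))
        return df

    def test_ratio_definition(self):
        m = self.make_matrix(["R1"])
        m.loc["R1", "TC_t_Epi"] = 10.0
        m.loc["R1", "TC_t_Str"] = 98.0
        out = compartment_ratio(m)
        assert out.loc["R1", "TC_ratio"] == pytest.approx(9.8)

    def test_both_zero_is_none_category(self):
        m = self.make_matrix(["R1"])
        out = compartment_ratio(m)
        assert out.loc["R1", "BC_category"] == "none"

    def test_empty_epithelium_is_unbounded(self):
        m = self.make_matrix(["R1"])
        m.loc["R1", "TREG_t_Str"] = 5.0
        out = compartment_ratio(m)
        assert np.isinf(out.loc["R1", "TREG_ratio"])

    def test_scale_invariance(self):
        m = self.make_matrix(["R1", "R2"])
        m.loc["R1", "TC_t_Epi"] = 4.0
        m.loc["R1", "TC_t_Str"] = 12.0
        m.loc["R2"] = m.loc["R1"] * 2
        out = compartment_ratio(m)
        assert out.loc["R1", "TC_ratio"] == pytest.approx(out.loc["R2", "TC_ratio"])
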