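"""Copy-ratio preprocessing, joint segmentation, burden and divergence."""

import itertools

import numpy as np
import pandas as pd
import pytest

from dcisatlas.cna import (
    CopyRatioBin,
    DiscretizationParams,
    cna_burden,
    discretize,
    joint_segment,
    pairwise_divergence,
    read_seg,
    sample_divergence,
    winsorize_bins,
    write_seg,
)

from conftest import bin_frame, profiles_from_means, segmentation_from_means


def flat_bins(values, chromosome="chr1"):
    return [
        CopyRatioBin(chromosome, i * 10, i * 10 + 10, float(v))
        for i, v in enumerate(values)
    ]


class TestWinsorize:
    def test_constant_signal_unchanged(self):
        bins = flat_bins([0.3] * 12)
        assert [b.log2_ratio for b in winsorize_bins(bins)] == [0.3] * 12

    def test_single_outlier_clipped_to_mad_bound(self):
        # ten 0.0 bins plus one at 5.0: median 0, MAD 0 -> clip to 0
        bins = flat_bins([0.0] * 10 + [5.0])
        out = winsorize_bins(bins, k_mad=2.5)
        assert out[-1].log2_ratio == pytest.approx(0.0)
        assert [b.log2_ratio for b in out[:-1]] == [0.0] * 10

    def test_nondegenerate_outlier_clipped_to_bound(self):
        rng = np.random.default_rng(0)
        values = np.concatenate([rng.normal(0, 0.1, 50), [3.0]])
        bins = flat_bins(values)
        med = np.median(values)
        mad = np.median(np.abs(values - med)) * 1.4826
        out = winsorize_bins(bins, k_mad=2.5)
        assert out[-1].log2_ratio == pytest.approx(med + 2.5 * mad)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        bins = flat_bins(rng.standard_t(2, size=60))
        once = winsorize_bins(bins)
        twice = winsorize_bins(once)
        assert [b.log2_ratio for b in once] == pytest.approx(
            [b.log2_ratio for b in twice]
        )

    def test_coordinates_and_order_unchanged(self):
        bins = flat_bins([0.0, 4.0, 0.0, -4.0, 0.0])
        out = winsorize_bins(bins)
        assert [(b.chromosome, b.start, b.end) for b in out] == [
            (b.chromosome, b.start, b.end) for b in bins
        ]

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            winsorize_bins([])


def brute_force_objective(values: np.ndarray, gamma: float) -> float:
    """Exhaustive minimum of the penalized SSE over all breakpoint subsets."""
    _, n = values.shape
    best = np.inf
    for k in range(n):
        for cuts in itertools.combinations(range(1, n), k):
            edges = [0, *cuts, n]
            sse = 0.0
            for a, b in itertools.pairwise(edges):
                seg = values[:, a:b]
                sse += ((seg - seg.mean(axis=1, keepdims=True)) ** 2).sum()
            best = min(best, sse + gamma * len(cuts))
    return best


def dp_objective(seg, values_by_region) -> float:
    obj = seg.gamma * (seg.n_segments - 1)
    for prof in seg.regions:
        vals = values_by_region[prof.region_id]
        i0 = 0
        for s in prof.segments:
            chunk = vals[i0 : i0 + s.n_bins]
            i0 += s.n_bins
            obj += ((chunk - chunk.mean()) ** 2).sum()
    return obj


class TestJointSegment:
    def test_shared_step_recovered_with_exact_means(self):
        lvl = {"R1": (0.0, 1.0), "R2": (0.5, -0.5)}
        bins = {
            rid: bin_frame([a] * 10 + [b] * 10) for rid, (a, b) in lvl.items()
        }
        seg = joint_segment(bins, gamma=0.5)
        assert seg.n_segments == 2
        for rid, (a, b) in lvl.items():
            assert seg.profile(rid).means == pytest.approx([a, b])
        assert [s.n_bins for s in seg.regions[0].segments] == [10, 10]

    def test_huge_gamma_gives_single_segment_with_chromosome_mean(self):
        rng = np.random.default_rng(2)
        values = rng.normal(0, 1, 30)
        seg = joint_segment({"R1": bin_frame(values), "R2": bin_frame(values + 1)},
                            gamma=1e6)
        assert seg.n_segments == 1
        assert seg.profile("R1").means == pytest.approx([values.mean()])
        assert seg.profile("R2").means == pytest.approx([values.mean() + 1])

    @pytest.mark.parametrize("n_regions", [1, 2, 3])
    def test_matches_brute_force_enumeration(self, n_regions):
        rng = np.random.default_rng(10 + n_regions)
        for _ in range(8):
            n = int(rng.integers(4, 13))
            values = rng.normal(0, 1, (n_regions, n))
            values[:, n // 2 :] += rng.normal(0, 1.5)
            gamma = float(rng.uniform(0.5, 6.0))
            bins = {f"R{i}": bin_frame(values[i]) for i in range(n_regions)}
            seg = joint_segment(bins, gamma=gamma)
            obj = dp_objective(seg, {f"R{i}": values[i] for i in range(n_regions)})
            assert obj == pytest.approx(brute_force_objective(values, gamma))

    def test_mismatched_grids_error_names_first_discordant_bin(self):
        a = bin_frame([0.0] * 5)
        b = bin_frame([0.0] * 5)
        b.loc[3, "start"] = 999
        with pytest.raises(ValueError, match="bin 3"):
            joint_segment({"A": a, "B": b}, gamma=1.0)

    def test_chromosomes_segmented_independently(self):
        df = pd.concat(
            [bin_frame([0.0] * 15, "chr1"), bin_frame([1.0] * 15, "chr2")],
            ignore_index=True,
        )
        seg = joint_segment({"A": df, "B": df}, gamma=5.0)
        assert seg.n_segments == 2
        assert {s.chromosome for s in seg.regions[0].segments} == {"chr1", "chr2"}


class TestBurden:
    def test_all_neutral_is_zero(self):
        (p,) = profiles_from_means({"R": [0.0, 0.1, -0.1]}, [10, 10, 10])
        assert cna_burden(p) == 0.0

    def test_fraction_of_covered_bases(self):
        # one gained segment spanning 14% of covered bases
        (p,) = profiles_from_means({"R": [0.8, 0.0]}, [14, 86])
        assert cna_burden(p) == pytest.approx(0.14)

    def test_whole_profile_loss_is_one(self):
        (p,) = profiles_from_means({"R": [-1.0, -1.2]}, [10, 20])
        assert cna_burden(p) == 1.0

    def test_monotone_as_cutoffs_tighten(self):
        rng = np.random.default_rng(3)
        (p,) = profiles_from_means({"R": list(rng.normal(0, 0.5, 20))}, [5] * 20)
        burdens = [
            cna_burden(p, gain_above=c, loss_below=-c) for c in (0.6, 0.4, 0.2, 0.1)
        ]
        assert burdens == sorted(burdens)
        assert all(0.0 <= b <= 1.0 for b in burdens)


class TestDivergence:
    def test_identical_profiles_are_zero(self):
        a, b = profiles_from_means({"A": [0.5, -0.5], "B": [0.5, -0.5]}, [10, 20])
        assert pairwise_divergence(a, b) == 0.0

    def test_hand_computed_value(self):
        a, b = profiles_from_means(
            {"A": [1.0, 0.0, -0.5], "B": [0.0, 0.0, -0.5]}, [10, 30, 60]
        )
        assert pairwise_divergence(a, b) == pytest.approx(0.1)

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(4)
        for _ in range(100):
            k = int(rng.integers(2, 8))
            bins = list(rng.integers(1, 50, size=k))
            means = {r: list(rng.normal(0, 1, k)) for r in "ABC"}
            a, b, c = profiles_from_means(means, bins)
            dab = pairwise_divergence(a, b)
            dba = pairwise_divergence(b, a)
            dac = pairwise_divergence(a, c)
            dcb = pairwise_divergence(c, b)
            assert dab >= 0
            assert dab == pytest.approx(dba)
            assert dab <= dac + dcb + 1e-12  # triangle inequality
        # identity of indiscernibles
        a, b = profiles_from_means({"A": [0.3, -0.2], "B": [0.3, -0.2]}, [5, 7])
        assert pairwise_divergence(a, b) == 0.0

    def test_mismatched_segmentation_raises(self):
        (a,) = profiles_from_means({"A": [0.0, 1.0]}, [10, 10])
        (b,) = profiles_from_means({"B": [0.0, 1.0]}, [10, 20])
        with pytest.raises(ValueError, match="shared segmentation"):
            pairwise_divergence(a, b)

    def test_sample_divergence_is_max_of_pairs(self):
        # three regions engineered to give pairwise divergences 0.1/0.2/0.3
        profs = profiles_from_means(
            {"A": [0.0, 0.0], "B": [0.2, 0.0], "C": [0.6, 0.0]}, [50, 50]
        )
        a, b, c = profs
        assert pairwise_divergence(a, b) == pytest.approx(0.1)
        assert pairwise_divergence(a, c) == pytest.approx(0.3)
        assert pairwise_divergence(b, c) == pytest.approx(0.2)
        assert sample_divergence(profs) == pytest.approx(0.3)

    def test_two_regions_equals_pairwise(self):
        a, b = profiles_from_means({"A": [0.1, 0.4], "B": [0.7, 0.0]}, [3, 9])
        assert sample_divergence([a, b]) == pairwise_divergence(a, b)

    def test_duplicate_region_never_changes_max(self):
        profs = profiles_from_means(
            {"A": [0.0, 0.0], "B": [0.2, 0.0], "C": [0.6, 0.0]}, [50, 50]
        )
        assert sample_divergence(profs + [profs[0]]) == sample_divergence(profs)

    def test_fewer_than_two_regions_raises(self):
        (a,) = profiles_from_means({"A": [0.0]}, [10])
        with pytest.raises(ValueError):
            sample_divergence([a])


class TestDiscretize:
    @pytest.mark.parametrize(
        "value, expected",
        [(-0.7, -1.0), (-0.5, np.nan), (-0.4, 0.0), (0.0, 0.0), (0.3, 0.0), (0.45, np.nan)],
    )
    def test_threshold_mapping(self, value, expected):
        seg = segmentation_from_means({"R": [value]}, [20])
        got = discretize(seg).iloc[0, 0]
        assert got == expected or (np.isnan(got) and np.isnan(expected))

    def test_gains_off_by_default_but_optional(self):
        seg = segmentation_from_means({"R": [0.8]}, [20])
        assert np.isnan(discretize(seg).iloc[0, 0])
        got = discretize(seg, DiscretizationParams(include_gains=True)).iloc[0, 0]
        assert got == 1.0

    def test_low_support_segments_dropped(self):
        seg = segmentation_from_means({"R": [-1.0, -1.0]}, [11, 12])
        cm = discretize(seg)
        assert cm.shape == (1, 1)
        assert cm.columns[0].endswith(f"{11 * 1000}-{23 * 1000}")

    def test_monotone_in_value(self):
        params = DiscretizationParams(include_gains=True)
        values = np.linspace(-1.2, 1.2, 49)
        codes = [params.code(v) for v in values]
        coded = [c for c in codes if not np.isnan(c)]
        assert coded == sorted(coded)


class TestSegIO:
    def test_seg_roundtrip(self, tmp_path):
        seg = segmentation_from_means({"A": [0.1, -0.6], "B": [0.0, 0.2]}, [15, 25])
        path = tmp_path / "toy.seg"
        write_seg(seg, str(path))
        again = read_seg(str(path))
        assert again.region_ids == seg.region_ids
        for r1, r2 in zip(seg.regions, again.regions):
            assert r1.segments == r2.segments
        # on-disk coordinates are 1-based inclusive
        df = pd.read_csv(path, sep="\t")
        assert df["loc.start"].iloc[0] == 1
        assert df["loc.end"].iloc[0] == 15 * 1000
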