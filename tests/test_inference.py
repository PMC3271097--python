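"""Permutation inference: stratified relabelling, p-values, clusters."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fixmap.density import GridSpec, stamp_matrix
from fixmap.inference import (
    PermutationSpec,
    PValueMap,
    cluster_correct,
    label_clusters,
    permute_labels,
    pixel_pvalues,
    resampled_difference_maps,
    run_contrast,
    threshold_map,
)
from fixmap.preprocessing import REQUIRED_COLUMNS


def toy_fixations(locs_by_condition, participant="p0"):
    """Build a fixation table from {condition: [(ordinal, x, y), ...]}."""
    rows = []
    trial = 0
    for cond, fixes in locs_by_condition.items():
        trial += 1
        for ordinal, x, y in fixes:
            rows.append((participant, trial, "study", "upright", cond,
                         "f0", ordinal, x, y, 100.0 * ordinal, 200.0))
    return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))


class TestPermuteLabels:
    def make_tables(self, rng, n_participants=4, n_per=3):
        rows_a, rows_b = [], []
        for p in range(n_participants):
            for ordinal in (1, 2):
                for t in range(n_per):
                    rows_a.append((f"p{p}", t, ordinal,
                                   rng.normal(), rng.normal()))
                    rows_b.append((f"p{p}", t + n_per, ordinal,
                                   rng.normal(), rng.normal()))
        cols = ["participant", "trial", "ordinal", "x", "y"]
        return pd.DataFrame(rows_a, columns=cols), \
            pd.DataFrame(rows_b, columns=cols)

    def test_preserves_pooled_multiset_per_stratum(self, rng):
        a, b = self.make_tables(rng)
        pa, pb = permute_labels(a, b, rng)
        for (p, o) in {(r.participant, r.ordinal) for r in a.itertuples()}:
            def locs(df):
                sub = df[(df["participant"] == p) & (df["ordinal"] == o)]
                return sorted(map(tuple, sub[["x", "y"]].to_numpy()))
            before = locs(a) + locs(b)
            after = locs(pa) + locs(pb)
            assert sorted(before) == sorted(after)

    def test_singleton_strata_swap_half_the_time(self, rng):
        """With one fixation per condition per stratum, the pair swaps
        with probability 1/2 (binomial check over many draws)."""
        a = pd.DataFrame({"participant": ["p0"], "trial": [1],
                          "ordinal": [1], "x": [0.0], "y": [0.0]})
        b = pd.DataFrame({"participant": ["p0"], "trial": [2],
                          "ordinal": [1], "x": [1.0], "y": [0.0]})
        n = 2000
        swaps = sum(
            permute_labels(a, b, rng)[0]["x"].iloc[0] == 1.0
            for _ in range(n)
        )
        se = np.sqrt(0.25 / n)
        assert swaps / n == pytest.approx(0.5, abs=4 * se)

    def test_non_location_fields_untouched(self, rng):
        a, b = self.make_tables(rng)
        pa, pb = permute_labels(a, b, rng)
        pd.testing.assert_frame_equal(a.drop(columns=["x", "y"]),
                                      pa.drop(columns=["x", "y"]))
        pd.testing.assert_frame_equal(b.drop(columns=["x", "y"]),
                                      pb.drop(columns=["x", "y"]))


class TestPixelPvalues:
    def test_add_one_formula(self):
        resampled = np.arange(9).reshape(9, 1).astype(float)
        pmap = pixel_pvalues(np.array([100.0]), resampled)
        assert pmap.p[0] == pytest.approx(1 / 10)

    def test_median_value_near_half(self, rng):
        resampled = rng.standard_normal((999, 1))
        true = np.array([np.median(resampled)])
        pmap = pixel_pvalues(true, resampled)
        assert pmap.p[0] == pytest.approx(0.5, abs=0.01)

    def test_negative_pixels_use_lower_tail(self):
        resampled = np.tile(np.arange(-4.0, 5.0), (1, 1)).T  # -4..4
        pmap = pixel_pvalues(np.array([-100.0]), resampled)
        assert pmap.p[0] == pytest.approx(1 / 10)
        assert pmap.sign[0] == -1

    def test_ties_count_toward_null(self):
        resampled = np.zeros((10, 1))
        pmap = pixel_pvalues(np.array([0.0]), resampled)
        assert pmap.p[0] == 1.0


class TestThresholdAndClusters:
    def test_threshold_edge_cases(self):
        g = GridSpec(0, 0, 1.0, 3, 1)
        pmap = PValueMap(g, np.array([[0.999, 0.5, 0.001]]),
                         np.array([[1, -1, 1]]))
        assert list(threshold_map(pmap, 0.01)[0]) == [0, 0, 1]
        assert list(threshold_map(pmap, 1.0)[0]) == [1, -1, 1]
        # monotone: stricter alpha yields a subset
        m1 = threshold_map(pmap, 0.01) != 0
        m2 = threshold_map(pmap, 0.6) != 0
        assert (m2 | ~m1).all()

    def test_diagonal_connectivity(self):
        mask = np.zeros((4, 4), dtype=int)
        mask[0, 0] = mask[1, 1] = 1
        c8 = label_clusters(mask, connectivity=8)
        c4 = label_clusters(mask, connectivity=4)
        assert len(c8) == 1 and c8["size"].iloc[0] == 2
        assert len(c4) == 2

    def test_signs_never_merge(self):
        mask = np.array([[1, -1, 1]])
        table = label_clusters(mask)
        assert len(table) == 3
        assert sorted(table["sign"]) == [-1, 1, 1]

    def test_matches_brute_force_flood_fill(self, rng):
        mask = rng.choice([0, 1, -1], size=(20, 20), p=[0.7, 0.15, 0.15])
        table = label_clusters(mask, connectivity=8)

        # independent flood fill
        seen = np.zeros_like(mask, dtype=bool)
        sizes = []
        for j0, i0 in zip(*np.nonzero(mask)):
            if seen[j0, i0]:
                continue
            sign = mask[j0, i0]
            stack, members = [(j0, i0)], 0
            seen[j0, i0] = True
            while stack:
                j, i = stack.pop()
                members += 1
                for dj in (-1, 0, 1):
                    for di in (-1, 0, 1):
                        jj, ii = j + dj, i + di
                        if 0 <= jj < 20 and 0 <= ii < 20 \
                                and not seen[jj, ii] and mask[jj, ii] == sign:
                            seen[jj, ii] = True
                            stack.append((jj, ii))
            sizes.append(members)
        assert sorted(table["size"]) == sorted(sizes)


class TestClusterCorrect:
    def template(self, sizes):
        return pd.DataFrame({
            "id": range(1, len(sizes) + 1),
            "sign": [1] * len(sizes),
            "size": sizes,
            "pixels": [np.array([0])] * len(sizes),
        })

    def test_nearest_rank_published_recipe(self):
        """Null sizes 1..20 at alpha=.05: nearest-rank threshold is 19;
        18 is eliminated, 19 survives."""
        null = np.arange(1, 21)
        out, thr = cluster_correct(self.template([18, 19]), null, 0.05,
                                   rule="nearest_rank")
        assert thr == 19
        assert list(out["survives"]) == [False, True]

    def test_exact_rule_add_one(self):
        """Exact rule: corrected p = (1 + #{null >= size}) / (K + 1)."""
        null = np.arange(1, 21)  # K = 20
        out, thr = cluster_correct(self.template([19, 20, 21]), null, 0.05)
        # p(19) = (1+2)/21, p(20) = (1+1)/21 > .05, p(21) = 1/21 < .05
        assert out["p_corrected"].tolist() == pytest.approx(
            [3 / 21, 2 / 21, 1 / 21])
        assert list(out["survives"]) == [False, False, True]
        assert thr == 21

    def test_cluster_above_all_null_survives(self):
        null = np.zeros(99)
        out, _ = cluster_correct(self.template([1]), null, 0.05)
        assert bool(out["survives"].iloc[0])

    def test_empty_cluster_table(self):
        out, _ = cluster_correct(self.template([]), np.arange(10), 0.05)
        assert len(out) == 0


class TestExactEnumerationOracle:
    """Monte Carlo pixel p-values against exhaustive enumeration of all
    stratum assignments on a toy problem."""

    def exact_pvalues(self, fixations, grid, spec):
        """Enumerate every within-stratum reassignment; p = fraction of
        assignments whose difference map is at least as extreme as the
        true (identity) assignment, ties and self included."""
        df = fixations.reset_index(drop=True)
        is_a = (df["start_position"] == "A").to_numpy()
        strata = df.groupby(["participant", "ordinal"]).indices
        M = stamp_matrix(df["x"].to_numpy(), df["y"].to_numpy(), grid)
        # per-slot weights for one participant, one trial per condition
        w_template = np.where(is_a, 1.0, -1.0)

        per_stratum_choices = []
        for idx in strata.values():
            k = int(is_a[idx].sum())
            per_stratum_choices.append([
                np.array(sel)
                for sel in itertools.combinations(idx, k)
            ])
        true_map = None
        maps = []
        for combo in itertools.product(*per_stratum_choices):
            w = np.full(len(df), -1.0)
            for sel in combo:
                w[sel] = 1.0
            maps.append(M.T @ w)
        maps = np.array(maps)
        true_map = M.T @ w_template
        count_ge = (maps >= true_map).sum(axis=0)
        count_le = (maps <= true_map).sum(axis=0)
        n = maps.shape[0]
        return np.where(true_map >= 0, count_ge, count_le) / n, true_map

    def test_monte_carlo_converges_to_enumeration(self):
        """<= 8 exchangeable assignments per stratum; sup-norm between
        MC p-values at 10^4 iterations and exact enumeration < 0.02."""
        rng = np.random.default_rng(3)
        conditions = {"A": [], "B": []}
        for cond in conditions:
            conditions[cond] = [(o, *rng.uniform(-1.5, 1.5, 2))
                                for o in (1, 2)]
        tables = [toy_fixations(conditions, participant=f"p{i}")
                  for i in range(2)]
        # re-randomize each participant's locations
        fix = pd.concat(tables, ignore_index=True)
        fix[["x", "y"]] = rng.uniform(-1.5, 1.5, (len(fix), 2))

        grid = GridSpec(-2.0, -2.0, 0.4, 10, 10)
        spec = PermutationSpec(n_iterations=10_000, n_cluster_maps=10)
        exact_p, true_map = self.exact_pvalues(fix, grid, spec)

        result = run_contrast(fix, "A", "B", grid, spec, seed=4,
                              condition_col="start_position")
        # run_contrast weights scale by 1/(P * n_trials); p-values are
        # scale-invariant so the comparison is direct
        mc_p = result.pvalues.p.ravel()
        assert np.abs(mc_p - exact_p).max() < 0.02


class TestRunContrast:
    def make_data(self, rng, n_participants=5, n_trials=4):
        rows = []
        for p in range(n_participants):
            trial = 0
            for cond in ("left", "right"):
                for _ in range(n_trials):
                    trial += 1
                    for o in (2, 3):
                        rows.append((f"p{p}", trial, "study", "upright",
                                     cond, "f0", o, *rng.normal(0, 1, 2),
                                     100.0 * o, 200.0))
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))

    @pytest.fixture
    def grid(self):
        return GridSpec(-4.0, -4.0, 0.25, 32, 32)

    def test_seed_reproducibility(self, rng, grid):
        fix = self.make_data(rng)
        spec = PermutationSpec(n_iterations=60, n_cluster_maps=20)
        r1 = run_contrast(fix, "left", "right", grid, spec, seed=9)
        r2 = run_contrast(fix, "left", "right", grid, spec, seed=9)
        assert np.array_equal(r1.pvalues.p, r2.pvalues.p)
        assert np.array_equal(r1.null_max_sizes, r2.null_max_sizes)
        assert np.array_equal(r1.true_map.values, r2.true_map.values)

    def test_dense_and_streaming_paths_agree(self, rng, grid):
        fix = self.make_data(rng)
        # identical block size: the permutation stream is consumed
        # block-wise, so block size is part of the reproducibility spec
        dense = PermutationSpec(n_iterations=60, n_cluster_maps=20,
                                block_size=7)
        stream = PermutationSpec(n_iterations=60, n_cluster_maps=20,
                                 dense_memory_mb=0, block_size=7)
        r1 = run_contrast(fix, "left", "right", grid, dense, seed=11)
        r2 = run_contrast(fix, "left", "right", grid, stream, seed=11)
        assert np.array_equal(r1.pvalues.p, r2.pvalues.p)
        assert np.array_equal(r1.null_max_sizes, r2.null_max_sizes)

    def test_participant_missing_condition_excluded(self, rng, grid, caplog):
        fix = self.make_data(rng)
        fix = fix[~((fix["participant"] == "p0")
                    & (fix["start_position"] == "right"))]
        spec = PermutationSpec(n_iterations=30, n_cluster_maps=10)
        with caplog.at_level("WARNING"):
            r = run_contrast(fix, "left", "right", grid, spec, seed=1)
        assert r.n_participants == 4
        assert "p0" in caplog.text

    def test_mean_resampled_map_near_zero_under_null(self, rng, grid):
        """Resampled group difference maps are centered on zero."""
        fix = self.make_data(rng, n_participants=6, n_trials=6)
        spec = PermutationSpec(n_iterations=400, n_cluster_maps=10)
        maps = np.array(list(resampled_difference_maps(
            fix, "left", "right", grid, spec, seed=2)))
        mean = maps.mean(axis=0)
        se = maps.std(axis=0, ddof=1) / np.sqrt(len(maps))
        ok = np.abs(mean) <= 4 * se + 1e-12
        assert ok.mean() > 0.99

    def test_surviving_cluster_sign_coherence(self, rng, grid):
        fix = self.make_data(rng)
        # plant a blatant effect so clusters exist
        sel = (fix["start_position"] == "left")
        fix.loc[sel, "x"] += 3.0
        spec = PermutationSpec(n_iterations=200, n_cluster_maps=50)
        r = run_contrast(fix, "left", "right", grid, spec, seed=3)
        mask_flat = r.mask.ravel()
        for row in r.clusters.itertuples():
            assert len(set(mask_flat[row.pixels])) == 1
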