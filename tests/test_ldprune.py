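"""Windowed LD pruning: r^2, greedy pruning, threshold search, spacing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tetrapanel import io as tio
from tetrapanel import ldprune as lp
from tetrapanel.errors import UndefinedStatisticError, UnreachableTargetError

from conftest import random_dosage_matrix


def greedy_prune_oracle(X, maf, threshold):
    """Exhaustive single-window greedy pruning, recomputed from scratch.

    Mirrors the removal contract: resolve the highest-r^2 offending pair
    first, dropping the lower-MAF member (tie: later in map order), until no
    pair exceeds the threshold.
    """
    alive = list(range(X.shape[1]))
    while True:
        worst, pair = threshold, None
        for ii, a in enumerate(alive):
            for b in alive[ii + 1:]:
                ok = np.isfinite(X[:, a]) & np.isfinite(X[:, b])
                if ok.sum() < 2:
                    continue
                xa, xb = X[ok, a], X[ok, b]
                if xa.std() == 0 or xb.std() == 0:
                    continue
                r2 = stats.pearsonr(xa, xb)[0] ** 2
                if r2 > worst:
                    worst, pair = r2, (a, b)
        if pair is None:
            return alive
        a, b = pair
        if (maf[a], -a) < (maf[b], -b):
            alive.remove(a)
        else:
            alive.remove(b)


class TestPairwiseR2:
    def test_self_correlation_is_one(self):
        x = np.array([0., 1, 2, 1, 0, 2])
        assert lp.pairwise_r2(x, x) == pytest.approx(1.0)

    def test_orthogonal_codes(self):
        assert lp.pairwise_r2([0, 1, 2, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_matches_independent_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            x = rng.integers(0, 3, size=20).astype(float)
            y = rng.integers(0, 3, size=20).astype(float)
            if x.std() == 0 or y.std() == 0:
                continue
            expected = stats.pearsonr(x, y)[0] ** 2
            assert lp.pairwise_r2(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_vector_gives_zero(self):
        assert lp.pairwise_r2([1, 1, 1, 1], [0, 1, 2, 0]) == 0.0

    def test_too_few_complete_pairs(self):
        x = np.array([1.0, np.nan, np.nan])
        y = np.array([0.0, 1.0, 2.0])
        with pytest.raises(UndefinedStatisticError):
            lp.pairwise_r2(x, y)

    def test_r2_matrix_matches_scalar(self):
        rng = np.random.default_rng(1)
        X = rng.integers(0, 3, size=(30, 8)).astype(float)
        X[rng.random(X.shape) < 0.15] = np.nan
        R = lp.r2_matrix(X)
        for a in range(8):
            for b in range(8):
                ok = np.isfinite(X[:, a]) & np.isfinite(X[:, b])
                if ok.sum() < 2:
                    continue
                assert R[a, b] == pytest.approx(
                    lp.pairwise_r2(X[:, a], X[:, b]), abs=1e-10)


class TestPruneChromosome:
    def test_orthogonal_markers_all_retained(self):
        X = np.eye(8)  # pairwise r^2 well below any positive threshold
        ids = [f"m{j}" for j in range(8)]
        out = lp.prune_chromosome(X, ids, lp.PruneParams(50, 10, 0.5))
        assert out == ids

    def test_identical_columns_collapse_to_one(self):
        col = np.array([0., 1, 2, 1, 0, 2, 1, 1])
        X = np.column_stack([col, col, col])
        out = lp.prune_chromosome(X, ["a", "b", "c"],
                                  lp.PruneParams(50, 10, 0.5))
        assert len(out) == 1

    def test_threshold_one_retains_all(self):
        rng = np.random.default_rng(2)
        X = rng.integers(0, 3, size=(40, 30)).astype(float)
        ids = [f"m{j}" for j in range(30)]
        out = lp.prune_chromosome(X, ids, lp.PruneParams(50, 10, 1.0))
        assert out == ids

    @pytest.mark.parametrize("seed", range(8))
    def test_single_window_equals_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_mark = int(rng.integers(5, 45))
        base = rng.integers(0, 3, size=(40, n_mark)).astype(float)
        # duplicate some columns with noise to create strong LD
        for j in range(1, n_mark):
            if rng.random() < 0.4:
                base[:, j] = base[:, j - 1]
                flip = rng.random(40) < 0.1
                base[flip, j] = rng.integers(0, 3, size=flip.sum())
        maf = np.minimum(base.mean(0) / 2, 1 - base.mean(0) / 2)
        ids = [f"m{j}" for j in range(n_mark)]
        thr = float(rng.uniform(0.1, 0.7))
        got = lp.prune_chromosome(base, ids, lp.PruneParams(50, 10, thr), maf)
        expected = [ids[j] for j in greedy_prune_oracle(base, maf, thr)]
        assert got == expected

    @pytest.mark.parametrize("seed", range(4))
    def test_exit_condition_multi_window(self, seed):
        rng = np.random.default_rng(100 + seed)
        n_mark = 150
        X = rng.integers(0, 3, size=(40, n_mark)).astype(float)
        for j in range(1, n_mark):
            if rng.random() < 0.5:
                X[:, j] = X[:, j - 1]
                flip = rng.random(40) < 0.15
                X[flip, j] = rng.integers(0, 3, size=flip.sum())
        ids = [f"m{j}" for j in range(n_mark)]
        params = lp.PruneParams(50, 10, 0.3)
        kept = lp.prune_chromosome(X, ids, params)
        kept_idx = [ids.index(m) for m in kept]
        Y = X[:, kept_idx]
        # re-slide the same windows over the retained set: no offending pair
        for start in range(0, len(kept_idx), params.step_snps):
            win = Y[:, start:start + params.window_snps]
            if win.shape[1] < 2:
                continue
            R = lp.r2_matrix(win)
            np.fill_diagonal(R, 0.0)
            assert R.max() <= params.r2_threshold + 1e-9

    def test_empty_chromosome(self):
        out = lp.prune_chromosome(np.empty((10, 0)), [],
                                  lp.PruneParams(50, 10, 0.5))
        assert out == []


class TestPruneGenome:
    def test_pruning_never_crosses_chromosomes(self):
        col = np.array([0., 1, 2, 1, 0, 2, 1, 1])
        X = np.column_stack([col, col])
        g = tio.DosageMatrix([f"s{i}" for i in range(8)], ["a", "b"], X,
                             ploidy=2)
        mm = pd.DataFrame({"marker": ["a", "b"], "chrom": ["1", "2"],
                           "pos_bp": [100, 100]})
        sub = lp.prune_genome(g, mm, lp.PruneParams(50, 10, 0.5),
                              np.array([0.3, 0.3]))
        assert sorted(sub.retained_marker_ids) == ["a", "b"]
        assert sub.per_chrom_counts == {"1": 1, "2": 1}

    def test_genome_is_union_of_per_chrom_prunes(self):
        rng = np.random.default_rng(3)
        g = random_dosage_matrix(rng, 30, 60, ploidy=2)
        chroms = ["1"] * 20 + ["2"] * 20 + ["3"] * 20
        mm = pd.DataFrame({"marker": g.marker_ids, "chrom": chroms,
                           "pos_bp": list(range(1, 21)) * 3})
        maf = tio.maf(g)
        params = lp.PruneParams(50, 10, 0.4)
        sub = lp.prune_genome(g, mm, params, maf)
        expected = []
        for chrom in ("1", "2", "3"):
            ids = [m for m, c in zip(g.marker_ids, chroms) if c == chrom]
            idx = g.marker_index(ids)
            expected.extend(lp.prune_chromosome(
                g.dosages[:, idx], ids, params, maf[idx]))
        assert sorted(sub.retained_marker_ids) == sorted(expected)


class TestTargetSearch:
    def test_target_equal_total_needs_no_pruning(self, filtered_genotypes,
                                                 study_sim):
        dip = tio.diploidize(filtered_genotypes)
        thr, sub = lp.subset_for_target_size(
            dip, study_sim.marker_map, dip.n_markers)
        assert sub.size == dip.n_markers

    def test_unreachable_target_reports_floor(self):
        col = np.array([0., 1, 2, 1, 0, 2, 1, 1])
        X = np.column_stack([col] * 10)
        g = tio.DosageMatrix([f"s{i}" for i in range(8)],
                             [f"m{j}" for j in range(10)], X, ploidy=2)
        mm = pd.DataFrame({"marker": g.marker_ids, "chrom": "1",
                           "pos_bp": range(1, 11)})
        # ten identical markers collapse to 1 at threshold 0; target 1 works
        thr, sub = lp.subset_for_target_size(g, mm, 1)
        assert 1 <= sub.size <= 2

    def test_target_below_floor_is_error(self, small_sim):
        g = tio.filter_maf(tio.filter_missingness(small_sim.genotypes))
        dip = tio.diploidize(g)
        floor = lp.prune_genome(dip, small_sim.marker_map,
                                lp.PruneParams(50, 10, 0.0)).size
        if floor > 1:
            with pytest.raises(UnreachableTargetError) as exc:
                lp.subset_for_target_size(dip, small_sim.marker_map, 1)
            assert exc.value.floor_size == floor


class TestSpacing:
    def test_mean_of_successive_gaps(self):
        mm = pd.DataFrame({"marker": ["a", "b", "c", "d"],
                           "chrom": ["1", "1", "1", "2"],
                           "pos_bp": [100, 200, 400, 50]})
        sub = lp.PanelSubset(["a", "b", "c", "d"], lp.PruneParams())
        rep = lp.spacing_report(sub, mm)
        assert rep["1"] == pytest.approx(150.0)
        assert np.isnan(rep["2"])   # single retained marker: undefined

    def test_stricter_threshold_widens_spacing(self, filtered_genotypes,
                                               study_sim):
        dip = tio.diploidize(filtered_genotypes)
        maf = tio.maf(filtered_genotypes)
        loose = lp.prune_genome(dip, study_sim.marker_map,
                                lp.PruneParams(50, 10, 0.6), maf)
        strict = lp.prune_genome(dip, study_sim.marker_map,
                                 lp.PruneParams(50, 10, 0.1), maf)
        sp_loose = lp.spacing_report(loose, study_sim.marker_map)
        sp_strict = lp.spacing_report(strict, study_sim.marker_map)
        both = sp_loose.dropna().index.intersection(sp_strict.dropna().index)
        assert (sp_strict[both] >= sp_loose[both]).mean() > 0.9

    def test_subset_file_roundtrip(self, tmp_path):
        sub = lp.PanelSubset(["a", "b", "c"], lp.PruneParams(50, 10, 0.25))
        path = tmp_path / "subset.txt"
        sub.write(path)
        back = lp.PanelSubset.read(path)
        assert back.retained_marker_ids == sub.retained_marker_ids
        assert back.params == sub.params
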