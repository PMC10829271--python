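"""Simulator: component bookkeeping, NB moments, doublets, down-sampling."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from demux2kit import (
    SimulationConfig,
    downsample_cells,
    downsample_reads,
    make_doublets,
    simulate_tags,
    zero_inflate,
)


class TestSimulateTags:
    def test_noise_free_limit_is_pure_staining(self):
        cfg = SimulationConfig(
            n_tags=3,
            contamination_range=(0.0, 0.0),
            ambient_range=(0.0, 0.0),
            doublet_fraction=0.0,
            zero_inflation_lambda=None,
            seed=1,
        )
        matrix, truth = simulate_tags(cfg)
        counts = np.asarray(matrix.counts.todense())
        np.testing.assert_array_equal(counts, truth.x_true)
        # every cell positive for exactly one tag
        assert np.all((counts > 0).sum(axis=1) == 1)

    def test_component_conservation_including_doublets(self):
        cfg = SimulationConfig(
            n_tags=5, doublet_fraction=0.15, zero_inflation_lambda=None, seed=2
        )
        matrix, truth = simulate_tags(cfg)
        np.testing.assert_array_equal(
            np.asarray(matrix.counts.todense()), truth.components_sum()
        )

    def test_cell_bound_contamination_mean_follows_fraction(self):
        # contamination of a negative cell ~ NB(p * N_total, theta):
        # law of large numbers on the stated mean
        cfg = SimulationConfig(
            n_tags=2,
            cells_per_tag_meanlog=8.6,  # ~5000 cells, capped
            cells_per_tag_sdlog=0.01,
            contamination_range=(0.05, 0.05),
            ambient_range=(0.0, 0.0),
            doublet_fraction=0.0,
            zero_inflation_lambda=None,
            seed=3,
        )
        matrix, truth = simulate_tags(cfg)
        own = truth.x_true.sum(axis=1).astype(float)
        tag0 = np.array(truth.labels, dtype=object) == truth.tag_names[0]
        # cells of tag 1 are negative for tag 0
        contam = truth.c_cell_bound[~tag0, 0]
        n_tot = own[~tag0]
        expect = 0.05 * n_tot.mean()
        theta = truth.tag_params["theta"][0]
        mu = 0.05 * n_tot
        se = np.sqrt(np.sum(mu + mu**2 / theta)) / len(mu)
        assert abs(contam.mean() - expect) < 3 * se

    def test_ambient_only_column_means(self):
        cfg = SimulationConfig(
            n_tags=3,
            cells_per_tag_meanlog=8.6,
            cells_per_tag_sdlog=0.01,
            contamination_range=(0.0, 0.0),
            ambient_range=(2.0, 6.0),
            doublet_fraction=0.0,
            zero_inflation_lambda=None,
            seed=4,
        )
        matrix, truth = simulate_tags(cfg)
        M = truth.tag_params["ambient"]
        theta = truth.tag_params["theta"]
        n = truth.c_ambient.shape[0]
        for k in range(3):
            se = np.sqrt((M[k] + M[k] ** 2 / theta[k]) / n)
            assert abs(truth.c_ambient[:, k].mean() - M[k]) < 3 * se

    def test_nb_component_moments(self):
        cfg = SimulationConfig(
            n_tags=2,
            cells_per_tag_meanlog=8.6,
            cells_per_tag_sdlog=0.01,
            contamination_range=(0.0, 0.0),
            ambient_range=(10.0, 10.0),
            theta_range=(4.0, 4.0),
            doublet_fraction=0.0,
            zero_inflation_lambda=None,
            seed=5,
        )
        _, truth = simulate_tags(cfg)
        col = truth.c_ambient[:, 0].astype(float)
        # variance mu + mu^2/theta = 10 + 100/4 = 35
        assert col.mean() == pytest.approx(10.0, rel=0.05)
        assert col.var() == pytest.approx(35.0, rel=0.15)

    def test_same_seed_bitwise_identical(self):
        cfg = SimulationConfig(n_tags=4, seed=6)
        m1, t1 = simulate_tags(cfg)
        m2, t2 = simulate_tags(cfg)
        assert (m1.counts != m2.counts).nnz == 0
        np.testing.assert_array_equal(t1.x_true, t2.x_true)
        assert t1.labels == t2.labels

    def test_different_seeds_same_distribution(self):
        # hold the per-tag parameters fixed (degenerate ranges) so that two
        # seeds differ only in cell-level sampling; per-droplet totals are
        # then draws from one distribution
        base = dict(
            n_tags=6,
            staining_logmean_range=(6.0, 6.0),
            theta_range=(4.0, 4.0),
            contamination_range=(0.01, 0.01),
            ambient_range=(2.0, 2.0),
            doublet_fraction=0.0,
            zero_inflation_lambda=None,
        )
        _, t1 = simulate_tags(SimulationConfig(**base, seed=101))
        _, t2 = simulate_tags(SimulationConfig(**base, seed=202))
        a = t1.components_sum().sum(axis=1)
        b = t2.components_sum().sum(axis=1)
        _, p = stats.kstest(np.log(a), np.log(b))
        assert p > 0.01

    def test_infeasible_bounds_rejected(self):
        with pytest.raises(ValueError, match="out of order"):
            SimulationConfig(theta_range=(10.0, 2.0))
        with pytest.raises(ValueError, match="doublet_fraction"):
            SimulationConfig(doublet_fraction=0.6)


class TestDoublets:
    @pytest.fixture()
    def singlets(self, rng):
        n, k = 400, 3
        x = np.zeros((n, k), dtype=np.int64)
        labels = []
        for i in range(n):
            j = i % k
            x[i, j] = rng.integers(100, 500)
            labels.append(f"t{j}")
        cb = rng.poisson(3.0, (n, k)).astype(np.int64)
        return x, cb, labels

    @staticmethod
    def sampler(n):
        return np.ones((n, 3), dtype=np.int64)

    def test_zero_fraction_is_identity(self, singlets, rng):
        x, cb, labels = singlets
        xt, cbt, amb, labs = make_doublets(x, cb, labels, self.sampler, 0.0, rng)
        np.testing.assert_array_equal(xt, x)
        assert labs == labels

    def test_merged_rows_are_pair_sums(self, singlets, rng):
        x, cb, labels = singlets
        xt, cbt, amb, labs = make_doublets(x, cb, labels, self.sampler, 0.1, rng)
        doublet_rows = [i for i, l in enumerate(labs) if isinstance(l, tuple)]
        assert doublet_rows  # some doublets were made
        for i in doublet_rows:
            # each doublet row must decompose as a sum of two singlet draws:
            # two nonzero x_true entries (or one entry formed by a same-tag pair)
            assert xt[i].sum() > 0
            assert (xt[i] > 0).sum() in (1, 2)
        # ambient drawn once per droplet
        np.testing.assert_array_equal(amb, np.ones_like(amb))

    def test_doublet_count_matches_floor_rule(self, singlets, rng):
        x, cb, labels = singlets
        frac = 0.1
        xt, _, _, labs = make_doublets(x, cb, labels, self.sampler, frac, rng)
        d = sum(isinstance(l, tuple) for l in labs)
        n_final = len(labs)
        assert d == int(np.floor(frac * n_final))
        # singlet bookkeeping: each doublet consumed two singlets
        assert n_final == len(labels) - d

    def test_infeasible_doublet_requests_rejected(self, rng):
        x = np.eye(3, dtype=np.int64)[:1] * 100
        with pytest.raises(ValueError, match="two singlets"):
            make_doublets(x, x * 0, ["a"], self.sampler, 0.4, rng)
        x4 = np.eye(4, dtype=np.int64) * 100
        with pytest.raises(ValueError, match="fraction"):
            make_doublets(x4, x4 * 0, list("abcd"), self.sampler, 0.6, rng)


class TestZeroInflation:
    def test_drop_rates_match_exponential_decay(self, rng):
        # value 1: p0 = exp(-lambda); ~14% at lambda 2, ~61% at lambda 0.5
        n = 200_000
        ones = np.ones((n, 1), dtype=np.int64)
        for lam, expect in [(2.0, np.exp(-2.0)), (0.5, np.exp(-0.5))]:
            dropped = 1 - zero_inflate(ones, lam, rng).mean()
            assert dropped == pytest.approx(expect, abs=0.01)

    def test_large_values_rarely_dropped(self, rng):
        big = np.full((10_000, 1), 10, dtype=np.int64)
        out = zero_inflate(big, 2.0, rng)
        assert (out == 0).mean() < 1e-3  # exp(-200) is negligible

    def test_zeros_stay_zero_and_matrix_path_matches(self, rng):
        arr = np.array([[0, 1], [3, 0]], dtype=np.int64)
        out = zero_inflate(arr, 2.0, np.random.default_rng(0))
        assert out[0, 0] == 0 and out[1, 1] == 0
        assert out[1, 0] in (0, 3)

    def test_nonpositive_lambda_rejected(self, rng):
        with pytest.raises(ValueError, match="positive"):
            zero_inflate(np.ones((2, 2), dtype=np.int64), 0.0, rng)


class TestDownsampling:
    @pytest.fixture()
    def matrix(self):
        import scipy.sparse as sp

        from demux2kit import TagCountMatrix

        counts = np.array([[8, 2], [100, 300], [0, 0]])
        return TagCountMatrix(sp.csr_matrix(counts), ["a", "b", "c"], ["t1", "t2"])

    def test_rate_one_is_identity(self, matrix, rng):
        out = downsample_reads(matrix, rate=1.0, rng=rng)
        assert (out.counts != matrix.counts).nnz == 0

    def test_row_sums_and_hypergeometric_mean(self, rng):
        # cell (8, 2) keeping 5 reads: tag-1 mean 5 * 8/10 = 4,
        # variance 5*(8/10)*(2/10)*(10-5)/(10-1) = 4/9 (Monte-Carlo oracle)
        import scipy.sparse as sp

        from demux2kit import TagCountMatrix

        reps = 20_000
        m = TagCountMatrix(
            sp.csr_matrix(np.tile([8, 2], (reps, 1))),
            [f"c{i}" for i in range(reps)],
            ["t1", "t2"],
        )
        out = np.asarray(downsample_reads(m, target=5, rng=rng).counts.todense())
        assert np.all(out.sum(axis=1) == 5)
        se = np.sqrt(4 / 9 / reps)
        assert out[:, 0].mean() == pytest.approx(4.0, abs=4 * se)

    def test_target_exceeding_total_errors(self, matrix, rng):
        with pytest.raises(ValueError, match="exceeds"):
            downsample_reads(matrix, target=11, rng=rng)

    def test_keep_zero_rate_rejected(self, matrix, rng):
        with pytest.raises(ValueError, match="rate"):
            downsample_reads(matrix, rate=0.0, rng=rng)

    def test_downsample_cells_alignment(self, rng):
        cfg = SimulationConfig(n_tags=3, seed=9)
        matrix, truth = simulate_tags(cfg)
        sub, sub_truth = downsample_cells(matrix, truth, 100, rng=rng)
        assert sub.n_cells == 100 and len(sub_truth.labels) == 100
        assert sub.cell_barcodes == sub_truth.cell_barcodes

    def test_downsample_cells_keep_all_identity(self, rng):
        cfg = SimulationConfig(n_tags=3, seed=9)
        matrix, truth = simulate_tags(cfg)
        sub, _ = downsample_cells(matrix, truth, matrix.n_cells, rng=rng)
        assert sub.n_cells == matrix.n_cells

    def test_classification_survives_cell_downsampling(self, moderate_sim, rng):
        """F-score within 0.02 of full data when keeping 5% of cells."""
        from demux2kit import ClassifyConfig, demultiplex, evaluate

        matrix, truth = moderate_sim
        full = demultiplex(matrix, ClassifyConfig(seed=5))
        f_full = evaluate(truth.eval_labels(), full.calls, truth.tag_names).macro_f
        sub, sub_truth = downsample_cells(matrix, truth, 0.05, rng=rng)
        small = demultiplex(sub, ClassifyConfig(seed=5))
        f_small = evaluate(
            sub_truth.eval_labels(), small.calls, sub_truth.tag_names
        ).macro_f
        assert abs(f_full - f_small) <= 0.02
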