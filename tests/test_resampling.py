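import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import rusmote as rm
from rusmote.resampling import _undersample_indices


def _dataset(minority, majority):
    X = np.vstack([minority, majority])
    y = np.concatenate([np.ones(len(minority), int), -np.ones(len(majority), int)])
    names = tuple(f"f{i}" for i in range(X.shape[1]))
    return rm.LabeledDataset(X, y, names)


class TestClassGeometry:
    def test_symmetric_pair(self):
        ds = _dataset([(0.0, 0.0), (2.0, 0.0)], [(5.0, 5.0), (7.0, 5.0)])
        g = rm.compute_class_geometry(ds)
        np.testing.assert_allclose(g.center_min, [1.0, 0.0])
        assert g.r_ave_min == pytest.approx(1.0)
        np.testing.assert_allclose(g.center_maj, [6.0, 5.0])
        assert g.r_ave_maj == pytest.approx(1.0)

    def test_singleton_class_has_zero_radius(self):
        ds = _dataset([(3.0, 4.0)], [(0.0, 0.0), (1.0, 1.0)])
        g = rm.compute_class_geometry(ds)
        assert g.r_ave_min == 0.0
        assert g.n_min == 1

    def test_matches_brute_force(self):
        rng = np.random.default_rng(7)
        minority = rng.standard_normal((80, 5))
        majority = rng.standard_normal((120, 5)) + 2.0
        ds = _dataset(minority, majority)
        g = rm.compute_class_geometry(ds)
        # explicit per-sample loop
        c = sum(row for row in minority) / len(minority)
        r = sum(math.dist(row, c) for row in minority) / len(minority)
        np.testing.assert_allclose(g.center_min, c, atol=1e-12)
        assert g.r_ave_min == pytest.approx(r, abs=1e-12)

    def test_empty_class_rejected(self):
        X = np.ones((3, 2))
        ds = rm.LabeledDataset(X, [1, 1, 1], ("a", "b"))
        with pytest.raises(ValueError):
            rm.compute_class_geometry(ds)


class TestBoundaryNoise:
    def test_well_separated_clusters_have_none(self, separated_dataset):
        assert rm.detect_boundary_noise(separated_dataset) == []

    def test_hand_built_intruder_flagged(self):
        # 19 majority points on the unit circle around (10, 0); 1 majority
        # point inside the minority cloud at the origin, farthest from the
        # majority center.  Verified against direct distance computation.
        angles = np.linspace(0, 2 * np.pi, 19, endpoint=False)
        ring = np.column_stack([10 + np.cos(angles), np.sin(angles)])
        intruder = np.array([[0.5, 0.0]])
        majority = np.vstack([ring, intruder])
        minority = np.array([[0.0, 1.0], [0.0, -1.0], [1.0, 0.0], [-1.0, 0.0]])
        ds = _dataset(minority, majority)
        g = rm.compute_class_geometry(ds)
        # brute-force check of the two clauses for the intruder
        d_maj = np.linalg.norm(majority - g.center_maj, axis=1)
        assert np.argmax(d_maj) == 19
        assert np.linalg.norm(intruder[0] - g.center_min) < g.r_ave_min
        flagged = rm.detect_boundary_noise(ds, g)
        assert flagged == [len(minority) + 19]

    def test_cap_and_majority_only(self):
        rng = np.random.default_rng(3)
        ds = _dataset(rng.standard_normal((40, 3)),
                      rng.standard_normal((100, 3)) * 3.0)
        flagged = rm.detect_boundary_noise(ds)
        assert len(flagged) <= math.ceil(0.05 * 100)
        assert all(ds.labels[i] == -1 for i in flagged)


class TestRandomUndersample:
    def test_reference_count_454_to_227(self):
        rng = np.random.default_rng(0)
        out = rm.random_undersample(rng.standard_normal((454, 8)), 1)
        assert len(out) == 227

    def test_zero_rounds_is_identity(self):
        X = np.arange(12.0).reshape(6, 2)
        np.testing.assert_array_equal(rm.random_undersample(X, 0), X)

    @given(m=st.integers(1, 600), n=st.integers(0, 4))
    @settings(max_examples=60, deadline=None)
    def test_output_size_law(self, m, n):
        X = np.linspace(0, 1, m)[:, None] * np.ones((1, 2))
        expect = m
        for _ in range(n):
            expect = math.ceil(expect / 2)
        assert len(rm.random_undersample(X, n)) == expect

    def test_rows_are_a_subset(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((101, 4))
        out = rm.random_undersample(X, 2)
        rows = {tuple(r) for r in X}
        assert all(tuple(r) in rows for r in out)

    def test_distribution_preserved_mean_var(self):
        # two-component mixture, 1e5 samples, two halving passes: retained
        # moments match the originals within 3 standard errors
        rng = np.random.default_rng(9)
        comp = rng.random(100_000) < 0.5
        X = np.where(comp[:, None], rng.normal(0, 1, (100_000, 2)),
                     rng.normal(4, 0.5, (100_000, 2)))
        Y = rm.random_undersample(X, 2)
        assert len(Y) == 25_000
        for j in range(2):
            se_mean = X[:, j].std() / math.sqrt(len(Y))
            assert abs(Y[:, j].mean() - X[:, j].mean()) < 3 * se_mean
            # variance SE via the fourth moment
            m4 = np.mean((X[:, j] - X[:, j].mean()) ** 4)
            se_var = math.sqrt((m4 - X[:, j].var() ** 2) / len(Y))
            assert abs(Y[:, j].var() - X[:, j].var()) < 3 * se_var

    def test_distribution_preserved_ks(self):
        # seed-averaged two-sample KS at significance 0.01 on 1e4 samples
        pvals = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            comp = rng.integers(0, 2, 10_000).astype(bool)
            X = np.where(comp[:, None], rng.normal(0, 1, (10_000, 2)),
                         rng.normal(3, 0.5, (10_000, 2)))
            Y = rm.random_undersample(X, 1)
            pvals += [stats.ks_2samp(X[:, j], Y[:, j]).pvalue for j in range(2)]
        assert np.mean(pvals) > 0.01
        assert min(pvals) > 0.01


class TestSmote:
    @pytest.mark.parametrize("amplification,expected", [(5, 375), (3, 225), (1, 75)])
    def test_counting_rule(self, amplification, expected):
        rng = np.random.default_rng(2)
        out, prov = rm.smote_oversample(rng.standard_normal((75, 8)), 5,
                                        amplification, seed=0)
        assert len(out) == expected
        assert len(prov) == (amplification - 1) * 75

    def test_amplification_one_returns_originals_only(self):
        X = np.arange(10.0).reshape(5, 2)
        out, prov = rm.smote_oversample(X, 3, 1, seed=0)
        np.testing.assert_array_equal(out, X)
        assert len(prov) == 0

    def test_provenance_replay(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((40, 6))
        out, prov = rm.smote_oversample(X, 4, 4, seed=12)
        synth = out[40:]
        base = X[prov.base_index]
        neigh = X[prov.neighbor_index]
        rebuilt = base + prov.delta[:, None] * (neigh - base)
        assert np.max(np.abs(synth - rebuilt)) < 1e-10
        assert np.all((prov.delta >= 0) & (prov.delta <= 1))

    def test_neighbors_are_among_k_nearest(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((30, 3))
        k = 3
        _, prov = rm.smote_oversample(X, k, 3, seed=7)
        d = np.linalg.norm(X[:, None] - X[None], axis=-1)
        np.fill_diagonal(d, np.inf)
        for b, t in zip(prov.base_index, prov.neighbor_index):
            assert t != b
            assert d[b, t] <= np.sort(d[b])[k - 1] + 1e-12

    def test_k_clamped_with_warning(self):
        X = np.arange(8.0).reshape(4, 2)
        with pytest.warns(UserWarning, match="k_neighbors"):
            out, _ = rm.smote_oversample(X, 10, 2, seed=0)
        assert len(out) == 8

    def test_too_few_minority_rejected(self):
        with pytest.raises(ValueError):
            rm.smote_oversample(np.ones((1, 2)), 3, 2, seed=0)


class TestParameterSelection:
    @pytest.mark.parametrize("ratio,ru,k", [(6, 2, 3), (10, 2, 5), (20, 4, 5)])
    def test_reference_settings(self, ratio, ru, k):
        p = rm.select_balance_parameters(75 * ratio, 75)
        assert p.ru == ru
        assert p.k_neighbors == k

    def test_constraints_hold_across_ratios(self):
        for n_maj in range(30, 1200, 37):
            p = rm.select_balance_parameters(n_maj, 30)
            assert p.ru >= 2
            assert 3 <= p.k_neighbors <= 6
            assert p.amplification >= 1

    def test_tiny_minority_rejected(self):
        with pytest.raises(ValueError):
            rm.select_balance_parameters(100, 1)


class TestBalance:
    def test_reference_counts_225_227(self, separated_dataset):
        params = rm.ResampleParams(ru_rounds=1, k_neighbors=3, amplification=3)
        out = rm.balance(separated_dataset, params, seed=17)
        assert out.n_minority == 225
        assert out.n_majority == 227

    def test_identity_when_parameters_are_neutral(self, separated_dataset):
        params = rm.ResampleParams(ru_rounds=0, k_neighbors=3, amplification=1)
        out = rm.balance(separated_dataset, params, seed=3)
        assert sorted(out.sample_ids) == sorted(separated_dataset.sample_ids)
        orig = dict(zip(separated_dataset.sample_ids, separated_dataset.features))
        for sid, row in zip(out.sample_ids, out.features):
            np.testing.assert_array_equal(row, orig[sid])

    def test_counts_compose_from_suboperations(self):
        # output counts equal N*n_min and ceil((n_maj - #noise)/2^ru) across
        # random datasets, with the noise count recomputed independently
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n_min = int(rng.integers(10, 40))
            n_maj = int(rng.integers(60, 200))
            spec = rm.GeneratorSpec(n_min, n_maj, dim=4,
                                    separation=float(rng.uniform(1, 4)),
                                    seed=seed)
            ds = rm.make_gaussian_imbalanced(spec)
            params = rm.ResampleParams(ru_rounds=1, k_neighbors=3, amplification=2)
            out, report = rm.balance(ds, params, seed=seed, return_report=True)
            n_noise = len(report.noise_indices)
            assert out.n_minority == 2 * n_min
            assert out.n_majority == math.ceil((n_maj - n_noise) / 2)
            # noise recomputed on the standardized copy used by balance
            Z = (ds.features - ds.features.mean(0)) / ds.features.std(0)
            zds = rm.LabeledDataset(Z, ds.labels, ds.feature_names, ds.sample_ids)
            assert list(report.noise_indices) == rm.detect_boundary_noise(zds)

    def test_deterministic_bit_for_bit(self, separated_dataset):
        params = rm.ResampleParams(ru_rounds=1, k_neighbors=3, amplification=3)
        a = rm.balance(separated_dataset, params, seed=5)
        b = rm.balance(separated_dataset, params, seed=5)
        assert a.features.tobytes() == b.features.tobytes()
        assert a.sample_ids == b.sample_ids

    @pytest.mark.parametrize("ratio", [6, 10, 20])
    def test_auto_balance_near_parity_at_reference_ratios(self, ratio):
        spec = rm.GeneratorSpec(50, 50 * ratio, separation=8.0, seed=ratio)
        out = rm.balance(rm.make_gaussian_imbalanced(spec), "auto", seed=1)
        n1, n2 = out.n_minority, out.n_majority
        assert abs(n1 - n2) / max(n1, n2) <= 0.15

    def test_auto_balance_ratio_bounded(self):
        for ratio in (1.5, 2, 3, 5, 8, 13, 20):
            spec = rm.GeneratorSpec(40, round(40 * ratio), separation=8.0,
                                    seed=int(ratio * 10))
            out = rm.balance(rm.make_gaussian_imbalanced(spec), "auto", seed=2)
            q = out.n_minority / out.n_majority
            assert 0.5 <= q <= 2.0
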