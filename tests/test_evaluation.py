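import numpy as np
import pytest
from scipy import stats

from swdeeg.clustering import kmeans_groups
from swdeeg.evaluation import (MetricsError, binary_metrics, group_band_power,
                               mann_whitney_u, multiclass_metrics, rank_auc)
from swdeeg.montage import generate_layout
from swdeeg.simulate import SimulationConfig, generate_dataset


class TestBinaryMetrics:
    def test_perfect_separation(self):
        rep = binary_metrics([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert rep.accuracy == rep.precision == rep.recall == rep.auc == 1.0
        assert rep.confusion.sum() == pytest.approx(100.0)
        assert np.trace(rep.confusion) == pytest.approx(100.0)

    def test_worked_auc_case(self):
        # 4 positive-negative pairs, 3 correctly ordered -> AUC 0.75
        rep = binary_metrics([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])
        assert rep.auc == pytest.approx(0.75)

    def test_random_scores_give_half_auc(self, rng):
        y = rng.integers(0, 2, 4000)
        s = rng.random(4000)
        rep = binary_metrics(y, s)
        assert rep.auc == pytest.approx(0.5, abs=0.05)
        assert rep.accuracy == pytest.approx(0.5, abs=0.05)

    def test_single_class_auc_undefined(self):
        with pytest.raises(MetricsError):
            binary_metrics([1, 1, 1], [0.5, 0.6, 0.7])

    def test_ties_counted_half(self):
        assert rank_auc(np.array([1, 0]), np.array([0.5, 0.5])) == 0.5


class TestRankVsTrapezoid:
    def test_agreement_to_1e10_on_random_instances(self, rng):
        from sklearn.metrics import roc_curve
        for _ in range(100):
            n = int(rng.integers(10, 80))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0] = 1 - y[0]
            s = np.round(rng.random(n), 2)  # ties on purpose
            fpr, tpr, _ = roc_curve(y, s)
            trap = np.trapezoid(tpr, fpr)
            assert abs(rank_auc(y, s) - trap) < 1e-10


class TestMulticlassMetrics:
    def test_perfect_classifier(self):
        y = np.array([0, 1, 2, 3])
        scores = np.eye(4)[y] * 0.96 + 0.01
        rep = multiclass_metrics(y, scores)
        assert rep.accuracy == rep.precision == rep.recall == 1.0
        assert rep.auc == 1.0 and len(rep.per_class_auc) == 4
        assert np.trace(rep.confusion) == pytest.approx(100.0)

    def test_uniform_scores_near_chance(self, rng):
        n = 4000
        y = rng.integers(0, 4, n)
        raw = rng.random((n, 4))
        scores = raw / raw.sum(axis=1, keepdims=True)
        rep = multiclass_metrics(y, scores)
        assert rep.accuracy == pytest.approx(0.25, abs=0.05)
        assert rep.auc == pytest.approx(0.5, abs=0.05)

    def test_three_instance_macro_oracle(self):
        # y = [0, 1, 1]; argmax predictions = [0, 0, 1]
        # class 0: tp=1 fp=1 fn=0 -> P=1/2, R=1
        # class 1: tp=1 fp=0 fn=1 -> P=1,   R=1/2
        # classes 2, 3 never occur/predicted -> P=R=0
        y = np.array([0, 1, 1])
        scores = np.array([[0.7, 0.1, 0.1, 0.1],
                           [0.6, 0.2, 0.1, 0.1],
                           [0.1, 0.7, 0.1, 0.1]])
        with pytest.warns(UserWarning):
            rep = multiclass_metrics(y, scores)
        assert rep.precision == pytest.approx((0.5 + 1.0 + 0 + 0) / 4)
        assert rep.recall == pytest.approx((1.0 + 0.5 + 0 + 0) / 4)
        assert rep.accuracy == pytest.approx(2 / 3)

    def test_unnormalized_rows_rejected(self):
        with pytest.raises(MetricsError):
            multiclass_metrics([0, 1], np.array([[0.9, 0.9, 0, 0],
                                                 [0.25, 0.25, 0.25, 0.25]]))


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1, abs=0.01)  # 2/C(6,3)

    def test_identical_samples_p_one(self):
        u, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_small_sample_worked_example(self):
        # pairwise count: pairs (a, b) with a>b: (10,3),(10,5),(10,8),(7,3),(7,5) -> U=5
        u, _ = mann_whitney_u([10, 7], [3, 5, 8])
        assert u == 5.0

    def test_u_matches_pairwise_counting_for_all_small_sizes(self, rng):
        for n1 in range(1, 9):
            for n2 in range(1, 9):
                a = rng.integers(0, 6, n1).astype(float)
                b = rng.integers(0, 6, n2).astype(float)
                u, _ = mann_whitney_u(a, b)
                brute = sum(1.0 if x > y else 0.5 if x == y else 0.0
                            for x in a for y in b)
                assert u == pytest.approx(brute)

    def test_exact_p_matches_scipy_without_ties(self, rng):
        for _ in range(20):
            a = rng.standard_normal(6)
            b = rng.standard_normal(7) + rng.uniform(-1, 1)
            _, p = mann_whitney_u(a, b)
            p_ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                       method="exact").pvalue
            assert p == pytest.approx(float(p_ref), abs=1e-12)

    def test_large_sample_uses_normal_approximation(self, rng):
        a = rng.standard_normal(30)
        b = rng.standard_normal(25) + 1.0
        _, p = mann_whitney_u(a, b)
        p_ref = stats.mannwhitneyu(a, b, alternative="two-sided",
                                   method="asymptotic").pvalue
        assert p == pytest.approx(float(p_ref))

    def test_empty_sample_rejected(self):
        with pytest.raises(MetricsError):
            mann_whitney_u([], [1.0])


@pytest.fixture(scope="module")
def setup():
    layout = generate_layout(24, seed=3)
    cfg = SimulationConfig(n_subjects=3, trials_per_class=2, n_channels=24,
                           n_samples=128, seed=8)
    ds = generate_dataset(cfg, layout)
    return layout, ds, kmeans_groups(layout)


class TestGroupBandPower:
    def test_shape_and_positivity(self, setup):
        _, ds, asg = setup
        power = group_band_power(ds, asg)
        assert power.shape == (3, 19)
        assert np.all(power > 0)

    def test_quadratic_amplitude_scaling(self, setup):
        _, ds, asg = setup
        import copy
        ds2 = copy.deepcopy(ds)
        for i, s in enumerate(ds2.subject_ids):
            if s == 0:
                ds2.trials[i] = ds2.trials[i].replace(ds2.trials[i].data * 2.0)
        p1 = group_band_power(ds, asg)
        p2 = group_band_power(ds2, asg)
        np.testing.assert_allclose(p2[0], 4.0 * p1[0], rtol=1e-10)
        np.testing.assert_allclose(p2[1:], p1[1:], rtol=1e-12)

    def test_zero_data_zero_power(self, setup):
        layout, ds, asg = setup
        import copy
        ds0 = copy.deepcopy(ds)
        for i in range(len(ds0.trials)):
            ds0.trials[i].data[:] = 0.0
        assert np.all(group_band_power(ds0, asg) == 0.0)


def test_null_pvalues_uniform_over_repetitions():
    """Gender-style comparison on null data: p-values ~ Uniform(0,1)."""
    layout = generate_layout(19, seed=2)
    asg = kmeans_groups(layout)
    ps = []
    for rep in range(200):
        cfg = SimulationConfig(n_subjects=24, trials_per_class=1,
                               n_channels=19, n_samples=128,
                               effect_scale=0.0, seed=1000 + rep)
        ds = generate_dataset(cfg, layout)
        power = group_band_power(ds, asg)
        g = rep % 19
        _, p = mann_whitney_u(power[:12, g], power[12:, g])
        ps.append(p)
    stat = stats.kstest(ps, "uniform").statistic
    # KS critical value at alpha=0.01 for n=200 is ~0.115
    assert stat < 0.115
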