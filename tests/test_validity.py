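import numpy as np
import pytest
from scipy import stats

from conftest import seg_config
from fcmgwo.fcm import init_membership
from fcmgwo.synth import SyntheticSpec, generate_cell_image
from fcmgwo.validity import (
    ComparisonReport,
    DegenerateTestError,
    UndefinedIndexError,
    calinski_harabasz,
    compare_methods,
    davies_bouldin,
    paired_t_test,
    partition_coefficient,
    partition_entropy,
    two_sided_t_pvalue,
)


def naive_davies_bouldin(X, labels):
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    cents = [X[labels == k].mean(axis=0) for k in uniq]
    scat = [np.mean(np.linalg.norm(X[labels == k] - c, axis=1))
            for k, c in zip(uniq, cents)]
    total = 0.0
    for j in range(len(uniq)):
        worst = max(
            (scat[j] + scat[k]) / np.linalg.norm(cents[j] - cents[k])
            for k in range(len(uniq)) if k != j
        )
        total += worst
    return total / len(uniq)


def naive_calinski_harabasz(X, labels):
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    n, c = X.shape[0], len(uniq)
    grand = X.mean(axis=0)
    B = sum((labels == k).sum() * np.sum((X[labels == k].mean(axis=0) - grand) ** 2)
            for k in uniq)
    W = sum(np.sum((X[labels == k] - X[labels == k].mean(axis=0)) ** 2) for k in uniq)
    return (B / (c - 1)) / (W / (n - c))


class TestPartitionCoefficient:
    def test_crisp_gives_one(self):
        u = np.eye(4)[[0, 1, 2, 3, 0]]
        assert partition_coefficient(u) == pytest.approx(1.0)

    def test_uniform_gives_reciprocal_c(self):
        u = np.full((10, 3), 1 / 3)
        assert partition_coefficient(u) == pytest.approx(1 / 3)

    def test_hand_computed(self):
        u = np.array([[0.8, 0.2], [0.5, 0.5]])
        assert partition_coefficient(u) == pytest.approx(0.59)

    def test_bounds_and_crispness_coupling(self):
        rng = np.random.default_rng(0)
        for _ in range(30):
            u = rng.random((20, 3))
            u /= u.sum(axis=1, keepdims=True)
            vpc = partition_coefficient(u)
            vpe = partition_entropy(u)
            assert 1 / 3 - 1e-12 <= vpc <= 1 + 1e-12
            crisp = np.allclose(np.sort(u, axis=1)[:, :-1], 0.0)
            assert (vpc == pytest.approx(1.0)) == crisp
            assert (vpe == pytest.approx(0.0, abs=1e-12)) == crisp


class TestPartitionEntropy:
    def test_crisp_gives_zero(self):
        assert partition_entropy(np.eye(3)) == pytest.approx(0.0)

    def test_uniform_two_clusters_ln2(self):
        u = np.full((6, 2), 0.5)
        assert partition_entropy(u) == pytest.approx(np.log(2))

    def test_base_c_normalizes_max_to_one(self):
        u = np.full((5, 3), 1 / 3)
        assert partition_entropy(u, log_base=3) == pytest.approx(1.0)


class TestCrispIndices:
    def test_db_worked_instance(self):
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        labels = [0, 0, 1, 1]
        assert davies_bouldin(X, labels) == pytest.approx(0.2)

    def test_db_zero_scatter(self):
        X = np.array([[0.0], [0.0], [10.0], [10.0]])
        assert davies_bouldin(X, [0, 0, 1, 1]) == pytest.approx(0.0)

    def test_ch_worked_instance(self):
        X = np.array([[0.0], [2.0], [10.0], [12.0]])
        assert calinski_harabasz(X, [0, 0, 1, 1]) == pytest.approx(50.0)

    def test_ch_scale_invariant(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(30, 2))
        labels = rng.integers(0, 3, 30)
        assert calinski_harabasz(X, labels) == pytest.approx(
            calinski_harabasz(X * 7.3, labels)
        )

    @pytest.mark.parametrize("fn", [davies_bouldin, calinski_harabasz])
    def test_single_cluster_undefined(self, fn):
        with pytest.raises(UndefinedIndexError):
            fn(np.arange(5.0)[:, None], [0] * 5)

    def test_ch_undefined_when_n_equals_c(self):
        with pytest.raises(UndefinedIndexError):
            calinski_harabasz(np.arange(3.0)[:, None], [0, 1, 2])

    def test_oracle_equivalence_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n, c = int(rng.integers(8, 30)), int(rng.integers(2, 4))
            X = rng.normal(size=(n, 2)) * rng.uniform(0.5, 5)
            labels = rng.integers(0, c, n)
            if np.unique(labels).size < 2:
                continue
            assert davies_bouldin(X, labels) == pytest.approx(
                naive_davies_bouldin(X, labels), rel=1e-9)
            assert calinski_harabasz(X, labels) == pytest.approx(
                naive_calinski_harabasz(X, labels), rel=1e-9)


class TestTTail:
    def test_zero_statistic(self):
        assert two_sided_t_pvalue(0.0, 5) == pytest.approx(1.0)

    def test_monotone_in_abs_t(self):
        ps = [two_sided_t_pvalue(t, 7) for t in np.linspace(0, 6, 25)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invalid_df(self):
        with pytest.raises(ValueError):
            two_sided_t_pvalue(1.0, 0)


class TestPairedT:
    def test_identical_samples(self):
        r = paired_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.t_statistic == 0.0 and r.p_value == pytest.approx(1.0)

    def test_hand_computed_differences(self):
        x = np.array([2.0, 4.0, 6.0, 8.0])
        y = x - np.array([1.0, 2.0, 3.0, 4.0])
        r = paired_t_test(x, y)
        assert r.t_statistic == pytest.approx(2.5 / (np.std([1, 2, 3, 4], ddof=1) / 2))
        assert r.degrees_of_freedom == 3
        # cross-check against scipy's paired t-test
        t_ref, p_ref = stats.ttest_rel(x, y)
        assert r.t_statistic == pytest.approx(t_ref)
        assert r.p_value == pytest.approx(p_ref)

    def test_antisymmetry(self):
        x, y = [1.0, 3.0, 2.0], [0.5, 1.0, 4.0]
        a, b = paired_t_test(x, y), paired_t_test(y, x)
        assert a.t_statistic == pytest.approx(-b.t_statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_zero_variance_nonzero_rejected(self):
        with pytest.raises(DegenerateTestError):
            paired_t_test([2.0, 3.0], [1.0, 2.0])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            paired_t_test([1.0, 2.0], [1.0])


@pytest.fixture(scope="module")
def four_images():
    return [
        generate_cell_image(
            SyntheticSpec(width=80, height=60, n_cells=3,
                          nucleus_radius_range=(3, 4),
                          cytoplasm_radius_range=(6, 8), seed=s)
        )[0]
        for s in range(4)
    ]


class TestCompareMethods:
    def test_reports_have_three_dof(self, four_images):
        reports = compare_methods(four_images, seg_config(seed=0))
        assert set(reports) == {"vpc", "vpe", "db", "ch"}
        for r in reports.values():
            assert r.degrees_of_freedom == 3
            assert 0.0 <= r.p_value <= 1.0
            assert len(r.pairs) == 4

    def test_method_aliasing_gives_null_t(self, four_images):
        reports = compare_methods(four_images[:2], seg_config(seed=0),
                                  methods=("fcm", "fcm"))
        for r in reports.values():
            assert r.t_statistic == 0.0 and r.p_value == pytest.approx(1.0)

    def test_report_json_round_trip(self):
        r = ComparisonReport("vpc", 1.5, 3, 0.23, [(0.9, 0.8), (0.7, 0.6)], 0.4)
        assert ComparisonReport.from_json(r.to_json()) == r
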