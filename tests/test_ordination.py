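"""Distances, isotonic regression, NMDS, and group-distance medians."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform

import phytoarray as pa
from tests.conftest import toy_expression


class TestEuclideanDistances:
    def make_expr(self, values):
        vals = pd.DataFrame(values,
                            columns=[f"s{j}" for j in
                                     range(np.shape(values)[1])])
        det = pd.DataFrame(True, index=vals.index, columns=vals.columns)
        return pa.ExpressionMatrix(vals, det)

    def test_duplicate_samples_zero(self):
        expr = self.make_expr([[1.0, 1.0], [2.0, 2.0]])
        d = pa.euclidean_distances(expr)
        assert d.iloc[0, 1] == 0.0

    def test_three_four_five(self):
        expr = self.make_expr([[0.0, 3.0], [0.0, 4.0]])
        d = pa.euclidean_distances(expr)
        assert d.iloc[0, 1] == pytest.approx(5.0)

    def test_gene_order_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(20, 4))
        a = pa.euclidean_distances(self.make_expr(vals))
        b = pa.euclidean_distances(self.make_expr(vals[::-1]))
        assert np.allclose(a.values, b.values)

    def test_single_sample_rejected(self):
        expr = self.make_expr([[1.0], [2.0]])
        with pytest.raises(ValueError):
            pa.euclidean_distances(expr)


def pava_qp_oracle(y):
    """Quadratic program: minimize ||x - y||^2 s.t. x non-decreasing."""
    y = np.asarray(y, float)
    n = len(y)
    cons = [{"type": "ineq", "fun": (lambda x, i=i: x[i + 1] - x[i])}
            for i in range(n - 1)]
    res = minimize(lambda x: ((x - y) ** 2).sum(), y.copy(),
                   constraints=cons, method="SLSQP",
                   options={"maxiter": 500, "ftol": 1e-12})
    return res.x


class TestMonotoneRegression:
    def test_monotone_input_unchanged(self):
        y = np.array([1.0, 2.0, 2.5, 7.0])
        assert np.allclose(pa.monotone_regression(y), y)

    def test_pooling_arithmetic(self):
        assert np.allclose(pa.monotone_regression([3.0, 1.0, 2.0]),
                           [2.0, 2.0, 2.0])

    def test_matches_qp_oracle_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(100):
            y = rng.normal(size=int(rng.integers(2, 9)))
            assert np.allclose(pa.monotone_regression(y),
                               pava_qp_oracle(y), atol=1e-5)

    def test_respects_supplied_order(self):
        y = np.array([5.0, 1.0, 3.0])
        order = np.array([1, 2, 0])  # fit along y[1], y[2], y[0]
        out = pa.monotone_regression(y, order)
        assert np.all(np.diff(out[order]) >= -1e-12)


class TestNMDS:
    def planar_distance(self, n=12, seed=5):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(n, 2))
        return pd.DataFrame(squareform(pdist(pts)))

    def test_embeddable_configuration_has_near_zero_stress(self):
        res = pa.nmds(self.planar_distance(), dim=2, restarts=5, seed=1)
        assert res.stress < 1e-3

    def test_collinear_points_into_two_dims(self):
        x = np.linspace(0, 5, 8)[:, None]
        d = pd.DataFrame(squareform(pdist(np.hstack([x, 0 * x]))))
        res = pa.nmds(d, dim=2, restarts=5, seed=2)
        assert res.stress < 1e-3

    def test_stress_path_non_increasing(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(15, 5))
        d = pd.DataFrame(squareform(pdist(pts)))
        res = pa.nmds(d, dim=2, restarts=3, seed=3)
        assert all(np.diff(res.stress_path) <= 1e-9)
        assert 0 <= res.stress <= 1

    def test_seeded_reproducibility(self):
        d = self.planar_distance(seed=8)
        a = pa.nmds(d, restarts=4, seed=9)
        b = pa.nmds(d, restarts=4, seed=9)
        assert a.stress == b.stress
        assert np.array_equal(a.coordinates.values, b.coordinates.values)

    def test_stress_invariant_to_similarity_transform(self):
        """Rotating/translating/scaling the coordinates rescales embedded
        distances uniformly, leaving rank-based stress unchanged."""
        d = self.planar_distance(seed=4)
        res = pa.nmds(d, restarts=3, seed=4)
        x = res.coordinates.to_numpy()
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        y = 3.0 * (x @ rot) + 5.0
        assert np.allclose(pdist(y), 3.0 * pdist(x), atol=1e-9)


class TestGroupDistances:
    def sheet(self):
        rows = []
        for tr, n in (("control", 3), ("urea", 1), ("NO3", 2)):
            for r in range(1, n + 1):
                rows.append((f"T24_{tr}_{r}", "T24", tr, r))
        for r in range(1, 4):
            rows.append((f"T0_control_{r}", "T0", "control", r))
        return pa.SampleSheet(pd.DataFrame(
            rows, columns=["sample_id", "timepoint", "treatment",
                           "replicate"]), strict=False)

    def distance_frame(self, values):
        sheet = self.sheet()
        ids = sheet.sample_ids
        d = pd.DataFrame(0.0, index=ids, columns=ids)
        for (a, b), v in values.items():
            d.loc[a, b] = d.loc[b, a] = v
        return d, sheet

    def test_single_replicate_median(self):
        d, sheet = self.distance_frame({
            ("T24_urea_1", "T0_control_1"): 1.0,
            ("T24_urea_1", "T0_control_2"): 2.0,
            ("T24_urea_1", "T0_control_3"): 3.0})
        med = pa.group_distance_summary(d, sheet)
        assert med["T24_urea"] == pytest.approx(2.0)

    def test_even_count_median(self):
        d, sheet = self.distance_frame({
            ("T24_NO3_1", "T0_control_1"): 1.0,
            ("T24_NO3_1", "T0_control_2"): 1.0,
            ("T24_NO3_2", "T0_control_1"): 3.0,
            ("T24_NO3_2", "T0_control_2"): 3.0})
        sheet.samples = sheet.samples[
            ~sheet.samples["sample_id"].eq("T0_control_3")]
        d = d.drop(index="T0_control_3", columns="T0_control_3")
        med = pa.group_distance_summary(d, sheet)
        assert med["T24_NO3"] == pytest.approx(2.0)

    def test_reference_excludes_self_pairs(self):
        d, sheet = self.distance_frame({
            ("T0_control_1", "T0_control_2"): 4.0,
            ("T0_control_1", "T0_control_3"): 4.0,
            ("T0_control_2", "T0_control_3"): 4.0})
        med = pa.group_distance_summary(d, sheet)
        assert med["T0_control"] == pytest.approx(4.0)  # not dragged to 0

    def test_replicates_cluster_on_fixture(self, default_sim, default_expr):
        """Strong implanted effects: within-treatment distances are smaller
        than between-treatment distances for most treatment pairs."""
        _design, _m, sheet, _truth = default_sim
        d = pa.euclidean_distances(default_expr)
        cond = sheet.samples.set_index("sample_id")
        labels = (cond["timepoint"] + "_" + cond["treatment"])[d.index]
        groups = labels.unique()
        within = {g: np.median([d.iloc[i, j]
                                for i in range(len(d))
                                for j in range(i + 1, len(d))
                                if labels.iloc[i] == g and
                                labels.iloc[j] == g])
                  for g in groups}
        wins = total = 0
        for i, g1 in enumerate(groups):
            for g2 in groups[i + 1:]:
                between = np.median(
                    [d.loc[a, b]
                     for a in labels.index[labels == g1]
                     for b in labels.index[labels == g2]])
                for g in (g1, g2):
                    total += 1
                    wins += within[g] < between
        assert wins / total >= 0.9
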