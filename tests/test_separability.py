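"""GDV and CSI cluster-separability measures."""

import numpy as np
import pytest

from hypnostats import (
    GeneratorConfig,
    LabeledPointSet,
    csi,
    gdv,
    generate_recording,
    hyperparameter_table,
    stage_distance_matrix,
    zscore_half,
)
from hypnostats.separability import DegenerateInputError, DuplicatePointError


def naive_gdv(points, labels):
    """Double-loop reference: z-score+halve, then the defining sums."""
    x = np.asarray(points, float)
    labels = np.asarray(labels)
    n, d = x.shape
    mu = x.mean(axis=0)
    sigma = np.sqrt(((x - mu) ** 2).mean(axis=0))
    s = 0.5 * (x - mu) / sigma
    classes = list(dict.fromkeys(labels))
    L = len(classes)

    def dist(a, b):
        return np.sqrt(((a - b) ** 2).sum())

    intra = []
    for c in classes:
        pts = s[labels == c]
        m = len(pts)
        tot = 0.0
        for i in range(m - 1):
            for j in range(i + 1, m):
                tot += dist(pts[i], pts[j])
        intra.append(2.0 / (m * (m - 1)) * tot)
    inter = 0.0
    for a in range(L - 1):
        for b in range(a + 1, L):
            pa, pb = s[labels == classes[a]], s[labels == classes[b]]
            tot = 0.0
            for i in range(len(pa)):
                for j in range(len(pb)):
                    tot += dist(pa[i], pb[j])
            inter += tot / (len(pa) * len(pb))
    return (np.mean(intra) - 2.0 / (L * (L - 1)) * inter) / np.sqrt(d)


def naive_csi(points, labels):
    x = np.asarray(points, float)
    labels = np.asarray(labels)
    logs = []
    for i in range(len(x)):
        d_same = min(np.sqrt(((x[i] - x[j]) ** 2).sum())
                     for j in range(len(x))
                     if j != i and labels[j] == labels[i])
        d_other = min(np.sqrt(((x[i] - x[j]) ** 2).sum())
                      for j in range(len(x)) if labels[j] != labels[i])
        logs.append(np.log(d_other / d_same))
    return float(np.mean(logs))


class TestZscoreHalf:
    def test_two_point_1d(self):
        for d in (0.5, 1.0, 123.4):
            ps = zscore_half(LabeledPointSet(np.array([[0.0], [d]]),
                                             np.array(["a", "b"])))
            np.testing.assert_allclose(ps.points.ravel(), [-0.5, 0.5],
                                       atol=1e-12)

    def test_standardized_dimension_halved(self, rng):
        x = rng.normal(size=(500, 1))
        x = (x - x.mean()) / x.std()
        ps = zscore_half(LabeledPointSet(x, np.repeat(["a", "b"], 250)))
        np.testing.assert_allclose(ps.points, x / 2, atol=1e-12)

    def test_translation_invariance(self, rng):
        x = rng.normal(size=(40, 3))
        labels = np.repeat(["a", "b"], 20)
        a = zscore_half(LabeledPointSet(x, labels)).points
        b = zscore_half(LabeledPointSet(x + 77.7, labels)).points
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_constant_dimension_dropped(self, rng):
        x = np.column_stack([rng.normal(size=20), np.full(20, 3.0)])
        ps = zscore_half(LabeledPointSet(x, np.repeat(["a", "b"], 10)))
        assert ps.points.shape == (20, 1)

    def test_all_constant_raises(self):
        with pytest.raises(DegenerateInputError):
            zscore_half(LabeledPointSet(np.ones((4, 2)),
                                        np.repeat(["a", "b"], 2)))


class TestGdv:
    @pytest.mark.parametrize("d", [0.1, 1.0, 250.0])
    @pytest.mark.parametrize("m", [2, 5])
    def test_coincident_point_classes_give_minus_one(self, d, m):
        pts = np.array([[0.0]] * m + [[d]] * m)
        labels = np.array(["a"] * m + ["b"] * m)
        assert gdv(LabeledPointSet(pts, labels)) == pytest.approx(-1.0,
                                                                  abs=1e-12)

    def test_same_distribution_near_zero(self, rng):
        x = rng.normal(size=(400, 3))
        labels = rng.permutation(np.repeat(["a", "b"], 200))
        assert abs(gdv(LabeledPointSet(x, labels))) < 0.05

    def test_scaling_invariance(self, rng):
        x = rng.normal(size=(60, 2)) + np.array([[0, 0]])
        x[30:] += 3.0
        labels = np.repeat(["a", "b"], 30)
        g1 = gdv(LabeledPointSet(x, labels))
        g2 = gdv(LabeledPointSet(x * 10.0, labels))
        assert g1 == pytest.approx(g2, abs=1e-12)

    def test_matches_naive_reference(self, rng):
        x = rng.normal(size=(30, 3))
        labels = rng.choice(["a", "b", "c"], size=30)
        while min((labels == c).sum() for c in "abc") < 2:
            labels = rng.choice(["a", "b", "c"], size=30)
        assert gdv(LabeledPointSet(x, labels)) == pytest.approx(
            naive_gdv(x, labels), abs=1e-12)

    def test_singleton_class_rejected(self):
        with pytest.raises(ValueError):
            gdv(LabeledPointSet(np.array([[0.0], [1.0], [2.0]]),
                                np.array(["a", "a", "b"])))


class TestCsi:
    def test_separated_clusters_worked_value(self):
        pts = np.array([0.0, 0.1, 0.2, 10.0, 10.1, 10.2])[:, None]
        labels = np.array(list("aaabbb"))
        expect = (np.log(100) + np.log(99) + np.log(98)) / 3
        assert csi(LabeledPointSet(pts, labels)) == pytest.approx(expect,
                                                                  abs=1e-12)
        assert expect == pytest.approx(4.595, abs=5e-4)

    def test_interleaved_grids_worked_value(self):
        pts = np.array([0.0, 2.0, 4.0, 1.0, 3.0, 5.0])[:, None]
        labels = np.array(list("aaabbb"))
        assert csi(LabeledPointSet(pts, labels)) == pytest.approx(
            np.log(0.5), abs=1e-12)

    def test_translation_and_scaling_invariance(self, rng):
        x = rng.normal(size=(50, 2))
        x[25:] += 2.0
        labels = np.repeat(["a", "b"], 25)
        c0 = csi(LabeledPointSet(x, labels))
        assert csi(LabeledPointSet(x * 7.0 - 100.0, labels)) == \
            pytest.approx(c0, abs=1e-12)

    def test_matches_naive_reference(self, rng):
        x = rng.normal(size=(40, 3))
        x[20:, 0] += 1.5
        labels = np.repeat(["a", "b"], 20)
        assert csi(LabeledPointSet(x, labels)) == pytest.approx(
            naive_csi(x, labels), abs=1e-12)

    def test_duplicate_points_raise_or_jitter(self):
        pts = np.array([[0.0], [0.0], [5.0], [6.0]])
        labels = np.array(["a", "a", "b", "b"])
        with pytest.raises(DuplicatePointError):
            csi(LabeledPointSet(pts, labels))
        val = csi(LabeledPointSet(pts, labels), jitter=1e-9)
        assert np.isfinite(val)


class TestJointBehavior:
    def test_monotone_in_center_separation(self, rng):
        gdvs, csis = [], []
        base = rng.normal(size=(200, 2))
        labels = np.repeat(["a", "b"], 100)
        for sep in (0.0, 1.0, 2.0, 4.0, 8.0):
            x = base.copy()
            x[100:, 0] += sep
            ps = LabeledPointSet(x, labels)
            gdvs.append(abs(gdv(ps)))
            csis.append(csi(ps))
        assert np.all(np.diff(gdvs) > -0.02)
        assert np.all(np.diff(csis) > -0.02)

    def test_parallel_lines_contrast(self):
        # two dense parallel diagonal lines with a small gap: every point's
        # nearest same-class neighbor is much closer than the other line,
        # so the CSI sees separation, while the all-pairs averaging of the
        # GDV is dominated by the lines' extent and sees none
        t = np.linspace(0.0, 100.0, 1000)
        pts = np.concatenate([
            np.column_stack([t, t]),
            np.column_stack([t, t + 1.0]),
        ])
        labels = np.repeat(["a", "b"], 1000)
        ps = LabeledPointSet(pts, labels)
        assert csi(ps) > 1.0
        assert abs(gdv(ps)) < 0.2


@pytest.fixture(scope="module")
def matrices():
    cfg = GeneratorConfig(n_epochs=300, seed=5)
    rec, hyp, _ = generate_recording(cfg)
    table = hyperparameter_table(rec, hyp)
    g = stage_distance_matrix(table, measure="gdv")
    c = stage_distance_matrix(table, measure="csi")
    return cfg, g, c


class TestStageDistanceMatrix:
    def test_symmetry_and_zero_diagonal(self, matrices):
        _, g, c = matrices
        for m in (g, c):
            np.testing.assert_allclose(m.values, m.values.T)
            np.testing.assert_allclose(np.diag(m.values), 0.0)

    def test_distance_grows_with_scale_separation(self, matrices):
        cfg, g, c = matrices
        # Wake(10) vs N3(300) further apart than Wake(10) vs REM(25)
        assert g.loc["Wake", "N3"] > g.loc["Wake", "REM"]
        assert c.loc["Wake", "N3"] > c.loc["Wake", "REM"]

    def test_identical_stage_parameters_near_zero(self):
        from hypnostats import StageParams, TransitionMatrix
        from hypnostats.synthetic import default_stage_params
        params = default_stage_params()
        # N1 and N2 generated with identical parameters
        params["N2"] = StageParams("N2", **{
            f: getattr(params["N1"], f)
            for f in ("ar_coefficient", "base_scale", "tail_dof",
                      "skew_coefficient", "variance_mod_sd",
                      "trend_per_epoch")})
        p = np.zeros((5, 5))
        p[2, 3] = 1.0
        p[3, 2] = 1.0
        p[0, 2] = 1.0
        p[1, 1] = p[4, 4] = 1.0
        cfg = GeneratorConfig(n_epochs=200, seed=4, initial_stage="N1",
                              transition_matrix=TransitionMatrix(p),
                              stage_params=params)
        rec, hyp, _ = generate_recording(cfg)
        table = hyperparameter_table(rec, hyp)
        g = stage_distance_matrix(table, measure="gdv")
        c = stage_distance_matrix(table, measure="csi")
        assert g.loc["N1", "N2"] < 0.1
        assert abs(c.loc["N1", "N2"]) < 0.25
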