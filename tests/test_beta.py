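"""Bray-Curtis, NMDS, ANOSIM, NPMANOVA and SIMPER."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import permanova as skbio_permanova

from trflpipe import beta


def dm_from_points(points):
    d = squareform(pdist(np.asarray(points, float)[:, None]))
    return DistanceMatrix(d, ids=[f"s{i}" for i in range(len(points))])


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        m = pd.DataFrame([[1, 2, 3], [1, 2, 3]], index=["a", "b"])
        assert beta.bray_curtis(m)["a", "b"] == 0.0

    def test_disjoint_supports_one(self):
        m = pd.DataFrame([[1, 0], [0, 1]], index=["a", "b"])
        assert beta.bray_curtis(m)["a", "b"] == 1.0

    def test_hand_computed(self):
        m = pd.DataFrame([[1, 2, 0], [2, 0, 1]], index=["a", "b"])
        assert beta.bray_curtis(m)["a", "b"] == pytest.approx(4 / 6)

    def test_double_zero_pair_defined_as_zero(self, caplog):
        m = pd.DataFrame([[0, 0], [0, 0], [1, 1]], index=["a", "b", "c"])
        with caplog.at_level("WARNING"):
            dm = beta.bray_curtis(m)
        assert dm["a", "b"] == 0.0
        assert "all-zero" in caplog.text

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            beta.bray_curtis(pd.DataFrame([[-1.0, 2.0]]))


class TestNmds:
    def test_planar_configuration_recovered(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        d = squareform(pdist(pts))
        dm = DistanceMatrix(d, ids=list("abcd"))
        res = beta.nmds(dm, k=2, restarts=8, seed=0)
        assert res.stress < 1e-3

    def test_extra_dimension_never_hurts(self):
        rng = np.random.default_rng(1)
        pts = rng.random((9, 5))
        dm = DistanceMatrix(squareform(pdist(pts)),
                            ids=[f"s{i}" for i in range(9)])
        s2 = beta.nmds(dm, k=2, restarts=20, seed=0).stress
        s3 = beta.nmds(dm, k=3, restarts=20, seed=0).stress
        assert s3 <= s2 + 1e-3

    def test_seeded_determinism(self):
        dm = dm_from_points([0.0, 1.0, 3.0, 6.0, 10.0])
        a = beta.nmds(dm, k=2, restarts=5, seed=7)
        b = beta.nmds(dm, k=2, restarts=5, seed=7)
        assert a.stress == b.stress
        pd.testing.assert_frame_equal(a.coordinates, b.coordinates)
        assert a.best_restart_seed == b.best_restart_seed

    def test_dimension_bound(self):
        dm = dm_from_points([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            beta.nmds(dm, k=2, restarts=1, seed=0)


class TestAnosim:
    def test_fully_separated_groups_r_one(self):
        d = np.array([
            [0.0, 0.1, 0.8, 0.85],
            [0.1, 0.0, 0.9, 0.95],
            [0.8, 0.9, 0.0, 0.2],
            [0.85, 0.95, 0.2, 0.0],
        ])
        dm = DistanceMatrix(d, ids=list("abcd"))
        res = beta.anosim(dm, ["g1", "g1", "g2", "g2"], n_perm=99, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert 0 < res.p_value <= 1

    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(4)
        x = rng.random((10, 6))
        m = pd.DataFrame(x, index=[f"s{i}" for i in range(10)])
        dm = beta.bray_curtis(m)
        groups = ["a"] * 5 + ["b"] * 5
        ours = beta.anosim(dm, groups, n_perm=99, seed=0)
        theirs = skbio_anosim(dm, grouping=groups, permutations=0)
        assert ours.statistic == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_null_r_near_zero_on_average(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.random((12, 8)), index=[f"s{i}" for i in range(12)])
        dm = beta.bray_curtis(m)
        stats = [
            beta.anosim(dm, list(rng.permutation(["a"] * 6 + ["b"] * 6)),
                        n_perm=9, seed=i).statistic
            for i in range(40)
        ]
        assert abs(np.mean(stats)) < 0.1

    def test_group_validation(self):
        dm = dm_from_points([0.0, 1.0, 2.0])
        with pytest.raises(ValueError):
            beta.anosim(dm, ["a", "a", "b"], n_perm=9)   # singleton group
        with pytest.raises(ValueError):
            beta.anosim(dm, ["a", "a", "a"], n_perm=9)   # one group


class TestNpmanova:
    def test_hand_computed_pseudo_f(self):
        # 1-D points {0,1} vs {10,11}: SS_T = 101, SS_W = 1, F = 200
        dm = dm_from_points([0.0, 1.0, 10.0, 11.0])
        res = beta.npmanova(dm, ["g1", "g1", "g2", "g2"], n_perm=99, seed=0)
        assert res.statistic == pytest.approx(200.0, rel=1e-12)

    def test_identical_groups_f_zero(self):
        dm = dm_from_points([0.0, 5.0, 0.0, 5.0])
        res = beta.npmanova(dm, ["g1", "g1", "g2", "g2"], n_perm=9, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)

    def test_label_swap_invariance(self):
        dm = dm_from_points([0.0, 1.5, 4.0, 9.0, 2.0, 7.0])
        g1 = ["a", "a", "a", "b", "b", "b"]
        g2 = ["b", "b", "b", "a", "a", "a"]
        f1 = beta.npmanova(dm, g1, n_perm=9, seed=0).statistic
        f2 = beta.npmanova(dm, g2, n_perm=9, seed=0).statistic
        assert f1 == pytest.approx(f2)

    def test_statistic_matches_skbio(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.random((9, 5)), index=[f"s{i}" for i in range(9)])
        dm = beta.bray_curtis(m)
        groups = ["a"] * 4 + ["b"] * 5
        ours = beta.npmanova(dm, groups, n_perm=99, seed=0)
        theirs = skbio_permanova(dm, grouping=groups, permutations=0)
        assert ours.statistic == pytest.approx(theirs["test statistic"], abs=1e-10)

    def test_p_never_zero(self):
        dm = dm_from_points([0.0, 1.0, 10.0, 11.0])
        res = beta.npmanova(dm, ["g1", "g1", "g2", "g2"], n_perm=999, seed=0)
        assert res.p_value >= 1 / 1000


class TestSimper:
    def test_single_pair_decomposition(self):
        m = pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"],
                         columns=["o1", "o2"])
        out = beta.simper(m, {"a": "g1", "b": "g2"}, cumulative_cutoff=0.25)
        np.testing.assert_allclose(out["contribution"], [0.5, 0.5])
        np.testing.assert_allclose(out["pct"], [50.0, 50.0])
        assert out.attrs["mean_between_group_dissimilarity"] == pytest.approx(1.0)
        # top 25% of dissimilarity reached within the first OTU
        assert list(out["reported"]) == [True, False]

    def test_identical_groups_empty_report(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]], index=["a", "b"])
        out = beta.simper(m, {"a": "g1", "b": "g2"})
        assert len(out) == 0

    def test_decomposition_identity(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.random((8, 12)), index=[f"s{i}" for i in range(8)])
        groups = {f"s{i}": ("g1" if i < 4 else "g2") for i in range(8)}
        out = beta.simper(m, groups)
        dm = beta.bray_curtis(m)
        between = [dm[f"s{i}", f"s{j}"] for i in range(4) for j in range(4, 8)]
        assert out["contribution"].sum() == pytest.approx(np.mean(between), rel=1e-12)

    def test_more_than_two_groups_rejected(self):
        m = pd.DataFrame(np.eye(3), index=["a", "b", "c"])
        with pytest.raises(ValueError):
            beta.simper(m, {"a": "g1", "b": "g2", "c": "g3"})


class TestConcat:
    def test_prefixes_and_alignment(self):
        m1 = pd.DataFrame([[1.0]], index=["s1"], columns=["100.00"])
        m2 = pd.DataFrame([[2.0], [3.0]], index=["s1", "s2"], columns=["100.00"])
        out = beta.concat_enzyme_matrices({"HaeIII": m1, "RsaI": m2})
        assert list(out.columns) == ["HaeIII:100.00", "RsaI:100.00"]
        assert out.loc["s2", "HaeIII:100.00"] == 0.0
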