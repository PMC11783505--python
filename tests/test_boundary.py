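"""Univariate boundary responses, PPI coactivation, ROI selection/merging."""

import itertools

import numpy as np
import pandas as pd
import pytest

from eventconn.boundary import (
    boundary_univariate_response,
    coactivation_matrix,
    merge_rois,
    ppi_coactivation,
    select_coactive_cluster,
)
from eventconn.events import BoundaryVector
from eventconn.timeseries import RoiTimeSeries


class TestUnivariateResponse:
    def test_constant_series_gives_zero(self, boundary_vector):
        y = np.full(boundary_vector.n_vols, 7.3)
        assert boundary_univariate_response(y, boundary_vector) == pytest.approx(0.0, abs=1e-12)

    def test_indicator_itself_gives_unit_contrast(self, boundary_vector):
        y = boundary_vector.indicator.astype(float)
        assert boundary_univariate_response(y, boundary_vector) == pytest.approx(1.0)

    def test_linearity_in_the_series(self, rng, boundary_vector):
        a = rng.standard_normal(boundary_vector.n_vols)
        b = rng.standard_normal(boundary_vector.n_vols)
        f = lambda y: boundary_univariate_response(y, boundary_vector)
        assert f(2.0 * a + 3.0 * b) == pytest.approx(2.0 * f(a) + 3.0 * f(b))

    def test_degenerate_vector_rejected(self):
        bvec = BoundaryVector(np.zeros(50, dtype=int), 2.47)
        with pytest.raises(ValueError, match="degenerate"):
            boundary_univariate_response(np.random.default_rng(0).standard_normal(50), bvec)

    def test_hrf_glm_estimator_recovers_injected_beta_sign(self, rng):
        from eventconn.boundary import hrf_double_gamma

        ind = np.zeros(400, dtype=int)
        ind[50:54] = ind[200:204] = ind[300:304] = 1
        bvec = BoundaryVector(ind, 2.47)
        reg = np.convolve(ind.astype(float), hrf_double_gamma(2.47))[:400]
        y = 0.8 * reg + 0.1 * rng.standard_normal(400)
        est = boundary_univariate_response(y, bvec, estimator="hrf_glm")
        assert est == pytest.approx(0.8, abs=0.1)


def _grid_search_mle(X, y, half_width=3.0, n_pts=7, n_zoom=18):
    """Independent logistic MLE by iterative dense grid refinement."""
    center = np.zeros(4)
    width = half_width
    for _ in range(n_zoom):
        axes = [np.linspace(c - width, c + width, n_pts) for c in center]
        grids = np.array(list(itertools.product(*axes)))
        eta = X @ grids.T
        nll = np.logaddexp(0, eta).sum(axis=0) - y @ eta
        center = grids[np.argmin(nll)]
        width *= 0.5
    return center


class TestPpiCoactivation:
    def test_null_beta_within_three_se(self, rng):
        n = 5000
        ind = np.zeros(n, dtype=int)
        ind[rng.choice(n, 500, replace=False)] = 1
        bvec = BoundaryVector(ind, 2.47)
        res = ppi_coactivation(rng.standard_normal(n), rng.standard_normal(n), bvec)
        assert abs(res.beta) < 3 * res.se

    def test_symmetric_under_argument_swap(self, rng, boundary_vector):
        z1 = rng.standard_normal(boundary_vector.n_vols)
        z2 = rng.standard_normal(boundary_vector.n_vols)
        a = ppi_coactivation(z1, z2, boundary_vector)
        b = ppi_coactivation(z2, z1, boundary_vector)
        assert a.beta == pytest.approx(b.beta, rel=1e-8)

    def test_invariant_to_additive_shift(self, rng, boundary_vector):
        z1 = rng.standard_normal(boundary_vector.n_vols)
        z2 = rng.standard_normal(boundary_vector.n_vols)
        a = ppi_coactivation(z1, z2, boundary_vector)
        b = ppi_coactivation(z1 + 100.0, z2 - 7.0, boundary_vector)
        assert a.beta == pytest.approx(b.beta, rel=1e-8)

    def test_matches_grid_search_mle(self, rng):
        # boundary timepoints carry pair correlation 0.8, within-event 0.0
        n = 5000
        ind = np.zeros(n, dtype=int)
        ind[rng.choice(n, 600, replace=False)] = 1
        common = rng.standard_normal(n)
        rho = np.where(ind == 1, 0.8, 0.0)
        z1 = np.sqrt(rho) * common + np.sqrt(1 - rho) * rng.standard_normal(n)
        z2 = np.sqrt(rho) * common + np.sqrt(1 - rho) * rng.standard_normal(n)
        bvec = BoundaryVector(ind, 2.47)
        res = ppi_coactivation(z1, z2, bvec)
        x1 = (z1 - z1.mean()) / z1.std()
        x2 = (z2 - z2.mean()) / z2.std()
        X = np.column_stack([np.ones(n), x1, x2, x1 * x2])
        oracle = _grid_search_mle(X, ind.astype(float))
        assert res.beta > 0
        assert res.beta == pytest.approx(oracle[3], abs=1e-3)

    def test_separation_falls_back_to_penalized_fit(self):
        # indicator perfectly determined by the product term -> separation
        n = 200
        rng = np.random.default_rng(3)
        z1 = rng.standard_normal(n)
        z2 = rng.standard_normal(n)
        ind = (z1 * z2 > 1.0).astype(int)
        res = ppi_coactivation(z1, z2, BoundaryVector(ind, 2.47))
        assert res.penalized
        assert np.isfinite(res.beta) and np.isfinite(res.se)
        assert res.beta > 0


class TestCoactivationMatrix:
    def test_two_rois_single_mirrored_value(self, rng, boundary_vector):
        ts = RoiTimeSeries(
            pd.DataFrame(rng.standard_normal((boundary_vector.n_vols, 2)), columns=["a", "b"]),
            2.47,
        )
        m = coactivation_matrix(ts, boundary_vector).betas
        assert np.isnan(m.loc["a", "a"]) and np.isnan(m.loc["b", "b"])
        assert m.loc["a", "b"] == m.loc["b", "a"]

    def test_permuting_rois_permutes_matrix(self, rng, boundary_vector):
        data = pd.DataFrame(
            rng.standard_normal((boundary_vector.n_vols, 4)), columns=list("abcd")
        )
        m1 = coactivation_matrix(RoiTimeSeries(data, 2.47), boundary_vector).betas
        perm = ["c", "a", "d", "b"]
        m2 = coactivation_matrix(RoiTimeSeries(data[perm], 2.47), boundary_vector).betas
        assert np.allclose(
            m1.loc[perm, perm].to_numpy(), m2.to_numpy(), equal_nan=True
        )


class TestSelectCoactiveCluster:
    @staticmethod
    def _matrix(labels, entries):
        m = pd.DataFrame(np.nan, index=labels, columns=labels)
        for (a, b), v in entries.items():
            m.loc[a, b] = m.loc[b, a] = v
        return m

    def test_all_positive_returns_full_candidate_set(self):
        labels = ["p1", "p2", "p3", "hipp"]
        entries = {(a, b): 0.5 for a, b in itertools.combinations(labels, 2)}
        m = self._matrix(labels, entries)
        got = select_coactive_cluster(m, ["p1", "p2", "p3"], "hipp")
        assert sorted(got) == ["p1", "p2", "p3"]

    def test_negative_entry_excluded_matches_bruteforce(self):
        labels = ["p1", "p2", "p3", "p4", "p5", "hipp"]
        rng = np.random.default_rng(11)
        entries = {
            (a, b): abs(rng.standard_normal()) + 0.1
            for a, b in itertools.combinations(labels, 2)
        }
        entries[("p2", "p4")] = -0.2
        m = self._matrix(labels, entries)
        cands = ["p1", "p2", "p3", "p4", "p5"]
        got = select_coactive_cluster(m, cands, "hipp")
        # brute force over all 2^5 subsets
        best = []
        for r in range(1, 6):
            for sub in itertools.combinations(cands, r):
                ok = all(m.loc[a, b] > 0 for a, b in itertools.combinations(sub, 2))
                ok = ok and all(m.loc[c, "hipp"] > 0 for c in sub)
                if ok and len(sub) > len(best):
                    best = list(sub)
        assert len(got) == len(best) == 4
        assert not {"p2", "p4"} <= set(got)
        # self-consistency: the output passes its own predicate
        assert all(m.loc[a, b] > 0 for a, b in itertools.combinations(got, 2))

    def test_empty_candidates_give_empty_result(self):
        m = self._matrix(["hipp"], {})
        assert select_coactive_cluster(m, [], "hipp") == []

    def test_no_qualifying_subset_warns(self):
        m = self._matrix(["p1", "hipp"], {("p1", "hipp"): -0.5})
        with pytest.warns(UserWarning):
            assert select_coactive_cluster(m, ["p1"], "hipp") == []


class TestMergeRois:
    def test_single_member_group_is_identity(self, random_timeseries):
        merged = merge_rois(random_timeseries, {"solo": ["roi0"]})
        assert np.allclose(merged.data["solo"], random_timeseries.data["roi0"])

    def test_hand_mean(self):
        df = pd.DataFrame({"a": [1.0], "b": [2.0], "c": [3.0]})
        merged = merge_rois(RoiTimeSeries(df, 2.47), {"m": ["a", "b", "c"]})
        assert merged.data["m"].iloc[0] == 2.0

    def test_unknown_label_rejected(self, random_timeseries):
        with pytest.raises(ValueError, match="nope"):
            merge_rois(random_timeseries, {"m": ["roi0", "nope"]})
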