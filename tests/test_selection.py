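import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from ogacp import (
    RegressionSeries,
    build_block_design,
    center_columns,
    hdic_stop,
    make_plan,
    oga_path,
    select_segments,
    trim,
)
from ogacp.exceptions import NoCandidateError
from ogacp.selection import default_dn, hdic_value

from conftest import random_instance


def greedy_oracle(y, Z, D):
    """Exhaustive-scan greedy selection using exact OLS residuals.

    Independent of the orthogonalized update: at each step the residual is
    recomputed by least squares on the raw selected columns and every
    remaining column is scanned.
    """
    sel = []
    for _ in range(D):
        if sel:
            coef, *_ = np.linalg.lstsq(Z[:, sel], y, rcond=None)
            r = y - Z[:, sel] @ coef
        else:
            r = y
        scores = np.full(Z.shape[1], -np.inf)
        for j in range(Z.shape[1]):
            if j not in sel:
                scores[j] = abs(Z[:, j] @ r) / np.linalg.norm(Z[:, j])
        sel.append(int(np.argmax(scores)))
    return sel


class TestCentering:
    def test_simple(self):
        yc, Zc, usable = center_columns(np.array([1.0, 2, 3]), np.ones((3, 1)))
        np.testing.assert_allclose(yc, [-1, 0, 1])
        assert not usable[0]  # constant column flagged

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=20)
        Z = rng.normal(size=(20, 3))
        yc, Zc, _ = center_columns(y, Z)
        yc2, Zc2, _ = center_columns(yc, Zc)
        np.testing.assert_allclose(yc, yc2, atol=1e-14)
        np.testing.assert_allclose(Zc, Zc2, atol=1e-14)
        assert abs(yc.mean()) < 1e-12 and np.abs(Zc.mean(axis=0)).max() < 1e-12

    def test_constant_column_excluded_from_path(self):
        rng = np.random.default_rng(1)
        Z = rng.normal(size=(30, 4))
        Z[:, 2] = 5.0
        y = Z[:, 0] + rng.normal(size=30)
        yc, Zc, usable = center_columns(y, Z)
        path = oga_path(yc, Zc, 3, usable)
        assert 2 not in path.selected


class TestOGAPath:
    def test_orthonormal_first_pick_closed_form(self):
        rng = np.random.default_rng(2)
        Q, _ = np.linalg.qr(rng.normal(size=(20, 5)))
        y = rng.normal(size=20)
        path = oga_path(y, Q, 2)
        assert path.selected[0] == int(np.argmax(np.abs(Q.T @ y)))
        j = path.selected[0]
        r1 = y - Q[:, j] * (Q[:, j] @ y)
        np.testing.assert_allclose(path.resid_norms[1], r1 @ r1, rtol=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_greedy_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        y, Z = random_instance(rng, n=8 + 4 * seed, p=5 + seed)
        D = min(4, Z.shape[1])
        path = oga_path(y, Z, D)
        assert path.selected == greedy_oracle(y, Z, D)

    def test_residual_norms_non_increasing(self):
        rng = np.random.default_rng(9)
        y, Z = random_instance(rng, n=50, p=12)
        path = oga_path(y, Z, 10)
        assert np.all(np.diff(path.resid_norms) <= 1e-10)

    def test_full_path_residual_beats_ols_on_selected(self):
        rng = np.random.default_rng(5)
        y, Z = random_instance(rng, n=25, p=10)
        path = oga_path(y, Z, 24)
        res = sm.OLS(y, Z[:, path.selected]).fit()
        assert path.resid_norms[-1] <= res.ssr + 1e-8

    def test_all_zero_columns_error(self):
        with pytest.raises(NoCandidateError):
            oga_path(np.ones(10), np.zeros((10, 3)), 2)


class TestHDIC:
    def test_empty_set_convention_is_mean_square(self):
        # with no columns the projection is zero, so sigma^2 = mean(y^2)
        y = np.array([1.0, -2, 3, 0.5])
        assert hdic_value(float(y @ y), 0, 4, 2.0, 10) == pytest.approx(
            np.log(np.mean(y**2))
        )

    def test_matches_per_subset_ols(self):
        rng = np.random.default_rng(4)
        y, Z = random_instance(rng, n=40, p=9)
        path = oga_path(y, Z, 6)
        hdic_stop(path, y, Z, c_n=2.0, r_n=Z.shape[1])
        for d in range(1, 7):
            cols = path.selected[:d]
            ssr = sm.OLS(y, Z[:, cols]).fit().ssr
            expect = np.log(ssr / y.size) + d * 2.0 * np.log(Z.shape[1]) / y.size
            assert path.hdic[d - 1] == pytest.approx(expect, abs=1e-8)

    def test_matches_projection_matrix_formula(self):
        rng = np.random.default_rng(14)
        y, Z = random_instance(rng, n=35, p=8)
        path = oga_path(y, Z, 5)
        hdic_stop(path, y, Z, c_n=1.5, r_n=Z.shape[1])
        n = y.size
        for d in range(1, 6):
            Zs = Z[:, path.selected[:d]]
            H = Zs @ np.linalg.pinv(Zs)
            sigma2 = y @ (np.eye(n) - H) @ y / n
            expect = np.log(sigma2) + d * 1.5 * np.log(Z.shape[1]) / n
            assert path.hdic[d - 1] == pytest.approx(expect, abs=1e-8)

    def test_zero_penalty_stops_at_path_end(self):
        rng = np.random.default_rng(6)
        y, Z = random_instance(rng, n=30, p=8)
        path = oga_path(y, Z, 6)
        assert hdic_stop(path, y, Z, c_n=0.0, r_n=8) == 6

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_stop_is_monotone_in_penalty(self, seed):
        rng = np.random.default_rng(seed)
        y, Z = random_instance(rng, n=40, p=10)
        path = oga_path(y, Z, 8)
        d_hats = [hdic_stop(path, y, Z, c_n=c, r_n=10) for c in (0.0, 1.0, 2.0, 5.0)]
        assert np.all(np.diff(d_hats) <= 0)


class TestTrim:
    def test_single_pick_kept(self):
        rng = np.random.default_rng(8)
        Z = rng.normal(size=(30, 4))
        y = 3 * Z[:, 1] + 0.1 * rng.normal(size=30)
        yc, Zc, _ = center_columns(y, Z)
        path = oga_path(yc, Zc, 4)
        hdic_stop(path, yc, Zc, c_n=5.0, r_n=4)
        if path.d_hat == 1:
            assert trim(path, yc, Zc, 5.0, 4) == [path.selected[0]]

    def test_planted_support_recovery(self):
        rng = np.random.default_rng(123)
        n, p = 150, 25
        Z = rng.normal(size=(n, p))
        support = [3, 11, 17]
        y = 3 * Z[:, 3] - 2.5 * Z[:, 11] + 4 * Z[:, 17] + 0.5 * rng.normal(size=n)
        yc, Zc, usable = center_columns(y, Z)
        path = oga_path(yc, Zc, default_dn(n, p), usable)
        hdic_stop(path, yc, Zc, c_n=2.0, r_n=p)
        assert sorted(trim(path, yc, Zc, 2.0, p)) == support

    def test_collinear_duplicates_at_most_one_survives(self):
        rng = np.random.default_rng(10)
        n = 60
        z = rng.normal(size=n)
        Z = np.column_stack([z, z, rng.normal(size=n)])
        y = 2 * z + 0.2 * rng.normal(size=n)
        yc, Zc, usable = center_columns(y, Z)
        path = oga_path(yc, Zc, 3, usable)
        hdic_stop(path, yc, Zc, c_n=2.0, r_n=3)
        J = trim(path, yc, Zc, 2.0, 3)
        assert len(set(J) & {0, 1}) <= 1


class TestSelectSegments:
    def make(self, n=240, m=24, q=1):
        plan = make_plan(n, m)
        colmap = tuple((l, c) for l in range(1, plan.p_n + 1) for c in range(1, q + 1))
        return plan, colmap

    def test_baseline_only_means_no_change(self):
        plan, colmap = self.make()
        seg = select_segments([0], colmap, plan, 1)
        assert seg.s_hat == 0 and seg.windows == ()

    def test_two_block_run_interior_change(self):
        plan, colmap = self.make()
        seg = select_segments([0, 6, 7], colmap, plan, 1)  # blocks {1,7,8}
        assert seg.C_hat == (7,)
        assert seg.windows == ((145, 192),)  # blocks 7 and 8
        assert seg.windows[0][1] - seg.windows[0][0] + 1 == 2 * plan.m

    def test_single_block_run_boundary_change(self):
        plan, colmap = self.make()
        seg = select_segments([0, 4], colmap, plan, 1)  # blocks {1,5}
        assert seg.C_hat == (4,)
        lo, hi = seg.windows[0]
        # the pre-specified cut-point between blocks 4 and 5 is interior
        cut = plan.blocks[3][1]
        assert lo < cut < hi

    def test_windows_disjoint_ordered_multiple_runs(self):
        plan, colmap = self.make()
        seg = select_segments([0, 3, 6, 7], colmap, plan, 1)  # blocks {1,4,7,8}
        assert seg.C_hat == (3, 7)
        (l1, h1), (l2, h2) = seg.windows
        assert h1 < l2 and all(1 <= b <= plan.n for b in (l1, h1, l2, h2))

    def test_any_surviving_column_marks_block(self):
        plan, colmap = self.make(q=2)
        # only the second covariate of block 5 survives
        j = 4 * 2 + 1  # (block 5, covariate 2)
        assert colmap[j] == (5, 2)
        seg = select_segments([0, j], colmap, plan, 2)
        assert 5 in seg.A_hat and seg.C_hat == (4,)
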