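"""Window planning and conditional-mean imputation."""

import numpy as np
import pytest

from zimpute.harmonize import harmonize
from zimpute.impute import (
    DirectImputation, ImputationError, SingularMatrixError, impute_all,
    impute_window, plan_windows,
)
from zimpute.sumstats import SumStatRecord

from conftest import make_panel


def random_joint_corr(rng, n_typed, n_untyped, n_obs=None):
    """Random PSD joint correlation matrix via a latent sample."""
    d = n_typed + n_untyped
    n_obs = n_obs or 4 * d
    X = rng.normal(size=(n_obs, d))
    R = np.corrcoef(X, rowvar=False)
    return R


def oracle_conditional_mean(R, n_typed, Zt):
    """Brute-force conditional mean/variance by explicit full-matrix inversion."""
    Stt = R[:n_typed, :n_typed]
    Sut = R[n_typed:, :n_typed]
    W = Sut @ np.linalg.inv(Stt)
    return W @ Zt, np.diag(W @ Sut.T)


def typed_untyped_panel(rng, n_hap, n_var, untyped_every=4):
    H = rng.integers(0, 2, size=(n_hap, n_var), dtype=np.uint8)
    for j in range(n_var):
        if H[:, j].min() == H[:, j].max():
            H[0, j] ^= 1
    panel = make_panel(H)
    typed = [i for i in range(n_var) if i % untyped_every]
    recs = [
        SumStatRecord("1", int(panel.pos[i]), panel.alt[i], panel.ref[i],
                      z=float(rng.normal()))
        for i in typed
    ]
    return panel, recs


class TestImputeWindow:
    def test_perfect_proxy(self):
        # target identical to typed SNP 2 (uncorrelated typed pair, so the
        # joint correlation with Sut row = e_2 is a valid PSD matrix)
        Zt = np.array([3.0, 1.0])
        Zu, r2 = impute_window(Zt, np.eye(2), np.array([[0.0, 1.0]]), lam=0.0)
        assert Zu[0] == pytest.approx(1.0) and r2[0] == pytest.approx(1.0)

    def test_zero_correlation_returns_null_mean(self):
        Zu, r2 = impute_window(
            np.array([3.0, 1.0]), np.eye(2), np.zeros((1, 2)), lam=0.0
        )
        assert Zu[0] == 0.0 and r2[0] == 0.0

    def test_two_typed_worked_example_matches_adjugate_oracle(self):
        # 2x2 inverse by the adjugate: inv([[1,.5],[.5,1]]) = [[1,-.5],[-.5,1]]/.75
        Stt = np.array([[1.0, 0.5], [0.5, 1.0]])
        det = 1.0 - 0.25
        inv = np.array([[1.0, -0.5], [-0.5, 1.0]]) / det
        Sut = np.array([[0.8, 0.4]])
        Zt = np.array([3.0, 1.0])
        zu_oracle = (Sut @ inv @ Zt).item()
        r2_oracle = (Sut @ inv @ Sut.T).item()
        assert zu_oracle == pytest.approx(2.4)
        assert r2_oracle == pytest.approx(0.64)
        Zu, r2 = impute_window(Zt, Stt, Sut, lam=0.0)
        assert Zu[0] == pytest.approx(2.4, abs=1e-12)
        assert r2[0] == pytest.approx(0.64, abs=1e-12)

    def test_matches_full_inversion_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(120):
            t = int(rng.integers(3, 13))
            u = int(rng.integers(1, 4))
            R = random_joint_corr(rng, t, u)
            Zt = rng.normal(size=t)
            zu_o, r2_o = oracle_conditional_mean(R, t, Zt)
            Zu, r2 = impute_window(Zt, R[:t, :t], R[t:, :t], lam=0.0)
            assert np.allclose(Zu, zu_o, atol=1e-10)
            assert np.allclose(r2, r2_o, atol=1e-10)

    def test_r2pred_within_unit_interval_at_lam_zero(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            t, u = int(rng.integers(2, 10)), int(rng.integers(1, 4))
            R = random_joint_corr(rng, t, u)
            _, r2 = impute_window(rng.normal(size=t), R[:t, :t], R[t:, :t], lam=0.0)
            assert np.all(r2 >= 0) and np.all(r2 <= 1 + 1e-8)

    def test_ridge_strictly_decreases_r2pred(self):
        rng = np.random.default_rng(4)
        R = random_joint_corr(rng, 6, 2)
        Zt = rng.normal(size=6)
        _, r2_0 = impute_window(Zt, R[:6, :6], R[6:, :6], lam=0.0)
        _, r2_l = impute_window(Zt, R[:6, :6], R[6:, :6], lam=0.05)
        assert np.all(r2_l < r2_0)

    def test_added_predictor_never_decreases_r2pred(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            t = int(rng.integers(3, 10))
            R = random_joint_corr(rng, t, 1)
            Zt = rng.normal(size=t)
            _, r2_full = impute_window(Zt, R[:t, :t], R[t:, :t], lam=0.0)
            _, r2_sub = impute_window(
                Zt[:-1], R[: t - 1, : t - 1], R[t:, : t - 1], lam=0.0
            )
            assert r2_full[0] >= r2_sub[0] - 1e-10

    def test_singular_block_raises_with_advice(self):
        Stt = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(SingularMatrixError, match="lam"):
            impute_window(np.array([1.0, 1.0]), Stt, np.array([[0.5, 0.5]]), lam=0.0)

    def test_dimension_mismatch(self):
        with pytest.raises(ImputationError):
            impute_window(np.ones(3), np.eye(2), np.ones((1, 2)))
        with pytest.raises(ImputationError):
            impute_window(np.ones(2), np.eye(2), np.ones((1, 3)))

    def test_negative_lam_rejected(self):
        with pytest.raises(ImputationError):
            impute_window(np.ones(2), np.eye(2), np.ones((1, 2)), lam=-1.0)


class TestPlanWindows:
    def _hset(self, typed_pos, untyped_pos):
        pos = sorted(typed_pos + untyped_pos)
        n = len(pos)
        rng = np.random.default_rng(0)
        H = rng.integers(0, 2, size=(10, n), dtype=np.uint8)
        for j in range(n):
            if H[:, j].min() == H[:, j].max():
                H[0, j] ^= 1
        panel = make_panel(H, pos=pos)
        recs = [
            SumStatRecord("1", p, panel.alt[pos.index(p)], panel.ref[pos.index(p)],
                          z=1.0)
            for p in typed_pos
        ]
        return harmonize(recs, panel), panel

    def test_two_windows_with_truncated_flanks(self):
        typed = [100 * i for i in range(1, 11)]           # 10 typed
        untyped = [150, 450, 850]                          # 3 interleaved
        hset, _ = self._hset(typed, untyped)
        windows = plan_windows(hset, pred_size=5, flank_size=2)
        assert len(windows) == 2
        w1 = windows[0]
        assert w1.core.size == 5
        assert w1.flank_left.size == 0 and w1.flank_right.size == 2
        # 150 and 450 fall before window 2's first core SNP (600)
        w1_pos = hset.panel.pos[w1.targets].tolist()
        assert w1_pos == [150, 450]
        assert hset.panel.pos[windows[1].targets].tolist() == [850]

    def test_untyped_upstream_of_all_typed_goes_to_first_window(self):
        hset, _ = self._hset([200, 300, 400, 500], [50])
        windows = plan_windows(hset, pred_size=2, flank_size=1)
        assert hset.panel.pos[windows[0].targets].tolist() == [50]

    def test_degenerate_single_window(self):
        hset, _ = self._hset([100, 200, 300], [150, 250])
        windows = plan_windows(hset, pred_size=10, flank_size=3)
        assert len(windows) == 1
        w = windows[0]
        assert w.core.size == 3 and w.flank_left.size == 0 and w.flank_right.size == 0
        assert w.targets.size == 2

    def test_every_untyped_variant_in_exactly_one_window(self):
        rng = np.random.default_rng(9)
        panel, recs = typed_untyped_panel(rng, 12, 60, untyped_every=3)
        hset = harmonize(recs, panel)
        windows = plan_windows(hset, pred_size=7, flank_size=3)
        seen = np.concatenate([w.targets for w in windows])
        assert sorted(seen.tolist()) == hset.untyped_indices.tolist()
        assert len(set(seen.tolist())) == len(seen)

    def test_no_typed_variants_is_error(self):
        rng = np.random.default_rng(1)
        panel, _ = typed_untyped_panel(rng, 10, 8)
        hset = harmonize([], panel)
        with pytest.raises(ImputationError, match="nothing to condition on"):
            plan_windows(hset, 3, 1)


class TestImputeAll:
    def test_all_typed_passes_through(self):
        rng = np.random.default_rng(2)
        panel, recs = typed_untyped_panel(rng, 20, 12, untyped_every=10**9)
        recs = [
            SumStatRecord("1", int(panel.pos[i]), panel.alt[i], panel.ref[i],
                          z=float(rng.normal()))
            for i in range(12)
        ]
        hset = harmonize(recs, panel)
        out = impute_all(hset, panel, pred_size=5, flank_size=2)
        assert all(r.status == "typed" for r in out)
        assert [r.z_imp for r in out] == pytest.approx(hset.z.tolist())
        assert all(r.r2pred == 1.0 for r in out)

    def test_perfect_typed_proxy_reproduces_z(self):
        # variants 0 and 1 share a haplotype column; 1 is untyped
        rng = np.random.default_rng(8)
        H = rng.integers(0, 2, size=(20, 6), dtype=np.uint8)
        H[:, 1] = H[:, 0]
        for j in range(6):
            if H[:, j].min() == H[:, j].max():
                H[:2, j] = [0, 1]
        H[:, 1] = H[:, 0]
        panel = make_panel(H)
        recs = [
            SumStatRecord("1", int(panel.pos[i]), panel.alt[i], panel.ref[i],
                          z=float(rng.normal()))
            for i in range(6) if i != 1
        ]
        hset = harmonize(recs, panel)
        out = impute_all(hset, panel, pred_size=10, flank_size=0, lam=0.0)
        rec1 = out[1]
        assert rec1.status == "imputed"
        assert rec1.z_imp == pytest.approx(hset.z[0], abs=1e-8)
        assert rec1.r2pred == pytest.approx(1.0, abs=1e-8)

    def test_whole_region_window_matches_full_matrix_oracle(self):
        rng = np.random.default_rng(12)
        panel, recs = typed_untyped_panel(rng, 40, 24, untyped_every=5)
        hset = harmonize(recs, panel)
        out = impute_all(hset, panel, pred_size=1000, flank_size=0, lam=0.0,
                         min_r2pred=0.0)
        t = hset.typed_indices
        u = hset.untyped_indices
        Xs = panel.standardized()
        R = Xs.T @ Xs / panel.n_hap
        np.fill_diagonal(R, 1.0)
        zu_o, _ = oracle_conditional_mean(
            R[np.ix_(np.r_[t, u], np.r_[t, u])], t.size, hset.z[t]
        )
        got = np.array([r.z_imp for r in out if r.status in ("imputed",)])
        assert np.allclose(got, zu_o, atol=1e-10)

    def test_windowed_equals_full_when_flanks_span_everything(self):
        rng = np.random.default_rng(13)
        panel, recs = typed_untyped_panel(rng, 40, 24, untyped_every=5)
        hset = harmonize(recs, panel)
        full = impute_all(hset, panel, pred_size=1000, flank_size=0, lam=0.0,
                          min_r2pred=0.0)
        windowed = impute_all(hset, panel, pred_size=4, flank_size=1000, lam=0.0,
                              min_r2pred=0.0)
        assert np.allclose(
            [r.z_imp for r in full if r.z_imp is not None],
            [r.z_imp for r in windowed if r.z_imp is not None],
            atol=1e-10,
        )

    def test_low_quality_targets_skipped(self):
        rng = np.random.default_rng(21)
        panel, recs = typed_untyped_panel(rng, 200, 20, untyped_every=4)
        hset = harmonize(recs, panel)
        out = impute_all(hset, panel, pred_size=30, flank_size=5, min_r2pred=0.9)
        # with an unstructured random panel most targets carry little LD info
        assert any(r.status == "skipped" for r in out)
        assert all(r.z_imp is None for r in out if r.status == "skipped")

    def test_collinear_pruning_recovers(self):
        # two identical typed columns with lam=0 force the pruning path
        H = np.array(
            [[0, 0, 1, 0], [1, 1, 0, 0], [0, 0, 1, 1], [1, 1, 1, 0],
             [0, 0, 0, 1], [1, 1, 0, 1]], dtype=np.uint8,
        )
        panel = make_panel(H)
        recs = [
            SumStatRecord("1", int(panel.pos[i]), panel.alt[i], panel.ref[i], z=1.0)
            for i in (0, 1, 3)
        ]
        hset = harmonize(recs, panel)
        out = impute_all(hset, panel, pred_size=10, flank_size=0, lam=0.0,
                         min_r2pred=0.0)
        assert out[2].status == "imputed" and np.isfinite(out[2].z_imp)


class TestModelInterface:
    def test_fit_returns_results_with_summary(self):
        rng = np.random.default_rng(30)
        panel, recs = typed_untyped_panel(rng, 30, 20, untyped_every=4)
        model = DirectImputation(recs, panel, pred_size=8, flank_size=3)
        res = model.fit()
        assert len(res.records) == panel.n_variant
        txt = res.summary()
        assert "typed" in txt and "r2pred" in txt
        df = res.frame()
        assert set(df["status"]) <= {"typed", "imputed", "skipped"}
        assert (df["pos"].values == panel.pos).all()

    def test_parameter_validation(self):
        rng = np.random.default_rng(31)
        panel, recs = typed_untyped_panel(rng, 10, 8)
        with pytest.raises(ImputationError):
            DirectImputation(recs, panel, lam=-0.1)
        with pytest.raises(ImputationError):
            DirectImputation(recs, panel, pred_size=0)
        with pytest.raises(ImputationError):
            DirectImputation(recs, panel, min_r2pred=1.5)

    def test_rescale_divides_by_sqrt_quality(self):
        rng = np.random.default_rng(32)
        panel, recs = typed_untyped_panel(rng, 40, 24, untyped_every=5)
        raw = DirectImputation(recs, panel, min_r2pred=0.0).fit()
        res = DirectImputation(recs, panel, min_r2pred=0.0, rescale=True).fit()
        for a, b in zip(raw.records, res.records):
            if a.status == "imputed" and a.r2pred > 0:
                assert b.z_imp == pytest.approx(a.z_imp / np.sqrt(a.r2pred))
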