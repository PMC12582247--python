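"""Return maps, error reduction, lag correlations, decay timescales."""

import numpy as np
import pandas as pd
import pytest

import stablegait as sg
from conftest import synthetic_deviation_set


def _ar1_deviation_set(lam=0.5, n=600, noise=0.0, seed=0, m=5):
    """DeviationSet whose body-y channel follows an AR(1) law.

    ``noise=0`` yields the deterministic linear system ``e_{k+1} = lam e_k``
    (exact at every pair); otherwise a stochastic AR(1) with the given
    innovation scale.
    """
    rng = np.random.default_rng(seed)
    if noise == 0:
        e = lam ** np.arange(n)
    else:
        e = np.empty(n)
        e[0] = rng.normal()
        for k in range(1, n):
            e[k] = lam * e[k - 1] + noise * rng.normal()
    dQ = np.zeros((n, m, 4))
    dQ[:, :, 1] = e[:, None]
    dQ[:, :, 0] = rng.normal(0, 1e-6, size=(n, m))
    dQ[:, :, 2] = rng.normal(0, 1e-6, size=(n, m))
    dQ[:, :, 3] = rng.normal(0, 1e-6, size=(n, m))
    index = pd.DataFrame({
        "animal_id": "a0", "leg": "left", "bout_id": "b0",
        "cycle_index": np.arange(n), "v_hat": 1.0, "duration": 1.0,
        "contact_time": np.arange(n, dtype=float),
        "reference_side": 1.0, "extrapolated": False,
    })
    return sg.DeviationSet(
        index=index, dQ=dQ, dQt=np.zeros((n, m, 4)),
        dP=np.column_stack([np.zeros(n), e]), dDur=np.zeros(n),
        dWidth=np.zeros(n), phase_grid=np.linspace(0, 1, m),
        Q_channels=("body:x", "body:y", "body:vx", "body:vy"),
        phi_swing={"left": 0.6})


class TestReturnMap:
    def test_noiseless_ar1_spectral_radius_exact(self):
        dev = _ar1_deviation_set(lam=0.5, n=60, noise=0.0)
        fit = sg.fit_return_map(dev, phase=0.75)
        assert fit.spectral_radius == pytest.approx(0.5, abs=1e-4)

    def test_simulator_closed_loop_radius(self, feedback_cohort):
        # theory: cycle map coefficient is a - G = 0.5
        p = feedback_cohort["params"]
        dev = feedback_cohort["dev"].for_leg("left")
        rhos = [sg.fit_return_map(dev.for_animal(a)).spectral_radius
                for a in sorted(dev.index["animal_id"].unique())]
        rhos = np.asarray(rhos)
        sem = rhos.std(ddof=1) / np.sqrt(len(rhos))
        assert abs(rhos.mean() - abs(p.a - p.gain)) <= max(3 * sem, 0.05)

    def test_backward_flag_changes_direction(self):
        dev = _ar1_deviation_set(lam=0.6, n=500, noise=1.0, seed=3)
        fwd = sg.fit_return_map(dev, forward=True)
        bwd = sg.fit_return_map(dev, forward=False)
        assert not np.allclose(fwd.K, bwd.K)

    def test_insufficient_pairs_error(self):
        dev = _ar1_deviation_set(n=20)
        with pytest.raises(ValueError, match="pairs"):
            sg.fit_return_map(dev)


class TestLagCorrelations:
    def test_iid_sequences_uncorrelated(self):
        rng = np.random.default_rng(4)
        seqs = [rng.normal(size=300) for _ in range(5)]
        r = sg.lag_correlation_profile(seqs, n_max=5)
        assert np.all(np.abs(r) < 0.07)

    def test_ar1_closed_form_decay(self):
        rng = np.random.default_rng(5)
        lam = 0.6
        seqs = []
        for _ in range(6):
            e = np.empty(4000)
            e[0] = rng.normal()
            for k in range(1, len(e)):
                e[k] = lam * e[k - 1] + rng.normal()
            seqs.append(e)
        r = sg.lag_correlation_profile(seqs, n_max=5)
        np.testing.assert_allclose(r, lam ** np.arange(1, 6), atol=0.03)

    def test_sequences_split_on_cycle_gaps_and_bouts(self):
        # pairs must never bridge a missing cycle or a bout boundary
        dev = synthetic_deviation_set(n=60)
        ci = np.arange(60)
        ci[30:] += 5  # gap after cycle 29
        dev.index["cycle_index"] = ci
        dev.index.loc[45:, "bout_id"] = "b1"
        seqs = sg.placement_sequences(dev, "left")
        assert sorted(len(s) for s in seqs) == [15, 15, 30]
        assert sum(len(s) for s in seqs) == 60


class TestDecayTimescale:
    def test_exact_exponential_recovered(self):
        lags = np.arange(1, 9)
        r = 0.8 * np.exp(-lags / 2.0)
        # feed the profile through the fitting core via synthetic sequences
        from stablegait.stability_timescale import _fit_exp_decay
        r0, tau = _fit_exp_decay(lags.astype(float), r)
        assert tau == pytest.approx(2.0, abs=1e-6)
        assert r0 == pytest.approx(0.8, abs=1e-6)

    def test_ar1_timescale_matches_analytic(self):
        rng = np.random.default_rng(6)
        lam = 0.6
        seqs = []
        for _ in range(10):
            e = np.empty(1500)
            e[0] = rng.normal()
            for k in range(1, len(e)):
                e[k] = lam * e[k - 1] + rng.normal()
            seqs.append(e)
        ts = sg.fit_decay_timescale(seqs, n_boot=300, seed=0)
        analytic = -1.0 / np.log(lam)   # ~1.958
        assert ts.tau_ci[0] <= analytic <= ts.tau_ci[1]
        assert ts.tau == pytest.approx(analytic, rel=0.15)

    def test_nonpositive_lag1_flagged_zero(self):
        rng = np.random.default_rng(7)
        seqs = [rng.normal(size=100) for _ in range(4)]
        # force negative lag-1 by alternating sign
        seqs = [s * np.where(np.arange(len(s)) % 2 == 0, 1, -1) * 5 + s
                for s in seqs]
        ts = sg.fit_decay_timescale(seqs, n_boot=0)
        assert ts.flagged
        assert ts.tau == 0.0

    def test_tau_rho_consistency_on_simulator(self, feedback_cohort):
        # two views of the same persistence: the cycle-map coefficient and
        # the placement-correlation decay imply consistent lambdas
        dev = feedback_cohort["dev"].for_leg("left")
        lam_rho = sg.fit_return_map(dev).spectral_radius_corrected
        seqs = sg.placement_sequences(feedback_cohort["dev"], "left")
        ts = sg.fit_decay_timescale(seqs, n_boot=0)
        lam_tau = float(np.exp(-1.0 / ts.tau))
        # each estimator's sampling sd is ~0.03-0.06 at this cohort size
        assert abs(lam_tau - lam_rho) < 0.15


class TestErrorReduction:
    def test_feedback_gives_positive_slope(self, feedback_cohort):
        dev = feedback_cohort["dev"]
        mask = dev.index["leg"].isin(["left", "right"]).to_numpy()
        res = sg.error_reduction_analysis(dev.subset(mask))
        assert res.slope > 0
        assert res.p_positive < 0.05
        assert res.n >= 500

    def test_null_has_no_stabilizing_association(self, null_cohort):
        dev = null_cohort["dev"]
        mask = dev.index["leg"].isin(["left", "right"]).to_numpy()
        res = sg.error_reduction_analysis(dev.subset(mask))
        assert res.p_positive >= 0.05

    def test_degenerate_input_errors(self):
        dev = synthetic_deviation_set(n=100)
        dev.dQ_ext = np.zeros((100, 5, 4))
        dev.ext_phases = np.linspace(1.1, 1.5, 5)
        dev.dQ[:, :, 1] = 0.0
        dev.dP[:, 1] = 0.0
        with pytest.raises(ValueError, match="degenerate"):
            sg.error_reduction_analysis(dev)

    def test_missing_extension_errors(self):
        dev = synthetic_deviation_set(n=100)
        with pytest.raises(ValueError, match="extended"):
            sg.error_reduction_analysis(dev)
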