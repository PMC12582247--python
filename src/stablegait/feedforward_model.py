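"""Velocity-dependent feedforward model and deviation bookkeeping.

The feedforward module of the controller maps the cycle-averaged movement
speed ``v_hat`` to nominal foot placement geometry and timing:

* step length and step width follow per-leg linear laws
  ``beta0 + beta1 * v_hat`` (ordinary least squares per animal per leg);
* cycle duration follows an exponential decay
  ``beta0 * exp(-beta1 (v_hat - beta2)) + beta3``;
* the full nominal gait pattern ``Q*_v(phi)`` is obtained by regressing every
  body-state channel on ``v_hat`` independently at every gait fraction, so
  body-state errors are deviations from the *velocity-conditioned* pattern
  rather than from the average behavior.

Deviations (``DeviationSet``) are the inputs of all feedback, stability and
timescale analyses: ``dQ = Q - Q*_v(phi)``, ``dP = P - f(v_hat)``, and the
analogous foot-state and duration residuals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .gait_processing import GaitCycle
from .stats_core import XiResult, chatterjee_xi

logger = logging.getLogger("stablegait")

__all__ = [
    "LinearFit",
    "ExponentialFit",
    "FeedforwardFit",
    "DeviationSet",
    "fit_linear_velocity_model",
    "fit_exponential_duration_model",
    "fit_nominal_pattern",
    "fit_feedforward",
    "compute_deviations",
    "timing_width_independence",
]


@dataclass(frozen=True)
class LinearFit:
    """OLS line ``y = beta0 + beta1 * v`` with slope inference."""
    beta0: float
    beta1: float
    p_slope: float
    r2: float
    n: int
    stderr: float

    def predict(self, v):
        return self.beta0 + self.beta1 * np.asarray(v, dtype=float)


@dataclass(frozen=True)
class ExponentialFit:
    """``y = beta0 * exp(-beta1 (v - beta2)) + beta3``.

    The raw parameterization is degenerate (``beta0`` and ``beta2`` trade off
    through ``beta0 * exp(beta1 beta2)``); ``amplitude_at_median`` reports
    the identifiable reduced form, the decay amplitude at the median speed.
    """
    beta: tuple[float, float, float, float]
    converged: bool
    n: int
    rmse: float
    v_median: float

    def predict(self, v):
        b0, b1, b2, b3 = self.beta
        return b0 * np.exp(-b1 * (np.asarray(v, dtype=float) - b2)) + b3

    @property
    def amplitude_at_median(self) -> float:
        b0, b1, b2, _ = self.beta
        return float(b0 * np.exp(-b1 * (self.v_median - b2)))


@dataclass
class FeedforwardFit:
    """Per-animal, per-leg feedforward model.

    ``nominal_coeffs`` maps ``"Q"``/``"Q_tilde"``/``"Q_ext"`` to arrays of
    shape (M, C, 2): per-phase intercept and velocity slope for every state
    channel.
    """
    animal_id: str
    leg: str
    n_cycles: int
    length: LinearFit
    width: LinearFit
    width_signed: LinearFit
    duration: ExponentialFit
    nominal_coeffs: dict[str, np.ndarray]
    v_range: tuple[float, float]


@dataclass
class DeviationSet:
    """Stacked deviations for a set of cycles, with bookkeeping.

    Arrays are aligned with ``index`` (one row per cycle, temporal order
    preserved within each bout): ``dQ`` (n, M, C), ``dQt`` (n, M, 4),
    ``dP`` (n, 2), ``dDur`` (n,), optional ``dQ_ext`` (n, M_ext, C).
    """
    index: pd.DataFrame
    dQ: np.ndarray
    dQt: np.ndarray
    dP: np.ndarray
    dDur: np.ndarray
    dWidth: np.ndarray
    phase_grid: np.ndarray
    Q_channels: tuple[str, ...]
    dQ_ext: np.ndarray | None = None
    ext_phases: np.ndarray | None = None
    phi_swing: dict[str, float] = field(default_factory=dict)

    def subset(self, mask: np.ndarray) -> "DeviationSet":
        return DeviationSet(
            index=self.index.loc[mask].reset_index(drop=True),
            dQ=self.dQ[mask], dQt=self.dQt[mask], dP=self.dP[mask],
            dDur=self.dDur[mask], dWidth=self.dWidth[mask],
            phase_grid=self.phase_grid,
            Q_channels=self.Q_channels,
            dQ_ext=None if self.dQ_ext is None else self.dQ_ext[mask],
            ext_phases=self.ext_phases, phi_swing=self.phi_swing,
        )

    def for_leg(self, leg: str) -> "DeviationSet":
        return self.subset((self.index["leg"] == leg).to_numpy())

    def for_animal(self, animal: str) -> "DeviationSet":
        return self.subset((self.index["animal_id"] == animal).to_numpy())

    @property
    def n(self) -> int:
        return len(self.index)


# ---------------------------------------------------------------------------
# Velocity models
# ---------------------------------------------------------------------------

def fit_linear_velocity_model(cycles: list[GaitCycle],
                              target: str = "length") -> LinearFit:
    """OLS of step length (``p_x``), step width (``|p_y|``) or signed lateral
    placement (``signed_width``) on cycle speed for one animal and leg."""
    v = np.asarray([c.v_hat for c in cycles])
    if target == "length":
        y = np.asarray([c.placement[0] for c in cycles])
    elif target == "width":
        y = np.asarray([abs(c.placement[1]) for c in cycles])
    elif target == "signed_width":
        y = np.asarray([c.placement[1] for c in cycles])
    elif target == "duration":
        y = np.asarray([c.duration for c in cycles])
    else:
        raise ValueError(f"unknown target {target!r}")
    if len(v) < 3 or np.ptp(v) == 0:
        raise ValueError("degenerate speed range for linear velocity model")
    res = stats.linregress(v, y)
    return LinearFit(beta0=float(res.intercept), beta1=float(res.slope),
                     p_slope=float(res.pvalue), r2=float(res.rvalue ** 2),
                     n=len(v), stderr=float(res.stderr))


def fit_exponential_duration_model(cycles: list[GaitCycle] | None = None,
                                   v: np.ndarray | None = None,
                                   durations: np.ndarray | None = None,
                                   ) -> ExponentialFit:
    """Nonlinear least squares for the exponential duration law with
    multi-start initialization.

    Starts: offset from the high-speed quartile mean, amplitude from the
    range, center from the median speed, and rate from the log-slope; a few
    perturbed restarts guard against local minima.  Non-convergence flags the
    fit so callers can fall back to a monotone alternative.
    """
    if cycles is not None:
        v = np.asarray([c.v_hat for c in cycles])
        durations = np.asarray([c.duration for c in cycles])
    v = np.asarray(v, dtype=float)
    y = np.asarray(durations, dtype=float)
    if len(v) < 8 or np.ptp(v) == 0:
        raise ValueError("need >= 8 cycles with nondegenerate speeds")
    v_med = float(np.median(v))
    hi = y[v >= np.quantile(v, 0.75)]
    b3_0 = float(hi.mean()) if len(hi) else float(y.min())
    b0_0 = max(float(y.max() - b3_0), 1e-6)
    # log-slope initial rate
    resid = np.clip(y - b3_0 * 0.95, 1e-9, None)
    slope = np.polyfit(v, np.log(resid), 1)[0]
    b1_0 = max(-float(slope), 0.1)

    def model(vv, b0, b1, b2, b3):
        return b0 * np.exp(np.clip(-b1 * (vv - b2), -700.0, 50.0)) + b3

    # bound the rate so the exponent stays numerically sane over the data
    b1_max = 200.0 / max(float(np.ptp(v)), 1e-6)
    bounds = ([0.0, 0.0, float(v.min()) - 10 * np.ptp(v), -np.inf],
              [np.inf, b1_max, float(v.max()) + 10 * np.ptp(v), np.inf])
    best = None
    starts = [(b0_0, b1_0, v_med, b3_0),
              (b0_0 * 2, b1_0 * 0.5, v_med, b3_0 * 0.9),
              (b0_0 * 0.5, min(b1_0 * 2, b1_max * 0.9),
               float(np.min(v)), b3_0)]
    for p0 in starts:
        p0 = tuple(np.clip(p0, [b + 1e-9 for b in bounds[0]],
                           [b - 1e-9 if np.isfinite(b) else b
                            for b in bounds[1]]))
        try:
            popt, _ = optimize.curve_fit(model, v, y, p0=p0, maxfev=20000,
                                         bounds=bounds)
        except (RuntimeError, optimize.OptimizeWarning):
            continue
        rmse = float(np.sqrt(np.mean((model(v, *popt) - y) ** 2)))
        if best is None or rmse < best[1]:
            best = (popt, rmse)
    if best is None:
        logger.warning("exponential duration fit failed to converge")
        return ExponentialFit(beta=(0.0, 0.0, v_med, float(np.mean(y))),
                              converged=False, n=len(v),
                              rmse=float(np.std(y)), v_median=v_med)
    popt, rmse = best
    return ExponentialFit(beta=tuple(float(b) for b in popt), converged=True,
                          n=len(v), rmse=rmse, v_median=v_med)


def fit_nominal_pattern(cycles: list[GaitCycle], block: str = "Q",
                        ) -> np.ndarray:
    """Per-phase, per-channel linear regression of a state block on speed.

    Returns coefficients of shape (M, C, 2): column 0 the intercept, column 1
    the velocity slope, so the nominal state is ``coef[...,0] +
    coef[...,1] * v_hat``.  With no velocity dependence this reduces exactly
    to per-phase averaging.
    """
    v = np.asarray([c.v_hat for c in cycles])
    if np.ptp(v) == 0:
        raise ValueError("degenerate speed range for nominal pattern")
    Y = np.stack([getattr(c, {"Q": "Q", "Q_tilde": "Q_tilde",
                              "Q_ext": "Q_ext"}[block]) for c in cycles])
    n, M, C = Y.shape
    X = np.column_stack([np.ones(n), v])
    coef, *_ = np.linalg.lstsq(X, Y.reshape(n, M * C), rcond=None)
    return coef.T.reshape(M, C, 2)


def fit_feedforward(cycles: list[GaitCycle]) -> FeedforwardFit:
    """Fit the full feedforward model for one animal and one leg."""
    if not cycles:
        raise ValueError("no cycles")
    animal = cycles[0].animal_id
    leg = cycles[0].leg
    assert all(c.animal_id == animal and c.leg == leg for c in cycles)
    v = np.asarray([c.v_hat for c in cycles])
    coeffs = {"Q": fit_nominal_pattern(cycles, "Q"),
              "Q_tilde": fit_nominal_pattern(cycles, "Q_tilde")}
    ext = [c for c in cycles if c.Q_ext is not None]
    if len(ext) >= 10 and len({c.Q_ext.shape for c in ext}) == 1:
        coeffs["Q_ext"] = fit_nominal_pattern(ext, "Q_ext")
    return FeedforwardFit(
        animal_id=animal, leg=leg, n_cycles=len(cycles),
        length=fit_linear_velocity_model(cycles, "length"),
        width=fit_linear_velocity_model(cycles, "width"),
        width_signed=fit_linear_velocity_model(cycles, "signed_width"),
        duration=fit_exponential_duration_model(cycles),
        nominal_coeffs=coeffs,
        v_range=(float(v.min()), float(v.max())),
    )


# ---------------------------------------------------------------------------
# Deviations
# ---------------------------------------------------------------------------

def compute_deviations(cycles: list[GaitCycle],
                       fits: dict[tuple[str, str], FeedforwardFit] | None = None,
                       ) -> DeviationSet:
    """Compute deviations of every cycle from its animal/leg nominal model.

    ``fits`` maps (animal_id, leg) to a fitted :class:`FeedforwardFit`; when
    omitted, models are fitted in-sample per animal and leg.  Cycle speeds
    more than 20% outside the fitted range are flagged ``extrapolated``.
    Temporal order of cycles within bouts is preserved.
    """
    if not cycles:
        raise ValueError("no cycles")
    groups: dict[tuple[str, str], list[GaitCycle]] = {}
    for c in cycles:
        groups.setdefault((c.animal_id, c.leg), []).append(c)
    if fits is None:
        fits = {key: fit_feedforward(cyc) for key, cyc in groups.items()}

    rows = []
    dQ, dQt, dP, dDur, dW, dQ_ext = [], [], [], [], [], []
    have_ext = all(c.Q_ext is not None for c in cycles)
    shapes = {c.Q_ext.shape for c in cycles if c.Q_ext is not None}
    have_ext = have_ext and len(shapes) == 1
    phase_grid = cycles[0].phase_grid
    channels = cycles[0].Q_channels
    ext_phases = cycles[0].ext_phases if have_ext else None
    phi_swing: dict[str, float] = {}
    for (animal, leg), cyc in groups.items():
        ff = fits[(animal, leg)]
        sw = np.asarray([c.phi_swing for c in cyc])
        sw = sw[np.isfinite(sw)]
        if len(sw):
            phi_swing[leg] = float(np.median(sw))
        lo, hi = ff.v_range
        span = hi - lo
        for c in cyc:
            nomQ = (ff.nominal_coeffs["Q"][..., 0]
                    + ff.nominal_coeffs["Q"][..., 1] * c.v_hat)
            nomQt = (ff.nominal_coeffs["Q_tilde"][..., 0]
                     + ff.nominal_coeffs["Q_tilde"][..., 1] * c.v_hat)
            dQ.append(c.Q - nomQ)
            dQt.append(c.Q_tilde - nomQt)
            dP.append(c.placement - np.array([
                ff.length.predict(c.v_hat),
                ff.width_signed.predict(c.v_hat)]))
            dW.append(abs(c.placement[1]) - float(ff.width.predict(c.v_hat)))
            if ff.duration.converged:
                dDur.append(c.duration - float(ff.duration.predict(c.v_hat)))
            else:
                dDur.append(c.duration - float(np.median(
                    [x.duration for x in cyc])))
            if have_ext:
                if "Q_ext" in ff.nominal_coeffs:
                    nomE = (ff.nominal_coeffs["Q_ext"][..., 0]
                            + ff.nominal_coeffs["Q_ext"][..., 1] * c.v_hat)
                    dQ_ext.append(c.Q_ext - nomE)
                else:
                    dQ_ext.append(np.full_like(c.Q_ext, np.nan))
            extrapolated = (c.v_hat < lo - 0.2 * span
                            or c.v_hat > hi + 0.2 * span)
            rows.append({
                "animal_id": animal, "leg": leg, "bout_id": c.bout_id,
                "cycle_index": c.cycle_index, "v_hat": c.v_hat,
                "duration": c.duration, "contact_time": c.contact_time,
                "reference_side": c.reference_side,
                "extrapolated": bool(extrapolated),
            })
    index = pd.DataFrame(rows)
    order = np.lexsort((index["cycle_index"], index["bout_id"],
                        index["leg"], index["animal_id"]))
    dev = DeviationSet(
        index=index.iloc[order].reset_index(drop=True),
        dQ=np.stack(dQ)[order], dQt=np.stack(dQt)[order],
        dP=np.stack(dP)[order], dDur=np.asarray(dDur)[order],
        dWidth=np.asarray(dW)[order],
        phase_grid=phase_grid, Q_channels=channels,
        dQ_ext=np.stack(dQ_ext)[order] if have_ext else None,
        ext_phases=ext_phases, phi_swing=phi_swing,
    )
    return dev


def timing_width_independence(dev: DeviationSet, leg: str | None = None,
                              ) -> XiResult:
    """Chatterjee-xi independence test between contact-timing deviations and
    step-width deviations (pooled over animals for one leg)."""
    d = dev if leg is None else dev.for_leg(leg)
    if d.n < 30:
        raise ValueError("need >= 30 paired deviations")
    return chatterjee_xi(d.dDur, d.dWidth)
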