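"""Phase-resolved linear feedback maps from body-state errors to placements.

At every gait fraction ``phi`` the corrective foot placement is regressed on
the body-state error vector (multiple OLS with intercept)::

    dP ~ gamma0 + sum_i gamma_i dQ_i(phi)

and compared against a baseline regression on the swinging foot's own
kinematic deviations ``dQ~(phi)`` -- the baseline controls for information
already present in the foot trajectory (by geometry its explained variance
approaches 1 as ``phi -> 1``).  Explained variance follows the uncentered
residual form ``R^2 = 1 - sum(r^2) / sum(dP^2)`` (deviations are zero-mean
regression residuals by construction).

The body-state model outperforming the baseline well before swing onset is
the signature of error-dependent feedback control; the *control magnitude*
summarizes it per individual as the maximal R^2 advantage across phases.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .feedforward_model import DeviationSet
from .stats_core import compare_groups

logger = logging.getLogger("stablegait")

__all__ = [
    "FeedbackFit",
    "ModelComparison",
    "fit_error_map",
    "fit_baseline_map",
    "r2_phase_profile",
    "control_magnitude",
    "directional_gains",
]

_DIRS = {"fore_aft": 0, "lateral": 1}

#: Ridge penalty (relative to the largest singular value) used when the
#: predictor matrix is rank deficient.
RIDGE_EPS = 1e-8


@dataclass
class FeedbackFit:
    """One linear map at one phase: intercept, per-channel gains, R^2."""
    phase: float
    direction: str
    intercept: float
    gains: np.ndarray
    channels: tuple[str, ...]
    r2: float
    n_cycles: int
    animal_id: str
    leg: str
    ridge: bool = False

    def gain_for(self, channel: str) -> float:
        return float(self.gains[self.channels.index(channel)])


@dataclass
class ModelComparison:
    """Per-phase R^2 distributions of both models across animals."""
    phase_grid: np.ndarray
    direction: str
    leg: str
    animals: list[str]
    r2_body: np.ndarray       # (n_animals, M)
    r2_baseline: np.ndarray   # (n_animals, M)
    ks_stat: np.ndarray | None
    ks_p: np.ndarray | None
    swing_onset_phase: float

    def median_iqr(self, which: str = "body"):
        arr = self.r2_body if which == "body" else self.r2_baseline
        return (np.median(arr, axis=0), np.percentile(arr, 25, axis=0),
                np.percentile(arr, 75, axis=0))


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, bool]:
    """OLS with intercept; tiny-ridge fallback on rank deficiency.

    Returns (coefficients incl. intercept first, R^2 uncentered-residual
    form, ridge_flag).
    """
    n = len(y)
    A = np.column_stack([np.ones(n), X])
    ridge = False
    coef, _, rank, sv = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        lam = RIDGE_EPS * (sv[0] ** 2 if len(sv) else 1.0)
        coef = np.linalg.solve(A.T @ A + lam * np.eye(A.shape[1]), A.T @ y)
        ridge = True
    resid = y - A @ coef
    denom = float(np.sum(y ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / denom if denom > 0 else 0.0
    return coef, r2, ridge


def _phase_index(dev: DeviationSet, phase: float) -> int:
    return int(np.argmin(np.abs(dev.phase_grid - phase)))


def _single_group(dev: DeviationSet) -> tuple[str, str]:
    animals = dev.index["animal_id"].unique()
    legs = dev.index["leg"].unique()
    if len(animals) != 1 or len(legs) != 1:
        raise ValueError("fit expects deviations of one animal and one leg; "
                         "use .for_animal()/.for_leg() to subset")
    return str(animals[0]), str(legs[0])


def _cv_r2(X: np.ndarray, y: np.ndarray, n_folds: int) -> float:
    """Out-of-sample R^2 from contiguous k-fold prediction."""
    n = len(y)
    resid = np.empty(n)
    bounds = np.linspace(0, n, n_folds + 1).astype(int)
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        train = np.r_[0:lo, hi:n]
        coef, _, _ = _ols(X[train], y[train])
        A = np.column_stack([np.ones(hi - lo), X[lo:hi]])
        resid[lo:hi] = y[lo:hi] - A @ coef
    denom = float(np.sum(y ** 2))
    return 1.0 - float(np.sum(resid ** 2)) / denom if denom > 0 else 0.0


def _fit_map(dev: DeviationSet, phase: float, direction: str,
             predictors: str, cv_folds: int = 0) -> FeedbackFit:
    animal, leg = _single_group(dev)
    m = _phase_index(dev, phase)
    if predictors == "body":
        X = dev.dQ[:, m, :]
        channels = dev.Q_channels
    else:
        X = dev.dQt[:, m, :]
        channels = ("foot:x", "foot:y", "foot:vx", "foot:vy")
    y = dev.dP[:, _DIRS[direction]]
    n, k = X.shape
    if n < 5 * (k + 1):
        raise ValueError(f"need n >= {5 * (k + 1)} cycles, got {n}")
    coef, r2, ridge = _ols(X, y)
    if cv_folds:
        r2 = _cv_r2(X, y, cv_folds)
    if ridge:
        logger.info("ridge fallback for %s/%s at phi=%.2f", animal, leg, phase)
    return FeedbackFit(phase=float(dev.phase_grid[m]), direction=direction,
                       intercept=float(coef[0]), gains=coef[1:],
                       channels=tuple(channels), r2=r2, n_cycles=n,
                       animal_id=animal, leg=leg, ridge=ridge)


def fit_error_map(dev: DeviationSet, phase: float,
                  direction: str = "lateral",
                  cv_folds: int = 0) -> FeedbackFit:
    """Body-state-error feedback map at one phase (one animal, one leg).

    ``cv_folds > 0`` replaces the default in-sample R^2 (the closed-form
    estimator the analyses report) with a contiguous k-fold out-of-sample
    R^2; gains are always the full-sample OLS solution.
    """
    return _fit_map(dev, phase, direction, "body", cv_folds)


def fit_baseline_map(dev: DeviationSet, phase: float,
                     direction: str = "lateral",
                     cv_folds: int = 0) -> FeedbackFit:
    """Baseline map from the swinging foot's own kinematic deviations."""
    return _fit_map(dev, phase, direction, "foot", cv_folds)


def r2_phase_profile(dev: DeviationSet, direction: str = "lateral",
                     leg: str | None = None, min_animals_ks: int = 5,
                     ) -> ModelComparison:
    """Fit both maps at every grid phase for every animal; compare per-phase
    R^2 samples across animals with a one-sided two-sample KS test.

    The KS alternative asks whether the body-state R^2 distribution lies
    *above* the baseline distribution (the direction in which feedback
    control manifests; near the predicted contact the baseline exceeds the
    body model for purely geometric reasons).  With fewer than
    ``min_animals_ks`` animals the KS step is skipped.
    """
    d = dev if leg is None else dev.for_leg(leg)
    leg_label = leg or str(d.index["leg"].unique()[0])
    animals = sorted(d.index["animal_id"].unique())
    M = len(d.phase_grid)
    r2_body = np.full((len(animals), M), np.nan)
    r2_base = np.full((len(animals), M), np.nan)
    for i, animal in enumerate(animals):
        da = d.for_animal(animal)
        y = da.dP[:, _DIRS[direction]]
        for m in range(M):
            _, r2b, _ = _ols(da.dQ[:, m, :], y)
            _, r2f, _ = _ols(da.dQt[:, m, :], y)
            r2_body[i, m] = r2b
            r2_base[i, m] = r2f
    ks_stat = ks_p = None
    if len(animals) >= min_animals_ks:
        ks_stat = np.empty(M)
        ks_p = np.empty(M)
        for m in range(M):
            if np.allclose(r2_body[:, m], r2_base[:, m]):
                ks_stat[m], ks_p[m] = 0.0, 1.0
                continue
            # alternative="less": CDF of body R^2 below baseline's, i.e.
            # body R^2 stochastically greater
            res = stats.ks_2samp(r2_body[:, m], r2_base[:, m],
                                 alternative="less")
            ks_stat[m], ks_p[m] = res.statistic, res.pvalue
    else:
        logger.warning("KS comparison skipped: %d animals < %d",
                       len(animals), min_animals_ks)
    swing = d.phi_swing.get(leg_label, float("nan"))
    return ModelComparison(phase_grid=d.phase_grid, direction=direction,
                           leg=leg_label, animals=animals, r2_body=r2_body,
                           r2_baseline=r2_base, ks_stat=ks_stat, ks_p=ks_p,
                           swing_onset_phase=swing)


def control_magnitude(comparison: ModelComparison) -> np.ndarray:
    """Per-animal maximal R^2 advantage of the body-state model over the
    baseline across phases (one scalar per animal)."""
    return np.max(comparison.r2_body - comparison.r2_baseline, axis=1)


def directional_gains(dev: DeviationSet, phase: float, leg: str,
                      channel: str | None = None,
                      min_cycles: int | None = None) -> dict:
    """Medial vs lateral feedback gains at one phase, compared across animals.

    Cycles are split by whether the lateral body error at ``phase`` points
    toward (medial) or away from (lateral) the reference stance foot; the
    error map is refitted on each subset per animal and the magnitude of the
    primary lateral-position gain is compared pairwise (Wilcoxon signed-rank
    or paired t via the stats gateway, with Cohen's d).  Animals whose
    subsets fall below the fitting minimum are excluded and logged.
    """
    d = dev.for_leg(leg)
    m = _phase_index(d, phase)
    if channel is None:
        ych = [c for c in d.Q_channels if c.endswith(":y")
               and ":v" not in c][0]
        channel = ych
    k = d.dQ.shape[2]
    need = min_cycles if min_cycles is not None else 5 * (k + 1)
    rows = {"medial": [], "lateral": []}
    animals_used = []
    for animal in sorted(d.index["animal_id"].unique()):
        da = d.for_animal(animal)
        err = da.dQ[:, m, da.Q_channels.index(channel)]
        toward = err * da.index["reference_side"].to_numpy() > 0
        sub_m = da.subset(toward)
        sub_l = da.subset(~toward)
        if sub_m.n < need or sub_l.n < need:
            logger.info("directional_gains: excluding %s (n_med=%d, "
                        "n_lat=%d < %d)", animal, sub_m.n, sub_l.n, need)
            continue
        g_m = abs(fit_error_map(sub_m, phase).gain_for(channel))
        g_l = abs(fit_error_map(sub_l, phase).gain_for(channel))
        rows["medial"].append(g_m)
        rows["lateral"].append(g_l)
        animals_used.append(animal)
    out = {"animals": animals_used,
           "medial": np.asarray(rows["medial"]),
           "lateral": np.asarray(rows["lateral"])}
    if len(animals_used) >= 3:
        out["comparison"] = compare_groups(
            {"lateral": out["lateral"], "medial": out["medial"]}, paired=True)
    return out
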