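"""Cycle-to-cycle stability, error reduction, and control timescales.

Three complementary views of how placement corrections stabilize the body:

* **Poincare return map** -- a linear map ``K`` fitted between body-state
  deviations sampled at the same gait fraction (default 0.75) on consecutive
  cycles.  The map is fitted *forward in time* (next cycle's deviation as the
  response): a spectral radius ``rho = max_i |lambda_i| < 1`` then indicates
  an orbitally stable gait.  A fitted map and its reversed-direction fit are
  not reciprocal under noise, so the direction matters; the backward variant
  is available behind a flag and its eigenvalues are reported as fitted.
* **Error reduction** -- the drop in mean absolute lateral body error from
  the half cycle before a contact to the half cycle after it, regressed on
  the magnitude of the lateral placement deviation.  A positive slope links
  larger corrective placements to larger subsequent error reductions.
* **Lag correlations and timescale** -- Pearson correlations between lateral
  placement deviations N cycles apart (never spanning bout boundaries) decay
  exponentially; the decay constant ``tau`` of ``r(N) = r0 exp(-N / tau)``
  is the control timescale in units of gait cycles, with a bootstrap CI
  resampling whole bouts to preserve serial structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .feedforward_model import DeviationSet

logger = logging.getLogger("stablegait")

__all__ = [
    "ReturnMapFit",
    "TimescaleFit",
    "ErrorReductionResult",
    "fit_return_map",
    "error_reduction_analysis",
    "lag_correlation_profile",
    "placement_sequences",
    "fit_decay_timescale",
]

DEFAULT_RETURN_PHASE = 0.75
DEFAULT_N_MAX = 8
DEFAULT_N_BOOT = 10_000
RIDGE_EPS = 1e-8


@dataclass
class ReturnMapFit:
    """Linear map of state deviations across one gait cycle.

    ``spectral_radius`` is the raw modulus of the dominant eigenvalue of the
    fitted map.  Least-squares autoregressive coefficients are biased low in
    finite samples (Kendall; Marriott-Pope: E[l_hat] ~ l - (1+3l)/n), so
    ``spectral_radius_corrected`` applies the scalar first-order correction
    -- appropriate when a single real eigenvalue dominates, as it does for
    one lateral error channel.
    """
    K: np.ndarray
    eigenvalues: np.ndarray
    spectral_radius: float
    phase: float
    n_pairs: int
    channels: tuple[str, ...]
    forward: bool = True
    ridge: bool = False

    @property
    def spectral_radius_corrected(self) -> float:
        rho = self.spectral_radius
        return float(rho + (1.0 + 3.0 * rho) / self.n_pairs)


@dataclass
class TimescaleFit:
    """Exponential decay of lagged placement correlations."""
    lags: np.ndarray
    r: np.ndarray
    r0: float
    tau: float
    tau_ci: tuple[float, float] | None
    n_boot: int
    ci_level: float
    flagged: bool = False


@dataclass
class ErrorReductionResult:
    """Regression of per-contact error reduction on placement magnitude.

    ``p`` is the two-sided slope p-value; ``p_positive`` the one-sided test
    of the stabilization hypothesis (larger placement deviations associated
    with larger subsequent error reductions, slope > 0).
    """
    delta_error: np.ndarray
    abs_dp: np.ndarray
    slope: float
    intercept: float
    p: float
    p_positive: float
    r: float
    n: int


# ---------------------------------------------------------------------------
# Return map
# ---------------------------------------------------------------------------

def _consecutive_pairs(dev: DeviationSet) -> tuple[np.ndarray, np.ndarray]:
    """Indices (i, j) of consecutive cycles of the same animal/leg/bout."""
    idx = dev.index
    ii, jj = [], []
    for _, grp in idx.groupby(["animal_id", "leg", "bout_id"], sort=False):
        grp = grp.sort_values("cycle_index")
        rows = grp.index.to_numpy()
        ci = grp["cycle_index"].to_numpy()
        for a, b, ca, cb in zip(rows[:-1], rows[1:], ci[:-1], ci[1:]):
            if cb - ca == 1:
                ii.append(a)
                jj.append(b)
    return np.asarray(ii, dtype=int), np.asarray(jj, dtype=int)


def fit_return_map(dev: DeviationSet, phase: float = DEFAULT_RETURN_PHASE,
                   forward: bool = True) -> ReturnMapFit:
    """Least-squares linear map between consecutive-cycle deviations sampled
    at ``phase``.

    ``forward=True`` fits the next cycle's deviation as the response (so
    eigenvalue moduli below 1 indicate contraction); ``forward=False`` fits
    the literal backward map with eigenvalues reported un-inverted.
    """
    m = int(np.argmin(np.abs(dev.phase_grid - phase)))
    ii, jj = _consecutive_pairs(dev)
    dim = dev.dQ.shape[2]
    if len(ii) < 10 * dim:
        raise ValueError(f"need >= {10 * dim} consecutive-cycle pairs, "
                         f"got {len(ii)}")
    X = dev.dQ[ii, m, :]
    Y = dev.dQ[jj, m, :]
    if not forward:
        X, Y = Y, X
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    ridge = False
    B, _, rank, sv = np.linalg.lstsq(Xc, Yc, rcond=None)
    if rank < dim:
        lam = RIDGE_EPS * (sv[0] ** 2 if len(sv) else 1.0)
        B = np.linalg.solve(Xc.T @ Xc + lam * np.eye(dim), Xc.T @ Yc)
        ridge = True
        logger.info("return map: ridge fallback (rank %d < %d)", rank, dim)
    K = B.T
    eig = np.linalg.eigvals(K)
    return ReturnMapFit(K=K, eigenvalues=eig,
                        spectral_radius=float(np.max(np.abs(eig))),
                        phase=float(dev.phase_grid[m]), n_pairs=len(ii),
                        channels=dev.Q_channels, forward=forward, ridge=ridge)


# ---------------------------------------------------------------------------
# Error reduction
# ---------------------------------------------------------------------------

def error_reduction_analysis(dev: DeviationSet, channel: str | None = None,
                             min_contacts: int = 30) -> ErrorReductionResult:
    """Regress the before-vs-after contact reduction in mean absolute lateral
    body error on the magnitude of the lateral placement deviation.

    The before window is phases [0.5, 1] of the cycle; the after window the
    extended phases (1, 1.5] (cycles lacking the extension are skipped).
    Absolute errors are used: a reduction must be sign-free to regress on
    ``|dP_y|``.
    """
    if dev.dQ_ext is None:
        raise ValueError("deviation set has no extended phases; segment "
                         "bouts with extension enabled")
    if channel is None:
        channel = [c for c in dev.Q_channels
                   if c.endswith(":y") and ":v" not in c][0]
    c = dev.Q_channels.index(channel)
    half = dev.phase_grid >= 0.5
    before = np.mean(np.abs(dev.dQ[:, half, c]), axis=1)
    after = np.mean(np.abs(dev.dQ_ext[:, :, c]), axis=1)
    ok = np.isfinite(after)
    delta = before[ok] - after[ok]
    abs_dp = np.abs(dev.dP[ok, 1])
    if len(delta) < min_contacts:
        raise ValueError(f"only {len(delta)} extendable contacts "
                         f"(need >= {min_contacts})")
    if np.ptp(abs_dp) == 0 or np.ptp(delta) == 0:
        raise ValueError("degenerate error-reduction data (constant input)")
    res = stats.linregress(abs_dp, delta)
    p_pos = res.pvalue / 2.0 if res.slope > 0 else 1.0 - res.pvalue / 2.0
    return ErrorReductionResult(delta_error=delta, abs_dp=abs_dp,
                                slope=float(res.slope),
                                intercept=float(res.intercept),
                                p=float(res.pvalue), p_positive=float(p_pos),
                                r=float(res.rvalue),
                                n=len(delta))


# ---------------------------------------------------------------------------
# Lag correlations and timescale
# ---------------------------------------------------------------------------

def placement_sequences(dev: DeviationSet, leg: str) -> list[np.ndarray]:
    """Ordered lateral placement deviations per (animal, bout) for one leg.

    Consecutive entries are consecutive cycles; gaps in the cycle index split
    the sequence so lagged pairs never bridge missing cycles.
    """
    d = dev.for_leg(leg)
    seqs: list[np.ndarray] = []
    for _, grp in d.index.groupby(["animal_id", "bout_id"], sort=True):
        rows = grp.sort_values("cycle_index")
        ci = rows["cycle_index"].to_numpy()
        vals = d.dP[rows.index.to_numpy(), 1]
        brk = np.where(np.diff(ci) != 1)[0]
        for chunk in np.split(np.arange(len(ci)), brk + 1):
            if len(chunk) >= 2:
                seqs.append(vals[chunk])
    return seqs


def lag_correlation_profile(sequences: list[np.ndarray],
                            n_max: int = DEFAULT_N_MAX) -> np.ndarray:
    """Pearson correlation between placements N cycles apart, for
    N = 1..n_max, pooling pairs within (never across) sequences.

    Lags with fewer than 3 pairs are NaN (truncated with a warning).
    """
    r = np.full(n_max, np.nan)
    for k, lag in enumerate(range(1, n_max + 1)):
        a_parts, b_parts = [], []
        for s in sequences:
            if len(s) > lag:
                a_parts.append(s[:-lag])
                b_parts.append(s[lag:])
        if not a_parts:
            logger.warning("lag %d: no pairs available; truncating", lag)
            continue
        a = np.concatenate(a_parts)
        b = np.concatenate(b_parts)
        if len(a) < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
            logger.warning("lag %d: insufficient pairs; truncating", lag)
            continue
        r[k] = stats.pearsonr(a, b).statistic
    return r


def _fit_exp_decay(lags: np.ndarray, r: np.ndarray) -> tuple[float, float]:
    """Fit r(N) = r0 * exp(-N / tau) over finite entries; returns (r0, tau)."""
    ok = np.isfinite(r)
    x, y = lags[ok], r[ok]
    pos = y > 0
    if pos.sum() >= 2:
        slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
        tau0 = -1.0 / slope if slope < 0 else 5.0
        r0_0 = float(np.exp(intercept))
    else:
        tau0, r0_0 = 1.0, max(float(y[0]), 0.1)
    tau0 = float(np.clip(tau0, 0.05, 50.0))
    try:
        popt, _ = optimize.curve_fit(
            lambda n, r0, tau: r0 * np.exp(-n / tau), x, y,
            p0=[np.clip(r0_0, 0.01, 1.5), tau0],
            bounds=([0.0, 1e-3], [1.5, 100.0]), maxfev=10000)
        return float(popt[0]), float(popt[1])
    except RuntimeError:
        return r0_0, tau0


def fit_decay_timescale(sequences: list[np.ndarray],
                        n_max: int = DEFAULT_N_MAX,
                        n_boot: int = DEFAULT_N_BOOT,
                        ci_level: float = 0.90,
                        seed: int = 0) -> TimescaleFit:
    """Exponential decay constant of the lag-correlation profile, with a
    bout-resampling bootstrap CI.

    A non-positive lag-1 correlation means no measurable persistence: tau is
    reported as 0 with ``flagged=True``.
    """
    lags = np.arange(1, n_max + 1, dtype=float)
    r = lag_correlation_profile(sequences, n_max)
    if np.isfinite(r).sum() < 3:
        raise ValueError("need >= 3 estimable lags")
    if not np.isfinite(r[0]) or r[0] <= 0:
        logger.warning("non-positive lag-1 correlation; tau flagged as 0")
        return TimescaleFit(lags=lags, r=r, r0=float(r[0]), tau=0.0,
                            tau_ci=None, n_boot=0, ci_level=ci_level,
                            flagged=True)
    r0, tau = _fit_exp_decay(lags, r)
    tau_ci = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        taus = np.empty(n_boot)
        n_seq = len(sequences)
        for b in range(n_boot):
            pick = rng.integers(0, n_seq, size=n_seq)
            rb = lag_correlation_profile([sequences[i] for i in pick], n_max)
            if np.isfinite(rb).sum() < 3 or not np.isfinite(rb[0]) or rb[0] <= 0:
                taus[b] = 0.0
                continue
            _, taus[b] = _fit_exp_decay(lags, rb)
        alpha = (1.0 - ci_level) / 2.0
        tau_ci = (float(np.quantile(taus, alpha)),
                  float(np.quantile(taus, 1.0 - alpha)))
    return TimescaleFit(lags=lags, r=r, r0=r0, tau=tau, tau_ci=tau_ci,
                        n_boot=n_boot, ci_level=ci_level)
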