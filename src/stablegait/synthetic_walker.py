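"""Stochastic kinematic walker with known feedforward and feedback structure.

The generator emulates the control structure the analysis pipeline is built to
infer: a velocity-dependent feedforward module prescribing nominal step
geometry and timing, plus a linear feedback module mapping the lateral body
state error to a corrective adjustment of the next foot placement.

Discrete step-to-step model
---------------------------
The lateral body error ``e`` evolves on the gait-cycle clock.  Once per cycle
(at the contact of the anchor front limb) the error produces a corrective
placement deviation and is updated::

    d_n     = G * e_n + eps_n          (placement deviation, execution noise eps)
    e_{n+1} = a * e_n - c * d_n + eta_n    (c = 1; body noise eta)

so the closed-loop cycle-to-cycle coefficient is ``lambda = a - G``.  All legs
express the corrective deviation ``G * e`` at their own contacts (with
independent execution noise); the error update is driven by the anchor limb's
realized correction.  Lag-N autocorrelations of lateral placement deviations
therefore decay as ``lambda**N`` and the cycle return map has spectral radius
``|lambda|``.

Feedforward geometry
--------------------
Per cycle a commanded speed ``v`` is drawn and the nominal step length follows
the linear law ``L = beta0 + beta1 * v``.  Because any rendered walker
satisfies the kinematic identity ``v * T_cycle = 2 * L`` exactly, the cycle
duration is induced as ``T = 2 * L / v`` (hyperbolic in ``v``, closely
approximated by an exponential decay over realistic speed ranges) rather than
drawn from an independent duration law; an explicit ``duration_beta`` override
is accepted, in which case the realized body speed becomes ``2 L / T``.

Lateral placements form a relative chain: each contact is positioned with
respect to the previous contact of the opposite-group front limb, which is
exactly the reference the processing pipeline subtracts during spatial
normalization.  The body's lateral coordinate is anchored to the most recent
front-limb contact plus the error state, so body-state deviations measured in
the pipeline's normalized frame equal ``e`` by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .species_io import ContactEvent, SpeciesProfile, TrajectoryBout, builtin_profile

__all__ = [
    "WalkerParams",
    "SimulationResult",
    "step_dynamics",
    "simulate_walker",
    "simulate_individuals",
    "render_trajectories",
]


@dataclass(frozen=True)
class WalkerParams:
    """Generative ground truth for the synthetic walker.

    Noise scales are in the same (species-native) length unit as the
    feedforward coefficients; defaults are human-scale metres.

    Parameters
    ----------
    v_mean, v_sd : float
        Commanded speed distribution (length/s), truncated to stay positive.
    length_beta : (beta0, beta1)
        Linear step-length law ``L = beta0 + beta1 * v``.
    width_beta : (beta0, beta1)
        Linear step-width law; the default slope of zero reflects walking
        step width being velocity-independent.
    duration_beta : optional (beta0, beta1, beta2, beta3)
        Explicit exponential step-duration law
        ``T = beta0 * exp(-beta1 (v - beta2)) + beta3``.  ``None`` (default)
        induces the duration from the kinematic identity ``T = 2 L / v``.
    duty : float
        Stance fraction of the gait cycle.
    a : float
        Step-to-step carry-over of the lateral body error, ``|a| < 1``.
    gain : float
        Lateral feedback gain G (fraction of the body error mapped into the
        next placement).
    medial_gain, lateral_gain : optional float
        Direction-specific gains overriding ``gain`` for errors directed
        toward / away from the reference stance foot.
    gain_by_leg : optional mapping
        Per-leg multiplicative scaling of the feedback gain.
    sigma_body : float
        Per-cycle lateral body-state noise (eta).
    sigma_foot : float
        Independent placement execution noise, applied per contact in x and y.
    sigma_obs : float
        Per-frame marker observation noise.
    sigma_time : float
        Contact-timing execution jitter in seconds.
    heading_rate : float
        Constant turning rate (rad/s); nonzero values exist to exercise
        straightness rejection, default straight.
    """

    profile: SpeciesProfile = field(default_factory=lambda: builtin_profile("biped"))
    v_mean: float = 1.2
    v_sd: float = 0.2
    length_beta: tuple[float, float] = (0.2, 0.4)
    width_beta: tuple[float, float] = (0.12, 0.0)
    duration_beta: tuple[float, float, float, float] | None = None
    duty: float = 0.6
    a: float = 0.9
    gain: float = 0.4
    medial_gain: float | None = None
    lateral_gain: float | None = None
    gain_by_leg: Mapping[str, float] | None = None
    sigma_body: float = 0.012
    sigma_foot: float = 0.004
    sigma_obs: float = 0.0005
    sigma_time: float = 0.01
    heading_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not abs(self.a) < 1:
            raise ValueError("persistence a must satisfy |a| < 1")
        if not 0 < self.duty < 1:
            raise ValueError("duty must be in (0, 1)")
        for name in ("sigma_body", "sigma_foot", "sigma_obs", "sigma_time"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        lo = max(self.v_mean - 4 * self.v_sd, 0.05 * self.v_mean)
        if self.step_length(lo) <= 0:
            raise ValueError("step-length law non-positive over the speed range")
        if self.duration_beta is not None and self.cycle_duration(lo) <= 0:
            raise ValueError("duration law non-positive over the speed range")

    # nominal feedforward laws -------------------------------------------
    def step_length(self, v):
        b0, b1 = self.length_beta
        return b0 + b1 * np.asarray(v, dtype=float)

    def step_width(self, v):
        b0, b1 = self.width_beta
        return b0 + b1 * np.asarray(v, dtype=float)

    def cycle_duration(self, v):
        """Gait-cycle duration; induced from the length law unless overridden."""
        v = np.asarray(v, dtype=float)
        if self.duration_beta is None:
            return 2.0 * self.step_length(v) / v
        b0, b1, b2, b3 = self.duration_beta
        return b0 * np.exp(-b1 * (v - b2)) + b3

    def directional_gain(self, medial: bool) -> float:
        if medial:
            return self.gain if self.medial_gain is None else self.medial_gain
        return self.gain if self.lateral_gain is None else self.lateral_gain

    def leg_gain_scale(self, leg: str) -> float:
        if self.gain_by_leg is None:
            return 1.0
        return float(self.gain_by_leg.get(leg, 1.0))


def step_dynamics(state_error: float, params: WalkerParams,
                  noise_draws: tuple[float, float] = (0.0, 0.0),
                  coupling: float = 1.0) -> tuple[float, float]:
    """One tick of the closed-loop lateral error map.

    Returns ``(next_state_error, placement_deviation)`` with
    ``placement_deviation = G e + eps_foot`` and
    ``next_state_error = a e - coupling * placement_deviation + eta_body``.
    The noise pair is ``(eta_body, eps_foot)``.
    """
    eta, eps = noise_draws
    d = params.gain * state_error + eps
    next_e = params.a * state_error - coupling * d + eta
    return next_e, d


# ---------------------------------------------------------------------------
# Discrete plan
# ---------------------------------------------------------------------------

# Lateral side sign per leg: +1 = left of travel.
def _leg_side(leg: str) -> float:
    return 1.0 if "left" in leg or leg == "left" else -1.0


# Fore-aft home offsets: fixed morphological stations along the body axis
# (anterior/posterior of the body centre), parsed from the leg label and
# scaled once by the nominal step length at the mean commanded speed.
def _leg_home_x(leg: str, L0: float) -> float:
    if leg.startswith("front"):
        return 0.35 * L0
    if leg.startswith("mid"):
        return 0.0
    if leg.startswith("hind"):
        return -0.35 * L0
    return 0.0


@dataclass
class _DiscretePlan:
    """Step-level output of the simulation, before rendering to frames."""
    cycle_starts: np.ndarray            # anchor-limb tick times, len n_cycles+1
    speeds: np.ndarray                  # commanded speed per cycle
    errors: np.ndarray                  # e_n at the tick times, len n_cycles+1
    contacts: dict[str, list[dict]]     # per leg: t_on, t_off, x, y, dev, ...
    widths: np.ndarray                  # nominal step width per cycle


@dataclass
class SimulationResult:
    """A rendered bout together with its generative ground truth."""
    bout: TrajectoryBout
    truth_contacts: dict[str, list[ContactEvent]]
    truth_states: np.ndarray
    truth_placement_dev: dict[str, np.ndarray]
    plan: _DiscretePlan
    params: WalkerParams


def _simulate_plan(params: WalkerParams, duration: float,
                   rng: np.random.Generator) -> _DiscretePlan:
    prof = params.profile
    t_mean = float(params.cycle_duration(params.v_mean))
    if duration < 3 * t_mean:
        raise ValueError(
            f"duration {duration:.3g}s covers fewer than 3 nominal gait cycles"
        )
    anchor = prof.front_leg(0)
    other_front = prof.front_leg(1)

    # Draw per-cycle commanded speeds until the plan covers `duration`.
    n_guess = int(np.ceil(duration / t_mean)) + 4
    speeds: list[float] = []
    starts = [0.0]
    while starts[-1] < duration:
        if len(speeds) >= n_guess:
            n_guess *= 2
        v = rng.normal(params.v_mean, params.v_sd)
        v = max(v, 0.2 * params.v_mean)
        speeds.append(v)
        starts.append(starts[-1] + float(params.cycle_duration(v)))
    v_arr = np.asarray(speeds)
    starts_arr = np.asarray(starts)
    n_cycles = len(speeds)
    lengths = params.step_length(v_arr)
    widths = params.step_width(v_arr)
    durations = np.diff(starts_arr)

    # Lateral error chain on the cycle clock, direction-dependent gain
    # classified against the side of the anchor leg's reference stance foot.
    lam = params.a - params.gain
    innov_sd = float(np.hypot(params.sigma_body, params.sigma_foot))
    e0_sd = innov_sd / max(np.sqrt(1 - lam ** 2), 1e-6)
    errors = np.empty(n_cycles + 1)
    errors[0] = rng.normal(0.0, e0_sd)
    anchor_dev = np.empty(n_cycles)
    ref_side_anchor = _leg_side(other_front)
    g_anchor = params.leg_gain_scale(anchor)
    for n in range(n_cycles):
        e = errors[n]
        medial = e * ref_side_anchor > 0
        g = params.directional_gain(medial) * g_anchor
        eps = rng.normal(0.0, params.sigma_foot)
        eta = rng.normal(0.0, params.sigma_body)
        d = g * e + eps
        errors[n + 1] = params.a * e - d + eta
        anchor_dev[n] = d

    # Contact chain.  Group 0 contacts at cycle starts, group 1 at mid-cycle.
    # Lateral placements are relative to the previous opposite-group front
    # contact; fore-aft placements ride the body's forward path.
    contacts: dict[str, list[dict]] = {leg: [] for leg in prof.leg_labels}
    home_scale = float(params.step_length(params.v_mean))
    # initial front-contact lanes (one per front leg), at nominal offsets
    w0 = widths[0]
    last_front_y = {
        anchor: _leg_side(anchor) * w0 / 2.0,
        other_front: _leg_side(other_front) * w0 / 2.0,
    }

    def body_x_at(t: float) -> float:
        # piecewise-linear forward path; body speed = 2 L / T per cycle
        i = int(np.clip(np.searchsorted(starts_arr, t, side="right") - 1,
                        0, n_cycles - 1))
        v_body = 2.0 * lengths[i] / durations[i]
        return float(np.sum(2.0 * lengths[:i]) + v_body * (t - starts_arr[i]))

    for n in range(n_cycles):
        t0, T = starts_arr[n], durations[n]
        w = widths[n]
        # each group's correction reads the lateral error as sensed at the
        # instant its reference limb (opposite-group front) touched down:
        # for the cycle-start group that was mid-previous-cycle (state e_n),
        # for the mid-cycle group it is the anchor touchdown at t0, whose
        # pre-exchange state is also e_n
        for group, (t_nom, e_now) in enumerate(
                [(t0, errors[n]), (t0 + T / 2.0, errors[n])]):
            ref_leg = prof.front_leg(1 - group)
            ref_side = _leg_side(ref_leg)
            ref_y = last_front_y[ref_leg]
            for leg in prof.limb_groups[group]:
                side = _leg_side(leg)
                if leg == anchor:
                    d = anchor_dev[n]
                else:
                    medial = e_now * ref_side > 0
                    g = params.directional_gain(medial) * params.leg_gain_scale(leg)
                    d = g * e_now + rng.normal(0.0, params.sigma_foot)
                t_c = t_nom + rng.normal(0.0, params.sigma_time)
                t_c = max(t_c, t_nom - 0.2 * T)
                cx = (body_x_at(t_c) + _leg_home_x(leg, home_scale)
                      + rng.normal(0.0, params.sigma_foot))
                cy = ref_y + (side - ref_side) * w / 2.0 + d
                contacts[leg].append({
                    "t_on": t_c, "t_off": t_c + params.duty * T,
                    "x": cx, "y": cy, "dev": d, "cycle": n, "v": v_arr[n],
                })
                if leg == ref_leg:
                    raise RuntimeError("reference leg cannot be in its own group")
            front = prof.front_leg(group)
            last_front_y[front] = contacts[front][-1]["y"]

    return _DiscretePlan(cycle_starts=starts_arr, speeds=v_arr, errors=errors,
                         contacts=contacts, widths=widths)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_trajectories(plan: _DiscretePlan, params: WalkerParams,
                        rng: np.random.Generator | None = None,
                        bout_id: str = "sim", animal_id: str = "",
                        ) -> TrajectoryBout:
    """Render a discrete plan to frame-rate marker trajectories.

    The body's fore-aft coordinate follows the commanded path; its lateral
    coordinate is anchored to the most recent front-limb contact plus the
    interpolated error state.  Feet are constant at their placement during
    stance and follow a cosine ease to the next placement during swing.
    Observation noise ``sigma_obs`` is added per frame.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed + 1)
    prof = params.profile
    fr = prof.frame_rate
    starts = plan.cycle_starts
    n_cycles = len(plan.speeds)
    t_end = starts[-1]
    t = np.arange(0.0, t_end, 1.0 / fr)

    # forward path (piecewise linear, slope 2 L / T per cycle)
    node_x = np.concatenate([[0.0], np.cumsum(2.0 * params.step_length(plan.speeds))])
    x_body = np.interp(t, starts, node_x)

    # lateral: most recent front-limb contact anchor + midline offset + error
    front_events = []  # (time, y, side, width of that cycle)
    for leg in prof.front_legs:
        for c in plan.contacts[leg]:
            front_events.append((c["t_on"], c["y"], _leg_side(leg),
                                 plan.widths[c["cycle"]]))
    front_events.sort()
    fe_t = np.asarray([f[0] for f in front_events])
    fe_y = np.asarray([f[1] for f in front_events])
    fe_side = np.asarray([f[2] for f in front_events])
    fe_w = np.asarray([f[3] for f in front_events])
    idx = np.clip(np.searchsorted(fe_t, t, side="right") - 1, 0, len(fe_t) - 1)
    # body error is step-discrete: it changes when a corrective contact
    # lands, so the rendered trace holds each state until the next anchor
    # contact (backward zero-order hold on the cycle clock)
    e_idx = np.clip(np.searchsorted(starts, t, side="left"), 0, n_cycles)
    e_state = plan.errors[e_idx]
    y_body = fe_y[idx] - fe_side[idx] * fe_w[idx] / 2.0 + e_state

    positions: dict[str, np.ndarray] = {}
    for marker in prof.body_markers:
        positions[marker] = np.column_stack([x_body, y_body])

    for leg in prof.leg_labels:
        evs = plan.contacts[leg]
        if not evs:
            raise ValueError(f"no contacts for leg {leg}")
        for a, b in zip(evs, evs[1:]):
            if b["t_on"] < a["t_off"]:
                raise ValueError(f"overlapping stance intervals for leg {leg}")
        fx = np.empty_like(t)
        fy = np.empty_like(t)
        fx[:] = evs[0]["x"]
        fy[:] = evs[0]["y"]
        for k, ev in enumerate(evs):
            in_stance = (t >= ev["t_on"]) & (t < ev["t_off"])
            fx[in_stance] = ev["x"]
            fy[in_stance] = ev["y"]
            if k + 1 < len(evs):
                nxt = evs[k + 1]
                in_swing = (t >= ev["t_off"]) & (t < nxt["t_on"])
                s = (t[in_swing] - ev["t_off"]) / (nxt["t_on"] - ev["t_off"])
                ease = 0.5 * (1.0 - np.cos(np.pi * s))
                fx[in_swing] = ev["x"] + (nxt["x"] - ev["x"]) * ease
                fy[in_swing] = ev["y"] + (nxt["y"] - ev["y"]) * ease
            else:
                fx[t >= ev["t_off"]] = ev["x"]
                fy[t >= ev["t_off"]] = ev["y"]
        fx[t < evs[0]["t_on"]] = evs[0]["x"]
        fy[t < evs[0]["t_on"]] = evs[0]["y"]
        positions[leg] = np.column_stack([fx, fy])

    if params.heading_rate != 0.0:
        positions = _bend_heading(t, x_body, positions, params.heading_rate)

    if params.sigma_obs > 0:
        for marker in positions:
            positions[marker] = positions[marker] + rng.normal(
                0.0, params.sigma_obs, size=positions[marker].shape)

    return TrajectoryBout(bout_id=bout_id, species=prof, t=t,
                          positions=positions,
                          animal_id=animal_id or bout_id)


def _bend_heading(t: np.ndarray, x_body: np.ndarray,
                  positions: dict[str, np.ndarray], rate: float,
                  ) -> dict[str, np.ndarray]:
    """Warp a straight-frame trajectory onto a constantly turning path."""
    theta = rate * t
    dx = np.diff(x_body, prepend=x_body[0])
    path = np.column_stack([np.cumsum(dx * np.cos(theta)),
                            np.cumsum(dx * np.sin(theta))])
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    out = {}
    for marker, xy in positions.items():
        rel_x = xy[:, 0] - x_body
        rel_y = xy[:, 1]
        out[marker] = np.column_stack([
            path[:, 0] + rel_x * cos_t - rel_y * sin_t,
            path[:, 1] + rel_x * sin_t + rel_y * cos_t,
        ])
    return out


# ---------------------------------------------------------------------------
# Top-level simulation
# ---------------------------------------------------------------------------

def simulate_walker(params: WalkerParams, duration: float,
                    bout_id: str = "sim", animal_id: str = "",
                    ) -> SimulationResult:
    """Simulate a bout of `duration` seconds and render it to frames.

    Identical parameters (including ``seed``) give bit-identical results.
    """
    rng = np.random.default_rng(params.seed)
    plan = _simulate_plan(params, duration, rng)
    bout = render_trajectories(plan, params, rng=rng, bout_id=bout_id,
                               animal_id=animal_id)
    t_frames = bout.t
    truth_contacts: dict[str, list[ContactEvent]] = {}
    truth_dev: dict[str, np.ndarray] = {}
    for leg, evs in plan.contacts.items():
        out = []
        for ev in evs:
            i_on = int(np.searchsorted(t_frames, ev["t_on"]))
            i_off = int(np.searchsorted(t_frames, ev["t_off"]))
            if i_off >= len(t_frames):
                continue
            if i_off <= i_on:
                i_off = i_on + 1
            out.append(ContactEvent(leg=leg, onset_index=i_on,
                                    offset_index=i_off,
                                    placement=(ev["x"], ev["y"]),
                                    onset_time=ev["t_on"],
                                    offset_time=ev["t_off"]))
        truth_contacts[leg] = out
        truth_dev[leg] = np.asarray([ev["dev"] for ev in evs])
    return SimulationResult(bout=bout, truth_contacts=truth_contacts,
                            truth_states=plan.errors,
                            truth_placement_dev=truth_dev,
                            plan=plan, params=params)


def simulate_individuals(params: WalkerParams, n_individuals: int,
                         duration: float, id_prefix: str = "ind",
                         ) -> list[SimulationResult]:
    """Simulate independent individuals (one bout each) with derived seeds."""
    results = []
    for i in range(n_individuals):
        p = replace(params, seed=(params.seed * 1000003 + i) % (2 ** 31 - 1))
        results.append(simulate_walker(p, duration,
                                       bout_id=f"{id_prefix}{i:02d}",
                                       animal_id=f"{id_prefix}{i:02d}"))
    return results
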