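"""Transform raw bouts into phase- and spatially-normalized gait cycles.

Processing order: straight-segment selection -> heading alignment -> contact
detection -> per-leg cycle segmentation -> phase normalization onto a fixed
gait-fraction grid -> spatial normalization against the last contact of the
opposite-group front limb.

Conventions
-----------
* Gait fraction ``phi`` runs from 0 at a leg's contact initiation to 1 at its
  next contact initiation (the contact being predicted).
* The contact detector's "extrema" method works on the *signed* fore-aft
  displacement of the foot relative to the body: touchdown is a maximum (the
  foot is maximally ahead), liftoff a minimum.  An unsigned distance would
  make both transitions maxima.
* Step length is the fore-aft component ``p_x`` and step width the lateral
  magnitude ``|p_y|`` of the placement expressed relative to the reference
  contact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .species_io import ContactEvent, SpeciesProfile, TrajectoryBout

logger = logging.getLogger("stablegait")

__all__ = [
    "GaitCycle",
    "select_straight_bouts",
    "align_heading",
    "detect_contacts",
    "segment_cycles",
    "phase_normalize",
    "spatial_normalize",
    "process_bouts",
]

#: Half-window (in frames) of the local linear fit used for velocities.
VEL_HALF_WINDOW = 5

#: Moving-average window (seconds) used to smooth velocity before heading.
HEADING_SMOOTH_S = 0.25

#: Peak prominence for the extrema contact detector, as a fraction of the
#: displacement range.
PEAK_PROMINENCE_FRAC = 0.10


@dataclass
class GaitCycle:
    """One phase- and spatially-normalized gait cycle of one leg.

    ``Q`` stacks the body-state channels over the phase grid (for every body
    marker: x position, y position, x velocity, y velocity); ``Q_tilde`` the
    same four channels for the cycle's own foot marker.  ``Q_ext`` extends the
    body state half a cycle past the predicted contact (phases (1, 1.5]),
    expressed relative to the placed contact, for error-reduction analyses.
    """

    leg: str
    animal_id: str
    bout_id: str
    cycle_index: int
    v_hat: float
    duration: float
    phase_grid: np.ndarray
    Q: np.ndarray                    # (M, 4 * n_body_markers)
    Q_channels: tuple[str, ...]
    Q_tilde: np.ndarray              # (M, 4)
    placement: np.ndarray            # (2,) spatially normalized
    contact_time: float
    phi_swing: float = float("nan")  # stance->swing phase of the placed foot
    reference_leg: str = ""
    reference_side: float = 0.0
    Q_ext: np.ndarray | None = None  # (M_ext, 4 * n_body_markers)
    ext_phases: np.ndarray | None = None
    normalized: bool = False
    meta: dict = field(default_factory=dict)

    @property
    def M(self) -> int:
        return len(self.phase_grid)


# ---------------------------------------------------------------------------
# Straightness selection and alignment
# ---------------------------------------------------------------------------

def _body_centroid(bout: TrajectoryBout) -> np.ndarray:
    return np.mean([bout.positions[m] for m in bout.species.body_markers], axis=0)


def _heading_series(bout: TrajectoryBout) -> np.ndarray:
    """Unwrapped heading (rad) of the smoothed body velocity."""
    pos = _body_centroid(bout)
    dt = float(np.median(np.diff(bout.t)))
    vel = np.gradient(pos, axis=0) / dt
    win = max(1, int(round(HEADING_SMOOTH_S / dt)))
    if win > 1:
        kernel = np.ones(win) / win
        vel = np.column_stack([
            np.convolve(vel[:, 0], kernel, mode="same"),
            np.convolve(vel[:, 1], kernel, mode="same"),
        ])
    return np.unwrap(np.arctan2(vel[:, 1], vel[:, 0]))


def _nominal_cycle_frames(bout: TrajectoryBout) -> int:
    """Rough frames-per-cycle estimate from the dominant oscillation of the
    first leg's fore-aft displacement relative to the body."""
    leg = bout.species.leg_labels[0]
    rel = bout.positions[leg][:, 0] - _body_centroid(bout)[:, 0]
    rel = rel - rel.mean()
    n = len(rel)
    if n < 16:
        return n
    spec = np.abs(np.fft.rfft(rel * np.hanning(n))) ** 2
    spec[0] = 0.0
    k = int(np.argmax(spec))
    if k == 0:
        return n
    return max(4, int(round(n / k)))


def select_straight_bouts(bouts: list[TrajectoryBout],
                          threshold: float | None = None,
                          ) -> list[TrajectoryBout]:
    """Keep maximal contiguous segments whose heading range stays within
    ``threshold`` degrees; segments shorter than three nominal gait cycles
    are dropped.  Turning portions are excised, possibly splitting a bout.
    """
    out: list[TrajectoryBout] = []
    for bout in bouts:
        thr_deg = (bout.species.straightness_threshold
                   if threshold is None else threshold)
        thr = np.deg2rad(thr_deg)
        heading = _heading_series(bout)
        min_len = 3 * _nominal_cycle_frames(bout)
        n = len(heading)
        segments: list[tuple[int, int]] = []
        start = 0
        lo = hi = heading[0]
        for i in range(1, n):
            lo, hi = min(lo, heading[i]), max(hi, heading[i])
            if hi - lo > thr:
                segments.append((start, i))
                start = i
                lo = hi = heading[i]
        segments.append((start, n))
        for k, (i0, i1) in enumerate(segments):
            if i1 - i0 < max(min_len, 8):
                logger.info("bout %s: dropped short/turning segment [%d:%d]",
                            bout.bout_id, i0, i1)
                continue
            sub = TrajectoryBout(
                bout_id=bout.bout_id if len(segments) == 1
                else f"{bout.bout_id}.s{k}",
                species=bout.species,
                t=bout.t[i0:i1].copy(),
                positions={m: p[i0:i1].copy()
                           for m, p in bout.positions.items()},
                animal_id=bout.animal_id,
                meta=dict(bout.meta),
            )
            out.append(sub)
    return out


def align_heading(bout: TrajectoryBout) -> TrajectoryBout:
    """Rigidly rotate a straight bout so its mean travel direction is +x.

    One planar rotation is applied to every marker, preserving all pairwise
    inter-marker distances.
    """
    pos = _body_centroid(bout)
    disp = pos[-1] - pos[0]
    norm = float(np.hypot(*disp))
    scale = float(np.max(np.abs(pos - pos[0]))) or 1.0
    if norm < 1e-9 * scale or norm == 0.0:
        raise ValueError(f"bout {bout.bout_id}: zero net displacement")
    angle = np.arctan2(disp[1], disp[0])
    c, s = np.cos(-angle), np.sin(-angle)
    rot = np.array([[c, -s], [s, c]])
    aligned = bout.copy()
    aligned.positions = {m: p @ rot.T for m, p in bout.positions.items()}
    aligned.meta["heading_rotation_rad"] = float(-angle)
    return aligned


# ---------------------------------------------------------------------------
# Contact detection
# ---------------------------------------------------------------------------

def _lowpass(x: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    nyq = fs / 2.0
    if cutoff >= 0.95 * nyq:
        return x
    b, a = sps.butter(2, cutoff / nyq)
    padlen = min(3 * max(len(a), len(b)), len(x) - 1)
    return sps.filtfilt(b, a, x, padlen=padlen)


def detect_contacts(bout: TrajectoryBout, leg: str,
                    method: str = "extrema",
                    speed_threshold_frac: float = 0.25,
                    smooth_cycles: float = 5.0,
                    ) -> list[ContactEvent]:
    """Detect stance periods of one leg on an aligned bout.

    ``extrema``: stance onsets are local maxima and stance ends local minima
    of the low-pass filtered signed fore-aft foot-minus-body displacement,
    with a minimum prominence of 10% of the displacement range and a minimum
    spacing of half the running median cycle.  ``velocity_threshold``: stance
    wherever the foot's planar speed stays below a fraction of the median
    body speed for a minimum dwell.  Placement is the mean foot position over
    stance.  Fewer than two detected cycles returns an empty list.
    """
    t = bout.t
    fs = 1.0 / float(np.median(np.diff(t)))
    foot = bout.positions[leg]
    body = _body_centroid(bout)
    period = _nominal_cycle_frames(bout)

    if method == "extrema":
        rel = foot[:, 0] - body[:, 0]
        rel_f = _lowpass(rel, fs, smooth_cycles * fs / period)
        rng_amp = float(np.ptp(rel_f))
        if rng_amp <= 0:
            return []
        prom = PEAK_PROMINENCE_FRAC * rng_amp
        # first pass without spacing to estimate the cycle, then re-detect
        maxima, _ = sps.find_peaks(rel_f, prominence=prom)
        if len(maxima) >= 3:
            period = int(np.median(np.diff(maxima)))
        dist = max(1, period // 2)
        maxima, _ = sps.find_peaks(rel_f, prominence=prom, distance=dist)
        minima, _ = sps.find_peaks(-rel_f, prominence=prom, distance=dist)
        # refine event frames: the displacement extremum leads/lags the true
        # transition slightly (the foot's speed crosses the body's before it
        # stops), so snap each event to where the foot becomes / ceases to
        # be stationary within a window around the coarse peak
        w = max(2, period // 10)
        n_rel = len(rel)
        step_foot = np.linalg.norm(np.diff(foot, axis=0), axis=1)
        thr = 0.3 * float(np.median(np.linalg.norm(np.diff(body, axis=0),
                                                   axis=1)))

        def snap_onset(i: int) -> int:
            lo, hi = max(i - w, 0), min(i + w, n_rel - 2)
            for j in range(lo, hi + 1):
                if step_foot[j] < thr:
                    return j
            return i

        def snap_offset(i: int) -> int:
            lo, hi = max(i - w, 1), min(i + w, n_rel - 1)
            for j in range(hi, lo - 1, -1):
                if step_foot[j - 1] < thr:
                    return j
            return i

        maxima = np.array([snap_onset(int(i)) for i in maxima])
        minima = np.array([snap_offset(int(i)) for i in minima])
        if len(maxima) < 2:
            logger.warning("bout %s leg %s: fewer than 2 cycles detected",
                           bout.bout_id, leg)
            return []
        events = []
        for i_on in maxima:
            later = minima[minima > i_on]
            if len(later) == 0:
                break
            i_off = int(later[0])
            nxt = maxima[maxima > i_on]
            if len(nxt) and i_off > nxt[0]:
                continue  # missing liftoff inside this cycle
            events.append((int(i_on), i_off))
    elif method == "velocity_threshold":
        dt = 1.0 / fs
        foot_v = np.linalg.norm(np.gradient(foot, axis=0) / dt, axis=1)
        body_v = np.linalg.norm(np.gradient(body, axis=0) / dt, axis=1)
        thr = speed_threshold_frac * float(np.median(body_v))
        slow = foot_v < thr
        min_dwell = max(2, int(0.1 * period))
        events = []
        i = 0
        n = len(slow)
        while i < n:
            if slow[i]:
                j = i
                while j < n and slow[j]:
                    j += 1
                if j - i >= min_dwell:
                    events.append((i, j - 1))
                i = j
            else:
                i += 1
        if len(events) < 2:
            logger.warning("bout %s leg %s: fewer than 2 cycles detected",
                           bout.bout_id, leg)
            return []
    else:
        raise ValueError(f"unknown contact detection method {method!r}")

    contacts = []
    for i_on, i_off in events:
        if i_off <= i_on:
            continue
        placement = foot[i_on:i_off + 1].mean(axis=0)
        contacts.append(ContactEvent(
            leg=leg, onset_index=i_on, offset_index=i_off,
            placement=(float(placement[0]), float(placement[1])),
            onset_time=float(t[i_on]), offset_time=float(t[i_off]),
        ))
    return contacts


# ---------------------------------------------------------------------------
# Segmentation and normalization
# ---------------------------------------------------------------------------

def _bout_velocities(bout: TrajectoryBout, markers: list[str],
                     half_window: int | None = None) -> dict[str, np.ndarray]:
    """Marker velocities as the slope of a centered local linear fit.

    A Savitzky-Golay first-derivative filter of polynomial order 1 over
    ``2 * half_window + 1`` frames: exact for locally linear motion, and it
    averages frame-to-frame tracking noise over the whole window instead of
    amplifying it the way an endpoint difference does.
    """
    t = bout.t
    out = {}
    k = VEL_HALF_WINDOW if half_window is None else half_window
    dt = float(np.median(np.diff(t)))
    win = min(2 * k + 1, len(t) if len(t) % 2 else len(t) - 1)
    for m in markers:
        p = bout.positions[m]
        if win < 3:
            v = np.gradient(p, axis=0) / dt
        else:
            v = sps.savgol_filter(p, window_length=win, polyorder=1,
                                  deriv=1, delta=dt, axis=0)
        out[m] = v
    return out


def segment_cycles(bout: TrajectoryBout,
                   contacts: dict[str, list[ContactEvent]],
                   profile: SpeciesProfile,
                   use_terminations: bool = False,
                   ) -> list[GaitCycle]:
    """Build raw (un-normalized) cycles per leg from consecutive contact
    initiations (or terminations if ``use_terminations``).

    ``v_hat`` is the mean fore-aft body velocity over the cycle.  Cycles with
    non-positive ``v_hat`` or durations beyond 3x the per-leg median are
    dropped and logged.  The raw cycle stores frame index bounds in ``meta``;
    phase/spatial normalization fill the state matrices.
    """
    body = _body_centroid(bout)
    t = bout.t
    cycles: list[GaitCycle] = []
    for leg in profile.leg_labels:
        evs = contacts.get(leg, [])
        if len(evs) < 2:
            continue
        marks = ([e.offset_index for e in evs] if use_terminations
                 else [e.onset_index for e in evs])
        durs = np.diff([t[i] for i in marks])
        med = float(np.median(durs)) if len(durs) else 0.0
        for k in range(len(marks) - 1):
            i0, i1 = marks[k], marks[k + 1]
            dur = float(t[i1] - t[i0])
            if med > 0 and dur > 3 * med:
                logger.info("bout %s leg %s: dropped duration-outlier cycle "
                            "%d (%.3fs > 3x median)", bout.bout_id, leg, k, dur)
                continue
            v_hat = float((body[i1, 0] - body[i0, 0]) / dur)
            if v_hat <= 0:
                logger.info("bout %s leg %s: dropped non-forward cycle %d",
                            bout.bout_id, leg, k)
                continue
            end_ev = evs[k + 1] if not use_terminations else evs[k + 1]
            # stance->swing transition of this leg inside the cycle
            phi_swing = float("nan")
            if not use_terminations:
                off_t = evs[k].offset_time
                if t[i0] < off_t < t[i1]:
                    phi_swing = (off_t - t[i0]) / dur
            cycles.append(GaitCycle(
                leg=leg, animal_id=bout.animal_id, bout_id=bout.bout_id,
                cycle_index=k, v_hat=v_hat, duration=dur,
                phase_grid=np.empty(0), Q=np.empty((0, 0)), Q_channels=(),
                Q_tilde=np.empty((0, 0)), placement=np.asarray(
                    end_ev.placement, dtype=float),
                contact_time=float(t[i0]), phi_swing=phi_swing,
                meta={"i0": int(i0), "i1": int(i1),
                      "end_contact": end_ev, "bout": bout},
            ))
    return cycles


def phase_normalize(cycle: GaitCycle, M: int | None = None,
                    ext_fraction: float = 0.5) -> GaitCycle | None:
    """Interpolate a raw cycle's positions and velocities onto ``M`` uniform
    gait fractions in [0, 1].

    Velocities are computed by central differences on raw frames before
    interpolation.  Cycles spanning fewer than 4 frames are dropped (None).
    When the bout extends at least ``ext_fraction`` of a cycle past the end
    contact, an extended body-state block over phases (1, 1 + ext_fraction]
    is attached for error-reduction analyses.
    """
    bout: TrajectoryBout = cycle.meta["bout"]
    profile = bout.species
    if M is None:
        M = profile.phase_grid_size
    i0, i1 = cycle.meta["i0"], cycle.meta["i1"]
    if i1 - i0 + 1 < 4:
        logger.info("bout %s leg %s: dropped cycle %d with <4 frames",
                    cycle.bout_id, cycle.leg, cycle.cycle_index)
        return None
    markers = list(profile.body_markers) + [cycle.leg]
    vel_key = "_velocities"
    if vel_key not in bout.meta:
        bout.meta[vel_key] = _bout_velocities(
            bout, list(profile.body_markers) + list(profile.leg_labels))
    vels = bout.meta[vel_key]

    t = bout.t
    phases = np.arange(M) / (M - 1) if M > 1 else np.zeros(1)
    t_grid = t[i0] + phases * (t[i1] - t[i0])
    seg = slice(i0, i1 + 1)

    def interp_block(ms: list[str], tq: np.ndarray, sl: slice) -> np.ndarray:
        cols = []
        for m in ms:
            p = bout.positions[m][sl]
            v = vels[m][sl]
            ts = t[sl]
            cols += [np.interp(tq, ts, p[:, 0]), np.interp(tq, ts, p[:, 1]),
                     np.interp(tq, ts, v[:, 0]), np.interp(tq, ts, v[:, 1])]
        return np.column_stack(cols)

    channels = []
    for m in profile.body_markers:
        channels += [f"{m}:x", f"{m}:y", f"{m}:vx", f"{m}:vy"]
    cycle.Q = interp_block(list(profile.body_markers), t_grid, seg)
    cycle.Q_channels = tuple(channels)
    cycle.Q_tilde = interp_block([cycle.leg], t_grid, seg)
    cycle.phase_grid = phases

    # extended window past the predicted contact
    m_ext = max(2, int(round(M * ext_fraction)))
    t_ext_end = t[i1] + ext_fraction * cycle.duration
    if t_ext_end <= t[-1]:
        i2 = int(np.searchsorted(t, t_ext_end))
        ext_phases = 1.0 + (np.arange(1, m_ext + 1) / m_ext) * ext_fraction
        tq = t[i1] + (ext_phases - 1.0) * cycle.duration
        cycle.Q_ext = interp_block(list(profile.body_markers), tq,
                                   slice(i1, min(i2 + 2, len(t))))
        cycle.ext_phases = ext_phases
    return cycle


def spatial_normalize(cycle: GaitCycle,
                      contacts: dict[str, list[ContactEvent]],
                      profile: SpeciesProfile) -> GaitCycle | None:
    """Express positions relative to the last contact of the opposite-group
    front limb preceding the cycle's end contact.

    Position channels of ``Q``, ``Q_tilde`` and the placement are shifted by
    the reference contact location (velocities are unaffected).  The extended
    block, when present, is instead referenced to the placed contact itself,
    which becomes the body's new support anchor.  Cycles without a qualifying
    reference contact are dropped (None).
    """
    ref_leg = profile.opposite_front(cycle.leg)
    end_time = cycle.contact_time + cycle.duration
    candidates = [e for e in contacts.get(ref_leg, [])
                  if e.onset_time < end_time - 1e-9
                  and e.onset_time >= cycle.contact_time - 1.5 * cycle.duration]
    if not candidates:
        logger.info("bout %s leg %s: dropped cycle %d without reference "
                    "contact of %s", cycle.bout_id, cycle.leg,
                    cycle.cycle_index, ref_leg)
        return None
    ref = max(candidates, key=lambda e: e.onset_time)
    ref_xy = np.asarray(ref.placement, dtype=float)

    def shift_positions(block: np.ndarray, origin: np.ndarray) -> np.ndarray:
        out = block.copy()
        ncols = block.shape[1]
        for c in range(0, ncols, 4):
            out[:, c] -= origin[0]
            out[:, c + 1] -= origin[1]
        return out

    cycle.Q = shift_positions(cycle.Q, ref_xy)
    cycle.Q_tilde = shift_positions(cycle.Q_tilde, ref_xy)
    own_xy = cycle.placement.copy()
    cycle.placement = cycle.placement - ref_xy
    if cycle.Q_ext is not None:
        cycle.Q_ext = shift_positions(cycle.Q_ext, own_xy)
    cycle.reference_leg = ref_leg
    cycle.reference_side = float(np.sign(ref_xy[1] - own_xy[1])) or 1.0
    cycle.normalized = True
    cycle.meta.pop("bout", None)
    cycle.meta.pop("end_contact", None)
    return cycle


def process_bouts(bouts: list[TrajectoryBout],
                  profile: SpeciesProfile,
                  method: str = "extrema",
                  M: int | None = None,
                  straightness_threshold: float | None = None,
                  provided_contacts: bool = True,
                  ) -> list[GaitCycle]:
    """Full processing chain: select straight segments, align heading,
    detect contacts, segment, phase- and spatially-normalize."""
    cycles: list[GaitCycle] = []
    for sub in select_straight_bouts(bouts, straightness_threshold):
        aligned = align_heading(sub)
        if provided_contacts and sub.provided_contacts is not None:
            # frame indices are taken as-is (valid for unsplit bouts);
            # placements are recomputed in the aligned frame
            contacts = {}
            for leg, evs in sub.provided_contacts.items():
                foot = aligned.positions[leg]
                contacts[leg] = [
                    ContactEvent(
                        leg=leg, onset_index=e.onset_index,
                        offset_index=e.offset_index,
                        placement=tuple(
                            foot[e.onset_index:e.offset_index + 1].mean(axis=0)),
                        onset_time=e.onset_time, offset_time=e.offset_time)
                    for e in evs
                    if e.offset_index < len(aligned.t)]
        else:
            contacts = {leg: detect_contacts(aligned, leg, method=method)
                        for leg in profile.leg_labels}
        raw = segment_cycles(aligned, contacts, profile)
        for cyc in raw:
            cyc = phase_normalize(cyc, M=M)
            if cyc is None:
                continue
            cyc = spatial_normalize(cyc, contacts, profile)
            if cyc is None:
                continue
            cycles.append(cyc)
    return cycles
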