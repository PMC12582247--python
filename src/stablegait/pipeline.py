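"""End-to-end orchestration: simulate or load -> process -> infer -> report.

``run_pipeline`` executes the full inference chain and returns a
machine-readable report (JSON-serializable dict) containing per-leg
feedforward coefficients and significance counts, R^2(phi) profiles for the
body-state and baseline models with per-phase KS results, control
magnitudes, return-map eigenvalues and spectral radius, the error-reduction
slope, decay timescales with bootstrap CIs, medial/lateral gains with their
paired test, and limb-pair lag-1 correlations with the group test.  The
report embeds the configuration hash and seeds, so identical configurations
reproduce byte-identical reports (timestamps aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import species_io
from .feedback_model import (control_magnitude, directional_gains,
                             r2_phase_profile)
from .feedforward_model import (DeviationSet, compute_deviations,
                                fit_feedforward, timing_width_independence)
from .gait_processing import process_bouts
from .species_io import SpeciesProfile, builtin_profile, load_profile
from .stability_timescale import (error_reduction_analysis, fit_decay_timescale,
                                  fit_return_map, lag_correlation_profile,
                                  placement_sequences)
from .stats_core import compare_groups
from .synthetic_walker import WalkerParams, simulate_individuals

logger = logging.getLogger("stablegait")

__all__ = ["RunConfig", "run_pipeline", "save_report"]


@dataclass
class RunConfig:
    """Configuration of an end-to-end run.

    ``source`` is ``"simulate"`` (using ``walker`` parameters) or ``"file"``
    (reading ``input_path``).  Stage parameters default to the values the
    individual modules document.
    """
    profile: SpeciesProfile | str = "biped"
    source: str = "simulate"
    input_path: str | None = None
    walker: dict = field(default_factory=dict)
    n_individuals: int = 5
    duration: float = 120.0
    seed: int = 0
    contact_method: str = "extrema"
    phase_grid_size: int | None = None
    return_phase: float = 0.75
    n_max: int = 8
    n_boot: int = 1000
    ci_level: float = 0.90
    stages: tuple[str, ...] = ("feedforward", "feedback", "stability",
                               "timescale", "modularity")
    output_dir: str | None = None

    def resolve_profile(self) -> SpeciesProfile:
        if isinstance(self.profile, SpeciesProfile):
            return self.profile
        if self.profile in ("biped", "quadruped", "hexapod"):
            return builtin_profile(self.profile)
        return load_profile(self.profile)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        if isinstance(self.profile, SpeciesProfile):
            d["profile"] = dataclasses.asdict(self.profile)
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return f if np.isfinite(f) else None
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, complex):
        return {"re": obj.real, "im": obj.imag}
    return obj


def _acquire_cycles(config: RunConfig, profile: SpeciesProfile):
    if config.source == "simulate":
        params = WalkerParams(profile=profile, seed=config.seed,
                              **config.walker)
        sims = simulate_individuals(params, config.n_individuals,
                                    config.duration)
        bouts = [s.bout for s in sims]
    elif config.source == "file":
        if not config.input_path:
            raise ValueError("source='file' requires input_path")
        bouts = species_io.load_bouts(config.input_path, profile)
    else:
        raise ValueError(f"unknown source {config.source!r}")
    cycles = process_bouts(bouts, profile, method=config.contact_method,
                           M=config.phase_grid_size)
    if not cycles:
        raise RuntimeError("no gait cycles survived processing")
    return bouts, cycles


def run_pipeline(config: RunConfig) -> dict:
    """Execute all configured stages; stage failures are recorded in the
    report (``report["failures"]``) without aborting later stages."""
    profile = config.resolve_profile()
    report: dict = {
        "schema": "stablegait-report-v1",
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "species": profile.name,
        "failures": {},
    }
    bouts, cycles = _acquire_cycles(config, profile)
    report["n_bouts"] = len(bouts)
    report["n_cycles"] = len(cycles)
    dev = compute_deviations(cycles)
    front = profile.front_leg(0)
    swing_phase = dev.phi_swing.get(front, 0.6)

    if "feedforward" in config.stages:
        try:
            report["feedforward"] = _feedforward_stage(cycles, dev, profile)
        except Exception as exc:  # noqa: BLE001 - recorded, not silenced
            logger.exception("feedforward stage failed")
            report["failures"]["feedforward"] = repr(exc)

    if "feedback" in config.stages:
        try:
            report["feedback"] = _feedback_stage(dev, profile, swing_phase)
        except Exception as exc:  # noqa: BLE001
            logger.exception("feedback stage failed")
            report["failures"]["feedback"] = repr(exc)

    if "stability" in config.stages:
        try:
            report["stability"] = _stability_stage(dev, profile, config)
        except Exception as exc:  # noqa: BLE001
            logger.exception("stability stage failed")
            report["failures"]["stability"] = repr(exc)

    if "timescale" in config.stages:
        try:
            report["timescale"] = _timescale_stage(dev, profile, config)
        except Exception as exc:  # noqa: BLE001
            logger.exception("timescale stage failed")
            report["failures"]["timescale"] = repr(exc)

    if "modularity" in config.stages:
        try:
            report["modularity"] = _modularity_stage(dev, profile, config)
        except Exception as exc:  # noqa: BLE001
            logger.exception("modularity stage failed")
            report["failures"]["modularity"] = repr(exc)

    return _jsonable(report)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def _feedforward_stage(cycles, dev: DeviationSet, profile) -> dict:
    groups: dict[tuple[str, str], list] = {}
    for c in cycles:
        groups.setdefault((c.animal_id, c.leg), []).append(c)
    per_leg: dict[str, dict] = {}
    for (animal, leg), cyc in sorted(groups.items()):
        if len(cyc) < 10:
            continue
        ff = fit_feedforward(cyc)
        entry = per_leg.setdefault(leg, {"animals": {},
                                         "n_significant_length": 0,
                                         "n_animals": 0})
        entry["animals"][animal] = {
            "length": {"beta0": ff.length.beta0, "beta1": ff.length.beta1,
                       "p": ff.length.p_slope, "r2": ff.length.r2,
                       "se": ff.length.stderr},
            "width": {"beta0": ff.width.beta0, "beta1": ff.width.beta1,
                      "p": ff.width.p_slope},
            "duration": {"beta": ff.duration.beta,
                         "converged": ff.duration.converged,
                         "amplitude_at_median":
                             ff.duration.amplitude_at_median},
            "n_cycles": ff.n_cycles,
        }
        entry["n_animals"] += 1
        if ff.length.p_slope < 0.05:
            entry["n_significant_length"] += 1
    out = {"per_leg": per_leg}
    try:
        xi = timing_width_independence(dev, leg=profile.front_leg(0))
        out["timing_width_xi"] = {"xi": xi.xi, "p": xi.p, "n": xi.n}
    except ValueError as exc:
        out["timing_width_xi"] = {"error": str(exc)}
    return out


def _feedback_stage(dev: DeviationSet, profile, swing_phase: float) -> dict:
    front = profile.front_leg(0)
    out: dict = {"leg": front, "swing_onset_phase": swing_phase}
    for direction in ("lateral", "fore_aft"):
        comp = r2_phase_profile(dev, direction=direction, leg=front)
        med_b, lo_b, hi_b = comp.median_iqr("body")
        med_f, lo_f, hi_f = comp.median_iqr("baseline")
        out[direction] = {
            "phase_grid": comp.phase_grid,
            "r2_body_median": med_b, "r2_body_iqr": [lo_b, hi_b],
            "r2_baseline_median": med_f, "r2_baseline_iqr": [lo_f, hi_f],
            "ks_p": comp.ks_p,
        }
        if direction == "lateral":
            mags = control_magnitude(comp)
            out["control_magnitude"] = {
                "per_animal": mags, "median": float(np.median(mags)),
                "iqr": [float(np.percentile(mags, 25)),
                        float(np.percentile(mags, 75))],
            }
    gains = directional_gains(dev, swing_phase, front)
    out["directional_gains"] = {
        "animals": gains["animals"],
        "medial": gains["medial"], "lateral": gains["lateral"],
        "comparison": gains.get("comparison"),
    }
    return out


def _stability_stage(dev: DeviationSet, profile, config: RunConfig) -> dict:
    front = profile.front_leg(0)
    rm = fit_return_map(dev.for_leg(front), phase=config.return_phase)
    out = {
        "leg": front,
        "phase": rm.phase,
        "eigenvalues": [{"re": z.real, "im": z.imag}
                        for z in rm.eigenvalues],
        "spectral_radius": rm.spectral_radius,
        "spectral_radius_corrected": rm.spectral_radius_corrected,
        "n_pairs": rm.n_pairs,
    }
    try:
        fronts = list(profile.front_legs)
        mask = dev.index["leg"].isin(fronts).to_numpy()
        err = error_reduction_analysis(dev.subset(mask))
        out["error_reduction"] = {"slope": err.slope, "p": err.p,
                                  "p_positive": err.p_positive,
                                  "r": err.r, "n": err.n}
    except ValueError as exc:
        out["error_reduction"] = {"error": str(exc)}
    return out


def _timescale_stage(dev: DeviationSet, profile, config: RunConfig) -> dict:
    out: dict = {"per_leg": {}}
    taus = {}
    for leg in profile.leg_labels:
        seqs = placement_sequences(dev, leg)
        if not seqs:
            continue
        try:
            ts = fit_decay_timescale(seqs, n_max=config.n_max,
                                     n_boot=config.n_boot,
                                     ci_level=config.ci_level,
                                     seed=config.seed)
        except ValueError as exc:
            out["per_leg"][leg] = {"error": str(exc)}
            continue
        out["per_leg"][leg] = {
            "r": ts.r, "r0": ts.r0, "tau": ts.tau, "tau_ci": ts.tau_ci,
            "flagged": ts.flagged,
        }
        taus[leg] = ts.tau
    if taus:
        best = max(taus, key=taus.get)
        out["max_tau"] = {"leg": best, "tau": taus[best],
                          "tau_ci": out["per_leg"][best]["tau_ci"]}
    return out


def _leg_pair(leg: str) -> str:
    """Anterior-posterior pair label from a leg label."""
    for prefix in ("front", "mid", "hind"):
        if leg.startswith(prefix):
            return prefix
    return "all"


def _modularity_stage(dev: DeviationSet, profile, config: RunConfig) -> dict:
    """Limb-pair lag-1 correlations (per animal) and their group comparison,
    plus per-pair decay timescales."""
    pairs: dict[str, list[str]] = {}
    for leg in profile.leg_labels:
        pairs.setdefault(_leg_pair(leg), []).append(leg)
    out: dict = {"pairs": {}}
    r1_by_pair: dict[str, np.ndarray] = {}
    animals = sorted(dev.index["animal_id"].unique())
    for pair, legs in pairs.items():
        r1_animals = []
        for animal in animals:
            da = dev.for_animal(animal)
            seqs = []
            for leg in legs:
                seqs.extend(placement_sequences(da, leg))
            r = lag_correlation_profile(seqs, n_max=config.n_max)
            if np.isfinite(r[0]):
                r1_animals.append(r[0])
        r1_by_pair[pair] = np.asarray(r1_animals)
        seqs_all = []
        for leg in legs:
            seqs_all.extend(placement_sequences(dev, leg))
        try:
            ts = fit_decay_timescale(seqs_all, n_max=config.n_max,
                                     n_boot=min(config.n_boot, 1000),
                                     ci_level=config.ci_level,
                                     seed=config.seed)
            tau_entry = {"tau": ts.tau, "tau_ci": ts.tau_ci,
                         "flagged": ts.flagged}
        except ValueError as exc:
            tau_entry = {"error": str(exc)}
        out["pairs"][pair] = {"lag1_per_animal": r1_by_pair[pair],
                              "timescale": tau_entry}
    usable = {p: v for p, v in r1_by_pair.items() if len(v) >= 3}
    if len(usable) >= 2:
        paired = len({len(v) for v in usable.values()}) == 1
        out["lag1_comparison"] = compare_groups(usable,
                                                paired=paired and
                                                len(usable) == 2)
    return out


def save_report(report: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return path
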