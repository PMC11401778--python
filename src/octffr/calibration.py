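"""Cohort calibration of the two empirical model components.

Two procedures, run on a cohort of vessels with observed physiology:

1. the territory reference conductance g_ref_10 is root-solved so the
   territory-average simulated hyperemic flow matches the average observed
   flow;
2. the effective-lumen-radius correction k_lumencorr is chosen from a grid of
   candidates as the one whose observed-vs-simulated distal-pressure
   regression slope is closest to 1 (ties toward the smaller correction).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cardiac_driver import PressureWaveforms, generate_waveforms
from .config import RunConfig
from .errors import CalibrationError, InvalidParameterError
from .lumen_geometry import LumenProfile
from .pulsatile_solver import CoronaryCase, SimulationResult, SolverSettings, simulate

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CohortRecord:
    """One vessel's inputs and observed hyperemic physiology."""

    vessel_id: str
    territory: str
    profile: LumenProfile  # uncorrected ROI lumen profile
    a_prox_ref: float
    a_dist_ref: float
    hr: float
    mean_pa: float
    observed_ffr: Optional[float] = None
    observed_pd: Optional[float] = None
    observed_q: Optional[float] = None
    observed_r: Optional[float] = None

    def __post_init__(self) -> None:
        if self.observed_ffr is not None and not 0 < self.observed_ffr <= 1.1:
            raise InvalidParameterError("observed FFR outside (0, 1.1]")
        if self.observed_pd is not None and self.observed_pd > self.mean_pa * 1.05:
            raise InvalidParameterError("observed Pd exceeds mean Pa")


@dataclass
class CalibrationResult:
    """Calibrated parameters with fit diagnostics."""

    g_ref_10: dict = field(default_factory=dict)  # per territory, mL/s/mmHg
    k_lumencorr: Optional[float] = None
    diagnostics: dict = field(default_factory=dict)


class WaveformCache:
    """Reuse driver waveforms across repeated simulations of one vessel."""

    def __init__(self):
        self._store: dict = {}

    def get(self, hr: float, mean_pa: float) -> PressureWaveforms:
        key = (round(hr, 3), round(mean_pa, 3))
        if key not in self._store:
            self._store[key] = generate_waveforms(hr, mean_pa)
        return self._store[key]


def simulate_record(record: CohortRecord, config: RunConfig,
                    settings: Optional[SolverSettings] = None,
                    cache: Optional[WaveformCache] = None) -> SimulationResult:
    """Patient-specific simulation of one cohort vessel under ``config``."""
    cache = cache or WaveformCache()
    settings = settings or SolverSettings(dt=config.dt,
                                          max_cycles=config.max_cycles,
                                          convergence_tol=config.convergence_tol,
                                          newton_tol=config.newton_tol)
    case = CoronaryCase(profile=record.profile, a_prox_ref=record.a_prox_ref,
                        a_dist_ref=record.a_dist_ref, territory=record.territory,
                        config=config)
    wf = cache.get(record.hr, record.mean_pa)
    return simulate(case.build(), wf, settings)


def _territory_records(cohort: Sequence[CohortRecord], territory: str,
                       needs: str) -> list[CohortRecord]:
    t = territory.upper().replace("/", "_")
    recs = [r for r in cohort
            if r.territory.upper().replace("/", "_") == t
            and getattr(r, needs) is not None]
    return recs


def calibrate_conductance(cohort: Sequence[CohortRecord], territory: str,
                          config: Optional[RunConfig] = None,
                          settings: Optional[SolverSettings] = None,
                          cache: Optional[WaveformCache] = None,
                          g_bounds: tuple[float, float] = (5e-3, 0.5),
                          rtol: float = 1e-3) -> float:
    """Root-solve g_ref_10 so mean simulated flow equals mean observed flow.

    Deterministic; monotone in the target mean flow. Raises a calibration
    error when no bracketing interval exists within ``g_bounds``.
    """
    cfg = config or RunConfig()
    cache = cache or WaveformCache()
    recs = _territory_records(cohort, territory, "observed_q")
    if not recs:
        raise CalibrationError(f"no records with observed flow in {territory}")
    target = float(np.mean([r.observed_q for r in recs]))
    t = territory.upper().replace("/", "_")
    key = "g_ref_10_lad" if t == "LAD" else "g_ref_10_cx_rca"

    def residual(g: float) -> float:
        c = cfg.replace(**{key: g})
        sims = [simulate_record(r, c, settings, cache).mean_q for r in recs]
        return float(np.mean(sims)) - target

    lo, hi = g_bounds
    f_lo, f_hi = residual(lo), residual(hi)
    if f_lo * f_hi > 0:
        raise CalibrationError(
            f"no bracketing interval for g_ref_10 in {g_bounds}: "
            f"residuals {f_lo:.3f}, {f_hi:.3f} mL/s")
    g = optimize.brentq(residual, lo, hi, rtol=rtol, xtol=1e-6)
    return float(g)


def calibrate_lumen_correction(cohort: Sequence[CohortRecord],
                               candidate_values: Sequence[float],
                               config: Optional[RunConfig] = None,
                               settings: Optional[SolverSettings] = None,
                               cache: Optional[WaveformCache] = None,
                               through_origin: bool = False) -> tuple[float, pd.DataFrame]:
    """Pick the candidate whose observed-vs-simulated Pd slope is closest to 1.

    Observed Pd is regressed on simulated Pd (ordinary least squares with an
    intercept unless ``through_origin``). Ties break toward the smaller |k|.
    Returns the chosen value and a per-candidate diagnostics table.
    """
    if not candidate_values:
        raise CalibrationError("empty candidate list")
    cfg = config or RunConfig()
    cache = cache or WaveformCache()
    recs = [r for r in cohort if r.observed_pd is not None]
    if len(candidate_values) == 1:
        return float(candidate_values[0]), pd.DataFrame(
            columns=["k_lumencorr", "slope", "intercept", "rms_residual"])
    if len(recs) < 3:
        raise CalibrationError("need at least 3 records with observed Pd")
    obs = np.array([r.observed_pd for r in recs], dtype=float)
    rows = []
    for k in candidate_values:
        sim = np.array([simulate_record(r, cfg.replace(k_lumencorr=k),
                                        settings, cache).mean_pd for r in recs])
        if np.ptp(sim) < 1e-9:
            raise CalibrationError("degenerate regression: simulated Pd has "
                                   "zero variance")
        if through_origin:
            slope = float(np.dot(sim, obs) / np.dot(sim, sim))
            intercept = 0.0
        else:
            fit = stats.linregress(sim, obs)
            slope, intercept = float(fit.slope), float(fit.intercept)
        rows.append({"k_lumencorr": float(k), "slope": slope,
                     "intercept": intercept,
                     "rms_residual": float(np.sqrt(np.mean((obs - (intercept + slope * sim)) ** 2)))})
    table = pd.DataFrame(rows)
    order = sorted(range(len(rows)),
                   key=lambda i: (abs(rows[i]["slope"] - 1.0),
                                  abs(rows[i]["k_lumencorr"])))
    return float(rows[order[0]]["k_lumencorr"]), table


def conductance_area_ratio(cohort: Sequence[CohortRecord]) -> dict:
    """Measured microvascular conductance per proximal reference lumen area.

    Returns mean and SD of (60 / observed_r) / a_prox_ref in
    mL/min/mmHg/mm², overall and per territory.
    """
    vals: dict[str, list[float]] = {"ALL": []}
    for r in cohort:
        if r.observed_r is None:
            continue
        if r.observed_r <= 0:
            raise InvalidParameterError("observed resistance must be positive")
        ratio = (60.0 / r.observed_r) / r.a_prox_ref
        t = r.territory.upper().replace("/", "_")
        vals.setdefault(t, []).append(ratio)
        vals["ALL"].append(ratio)
    if not vals["ALL"]:
        raise CalibrationError("no records with observed resistance")
    return {k: (float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
            for k, v in vals.items() if v}


def calibrate(cohort: Sequence[CohortRecord],
              candidate_k: Sequence[float] = (0.0, -0.05, -0.075, -0.1),
              config: Optional[RunConfig] = None,
              settings: Optional[SolverSettings] = None) -> CalibrationResult:
    """Run both calibration procedures (flow first, then the lumen slope)."""
    cfg = config or RunConfig()
    cache = WaveformCache()
    result = CalibrationResult()
    for territory, key in (("LAD", "g_ref_10_lad"), ("CX_RCA", "g_ref_10_cx_rca")):
        if _territory_records(cohort, territory, "observed_q"):
            g = calibrate_conductance(cohort, territory, cfg, settings, cache)
            result.g_ref_10[territory] = g
            cfg = cfg.replace(**{key: g})
    k, table = calibrate_lumen_correction(cohort, candidate_k, cfg, settings, cache)
    result.k_lumencorr = k
    result.diagnostics = {"slope_table": table.to_dict(orient="records")}
    return result
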