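"""Synthetic lumen profiles and cohorts with known ground truth.

Stands in for patient OCT pullbacks (no deposited data exists): a linearly
tapering reference vessel with a Gaussian-bump focal stenosis and optional
frame-level measurement noise. Cohort generation draws geometry and
physiology from distributions centred on the study cohort (ROI length
50 ± 13 mm, proximal reference 10.57 ± 2.68 mm², distal reference
5.69 ± 2.09 mm², hyperemic mean Pa 83 ± 14 mmHg, LAD share 28/48) and
produces "observed" Pd/Q/FFR by running the simulator at the ground-truth
parameters and adding measurement noise (multiplicative on flow, additive on
distal pressure).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .calibration import CohortRecord, WaveformCache
from .config import RunConfig
from .errors import InvalidParameterError
from .lumen_geometry import LumenProfile

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticLesionSpec:
    """Parameters of one synthetic vessel/lesion.

    depth is the fraction of the local reference area removed at the stenosis
    centre; width is the Gaussian sigma in mm; noise_sd is additive area
    noise in mm².
    """

    roi_length: float = 50.0
    a_prox_ref: float = 10.57
    a_dist_ref: float = 5.69
    center: float = 25.0
    depth: float = 0.5
    width: float = 3.0
    noise_sd: float = 0.0
    spacing: float = 0.2
    seed: int = 0
    ectatic: bool = False
    second_lesion: Optional[tuple[float, float, float]] = None  # (center, depth, width)

    def __post_init__(self) -> None:
        if not 0 <= self.depth < 1:
            raise InvalidParameterError("depth must lie in [0, 1)")
        if self.width <= 0 or self.roi_length <= 0 or self.spacing <= 0:
            raise InvalidParameterError("width/length/spacing must be positive")
        if self.a_dist_ref > self.a_prox_ref or self.a_dist_ref <= 0:
            raise InvalidParameterError("need 0 < a_dist_ref <= a_prox_ref")


def synth_lumen_profile(spec: SyntheticLesionSpec) -> LumenProfile:
    """Deterministic (per seed) tapered vessel with a Gaussian-bump stenosis."""
    n = int(round(spec.roi_length / spec.spacing))
    x = np.arange(n + 1) * spec.spacing
    a_ref = spec.a_prox_ref + (spec.a_dist_ref - spec.a_prox_ref) * x / spec.roi_length
    shape = 1.0 - spec.depth * np.exp(-0.5 * ((x - spec.center) / spec.width) ** 2)
    if spec.second_lesion is not None:
        c2, d2, w2 = spec.second_lesion
        shape *= 1.0 - d2 * np.exp(-0.5 * ((x - c2) / w2) ** 2)
    if spec.ectatic:
        shape *= 1.0 + 0.5 * np.exp(-0.5 * ((x - 0.75 * spec.roi_length) / 6.0) ** 2)
    area = a_ref * shape
    if np.any(area <= 0):
        raise InvalidParameterError("lesion spec produces non-positive areas")
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        area = area + rng.normal(0.0, spec.noise_sd, area.size)
        area = np.maximum(area, 0.05)  # clip to a small positive lumen
    return LumenProfile(x, area, spec.spacing)


@dataclass
class SyntheticCohort:
    """Generated cohort plus the ground truth that produced it."""

    records: list
    specs: list
    ground_truth: dict
    seed: int


def synth_cohort(n: int = 20, lad_fraction: float = 28 / 48,
                 g_true: Optional[dict] = None, k_true: float = -0.075,
                 flow_noise: float = 0.05, pd_noise: float = 1.5,
                 lumen_noise_sd: float = 0.1, seed: int = 0,
                 config: Optional[RunConfig] = None,
                 cache: Optional[WaveformCache] = None) -> SyntheticCohort:
    """Generate a cohort whose observed physiology comes from the simulator
    run at the ground-truth (g_ref_10 per territory, k_lumencorr).

    flow_noise is the multiplicative SD applied to observed flow; pd_noise
    the additive SD (mmHg) applied to observed distal pressure. With both
    zero the observations equal the simulated values exactly.
    """
    from .calibration import simulate_record  # local import to avoid cycle

    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    base = config or RunConfig()
    g_true = g_true or {"LAD": base.g_ref_10_lad, "CX_RCA": base.g_ref_10_cx_rca}
    truth_cfg = base.replace(k_lumencorr=k_true,
                             g_ref_10_lad=g_true["LAD"],
                             g_ref_10_cx_rca=g_true["CX_RCA"])
    rng = np.random.default_rng(seed)
    cache = cache or WaveformCache()
    # stenosis severities cover mild to near-obstructive (FFR ~0.97 .. ~0.40)
    depths = rng.uniform(0.25, 0.95, n)
    records, specs = [], []
    for i in range(n):
        territory = "LAD" if (i < max(1, round(n * lad_fraction))) else "CX_RCA"
        roi = float(np.clip(rng.normal(50.0, 13.0), 30.0, 75.0))
        a_prox = float(np.clip(rng.normal(10.57, 2.68), 5.0, 18.0))
        ratio = float(np.clip(rng.normal(5.69 / 10.57, 0.08), 0.35, 0.8))
        spec = SyntheticLesionSpec(
            roi_length=roi, a_prox_ref=a_prox, a_dist_ref=a_prox * ratio,
            center=float(rng.uniform(0.25 * roi, 0.75 * roi)),
            depth=float(depths[i]),
            width=float(np.clip(rng.lognormal(np.log(3.0), 0.35), 1.5, 8.0)),
            noise_sd=lumen_noise_sd, seed=int(rng.integers(0, 2 ** 31 - 1)))
        profile = synth_lumen_profile(spec)
        # hyperemic hemodynamic state (heart rate quantized for waveform reuse)
        hr = float(np.clip(np.round(rng.normal(75.0, 8.0)), 55.0, 100.0))
        mean_pa = float(np.clip(np.round(rng.normal(83.0, 14.0)), 55.0, 115.0))
        rec = CohortRecord(
            vessel_id=f"SYN{i:03d}", territory=territory, profile=profile,
            a_prox_ref=spec.a_prox_ref, a_dist_ref=spec.a_dist_ref,
            hr=hr, mean_pa=mean_pa)
        result = simulate_record(rec, truth_cfg, cache=cache)
        q_obs = result.mean_q * (1.0 + flow_noise * rng.standard_normal())
        pd_obs = result.mean_pd + pd_noise * rng.standard_normal()
        rec = replace(rec, observed_q=float(q_obs), observed_pd=float(pd_obs),
                      observed_ffr=float(pd_obs / result.mean_pa),
                      observed_r=float(pd_obs / q_obs) if q_obs > 0 else None)
        records.append(rec)
        specs.append(spec)
    return SyntheticCohort(records=records, specs=specs, seed=seed,
                           ground_truth={"g_ref_10": dict(g_true),
                                         "k_lumencorr": k_true,
                                         "flow_noise": flow_noise,
                                         "pd_noise": pd_noise})
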