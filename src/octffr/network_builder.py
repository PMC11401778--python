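"""Assembly of the coronary network from a corrected lumen profile.

The epicardial region of interest becomes a chain of viscous (Poiseuille)
loss elements with a single quadratic (Borda-Carnot) expansion loss at the
MLA exit. Side-branch flow is a continuous leak along the assumed linear
reference taper: the leak conductance attached at each segment boundary is
the decrement of the Huo-Kassab conductance of the local reference area. The
distal microvascular bed and every leak path share a 75/25 proximal/distal
resistance split around a common venous node that feels half the LV cavity
pressure (single-layer intramyocardial pump); the outlet is right-atrial
pressure.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import (C_DIST_COHORT_MEAN, C_MICRO_COHORT_MEAN, R_MICRO_COHORT_MEAN,
                     QUADRATIC_SI_TO_CLINICAL, RESISTANCE_SI_TO_CLINICAL, RunConfig)
from .errors import BuildError, InvalidParameterError
from .lumen_geometry import LumenProfile, ReferenceTaper

log = logging.getLogger(__name__)

#: lumen area below which the OCT catheter itself (~1 mm²) may hold a tight
#: lesion open, so the simulation will tend to underestimate severity
CATHETER_AREA_MM2 = 1.0


@dataclass(frozen=True)
class TerritoryConstants:
    """Territory-specific microvascular conductance scaling.

    g_ref_10 is the conductance expected downstream of a 10 mm² reference
    lumen; conductance for other calibers follows the Huo-Kassab allometric
    law g = g_ref_10 * (A/10)**(7/6).
    """

    territory: str
    g_ref_10: float
    hk_exponent: float = 7.0 / 6.0

    def __post_init__(self) -> None:
        if self.g_ref_10 <= 0:
            raise InvalidParameterError("g_ref_10 must be positive")

    @classmethod
    def for_territory(cls, territory: str,
                      config: Optional[RunConfig] = None) -> "TerritoryConstants":
        cfg = config or RunConfig()
        t = territory.upper().replace("/", "_")
        t = "LAD" if t == "LAD" else "CX_RCA"
        return cls(territory=t, g_ref_10=cfg.g_ref_10(t), hk_exponent=cfg.hk_exponent)


@dataclass(frozen=True)
class StenosisCoefficients:
    """Gould-type stenosis loss decomposition: dP = K_visc*Q + K_conv*Q|Q|."""

    k_visc_segments: np.ndarray  # mmHg·s/mL per segment
    k_conv: float  # mmHg·s²/mL²

    @property
    def k_visc_total(self) -> float:
        return float(np.sum(self.k_visc_segments))


@dataclass(frozen=True)
class MicrovascularBed:
    """Distal microvascular compartment (clinical units; compliances mL/mmHg)."""

    r_micro: float
    r_micro_prox: float
    r_micro_dist: float
    c_micro: float
    c_dist: float
    im_coupling: float = 0.5

    def __post_init__(self) -> None:
        if min(self.r_micro, self.r_micro_prox, self.r_micro_dist,
               self.c_micro, self.c_dist) <= 0:
            raise InvalidParameterError("bed parameters must be positive")
        if abs(self.r_micro - self.r_micro_prox - self.r_micro_dist) > 1e-9:
            raise InvalidParameterError("r_micro must equal prox + dist parts")


def huo_kassab_conductance(a_ref: float, constants: TerritoryConstants) -> float:
    """Microvascular conductance downstream of a vessel of reference area
    ``a_ref`` mm², mL/s/mmHg."""
    if np.any(np.asarray(a_ref) <= 0):
        raise InvalidParameterError("reference area must be positive")
    return constants.g_ref_10 * (np.asarray(a_ref, dtype=float) / 10.0) ** constants.hk_exponent


def split_resistance(g: float, split_fraction: float = 0.75) -> tuple[float, float]:
    """Split a path conductance into proximal/distal resistances in series."""
    if g <= 0:
        raise InvalidParameterError("conductance must be positive")
    if not 0 < split_fraction < 1:
        raise InvalidParameterError("split fraction must lie in (0, 1)")
    return split_fraction / g, (1.0 - split_fraction) / g


def viscous_coefficients(profile: LumenProfile, mu: float = 3.5e-3) -> np.ndarray:
    """Per-segment Poiseuille coefficients 8*pi*mu*dx/A², mmHg·s/mL.

    Trapezoidal integration of 8*pi*mu/A(x)² over each inter-frame segment.
    """
    if mu <= 0:
        raise InvalidParameterError("viscosity must be positive")
    if profile.position.size < 2:
        raise BuildError("profile needs at least two samples")
    a_m2 = profile.area * 1e-6
    dx_m = np.diff(profile.position) * 1e-3
    inv_a2 = 1.0 / a_m2 ** 2
    k_si = 8.0 * math.pi * mu * dx_m * 0.5 * (inv_a2[:-1] + inv_a2[1:])
    return k_si * RESISTANCE_SI_TO_CLINICAL


def expansion_coefficient(profile: LumenProfile, taper: ReferenceTaper,
                          rho: float = 1060.0,
                          recovery_distance: float = 5.0) -> float:
    """Borda-Carnot expansion loss coefficient at the MLA exit, mmHg·s²/mL².

    The recovery area is the taper-interpolated reference area
    ``recovery_distance`` mm distal to the MLA (bounded by the ROI end).
    """
    if rho <= 0:
        raise InvalidParameterError("density must be positive")
    i = int(np.argmin(profile.area))
    a_mla = profile.area[i] * 1e-6
    x_rec = min(profile.position[i] + recovery_distance, profile.length)
    a_rec = float(taper.a_ref(x_rec)) * 1e-6
    k_si = 0.5 * rho * (1.0 / a_mla - 1.0 / a_rec) ** 2
    return k_si * QUADRATIC_SI_TO_CLINICAL


@dataclass
class NetworkModel:
    """Assembled nonlinear resistive-capacitive coronary network.

    Node i sits at position[i]; segment i joins nodes i-1 and i and carries
    k_visc_segments[i-1]; leak_g[i-1] is the side-branch conductance attached
    at node i (the last one at the distal ROI node). conv_segment is the
    1-based index of the segment carrying the quadratic loss.
    """

    position: np.ndarray
    k_visc_segments: np.ndarray
    k_conv: float
    conv_segment: int
    leak_g: np.ndarray
    bed: MicrovascularBed
    g_total: float
    g_bed: float
    p_ra: float = 2.0
    split_fraction: float = 0.75
    venous_waterfall: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = self.k_visc_segments.size
        if self.position.size != n + 1 or self.leak_g.size != n:
            raise BuildError("inconsistent segment/leak array sizes")
        if not 1 <= self.conv_segment <= n:
            raise BuildError("conv_segment out of range")
        if np.any(self.k_visc_segments < 0) or np.any(self.leak_g < -1e-15):
            raise BuildError("loss coefficients and leaks must be non-negative")
        total = float(np.sum(self.leak_g)) + self.g_bed
        if abs(total - self.g_total) > 1e-9 * max(self.g_total, 1e-12):
            raise BuildError("conductance conservation violated")

    @property
    def n_segments(self) -> int:
        return int(self.k_visc_segments.size)

    @property
    def k_visc_total(self) -> float:
        return float(np.sum(self.k_visc_segments))

    def to_json(self, path=None) -> str:
        payload = {
            "position_mm": self.position.tolist(),
            "k_visc_segments": self.k_visc_segments.tolist(),
            "k_conv": self.k_conv,
            "conv_segment": self.conv_segment,
            "leak_g": self.leak_g.tolist(),
            "bed": {k: getattr(self.bed, k) for k in
                    ("r_micro", "r_micro_prox", "r_micro_dist",
                     "c_micro", "c_dist", "im_coupling")},
            "g_total": self.g_total,
            "g_bed": self.g_bed,
            "p_ra": self.p_ra,
            "split_fraction": self.split_fraction,
            "meta": self.meta,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)
        return text


def build_network(profile: LumenProfile, taper: ReferenceTaper,
                  constants: TerritoryConstants,
                  config: Optional[RunConfig] = None,
                  p_ra: Optional[float] = None) -> NetworkModel:
    """Assemble the full coronary network from a corrected, resampled profile."""
    cfg = config or RunConfig()
    if not profile.corrected:
        raise BuildError("profile must be lumen-corrected before network build")
    if abs(profile.length - taper.roi_length) > profile.spacing + 1e-6:
        raise BuildError(
            f"taper extent {taper.roi_length:.2f} mm inconsistent with "
            f"profile length {profile.length:.2f} mm")

    mla = float(np.min(profile.area))
    if mla < CATHETER_AREA_MM2:
        log.warning(
            "MLA %.2f mm² is at the OCT catheter scale; a crossed catheter may "
            "hold the lesion open and severity will tend to be underestimated", mla)
    rel = profile.area / taper.a_ref(profile.position)
    if np.mean(rel > 1.2) > 0.3:
        log.warning("large fraction of lumen above the reference taper "
                    "(ectasia/positive remodeling); reference entry is suspect")
    if np.all(rel < 0.8):
        log.warning("entire lumen below the reference taper (diffuse disease); "
                    "reference entry is suspect")

    k_visc = viscous_coefficients(profile, cfg.mu)
    k_conv = expansion_coefficient(profile, taper, cfg.rho, cfg.recovery_distance_mm)
    i_mla = int(np.argmin(profile.area))
    conv_segment = min(i_mla + 1, k_visc.size)  # segment leaving the MLA node

    g_nodes = huo_kassab_conductance(taper.a_ref(profile.position), constants)
    leak_g = np.maximum(g_nodes[:-1] - g_nodes[1:], 0.0)
    g_total = float(g_nodes[0])
    g_bed = float(g_nodes[-1])
    # exact telescoping so the conservation invariant holds to round-off
    leak_g[-1] = g_total - g_bed - float(np.sum(leak_g[:-1]))

    r_prox, r_dist = split_resistance(g_bed, cfg.split_fraction)
    scale = g_bed * R_MICRO_COHORT_MEAN  # relative to the cohort-mean bed
    bed = MicrovascularBed(
        r_micro=1.0 / g_bed, r_micro_prox=r_prox, r_micro_dist=r_dist,
        c_micro=C_MICRO_COHORT_MEAN * scale, c_dist=C_DIST_COHORT_MEAN * scale,
        im_coupling=cfg.im_coupling)
    return NetworkModel(
        position=profile.position.copy(), k_visc_segments=k_visc,
        k_conv=k_conv, conv_segment=conv_segment, leak_g=leak_g, bed=bed,
        g_total=g_total, g_bed=g_bed,
        p_ra=cfg.p_ra if p_ra is None else p_ra,
        split_fraction=cfg.split_fraction,
        venous_waterfall=cfg.venous_waterfall,
        meta={"territory": constants.territory, "g_ref_10": constants.g_ref_10,
              "mla_mm2": mla, "config_hash": cfg.hash()})
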