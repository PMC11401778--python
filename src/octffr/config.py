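"""Run-level configuration and unit constants.

All hemodynamic quantities are carried in clinical units: pressure in mmHg,
flow in mL/s, resistance in mmHg·s/mL, compliance in mL/mmHg (module surfaces
that quote µL/mmHg convert on entry), length in mm, area in mm².
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .errors import ConfigError

MMHG_PA = 133.322  # 1 mmHg in Pa
# Pa·s/m^3 -> mmHg·s/mL  (linear resistance)
RESISTANCE_SI_TO_CLINICAL = 1.0 / (MMHG_PA * 1e6)
# Pa·s^2/m^6 -> mmHg·s^2/mL^2  (quadratic loss coefficient)
QUADRATIC_SI_TO_CLINICAL = 1.0 / (MMHG_PA * 1e12)

#: cohort-mean microvascular resistance used as the compliance-scaling anchor,
#: mmHg/(mL/s)
R_MICRO_COHORT_MEAN = 46.2
#: cohort-mean distal/microvascular compliances at that anchor, mL/mmHg
C_DIST_COHORT_MEAN = 1.1e-3
C_MICRO_COHORT_MEAN = 4.5e-3


@dataclass
class RunConfig:
    """Bundle of model defaults shared across the pipeline.

    Parameters
    ----------
    mu : blood dynamic viscosity, Pa·s.
    rho : blood density, kg/m³.
    g_ref_10_lad, g_ref_10_cx_rca : microvascular conductance expected
        downstream of a 10 mm² reference lumen, mL/s/mmHg, per territory.
    hk_exponent : Huo–Kassab area exponent for conductance scaling.
    k_lumencorr : effective-lumen-radius correction, mm.
    split_fraction : proximal share of microvascular resistance.
    im_coupling : fraction of LV cavity pressure felt by the venous
        microcirculation (single transmural layer).
    p_ra : right-atrial outlet pressure, mmHg.
    recovery_distance_mm : distance distal to the MLA at which flow is assumed
        to have re-expanded to the reference taper.
    resample_spacing_mm : uniform lumen-profile grid used for simulation.
    """

    mu: float = 3.5e-3
    rho: float = 1060.0
    g_ref_10_lad: float = 0.064
    g_ref_10_cx_rca: float = 0.043
    hk_exponent: float = 7.0 / 6.0
    k_lumencorr: float = -0.075
    split_fraction: float = 0.75
    im_coupling: float = 0.5
    p_ra: float = 2.0
    venous_waterfall: bool = True
    recovery_distance_mm: float = 5.0
    resample_spacing_mm: float = 0.2
    dt: float = 1e-3
    max_cycles: int = 50
    convergence_tol: float = 1e-4
    newton_tol: float = 1e-9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.rho <= 0:
            raise ConfigError("mu and rho must be positive")
        if self.g_ref_10_lad <= 0 or self.g_ref_10_cx_rca <= 0:
            raise ConfigError("reference conductances must be positive")
        if not 0 < self.split_fraction < 1:
            raise ConfigError("split_fraction must lie in (0, 1)")
        if not 0 <= self.im_coupling <= 1:
            raise ConfigError("im_coupling must lie in [0, 1]")
        if self.resample_spacing_mm <= 0 or self.dt <= 0:
            raise ConfigError("grid spacings must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("configuration file must contain a mapping")
        return cls.from_dict(data)

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def g_ref_10(self, territory: str) -> float:
        t = territory.upper().replace("/", "_")
        if t == "LAD":
            return self.g_ref_10_lad
        if t in ("CX_RCA", "CX", "RCA"):
            return self.g_ref_10_cx_rca
        raise ConfigError(f"unknown territory {territory!r}")


DEFAULT_CONFIG = RunConfig()
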