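"""OCT lumen-profile handling.

Reads the comma-separated lumen exports of an OCT workstation, merges
overlapping pullbacks at a shared landmark frame, crops to the region of
interest, applies the effective-lumen-radius correction, and computes the
reference taper and standard lesion metrics (MLA, RVA, plaque burden, area and
diameter stenosis).

Positions are millimetres from the proximal ROI boundary, increasing distally.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd

from .errors import CorrectionError, FormatError, InvalidParameterError, MergeError

log = logging.getLogger(__name__)

#: OCT survey-mode frame pitch, mm/frame, used when the export carries frame
#: indices but no position column.
DEFAULT_FRAME_PITCH = 0.2


@dataclass
class LumenProfile:
    """Sampled lumen area along the vessel.

    position : mm from ROI start, strictly increasing.
    area : lumen area, mm².
    d_min, d_max : optional min/max lumen diameters, mm.
    spacing : nominal frame pitch, mm.
    corrected : whether the effective-lumen-radius correction was applied.
    """

    position: np.ndarray
    area: np.ndarray
    spacing: float
    d_min: Optional[np.ndarray] = None
    d_max: Optional[np.ndarray] = None
    corrected: bool = False

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.area = np.asarray(self.area, dtype=float)
        if self.position.ndim != 1 or self.position.size == 0:
            raise InvalidParameterError("profile needs at least one sample")
        if self.position.size != self.area.size:
            raise InvalidParameterError("position/area length mismatch")
        if self.spacing <= 0:
            raise InvalidParameterError("spacing must be positive")
        if np.any(np.diff(self.position) <= 0):
            raise InvalidParameterError("positions must be strictly increasing")
        if abs(self.position[0]) > 1e-9:
            raise InvalidParameterError("profile must start at position 0")
        if not np.all(np.isfinite(self.area)) or np.any(self.area <= 0):
            raise InvalidParameterError("lumen areas must be finite and positive")

    @property
    def length(self) -> float:
        """ROI extent, mm."""
        return float(self.position[-1])

    def resample(self, spacing: float) -> "LumenProfile":
        """Linear resampling onto a uniform grid of the given pitch."""
        if spacing <= 0:
            raise InvalidParameterError("spacing must be positive")
        n = max(int(round(self.length / spacing)), 1)
        pos = np.linspace(0.0, n * spacing, n + 1)
        pos = pos[pos <= self.length + 1e-9]
        area = np.interp(pos, self.position, self.area)
        return LumenProfile(pos, area, spacing, corrected=self.corrected)

    def to_frame(self) -> pd.DataFrame:
        d = {"frame": np.arange(self.position.size),
             "position_mm": self.position, "area_mm2": self.area}
        if self.d_min is not None:
            d["dmin_mm"] = self.d_min
        if self.d_max is not None:
            d["dmax_mm"] = self.d_max
        return pd.DataFrame(d)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ReferenceTaper:
    """Assumed linear decrease of healthy lumen area along the ROI."""

    a_prox_ref: float
    a_dist_ref: float
    roi_length: float

    def __post_init__(self) -> None:
        if self.a_dist_ref <= 0:
            raise InvalidParameterError("reference areas must be positive")
        if self.a_dist_ref > self.a_prox_ref:
            raise InvalidParameterError(
                "distal reference area exceeds proximal reference area")
        if self.roi_length <= 0:
            raise InvalidParameterError("ROI length must be positive")

    def a_ref(self, x) -> np.ndarray | float:
        """Reference lumen area at position x (mm), linearly interpolated."""
        frac = np.clip(np.asarray(x, dtype=float) / self.roi_length, 0.0, 1.0)
        out = self.a_prox_ref + (self.a_dist_ref - self.a_prox_ref) * frac
        return float(out) if np.isscalar(x) else out


@dataclass(frozen=True)
class LesionMetrics:
    mla: float
    mla_position: float
    rva: float
    plaque_burden: float
    area_stenosis: float
    diameter_stenosis: float


def read_lumen_csv(path, frame_pitch: float = DEFAULT_FRAME_PITCH) -> LumenProfile:
    """Read a workstation lumen export.

    Expected columns: ``frame``, ``area_mm2`` (required), ``position_mm``,
    ``dmin_mm``, ``dmax_mm`` (optional). Rows with missing area are dropped
    with a logged count; non-numeric cells raise a row-level error.
    """
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    cols = {c.strip().lower(): c for c in df.columns}
    if "area_mm2" not in cols:
        raise FormatError(f"{path}: missing required column 'area_mm2'")

    def numeric(colkey):
        raw = df[cols[colkey]]
        vals = pd.to_numeric(raw, errors="coerce")
        bad = vals.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise FormatError(
                f"{path}: non-numeric value in column '{colkey}' at line {line}")
        return vals

    area = numeric("area_mm2")
    missing = area.isna()
    if missing.any():
        log.warning("%s: dropping %d rows with missing lumen area",
                    path, int(missing.sum()))
    keep = ~missing

    if "position_mm" in cols:
        pos = numeric("position_mm")[keep].to_numpy()
        pos = pos - pos[0]
        spacing = float(np.median(np.diff(pos))) if pos.size > 1 else frame_pitch
    else:
        if "frame" in cols:
            frames = numeric("frame")[keep].to_numpy()
        else:
            frames = np.flatnonzero(keep.to_numpy()).astype(float)
        pos = (frames - frames[0]) * frame_pitch
        spacing = frame_pitch

    kw = {}
    for key, name in (("dmin_mm", "d_min"), ("dmax_mm", "d_max")):
        if key in cols:
            kw[name] = numeric(key)[keep].to_numpy()
    return LumenProfile(pos, area[keep].to_numpy(), spacing, **kw)


def merge_pullbacks(proximal: LumenProfile, distal: LumenProfile,
                    landmark_frame_prox: int, landmark_frame_dist: int) -> LumenProfile:
    """Merge two overlapping pullbacks aligned at a shared landmark frame.

    In the overlap the proximal pullback's samples are kept (less
    catheter-induced distortion proximally); positions are re-zeroed.
    """
    for prof, idx, name in ((proximal, landmark_frame_prox, "proximal"),
                            (distal, landmark_frame_dist, "distal")):
        if not 0 <= idx < prof.position.size:
            raise MergeError(f"landmark frame {idx} outside {name} pullback")
    # shift distal positions so the landmarks coincide
    offset = proximal.position[landmark_frame_prox] - distal.position[landmark_frame_dist]
    dist_pos = distal.position + offset
    prox_end = proximal.position[-1]
    if dist_pos[0] > prox_end + 1e-9:
        raise MergeError(
            f"pullbacks do not overlap after alignment (gap of "
            f"{dist_pos[0] - prox_end:.2f} mm)")
    if dist_pos[-1] < prox_end - 1e-9:
        raise MergeError(
            "landmark alignment leaves no distal extension "
            "(mismatched landmark frames)")
    keep = dist_pos > prox_end + 1e-9
    log.info("merge: keeping proximal pullback over %.1f mm overlap",
             float(min(prox_end, dist_pos[-1]) - dist_pos[0]))
    pos = np.concatenate([proximal.position, dist_pos[keep]])
    area = np.concatenate([proximal.area, distal.area[keep]])
    pos = pos - pos[0]
    return LumenProfile(pos, area, proximal.spacing,
                        corrected=proximal.corrected and distal.corrected)


def crop_roi(profile: LumenProfile, start: float, end: float) -> LumenProfile:
    """Crop to [start, end] mm and re-zero positions at the new start."""
    if not (0 <= start < end <= profile.length + 1e-9):
        raise InvalidParameterError(
            f"invalid crop range [{start}, {end}] for profile of "
            f"length {profile.length:.2f} mm")
    mask = (profile.position >= start - 1e-9) & (profile.position <= end + 1e-9)
    if not mask.any():
        raise InvalidParameterError("crop produced an empty profile")
    pos = profile.position[mask] - profile.position[mask][0]
    kw = {}
    if profile.d_min is not None:
        kw["d_min"] = profile.d_min[mask]
    if profile.d_max is not None:
        kw["d_max"] = profile.d_max[mask]
    return LumenProfile(pos, profile.area[mask], profile.spacing,
                        corrected=profile.corrected, **kw)


def ellipse_area(d_min: float, d_max: float) -> float:
    """Reference vessel area from two orthogonal diameters, mm²."""
    if d_min <= 0 or d_max <= 0:
        raise InvalidParameterError("diameters must be positive")
    return math.pi * d_min * d_max / 4.0


def apply_lumen_correction(profile: LumenProfile, k_lumencorr: float) -> LumenProfile:
    """Apply the effective-lumen-radius correction.

    Each area A becomes pi*(sqrt(A/pi) + k)**2. The correction compensates for
    a systematic, modality-specific offset of segmented lumen size; the
    calibrated default is -0.075 mm.
    """
    if profile.corrected:
        raise InvalidParameterError("profile is already corrected")
    radius = np.sqrt(profile.area / math.pi) + k_lumencorr
    if np.any(radius <= 0):
        pos = profile.position[int(np.argmax(radius <= 0))]
        raise CorrectionError(
            f"corrected lumen radius non-positive at {pos:.2f} mm "
            f"(k_lumencorr={k_lumencorr} mm)")
    return replace(profile, area=math.pi * radius ** 2, corrected=True)


def suggest_references(profile: LumenProfile, edge_length: float = 10.0) -> tuple[float, float]:
    """Automatic reference-area suggestion the operator may override.

    Takes the 90th percentile of observed areas within the proximal and distal
    ``edge_length`` mm as least-diseased estimates, ordered so the proximal
    value is the larger.
    """
    prox = profile.area[profile.position <= edge_length]
    dist = profile.area[profile.position >= profile.length - edge_length]
    a_p = float(np.percentile(prox, 90))
    a_d = float(np.percentile(dist, 90))
    if a_d > a_p:  # taper must be non-increasing
        a_p = a_d = max(a_p, a_d)
    return a_p, a_d


def fit_reference_taper(profile: LumenProfile, a_prox_ref: float,
                        a_dist_ref: float) -> ReferenceTaper:
    """Anchor the linear reference taper at the operator-entered areas."""
    return ReferenceTaper(a_prox_ref, a_dist_ref, profile.length)


def lesion_metrics(profile: LumenProfile, taper: ReferenceTaper, rva: float) -> LesionMetrics:
    """Standard lesion metrics from the (uncorrected) observed areas.

    plaque burden = 1 - MLA/RVA; area stenosis is referenced to the
    taper-interpolated local reference area at the MLA.
    """
    if rva <= 0:
        raise InvalidParameterError("RVA must be positive")
    i = int(np.argmin(profile.area))
    mla = float(profile.area[i])
    mla_pos = float(profile.position[i])
    if mla > rva:
        log.warning("MLA %.2f mm² exceeds RVA %.2f mm² (positive remodeling)",
                    mla, rva)
    a_local = float(taper.a_ref(mla_pos))
    return LesionMetrics(
        mla=mla,
        mla_position=mla_pos,
        rva=rva,
        plaque_burden=1.0 - mla / rva,
        area_stenosis=1.0 - mla / a_local,
        diameter_stenosis=1.0 - math.sqrt(max(mla / a_local, 0.0)),
    )
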