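"""Cardiac pressure-waveform driver.

Generates simultaneous aortic and left-ventricular pressure traces at a given
heart rate, with the cycle-mean aortic pressure matched to an observed target,
or ingests a measured aortic trace. The generator is a minimal open-loop
model: a double-Hill time-varying-elastance LV filling from a constant venous
pressure, an aortic valve with characteristic impedance and blood inertance, a
proximal aortic root element (compliance) that produces the dicrotic notch at
valve closure, and a two-element Windkessel whose peripheral resistance is
iterated so the simulated mean aortic pressure matches the target.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _kernels
from .errors import ConvergenceError, FormatError, InvalidParameterError

log = logging.getLogger(__name__)

_SUBSTEPS_PER_SAMPLE = 10  # internal Euler substeps per 1 kHz output sample
_WARMUP_CYCLES = 10
_PERIODICITY_TOL = 0.1  # mmHg, max cycle-to-cycle aortic difference


@dataclass(frozen=True)
class DriverParams:
    """Lumped driver parameters (versioned default set, tuned once).

    Elastances in mmHg/mL, resistances in mmHg·s/mL, compliances in mL/mmHg,
    inertance in mmHg·s²/mL, volumes in mL. Activation timing constants are
    fractions of the cycle length (double-Hill rise/decay).
    """

    e_max: float = 2.6
    e_min: float = 0.08
    lv_volume_ref: float = 10.0
    m1: float = 1.9
    m2: float = 21.9
    tau1_frac: float = 0.269
    tau2_frac: float = 0.452
    r_mitral: float = 0.03
    p_venous: float = 11.0
    r_c: float = 0.045
    l_valve: float = 4.0e-4
    c_prox: float = 0.1
    r_prox: float = 0.05
    l_prox: float = 5.0e-3
    c_a: float = 0.9
    r_p: float = 1.0

    def __post_init__(self) -> None:
        for name in ("e_max", "e_min", "r_mitral", "r_c", "l_valve",
                     "c_prox", "r_prox", "l_prox", "c_a", "r_p",
                     "tau1_frac", "tau2_frac", "m1", "m2"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be positive")
        if self.e_max <= self.e_min:
            raise InvalidParameterError("e_max must exceed e_min")


DEFAULT_DRIVER_PARAMS = DriverParams()


@dataclass
class PressureWaveforms:
    """Time-aligned aortic and LV pressure over an integer number of cycles."""

    time: np.ndarray
    pa: np.ndarray
    plv: np.ndarray
    heart_rate: float
    cycle_length: float
    mean_pa: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.pa = np.asarray(self.pa, dtype=float)
        self.plv = np.asarray(self.plv, dtype=float)
        if not (self.time.size == self.pa.size == self.plv.size):
            raise InvalidParameterError("trace length mismatch")
        if abs(self.cycle_length - 60.0 / self.heart_rate) > 1e-9:
            raise InvalidParameterError("cycle_length must equal 60/heart_rate")
        if not np.all(np.isfinite(self.pa)) or not np.all(np.isfinite(self.plv)):
            raise InvalidParameterError("pressures must be finite")
        if np.any(self.pa <= 0):
            raise InvalidParameterError("aortic pressure must stay positive")
        n_cyc = self.time.size * self.dt / self.cycle_length
        if abs(n_cyc - round(n_cyc)) > 1e-6:
            raise InvalidParameterError("traces must cover an integer number of cycles")
        if self.mean_pa is None:
            self.mean_pa = float(np.mean(self.pa))
        elif abs(self.mean_pa - float(np.mean(self.pa))) > 1e-9:
            raise InvalidParameterError("mean_pa inconsistent with trace")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0])

    @property
    def samples_per_cycle(self) -> int:
        return int(round(self.cycle_length / self.dt))

    @property
    def n_cycles(self) -> int:
        return self.time.size // self.samples_per_cycle

    def one_cycle(self) -> tuple[np.ndarray, np.ndarray]:
        """First full cycle of (pa, plv)."""
        n = self.samples_per_cycle
        return self.pa[:n].copy(), self.plv[:n].copy()

    def on_grid(self, dt: float) -> tuple[np.ndarray, np.ndarray]:
        """One cycle of (pa, plv) resampled periodically onto step ``dt``."""
        n = int(round(self.cycle_length / dt))
        if n < 8:
            raise InvalidParameterError("solver step too coarse for the cycle")
        pa_c, plv_c = self.one_cycle()
        if n == self.samples_per_cycle:
            return pa_c, plv_c
        t_new = np.arange(n) * (self.cycle_length / n)
        t_old = np.arange(pa_c.size) * self.dt
        # periodic interpolation: append the wrap-around sample
        t_ext = np.append(t_old, self.cycle_length)
        return (np.interp(t_new, t_ext, np.append(pa_c, pa_c[0])),
                np.interp(t_new, t_ext, np.append(plv_c, plv_c[0])))

    def write_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, "pressure_mmhg": self.pa}).to_csv(
            path, index=False)


def _activation_shape(n: int, params: DriverParams) -> np.ndarray:
    """Normalized double-Hill activation over one cycle (max 1, zero at t=0)."""
    s = np.arange(n) / n
    h1 = (s / params.tau1_frac) ** params.m1
    h2 = (s / params.tau2_frac) ** params.m2
    shape = (h1 / (1.0 + h1)) / (1.0 + h2)
    return shape / shape.max()


def lv_elastance(t_in_cycle, params: DriverParams = DEFAULT_DRIVER_PARAMS,
                 cycle_length: float = 0.8):
    """Time-varying LV elastance e(t) within one cycle, mmHg/mL.

    Smooth, periodic in ``cycle_length``, rising from e_min at cycle start to
    a single maximum e_max during systole.
    """
    if cycle_length <= 0:
        raise InvalidParameterError("cycle length must be positive")
    t = np.mod(np.asarray(t_in_cycle, dtype=float), cycle_length)
    s = t / cycle_length
    h1 = (s / params.tau1_frac) ** params.m1
    h2 = (s / params.tau2_frac) ** params.m2
    raw = (h1 / (1.0 + h1)) / (1.0 + h2)
    # normalization constant of the double-Hill shape on a dense grid
    dense = np.arange(4096) / 4096
    d1 = (dense / params.tau1_frac) ** params.m1
    d2 = (dense / params.tau2_frac) ** params.m2
    peak = ((d1 / (1.0 + d1)) / (1.0 + d2)).max()
    e = params.e_min + (params.e_max - params.e_min) * np.minimum(raw / peak, 1.0)
    return float(e) if np.isscalar(t_in_cycle) else e


def _run_driver(heart_rate: float, params: DriverParams, r_p: float,
                n_store_cycles: int, warmup: int = _WARMUP_CYCLES,
                state=None):
    cycle = 60.0 / heart_rate
    n_out = int(round(cycle / 1e-3))
    n_sub = n_out * _SUBSTEPS_PER_SAMPLE
    dt_sub = cycle / n_sub
    shape = _activation_shape(n_sub, params)
    v0, p0 = (120.0, 80.0) if state is None else state
    pa, plv, v_end, p_end = _kernels.driver_loop(
        shape, dt_sub, warmup, n_store_cycles, _SUBSTEPS_PER_SAMPLE,
        params.e_max, params.e_min, params.lv_volume_ref,
        params.r_mitral, params.p_venous, params.r_c, params.l_valve,
        params.c_prox, params.r_prox, params.l_prox, params.c_a, r_p, v0, p0)
    return pa, plv, cycle / n_out, (v_end, p_end)


def generate_waveforms(heart_rate: float, target_mean_pa: float,
                       params: DriverParams = DEFAULT_DRIVER_PARAMS,
                       n_cycles: int = 1, mean_tol: float = 0.1,
                       max_iter: int = 50) -> PressureWaveforms:
    """Periodic steady-state waveforms with mean Pa matched to the target.

    The peripheral Windkessel resistance is adjusted by bounded secant
    iteration until the cycle-mean aortic pressure is within ``mean_tol``
    mmHg of ``target_mean_pa`` (contract tolerance 0.5 mmHg).
    """
    if not 30 <= heart_rate <= 200:
        raise InvalidParameterError("heart rate outside 30-200 bpm")
    if not 40 <= target_mean_pa <= 200:
        raise InvalidParameterError("target mean Pa outside 40-200 mmHg")
    if n_cycles < 1:
        raise InvalidParameterError("n_cycles must be >= 1")

    def mean_for(r_p, store=2, state=None):
        pa, plv, dt, state = _run_driver(heart_rate, params, r_p, store, state=state)
        n = int(round((60.0 / heart_rate) / dt))
        return float(np.mean(pa[-n:])), pa, plv, dt, state

    r0 = params.r_p
    m0, pa, plv, dt, state = mean_for(r0)
    r1 = float(np.clip(r0 * target_mean_pa / m0, 0.02, 80.0))
    history = [(r0, m0)]
    for it in range(max_iter):
        m1, pa, plv, dt, state = mean_for(r1, state=state)
        history.append((r1, m1))
        if abs(m1 - target_mean_pa) <= mean_tol:
            break
        (ra, ma), (rb, mb) = history[-2], history[-1]
        if abs(mb - ma) < 1e-12:
            r1 = rb * target_mean_pa / max(mb, 1.0)
        else:
            r1 = rb + (target_mean_pa - mb) * (rb - ra) / (mb - ma)
        r1 = float(np.clip(r1, 0.02, 80.0))
    else:
        raise ConvergenceError(
            f"mean-Pa matching did not converge: residual "
            f"{history[-1][1] - target_mean_pa:+.2f} mmHg after {max_iter} iterations")

    # periodic steady state: two stored cycles must agree
    n = int(round((60.0 / heart_rate) / dt))
    for extra in (0, 20, 40):
        if extra:
            _, pa, plv, dt, state = mean_for(history[-1][0], store=2, state=state)
        if float(np.max(np.abs(pa[:n] - pa[n:2 * n]))) < _PERIODICITY_TOL:
            break
    else:
        raise ConvergenceError("driver did not reach a periodic steady state")

    pa_c, plv_c = pa[-n:], plv[-n:]
    time = np.arange(n * n_cycles) * dt
    wf = PressureWaveforms(time=time, pa=np.tile(pa_c, n_cycles),
                           plv=np.tile(plv_c, n_cycles),
                           heart_rate=heart_rate, cycle_length=60.0 / heart_rate)
    wf.r_p = history[-1][0]  # fitted peripheral resistance, for diagnostics
    return wf


def has_dicrotic_notch(wf: PressureWaveforms, min_rebound: float = 0.3) -> bool:
    """True if the aortic trace shows an interior local minimum after the
    systolic peak followed by a rebound of at least ``min_rebound`` mmHg."""
    pa, _ = wf.one_cycle()
    k = np.ones(5) / 5.0
    sm = np.convolve(np.concatenate([pa[-4:], pa, pa[:4]]), k, mode="same")[4:-4]
    peak = int(np.argmax(sm))
    seg = sm[peak:]
    for i in range(1, seg.size - 1):
        if seg[i] < seg[i - 1] and seg[i] <= seg[i + 1]:
            if np.max(seg[i:]) > seg[i] + min_rebound:
                return True
    return False


def load_measured_waveform(table, heart_rate: float,
                           params: DriverParams = DEFAULT_DRIVER_PARAMS) -> PressureWaveforms:
    """Ingest a measured aortic trace (CSV path or DataFrame with columns
    ``time_s``, ``pressure_mmhg``), resample it to the solver's uniform grid,
    and synthesize a phase-locked LV trace from the elastance driver.
    """
    if isinstance(table, (str, bytes)) or hasattr(table, "__fspath__"):
        df = pd.read_csv(table)
    else:
        df = pd.DataFrame(table)
    cols = {c.strip().lower(): c for c in df.columns}
    if "time_s" not in cols or "pressure_mmhg" not in cols:
        raise FormatError("measured trace needs columns time_s, pressure_mmhg")
    t = pd.to_numeric(df[cols["time_s"]], errors="coerce").to_numpy()
    p = pd.to_numeric(df[cols["pressure_mmhg"]], errors="coerce").to_numpy()
    if np.any(~np.isfinite(t)) or np.any(~np.isfinite(p)):
        raise FormatError("non-numeric values in measured trace")
    if np.any(np.diff(t) <= 0):
        raise FormatError("time must be strictly increasing")
    steps = np.diff(t)
    if steps.size and np.max(steps) > 3.0 * np.median(steps):
        raise FormatError("gap in measured trace exceeds 2 samples")

    cycle = 60.0 / heart_rate
    # a cycle sampled on [0, T) ends one sample short of T
    duration = t[-1] - t[0] + (float(np.median(steps)) if steps.size else 0.0)
    n_cycles = int(np.floor(duration / cycle + 1e-9))
    if n_cycles < 1:
        raise FormatError("measured trace shorter than one cardiac cycle")
    n_per = int(round(cycle / 1e-3))
    dt = cycle / n_per
    grid = t[0] + np.arange(n_per * n_cycles) * dt
    pa = np.interp(grid, t, p)

    # LV trace: phase-lock a generated driver cycle to the measured aortic one
    target = float(np.clip(np.mean(pa), 40.0, 200.0))
    ref = generate_waveforms(heart_rate, target, params=params)
    pa_ref, plv_ref = ref.one_cycle()
    pa_c = pa[:n_per]
    if np.std(pa_c) > 0.5:
        a = pa_c - pa_c.mean()
        b = pa_ref - pa_ref.mean()
        corr = np.array([np.dot(a, np.roll(b, s)) for s in range(n_per)])
        lag = int(np.argmax(corr))
    else:
        lag = 0
    plv = np.tile(np.roll(plv_ref, lag), n_cycles)
    return PressureWaveforms(time=grid - grid[0], pa=pa, plv=plv,
                             heart_rate=heart_rate, cycle_length=cycle)
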