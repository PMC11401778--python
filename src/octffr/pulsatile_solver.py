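"""Whole-cycle integration of the coronary network and simFFR computation.

The interior epicardial chain is quasi-steady (capacitance-free) and linear in
the node pressures except for the single quadratic expansion element at the
MLA exit. It is therefore reduced once per network to exact affine maps
(inlet flow, distal flow, interior leak sum, MLA-exit flow) in the boundary
values (Pa, Pd, Pv) and the expansion drop d, via one tridiagonal solve with
four right-hand sides. The two compliance states (distal epicardial pressure
Pd and venous node pressure Pv) are advanced by implicit Euler with a
fixed-point iteration on d; cycles are repeated until the cycle-mean Pd is
periodic. simFFR is the ratio of the cycle means of Pd and Pa.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import solve_banded

from . import _kernels
from .cardiac_driver import PressureWaveforms
from .config import RunConfig
from .errors import ConfigError, ConvergenceError, InvalidParameterError, OctFfrError
from .lumen_geometry import (LumenProfile, ReferenceTaper, apply_lumen_correction,
                             fit_reference_taper)
from .network_builder import NetworkModel, TerritoryConstants, build_network

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings for the whole-cycle solver."""

    dt: float = 1e-3
    max_cycles: int = 50
    convergence_tol: float = 1e-4
    newton_tol: float = 1e-9
    p_ra: Optional[float] = None  # override network outlet pressure, mmHg

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.convergence_tol <= 0 or self.newton_tol <= 0:
            raise InvalidParameterError("dt and tolerances must be positive")
        if self.max_cycles < 1:
            raise InvalidParameterError("max_cycles must be >= 1")


@dataclass
class SimulationResult:
    """Converged whole-cycle traces and scalar outputs (last cycle)."""

    time: np.ndarray
    pa: np.ndarray
    plv: np.ndarray
    pd: np.ndarray
    pv: np.ndarray
    q_inlet: np.ndarray
    q_distal: np.ndarray
    q_leak_total: np.ndarray
    mean_pa: float
    mean_pd: float
    mean_q: float
    sim_ffr: float
    cycles_to_converge: int
    max_flow_residual: float
    settings: SolverSettings = field(default=None)  # type: ignore[assignment]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time_s": self.time, "pa_mmhg": self.pa, "plv_mmhg": self.plv,
            "pd_mmhg": self.pd, "pv_mmhg": self.pv,
            "q_inlet_mls": self.q_inlet, "q_distal_mls": self.q_distal,
            "q_leak_mls": self.q_leak_total})

    def scalars(self) -> dict:
        return {"sim_ffr": self.sim_ffr, "mean_pa": self.mean_pa,
                "mean_pd": self.mean_pd, "mean_q": self.mean_q,
                "cycles_to_converge": self.cycles_to_converge,
                "max_flow_residual": self.max_flow_residual}


class ChainReduction:
    """Exact affine reduction of the quasi-steady epicardial chain.

    For any boundary vector u = (Pa, Pd, Pv, d), the interior node pressures
    are p = S u and every chain flow is a fixed linear functional of u; the
    quadratic element closes the system through d = K_conv * q_m |q_m|.
    """

    def __init__(self, network: NetworkModel):
        self.network = network
        k = network.k_visc_segments
        if np.any(k <= 0):
            raise InvalidParameterError("segment coefficients must be positive")
        c = 1.0 / k
        n = k.size
        m = network.conv_segment  # 1-based
        split = network.split_fraction
        gl = network.leak_g[:-1] / split  # interior leak path conductances
        self.c = c
        self.m = m
        self.k_conv = network.k_conv
        self.g_pdv = (network.leak_g[-1] + network.g_bed) / split
        self.g_bed_path = network.g_bed / split
        self.g_leak_n_path = network.leak_g[-1] / split
        self.g_vout = network.g_total / (1.0 - split)

        M = n - 1
        if M == 0:
            self.S = np.zeros((0, 4))
            delta = 1.0  # conv element is the only segment
            base = np.array([c[0], -c[0], 0.0, -c[0] * delta])
            self.coef_q_in = base
            self.coef_q_out = base
            self.coef_q_m = base
            self.coef_leak = np.zeros(4)
            return

        diag = c[:-1] + c[1:] + gl
        ab = np.zeros((3, M))
        ab[0, 1:] = -c[1:M]      # upper: -c_{i+1}
        ab[1, :] = diag
        ab[2, :-1] = -c[1:M]     # lower: -c_i for rows 2..M
        B = np.zeros((M, 4))
        B[0, 0] = c[0]           # Pa enters node 1
        B[M - 1, 1] = c[n - 1]   # Pd enters node M
        B[:, 2] = gl             # Pv through interior leaks
        if m <= M:
            B[m - 1, 3] -= c[m - 1]
        if 2 <= m <= M + 1:
            B[m - 2, 3] += c[m - 1]
        self.S = solve_banded((1, 1), ab, B)

        e_pa = np.array([1.0, 0.0, 0.0, 0.0])
        e_pd = np.array([0.0, 1.0, 0.0, 0.0])
        e_d = np.array([0.0, 0.0, 0.0, 1.0])

        def node_coef(i: int) -> np.ndarray:
            # boundary-inclusive interior pressure coefficients, i in 0..n
            if i == 0:
                return e_pa
            if i == n:
                return e_pd
            return self.S[i - 1]

        self.coef_q_in = c[0] * (e_pa - node_coef(1)) - (c[0] * e_d if m == 1 else 0.0)
        self.coef_q_out = c[n - 1] * (node_coef(n - 1) - e_pd) - (
            c[n - 1] * e_d if m == n else 0.0)
        self.coef_q_m = c[m - 1] * (node_coef(m - 1) - node_coef(m) - e_d)
        self.coef_leak = gl @ self.S - np.array([0.0, 0.0, float(np.sum(gl)), 0.0])

    def solve_d(self, pa: float, pd: float, pv: float) -> tuple[float, float]:
        """Self-consistent MLA-exit flow and expansion drop for fixed states."""
        ka, kd, kv, kdd = self.coef_q_m
        a0 = ka * pa + kd * pd + kv * pv
        beta = -kdd * self.k_conv
        if beta <= 0:
            return a0, self.k_conv * a0 * abs(a0)
        s = 1.0 if a0 >= 0 else -1.0
        qm = s * (np.sqrt(1.0 + 4.0 * beta * abs(a0)) - 1.0) / (2.0 * beta)
        return qm, self.k_conv * qm * abs(qm)

    def interior_pressures(self, pa: float, pd: float, pv: float, d: float) -> np.ndarray:
        return self.S @ np.array([pa, pd, pv, d])


@dataclass
class EpicardialSolution:
    """Per-instant algebraic solution of the epicardial chain."""

    node_pressures: np.ndarray  # inlet .. distal, inclusive
    q_segments: np.ndarray
    q_leaks: np.ndarray  # interior leak flows toward the venous node
    d: float
    max_residual: float


def solve_epicardial(inlet_p: float, node_states: tuple[float, float],
                     network: NetworkModel,
                     newton_tol: float = 1e-9,
                     reduction: Optional[ChainReduction] = None) -> EpicardialSolution:
    """Solve the quasi-steady nonlinear chain for given boundary pressures.

    node_states = (Pd, Pv). Flows satisfy conservation at every interior node
    to within ``newton_tol`` (mL/s); violation raises a convergence error.
    """
    red = reduction or ChainReduction(network)
    pd_, pv = node_states
    if not np.all(np.isfinite([inlet_p, pd_, pv])):
        raise InvalidParameterError("boundary pressures must be finite")
    qm, d = red.solve_d(inlet_p, pd_, pv)
    p_int = red.interior_pressures(inlet_p, pd_, pv, d)
    nodes = np.concatenate([[inlet_p], p_int, [pd_]])
    c = red.c
    n = c.size
    drop = np.zeros(n)
    drop[red.m - 1] = d
    q_seg = c * (nodes[:-1] - nodes[1:] - drop)
    # the conv-segment flow is known exactly from the scalar closure;
    # recomputing it from the pressure drop cancels catastrophically when
    # the segment's viscous coefficient is small
    q_seg[red.m - 1] = qm
    gl = network.leak_g[:-1] / network.split_fraction
    q_leaks = gl * (p_int - pv)
    resid = np.abs(q_seg[:-1] - q_seg[1:] - q_leaks) if n > 1 else np.zeros(0)
    max_res = float(resid.max()) if resid.size else 0.0
    if max_res > max(newton_tol, 1e-12):
        raise ConvergenceError(
            f"epicardial solve residual {max_res:.3e} mL/s exceeds tolerance")
    return EpicardialSolution(nodes, q_seg, q_leaks, d, max_res)


def simulate(network: NetworkModel, waveforms: PressureWaveforms,
             settings: SolverSettings = SolverSettings()) -> SimulationResult:
    """Integrate to the periodic steady state and return the last cycle."""
    red = ChainReduction(network)
    pa_c, plv_c = waveforms.on_grid(settings.dt)
    n = pa_c.size
    p_ra = network.p_ra if settings.p_ra is None else settings.p_ra
    mean_pa = float(np.mean(pa_c))
    pd0 = pv0 = mean_pa  # documented initialization; result is periodic

    ka, kd, kv, kdd = red.coef_q_m
    na, nd, nv, ndd = red.coef_q_out
    la, ld, lv, ldd = red.coef_leak
    ia, id_, iv, idd = red.coef_q_in
    out = _kernels.coronary_loop(
        pa_c, plv_c, settings.dt,
        ka, kd, kv, kdd, red.k_conv,
        na, nd, nv, ndd, la, ld, lv, ldd, ia, id_, iv, idd,
        red.g_pdv, red.g_vout, network.bed.c_dist, network.bed.c_micro,
        network.bed.im_coupling, p_ra,
        network.bed.im_coupling if network.venous_waterfall else 0.0,
        settings.max_cycles, settings.convergence_tol,
        max(settings.newton_tol * 1e-3, 1e-13), pd0, pv0)
    pd_tr, pv_tr, qin_tr, qout_tr, leak_tr, d_tr, cycles, max_res, converged = out
    if not converged:
        raise ConvergenceError(
            f"cycle-mean Pd not periodic after {cycles} cycles "
            f"(tol {settings.convergence_tol:g}); last mean Pd "
            f"{float(np.mean(pd_tr)):.2f} mmHg")

    q_distal = (pd_tr - pv_tr) * red.g_bed_path
    q_leak_total = leak_tr + (pd_tr - pv_tr) * red.g_leak_n_path
    mean_pd = float(np.mean(pd_tr))
    mean_q = float(np.mean(qin_tr))
    sim_ffr = mean_pd / mean_pa
    if not 0.0 < sim_ffr <= 1.05:
        raise OctFfrError(f"simFFR {sim_ffr:.3f} outside the physical guard (0, 1.05]")
    return SimulationResult(
        time=np.arange(n) * settings.dt, pa=pa_c, plv=plv_c, pd=pd_tr, pv=pv_tr,
        q_inlet=qin_tr, q_distal=q_distal, q_leak_total=q_leak_total,
        mean_pa=mean_pa, mean_pd=mean_pd, mean_q=mean_q, sim_ffr=sim_ffr,
        cycles_to_converge=int(cycles), max_flow_residual=float(max_res),
        settings=settings)


def compute_simffr(result: SimulationResult) -> float:
    """simFFR as the ratio of cycle means (not the mean of instant ratios)."""
    if result.mean_pa <= 0:
        raise InvalidParameterError("mean aortic pressure must be positive")
    return result.mean_pd / result.mean_pa


def systolic_diastolic_means(result: SimulationResult) -> tuple[float, float]:
    """Mean inlet flow during systole and diastole.

    Systole is taken as the interval where LV pressure exceeds the diastolic
    aortic pressure (valve-open proxy); used for diagnostics only.
    """
    thresh = float(np.min(result.pa))
    systole = result.plv > thresh
    if not systole.any() or systole.all():
        raise InvalidParameterError("cannot partition cycle into phases")
    return (float(np.mean(result.q_inlet[systole])),
            float(np.mean(result.q_inlet[~systole])))


@dataclass
class CoronaryCase:
    """Bundle of geometry inputs that can be rebuilt under varied parameters.

    ``profile`` is the cropped, uncorrected ROI lumen profile; the build step
    resamples it, applies the lumen correction from the active config, anchors
    the reference taper at the entered reference areas and assembles the
    network.
    """

    profile: LumenProfile
    a_prox_ref: float
    a_dist_ref: float
    territory: str
    config: RunConfig = field(default_factory=RunConfig)

    def build(self, config: Optional[RunConfig] = None) -> NetworkModel:
        cfg = config or self.config
        prof = self.profile.resample(cfg.resample_spacing_mm)
        prof = apply_lumen_correction(prof, cfg.k_lumencorr)
        taper = fit_reference_taper(prof, self.a_prox_ref, self.a_dist_ref)
        constants = TerritoryConstants.for_territory(self.territory, cfg)
        return build_network(prof, taper, constants, cfg)


def parameter_sweep(case: CoronaryCase, waveforms: PressureWaveforms,
                    settings: SolverSettings, parameter: str,
                    values: Sequence[float]) -> pd.DataFrame:
    """One simulation per parameter value; deterministic input ordering."""
    cfg_fields = {f for f in RunConfig().to_dict()}
    if parameter == "g_ref_10":
        t = case.territory.upper().replace("/", "_")
        key = "g_ref_10_lad" if t == "LAD" else "g_ref_10_cx_rca"
    elif parameter in cfg_fields:
        key = parameter
    else:
        raise ConfigError(f"unknown sweep parameter {parameter!r}")
    rows = []
    for v in values:
        cfg = case.config.replace(**{key: v})
        result = simulate(case.build(cfg), waveforms, settings)
        rows.append({"parameter": parameter, "value": v,
                     "sim_ffr": result.sim_ffr, "mean_pd": result.mean_pd,
                     "mean_q": result.mean_q})
    return pd.DataFrame(rows, columns=["parameter", "value", "sim_ffr",
                                       "mean_pd", "mean_q"])
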