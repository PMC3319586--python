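"""Time integration of the lumped vascular network.

The network equations are assembled in modified nodal analysis (MNA) form:
unknowns are the free node pressures (plus one internal node per windkessel)
and the flow through every segment and anastomosis branch.  Capacitors and
inductors are handled with trapezoidal companion models at a fixed step of
``cardiac_period / steps_per_cycle``, which keeps the scheme A-stable on the
stiff RC ladder and bit-reproducible.  The two nonlinear anastomosis
resistors are linearized around a lagged flow iterate, refreshed within each
step until the iterate is stationary; their contribution enters the
prefactorized system matrix through a low-rank (Woodbury) correction so the
LU factorization of the constant part is reused for the whole run.

Boundary conditions: the aortic inflow is a prescribed periodic flow
injection, the central venous pressure is prescribed at the subclavian-vein
outflow node (and is the reference for windkessels and side-branch
leakage).  The run starts from the DC operating point of the network driven
by the mean inflow and marches cycle by cycle until the mean aortic pressure
and mean brachial flow change by less than a relative tolerance between
consecutive cycles.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from . import units
from .errors import SimulationError, ValidationError
from .network import VascularNetwork
from .vessels import ASCENDING_AORTA, AXILLARY_BRACHIAL
from .waveforms import Waveform

__all__ = [
    "SolverControls",
    "SimulationResult",
    "BaroreflexResult",
    "simulate",
    "baroreflex_scale",
]


@dataclass(frozen=True)
class SolverControls:
    """Numerical policy of the solver (fixed => deterministic runs)."""

    steps_per_cycle: int = 1000
    periodic_tol: float = 1e-3     # relative cycle-to-cycle change
    max_cycles: int = 50
    min_cycles: int = 3
    anastomosis_tol: float = 1e-6  # relative change of the lagged flow iterate
    max_anastomosis_iter: int = 50


DEFAULT_CONTROLS = SolverControls()


@dataclass
class SolverState:
    """Integrator state carried between cycles (and warm starts)."""

    p: np.ndarray    # unknown pressures (free nodes + windkessel nodes), Pa
    q: np.ndarray    # branch flows, m^3/s
    i_c: np.ndarray  # capacitor companion currents
    v_l: np.ndarray  # inductor companion voltages
    t: float = 0.0

    def copy(self) -> "SolverState":
        return SolverState(self.p.copy(), self.q.copy(), self.i_c.copy(),
                           self.v_l.copy(), self.t)


class CompiledNetwork:
    """MNA assembly of one network at a fixed step size.

    Public attributes used by downstream analyses (conservation checks):
    ``pcol`` (node id -> pressure-unknown column), ``wk_col`` (terminal
    vessel -> windkessel-node column), ``branch_nodes`` ((a, b) per branch),
    ``node_capacitance``, ``node_leak_g`` (SI, indexed by pressure column),
    ``p_ven`` (Pa) and ``n_p``/``n_b``.
    """

    def __init__(self, network: VascularNetwork, venous_pressure_mmhg: float,
                 dt: Optional[float]):
        if any(t is None for t in network.terminals.values()):
            raise ValidationError("network has unpersonalized windkessel terminals")
        self.network = network
        self.dt = dt
        self.p_ven = units.mmhg_to_pa(venous_pressure_mmhg)

        prescribed = network.venous_outflow_node
        self.node_ids = [n for n in range(network.n_nodes) if n != prescribed]
        self.pcol = {n: i for i, n in enumerate(self.node_ids)}
        self.wk_col = {}
        for j, vid in enumerate(sorted(network.terminals)):
            self.wk_col[vid] = len(self.node_ids) + j
        self.n_p = len(self.node_ids) + len(self.wk_col)

        branches = list(network.branches) + list(network.anastomosis_branches)
        self.n_seg = len(network.branches)
        self.n_b = len(branches)
        self.branch_nodes = [(br.node_a, br.node_b) for br in branches]
        n = self.n_p + self.n_b
        self.n = n

        R = np.zeros(self.n_b)
        L = np.zeros(self.n_b)
        self.node_capacitance = np.zeros(self.n_p)
        self.node_leak_g = np.zeros(self.n_p)
        for i, br in enumerate(network.branches):
            el = br.elements
            R[i], L[i] = el.R, el.L
            for node, half in ((br.node_a, el.C / 2.0), (br.node_b, el.C / 2.0)):
                if node != prescribed:
                    self.node_capacitance[self.pcol[node]] += half
            if el.R_L is not None and br.node_b != prescribed:
                self.node_leak_g[self.pcol[br.node_b]] += 1.0 / el.R_L
        self.anast_rows = []
        self.anast_coeff = []
        rho = network.blood.density_kg_m3
        for k, ab in enumerate(network.anastomosis_branches):
            i = self.n_seg + k
            R[i] = ab.r_linear
            self.anast_rows.append(self.n_p + i)
            self.anast_coeff.append(ab.loss_k * rho / (2.0 * ab.area_m2 ** 2))
        self.anast_coeff = np.asarray(self.anast_coeff)
        self.R, self.L = R, L

        for vid, t in network.terminals.items():
            if t.Z_wk <= 0:
                raise ValidationError(f"{vid}: Z_wk must be positive to stamp the terminal")
            self.node_capacitance[self.wk_col[vid]] += t.C_wk

        self.g_c = np.zeros(self.n_p)
        self.g_l = np.zeros(self.n_b)
        if dt is not None:
            self.g_c = 2.0 * self.node_capacitance / dt
            self.g_l = 2.0 * self.L / dt

        M = np.zeros((n, n))
        base = np.zeros(n)

        # node KCL rows: conductances on the diagonal, +/-1 branch couplings
        idx = np.arange(self.n_p)
        M[idx, idx] += self.g_c + self.node_leak_g
        base[: self.n_p] += self.node_leak_g * self.p_ven
        for i, (a, bnode) in enumerate(self.branch_nodes):
            col = self.n_p + i
            row = col
            # branch equation p_a - p_b - (R + g_L) q = h
            M[row, col] = -(R[i] + self.g_l[i])
            if a != prescribed:
                M[self.pcol[a], col] += 1.0   # flow leaves node a
                M[row, self.pcol[a]] += 1.0
            else:
                base[row] -= self.p_ven
            if bnode != prescribed:
                M[self.pcol[bnode], col] -= 1.0  # flow enters node b
                M[row, self.pcol[bnode]] -= 1.0
            else:
                base[row] += self.p_ven

        # windkessel stamps: Z between terminal node and internal node,
        # R_wk from internal node to the venous reference
        for vid, t in network.terminals.items():
            tn = self.pcol[network.terminal_nodes[vid]]
            w = self.wk_col[vid]
            g_z = 1.0 / t.Z_wk
            g_r = 1.0 / t.R_wk
            M[tn, tn] += g_z
            M[tn, w] -= g_z
            M[w, tn] -= g_z
            M[w, w] += g_z + g_r
            base[w] += g_r * self.p_ven

        self.M = M
        self.base = base
        self.inflow_row = self.pcol[network.inflow_node]
        self._lu = lu_factor(M) if dt is not None else None
        if self.anast_rows and dt is not None:
            E = np.zeros((n, len(self.anast_rows)))
            for j, r in enumerate(self.anast_rows):
                E[r, j] = 1.0
            self._Y = lu_solve(self._lu, E)  # M0^{-1} e_r for Woodbury
        else:
            self._Y = None
        self.anast_cols = np.array([r for r in self.anast_rows], dtype=int)

        # observables (hand-built networks without a brachial artery fall
        # back to the first branch as the reference flow)
        self.aortic_p_col = self.pcol[network.inflow_node]
        if AXILLARY_BRACHIAL in network.vessel_branches:
            self.brachial_branch = network.proximal_branch(AXILLARY_BRACHIAL)
        else:
            self.brachial_branch = 0

    # ------------------------------------------------------------------
    def _solve_anastomosis(self, x0: np.ndarray, q_init: np.ndarray,
                           controls: SolverControls) -> np.ndarray:
        """Resolve the nonlinear anastomosis branches by Newton iteration.

        The quadratic loss dp = c q|q| is linearized around the iterate q*
        (slope 2c|q*|, source -c q*|q*|); both enter the prefactorized
        system through a low-rank Woodbury correction, so each iteration is
        a handful of vector operations on top of the single base solve
        ``x0 = M0^{-1} rhs``.
        """
        rows = self.anast_cols
        q_star = q_init.copy()
        for _ in range(controls.max_anastomosis_iter):
            deltas = 2.0 * self.anast_coeff * np.abs(q_star)
            src = -self.anast_coeff * q_star * np.abs(q_star)
            xb = x0 + self._Y @ src  # rhs correction on the branch rows
            act = deltas > 0
            if np.any(act):
                Yd = self._Y[:, act] * (-deltas[act])
                small = np.eye(int(act.sum())) + Yd[rows[act], :]
                coef = np.linalg.solve(small, xb[rows[act]])
                x = xb - Yd @ coef
            else:
                x = xb
            q_new = x[rows]
            if np.all(np.abs(q_new - q_star)
                      <= controls.anastomosis_tol * np.maximum(np.abs(q_new), 1e-12)):
                return x
            q_star = q_new
        raise SimulationError("anastomosis linearization did not settle")

    def step(self, state: SolverState, inj: float,
             controls: SolverControls) -> None:
        """Advance one fixed time step in place."""
        rhs = self.base.copy()
        rhs[: self.n_p] += self.g_c * state.p + state.i_c
        rhs[self.inflow_row] += inj
        rhs[self.n_p:] += -(self.g_l * state.q) - state.v_l

        x0 = lu_solve(self._lu, rhs)
        if self.anast_rows:
            x = self._solve_anastomosis(x0, state.q[self.anast_cols - self.n_p],
                                        controls)
        else:
            x = x0

        p_new = x[: self.n_p]
        q_new = x[self.n_p:]
        if not np.all(np.isfinite(p_new)):
            raise SimulationError("non-finite pressures (unstable step)")
        state.i_c = self.g_c * (p_new - state.p) - state.i_c
        state.v_l = self.g_l * (q_new - state.q) - state.v_l
        state.p = p_new
        state.q = q_new

    def dc_state(self, mean_inflow: float, controls: SolverControls) -> SolverState:
        """DC operating point (L shorted, C open) as the initial state."""
        static = CompiledNetwork(self.network, units.pa_to_mmhg(self.p_ven), None)
        rhs = static.base.copy()
        rhs[static.inflow_row] += mean_inflow
        q_star = np.zeros(len(static.anast_rows))
        x = np.linalg.solve(static.M, rhs)
        for _ in range(controls.max_anastomosis_iter if static.anast_rows else 0):
            # Newton on the static system (cheap, done once per run)
            M = static.M.copy()
            r = rhs.copy()
            for j, row in enumerate(static.anast_rows):
                M[row, row] -= 2.0 * static.anast_coeff[j] * abs(q_star[j])
                r[row] -= static.anast_coeff[j] * q_star[j] * abs(q_star[j])
            x = np.linalg.solve(M, r)
            q_new = x[static.anast_cols]
            if np.all(np.abs(q_new - q_star)
                      <= controls.anastomosis_tol * np.maximum(np.abs(q_new), 1e-12)):
                break
            q_star = q_new
        return SolverState(p=x[: self.n_p].copy(), q=x[self.n_p:].copy(),
                           i_c=np.zeros(self.n_p), v_l=np.zeros(self.n_b))


@dataclass
class SimulationResult:
    """Pressure/flow traces over the final (periodic) cardiac cycle."""

    time_s: np.ndarray
    pressures_pa: np.ndarray       # (n_p, nt): free nodes then windkessel nodes
    flows_m3_s: np.ndarray         # (n_b, nt)
    mean_aortic_pressure_mmhg: float
    mean_brachial_flow_ml_min: float
    converged: bool
    cycles_run: int
    system: CompiledNetwork
    final_state: SolverState

    @property
    def network(self) -> VascularNetwork:
        return self.system.network

    def node_pressure_mmhg(self, node: int) -> np.ndarray:
        if node == self.network.venous_outflow_node:
            return np.full_like(self.time_s, units.pa_to_mmhg(self.system.p_ven))
        return units.pa_to_mmhg(self.pressures_pa[self.system.pcol[node]])

    def vessel_flow_ml_min(self, vessel_id: str, where: str = "proximal") -> np.ndarray:
        idxs = self.network.vessel_branches[vessel_id]
        i = idxs[0] if where == "proximal" else idxs[-1]
        return units.m3_per_s_to_ml_per_min(self.flows_m3_s[i])

    def mean_vessel_flow_ml_min(self, vessel_id: str, where: str = "proximal") -> float:
        return float(np.mean(self.vessel_flow_ml_min(vessel_id, where)))


def _compile(network: VascularNetwork, venous_pressure_mmhg: float,
             cardiac_period_s: float, controls: SolverControls) -> CompiledNetwork:
    dt = cardiac_period_s / controls.steps_per_cycle
    return CompiledNetwork(network, venous_pressure_mmhg, dt)


def _run(compiled: CompiledNetwork, inflow: Waveform,
         controls: SolverControls,
         initial_state: Optional[SolverState] = None) -> SimulationResult:
    nt = controls.steps_per_cycle
    dt = compiled.dt
    period = inflow.period_s
    t_grid = (np.arange(nt) + 1.0) * dt
    inj = units.ml_per_s_to_m3_per_s(inflow.sample(t_grid))

    if initial_state is None:
        state = compiled.dc_state(units.ml_per_s_to_m3_per_s(inflow.mean()), controls)
    else:
        state = initial_state.copy()

    p_tr = np.empty((compiled.n_p, nt))
    q_tr = np.empty((compiled.n_b, nt))
    prev_map = None
    prev_qb = None
    converged = False
    cycles = 0
    for cycle in range(controls.max_cycles):
        for k in range(nt):
            compiled.step(state, inj[k], controls)
            p_tr[:, k] = state.p
            q_tr[:, k] = state.q
        cycles += 1
        map_pa = float(np.mean(p_tr[compiled.aortic_p_col]))
        qb = float(np.mean(q_tr[compiled.brachial_branch]))
        if prev_map is not None and cycles >= controls.min_cycles:
            d_map = abs(map_pa - prev_map) / max(abs(prev_map), 1e-12)
            d_qb = abs(qb - prev_qb) / max(abs(prev_qb), 1e-12)
            if d_map < controls.periodic_tol and d_qb < controls.periodic_tol:
                converged = True
        prev_map, prev_qb = map_pa, qb
        if converged:
            break

    return SimulationResult(
        time_s=t_grid, pressures_pa=p_tr, flows_m3_s=q_tr,
        mean_aortic_pressure_mmhg=units.pa_to_mmhg(prev_map),
        mean_brachial_flow_ml_min=units.m3_per_s_to_ml_per_min(prev_qb),
        converged=converged, cycles_run=cycles, system=compiled,
        final_state=state)


def simulate(network: VascularNetwork, inflow_waveform: Waveform,
             venous_pressure_mmhg: float = 10.0,
             controls: SolverControls = DEFAULT_CONTROLS,
             initial_state: Optional[SolverState] = None) -> SimulationResult:
    """Integrate the network to its periodic steady state.

    ``inflow_waveform`` is the aortic flow in ml/s over one cardiac cycle;
    the venous pressure is prescribed at the subclavian-vein outflow node
    and acts as the reference for the windkessels and leakage resistors.
    A run that does not settle within ``max_cycles`` is returned with
    ``converged=False`` rather than raising.
    """
    compiled = _compile(network, venous_pressure_mmhg, inflow_waveform.period_s,
                        controls)
    return _run(compiled, inflow_waveform, controls, initial_state)


@dataclass
class BaroreflexResult:
    """Outcome of the inflow-scaling (baroreflex) iteration."""

    scale: float
    result: SimulationResult
    target_map_mmhg: float
    restored: bool
    simulations: int

    @property
    def map_error(self) -> float:
        return abs(self.result.mean_aortic_pressure_mmhg - self.target_map_mmhg) \
            / self.target_map_mmhg


def baroreflex_scale(network_postop: VascularNetwork,
                     preop_result: SimulationResult,
                     inflow_waveform_preop: Waveform,
                     venous_pressure_mmhg: float = 10.0,
                     controls: SolverControls = DEFAULT_CONTROLS,
                     map_tol: float = 1e-3,
                     s_max: float = 5.0,
                     max_simulations: int = 30) -> BaroreflexResult:
    """Scale the preoperative inflow until the mean aortic pressure is restored.

    Mimics short-term pressure regulation: creating the fistula lowers the
    total systemic resistance, so at unchanged inflow the mean aortic
    pressure falls; the heart responds by raising output.  All other
    preoperative parameters (windkessels in particular) are held constant
    while a bracketed secant iteration finds the scalar ``s >= 1`` with
    ``|MAP(s) - MAP_preop| / MAP_preop < map_tol``.  If no ``s`` in
    ``[1, s_max]`` restores the pressure the result is flagged
    ``restored=False``.
    """
    if not preop_result.converged:
        raise ValidationError("preoperative simulation did not converge")
    target = preop_result.mean_aortic_pressure_mmhg

    compiled = _compile(network_postop, venous_pressure_mmhg,
                        inflow_waveform_preop.period_s, controls)
    n_sim = 0
    state: Optional[SolverState] = None

    def run(s: float) -> SimulationResult:
        nonlocal n_sim, state
        n_sim += 1
        res = _run(compiled, inflow_waveform_preop.scaled(s), controls,
                   initial_state=state)
        state = res.final_state
        return res

    res = run(1.0)
    err = res.mean_aortic_pressure_mmhg - target
    if abs(err) / target < map_tol or err > 0:
        # no pressure deficit to compensate (s is constrained to >= 1)
        return BaroreflexResult(1.0, res, target,
                                abs(err) / target < map_tol, n_sim)

    s_lo, f_lo = 1.0, err
    # proportional first guess: MAP is close to linear in the inflow scale
    s_hi = min(s_max, max(1.05, target / res.mean_aortic_pressure_mmhg))
    res_hi = run(s_hi)
    f_hi = res_hi.mean_aortic_pressure_mmhg - target
    while f_hi < 0 and s_hi < s_max and n_sim < max_simulations:
        s_lo, f_lo = s_hi, f_hi
        s_hi = min(s_max, s_hi * 1.4)
        res_hi = run(s_hi)
        f_hi = res_hi.mean_aortic_pressure_mmhg - target
    if abs(f_hi) / target < map_tol:
        return BaroreflexResult(s_hi, res_hi, target, True, n_sim)
    if f_hi < 0:
        return BaroreflexResult(s_hi, res_hi, target, False, n_sim)

    best_s, best_res = s_hi, res_hi
    while n_sim < max_simulations:
        # secant step, kept inside the bracket
        s_new = s_hi - f_hi * (s_hi - s_lo) / (f_hi - f_lo)
        if not s_lo < s_new < s_hi:
            s_new = 0.5 * (s_lo + s_hi)
        res_new = run(s_new)
        f_new = res_new.mean_aortic_pressure_mmhg - target
        if abs(f_new) / target < map_tol:
            return BaroreflexResult(s_new, res_new, target, True, n_sim)
        if f_new < 0:
            s_lo, f_lo = s_new, f_new
        else:
            s_hi, f_hi = s_new, f_new
            best_s, best_res = s_new, res_new
    return BaroreflexResult(
        best_s, best_res, target,
        abs(best_res.mean_aortic_pressure_mmhg - target) / target < map_tol,
        n_sim)
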