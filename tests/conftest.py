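"""Shared fixtures and independent check helpers."""

from __future__ import annotations

import numpy as np
import pytest

from avfplan import units
from avfplan.network import (
    Branch,
    DEFAULT_BLOOD,
    SegmentElements,
    VascularNetwork,
    WindkesselTerminal,
)
from avfplan.synthesis import DEFAULT_COHORT_SPEC, generate_patient
from avfplan.waveforms import Waveform


@pytest.fixture(scope="session")
def patient():
    """First patient of the default synthetic cohort."""
    return generate_patient(DEFAULT_COHORT_SPEC, 0)


@pytest.fixture()
def constant_inflow():
    def make(q_ml_s: float, period_s: float = 1.0) -> Waveform:
        return Waveform(np.array([0.0, period_s]), np.array([q_ml_s, q_ml_s]))

    return make


# ---------------------------------------------------------------------------
# hand-built networks and independent oracles
# ---------------------------------------------------------------------------

def random_resistive_tree(rng: np.random.Generator) -> VascularNetwork:
    """A random tree of purely resistive segments with windkessel leaves.

    All segment C and L are zero, so with a constant inflow the periodic
    solution must coincide with the static resistor-network solution.
    """
    n_nodes = int(rng.integers(4, 10))
    branches = []
    children = {i: 0 for i in range(n_nodes)}
    for node in range(1, n_nodes):
        parent = int(rng.integers(0, node))
        children[parent] += 1
        r_si = units.r_clinical_to_si(float(rng.uniform(0.2, 5.0)))
        el = SegmentElements(R=r_si, L=0.0, C=0.0, seg_length_cm=1.0)
        branches.append(Branch(parent, node, el, f"seg{node}"))
    leaves = [i for i in range(n_nodes) if children[i] == 0 and i != 0]
    terminals = {}
    terminal_nodes = {}
    for j, leaf in enumerate(leaves):
        r_tot = units.r_clinical_to_si(float(rng.uniform(20.0, 120.0)))
        terminals[f"term{j}"] = WindkesselTerminal(
            Z_wk=0.1 * r_tot, R_wk=0.9 * r_tot,
            C_wk=units.c_clinical_to_si(1e-4))
        terminal_nodes[f"term{j}"] = leaf
    return VascularNetwork(
        configuration="preoperative", side="left", n_nodes=n_nodes,
        branches=branches, anastomosis=None, anastomosis_branches=[],
        terminal_nodes=terminal_nodes, terminals=terminals,
        inflow_node=0, venous_outflow_node=None, blood=DEFAULT_BLOOD,
        vessel_branches={br.vessel_id: [i] for i, br in enumerate(branches)},
    )


def direct_resistive_solution(network: VascularNetwork, q_in_m3_s: float,
                              p_ven_pa: float) -> np.ndarray:
    """Independent nodal (Laplacian) solve of a resistive network.

    Windkessels are series resistors Z + R to the venous reference at
    steady state.  Returns node pressures (Pa) indexed by node id.
    """
    n = network.n_nodes
    G = np.zeros((n, n))
    b = np.zeros(n)
    for br in network.branches:
        g = 1.0 / br.elements.R
        a, c = br.node_a, br.node_b
        G[a, a] += g
        G[c, c] += g
        G[a, c] -= g
        G[c, a] -= g
    for vid, t in network.terminals.items():
        node = network.terminal_nodes[vid]
        g = 1.0 / (t.Z_wk + t.R_wk)
        G[node, node] += g
        b[node] += g * p_ven_pa
    b[network.inflow_node] += q_in_m3_s
    return np.linalg.solve(G, b)


def node_balance_residuals(result, inflow_waveform) -> np.ndarray:
    """Cycle-mean flow balance at every pressure unknown, from the traces.

    At the periodic steady state the net compliance storage over a cycle
    vanishes, so (branch flows in - out + injection - leakage - windkessel
    outflow) must be ~0 at every node.  Computed from the result traces and
    the network element values only, independently of the solver internals.
    """
    sys_ = result.system
    net = sys_.network
    prescribed = net.venous_outflow_node
    mean_p = result.pressures_pa.mean(axis=1)
    mean_q = result.flows_m3_s.mean(axis=1)
    resid = np.zeros(sys_.n_p)
    for i, (a, b) in enumerate(sys_.branch_nodes):
        if a != prescribed:
            resid[sys_.pcol[a]] -= mean_q[i]
        if b != prescribed:
            resid[sys_.pcol[b]] += mean_q[i]
    inj = units.ml_per_s_to_m3_per_s(inflow_waveform.sample(result.time_s))
    resid[sys_.pcol[net.inflow_node]] += float(np.mean(inj))
    resid -= sys_.node_leak_g * (mean_p - sys_.p_ven)
    for vid, t in net.terminals.items():
        tn = sys_.pcol[net.terminal_nodes[vid]]
        w = sys_.wk_col[vid]
        q_z = (mean_p[tn] - mean_p[w]) / t.Z_wk
        resid[tn] -= q_z
        resid[w] += q_z - (mean_p[w] - sys_.p_ven) / t.R_wk
    return resid
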