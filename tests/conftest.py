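import numpy as np
import pytest

from biogeodiv.dec import (AreaSystem, build_q_matrix,
                           enumerate_states, split_scenarios)
from biogeodiv.treeio import TimeTree


@pytest.fixture
def ab_system():
    """Two areas, adjacent, ranges up to both."""
    return AreaSystem.from_pairs("AB", [("A", "B")], 2)


@pytest.fixture
def chain5_system():
    """Five areas in a chain (A-B-C-D-E), max range two."""
    return AreaSystem.from_pairs(
        "ABCDE", [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")], 2)


@pytest.fixture
def cherry():
    return TimeTree.from_newick("(A:1,B:1);")


@pytest.fixture
def balanced4():
    return TimeTree.from_newick("((t1:1,t2:1):1,(t3:1,t4:1):1);")


def euler_propagator(q: np.ndarray, t: float, dt: float = 1e-6
                     ) -> np.ndarray:
    """Independent discretized propagator: (I + Q dt)^(t/dt)."""
    n_steps = max(int(round(t / dt)), 1)
    return np.linalg.matrix_power(np.eye(q.shape[0]) + q * (t / n_steps),
                                  n_steps)


def dec_brute_force_cherry(system, tip_states, branch_lengths, params,
                           dt=1e-6):
    """Likelihood of a two-tip tree summed state-by-state with the Euler
    propagator; returns (logL, scenario probability dict)."""
    states = enumerate_states(system)
    idx = {s: i for i, s in enumerate(states)}
    allowed = set(states)
    q = build_q_matrix(system, params, states)
    p_left = euler_propagator(q, branch_lengths[0], dt)
    p_right = euler_propagator(q, branch_lengths[1], dt)
    ia, ib = idx[tip_states[0]], idx[tip_states[1]]
    nonempty = [s for s in states if s]
    raw = {}
    for s in nonempty:
        scns = split_scenarios(s, allowed)
        for l, r in scns:
            raw[(l, r)] = raw.get((l, r), 0.0) + (
                (1.0 / len(nonempty)) * (1.0 / len(scns))
                * p_left[idx[l], ia] * p_right[idx[r], ib])
    total = sum(raw.values())
    return np.log(total), {k: v / total for k, v in raw.items()}


@pytest.fixture
def dec_oracle():
    return dec_brute_force_cherry
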