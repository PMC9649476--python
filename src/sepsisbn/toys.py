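"""Toy Boolean networks with exactly computable long-run behaviour.

Small delay-free networks (plus one delayed chain for delay tests) whose
stochastic long-run activation can be computed exactly from the full
state-space Markov chain.  These stand in for external data: the engine's
Monte-Carlo estimates are validated against :func:`exact_stationary`
(the independent oracle) on every motif and both update schemes.

Motifs
------
``chain``          A = A; B = A; C = B; ... — a self-sustaining source
                   feeding a feed-forward cascade; everything converges to 1.
``or_redundant``   SrcX = SrcX; SrcY = SrcY; End = SrcX | SrcY — an endpoint
                   with two redundant inputs; only the double knock-out
                   silences it.
``oscillator``     A = !A; B = A — a negative self-loop; the Cesàro
                   time-average activation of A is 1/2 under both schemes.
``scheme_gap``     a fixture whose stationary activations differ between the
                   single_node and random_order schemes.
``delayed_chain``  A = A; B = THR_A[lag] with delay 2 — for testing
                   consecutive-activity threshold semantics.
``random``         reproducible random two-regulator rules.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd

from .model import BooleanModel
from .rules import And, Not, Or, RuleExpr, Thr, Var

__all__ = ["make_toy_network", "exact_stationary", "MOTIFS"]

MOTIFS = ("chain", "or_redundant", "oscillator", "scheme_gap",
          "delayed_chain", "random")

_NAMES = "ABCDEFGHIJ"


def make_toy_network(n: int = 3, seed: int = 0,
                     motif: str = "chain") -> BooleanModel:
    """Build a toy model (<= 10 nodes) with documented expected behaviour."""
    if not (1 <= n <= 10):
        raise ValueError("toy networks support 1..10 nodes")
    if motif == "chain":
        lines = [f"{_NAMES[0]} = {_NAMES[0]}"]
        lines += [f"{_NAMES[i]} = {_NAMES[i - 1]}" for i in range(1, n)]
        return BooleanModel.from_rules(
            "\n".join(lines), initial_state={_NAMES[0]: 1},
            name=f"chain{n}")
    if motif == "or_redundant":
        text = "SrcX = SrcX\nSrcY = SrcY\nEnd = SrcX | SrcY"
        return BooleanModel.from_rules(
            text, initial_state={"SrcX": 1, "SrcY": 1}, name="or_redundant")
    if motif == "oscillator":
        return BooleanModel.from_rules(
            "A = !A\nB = A", initial_state={"A": 1}, name="oscillator")
    if motif == "scheme_gap":
        # B copies A while A flips: under random_order both nodes are
        # updated every step and the copy lags coherently; under
        # single_node only one of them moves per step.  The long-run
        # activation of C = A & B separates the schemes.
        text = "A = !A\nB = A\nC = A & B"
        return BooleanModel.from_rules(text, initial_state={"A": 1},
                                       name="scheme_gap")
    if motif == "delayed_chain":
        return BooleanModel.from_rules(
            "A = A\nB = THR_A[lag]", delays={"lag": 2},
            initial_state={"A": 1}, name="delayed_chain")
    if motif == "random":
        rng = np.random.RandomState(seed)
        lines = []
        names = [_NAMES[i] for i in range(n)]
        for i, name in enumerate(names):
            r1, r2 = names[rng.randint(n)], names[rng.randint(n)]
            lit1 = f"!{r1}" if rng.randint(2) else r1
            lit2 = f"!{r2}" if rng.randint(2) else r2
            op = "&" if rng.randint(2) else "|"
            lines.append(f"{name} = {lit1} {op} {lit2}")
        init = {names[i]: 1 for i in range(n) if rng.randint(2)}
        if not init:
            init = {names[0]: 1}
        return BooleanModel.from_rules("\n".join(lines), initial_state=init,
                                       name=f"random{n}_s{seed}")
    raise ValueError(f"unknown motif {motif!r}; choose from {MOTIFS}")


# ---------------------------------------------------------------------------
# Exact long-run oracle
# ---------------------------------------------------------------------------

def _eval_state(expr: RuleExpr, bits: np.ndarray, index: dict[str, int]) -> int:
    if isinstance(expr, Var):
        return int(bits[index[expr.name]])
    if isinstance(expr, Not):
        return 1 - _eval_state(expr.child, bits, index)
    if isinstance(expr, And):
        return int(all(_eval_state(c, bits, index) for c in expr.children))
    if isinstance(expr, Or):
        return int(any(_eval_state(c, bits, index) for c in expr.children))
    if isinstance(expr, Thr):
        raise ValueError("exact_stationary supports delay-free models only")
    raise TypeError(f"not a RuleExpr: {expr!r}")


def exact_stationary(model: BooleanModel, scheme: str = "single_node",
                     tol: float = 1e-10) -> pd.Series:
    """Exact per-node long-run activation from the full Markov chain.

    Builds the state-transition probability matrix of the chosen update
    scheme over all 2^n network states (n <= 10 for ``single_node``; n <= 5
    for ``random_order``, whose kernel averages over all n! within-step
    orders), then power-iterates the initial distribution through the lazy
    chain (I+P)/2 — same long-run behaviour, guaranteed aperiodic — to the
    requested tolerance.  For periodic or multi-attractor chains the result
    is the Cesàro (time-average) limit, matching the engine's
    window-averaged readout.
    """
    if model.has_delays():
        raise ValueError("exact_stationary supports delay-free models only")
    n = model.n_nodes
    cap = 10 if scheme == "single_node" else 5
    if scheme not in ("single_node", "random_order"):
        raise ValueError(f"unknown scheme {scheme!r}")
    if n > cap:
        raise ValueError(f"{scheme} oracle capped at {cap} nodes, got {n}")
    index = model.node_index
    exprs = [model.rules[name] for name in model.nodes]
    n_states = 1 << n

    def to_bits(s: int) -> np.ndarray:
        return np.array([(s >> i) & 1 for i in range(n)], dtype=np.int8)

    def from_bits(bits: np.ndarray) -> int:
        return int(sum(int(b) << i for i, b in enumerate(bits)))

    P = np.zeros((n_states, n_states))
    if scheme == "single_node":
        w = 1.0 / n
        for s in range(n_states):
            bits = to_bits(s)
            for i in range(n):
                new = bits.copy()
                new[i] = _eval_state(exprs[i], bits, index)
                P[s, from_bits(new)] += w
    else:
        orders = list(permutations(range(n)))
        w = 1.0 / len(orders)
        for s in range(n_states):
            bits = to_bits(s)
            for order in orders:
                cur = bits.copy()
                for i in order:
                    cur[i] = _eval_state(exprs[i], cur, index)
                P[s, from_bits(cur)] += w

    lazy = 0.5 * (np.eye(n_states) + P)
    mu = np.zeros(n_states)
    mu[from_bits(model.initial_vector())] = 1.0
    for _ in range(1_000_000):
        nxt = mu @ lazy
        if np.max(np.abs(nxt - mu)) < tol:
            mu = nxt
            break
        mu = nxt
    activation = np.zeros(n)
    for s in range(n_states):
        if mu[s] > 0:
            activation += mu[s] * to_bits(s)
    return pd.Series(activation, index=list(model.nodes))
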