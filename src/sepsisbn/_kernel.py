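"""Compiled simulation core.

Rules are flattened to postfix programs (opcodes below) executed by a
numba-jitted interpreter, which makes the screen pipelines (hundreds of
conditions x 100 repetitions) run in seconds.  All randomness is drawn as
uniform doubles from the legacy NumPy Mersenne Twister, seeded per
repetition, so a pure-Python mirror using ``np.random.RandomState`` consumes
the identical stream and reproduces trajectories bit for bit (asserted in
the test suite).

Threshold (THR) terms always read *committed* whole-step history through
consecutive-activity run counters, so delay semantics do not depend on the
within-step update order.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .rules import And, Not, Or, RuleExpr, Thr, Var

OP_VAR = 0   # push state[arg]
OP_THR = 1   # push threshold bit of slot arg
OP_NOT = 2
OP_AND = 3
OP_OR = 4

SCHEME_RANDOM_ORDER = 0
SCHEME_SINGLE_NODE = 1

_SEED_MOD = 2147483647  # per-rep seeds stay below 2**31


class CompiledModel:
    """Postfix programs + threshold slots for one BooleanModel."""

    def __init__(self, model) -> None:
        index = model.node_index
        slots: dict[tuple[int, int], int] = {}
        code_op: list[int] = []
        code_arg: list[int] = []
        starts = np.zeros(model.n_nodes, dtype=np.int64)
        lengths = np.zeros(model.n_nodes, dtype=np.int64)

        def emit(expr: RuleExpr) -> None:
            if isinstance(expr, Var):
                code_op.append(OP_VAR)
                code_arg.append(index[expr.name])
            elif isinstance(expr, Thr):
                key = (index[expr.name], model.delays[expr.tag])
                slot = slots.setdefault(key, len(slots))
                code_op.append(OP_THR)
                code_arg.append(slot)
            elif isinstance(expr, Not):
                emit(expr.child)
                code_op.append(OP_NOT)
                code_arg.append(0)
            elif isinstance(expr, (And, Or)):
                op = OP_AND if isinstance(expr, And) else OP_OR
                emit(expr.children[0])
                for child in expr.children[1:]:
                    emit(child)
                    code_op.append(op)
                    code_arg.append(0)
            else:  # pragma: no cover
                raise TypeError(f"not a RuleExpr: {expr!r}")

        for i, name in enumerate(model.nodes):
            starts[i] = len(code_op)
            emit(model.rules[name])
            lengths[i] = len(code_op) - starts[i]

        self.code_op = np.array(code_op, dtype=np.int64)
        self.code_arg = np.array(code_arg, dtype=np.int64)
        self.starts = starts
        self.lengths = lengths
        if slots:
            pairs = sorted(slots, key=slots.get)
            self.thr_node = np.array([p[0] for p in pairs], dtype=np.int64)
            self.thr_delay = np.array([p[1] for p in pairs], dtype=np.int64)
        else:
            self.thr_node = np.zeros(0, dtype=np.int64)
            self.thr_delay = np.zeros(0, dtype=np.int64)
        self.init = model.initial_vector()


def compiled(model) -> CompiledModel:
    """Compile (and cache on the model instance) the postfix programs."""
    cm = getattr(model, "_compiled_cache", None)
    if cm is None:
        cm = CompiledModel(model)
        model._compiled_cache = cm
    return cm


@njit(cache=False)
def _eval_postfix(code_op, code_arg, start, length, src, thr_bits, stack):
    sp = 0
    for k in range(start, start + length):
        op = code_op[k]
        a = code_arg[k]
        if op == 0:
            stack[sp] = src[a]
            sp += 1
        elif op == 1:
            stack[sp] = thr_bits[a]
            sp += 1
        elif op == 2:
            stack[sp - 1] = 1 - stack[sp - 1]
        elif op == 3:
            sp -= 1
            if stack[sp] == 0:
                stack[sp - 1] = 0
        else:
            sp -= 1
            if stack[sp] == 1:
                stack[sp - 1] = 1
    return stack[0]


@njit(cache=False)
def run_ensemble(code_op, code_arg, starts, lengths, thr_node, thr_delay,
                 init_raw, clamp_sched, poly, steps, reps, scheme, seed):
    """Simulate *reps* independent trajectories of *steps* update rounds.

    Returns an int8 array of shape (reps, steps+1, n); row 0 is the initial
    state with step-0 clamps applied.  ``clamp_sched[t, i]`` is -1 (free) or
    the clamped bit.  ``poly[i]`` is the polymorphism activity fraction;
    1.0 bypasses the RNG entirely.
    """
    n = init_raw.shape[0]
    n_slots = thr_node.shape[0]
    out = np.zeros((reps, steps + 1, n), dtype=np.int8)
    stack = np.empty(128, dtype=np.int8)
    run = np.empty(n, dtype=np.int64)
    thr_bits = np.empty(max(n_slots, 1), dtype=np.int8)
    perm = np.empty(n, dtype=np.int64)
    big = np.int64(1) << np.int64(40)

    for rep in range(reps):
        np.random.seed((seed + rep) % _SEED_MOD)
        for i in range(n):
            c = clamp_sched[0, i]
            out[rep, 0, i] = c if c >= 0 else init_raw[i]
            # infinite pre-history of the raw initial state
            run[i] = big if init_raw[i] == 1 else 0
        for t in range(1, steps + 1):
            prev = out[rep, t - 1]
            for i in range(n):
                if prev[i] == 1:
                    run[i] += 1
                else:
                    run[i] = 0
            for k in range(n_slots):
                thr_bits[k] = 1 if run[thr_node[k]] >= thr_delay[k] else 0
            s = out[rep, t]
            for i in range(n):
                s[i] = prev[i]
            if scheme == 0:
                # every node once, fresh uniform order, sequential updates
                # reading the freshest within-step values
                for i in range(n):
                    perm[i] = i
                for i in range(n - 1, 0, -1):
                    j = int(np.random.random() * (i + 1))
                    tmp = perm[i]
                    perm[i] = perm[j]
                    perm[j] = tmp
                for p in range(n):
                    i = perm[p]
                    c = clamp_sched[t, i]
                    if c >= 0:
                        s[i] = c
                        continue
                    v = _eval_postfix(code_op, code_arg, starts[i],
                                      lengths[i], s, thr_bits, stack)
                    if v == 1 and poly[i] < 1.0:
                        if np.random.random() >= poly[i]:
                            v = 0
                    s[i] = v
            else:
                # one uniformly chosen node per step, reading committed state
                j = int(np.random.random() * n)
                c = clamp_sched[t, j]
                if c >= 0:
                    s[j] = c
                else:
                    v = _eval_postfix(code_op, code_arg, starts[j],
                                      lengths[j], prev, thr_bits, stack)
                    if v == 1 and poly[j] < 1.0:
                        if np.random.random() >= poly[j]:
                            v = 0
                    s[j] = v
                # clamps dominate carried-over states too
                for i in range(n):
                    c = clamp_sched[t, i]
                    if c >= 0:
                        s[i] = c
    return out
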