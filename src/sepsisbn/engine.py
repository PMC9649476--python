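"""Stochastic asynchronous simulation with timed clamps and polymorphisms.

Two update schemes are provided:

``random_order`` (default)
    Every node is updated once per time step, in a fresh uniform random
    permutation; updates within a step are sequential and read the freshest
    within-step values.  Threshold (delay) terms always read committed
    whole-step history, so delay semantics are scheme-independent.

``single_node``
    Classical asynchronous updating: one uniformly chosen node is updated
    per step, reading the committed previous state; all others carry over.

Perturbations are clamps — knock-out (KO, hold 0) or over-expression (OE,
hold 1) — active on a step interval, open-ended by default, and dominating
rule evaluation, polymorphism and the initial state.  A polymorphism with
activity ``p`` lets a node switch on only a fraction ``p`` of the times its
rule fires (independent draws); ``p = 1`` bypasses the RNG entirely.

Given identical inputs and seed the trajectory is reproducible bit for bit.
Repetition ``r`` uses its own generator seeded ``seed + r``, so repetitions
are independently reproducible.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from . import _kernel
from .model import BooleanModel
from .rules import evaluate

__all__ = [
    "SimConfig",
    "PerturbationSpec",
    "PolymorphismSpec",
    "Trajectory",
    "simulate",
    "simulate_ensemble",
    "SCHEMES",
]

SCHEMES = ("random_order", "single_node")

KO, OE = "KO", "OE"


@dataclass(frozen=True)
class SimConfig:
    """Simulation settings: total update rounds, repetitions, scheme."""

    steps: int = 60
    reps: int = 100
    seed: int = 0
    scheme: str = "random_order"

    def __post_init__(self) -> None:
        if self.steps < 1:
            raise ValueError("steps must be >= 1")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")


@dataclass(frozen=True)
class PerturbationSpec:
    """KO/OE clamp on *node* over steps [start, end] (end=None: open-ended)."""

    node: str
    mode: str
    start: int = 0
    end: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in (KO, OE):
            raise ValueError(f"mode must be 'KO' or 'OE', got {self.mode!r}")
        if self.start < 0:
            raise ValueError("start must be >= 0")
        if self.end is not None and self.end < self.start:
            raise ValueError("end must be >= start")

    @property
    def value(self) -> int:
        return 0 if self.mode == KO else 1

    @classmethod
    def parse(cls, text: str) -> "PerturbationSpec":
        """Parse a ``NODE:MODE[:START[:END]]`` triplet (CLI encoding)."""
        parts = text.split(":")
        if len(parts) < 2 or len(parts) > 4:
            raise ValueError(f"cannot parse perturbation {text!r}")
        node, mode = parts[0], parts[1].upper()
        start = int(parts[2]) if len(parts) > 2 else 0
        end = int(parts[3]) if len(parts) > 3 else None
        return cls(node, mode, start, end)


@dataclass(frozen=True)
class PolymorphismSpec:
    """Fractional responsiveness of *node*: rule firings succeed w.p. *activity*."""

    node: str
    activity: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.activity <= 1.0):
            raise ValueError("activity must be in [0, 1]")


@dataclass
class Trajectory:
    """One binary state history: row per committed step, column per node."""

    states: np.ndarray  # (steps+1, n) int8; row 0 = initial (clamped) state
    nodes: list[str]

    @property
    def steps(self) -> int:
        return self.states.shape[0] - 1

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["step", *self.nodes])
            for t, row in enumerate(self.states):
                w.writerow([t, *row.tolist()])


# ---------------------------------------------------------------------------
# Input preparation
# ---------------------------------------------------------------------------

def _clamp_schedule(model: BooleanModel, steps: int,
                    perturbations: Sequence[PerturbationSpec]) -> np.ndarray:
    index = model.node_index
    sched = np.full((steps + 1, model.n_nodes), -1, dtype=np.int8)
    for spec in perturbations:
        if spec.node not in index:
            raise ValueError(f"unknown node {spec.node!r} in perturbation")
        i = index[spec.node]
        hi = steps if spec.end is None else min(spec.end, steps)
        for t in range(min(spec.start, steps + 1), hi + 1):
            if sched[t, i] >= 0 and sched[t, i] != spec.value:
                raise ValueError(
                    f"conflicting clamps on node {spec.node!r} at step {t}")
            sched[t, i] = spec.value
    return sched


def _poly_vector(model: BooleanModel,
                 polymorphisms: Sequence[PolymorphismSpec]) -> np.ndarray:
    index = model.node_index
    poly = np.ones(model.n_nodes, dtype=np.float64)
    seen: set[str] = set()
    for spec in polymorphisms:
        if spec.node not in index:
            raise ValueError(f"unknown node {spec.node!r} in polymorphism")
        if spec.node in seen:
            raise ValueError(f"multiple polymorphisms on node {spec.node!r}")
        seen.add(spec.node)
        poly[index[spec.node]] = spec.activity
    return poly


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def simulate_ensemble(
    model: BooleanModel,
    config: SimConfig | None = None,
    perturbations: Iterable[PerturbationSpec] = (),
    polymorphisms: Iterable[PolymorphismSpec] = (),
    seed: int | None = None,
    backend: str = "numba",
) -> np.ndarray:
    """Run ``config.reps`` repetitions; returns int8 (reps, steps+1, n)."""
    cfg = config or SimConfig()
    if seed is not None:
        cfg = replace(cfg, seed=seed)
    perts = list(perturbations)
    polys = list(polymorphisms)
    sched = _clamp_schedule(model, cfg.steps, perts)
    poly = _poly_vector(model, polys)
    scheme = _kernel.SCHEME_RANDOM_ORDER if cfg.scheme == "random_order" \
        else _kernel.SCHEME_SINGLE_NODE
    if backend == "numba":
        cm = _kernel.compiled(model)
        return _kernel.run_ensemble(
            cm.code_op, cm.code_arg, cm.starts, cm.lengths,
            cm.thr_node, cm.thr_delay, cm.init, sched, poly,
            cfg.steps, cfg.reps, scheme, cfg.seed)
    if backend == "python":
        return _run_python(model, cfg, sched, poly, scheme)
    raise ValueError(f"unknown backend {backend!r}")


def simulate(
    model: BooleanModel,
    config: SimConfig | None = None,
    perturbations: Iterable[PerturbationSpec] = (),
    polymorphisms: Iterable[PolymorphismSpec] = (),
    seed: int | None = None,
    backend: str = "numba",
) -> Trajectory:
    """Run a single trajectory (repetition 0 of the ensemble)."""
    cfg = replace(config or SimConfig(), reps=1)
    ens = simulate_ensemble(model, cfg, perturbations, polymorphisms,
                            seed=seed, backend=backend)
    return Trajectory(states=ens[0], nodes=list(model.nodes))


def _run_python(model: BooleanModel, cfg: SimConfig, sched: np.ndarray,
                poly: np.ndarray, scheme: int) -> np.ndarray:
    """Reference backend: mirrors the kernel draw-for-draw via the rule AST
    evaluator.  Slow; used on toy models to validate the compiled path."""
    n = model.n_nodes
    init_raw = model.initial_vector()
    node_index = model.node_index
    out = np.zeros((cfg.reps, cfg.steps + 1, n), dtype=np.int8)
    exprs = [model.rules[name] for name in model.nodes]
    for rep in range(cfg.reps):
        rng = np.random.RandomState((cfg.seed + rep) % _kernel._SEED_MOD)
        row0 = np.where(sched[0] >= 0, sched[0], init_raw).astype(np.int8)
        out[rep, 0] = row0
        states = out[rep]
        for t in range(1, cfg.steps + 1):
            s = states[t]
            s[:] = states[t - 1]
            if scheme == _kernel.SCHEME_RANDOM_ORDER:
                perm = np.arange(n)
                for i in range(n - 1, 0, -1):
                    j = int(rng.random_sample() * (i + 1))
                    perm[i], perm[j] = perm[j], perm[i]
                order = perm
                src = s
            else:
                j = int(rng.random_sample() * n)
                order = np.array([j])
                src = states[t - 1].copy()
            for i in order:
                c = sched[t, i]
                if c >= 0:
                    s[i] = c
                    continue
                v = evaluate(exprs[i], states[: t], t, model.delays,
                             node_index=node_index, initial_state=init_raw,
                             snapshot=src)
                if v == 1 and poly[i] < 1.0:
                    if rng.random_sample() >= poly[i]:
                        v = 0
                s[i] = v
            if scheme == _kernel.SCHEME_SINGLE_NODE:
                clamped = sched[t] >= 0
                s[clamped] = sched[t][clamped]
    return out
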