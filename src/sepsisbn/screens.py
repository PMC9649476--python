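"""In-silico perturbation screens against the clinical-surrogate endpoints.

Every screen condition clamps one or two nodes (knock-out or
over-expression, optionally starting mid-simulation), estimates the
attractor % activation profile, and scores each endpoint by the relative
activation change

    relative_change = (pct_perturbed - pct_baseline) / pct_baseline

versus the unperturbed profile, with the companion Perturbation Index
PI = pct_perturbed / pct_baseline (categories: negative PI < 0.8, neutral
0.8 <= PI <= 1.25, positive PI > 1.25).  A condition is a *hit* for an
endpoint when |relative_change| passes the efficacy cut-off (default 20%)
in that endpoint's beneficial direction — decreases for the organ-damage
surrogates (Thrombosis, Ang2), increases for the bacterial-clearance
surrogates (MAC, Phagocytosis).

Each condition draws its own seed from a stable hash of its descriptor plus
the master seed, so results are invariant to the order in which conditions
are evaluated and adding conditions never changes existing ones.  A
condition that normalises to no perturbation at all (e.g. a clamp starting
beyond the simulated horizon, or a polymorphism at 100% activity) reuses
the baseline descriptor and therefore reproduces the baseline exactly.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .attractor import ActivationProfile, estimate_attractor
from .engine import KO, OE, PerturbationSpec, PolymorphismSpec, SimConfig
from .model import BooleanModel

__all__ = [
    "relative_change",
    "UNDEFINED_INCREASE",
    "pi_value",
    "pi_category",
    "perturbation_index",
    "ScreenResult",
    "condition_seed",
    "condition_descriptor",
    "mono_screen",
    "pair_screen",
    "antibiotic_screen",
    "timing_sweep",
    "DEFAULT_CUTOFF",
]

DEFAULT_CUTOFF = 0.2

#: sentinel for a change from a silent baseline (0% -> something positive):
#: the ratio is undefined, the condition is excluded from ratio-based hit
#: calling and reported separately.
UNDEFINED_INCREASE = math.inf

PI_NEGATIVE_BELOW = 0.8
PI_POSITIVE_ABOVE = 1.25


# ---------------------------------------------------------------------------
# Scores
# ---------------------------------------------------------------------------

def _check_pct(x: float, what: str) -> float:
    if not (0.0 <= x <= 100.0):
        raise ValueError(f"{what} must be in [0, 100], got {x}")
    return float(x)


def relative_change(baseline_pct: float, perturbed_pct: float) -> float:
    """Signed relative activation change of an endpoint (Eq.-1 style ratio).

    ``(0, 0) -> 0``; ``(0, x>0) -> UNDEFINED_INCREASE`` (inf sentinel).
    """
    b = _check_pct(baseline_pct, "baseline_pct")
    p = _check_pct(perturbed_pct, "perturbed_pct")
    if b == 0.0:
        return 0.0 if p == 0.0 else UNDEFINED_INCREASE
    return (p - b) / b


def pi_value(baseline_pct: float, perturbed_pct: float) -> float:
    """Perturbation Index: perturbed / baseline activation ratio.

    Consistent with :func:`relative_change`: PI = 1 + relative change
    whenever the baseline is positive; ``(0, 0) -> 1``; ``(0, x>0)`` ->
    inf sentinel.
    """
    b = _check_pct(baseline_pct, "baseline_pct")
    p = _check_pct(perturbed_pct, "perturbed_pct")
    if b == 0.0:
        return 1.0 if p == 0.0 else UNDEFINED_INCREASE
    return p / b


def pi_category(pi: float) -> str:
    """negative (PI < 0.8), neutral (0.8 <= PI <= 1.25), positive (PI > 1.25)."""
    if not math.isfinite(pi):
        return "undefined"
    if pi < PI_NEGATIVE_BELOW:
        return "negative"
    if pi > PI_POSITIVE_ABOVE:
        return "positive"
    return "neutral"


def perturbation_index(baseline_profile: ActivationProfile | pd.Series,
                       perturbed_profile: ActivationProfile | pd.Series,
                       ) -> pd.DataFrame:
    """Per-node PI with category labels for two whole-network profiles."""
    base = getattr(baseline_profile, "percent", baseline_profile)
    pert = getattr(perturbed_profile, "percent", perturbed_profile)
    if list(base.index) != list(pert.index):
        raise ValueError("profiles cover different node sets")
    rows = []
    for node in base.index:
        pi = pi_value(float(base[node]), float(pert[node]))
        rows.append({"node": node, "PI": pi, "category": pi_category(pi)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Condition bookkeeping
# ---------------------------------------------------------------------------

def condition_descriptor(perturbations: Sequence[PerturbationSpec] = (),
                         polymorphisms: Sequence[PolymorphismSpec] = (),
                         horizon: int | None = None) -> str:
    """Canonical, order-independent description of a screen condition.

    No-op components are dropped: clamps starting past the simulated horizon
    and polymorphisms at activity 1.  The empty condition is ``"baseline"``.
    """
    parts: list[str] = []
    for p in perturbations:
        if horizon is not None and p.start > horizon:
            continue
        end = "" if p.end is None else str(p.end)
        parts.append(f"{p.mode}:{p.node}@{p.start}-{end}")
    for p in polymorphisms:
        if p.activity >= 1.0:
            continue
        parts.append(f"POLY:{p.node}={p.activity:.6g}")
    parts = sorted(set(parts))
    return "+".join(parts) if parts else "baseline"


def condition_seed(master_seed: int, descriptor: str) -> int:
    """Stable per-condition seed (< 2**31) from the master seed + descriptor."""
    h = int.from_bytes(
        hashlib.blake2s(descriptor.encode(), digest_size=4).digest(), "big")
    return (master_seed * 2654435761 + h) % 2147483629


@dataclass
class ScreenResult:
    """One perturbation condition x endpoint record."""

    condition_id: str
    perturbations: tuple[PerturbationSpec, ...]
    endpoint: str
    baseline_pct: float
    perturbed_pct: float
    relative_change: float
    PI: float
    category: str
    hit: bool
    t_init: int


def _is_hit(rel: float, direction: str, cutoff: float) -> bool:
    if not math.isfinite(rel):
        return False
    if direction == "decrease":
        return rel <= -cutoff
    return rel >= cutoff


class _Screen:
    """Shared profile/scoring machinery for the concrete screens."""

    def __init__(self, model: BooleanModel, config: SimConfig | None,
                 endpoints: Sequence[str] | None, cutoff: float, seed: int,
                 backend: str = "numba"):
        self.model = model
        self.cfg = config or SimConfig()
        self.cutoff = cutoff
        self.seed = seed
        self.backend = backend
        if endpoints is None:
            self.endpoints = dict(model.endpoints)
        else:
            self.endpoints = {e: model.endpoints.get(e, "increase")
                              for e in endpoints}
        self._profiles: dict[str, ActivationProfile] = {}
        self.baseline = self.profile([], [])

    def profile(self, perts: Sequence[PerturbationSpec],
                polys: Sequence[PolymorphismSpec] = ()) -> ActivationProfile:
        desc = condition_descriptor(perts, polys, horizon=self.cfg.steps)
        if desc not in self._profiles:
            self._profiles[desc] = estimate_attractor(
                self.model, self.cfg, perts, polys,
                seed=condition_seed(self.seed, desc), backend=self.backend)
        return self._profiles[desc]

    def score(self, perts: Sequence[PerturbationSpec], t_init: int,
              extra: Mapping | None = None) -> list[dict]:
        desc = condition_descriptor(perts, horizon=self.cfg.steps)
        prof = self.profile(perts)
        rows = []
        for ep, direction in self.endpoints.items():
            b = float(self.baseline.percent[ep])
            p = float(prof.percent[ep])
            rel = relative_change(b, p)
            pi = pi_value(b, p)
            row = {
                "condition_id": desc,
                "endpoint": ep,
                "t_init": t_init,
                "baseline_pct": b,
                "perturbed_pct": p,
                "relative_change": rel,
                "PI": pi,
                "category": pi_category(pi),
                "hit": _is_hit(rel, direction, self.cutoff),
            }
            if extra:
                row.update(extra)
            rows.append(row)
        return rows


# ---------------------------------------------------------------------------
# Concrete screens
# ---------------------------------------------------------------------------

def mono_screen(
    model: BooleanModel,
    screen_set: Sequence[str] | None = None,
    modes: Sequence[str] = (KO, OE),
    endpoints: Sequence[str] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    t_init: int = 0,
    config: SimConfig | None = None,
    seed: int = 0,
    backend: str = "numba",
) -> pd.DataFrame:
    """Single-mediator KO/OE screen.

    Returns one row per (node, mode, endpoint) with the Eq.-1 relative
    change, PI/category and the beneficial-direction hit flag.
    """
    nodes = list(screen_set) if screen_set is not None else list(model.screen_set)
    sc = _Screen(model, config, endpoints, cutoff, seed, backend)
    rows: list[dict] = []
    for node in nodes:
        for mode in modes:
            spec = PerturbationSpec(node, mode, start=t_init)
            rows.extend(sc.score([spec], t_init,
                                 extra={"node": node, "mode": mode}))
    df = pd.DataFrame(rows)
    cols = ["condition_id", "node", "mode", "t_init", "endpoint",
            "baseline_pct", "perturbed_pct", "relative_change", "PI",
            "category", "hit"]
    return df[cols]


_PAIR_MODE_COMBOS = ((KO, KO), (OE, OE), (KO, OE), (OE, KO))


def pair_screen(
    model: BooleanModel,
    screen_set: Sequence[str] | None = None,
    endpoints: Sequence[str] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    t_init: int = 0,
    config: SimConfig | None = None,
    seed: int = 0,
    pairs: Sequence[tuple[str, str]] | None = None,
    mono: pd.DataFrame | None = None,
    backend: str = "numba",
) -> pd.DataFrame:
    """Two-mediator combination screen.

    All unordered node pairs are clamped under every KO/OE mode assignment
    (KO+KO, OE+OE and both mixed assignments).  Besides the raw ``hit``
    flag, ``combination_strategy`` marks hits that neither constituent mono
    perturbation achieved alone for that endpoint — the combinations that
    add value over mono-therapy.
    """
    nodes = list(screen_set) if screen_set is not None else list(model.screen_set)
    if pairs is None:
        pairs = list(combinations(nodes, 2))
    sc = _Screen(model, config, endpoints, cutoff, seed, backend)
    if mono is None:
        mono = mono_screen(model, nodes, (KO, OE), endpoints, cutoff,
                           t_init, config, seed, backend)
    mono_hit = {(r.node, r.mode, r.endpoint): bool(r.hit)
                for r in mono.itertuples()}
    rows: list[dict] = []
    for a, b in pairs:
        for mode_a, mode_b in _PAIR_MODE_COMBOS:
            if a == b and mode_a != mode_b:
                continue  # contradictory clamp on a degenerate pair
            specs = [PerturbationSpec(a, mode_a, start=t_init),
                     PerturbationSpec(b, mode_b, start=t_init)]
            extra = {"node_a": a, "mode_a": mode_a,
                     "node_b": b, "mode_b": mode_b}
            for row in sc.score(specs, t_init, extra=extra):
                ep = row["endpoint"]
                row["combination_strategy"] = bool(
                    row["hit"]
                    and not mono_hit.get((a, mode_a, ep), False)
                    and not mono_hit.get((b, mode_b, ep), False))
                rows.append(row)
    df = pd.DataFrame(rows)
    cols = ["condition_id", "node_a", "mode_a", "node_b", "mode_b", "t_init",
            "endpoint", "baseline_pct", "perturbed_pct", "relative_change",
            "PI", "category", "hit", "combination_strategy"]
    return df[cols]


def antibiotic_screen(
    model: BooleanModel,
    screen_set: Sequence[str] | None = None,
    modes: Sequence[str] = (KO, OE),
    endpoints: Sequence[str] | None = None,
    cutoff: float = DEFAULT_CUTOFF,
    ab_time: int = 20,
    t_init: int = 0,
    config: SimConfig | None = None,
    seed: int = 0,
    antibiotic_node: str = "Bacteria",
    backend: str = "numba",
) -> pd.DataFrame:
    """Mediator modulation combined with antibiotic treatment.

    The antibiotic is a KO clamp on the bacterial node starting at
    ``ab_time``.  The antibiotic-only condition is scored as its own row set
    (``node`` = ``"<antibiotic>"``).  Relative changes are computed against
    the fully unperturbed baseline; ``ab_baseline_pct`` and ``rel_vs_ab``
    additionally report each combination against the antibiotic-only
    profile.
    """
    nodes = list(screen_set) if screen_set is not None else list(model.screen_set)
    sc = _Screen(model, config, endpoints, cutoff, seed, backend)
    ab = PerturbationSpec(antibiotic_node, KO, start=ab_time)
    rows: list[dict] = []
    ab_rows = sc.score([ab], t_init,
                       extra={"node": "<antibiotic>", "mode": KO,
                              "ab_time": ab_time})
    ab_pct = {r["endpoint"]: r["perturbed_pct"] for r in ab_rows}
    for row in ab_rows:
        row["ab_baseline_pct"] = ab_pct[row["endpoint"]]
        row["rel_vs_ab"] = 0.0
        rows.append(row)
    for node in nodes:
        for mode in modes:
            specs = [ab, PerturbationSpec(node, mode, start=t_init)]
            for row in sc.score(specs, t_init,
                                extra={"node": node, "mode": mode,
                                       "ab_time": ab_time}):
                ep = row["endpoint"]
                row["ab_baseline_pct"] = ab_pct[ep]
                row["rel_vs_ab"] = relative_change(ab_pct[ep],
                                                   row["perturbed_pct"])
                rows.append(row)
    df = pd.DataFrame(rows)
    cols = ["condition_id", "node", "mode", "ab_time", "t_init", "endpoint",
            "baseline_pct", "ab_baseline_pct", "perturbed_pct",
            "relative_change", "rel_vs_ab", "PI", "category", "hit"]
    return df[cols]


def timing_sweep(
    model: BooleanModel,
    screen: str = "mono",
    t_inits: Sequence[int] = (0, 4, 8, 12, 20),
    **kwargs,
) -> pd.DataFrame:
    """Re-run a screen over a grid of perturbation initiation times.

    ``screen`` is ``"mono"``, ``"pair"`` or ``"antibiotic"``; for the
    antibiotic screen the grid varies the antibiotic start time instead.
    Results are concatenated with their ``t_init`` (or ``ab_time``) column.
    """
    frames = []
    for t0 in t_inits:
        if screen == "mono":
            frames.append(mono_screen(model, t_init=t0, **kwargs))
        elif screen == "pair":
            frames.append(pair_screen(model, t_init=t0, **kwargs))
        elif screen == "antibiotic":
            frames.append(antibiotic_screen(model, ab_time=t0, **kwargs))
        else:
            raise ValueError(f"unknown screen {screen!r}")
    return pd.concat(frames, ignore_index=True)
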