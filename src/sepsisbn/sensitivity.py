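"""Immune-cell polymorphism sensitivity sweep.

Each immune-cell node's activity fraction is swept from 0% (fully
unresponsive) to 100% (normal) in 10% increments; for every (cell, level)
the attractor profile is re-estimated and each endpoint scored by the
relative activation change against the unaltered network.  The level-100
condition normalises to the baseline condition (same seed) and therefore
reproduces it exactly.  Cell/endpoint pairs whose endpoint shifts by at
least the efficacy cut-off at full deactivation are reported as
considerable effects.
"""

from __future__ import annotations

import math
from typing import Sequence

import pandas as pd

from .engine import PolymorphismSpec, SimConfig
from .model import BooleanModel
from .screens import (DEFAULT_CUTOFF, _Screen, pi_category, pi_value,
                      relative_change)

__all__ = ["polymorphism_sweep", "identify_cell_effects", "DEFAULT_LEVELS"]

DEFAULT_LEVELS = tuple(range(0, 101, 10))


def polymorphism_sweep(
    model: BooleanModel,
    cell_nodes: Sequence[str] | None = None,
    levels: Sequence[int] = DEFAULT_LEVELS,
    endpoints: Sequence[str] | None = None,
    config: SimConfig | None = None,
    seed: int = 0,
    backend: str = "numba",
) -> pd.DataFrame:
    """Sweep cell-node activity levels; returns the heatmap-style long table.

    One row per (cell node, activity level %, endpoint) with the perturbed
    and baseline endpoint % activation and their relative change.
    """
    if cell_nodes is None:
        cell_nodes = model.nodes_of_class("host_cell")
    unknown = [n for n in cell_nodes if n not in model.node_index]
    if unknown:
        raise ValueError(f"unknown cell nodes {unknown}")
    sc = _Screen(model, config, endpoints, DEFAULT_CUTOFF, seed, backend)
    rows: list[dict] = []
    for node in cell_nodes:
        for level in levels:
            poly = [PolymorphismSpec(node, level / 100.0)]
            prof = sc.profile([], poly)
            for ep, _direction in sc.endpoints.items():
                b = float(sc.baseline.percent[ep])
                p = float(prof.percent[ep])
                rel = relative_change(b, p)
                rows.append({
                    "node": node,
                    "level": level,
                    "endpoint": ep,
                    "baseline_pct": b,
                    "perturbed_pct": p,
                    "relative_change": rel,
                    "category": pi_category(pi_value(b, p)),
                })
    return pd.DataFrame(rows)


def identify_cell_effects(sweep: pd.DataFrame,
                          cutoff: float = DEFAULT_CUTOFF) -> pd.DataFrame:
    """Cell/endpoint pairs with a considerable effect at full deactivation.

    A pair qualifies when |relative change| at the lowest swept activity
    level is >= *cutoff* (inclusive).  Returns a sorted table with the
    effect direction.
    """
    level0 = sweep[sweep["level"] == sweep["level"].min()]
    rows = []
    for r in level0.itertuples():
        rel = r.relative_change
        if math.isfinite(rel) and abs(rel) >= cutoff:
            rows.append({
                "node": r.node,
                "endpoint": r.endpoint,
                "relative_change": rel,
                "direction": "decrease" if rel < 0 else "increase",
            })
    out = pd.DataFrame(rows, columns=["node", "endpoint", "relative_change",
                                      "direction"])
    return out.sort_values(["node", "endpoint"]).reset_index(drop=True)
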