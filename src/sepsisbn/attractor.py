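"""Long-run % activation readout ("attractor" profiles).

The long-run behaviour of the stochastically updated network is summarised
per node as the percentage of time the node is active, averaged over a tail
window of each trajectory and over repetitions.  Under stochastic
asynchronous updating individual trajectories need not settle into a crisp
cycle, so the readout is a window time-average rather than an explicit
cycle detection; a stationarity check (first vs second half of the window)
doubles the simulated length until the estimate is stable or a cap is hit.
"""

from __future__ import annotations

import csv
import logging
import warnings
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .engine import (PerturbationSpec, PolymorphismSpec, SimConfig,
                     simulate_ensemble)
from .model import BooleanModel

__all__ = ["ActivationProfile", "estimate_attractor", "activation_timecourse"]

log = logging.getLogger(__name__)

#: stationarity tolerance (percentage points) and step cap
DEFAULT_TOL_PP = 2.0
DEFAULT_MAX_STEPS = 480


@dataclass
class ActivationProfile:
    """Per-node long-run % activation in [0, 100]."""

    percent: pd.Series          # index: node names
    window: tuple[int, int]     # [burn_in, steps] rows averaged
    reps: int
    steps: int
    stationary: bool

    def __getitem__(self, node: str) -> float:
        return float(self.percent[node])

    def to_csv(self, path, condition_id: str = "baseline") -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["node", "percent_activation", "condition_id"])
            for node, pct in self.percent.items():
                w.writerow([node, f"{pct:.6f}", condition_id])


def _half_window_drift(window: np.ndarray) -> float:
    """Largest statistically significant first-vs-second half mean shift.

    For each node the per-repetition difference between the first- and
    second-half window means is an iid sample across repetitions (a
    Geweke-style diagnostic), so drift is only counted when the mean
    difference exceeds four standard errors; smaller differences are
    Monte-Carlo noise and reported as zero.  Returns the largest
    significant per-node shift in percentage points.
    """
    half = window.shape[1] // 2
    if half == 0:
        return np.inf
    d = (window[:, :half, :].mean(axis=1)
         - window[:, half:2 * half, :].mean(axis=1)) * 100.0  # (reps, n)
    mean_d = np.abs(d.mean(axis=0))
    se = d.std(axis=0, ddof=1) / np.sqrt(d.shape[0]) if d.shape[0] > 1 else \
        np.full(d.shape[1], np.inf)
    significant = mean_d > 4.0 * se
    return float(np.max(np.where(significant, mean_d, 0.0)))


def estimate_attractor(
    model: BooleanModel,
    config: SimConfig | None = None,
    perturbations: Iterable[PerturbationSpec] = (),
    polymorphisms: Iterable[PolymorphismSpec] = (),
    seed: int | None = None,
    burn_in: int | None = None,
    tol: float = DEFAULT_TOL_PP,
    max_steps: int = DEFAULT_MAX_STEPS,
    backend: str = "numba",
) -> ActivationProfile:
    """Estimate the attractor % activation profile.

    Simulates ``config.reps`` trajectories, discards a burn-in (half the
    simulated steps unless given explicitly), and averages each node's state
    over the retained window across all repetitions.  If the per-node means
    of the two window halves differ by more than *tol* percentage points the
    simulation length is doubled (same seeds, repetitions extend
    deterministically) up to *max_steps*; if still unstable the profile is
    returned with ``stationary=False`` and a warning.
    """
    cfg = config or SimConfig()
    perts = list(perturbations)
    polys = list(polymorphisms)
    steps = cfg.steps
    while True:
        run_cfg = replace(cfg, steps=steps)
        ens = simulate_ensemble(model, run_cfg, perts, polys, seed=seed,
                                backend=backend)
        b = steps // 2 if burn_in is None else burn_in
        window = ens[:, b:, :]
        means = window.mean(axis=(0, 1)) * 100.0
        drift = _half_window_drift(window)
        if drift <= tol:
            stationary = True
            break
        if steps * 2 > max_steps:
            stationary = False
            warnings.warn(
                f"activation profile not stationary at {steps} steps "
                f"(max per-node drift {drift:.2f} pp > {tol} pp)",
                stacklevel=2)
            break
        log.debug("profile drift %.2f pp at %d steps; doubling", drift, steps)
        steps *= 2
    return ActivationProfile(
        percent=pd.Series(means, index=list(model.nodes)),
        window=(b, steps),
        reps=cfg.reps,
        steps=steps,
        stationary=stationary,
    )


def activation_timecourse(
    model: BooleanModel,
    config: SimConfig | None = None,
    perturbations: Iterable[PerturbationSpec] = (),
    polymorphisms: Iterable[PolymorphismSpec] = (),
    seed: int | None = None,
    backend: str = "numba",
) -> pd.DataFrame:
    """Mean % activation per step over repetitions (no burn-in).

    Returns a DataFrame indexed by step (0..steps) with one column per node,
    as used for the antibiotic-timing time-course figures.
    """
    cfg = config or SimConfig()
    ens = simulate_ensemble(model, cfg, list(perturbations),
                            list(polymorphisms), seed=seed, backend=backend)
    mean = ens.mean(axis=0) * 100.0
    df = pd.DataFrame(mean, columns=list(model.nodes))
    df.index.name = "step"
    return df
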