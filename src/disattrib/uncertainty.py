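"""Bootstrap confidence intervals for pipeline statistics.

Records are resampled iid with replacement, carrying their sampling
weights, and the full statistic (typically refit + attribution) is
recomputed per replicate.  The default interval is the normal type,
point estimate +/- 1.96 bootstrap standard deviations: unlike the
percentile interval it can extend below zero for statistics that are
constrained non-negative, which is how lower bounds below zero arise
for boundary-near parameters.  Default replicate count is 1000; tests
and scaled-down analyses use fewer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .standardize import Z95
from .survey_data import Cohort

__all__ = ["BootstrapResult", "bootstrap"]


@dataclass
class BootstrapResult:
    """Point estimates with bootstrap intervals, one row per output."""

    table: pd.DataFrame  # columns: point, lower, upper
    n_reps: int
    n_failed: int
    ci_method: str
    flagged: bool  # more than 10% of replicates failed

    def __getitem__(self, name: str) -> tuple[float, float, float]:
        row = self.table.loc[name]
        return float(row["point"]), float(row["lower"]), float(row["upper"])


def _as_mapping(value) -> dict[str, float]:
    if isinstance(value, Mapping):
        return {str(k): float(v) for k, v in value.items()}
    if np.isscalar(value):
        return {"value": float(value)}
    arr = np.asarray(value, dtype=float).ravel()
    return {f"value_{i}": float(v) for i, v in enumerate(arr)}


def bootstrap(
    cohort: Cohort,
    statistic: Callable[[Cohort], Mapping[str, float] | float],
    n_reps: int = 1000,
    seed: int = 0,
    ci_method: str = "normal",
) -> BootstrapResult:
    """Bootstrap CI for any statistic of a cohort.

    ``statistic`` maps a cohort to a scalar or a mapping of named
    scalars and must be deterministic given the cohort.  Replicates
    whose statistic raises are dropped and counted; the result is
    flagged when more than 10% fail.  Reproducible from ``seed``.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if ci_method not in ("normal", "percentile"):
        raise ValueError(f"unknown ci_method {ci_method!r}")

    point = _as_mapping(statistic(cohort))
    names = list(point)
    rng = np.random.default_rng(seed)
    reps: list[np.ndarray] = []
    n_failed = 0
    for _ in range(n_reps):
        resampled = cohort.resample(rng)
        try:
            rep = _as_mapping(statistic(resampled))
        except Exception:
            n_failed += 1
            continue
        reps.append(np.array([rep[k] for k in names]))

    if not reps:
        raise RuntimeError("all bootstrap replicates failed")
    mat = np.vstack(reps)
    pt = np.array([point[k] for k in names])
    if ci_method == "normal":
        sd = mat.std(axis=0, ddof=1)
        lower, upper = pt - Z95 * sd, pt + Z95 * sd
    else:
        lower = np.percentile(mat, 2.5, axis=0)
        upper = np.percentile(mat, 97.5, axis=0)

    table = pd.DataFrame({"point": pt, "lower": lower, "upper": upper}, index=names)
    table.index.name = "statistic"
    return BootstrapResult(
        table=table,
        n_reps=n_reps,
        n_failed=n_failed,
        ci_method=ci_method,
        flagged=n_failed > 0.1 * n_reps,
    )
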