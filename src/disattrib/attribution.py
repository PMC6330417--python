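"""Additive partition of disability prevalence into disease contributions.

Under the additive hazard model each respondent's disability
probability ``pi = 1 - exp(-eta)`` is split over the competing causes
in proportion to their share of the cumulative rate ``eta``:

    share_d   = pi * beta_d X_d / eta
    background = pi * alpha / eta

so the shares sum to ``pi`` exactly (all zero when ``eta = 0``).
Population-level contributions are survey-weighted means of these
individual shares; the quantity partitioned is therefore the
model-predicted prevalence (the weighted mean of ``pi``), and the
partition is additive by construction.  The gap between predicted and
observed prevalence is exposed as a fit diagnostic, not folded back
into the contributions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .additive_hazard import ModelParams, eta_arrays, linear_predictor
from .survey_data import Cohort, SurveyRecord

__all__ = ["AttributionResult", "individual_shares", "population_attribution"]

ADDITIVITY_TOL = 1e-10


@dataclass
class AttributionResult:
    """Disability prevalence split into cause contributions for one scope.

    All quantities share one scale (proportions by default; rendered
    tables use percent).  ``background + sum(contributions) ==
    prevalence`` to ``atol`` (loosen ``atol`` when building a result
    from externally rounded figures).
    """

    scope: dict = field(default_factory=dict)
    prevalence: float = 0.0
    contributions: dict[str, float] = field(default_factory=dict)
    background: float = 0.0
    n_effective: float = 0.0
    observed_prevalence: float | None = None
    note: str = ""
    atol: float = ADDITIVITY_TOL

    def __post_init__(self) -> None:
        if self.background < -self.atol:
            raise ValueError("background contribution must be non-negative")
        for name, v in self.contributions.items():
            if v < -self.atol:
                raise ValueError(f"contribution of {name} must be non-negative")
        if abs(self.total_causes - self.prevalence) > self.atol:
            raise ValueError(
                f"additivity violated: causes sum to {self.total_causes}, "
                f"prevalence is {self.prevalence}"
            )

    @property
    def total_causes(self) -> float:
        return self.background + float(sum(self.contributions.values()))

    @property
    def causes(self) -> tuple[str, ...]:
        return tuple(self.contributions)

    def as_series(self) -> pd.Series:
        data = dict(self.contributions)
        data["background"] = self.background
        data["prevalence"] = self.prevalence
        return pd.Series(data)

    def scaled(self, factor: float) -> "AttributionResult":
        return AttributionResult(
            scope=dict(self.scope),
            prevalence=self.prevalence * factor,
            contributions={k: v * factor for k, v in self.contributions.items()},
            background=self.background * factor,
            n_effective=self.n_effective,
            observed_prevalence=(
                None
                if self.observed_prevalence is None
                else self.observed_prevalence * factor
            ),
            note=self.note,
            atol=max(self.atol, self.atol * abs(factor)),
        )


def shares_arrays(
    params: ModelParams, arrs: dict[str, np.ndarray]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized (pi, background share, per-disease shares) for a cohort.

    Returns arrays of shape (n,), (n,), (n, m); rows with eta == 0
    have all shares zero.
    """
    eta = eta_arrays(params, arrs)
    pi = -np.expm1(-eta)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(eta > 0, pi / np.where(eta > 0, eta, 1.0), 0.0)
    bg = ratio * params.alpha[arrs["a"], arrs["e"]]
    beta_x = params.gamma[arrs["c"]][:, None] * params.delta[:, arrs["e"]].T * arrs["X"]
    dis = ratio[:, None] * beta_x
    return pi, bg, dis


def individual_shares(
    params: ModelParams, record: SurveyRecord
) -> tuple[float, dict[str, float]]:
    """Background and per-disease shares of one respondent's pi.

    Shares sum to pi exactly; an individual with eta = 0 contributes
    nothing to any cause.
    """
    eta = linear_predictor(params, record)
    if eta == 0.0:
        return 0.0, {d: 0.0 for d in params.design.diseases}
    pi = -np.expm1(-eta)
    from .survey_data import assign_band

    g = params.design.grouping
    a = assign_band(record.age_years, g.background_bands)
    c = assign_band(record.age_years, g.rank_bands)
    e = params.design.education_index(record.education)
    bg = pi * params.alpha[a, e] / eta
    shares = {
        d: pi * params.gamma[c] * params.delta[i, e] * record.diseases[i] / eta
        for i, d in enumerate(params.design.diseases)
    }
    return float(bg), shares


def population_attribution(
    params: ModelParams,
    cohort: Cohort,
    sex: str | None = None,
    education: str | None = None,
    age_band: tuple[float, float] | None = None,
) -> AttributionResult:
    """Survey-weighted attribution over a scope of the cohort.

    Prevalence is the weighted mean of the model-predicted pi; each
    cause's contribution is the weighted mean of its individual shares.
    Raises on an empty scope.
    """
    scope: dict = {}
    if sex is not None or education is not None:
        cohort = cohort.filter(sex=sex, education=education)
        scope = {k: v for k, v in (("sex", sex), ("education", education)) if v}
    if age_band is not None:
        ages = cohort.frame["age"].to_numpy()
        cohort = cohort.subset((ages >= age_band[0]) & (ages < age_band[1]))
        scope["age_band"] = age_band

    arrs = cohort.arrays()
    w = arrs["w"]
    pi, bg, dis = shares_arrays(params, arrs)
    wsum = w.sum()
    prevalence = float(w @ pi / wsum)
    background = float(w @ bg / wsum)
    contribs = dict(zip(params.design.diseases, (w @ dis) / wsum))
    result = AttributionResult(
        scope=scope,
        prevalence=prevalence,
        contributions={k: float(v) for k, v in contribs.items()},
        background=background,
        n_effective=float(wsum),
        observed_prevalence=float(w @ arrs["Y"] / wsum),
    )
    return result
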