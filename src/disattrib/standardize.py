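"""Direct age standardization, weighted prevalence and crude odds ratios.

Standardization is a fixed-weight average over age bands, so it is
linear: standardizing each cause's band-specific contribution and the
band-specific prevalence with the same weights preserves the additive
partition exactly.  Confidence intervals for weighted proportions use a
normal approximation with the Kish effective sample size
``n_eff = (sum w)^2 / sum w^2``.
"""

from __future__ import annotations

import math

import numpy as np

from .additive_hazard import ModelParams
from .attribution import AttributionResult, population_attribution
from .survey_data import Cohort, StandardPopulation, band_label

__all__ = [
    "weighted_prevalence",
    "age_standardize",
    "odds_ratio",
    "standardized_attribution",
    "kish_effective_n",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


def kish_effective_n(weights: np.ndarray) -> float:
    w = np.asarray(weights, dtype=float)
    return float(w.sum() ** 2 / (w**2).sum())


def weighted_prevalence(
    cohort: Cohort,
    sex: str | None = None,
    education: str | None = None,
    outcome: str = "disability",
) -> tuple[float, tuple[float, float]]:
    """Survey-weighted proportion with a 95% normal-approximation CI.

    Variance uses the Kish effective sample size; the interval is
    clipped to [0, 1].
    """
    if sex is not None or education is not None:
        cohort = cohort.filter(sex=sex, education=education)
    y = cohort.frame[outcome].to_numpy(dtype=float)
    w = cohort.frame["weight"].to_numpy(dtype=float)
    p = float(w @ y / w.sum())
    n_eff = kish_effective_n(w)
    se = math.sqrt(max(p * (1.0 - p), 0.0) / n_eff)
    lo, hi = max(0.0, p - Z95 * se), min(1.0, p + Z95 * se)
    return p, (lo, hi)


def age_standardize(
    stratum_values, std_pop: StandardPopulation, sex: str
) -> float:
    """Directly standardized value: sum_a value_a * w_a over normalized w.

    ``stratum_values`` is an array over the background bands or a
    mapping from band label to value.  A missing (NaN) value in a band
    with positive standard-population weight is an error; bands with
    zero weight may be missing.
    """
    w = std_pop.band_weights(sex)
    g = std_pop.grouping
    if isinstance(stratum_values, dict):
        vals = np.array(
            [
                stratum_values.get(band_label(b), np.nan)
                for b in g.background_bands
            ],
            dtype=float,
        )
    else:
        vals = np.asarray(stratum_values, dtype=float)
        if vals.shape != (g.n_background,):
            raise ValueError(
                f"expected {g.n_background} band values, got {vals.shape}"
            )
    bad = np.isnan(vals) & (w > 0)
    if bad.any():
        labels = [band_label(b) for b, m in zip(g.background_bands, bad) if m]
        raise ValueError(f"missing values for weighted bands: {', '.join(labels)}")
    vals = np.where(w > 0, vals, 0.0)
    return float(vals @ w)


def odds_ratio(
    cohort: Cohort,
    exposure: tuple[str, str] = ("low", "high"),
    sex: str | None = None,
    outcome: str = "disability",
) -> tuple[float, tuple[float, float]]:
    """Crude weighted odds ratio of the outcome between education levels.

    ``exposure = (exposed, reference)``.  The Woolf-type 95% CI on the
    log scale uses Kish-effective cell counts; a zero cell raises (no
    continuity correction).
    """
    exposed, reference = exposure
    if exposed == reference:
        raise ValueError("exposure levels must differ")
    if sex is not None:
        cohort = cohort.filter(sex=sex)
    frame = cohort.frame
    frame = frame[frame["education"].isin([exposed, reference])]
    if len(frame) == 0:
        raise ValueError("empty scope")
    w = frame["weight"].to_numpy(dtype=float)
    y = frame[outcome].to_numpy(dtype=float)
    exp_mask = (frame["education"] == exposed).to_numpy()

    cells = np.array(
        [
            w[exp_mask & (y == 1)].sum(),
            w[exp_mask & (y == 0)].sum(),
            w[~exp_mask & (y == 1)].sum(),
            w[~exp_mask & (y == 0)].sum(),
        ]
    )
    if np.any(cells <= 0):
        raise ValueError("zero weighted cell in 2x2 table")
    a, b, c, d = cells
    or_hat = (a * d) / (b * c)
    # scale weighted cells to the Kish effective sample size for the SE
    k = kish_effective_n(w) / w.sum()
    se = math.sqrt(np.sum(1.0 / (k * cells)))
    log_or = math.log(or_hat)
    return or_hat, (math.exp(log_or - Z95 * se), math.exp(log_or + Z95 * se))


def standardized_attribution(
    params: ModelParams,
    cohort: Cohort,
    std_pop: StandardPopulation,
    sex: str,
    education: str | None = None,
) -> AttributionResult:
    """Age-standardized attribution: band-wise partition averaged with
    standard-population weights.

    Linearity of the standardization keeps the result additive.  A band
    with positive standard weight but no respondents in scope raises.
    """
    scoped = cohort.filter(sex=sex, education=education)
    w = std_pop.band_weights(sex)
    g = std_pop.grouping
    diseases = params.design.diseases

    prevalence = 0.0
    background = 0.0
    observed = 0.0
    contribs = {d: 0.0 for d in diseases}
    n_effective = 0.0
    for band, wt in zip(g.background_bands, w):
        if wt == 0:
            continue
        try:
            res = population_attribution(params, scoped, age_band=band)
        except ValueError:
            raise ValueError(
                f"no respondents in band {band_label(band)} (standard weight {wt:g})"
            ) from None
        prevalence += wt * res.prevalence
        background += wt * res.background
        observed += wt * res.observed_prevalence
        for d in diseases:
            contribs[d] += wt * res.contributions[d]
        n_effective += res.n_effective

    scope = {"sex": sex, "standardized": True}
    if education is not None:
        scope["education"] = education
    return AttributionResult(
        scope=scope,
        prevalence=prevalence,
        contributions=contribs,
        background=background,
        n_effective=n_effective,
        observed_prevalence=observed,
        atol=1e-9,
    )
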