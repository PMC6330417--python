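"""Binomial additive hazard model with rank-one disease impacts.

The probability that respondent *i* reports disability is

    pi_i = 1 - exp(-eta_i),      eta_i = alpha_{a,e} + sum_d beta_{c,d,e} X_{d,i}

where ``alpha`` is the background cumulative disability rate per
background age band *a* and education *e*, and the age- and
education-specific disease impacts are factored with rank one,
``beta_{c,d,e} = gamma_c * delta_{d,e}``: one age pattern ``gamma``
shared by all diseases (fixed to 1 in the youngest rank band for
identifiability) times a disease-by-education effect ``delta``.  All
parameters are non-negative, so hazards -- and hence cause
contributions -- cannot be negative.

Fitting maximizes the survey-weighted Bernoulli likelihood by
block-alternating bounded quasi-Newton steps: with ``gamma`` fixed the
problem is an additive hazard in ``(alpha, delta)`` under box
constraints at zero; with ``(alpha, delta)`` fixed, ``gamma`` solves a
small constrained problem.  Multi-start with jittered initializations
guards against local optima of the bilinear parameterization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .survey_data import (
    DEFAULT_DESIGN,
    Cohort,
    StandardPopulation,
    StudyDesign,
    SurveyRecord,
    assign_band,
    band_label,
)

__all__ = [
    "ModelParams",
    "FitResult",
    "linear_predictor",
    "disability_prob",
    "neg_log_likelihood",
    "fit",
    "disabling_impact",
]

PI_FLOOR = 1e-12  # floor on pi for disabled records with eta == 0
ZERO_TOL = 1e-6  # parameters below this are flagged as boundary


@dataclass
class ModelParams:
    """Non-negative parameters of the additive hazard model.

    alpha : (n_background_bands, n_education) background cumulative rates
    gamma : (n_rank_bands,) shared age pattern, ``gamma[0] == 1``
    delta : (n_diseases, n_education) disease effects at reference age
    """

    alpha: np.ndarray
    gamma: np.ndarray
    delta: np.ndarray
    design: StudyDesign = field(default_factory=lambda: DEFAULT_DESIGN)

    def __post_init__(self) -> None:
        d = self.design
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.delta = np.asarray(self.delta, dtype=float)
        expect = {
            "alpha": (d.grouping.n_background, d.n_education),
            "gamma": (d.grouping.n_rank,),
            "delta": (d.n_diseases, d.n_education),
        }
        for name, shape in expect.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name}: expected shape {shape}, got {arr.shape}")
            if np.any(arr < 0):
                raise ValueError(f"{name}: negative entries not allowed")
        if not np.isclose(self.gamma[0], 1.0, atol=1e-12):
            raise ValueError("gamma[0] must be fixed at 1 (reference rank band)")

    def beta(self) -> np.ndarray:
        """Implied impacts beta[c, d, e] = gamma[c] * delta[d, e]."""
        return self.gamma[:, None, None] * self.delta[None, :, :]

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.alpha.copy(), self.gamma.copy(), self.delta.copy(), self.design
        )

    def to_dict(self) -> dict:
        g = self.design.grouping
        return {
            "alpha": {
                band_label(b): {
                    e: float(self.alpha[a, j])
                    for j, e in enumerate(self.design.education_levels)
                }
                for a, b in enumerate(g.background_bands)
            },
            "gamma": {
                band_label(b): float(self.gamma[c]) for c, b in enumerate(g.rank_bands)
            },
            "delta": {
                d: {
                    e: float(self.delta[i, j])
                    for j, e in enumerate(self.design.education_levels)
                }
                for i, d in enumerate(self.design.diseases)
            },
        }

    @classmethod
    def from_dict(cls, payload: dict, design: StudyDesign = DEFAULT_DESIGN) -> "ModelParams":
        g = design.grouping
        alpha = np.array(
            [
                [payload["alpha"][band_label(b)][e] for e in design.education_levels]
                for b in g.background_bands
            ]
        )
        gamma = np.array([payload["gamma"][band_label(b)] for b in g.rank_bands])
        delta = np.array(
            [
                [payload["delta"][d][e] for e in design.education_levels]
                for d in design.diseases
            ]
        )
        return cls(alpha, gamma, delta, design)


@dataclass
class FitResult:
    params: ModelParams
    loglik: float
    converged: bool
    n_iter: int
    boundary_flags: frozenset[str]
    n_obs: int
    sum_weights: float
    n_starts: int = 1


# ---------------------------------------------------------------------------
# linear predictor / likelihood


def eta_arrays(params: ModelParams, arrs: dict[str, np.ndarray]) -> np.ndarray:
    """Vectorized linear predictor for a cohort's design arrays."""
    s = np.einsum("nd,nd->n", arrs["X"], params.delta[:, arrs["e"]].T)
    return params.alpha[arrs["a"], arrs["e"]] + params.gamma[arrs["c"]] * s


def linear_predictor(params: ModelParams, record: SurveyRecord) -> float:
    """Cumulative disability rate eta for a single respondent."""
    g = params.design.grouping
    a = assign_band(record.age_years, g.background_bands)
    c = assign_band(record.age_years, g.rank_bands)
    e = params.design.education_index(record.education)
    x = np.asarray(record.diseases, dtype=float)
    return float(params.alpha[a, e] + params.gamma[c] * (params.delta[:, e] @ x))


def disability_prob(eta) -> np.ndarray | float:
    """pi = 1 - exp(-eta), computed stably; eta must be non-negative."""
    eta = np.asarray(eta, dtype=float)
    if np.any(eta < 0):
        raise ValueError("eta must be non-negative")
    pi = -np.expm1(-eta)
    return float(pi) if pi.ndim == 0 else pi


def neg_log_likelihood(
    params: ModelParams, cohort: Cohort, use_weights: bool = True
) -> float:
    """Weighted Bernoulli negative log-likelihood of the cohort."""
    arrs = cohort.arrays()
    w = arrs["w"] if use_weights else np.ones_like(arrs["w"])
    return _nll(eta_arrays(params, arrs), arrs["Y"], w)


def _nll(eta: np.ndarray, Y: np.ndarray, w: np.ndarray) -> float:
    # log(1 - pi) = -eta exactly; pi floored at PI_FLOOR for Y=1, eta=0
    pi = np.clip(-np.expm1(-eta), PI_FLOOR, 1 - PI_FLOOR)
    return float(-np.sum(w * (Y * np.log(pi) - (1.0 - Y) * eta)))


def _nll_grad_eta(eta: np.ndarray, Y: np.ndarray, w: np.ndarray) -> np.ndarray:
    pi = np.clip(-np.expm1(-eta), PI_FLOOR, 1 - PI_FLOOR)
    return w * ((1.0 - Y) - Y * np.exp(-eta) / pi)


# ---------------------------------------------------------------------------
# fitting


def _init_params(arrs: dict, design: StudyDesign, w: np.ndarray) -> ModelParams:
    """Deterministic near-feasible starting point.

    alpha from disability rates among the disease-free in each
    band-by-education cell; delta from crude marginal attributable
    rates within education; gamma flat at 1.
    """
    g = design.grouping
    a, e, X, Y = arrs["a"], arrs["e"], arrs["X"], arrs["Y"]
    disease_free = X.sum(axis=1) == 0

    overall = np.average(Y, weights=w)
    alpha = np.empty((g.n_background, design.n_education))
    for ai in range(g.n_background):
        for ei in range(design.n_education):
            m = (a == ai) & (e == ei) & disease_free
            rate = np.average(Y[m], weights=w[m]) if m.sum() >= 5 else overall
            alpha[ai, ei] = -np.log1p(-np.clip(rate, 1e-4, 0.95))

    delta = np.zeros((design.n_diseases, design.n_education))
    for ei in range(design.n_education):
        me = e == ei
        for di in range(design.n_diseases):
            with_d = me & (X[:, di] == 1)
            without = me & (X[:, di] == 0)
            if with_d.sum() < 5 or without.sum() < 5:
                delta[di, ei] = 0.05
                continue
            r1 = np.clip(np.average(Y[with_d], weights=w[with_d]), 1e-4, 0.95)
            r0 = np.clip(np.average(Y[without], weights=w[without]), 1e-4, 0.95)
            delta[di, ei] = max(0.01, np.log1p(-r0) - np.log1p(-r1))

    gamma = np.ones(g.n_rank)
    return ModelParams(alpha, gamma, delta, design)


def _optimize_alpha_delta(
    params: ModelParams,
    arrs: dict,
    w: np.ndarray,
    pinned: np.ndarray,
    tol: float,
) -> ModelParams:
    """Bounded quasi-Newton step in (alpha, delta) with gamma fixed."""
    design = params.design
    n_a = params.alpha.size
    a_idx, c_idx, e_idx, X, Y = arrs["a"], arrs["c"], arrs["e"], arrs["X"], arrs["Y"]
    n_edu = design.n_education
    flat_ae = a_idx * n_edu + e_idx
    gX = params.gamma[c_idx][:, None] * X  # (n, m): d eta / d delta[:, e_i]
    e_masks = [e_idx == ei for ei in range(n_edu)]

    def unpack(theta):
        alpha = theta[:n_a].reshape(params.alpha.shape)
        delta = theta[n_a:].reshape(params.delta.shape)
        return alpha, delta

    def fun(theta):
        alpha, delta = unpack(theta)
        eta = alpha.ravel()[flat_ae] + np.einsum("nd,nd->n", gX, delta[:, e_idx].T)
        f = _nll(eta, Y, w)
        g_eta = _nll_grad_eta(eta, Y, w)
        g_alpha = np.bincount(flat_ae, weights=g_eta, minlength=n_a)
        g_delta = np.empty_like(delta)
        for ei, m in enumerate(e_masks):
            g_delta[:, ei] = gX[m].T @ g_eta[m]
        return f, np.concatenate([g_alpha, g_delta.ravel()])

    bounds = [(0.0, None)] * n_a + [
        (0.0, 0.0) if pin else (0.0, None) for pin in pinned.ravel()
    ]
    theta0 = np.concatenate([params.alpha.ravel(), params.delta.ravel()])
    res = minimize(
        fun, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 500, "ftol": tol * 1e-2, "gtol": 1e-9},
    )
    alpha, delta = unpack(res.x)
    return replace(params, alpha=alpha, delta=delta)


def _optimize_joint(
    params: ModelParams,
    arrs: dict,
    w: np.ndarray,
    pinned: np.ndarray,
    tol: float,
) -> ModelParams:
    """Joint bounded quasi-Newton polish over (alpha, delta, gamma[1:]).

    Run after the block sweeps are near the optimum; the bilinear
    coupling is then mild and a single box-constrained step removes the
    slow zigzag of pure alternation.
    """
    design = params.design
    n_a = params.alpha.size
    n_d = params.delta.size
    n_rank = params.gamma.size
    a_idx, c_idx, e_idx, X, Y = arrs["a"], arrs["c"], arrs["e"], arrs["X"], arrs["Y"]
    n_edu = design.n_education
    flat_ae = a_idx * n_edu + e_idx
    e_masks = [e_idx == ei for ei in range(n_edu)]

    def unpack(theta):
        alpha = theta[:n_a].reshape(params.alpha.shape)
        delta = theta[n_a : n_a + n_d].reshape(params.delta.shape)
        gamma = np.concatenate([[1.0], theta[n_a + n_d :]])
        return alpha, delta, gamma

    def fun(theta):
        alpha, delta, gamma = unpack(theta)
        s = np.einsum("nd,nd->n", X, delta[:, e_idx].T)
        gc = gamma[c_idx]
        eta = alpha.ravel()[flat_ae] + gc * s
        f = _nll(eta, Y, w)
        g_eta = _nll_grad_eta(eta, Y, w)
        g_alpha = np.bincount(flat_ae, weights=g_eta, minlength=n_a)
        t = g_eta * gc
        g_delta = np.empty_like(delta)
        for ei, m in enumerate(e_masks):
            g_delta[:, ei] = X[m].T @ t[m]
        g_gamma = np.bincount(c_idx, weights=g_eta * s, minlength=n_rank)[1:]
        return f, np.concatenate([g_alpha, g_delta.ravel(), g_gamma])

    bounds = (
        [(0.0, None)] * n_a
        + [(0.0, 0.0) if pin else (0.0, None) for pin in pinned.ravel()]
        + [(0.0, None)] * (n_rank - 1)
    )
    theta0 = np.concatenate(
        [params.alpha.ravel(), params.delta.ravel(), params.gamma[1:]]
    )
    res = minimize(
        fun, theta0, jac=True, method="L-BFGS-B", bounds=bounds,
        options={"maxiter": 1000, "ftol": tol * 1e-2, "gtol": 1e-10},
    )
    alpha, delta, gamma = unpack(res.x)
    return replace(params, alpha=alpha, delta=delta, gamma=gamma)


def _optimize_gamma(
    params: ModelParams, arrs: dict, w: np.ndarray, tol: float
) -> ModelParams:
    """Bounded quasi-Newton step in gamma[1:] with (alpha, delta) fixed."""
    if params.gamma.size == 1:
        return params
    a_idx, c_idx, e_idx, X, Y = arrs["a"], arrs["c"], arrs["e"], arrs["X"], arrs["Y"]
    s = np.einsum("nd,nd->n", X, params.delta[:, e_idx].T)
    base = params.alpha[a_idx, e_idx]
    n_rank = params.gamma.size

    def fun(g_free):
        gamma = np.concatenate([[1.0], g_free])
        eta = base + gamma[c_idx] * s
        f = _nll(eta, Y, w)
        g_eta = _nll_grad_eta(eta, Y, w)
        grad = np.bincount(c_idx, weights=g_eta * s, minlength=n_rank)[1:]
        return f, grad

    res = minimize(
        fun, params.gamma[1:], jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * (n_rank - 1),
        options={"maxiter": 200, "ftol": tol * 1e-2, "gtol": 1e-9},
    )
    return replace(params, gamma=np.concatenate([[1.0], res.x]))


def fit(
    cohort: Cohort,
    sex: str | None = None,
    *,
    tol: float = 1e-9,
    max_iter: int = 100,
    n_starts: int = 2,
    seed: int = 0,
    use_weights: bool = True,
    init_params: ModelParams | None = None,
) -> FitResult:
    """Weighted maximum-likelihood fit for one sex.

    Alternates bounded quasi-Newton blocks over (alpha, delta) and gamma
    until the relative log-likelihood change falls below ``tol``.  The
    best of ``n_starts`` jittered initializations is kept (start 0 is
    the deterministic moment-style initialization, or ``init_params``
    when supplied, e.g. to warm-start bootstrap replicate fits).
    Non-convergence is flagged on the result, never raised.  Diseases
    absent from an education stratum have delta pinned at zero.
    """
    if sex is not None:
        cohort = cohort.filter(sex=sex)
    design = cohort.design
    arrs = cohort.arrays()
    n = len(cohort)
    if use_weights:
        w = arrs["w"] / arrs["w"].mean()  # pseudo-likelihood, mean-1 weights
    else:
        w = np.ones(n)

    # diseases never observed within an education stratum: delta pinned at 0
    pinned = np.zeros((design.n_diseases, design.n_education), dtype=bool)
    for ei in range(design.n_education):
        m = arrs["e"] == ei
        pinned[:, ei] = arrs["X"][m].sum(axis=0) == 0

    base = init_params.copy() if init_params is not None else _init_params(arrs, design, w)
    base.delta[pinned] = 0.0
    rng = np.random.default_rng(seed)

    best: tuple[float, ModelParams, bool, int] | None = None
    for start in range(max(1, n_starts)):
        params = base.copy()
        if start > 0:
            params.alpha *= np.exp(rng.uniform(-0.5, 0.5, params.alpha.shape))
            params.delta *= np.exp(rng.uniform(-0.5, 0.5, params.delta.shape))
            params.gamma[1:] = np.exp(rng.uniform(-0.3, 0.7, params.gamma.size - 1))
            params.delta[pinned] = 0.0

        nll = _nll(eta_arrays(params, arrs), arrs["Y"], w)
        # block sweeps handle the bilinear coupling; a warm start is
        # already near the optimum, so the joint polish alone suffices
        block_tol = max(tol, 1e-6)
        sweeps = 0 if init_params is not None else max_iter
        it = 0
        for it in range(1, sweeps + 1):
            params = _optimize_alpha_delta(params, arrs, w, pinned, block_tol)
            nll_a = _nll(eta_arrays(params, arrs), arrs["Y"], w)
            params = _optimize_gamma(params, arrs, w, block_tol)
            nll_g = _nll(eta_arrays(params, arrs), arrs["Y"], w)
            # monotone ascent: each block may only improve the likelihood
            slack = 1e-8 * (1.0 + abs(nll))
            if nll_a > nll + slack or nll_g > nll_a + slack:
                raise RuntimeError(
                    f"likelihood decreased across a block ({nll} -> {nll_a} -> {nll_g})"
                )
            done = abs(nll - nll_g) <= block_tol * (1.0 + abs(nll))
            nll = nll_g
            if done:
                break
        # joint bounded polish from the block solution
        params = _optimize_joint(params, arrs, w, pinned, tol)
        nll_j = _nll(eta_arrays(params, arrs), arrs["Y"], w)
        if nll_j > nll + 1e-8 * (1.0 + abs(nll)):
            raise RuntimeError(
                f"likelihood decreased in joint polish ({nll} -> {nll_j})"
            )
        converged = it < max_iter or abs(nll - nll_j) <= tol * (1.0 + abs(nll))
        nll = nll_j
        if best is None or nll < best[0] - 1e-12:
            best = (nll, params, converged, it)

    nll, params, converged, it = best
    flags = _boundary_flags(params)
    return FitResult(
        params=params,
        loglik=-nll,
        converged=converged,
        n_iter=it,
        boundary_flags=flags,
        n_obs=n,
        sum_weights=float(arrs["w"].sum()),
        n_starts=max(1, n_starts),
    )


def _boundary_flags(params: ModelParams) -> frozenset[str]:
    flags = set()
    g = params.design.grouping
    for a, b in enumerate(g.background_bands):
        for j, e in enumerate(params.design.education_levels):
            if params.alpha[a, j] < ZERO_TOL:
                flags.add(f"alpha[{band_label(b)},{e}]")
    for c, b in enumerate(g.rank_bands):
        if c > 0 and params.gamma[c] < ZERO_TOL:
            flags.add(f"gamma[{band_label(b)}]")
    for i, d in enumerate(params.design.diseases):
        for j, e in enumerate(params.design.education_levels):
            if params.delta[i, j] < ZERO_TOL:
                flags.add(f"delta[{d},{e}]")
    return frozenset(flags)


def disabling_impact(
    params: ModelParams, std_pop: StandardPopulation, sex: str
) -> pd.DataFrame:
    """Age-standardized disabling impact per disease and education.

    The impact of disease *d* in education *e* at rank band *c* is
    ``beta = gamma_c * delta_{d,e}``; the reported figure averages beta
    over the standard population's age structure, i.e.
    ``(sum_c w_c gamma_c) * delta_{d,e}``.
    """
    w = std_pop.rank_band_weights(sex)
    gbar = float(w @ params.gamma)
    table = pd.DataFrame(
        gbar * params.delta,
        index=list(params.design.diseases),
        columns=list(params.design.education_levels),
    )
    table.index.name = "disease"
    return table
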