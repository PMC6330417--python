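"""End-to-end orchestration: fit per sex, attribute, run counterfactuals.

The full analysis mirrors the survey workflow: the additive hazard
model is fitted separately for men and women; age-standardized
disabling impacts (one table: prevalence-style columns per education)
and per-education attributions are computed; the two counterfactual
scenarios are run for a donor/recipient education pair; and the
educational gap is decomposed.  Optional bootstrap replication wraps
the whole fit-plus-attribution statistic.

All randomness (multi-start jitter, bootstrap, any Monte-Carlo
fallback) flows from one top-level seed through named substreams, so a
re-run with the same configuration is byte-identical.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import additive_hazard as ah
from .attribution import AttributionResult
from .counterfactual import (
    CounterfactualScenario,
    GapDecomposition,
    baseline_attribution,
    decompose_gap,
    run_scenario,
)
from .survey_data import Cohort, StandardPopulation, read_cohort, read_standard_population
from .synthetic_cohort import default_standard_population, default_truth, generate_cohort
from .uncertainty import BootstrapResult, bootstrap

__all__ = ["PipelineError", "AnalysisReport", "run_full_analysis", "render_table2", "substream_seed"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def substream_seed(seed: int, name: str) -> int:
    """Deterministic named substream seed below 2**31."""
    ss = np.random.SeedSequence([seed, abs(hash_name(name))])
    return int(ss.generate_state(1)[0] % 2**31)


def hash_name(name: str) -> int:
    # stable across processes (builtin hash of str is salted)
    h = 0
    for ch in name:
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


@dataclass
class SexReport:
    fit: ah.FitResult
    impacts: pd.DataFrame
    attributions: dict[str, AttributionResult]
    scenarios: dict[str, AttributionResult]
    gap: GapDecomposition
    table2: pd.DataFrame
    bootstrap: BootstrapResult | None = None


@dataclass
class AnalysisReport:
    per_sex: dict[str, SexReport]
    log: list[str] = field(default_factory=list)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for sex, rep in self.per_sex.items():
            rep.impacts.to_csv(out / f"impacts_{sex}.csv")
            rep.table2.to_csv(out / f"table2_{sex}.csv", float_format="%.1f")
            rep.gap.per_cause.to_csv(out / f"decomposition_{sex}.csv")
            with open(out / f"params_{sex}.json", "w") as fh:
                json.dump(rep.fit.params.to_dict(), fh, indent=2)
            if rep.bootstrap is not None:
                rep.bootstrap.table.to_csv(out / f"bootstrap_{sex}.csv")
        (out / "run.log").write_text("\n".join(self.log) + "\n")


def _log(log: list[str], msg: str) -> None:
    log.append(f"{time.strftime('%Y-%m-%d %H:%M:%S')} {msg}")


def _stage(log: list[str], name: str):
    class _Ctx:
        def __enter__(self):
            _log(log, f"stage {name}: start")

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                _log(log, f"stage {name}: FAILED: {exc}")
                raise PipelineError(f"stage {name}: {exc}") from exc
            _log(log, f"stage {name}: done")

    return _Ctx()


def run_full_analysis(config: dict) -> AnalysisReport:
    """Run the complete analysis described by a configuration mapping.

    Keys (all optional unless noted):

    - ``cohort``: path to a cohort CSV; if absent, a synthetic cohort is
      generated from the ground-truth fixture with ``n`` and ``seed``.
    - ``std_pop``: path to a standard-population CSV; default fixture
      population otherwise.
    - ``seed`` (int): top-level seed for all substreams.
    - ``sexes``: subset of ("male", "female"), default both.
    - ``donor`` / ``recipient``: education pair for the counterfactuals,
      default high -> low.
    - ``bootstrap_reps`` (int): 0 disables bootstrap CIs.
    - ``fit``: optional dict of fit options (tol, max_iter, n_starts).
    - ``out_dir``: if given, tidy tables and the run log are written.
    """
    log: list[str] = []
    seed = int(config.get("seed", 0))
    _log(log, f"run_full_analysis seed={seed} numpy={np.__version__}")

    with _stage(log, "load"):
        if "cohort" in config and config["cohort"]:
            cohort = read_cohort(config["cohort"])
        else:
            truth = default_truth(
                n=int(config.get("n", 23_348)),
                seed=substream_seed(seed, "synth"),
            )
            cohort = generate_cohort(truth)
        std_pop = (
            read_standard_population(config["std_pop"])
            if config.get("std_pop")
            else default_standard_population()
        )
        _log(log, f"cohort n={len(cohort)}")

    sexes = tuple(config.get("sexes", ("male", "female")))
    donor = config.get("donor", "high")
    recipient = config.get("recipient", "low")
    fit_opts = dict(config.get("fit", {}))
    reps = int(config.get("bootstrap_reps", 0))

    per_sex: dict[str, SexReport] = {}
    try:
        _run_sexes(
            per_sex, cohort, std_pop, sexes, donor, recipient, fit_opts, reps, seed, log
        )
    finally:
        # preserve whatever completed, plus the log, even on stage failure
        if config.get("out_dir"):
            AnalysisReport(per_sex=per_sex, log=log).write(config["out_dir"])
    return AnalysisReport(per_sex=per_sex, log=log)


def _run_sexes(per_sex, cohort, std_pop, sexes, donor, recipient, fit_opts, reps, seed, log):
    for sex in sexes:
        with _stage(log, f"fit[{sex}]"):
            result = ah.fit(
                cohort, sex, seed=substream_seed(seed, f"fit_{sex}"), **fit_opts
            )
            _log(
                log,
                f"fit[{sex}]: loglik={result.loglik:.4f} converged={result.converged} "
                f"iters={result.n_iter} starts={result.n_starts} "
                f"boundary={sorted(result.boundary_flags)}",
            )
        with _stage(log, f"impacts[{sex}]"):
            impacts = ah.disabling_impact(result.params, std_pop, sex)
        with _stage(log, f"attribution[{sex}]"):
            attributions = {
                edu: baseline_attribution(result.params, cohort, std_pop, sex, edu)
                for edu in cohort.design.education_levels
            }
        with _stage(log, f"counterfactual[{sex}]"):
            scenarios = {
                kind: run_scenario(
                    result.params,
                    cohort,
                    CounterfactualScenario(kind, donor, recipient, sex),
                    std_pop,
                )
                for kind in ("swap_prevalence", "swap_impact")
            }
        with _stage(log, f"decompose[{sex}]"):
            gap = decompose_gap(
                attributions[recipient],
                attributions[donor],
                scenarios["swap_prevalence"],
                scenarios["swap_impact"],
            )
            table2 = render_table2(gap)
            _log(
                log,
                f"gap[{sex}]: baseline={100 * gap.baseline_gap:.1f}pp "
                f"equal-prevalence={100 * gap.remaining_gap_equal_prevalence:.1f}pp "
                f"equal-impact={100 * gap.remaining_gap_equal_impact:.1f}pp",
            )

        boot = None
        if reps > 0:
            with _stage(log, f"bootstrap[{sex}]"):
                boot = _bootstrap_sex(
                    cohort, std_pop, sex, recipient, donor, result, reps,
                    substream_seed(seed, f"bootstrap_{sex}"),
                )
                _log(log, f"bootstrap[{sex}]: reps={reps} failed={boot.n_failed}")

        per_sex[sex] = SexReport(
            fit=result,
            impacts=impacts,
            attributions=attributions,
            scenarios=scenarios,
            gap=gap,
            table2=table2,
            bootstrap=boot,
        )



def _bootstrap_sex(
    cohort: Cohort,
    std_pop: StandardPopulation,
    sex: str,
    recipient: str,
    donor: str,
    main_fit: ah.FitResult,
    reps: int,
    seed: int,
) -> BootstrapResult:
    """Bootstrap CIs for impacts and contributions of one sex.

    Replicate fits warm-start at the full-data optimum with a single
    start, which leaves the statistic deterministic per replicate.
    """
    sex_cohort = cohort.filter(sex=sex)
    design = cohort.design

    def statistic(c: Cohort) -> dict[str, float]:
        res = ah.fit(c, n_starts=1, init_params=main_fit.params, tol=1e-8)
        out: dict[str, float] = {}
        impacts = ah.disabling_impact(res.params, std_pop, sex)
        for d in design.diseases:
            for e in (recipient, donor):
                out[f"impact[{d},{e}]"] = impacts.loc[d, e]
        for e in (recipient, donor):
            attr = baseline_attribution(res.params, c, std_pop, sex, e)
            out[f"prevalence[{e}]"] = attr.prevalence
            out[f"background[{e}]"] = attr.background
            for d in design.diseases:
                out[f"contribution[{d},{e}]"] = attr.contributions[d]
        return out

    return bootstrap(sex_cohort, statistic, n_reps=reps, seed=seed)


TABLE2_COLUMNS = {
    "low": "recipient (1)",
    "high": "donor (2)",
    "cf_prevalence": "cf prevalence of donor (3)",
    "cf_impact": "cf impact of donor (4)",
    "baseline_diff": "baseline gap (1-2)",
    "diff_equal_prevalence": "gap, equal prevalence (3-2)",
    "diff_equal_impact": "gap, equal impact (4-2)",
}


def render_table2(gap: GapDecomposition, percent: bool = True) -> pd.DataFrame:
    """Seven-column contribution/counterfactual table, one row per cause
    plus Background and Disability prevalence; values in percent."""
    table = gap.per_cause.copy()
    required = {"low", "high", "cf_prevalence", "cf_impact"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing result columns: {sorted(missing)}")
    if "background" not in table.index or "prevalence" not in table.index:
        raise ValueError("missing background/prevalence rows")
    table = table.rename(
        index={"background": "Background", "prevalence": "Disability prevalence"},
        columns=TABLE2_COLUMNS,
    )
    return table * 100.0 if percent else table
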