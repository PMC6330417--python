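"""Domain types and delimited-text I/O for disability survey cohorts.

A cohort is a flat table with one row per respondent: demographics
(sex, age in completed years, education coded low/middle/high), a block
of binary chronic-disease indicators, the binary disability outcome
(GALI: limited or severely limited vs. not limited), and a positive
sampling weight.  Age enters the model through two groupings: the
*background* bands used for the background disability rate and the
coarser *rank* bands that carry the shared age pattern of the disease
impacts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DISEASES",
    "EDUCATION_LEVELS",
    "SEXES",
    "AgeGrouping",
    "DEFAULT_GROUPING",
    "StudyDesign",
    "DEFAULT_DESIGN",
    "SurveyRecord",
    "Cohort",
    "StandardPopulation",
    "assign_band",
    "read_cohort",
    "write_cohort",
    "read_standard_population",
    "CohortSchemaError",
    "CohortValidationError",
]

#: The 13 chronic-condition groups, in canonical column order.
DISEASES: tuple[str, ...] = (
    "spine_disorders",
    "arthritis",
    "dementia",
    "stroke",
    "other_neurologic",
    "ischemic_heart_pad",
    "other_heart",
    "copd",
    "psychiatric",
    "sensorial",
    "cancer",
    "diabetes",
    "accidents",
)

EDUCATION_LEVELS: tuple[str, ...] = ("low", "middle", "high")
SEXES: tuple[str, ...] = ("male", "female")

MIN_AGE = 25


class CohortSchemaError(ValueError):
    """Input table is missing required columns."""


class CohortValidationError(ValueError):
    """One or more rows violate field-level constraints."""


@dataclass(frozen=True)
class AgeGrouping:
    """Half-open age bands: ``[lo, hi)``, the last band open-ended.

    ``background_bands`` index the background rate alpha;
    ``rank_bands`` index the shared age pattern gamma of disease
    impacts.  Both partitions cover ``[MIN_AGE, inf)``.
    """

    background_bands: tuple[tuple[float, float], ...]
    rank_bands: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        for bands in (self.background_bands, self.rank_bands):
            _check_partition(bands)

    @property
    def n_background(self) -> int:
        return len(self.background_bands)

    @property
    def n_rank(self) -> int:
        return len(self.rank_bands)


def _check_partition(bands: Sequence[tuple[float, float]]) -> None:
    if not bands:
        raise ValueError("empty band list")
    lo0 = bands[0][0]
    if lo0 != MIN_AGE:
        raise ValueError(f"bands must start at {MIN_AGE}, got {lo0}")
    for (lo, hi), (lo2, _) in zip(bands, bands[1:]):
        if hi != lo2:
            raise ValueError(f"bands not contiguous at {hi} != {lo2}")
        if hi <= lo:
            raise ValueError(f"band [{lo}, {hi}) is empty")
    if not math.isinf(bands[-1][1]):
        raise ValueError("last band must be open-ended (hi = inf)")


#: Background bands 25-39, 40-49, 50-59, 60-69, 70-79, 80+ and rank
#: bands 25-39, 40-54, 55-69, 70+ (labels are inclusive integer ages;
#: intervals are half-open).
DEFAULT_GROUPING = AgeGrouping(
    background_bands=((25, 40), (40, 50), (50, 60), (60, 70), (70, 80), (80, math.inf)),
    rank_bands=((25, 40), (40, 55), (55, 70), (70, math.inf)),
)


def assign_band(age_years: float, bands: Sequence[tuple[float, float]]) -> int:
    """Index of the unique half-open band ``[lo, hi)`` containing the age.

    Raises
    ------
    ValueError
        If ``age_years`` is below the first band's lower edge.
    """
    if age_years < bands[0][0]:
        raise ValueError(f"age {age_years} below minimum {bands[0][0]}")
    for i, (lo, hi) in enumerate(bands):
        if lo <= age_years < hi:
            return i
    raise ValueError(f"age {age_years} not covered by bands")  # pragma: no cover


def band_label(band: tuple[float, float]) -> str:
    lo, hi = band
    if math.isinf(hi):
        return f"{int(lo)}+"
    return f"{int(lo)}-{int(hi) - 1}"


@dataclass(frozen=True)
class StudyDesign:
    """Fixed structure of an analysis: diseases, strata and age bands.

    The defaults reproduce the survey layout: 13 disease groups, three
    ISCED-based education levels, six background bands and four rank
    bands from age 25.  Tests and reduced problems may supply smaller
    designs; every downstream module is generic in this object.
    """

    diseases: tuple[str, ...] = DISEASES
    education_levels: tuple[str, ...] = EDUCATION_LEVELS
    grouping: AgeGrouping = DEFAULT_GROUPING
    sexes: tuple[str, ...] = SEXES

    def __post_init__(self) -> None:
        if len(set(self.diseases)) != len(self.diseases):
            raise ValueError("duplicate disease names")
        if not self.diseases:
            raise ValueError("at least one disease required")

    @property
    def n_diseases(self) -> int:
        return len(self.diseases)

    @property
    def n_education(self) -> int:
        return len(self.education_levels)

    def education_index(self, level: str) -> int:
        try:
            return self.education_levels.index(level)
        except ValueError:
            raise ValueError(f"unknown education level {level!r}") from None


DEFAULT_DESIGN = StudyDesign()


@dataclass(frozen=True)
class SurveyRecord:
    """One respondent."""

    id: str
    sex: str
    age_years: int
    education: str
    diseases: tuple[int, ...]
    disability: int
    weight: float

    def validate(self, design: StudyDesign = DEFAULT_DESIGN) -> None:
        if self.sex not in design.sexes:
            raise CohortValidationError(f"record {self.id}: bad sex {self.sex!r}")
        if self.age_years < MIN_AGE:
            raise CohortValidationError(
                f"record {self.id}: age {self.age_years} below {MIN_AGE}"
            )
        if self.education not in design.education_levels:
            raise CohortValidationError(
                f"record {self.id}: bad education {self.education!r}"
            )
        if len(self.diseases) != design.n_diseases:
            raise CohortValidationError(
                f"record {self.id}: expected {design.n_diseases} disease "
                f"indicators, got {len(self.diseases)}"
            )
        if any(x not in (0, 1) for x in self.diseases):
            raise CohortValidationError(f"record {self.id}: non-binary disease flag")
        if self.disability not in (0, 1):
            raise CohortValidationError(f"record {self.id}: non-binary disability")
        if not (self.weight > 0):
            raise CohortValidationError(
                f"record {self.id}: weight {self.weight} not positive"
            )


class Cohort:
    """A validated collection of survey records backed by a DataFrame.

    Column layout: ``id, sex, age, education, <diseases...>, disability,
    weight``.  All model modules consume this container through
    :meth:`arrays`, which maps rows to band/education indices and the
    disease indicator matrix.
    """

    def __init__(self, frame: pd.DataFrame, design: StudyDesign = DEFAULT_DESIGN):
        self.design = design
        self.frame = _validate_frame(frame, design)

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_records(
        cls, records: Iterable[SurveyRecord], design: StudyDesign = DEFAULT_DESIGN
    ) -> "Cohort":
        rows = []
        for r in records:
            r.validate(design)
            row = {"id": r.id, "sex": r.sex, "age": r.age_years, "education": r.education}
            row.update(dict(zip(design.diseases, r.diseases)))
            row["disability"] = r.disability
            row["weight"] = r.weight
            rows.append(row)
        return cls(pd.DataFrame(rows), design)

    def records(self) -> list[SurveyRecord]:
        out = []
        for row in self.frame.itertuples(index=False):
            d = row._asdict()
            out.append(
                SurveyRecord(
                    id=str(d["id"]),
                    sex=d["sex"],
                    age_years=int(d["age"]),
                    education=d["education"],
                    diseases=tuple(int(d[name]) for name in self.design.diseases),
                    disability=int(d["disability"]),
                    weight=float(d["weight"]),
                )
            )
        return out

    def subset(self, mask: np.ndarray | pd.Series) -> "Cohort":
        sub = self.frame.loc[np.asarray(mask)].reset_index(drop=True)
        if len(sub) == 0:
            raise ValueError("empty cohort subset")
        c = object.__new__(Cohort)
        c.design = self.design
        c.frame = sub
        return c

    def filter(self, sex: str | None = None, education: str | None = None) -> "Cohort":
        mask = np.ones(len(self.frame), dtype=bool)
        if sex is not None:
            mask &= (self.frame["sex"] == sex).to_numpy()
        if education is not None:
            mask &= (self.frame["education"] == education).to_numpy()
        return self.subset(mask)

    def resample(self, rng: np.random.Generator) -> "Cohort":
        """Bootstrap resample of rows with replacement (weights carried)."""
        n = len(self.frame)
        idx = rng.integers(0, n, size=n)
        c = object.__new__(Cohort)
        c.design = self.design
        c.frame = self.frame.iloc[idx].reset_index(drop=True)
        return c

    def arrays(self) -> dict[str, np.ndarray]:
        """Model design arrays: band/education indices, X, Y, weights."""
        g = self.design.grouping
        ages = self.frame["age"].to_numpy(dtype=float)
        a_idx = _digitize(ages, g.background_bands)
        c_idx = _digitize(ages, g.rank_bands)
        e_idx = pd.Categorical(
            self.frame["education"], categories=self.design.education_levels
        ).codes.astype(np.int64)
        X = self.frame[list(self.design.diseases)].to_numpy(dtype=float)
        Y = self.frame["disability"].to_numpy(dtype=float)
        w = self.frame["weight"].to_numpy(dtype=float)
        return {"a": a_idx, "c": c_idx, "e": e_idx, "X": X, "Y": Y, "w": w}


def _digitize(ages: np.ndarray, bands: Sequence[tuple[float, float]]) -> np.ndarray:
    edges = [lo for lo, _ in bands[1:]]
    return np.searchsorted(np.asarray(edges), ages, side="right").astype(np.int64)


def _validate_frame(frame: pd.DataFrame, design: StudyDesign) -> pd.DataFrame:
    required = ["id", "sex", "age", "education", *design.diseases, "disability", "weight"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise CohortSchemaError(f"missing columns: {', '.join(missing)}")
    frame = frame[required].copy()

    problems: list[str] = []

    def check(mask: pd.Series, message: str) -> None:
        bad = frame.index[mask.fillna(True)]
        for i in bad[:20]:
            problems.append(f"row {i}: {message}")

    if frame[required].isna().any().any():
        na_rows = frame.index[frame[required].isna().any(axis=1)]
        for i in na_rows[:20]:
            problems.append(f"row {i}: missing value")
        frame = frame.dropna(subset=required)

    check(~frame["sex"].isin(design.sexes), "sex must be one of " + "/".join(design.sexes))
    check(frame["age"] < MIN_AGE, f"age below {MIN_AGE}")
    check(
        ~frame["education"].isin(design.education_levels),
        "education must be one of " + "/".join(design.education_levels),
    )
    for name in design.diseases:
        check(~frame[name].isin([0, 1]), f"{name} must be 0/1")
    check(~frame["disability"].isin([0, 1]), "disability must be 0/1")
    check(~(frame["weight"] > 0), "weight must be > 0")

    if problems:
        raise CohortValidationError("; ".join(problems))

    frame["age"] = frame["age"].astype(int)
    for name in (*design.diseases, "disability"):
        frame[name] = frame[name].astype(np.int8)
    frame["weight"] = frame["weight"].astype(float)
    frame["id"] = frame["id"].astype(str)
    return frame.reset_index(drop=True)


def read_cohort(path, design: StudyDesign = DEFAULT_DESIGN) -> Cohort:
    """Read a comma-delimited cohort file.

    Raises :class:`CohortSchemaError` for missing columns and
    :class:`CohortValidationError` naming the offending rows for bad
    field values.  Records with any missing field are rejected.
    """
    frame = pd.read_csv(path)
    return Cohort(frame, design)


def write_cohort(cohort: Cohort, path) -> None:
    cohort.frame.to_csv(path, index=False)


class StandardPopulation:
    """Age structure of a standard population, per sex.

    Maps each background band to the proportion of the (sex-specific)
    standard population in that band; used for direct standardization.
    Weights are normalized to sum to one per sex at construction.
    """

    def __init__(
        self,
        weights: dict[str, np.ndarray],
        grouping: AgeGrouping = DEFAULT_GROUPING,
    ):
        self.grouping = grouping
        self.weights: dict[str, np.ndarray] = {}
        for sex, w in weights.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (grouping.n_background,):
                raise ValueError(
                    f"{sex}: expected {grouping.n_background} band weights, got {w.shape}"
                )
            if np.any(w < 0) or w.sum() <= 0:
                raise ValueError(f"{sex}: weights must be non-negative, sum > 0")
            self.weights[sex] = w / w.sum()

    def band_weights(self, sex: str) -> np.ndarray:
        return self.weights[sex]

    def rank_band_weights(self, sex: str) -> np.ndarray:
        """Standard-population weights aggregated onto the rank bands.

        Background-band mass is spread uniformly over integer ages
        within the band (open-ended bands get a nominal 20-year width)
        and re-aggregated, so bands straddling a rank-band boundary are
        split proportionally.
        """
        g = self.grouping
        out = np.zeros(g.n_rank)
        for (lo, hi), w in zip(g.background_bands, self.weights[sex]):
            hi_eff = lo + 20 if math.isinf(hi) else hi
            for j, (rlo, rhi) in enumerate(g.rank_bands):
                rhi_eff = max(hi_eff, rlo + 1) if math.isinf(rhi) else rhi
                overlap = max(0.0, min(hi_eff, rhi_eff) - max(lo, rlo))
                out[j] += w * overlap / (hi_eff - lo)
        return out / out.sum()


def read_standard_population(
    path, grouping: AgeGrouping = DEFAULT_GROUPING
) -> StandardPopulation:
    """Read a standard population table: columns sex, band_lo, band_hi, weight.

    ``band_hi`` may be blank or ``inf`` for the open-ended band.  Every
    background band of ``grouping`` must be present for each sex listed.
    """
    frame = pd.read_csv(path)
    required = {"sex", "band_lo", "band_hi", "weight"}
    missing = required - set(frame.columns)
    if missing:
        raise CohortSchemaError(f"missing columns: {', '.join(sorted(missing))}")
    weights: dict[str, np.ndarray] = {}
    for sex, grp in frame.groupby("sex"):
        w = np.full(grouping.n_background, np.nan)
        for row in grp.itertuples(index=False):
            hi = float(row.band_hi) if pd.notna(row.band_hi) else math.inf
            band = (float(row.band_lo), hi)
            try:
                i = grouping.background_bands.index(band)
            except ValueError:
                raise CohortValidationError(
                    f"{sex}: band [{band[0]}, {band[1]}) not in grouping"
                ) from None
            w[i] = float(row.weight)
        if np.isnan(w).any():
            raise CohortValidationError(f"{sex}: missing bands in standard population")
        weights[str(sex)] = w
    return StandardPopulation(weights, grouping)


def write_standard_population(std_pop: StandardPopulation, path) -> None:
    rows = []
    for sex, w in std_pop.weights.items():
        for (lo, hi), wt in zip(std_pop.grouping.background_bands, w):
            rows.append(
                {
                    "sex": sex,
                    "band_lo": lo,
                    "band_hi": "" if math.isinf(hi) else hi,
                    "weight": wt,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
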