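"""Domain types, delimited-text I/O, and validation for DHS-style survey extracts.

A :class:`Survey` bundles three tables:

* **respondents** — women 15-49 with sampling weight, cluster and stratum ids,
  and dates of birth and interview (century-month codes);
* **siblings** — each respondent's sibling roster with vital status, dates,
  the pregnancy-timing-of-death flag, and the violent/accidental-death flag;
* **pregnancies** — each respondent's pregnancy record (calendar or full
  pregnancy history): end date, gestation duration in months, and outcome.

Tables are stored as pandas DataFrames with a fixed canonical column
vocabulary; :class:`SchemaConfig` maps arbitrary delimited-text extracts onto
it (column renames, weight rescaling, year+month date pairs). Malformed rows
are quarantined with ids and reported, never silently dropped.
"""

from __future__ import annotations

import dataclasses
import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, SurveyValidationError
from .agegroups import MAX_AGE_MONTHS, MIN_AGE_MONTHS

__all__ = [
    "Sex",
    "DeathTiming",
    "PregnancyOutcome",
    "Respondent",
    "SiblingRecord",
    "PregnancyRecord",
    "Survey",
    "Issue",
    "SchemaConfig",
    "DHS_IR_PRESET",
    "read_survey",
    "read_survey_dir",
    "write_survey",
    "write_estimates",
    "read_estimates",
    "validate_survey",
]


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"


class DeathTiming(str, enum.Enum):
    """Timing of a sister's death relative to pregnancy, as reported.

    The first three categories make a death pregnancy-related (death during
    pregnancy, during delivery, or within two months of the end of the
    pregnancy, irrespective of cause).
    """

    NOT_APPLICABLE = "not_applicable"
    DURING_PREGNANCY = "during_pregnancy"
    DURING_DELIVERY = "during_delivery"
    WITHIN_TWO_MONTHS_POSTPARTUM = "within_two_months_postpartum"
    NONE_OF_THESE = "none_of_these"


PREGNANCY_RELATED_TIMINGS = frozenset(
    {
        DeathTiming.DURING_PREGNANCY.value,
        DeathTiming.DURING_DELIVERY.value,
        DeathTiming.WITHIN_TWO_MONTHS_POSTPARTUM.value,
    }
)


class PregnancyOutcome(str, enum.Enum):
    """Reported pregnancy outcome.

    Full pregnancy histories differentiate miscarriage from induced abortion;
    reproductive calendars record losses before seven months undifferentiated
    (``loss_unclassified``).
    """

    LIVE_BIRTH = "live_birth"
    STILLBIRTH = "stillbirth"
    MISCARRIAGE = "miscarriage"
    INDUCED_ABORTION = "induced_abortion"
    LOSS_UNCLASSIFIED = "loss_unclassified"


@dataclass(frozen=True)
class Respondent:
    id: str
    weight: float
    cluster: str
    stratum: str
    dob_cmc: int
    interview_cmc: int


@dataclass(frozen=True)
class SiblingRecord:
    respondent_id: str
    sex: Sex
    alive: bool
    dob_cmc: int
    dod_cmc: int | None = None
    death_timing: DeathTiming = DeathTiming.NOT_APPLICABLE
    violent_or_accidental: bool | None = None


@dataclass(frozen=True)
class PregnancyRecord:
    respondent_id: str
    end_cmc: int
    duration_months: int
    outcome: PregnancyOutcome


@dataclass(frozen=True)
class Issue:
    """One validation finding: ('error'|'warning', offending record id, message)."""

    severity: str
    record_id: str
    message: str


RESPONDENT_COLUMNS = ("resp_id", "weight", "cluster", "stratum", "dob_cmc", "interview_cmc")
SIBLING_COLUMNS = ("resp_id", "sex", "alive", "dob_cmc", "dod_cmc", "death_timing", "violent")
PREGNANCY_COLUMNS = ("resp_id", "end_cmc", "duration_months", "outcome")

#: The violence flag is optional (pre-DHS-VI surveys lack it); without it the
#: survey supports PRMR but not MMR.
OPTIONAL_COLUMNS = {"violent"}


@dataclass
class Survey:
    """Respondent, sibling, and pregnancy tables plus design metadata."""

    respondents: pd.DataFrame
    siblings: pd.DataFrame
    pregnancies: pd.DataFrame
    meta: dict = field(default_factory=dict)
    issues: list = field(default_factory=list)

    @classmethod
    def from_records(
        cls,
        respondents: Sequence[Respondent],
        siblings: Sequence[SiblingRecord] = (),
        pregnancies: Sequence[PregnancyRecord] = (),
        meta: dict | None = None,
    ) -> "Survey":
        resp = pd.DataFrame(
            {
                "resp_id": [r.id for r in respondents],
                "weight": [r.weight for r in respondents],
                "cluster": [str(r.cluster) for r in respondents],
                "stratum": [str(r.stratum) for r in respondents],
                "dob_cmc": [r.dob_cmc for r in respondents],
                "interview_cmc": [r.interview_cmc for r in respondents],
            }
        )
        sib = pd.DataFrame(
            {
                "resp_id": [s.respondent_id for s in siblings],
                "sex": [Sex(s.sex).value for s in siblings],
                "alive": [bool(s.alive) for s in siblings],
                "dob_cmc": [s.dob_cmc for s in siblings],
                "dod_cmc": [np.nan if s.dod_cmc is None else float(s.dod_cmc) for s in siblings],
                "death_timing": [DeathTiming(s.death_timing).value for s in siblings],
                "violent": [s.violent_or_accidental for s in siblings],
            }
        )
        preg = pd.DataFrame(
            {
                "resp_id": [p.respondent_id for p in pregnancies],
                "end_cmc": [p.end_cmc for p in pregnancies],
                "duration_months": [p.duration_months for p in pregnancies],
                "outcome": [PregnancyOutcome(p.outcome).value for p in pregnancies],
            }
        )
        if sib.empty:
            sib = _empty_siblings()
        if preg.empty:
            preg = _empty_pregnancies()
        return cls(resp, sib, preg, meta=dict(meta or {}))

    @property
    def n_respondents(self) -> int:
        return len(self.respondents)

    @property
    def has_violence_flags(self) -> bool:
        """True when every dead sibling carries a violent/accidental flag."""
        sib = self.siblings
        if "violent" not in sib.columns:
            return False
        dead = sib.loc[~sib["alive"].astype(bool), "violent"]
        return bool(dead.notna().all())

    def cluster_keys(self) -> pd.DataFrame:
        """Distinct (stratum, cluster) pairs, in first-appearance order."""
        return self.respondents[["stratum", "cluster"]].drop_duplicates().reset_index(drop=True)

    def drop_cluster(self, stratum: str, cluster: str) -> "Survey":
        """A copy of the survey with one sampling cluster removed (jackknife subsample)."""
        resp = self.respondents
        keep = ~((resp["stratum"] == stratum) & (resp["cluster"] == cluster))
        kept = resp.loc[keep]
        ids = set(kept["resp_id"])
        return Survey(
            kept.reset_index(drop=True),
            self.siblings.loc[self.siblings["resp_id"].isin(ids)].reset_index(drop=True),
            self.pregnancies.loc[self.pregnancies["resp_id"].isin(ids)].reset_index(drop=True),
            meta=dict(self.meta),
        )


def _empty_siblings() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "resp_id": pd.Series(dtype=object),
            "sex": pd.Series(dtype=object),
            "alive": pd.Series(dtype=bool),
            "dob_cmc": pd.Series(dtype=np.int64),
            "dod_cmc": pd.Series(dtype=float),
            "death_timing": pd.Series(dtype=object),
            "violent": pd.Series(dtype=object),
        }
    )


def _empty_pregnancies() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "resp_id": pd.Series(dtype=object),
            "end_cmc": pd.Series(dtype=np.int64),
            "duration_months": pd.Series(dtype=np.int64),
            "outcome": pd.Series(dtype=object),
        }
    )


# ---------------------------------------------------------------------------
# Schema configuration


@dataclass
class SchemaConfig:
    """Maps a delimited-text extract onto the canonical column vocabulary.

    ``*_columns`` map canonical names to source column names. A date column
    may instead be given as ``{"year": <col>, "month": <col>}`` and is
    converted to a century-month code on read. ``weight_scale`` divides the
    raw weight column (DHS individual recodes store weights times 10^6).
    """

    delimiter: str = ","
    weight_scale: float = 1.0
    respondent_columns: dict = field(default_factory=dict)
    sibling_columns: dict = field(default_factory=dict)
    pregnancy_columns: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SchemaConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown schema keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))


#: Column-name preset for exports of DHS individual-recode (IR) variables.
#: This is a mapping only — values (sex codes, outcome codes, timing codes)
#: must already be recoded to the generic vocabulary; native binary formats
#: are out of scope.
DHS_IR_PRESET = {
    "respondent_columns": {
        "resp_id": "caseid",
        "weight": "v005",
        "cluster": "v001",
        "stratum": "v023",
        "dob_cmc": "v011",
        "interview_cmc": "v008",
    },
    "sibling_columns": {
        "resp_id": "caseid",
        "sex": "mm1",
        "alive": "mm2",
        "dob_cmc": "mm4",
        "dod_cmc": "mm8",
        "death_timing": "mm9",
        "violent": "mm16",
    },
    "pregnancy_columns": {
        "resp_id": "caseid",
        "end_cmc": "p3",
        "duration_months": "p20",
        "outcome": "p32",
    },
    "weight_scale": 1e6,
}


def _resolve_columns(
    df: pd.DataFrame,
    canonical: Sequence[str],
    mapping: dict,
    table: str,
) -> pd.DataFrame:
    """Rename/derive canonical columns from a raw table per the schema mapping."""
    out = pd.DataFrame(index=df.index)
    for name in canonical:
        spec = mapping.get(name, name)
        if isinstance(spec, dict):  # year+month pair -> CMC
            ycol, mcol = spec.get("year"), spec.get("month")
            for col in (ycol, mcol):
                if col not in df.columns:
                    raise ConfigurationError(
                        f"{table}: mapped column {col!r} for {name!r} not found"
                    )
            out[name] = 12 * (pd.to_numeric(df[ycol]) - 1900) + pd.to_numeric(df[mcol])
        elif spec in df.columns:
            out[name] = df[spec]
        elif name in OPTIONAL_COLUMNS:
            out[name] = np.nan
        else:
            raise ConfigurationError(f"{table}: mandatory column {spec!r} missing")
    return out


_TRUE = {"1", "true", "yes", "y", "t"}
_FALSE = {"0", "false", "no", "n", "f", ""}


def _coerce_bool(v):
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return None
    s = str(v).strip().lower()
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValueError(f"cannot interpret {v!r} as a flag")


def _coerce_rows(df: pd.DataFrame, coercers: dict, table: str, issues: list[Issue]) -> pd.DataFrame:
    """Apply per-column coercions row-wise; quarantine rows that fail.

    Failing rows are excluded from the returned clean table and reported as
    error-severity issues carrying the offending respondent id.
    """
    bad = np.zeros(len(df), dtype=bool)
    cols = {}
    for name, fn in coercers.items():
        vals = []
        for i, v in enumerate(df[name].tolist()):
            try:
                vals.append(fn(v))
            except (ValueError, TypeError) as exc:
                vals.append(None)
                if not bad[i]:
                    rid = str(df["resp_id"].iloc[i])
                    issues.append(
                        Issue("error", rid, f"{table} row {i}: bad {name}: {exc}")
                    )
                bad[i] = True
        cols[name] = vals
    clean = pd.DataFrame(cols, index=df.index).loc[~bad].reset_index(drop=True)
    return clean


def _opt_int(v):
    if v is None or v == "" or (isinstance(v, float) and np.isnan(v)):
        return np.nan
    return float(int(float(v)))


def _timing(v):
    if v is None or v == "" or (isinstance(v, float) and np.isnan(v)):
        return DeathTiming.NOT_APPLICABLE.value
    return DeathTiming(str(v).strip()).value


def read_survey(
    respondents_path: str | Path,
    siblings_path: str | Path,
    pregnancies_path: str | Path,
    schema: SchemaConfig | None = None,
    meta: dict | None = None,
) -> Survey:
    """Read a survey from three delimited-text files and validate it.

    Rows failing type coercion are quarantined and reported on the returned
    survey's ``issues`` list; they never enter the clean tables. Orphan
    sibling or pregnancy rows (referencing no respondent) raise
    :class:`SurveyValidationError` naming the offending ids.
    """
    schema = schema or SchemaConfig()
    issues: list[Issue] = []

    raw_resp = pd.read_csv(respondents_path, sep=schema.delimiter, dtype=object)
    raw_sib = pd.read_csv(siblings_path, sep=schema.delimiter, dtype=object)
    raw_preg = pd.read_csv(pregnancies_path, sep=schema.delimiter, dtype=object)

    resp = _resolve_columns(raw_resp, RESPONDENT_COLUMNS, schema.respondent_columns, "respondents")
    sib = _resolve_columns(raw_sib, SIBLING_COLUMNS, schema.sibling_columns, "siblings")
    preg = _resolve_columns(raw_preg, PREGNANCY_COLUMNS, schema.pregnancy_columns, "pregnancies")

    resp = _coerce_rows(
        resp,
        {
            "resp_id": str,
            "weight": lambda v: float(v) / schema.weight_scale,
            "cluster": str,
            "stratum": str,
            "dob_cmc": lambda v: int(float(v)),
            "interview_cmc": lambda v: int(float(v)),
        },
        "respondents",
        issues,
    )
    sib = _coerce_rows(
        sib,
        {
            "resp_id": str,
            "sex": lambda v: Sex(str(v).strip().lower()).value,
            "alive": lambda v: bool(_coerce_bool(v)),
            "dob_cmc": lambda v: int(float(v)),
            "dod_cmc": _opt_int,
            "death_timing": _timing,
            "violent": _coerce_bool,
        },
        "siblings",
        issues,
    )
    preg = _coerce_rows(
        preg,
        {
            "resp_id": str,
            "end_cmc": lambda v: int(float(v)),
            "duration_months": lambda v: int(float(v)),
            "outcome": lambda v: PregnancyOutcome(str(v).strip()).value,
        },
        "pregnancies",
        issues,
    )

    ids = set(resp["resp_id"])
    for table, df in (("siblings", sib), ("pregnancies", preg)):
        orphans = sorted(set(df["resp_id"]) - ids)
        if orphans:
            raise SurveyValidationError(
                f"{table} reference unknown respondent ids: {orphans[:10]}"
            )

    survey = Survey(resp, sib, preg, meta=dict(meta or {}), issues=issues)
    return survey


def read_survey_dir(directory: str | Path, schema: SchemaConfig | None = None) -> Survey:
    """Read ``respondents.csv``, ``siblings.csv``, ``pregnancies.csv`` from a directory."""
    d = Path(directory)
    meta: dict = {}
    meta_path = d / "meta.yaml"
    if meta_path.exists():
        meta = yaml.safe_load(meta_path.read_text()) or {}
    return read_survey(
        d / "respondents.csv", d / "siblings.csv", d / "pregnancies.csv", schema, meta=meta
    )


def write_survey(survey: Survey, directory: str | Path) -> None:
    """Write a survey as three canonical CSV files plus ``meta.yaml``."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    survey.respondents.to_csv(d / "respondents.csv", index=False)
    sib = survey.siblings.copy()
    # store CMCs as integers where present, not "1234.0"
    sib["dod_cmc"] = sib["dod_cmc"].map(lambda v: "" if pd.isna(v) else str(int(v)))
    sib["violent"] = sib["violent"].map(lambda v: "" if pd.isna(v) else str(bool(v)).lower())
    sib.to_csv(d / "siblings.csv", index=False)
    survey.pregnancies.to_csv(d / "pregnancies.csv", index=False)
    (d / "meta.yaml").write_text(yaml.safe_dump(survey.meta, sort_keys=True))


def write_estimates(estimates: Iterable, path: str | Path) -> None:
    """Write ratio estimates as a long-format delimited table.

    Columns: metric, scenario, estimate, se, ci_low, ci_high. Values
    round-trip losslessly (shortest-repr float formatting).
    """
    rows = list(estimates)
    if not rows:
        raise ValueError("refusing to write an empty estimates table")
    df = pd.DataFrame(
        {
            "metric": [e.metric for e in rows],
            "scenario": [getattr(e.scenario, "value", e.scenario) for e in rows],
            "estimate": [e.value for e in rows],
            "se": [e.se for e in rows],
            "ci_low": [e.ci_low for e in rows],
            "ci_high": [e.ci_high for e in rows],
        }
    )
    df.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_estimates(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")


# ---------------------------------------------------------------------------
# Validation


def validate_survey(survey: Survey) -> list[Issue]:
    """Check every structural invariant; return findings, empty iff all hold.

    Pure and deterministic: the same survey always yields the same report.
    Error severity marks records the pipeline must not run on; warnings mark
    suspect but usable records.
    """
    issues: list[Issue] = []
    resp = survey.respondents

    ids = set(resp["resp_id"])
    dup = resp["resp_id"][resp["resp_id"].duplicated()]
    for rid in dup:
        issues.append(Issue("error", str(rid), "duplicate respondent id"))

    for _, r in resp.iterrows():
        rid = str(r["resp_id"])
        w = r["weight"]
        if not np.isfinite(w) or w <= 0:
            issues.append(Issue("error", rid, f"non-positive or non-finite weight {w}"))
        for col in ("cluster", "stratum"):
            if pd.isna(r[col]) or str(r[col]) == "":
                issues.append(Issue("error", rid, f"missing {col} id"))
        if r["interview_cmc"] <= r["dob_cmc"]:
            issues.append(Issue("error", rid, "interview date not after birth date"))
        else:
            age_m = int(r["interview_cmc"]) - int(r["dob_cmc"])
            if age_m < MIN_AGE_MONTHS or age_m > MAX_AGE_MONTHS:
                issues.append(
                    Issue("error", rid, f"respondent aged {age_m // 12} at interview, outside 15-49")
                )

    for i, s in survey.siblings.iterrows():
        rid = str(s["resp_id"])
        tag = f"sibling row {i}"
        if rid not in ids:
            issues.append(Issue("error", rid, f"{tag}: unknown respondent id"))
            continue
        if s["alive"]:
            if not pd.isna(s["dod_cmc"]):
                issues.append(Issue("error", rid, f"{tag}: living sibling has a death date"))
            if s["death_timing"] != DeathTiming.NOT_APPLICABLE.value:
                issues.append(
                    Issue("error", rid, f"{tag}: living sibling has death timing {s['death_timing']}")
                )
        else:
            if pd.isna(s["dod_cmc"]):
                issues.append(Issue("error", rid, f"{tag}: dead sibling lacks a death date"))
            elif s["dod_cmc"] < s["dob_cmc"]:
                issues.append(Issue("error", rid, f"{tag}: death precedes birth"))

    resp_idx = resp.set_index("resp_id")
    for i, p in survey.pregnancies.iterrows():
        rid = str(p["resp_id"])
        tag = f"pregnancy row {i}"
        if rid not in ids:
            issues.append(Issue("error", rid, f"{tag}: unknown respondent id"))
            continue
        mother = resp_idx.loc[rid]
        if isinstance(mother, pd.DataFrame):
            mother = mother.iloc[0]
        if not (mother["dob_cmc"] <= p["end_cmc"] <= mother["interview_cmc"]):
            issues.append(
                Issue("error", rid, f"{tag}: end date {p['end_cmc']} outside mother's lifespan")
            )
        if not 1 <= int(p["duration_months"]) <= 10:
            issues.append(Issue("error", rid, f"{tag}: duration {p['duration_months']} months"))
        if (
            p["outcome"] == PregnancyOutcome.LOSS_UNCLASSIFIED.value
            and int(p["duration_months"]) >= 7
        ):
            # Calendar convention codes >=7-month losses as stillbirths; an
            # unclassified loss at 7+ months is suspect but classifiable.
            issues.append(
                Issue("warning", rid, f"{tag}: unclassified loss at {p['duration_months']} months")
            )

    return issues


def require_valid(survey: Survey) -> None:
    """Raise if the survey (or its read report) carries error-severity issues."""
    errors = [i for i in list(survey.issues) + validate_survey(survey) if i.severity == "error"]
    if errors:
        head = "; ".join(f"{i.record_id}: {i.message}" for i in errors[:5])
        raise SurveyValidationError(f"{len(errors)} error-severity issues, e.g. {head}")
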