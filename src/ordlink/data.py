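"""Domain types and file I/O for sugar/fat preference test (SFPT) score data.

The SFPT presents 16 dairy solutions (4 fat levels x 4 sugar levels, %w/w)
which each subject rates for sweetness, creaminess and pleasantness on a
9-point scale (1 = "not at all", 9 = "extremely"), in two scoring sessions.
This module holds the record/parameter containers, the long-format CSV
reader/writer and the parameter-file reader/writer used by every other
module.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
import yaml

ENDPOINTS = ("sweetness", "creaminess", "pleasantness")
VARIANTS = ("amounts", "linked", "observed_scores", "score_link")

#: CSV TYPE column codes <-> endpoint names
TYPE_CODES = {"SWEET": "sweetness", "CREAM": "creaminess", "PLEAS": "pleasantness"}
ENDPOINT_CODES = {v: k for k, v in TYPE_CODES.items()}

CSV_COLUMNS = ["ID", "OCC", "ORDER", "FAT", "SUGAR", "TYPE", "DV"]

SCHEMA_VERSION = 1


class ValidationError(ValueError):
    """Input data violates a schema or range constraint."""


class DesignDomainError(ValidationError):
    """Value is valid in general but outside the study design's domain."""


# --------------------------------------------------------------------------
# subjects and records
# --------------------------------------------------------------------------

def classify_bmi(bmi: float, permissive: bool = False) -> str:
    """Classify BMI (kg/m^2) into the study's strata.

    The study enrolled lean (BMI < 25), obese (30 <= BMI < 35) and very
    obese (BMI >= 35) subjects only; the overweight band [25, 30) did not
    occur.  By default a BMI in that band raises :class:`DesignDomainError`;
    ``permissive=True`` maps it to ``"overweight"`` instead.
    """
    if not np.isfinite(bmi) or bmi <= 0:
        raise ValidationError(f"BMI must be a positive finite number, got {bmi!r}")
    if bmi < 25:
        return "lean"
    if bmi < 30:
        if permissive:
            return "overweight"
        raise DesignDomainError(
            f"BMI {bmi} falls in the overweight band [25, 30) which is outside "
            "the study design; pass permissive=True to allow it"
        )
    if bmi < 35:
        return "obese"
    return "very_obese"


@dataclass(frozen=True)
class Solution:
    """One dairy solution, identified by its fat and sugar content (%w/w)."""

    fat: float
    sugar: float

    def __post_init__(self):
        if self.fat < 0 or self.sugar < 0:
            raise ValidationError(f"fat/sugar must be nonnegative, got {self}")


@dataclass(frozen=True)
class Subject:
    id: int
    sex: Optional[str] = None  # "male" | "female"
    bmi: Optional[float] = None
    bmi_class: Optional[str] = None

    def __post_init__(self):
        if self.sex is not None and self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.bmi is not None and self.bmi_class is None:
            object.__setattr__(self, "bmi_class", classify_bmi(self.bmi))


@dataclass(frozen=True)
class ScoreRecord:
    """One rating event: a subject scores one solution on one endpoint."""

    subject_id: int
    occasion: int
    solution: Solution
    endpoint: str
    score: int
    presentation_order: int = 1

    def __post_init__(self):
        if self.endpoint not in ENDPOINTS:
            raise ValidationError(f"unknown endpoint {self.endpoint!r}")
        if not (isinstance(self.score, (int, np.integer)) and 1 <= self.score <= 9):
            raise ValidationError(f"score must be an integer in 1..9, got {self.score!r}")
        if self.occasion < 1:
            raise ValidationError(f"occasion must be >= 1, got {self.occasion}")
        if self.presentation_order < 1:
            raise ValidationError(f"presentation_order must be >= 1, got {self.presentation_order}")


@dataclass
class SFPTDataset:
    subjects: list[Subject]
    records: list[ScoreRecord]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        ids = [s.id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate subject ids")
        known = set(ids)
        seen = set()
        for i, r in enumerate(self.records):
            if r.subject_id not in known:
                raise ValidationError(f"record {i}: unknown subject id {r.subject_id}")
            key = (r.subject_id, r.occasion, r.endpoint, r.solution.fat, r.solution.sugar)
            if key in seen:
                raise ValidationError(f"record {i}: duplicate (subject, occasion, endpoint, solution) {key}")
            seen.add(key)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (r.subject_id, r.occasion, r.presentation_order, r.solution.fat,
             r.solution.sugar, ENDPOINT_CODES[r.endpoint], r.score)
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _records_from_frame(df: pd.DataFrame, source: str = "<frame>") -> list[ScoreRecord]:
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        code = str(row.TYPE)
        if code not in TYPE_CODES:
            raise ValidationError(f"{source}, row {line}: unknown TYPE {code!r}")
        dv = row.DV
        if float(dv) != int(dv):
            raise ValidationError(f"{source}, row {line}: non-integer score {dv!r}")
        dv = int(dv)
        if not 1 <= dv <= 9:
            raise ValidationError(f"{source}, row {line}: score {dv} outside 1..9")
        try:
            rec = ScoreRecord(
                subject_id=int(row.ID),
                occasion=int(row.OCC),
                solution=Solution(fat=float(row.FAT), sugar=float(row.SUGAR)),
                endpoint=TYPE_CODES[code],
                score=dv,
                presentation_order=int(row.ORDER),
            )
        except ValidationError as e:
            raise ValidationError(f"{source}, row {line}: {e}") from None
        records.append(rec)
    return records


def read_dataset(path, subjects_path=None) -> SFPTDataset:
    """Read a long-format score CSV (columns ID,OCC,ORDER,FAT,SUGAR,TYPE,DV).

    ``subjects_path`` optionally points to a subject table CSV with columns
    ID,SEX,BMI; without it subjects carry ids only.
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    records = _records_from_frame(df[CSV_COLUMNS], source=str(path))
    if subjects_path is not None:
        subjects = read_subjects(subjects_path)
    else:
        ids = sorted({r.subject_id for r in records})
        subjects = [Subject(id=i) for i in ids]
    ds = SFPTDataset(subjects=subjects, records=records)
    return ds


def write_dataset(dataset: SFPTDataset, path, subjects_path=None) -> None:
    df = dataset.to_frame()
    df.to_csv(path, index=False)
    if subjects_path is not None:
        write_subjects(dataset.subjects, subjects_path)


def read_subjects(path) -> list[Subject]:
    df = pd.read_csv(path)
    for c in ("ID", "SEX", "BMI"):
        if c not in df.columns:
            raise ValidationError(f"{path}: missing column {c}")
    return [
        Subject(id=int(r.ID), sex=str(r.SEX), bmi=float(r.BMI))
        for r in df.itertuples(index=False)
    ]


def write_subjects(subjects: Iterable[Subject], path) -> None:
    rows = [(s.id, s.sex, s.bmi, s.bmi_class) for s in subjects]
    pd.DataFrame(rows, columns=["ID", "SEX", "BMI", "BMI_CLASS"]).to_csv(path, index=False)


# --------------------------------------------------------------------------
# parameter sets
# --------------------------------------------------------------------------

def _cutpoint_names(prefix: str) -> list[str]:
    return [f"alpha_{prefix}1"] + [f"alpha_{prefix}{x}_{x + 1}" for x in range(2, 9)]


SWEET_CUTPOINTS = _cutpoint_names("S")
CREAM_CUTPOINTS = _cutpoint_names("C")
PLEAS_CUTPOINTS = _cutpoint_names("P")

SWEET_PARAMS = SWEET_CUTPOINTS + ["Smax_Sugar", "SSugar50", "SL_S_Fat", "omega2_S", "omega2_Smax"]
CREAM_PARAMS = CREAM_CUTPOINTS + ["SL_C_Fat", "SL_C_Sugar", "omega2_C"]

#: the six pleasantness link parameters, per driver variant
PLEAS_LINK_AMOUNTS = ["Pmax_Sugar", "PSugar50", "Pmax_Fat", "PFat50", "IP_Sugar_Fat", "wIP_Sugar"]
PLEAS_LINK_LINKED = ["Pmax_Sweet", "PSweet50", "Pmax_Cream", "PCream50", "IP_Sweet_Cream", "wIP_Sweet"]

BETA_PARAMS = ["beta_Sugar5", "beta_Fat3", "beta_Fat4", "beta_Fat7"]
IOV_PARAMS = ["pi2_S", "pi2_C", "pi2_P"]


def pleasantness_link_names(variant: str) -> list[str]:
    if variant == "amounts":
        return list(PLEAS_LINK_AMOUNTS)
    if variant in ("linked", "observed_scores", "score_link"):
        return list(PLEAS_LINK_LINKED)
    raise ValidationError(f"unknown variant {variant!r}")


def pleasantness_params(variant: str) -> list[str]:
    return PLEAS_CUTPOINTS + pleasantness_link_names(variant) + BETA_PARAMS + ["omega2_P"]


def parameter_names(variant: str, iov: bool = False) -> list[str]:
    names = SWEET_PARAMS + CREAM_PARAMS + pleasantness_params(variant)
    if iov:
        names += IOV_PARAMS
    return names


def _is_variance(name: str) -> bool:
    return name.startswith("omega2_") or name.startswith("pi2_")


def _is_halfmax(name: str) -> bool:
    return name.endswith("50")


def _is_increment(name: str) -> bool:
    return name.startswith("alpha_") and "_" in name[6:]


@dataclass
class ParameterSet(Mapping):
    """Named fixed effects and variances for the three endpoint submodels.

    ``variant`` selects which pleasantness driver the link parameters refer
    to: ``amounts`` (sugar and fat content) or ``linked`` (individual
    predicted odds of sweetness/creaminess scores > 1; also used by the
    ``observed_scores`` and ``score_link`` exploratory drivers).
    ``rse_percent`` is optional metadata (relative standard errors).
    """

    variant: str
    values: dict[str, float]
    rse_percent: Optional[dict[str, float]] = None
    validate_increments: bool = False

    def __post_init__(self):
        self.values = {k: float(v) for k, v in self.values.items()}
        self.validate()

    # Mapping interface
    def __getitem__(self, key):
        return self.values[key]

    def __iter__(self):
        return iter(self.values)

    def __len__(self):
        return len(self.values)

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown variant {self.variant!r}")
        required = set(parameter_names(self.variant))
        allowed = required | set(IOV_PARAMS)
        got = set(self.values)
        if got - allowed:
            raise ValidationError(f"unknown parameter(s): {sorted(got - allowed)}")
        if required - got:
            raise ValidationError(f"missing parameter(s): {sorted(required - got)}")
        for name, v in self.values.items():
            if not np.isfinite(v):
                raise ValidationError(f"{name} is not finite: {v}")
            if _is_variance(name) and v < 0:
                raise ValidationError(f"variance {name} must be >= 0, got {v}")
            if _is_halfmax(name) and v <= 0:
                raise ValidationError(f"half-max constant {name} must be > 0, got {v}")
            if self.validate_increments and _is_increment(name) and v > 0:
                raise ValidationError(f"cutpoint increment {name} must be <= 0, got {v}")

    def replace(self, **updates) -> "ParameterSet":
        vals = dict(self.values)
        vals.update(updates)
        return ParameterSet(self.variant, vals, rse_percent=self.rse_percent)

    def with_variant(self, variant: str) -> "ParameterSet":
        """Re-label the link parameters for another driver variant.

        The linked, observed-scores and score-link variants share parameter
        names; translating to/from the amounts variant maps positionally
        (Pmax_Sugar <-> Pmax_Sweet, ...).
        """
        if variant == self.variant:
            return ParameterSet(variant, dict(self.values), rse_percent=self.rse_percent)
        src = pleasantness_link_names(self.variant)
        dst = pleasantness_link_names(variant)
        vals = {}
        for k, v in self.values.items():
            vals[dst[src.index(k)] if k in src else k] = v
        return ParameterSet(variant, vals)

    # serialization ---------------------------------------------------------
    def to_dict(self) -> dict:
        out = {"schema_version": SCHEMA_VERSION, "variant": self.variant,
               "parameters": dict(self.values)}
        if self.rse_percent is not None:
            out["rse_percent"] = dict(self.rse_percent)
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        d = dict(d)
        if "schema_version" not in d:
            raise ValidationError("parameter file missing 'schema_version'")
        if int(d.pop("schema_version")) != SCHEMA_VERSION:
            raise ValidationError("unsupported schema_version")
        variant = d.pop("variant", None)
        params = d.pop("parameters", None)
        rse = d.pop("rse_percent", None)
        if d:
            raise ValidationError(f"unknown key(s) in parameter file: {sorted(d)}")
        if variant is None or params is None:
            raise ValidationError("parameter file must contain 'variant' and 'parameters'")
        return cls(variant=variant, values=dict(params), rse_percent=rse)


def write_parameters(params: ParameterSet, path) -> None:
    path = Path(path)
    d = params.to_dict()
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=1) + "\n")


def read_parameters(path) -> ParameterSet:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        d = yaml.safe_load(text)
    else:
        d = json.loads(text)
    if not isinstance(d, dict):
        raise ValidationError(f"{path}: not a mapping")
    try:
        return ParameterSet.from_dict(d)
    except ValidationError as e:
        raise ValidationError(f"{path}: {e}") from None


def load_reference_parameters(column: str) -> ParameterSet:
    """Load one of the two packaged reference estimate sets.

    ``column`` is ``"amounts"`` (model driven by sugar/fat content) or
    ``"odds"`` (linked model driven by individual predicted odds).
    """
    fname = {"amounts": "reference_amounts.json", "odds": "reference_odds.json"}
    if column not in fname:
        raise ValidationError(f"column must be 'amounts' or 'odds', got {column!r}")
    with resources.files("ordlink.params").joinpath(fname[column]).open() as fh:
        return ParameterSet.from_dict(json.load(fh))
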