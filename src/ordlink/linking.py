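"""Approaches for joining the sweetness/creaminess submodels to pleasantness.

Three estimation strategies, mirroring simultaneous vs. sequential
population PK/PD fitting:

- SIM: one joint fit; all submodel parameters share the likelihood and the
  per-subject random-effect vector spans all endpoints.
- PPP&D (population parameters and data): sweetness/creaminess population
  parameters are fixed at stage-1 estimates, but their data stay in the
  joint likelihood, so the driver random effects remain informed by their
  own scores while the pleasantness parameters are estimated.
- IPP (individual parameters): stage-1 empirical Bayes estimates give each
  subject fixed predicted odds of sweetness/creaminess > 1, written into
  the dataset as covariates; pleasantness is then fit alone with a single
  random effect.

The operative distinction: in SIM and PPP&D the odds driving pleasantness
are recomputed from the current random-effect values inside every
conditional-density evaluation; in IPP they are frozen covariates.  IPP
therefore does not propagate stage-1 uncertainty into its standard errors
(its known limitation).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import model as m
from .data import (
    CREAM_PARAMS,
    SWEET_PARAMS,
    ParameterSet,
    SFPTDataset,
    Solution,
    ValidationError,
    pleasantness_link_names,
    pleasantness_params,
)
from .estimate import (
    FitResult,
    ModelSpec,
    compute_ebes,
    fit as _fit,
)

IPP_COVARIATE_COLUMNS = ["ID", "OCC", "SUGAR", "FAT", "ODDS_SWEET", "ODDS_CREAM"]


@dataclass
class LinkedFitReport:
    """One approach's outcome, with the pleasantness-parameter comparison table."""

    approach: str
    stage1: Optional[Union[FitResult, ParameterSet]]
    fit: FitResult
    pleasantness_table: pd.DataFrame


def _endpoints_present(dataset: SFPTDataset) -> set[str]:
    return {r.endpoint for r in dataset.records}


def _pleasantness_table(fit: FitResult, approach: str) -> pd.DataFrame:
    names = pleasantness_link_names(fit.params.variant)
    rows = [{
        "approach": approach,
        "parameter": n,
        "estimate": fit.params[n],
        "se": (fit.se or {}).get(n, np.nan),
    } for n in names]
    return pd.DataFrame(rows)


def _stage1_values(stage1) -> ParameterSet:
    if isinstance(stage1, FitResult):
        if not stage1.converged:
            warnings.warn("stage-1 fit did not converge; proceeding with its best-found values")
        return stage1.params
    return stage1


def fit_stage1(dataset: SFPTDataset, start: ParameterSet,
               free: Optional[Sequence[str]] = None, **fit_kwargs) -> FitResult:
    """Joint sweetness + creaminess fit (stage 1 of the sequential approaches).

    The two submodels share no parameters, so the joint fit equals two
    separate fits; done jointly for a single code path.
    """
    spec = ModelSpec(endpoints=("sweetness", "creaminess"), variant=start.variant)
    if free is None:
        free = SWEET_PARAMS + CREAM_PARAMS
    fit_kwargs.setdefault("compute_se", False)
    return _fit(dataset, spec, start, free=list(free), **fit_kwargs)


def fit_sim(dataset: SFPTDataset, start: ParameterSet,
            free: Optional[Sequence[str]] = None, **fit_kwargs) -> LinkedFitReport:
    """Simultaneous approach: all endpoint parameters estimated jointly.

    If the dataset carries no pleasantness records the fit degrades to the
    joint two-submodel fit with the pleasantness parameters masked.
    """
    present = _endpoints_present(dataset)
    if not {"sweetness", "creaminess"} <= present:
        raise ValidationError(f"SIM requires sweetness and creaminess data; found {sorted(present)}")
    endpoints = tuple(e for e in ("sweetness", "creaminess", "pleasantness") if e in present)
    spec = ModelSpec(endpoints=endpoints, variant=start.variant, driver="eta")
    result = _fit(dataset, spec, start, free=free, **fit_kwargs)
    return LinkedFitReport(approach="SIM", stage1=None, fit=result,
                           pleasantness_table=_pleasantness_table(result, "SIM"))


def fit_pppd(dataset: SFPTDataset, stage1_params, free: Optional[Sequence[str]] = None,
             **fit_kwargs) -> LinkedFitReport:
    """PPP&D: driver population parameters fixed, driver data retained.

    Only pleasantness parameters are estimated, but the joint likelihood
    still spans all three endpoints so the sweetness/creaminess random
    effects stay informed by their own scores.
    """
    values = _stage1_values(stage1_params)
    spec = ModelSpec(endpoints=("sweetness", "creaminess", "pleasantness"),
                     variant=values.variant, driver="eta")
    fixed = {n: values[n] for n in SWEET_PARAMS + CREAM_PARAMS}
    if free is None:
        free = pleasantness_params(values.variant)
    result = _fit(dataset, spec, values, free=list(free), fixed=fixed, **fit_kwargs)
    return LinkedFitReport(approach="PPP&D", stage1=stage1_params, fit=result,
                           pleasantness_table=_pleasantness_table(result, "PPP&D"))


def ipp_covariate_table(dataset: SFPTDataset, stage1_params) -> pd.DataFrame:
    """Per-record individual odds of sweetness/creaminess > 1 from stage-1 EBEs.

    The empirical Bayes modes are computed from the sweetness and creaminess
    data only; the resulting odds are the frozen covariates of the IPP
    stage-2 fit.
    """
    values = _stage1_values(stage1_params)
    stage1_spec = ModelSpec(endpoints=("sweetness", "creaminess"), variant=values.variant)
    ebes = {e.subject_id: e.eta for e in compute_ebes(dataset, values, stage1_spec)}
    driver_subjects = {r.subject_id for r in dataset.records
                       if r.endpoint in ("sweetness", "creaminess")}
    rows = []
    seen = set()
    for r in dataset.records:
        if r.endpoint != "pleasantness":
            continue
        if r.subject_id not in driver_subjects:
            raise ValidationError(
                f"subject {r.subject_id} has pleasantness data but no stage-1 "
                "sweetness/creaminess data; no individual odds available")
        key = (r.subject_id, r.occasion, r.solution.sugar, r.solution.fat)
        if key in seen:
            continue
        seen.add(key)
        eta = ebes[r.subject_id]
        rev = m.RandomEffectVector(eta_S_base=eta.get("eta_S_base", 0.0),
                                   eta_Smax=eta.get("eta_Smax", 0.0),
                                   eta_C_base=eta.get("eta_C_base", 0.0))
        odds_s = float(m.individual_odds("sweetness", r.solution, values, rev))
        odds_c = float(m.individual_odds("creaminess", r.solution, values, rev))
        rows.append(dict(zip(IPP_COVARIATE_COLUMNS,
                             [r.subject_id, r.occasion, r.solution.sugar, r.solution.fat,
                              odds_s, odds_c])))
    return pd.DataFrame(rows, columns=IPP_COVARIATE_COLUMNS)


def fit_ipp(dataset: SFPTDataset, stage1_params, free: Optional[Sequence[str]] = None,
            ipp_covariates: Optional[pd.DataFrame] = None, **fit_kwargs) -> LinkedFitReport:
    """IPP: stage-1 individual predictions frozen as covariates.

    Stage 2 fits pleasantness alone with a one-dimensional random effect,
    treating the per-record odds as known quantities.
    """
    values = _stage1_values(stage1_params)
    if ipp_covariates is None:
        ipp_covariates = ipp_covariate_table(dataset, stage1_params)
    spec = ModelSpec(endpoints=("pleasantness",), variant=values.variant, driver="covariate")
    if free is None:
        free = pleasantness_params(values.variant)
    result = _fit(dataset, spec, values, free=list(free),
                  ipp_covariates=ipp_covariates, **fit_kwargs)
    return LinkedFitReport(approach="IPP", stage1=stage1_params, fit=result,
                           pleasantness_table=_pleasantness_table(result, "IPP"))


def compare_approaches(dataset: SFPTDataset, start: ParameterSet,
                       free: Optional[Sequence[str]] = None,
                       stage1_params: Optional[ParameterSet] = None,
                       **fit_kwargs):
    """Run SIM, PPP&D and IPP and tabulate the pleasantness link parameters.

    Returns ``(reports, table)``: a dict of :class:`LinkedFitReport` (or the
    exception an approach raised -- member failures do not abort the
    others) and a tidy frame (approach, parameter, estimate, se).  ``free``
    restricts the *pleasantness* parameters estimated; SIM additionally
    frees the driver submodel parameters, which is what distinguishes it
    from PPP&D.
    """
    fit_kwargs.setdefault("compute_se", True)
    if stage1_params is None:
        stage1 = fit_stage1(dataset, start)
        stage1_values = stage1.params
    else:
        stage1 = stage1_values = stage1_params
    pleas_free = list(free) if free is not None else pleasantness_params(start.variant)
    sim_free = SWEET_PARAMS + CREAM_PARAMS + pleas_free

    reports: dict[str, Union[LinkedFitReport, Exception]] = {}
    runners = {
        "SIM": lambda: fit_sim(dataset, start, free=sim_free, **fit_kwargs),
        "PPP&D": lambda: fit_pppd(dataset, stage1_values, free=pleas_free, **fit_kwargs),
        "IPP": lambda: fit_ipp(dataset, stage1_values, free=pleas_free, **fit_kwargs),
    }
    for name, run in runners.items():
        try:
            reports[name] = run()
        except Exception as exc:  # propagate per-approach, don't abort the rest
            warnings.warn(f"{name} approach failed: {exc}")
            reports[name] = exc
    tables = [r.pleasantness_table for r in reports.values() if isinstance(r, LinkedFitReport)]
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(
        columns=["approach", "parameter", "estimate", "se"])
    return reports, table


def write_ipp_covariates(table: pd.DataFrame, path) -> None:
    # shortest round-trippable float representation, so re-reading the file
    # reproduces the stage-2 likelihood bit-exactly
    table.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_ipp_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in IPP_COVARIATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    return df
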