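"""Visual predictive checks and parameter reporting for categorical scores.

A categorical VPC simulates many replicates of the study on the *realized*
design (same subjects, occasions and solutions as the observed dataset,
fresh random effects and scores each replicate), then compares observed
per-category incidence proportions with the simulation's 95% interval,
binned by the design levels of sugar or fat.
"""
from __future__ import annotations

from typing import Optional

import numpy as np
import pandas as pd

from .data import (
    CREAM_CUTPOINTS,
    PLEAS_CUTPOINTS,
    SWEET_CUTPOINTS,
    ParameterSet,
    SFPTDataset,
    ValidationError,
    pleasantness_link_names,
)
from .estimate import (
    DataBundle,
    FitResult,
    ModelSpec,
    compile_bundle,
    re_layout,
    record_probabilities,
)

VPC_COLUMNS = ["endpoint", "bin_var", "bin_value", "category",
               "observed", "sim_median", "sim_lo", "sim_hi", "n_replicates"]


def _bin_proportions(scores: np.ndarray, bin_masks: list[np.ndarray]) -> np.ndarray:
    """(n_bins, 9) incidence proportions of scores 1..9 within each bin."""
    out = np.empty((len(bin_masks), 9))
    for i, mask in enumerate(bin_masks):
        vals = scores[mask]
        out[i] = np.bincount(vals - 1, minlength=9) / len(vals)
    return out


def run_vpc(dataset: SFPTDataset, params: ParameterSet, spec: ModelSpec,
            n_replicates: int = 1000, seed: int = 0,
            bin_vars: tuple[str, ...] = ("sugar", "fat")) -> pd.DataFrame:
    """Simulate ``n_replicates`` studies on the realized design and tabulate
    observed vs. simulated per-category incidence proportions.

    Random effects are resampled fresh from the population distributions
    each replicate (a population VPC, not conditioned on the EBEs).  The
    95% band uses empirical 2.5/97.5 percentiles (linear interpolation)
    across replicates.
    """
    if not dataset.records:
        raise ValidationError("empty dataset")
    sim_spec = ModelSpec(endpoints=spec.endpoints, variant=spec.variant, driver="eta",
                         iov=spec.iov, re_form=spec.re_form)
    bundle = compile_bundle(dataset, sim_spec)
    layout = re_layout(sim_spec, params, len(bundle.occasions))
    sd = np.array([np.sqrt(params[d.var_param]) for d in layout])
    rng = np.random.default_rng(seed)

    # bin masks on the realized design, per endpoint and binning variable
    bins: dict[tuple[str, str], tuple[list[float], list[np.ndarray]]] = {}
    for e in sim_spec.endpoints:
        b = bundle.blocks[e]
        for var in bin_vars:
            cov = getattr(b, var)
            values = sorted(np.unique(cov[b.mask]).tolist())
            masks = [(cov == v) & b.mask for v in values]
            bins[(e, var)] = (values, masks)

    observed = {key: _bin_proportions(bundle.blocks[key[0]].score, masks)
                for key, (_, masks) in bins.items()}

    sims = {key: np.empty((n_replicates, len(vals), 9)) for key, (vals, _) in bins.items()}
    S = bundle.n_subjects
    for r in range(n_replicates):
        E = rng.standard_normal((S, len(layout))) * sd
        probs = record_probabilities(bundle, params, sim_spec, E)
        for e in sim_spec.endpoints:
            p = probs[e]
            u = rng.random(p.shape[:-1])
            scores = (u[..., None] > p.cumsum(axis=-1)).sum(axis=-1) + 1
            for var in bin_vars:
                _, masks = bins[(e, var)]
                sims[(e, var)][r] = _bin_proportions(scores, masks)

    rows = []
    for (e, var), (values, _) in bins.items():
        sim = sims[(e, var)]
        lo, med, hi = np.percentile(sim, [2.5, 50.0, 97.5], axis=0)
        obs = observed[(e, var)]
        for i, v in enumerate(values):
            for k in range(9):
                rows.append({
                    "endpoint": e, "bin_var": var, "bin_value": v, "category": k + 1,
                    "observed": obs[i, k], "sim_median": med[i, k],
                    "sim_lo": lo[i, k], "sim_hi": hi[i, k], "n_replicates": n_replicates,
                })
    return pd.DataFrame(rows, columns=VPC_COLUMNS)


def render_vpc(table: pd.DataFrame, path) -> None:
    """Draw the VPC panel grid: one row per (endpoint, binning variable),
    one panel per bin, observed proportions as lines over shaded 95% bands."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    groups = list(table.groupby(["endpoint", "bin_var"], sort=True))
    n_bins = table.groupby(["endpoint", "bin_var"])["bin_value"].nunique().max()
    fig, axes = plt.subplots(len(groups), int(n_bins),
                             figsize=(3.0 * n_bins, 2.4 * len(groups)),
                             squeeze=False, sharey=True)
    for row, ((endpoint, bin_var), sub) in enumerate(groups):
        for col, (bv, cell) in enumerate(sub.groupby("bin_value", sort=True)):
            ax = axes[row][col]
            cell = cell.sort_values("category")
            k = cell["category"].to_numpy()
            ax.fill_between(k, cell["sim_lo"], cell["sim_hi"], alpha=0.3, color="C0", lw=0)
            ax.plot(k, cell["sim_median"], color="C0", lw=1, ls="--")
            ax.plot(k, cell["observed"], color="C3", lw=1.5)
            ax.set_title(f"{endpoint}, {bin_var}={bv:g}", fontsize=8)
            ax.set_xticks([1, 5, 9])
        axes[row][0].set_ylabel("proportion", fontsize=8)
    for ax in axes[-1]:
        ax.set_xlabel("score", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": None} if str(path).endswith(".png") else None)
    plt.close(fig)


def plot_approaches(table: pd.DataFrame, path) -> None:
    """Forest-style view of the approach comparison: one panel per
    pleasantness parameter, estimate +/- SE per approach."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    params = list(dict.fromkeys(table["parameter"]))
    approaches = list(dict.fromkeys(table["approach"]))
    fig, axes = plt.subplots(1, len(params), figsize=(2.2 * len(params), 3.0), squeeze=False)
    for col, name in enumerate(params):
        ax = axes[0][col]
        sub = table[table.parameter == name]
        for i, a in enumerate(approaches):
            row = sub[sub.approach == a]
            if row.empty:
                continue
            est = float(row.estimate.iloc[0])
            se = float(row.se.iloc[0]) if np.isfinite(row.se.iloc[0]) else 0.0
            ax.errorbar([est], [i], xerr=[se], fmt="o", color=f"C{i}", capsize=3)
        ax.set_yticks(range(len(approaches)))
        ax.set_yticklabels(approaches if col == 0 else [""] * len(approaches), fontsize=8)
        ax.set_title(name, fontsize=8)
        ax.invert_yaxis()
    fig.tight_layout()
    fig.savefig(path, dpi=100, metadata={"Software": None} if str(path).endswith(".png") else None)
    plt.close(fig)


#: row order of the published parameter table
_REPORT_ORDER = (
    SWEET_CUTPOINTS + ["Smax_Sugar", "SSugar50", "SL_S_Fat"]
    + CREAM_CUTPOINTS + ["SL_C_Fat", "SL_C_Sugar"]
    + PLEAS_CUTPOINTS
)


def _report_rows(params: ParameterSet) -> list[str]:
    return (_REPORT_ORDER
            + pleasantness_link_names(params.variant)
            + ["beta_Sugar5", "beta_Fat3", "beta_Fat4", "beta_Fat7"]
            + ["omega2_S", "omega2_C", "omega2_P", "omega2_Smax"])


def parameter_report(fit: FitResult) -> str:
    """Plain-text estimate/RSE% table in the published row order.

    RSE% = 100 * SE / |estimate|; the column is blank where no standard
    error is available (fixed parameters, or an uninvertible Hessian).
    """
    rse = fit.rse_percent or {}
    lines = [f"{'Parameter':<16}{'Estimate':>12}  {'RSE (%)':>8}",
             "-" * 38]
    for name in _report_rows(fit.params):
        if name not in fit.params.values:
            continue
        est = fit.params[name]
        r = f"{rse[name]:.3g}" if name in rse else ""
        lines.append(f"{name:<16}{est:>12.4g}  {r:>8}")
    return "\n".join(lines)
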