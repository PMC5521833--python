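"""End-to-end analysis plan: QC -> derived phenotypes -> eight path models
(four fatty-acid exposures x SBP/DBP) -> effect decomposition -> FDR ->
reports, plus the weight-status-stratified EPA analysis.

Each model relates the additive rs174546 genotype, one focal fatty-acid
exposure (DGLA, ARA, EPA or the D5D index), BMI z-score and one BP z-score
through the recursive system

    SNP -> FA,  SNP -> BMI,  FA -> BMI,  SNP -> BP,  FA -> BP,  BMI -> BP.

Reports mirror the published table layout: standardized direct effects,
per-path and total indirect effects with delta-method p-values, and
Benjamini-Hochberg FDR flags per outcome family.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import mediation, phenotypes, sem

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisPlan",
    "core_model_spec",
    "run_plan",
    "run_stratified",
    "qc_report",
]

EXPOSURES = ("DGLA", "ARA", "EPA", "D5D")
OUTCOMES = ("SBP", "DBP")
MODEL_IDS = {
    ("DGLA", "SBP"): "1a", ("ARA", "SBP"): "2a", ("EPA", "SBP"): "3a",
    ("D5D", "SBP"): "4a", ("DGLA", "DBP"): "1b", ("ARA", "DBP"): "2b",
    ("EPA", "DBP"): "3b", ("D5D", "DBP"): "4b",
}
MODEL_IDS_INV = {m: pair for pair, m in MODEL_IDS.items()}


def core_model_spec(
    exposure: str, outcome: str, covariates: tuple[str, ...] = ()
) -> sem.PathModelSpec:
    """The six-edge core model for one exposure/outcome pair.

    ``covariates`` are additional exogenous variables given edges into
    every endogenous variable (fish-consumption frequency is included for
    the EPA models by the plan, not here).
    """
    variables = ["SNP", exposure, "BMI", outcome, *covariates]
    edges = [
        ("SNP", exposure),
        ("SNP", "BMI"),
        (exposure, "BMI"),
        ("SNP", outcome),
        (exposure, outcome),
        ("BMI", outcome),
    ]
    for cov in covariates:
        edges += [(cov, exposure), (cov, "BMI"), (cov, outcome)]
    return sem.PathModelSpec(variables=tuple(variables), edges=tuple(edges))


@dataclass
class AnalysisPlan:
    """Which models to run and how to adjust for multiplicity."""

    outcomes: tuple[str, ...] = OUTCOMES
    exposures: tuple[str, ...] = EXPOSURES
    covariates: dict[str, tuple[str, ...]] = field(default_factory=dict)
    fish_covariate: str | None = None  # added to every EPA model when present
    fdr_q: float = 0.05
    stratum_var: str = "weight_status"

    def model_specs(self) -> dict[str, sem.PathModelSpec]:
        specs = {}
        for outcome in self.outcomes:
            for exposure in self.exposures:
                if exposure not in EXPOSURES:
                    raise ValueError(f"unknown exposure {exposure!r}")
                if outcome not in OUTCOMES:
                    raise ValueError(f"unknown outcome {outcome!r}")
                covs = tuple(self.covariates.get(exposure, ()))
                if exposure == "EPA" and self.fish_covariate:
                    covs = covs + (self.fish_covariate,)
                mid = MODEL_IDS[(exposure, outcome)]
                specs[mid] = core_model_spec(exposure, outcome, covs)
        return specs


def _decomposition_rows(fitted, model_id, exposure, outcome):
    """Direct + indirect effect rows, with delta-method inference."""
    rows = []
    std = fitted.std_solution
    table = fitted.parameter_table()
    for _, r in table.iterrows():
        s, t = r["parameter"].split("->")
        rows.append(
            {
                "model": model_id,
                "source": s,
                "target": t,
                "effect_type": "direct",
                "path": r["parameter"],
                "estimate": r["standardized"],
                "p": r["p"],
            }
        )
    for source, target in [
        ("SNP", "BMI"),
        ("SNP", outcome),
        (exposure, outcome),
    ]:
        dec = mediation.decompose(fitted, source, target)
        inf = mediation.indirect_se(fitted, source, target, which="total_indirect")
        rows.append(
            {
                "model": model_id,
                "source": source,
                "target": target,
                "effect_type": "indirect_total",
                "path": "(all mediated)",
                "estimate": dec.total_indirect,
                "p": inf["p"],
                "se": inf["se"],
            }
        )
        tot = mediation.indirect_se(fitted, source, target, which="total")
        rows.append(
            {
                "model": model_id,
                "source": source,
                "target": target,
                "effect_type": "total",
                "path": "(direct + mediated)",
                "estimate": dec.total,
                "p": tot["p"],
                "se": tot["se"],
            }
        )
    return rows


def run_plan(cohort: pd.DataFrame, plan: AnalysisPlan | None = None) -> dict:
    """Fit every model of the plan and assemble the report bundle.

    Returns a dict with per-model fit indices and effect tables plus the
    per-outcome FDR families over the reported effects.  A non-converged
    model is flagged and recorded but does not abort the run; the bundle's
    ``ok`` flag goes False.
    """
    plan = plan or AnalysisPlan()
    specs = plan.model_specs()
    bundle = {"models": {}, "fdr": {}, "ok": True}
    all_rows: list[dict] = []
    for model_id, spec in specs.items():
        exposure, outcome = MODEL_IDS_INV[model_id]
        fitted = sem.fit(spec, cohort.dropna(subset=list(spec.variables)))
        logger.info(
            "model %s: n=%d iter=%d f_min=%.3e converged=%s",
            model_id, fitted.n, fitted.n_iter, fitted.f_min, fitted.converged,
        )
        entry = {"n": fitted.n, "converged": fitted.converged}
        if fitted.converged:
            fi = sem.fit_indices(fitted)
            entry["fit_indices"] = {
                "chi2": fi.chi2, "df": fi.df, "p": fi.p_chi2,
                "cfi": fi.cfi, "rmsea": fi.rmsea, "pass": fi.all_pass,
                "saturated": fi.saturated,
            }
            rows = _decomposition_rows(fitted, model_id, exposure, outcome)
            entry["effects"] = rows
            all_rows.extend(rows)
        else:
            bundle["ok"] = False
            logger.warning("model %s did not converge", model_id)
        bundle["models"][model_id] = entry

    for outcome in plan.outcomes:
        fam = {
            f"{r['model']}:{r['effect_type']}:{r['path']}": r["p"]
            for r in all_rows
            if r["target"] == outcome and np.isfinite(r.get("p", np.nan))
        }
        if not fam:
            continue
        res = mediation.bh_fdr(fam, q=plan.fdr_q)
        bundle["fdr"][outcome] = {
            "alpha_adj": res.alpha_adj,
            "rejected": sorted(res.rejected),
        }
        for r in all_rows:
            key = f"{r['model']}:{r['effect_type']}:{r['path']}"
            if r["target"] == outcome:
                r["fdr_significant"] = key in res.rejected
    return bundle


def run_stratified(
    cohort: pd.DataFrame,
    exposure: str = "EPA",
    stratum: str = "weight_status",
    outcomes: tuple[str, ...] = OUTCOMES,
) -> dict:
    """Per-stratum EPA -> BMI -> BP analysis (effect modification check).

    Fits the three-variable path model (exposure -> BMI, exposure -> BP,
    BMI -> BP) separately within each of the two strata and, as a pooled
    alternative, a model with a centered exposure x stratum product term.
    """
    if stratum not in cohort.columns:
        raise KeyError(f"stratum variable {stratum!r} not in cohort")
    levels = [lv for lv in pd.unique(cohort[stratum]) if not pd.isna(lv)]
    if len(levels) < 2:
        raise ValueError("stratified analysis needs two strata in the cohort")
    report: dict = {"strata": {}, "interaction": {}}
    for outcome in outcomes:
        spec = sem.PathModelSpec(
            variables=(exposure, "BMI", outcome),
            edges=((exposure, "BMI"), (exposure, outcome), ("BMI", outcome)),
        )
        for lv in levels:
            sub = cohort[cohort[stratum] == lv].dropna(
                subset=[exposure, "BMI", outcome]
            )
            if len(sub) <= 3:
                report["strata"].setdefault(str(lv), {})[outcome] = {"flag": "too few subjects"}
                continue
            fitted = sem.fit(spec, sub)
            dec = mediation.decompose(fitted, exposure, outcome)
            inf = mediation.indirect_se(fitted, exposure, outcome)
            report["strata"].setdefault(str(lv), {})[outcome] = {
                "n": fitted.n,
                "direct_on_bmi": fitted.std_solution[(exposure, "BMI")],
                "direct_on_bp": fitted.std_solution[(exposure, outcome)],
                "bmi_on_bp": fitted.std_solution[("BMI", outcome)],
                "indirect_via_bmi": dec.total_indirect,
                "indirect_p": inf["p"],
                "converged": fitted.converged,
            }
        # pooled interaction variant: centered exposure x stratum indicator
        ind = (cohort[stratum] == levels[1]).astype(float)
        centered = cohort[exposure] - cohort[exposure].mean()
        pooled = cohort.assign(
            _stratum_ind=ind, _interaction=centered * ind
        ).dropna(subset=[exposure, "BMI", outcome])
        ispec = sem.PathModelSpec(
            variables=(exposure, "_stratum_ind", "_interaction", "BMI", outcome),
            edges=(
                (exposure, "BMI"),
                ("_stratum_ind", "BMI"),
                ("_interaction", "BMI"),
                (exposure, outcome),
                ("_stratum_ind", outcome),
                ("_interaction", outcome),
                ("BMI", outcome),
            ),
        )
        ifit = sem.fit(ispec, pooled)
        report["interaction"][outcome] = {
            "epa_bmi_interaction_raw": ifit.coefficient("_interaction", "BMI"),
            "epa_bmi_interaction_std": ifit.std_solution[("_interaction", "BMI")],
            "converged": ifit.converged,
        }
    return report


def qc_report(
    cohort: pd.DataFrame,
    *,
    fasting_col: str = "fasting",
    bp_cols: tuple[str, ...] = ("SBP",),
    covariate_cols: tuple[str, ...] = (),
    genotype_col: str = "SNP",
) -> dict:
    """Exclusion ledger in the study's fixed order plus a genotype summary.

    Order: non-fasting -> missing BP -> missing covariates -> missing
    genotype.  Counts refer to subjects newly excluded at each step, so
    they sum to (input n - analyzed n).
    """
    n_in = len(cohort)
    remaining = cohort
    ledger = {}
    if fasting_col in remaining.columns:
        bad = remaining[fasting_col].fillna(1).astype(float) == 0
        ledger["non_fasting"] = int(bad.sum())
        remaining = remaining[~bad]
    else:
        ledger["non_fasting"] = 0
    present_bp = [c for c in bp_cols if c in remaining.columns]
    bad = remaining[present_bp].isna().any(axis=1) if present_bp else pd.Series(False, index=remaining.index)
    ledger["missing_bp"] = int(bad.sum())
    remaining = remaining[~bad]
    present_cov = [c for c in covariate_cols if c in remaining.columns]
    bad = remaining[present_cov].isna().any(axis=1) if present_cov else pd.Series(False, index=remaining.index)
    ledger["missing_covariates"] = int(bad.sum())
    remaining = remaining[~bad]
    if genotype_col in remaining.columns:
        bad = remaining[genotype_col].isna()
        ledger["missing_genotype"] = int(bad.sum())
        remaining = remaining[~bad]
    else:
        ledger["missing_genotype"] = 0
    for rule, count in ledger.items():
        if count:
            logger.warning("QC excluded %d subjects: %s", count, rule)
    report = {
        "n_input": n_in,
        "n_analyzed": len(remaining),
        "exclusions": ledger,
    }
    if genotype_col in cohort.columns and remaining[genotype_col].notna().any():
        gs = phenotypes.genotype_summary(remaining[genotype_col])
        report["genotype"] = {
            "counts": gs.counts,
            "maf": gs.maf,
            "hwe_chi2": gs.hwe_chi2,
            "hwe_p": gs.hwe_p,
            "hwe_exact_p": gs.hwe_exact_p,
        }
    return report


# ---------------------------------------------------------------------------
# report writers


def write_report(bundle: dict, out_dir, fmt: str = "tsv") -> list[Path]:
    """Write the run_plan bundle: rounded effect tables (3 dp, as printed
    conventionally) plus a full-precision JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    sidecar = out_dir / "report_full.json"
    with open(sidecar, "w") as fh:
        json.dump(bundle, fh, indent=2, default=_jsonable)
    written.append(sidecar)
    rows = [
        r
        for entry in bundle.get("models", {}).values()
        for r in entry.get("effects", [])
    ]
    if rows:
        table = pd.DataFrame(rows)
        table["estimate"] = table["estimate"].round(3)
        path = out_dir / ("effects.tsv" if fmt == "tsv" else "effects.json")
        if fmt == "tsv":
            table.to_csv(path, sep="\t", index=False)
        else:
            table.to_json(path, orient="records", indent=2)
        written.append(path)
    return written


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    raise TypeError(f"cannot serialize {type(obj)!r}")
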