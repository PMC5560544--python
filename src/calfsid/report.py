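"""End-to-end analysis pipeline over a cohort dataframe.

``run_report`` replicates the analysis order of the mortality study on
whatever cohort it is given (real or simulated): derive acid-base columns
→ rule-based classification → univariate odds-ratio table → decile
survival analysis → classification tree → backward-eliminated logistic
model on the tree's binary features → ROC/Youden evaluation → report
bundle (CSV/JSON files plus a plain-text run log).
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, acid_base, evaluation
from .errors import CalfsidError
from .prognosis import PH_RULE_CUTPOINT
from .regression import ContingencyTable, Term, backward_eliminate, odds_ratio
from .tree import CartModel, TreeControls

__all__ = ["derive_columns", "univariate_table", "run_report"]

#: ordinal/flag variables entering the univariate table (reference = first level)
UNIVARIATE_VARIABLES = [
    "suckling_reflex",
    "behavior",
    "posture",
    "enophthalmos",
    "body_condition",
    "hypothermia",
    "sirs",
    "abdominal_emergency",
    "cns_involvement",
    "orthopedic_problems",
    "clinical_septicemia",
    "bronchopneumonia",
    "navel_infection",
]

#: analytes shown as decile survival tables
DECILE_VARIABLES = ["ph", "na", "glucose", "ggt", "l_lactate", "urea"]

#: candidate predictors offered to the classification tree
TREE_FEATURES = [
    "abdominal_emergency",
    "cns_involvement",
    "orthopedic_problems",
    "body_condition",
    "posture",
    "behavior",
    "suckling_reflex",
    "bronchopneumonia",
    "ph",
    "na",
    "glucose",
    "ggt",
    "thrombocytes",
    "l_lactate",
    "d_lactate",
    "urea",
    "total_protein",
]


def derive_columns(df: pd.DataFrame) -> pd.DataFrame:
    """Append (or overwrite) the eight derived acid-base columns."""
    out = df.copy()
    out["hco3"] = acid_base.bicarbonate(out["ph"], out["pco2"])
    out["base_excess"] = acid_base.base_excess(out["ph"], out["hco3"], out["hemoglobin"])
    out["anion_gap"] = acid_base.anion_gap(out["na"], out["k"], out["cl"], out["hco3"])
    out["atot"] = acid_base.atot(out["total_protein"])
    out["a_minus"] = acid_base.a_minus(out["atot"], out["ph"])
    out["sid_m"] = acid_base.sid_measured(
        out["na"], out["k"], out["cl"], out["d_lactate"], out["l_lactate"]
    )
    out["sig"] = out["a_minus"] - out["anion_gap"]
    out["usi"] = acid_base.unidentified_strong_ions(
        out["sig"], out["d_lactate"], out["l_lactate"]
    )
    return out


def univariate_table(df: pd.DataFrame, outcome: str = "died_observed") -> pd.DataFrame:
    """Per-category univariate odds ratios against each variable's
    reference level, in the layout of the study's clinical-signs table."""
    work = df.copy()
    if "hypothermia" not in work.columns and "rectal_temp" in work.columns:
        work["hypothermia"] = (work["rectal_temp"] < 38.5).astype(float).where(
            work["rectal_temp"].notna()
        )
    rows = []
    y = work[outcome]
    for var in UNIVARIATE_VARIABLES:
        if var not in work.columns:
            continue
        v = work[var]
        ok = v.notna() & y.notna()
        levels = sorted(v[ok].unique())
        if len(levels) < 2:
            continue
        ref = levels[0]
        ref_events = int(((v == ref) & (y == 1) & ok).sum())
        ref_non = int(((v == ref) & (y == 0) & ok).sum())
        rows.append(
            {
                "variable": var,
                "category": ref,
                "n": ref_events + ref_non,
                "events": ref_events,
                "or": 1.0,
                "ci_low": np.nan,
                "ci_high": np.nan,
                "p_value": np.nan,
                "reference": True,
            }
        )
        for lev in levels[1:]:
            a = int(((v == lev) & (y == 1) & ok).sum())
            b = int(((v == lev) & (y == 0) & ok).sum())
            est = odds_ratio(ContingencyTable(a, b, ref_events, ref_non))
            rows.append(
                {
                    "variable": var,
                    "category": lev,
                    "n": a + b,
                    "events": a,
                    "or": est.or_point,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                    "p_value": est.p_value,
                    "reference": False,
                }
            )
    return pd.DataFrame(rows)


def run_report(
    cohort: pd.DataFrame,
    out_dir,
    seed: int = 0,
    outcome: str = "died_observed",
    tree_controls: TreeControls = TreeControls(),
    alpha: float = 0.01,
) -> dict:
    """Run the full pipeline and write the report bundle to ``out_dir``.

    Returns a dict of the in-memory results.  Stages that cannot run on a
    degenerate cohort (too few calves, one outcome class) are skipped with
    the reason recorded in the run log; the derivation stage always runs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"calfsid {__version__} on python {platform.python_version()}",
        f"seed = {seed}, n = {len(cohort)}, outcome column = {outcome!r}",
    ]
    results: dict = {}

    df = derive_columns(cohort)
    from .io import write_cohort

    write_cohort(df, out / "cohort_derived.csv")
    log.append("derived acid-base columns written to cohort_derived.csv")

    def guarded(stage, fn):
        try:
            fn()
        except (CalfsidError, ValueError) as exc:
            log.append(f"{stage}: skipped ({exc})")

    def _univariate():
        tab = univariate_table(df, outcome)
        if tab.empty:
            raise CalfsidError("no categorical variables with >= 2 levels")
        tab.to_csv(out / "univariate_odds_ratios.csv", index=False)
        results["univariate"] = tab
        log.append(f"univariate OR table: {tab['variable'].nunique()} variables")

    def _deciles():
        frames = []
        for var in DECILE_VARIABLES:
            if var not in df.columns or var not in evaluation.REFERENCE_INTERVALS:
                continue
            dt = evaluation.decile_survival(
                df[var], df[outcome], evaluation.REFERENCE_INTERVALS[var]
            )
            t = dt.table.copy()
            t.insert(0, "variable", var)
            t["reference_decile"] = dt.reference_decile
            frames.append(t)
        tab = pd.concat(frames, ignore_index=True)
        tab.to_csv(out / "decile_survival.csv", index=False)
        results["deciles"] = tab
        log.append(f"decile survival tables for {tab['variable'].nunique()} analytes")

    def _tree_and_logit():
        feats = [f for f in TREE_FEATURES if f in df.columns]
        res = CartModel(df, outcome, feats, tree_controls).fit(seed=seed)
        res.to_json(out / "classification_tree.json")
        res.flat_table().to_csv(out / "classification_tree_nodes.csv", index=False)
        results["tree"] = res
        log.append("tree: " + res.summary().splitlines()[0])
        predictors = res.extract_binary_predictors()
        if not predictors:
            raise CalfsidError("pruned tree is the root; no predictors to model")
        terms = [
            Term(p["name"], p["variable"], op=p["op"], threshold=p["threshold"])
            for p in predictors
        ]
        model = backward_eliminate(df, outcome, terms, alpha=alpha)
        model.to_json(out / "fitted_model.json")
        results["model"] = model
        log.append(
            f"logistic model: {len(model.terms)} terms retained of {len(terms)} "
            f"(backward Wald, alpha = {alpha})"
        )
        scores = model.predict(df.dropna(subset=[t.variable for t in model.terms] + [outcome]))
        labels = df.dropna(subset=[t.variable for t in model.terms] + [outcome])[outcome]
        roc = evaluation.roc_curve(scores, labels.astype(int))
        cut = evaluation.youden_optimal(roc)
        results["roc"] = roc
        results["cutpoint"] = cut
        log.append(
            f"model AUC = {roc.auc:.3f} (95% CI {roc.auc_ci[0]:.3f}-{roc.auc_ci[1]:.3f}); "
            f"Youden cutpoint {cut.threshold:.3f} "
            f"(sens {cut.sensitivity:.3f}, spec {cut.specificity:.3f})"
        )

    def _ph_rule():
        flags = (df["ph"] < PH_RULE_CUTPOINT).astype(float).where(df["ph"].notna())
        perf = evaluation.binary_rule_performance(flags, df[outcome])
        results["ph_rule"] = perf
        (out / "ph_rule_performance.json").write_text(json.dumps(perf, indent=2))
        log.append(
            f"pH < {PH_RULE_CUTPOINT} rule: sens {perf['sensitivity']:.3f}, "
            f"spec {perf['specificity']:.3f}"
        )

    guarded("univariate", _univariate)
    guarded("deciles", _deciles)
    guarded("tree/logit", _tree_and_logit)
    guarded("ph_rule", _ph_rule)

    (out / "run_log.txt").write_text("\n".join(log) + "\n")
    results["log"] = log
    return results
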