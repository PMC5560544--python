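"""Logistic mortality modelling and the univariate statistics around it.

The centre of the module is the ``LogisticModel`` artifact: an intercept
plus named terms, where each term is either a raw covariate (a 0/1 flag or
a continuous column) or a binary feature defined by a variable, a
comparison operator and a threshold ("ph < 6.85", "na >= 151").  The same
artifact serves three roles:

* the serializable output of a fit (coefficients, SEs, Wald p-values);
* the scoring function for published prognostic models;
* the outcome mechanism of the synthetic cohort generator.

Fitting follows the statsmodels Model/Results idiom: build a
``MortalityLogit`` from a dataframe, call ``fit()``, get a
``MortalityLogitResults`` with estimates, SEs, a ``summary()`` table and
``backward_eliminate()``.  Maximum-likelihood optimisation itself is
delegated to statsmodels' Logit; everything modelling-strategy-specific
(complete-case handling, separation detection, backward Wald selection,
Hosmer-Lemeshow grouping) lives here.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ModelSpecificationError, SeparationError, ValidationError

__all__ = [
    "Term",
    "LogisticModel",
    "MortalityLogit",
    "MortalityLogitResults",
    "ContingencyTable",
    "OddsRatioEstimate",
    "HosmerLemeshowResult",
    "odds_ratio",
    "fit_logistic",
    "backward_eliminate",
    "hosmer_lemeshow",
    "mann_whitney",
    "inverse_logit",
]

_OPS = {
    "lt": np.less,
    "le": np.less_equal,
    "gt": np.greater,
    "ge": np.greater_equal,
    "eq": np.equal,
}
_OP_SYMBOL = {"lt": "<", "le": "<=", "gt": ">", "ge": ">=", "eq": "=="}


def inverse_logit(x):
    """Numerically stable logistic function."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass(frozen=True)
class Term:
    """One model term: a named coefficient with its feature definition.

    ``op``/``threshold`` of None means the raw column is used as-is
    (continuous covariate or an already-binary flag); otherwise the
    feature is the indicator ``variable op threshold``.
    """

    name: str
    variable: str
    coefficient: float = 0.0
    se: Optional[float] = None
    p_value: Optional[float] = None
    op: Optional[str] = None
    threshold: Optional[float] = None

    def __post_init__(self):
        if self.op is not None and self.op not in _OPS:
            raise ModelSpecificationError(f"unknown operator {self.op!r} in term {self.name!r}")
        if (self.op is None) != (self.threshold is None):
            raise ModelSpecificationError(
                f"term {self.name!r}: op and threshold must be given together"
            )

    @property
    def definition(self) -> str:
        if self.op is None:
            return self.variable
        return f"{self.variable} {_OP_SYMBOL[self.op]} {self.threshold:g}"

    def feature(self, data) -> np.ndarray:
        """Evaluate the term's feature on a dataframe or record mapping.

        Missing inputs propagate as NaN — thresholded features are never
        silently imputed to 0.
        """
        if isinstance(data, pd.DataFrame):
            if self.variable not in data.columns:
                raise ModelSpecificationError(
                    f"term {self.name!r} needs column {self.variable!r}"
                )
            x = data[self.variable].to_numpy(dtype=float)
        else:
            if self.variable not in data or data[self.variable] is None:
                return np.array(np.nan)
            x = np.asarray(data[self.variable], dtype=float)
        if self.op is None:
            return x
        out = _OPS[self.op](x, self.threshold).astype(float)
        return np.where(np.isnan(x), np.nan, out)


@dataclass
class LogisticModel:
    """Intercept plus named terms; the serializable scoring artifact."""

    intercept: float
    terms: list[Term]
    intercept_se: Optional[float] = None
    n: Optional[int] = None
    log_likelihood: Optional[float] = None
    converged: bool = True
    metadata: dict = field(default_factory=dict)

    # -- scoring ---------------------------------------------------------
    def feature_matrix(self, data: pd.DataFrame) -> pd.DataFrame:
        return pd.DataFrame(
            {t.name: t.feature(data) for t in self.terms}, index=data.index
        )

    def linear_predictor(self, data: pd.DataFrame) -> np.ndarray:
        lp = np.full(len(data), self.intercept, dtype=float)
        for t in self.terms:
            lp += t.coefficient * t.feature(data)
        return lp

    def predict(self, data: pd.DataFrame) -> np.ndarray:
        return inverse_logit(self.linear_predictor(data))

    def predict_record(self, record: dict) -> float:
        lp = self.intercept
        for t in self.terms:
            f = float(t.feature(record))
            if math.isnan(f):
                raise ModelSpecificationError(
                    f"record is missing {t.variable!r} required by term {t.name!r}"
                )
            lp += t.coefficient * f
        return float(inverse_logit(lp))

    def odds_ratios(self, z: float = 1.96) -> pd.DataFrame:
        """Per-term OR with Wald 95% CI, mirroring the printed table layout."""
        rows = []
        for t in self.terms:
            or_ = math.exp(t.coefficient)
            lo = hi = float("nan")
            if t.se is not None:
                lo = math.exp(t.coefficient - z * t.se)
                hi = math.exp(t.coefficient + z * t.se)
            rows.append(
                {
                    "term": t.name,
                    "definition": t.definition,
                    "coefficient": t.coefficient,
                    "se": t.se,
                    "odds_ratio": or_,
                    "ci_low": lo,
                    "ci_high": hi,
                    "p_value": t.p_value,
                }
            )
        return pd.DataFrame(rows)

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "intercept_se": self.intercept_se,
            "terms": [
                {
                    "name": t.name,
                    "variable": t.variable,
                    "coefficient": t.coefficient,
                    "se": t.se,
                    "p_value": t.p_value,
                    "op": t.op,
                    "threshold": t.threshold,
                }
                for t in self.terms
            ],
            "n": self.n,
            "log_likelihood": self.log_likelihood,
            "converged": self.converged,
            "metadata": self.metadata,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogisticModel":
        return cls(
            intercept=d["intercept"],
            intercept_se=d.get("intercept_se"),
            terms=[Term(**t) for t in d["terms"]],
            n=d.get("n"),
            log_likelihood=d.get("log_likelihood"),
            converged=d.get("converged", True),
            metadata=d.get("metadata", {}),
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LogisticModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


# ---------------------------------------------------------------------------
# univariate odds ratios
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 exposure-outcome counts: a/b exposed with/without event, c/d unexposed."""

    a: float
    b: float
    c: float
    d: float

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValidationError("counts", "negative cell count")
        if self.a + self.b <= 0 or self.c + self.d <= 0:
            raise ValidationError("counts", "a row of the 2x2 table has zero total")


@dataclass(frozen=True)
class OddsRatioEstimate:
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float


def odds_ratio(table: ContingencyTable, z: float = 1.96) -> OddsRatioEstimate:
    """Odds ratio ad/bc with Wald 95% CI on the log scale.

    Any zero cell triggers the Haldane-Anscombe 0.5 correction of all four
    cells (with a warning); this is a guard for degenerate synthetic
    tables, not something the study's own counts exercise.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        warnings.warn("zero cell in 2x2 table; applying Haldane-Anscombe 0.5 correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    p = 2.0 * stats.norm.sf(abs(log_or) / se)
    return OddsRatioEstimate(
        or_point=math.exp(log_or),
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        p_value=float(p),
    )


# ---------------------------------------------------------------------------
# logistic fitting (Model/Results surface over statsmodels)
# ---------------------------------------------------------------------------

#: log-odds magnitude beyond which we declare perfect separation
SEPARATION_LIMIT = 15.0


def _as_terms(terms: Sequence) -> list[Term]:
    out = []
    for t in terms:
        if isinstance(t, Term):
            out.append(t)
        elif isinstance(t, str):
            out.append(Term(name=t, variable=t))
        else:
            raise ModelSpecificationError(f"cannot interpret term specification {t!r}")
    return out


class MortalityLogit:
    """Binary-outcome logistic model built from a cohort dataframe.

    Parameters
    ----------
    data : DataFrame with one row per calf.
    outcome : name of the 0/1 outcome column (1 = event, e.g. death).
    terms : term specifications — ``Term`` instances or plain column names.

    Rows missing the outcome or any model feature are dropped
    (complete-case per model, as per-model n's are reported).
    """

    def __init__(self, data: pd.DataFrame, outcome: str, terms: Sequence):
        self.terms = _as_terms(terms)
        if outcome not in data.columns:
            raise ModelSpecificationError(f"outcome column {outcome!r} not in data")
        self.outcome = outcome
        feats = pd.DataFrame(
            {t.name: t.feature(data) for t in self.terms}, index=data.index
        )
        y = pd.to_numeric(data[outcome], errors="coerce")
        keep = y.notna() & feats.notna().all(axis=1)
        self.endog = y[keep].to_numpy(dtype=float)
        self.exog = feats.loc[keep]
        uniq = np.unique(self.endog)
        if not np.isin(uniq, [0.0, 1.0]).all():
            raise ModelSpecificationError(
                f"outcome column {outcome!r} is not binary 0/1 (values {uniq[:5]})"
            )
        self.nobs = int(keep.sum())
        if self.terms and self.nobs < 10 * len(self.terms):
            warnings.warn(
                f"only {self.nobs} complete cases for {len(self.terms)} terms "
                "(< 10 events-per-variable heuristic)"
            )

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str, terms: Sequence):
        return cls(data, outcome, terms)

    def _separation_diagnosis(self) -> Exception:
        """Name a term whose feature perfectly separates the outcome."""
        y = self.endog
        for t in self.terms:
            x = self.exog[t.name].to_numpy(dtype=float)
            x0, x1 = x[y == 0], x[y == 1]
            if len(x0) and len(x1) and (x0.max() < x1.min() or x1.max() < x0.min()):
                return SeparationError(t.name, float("inf"))
        return SeparationError("(undetermined term)", float("inf"))

    def fit(self) -> "MortalityLogitResults":
        import statsmodels.api as sm

        X = sm.add_constant(self.exog.to_numpy(dtype=float), has_constant="add")
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(self.endog, X).fit(disp=0, maxiter=200)
        except np.linalg.LinAlgError:
            # singular information matrix: diagnose a separating term
            raise self._separation_diagnosis() from None
        params = np.asarray(res.params, dtype=float)
        bse = np.asarray(res.bse, dtype=float)
        for name, coef in zip(["(intercept)"] + [t.name for t in self.terms], params):
            if abs(coef) > SEPARATION_LIMIT:
                raise SeparationError(name, coef)
        pvals = 2.0 * stats.norm.sf(np.abs(params) / bse)
        fitted_terms = [
            replace(t, coefficient=float(b), se=float(s), p_value=float(p))
            for t, b, s, p in zip(self.terms, params[1:], bse[1:], pvals[1:])
        ]
        model = LogisticModel(
            intercept=float(params[0]),
            intercept_se=float(bse[0]),
            terms=fitted_terms,
            n=self.nobs,
            log_likelihood=float(res.llf),
            converged=bool(res.mle_retvals.get("converged", True)),
        )
        return MortalityLogitResults(self, model, res)


class MortalityLogitResults:
    """Fitted logistic model: estimates, uncertainties, diagnostics."""

    def __init__(self, model: MortalityLogit, artifact: LogisticModel, smres):
        self.model = model
        self.artifact = artifact
        self._smres = smres

    @property
    def params(self) -> pd.Series:
        names = ["(intercept)"] + [t.name for t in self.artifact.terms]
        return pd.Series(
            [self.artifact.intercept] + [t.coefficient for t in self.artifact.terms],
            index=names,
        )

    @property
    def bse(self) -> pd.Series:
        names = ["(intercept)"] + [t.name for t in self.artifact.terms]
        return pd.Series(
            [self.artifact.intercept_se] + [t.se for t in self.artifact.terms],
            index=names,
        )

    @property
    def pvalues(self) -> pd.Series:
        z = self.params / self.bse
        return pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=self.params.index)

    @property
    def llf(self) -> float:
        return self.artifact.log_likelihood

    def predict(self, data: Optional[pd.DataFrame] = None) -> np.ndarray:
        if data is None:
            lp = self.artifact.intercept + self.model.exog.to_numpy(float) @ np.array(
                [t.coefficient for t in self.artifact.terms]
            )
            return inverse_logit(lp)
        return self.artifact.predict(data)

    def summary(self) -> str:
        """Coefficient / SE / OR / 95% CI / p table in the printed-table layout."""
        lines = [
            f"Logistic regression (n = {self.artifact.n}, "
            f"log-likelihood = {self.artifact.log_likelihood:.2f})",
            f"{'term':<28}{'coef':>9}{'SE':>8}{'OR':>9}{'95% CI':>18}{'P':>9}",
        ]
        lines.append(
            f"{'(intercept)':<28}{self.artifact.intercept:>9.3f}"
            f"{self.artifact.intercept_se:>8.3f}{'':>9}{'':>18}{'':>9}"
        )
        for r in self.artifact.odds_ratios().itertuples():
            p = "< 0.001" if r.p_value is not None and r.p_value < 0.001 else (
                f"{r.p_value:.3f}" if r.p_value is not None else ""
            )
            lines.append(
                f"{r.term:<28}{r.coefficient:>9.3f}{r.se:>8.3f}{r.odds_ratio:>9.2f}"
                f"{f'{r.ci_low:.2f}-{r.ci_high:.2f}':>18}{p:>9}"
            )
        return "\n".join(lines)

    def backward_eliminate(self, alpha: float = 0.01) -> "MortalityLogitResults":
        """Backward Wald selection: see module-level ``backward_eliminate``."""
        data = pd.concat(
            [self.model.exog, pd.Series(self.model.endog, index=self.model.exog.index, name=self.model.outcome)],
            axis=1,
        )
        terms = [replace(t, op=None, threshold=None, variable=t.name) for t in self.artifact.terms]
        res, log = _backward(data, self.model.outcome, terms, alpha)
        res.artifact.metadata["elimination_order"] = log
        return res

    def hosmer_lemeshow(self, groups: int = 10) -> "HosmerLemeshowResult":
        return hosmer_lemeshow(self.predict(), self.model.endog, groups=groups)


def fit_logistic(data: pd.DataFrame, outcome: str, terms: Sequence) -> LogisticModel:
    """Fit a logistic model and return the serializable artifact.

    Functional convenience over ``MortalityLogit(...).fit()``.
    """
    return MortalityLogit(data, outcome, terms).fit().artifact


def _backward(data, outcome, terms, alpha):
    log = []
    current = list(terms)
    while True:
        res = MortalityLogit(data, outcome, current).fit()
        term_p = {t.name: t.p_value for t in res.artifact.terms}
        if not term_p:
            return res, log
        worst = max(term_p, key=term_p.get)
        if term_p[worst] <= alpha:
            return res, log
        log.append({"removed": worst, "p_value": term_p[worst]})
        current = [t for t in current if t.name != worst]


def backward_eliminate(
    data: pd.DataFrame, outcome: str, terms: Sequence, alpha: float = 0.01
) -> LogisticModel:
    """Stepwise backward elimination with a Wald P < alpha retention criterion.

    At each step the term with the largest Wald p-value is removed if that
    p-value exceeds alpha, and the model is refitted; the intercept is
    always retained.  The elimination order is recorded in the returned
    model's metadata.
    """
    res, log = _backward(data, outcome, _as_terms(terms), alpha)
    model = res.artifact
    model.metadata["elimination_order"] = log
    return model


# ---------------------------------------------------------------------------
# goodness of fit / two-group comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HosmerLemeshowResult:
    chi_square: float
    degrees_of_freedom: int
    p_value: float
    groups: int


def hosmer_lemeshow(probabilities, outcomes, groups: int = 10) -> HosmerLemeshowResult:
    """Hosmer-Lemeshow goodness-of-fit with tie-aware decile grouping.

    Cases are sorted by predicted risk and cut into ``groups``
    equal-frequency bins; all cases sharing a predicted value stay in the
    same bin, and bins with identical quantile boundaries merge — so with
    few distinct predicted values (binary-feature models) the effective
    group count g can be much smaller than requested.  df = g − 2.
    """
    if groups < 3:
        raise ValidationError("groups", "need at least 3 groups for df >= 1")
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    n_all = len(p)
    order = np.argsort(p, kind="stable")
    prelim = (np.arange(n_all) * groups) // n_all
    ps = p[order]
    bins_sorted = prelim.copy()
    for i in range(1, n_all):  # tied predictions stay in one group
        if ps[i] == ps[i - 1]:
            bins_sorted[i] = bins_sorted[i - 1]
    bins = np.empty(n_all, dtype=int)
    bins[order] = bins_sorted
    df = pd.DataFrame({"p": p, "y": y, "bin": bins})
    agg = df.groupby("bin", observed=True).agg(n=("y", "size"), obs=("y", "sum"), exp=("p", "sum"))
    agg = agg[agg["n"] > 0]
    g = len(agg)
    if g < 3:
        raise ValidationError(
            "groups", f"only {g} distinct risk groups after tie collapsing; df would be < 1"
        )
    obs1, exp1, n = agg["obs"].to_numpy(), agg["exp"].to_numpy(), agg["n"].to_numpy()
    chi2 = float(np.sum((obs1 - exp1) ** 2 / exp1) + np.sum(((n - obs1) - (n - exp1)) ** 2 / (n - exp1)))
    ddof = g - 2
    return HosmerLemeshowResult(chi2, ddof, float(stats.chi2.sf(chi2, ddof)), g)


def mann_whitney(group_a: Iterable[float], group_b: Iterable[float]):
    """Two-sided Mann-Whitney U test.

    Exact enumeration for small tie-free samples (both n <= 20), normal
    approximation with tie correction otherwise.  Returns (U, p) where U
    counts pairs in which a-value > b-value (ties half), so complete
    separation with all a below all b gives U = 0.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("groups", "both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:
        # all values identical: no evidence either way
        return len(a) * len(b) / 2.0, 1.0
    method = "exact" if (len(a) <= 20 and len(b) <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
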