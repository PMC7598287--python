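"""Diagnostic-accuracy statistics: the univariate / ROC / multivariate cascade.

The cascade mirrors a conventional radiomics read-out for a two-class
lesion cohort:

1. the three selection schemes each nominate 10 features; their union
   (plus one slot for the age covariate) sets the Bonferroni divisor m;
2. each nominated feature is compared between classes with a two-sided
   Mann-Whitney U test at the corrected threshold alpha / m;
3. each significant feature gets an empirical ROC curve: AUC with a
   DeLong 95% CI, the Youden-optimal cutoff with its orientation, and
   sensitivity / specificity with Clopper-Pearson exact CIs;
4. all significant features enter a multiple linear regression of the
   0/1 class outcome simultaneously ("enter" model, no stepwise), with
   per-predictor t-test p-values and variance inflation factors;
5. the fitted values of that model are scored by ROC as the combined
   prediction model.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .errors import ParameterError, SingularDesignError
from .feature_selection import (
    DEFAULT_K,
    DEFAULT_MI_BINS,
    METHODS,
    SelectionResult,
    select_top,
)

logger = logging.getLogger(__name__)

#: pooled sample size up to which the Mann-Whitney p is computed by exact
#: enumeration (when tieless)
EXACT_MW_LIMIT = 12


# ---------------------------------------------------------------------------
# elementary pieces
# ---------------------------------------------------------------------------

def bonferroni_alpha(alpha: float = 0.05, m: int = 1) -> tuple[float, float]:
    """Corrected threshold alpha/m: (full precision, rounded to 4 decimals)."""
    if m < 1:
        raise ParameterError("Bonferroni divisor must be >= 1")
    exact = alpha / m
    return exact, round(exact, 4)


def youden_index(sensitivity: float, specificity: float) -> float:
    """J = Se + Sp - 1, on proportions in [0, 1]."""
    return sensitivity + specificity - 1.0


def clopper_pearson(
    successes: int, trials: int, level: float = 0.95
) -> tuple[float, float]:
    """Exact binomial (beta-quantile) confidence limits for a proportion."""
    if not 0 <= successes <= trials or trials < 1:
        raise ParameterError(f"invalid counts {successes}/{trials}")
    a = 1.0 - level
    lower = 0.0 if successes == 0 else float(
        sps.beta.ppf(a / 2, successes, trials - successes + 1)
    )
    upper = 1.0 if successes == trials else float(
        sps.beta.ppf(1 - a / 2, successes + 1, trials - successes)
    )
    return lower, upper


@dataclasses.dataclass
class MannWhitneyResult:
    u: float
    p_value: float
    method: str  # exact | asymptotic
    median_a: float
    iqr_a: tuple[float, float]
    median_b: float
    iqr_b: tuple[float, float]


def mann_whitney(group_a, group_b) -> MannWhitneyResult:
    """Two-sided Mann-Whitney U with medians and interquartile ranges.

    The p-value is by exact enumeration when the pooled sample size is at
    most 12 and there are no ties, otherwise by the normal approximation
    with tie and continuity corrections.  Quartiles use linear
    interpolation.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    tieless = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= EXACT_MW_LIMIT and tieless) else "asymptotic"
    res = sps.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=True
    )
    qa = np.percentile(a, [25, 75])
    qb = np.percentile(b, [25, 75])
    return MannWhitneyResult(
        u=float(res.statistic),
        p_value=float(min(res.pvalue, 1.0)),
        method=method,
        median_a=float(np.median(a)),
        iqr_a=(float(qa[0]), float(qa[1])),
        median_b=float(np.median(b)),
        iqr_b=(float(qb[0]), float(qb[1])),
    )


# ---------------------------------------------------------------------------
# ROC analysis
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RocResult:
    id: str
    auc: float
    auc_ci: tuple[float, float]
    youden_j: float
    cutoff: float
    orientation: str  # ">" (positive above cutoff) or "<=" (positive at/below)
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    n_pos: int
    n_neg: int

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["auc_ci"] = list(self.auc_ci)
        d["sensitivity_ci"] = list(self.sensitivity_ci)
        d["specificity_ci"] = list(self.specificity_ci)
        return d


def _auc_mann_whitney(pos: np.ndarray, neg: np.ndarray) -> float:
    """Tie-corrected AUC = U / (n_pos * n_neg) via midranks."""
    ranks = sps.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong variance of the empirical AUC (two-class, single curve)."""
    m, n = pos.size, neg.size
    tz = sps.rankdata(np.concatenate([pos, neg]))
    tx = sps.rankdata(pos)
    ty = sps.rankdata(neg)
    v10 = (tz[:m] - tx) / n  # placement of each positive among negatives
    v01 = 1.0 - (tz[m:] - ty) / m
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def roc_analysis(scores, labels, id: str = "feature") -> RocResult:
    """Empirical ROC of a continuous score against boolean labels.

    The score orientation is flipped when the raw AUC is below 0.5 and
    recorded as ``<=`` (positive at or below the cutoff) versus ``>``.
    The reported cutoff is the observed value maximizing the Youden index
    J = Se + Sp - 1, ties resolved toward higher sensitivity.  The AUC CI
    uses the DeLong variance (normal interval clipped to [0, 1]); Se and
    Sp get Clopper-Pearson exact CIs.
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=bool)
    pos, neg = scores[labels], scores[~labels]
    if pos.size == 0 or neg.size == 0:
        raise ParameterError("both classes must be present for ROC analysis")

    auc_raw = _auc_mann_whitney(pos, neg)
    if auc_raw >= 0.5:
        orientation = ">"
        spos, sneg = pos, neg
    else:
        orientation = "<="
        spos, sneg = -pos, -neg
    auc = _auc_mann_whitney(spos, sneg)
    se_auc = np.sqrt(_delong_variance(spos, sneg))
    z = sps.norm.ppf(0.975)
    auc_ci = (max(0.0, auc - z * se_auc), min(1.0, auc + z * se_auc))

    best = None  # (J, Se, Sp, cutoff)
    for c in np.unique(scores):
        if orientation == ">":
            se = float(np.mean(pos > c))
            sp = float(np.mean(neg <= c))
        else:
            se = float(np.mean(pos <= c))
            sp = float(np.mean(neg > c))
        j = youden_index(se, sp)
        if best is None or j > best[0] + 1e-12 or (
            abs(j - best[0]) <= 1e-12 and se > best[1] + 1e-12
        ):
            best = (j, se, sp, float(c))
    j, se, sp, cutoff = best

    tp = int(round(se * pos.size))
    tn = int(round(sp * neg.size))
    return RocResult(
        id=id,
        auc=auc,
        auc_ci=auc_ci,
        youden_j=j,
        cutoff=cutoff,
        orientation=orientation,
        sensitivity=se,
        sensitivity_ci=clopper_pearson(tp, pos.size),
        specificity=sp,
        specificity_ci=clopper_pearson(tn, neg.size),
        n_pos=int(pos.size),
        n_neg=int(neg.size),
    )


# ---------------------------------------------------------------------------
# enter-model multiple regression
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class RegressionResult:
    coefficients: pd.DataFrame  # index: predictor; coef, std_err, p_value, vif
    intercept: float
    f_pvalue: float
    r_squared: float
    r_squared_adj: float
    multiple_r: float
    fitted: np.ndarray

    def to_dict(self) -> dict:
        return {
            "intercept": self.intercept,
            "f_pvalue": self.f_pvalue,
            "r_squared": self.r_squared,
            "r_squared_adj": self.r_squared_adj,
            "multiple_r": self.multiple_r,
            "coefficients": json.loads(
                self.coefficients.to_json(orient="index")
            ),
        }


def enter_regression(predictors: pd.DataFrame, labels) -> RegressionResult:
    """OLS of the 0/1 outcome on all predictors simultaneously.

    All columns enter at once ("enter" input model).  Reports
    per-predictor coefficient, standard error, t-test p-value and VIF
    (1 / (1 - R^2) of that predictor regressed on the others), plus the
    overall F-test significance, R^2, adjusted R^2, and the multiple
    correlation coefficient sqrt(R^2).
    """
    y = np.asarray(labels, dtype=np.float64)
    x = predictors.to_numpy(dtype=np.float64)
    n, p = x.shape
    if n <= p + 1:
        raise ParameterError(
            f"need more than {p + 1} observations for {p} predictors, got {n}"
        )
    design = np.column_stack([np.ones(n), x])
    if np.linalg.matrix_rank(design) < p + 1:
        corr = np.corrcoef(x, rowvar=False)
        collinear = [
            (predictors.columns[i], predictors.columns[j])
            for i in range(p)
            for j in range(i + 1, p)
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise SingularDesignError(
            f"design matrix is rank-deficient; collinear pairs: {collinear}",
            collinear=[c for pair in collinear for c in pair],
        )
    model = sm.OLS(y, design).fit()

    vifs = []
    for j in range(p):
        others = np.column_stack([np.ones(n), np.delete(x, j, axis=1)])
        r2_j = sm.OLS(x[:, j], others).fit().rsquared if p > 1 else 0.0
        vifs.append(1.0 / (1.0 - r2_j) if r2_j < 1.0 else np.inf)

    table = pd.DataFrame(
        {
            "coef": model.params[1:],
            "std_err": model.bse[1:],
            "p_value": model.pvalues[1:],
            "vif": vifs,
        },
        index=predictors.columns,
    )
    return RegressionResult(
        coefficients=table,
        intercept=float(model.params[0]),
        f_pvalue=float(model.f_pvalue),
        r_squared=float(model.rsquared),
        r_squared_adj=float(model.rsquared_adj),
        multiple_r=float(np.sqrt(model.rsquared)),
        fitted=np.asarray(model.fittedvalues),
    )


def prediction_model_roc(regression: RegressionResult, labels) -> RocResult:
    """ROC of the enter-model fitted values as a continuous score."""
    return roc_analysis(regression.fitted, labels, id="prediction_model")


# ---------------------------------------------------------------------------
# the full cascade
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class CascadeConfig:
    selection_k: int = DEFAULT_K
    mi_bins: int = DEFAULT_MI_BINS
    alpha: float = 0.05
    include_age_slot: bool = True  # one extra Bonferroni slot for age
    bonferroni_m: Optional[int] = None  # override; default = union size (+1)


@dataclasses.dataclass
class DiagnosticReport:
    selections: dict[str, SelectionResult]
    selected_union: list[str]
    m: int
    alpha_corrected: float
    univariate: pd.DataFrame
    roc: list[RocResult]
    regression: Optional[RegressionResult]
    model_roc: Optional[RocResult]

    @property
    def significant_features(self) -> list[str]:
        return list(self.univariate.index[self.univariate["significant"]])

    def write(self, outdir) -> None:
        """Emit selection / univariate / ROC / regression reports."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "selection.json", "w") as fh:
            json.dump(
                {m: s.to_dict() for m, s in self.selections.items()},
                fh, indent=2,
            )
        self.univariate.to_csv(outdir / "univariate.csv")
        roc_rows = [r.to_dict() for r in self.roc]
        if self.model_roc is not None:
            roc_rows.append(self.model_roc.to_dict())
        pd.json_normalize(roc_rows).to_csv(outdir / "roc.csv", index=False)
        if self.regression is not None:
            reg = self.regression.coefficients.copy()
            reg.to_csv(outdir / "regression.csv")
        summary = {
            "m": self.m,
            "alpha_corrected": self.alpha_corrected,
            "selected_union": self.selected_union,
            "significant_features": self.significant_features,
            "model": None
            if self.regression is None
            else {
                **self.regression.to_dict(),
                "roc": self.model_roc.to_dict(),
            },
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)


def run_cascade(
    features: pd.DataFrame,
    labels: Sequence[bool],
    config: CascadeConfig = CascadeConfig(),
) -> DiagnosticReport:
    """Run the full selection -> univariate -> ROC -> regression cascade.

    ``features`` holds feature columns only (no label column); ``labels``
    is boolean, True for the positive (endometrioma-like) class.  When no
    feature survives the corrected threshold the cascade stops after the
    univariate step and the regression / model-ROC slots stay empty.
    """
    labels = np.asarray(labels, dtype=bool)
    selections = {
        method: select_top(
            features, labels, method, k=config.selection_k,
            mi_bins=config.mi_bins,
        )
        for method in METHODS
    }
    union = sorted(set().union(*(s.features for s in selections.values())))
    m = (
        config.bonferroni_m
        if config.bonferroni_m is not None
        else len(union) + (1 if config.include_age_slot else 0)
    )
    threshold, _ = bonferroni_alpha(config.alpha, m)

    rows = []
    for name in union:
        v = features[name].to_numpy(dtype=np.float64)
        mw = mann_whitney(v[labels], v[~labels])
        rows.append(
            {
                "feature": name,
                "U": mw.u,
                "p_value": mw.p_value,
                "median_pos": mw.median_a,
                "q1_pos": mw.iqr_a[0],
                "q3_pos": mw.iqr_a[1],
                "median_neg": mw.median_b,
                "q1_neg": mw.iqr_b[0],
                "q3_neg": mw.iqr_b[1],
                "significant": mw.p_value < threshold,
            }
        )
    univariate = pd.DataFrame(rows).set_index("feature")

    significant = list(univariate.index[univariate["significant"]])
    roc_results = [
        roc_analysis(features[name], labels, id=name) for name in significant
    ]

    regression = None
    model_roc = None
    if significant:
        predictors = features[significant]
        # exact duplicate columns would make the enter design singular;
        # keep the lexicographically first of each duplicate group
        dup = predictors.T.duplicated()
        if dup.any():
            dropped = list(predictors.columns[dup])
            logger.warning(
                "dropping %d duplicated significant feature(s) before "
                "regression: %s", len(dropped), dropped,
            )
            predictors = predictors.loc[:, ~dup]
        max_predictors = labels.size - 2
        if predictors.shape[1] > max_predictors:
            # an enter model needs n > p + 1; keep the lowest-p features
            keep = (
                univariate.loc[predictors.columns, "p_value"]
                .sort_values(kind="stable")
                .index[:max_predictors]
            )
            logger.warning(
                "capping enter model at %d of %d significant features "
                "(cohort of %d lesions)",
                max_predictors, predictors.shape[1], labels.size,
            )
            predictors = predictors[sorted(keep)]
        regression = enter_regression(predictors, labels)
        model_roc = prediction_model_roc(regression, labels)

    return DiagnosticReport(
        selections=selections,
        selected_union=union,
        m=m,
        alpha_corrected=threshold,
        univariate=univariate,
        roc=roc_results,
        regression=regression,
        model_roc=model_roc,
    )
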