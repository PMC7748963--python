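"""Longitudinal inference layer.

Implements the analysis stack applied to the per-window feature table:
variance-inflation-factor (VIF) pruning of collinear features, marginal
Gamma regression of SSRT on features via generalized estimating equations
(GEE) with participant clusters, repeated-measures correlation (rmcorr),
participant-wise median-split state labels, and gradient-boosted-tree
classification evaluated with leave-one-subject-out (LOSO) and
mixed-fraction cross-validation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import accuracy_score, roc_auc_score
from statsmodels.stats.outliers_influence import variance_inflation_factor

__all__ = [
    "GEEFit",
    "RmcorrResult",
    "ClassifierEval",
    "GBTConfig",
    "vif_prune",
    "fit_gee",
    "rmcorr",
    "label_states",
    "train_eval_loso",
    "train_eval_mixed",
]


def vif_prune(matrix: pd.DataFrame, threshold: float = 5.0) -> list[str]:
    """Iteratively drop the highest-VIF feature until all VIF <= threshold.

    VIF is computed against an intercept-augmented design; ties break
    alphabetically by feature name.  Returns the retained feature names in
    the original column order.
    """
    cols = list(matrix.columns)
    x = matrix.astype(float)
    while len(cols) > 1:
        design = sm.add_constant(x[cols].to_numpy(), has_constant="add")
        vifs = {}
        for j, c in enumerate(cols):
            with np.errstate(divide="ignore", invalid="ignore"):
                v = variance_inflation_factor(design, j + 1)
            vifs[c] = np.inf if not np.isfinite(v) else float(v)
        worst = max(vifs.values())
        if worst <= threshold:
            break
        # alphabetical tie-break among features attaining the max
        cols.remove(sorted(c for c, v in vifs.items() if v == worst)[0])
    return [c for c in matrix.columns if c in cols]


@dataclass
class GEEFit:
    """Coefficient table and metadata of one GEE fit."""

    table: pd.DataFrame  # index: term; columns: coef, ci_low, ci_high, p
    family: str
    link: str
    cov_struct: str
    cov_type: str
    n_clusters: int
    n_obs: int
    converged: bool
    result: object = field(repr=False, default=None)


def fit_gee(
    matrix: pd.DataFrame,
    features: list[str],
    outcome: str = "ssrt_ms",
    groups: str = "participant_id",
    cov_type: str = "bias_reduced",
) -> GEEFit:
    """Marginal Gamma regression of the outcome on features via GEE.

    Gamma family with log link, exchangeable working correlation,
    participant clusters, and sandwich standard errors (the Mancl-DeRouen
    bias-reduced variant by default).  With few clusters, normal-referenced
    sandwich tests are anti-conservative, so p-values and confidence
    intervals use a t reference with n_clusters - 1 degrees of freedom.
    Complete cases only.
    """
    cc = matrix[features + [outcome, groups]].dropna()
    n_clusters = int(cc[groups].nunique())
    if n_clusters < 2:
        raise ValueError("GEE requires at least 2 clusters")
    y = cc[outcome].astype(float)
    X = sm.add_constant(cc[features].astype(float), has_constant="add")
    model = sm.GEE(
        y,
        X,
        groups=cc[groups],
        family=sm.families.Gamma(link=sm.families.links.Log()),
        cov_struct=sm.cov_struct.Exchangeable(),
    )
    res = model.fit(cov_type=cov_type)
    dof = max(n_clusters - 1, 1)
    tstat = res.params / res.bse
    pvals = 2.0 * stats.t.sf(np.abs(tstat), dof)
    tcrit = stats.t.ppf(0.975, dof)
    table = pd.DataFrame(
        {
            "coef": res.params,
            "ci_low": res.params - tcrit * res.bse,
            "ci_high": res.params + tcrit * res.bse,
            "p": pvals,
        }
    )
    return GEEFit(
        table=table,
        family="Gamma",
        link="log",
        cov_struct="exchangeable",
        cov_type=cov_type,
        n_clusters=n_clusters,
        n_obs=int(len(cc)),
        converged=bool(getattr(res, "converged", True)),
        result=res,
    )


@dataclass
class RmcorrResult:
    r: float
    ci_low: float
    ci_high: float
    p: float
    df: int


def rmcorr(x, y, subject) -> RmcorrResult:
    """Repeated-measures correlation: the common within-subject association.

    ANCOVA formulation: y is regressed on x plus subject indicators; the
    correlation is sign(common slope) * sqrt(SS_x / (SS_x + SS_error)) with
    df = N - n_subjects - 1.  The confidence interval uses the Fisher
    z-transform with the same error degrees of freedom.
    """
    df_in = pd.DataFrame({"x": x, "y": y, "s": subject}).dropna()
    n = len(df_in)
    k = df_in["s"].nunique()
    dof = n - k - 1
    if dof < 1:
        raise ValueError("not enough observations for rmcorr")
    dummies = pd.get_dummies(df_in["s"], drop_first=False, dtype=float)
    X_full = np.column_stack([df_in["x"].to_numpy(float), dummies.to_numpy()])
    y_arr = df_in["y"].to_numpy(float)
    fit_full = np.linalg.lstsq(X_full, y_arr, rcond=None)
    resid_full = y_arr - X_full @ fit_full[0]
    sse_full = float(resid_full @ resid_full)
    fit_red = np.linalg.lstsq(dummies.to_numpy(), y_arr, rcond=None)
    resid_red = y_arr - dummies.to_numpy() @ fit_red[0]
    sse_red = float(resid_red @ resid_red)
    ss_x = max(sse_red - sse_full, 0.0)
    slope = float(fit_full[0][0])
    denom = ss_x + sse_full
    r = math.copysign(math.sqrt(ss_x / denom), slope) if denom > 0 else 0.0
    if abs(r) >= 1.0:
        p = 0.0
        return RmcorrResult(r=r, ci_low=r, ci_high=r, p=p, df=dof)
    t = r * math.sqrt(dof / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), dof)
    z = np.arctanh(r)
    se = 1.0 / math.sqrt(max(dof - 1, 1))
    lo, hi = np.tanh(z - 1.959963984540054 * se), np.tanh(z + 1.959963984540054 * se)
    return RmcorrResult(r=r, ci_low=float(lo), ci_high=float(hi), p=float(p), df=dof)


def label_states(matrix: pd.DataFrame, outcome: str = "ssrt_ms",
                 groups: str = "participant_id") -> pd.Series:
    """Binary low-inhibitory-control labels by participant-wise median split.

    A session is labeled 1 (low control, the positive class) iff its SSRT
    is strictly above that participant's median; ties go to high control.
    """
    med = matrix.groupby(groups)[outcome].transform("median")
    return (matrix[outcome] > med).astype(int)


@dataclass(frozen=True)
class GBTConfig:
    """Gradient-boosted-tree hyperparameters (fixed, seeded)."""

    n_estimators: int = 200
    max_depth: int = 3
    learning_rate: float = 0.1
    random_state: int = 0

    def make(self) -> GradientBoostingClassifier:
        return GradientBoostingClassifier(
            n_estimators=self.n_estimators,
            max_depth=self.max_depth,
            learning_rate=self.learning_rate,
            random_state=self.random_state,
        )


@dataclass
class ClassifierEval:
    accuracy_pct: float
    auc_pct: float
    folds: list[dict]
    scheme: str
    fraction: float = 0.0


def _zscore(train: np.ndarray, test: np.ndarray):
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _eval_folds(matrix, features, labels, groups_col, order_col,
                fraction, config) -> ClassifierEval:
    cc = matrix[features + [groups_col, order_col]].copy()
    cc["_y"] = np.asarray(labels)
    cc = cc.dropna()
    participants = sorted(cc[groups_col].unique())
    if len(participants) < 2:
        raise ValueError("LOSO requires at least 2 participants")
    folds = []
    for pid in participants:
        test = cc[cc[groups_col] == pid].sort_values(order_col)
        train = cc[cc[groups_col] != pid]
        n_mix = math.ceil(fraction * len(test)) if fraction > 0 else 0
        if n_mix:
            train = pd.concat([train, test.iloc[:n_mix]])
            test = test.iloc[n_mix:]
        if not len(test):
            continue
        Xtr, Xte = _zscore(
            train[features].to_numpy(float), test[features].to_numpy(float)
        )
        ytr, yte = train["_y"].to_numpy(), test["_y"].to_numpy()
        if len(np.unique(ytr)) < 2:
            continue
        clf = config.make()
        clf.fit(Xtr, ytr)
        pred = clf.predict(Xte)
        score = clf.predict_proba(Xte)[:, 1]
        acc = accuracy_score(yte, pred)
        auc = roc_auc_score(yte, score) if len(np.unique(yte)) > 1 else np.nan
        folds.append(
            {"participant": pid, "n_test": int(len(yte)),
             "accuracy": float(acc), "auc": float(auc) if np.isfinite(auc) else None}
        )
    accs = [f["accuracy"] for f in folds]
    aucs = [f["auc"] for f in folds if f["auc"] is not None]
    return ClassifierEval(
        accuracy_pct=100.0 * float(np.mean(accs)) if accs else float("nan"),
        auc_pct=100.0 * float(np.mean(aucs)) if aucs else float("nan"),
        folds=folds,
        scheme="mixed" if fraction > 0 else "loso",
        fraction=fraction,
    )


def train_eval_loso(
    matrix: pd.DataFrame,
    features: list[str],
    labels,
    groups: str = "participant_id",
    order: str = "end_s",
    config: GBTConfig | None = None,
) -> ClassifierEval:
    """Leave-one-subject-out evaluation of a gradient-boosted classifier.

    Features are z-standardized with training-fold statistics only; the
    held-out participant never influences scaling or training.  Reports
    mean accuracy and mean AUC-ROC across folds (percent).
    """
    return _eval_folds(matrix, features, labels, groups, order, 0.0,
                       config or GBTConfig())


def train_eval_mixed(
    matrix: pd.DataFrame,
    features: list[str],
    labels,
    fraction: float,
    groups: str = "participant_id",
    order: str = "end_s",
    config: GBTConfig | None = None,
) -> ClassifierEval:
    """LOSO variant where the chronologically first ``fraction`` of the test
    participant's sessions join the training set; evaluation covers only
    the remaining sessions."""
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    return _eval_folds(matrix, features, labels, groups, order, fraction,
                       config or GBTConfig())
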