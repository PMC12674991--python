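"""LASSO stability selection of translatable PCs and per-PC logistic GLMs.

All retained PCs from all disease models enter one penalized logistic
regression of human AD status, under four covariate configurations (none,
sex, age, sex+age).  Each of ``rounds`` rounds draws a fresh stratified
fold assignment, picks the penalty minimizing cross-validated deviance,
refits on all subjects, and records which PC coefficients are nonzero.
PCs nonzero in strictly more than half the rounds are "selected".
Selected PCs are then tested one at a time in an unpenalized binomial GLM,
with significance read from a likelihood-ratio test against the
covariates-only null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from ._lasso import binomial_deviance, lambda_grid, logistic_lasso_path
from .pca import HumanScores


@dataclass(frozen=True)
class CovariateSpec:
    """Which demographic covariates enter the design (sex 0/1, age z-scored)."""

    sex: bool = False
    age: bool = False

    @property
    def name(self) -> str:
        parts = ["pcs"] + (["sex"] if self.sex else []) + (["age"] if self.age else [])
        return "+".join(parts)

    def covariate_names(self) -> list[str]:
        return (["sex"] if self.sex else []) + (["age"] if self.age else [])


#: The four covariate configurations run in the stability selection.
ALL_COVARIATE_SPECS = (
    CovariateSpec(False, False),
    CovariateSpec(True, False),
    CovariateSpec(False, True),
    CovariateSpec(True, True),
)


def encode_covariates(scores: HumanScores, spec: CovariateSpec) -> pd.DataFrame:
    """Sex as 0 (M) / 1 (F); age standardized (penalization is scale-sensitive)."""
    out = {}
    if spec.sex:
        sex = scores.sex
        bad = sorted(set(sex.unique()) - {"F", "M"})
        if bad:
            raise ValueError(f"cannot encode sex values {bad}; need F/M")
        out["sex"] = (sex == "F").astype(float)
    if spec.age:
        age = scores.age.astype(float)
        if age.isna().any():
            raise ValueError("missing age for some subjects")
        sd = age.std(ddof=1)
        if sd == 0:
            raise ValueError("age has zero variance; cannot standardize")
        out["age"] = (age - age.mean()) / sd
    return pd.DataFrame(out, index=scores.scores.index)


def _stratified_folds(
    y: np.ndarray, folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Class-balanced fold labels in 0..folds-1."""
    assignment = np.empty(len(y), dtype=np.int64)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) < folds:
            raise ValueError(
                f"class {cls} has {len(idx)} subjects, fewer than {folds} folds"
            )
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % folds
    return assignment


def run_lasso_stability(
    scores: HumanScores,
    spec: CovariateSpec,
    rounds: int = 100,
    folds: int = 5,
    seed: int = 0,
    n_lambdas: int = 30,
    penalize_covariates: bool = False,
) -> pd.DataFrame:
    """Stability-selection frequency of each PC under one covariate spec.

    Returns a DataFrame indexed by PC label with columns ``count`` (rounds
    with a nonzero coefficient) and ``frequency`` (count rescaled to a
    0-100 scale so the select-if-greater-than-50 rule is round-count
    independent).  Deterministic for a fixed seed.
    """
    pc_cols = scores.pc_labels
    Xpc = scores.scores.to_numpy(dtype=float)
    # standardize PC columns so a single penalty weight is comparable across PCs
    Xpc = (Xpc - Xpc.mean(axis=0)) / Xpc.std(axis=0, ddof=1)
    cov = encode_covariates(scores, spec)
    X = np.column_stack([Xpc, cov.to_numpy(dtype=float)]) if spec.covariate_names() else Xpc
    y = scores.outcome.to_numpy(dtype=float)
    n_pc = len(pc_cols)
    pf = np.ones(X.shape[1])
    if not penalize_covariates:
        pf[n_pc:] = 0.0
    lambdas = lambda_grid(X, y, pf, n_lambdas=n_lambdas)
    # the full-data path does not depend on the round; fit it once
    full_icepts, full_coefs = logistic_lasso_path(X, y, lambdas, pf)
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_pc, dtype=int)
    for _round in range(rounds):
        fold_of = _stratified_folds(y.astype(int), folds, rng)
        cv_dev = np.zeros(len(lambdas))
        for f in range(folds):
            tr = fold_of != f
            te = ~tr
            ic, co = logistic_lasso_path(X[tr], y[tr], lambdas, pf)
            cv_dev += binomial_deviance(ic, co, X[te], y[te])
        best = int(np.argmin(cv_dev))  # ties -> largest penalty (sparser)
        counts += full_coefs[best, :n_pc] != 0.0
    freq = pd.DataFrame(
        {"count": counts, "frequency": 100.0 * counts / rounds}, index=pc_cols
    )
    freq.index.name = "pc"
    return freq


def select_pcs(
    freqs: dict[str, pd.DataFrame], threshold: float = 50.0
) -> pd.DataFrame:
    """Combine per-covariate-model frequency tables into a selection summary.

    A PC is selected under a covariate model iff its frequency is strictly
    greater than ``threshold`` (on the 0-100 scale).  The summary marks PCs
    selected under all models ("consistent"), some, or none, and how many.
    """
    models = list(freqs)
    if not models:
        raise ValueError("no frequency tables given")
    index = freqs[models[0]].index
    out = pd.DataFrame(index=index)
    for name, table in freqs.items():
        if not table.index.equals(index):
            raise ValueError("frequency tables cover different PC sets")
        out[f"freq_{name}"] = table["frequency"]
        out[f"selected_{name}"] = table["frequency"] > threshold
    sel_cols = [c for c in out.columns if c.startswith("selected_")]
    out["n_models_selected"] = out[sel_cols].sum(axis=1).astype(int)
    out["selected_any"] = out["n_models_selected"] > 0
    out["consistent"] = out["n_models_selected"] == len(models)
    return out


def fit_pc_glm(
    scores: HumanScores, pc: str, spec: CovariateSpec = CovariateSpec()
) -> dict:
    """Binomial GLM (logit link) of AD status on one PC plus covariates.

    Reports the PC coefficient, its standard error and Wald p, and a model
    p from the likelihood-ratio test against the covariates-only null.
    Perfect separation is flagged and the p-values reported as NaN.
    """
    if pc not in scores.scores.columns:
        raise KeyError(f"unknown PC column {pc!r}")
    y = scores.outcome.to_numpy(dtype=float)
    cov = encode_covariates(scores, spec)
    x_pc = scores.scores[pc].to_numpy(dtype=float)
    X_full = sm.add_constant(
        np.column_stack([x_pc] + [cov[c].to_numpy() for c in cov.columns]),
        has_constant="add",
    )
    X_null = (
        sm.add_constant(cov.to_numpy(dtype=float), has_constant="add")
        if spec.covariate_names()
        else np.ones((len(y), 1))
    )
    row = {
        "pc": pc,
        "covariates": spec.name,
        "coef": np.nan,
        "se": np.nan,
        "wald_p": np.nan,
        "model_p": np.nan,
        "significant": False,
        "separation": False,
    }
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
            full = sm.GLM(y, X_full, family=sm.families.Binomial()).fit()
            null = sm.GLM(y, X_null, family=sm.families.Binomial()).fit()
    except (sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning):
        row["separation"] = True
        return row
    # escapes the IRLS warning machinery but is still numerically separated
    if np.abs(full.params[1]) > 1e3:
        row["separation"] = True
        return row
    lr = 2.0 * (full.llf - null.llf)
    row["coef"] = float(full.params[1])
    row["se"] = float(full.bse[1])
    row["wald_p"] = float(full.pvalues[1])
    row["model_p"] = float(stats.chi2.sf(max(lr, 0.0), df=1))
    row["significant"] = bool(row["model_p"] < 0.05)
    return row


def glm_table(
    scores: HumanScores,
    pcs: list[str],
    specs: tuple[CovariateSpec, ...] = (CovariateSpec(), CovariateSpec(True, True)),
) -> pd.DataFrame:
    """Per-PC GLM rows under each requested covariate spec."""
    rows = [fit_pc_glm(scores, pc, spec) for pc in pcs for spec in specs]
    return pd.DataFrame(rows)


def multi_pc_collinearity_check(scores: HumanScores, selected: list[str]) -> pd.DataFrame:
    """Pairwise correlations and VIFs among selected PC columns.

    Diagnostic only — the multi-PC GLM itself is not fitted, because
    cross-model PC columns are typically collinear enough to make joint
    coefficients uninterpretable.  VIF_j = 1/(1-R2_j) from regressing
    column j on the others; a numerically singular fit is flagged inf.
    """
    if len(selected) < 2:
        raise ValueError("need >=2 selected PCs for a collinearity check")
    X = scores.scores[selected].to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    corr = np.corrcoef(X, rowvar=False)
    rows = []
    for j, pc in enumerate(selected):
        others = np.delete(X, j, axis=1)
        xj = X[:, j]
        coef, *_ = np.linalg.lstsq(others, xj, rcond=None)
        resid = xj - others @ coef
        ss_tot = float((xj**2).sum())
        r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 0.0
        vif = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append(
            {
                "pc": pc,
                "r_squared_on_others": r2,
                "vif": vif,
                "max_abs_corr": float(
                    np.max(np.abs(np.delete(corr[j], j)))
                ),
            }
        )
    return pd.DataFrame(rows)
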