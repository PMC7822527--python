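"""Group-level inference.

The rate analyses use a Gaussian linear mixed model on per-event SCR rates:
two binary fixed factors plus their interaction, and random intercepts for
dyad and for participant nested in dyad (each participant appears in many
events, and the two members of a dyad interact with one another, so both
grouping levels are non-independent). Estimation is REML via statsmodels
MixedLM; degrees of freedom for the t-statistics use the Satterthwaite
approximation, and explained variance is summarized by Nakagawa's marginal
and conditional R² (fixed effects alone vs fixed plus random).

Satterthwaite df for a coefficient b_i: with v(θ) = [(X'V(θ)⁻¹X)⁻¹]_ii and
θ the variance components, df = 2 v(θ̂)² / (g' A g) where g = ∇v(θ̂) and A is
the asymptotic covariance of θ̂ (inverse observed information of the REML
log-likelihood). Gradient and information are evaluated by central finite
differences on the variance-component scale.

Also here: the classical dependent t-test with paired Cohen's d, and
Cohen's kappa for inter-rater agreement of annotation categories.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

import statsmodels.formula.api as smf

from .dyad_metrics import RateRecord
from .errors import (DataError, DegenerateSignalError, InsufficientDataError,
                     ParameterError)

#: Variance components smaller than this fraction of total variance are
#: treated as on the boundary (singular fit).
_SINGULAR_FRAC = 1e-8


@dataclass(frozen=True)
class CoefRow:
    name: str
    estimate: float
    std_error: float
    df: float
    t: float
    p: float


@dataclass
class GLMMResult:
    """Mixed-model summary in the layout of a coefficient table."""

    coefficients: list[CoefRow]
    var_dyad: float
    var_participant: float
    var_residual: float
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_dyads: int
    singular: bool = False
    notes: list[str] = field(default_factory=list)

    def coef(self, name: str) -> CoefRow:
        for row in self.coefficients:
            if row.name == name:
                return row
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "coefficients": [
                {"name": r.name, "estimate": r.estimate, "std_error": r.std_error,
                 "df": r.df, "t": r.t, "p": r.p}
                for r in self.coefficients
            ],
            "variance_components": {
                "dyad": self.var_dyad, "participant": self.var_participant,
                "residual": self.var_residual,
            },
            "r2_marginal": self.r2_marginal,
            "r2_conditional": self.r2_conditional,
            "n_obs": self.n_obs, "n_dyads": self.n_dyads,
            "singular": self.singular, "notes": self.notes,
        }


@dataclass
class KappaResult:
    kappa: float
    p_observed: float
    p_expected: float
    confusion: pd.DataFrame

    def to_dict(self) -> dict:
        return {"kappa": self.kappa, "p_observed": self.p_observed,
                "p_expected": self.p_expected,
                "confusion": self.confusion.to_dict()}


# ---------------------------------------------------------------------------
# REML machinery (block-diagonal by dyad)
# ---------------------------------------------------------------------------

def _design(df: pd.DataFrame, f1: str, f2: str):
    """Fixed-effect design with intercept, two binary factors, interaction."""
    x1 = df[f1].to_numpy(dtype=float)
    x2 = df[f2].to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(df)), x1, x2, x1 * x2])
    y = df["rate"].to_numpy(dtype=float)
    return y, X


def _group_blocks(df: pd.DataFrame, y: np.ndarray, X: np.ndarray):
    """Split (y, X, participant indicators) into per-dyad blocks."""
    blocks = []
    for _, idx in df.groupby("dyad_id", sort=True).indices.items():
        idx = np.asarray(idx)
        pids = df["participant_id"].to_numpy()[idx]
        _, pcode = np.unique(pids, return_inverse=True)
        P = np.zeros((idx.size, pcode.max() + 1))
        P[np.arange(idx.size), pcode] = 1.0
        blocks.append((y[idx], X[idx], P))
    return blocks


def _reml_quantities(theta: np.ndarray, blocks, p: int):
    """Return (-2 REML loglik up to a constant, (X'V⁻¹X)⁻¹, beta_hat)."""
    s2d, s2p, s2e = theta
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    logdet = 0.0
    yViy = 0.0
    parts = []
    for yg, Xg, Pg in blocks:
        ng = yg.size
        V = s2e * np.eye(ng) + s2d * np.ones((ng, ng)) + s2p * (Pg @ Pg.T)
        sign, ld = np.linalg.slogdet(V)
        if sign <= 0:
            return np.inf, None, None
        logdet += ld
        Vi_X = np.linalg.solve(V, Xg)
        Vi_y = np.linalg.solve(V, yg)
        XtViX += Xg.T @ Vi_X
        XtViy += Xg.T @ Vi_y
        yViy += yg @ Vi_y
        parts.append((yg, Xg, Vi_y, Vi_X))
    C = np.linalg.inv(XtViX)
    beta = C @ XtViy
    # r'V⁻¹r = y'V⁻¹y - 2 b'X'V⁻¹y + b'X'V⁻¹X b
    quad = yViy - 2 * beta @ XtViy + beta @ XtViX @ beta
    sign, ld2 = np.linalg.slogdet(XtViX)
    neg2ll = logdet + ld2 + quad
    return neg2ll, C, beta


def _satterthwaite_df(theta_hat: np.ndarray, blocks, p: int,
                      free: np.ndarray) -> np.ndarray:
    """Satterthwaite df per coefficient via finite differences over free θ."""
    scale = max(float(theta_hat.sum()), 1e-12)
    steps = np.maximum(1e-4 * theta_hat, 1e-7 * scale)

    def cov_diag(th):
        _, C, _ = _reml_quantities(np.maximum(th, 0.0), blocks, p)
        if C is None:
            return np.full(p, np.nan)
        return np.diag(C)

    def neg_ll(th):
        v, _, _ = _reml_quantities(np.maximum(th, 0.0), blocks, p)
        return 0.5 * v

    kfree = np.flatnonzero(free)
    m = kfree.size
    if m == 0:
        return np.full(p, np.nan)
    # gradient of v_i(θ) over free components
    grad = np.zeros((m, p))
    for j, k in enumerate(kfree):
        e = np.zeros(3)
        e[k] = steps[k]
        grad[j] = (cov_diag(theta_hat + e) - cov_diag(theta_hat - e)) / (2 * steps[k])
    # observed information of free components
    H = np.zeros((m, m))
    f0 = neg_ll(theta_hat)
    for j, k in enumerate(kfree):
        ek = np.zeros(3)
        ek[k] = steps[k]
        H[j, j] = (neg_ll(theta_hat + ek) - 2 * f0 + neg_ll(theta_hat - ek)) / steps[k] ** 2
        for l, q in enumerate(kfree[:j]):
            eq = np.zeros(3)
            eq[q] = steps[q]
            H[j, l] = H[l, j] = (
                neg_ll(theta_hat + ek + eq) - neg_ll(theta_hat + ek - eq)
                - neg_ll(theta_hat - ek + eq) + neg_ll(theta_hat - ek - eq)
            ) / (4 * steps[k] * steps[q])
    try:
        A = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.full(p, np.nan)
    v0 = cov_diag(theta_hat)
    dfs = np.empty(p)
    for i in range(p):
        g = grad[:, i]
        denom = float(g @ A @ g)
        dfs[i] = 2.0 * v0[i] ** 2 / denom if denom > 0 else np.nan
    return dfs


def _fit_lmm(df: pd.DataFrame, f1: str, f2: str,
             coef_names: list[str]) -> GLMMResult:
    if df["dyad_id"].nunique() < 2:
        raise InsufficientDataError("need at least 2 dyads to fit the model")
    y, X = _design(df, f1, f2)
    p = X.shape[1]
    notes: list[str] = []

    if np.ptp(y) == 0:
        # constant response: intercept is that constant, everything else 0
        rows = [CoefRow("(Intercept)", float(y[0]), 0.0, np.nan, np.nan, np.nan)]
        rows += [CoefRow(n, 0.0, 0.0, np.nan, np.nan, np.nan)
                 for n in coef_names[1:]]
        return GLMMResult(rows, 0.0, 0.0, 0.0, 0.0, 0.0,
                          len(df), df["dyad_id"].nunique(), singular=True,
                          notes=["constant response: zero residual variance"])

    formula = f"rate ~ {f1} * {f2}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, df, groups="dyad_id", re_formula="1",
                            vc_formula={"participant": "0 + C(participant_id)"})
        fit = model.fit(reml=True, method=["lbfgs", "powell"])
    if not fit.converged:
        notes.append("REML optimizer did not report convergence")
    s2d = float(np.asarray(fit.cov_re)[0, 0])
    s2p = float(fit.vcomp[0]) if len(fit.vcomp) else 0.0
    s2e = float(fit.scale)
    theta = np.array([max(s2d, 0.0), max(s2p, 0.0), s2e])

    blocks = _group_blocks(df, y, X)
    _, C, beta = _reml_quantities(theta, blocks, p)
    total = theta.sum()
    free = theta > _SINGULAR_FRAC * total
    free[2] = True  # residual variance is always estimated
    singular = not (free[0] and free[1])
    if singular:
        notes.append("variance component estimated at the boundary (singular fit)")
    dfs = _satterthwaite_df(theta, blocks, p, free)
    if np.any(~np.isfinite(dfs)):
        # fall back to residual df where the approximation degenerates
        fallback = float(len(df) - p)
        dfs = np.where(np.isfinite(dfs), dfs, fallback)
        notes.append("Satterthwaite df fell back to residual df for some terms")

    se = np.sqrt(np.diag(C))
    tvals = beta / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dfs)
    rows = [CoefRow(coef_names[i], float(beta[i]), float(se[i]),
                    float(dfs[i]), float(tvals[i]), float(pvals[i]))
            for i in range(p)]

    var_fixed = float(np.var(X @ beta))
    denom = var_fixed + theta[0] + theta[1] + theta[2]
    r2m = var_fixed / denom
    r2c = (var_fixed + theta[0] + theta[1]) / denom
    return GLMMResult(rows, float(theta[0]), float(theta[1]), float(theta[2]),
                      float(r2m), float(r2c), len(df),
                      df["dyad_id"].nunique(), singular=singular, notes=notes)


# ---------------------------------------------------------------------------
# Public model fits
# ---------------------------------------------------------------------------

def records_to_frame(table: list[RateRecord]) -> pd.DataFrame:
    """RateRecords as a DataFrame with the model's 0/1 codings.

    Role: 0 = recipient, 1 = proposer. Diagnosis: 0 = none, 1 = depression.
    Response: 0 = non-accepting, 1 = accepting.
    """
    df = pd.DataFrame([{
        "dyad_id": r.dyad_id, "participant_id": r.participant_id,
        "event_id": r.event_id, "role": r.role, "diagnosis": r.diagnosis,
        "response": r.response, "rate": r.rate,
    } for r in table])
    if len(df):
        df["Role"] = (df["role"] == "proposer").astype(float)
        df["Diagnosis"] = df["diagnosis"].astype(float)
        df["Response"] = (df["response"] == "accepting").astype(float)
    return df


def fit_role_diagnosis_glmm(table: list[RateRecord] | pd.DataFrame) -> GLMMResult:
    """Rate ~ Role * Diagnosis with dyad and participant-in-dyad intercepts.

    Both roles must be present for at least 2 dyads.
    """
    df = table if isinstance(table, pd.DataFrame) else records_to_frame(table)
    if not len(df):
        raise InsufficientDataError("empty rate table")
    both = df.groupby("dyad_id")["Role"].nunique()
    if (both == 2).sum() < 2:
        raise InsufficientDataError(
            "need both roles observed in at least 2 dyads"
        )
    return _fit_lmm(df, "Role", "Diagnosis",
                    ["(Intercept)", "Role", "Diagnosis", "Role:Diagnosis"])


def fit_response_diagnosis_glmm(table: list[RateRecord] | pd.DataFrame) -> GLMMResult:
    """Rate ~ Response * Diagnosis on proposer rows only."""
    df = table if isinstance(table, pd.DataFrame) else records_to_frame(table)
    if not len(df):
        raise InsufficientDataError("empty rate table")
    if (df["role"] != "proposer").any():
        raise DataError(
            "response model expects proposer rows only; filter recipients first"
        )
    if (df["response"] == "rejecting").any():
        raise DataError("rejecting events must be excluded upstream")
    return _fit_lmm(df, "Response", "Diagnosis",
                    ["(Intercept)", "Response", "Diagnosis", "Response:Diagnosis"])


# ---------------------------------------------------------------------------
# Dependent t-test and Cohen's kappa
# ---------------------------------------------------------------------------

def paired_t(x, y) -> tuple[float, float, float]:
    """Classical dependent t-test with paired Cohen's d = mean(d)/SD(d)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("paired_t needs two equal-length 1-D sequences")
    if x.size < 2:
        raise InsufficientDataError("paired_t needs at least 2 pairs")
    diff = x - y
    sd = float(np.std(diff, ddof=1))
    if sd == 0:
        raise DegenerateSignalError("paired differences have zero variance")
    res = stats.ttest_rel(x, y)
    d = float(np.mean(diff)) / sd
    return float(res.statistic), float(res.pvalue), d


def cohens_kappa(labels_a, labels_b) -> KappaResult:
    """Chance-corrected inter-rater agreement from the confusion matrix."""
    a = pd.Series(list(labels_a), dtype="object")
    b = pd.Series(list(labels_b), dtype="object")
    if len(a) != len(b):
        raise ParameterError(
            f"label sequences differ in length ({len(a)} vs {len(b)})"
        )
    if len(a) == 0:
        raise InsufficientDataError("cohens_kappa needs at least 1 item")
    cats = sorted(set(a) | set(b))
    conf = pd.crosstab(a, b).reindex(index=cats, columns=cats, fill_value=0)
    n = len(a)
    p_o = float(np.trace(conf.to_numpy())) / n
    p_e = float(conf.sum(axis=1) @ conf.sum(axis=0)) / n ** 2
    if p_e == 1.0:
        # both raters used a single shared category throughout
        kappa = 1.0 if p_o == 1.0 else 0.0
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
    return KappaResult(kappa=float(kappa), p_observed=p_o, p_expected=p_e,
                       confusion=conf)
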