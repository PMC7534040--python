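"""Mixed-effects inference for coherence and accuracy data.

Four analyses are provided:

* :func:`group_comparison` — a linear mixed model (LMM) for response-level
  GC or LC with fixed effects of group and response length, crossed random
  intercepts for participants and prompts plus a by-prompt random slope for
  group, fitted by REML, with the group effect tested by a t-test using the
  Satterthwaite approximation to the denominator degrees of freedom.
* :func:`single_case_test` — the same model applied to the control group
  plus one patient, testing the case-vs-controls fixed effect; the
  mixed-model analogue of the classical modified t-test that additionally
  accounts for item (prompt) effects.
* :func:`accuracy_glmm` — a logistic mixed model for trial-level accuracy
  with a 2x2x2 factorial fixed structure (group x task x control demand,
  sum-coded +/-0.5), random intercepts for participants and items with
  within-unit random slopes, fitted by Laplace-approximate maximum
  likelihood; each fixed effect assessed by a likelihood-ratio test against
  the reduced model without it.
* :func:`correlate` — Pearson correlation with the two-sided t-transform p.

The LMM machinery here is self-contained (REML profile likelihood over
variance ratios, GLS fixed effects, finite-difference Satterthwaite), so the
module fully owns the model specification, the random-structure
simplification ladder, and the df computation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "ModelResult",
    "CaseComparison",
    "LMMFit",
    "SeparationError",
    "FitError",
    "fit_lmm",
    "group_comparison",
    "single_case_test",
    "accuracy_glmm",
    "correlate",
    "crawford_howell",
]

ALPHA = 0.05


class SeparationError(ValueError):
    """Complete separation in a logistic model; names the offending cell."""


class FitError(RuntimeError):
    """Model fitting failed even after the simplification ladder."""


@dataclass
class ModelResult:
    """One fixed-effect row: estimate, SE, test statistic, df, p."""

    term: str
    estimate: float
    se: float
    stat: float
    df: float | None
    p: float
    method: str

    def __str__(self) -> str:
        df_txt = f", df = {self.df:.1f}" if self.df is not None else ""
        return (
            f"{self.term}: B = {self.estimate:.3g}, se = {self.se:.3g}, "
            f"stat = {self.stat:.2f}{df_txt}, p = {self.p:.3g} [{self.method}]"
        )


@dataclass
class CaseComparison:
    """Single-case deficit test: one patient against the control group."""

    patient_id: str
    measure: str
    estimate: float
    se: float
    stat: float
    df: float | None
    p: float
    significant: bool
    simplifications: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Linear mixed model: REML with profiled residual variance
# ---------------------------------------------------------------------------


@dataclass
class LMMFit:
    """Fitted linear mixed model."""

    beta: np.ndarray
    vcov_beta: np.ndarray
    sigma2: float                      # residual variance
    gamma: np.ndarray                  # variance ratios, one per component
    component_names: list[str]
    fixed_names: list[str]
    reml_loglik: float
    n: int
    converged: bool
    singular: bool
    simplifications: list[str] = field(default_factory=list)
    _X: np.ndarray | None = None
    _y: np.ndarray | None = None
    _Z: list[np.ndarray] | None = None

    @property
    def variance_components(self) -> dict[str, float]:
        out = {name: self.sigma2 * g for name, g in
               zip(self.component_names, self.gamma)}
        out["residual"] = self.sigma2
        return out


def _indicator(labels: Sequence) -> np.ndarray:
    """n x q indicator matrix for a grouping factor."""
    codes, _ = pd.factorize(np.asarray(labels))
    q = codes.max() + 1
    Z = np.zeros((len(codes), q))
    Z[np.arange(len(codes)), codes] = 1.0
    return Z


def _neg_reml_profiled(gamma, X, y, Z_list):
    """-2x REML log-likelihood with the residual variance profiled out."""
    n, p = X.shape
    V0 = np.eye(n)
    for g, Z in zip(gamma, Z_list):
        if g > 0:
            V0 += g * (Z @ Z.T)
    try:
        L = np.linalg.cholesky(V0)
    except np.linalg.LinAlgError:
        return np.inf, None, None, None
    logdet_V0 = 2.0 * np.sum(np.log(np.diag(L)))
    Xi = np.linalg.solve(L, X)
    yi = np.linalg.solve(L, y)
    XtViX = Xi.T @ Xi
    try:
        beta = np.linalg.solve(XtViX, Xi.T @ yi)
    except np.linalg.LinAlgError:
        return np.inf, None, None, None
    r = yi - Xi @ beta
    q = float(r @ r)
    sigma2 = q / (n - p)
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0 or sigma2 <= 0:
        return np.inf, None, None, None
    crit = (n - p) * np.log(sigma2) + logdet_V0 + logdet_XtViX
    return crit, beta, sigma2, XtViX


def _reml_criterion_full(theta, X, y, Z_list):
    """-2x REML log-likelihood as a function of the full variance vector
    theta = (sigma2_resid, sigma2_1, ..., sigma2_k); used for the
    Satterthwaite information matrix."""
    n, p = X.shape
    V = theta[0] * np.eye(n)
    for s2, Z in zip(theta[1:], Z_list):
        V += s2 * (Z @ Z.T)
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        return np.inf
    logdet_V = 2.0 * np.sum(np.log(np.diag(L)))
    Xi = np.linalg.solve(L, X)
    yi = np.linalg.solve(L, y)
    XtViX = Xi.T @ Xi
    beta = np.linalg.solve(XtViX, Xi.T @ yi)
    r = yi - Xi @ beta
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    return logdet_V + logdet_XtViX + float(r @ r)


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    random_effects: dict[str, np.ndarray],
    fixed_names: Sequence[str] | None = None,
    boundary_tol: float = 1e-6,
) -> LMMFit:
    """Fit y = X beta + sum_i Z_i b_i + e by REML.

    Each entry of ``random_effects`` maps a component name to its n x q_i
    design matrix; each component has a single variance parameter.  The
    residual variance is profiled out and the variance *ratios* are
    optimized with L-BFGS-B.  A component whose ratio lands on the zero
    boundary marks the fit singular.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    names = list(random_effects.keys())
    Z_list = [np.asarray(Z, dtype=float) for Z in random_effects.values()]
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        raise FitError("fixed-effects design matrix is rank deficient")
    if np.allclose(np.std(y), 0.0):
        raise FitError("response has zero variance; model is degenerate")

    k = len(Z_list)
    if k == 0:
        crit, beta, sigma2, XtViX = _neg_reml_profiled(np.empty(0), X, y, Z_list)
        gamma_hat = np.empty(0)
        converged = True
    else:
        def objective(g):
            return _neg_reml_profiled(g, X, y, Z_list)[0]

        best = None
        for x0 in ([0.5] * k, [0.05] * k, [2.0] * k):
            res = optimize.minimize(
                objective,
                x0=np.asarray(x0, dtype=float),
                method="L-BFGS-B",
                bounds=[(0.0, None)] * k,
            )
            if best is None or res.fun < best.fun - 1e-10:
                best = res
        gamma_hat = np.clip(best.x, 0.0, None)
        converged = bool(best.success) or np.isfinite(best.fun)
        crit, beta, sigma2, XtViX = _neg_reml_profiled(gamma_hat, X, y, Z_list)
        if not np.isfinite(crit):
            raise FitError("REML criterion not finite at the optimum")

    vcov_beta = sigma2 * np.linalg.inv(XtViX)
    singular = bool(np.any(gamma_hat <= boundary_tol)) if k else False
    return LMMFit(
        beta=beta,
        vcov_beta=vcov_beta,
        sigma2=sigma2,
        gamma=gamma_hat,
        component_names=names,
        fixed_names=list(fixed_names) if fixed_names is not None
        else [f"x{i}" for i in range(p)],
        reml_loglik=-0.5 * crit,
        n=n,
        converged=converged,
        singular=singular,
        _X=X,
        _y=y,
        _Z=Z_list,
    )


def satterthwaite_df(fit: LMMFit, contrast: np.ndarray) -> float:
    """Approximate denominator df for the t-test of ``contrast @ beta``.

    df = 2 f^2 / (g' A g) where f(theta) = c'(X'V^-1 X)^-1 c, g is the
    finite-difference gradient of f at the REML estimate, and A is the
    asymptotic covariance of the variance estimates (inverse of the
    observed information of the REML criterion).  Variance components stuck
    at the zero boundary are treated as known zeros and excluded.
    """
    c = np.asarray(contrast, dtype=float)
    X, y, Z_all = fit._X, fit._y, fit._Z
    n, p = X.shape

    active = [i for i, g in enumerate(fit.gamma) if g > 1e-6]
    Z_list = [Z_all[i] for i in active]
    theta = np.concatenate(
        [[fit.sigma2], [fit.sigma2 * fit.gamma[i] for i in active]]
    )

    def f(th):
        V = th[0] * np.eye(n)
        for s2, Z in zip(th[1:], Z_list):
            V += s2 * (Z @ Z.T)
        Vi_X = np.linalg.solve(V, X)
        return float(c @ np.linalg.solve(X.T @ Vi_X, c))

    m = len(theta)
    h = np.maximum(np.abs(theta), 1e-8) * 1e-4
    grad = np.zeros(m)
    for i in range(m):
        e = np.zeros(m)
        e[i] = h[i]
        grad[i] = (f(theta + e) - f(np.maximum(theta - e, 1e-12))) / (
            (theta + e)[i] - max(theta[i] - h[i], 1e-12)
        )

    def criterion(th):
        return _reml_criterion_full(np.maximum(th, 1e-12), X, y, Z_list)

    H = np.zeros((m, m))
    f0 = criterion(theta)
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = h[i]
            ej = np.zeros(m); ej[j] = h[j]
            fpp = criterion(theta + ei + ej)
            fpm = criterion(theta + ei - ej)
            fmp = criterion(theta - ei + ej)
            fmm = criterion(theta - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    # criterion is -2 log REML, so information = H / 2
    try:
        A = np.linalg.inv(H / 2.0)
    except np.linalg.LinAlgError:
        A = np.linalg.pinv(H / 2.0)
    denom = float(grad @ A @ grad)
    fval = f(theta)
    if denom <= 0 or not np.isfinite(denom):
        return float(n - p)
    df = 2.0 * fval**2 / denom
    return float(np.clip(df, 1e-3, n - p))


def _term_test(fit: LMMFit, term: str, method: str) -> ModelResult:
    idx = fit.fixed_names.index(term)
    c = np.zeros(len(fit.fixed_names))
    c[idx] = 1.0
    est = float(fit.beta[idx])
    se = float(np.sqrt(fit.vcov_beta[idx, idx]))
    df = satterthwaite_df(fit, c)
    t = est / se
    p = 2.0 * sps.t.sf(abs(t), df)
    return ModelResult(term=term, estimate=est, se=se, stat=t, df=df,
                       p=float(p), method=method)


_LADDER = [
    ("full", ("participant", "prompt", "group_by_prompt")),
    ("drop group-by-prompt slope", ("participant", "prompt")),
    ("drop prompt intercept", ("participant",)),
]


def group_comparison(
    data: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    length: str = "length",
    participant: str = "participant",
    prompt: str = "prompt",
    reference_group: str | None = None,
    random_structure: str = "full",
    include_length: bool = True,
) -> tuple[list[ModelResult], LMMFit]:
    """Mixed-model comparison of two groups on a response-level measure.

    Fixed effects: intercept, group (dummy-coded: the non-reference group's
    offset relative to ``reference_group``), and mean-centred response
    length.  Random structure: participant and prompt intercepts plus a
    by-prompt random slope for group ("full"); on a singular fit the
    structure is simplified (slope dropped, then the prompt intercept) and
    every simplification is recorded on the returned fit.
    """
    df = data.dropna(subset=[value]).reset_index(drop=True)
    groups = sorted(df[group].unique())
    if reference_group is None:
        reference_group = groups[0]
    y = df[value].to_numpy(dtype=float)
    g_code = (df[group] != reference_group).astype(float).to_numpy()
    cols = [np.ones(len(df)), g_code]
    names = ["intercept", "group"]
    if include_length:
        ln = df[length].to_numpy(dtype=float)
        cols.append(ln - ln.mean())
        names.append("length")
    X = np.column_stack(cols)

    Zp = _indicator(df[participant])
    Zq = _indicator(df[prompt])
    Zs = Zq * g_code[:, None]
    available = {
        "participant": Zp,
        "prompt": Zq,
        "group_by_prompt": Zs,
    }

    start = 0 if random_structure == "full" else 1
    simplifications: list[str] = []
    fit = None
    last_err: Exception | None = None
    for label, components in _LADDER[start:]:
        try:
            fit = fit_lmm(
                y, X,
                {k: available[k] for k in components},
                fixed_names=names,
            )
        except (FitError, np.linalg.LinAlgError) as err:
            last_err = err
            simplifications.append(f"{label}: failed ({err})")
            continue
        if fit.singular and label != _LADDER[-1][0]:
            simplifications.append(f"{label}: singular, simplifying")
            continue
        break
    if fit is None:
        raise FitError(f"all random structures failed: {last_err}")
    fit.simplifications = simplifications
    results = [_term_test(fit, t, "lmm_reml_satterthwaite") for t in names]
    return results, fit


def single_case_test(
    case_data: pd.DataFrame,
    control_data: pd.DataFrame,
    value: str = "value",
    measure: str = "",
    length: str = "length",
    participant: str = "participant",
    prompt: str = "prompt",
    random_structure: str = "intercepts",
    include_length: bool = True,
) -> CaseComparison:
    """Test whether one patient's scores differ from the control group.

    The control responses and the case's responses are pooled and the
    group comparison model is fitted with a case indicator; the case fixed
    effect gives the estimated deficit.  By default the random structure
    uses participant and prompt intercepts (a by-prompt slope for a single
    case is not identifiable apart from the residual).
    """
    if case_data.empty:
        raise ValueError("case has no eligible responses")
    if control_data[participant].nunique() < 2:
        raise ValueError("need at least two control participants")
    case = case_data.copy()
    ctrl = control_data.copy()
    case["_role"], ctrl["_role"] = "case", "control"
    combined = pd.concat([ctrl, case], ignore_index=True)
    results, fit = group_comparison(
        combined, value=value, group="_role", length=length,
        participant=participant, prompt=prompt,
        reference_group="control", random_structure=random_structure,
        include_length=include_length,
    )
    res = next(r for r in results if r.term == "group")
    return CaseComparison(
        patient_id=str(case_data[participant].iloc[0]),
        measure=measure or value,
        estimate=res.estimate,
        se=res.se,
        stat=res.stat,
        df=res.df,
        p=res.p,
        significant=res.p < ALPHA,
        simplifications=fit.simplifications,
    )


# ---------------------------------------------------------------------------
# Logistic mixed model (Laplace approximation)
# ---------------------------------------------------------------------------


def _glmm_profile(log_sd, X, Z, block_sizes, y, u_start=None):
    """Penalized IRLS at fixed variance parameters.

    Jointly solves for the fixed effects and the random-effect modes (the
    coefficients are unpenalized, the modes are ridge-penalized by the
    inverse variances), then applies the Laplace correction, mirroring the
    standard profiled-Laplace scheme for logistic mixed models.
    Returns (loglik, beta, b, vcov_beta).
    """
    n, p = X.shape
    q = Z.shape[1]
    d = np.concatenate([
        np.full(m, np.exp(2.0 * ls)) for m, ls in zip(block_sizes, log_sd)
    ]) if q else np.zeros(0)
    dinv = 1.0 / np.maximum(d, 1e-10)
    C = np.hstack([X, Z])
    pen = np.concatenate([np.zeros(p), dinv])
    u = np.zeros(p + q) if u_start is None else u_start.copy()
    for it in range(100):
        eta = C @ u
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        grad = C.T @ (y - mu) - pen * u
        H = (C.T * w) @ C + np.diag(pen)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return -np.inf, None, None, None, None
        # step-halving for stability
        f0 = float(y @ eta - np.logaddexp(0.0, eta).sum()) - 0.5 * float(
            u @ (pen * u)
        )
        scale = 1.0
        for _ in range(20):
            u_new = u + scale * step
            eta_new = C @ u_new
            f1 = float(
                y @ eta_new - np.logaddexp(0.0, eta_new).sum()
            ) - 0.5 * float(u_new @ (pen * u_new))
            if f1 >= f0 - 1e-12:
                break
            scale *= 0.5
        u = u_new
        if np.max(np.abs(scale * step)) < 1e-8:
            break
    eta = C @ u
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    joint = float(y @ eta - np.logaddexp(0.0, eta).sum()) - 0.5 * float(
        u[p:] @ (dinv * u[p:])
    )
    if q:
        Hb = (Z.T * w) @ Z + np.diag(dinv)
        sign, logdet = np.linalg.slogdet(Hb)
        if sign <= 0:
            return -np.inf, None, None, None, None
        ll = joint - 0.5 * float(np.sum(np.log(d))) - 0.5 * logdet
    else:
        ll = joint
    # vcov of beta from the Schur complement of the joint Hessian
    H = (C.T * w) @ C + np.diag(pen)
    try:
        vcov_beta = np.linalg.inv(H)[:p, :p]
    except np.linalg.LinAlgError:
        vcov_beta = np.full((p, p), np.nan)
    return ll, u[:p], u[p:], vcov_beta, u


def _laplace_ll_beta(beta, log_sd, X, Z, block_sizes, y, b_start=None):
    """Laplace marginal log-likelihood at a fixed beta (modes re-solved)."""
    n = len(y)
    q = Z.shape[1]
    offset = X @ beta
    d = np.concatenate([
        np.full(m, np.exp(2.0 * ls)) for m, ls in zip(block_sizes, log_sd)
    ]) if q else np.zeros(0)
    dinv = 1.0 / np.maximum(d, 1e-10)
    b = np.zeros(q) if b_start is None else b_start.copy()
    for _ in range(100):
        eta = offset + Z @ b
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        grad = Z.T @ (y - mu) - dinv * b
        H = (Z.T * w) @ Z + np.diag(dinv)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return -np.inf, b
        b = b + step
        if np.max(np.abs(step)) < 1e-9:
            break
    eta = offset + Z @ b
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -30, 30)))
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    joint = float(y @ eta - np.logaddexp(0.0, eta).sum()) - 0.5 * float(
        b @ (dinv * b)
    )
    if q:
        H = (Z.T * w) @ Z + np.diag(dinv)
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            return -np.inf, b
        joint -= 0.5 * float(np.sum(np.log(d))) + 0.5 * logdet
    return joint, b


def _fit_glmm(X, Z_blocks, y, log_sd0=None):
    """Laplace-approximate ML fit of a Bernoulli-logit mixed model.

    Stage 1: Nelder-Mead over the log random-effect SDs with the fixed
    effects profiled at the joint penalized mode (fast, stable).  Stage 2:
    refine the fixed effects by maximizing the Laplace objective directly
    at the estimated variance parameters (removes the slight attenuation
    of the profiled estimates).
    """
    p = X.shape[1]
    k = len(Z_blocks)
    Z = np.hstack(Z_blocks) if Z_blocks else np.zeros((len(y), 0))
    block_sizes = [zb.shape[1] for zb in Z_blocks]
    state = {"u": None}

    def nll(log_sd):
        ll = _glmm_profile(np.clip(log_sd, -5, 3), X, Z, block_sizes, y,
                           u_start=state["u"])
        if ll[0] > -np.inf:
            state["u"] = ll[4]
        return -ll[0]

    if k:
        x0 = np.full(k, np.log(0.5)) if log_sd0 is None else np.asarray(log_sd0)
        res = optimize.minimize(nll, x0=x0, method="Nelder-Mead",
                                options={"xatol": 1e-4, "fatol": 1e-6,
                                         "maxiter": 400})
        log_sd_hat = np.clip(res.x, -5, 3)
        converged = bool(res.success)
    else:
        log_sd_hat = np.zeros(0)
        converged = True
    ll, beta, b, vcov_beta, _ = _glmm_profile(log_sd_hat, X, Z, block_sizes, y,
                                              u_start=state["u"])
    if beta is None:
        return {"beta": None, "se": None, "log_sd": log_sd_hat,
                "loglik": -np.inf, "converged": False}

    # stage 2: Laplace-ML refinement of the fixed effects
    bstate = {"b": b.copy()}

    def nll_beta(beta_):
        ll_, b_ = _laplace_ll_beta(beta_, log_sd_hat, X, Z, block_sizes, y,
                                   b_start=bstate["b"])
        if np.isfinite(ll_):
            bstate["b"] = b_
        return -ll_

    res_b = optimize.minimize(nll_beta, x0=beta, method="BFGS",
                              options={"gtol": 1e-6, "maxiter": 200})
    if np.isfinite(res_b.fun) and res_b.fun <= -ll + 1e-9:
        beta = res_b.x
        ll = -res_b.fun
    # SEs from the joint-Hessian Schur complement at the refined beta
    ll2, _, _, vcov_beta2, _ = _glmm_profile(
        log_sd_hat, X, Z, block_sizes, y, u_start=state["u"]
    )
    if vcov_beta2 is not None:
        vcov_beta = vcov_beta2
    se = np.sqrt(np.clip(np.diag(vcov_beta), 0.0, None))
    return {
        "beta": beta,
        "se": se,
        "log_sd": log_sd_hat,
        "loglik": ll,
        "converged": converged and np.all(np.isfinite(se)),
    }


def _factorial_design(df, group, task, demand):
    """Sum-coded (+/-0.5) 2x2x2 design matrix with all interactions."""
    def code(col):
        levels = sorted(df[col].unique())
        if len(levels) != 2:
            raise ValueError(f"factor {col!r} must have exactly 2 levels")
        return np.where(df[col] == levels[1], 0.5, -0.5)

    g, t, dm = code(group), code(task), code(demand)
    X = np.column_stack([
        np.ones(len(df)), g, t, dm, g * t, g * dm, t * dm, g * t * dm,
    ])
    names = ["intercept", "group", "task", "demand", "group:task",
             "group:demand", "task:demand", "group:task:demand"]
    return X, names, {"group": g, "task": t, "demand": dm}


def accuracy_glmm(
    trials: pd.DataFrame,
    correct: str = "correct",
    group: str = "group",
    task: str = "task",
    demand: str = "demand",
    participant: str = "participant",
    item: str = "item",
    random_slopes: bool = True,
    terms: Sequence[str] | None = None,
) -> list[ModelResult]:
    """Factorial logistic mixed model for task accuracy.

    Fixed effects: the full 2x2x2 factorial (sum contrasts +/-0.5).  Random
    effects: participant and item intercepts, plus (when ``random_slopes``)
    participant slopes for the within-participant factors task and demand
    and an item slope for group; slopes are dropped block by block if the
    fit fails.  Each fixed effect's p-value comes from a likelihood-ratio
    test of the full model against the model without that term.
    """
    y = trials[correct].to_numpy(dtype=float)
    if np.all(y == y[0]):
        raise SeparationError(
            "all trials have the same outcome; the model is separated"
        )
    X, names, codes = _factorial_design(trials, group, task, demand)
    for cell, sub in trials.groupby([group, task, demand]):
        vals = sub[correct].to_numpy()
        if len(vals) and np.all(vals == vals[0]):
            raise SeparationError(
                f"design cell {cell} has all-{'correct' if vals[0] else 'incorrect'}"
                " outcomes (complete separation)"
            )

    Zp = _indicator(trials[participant])
    Zi = _indicator(trials[item])
    structures = []
    if random_slopes:
        structures.append([
            Zp, Zi,
            Zp * codes["task"][:, None],
            Zp * codes["demand"][:, None],
            Zi * codes["group"][:, None],
        ])
    structures.append([Zp, Zi])

    full = None
    blocks = None
    for Z_blocks in structures:
        fit = _fit_glmm(X, Z_blocks, y)
        if fit["converged"] and np.all(np.isfinite(fit["se"])):
            full, blocks = fit, Z_blocks
            break
    if full is None:
        raise FitError("logistic mixed model failed to converge")

    results = []
    for j, term in enumerate(names):
        if term == "intercept" or (terms is not None and term not in terms):
            continue
        X_red = np.delete(X, j, axis=1)
        red = _fit_glmm(X_red, blocks, y, log_sd0=full["log_sd"])
        lr = max(0.0, 2.0 * (full["loglik"] - red["loglik"]))
        p = float(sps.chi2.sf(lr, df=1))
        results.append(ModelResult(
            term=term,
            estimate=float(full["beta"][j]),
            se=float(full["se"][j]),
            stat=float(np.sign(full["beta"][j]) * np.sqrt(lr)),
            df=None,
            p=p,
            method="glmm_laplace_lrt",
        ))
    return results


# ---------------------------------------------------------------------------
# Correlations and the classical single-case cross-check
# ---------------------------------------------------------------------------


def correlate(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided p from the t transform.

    Pairs with a missing value in either variable are dropped
    (pairwise-complete); at least 3 complete pairs are required.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance variable")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def crawford_howell(case_score: float, control_scores) -> tuple[float, float, float]:
    """Classical modified t-test of a single case against a small control
    sample (cross-check utility for the mixed-model single-case test).

    Returns (t, df, two-sided p).
    """
    c = np.asarray(control_scores, dtype=float)
    n = len(c)
    if n < 2:
        raise ValueError("need at least 2 control scores")
    t = (case_score - c.mean()) / (c.std(ddof=1) * np.sqrt((n + 1) / n))
    df = n - 1
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)
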