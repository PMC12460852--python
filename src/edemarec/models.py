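"""Feature screening and classification over the paired sub-volume cohort.

The modelling chain mirrors a common radiomics workflow: an L1-penalized
(LASSO) logistic screen with the penalty chosen by 10-fold
cross-validated deviance at the minimum, followed by forward stepwise
logistic regression over the surviving features, ROC analysis of the
final model, and SVM / random-forest comparison classifiers under the
same seeded cross-validation.

Each case contributes two observations — its recurrence-overlapped and
its spared edema sub-volume — with the sub-volume identity as the binary
label.  The pairing is deliberately ignored by these models (it is kept
for the Wilcoxon test); that is the only reading consistent with an ROC
over sub-volumes.

The LASSO path is solved by cyclic coordinate descent inside an IRLS
loop on internally standardized features, glmnet-style: objective
(1/n) * negative log-likelihood + lambda * ||beta||_1, lambda grid
log-spaced over four decades below lambda_max (the smallest lambda with
an all-zero penalized solution).  KKT conditions are checked at every
reported solution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import auc_mann_whitney

__all__ = [
    "LassoResult", "StepwiseModel", "validate_cohort_table",
    "lasso_logistic_path", "fit_lasso_logistic",
    "forward_stepwise_logistic", "comparison_classifiers",
    "stratified_folds", "kkt_residual",
]


class SeparationWarning(UserWarning):
    """Quasi-complete separation detected; estimates are unstable."""


def validate_cohort_table(table: pd.DataFrame) -> None:
    """Check the paired design: one rec and one no_rec row per case."""
    for col in ("case_id", "subvolume", "label"):
        if col not in table.columns:
            raise ValueError(f"cohort table lacks required column {col!r}")
    if table["label"].isna().any():
        raise ValueError("cohort table has missing labels")
    counts = table.groupby("case_id")["subvolume"].apply(
        lambda s: sorted(s.tolist()))
    bad = counts[counts.apply(lambda v: v != ["no_rec", "rec"])]
    if len(bad):
        raise ValueError(
            f"cases without exactly one rec and one no_rec row: "
            f"{list(bad.index)[:5]}")


# ---------------------------------------------------------------------------
# L1 logistic path


@dataclass
class LassoResult:
    feature_names: list[str]
    lambda_grid: np.ndarray          # descending
    coef_path: np.ndarray            # (n_lambda, p), standardized scale
    intercept_path: np.ndarray       # (n_lambda,)
    cv_mean: np.ndarray              # mean CV deviance per lambda
    cv_sd: np.ndarray
    lambda_min: float
    selected_features: list[str]
    kkt_max_residual: float
    x_mean: np.ndarray
    x_scale: np.ndarray

    @property
    def coef_at_min(self) -> np.ndarray:
        i = int(np.argmin(np.abs(self.lambda_grid - self.lambda_min)))
        return self.coef_path[i]


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _soft(x, t):
    return np.sign(x) * max(abs(x) - t, 0.0)


def fit_lasso_logistic(X: np.ndarray, y: np.ndarray, lam: float,
                       beta0: float = 0.0, beta: np.ndarray | None = None,
                       tol: float = 1e-11, max_outer: int = 200,
                       max_inner: int = 2000) -> tuple[float, np.ndarray, bool]:
    """Solve (1/n) nll + lam * ||beta||_1 by IRLS + coordinate descent.

    ``X`` must already be standardized.  Returns (intercept, coefficients,
    converged).  Warm-startable through ``beta0`` / ``beta``.
    """
    n, p = X.shape
    beta = np.zeros(p) if beta is None else beta.copy()
    eta = beta0 + X @ beta
    prev_obj = np.inf
    converged = False
    for _ in range(max_outer):
        mu = _sigmoid(eta)
        w = np.clip(mu * (1.0 - mu), 1e-6, None)
        z = eta + (y - mu) / w
        # inner CD on the penalized weighted least squares
        wn = w / n
        xw_sq = (X ** 2 * wn[:, None]).sum(axis=0)
        r = z - beta0 - X @ beta
        for _ in range(max_inner):
            max_step = 0.0
            for j in range(p):
                bj = beta[j]
                rho = (X[:, j] * wn * r).sum() + xw_sq[j] * bj
                bn = _soft(rho, lam) / xw_sq[j]
                if bn != bj:
                    r += X[:, j] * (bj - bn)
                    beta[j] = bn
                    max_step = max(max_step, abs(bn - bj))
            b0n = beta0 + (wn * r).sum() / wn.sum()
            if b0n != beta0:
                r += beta0 - b0n
                max_step = max(max_step, abs(b0n - beta0))
                beta0 = b0n
            if max_step < tol:
                break
        eta = beta0 + X @ beta
        nll = float(np.mean(np.logaddexp(0.0, eta) - y * eta))
        obj = nll + lam * np.abs(beta).sum()
        if abs(prev_obj - obj) < 1e-12 * max(1.0, abs(obj)):
            converged = True
            break
        prev_obj = obj
    return beta0, beta, converged


def kkt_residual(X: np.ndarray, y: np.ndarray, beta0: float,
                 beta: np.ndarray, lam: float) -> float:
    """Max violation of the stationarity conditions of the L1 problem."""
    n = X.shape[0]
    mu = _sigmoid(beta0 + X @ beta)
    g = X.T @ (mu - y) / n
    res = abs(float(np.mean(mu - y)))  # unpenalized intercept
    for j in range(X.shape[1]):
        if beta[j] == 0.0:
            res = max(res, max(abs(g[j]) - lam, 0.0))
        else:
            res = max(res, abs(g[j] + lam * np.sign(beta[j])))
    return res


def stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Seeded stratified fold assignment (round-robin within class)."""
    rng = np.random.default_rng(seed)
    folds = np.empty(y.size, dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        folds[idx] = np.arange(idx.size) % k
    return folds


def _binomial_deviance(y, eta):
    return float(2.0 * np.mean(np.logaddexp(0.0, eta) - y * eta))


def lasso_logistic_path(table: pd.DataFrame, features: list[str],
                        folds: int = 10, seed: int = 0,
                        n_lambda: int = 100, decades: float = 4.0,
                        label_col: str = "label") -> LassoResult:
    """Cross-validated L1 logistic path over the cohort table.

    Features are standardized internally (zero mean, unit population sd).
    The grid runs from lambda_max down ``decades`` decades; fold
    assignment is stratified by label and seeded.  ``lambda_min``
    minimizes the mean cross-validated deviance.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 candidate features")
    y = np.asarray(table[label_col], dtype=float)
    if set(np.unique(y)) != {0.0, 1.0}:
        raise ValueError("label must be binary with both classes present")
    Xraw = np.asarray(table[list(features)], dtype=float)
    if np.isnan(Xraw).any():
        raise ValueError("features contain missing values")
    x_mean = Xraw.mean(axis=0)
    x_scale = Xraw.std(axis=0)
    if np.any(x_scale == 0):
        zero = [f for f, s in zip(features, x_scale) if s == 0]
        raise ValueError(f"constant features cannot be standardized: {zero}")
    X = (Xraw - x_mean) / x_scale
    n = X.shape[0]

    lam_max = float(np.max(np.abs(X.T @ (y - y.mean()))) / n)
    grid = np.logspace(np.log10(lam_max), np.log10(lam_max) - decades, n_lambda)

    def path_fit(Xf, yf):
        coefs = np.zeros((n_lambda, X.shape[1]))
        icpts = np.zeros(n_lambda)
        b0, b = float(np.log(yf.mean() / (1 - yf.mean()))), None
        truncated_at = None
        for i, lam in enumerate(grid):
            b0, b, ok = fit_lasso_logistic(Xf, yf, lam, beta0=b0, beta=b)
            if not ok or np.max(np.abs(b)) > 1e3:
                warnings.warn(
                    "separation along the L1 path; truncating remaining "
                    "lambdas", SeparationWarning, stacklevel=3)
                truncated_at = i
                coefs[i:] = coefs[i - 1] if i else 0.0
                icpts[i:] = icpts[i - 1] if i else b0
                break
            coefs[i], icpts[i] = b, b0
        return icpts, coefs, truncated_at

    icpts, coefs, truncated_at = path_fit(X, y)
    n_eff = n_lambda if truncated_at is None else truncated_at

    kkt = max(
        (kkt_residual(X, y, icpts[i], coefs[i], grid[i]) for i in range(n_eff)),
        default=np.inf)

    fold_id = stratified_folds(y.astype(int), folds, seed)
    dev = np.full((folds, n_lambda), np.nan)
    for f in range(folds):
        tr, te = fold_id != f, fold_id == f
        ic_f, co_f, trunc_f = path_fit(X[tr], y[tr])
        stop = n_lambda if trunc_f is None else trunc_f
        for i in range(stop):
            eta = ic_f[i] + X[te] @ co_f[i]
            dev[f, i] = _binomial_deviance(y[te], eta)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        cv_mean = np.nanmean(dev, axis=0)
        cv_sd = np.nanstd(dev, axis=0, ddof=1)
    valid = np.isfinite(cv_mean)
    valid[n_eff:] = False
    i_min = int(np.flatnonzero(valid)[np.argmin(cv_mean[valid])])
    selected = [f for f, c in zip(features, coefs[i_min]) if c != 0.0]

    return LassoResult(
        feature_names=list(features), lambda_grid=grid, coef_path=coefs,
        intercept_path=icpts, cv_mean=cv_mean, cv_sd=cv_sd,
        lambda_min=float(grid[i_min]), selected_features=selected,
        kkt_max_residual=float(kkt), x_mean=x_mean, x_scale=x_scale)


# ---------------------------------------------------------------------------
# Unpenalized logistic (IRLS) and forward stepwise selection


def irls_logistic(X: np.ndarray, y: np.ndarray, tol: float = 1e-8,
                  max_iter: int = 200):
    """Maximum-likelihood logistic fit with an intercept column prepended.

    Returns (beta, deviance, cov, converged); ``cov`` is the inverse
    observed information (Wald covariance).  Stops early on divergence
    (quasi-separation) and reports converged=False.
    """
    n, p = X.shape
    Z = np.column_stack([np.ones(n), X])
    beta = np.zeros(p + 1)
    beta[0] = np.log(np.clip(y.mean(), 1e-12, 1 - 1e-12)
                     / np.clip(1 - y.mean(), 1e-12, 1 - 1e-12))
    dev_prev = np.inf
    converged = False
    for _ in range(max_iter):
        eta = Z @ beta
        mu = _sigmoid(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        zadj = eta + (y - mu) / w
        WZ = Z * w[:, None]
        H = Z.T @ WZ
        try:
            beta = np.linalg.solve(H, Z.T @ (w * zadj))
        except np.linalg.LinAlgError:
            break
        dev = 2.0 * np.sum(np.logaddexp(0.0, Z @ beta) - y * (Z @ beta))
        if abs(dev_prev - dev) < tol:
            converged = True
            dev_prev = dev
            break
        dev_prev = dev
        if np.max(np.abs(beta)) > 1e4:
            break
    eta = Z @ beta
    mu = _sigmoid(eta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    H = Z.T @ (Z * w[:, None])
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.full((p + 1, p + 1), np.nan)
    dev = 2.0 * float(np.sum(np.logaddexp(0.0, eta) - y * eta))
    return beta, dev, cov, converged


@dataclass
class StepwiseModel:
    included_features: list[str]
    intercept: float
    coefficients: np.ndarray
    odds_ratios: np.ndarray
    p_values: np.ndarray            # Wald, per included feature
    entry_p_values: np.ndarray      # LRT p at the step each feature entered
    n_obs: int
    intercept_only: bool = False
    separation_flag: bool = False

    def linear_score(self, table: pd.DataFrame) -> np.ndarray:
        X = np.asarray(table[self.included_features], dtype=float) \
            if self.included_features else np.zeros((len(table), 0))
        return self.intercept + X @ self.coefficients

    def predicted_probability(self, table: pd.DataFrame) -> np.ndarray:
        return _sigmoid(self.linear_score(table))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "feature": self.included_features,
            "coefficient": self.coefficients,
            "odds_ratio": self.odds_ratios,
            "wald_p": self.p_values,
            "entry_lrt_p": self.entry_p_values,
        })


def forward_stepwise_logistic(table: pd.DataFrame, candidates: list[str],
                              alpha_entry: float = 0.05,
                              label_col: str = "label") -> StepwiseModel:
    """Greedy forward entry by smallest likelihood-ratio p-value.

    Candidates are admitted while the LRT p of the best addition is below
    ``alpha_entry``; the final model is refit by IRLS to convergence and
    reported with Wald p-values and odds ratios.  With no admissible
    candidate the intercept-only model is returned with an explicit flag.
    """
    from scipy.stats import chi2, norm

    y = np.asarray(table[label_col], dtype=float)
    included: list[str] = []
    entry_ps: list[float] = []
    remaining = list(candidates)
    n = len(table)

    def dev_of(feats):
        X = (np.asarray(table[feats], dtype=float)
             if feats else np.zeros((n, 0)))
        beta, dev, cov, conv = irls_logistic(X, y)
        return beta, dev, cov, conv

    _, dev_cur, _, _ = dev_of([])
    while remaining:
        best = None
        for f in remaining:
            _, dev_f, _, _ = dev_of(included + [f])
            lr = max(dev_cur - dev_f, 0.0)
            p = float(chi2.sf(lr, df=1))
            if best is None or p < best[1]:
                best = (f, p, dev_f)
        if best is None or best[1] >= alpha_entry:
            break
        included.append(best[0])
        entry_ps.append(best[1])
        remaining.remove(best[0])
        dev_cur = best[2]

    if not included:
        beta, dev, cov, conv = dev_of([])
        return StepwiseModel(
            included_features=[], intercept=float(beta[0]),
            coefficients=np.zeros(0), odds_ratios=np.zeros(0),
            p_values=np.zeros(0), entry_p_values=np.zeros(0),
            n_obs=n, intercept_only=True, separation_flag=not conv)

    beta, dev, cov, conv = dev_of(included)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    coefs = beta[1:]
    with np.errstate(divide="ignore", invalid="ignore"):
        zvals = coefs / se[1:]
    wald_p = 2.0 * norm.sf(np.abs(zvals))
    sep = (not conv) or bool(np.max(np.abs(coefs)) > 30)
    if sep:
        warnings.warn("quasi-complete separation in the stepwise refit; "
                      "coefficients are unstable", SeparationWarning,
                      stacklevel=2)
    return StepwiseModel(
        included_features=included, intercept=float(beta[0]),
        coefficients=coefs, odds_ratios=np.exp(coefs),
        p_values=np.asarray(wald_p), entry_p_values=np.asarray(entry_ps),
        n_obs=n, intercept_only=False, separation_flag=sep)


def select_features_chain(table: pd.DataFrame, features: list[str],
                          folds: int = 10, seed: int = 0,
                          alpha_entry: float | None = None,
                          label_col: str = "label"
                          ) -> tuple[LassoResult, StepwiseModel]:
    """The full screening chain: LASSO at lambda_min, then forward stepwise.

    Stepwise entry p-values computed on LASSO-screened candidates are
    selection-biased (a surviving noise feature is roughly the best of
    the screened universe), so by default the chain Bonferroni-adjusts
    the 0.05 entry level over the *original* feature universe
    (``0.05 / len(features)``) rather than applying it per screened
    candidate.  Pass ``alpha_entry`` explicitly to override.
    """
    lasso = lasso_logistic_path(table, features, folds=folds, seed=seed,
                                label_col=label_col)
    if alpha_entry is None:
        alpha_entry = 0.05 / len(features)
    stepwise = forward_stepwise_logistic(table, lasso.selected_features,
                                         alpha_entry=alpha_entry,
                                         label_col=label_col)
    return lasso, stepwise


# ---------------------------------------------------------------------------
# Comparison classifiers


def comparison_classifiers(table: pd.DataFrame, features: list[str],
                           folds: int = 10, seed: int = 0,
                           label_col: str = "label") -> dict[str, float]:
    """SVM (RBF) and random-forest AUCs under seeded stratified CV.

    Features are standardized for the SVM.  Reported value per model is
    the mean of per-fold AUCs (higher decision score taken as the
    positive class, no orientation flip).  The contract is
    reproducibility under a fixed seed, not specific values.
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.svm import SVC

    y = np.asarray(table[label_col]).astype(int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("label must be binary with both classes present")
    X = np.asarray(table[list(features)], dtype=float)
    fold_id = stratified_folds(y, folds, seed)
    aucs: dict[str, list[float]] = {"svm_rbf": [], "random_forest": []}
    for f in range(folds):
        tr, te = fold_id != f, fold_id == f
        if len(np.unique(y[te])) < 2:
            continue
        mu, sd = X[tr].mean(axis=0), X[tr].std(axis=0)
        sd[sd == 0] = 1.0
        Xtr, Xte = (X[tr] - mu) / sd, (X[te] - mu) / sd
        svm = SVC(kernel="rbf", C=1.0, gamma="scale")
        svm.fit(Xtr, y[tr])
        aucs["svm_rbf"].append(auc_mann_whitney(svm.decision_function(Xte), y[te]))
        rf = RandomForestClassifier(n_estimators=200,
                                    random_state=(seed + 7919 * f) % (2 ** 31))
        rf.fit(X[tr], y[tr])
        aucs["random_forest"].append(
            auc_mann_whitney(rf.predict_proba(X[te])[:, 1], y[te]))
    return {k: float(np.mean(v)) for k, v in aucs.items()}
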