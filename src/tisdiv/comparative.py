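"""Cross-species comparative statistics for TIS-diversity effect lengths.

Species-level estimates (effect length Le, effect size Se, structure
effect Sss, recombination-to-mutation ratio r/m, rRNA count, codon usage
bias of highly expressed genes, strain count, doubling time) are related
by rank correlations, collinearity checks (VIF), standardized multiple
regression, phylogenetic generalized least squares with Pagel's lambda,
and predictor selection by backward elimination under repeated k-fold
cross-validation.

Pagel's lambda scales the off-diagonal entries of the tree-derived
(Brownian-motion) covariance matrix: lambda = 0 means phylogenetically
independent residuals, lambda = 1 full Brownian covariance.  The GLS
estimator is beta = (X' V^-1 X)^-1 X' V^-1 y with V = V(lambda), sigma^2
profiled out, and lambda estimated by maximizing the (restricted)
log-likelihood over [0, 1].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from sklearn.model_selection import KFold

__all__ = [
    "box_cox_transform",
    "spearman",
    "correlation_matrix",
    "vif",
    "scaled_ols",
    "tree_covariance",
    "pagel_covariance",
    "GLSFit",
    "pgls_pagel",
    "backward_elimination_cv",
    "filter_extreme",
]

logger = logging.getLogger(__name__)

_CHI2_95_1DF = stats.chi2.ppf(0.95, 1)


def box_cox_transform(x, lam: float):
    """Box-Cox power transform: ln x at lam = 0, else (x^lam - 1)/lam.

    Strictly increasing for every lam; affinely equivalent to the plain
    log / power transforms, so rank statistics and regression fits agree
    with either convention.  Rejects non-positive input.
    """
    arr = np.asarray(x, dtype=float)
    bad = np.flatnonzero(~(arr > 0))
    if bad.size:
        raise ValueError(f"box_cox_transform requires positive input; offending rows: {bad.tolist()[:10]}")
    from scipy.special import boxcox as _boxcox  # underflow-safe near lam = 0

    return _boxcox(arr, lam)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with its
    large-sample p-value, on pairwise-complete observations."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    if ok.sum() < 5:
        raise ValueError(f"need >= 5 complete pairs, got {int(ok.sum())}")
    if np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
        raise ValueError("constant input: correlation undefined")
    rho, p = stats.spearmanr(x[ok], y[ok])
    return float(rho), float(p)


def correlation_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Spearman correlations among all columns."""
    cols = list(df.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            try:
                rho, _ = spearman(df[a], df[b])
            except ValueError:
                rho = np.nan
            out.loc[a, b] = out.loc[b, a] = rho
    return out


def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1 - R^2) per predictor.

    Each predictor is regressed (with intercept) on the remaining ones;
    perfect collinearity yields inf.
    """
    if design.shape[1] < 2:
        raise ValueError("need >= 2 predictors")
    if design.shape[0] <= design.shape[1]:
        raise ValueError("need more rows than predictors")
    out = {}
    for col in design.columns:
        others = sm.add_constant(design.drop(columns=col).to_numpy())
        r2 = sm.OLS(design[col].to_numpy(), others).fit().rsquared
        out[col] = math.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    s = pd.Series(out)
    if np.isinf(s).any():
        logger.warning("perfect collinearity: infinite VIF for %s",
                       list(s.index[np.isinf(s)]))
    return s


def _standardize(a: np.ndarray) -> np.ndarray:
    sd = a.std(axis=0, ddof=1)
    if np.any(sd == 0):
        raise ValueError("cannot scale a constant column")
    return (a - a.mean(axis=0)) / sd


def scaled_ols(response, predictors: pd.DataFrame):
    """OLS on variables centered and scaled to unit SD.

    Standardization makes coefficients directly comparable across
    predictors.  Returns the statsmodels results object; raises on rank
    deficiency, naming the aliased columns.
    """
    y = _standardize(np.asarray(response, dtype=float).reshape(-1, 1)).ravel()
    X = _standardize(predictors.to_numpy(dtype=float))
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1, got n={n}, p={p}")
    if np.linalg.matrix_rank(X) < p:
        _, r = np.linalg.qr(X)
        aliased = [predictors.columns[i] for i in range(p) if abs(r[i, i]) < 1e-10]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    model = sm.OLS(y, sm.add_constant(X))
    res = model.fit()
    res.model.exog_names[:] = ["const", *predictors.columns]
    return res


# ---------------------------------------------------------------------------
# phylogenetic GLS


def tree_covariance(tree: dendropy.Tree | str, taxa: list[str] | None = None) -> pd.DataFrame:
    """Brownian-motion covariance from a phylogeny.

    C[i, j] is the shared branch length from the root to the most recent
    common ancestor of tips i and j; C[i, i] is the root-to-tip depth.
    ``tree`` may be a dendropy Tree or a newick string/path.
    """
    if isinstance(tree, str):
        src = {"path": tree} if "(" not in tree else {"data": tree}
        tree = dendropy.Tree.get(schema="newick", **src)
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))

    def walk(node, depth: float) -> list[int]:
        elen = node.edge.length or 0.0
        d = depth + (elen if node.parent_node is not None else 0.0)
        if node.is_leaf():
            i = idx[node.taxon.label]
            C[i, i] = d
            return [i]
        groups = [walk(ch, d) for ch in node.child_nodes()]
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                for a in groups[gi]:
                    for b in groups[gj]:
                        C[a, b] = C[b, a] = d
        return [i for g in groups for i in g]

    walk(tree.seed_node, 0.0)
    df = pd.DataFrame(C, index=labels, columns=labels)
    if taxa is not None:
        missing = sorted(set(taxa) - set(labels))
        if missing:
            raise ValueError(f"species missing from tree: {missing}")
        df = df.loc[taxa, taxa]
    return df


def pagel_covariance(C: np.ndarray, lam: float) -> np.ndarray:
    """Multiply the off-diagonal entries of C by Pagel's lambda."""
    V = lam * C
    np.fill_diagonal(V, np.diag(C))
    return V


@dataclass
class GLSFit:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    lam: float
    lam_ci: tuple[float, float]
    loglik: float
    sigma2: float
    residuals: np.ndarray
    n: int
    method: str


def _gls_profile(y: np.ndarray, X: np.ndarray, V: np.ndarray, reml: bool):
    """GLS estimates and profiled log-likelihood for a fixed covariance V."""
    n, p = X.shape
    L = np.linalg.cholesky(V)
    Xi = np.linalg.solve(L, X)
    yi = np.linalg.solve(L, y)
    XtX = Xi.T @ Xi
    beta = np.linalg.solve(XtX, Xi.T @ yi)
    r = yi - Xi @ beta
    rss = float(r @ r)
    logdetV = 2.0 * float(np.sum(np.log(np.diag(L))))
    if reml:
        s2 = rss / (n - p)
        sign, logdetXtX = np.linalg.slogdet(XtX)
        ll = -0.5 * ((n - p) * math.log(2 * math.pi * s2) + logdetV
                     + logdetXtX + (n - p))
    else:
        s2 = rss / n
        ll = -0.5 * (n * math.log(2 * math.pi * s2) + logdetV + n)
    # coefficient covariance with the usual dof-corrected variance
    s2_dof = rss / (n - p)
    cov_beta = np.linalg.inv(XtX) * s2_dof
    resid_orig = y - X @ beta
    return beta, cov_beta, s2_dof, ll, resid_orig


def pgls_pagel(
    response,
    predictors: pd.DataFrame,
    tree,
    lambda_mode: float | str = "ML",
    scale: bool = True,
    reml: bool = False,
) -> GLSFit:
    """Phylogenetic GLS with a Pagel's-lambda correlation structure.

    ``lambda_mode`` is either a fixed value in [0, 1] or "ML" to estimate
    lambda by golden-section maximization of the (restricted) likelihood.
    With ``scale=True`` response and predictors are standardized first, so
    a lambda = 0 fit reproduces the scaled OLS coefficients.  The 95% CI
    for lambda comes from the profile likelihood (chi-square(1) cutoff),
    clipped to [0, 1].
    """
    y = np.asarray(response, dtype=float)
    Cdf = tree_covariance(tree, taxa=list(predictors.index)) if not isinstance(tree, pd.DataFrame) else tree.loc[predictors.index, predictors.index]
    C = Cdf.to_numpy(dtype=float)
    if scale:
        y = _standardize(y.reshape(-1, 1)).ravel()
        X = _standardize(predictors.to_numpy(dtype=float))
    else:
        X = predictors.to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(y)), X])
    names = ["const", *predictors.columns]
    n, p = X.shape

    def negll(lam: float) -> float:
        V = pagel_covariance(C, lam)
        try:
            return -_gls_profile(y, X, V, reml)[3]
        except np.linalg.LinAlgError:
            return math.inf

    if isinstance(lambda_mode, str):
        if lambda_mode.upper() not in ("ML", "REML"):
            raise ValueError(f"unknown lambda_mode {lambda_mode!r}")
        reml = reml or lambda_mode.upper() == "REML"
        opt = optimize.minimize_scalar(negll, bounds=(0.0, 1.0), method="bounded",
                                       options={"xatol": 1e-6})
        lam = float(opt.x)
        # boundary beats interior optimum sometimes; check ends explicitly
        for cand in (0.0, 1.0):
            if negll(cand) < negll(lam):
                lam = cand
    else:
        lam = float(lambda_mode)
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda must be in [0, 1], got {lam}")

    V = pagel_covariance(C, lam)
    try:
        beta, cov_beta, s2, ll, resid = _gls_profile(y, X, V, reml)
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"non-positive-definite covariance at lambda={lam}: {exc}")
    se = np.sqrt(np.diag(cov_beta))
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), df=n - p)

    # profile-likelihood CI
    cut = -(ll - _CHI2_95_1DF / 2.0)

    def diff(l2: float) -> float:
        return negll(l2) - cut

    lo, hi = 0.0, 1.0
    if diff(0.0) > 0:
        lo = optimize.brentq(diff, 0.0, lam) if lam > 0 else 0.0
    if diff(1.0) > 0:
        hi = optimize.brentq(diff, lam, 1.0) if lam < 1 else 1.0

    return GLSFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        lam=lam,
        lam_ci=(float(lo), float(hi)),
        loglik=float(ll),
        sigma2=float(s2),
        residuals=resid,
        n=n,
        method="REML" if reml else "ML",
    )


# ---------------------------------------------------------------------------
# backward elimination with repeated k-fold cross-validation


def _cv_metrics(y: np.ndarray, X: np.ndarray, k: int, reps: int, seed: int):
    """Mean (rmse, r2, mae) of held-out predictions over ``reps`` repetitions.

    Within each repetition, every row is predicted from the fold that holds
    it out and the metrics pool all held-out errors, so k = n gives exact
    leave-one-out prediction error.  Folds whose training response is
    constant are skipped and logged.
    """
    n = len(y)
    Xc = np.column_stack([np.ones(n), X]) if X.size else np.ones((n, 1))
    rmses, r2s, maes = [], [], []
    for rep in range(reps):
        kf = KFold(n_splits=k, shuffle=True, random_state=seed + rep)
        errs = np.full(n, np.nan)
        for train, test in kf.split(Xc):
            if np.ptp(y[train]) == 0:
                logger.info("fold with constant training response skipped")
                continue
            beta, *_ = np.linalg.lstsq(Xc[train], y[train], rcond=None)
            errs[test] = y[test] - Xc[test] @ beta
        ok = ~np.isnan(errs)
        e, yo = errs[ok], y[ok]
        rmses.append(math.sqrt(float(np.mean(e**2))))
        maes.append(float(np.mean(np.abs(e))))
        sst = float(np.sum((yo - yo.mean()) ** 2))
        r2s.append(1.0 - float(np.sum(e**2)) / sst)
    return float(np.mean(rmses)), float(np.mean(r2s)), float(np.mean(maes))


def backward_elimination_cv(
    response,
    predictors: pd.DataFrame,
    k: int = 10,
    reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Backward elimination scored by repeated k-fold CV prediction error.

    Starting from the full model, the predictor whose removal minimizes
    the mean cross-validated RMSE is dropped at each step, down to a
    single predictor.  The returned ladder has one row per model size with
    per-predictor inclusion flags and mean RMSE, R2 and MAE over
    reps x folds; the row with minimal RMSE marks the selected model.
    Bit-reproducible under ``seed``.
    """
    y = np.asarray(response, dtype=float)
    n = len(y)
    if k != n and n < 3 * k:  # k = n is exact leave-one-out
        raise ValueError(f"need n >= 3k rows, got n={n}, k={k}")
    cols = list(predictors.columns)
    Xfull = predictors.to_numpy(dtype=float)

    rows = []
    current = list(range(len(cols)))
    while current:
        rmse, r2, mae = _cv_metrics(y, Xfull[:, current], k, reps, seed)
        rows.append({**{c: (i in current) for i, c in enumerate(cols)},
                     "size": len(current), "rmse": rmse, "r2": r2, "mae": mae})
        if len(current) == 1:
            break
        scores = []
        for drop in current:
            sub = [i for i in current if i != drop]
            scores.append((_cv_metrics(y, Xfull[:, sub], k, reps, seed)[0], drop))
        _, worst = min(scores)
        current = [i for i in current if i != worst]
    ladder = pd.DataFrame(rows).sort_values("size").reset_index(drop=True)
    ladder["selected"] = ladder["rmse"] == ladder["rmse"].min()
    return ladder


def filter_extreme(values: pd.Series, lower: float = 1e-3, upper: float = 1e3) -> pd.Series:
    """Drop rows outside [lower, upper]; used for extreme r/m estimates."""
    keep = (values >= lower) & (values <= upper)
    dropped = values.index[~keep & values.notna()]
    if len(dropped):
        logger.info("filter_extreme: dropped %s", list(dropped))
    return values[keep]
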