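"""Diversity-vs-position profiles and the asymptotic regression fit.

Mean silent-site diversity rises with distance l from the translation
initiation site (TIS) and saturates.  The profile is modelled with the
negative-exponential asymptotic regression

    pibar(l) = dmax + (dmin - dmax) * exp(-c * l) + eps,   eps ~ (0, sigma^2 / w(l))

where dmin is the mean diversity at l = 0, dmax the asymptote, and c the
relative rate of approach.  Weights w(l) are the number of genes
contributing at position l.  Two derived quantities summarize the gradient:

    Effect Size   Se = log2(dmax / dmin)      (log-2 fold reduction at the TIS)
    Effect Length Le = ln 2 / c               (position of the half-way point)

with standard errors by the delta method from the parameter covariance.
The fit is parameterized in (dmin, dmax, K = ln c) so that c stays
positive, and minimized by Levenberg-Marquardt least squares with
self-start initial values.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "DiversityProfile",
    "ASRFit",
    "EffectEstimates",
    "aggregate_profile",
    "fit_asr",
    "asr_model",
    "effect_estimates",
    "effect_standard_errors",
    "observed_effect_size",
    "diversity_length_correlation",
]

logger = logging.getLogger(__name__)


@dataclass
class DiversityProfile:
    """Positions l, mean diversity pibar(l), and gene-count weights w(l)."""

    l: np.ndarray
    mean_pi: np.ndarray
    weight: np.ndarray

    def __post_init__(self) -> None:
        self.l = np.asarray(self.l, dtype=np.float64)
        self.mean_pi = np.asarray(self.mean_pi, dtype=np.float64)
        self.weight = np.asarray(self.weight, dtype=np.float64)
        if not (len(self.l) == len(self.mean_pi) == len(self.weight)):
            raise ValueError("profile arrays must have equal length")
        if (self.weight < 1).any():
            raise ValueError("profile weights must be >= 1")

    def __len__(self) -> int:
        return len(self.l)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"l": self.l.astype(int), "mean_pi": self.mean_pi,
                             "n_genes": self.weight.astype(int)})


@dataclass
class ASRFit:
    """Result of the weighted asymptotic-regression fit.

    ``cov`` is the 3x3 covariance of (dmin, dmax, K) where K = ln c.
    """

    dmin: float
    dmax: float
    c: float
    cov: np.ndarray | None
    resid_var: float
    converged: bool
    n_positions: int
    message: str = ""

    @property
    def K(self) -> float:
        return math.log(self.c) if self.c > 0 else math.nan


@dataclass
class EffectEstimates:
    Se: float
    Le: float
    sigma_Se: float
    sigma_Le: float
    saturation_point: float = field(init=False)
    positive_effect: bool = field(init=False)

    def __post_init__(self) -> None:
        self.saturation_point = 4.0 * self.Le
        self.positive_effect = self.Se > 0


def aggregate_profile(
    tables: Iterable[pd.DataFrame], max_l: int = 500, min_genes: int = 20
) -> DiversityProfile:
    """Average per-gene 4-fold site diversities by offset l.

    For each l <= ``max_l``, the mean of pi over genes contributing a
    retained 4-fold site at that offset; positions with fewer than
    ``min_genes`` contributors are dropped.
    """
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    n_tables = 0
    for tab in tables:
        n_tables += 1
        four = tab[tab["fourfold"] & tab["pi"].notna() & (tab["offset_l"] <= max_l)
                   & (tab["offset_l"] >= 0)]
        for l, pi in zip(four["offset_l"].to_numpy(), four["pi"].to_numpy()):
            sums[int(l)] = sums.get(int(l), 0.0) + float(pi)
            counts[int(l)] = counts.get(int(l), 0) + 1
    if n_tables == 0:
        raise ValueError("no gene tables supplied")
    ls = sorted(l for l, n in counts.items() if n >= min_genes)
    if not ls:
        raise ValueError(
            f"empty profile: no position has >= {min_genes} contributing genes"
        )
    mean = np.array([sums[l] / counts[l] for l in ls])
    w = np.array([counts[l] for l in ls], dtype=float)
    return DiversityProfile(np.array(ls, dtype=float), mean, w)


def asr_model(l, dmin: float, dmax: float, c: float):
    """dmax + (dmin - dmax) * exp(-c l)."""
    return dmax + (dmin - dmax) * np.exp(-c * np.asarray(l, dtype=np.float64))


def _self_start(profile: DiversityProfile) -> tuple[float, float, float]:
    """Classic asymptotic self-start: asymptote from the tail, intercept
    from the head, rate from a log-linear fit of the residual decay."""
    order = np.argsort(profile.l)
    l = profile.l[order]
    y = profile.mean_pi[order]
    q = max(1, len(l) // 4)
    dmax0 = float(np.mean(y[-q:]))
    dmin0 = max(float(y[0]), 1e-6)
    resid = dmax0 - y
    ok = resid > 0
    if ok.sum() >= 2 and np.ptp(l[ok]) > 0:
        slope = np.polyfit(l[ok], np.log(resid[ok]), 1)[0]
        c0 = max(-float(slope), 1e-6)
    else:
        c0 = math.log(2) / max(float(np.ptp(l)) / 2.0, 1.0)
    return dmin0, dmax0, c0


def fit_asr(profile: DiversityProfile, max_iter: int = 200, xtol: float = 1e-10) -> ASRFit:
    """Weighted nonlinear least squares of the asymptotic model.

    Minimizes sum_l w(l) (pibar(l) - model(l))^2 over (dmin, dmax, K=ln c)
    using Levenberg-Marquardt.  The parameter covariance is
    (J^T W J)^{-1} * sigma_hat^2 with sigma_hat^2 the weighted residual
    mean square.  Failure to converge or a singular Jacobian is reported
    via ``converged=False``, never raised.
    """
    if len(profile) < 10:
        raise ValueError(f"need >= 10 profile positions, got {len(profile)}")
    if np.ptp(profile.l) <= 0:
        raise ValueError("profile positions span no range")
    l, y, w = profile.l, profile.mean_pi, profile.weight
    sw = np.sqrt(w)
    dmin0, dmax0, c0 = _self_start(profile)

    def resid(theta: np.ndarray) -> np.ndarray:
        dmin, dmax, K = theta
        return sw * (y - asr_model(l, dmin, dmax, math.exp(K)))

    def jac(theta: np.ndarray) -> np.ndarray:
        dmin, dmax, K = theta
        c = math.exp(K)
        e = np.exp(-c * l)
        J = np.empty((len(l), 3))
        J[:, 0] = -sw * e                                   # d/d dmin
        J[:, 1] = -sw * (1.0 - e)                           # d/d dmax
        J[:, 2] = -sw * (dmax - dmin) * l * e * c           # d/dK (chain rule)
        return J

    theta0 = np.array([dmin0, dmax0, math.log(c0)])
    try:
        res = optimize.least_squares(
            resid, theta0, jac=jac, method="lm", xtol=xtol, ftol=xtol,
            gtol=xtol, max_nfev=max_iter * 10,
        )
    except Exception as exc:  # pathological inputs; report, don't raise
        return ASRFit(dmin0, dmax0, c0, None, math.nan, False, len(profile),
                      message=f"optimizer error: {exc}")

    dmin, dmax, K = res.x
    c = math.exp(K)
    dof = max(len(l) - 3, 1)
    s2 = float(np.sum(res.fun**2)) / dof
    cov: np.ndarray | None = None
    converged = bool(res.success)
    msg = res.message
    J = jac(res.x)
    JtJ = J.T @ J
    if np.linalg.cond(JtJ) < 1e12:
        cov = np.linalg.inv(JtJ) * s2
    else:
        converged = False
        msg = f"singular Jacobian (cond={np.linalg.cond(JtJ):.2e}); {msg}"
    return ASRFit(float(dmin), float(dmax), float(c), cov, s2, converged,
                  len(profile), message=msg)


def effect_estimates(fit: ASRFit, higher_order: bool = False) -> EffectEstimates:
    """Se = log2(dmax/dmin), Le = ln2/c, with delta-method standard errors."""
    if not fit.converged:
        raise ValueError(f"fit did not converge: {fit.message}")
    if fit.dmin <= 0:
        raise ValueError("dmin <= 0: Effect Size undefined")
    Se = math.log2(fit.dmax / fit.dmin)
    Le = math.log(2) / fit.c
    s_Se, s_Le = effect_standard_errors(fit, higher_order=higher_order)
    return EffectEstimates(Se, Le, s_Se, s_Le)


def effect_standard_errors(fit: ASRFit, higher_order: bool = False) -> tuple[float, float]:
    """Delta-method standard errors (sigma_Se, sigma_Le).

    sigma_Le = ln2 * sigma_K * exp(-K); with ``higher_order`` a small
    second-order correction factor (1 - sigma_K^2 / 4) is applied.
    sigma_Se = (1/ln2) * sqrt(s_dmax^2/dmax^2 + s_dmin^2/dmin^2
                              - 2 cov(dmax, dmin)/(dmax dmin)).
    """
    if fit.cov is None:
        raise ValueError("fit has no covariance; cannot compute standard errors")
    v = fit.cov
    s_dmin2, s_dmax2, s_K2 = v[0, 0], v[1, 1], v[2, 2]
    cov_dd = v[0, 1]
    ln2 = math.log(2)
    s_K = math.sqrt(max(s_K2, 0.0))
    sigma_Le = ln2 * s_K * math.exp(-fit.K)
    if higher_order:
        sigma_Le *= max(1.0 - s_K2 / 4.0, 0.0)
    arg = (s_dmax2 / fit.dmax**2 + s_dmin2 / fit.dmin**2
           - 2.0 * cov_dd / (fit.dmax * fit.dmin))
    if arg < 0:
        logger.warning("negative variance argument (%.3e) for sigma_Se; undefined", arg)
        return math.nan, sigma_Le
    sigma_Se = math.sqrt(arg) / ln2
    return sigma_Se, sigma_Le


def observed_effect_size(profile: DiversityProfile, window: int = 500) -> float:
    """Model-free effect size: log2 of max mean diversity over the first
    ``window`` sites relative to the mean diversity at the first position."""
    inside = profile.l <= window
    if inside.sum() < 2:
        raise ValueError("profile covers fewer than 2 positions in the window")
    l = profile.l[inside]
    y = profile.mean_pi[inside]
    start = y[np.argmin(l)]
    if start <= 0:
        raise ValueError("mean diversity at the first position is 0; undefined")
    return float(np.log2(y.max() / start))


def diversity_length_correlation(gene_summaries: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Spearman correlation (rho_l, p) between gene length and mean diversity."""
    if len(gene_summaries) < 10:
        raise ValueError(f"need >= 10 genes, got {len(gene_summaries)}")
    arr = np.asarray(gene_summaries, dtype=float)
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        raise ValueError("constant vector: correlation undefined")
    rho, p = stats.spearmanr(arr[:, 0], arr[:, 1])
    return float(rho), float(p)
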