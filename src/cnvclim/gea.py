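"""Genotype-environment association scans for binary CNV states.

Two complementary scans are provided.  The univariate logistic scan
(Samβada-style) fits one logistic regression per (CNV locus, climate
variable) pair, optionally with population-structure covariates, and
selects models by Bonferroni-corrected Wald p-values.  The latent factor
mixed model (LFMM) scan absorbs population structure into K latent
factors estimated from the genotype residuals, recalibrates the z-scores
with the genomic inflation factor, and applies Benjamini-Hochberg
correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA
from statsmodels.api import Logit
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "LogisticFit",
    "LatentModel",
    "env_pca",
    "logistic_wald",
    "sambada_scan",
    "lfmm_scan",
    "model_count",
    "bonferroni",
    "benjamini_hochberg",
    "genomic_inflation",
]

_CHI2_1_MEDIAN = float(stats.chi2.ppf(0.5, 1))  # 0.4549...


def model_count(n_loci: int, n_variables: int) -> int:
    """Number of univariate models in a full locus x variable scan."""
    return int(n_loci) * int(n_variables)


def bonferroni(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment over ``m`` tests (defaults to ``len(p)``)."""
    p = np.asarray(p, dtype=float)
    m = len(p) if m is None else int(m)
    return np.minimum(p * m, 1.0)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """Step-up FDR adjustment; NaN entries propagate as NaN."""
    p = np.asarray(p, dtype=float)
    out = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def genomic_inflation(z: np.ndarray) -> float:
    """Genomic inflation factor lambda = median(z^2) / median of chi2(1)."""
    z = np.asarray(z, dtype=float)
    z = z[np.isfinite(z)]
    if not len(z):
        raise ValueError("no finite z-scores")
    return float(np.median(z**2) / _CHI2_1_MEDIAN)


def env_pca(climate: pd.DataFrame, n_components: int = 2,
            exclude: tuple = ("latitude", "longitude")) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """PCA of standardized climate variables (and elevation).

    Returns per-row component scores, per-variable loadings and the
    explained variance ratio.  Constant columns are dropped with a
    warning; each component's sign is fixed so its largest-magnitude
    loading is positive.
    """
    cols = [c for c in climate.columns if c not in exclude]
    X = climate[cols].to_numpy(dtype=float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 variables for PCA")
    sd = X.std(axis=0, ddof=0)
    const = sd == 0
    if const.any():
        warnings.warn(f"dropping {const.sum()} constant climate column(s)")
        cols = [c for c, bad in zip(cols, const) if not bad]
        X, sd = X[:, ~const], sd[~const]
    Xs = (X - X.mean(axis=0)) / sd
    pca = PCA(n_components=min(n_components, Xs.shape[1], Xs.shape[0]))
    scores = pca.fit_transform(Xs)
    loadings = pca.components_
    for k in range(loadings.shape[0]):
        if loadings[k, np.argmax(np.abs(loadings[k]))] < 0:
            loadings[k] *= -1
            scores[:, k] *= -1
    names = [f"PC{k + 1}" for k in range(loadings.shape[0])]
    return (pd.DataFrame(scores, index=climate.index, columns=names),
            pd.DataFrame(loadings.T, index=cols, columns=names),
            pca.explained_variance_ratio_)


@dataclass
class LogisticFit:
    """One univariate logistic fit: slope, Wald statistic and status."""

    beta: float
    se: float
    wald: float
    p: float
    converged: bool
    status: str = "ok"  # ok | separation | failed

    @property
    def usable(self) -> bool:
        return self.status == "ok" and self.converged


def logistic_wald(y, x, covariates=None, maxiter: int = 100) -> LogisticFit:
    """Logistic regression of binary ``y`` on ``x`` (plus covariates).

    The fit is a Newton/IRLS maximum-likelihood fit; the Wald statistic
    is (beta/se)^2 with a two-sided chi-square(1) p-value.  Quasi-complete
    separation and non-convergence are flagged (``status``) instead of
    being reported as finite estimates.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("y and x must have the same length")
    classes = np.unique(y)
    if not np.all(np.isin(classes, (0.0, 1.0))):
        raise ValueError("response must be binary 0/1")
    if len(classes) < 2:
        raise ValueError("degenerate response: only one class present")
    D = [np.ones_like(x)]
    if covariates is not None:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != len(y):
            cov = cov.T
        D.append(cov)
    D.append(x[:, None])
    X = np.column_stack(D)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = Logit(y, X).fit(method="newton", maxiter=maxiter, disp=0)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return LogisticFit(np.nan, np.nan, np.nan, np.nan, False, "separation")
    beta = float(res.params[-1])
    se = float(res.bse[-1])
    converged = bool(res.mle_retvals.get("converged", False))
    # diverging estimates betray (quasi-)separation even when the
    # optimizer reports convergence
    if not np.isfinite(se) or se > 1e3 or abs(beta) > 1e2:
        return LogisticFit(beta, se, np.nan, np.nan, converged, "separation")
    if not converged:
        return LogisticFit(beta, se, np.nan, np.nan, False, "failed")
    wald = (beta / se) ** 2
    p = float(stats.chi2.sf(wald, df=1))
    return LogisticFit(beta, se, float(wald), p, True, "ok")


def sambada_scan(G: pd.DataFrame, env: pd.DataFrame, covariates=None,
                 alpha: float = 0.01, wald_min: float = 34.0,
                 min_carriers: int = 5) -> pd.DataFrame:
    """Univariate logistic scan over every (locus, variable) pair.

    ``G`` is a samples x loci binary matrix, ``env`` a samples x
    variables climate matrix on the same index.  Bonferroni correction
    uses the full model count (loci x variables) including skipped
    models.  A model is selected when the adjusted p-value is below
    ``alpha`` and its Wald score exceeds ``wald_min``.  Loci with fewer
    than ``min_carriers`` carriers (or non-carriers) are skipped: their
    fits are too unstable to report.
    """
    if not G.index.equals(env.index):
        raise ValueError("genotype and environment tables must share the sample index")
    m = model_count(G.shape[1], env.shape[1])
    rows = []
    env_vals = {v: env[v].to_numpy(dtype=float) for v in env.columns}
    for locus in G.columns:
        y = G[locus].to_numpy(dtype=float)
        carriers = int(y.sum())
        skip = carriers < min_carriers or (len(y) - carriers) < min_carriers
        for var in env.columns:
            if skip:
                rows.append((locus, var, np.nan, np.nan, np.nan, np.nan, "skipped"))
                continue
            fit = logistic_wald(y, env_vals[var], covariates=covariates)
            rows.append((locus, var, fit.beta, fit.se, fit.wald, fit.p, fit.status))
    out = pd.DataFrame(rows, columns=["locus", "variable", "beta", "se",
                                      "wald", "p_raw", "status"])
    out["p_adj"] = bonferroni(out["p_raw"].to_numpy(), m=m)
    out["selected"] = ((out["status"] == "ok")
                       & (out["p_adj"] < alpha)
                       & (out["wald"] > wald_min))
    out.attrs["n_models"] = m
    return out


@dataclass
class LatentModel:
    """Fitted latent-factor structure of an LFMM scan."""

    k: int
    factors: pd.DataFrame      # samples x K, orthonormal columns
    lambda_gif: float          # genomic inflation factor of the scan z-scores
    z: pd.DataFrame            # loci x variables


def lfmm_scan(G: pd.DataFrame, X: pd.DataFrame, k: int,
              z_min: float = 10.0, p_adj_max: float = 1e-6,
              ridge: float = 1e-5, factor_method: str = "ridge",
              calibrate: bool = True) -> tuple[LatentModel, pd.DataFrame]:
    """Latent factor mixed model scan (least-squares variant).

    Algorithm: center ``G`` and standardize ``X``; estimate ``k``
    orthonormal latent factors from the genotype matrix; refit every
    locus on [1, X, factors]; convert the environment effects to
    z-scores; recalibrate with the genomic inflation factor; BH-adjust
    the calibrated p-values.  With ``k=0`` the scan is an ordinary
    per-locus regression.  Selection requires |z| >= ``z_min`` and
    adjusted p < ``p_adj_max``.

    ``factor_method`` controls the factor estimate:

    * ``"ridge"`` (default, the estimator of the cited least-squares
      LFMM): the environment directions of ``G`` are damped by
      sqrt(ridge / (ridge + s_j^2)) (singular values s_j of ``X``)
      before the SVD and re-inflated afterwards.  A small ``ridge``
      keeps the factors nearly orthogonal to ``X``, preserving
      environment-aligned effects — the discovery-oriented choice.
    * ``"svd"``: top-k left singular vectors of the centered genotype
      matrix.  The factors are free to absorb structure collinear with
      the environment, which keeps null z-scores calibrated under
      strong structure-environment confounding, at the cost of power
      for effects aligned with structure — the calibration-oriented
      choice.
    """
    if not G.index.equals(X.index):
        raise ValueError("genotype and environment tables must share the sample index")
    n, L = G.shape
    if k < 0 or (k > 0 and k >= min(n, L)):
        raise ValueError("k must satisfy 0 <= k < min(n_samples, n_loci)")

    Y = G.to_numpy(dtype=float)
    Y = Y - Y.mean(axis=0)
    Xv = X.to_numpy(dtype=float)
    sd = Xv.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("constant environment column")
    Xs = (Xv - Xv.mean(axis=0)) / sd

    if k > 0:
        if factor_method == "svd":
            U, _, _ = np.linalg.svd(Y, full_matrices=False)
            factors = U[:, :k]
        elif factor_method == "ridge":
            if ridge <= 0:
                raise ValueError("ridge penalty must be positive")
            Qx, sv, _ = np.linalg.svd(Xs, full_matrices=False)
            shrink = np.sqrt(ridge / (ridge + sv**2))
            DY = Y - Qx @ ((1.0 - shrink)[:, None] * (Qx.T @ Y))
            U, _, _ = np.linalg.svd(DY, full_matrices=False)
            Uk = U[:, :k]
            # undo the shrinkage on the environment directions so structure
            # collinear with X is represented in the factors
            Uk = Uk + Qx @ ((1.0 / shrink - 1.0)[:, None] * (Qx.T @ Uk))
            factors, _ = np.linalg.qr(Uk)
        else:
            raise ValueError("factor_method must be 'svd' or 'ridge'")
        D = np.column_stack([np.ones(n), Xs, factors])
    else:
        factors = np.empty((n, 0))
        D = np.column_stack([np.ones(n), Xs])

    DtD = D.T @ D
    penalty = 0.0
    if np.linalg.cond(DtD) > 1e10:
        penalty = ridge * np.trace(DtD) / DtD.shape[0]
        warnings.warn(f"collinear design; applying ridge penalty {penalty:.3g}")
        DtD = DtD + penalty * np.eye(DtD.shape[0])
    DtD_inv = np.linalg.inv(DtD)
    beta = DtD_inv @ (D.T @ Y)                       # p x L
    resid = Y - D @ beta
    dof = n - D.shape[1]
    if dof <= 0:
        raise ValueError("not enough samples for the requested design")
    sigma2 = (resid**2).sum(axis=0) / dof            # per locus
    var_idx = slice(1, 1 + Xs.shape[1])
    se = np.sqrt(np.outer(np.diag(DtD_inv)[var_idx], sigma2))  # vars x L
    z = beta[var_idx] / se                                     # vars x L

    lam = genomic_inflation(z)
    z2 = z**2 / lam if calibrate else z**2
    p_cal = stats.chi2.sf(z2, df=1)

    loci, variables = list(G.columns), list(X.columns)
    out = pd.DataFrame({
        "locus": np.repeat(loci, len(variables)),
        "variable": np.tile(variables, len(loci)),
        "beta": beta[var_idx].T.ravel(),
        "se": se.T.ravel(),
        "z": z.T.ravel(),
        "p_raw": p_cal.T.ravel(),
    })
    out["p_adj"] = benjamini_hochberg(out["p_raw"].to_numpy())
    out["selected"] = (np.abs(out["z"]) >= z_min) & (out["p_adj"] < p_adj_max)
    model = LatentModel(
        k=k,
        factors=pd.DataFrame(factors, index=G.index,
                             columns=[f"LF{j + 1}" for j in range(k)]),
        lambda_gif=lam,
        z=pd.DataFrame(z.T, index=loci, columns=variables),
    )
    return model, out
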