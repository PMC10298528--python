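"""Probe-based association of CNV occurrence with solar radiation.

CNV calls are converted into binary samples x probes occurrence matrices
(deletions and duplications separately).  Sample relatedness is captured
by a Balding-Nichols kinship matrix built from frequency-standardized
probe deviations.  Association runs in two orientations:

* a variance-component mixed model (EMMAX-style): radiation is the
  response, each probe the tested predictor, with covariance
  sigma_g^2 K + sigma_e^2 I whose variance ratio delta = sigma_e^2 /
  sigma_g^2 is REML-estimated once on the null model and reused by all
  probe tests (generalized least squares);
* a logistic regression of probe occurrence on radiation with principal
  component covariates.

Significant probes are merged into regions along the probe map, and the
regions' family-wise significance is assessed by max(T) permutation of
the radiation phenotype.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from . import gea
from .cnv import DELETION_CLASSES, DUPLICATION_CLASSES, validate_calls

__all__ = [
    "build_probe_matrix",
    "combined_occurrence",
    "stratification_pcs",
    "bn_kinship",
    "EmmaFit",
    "emma_reml_fit",
    "reml_loglik",
    "mlm_scan",
    "logistic_scan",
    "consensus_probes",
    "merge_probes_to_regions",
    "maxt_adjust",
]

_POLARITY_CLASSES = {"del": DELETION_CLASSES, "dup": DUPLICATION_CLASSES}


def _check_probes(probes: pd.DataFrame) -> pd.DataFrame:
    if not len(probes):
        raise ValueError("probe map is empty")
    probes = probes.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    for _, grp in probes.groupby("chrom"):
        if (np.diff(grp["pos"].to_numpy()) <= 0).any():
            raise ValueError("probe positions must be strictly increasing within a chromosome")
    return probes


def build_probe_matrix(calls: pd.DataFrame, probes: pd.DataFrame, polarity: str,
                       samples=None) -> pd.DataFrame:
    """Binary occurrence matrix: 1 iff a call of ``polarity`` spans the probe.

    ``polarity`` is ``"del"`` (copy number 0/1) or ``"dup"`` (3/4); a
    call spans a probe when ``start <= pos <= end`` (inclusive on both
    boundaries).  ``samples`` fixes the row universe (defaults to the
    samples present in ``calls``).
    """
    if polarity not in _POLARITY_CLASSES:
        raise ValueError("polarity must be 'del' or 'dup'")
    validate_calls(calls)
    probes = _check_probes(probes)
    if samples is None:
        samples = sorted(calls["sample"].unique())
    sample_idx = {s: i for i, s in enumerate(samples)}
    mat = np.zeros((len(samples), len(probes)), dtype=np.int8)
    keep = calls["cn"].isin(_POLARITY_CLASSES[polarity])
    for chrom, grp in calls.loc[keep].groupby("chrom"):
        pmask = probes["chrom"] == chrom
        if not pmask.any():
            continue
        pos = probes.loc[pmask, "pos"].to_numpy()
        offset = int(np.flatnonzero(pmask.to_numpy())[0])
        lo = np.searchsorted(pos, grp["start"].to_numpy(), side="left")
        hi = np.searchsorted(pos, grp["end"].to_numpy(), side="right")
        for s, a, b in zip(grp["sample"], lo, hi):
            if b > a and s in sample_idx:
                mat[sample_idx[s], offset + a:offset + b] = 1
    return pd.DataFrame(mat, index=pd.Index(samples, name="sample"),
                        columns=probes["probe"].to_numpy())


def combined_occurrence(calls: pd.DataFrame, probes: pd.DataFrame,
                        samples=None) -> pd.DataFrame:
    """Deletion and duplication occurrence matrices, column-concatenated.

    The genome-wide marker set used for kinship and stratification PCs:
    structure estimated from a single polarity is markedly noisier.
    Monomorphic columns are dropped.
    """
    mats = []
    for pol in ("del", "dup"):
        m = build_probe_matrix(calls, probes, pol, samples=samples)
        m.columns = [f"{c}_{pol}" for c in m.columns]
        mats.append(m)
    out = pd.concat(mats, axis=1)
    return out.loc[:, out.std() > 0]


def stratification_pcs(occurrence: pd.DataFrame, sites=None,
                       n_components: int = 4) -> pd.DataFrame:
    """Population-stratification principal components for the probe scans.

    With ``sites`` (a per-sample site label aligned to the occurrence
    matrix rows) the PCA runs on site-mean occurrence frequencies and the
    site scores are broadcast back to samples.  Averaging within sites
    denoises the structure axes considerably, which matters when the
    tested phenotype itself varies at the site level; without ``sites``
    the PCA runs on the sample-level matrix.
    """
    if sites is None:
        scores, _, _ = gea.env_pca(occurrence.astype(float),
                                   n_components=n_components, exclude=())
        return scores
    sites = pd.Series(np.asarray(sites), index=occurrence.index)
    freq = occurrence.astype(float).groupby(sites).mean()
    freq = freq.loc[:, freq.std() > 0]
    scores, _, _ = gea.env_pca(freq, n_components=n_components, exclude=())
    out = scores.loc[sites.to_numpy()]
    out.index = occurrence.index
    return out


def bn_kinship(M: pd.DataFrame, psd_tol: float = 1e-8) -> pd.DataFrame:
    """Balding-Nichols kinship from a binary occurrence matrix.

    K_ij = (1/M*) sum_m (x_im - p_m)(x_jm - p_m) / (p_m (1 - p_m)) over
    the M* polymorphic probes (0 < p_m < 1).  The result is symmetrized
    and, if numerically indefinite, shifted by the minimal diagonal
    ridge needed to be positive semidefinite (with a warning).
    """
    if M.shape[0] < 2:
        raise ValueError("need at least two samples")
    X = M.to_numpy(dtype=float)
    p = X.mean(axis=0)
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic probes")
    Xs = (X[:, poly] - p[poly]) / np.sqrt(p[poly] * (1 - p[poly]))
    K = (Xs @ Xs.T) / poly.sum()
    K = (K + K.T) / 2.0
    w = np.linalg.eigvalsh(K)
    if w[0] < -psd_tol:
        warnings.warn(f"kinship indefinite (min eigenvalue {w[0]:.3g}); "
                      "adding minimal diagonal ridge")
        K = K + (-w[0]) * np.eye(K.shape[0])
    return pd.DataFrame(K, index=M.index, columns=M.index)


def _design(n: int, covariates) -> np.ndarray:
    cols = [np.ones(n)]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float)
        if cov.ndim == 1:
            cov = cov[:, None]
        if cov.shape[0] != n:
            raise ValueError("covariate rows must match samples")
        cols.append(cov)
    return np.column_stack(cols)


def reml_loglik(log_delta: float, lam: np.ndarray, eta2: np.ndarray) -> float:
    """Restricted log-likelihood of the variance ratio delta (spectral form).

    ``lam`` are the nonzero eigenvalues of S K S (S the projection off
    the fixed effects), ``eta2`` the squared projections of the response
    on the corresponding eigenvectors.
    """
    delta = math.exp(log_delta)
    nq = len(lam)
    denom = lam + delta
    total = float(np.sum(eta2 / denom))
    return 0.5 * (nq * math.log(nq / (2 * math.pi)) - nq
                  - nq * math.log(total) - float(np.sum(np.log(denom))))


@dataclass
class EmmaFit:
    """REML variance components and the spectral caches reused by the scan."""

    delta: float               # sigma_e^2 / sigma_g^2
    sigma_g2: float
    sigma_e2: float
    loglik: float
    k_eigvals: np.ndarray      # eigenvalues of K (ascending, clipped at 0)
    k_eigvecs: np.ndarray
    reml_eigvals: np.ndarray   # nonzero eigenvalues of S K S
    reml_eta2: np.ndarray

    def whitening(self) -> np.ndarray:
        """T with T V T' proportional to I for V = K + delta*I."""
        return (self.k_eigvecs / np.sqrt(self.k_eigvals + self.delta)).T


def emma_reml_fit(y, K: pd.DataFrame | np.ndarray, covariates=None,
                  log_delta_bounds: tuple[float, float] = (-10.0, 10.0),
                  n_grid: int = 100) -> EmmaFit:
    """REML fit of the variance ratio delta for y ~ covariates + u, u ~ K.

    The restricted likelihood is profiled on the spectrum of S K S and
    maximized over log(delta) by a coarse grid followed by bounded local
    refinement, so secondary modes are not missed.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    Kv = K.to_numpy(dtype=float) if isinstance(K, pd.DataFrame) else np.asarray(K, dtype=float)
    n = len(y)
    if Kv.shape != (n, n):
        raise ValueError("kinship dimensions must match the response")
    X = _design(n, covariates)
    q = X.shape[1]

    S = np.eye(n) - X @ np.linalg.solve(X.T @ X, X.T)
    w, U = np.linalg.eigh((S @ Kv @ S + (S @ Kv @ S).T) / 2.0)
    order = np.argsort(w)[::-1][: n - q]      # drop the q null directions
    lam = np.clip(w[order], 0.0, None)
    if lam.max() <= 0:
        raise ValueError("kinship is null on the residual space")
    eta = U[:, order].T @ y
    eta2 = eta**2

    lo, hi = log_delta_bounds
    grid = np.linspace(lo, hi, n_grid)
    vals = np.array([reml_loglik(g, lam, eta2) for g in grid])
    i = int(np.argmax(vals))
    a, b = grid[max(i - 1, 0)], grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(lambda g: -reml_loglik(g, lam, eta2),
                                   bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-8})
    best = float(res.x) if -res.fun >= vals[i] else float(grid[i])
    delta = math.exp(best)

    sigma_g2 = float(np.sum(eta2 / (lam + delta)) / (n - q))
    kw, kU = np.linalg.eigh((Kv + Kv.T) / 2.0)
    if kw[0] < -1e-8:
        raise ValueError("kinship matrix is not positive semidefinite")
    return EmmaFit(delta=delta, sigma_g2=sigma_g2, sigma_e2=delta * sigma_g2,
                   loglik=reml_loglik(best, lam, eta2),
                   k_eigvals=np.clip(kw, 0.0, None), k_eigvecs=kU,
                   reml_eigvals=lam, reml_eta2=eta2)


def _gls_workspace(y, M: pd.DataFrame, K, covariates, fit: EmmaFit | None):
    """Whiten by (K + delta I)^{-1/2} and residualize off the covariates."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    if K is None:
        Kv = np.eye(n)
    else:
        Kv = K.to_numpy(dtype=float) if isinstance(K, pd.DataFrame) else np.asarray(K, dtype=float)
    if fit is None:
        fit = emma_reml_fit(y, Kv, covariates=covariates)
    T = fit.whitening()
    X = _design(n, covariates)
    Xt = T @ X
    Q, _ = np.linalg.qr(Xt)
    yt = T @ y
    yr = yt - Q @ (Q.T @ yt)
    Mt = T @ M.to_numpy(dtype=float)
    Mr = Mt - Q @ (Q.T @ Mt)
    s2 = (Mr**2).sum(axis=0)
    raw_var = M.to_numpy(dtype=float).std(axis=0) > 0
    testable = raw_var & (s2 > 1e-12)
    df = n - X.shape[1] - 1
    return fit, T, Q, yr, Mr, s2, testable, df


def mlm_scan(y, M: pd.DataFrame, K=None, covariates=None, fit: EmmaFit | None = None,
             suggestive_p: float = 5e-4) -> pd.DataFrame:
    """Mixed-model (GLS) association of each probe with the response ``y``.

    Per probe the effect is estimated by generalized least squares under
    covariance sigma_g^2 K + sigma_e^2 I at the REML delta; the residual
    scale is profiled per probe, so with K = I the test reduces exactly
    to the OLS t-test.  Probes constant across samples are skipped.
    """
    fit, _, _, yr, Mr, s2, testable, df = _gls_workspace(y, M, K, covariates, fit)
    if df <= 0:
        raise ValueError("not enough samples for the covariate design")
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = (Mr.T @ yr) / s2
        rss = float(yr @ yr) - beta**2 * s2
        sigma2 = rss / df
        se = np.sqrt(sigma2 / s2)
        t = beta / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    out = pd.DataFrame({
        "probe": M.columns,
        "beta": np.where(testable, beta, np.nan),
        "se": np.where(testable, se, np.nan),
        "stat": np.where(testable, t, np.nan),
        "p": np.where(testable, p, np.nan),
        "status": np.where(testable, "ok", "skipped"),
    })
    out["suggestive"] = (out["status"] == "ok") & (out["p"] < suggestive_p)
    out.attrs["delta"] = fit.delta
    return out


def logistic_scan(M: pd.DataFrame, radiation, pcs=None,
                  p_threshold: float = 5e-5) -> pd.DataFrame:
    """Logistic regression of probe occurrence on radiation (plus PCs)."""
    radiation = np.asarray(radiation, dtype=float)
    rows = []
    for probe in M.columns:
        y = M[probe].to_numpy(dtype=float)
        if len(np.unique(y)) < 2:
            rows.append((probe, np.nan, np.nan, np.nan, np.nan, "skipped"))
            continue
        f = gea.logistic_wald(y, radiation, covariates=pcs)
        rows.append((probe, f.beta, f.se, f.wald, f.p, f.status))
    out = pd.DataFrame(rows, columns=["probe", "beta", "se", "wald", "p", "status"])
    out["p_adj"] = gea.benjamini_hochberg(out["p"].to_numpy())
    out["significant"] = (out["status"] == "ok") & (out["p"] < p_threshold)
    return out


def consensus_probes(res_a: pd.DataFrame, res_b: pd.DataFrame,
                     thr_a: float = 5e-4, thr_b: float = 5e-5,
                     p_col: str = "p") -> set:
    """Probes significant under both scans at their respective thresholds."""
    sig_a = set(res_a.loc[res_a[p_col] < thr_a, "probe"])
    sig_b = set(res_b.loc[res_b[p_col] < thr_b, "probe"])
    return sig_a & sig_b


def merge_probes_to_regions(pvals: pd.Series, probes: pd.DataFrame, p_thr: float,
                            min_probes: int = 3, max_gap_bp: float = 1e6) -> pd.DataFrame:
    """Merge runs of significant adjacent probes into candidate regions.

    Probes with p < ``p_thr`` are grouped per chromosome; consecutive
    significant probes separated by at most ``max_gap_bp`` extend the
    same run.  Runs with fewer than ``min_probes`` probes are dropped.
    The region raw p-value is the minimum probe p-value (peak probe).
    """
    probes = _check_probes(probes)
    pv = probes.assign(p=probes["probe"].map(pvals))
    sig = pv[(pv["p"] < p_thr) & pv["p"].notna()]
    regions = []
    for chrom, grp in sig.groupby("chrom", sort=True):
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > max_gap_bp)
        bounds = np.concatenate([[0], breaks + 1, [len(pos)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            run = grp.iloc[a:b]
            if len(run) < min_probes:
                continue
            regions.append({
                "chrom": chrom,
                "start": int(run["pos"].min()),
                "end": int(run["pos"].max()),
                "n_probes": int(len(run)),
                "p_min": float(run["p"].min()),
                "probes": tuple(run["probe"]),
            })
    return pd.DataFrame(regions, columns=["chrom", "start", "end", "n_probes",
                                          "p_min", "probes"])


def maxt_adjust(regions: pd.DataFrame, y, M: pd.DataFrame, K=None, covariates=None,
                fit: EmmaFit | None = None, B: int = 10_000, seed: int = 0,
                alpha: float = 0.05, chunk: int = 500) -> pd.DataFrame:
    """max(T) permutation adjustment of region p-values.

    The radiation phenotype is permuted ``B`` times; each permutation is
    rescanned with the mixed-model statistic at the cached REML delta,
    and the genome-wide maximum |t| recorded.  A region's adjusted p is
    (1 + #{permutation max >= observed region max |t|}) / (B + 1).
    """
    if B < 1:
        raise ValueError("need at least one permutation")
    out = regions.copy()
    if not len(regions):
        out["max_stat"] = pd.Series(dtype=float)
        out["p_adj"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
        return out

    y = np.asarray(y, dtype=float)
    fit, T, Q, yr, Mr, s2, testable, df = _gls_workspace(y, M, K, covariates, fit)
    Mr = Mr[:, testable]
    s2t = s2[testable]
    probe_col = {p: j for j, p in enumerate(np.asarray(M.columns)[testable])}

    def stats_for(yr_rows: np.ndarray) -> np.ndarray:
        """|t| per probe for each (already whitened+residualized) row of y."""
        C = yr_rows @ Mr                                    # b x p
        rown2 = (yr_rows**2).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            rss = rown2[:, None] - C**2 / s2t[None, :]
            t2 = (C**2 / s2t[None, :]) * df / rss
        return np.sqrt(np.clip(t2, 0.0, None))

    obs_t = stats_for(yr[None, :])[0]
    obs_region = np.array([
        max((obs_t[probe_col[p]] for p in row.probes if p in probe_col), default=np.nan)
        for row in out.itertuples(index=False)
    ])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(out), dtype=int)
    done = 0
    n = len(y)
    while done < B:
        b = min(chunk, B - done)
        perms = np.array([rng.permutation(n) for _ in range(b)])
        Yt = y[perms] @ T.T
        Yr = Yt - (Yt @ Q) @ Q.T
        maxstat = stats_for(Yr).max(axis=1)
        exceed += (maxstat[None, :] >= obs_region[:, None]).sum(axis=1)
        done += b
    out["max_stat"] = obs_region
    out["p_adj"] = (1.0 + exceed) / (B + 1.0)
    out["significant"] = out["p_adj"] < alpha
    return out
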