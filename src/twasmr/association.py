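"""Per-feature association engines.

The discovery TWAS uses a kinship random-effect linear mixed model
(REML via one spectral decomposition of the kinship matrix and a 1-D
optimisation over the variance ratio); replication cohorts use ordinary
per-gene linear models; the GWAS scan is an additive per-SNP linear
model behind call-rate/HWE/MAF/imputation-quality filters. Multiplicity
is handled by Benjamini-Hochberg FDR and Bonferroni thresholds, with
the genomic inflation factor as the calibration diagnostic.

All Wald p-values use the t reference with residual degrees of freedom
n - p, which is exact for the ordinary linear models and the standard
approximation under REML; at an identity kinship the mixed model and
the ordinary model therefore agree to numerical precision.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

log = logging.getLogger(__name__)

__all__ = [
    "LmmFit",
    "QcThresholds",
    "fit_lmm",
    "twas",
    "glm_assoc",
    "compute_expression_pcs",
    "bh_fdr",
    "bonferroni_threshold",
    "hwe_test",
    "qc_filter",
    "gwas_scan",
    "genomic_lambda",
]

RESULT_COLUMNS = ["feature_id", "beta", "se", "stat", "p", "q", "n"]
GENOME_WIDE_ALPHA = 5e-8


@dataclass
class LmmFit:
    """REML fit of y = X beta + u + e with u ~ N(0, sg2 K), e ~ N(0, se2 I)."""

    beta_hat: np.ndarray
    se: np.ndarray
    sigma_g2: float
    sigma_e2: float
    loglik_reml: float
    converged: bool
    boundary: bool = False


@dataclass(frozen=True)
class QcThresholds:
    """SNP quality-control cutoffs (all retained-if-at-least rules except
    HWE, which excludes below ``hwe_p_min``)."""

    call_rate_min: float = 0.95
    hwe_p_min: float = 1e-6
    maf_min: float = 0.01
    info_min: float = 0.2

    def __post_init__(self) -> None:
        for name in ("call_rate_min", "hwe_p_min", "maf_min", "info_min"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")


# ---------------------------------------------------------------------------
# linear mixed model


def _check_kinship(K: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    K = np.asarray(K, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("kinship matrix must be square")
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship matrix must be symmetric")
    s, U = np.linalg.eigh(K)
    if s.min() < -tol:
        raise ValueError(f"kinship matrix not PSD (min eigenvalue {s.min():.3g})")
    return s.clip(0.0), U


def _check_design(X: np.ndarray) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the collinear columns by Gram-Schmidt-style elimination
        bad = []
        for j in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, : j + 1]) <= np.linalg.matrix_rank(X[:, :j]):
                bad.append(j)
        raise ValueError(f"design matrix is rank deficient (columns {bad})")


def _reml_profile(log_delta: float, yt: np.ndarray, Xt: np.ndarray, s: np.ndarray):
    """Profiled REML log-likelihood pieces at variance ratio delta=sg2/se2."""
    n, p = Xt.shape
    delta = math.exp(log_delta)
    w = 1.0 / (delta * s + 1.0)
    XtW = Xt * w[:, None]
    XtWX = Xt.T @ XtW
    beta = np.linalg.solve(XtWX, XtW.T @ yt)
    resid = yt - Xt @ beta
    rss = float(np.sum(w * resid**2))
    sigma_e2 = rss / (n - p)
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    ll = -0.5 * (
        (n - p) * math.log(sigma_e2)
        - float(np.sum(np.log(w)))
        + logdet_XtWX
        + (n - p)
    )
    return ll, beta, sigma_e2, XtWX


def fit_lmm(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray | None = None,
    *,
    spectral: tuple[np.ndarray, np.ndarray] | None = None,
    tol: float = 1e-8,
) -> LmmFit:
    """REML fit by spectral rotation and 1-D search over the variance ratio.

    ``spectral`` may carry a precomputed ``(eigenvalues, eigenvectors)``
    of K so that a scan over many responses decomposes the kinship only
    once. When K is (numerically) the identity the variance split is
    unidentified; only sigma_g2 + sigma_e2 is interpretable and the
    fixed effects equal GLS/OLS.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y.shape[0] != X.shape[0]:
        raise ValueError("y and X have inconsistent dimensions")
    _check_design(X)
    if spectral is None:
        if K is None:
            raise ValueError("either K or spectral must be given")
        if K.shape[0] != y.shape[0]:
            raise ValueError("K dimension inconsistent with y")
        s, U = _check_kinship(np.asarray(K, dtype=float))
    else:
        s, U = spectral
    n, p = X.shape
    yt = U.T @ y
    Xt = U.T @ X

    lo, hi = math.log(1e-6), math.log(1e6)
    neg = lambda ld: -_reml_profile(ld, yt, Xt, s)[0]
    res = optimize.minimize_scalar(
        neg, bounds=(lo, hi), method="bounded",
        options={"xatol": tol},
    )
    candidates = [(float(res.x), -float(res.fun))]
    for b in (lo, hi):
        candidates.append((b, _reml_profile(b, yt, Xt, s)[0]))
    log_delta, best_ll = max(candidates, key=lambda c: c[1])
    boundary = log_delta in (lo, hi) or abs(log_delta - lo) < 1e-9 or abs(log_delta - hi) < 1e-9

    ll, beta, sigma_e2, XtWX = _reml_profile(log_delta, yt, Xt, s)
    cov = sigma_e2 * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov))
    delta = math.exp(log_delta)
    return LmmFit(
        beta_hat=beta,
        se=se,
        sigma_g2=delta * sigma_e2,
        sigma_e2=sigma_e2,
        loglik_reml=ll,
        converged=bool(res.success) or boundary,
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# multiplicity and diagnostics


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (original order)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1].clip(max=1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0.0 < alpha <= 1.0):
        raise ValueError("alpha must be in (0, 1]")
    return alpha / m


def genomic_lambda(p) -> float:
    """Genomic inflation factor: median implied 1-df chi-square over its
    null median (~0.4549)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / stats.chi2.ppf(0.5, df=1))


def hwe_test(n_aa: int, n_ab: int, n_bb: int) -> float:
    """1-df chi-square goodness-of-fit p against Hardy-Weinberg proportions.

    Monomorphic SNPs return p = 1 by convention (there is nothing to
    test; the MAF filter removes them instead).
    """
    counts = np.array([n_aa, n_ab, n_bb], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be nonnegative")
    n = counts.sum()
    if n == 0:
        raise ValueError("total genotype count is zero")
    p_a = (2 * counts[0] + counts[1]) / (2 * n)
    if p_a in (0.0, 1.0):
        return 1.0
    expected = n * np.array([p_a**2, 2 * p_a * (1 - p_a), (1 - p_a) ** 2])
    chi2 = float(np.sum((counts - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


def qc_filter(
    snp_metrics: pd.DataFrame, thresholds: QcThresholds = QcThresholds()
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply SNP QC; returns (retained metrics, exclusion log).

    ``snp_metrics`` needs columns ``snp_id``, ``call_rate``, ``maf``,
    ``info`` and either ``hwe_p`` or genotype counts ``n_aa, n_ab,
    n_bb``. The exclusion log records the first failing rule per SNP in
    the order call_rate, hwe, maf, info.
    """
    required = {"snp_id", "call_rate", "maf", "info"}
    missing = required - set(snp_metrics.columns)
    if missing:
        raise ValueError(f"missing QC metric columns: {sorted(missing)}")
    df = snp_metrics.copy()
    if "hwe_p" not in df.columns:
        if not {"n_aa", "n_ab", "n_bb"} <= set(df.columns):
            raise ValueError("need hwe_p or genotype counts n_aa/n_ab/n_bb")
        df["hwe_p"] = [
            hwe_test(r.n_aa, r.n_ab, r.n_bb) for r in df.itertuples()
        ]
    t = thresholds
    reasons = []
    for r in df.itertuples():
        if r.call_rate < t.call_rate_min:
            reasons.append("call_rate")
        elif r.hwe_p < t.hwe_p_min:
            reasons.append("hwe")
        elif r.maf < t.maf_min:
            reasons.append("maf")
        elif r.info < t.info_min:
            reasons.append("info")
        else:
            reasons.append("")
    df["exclusion_reason"] = reasons
    retained = df[df.exclusion_reason == ""].drop(columns="exclusion_reason")
    excluded = df[df.exclusion_reason != ""][["snp_id", "exclusion_reason"]]
    log.info("qc_filter: %d retained, %d excluded", len(retained), len(excluded))
    return retained.reset_index(drop=True), excluded.reset_index(drop=True)


# ---------------------------------------------------------------------------
# scans


def _build_design(
    trait: pd.Series, covariates: pd.DataFrame | None, *, adjust_eosinophils: bool
) -> tuple[np.ndarray, list[str]]:
    cols: list[str] = ["intercept", "trait"]
    parts = [np.ones(len(trait)), trait.to_numpy(dtype=float)]
    if covariates is not None:
        cov = covariates
        if not adjust_eosinophils and "eosinophil_fraction" in cov.columns:
            cov = cov.drop(columns="eosinophil_fraction")
        for c in cov.columns:
            parts.append(cov[c].to_numpy(dtype=float))
            cols.append(c)
    return np.column_stack(parts), cols


def _finalize(results: pd.DataFrame) -> pd.DataFrame:
    results = results.copy()
    results["q"] = bh_fdr(results["p"].to_numpy())
    results = results.sort_values(["p", "feature_id"], kind="stable")
    return results[RESULT_COLUMNS].reset_index(drop=True)


def _align(expression: pd.DataFrame, trait: pd.Series,
           covariates: pd.DataFrame | None):
    ids = expression.columns
    missing = ids.difference(trait.index)
    if len(missing):
        raise ValueError(f"trait missing samples: {list(missing)[:5]}")
    trait = trait.loc[ids]
    if covariates is not None:
        missing = ids.difference(covariates.index)
        if len(missing):
            raise ValueError(f"covariates missing samples: {list(missing)[:5]}")
        covariates = covariates.loc[ids]
    return trait, covariates


def twas(
    expression: pd.DataFrame,
    trait: pd.Series,
    covariates: pd.DataFrame | None,
    kinship: pd.DataFrame,
    *,
    adjust_eosinophils: bool = False,
) -> pd.DataFrame:
    """Kinship-adjusted discovery TWAS: per-gene LMM of expression on trait.

    Each gene's expression is the response, the (log10) trait the
    predictor of interest, with covariates fixed and a kinship random
    effect; Wald test on the trait coefficient, BH q across genes.
    The eosinophil fraction enters only when ``adjust_eosinophils`` —
    the secondary, conservatively adjusted analysis.
    """
    trait, covariates = _align(expression, trait, covariates)
    K = kinship.loc[expression.columns, expression.columns].to_numpy()
    X, _ = _build_design(trait, covariates, adjust_eosinophils=adjust_eosinophils)
    spectral = _check_kinship(K)
    _check_design(X)
    n, p = X.shape
    df = n - p

    rows = []
    for gene, y in expression.iterrows():
        yv = y.to_numpy(dtype=float)
        if np.ptp(yv) == 0.0:
            log.warning("gene %s has zero variance; p set to 1", gene)
            rows.append((gene, 0.0, np.nan, 0.0, 1.0, n))
            continue
        fit = fit_lmm(yv, X, spectral=spectral)
        beta, se = float(fit.beta_hat[1]), float(fit.se[1])
        tstat = beta / se
        pval = 2.0 * float(stats.t.sf(abs(tstat), df))
        rows.append((gene, beta, se, tstat, max(pval, np.nextafter(0, 1)), n))
    out = pd.DataFrame(rows, columns=["feature_id", "beta", "se", "stat", "p", "n"])
    return _finalize(out)


def glm_assoc(
    expression: pd.DataFrame,
    trait: pd.Series,
    covariates: pd.DataFrame | None = None,
    *,
    adjust_eosinophils: bool = True,
) -> pd.DataFrame:
    """Replication-cohort association: per-gene ordinary linear model.

    Fits expression_g ~ intercept + log10 trait + covariates for every
    gene with shared design (vectorised OLS), Wald t test on the trait
    coefficient, BH q across genes. Covariates typically include the
    first expression principal components.
    """
    trait, covariates = _align(expression, trait, covariates)
    X, _ = _build_design(trait, covariates, adjust_eosinophils=adjust_eosinophils)
    _check_design(X)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"no residual degrees of freedom (n={n}, p={p})")
    df = n - p

    Y = expression.to_numpy(dtype=float).T  # samples x genes
    XtX_inv = np.linalg.inv(X.T @ X)
    B = XtX_inv @ X.T @ Y                    # p x genes
    resid = Y - X @ B
    sigma2 = (resid**2).sum(axis=0) / df
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    beta = B[1]
    se_beta = se[1]
    zero_var = np.ptp(Y, axis=0) == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(zero_var, 0.0, beta / se_beta)
    pval = np.where(zero_var, 1.0, 2.0 * stats.t.sf(np.abs(tstat), df))
    if zero_var.any():
        log.warning("%d genes with zero variance; p set to 1", int(zero_var.sum()))
    out = pd.DataFrame(
        {
            "feature_id": expression.index,
            "beta": np.where(zero_var, 0.0, beta),
            "se": np.where(zero_var, np.nan, se_beta),
            "stat": tstat,
            "p": pval.clip(min=np.nextafter(0, 1)),
            "n": n,
        }
    )
    return _finalize(out)


def compute_expression_pcs(expression: pd.DataFrame, k: int) -> pd.DataFrame:
    """Top-k principal-component scores of the centred gene-by-sample matrix.

    Sign convention: each component's largest-|loading| gene loads
    positively. Returns a samples x k score table (columns PC1..PCk).
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= min(expression.shape):
        raise ValueError("k must be smaller than both matrix dimensions")
    M = expression.to_numpy(dtype=float)
    M = M - M.mean(axis=1, keepdims=True)
    U, svals, Vt = np.linalg.svd(M, full_matrices=False)
    for j in range(k):
        i_max = np.argmax(np.abs(U[:, j]))
        if U[i_max, j] < 0:
            U[:, j] *= -1
            Vt[j] *= -1
    scores = (Vt[:k].T * svals[:k])
    return pd.DataFrame(
        scores, index=expression.columns, columns=[f"PC{j+1}" for j in range(k)]
    )


def gwas_scan(
    dosages: pd.DataFrame,
    trait: pd.Series,
    covariates: pd.DataFrame | None = None,
    *,
    significance: float = GENOME_WIDE_ALPHA,
) -> pd.DataFrame:
    """Additive per-SNP scan: trait ~ dosage + covariates, Wald t test.

    Implemented by Frisch-Waugh-Lovell residualisation of trait and
    dosages on the covariates, so thousands of SNPs are one matrix
    product. Adds a ``genome_wide`` flag at the conventional 5e-8.
    """
    ids = dosages.index
    trait = trait.loc[ids]
    parts = [np.ones(len(ids))]
    if covariates is not None:
        covariates = covariates.loc[ids]
        parts += [covariates[c].to_numpy(dtype=float) for c in covariates.columns]
    C = np.column_stack(parts)
    _check_design(C)
    n = len(ids)
    p_cov = C.shape[1]
    df = n - p_cov - 1

    Q, _ = np.linalg.qr(C)
    y = trait.to_numpy(dtype=float)
    y_r = y - Q @ (Q.T @ y)
    D = dosages.to_numpy(dtype=float)
    D_r = D - Q @ (Q.T @ D)
    sxx = (D_r**2).sum(axis=0)
    const = sxx <= 1e-12
    sxx_safe = np.where(const, np.nan, sxx)
    beta = D_r.T @ y_r / sxx_safe
    rss = (y_r @ y_r) - beta**2 * sxx_safe
    se = np.sqrt(rss / df / sxx_safe)
    with np.errstate(invalid="ignore"):
        tstat = beta / se
    pval = 2.0 * stats.t.sf(np.abs(tstat), df)
    if const.any():
        log.warning("%d constant dosage columns; p set to 1", int(const.sum()))
    out = pd.DataFrame(
        {
            "feature_id": dosages.columns,
            "beta": np.where(const, 0.0, beta),
            "se": np.where(const, np.nan, se),
            "stat": np.where(const, 0.0, tstat),
            "p": np.where(const, 1.0, pval).clip(min=np.nextafter(0, 1)),
            "n": n,
        }
    )
    out = _finalize(out)
    out["genome_wide"] = out["p"] < significance
    return out
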