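"""Mendelian randomization: one-sample bidirectional 2SLS and two-sample MR.

Forward causality (expression -> trait) is probed per gene with its top
cis-eQTL as instrument; reverse causality (trait -> expression) with a
six-locus genetic risk score. Instruments with first-stage F < 10 are
treated as weak and excluded by default. Two-sample MR against disease
GWAS summary statistics harmonises effect alleles, then dispatches to
the Wald ratio (one SNP) or fixed-effect inverse-variance weighting
(two or more SNPs).

Classification rule for one-sample bidirectional MR at level alpha:
``putative_causal`` iff the forward p is significant and the reverse is
not; ``reverse`` for the mirror image; ``bidirectional`` when both are
significant; ``none`` otherwise. Strict < at alpha for significance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .simulate import DEFAULT_PRS_SNPS

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_PRS_SNPS_WEIGHTS",
    "Instrument",
    "PrsWeights",
    "MrResult",
    "WEAK_INSTRUMENT_F",
    "select_instrument",
    "f_statistic",
    "tsls",
    "build_prs",
    "bidirectional_mr",
    "harmonize",
    "wald_ratio",
    "ivw",
    "two_sample_mr",
]

WEAK_INSTRUMENT_F = 10.0
_P_FLOOR = 1e-300

MR_RESULT_COLUMNS = [
    "feature_id", "direction", "method", "nsnp", "beta", "se", "p", "classification",
]


@dataclass
class Instrument:
    """Selected instrumental variable for one gene."""

    feature_id: str
    snp_id: str
    f_stat: float
    r2: float
    source: str = "cis_eqtl"


@dataclass(frozen=True)
class PrsWeights:
    """Per-allele weights of the trait genetic risk score."""

    snp_id: tuple[str, ...]
    effect_allele: tuple[str, ...]
    weight: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(set(self.snp_id)) != len(self.snp_id):
            raise ValueError("duplicate SNP IDs in risk-score weights")
        if not (len(self.snp_id) == len(self.effect_allele) == len(self.weight)):
            raise ValueError("weight table fields have unequal lengths")
        if not np.all(np.isfinite(self.weight)):
            raise ValueError("weights must be finite")


#: Equal-weight score over the six canonical IgE risk loci; effect allele
#: "." means "whatever allele the dosage column counts" (no flipping).
DEFAULT_PRS_SNPS_WEIGHTS = PrsWeights(
    snp_id=DEFAULT_PRS_SNPS,
    effect_allele=(".",) * len(DEFAULT_PRS_SNPS),
    weight=(1.0,) * len(DEFAULT_PRS_SNPS),
)


@dataclass
class MrResult:
    """One MR estimate with its method tag and causal classification."""

    feature_id: str
    direction: str           # forward | reverse
    beta: float
    se: float
    p: float
    method: str              # tsls | wald_ratio | ivw
    nsnp: int
    classification: str = ""
    f_stat: float = np.nan


def f_statistic(g, x) -> tuple[float, float]:
    """Instrument strength: (F, r2) from the simple regression x ~ g.

    F = (n - 2) r^2 / (1 - r^2), the square of the first-stage Wald t.
    """
    g = np.asarray(g, dtype=float)
    x = np.asarray(x, dtype=float)
    n = g.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(g) == 0.0:
        raise ValueError("instrument is constant")
    r = np.corrcoef(g, x)[0, 1]
    r2 = float(r**2)
    if r2 >= 1.0:
        return float("inf"), 1.0
    return (n - 2) * r2 / (1.0 - r2), r2


def select_instrument(eqtl_table: pd.DataFrame) -> pd.DataFrame:
    """Top cis-eQTL per gene as its instrument.

    ``eqtl_table`` columns: gene, snp_id, beta, se, p, n. Minimum p wins;
    ties break to larger |beta|, then lexicographic snp_id. F recovered
    from the Wald t (F = t^2, equivalently r2 = t2/(t2 + n - 2)). Genes
    without any record are simply absent (logged by the caller's join).
    """
    required = {"gene", "snp_id", "beta", "se", "p", "n"}
    missing = required - set(eqtl_table.columns)
    if missing:
        raise ValueError(f"eQTL table missing columns: {sorted(missing)}")
    df = eqtl_table.copy()
    df["_absbeta"] = df["beta"].abs()
    df = df.sort_values(
        ["gene", "p", "_absbeta", "snp_id"],
        ascending=[True, True, False, True],
        kind="stable",
    )
    top = df.groupby("gene", sort=True).head(1).drop(columns="_absbeta")
    t2 = (top["beta"] / top["se"]) ** 2
    top = top.assign(
        f_stat=t2.to_numpy(),
        r2=(t2 / (t2 + top["n"] - 2)).to_numpy(),
        source="cis_eqtl",
    )
    return top.rename(columns={"gene": "feature_id"}).reset_index(drop=True)


def tsls(
    g,
    x,
    y,
    covariates: pd.DataFrame | np.ndarray | None = None,
    *,
    feature_id: str = "",
    direction: str = "forward",
    min_f: float = WEAK_INSTRUMENT_F,
    allow_weak: bool = False,
) -> MrResult:
    """Two-stage least squares with a single instrument (or score).

    Stage 1 regresses the exposure x on the instrument g (+covariates);
    stage 2 regresses the outcome y on the fitted exposure. The SE uses
    the 2SLS convention: residuals are recomputed with the original x
    at the 2SLS coefficient, not the naive stage-2 residuals. p is
    two-sided normal. Instruments with first-stage F below ``min_f``
    return a ``weak_instrument`` result with no estimate unless
    ``allow_weak``.
    """
    g = np.asarray(g, dtype=float)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if not (g.size == x.size == n):
        raise ValueError("g, x, y must be equally long")
    f_stat, _ = f_statistic(g, x)
    if f_stat < min_f and not allow_weak:
        return MrResult(feature_id, direction, np.nan, np.nan, np.nan,
                        "tsls", 1, "weak_instrument", f_stat)

    if covariates is None:
        C = np.ones((n, 1))
    else:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        C = np.column_stack([np.ones(n), C])
    Z = np.column_stack([g, C])        # instruments
    W = np.column_stack([x, C])        # regressors
    Qz, _ = np.linalg.qr(Z)
    W_hat = Qz @ (Qz.T @ W)
    if np.linalg.matrix_rank(W_hat) < W_hat.shape[1]:
        raise ValueError("fitted exposure collinear with covariates")
    coef = np.linalg.lstsq(W_hat, y, rcond=None)[0]
    resid = y - W @ coef               # ORIGINAL regressors at 2SLS coef
    dof = n - W.shape[1]
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(W_hat.T @ W_hat)
    beta = float(coef[0])
    se = float(np.sqrt(cov[0, 0]))
    p = float(np.clip(2.0 * stats.norm.sf(abs(beta / se)), _P_FLOOR, 1.0))
    return MrResult(feature_id, direction, beta, se, p, "tsls", 1, "", f_stat)


def build_prs(
    dosages: pd.DataFrame,
    weights: PrsWeights,
    counted_alleles: pd.Series | None = None,
) -> pd.Series:
    """Weighted allele score over the risk-score SNPs.

    ``counted_alleles`` maps snp_id -> the allele the dosage column
    counts; when it differs from the weight's effect allele the dosage
    is flipped to 2 - d before weighting. Without the map, dosages are
    assumed already aligned to the effect alleles.
    """
    missing = [s for s in weights.snp_id if s not in dosages.columns]
    if missing:
        raise KeyError(f"risk-score SNPs missing from dosages: {missing}")
    score = np.zeros(len(dosages))
    for snp, ea, w in zip(weights.snp_id, weights.effect_allele, weights.weight):
        d = dosages[snp].to_numpy(dtype=float)
        if counted_alleles is not None and counted_alleles.get(snp, ea) != ea:
            d = 2.0 - d
        score += w * d
    return pd.Series(score, index=dosages.index, name="prs")


def _classify(p_fwd: float, p_rev: float, alpha: float) -> str:
    fwd = p_fwd < alpha
    rev = p_rev < alpha
    if fwd and not rev:
        return "putative_causal"
    if rev and not fwd:
        return "reverse"
    if fwd and rev:
        return "bidirectional"
    return "none"


def bidirectional_mr(
    expression: pd.DataFrame,
    trait: pd.Series,
    dosages: pd.DataFrame,
    instruments: pd.DataFrame,
    prs: pd.Series,
    *,
    alpha: float = 0.05,
    covariates: pd.DataFrame | None = None,
    min_f: float = WEAK_INSTRUMENT_F,
    prs_min_f: float = WEAK_INSTRUMENT_F,
) -> pd.DataFrame:
    """Per-gene bidirectional one-sample MR with the classification rule.

    Forward: 2SLS of trait on expression instrumented by the gene's top
    cis-eQTL. Reverse: 2SLS of expression on trait instrumented by the
    shared genetic risk score. Returns one row per gene with forward
    estimates plus reverse p and the classification; genes whose
    forward instrument is weak are labelled ``weak_instrument``.
    """
    ids = expression.columns
    trait = trait.loc[ids]
    dosages = dosages.loc[ids]
    prs_v = prs.loc[ids].to_numpy(dtype=float)
    cov_arr = covariates.loc[ids].to_numpy(dtype=float) if covariates is not None else None
    t = trait.to_numpy(dtype=float)

    rows = []
    inst = instruments.set_index("feature_id")
    for gene in expression.index:
        if gene not in inst.index:
            log.info("gene %s has no instrument; skipped", gene)
            continue
        snp = inst.loc[gene, "snp_id"]
        if snp not in dosages.columns:
            log.warning("instrument %s for gene %s missing from dosages", snp, gene)
            continue
        g = dosages[snp].to_numpy(dtype=float)
        e = expression.loc[gene].to_numpy(dtype=float)
        fwd = tsls(g, e, t, cov_arr, feature_id=gene, direction="forward",
                   min_f=min_f)
        if fwd.classification == "weak_instrument":
            rows.append((gene, "forward", "tsls", 1, np.nan, np.nan, np.nan,
                         "weak_instrument", np.nan, fwd.f_stat))
            continue
        rev = tsls(prs_v, t, e, cov_arr, feature_id=gene, direction="reverse",
                   min_f=prs_min_f)
        if rev.classification == "weak_instrument":
            rows.append((gene, "forward", "tsls", 1, fwd.beta, fwd.se, fwd.p,
                         "weak_instrument", np.nan, fwd.f_stat))
            continue
        cls = _classify(fwd.p, rev.p, alpha)
        rows.append((gene, "forward", "tsls", 1, fwd.beta, fwd.se, fwd.p, cls,
                     rev.p, fwd.f_stat))
    out = pd.DataFrame(
        rows,
        columns=["feature_id", "direction", "method", "nsnp", "beta", "se", "p",
                 "classification", "p_reverse", "f_stat"],
    )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# two-sample MR

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    *,
    drop_palindromic: bool = False,
) -> pd.DataFrame:
    """Align outcome effects to the exposure effect allele per SNP.

    Swapped allele pairs flip the outcome beta sign; irreconcilable
    allele sets are dropped (reason ``allele_mismatch``); A/T and C/G
    pairs are flagged palindromic and dropped only under
    ``drop_palindromic``. Idempotent: harmonized input passes through.
    """
    common = set(exposure["snp_id"]) & set(outcome["snp_id"])
    if not common:
        raise ValueError("no SNPs shared between exposure and outcome")
    exp = exposure.set_index("snp_id")
    out = outcome.set_index("snp_id")
    rows = []
    for snp in sorted(common):
        e, o = exp.loc[snp], out.loc[snp]
        ea_e, oa_e = str(e["effect_allele"]).upper(), str(e["other_allele"]).upper()
        ea_o, oa_o = str(o["effect_allele"]).upper(), str(o["other_allele"]).upper()
        palindromic = _is_palindromic(ea_e, oa_e)
        flipped = False
        dropped = False
        reason = ""
        beta_out = float(o["beta"])
        if (ea_o, oa_o) == (ea_e, oa_e):
            pass
        elif (ea_o, oa_o) == (oa_e, ea_e):
            beta_out = -beta_out
            flipped = True
        else:
            dropped, reason = True, "allele_mismatch"
        if not dropped and palindromic and drop_palindromic:
            dropped, reason = True, "palindromic"
        rows.append(
            {
                "snp_id": snp,
                "effect_allele": ea_e,
                "other_allele": oa_e,
                "beta_exposure": float(e["beta"]),
                "se_exposure": float(e["se"]),
                "beta_outcome": beta_out,
                "se_outcome": float(o["se"]),
                "flipped": flipped,
                "palindromic": palindromic,
                "dropped": dropped,
                "drop_reason": reason,
            }
        )
    return pd.DataFrame(rows)


def wald_ratio(
    beta_gx: float, se_gx: float, beta_gy: float, se_gy: float,
    *, feature_id: str = "",
) -> MrResult:
    """Single-instrument MR: beta_gy / beta_gx with first-order SE."""
    if beta_gx == 0:
        raise ValueError("exposure effect beta_gx must be nonzero")
    beta = beta_gy / beta_gx
    se = se_gy / abs(beta_gx)
    if beta == 0:
        p = 1.0
    else:
        p = float(np.clip(2.0 * stats.norm.sf(abs(beta / se)), _P_FLOOR, 1.0))
    return MrResult(feature_id, "forward", float(beta), float(se), p,
                    "Wald ratio", 1)


def ivw(betas, ses, *, feature_id: str = "") -> MrResult:
    """Fixed-effect inverse-variance-weighted combination of Wald ratios."""
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.size == 0 or betas.size != ses.size:
        raise ValueError("betas and ses must be non-empty and equally long")
    if np.any(ses <= 0):
        raise ValueError("all SEs must be positive")
    w = 1.0 / ses**2
    beta = float(np.sum(w * betas) / np.sum(w))
    se = float(1.0 / np.sqrt(np.sum(w)))
    p = float(np.clip(2.0 * stats.norm.sf(abs(beta / se)), _P_FLOOR, 1.0))
    return MrResult(feature_id, "forward", beta, se, p,
                    "Inverse variance weighted", int(betas.size))


def two_sample_mr(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    *,
    alpha: float = 0.05,
    drop_palindromic: bool = False,
) -> pd.DataFrame:
    """Gene-by-gene two-sample MR against outcome summary statistics.

    ``exposure`` carries per-gene instrument effects on expression
    (columns gene, snp_id, effect_allele, other_allele, beta, se);
    ``outcome`` is a GWAS summary table over (at least) those SNPs.
    Per gene the harmonised SNP set dispatches to the Wald ratio
    (nsnp = 1) or IVW (nsnp >= 2); the significance flag applies a
    Bonferroni threshold alpha over genes tested.
    """
    results = []
    genes = sorted(exposure["gene"].unique())
    for gene in genes:
        sub = exposure[exposure["gene"] == gene]
        try:
            pairs = harmonize(sub, outcome, drop_palindromic=drop_palindromic)
        except ValueError:
            log.info("gene %s: no SNPs shared with outcome; omitted", gene)
            continue
        pairs = pairs[~pairs["dropped"] & (pairs["beta_exposure"] != 0)]
        if pairs.empty:
            log.info("gene %s: no surviving SNPs after harmonization; omitted", gene)
            continue
        ratios = pairs["beta_outcome"] / pairs["beta_exposure"]
        ratio_ses = pairs["se_outcome"] / pairs["beta_exposure"].abs()
        if len(pairs) == 1:
            r = pairs.iloc[0]
            res = wald_ratio(r["beta_exposure"], r["se_exposure"],
                             r["beta_outcome"], r["se_outcome"], feature_id=gene)
        else:
            res = ivw(ratios.to_numpy(), ratio_ses.to_numpy(), feature_id=gene)
        results.append(res)
    if not results:
        return pd.DataFrame(columns=MR_RESULT_COLUMNS + ["significant"])
    m = len(results)
    threshold = alpha / m
    out = pd.DataFrame(
        [
            (r.feature_id, r.direction, r.method, r.nsnp, r.beta, r.se, r.p,
             "putative_causal" if r.p < threshold else "none")
            for r in results
        ],
        columns=MR_RESULT_COLUMNS,
    )
    out["significant"] = out["p"] < threshold
    return out.sort_values(["p", "feature_id"], kind="stable").reset_index(drop=True)
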