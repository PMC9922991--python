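"""Synthetic family cohorts with known genetic architecture.

Generates genotype dosages for sib-pair/sib-ship families plus unrelated
singletons, cis-eQTL-driven expression, and a quantitative trait on a
log10-immunoglobulin-like scale under one of four causal scenarios:

``forward``
    expression of designated causal genes -> trait (effect ``theta``).
``reverse``
    trait is generated first (covariates + a six-SNP polygenic score +
    noise) and feeds back into expression of the causal genes.
``mediated``
    causal-gene expression raises the eosinophil fraction, which raises
    the trait; no direct edge.
``null``
    expression and trait share no path.

Every generator is driven by a single ``numpy.random.Generator`` seeded
from the config, so identical configs reproduce identical cohorts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_PRS_SNPS",
    "SimulationConfig",
    "CohortDataset",
    "simulate_genotypes",
    "simulate_expression_and_trait",
    "simulate_cohort",
    "simulate_disease_summary_stats",
]

#: rsIDs of the six loci conventionally combined into the IgE genetic risk
#: score (FCER1A, STAT6, IL13, HLA-G, HLA-A, HLA-DQA2 region variants).
DEFAULT_PRS_SNPS = (
    "rs2251746",
    "rs1059513",
    "rs1295686",
    "rs2523809",
    "rs2517754",
    "rs2858331",
)

_BASES = np.array(list("ACGT"))

GWAS_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "p", "eaf", "n", "info",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic cohort.

    Variance fractions are of the marginal expression (``eqtl_r2``,
    ``polygenic_var``) or trait (``prs_r2``, ``mediator_strength``)
    variance; ``theta`` is the causal effect in trait units per
    expression unit (forward/mediated) or expression units per trait
    unit (reverse).
    """

    n_subjects: int = 1000
    n_families: int = 200
    sibs_per_family: int = 2
    n_snps: int = 220
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int = 200
    eqtl_r2: float = 0.2
    polygenic_var: float = 0.1
    scenario: str = "null"
    theta: float = 0.0
    n_causal: int = 1
    mediator_strength: float = 0.3
    prs_r2: float = 0.1
    noise_sd: float = 0.5
    prs_weights: tuple[float, ...] | None = None  # per-SNP, equal if None
    covariate_betas: dict[str, float] = field(
        default_factory=lambda: {
            "age": 0.003, "sex": -0.05, "smoke_former": 0.05,
            "smoke_current": 0.10, "pack_years": 0.002,
        }
    )
    trait_mean: float = 1.52
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_snps", "n_genes", "sibs_per_family"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_families < 0:
            raise ValueError("n_families must be >= 0")
        if self.n_families * self.sibs_per_family > self.n_subjects:
            raise ValueError(
                "n_subjects cannot accommodate the requested family "
                f"structure ({self.n_families} x {self.sibs_per_family} "
                f"> {self.n_subjects})"
            )
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0.0 <= self.eqtl_r2 < 1.0):
            raise ValueError("eqtl_r2 must be in [0, 1)")
        if self.eqtl_r2 + self.polygenic_var >= 1.0:
            raise ValueError("eqtl_r2 + polygenic_var must be < 1")
        if self.scenario not in {"forward", "reverse", "null", "mediated"}:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "mediated" and not (0.0 <= self.mediator_strength < 1.0):
            raise ValueError("mediator_strength must be in [0, 1)")
        if not (0.0 <= self.prs_r2 < 1.0):
            raise ValueError("prs_r2 must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.n_causal > self.n_genes:
            raise ValueError("n_causal cannot exceed n_genes")
        if self.n_snps < len(DEFAULT_PRS_SNPS) + 1:
            raise ValueError(
                f"n_snps must be at least {len(DEFAULT_PRS_SNPS) + 1} "
                "(six risk-score SNPs plus one cis-eQTL)"
            )


@dataclass
class CohortDataset:
    """One synthetic cohort: genotypes, kinship, expression, trait, truth.

    ``kinship`` uses the numerator-relationship convention: unit diagonal,
    0.5 expected for full sibs, 0 across families.
    """

    dosages: pd.DataFrame          # subjects x SNPs
    snp_info: pd.DataFrame         # snp_id, chrom, pos, ref, alt, maf
    kinship: pd.DataFrame          # subjects x subjects
    expression: pd.DataFrame | None = None   # genes x subjects
    phenotype: pd.Series | None = None       # per-subject trait
    covariates: pd.DataFrame | None = None
    truth: pd.DataFrame | None = None        # gene, cis_snp, scenario, theta
    config: SimulationConfig | None = None

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def sample_ids(self) -> pd.Index:
        return self.dosages.index


def _rng(seed: int, stream: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


def simulate_genotypes(config: SimulationConfig) -> CohortDataset:
    """Draw Hardy-Weinberg dosages with sib-block family structure.

    Each family shares two simulated parents per SNP; each sib inherits
    one allele from each parent independently, giving expected
    relatedness 0.5 within a sib-ship. Remaining subjects are unrelated
    HWE draws. Returns a dataset holding dosages, SNP metadata and the
    pedigree-expected kinship matrix.
    """
    rng = _rng(config.seed, 0)
    n, m = config.n_subjects, config.n_snps
    mafs = rng.uniform(*config.maf_range, size=m)

    n_fam_members = config.n_families * config.sibs_per_family
    dos = np.empty((n, m), dtype=float)
    if config.n_families > 0:
        # parental alleles: (families, 4 alleles, snps)
        par = rng.random((config.n_families, 4, m)) < mafs
        for s in range(config.sibs_per_family):
            pick_m = rng.integers(0, 2, size=(config.n_families, m))
            pick_f = rng.integers(0, 2, size=(config.n_families, m))
            mat = np.take_along_axis(par[:, 0:2, :], pick_m[:, None, :], axis=1)[:, 0, :]
            pat = np.take_along_axis(par[:, 2:4, :], pick_f[:, None, :], axis=1)[:, 0, :]
            rows = np.arange(config.n_families) * config.sibs_per_family + s
            dos[rows] = mat.astype(float) + pat.astype(float)
    n_single = n - n_fam_members
    if n_single:
        dos[n_fam_members:] = rng.binomial(2, mafs, size=(n_single, m)).astype(float)

    kin = np.eye(n)
    for f in range(config.n_families):
        a = f * config.sibs_per_family
        b = a + config.sibs_per_family
        kin[a:b, a:b] = 0.5
    np.fill_diagonal(kin, 1.0)

    samples = pd.Index([f"S{i:05d}" for i in range(n)], name="sample_id")
    snp_ids = list(DEFAULT_PRS_SNPS) + [
        f"snp{j:05d}" for j in range(len(DEFAULT_PRS_SNPS), m)
    ]
    ref_idx = rng.integers(0, 4, size=m)
    alt_idx = (ref_idx + rng.integers(1, 4, size=m)) % 4
    snp_info = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": (rng.integers(1, 23, size=m)).astype(str),
            "pos": np.sort(rng.integers(1, 2_000_000, size=m)),
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "maf": mafs,
        }
    )
    dosages = pd.DataFrame(dos, index=samples, columns=snp_ids)
    kinship = pd.DataFrame(kin, index=samples, columns=samples)
    return CohortDataset(dosages=dosages, snp_info=snp_info, kinship=kinship,
                         config=config)


def _simulate_covariates(rng: np.random.Generator, samples: pd.Index) -> pd.DataFrame:
    n = len(samples)
    age = rng.normal(55.0, 13.0, n).clip(18, 95)
    sex = rng.integers(0, 2, n).astype(float)
    smoking = rng.choice([0, 1, 2], size=n, p=[0.55, 0.30, 0.15])
    pack_years = np.where(smoking > 0, rng.gamma(2.0, 8.0, n), 0.0)
    eos = rng.beta(2.0, 60.0, n)          # eosinophil fraction ~3%
    lymph = rng.beta(8.0, 18.0, n)        # lymphocyte fraction ~30%
    return pd.DataFrame(
        {
            "age": age,
            "sex": sex,
            "smoke_former": (smoking == 1).astype(float),
            "smoke_current": (smoking == 2).astype(float),
            "pack_years": pack_years,
            "eosinophil_fraction": eos,
            "lymphocyte_fraction": lymph,
        },
        index=samples,
    )


def _scaled(vec: np.ndarray, target_var: float) -> np.ndarray:
    """Rescale ``vec`` (centered) to the requested sample variance."""
    v = vec - vec.mean()
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return v * np.sqrt(target_var) / sd


def simulate_expression_and_trait(
    genotypes: CohortDataset, config: SimulationConfig
) -> CohortDataset:
    """Complete a genotype-only cohort with expression, trait and truth.

    Per gene: one cis-SNP whose dosage explains ``eqtl_r2`` of the
    (unit) expression variance, a kinship-correlated polygenic term
    explaining ``polygenic_var``, and Gaussian noise. The trait follows
    the configured scenario; causal genes are the first ``n_causal``
    genes (zero causal genes under ``null``).
    """
    cfg = config
    rng = _rng(cfg.seed, 1)
    dos = genotypes.dosages.to_numpy()
    n = dos.shape[0]
    samples = genotypes.sample_ids
    covs = _simulate_covariates(rng, samples)

    # cis-SNPs: cycle through SNPs after the six risk-score loci
    n_prs = len(DEFAULT_PRS_SNPS)
    cis_idx = n_prs + (np.arange(cfg.n_genes) % (cfg.n_snps - n_prs))
    gene_ids = [f"gene{g:05d}" for g in range(cfg.n_genes)]

    # polygenic family effect with covariance K: sib-block kinship is
    # 0.5 I + 0.5 (block of ones), so a shared per-family component plus
    # an individual component samples u ~ N(0, K) exactly in O(n)
    def _polygenic() -> np.ndarray:
        u = rng.standard_normal(n)
        if cfg.n_families > 0:
            n_fam_members = cfg.n_families * cfg.sibs_per_family
            fam = np.repeat(rng.standard_normal(cfg.n_families),
                            cfg.sibs_per_family)
            u[:n_fam_members] = np.sqrt(0.5) * (u[:n_fam_members] + fam)
        return u

    resid_var = 1.0 - cfg.eqtl_r2 - cfg.polygenic_var
    expr = np.empty((cfg.n_genes, n))
    for g in range(cfg.n_genes):
        e = _scaled(dos[:, cis_idx[g]], cfg.eqtl_r2)
        e += _scaled(_polygenic(), cfg.polygenic_var)
        e += rng.normal(0.0, np.sqrt(resid_var), n)
        expr[g] = e

    cov_effect = sum(
        beta * covs[name].to_numpy()
        for name, beta in cfg.covariate_betas.items()
        if name in covs
    )
    cov_effect = np.asarray(cov_effect, dtype=float)
    noise = rng.normal(0.0, cfg.noise_sd, n)

    causal = np.arange(cfg.n_causal) if cfg.scenario != "null" else np.arange(0)
    theta_vec = np.zeros(cfg.n_genes)
    theta_vec[causal] = cfg.theta

    # six risk-score loci act on the trait in every scenario (they are
    # genome-wide trait hits regardless of any expression-trait edge),
    # explaining prs_r2 of the genetic-plus-noise trait variance
    weights = (
        np.asarray(cfg.prs_weights, dtype=float)
        if cfg.prs_weights is not None
        else np.ones(n_prs)
    )
    prs = dos[:, :n_prs] @ weights
    prs_term = _scaled(prs, cfg.prs_r2 / (1 - cfg.prs_r2) * cfg.noise_sd**2)
    base = cfg.trait_mean + cov_effect + prs_term + noise

    if cfg.scenario in ("forward", "null"):
        trait = base.copy()
        for g in causal:
            trait = trait + cfg.theta * expr[g]
    elif cfg.scenario == "reverse":
        trait = base.copy()
        for g in causal:
            expr[g] = expr[g] + cfg.theta * (trait - trait.mean())
    elif cfg.scenario == "mediated":
        # expression -> eosinophil fraction -> trait
        eos = covs["eosinophil_fraction"].to_numpy().copy()
        for g in causal:
            eos = eos + _scaled(expr[g], cfg.mediator_strength * eos.var())
        covs["eosinophil_fraction"] = np.clip(eos, 0.0, 1.0)
        eos_term = _scaled(
            covs["eosinophil_fraction"].to_numpy(),
            cfg.mediator_strength / (1 - cfg.mediator_strength) * cfg.noise_sd**2,
        )
        trait = base + eos_term
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(cfg.scenario)

    truth = pd.DataFrame(
        {
            "gene": gene_ids,
            "cis_snp": [genotypes.dosages.columns[j] for j in cis_idx],
            "scenario": cfg.scenario,
            "theta": theta_vec,
        }
    )
    return CohortDataset(
        dosages=genotypes.dosages,
        snp_info=genotypes.snp_info,
        kinship=genotypes.kinship,
        expression=pd.DataFrame(expr, index=pd.Index(gene_ids, name="gene"),
                                columns=samples),
        phenotype=pd.Series(trait, index=samples, name="log10_ige"),
        covariates=covs,
        truth=truth,
        config=cfg,
    )


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Convenience wrapper: genotypes then expression/trait."""
    return simulate_expression_and_trait(simulate_genotypes(config), config)


def simulate_disease_summary_stats(
    cohort: CohortDataset,
    liability_effects: dict[str, float] | None = None,
    prevalence: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Binary-disease GWAS summary statistics under a liability threshold.

    A standard-normal liability gets the stated per-allele effects added
    (``liability_effects``: snp_id -> effect on liability per alt
    allele); cases are the top ``prevalence`` fraction. Per-SNP effects
    are then estimated by linear regression of case status on dosage,
    exactly as a GWAS on the observed data would, and returned in the
    canonical summary-statistic column order.
    """
    if cohort.phenotype is None:
        raise ValueError("cohort must be completed before simulating disease")
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must be in (0, 1)")
    rng = _rng(seed, 2)
    dos = cohort.dosages.to_numpy()
    n, m = dos.shape
    liability = rng.standard_normal(n)
    if liability_effects:
        cols = cohort.dosages.columns
        for snp, eff in liability_effects.items():
            if snp not in cols:
                raise KeyError(f"liability SNP {snp!r} not in cohort dosages")
            j = cols.get_loc(snp)
            liability = liability + eff * (dos[:, j] - dos[:, j].mean())
    threshold = np.quantile(liability, 1.0 - prevalence)
    disease = (liability > threshold).astype(float)

    # per-SNP simple regression disease ~ dosage (vectorised)
    d = dos - dos.mean(axis=0)
    y = disease - disease.mean()
    sxx = (d * d).sum(axis=0)
    sxx = np.where(sxx == 0, np.nan, sxx)
    beta = d.T @ y / sxx
    resid_ss = (y @ y) - beta**2 * sxx
    df = n - 2
    se = np.sqrt(resid_ss / df / sxx)
    tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)

    out = cohort.snp_info.copy()
    out["beta"] = np.nan_to_num(beta, nan=0.0)
    out["se"] = np.where(np.isfinite(se), se, np.inf)
    out["p"] = np.where(np.isfinite(p), p, 1.0)
    out["eaf"] = dos.mean(axis=0) / 2.0
    out["n"] = n
    out["info"] = 1.0
    out = out.rename(columns={"alt": "effect_allele", "ref": "other_allele"})
    return out[GWAS_COLUMNS]
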