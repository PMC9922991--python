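"""End-to-end pipeline: simulate -> discovery TWAS -> replication GLMs ->
meta-analysis -> bidirectional replication -> MR -> two-sample MR -> ORA.

Replays the study workflow on synthetic cohorts (or user tables via the
CLI): a large family-structured discovery cohort analysed with the
kinship mixed model and two smaller unrelated replication cohorts
analysed with ordinary per-gene linear models, combined by weighted
inverse-normal meta-analysis, replicated in both directions, then
probed causally with bidirectional one-sample 2SLS and two-sample MR
against simulated disease GWAS summary statistics, and finally a
hypergeometric over-representation pass on the bidirectional gene set.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .association import bh_fdr, glm_assoc, compute_expression_pcs, twas
from .enrich import ora, read_gmt
from .io import write_cohort, write_table
from .meta import bidirectional_replication, meta_analyze, replicate
from .mr import (
    DEFAULT_PRS_SNPS_WEIGHTS,
    bidirectional_mr,
    build_prs,
    select_instrument,
    two_sample_mr,
)
from .simulate import (
    DEFAULT_PRS_SNPS,
    SimulationConfig,
    simulate_cohort,
    simulate_disease_summary_stats,
)

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "eqtl_scan"]


@dataclass
class PipelineConfig:
    """Configuration of one synthetic end-to-end run."""

    seed: int = 0
    out_dir: str = "run"
    scenario: str = "forward"
    theta: float = 0.5
    n_causal: int = 10
    n_genes: int = 200
    n_discovery: int = 2000
    n_replication: tuple[int, ...] = (610, 326)
    discovery_fdr: float = 0.05
    mr_alpha: float = 0.05
    weight_scheme: str = "sqrt-n"
    eqtl_r2: float = 0.2
    disease_prevalence: float = 0.1
    run_enrichment: bool = True
    run_mr: bool = True
    gmt_path: str | None = None

    def __post_init__(self) -> None:
        for a in (self.discovery_fdr, self.mr_alpha):
            if not (0.0 < a < 1.0):
                raise ValueError("alpha levels must lie in (0, 1)")
        if self.gmt_path is not None and not Path(self.gmt_path).exists():
            raise FileNotFoundError(self.gmt_path)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def eqtl_scan(expression: pd.DataFrame, dosages: pd.DataFrame,
              top_per_gene: int = 5) -> pd.DataFrame:
    """All-pairs expression-on-dosage simple regressions; keep the
    strongest ``top_per_gene`` records per gene as candidate cis-eQTLs."""
    ids = expression.columns
    D = dosages.loc[ids].to_numpy(dtype=float)
    E = expression.to_numpy(dtype=float).T  # samples x genes
    n = D.shape[0]
    Dc = D - D.mean(axis=0)
    Ec = E - E.mean(axis=0)
    sxx = (Dc**2).sum(axis=0)
    sxx = np.where(sxx == 0, np.nan, sxx)
    B = (Dc.T @ Ec) / sxx[:, None]             # snps x genes
    syy = (Ec**2).sum(axis=0)
    rss = syy[None, :] - B**2 * sxx[:, None]
    se = np.sqrt(rss / (n - 2) / sxx[:, None])
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = B / se
    p = 2.0 * stats.t.sf(np.abs(tstat), n - 2)
    records = []
    snp_ids = np.asarray(dosages.columns)
    for j, gene in enumerate(expression.index):
        order = np.argsort(p[:, j], kind="stable")[:top_per_gene]
        for i in order:
            if not np.isfinite(p[i, j]):
                continue
            records.append((gene, snp_ids[i], B[i, j], se[i, j], p[i, j], n))
    return pd.DataFrame(records, columns=["gene", "snp_id", "beta", "se", "p", "n"])


def _write_synthetic_gmt(path: Path, genes: list[str], causal: list[str],
                         rng: np.random.Generator) -> Path:
    """Synthetic gene-set collection: one set enriched in causal genes plus
    random sets of comparable size (labelled synthetic by construction)."""
    with open(path, "w", newline="\n") as fh:
        enriched = sorted(set(causal) | set(rng.choice(genes, size=5, replace=False)))
        fh.write("causal_enriched_synthetic\tsynthetic\t" + "\t".join(enriched) + "\n")
        for i in range(9):
            members = sorted(rng.choice(genes, size=15, replace=False))
            fh.write(f"random_set_{i:02d}\tsynthetic\t" + "\t".join(members) + "\n")
    return path


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage; returns the run directory.

    Writes one TSV per stage plus ``manifest.json`` (config hash, seed,
    versions, per-stage row counts). Identical configs reproduce
    byte-identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 99]))

    # --- simulate ---------------------------------------------------------
    disc_cfg = SimulationConfig(
        n_subjects=config.n_discovery,
        n_families=config.n_discovery // 4,
        sibs_per_family=2,
        n_genes=config.n_genes,
        n_causal=config.n_causal,
        scenario=config.scenario,
        theta=config.theta,
        eqtl_r2=config.eqtl_r2,
        seed=config.seed,
    )
    discovery = simulate_cohort(disc_cfg)
    write_cohort(discovery, out / "discovery")
    replication = []
    for i, n_i in enumerate(config.n_replication):
        rep_cfg = dataclasses.replace(
            disc_cfg, n_subjects=n_i, n_families=0, sibs_per_family=1,
            seed=config.seed + 1000 * (i + 1),
        )
        replication.append(simulate_cohort(rep_cfg))
    counts["genes_simulated"] = config.n_genes

    # --- discovery TWAS ---------------------------------------------------
    twas_res = twas(
        discovery.expression, discovery.phenotype, discovery.covariates,
        discovery.kinship,
    )
    write_table(twas_res, out / "twas_discovery.tsv")
    counts["twas_discovery"] = len(twas_res)

    # --- replication GLMs and meta ---------------------------------------
    rep_tables = []
    for i, coh in enumerate(replication):
        pcs = compute_expression_pcs(coh.expression, 2)
        covs = coh.covariates[["age", "sex"]].join(pcs)
        res = glm_assoc(coh.expression, coh.phenotype, covs)
        write_table(res, out / f"glm_replication_{i}.tsv")
        rep_tables.append(res)
    meta_res = meta_analyze(rep_tables, weight_scheme=config.weight_scheme)
    write_table(meta_res, out / "meta_replication.tsv")
    counts["meta_replication"] = len(meta_res)

    # --- bidirectional replication ---------------------------------------
    fwd_report = replicate(twas_res, meta_res, alpha=0.05,
                           discovery_q=config.discovery_fdr)
    meta_disc = meta_res.assign(q=bh_fdr(meta_res["combined_p"].to_numpy()))
    twas_as_rep = twas_res.rename(columns={"p": "combined_p"})
    rev_report = replicate(meta_disc, twas_as_rep, alpha=0.05,
                           discovery_q=config.discovery_fdr)
    both = bidirectional_replication(fwd_report, rev_report)
    write_table(
        pd.DataFrame(
            {
                "feature_id": sorted(
                    set(fwd_report.replicated_set) | set(rev_report.replicated_set)
                ),
            }
        ).assign(
            replicated_forward=lambda d: d.feature_id.isin(fwd_report.replicated_set),
            replicated_reverse=lambda d: d.feature_id.isin(rev_report.replicated_set),
            bidirectional=lambda d: d.feature_id.isin(both),
        ),
        out / "replication_report.tsv",
    )
    counts["replicated_forward"] = len(fwd_report.replicated_set)
    counts["replicated_reverse"] = len(rev_report.replicated_set)
    counts["bidirectional"] = len(both)

    mr_res = pd.DataFrame()
    if config.run_mr:
        # --- instruments and bidirectional MR -----------------------------
        eqtl = eqtl_scan(discovery.expression, discovery.dosages)
        write_table(eqtl, out / "eqtl_candidates.tsv")
        instruments = select_instrument(eqtl)
        write_table(instruments, out / "instruments.tsv")
        prs = build_prs(discovery.dosages, DEFAULT_PRS_SNPS_WEIGHTS)
        mr_res = bidirectional_mr(
            discovery.expression, discovery.phenotype, discovery.dosages,
            instruments, prs, alpha=config.mr_alpha,
        )
        write_table(mr_res, out / "mr_bidirectional.tsv")
        counts["mr_tested"] = len(mr_res)
        counts["putative_causal"] = int(
            (mr_res["classification"] == "putative_causal").sum()
        )

        # --- two-sample MR against simulated disease GWAS -----------------
        outcome = simulate_disease_summary_stats(
            discovery,
            liability_effects=None,
            prevalence=config.disease_prevalence,
            seed=config.seed,
        )
        write_table(outcome, out / "disease_gwas.tsv")
        snp_alleles = discovery.snp_info.set_index("snp_id")
        exp_rows = instruments.merge(
            snp_alleles[["alt", "ref"]], left_on="snp_id", right_index=True
        ).rename(
            columns={"feature_id": "gene", "alt": "effect_allele",
                     "ref": "other_allele"}
        )
        ts_res = two_sample_mr(
            exp_rows[["gene", "snp_id", "effect_allele", "other_allele",
                      "beta", "se"]],
            outcome,
            alpha=config.mr_alpha,
        )
        write_table(ts_res, out / "mr_two_sample.tsv")
        counts["two_sample_mr_tested"] = len(ts_res)

    # --- over-representation ---------------------------------------------
    if config.run_enrichment:
        if not both:
            log.warning("enrichment skipped: empty bidirectional set")
        else:
            genes = list(discovery.expression.index)
            if config.gmt_path is None:
                gmt_path = _write_synthetic_gmt(
                    out / "gene_sets_synthetic.gmt", genes,
                    list(discovery.truth.loc[discovery.truth.theta != 0, "gene"]),
                    rng,
                )
            else:
                gmt_path = Path(config.gmt_path)
            collection = read_gmt(gmt_path, universe=genes)
            enr = ora(both, collection)
            write_table(enr, out / "enrichment.tsv")
            counts["gene_sets_tested"] = len(enr)

    # --- manifest ---------------------------------------------------------
    cfg_yaml = yaml.safe_dump(config.to_dict(), sort_keys=True)
    manifest = {
        "config": config.to_dict(),
        "config_sha256": hashlib.sha256(cfg_yaml.encode()).hexdigest(),
        "seed": config.seed,
        "versions": {
            "twasmr": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "row_counts": counts,
    }
    with open(out / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out
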