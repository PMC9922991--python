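"""Table and VCF readers/writers with deterministic formatting.

All tables are tab-separated with a header row; floats are written at 6
significant digits with LF endings so repeated runs are byte-identical.
Sample alignment everywhere in the package is by ID join, never by
position.
"""

from __future__ import annotations

import importlib.resources
import logging
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "read_table",
    "write_table",
    "read_dosage_vcf",
    "write_dosage_vcf",
    "write_cohort",
    "load_published_replication_table",
    "load_published_mr_table",
]

FLOAT_FORMAT = "%.6g"


def read_table(
    path,
    required: dict[str, type] | None = None,
    index_col=None,
) -> pd.DataFrame:
    """Read a TSV, validating required columns and their types.

    ``required`` maps column name -> expected scalar type (float/int/str);
    numeric columns that fail to parse raise. Extra columns pass through.
    """
    df = pd.read_csv(path, sep="\t", index_col=index_col)
    if required:
        missing = set(required) - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing required columns {sorted(missing)}")
        for col, typ in required.items():
            if typ in (float, int):
                try:
                    df[col] = pd.to_numeric(df[col], errors="raise")
                except (ValueError, TypeError) as exc:
                    raise ValueError(
                        f"{path}: column {col!r} is not numeric"
                    ) from exc
            else:
                df[col] = df[col].astype(str)
    return df


def write_table(df: pd.DataFrame, path, index: bool = False) -> Path:
    """Write a TSV deterministically (6 significant digits, LF endings)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FORMAT,
              lineterminator="\n")
    return path


# ---------------------------------------------------------------------------
# VCF


def read_dosage_vcf(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read dosages from a VCF: the DS FORMAT field when present, else the
    count of alternate alleles from hard genotypes (missing -> NaN).

    Returns (subjects x SNPs dosage frame, SNP metadata frame with
    snp_id, chrom, pos (1-based), ref, alt).
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises on malformed headers
        raise ValueError(f"{path}: malformed VCF ({exc})") from exc
    samples = list(vcf.samples)
    ids, chroms, poss, refs, alts = [], [], [], [], []
    rows = []
    for var in vcf:
        ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0] if var.ALT else ".")
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gt = np.asarray(var.genotype.array())[:, :2].astype(float)
            gt[gt < 0] = np.nan
            d = gt.sum(axis=1)
        rows.append(d)
    meta = pd.DataFrame(
        {"snp_id": ids, "chrom": chroms, "pos": poss, "ref": refs, "alt": alts}
    )
    dosages = pd.DataFrame(
        np.array(rows).T if rows else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="sample_id"),
        columns=ids,
    )
    return dosages, meta


def write_dosage_vcf(dosages: pd.DataFrame, snp_info: pd.DataFrame, path) -> Path:
    """Write dosages as a minimal VCFv4.2 with a DS FORMAT field."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    info = snp_info.set_index("snp_id")
    with open(path, "w", newline="\n") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(dosages.index)
            + "\n"
        )
        for snp in dosages.columns:
            r = info.loc[snp]
            vals = "\t".join(FLOAT_FORMAT % v for v in dosages[snp])
            fh.write(
                f"{r['chrom']}\t{int(r['pos'])}\t{snp}\t{r['ref']}\t{r['alt']}"
                f"\t.\t.\t.\tDS\t{vals}\n"
            )
    return path


# ---------------------------------------------------------------------------
# cohort round-trip


def write_cohort(cohort, out_dir, vcf: bool = True) -> dict[str, Path]:
    """Write a simulated cohort's files; returns name -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    if vcf:
        paths["dosages"] = write_dosage_vcf(
            cohort.dosages, cohort.snp_info, out / "dosages.vcf"
        )
    else:
        paths["dosages"] = write_table(cohort.dosages, out / "dosages.tsv", index=True)
    paths["snp_info"] = write_table(cohort.snp_info, out / "snp_info.tsv")
    paths["kinship"] = write_table(cohort.kinship, out / "kinship.tsv", index=True)
    if cohort.expression is not None:
        paths["expression"] = write_table(
            cohort.expression, out / "expression.tsv", index=True
        )
    if cohort.phenotype is not None:
        pheno = cohort.covariates.copy() if cohort.covariates is not None else pd.DataFrame(index=cohort.phenotype.index)
        pheno.insert(0, cohort.phenotype.name or "trait", cohort.phenotype)
        paths["phenotype"] = write_table(pheno, out / "phenotype.tsv", index=True)
    if cohort.truth is not None:
        paths["truth"] = write_table(cohort.truth, out / "truth.tsv")
    return paths


# ---------------------------------------------------------------------------
# bundled published summary tables


def _load_data(name: str, required: dict[str, type]) -> pd.DataFrame:
    ref = importlib.resources.files("twasmr.data").joinpath(name)
    with importlib.resources.as_file(ref) as p:
        return read_table(p, required=required)


def load_published_replication_table() -> pd.DataFrame:
    """Published whole-blood IgE TWAS replication summary: per-gene
    discovery p/q and the two-cohort meta-analysis p."""
    return _load_data(
        "ige_replication_meta.tsv",
        {"gene": str, "discovery_q": float, "discovery_p": float, "meta_p": float},
    )


def load_published_mr_table() -> pd.DataFrame:
    """Published bidirectional MR rows (forward and reverse estimates) for
    the genes reported as putatively causal for circulating IgE."""
    return _load_data(
        "ige_bidirectional_mr.tsv",
        {"gene": str, "p_fwd": float, "p_rev": float},
    )
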