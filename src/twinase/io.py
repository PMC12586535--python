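"""TSV / VCF / YAML interchange for the twin ASE pipeline.

Canonical interchange is tab-separated UTF-8 with a header row and '.' for
missing values. Genotypes can alternatively be ingested from VCF 4.2 (GT
field, one sample per twin pair — MZ co-twins share genotypes).
"""
from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
import yaml

from .types import (
    ANNOTATION_COLUMNS,
    COUNT_COLUMNS,
    GENOTYPE_COLUMNS,
    VARIANT_COLUMNS,
    AllelicCountRecord,
    GenotypeTable,
)

logger = logging.getLogger("twinase")

PathLike = Union[str, Path]


def _read_tsv(path: PathLike, required: list, dtypes: Optional[dict] = None) -> pd.DataFrame:
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, na_values=["."], keep_default_na=False)
    except Exception as exc:  # surface the offending file and line
        raise ValueError(f"cannot parse TSV {path}: {exc}") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if dtypes:
        for col, typ in dtypes.items():
            try:
                frame[col] = frame[col].astype(typ)
            except (TypeError, ValueError) as exc:
                bad = frame[pd.to_numeric(frame[col], errors="coerce").isna() & frame[col].notna()]
                line = int(bad.index[0]) + 2 if len(bad) else "?"
                raise ValueError(
                    f"{path}: column {col!r} is not {typ} (first bad value at line {line})"
                ) from exc
    return frame


def _write_tsv(frame: pd.DataFrame, path: PathLike) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep=".")


# --------------------------------------------------------------------------
# counts


def write_counts_tsv(records, path: PathLike) -> None:
    frame = pd.DataFrame(
        [(r.snp_id, r.transcript_id, r.pair_id, r.member, r.alt_count, r.ref_count) for r in records],
        columns=COUNT_COLUMNS,
    )
    _write_tsv(frame, path)


def read_counts_tsv(path: PathLike) -> list:
    frame = _read_tsv(path, COUNT_COLUMNS, {"alt_count": int, "ref_count": int})
    records = []
    for i, row in enumerate(frame.itertuples(index=False)):
        try:
            records.append(
                AllelicCountRecord(
                    pair_id=row.pair_id,
                    member=row.member,
                    snp_id=row.snp_id,
                    transcript_id=row.transcript_id,
                    alt_count=int(row.alt_count),
                    ref_count=int(row.ref_count),
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {i + 2}: {exc}") from exc
    return records


# --------------------------------------------------------------------------
# genotypes (TSV and VCF)


def write_genotypes_tsv(genotypes: GenotypeTable, path: PathLike) -> None:
    _write_tsv(genotypes.to_frame(), path)


def read_genotypes_tsv(path: PathLike) -> GenotypeTable:
    frame = _read_tsv(path, GENOTYPE_COLUMNS)
    frame["genotype"] = frame["genotype"].fillna(".")
    return GenotypeTable.from_frame(frame)


_GT_MAP = {(0, 0): "hom_ref", (0, 1): "het", (1, 0): "het", (1, 1): "hom_alt"}


def read_genotypes_vcf(path: PathLike) -> GenotypeTable:
    """GenotypeTable from a VCF 4.2 file with one sample column per twin pair.

    GT "0/0" -> hom_ref, "0/1"/"1/0" -> het, "1/1" -> hom_alt, "./." ->
    missing. Multi-allelic records are skipped with a logged warning.
    Malformed lines raise with their line number.
    """
    import cyvcf2

    path = Path(path)
    # light structural pre-check so format errors carry a line number
    n_cols = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("##") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if line.startswith("#CHROM"):
                if len(fields) < 10:
                    raise ValueError(
                        f"{path}: line {lineno}: VCF needs at least one sample column"
                    )
                n_cols = len(fields)
                continue
            if n_cols is None:
                raise ValueError(f"{path}: line {lineno}: data before #CHROM header")
            if len(fields) != n_cols:
                raise ValueError(
                    f"{path}: line {lineno}: expected {n_cols} columns, found {len(fields)}"
                )
            if not fields[1].isdigit():
                raise ValueError(f"{path}: line {lineno}: POS {fields[1]!r} is not an integer")
    if n_cols is None:
        raise ValueError(f"{path}: no #CHROM header line found")

    table = GenotypeTable()
    vcf = cyvcf2.VCF(str(path))
    samples = list(vcf.samples)
    n_multi = 0
    for variant in vcf:
        if len(variant.ALT) != 1:
            n_multi += 1
            logger.warning(
                "skipping multi-allelic record %s:%s (%s)",
                variant.CHROM, variant.POS, variant.ID or ".",
            )
            continue
        snp_id = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        for sample, gt in zip(samples, variant.genotypes):
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0:
                table.set(snp_id, sample, None)
            else:
                table.set(snp_id, sample, _GT_MAP[(min(a0, 1), min(a1, 1))])
    vcf.close()
    if n_multi:
        logger.warning("skipped %d multi-allelic record(s) in %s", n_multi, path)
    return table


def write_genotypes_vcf(
    genotypes: GenotypeTable, variants: pd.DataFrame, path: PathLike
) -> None:
    """Minimal VCF 4.2 (GT only), one sample column per twin pair."""
    pairs = genotypes.pairs()
    gt_code = {"hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1", None: "./."}
    var = variants.set_index("snp_id")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(pairs) + "\n")
        for snp_id in genotypes.snps():
            if snp_id not in var.index:
                continue
            v = var.loc[snp_id]
            gts = "\t".join(gt_code[genotypes.get(snp_id, p)] for p in pairs)
            fh.write(
                f"{v['chrom']}\t{int(v['pos'])}\t{snp_id}\t{v['ref_allele']}\t"
                f"{v['alt_allele']}\t.\tPASS\t.\tGT\t{gts}\n"
            )


# --------------------------------------------------------------------------
# variants / annotation / truth


def write_variants_tsv(variants: pd.DataFrame, path: PathLike) -> None:
    _write_tsv(variants[VARIANT_COLUMNS], path)


def read_variants_tsv(path: PathLike) -> pd.DataFrame:
    return _read_tsv(path, VARIANT_COLUMNS, {"pos": int})


def write_annotation_tsv(annotation: pd.DataFrame, path: PathLike) -> None:
    _write_tsv(annotation[ANNOTATION_COLUMNS], path)


def read_annotation_tsv(path: PathLike) -> pd.DataFrame:
    return _read_tsv(path, ANNOTATION_COLUMNS, {"start": int, "end": int})


def write_truth_tsv(truth: pd.DataFrame, path: PathLike) -> None:
    _write_tsv(truth, path)


# --------------------------------------------------------------------------
# expression panels


def write_expression_panel(panel, expr_path: PathLike, geno_path: PathLike) -> None:
    """Panel as samples x (lncRNA + genes) TSV plus a sample-group TSV."""
    frame = panel.gene_expr.copy()
    frame.insert(0, "lncRNA", panel.lnc_expr)
    frame.index.name = "sample_id"
    frame.to_csv(expr_path, sep="\t")
    geno = pd.DataFrame(
        {"sample_id": panel.sample_ids, "group": panel.genotype_group.to_numpy()}
    )
    _write_tsv(geno, geno_path)


def read_expression_panel(expr_path: PathLike, geno_path: PathLike):
    from .simulate import ExpressionPanel

    expr = pd.read_csv(expr_path, sep="\t", index_col="sample_id")
    if "lncRNA" not in expr.columns:
        raise ValueError(f"{expr_path}: missing the focal 'lncRNA' column")
    geno = _read_tsv(geno_path, ["sample_id", "group"]).set_index("sample_id")["group"]
    geno = geno.reindex(expr.index)
    if geno.isna().any():
        missing = list(expr.index[geno.isna()])[:3]
        raise ValueError(f"{geno_path}: no genotype group for sample(s) {missing}")
    bad = set(geno.unique()) - {"WT", "Heter"}
    if bad:
        raise ValueError(f"{geno_path}: unknown genotype group(s) {sorted(bad)}")
    return ExpressionPanel(
        sample_ids=list(expr.index),
        genotype_group=geno,
        lnc_expr=expr["lncRNA"],
        gene_expr=expr.drop(columns=["lncRNA"]),
    )


# --------------------------------------------------------------------------
# TPM bridge


def tpm_to_effective_counts(
    tpm_ref: float, tpm_alt: float, library_scale: float = 1.0
) -> tuple[int, int]:
    """Haplotype TPM pair -> effective integer counts for the count likelihood.

    counts = round-half-even(tpm * library_scale); raising when both round
    to zero keeps zero-depth observations out of the binomial model.
    """
    if tpm_ref < 0 or tpm_alt < 0:
        raise ValueError("TPM values must be non-negative")
    if library_scale <= 0:
        raise ValueError("library_scale must be positive")
    if tpm_ref + tpm_alt <= 0:
        raise ValueError("tpm_ref + tpm_alt must be positive")
    ref = int(np.rint(tpm_ref * library_scale))
    alt = int(np.rint(tpm_alt * library_scale))
    if ref == 0 and alt == 0:
        raise ValueError(
            "zero effective depth after rounding; increase library_scale"
        )
    return ref, alt


# --------------------------------------------------------------------------
# config snapshots


def load_config(path: PathLike) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a YAML/JSON mapping")
    return cfg


def save_config(config: dict, path: PathLike) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)


def save_json(obj, path: PathLike) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=default)
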