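"""The end-to-end ASE screening cascade.

Mirrors the study's flow: pair SNPs with the lncRNA transcripts whose
exons contain them, keep SNPs heterozygous in at least one twin pair,
drop SNPs where one pair is homozygous-reference and another
homozygous-alternative (those cannot be aligned across pairs), then run
the Bayes-factor model comparison per surviving SNP-transcript pair and
report hits (BF above threshold), per-individual AAF summaries and
stage-by-stage retention counts.

AAF, the signed allelic-imbalance summary, is (alt - ref) / (alt + ref):
positive values mean the alternative haplotype dominates, negative the
reference haplotype.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .models import BFRecord, PriorSpec, bayes_factor
from .types import AllelicCountRecord, GenotypeTable, SnpTranscriptPair

__all__ = [
    "SnpTranscriptPair",
    "GenotypeTable",
    "ScreenResult",
    "pair_snps_to_transcripts",
    "filter_informative",
    "filter_discordant_homozygous",
    "compute_aaf",
    "run_ase_screen",
    "summarize_hits",
]


@dataclass
class ScreenResult:
    retained_pairs: list  # list[SnpTranscriptPair] surviving all filters
    bf_records: list  # list[BFRecord]
    hits: list  # list[BFRecord] with call=True
    summary: dict  # per-stage counts
    aaf_table: pd.DataFrame  # per (snp, transcript, pair, member) signed AAF


def _to_internal_exons(annotation: pd.DataFrame) -> pd.DataFrame:
    """1-based inclusive (GTF-like) exon rows -> 0-based half-open."""
    for col in ("transcript_id", "gene_id", "chrom", "start", "end"):
        if col not in annotation.columns:
            raise ValueError(f"annotation is missing column {col!r}")
    bad = annotation[annotation["start"] > annotation["end"]]
    if len(bad):
        row = bad.iloc[0]
        raise ValueError(
            f"malformed exon interval start > end for transcript "
            f"{row['transcript_id']} at {row['chrom']}:{row['start']}-{row['end']}"
        )
    out = annotation.copy()
    out["start0"] = out["start"] - 1  # inclusive, 0-based
    out["end0"] = out["end"]  # exclusive
    return out


def pair_snps_to_transcripts(
    variants: pd.DataFrame, annotation: pd.DataFrame
) -> list:
    """One SnpTranscriptPair per (SNP, transcript) whose exon contains it.

    ``variants``: columns snp_id, chrom, pos (1-based), ref_allele,
    alt_allele. ``annotation``: one row per exon with transcript_id,
    gene_id, chrom, start, end (1-based inclusive). A SNP inside exons of
    several transcripts yields several pairs.
    """
    exons = _to_internal_exons(annotation)
    pairs: list[SnpTranscriptPair] = []
    for chrom, var_c in variants.groupby("chrom", sort=False):
        ex_c = exons[exons["chrom"] == chrom]
        if ex_c.empty:
            continue
        merged = var_c.drop(columns=["chrom"]).merge(
            ex_c.drop(columns=["chrom"]), how="cross"
        )
        inside = merged[
            (merged["pos"] - 1 >= merged["start0"]) & (merged["pos"] - 1 < merged["end0"])
        ]
        seen = set()
        for row in inside.itertuples(index=False):
            key = (row.snp_id, row.transcript_id)
            if key in seen:  # SNP may sit in several exons of one transcript
                continue
            seen.add(key)
            pairs.append(
                SnpTranscriptPair(
                    snp_id=row.snp_id,
                    chrom=chrom,
                    pos=int(row.pos),
                    ref_allele=row.ref_allele,
                    alt_allele=row.alt_allele,
                    transcript_id=row.transcript_id,
                    gene_id=row.gene_id,
                )
            )
    pairs.sort(key=lambda p: (p.snp_id, p.transcript_id))
    return pairs


def filter_informative(
    pairs: Sequence[SnpTranscriptPair], genotypes: GenotypeTable
) -> list:
    """Keep SNP-transcript pairs whose SNP is het in at least one twin pair.

    Missing genotypes count as non-heterozygous (never imputed).
    """
    return [p for p in pairs if len(genotypes.het_pairs(p.snp_id)) >= 1]


def filter_discordant_homozygous(
    pairs: Sequence[SnpTranscriptPair], genotypes: GenotypeTable
) -> list:
    """Drop SNPs where one twin pair is hom_ref and another hom_alt.

    Such loci have no shared heterozygous configuration to compare across
    pairs and are excluded outright; every other genotype mixture is kept.
    """
    out = []
    for p in pairs:
        genos = set(genotypes.genotypes_at(p.snp_id).values())
        if "hom_ref" in genos and "hom_alt" in genos:
            continue
        out.append(p)
    return out


def compute_aaf(record: AllelicCountRecord) -> float:
    """Signed alternative-allele fraction (alt - ref) / (alt + ref) in [-1, 1]."""
    depth = record.alt_count + record.ref_count
    if depth == 0:
        raise ValueError(
            f"zero depth for AAF at {record.snp_id}/{record.pair_id}/{record.member}"
        )
    return (record.alt_count - record.ref_count) / depth


def _aaf_table(counts: Iterable[AllelicCountRecord], keys: set) -> pd.DataFrame:
    """Per-individual AAF from summed counts across that individual's records."""
    sums: dict = defaultdict(lambda: [0, 0])
    for r in counts:
        if (r.snp_id, r.transcript_id) not in keys:
            continue
        acc = sums[(r.snp_id, r.transcript_id, r.pair_id, r.member)]
        acc[0] += r.alt_count
        acc[1] += r.ref_count
    rows = [
        (snp, tx, pair, member, (a - b) / (a + b))
        for (snp, tx, pair, member), (a, b) in sorted(sums.items())
        if a + b > 0
    ]
    return pd.DataFrame(
        rows, columns=["snp_id", "transcript_id", "pair_id", "member", "aaf"]
    )


def run_ase_screen(
    cohort,
    annotation: Optional[pd.DataFrame] = None,
    priors: PriorSpec = PriorSpec(),
    bf_threshold: float = 5.0,
    method: str = "laplace_aghq",
) -> ScreenResult:
    """Run the full cascade on a cohort (simulated or ingested).

    ``cohort`` needs ``variants``, ``genotypes`` and ``counts`` attributes
    (a :class:`twinase.simulate.Cohort` fits); ``annotation`` defaults to
    the cohort's own. Counts at non-heterozygous pairs are ignored (and
    tallied in the summary) — only het carriers are ASE-informative.
    Deterministic given (cohort, priors, threshold).
    """
    if not cohort.counts:
        raise ValueError("uninformative cohort: no allelic count records")
    annotation = cohort.annotation if annotation is None else annotation
    genotypes: GenotypeTable = cohort.genotypes

    pairs = pair_snps_to_transcripts(cohort.variants, annotation)
    n_initial = len(pairs)
    informative = filter_informative(pairs, genotypes)
    retained = filter_discordant_homozygous(informative, genotypes)
    keys = {(p.snp_id, p.transcript_id) for p in retained}

    by_key: dict = defaultdict(list)
    n_nonhet_records = 0
    for r in cohort.counts:
        if (r.snp_id, r.transcript_id) not in keys:
            continue
        if genotypes.get(r.snp_id, r.pair_id) != "het":
            n_nonhet_records += 1
            continue
        by_key[(r.snp_id, r.transcript_id)].append(r)

    bf_records: list[BFRecord] = []
    n_no_counts = 0
    for key in sorted(by_key):
        recs = by_key[key]
        bf_records.append(
            bayes_factor(
                recs,
                priors=priors,
                threshold=bf_threshold,
                method=method,
                snp_id=key[0],
                transcript_id=key[1],
            )
        )
    n_no_counts = len(keys) - len(by_key)
    hits = [b for b in bf_records if b.call]
    n_nonconverged = sum(1 for b in bf_records if not b.converged)

    summary = {
        "n_pairs_annotated": n_initial,
        "n_pairs_het_informative": len(informative),
        "n_pairs_after_discordant_hom": len(retained),
        "n_pairs_with_counts": len(by_key),
        "n_pairs_without_counts": n_no_counts,
        "n_nonhet_count_records_ignored": n_nonhet_records,
        "n_nonconverged": n_nonconverged,
        "n_hits": len(hits),
        "bf_threshold": bf_threshold,
    }
    return ScreenResult(
        retained_pairs=retained,
        bf_records=bf_records,
        hits=hits,
        summary=summary,
        aaf_table=_aaf_table(cohort.counts, keys),
    )


def summarize_hits(result: ScreenResult) -> dict:
    """Distinct SNP / transcript / gene counts among hits, plus stage counts."""
    gene_of = {p.transcript_id: p.gene_id for p in result.retained_pairs}
    snps = {h.snp_id for h in result.hits}
    txs = {h.transcript_id for h in result.hits}
    genes = {gene_of[t] for t in txs if t in gene_of}
    return {
        "n_hit_snps": len(snps),
        "n_hit_transcripts": len(txs),
        "n_hit_genes": len(genes),
        **result.summary,
    }
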