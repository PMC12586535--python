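"""Shared domain types for the twin ASE screen.

The unit of observation throughout the package is one individual's allelic
read counts at one SNP inside one lncRNA transcript: an
:class:`AllelicCountRecord`. Monozygotic co-twins share genotypes, so the
genotype table is keyed by (snp, twin pair), not by individual.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import pandas as pd

GENOTYPES = ("hom_ref", "het", "hom_alt")
MEMBERS = ("affected", "unaffected")

#: canonical column orders of the TSV interchange schemas
COUNT_COLUMNS = ["snp_id", "transcript_id", "pair_id", "member", "alt_count", "ref_count"]
GENOTYPE_COLUMNS = ["snp_id", "pair_id", "member", "genotype"]
VARIANT_COLUMNS = ["snp_id", "chrom", "pos", "ref_allele", "alt_allele"]
ANNOTATION_COLUMNS = ["transcript_id", "gene_id", "chrom", "start", "end"]


@dataclass(frozen=True)
class AllelicCountRecord:
    """Allelic read counts of one co-twin at one SNP-transcript pair."""

    pair_id: str
    member: str  # "affected" | "unaffected"
    snp_id: str
    transcript_id: str
    alt_count: int
    ref_count: int

    def __post_init__(self) -> None:
        if self.member not in MEMBERS:
            raise ValueError(f"member must be one of {MEMBERS}, got {self.member!r}")
        if self.alt_count < 0 or self.ref_count < 0:
            raise ValueError(
                f"negative counts for {self.snp_id}/{self.pair_id}: "
                f"alt={self.alt_count}, ref={self.ref_count}"
            )

    @property
    def depth(self) -> int:
        return self.alt_count + self.ref_count


@dataclass(frozen=True)
class SnpTranscriptPair:
    """A SNP located in an exon of a lncRNA transcript."""

    snp_id: str
    chrom: str
    pos: int  # 1-based, VCF convention
    ref_allele: str
    alt_allele: str
    transcript_id: str
    gene_id: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1 (1-based), got {self.pos}")
        if (
            len(self.ref_allele) != 1
            or len(self.alt_allele) != 1
            or self.ref_allele == self.alt_allele
        ):
            raise ValueError(
                f"alleles must be single distinct bases: {self.ref_allele}/{self.alt_allele}"
            )


class GenotypeTable:
    """Per-(SNP, twin pair) genotypes; co-twins share genotype by zygosity.

    Unknown genotypes are stored as missing (``None``) and are never imputed;
    every consumer treats missing as non-heterozygous.
    """

    def __init__(self, mapping: Optional[Mapping[tuple, Optional[str]]] = None):
        self._geno: dict[tuple, Optional[str]] = {}
        if mapping:
            for (snp, pair), g in mapping.items():
                self.set(snp, pair, g)

    def set(self, snp_id: str, pair_id: str, genotype: Optional[str]) -> None:
        if genotype is not None and genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {genotype!r} for ({snp_id}, {pair_id})")
        self._geno[(snp_id, pair_id)] = genotype

    def get(self, snp_id: str, pair_id: str) -> Optional[str]:
        """Genotype at (snp, pair); None when unobserved or recorded missing."""
        return self._geno.get((snp_id, pair_id))

    def pairs(self) -> list:
        return sorted({p for _, p in self._geno})

    def snps(self) -> list:
        return sorted({s for s, _ in self._geno})

    def genotypes_at(self, snp_id: str) -> dict:
        return {p: g for (s, p), g in self._geno.items() if s == snp_id}

    def het_pairs(self, snp_id: str) -> list:
        return sorted(p for (s, p), g in self._geno.items() if s == snp_id and g == "het")

    def n_missing(self) -> int:
        return sum(1 for g in self._geno.values() if g is None)

    def __len__(self) -> int:
        return len(self._geno)

    def __eq__(self, other) -> bool:
        return isinstance(other, GenotypeTable) and self._geno == other._geno

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with one row per (snp, pair, member).

        Both co-twins are written with identical genotype, matching the
        on-disk schema; missing genotypes serialize as '.'.
        """
        rows = []
        for (snp, pair), g in sorted(self._geno.items()):
            for member in MEMBERS:
                rows.append((snp, pair, member, g if g is not None else "."))
        return pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "GenotypeTable":
        table = cls()
        for (snp, pair), grp in frame.groupby(["snp_id", "pair_id"], sort=True):
            vals = set(grp["genotype"])
            if len(vals) != 1:
                raise ValueError(
                    f"co-twins disagree on genotype at ({snp}, {pair}): {sorted(vals)}"
                )
            g = vals.pop()
            table.set(str(snp), str(pair), None if g in (".", "missing") else str(g))
        return table
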