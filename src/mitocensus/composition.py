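"""Genome composition statistics, codon counting and RSCU.

The genic/intergenic partition is a per-base union of a chosen feature set
(overlapping annotations counted once); relative synonymous codon usage
(RSCU) for a codon is its observed count divided by the mean count of its
synonymous family, so an unbiased family sits at exactly 1.  Ambiguous (N)
bases are excluded from GC statistics and codons containing N are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import unambiguous_dna_by_id

from .genome_io import Feature, FeatureTable, SequenceRecord, extract_feature_sequence

logger = logging.getLogger(__name__)

__all__ = [
    "gc_content",
    "CompositionReport",
    "composition_report",
    "CodonUsageTable",
    "count_codons",
    "rscu",
    "synonymous_families",
]

BASES = "TCAG"
ALL_CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]


def genetic_code(table_id: int = 1) -> dict[str, str]:
    """Codon -> 1-letter amino acid, with '*' for stops."""
    table = unambiguous_dna_by_id[table_id]
    code = dict(table.forward_table)
    for stop in table.stop_codons:
        code[stop] = "*"
    return {c: code[c] for c in ALL_CODONS}


def synonymous_families(table_id: int = 1) -> dict[str, list[str]]:
    """Amino acid (or '*') -> its synonymous codon family."""
    code = genetic_code(table_id)
    fams: dict[str, list[str]] = {}
    for codon, aa in code.items():
        fams.setdefault(aa, []).append(codon)
    return fams


def gc_content(seq: str) -> float:
    """(G + C) / (A + C + G + T); N excluded from both counts.

    Raises ValueError for a sequence with no unambiguous bases.
    """
    g = seq.count("G")
    c = seq.count("C")
    denom = g + c + seq.count("A") + seq.count("T")
    if denom == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return (g + c) / denom


@dataclass
class CompositionReport:
    genome_size: int
    gc_total: float
    gene_number: int
    gene_total_length: int
    gene_gc: float | None
    intergenic_length: int
    intergenic_gc: float | None
    pct_genic: float
    pct_intergenic: float

    def to_frame(self) -> pd.DataFrame:
        def pct(x):
            return None if x is None else round(100 * x, 2)

        rows = [
            ("Genome Size (bp)", self.genome_size),
            ("GC Content (%)", pct(self.gc_total)),
            ("Gene Number", self.gene_number),
            ("Gene Total Length (bp)", self.gene_total_length),
            ("Gene Average Length (bp)",
             round(self.gene_total_length / self.gene_number) if self.gene_number else 0),
            ("Gene's GC Content", pct(self.gene_gc)),
            ("% of Genome (Genes)", round(100 * self.pct_genic, 2)),
            ("Intergenic Region Length (bp)", self.intergenic_length),
            ("Intergenic's GC Content", pct(self.intergenic_gc)),
            ("% of Genome (Intergenic)", round(100 * self.pct_intergenic, 2)),
        ]
        return pd.DataFrame(rows, columns=["Item", "Value"])


def _union_mask(length: int, features: list[Feature]) -> np.ndarray:
    mask = np.zeros(length, dtype=bool)
    for feat in features:
        for start, end in feat.location:
            mask[start:end] = True
    return mask


def composition_report(
    record: SequenceRecord,
    table: FeatureTable,
    genic_kinds: tuple[str, ...] = ("CDS",),
) -> CompositionReport:
    """Partition the genome into genic (feature union) and intergenic bases.

    ``genic_kinds`` selects which feature kinds define the genic set; the
    default counts protein-coding CDS only.
    """
    feats = table.of_kind(*genic_kinds)
    mask = _union_mask(record.length, feats)
    arr = np.frombuffer(record.seq.encode(), dtype="S1")
    genic_seq = arr[mask].tobytes().decode()
    inter_seq = arr[~mask].tobytes().decode()
    genic_len = int(mask.sum())
    inter_len = record.length - genic_len

    def safe_gc(s: str) -> float | None:
        try:
            return gc_content(s)
        except ValueError:
            return None

    return CompositionReport(
        genome_size=record.length,
        gc_total=gc_content(record.seq),
        gene_number=len(feats),
        gene_total_length=genic_len,
        gene_gc=safe_gc(genic_seq),
        intergenic_length=inter_len,
        intergenic_gc=safe_gc(inter_seq),
        pct_genic=genic_len / record.length,
        pct_intergenic=inter_len / record.length,
    )


@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    table_id: int = 1
    rscu_values: dict[str, float] | None = None

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    def amino_acid_counts(self) -> dict[str, int]:
        code = genetic_code(self.table_id)
        out: dict[str, int] = {}
        for codon, n in self.counts.items():
            aa = code[codon]
            out[aa] = out.get(aa, 0) + n
        return out

    def to_frame(self) -> pd.DataFrame:
        code = genetic_code(self.table_id)
        total = self.total_codons
        rows = []
        for codon in ALL_CODONS:
            n = self.counts.get(codon, 0)
            rows.append(
                {
                    "codon": codon,
                    "amino_acid": code[codon],
                    "count": n,
                    "fraction": n / total if total else 0.0,
                    "rscu": (self.rscu_values or {}).get(codon, float("nan")),
                }
            )
        return pd.DataFrame(rows)


def count_codons(
    cds_sequences: list[str],
    include_stop: bool = True,
    table_id: int = 1,
) -> CodonUsageTable:
    """Accumulate codon counts over CDS sequences.

    A CDS whose length is not divisible by 3 has its trailing 1-2 nt dropped
    with a warning; codons containing N are skipped and logged.  Stop codons
    are counted when ``include_stop`` is true.
    """
    code = genetic_code(table_id)
    counts = {c: 0 for c in ALL_CODONS}
    skipped_n = 0
    for idx, cds in enumerate(cds_sequences):
        rem = len(cds) % 3
        if rem:
            logger.warning("CDS %d length %d not divisible by 3; trailing %d nt dropped",
                           idx, len(cds), rem)
            cds = cds[: len(cds) - rem]
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3]
            if codon not in counts:
                skipped_n += 1
                continue
            if not include_stop and code[codon] == "*":
                continue
            counts[codon] += 1
    if skipped_n:
        logger.warning("%d codons containing ambiguous bases skipped", skipped_n)
    return CodonUsageTable(counts=counts, table_id=table_id)


def rscu(table: CodonUsageTable) -> CodonUsageTable:
    """Fill RSCU: count(c) * family_size / family_total.

    Stops are treated as one 3-member family; a family with zero total gets
    RSCU 0 for every member, so the mean-equals-1 identity applies only to
    observed families.
    """
    fams = synonymous_families(table.table_id)
    values: dict[str, float] = {}
    for codons in fams.values():
        total = sum(table.counts.get(c, 0) for c in codons)
        k = len(codons)
        for c in codons:
            values[c] = table.counts.get(c, 0) * k / total if total else 0.0
    return CodonUsageTable(counts=table.counts, table_id=table.table_id, rscu_values=values)


def cds_sequences_from_annotation(
    record: SequenceRecord, table: FeatureTable
) -> list[str]:
    """Spliced CDS sequences for every CDS feature copy, in table order."""
    return [extract_feature_sequence(record, f) for f in table.of_kind("CDS")]
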