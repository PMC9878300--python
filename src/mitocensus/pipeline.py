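"""End-to-end census orchestration: run the stages and emit report tables.

``run_census`` drives the characterization of one annotated genome —
composition, gene/intron census, SSRs, repeats, codon usage/RSCU, optional
plastid-transfer detection, multi-genome constitution and a distance tree —
and writes each product as a TSV/BED/Newick file plus a JSON manifest that
records every parameter and input digest, so a run is reproducible from its
manifest alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .composition import (
    cds_sequences_from_annotation,
    composition_report,
    count_codons,
    rscu,
)
from .genome_io import (
    FeatureTable,
    SequenceRecord,
    read_fasta,
    read_genbank_features,
    read_maf_blocks,
    write_bed,
    write_newick,
)
from .homology import (
    accumulation_curves,
    classify_fragments,
    detect_transfers,
    gc_by_class,
    local_align_segments,
)
from .kaks import kaks_matrix
from .phylo import kmer_distance_matrix, neighbor_joining
from .repeats import bin_repeats, find_maximal_repeats, large_repeats, repeats_to_frame
from .ssr import find_ssrs, ssrs_to_frame, summarize_ssrs

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_census", "intron_census"]


@dataclass
class RunConfig:
    """Paths, stage toggles and stage parameters for one census run."""

    genome_fasta: str | None = None
    genbank: str | None = None
    cp_fasta: str | None = None
    maf: str | None = None
    family_fastas: list[str] = field(default_factory=list)
    gene_fastas: dict[str, str] = field(default_factory=dict)
    out_dir: str = "census_out"
    seed: int = 0
    stages: tuple[str, ...] = (
        "composition", "genes", "ssr", "repeats", "rscu",
        "transfer", "pancore", "phylo",
    )
    ssr_thresholds: dict[int, int] | None = None
    repeat_min_len: int = 30
    transfer_min_identity: float = 0.93
    transfer_min_len: int = 300
    transfer_max_evalue: float = 1e-5
    word_size: int = 7
    n_permutations: int = 100
    genic_kinds: tuple[str, ...] = ("CDS",)

    def to_manifest(self) -> dict:
        out = {k: v for k, v in self.__dict__.items()}
        out["stages"] = list(self.stages)
        out["genic_kinds"] = list(self.genic_kinds)
        return out


def intron_census(table: FeatureTable) -> pd.DataFrame:
    """Intron counts per gene copy: interval count minus one."""
    rows = [
        {
            "gene": f.name,
            "copy": f.copy_index,
            "kind": f.kind,
            "n_exons": len(f.location),
            "n_introns": f.n_introns,
        }
        for f in table.of_kind("CDS", "tRNA", "rRNA", "gene")
    ]
    return pd.DataFrame(rows, columns=["gene", "copy", "kind", "n_exons", "n_introns"])


def _digest(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, lineterminator="\n")


def run_census(config: RunConfig) -> dict:
    """Run the requested stages; returns a manifest dict (also written to
    ``manifest.json``).  A stage whose inputs are missing is recorded as an
    error in the manifest and the run continues."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "mitocensus",
        "version": __version__,
        "config": config.to_manifest(),
        "inputs": {},
        "stages": {},
    }

    record: SequenceRecord | None = None
    table: FeatureTable | None = None
    if config.genbank:
        record, table = read_genbank_features(config.genbank)
        manifest["inputs"]["genbank"] = _digest(config.genbank)
    elif config.genome_fasta:
        record = read_fasta(config.genome_fasta)[0]
        manifest["inputs"]["genome_fasta"] = _digest(config.genome_fasta)

    def stage_error(stage: str, message: str) -> None:
        logger.error("[%s] %s", stage, message)
        manifest["stages"][stage] = {"ok": False, "error": message}

    def stage_ok(stage: str, **info) -> None:
        logger.info("[%s] done", stage)
        manifest["stages"][stage] = {"ok": True, **info}

    if "composition" in config.stages:
        if record is None or table is None:
            stage_error("composition", "needs an annotated GenBank record")
        else:
            report = composition_report(record, table, config.genic_kinds)
            _write_tsv(report.to_frame(), out / "composition.tsv")
            stage_ok("composition", genome_size=report.genome_size,
                     gc_total=round(report.gc_total, 4))

    if "genes" in config.stages:
        if table is None:
            stage_error("genes", "needs an annotated GenBank record")
        else:
            genes = intron_census(table)
            _write_tsv(genes, out / "genes.tsv")
            stage_ok("genes", n_features=len(genes))

    if "ssr" in config.stages:
        if record is None:
            stage_error("ssr", "needs a genome sequence")
        else:
            loci = find_ssrs(record, config.ssr_thresholds)
            _write_tsv(ssrs_to_frame(loci, record.id), out / "ssr.tsv")
            summary = summarize_ssrs(loci)
            _write_tsv(summary["by_unit"], out / "ssr_summary.tsv")
            _write_tsv(summary["by_class"], out / "ssr_classes.tsv")
            write_bed([(l.start, l.end, l.motif) for l in loci],
                      out / "ssr.bed", record.id)
            stage_ok("ssr", n_ssrs=len(loci))

    if "repeats" in config.stages:
        if record is None:
            stage_error("repeats", "needs a genome sequence")
        else:
            pairs = find_maximal_repeats(record, config.repeat_min_len)
            _write_tsv(repeats_to_frame(pairs), out / "repeats.tsv")
            bins = bin_repeats(pairs)
            _write_tsv(bins, out / "repeat_bins.tsv")
            big = large_repeats(pairs)
            stage_ok("repeats", n_repeats=len(pairs),
                     n_over_1kb=len(big),
                     totals=bins.attrs["totals"])

    if "rscu" in config.stages:
        if record is None or table is None:
            stage_error("rscu", "needs an annotated GenBank record")
        else:
            cds = cds_sequences_from_annotation(record, table)
            usage = rscu(count_codons(cds, include_stop=True))
            _write_tsv(usage.to_frame(), out / "codon_rscu.tsv")
            stage_ok("rscu", total_codons=usage.total_codons)

    if "transfer" in config.stages:
        if record is None or not config.cp_fasta:
            stage_error("transfer", "needs both the mitogenome and a chloroplast FASTA")
        else:
            cp = read_fasta(config.cp_fasta)[0]
            manifest["inputs"]["cp_fasta"] = _digest(config.cp_fasta)
            transfers = detect_transfers(
                record, cp,
                min_identity=config.transfer_min_identity,
                max_evalue=config.transfer_max_evalue,
                min_len=config.transfer_min_len,
                word_size=config.word_size,
            )
            _write_tsv(transfers, out / "transfers.tsv")
            stage_ok("transfer", **transfers.attrs["summary"])

    if "pancore" in config.stages:
        genomes: list[SequenceRecord] = []
        for path in config.family_fastas:
            genomes.extend(read_fasta(path))
            manifest["inputs"][path] = _digest(path)
        if len(genomes) < 2 and not config.maf:
            stage_error("pancore", "needs >=2 family genomes or a MAF file")
        else:
            if config.maf:
                evidence = read_maf_blocks(config.maf)
                manifest["inputs"]["maf"] = _digest(config.maf)
            else:
                evidence = {}
                for i in range(len(genomes)):
                    for j in range(i + 1, len(genomes)):
                        evidence[(genomes[i].id, genomes[j].id)] = local_align_segments(
                            genomes[i], genomes[j],
                            word_size=config.word_size,
                            min_len=config.transfer_min_len,
                            max_evalue=config.transfer_max_evalue,
                        )
            cmap = classify_fragments(genomes, evidence)
            rows = []
            for gid in cmap.genome_ids:
                for s, e, lab in cmap.intervals[gid]:
                    rows.append(f"{gid}\t{s}\t{e}\t{lab}")
            (out / "constitution.bed").write_text("\n".join(rows) + "\n")
            acc = accumulation_curves(genomes, evidence,
                                      n_permutations=config.n_permutations,
                                      seed=config.seed)
            _write_tsv(acc, out / "accumulation.tsv")
            _write_tsv(gc_by_class(cmap, genomes), out / "gc_by_class.tsv")
            stage_ok("pancore", n_genomes=len(genomes))

    if "phylo" in config.stages:
        genomes = []
        for path in config.family_fastas:
            genomes.extend(read_fasta(path))
        if record is not None and record.id not in {g.id for g in genomes}:
            genomes.append(record)
        if len(genomes) < 3:
            stage_error("phylo", "needs >=3 genomes for a tree")
        else:
            dm = kmer_distance_matrix({g.id: g.seq for g in genomes})
            (out / "distances.tsv").write_text(dm.to_phylip())
            tree = neighbor_joining(dm)
            write_newick(tree.newick(), out / "tree.nwk")
            stage_ok("phylo", n_taxa=len(genomes))

    if "kaks" in config.stages:
        if not config.gene_fastas:
            stage_error("kaks", "needs per-gene CDS FASTA inputs")
        else:
            gene_seqs: dict[str, dict[str, str]] = {}
            for gene, path in config.gene_fastas.items():
                gene_seqs[gene] = {r.id: r.seq for r in read_fasta(path)}
                manifest["inputs"][path] = _digest(path)
            species = sorted({s for d in gene_seqs.values() for s in d})
            pairs = [(species[0], s) for s in species[1:]]
            frame = kaks_matrix(gene_seqs, pairs)
            _write_tsv(frame, out / "kaks.tsv")
            stage_ok("kaks", n_rows=len(frame), **frame.attrs["summary"])

    with open(out / "manifest.json", "w", newline="\n") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return manifest
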