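"""Sequence and annotation I/O for organelle genomes.

All coordinates are 0-based, half-open throughout the package; conversion to
the 1-based inclusive conventions of GenBank and GFF3 happens only at the
format boundary.  Features that wrap the origin of a circular molecule are
stored as two intervals (end-of-sequence piece first, in transcript order)
with ``wraps_origin`` set, so ordinary interval arithmetic stays valid.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "Feature",
    "FeatureTable",
    "MAFSegment",
    "MAFBlock",
    "read_fasta",
    "write_fasta",
    "read_genbank_features",
    "extract_feature_sequence",
    "reverse_complement",
    "write_gff3",
    "write_bed",
    "read_maf_blocks",
    "write_newick",
]

_ALLOWED = set("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

FEATURE_KINDS = ("gene", "CDS", "tRNA", "rRNA")


class FastaError(ValueError):
    """Malformed FASTA input (empty file, duplicate ids, illegal symbols)."""


class LocationError(ValueError):
    """Feature location inconsistent with its record."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named nucleotide sequence, optionally circular.

    ``seq`` is uppercase over {A, C, G, T, N}; ``length`` always equals
    ``len(seq)``.
    """

    id: str
    seq: str
    circular: bool = False

    @property
    def length(self) -> int:
        return len(self.seq)

    def __post_init__(self) -> None:
        bad = set(self.seq) - _ALLOWED
        if bad:
            raise FastaError(
                f"record {self.id!r}: illegal symbol(s) {sorted(bad)} in sequence"
            )


@dataclass
class Feature:
    """A typed, stranded, possibly multi-interval annotation.

    ``location`` lists [start, end) intervals in transcript order.  For a
    minus-strand feature transcript order runs right-to-left on the genome,
    matching GenBank's ``complement(join(...))`` reading.
    """

    kind: str
    name: str
    strand: str
    location: list[tuple[int, int]]
    copy_index: int = 1
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.location:
            raise LocationError(f"feature {self.name}: empty location")
        for start, end in self.location:
            if start < 0 or start >= end:
                raise LocationError(
                    f"feature {self.name}: bad interval [{start}, {end})"
                )

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.location)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.location)

    @property
    def end(self) -> int:
        return max(e for _, e in self.location)

    @property
    def n_introns(self) -> int:
        return len(self.location) - 1


@dataclass
class FeatureTable:
    record_id: str
    features: list[Feature] = field(default_factory=list)

    def __iter__(self):
        return iter(self.features)

    def __len__(self) -> int:
        return len(self.features)

    def of_kind(self, *kinds: str) -> list[Feature]:
        return [f for f in self.features if f.kind in kinds]


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read FASTA into records; uppercase, U mapped to T, strict alphabet.

    Raises :class:`FastaError` on an empty file, duplicate ids, or any symbol
    outside {A, C, G, T, N, U} (reported with its record and position).
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace("U", "T")
        bad_at = next((i for i, c in enumerate(seq) if c not in _ALLOWED), None)
        if bad_at is not None:
            raise FastaError(
                f"record {rec.id!r}: illegal symbol {seq[bad_at]!r} at position {bad_at}"
            )
        records.append(SequenceRecord(id=rec.id, seq=seq))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    with open(path, "w", newline="\n") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GenBank

def _genbank_feature_name(feat) -> str | None:
    for key in ("gene", "product", "locus_tag"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    return None


def read_genbank_features(path: str | Path) -> tuple[SequenceRecord, FeatureTable]:
    """Parse a GenBank flat file into a record plus its feature table.

    ``join(...)`` locations become ordered interval lists, ``complement``
    sets strand '-', and coordinates are converted from 1-based inclusive to
    0-based half-open.  Duplicated (kind, name) combinations get
    ``copy_index`` 1, 2, ... in file order.
    """
    gb = SeqIO.read(str(path), "genbank")
    seq = str(gb.seq).upper().replace("U", "T")
    circular = gb.annotations.get("topology", "") == "circular"
    record = SequenceRecord(id=gb.id or gb.name, seq=seq, circular=circular)

    features: list[Feature] = []
    copy_counter: Counter[tuple[str, str]] = Counter()
    n = record.length
    for feat in gb.features:
        if feat.type not in FEATURE_KINDS:
            continue
        name = _genbank_feature_name(feat)
        if name is None:
            continue
        strand = "-" if feat.location.strand == -1 else "+"
        parts = [(int(p.start), int(p.end)) for p in feat.location.parts]
        if strand == "-":
            # Biopython lists parts in genomic order for complement(join());
            # transcript order for a minus-strand feature is right-to-left.
            parts = parts[::-1] if parts[0][0] < parts[-1][0] else parts
        wraps = False
        for start, end in parts:
            if start < 0 or end > n:
                raise LocationError(
                    f"feature {name}: interval [{start}, {end}) outside record of length {n}"
                )
        if len(parts) == 2 and parts[0][1] == n and parts[1][0] == 0:
            wraps = True
        copy_counter[(feat.type, name)] += 1
        features.append(
            Feature(
                kind=feat.type,
                name=name,
                strand=strand,
                location=parts,
                copy_index=copy_counter[(feat.type, name)],
                wraps_origin=wraps and circular,
            )
        )
    return record, FeatureTable(record_id=record.id, features=features)


def extract_feature_sequence(record: SequenceRecord, feature: Feature) -> str:
    """Spliced feature sequence in transcript orientation.

    Intervals are concatenated in transcript order; minus-strand features are
    reverse-complemented per interval after concatenation of the plus-strand
    pieces in genomic transcript order.
    """
    if feature.wraps_origin and not record.circular:
        raise LocationError(
            f"feature {feature.name} wraps the origin but record {record.id} is linear"
        )
    for start, end in feature.location:
        if end > record.length:
            raise LocationError(
                f"feature {feature.name}: interval [{start}, {end}) exceeds record length"
            )
    if feature.strand == "+":
        return "".join(record.seq[s:e] for s, e in feature.location)
    # transcript order intervals are right-to-left on the genome: revcomp each
    return "".join(reverse_complement(record.seq[s:e]) for s, e in feature.location)


# ---------------------------------------------------------------------------
# GFF3 / BED

def write_gff3(table: FeatureTable, path: str | Path, source: str = "mitocensus") -> None:
    """Write a feature table as GFF3 (1-based inclusive, column 7 strand)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("##gff-version 3\n")
        for i, feat in enumerate(table.features):
            fid = f"{feat.kind}-{feat.name}-{feat.copy_index}"
            for start, end in feat.location:
                fh.write(
                    "\t".join(
                        [
                            table.record_id,
                            source,
                            feat.kind,
                            str(start + 1),
                            str(end),
                            ".",
                            feat.strand,
                            ".",
                            f"ID={fid};Name={feat.name};copy={feat.copy_index}",
                        ]
                    )
                    + "\n"
                )


def read_gff3(path: str | Path) -> FeatureTable:
    """Read back GFF3 written by :func:`write_gff3` (grouping rows by ID)."""
    rows: dict[str, dict] = {}
    record_id = ""
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            record_id = cols[0]
            attrs = dict(kv.split("=", 1) for kv in cols[8].split(";"))
            fid = attrs["ID"]
            if fid not in rows:
                rows[fid] = {
                    "kind": cols[2],
                    "name": attrs.get("Name", fid),
                    "strand": cols[6],
                    "copy": int(attrs.get("copy", 1)),
                    "ivs": [],
                }
                order.append(fid)
            rows[fid]["ivs"].append((int(cols[3]) - 1, int(cols[4])))
    feats = []
    for fid in order:
        r = rows[fid]
        ivs = r["ivs"]
        if r["strand"] == "-":
            ivs = sorted(ivs, reverse=True)
        feats.append(
            Feature(kind=r["kind"], name=r["name"], strand=r["strand"],
                    location=ivs, copy_index=r["copy"])
        )
    return FeatureTable(record_id=record_id, features=feats)


def write_bed(intervals: Iterable[tuple], path: str | Path, record_id: str = "genome") -> None:
    """Write (start, end[, name[, strand]]) tuples as BED (0-based half-open)."""
    with open(path, "w", newline="\n") as fh:
        for iv in intervals:
            start, end = iv[0], iv[1]
            name = iv[2] if len(iv) > 2 else "."
            fields = [record_id, str(start), str(end), str(name)]
            if len(iv) > 3:
                fields += ["0", iv[3]]
            fh.write("\t".join(fields) + "\n")


# ---------------------------------------------------------------------------
# MAF

@dataclass
class MAFSegment:
    """One 's' line of a MAF block, with gaps retained in ``text``."""

    source: str
    start: int           # 0-based on + strand of source when strand == '+'
    size: int            # bases of source sequence in the segment
    strand: str
    src_size: int
    text: str

    @property
    def interval(self) -> tuple[int, int]:
        """Forward-strand [start, end) interval on the source sequence."""
        if self.strand == "+":
            return self.start, self.start + self.size
        return self.src_size - self.start - self.size, self.src_size - self.start


@dataclass
class MAFBlock:
    score: float
    segments: list[MAFSegment]


def read_maf_blocks(path: str | Path) -> list[MAFBlock]:
    """Parse MAF 'a'/'s' lines into alignment blocks.

    Raises ValueError when the aligned texts within one block disagree in
    length.
    """
    blocks: list[MAFBlock] = []
    current: MAFBlock | None = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("a"):
                current = MAFBlock(score=0.0, segments=[])
                m = re.search(r"score=([-\d.eE+]+)", line)
                if m:
                    current.score = float(m.group(1))
                blocks.append(current)
            elif line.startswith("s") and current is not None:
                _, src, start, size, strand, src_size, text = line.split()
                current.segments.append(
                    MAFSegment(src, int(start), int(size), strand, int(src_size), text)
                )
    for block in blocks:
        lengths = {len(seg.text) for seg in block.segments}
        if len(lengths) > 1:
            raise ValueError(
                f"MAF block has inconsistent aligned-text lengths: {sorted(lengths)}"
            )
    return [b for b in blocks if b.segments]


# ---------------------------------------------------------------------------
# Newick

def write_newick(newick: str, path: str | Path) -> None:
    """Write a Newick string (terminating ';' added if missing)."""
    text = newick.strip()
    if not text.endswith(";"):
        text += ";"
    with open(path, "w", newline="\n") as fh:
        fh.write(text + "\n")
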