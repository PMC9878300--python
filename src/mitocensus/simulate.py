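"""Synthetic organelle genomes with planted, truth-tabled features.

Every generator is deterministic given its seed, and every planted feature
is recorded in a machine-readable :class:`TruthTable` so detectors can be
closed-loop tested: run the detector on the synthetic genome and compare
with the truth.  Backgrounds are rejection-sampled until they carry no
accidental SSR or repeat above the detection thresholds, so anything a
detector reports is either planted or a bug.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field

import numpy as np
from Bio import Phylo

from .composition import synonymous_families
from .genome_io import SequenceRecord, reverse_complement
from .repeats import find_maximal_repeats
from .ssr import DEFAULT_THRESHOLDS, find_ssrs

__all__ = [
    "TruthTable",
    "PlantSpec",
    "make_genome",
    "clean_background",
    "plant_features",
    "evolve_genome",
    "make_genome_family",
]

BASES = np.array(list("ACGT"))
MAX_RETRIES = 50


@dataclass
class TruthTable:
    """Machine-readable record of everything planted into a scenario."""

    seed: int
    ssrs: list[dict] = field(default_factory=list)
    repeats: list[dict] = field(default_factory=list)
    cds: list[dict] = field(default_factory=list)
    transfers: list[dict] = field(default_factory=list)
    fragment_tracts: list[dict] = field(default_factory=list)
    tree: str | None = None

    def to_json(self, path=None) -> str:
        text = json.dumps(self.__dict__, indent=2, default=str)
        if path is not None:
            with open(path, "w", newline="\n") as fh:
                fh.write(text + "\n")
        return text


@dataclass
class PlantSpec:
    """What to plant: see the individual field docstrings in the methods
    documentation; positions are optional and chosen non-overlapping when
    omitted."""

    ssrs: list[tuple[str, int]] = field(default_factory=list)        # (motif, copies)
    repeats: list[tuple[int, str]] = field(default_factory=list)     # (arm_len, 'F'|'P')
    cds: list[tuple[str, int, dict[str, float] | None]] = field(default_factory=list)
    # (name, n_codons, codon frequency vector over sense codons or None=uniform)
    transfers: list[tuple[str, float]] = field(default_factory=list)  # (donor segment, identity)


def _random_bases(n: int, gc: float, rng: np.random.Generator) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(BASES, size=n, p=probs))


def make_genome(length: int, gc: float, seed: int) -> SequenceRecord:
    """Circular i.i.d. random genome of the requested length and GC.

    Length is bounded to the organelle-plausible 1 kb - 10 Mb range and GC
    must be strictly inside (0, 1).
    """
    if not 1_000 <= length <= 10_000_000:
        raise ValueError("length must be between 1 kb and 10 Mb")
    if not 0 < gc < 1:
        raise ValueError("gc must be strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    return SequenceRecord(id=f"synth_{seed}", seq=_random_bases(length, gc, rng),
                          circular=True)


def clean_background(length: int, gc: float, seed: int, min_repeat_len: int = 30) -> SequenceRecord:
    """A random genome with no accidental SSRs or repeats above thresholds.

    Rejection-samples up to 50 candidate backgrounds; raises RuntimeError if
    none is clean (practically only for extreme lengths or GC).
    """
    for attempt in range(MAX_RETRIES):
        record = make_genome(length, gc, seed + 1_000_003 * attempt)
        if find_ssrs(record, DEFAULT_THRESHOLDS):
            continue
        if find_maximal_repeats(record, min_len=min_repeat_len):
            continue
        return record
    raise RuntimeError(f"no clean background found in {MAX_RETRIES} attempts")


def _place(rng: np.random.Generator, occupied: list[tuple[int, int]],
           size: int, genome_len: int, margin: int = 40) -> int:
    """Random start for a feature of ``size`` avoiding existing placements."""
    for _ in range(500):
        start = int(rng.integers(margin, genome_len - size - margin))
        iv = (start - margin, start + size + margin)
        if all(iv[1] <= s or iv[0] >= e for s, e in occupied):
            occupied.append(iv)
            return start
    raise ValueError("feature placement overflow: features do not fit")


def _sense_codons(table_id: int = 1) -> list[str]:
    fams = synonymous_families(table_id)
    return sorted(c for aa, codons in fams.items() if aa != "*" for c in codons)


def plant_features(record: SequenceRecord, spec: PlantSpec, seed: int = 0
                   ) -> tuple[SequenceRecord, TruthTable]:
    """Overwrite planted features into a (clean) background genome.

    SSR tracts, repeat pairs (forward or palindromic), valid ORFs with the
    requested codon composition, and copies of donor segments at a target
    identity are written at recorded coordinates; the truth table lists them
    all.  Raises ValueError when the requested features cannot be placed.
    """
    rng = np.random.default_rng(seed)
    seq = list(record.seq)
    n = len(seq)
    occupied: list[tuple[int, int]] = []
    truth = TruthTable(seed=seed)

    def guard(pos: int, *avoid: str) -> None:
        """Force seq[pos] to differ from every base in ``avoid``."""
        if 0 <= pos < n and seq[pos] in avoid:
            seq[pos] = next(b for b in "ACGT" if b not in avoid)

    for motif, copies in spec.ssrs:
        tract = motif * copies
        start = _place(rng, occupied, len(tract), n)
        seq[start : start + len(tract)] = tract
        # break the tandem at both flanks so the locus is exactly maximal
        guard(start - 1, motif[-1])
        guard(start + len(tract), motif[0])
        truth.ssrs.append(
            {"motif": motif, "copies": copies, "start": start,
             "end": start + len(tract)}
        )

    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    for arm_len, orientation in spec.repeats:
        arm = _random_bases(arm_len, 0.5, rng)
        p1 = _place(rng, occupied, arm_len, n)
        p2 = _place(rng, occupied, arm_len, n)
        p1, p2 = sorted((p1, p2))
        second = arm if orientation == "F" else reverse_complement(arm)
        seq[p1 : p1 + arm_len] = arm
        seq[p2 : p2 + arm_len] = second
        # break the match one base beyond each arm end so the pair is maximal
        if orientation == "F":
            guard(p2 - 1, seq[p1 - 1])
            guard(p2 + arm_len, seq[p1 + arm_len])
        else:
            if p1 + arm_len <= n and p2 - 1 >= 0:
                guard(p2 + arm_len, comp[seq[p1 - 1]] if p1 >= 1 else "")
                guard(p2 - 1, comp[seq[p1 + arm_len]] if p1 + arm_len < n else "")
        truth.repeats.append(
            {"arm_len": arm_len, "orientation": orientation, "pos1": p1, "pos2": p2}
        )

    sense = _sense_codons()
    for name, n_codons, freqs in spec.cds:
        if freqs is None:
            codons = list(rng.choice(sense, size=n_codons))
        else:
            keys = sorted(freqs)
            p = np.array([freqs[k] for k in keys], dtype=float)
            p = p / p.sum()
            codons = list(rng.choice(keys, size=n_codons, p=p))
        body = "ATG" + "".join(codons) + "TAA"
        start = _place(rng, occupied, len(body), n)
        seq[start : start + len(body)] = body
        truth.cds.append(
            {"name": name, "start": start, "end": start + len(body),
             "strand": "+", "n_codons": n_codons,
             "codon_freqs": freqs}
        )

    for donor_seq, identity in spec.transfers:
        segment = list(donor_seq)
        n_mut = int(round((1 - identity) * len(segment)))
        sites = rng.choice(len(segment), size=n_mut, replace=False)
        for s in sites:
            alts = [b for b in "ACGT" if b != segment[s]]
            segment[s] = alts[int(rng.integers(0, 3))]
        start = _place(rng, occupied, len(segment), n)
        seq[start : start + len(segment)] = segment
        truth.transfers.append(
            {"start": start, "end": start + len(segment),
             "identity_target": identity, "donor_len": len(donor_seq)}
        )

    planted = SequenceRecord(id=record.id, seq="".join(seq), circular=record.circular)
    return planted, truth


# ---------------------------------------------------------------------------
# evolution

_TS = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TV = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def evolve_genome(
    record: SequenceRecord,
    subst_rate: float,
    kappa: float = 2.0,
    indel_rate: float = 0.0,
    seed: int = 0,
    cds_regions: list[tuple[int, int]] | None = None,
    omega: float | None = None,
) -> SequenceRecord:
    """Kimura two-parameter evolution of a genome copy.

    ``subst_rate`` is the per-site substitution probability; a substitution
    is a transition with probability kappa/(kappa+2).  With ``cds_regions``
    and ``omega`` set, a substitution inside a CDS that changes the encoded
    amino acid is accepted only with probability omega (purifying-selection
    mode; omega=0 permits only synonymous change).  Indels (rate per site,
    lengths 1-3) are off by default.
    """
    if subst_rate < 0 or indel_rate < 0:
        raise ValueError("rates must be non-negative")
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    rng = np.random.default_rng(seed)
    seq = list(record.seq)
    n = len(seq)
    in_cds = None
    code = None
    if cds_regions and omega is not None:
        in_cds = np.zeros(n, dtype=bool)
        frame_start = np.zeros(n, dtype=np.int64)
        for s, e in cds_regions:
            in_cds[s:e] = True
            frame_start[s:e] = s
        from .composition import genetic_code
        code = genetic_code(1)

    hit = np.flatnonzero(rng.random(n) < subst_rate)
    p_ts = kappa / (kappa + 2)
    for i in hit:
        base = seq[i]
        if base not in _TS:
            continue
        if rng.random() < p_ts:
            new = _TS[base]
        else:
            new = _TV[base][int(rng.integers(0, 2))]
        if in_cds is not None and in_cds[i]:
            fs = frame_start[i]
            off = (i - fs) % 3
            cstart = i - off
            codon = "".join(seq[cstart : cstart + 3])
            mutant = codon[:off] + new + codon[off + 1 :]
            if len(codon) == 3 and codon in code and mutant in code:
                syn = code[codon] == code[mutant] and code[mutant] != "*"
                if not syn and rng.random() >= omega:
                    continue
        seq[i] = new

    if indel_rate > 0:
        n_events = rng.poisson(indel_rate * n)
        for _ in range(n_events):
            pos = int(rng.integers(0, len(seq)))
            size = int(rng.integers(1, 4))
            if rng.random() < 0.5 and len(seq) > size:
                del seq[pos : pos + size]
            else:
                seq[pos:pos] = list(_random_bases(size, 0.5, rng))

    return SequenceRecord(id=record.id, seq="".join(seq), circular=record.circular)


def make_genome_family(
    tree_newick: str,
    root_record: SequenceRecord,
    seed: int = 0,
    kappa: float = 2.0,
    lineage_events: dict[str, list[tuple[str, int, int]]] | None = None,
) -> tuple[dict[str, SequenceRecord], TruthTable]:
    """Evolve a root genome along a rooted Newick tree with branch lengths.

    Branch lengths are substitutions per site.  ``lineage_events`` maps a
    leaf name to ('delete', start, length) or ('insert', pos, length)
    events applied after evolution, producing known specific/variable
    structure; everything is recorded in the truth table.
    """
    tree = Phylo.read(io.StringIO(tree_newick), "newick")
    truth = TruthTable(seed=seed, tree=tree_newick.strip())
    rng = np.random.default_rng(seed)
    leaves: dict[str, SequenceRecord] = {}

    def walk(clade, genome: SequenceRecord) -> None:
        branch = clade.branch_length or 0.0
        sub_seed = int(rng.integers(0, 2**31 - 1))
        evolved = evolve_genome(genome, branch, kappa=kappa, seed=sub_seed) \
            if branch > 0 else SequenceRecord(genome.id, genome.seq, genome.circular)
        if clade.is_terminal():
            name = clade.name or f"taxon{len(leaves)}"
            rec = SequenceRecord(id=name, seq=evolved.seq, circular=genome.circular)
            for kind, a, b in (lineage_events or {}).get(name, []):
                s = list(rec.seq)
                if kind == "delete":
                    removed = "".join(s[a : a + b])
                    del s[a : a + b]
                    truth.fragment_tracts.append(
                        {"taxon": name, "event": "delete", "start": a,
                         "length": b, "sequence": removed[:50]}
                    )
                elif kind == "insert":
                    ins = _random_bases(b, 0.5, rng)
                    s[a:a] = list(ins)
                    truth.fragment_tracts.append(
                        {"taxon": name, "event": "insert", "start": a, "length": b}
                    )
                else:
                    raise ValueError(f"unknown lineage event {kind!r}")
                rec = SequenceRecord(id=name, seq="".join(s), circular=rec.circular)
            leaves[name] = rec
        else:
            for child in clade.clades:
                walk(child, evolved)

    walk(tree.root, root_record)
    return leaves, truth
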