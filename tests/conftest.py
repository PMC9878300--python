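"""Shared fixtures and independent oracles for the test suite.

The oracles here are deliberately naive (O(n^2) scans, explicit
enumeration) and independent of the library's algorithms, so agreement is
meaningful.  All fixture data is generated programmatically; the GenBank
fixture is a synthetic record written through Biopython's own writer.
"""

from __future__ import annotations

import numpy as np
import pytest

from mitocensus.genome_io import reverse_complement


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) intervals of consecutive True values."""
    if mask.size == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


def brute_maximal_repeats(seq: str, min_len: int,
                          orientations: tuple[str, ...] = ("F", "P")
                          ) -> set[tuple[int, int, int, str]]:
    """All maximal exact repeat pairs by exhaustive diagonal comparison.

    Returns {(pos1, pos2, arm_len, orientation)}; the forward scan walks
    every self-comparison diagonal, the palindromic scan every diagonal of
    sequence vs its reverse complement.  N never matches.
    """
    s = np.frombuffer(seq.encode(), dtype="S1")
    n = len(seq)
    valid = s != b"N"
    out: set[tuple[int, int, int, str]] = set()
    if "F" in orientations:
        for d in range(1, n):
            L = n - d
            if L < min_len:
                break
            eq = (s[:L] == s[d:]) & valid[:L] & valid[d:]
            for a, b in _true_runs(eq):
                if b - a >= min_len:
                    out.add((a, a + d, b - a, "F"))
    if "P" in orientations:
        r = np.frombuffer(reverse_complement(seq).encode(), dtype="S1")
        rvalid = r != b"N"
        for o in range(-(n - 1), n):
            i0 = max(0, o)
            p0 = i0 - o
            L = n - max(i0, p0)
            if L < min_len:
                continue
            eq = (s[i0 : i0 + L] == r[p0 : p0 + L]) & valid[i0 : i0 + L] & rvalid[p0 : p0 + L]
            for a, b in _true_runs(eq):
                arm = b - a
                if arm < min_len:
                    continue
                i = i0 + a
                p = p0 + a
                j = n - p - arm
                if i == j:
                    continue
                lo, hi = (i, j) if i < j else (j, i)
                out.add((lo, hi, arm, "P"))
    return out


def brute_ssrs(seq: str, thresholds: dict[int, int]) -> set[tuple[str, int, int]]:
    """{(motif, start, copies)} by direct per-position copy counting.

    A start qualifies when the motif is primitive, the copy count meets the
    threshold, and the run extends neither a single base leftward (per-base
    periodicity) nor by construction rightward beyond the counted copies.
    """
    n = len(seq)
    found: set[tuple[str, int, int]] = set()
    for u, min_copies in thresholds.items():
        for i in range(n - u * min_copies + 1):
            motif = seq[i : i + u]
            if "N" in motif:
                continue
            if any(motif == motif[:d] * (u // d) for d in range(1, u) if u % d == 0):
                continue
            # left per-base extension means this is not the run start
            if i > 0 and i + u - 1 < n and seq[i - 1] == seq[i - 1 + u] and seq[i - 1] != "N":
                continue
            copies = 1
            while seq[i + copies * u : i + (copies + 1) * u] == motif:
                copies += 1
            if copies >= min_copies:
                found.add((motif, i, copies))
    # resolve same-period overlaps as the contract does: longer locus wins
    resolved: set[tuple[str, int, int]] = set()
    by_u: dict[int, list[tuple[str, int, int]]] = {}
    for motif, start, copies in found:
        by_u.setdefault(len(motif), []).append((motif, start, copies))
    for u, items in by_u.items():
        items.sort(key=lambda t: (t[1], -t[2]))
        kept: list[tuple[str, int, int]] = []
        for motif, start, copies in items:
            if kept and start < kept[-1][1] + len(kept[-1][0]) * kept[-1][2]:
                if copies * u > len(kept[-1][0]) * kept[-1][2]:
                    kept[-1] = (motif, start, copies)
                continue
            kept.append((motif, start, copies))
        resolved.update(kept)
    return resolved


@pytest.fixture(scope="session")
def synthetic_genbank(tmp_path_factory):
    """A small synthetic annotated GenBank record written via Biopython.

    Layout (0-based): gene1 CDS join(100..250, 300..450) on +;
    trn1 tRNA complement(500..571); two copies of CDS dup at 600 and 800;
    an rRNA at 1000.  Synthetic stand-in for a deposited organelle record.
    """
    from Bio.Seq import Seq
    from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
    from Bio.SeqRecord import SeqRecord
    from Bio import SeqIO

    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list("ACGT"), size=1500))
    record = SeqRecord(Seq(seq), id="SYNTH1", name="SYNTH1",
                       annotations={"molecule_type": "DNA", "topology": "circular"})
    record.features = [
        SeqFeature(CompoundLocation([SimpleLocation(100, 250, 1),
                                     SimpleLocation(300, 450, 1)]),
                   type="CDS", qualifiers={"gene": ["gene1"]}),
        SeqFeature(SimpleLocation(500, 572, -1), type="tRNA",
                   qualifiers={"gene": ["trn1-UUU"]}),
        SeqFeature(SimpleLocation(600, 699, 1), type="CDS",
                   qualifiers={"gene": ["dup"]}),
        SeqFeature(SimpleLocation(800, 899, 1), type="CDS",
                   qualifiers={"gene": ["dup"]}),
        SeqFeature(SimpleLocation(1000, 1282, 1), type="rRNA",
                   qualifiers={"gene": ["rrn-small"]}),
    ]
    path = tmp_path_factory.mktemp("gb") / "synthetic_record.gb"
    SeqIO.write(record, str(path), "genbank")
    return path, seq
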