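"""Enumeration of maximal exact repeat pairs (forward and palindromic).

A repeat pair is two occurrences of the same word — on the same strand
(forward, F) or as reverse complements (palindromic, P) — that cannot be
extended by one base at either end without breaking the match.  Detection is
exact (Hamming distance 0) and exhaustive above a minimum arm length.

The scan is seed-based: every pair of occurrences of a shared ``min_len``-mer
whose preceding characters differ marks the unique left end of a maximal
pair, which is then extended to the right.  This enumerates each maximal
pair exactly once, with work proportional to the repeat content rather than
the square of the genome length.
"""

from __future__ import annotations

import hashlib
from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .genome_io import SequenceRecord, reverse_complement

__all__ = ["RepeatPair", "find_maximal_repeats", "bin_repeats", "large_repeats"]


@dataclass(frozen=True)
class RepeatPair:
    arm_len: int
    pos1: int
    pos2: int
    orientation: str  # 'F' or 'P'
    seq_hash: str

    @property
    def arm1(self) -> tuple[int, int]:
        return self.pos1, self.pos1 + self.arm_len

    @property
    def arm2(self) -> tuple[int, int]:
        return self.pos2, self.pos2 + self.arm_len


def _chars_match(a: str, b: str) -> bool:
    return a == b and a != "N"


def _kmer_index(s: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(s) - k + 1):
        kmer = s[i : i + k]
        if "N" not in kmer:
            index[kmer].append(i)
    return index


def _forward_pairs(s: str, k: int) -> set[tuple[int, int, int]]:
    """(pos1, pos2, arm_len) for maximal same-strand pairs, pos1 < pos2."""
    n = len(s)
    out: set[tuple[int, int, int]] = set()
    for positions in _kmer_index(s, k).values():
        if len(positions) < 2:
            continue
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                i, j = positions[a], positions[b]
                if i > 0 and j > 0 and _chars_match(s[i - 1], s[j - 1]):
                    continue  # not left-maximal; counted at its true left end
                l = k
                while i + l < n and j + l < n and _chars_match(s[i + l], s[j + l]):
                    l += 1
                out.add((i, j, l))
    return out


def _palindromic_pairs(s: str, k: int) -> set[tuple[int, int, int]]:
    """(pos1, pos2, arm_len) for maximal reverse-complement pairs."""
    n = len(s)
    r = reverse_complement(s)
    out: set[tuple[int, int, int]] = set()
    r_index = _kmer_index(r, k)
    seen_kmers: set[str] = set()
    for i in range(n - k + 1):
        kmer = s[i : i + k]
        if "N" in kmer or kmer not in r_index:
            continue
        for p in r_index[kmer]:
            if i > 0 and p > 0 and _chars_match(s[i - 1], r[p - 1]):
                continue
            l = k
            while i + l < n and p + l < n and _chars_match(s[i + l], r[p + l]):
                l += 1
            j = n - p - l  # second arm start back on the forward strand
            if i == j:
                continue  # a word that is its own reverse complement
            pos1, pos2 = (i, j) if i < j else (j, i)
            out.add((pos1, pos2, l))
    return out


def find_maximal_repeats(
    record: SequenceRecord,
    min_len: int = 30,
    orientations: tuple[str, ...] = ("F", "P"),
    circular: bool = False,
) -> list[RepeatPair]:
    """All maximal exact repeat pairs with arms >= ``min_len``.

    Symmetric duplicates are reported once (pos1 < pos2 for F; the P mirror
    collapsed); ordering is deterministic: arm length descending, then
    positions.  A record shorter than ``min_len`` yields an empty list.
    ``circular`` scans the doubled sequence (capped at 2n-1) and de-duplicates
    pairs modulo the genome length, catching origin-spanning arms.
    """
    if min_len < 8:
        raise ValueError("min_len below 8 would flood the output; raise the cutoff")
    s = record.seq
    n = len(s)
    if n < min_len:
        return []
    scan = s + s[: n - 1] if (circular and record.circular) else s

    raw: set[tuple[int, int, int, str]] = set()
    if "F" in orientations:
        raw |= {(p1, p2, l, "F") for p1, p2, l in _forward_pairs(scan, min_len)}
    if "P" in orientations:
        raw |= {(p1, p2, l, "P") for p1, p2, l in _palindromic_pairs(scan, min_len)}

    if circular and record.circular:
        canon: set[tuple[int, int, int, str]] = set()
        for p1, p2, l, o in raw:
            if l >= n:
                continue  # whole-genome self-overlap artifact of doubling
            a, b = p1 % n, p2 % n
            a, b = (a, b) if a <= b else (b, a)
            canon.add((a, b, l, o))
        raw = {t for t in canon if not (t[0] == t[1] and t[3] == "F")}

    pairs = [
        RepeatPair(
            arm_len=l,
            pos1=p1,
            pos2=p2,
            orientation=o,
            seq_hash=hashlib.sha1(scan[p1 : p1 + l].encode()).hexdigest()[:12],
        )
        for p1, p2, l, o in raw
    ]
    pairs.sort(key=lambda p: (-p.arm_len, p.pos1, p.pos2, p.orientation))
    return pairs


def bin_repeats(
    pairs: list[RepeatPair],
    bin_edges: tuple[int, ...] = (30, 40, 50, 60, 70, 80, 90, 100),
) -> pd.DataFrame:
    """Histogram of arm lengths in decade bins plus an open top bin.

    Also returns per-orientation totals (count and summed arm length) as
    attrs ``totals`` on the frame.
    """
    edges = list(bin_edges)
    labels = [f"{edges[i]}-{edges[i + 1] - 1}" for i in range(len(edges) - 1)]
    labels.append(f">={edges[-1]}")
    rows = []
    for i, label in enumerate(labels):
        lo = edges[i]
        hi = edges[i + 1] if i + 1 < len(edges) else None
        sel = [
            p for p in pairs if p.arm_len >= lo and (hi is None or p.arm_len < hi)
        ]
        row = {"bin": label, "count": len(sel)}
        for o in ("F", "P"):
            row[f"count_{o}"] = sum(1 for p in sel if p.orientation == o)
        rows.append(row)
    frame = pd.DataFrame(rows)
    frame.attrs["totals"] = {
        o: {
            "count": sum(1 for p in pairs if p.orientation == o),
            "total_length": sum(p.arm_len for p in pairs if p.orientation == o),
        }
        for o in ("F", "P")
    }
    return frame


def large_repeats(pairs: list[RepeatPair], cutoff: int = 1000) -> list[RepeatPair]:
    """Pairs with arms strictly longer than ``cutoff`` bp."""
    return [p for p in pairs if p.arm_len > cutoff]


def repeats_to_frame(pairs: list[RepeatPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "arm_len": p.arm_len,
                "pos1": p.pos1,
                "pos2": p.pos2,
                "orientation": p.orientation,
            }
            for p in pairs
        ],
        columns=["arm_len", "pos1", "pos2", "orientation"],
    )
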