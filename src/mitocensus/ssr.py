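"""Microsatellite (SSR) detection in the style of the MISA tool.

A simple sequence repeat is a perfect tandem of a 1-6 bp motif reaching a
per-unit-length minimum copy number.  Defaults are the MISA convention:
10 copies for monomers, 6 for dimers, 5 for tri- to hexamers.  Runs whose
motif is itself periodic (e.g. ``AA`` as a dimer) are reported at the
smallest period only, and a locus spans full motif copies (partial trailing
units are not included), so ``end - start == unit_len * copies`` always.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .genome_io import SequenceRecord, reverse_complement

__all__ = [
    "SSRLocus",
    "DEFAULT_THRESHOLDS",
    "find_ssrs",
    "canonical_motif_class",
    "summarize_ssrs",
]

DEFAULT_THRESHOLDS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass(frozen=True)
class SSRLocus:
    motif: str
    unit_len: int
    copies: int
    start: int
    end: int
    motif_class: str

    @property
    def length(self) -> int:
        return self.end - self.start


def _smallest_period(motif: str) -> int:
    u = len(motif)
    for d in range(1, u):
        if u % d == 0 and motif == motif[:d] * (u // d):
            return d
    return u


def canonical_motif_class(motif: str) -> str:
    """Canonical class label pairing a motif family with its complement.

    Both the motif and its reverse complement are reduced to their
    lexicographically smallest rotation; the label joins the two reduced
    forms, smaller first (``T`` -> ``A/T``, ``GA`` -> ``AG/CT``).
    """
    if not 1 <= len(motif) <= 6:
        raise ValueError(f"motif length must be 1-6, got {motif!r}")

    def min_rotation(m: str) -> str:
        return min(m[i:] + m[:i] for i in range(len(m)))

    a = min_rotation(motif)
    b = min_rotation(reverse_complement(motif))
    lo, hi = sorted((a, b))
    return f"{lo}/{hi}"


def _scan_period(seq: str, u: int, min_copies: int) -> list[SSRLocus]:
    """Maximal perfect tandem runs of period u meeting min_copies."""
    n = len(seq)
    loci: list[SSRLocus] = []
    i = 0
    min_span = u * min_copies
    while i + u < n:
        if seq[i] == seq[i + u] and seq[i] != "N":
            j = i
            while j + u < n and seq[j] == seq[j + u] and seq[j] != "N":
                j += 1
            span = j - i + u  # length of the perfect tandem tract
            copies = span // u
            if copies >= min_copies and span >= min_span:
                motif = seq[i : i + u]
                if _smallest_period(motif) == u:
                    loci.append(
                        SSRLocus(
                            motif=motif,
                            unit_len=u,
                            copies=copies,
                            start=i,
                            end=i + copies * u,
                            motif_class=canonical_motif_class(motif),
                        )
                    )
            i = j + 1
        else:
            i += 1
    # same-period loci must not overlap; keep the longer on conflict
    loci.sort(key=lambda l: (l.start, -l.copies))
    kept: list[SSRLocus] = []
    for loc in loci:
        if kept and loc.start < kept[-1].end:
            if loc.length > kept[-1].length:
                kept[-1] = loc
            continue
        kept.append(loc)
    return kept


def find_ssrs(
    record: SequenceRecord,
    thresholds: dict[int, int] | None = None,
    circular_scan: bool = False,
) -> list[SSRLocus]:
    """All maximal perfect SSR loci on the forward strand, sorted by start.

    With ``circular_scan`` on a circular record, the scan window extends past
    the origin so origin-spanning runs are caught; such loci keep their
    pre-origin start and may have ``end`` > record length (wrap).  N breaks
    every run.
    """
    thresholds = dict(DEFAULT_THRESHOLDS if thresholds is None else thresholds)
    seq = record.seq
    n = len(seq)
    wrap = 0
    if circular_scan and record.circular and n > 0:
        wrap = max(u * c for u, c in thresholds.items()) - 1
        wrap = min(wrap, n)
        seq = seq + seq[:wrap]

    loci: list[SSRLocus] = []
    for u, min_copies in sorted(thresholds.items()):
        loci.extend(_scan_period(seq, u, min_copies))

    if wrap:
        loci = [l for l in loci if l.start < n]
        # drop rotations of origin-spanning runs reported again from base 0
        wrapping = [l for l in loci if l.end > n]
        covered = [(0, l.end - n, l.unit_len) for l in wrapping]
        loci = [
            l
            for l in loci
            if not any(
                l.end <= c_end and l.unit_len == c_u and l.start >= c_start
                for c_start, c_end, c_u in covered
            )
            or l.end > n
        ]
    return sorted(loci, key=lambda l: (l.start, l.unit_len))


UNIT_NAMES = {1: "monomer", 2: "dimer", 3: "trimer", 4: "tetramer", 5: "pentamer", 6: "hexamer"}


def summarize_ssrs(loci: list[SSRLocus]) -> dict[str, pd.DataFrame]:
    """Counts and percentages per unit length and per canonical motif class.

    The by-class table reports both the share of all SSRs and the share
    within the class's own unit length, since the two are easy to conflate.
    """
    total = len(loci)
    by_unit_rows = []
    for u in range(1, 7):
        n = sum(1 for l in loci if l.unit_len == u)
        by_unit_rows.append(
            {
                "unit_len": u,
                "type": UNIT_NAMES[u],
                "count": n,
                "pct_of_all": 100 * n / total if total else 0.0,
            }
        )
    unit_counts = {r["unit_len"]: r["count"] for r in by_unit_rows}

    class_rows = []
    classes = sorted({(l.unit_len, l.motif_class) for l in loci})
    for u, cls in classes:
        n = sum(1 for l in loci if l.motif_class == cls and l.unit_len == u)
        class_rows.append(
            {
                "unit_len": u,
                "motif_class": cls,
                "count": n,
                "pct_of_all": 100 * n / total if total else 0.0,
                "pct_of_unit": 100 * n / unit_counts[u] if unit_counts[u] else 0.0,
            }
        )
    return {
        "by_unit": pd.DataFrame(by_unit_rows),
        "by_class": pd.DataFrame(class_rows),
    }


def ssrs_to_frame(loci: list[SSRLocus], record_id: str = "genome") -> pd.DataFrame:
    """MISA-like locus table (1-based start/end in the size columns)."""
    rows = [
        {
            "id": record_id,
            "ssr_nr": i + 1,
            "type": f"p{l.unit_len}",
            "motif": f"({l.motif}){l.copies}",
            "size": l.length,
            "start": l.start + 1,
            "end": l.end,
        }
        for i, l in enumerate(loci)
    ]
    return pd.DataFrame(
        rows, columns=["id", "ssr_nr", "type", "motif", "size", "start", "end"]
    )
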