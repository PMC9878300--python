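"""Anchored local alignment and multi-genome constitution analysis.

``local_align_segments`` is a seed-chain-extend local aligner: exact
word-size anchors on both strands are merged into exact runs per diagonal,
runs are chained within a diagonal band, inter-run gaps are closed by an
affine-gap global alignment, and the ends are extended ungapped with an
X-drop rule.  Scoring is match +1, mismatch -2, gap open -5, gap extend -2;
significance is a Karlin-Altschul style E-value with the standard ungapped
nucleotide parameters for the +1/-2 scheme (lambda = 1.33, K = 0.621),
which is approximate for gapped segments.

On top of it sit transfer-segment detection (plastid-to-mitochondrion),
per-base core/variable/specific classification across a genome set, the
pan/core accumulation curves, and GC content by fragment class.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome_io import MAFBlock, SequenceRecord, reverse_complement

__all__ = [
    "HomologySegment",
    "FragmentClassMap",
    "local_align_segments",
    "detect_transfers",
    "classify_fragments",
    "accumulation_curves",
    "gc_by_class",
]

MATCH, MISMATCH, GAP_OPEN, GAP_EXTEND = 1, -2, -5, -2
KA_LAMBDA, KA_K = 1.33, 0.621
XDROP = 20
MAX_GAP_CELLS = 400_000  # cap on the inter-run DP; larger gaps split the chain


@dataclass
class HomologySegment:
    query_iv: tuple[int, int]
    subject_iv: tuple[int, int]
    strand: str
    identity: float
    aln_len: int
    matches: int
    score: float
    evalue: float


# ---------------------------------------------------------------------------
# low-level alignment pieces

def _global_affine(a: str, b: str) -> tuple[int, int, int]:
    """Affine-gap global alignment of two short strings.

    Returns (score, matches, alignment columns).  A gap of length g costs
    ``-(5 + 2*(g-1))``.
    """
    la, lb = len(a), len(b)
    if la == 0 and lb == 0:
        return 0, 0, 0
    if la == 0 or lb == 0:
        g = max(la, lb)
        return GAP_OPEN + GAP_EXTEND * (g - 1), 0, g
    NEG = -(10 ** 9)
    # H: match/mismatch end, E: gap in a (consume b), F: gap in b (consume a)
    H = [[NEG] * (lb + 1) for _ in range(la + 1)]
    E = [[NEG] * (lb + 1) for _ in range(la + 1)]
    F = [[NEG] * (lb + 1) for _ in range(la + 1)]
    H[0][0] = 0
    for j in range(1, lb + 1):
        E[0][j] = GAP_OPEN + GAP_EXTEND * (j - 1)
    for i in range(1, la + 1):
        F[i][0] = GAP_OPEN + GAP_EXTEND * (i - 1)
    for i in range(1, la + 1):
        ai = a[i - 1]
        for j in range(1, lb + 1):
            sub = MATCH if (ai == b[j - 1] and ai != "N") else MISMATCH
            H[i][j] = max(H[i - 1][j - 1], E[i - 1][j - 1], F[i - 1][j - 1]) + sub
            E[i][j] = max(H[i][j - 1] + GAP_OPEN, E[i][j - 1] + GAP_EXTEND,
                          F[i][j - 1] + GAP_OPEN)
            F[i][j] = max(H[i - 1][j] + GAP_OPEN, F[i - 1][j] + GAP_EXTEND,
                          E[i - 1][j] + GAP_OPEN)
    # traceback for match/column counting
    i, j = la, lb
    state = max((H[i][j], "H"), (E[i][j], "E"), (F[i][j], "F"))[1]
    score = max(H[i][j], E[i][j], F[i][j])
    matches = 0
    cols = 0
    while i > 0 or j > 0:
        cols += 1
        if state == "H":
            if a[i - 1] == b[j - 1] and a[i - 1] != "N":
                matches += 1
            prev = max((H[i - 1][j - 1], "H"), (E[i - 1][j - 1], "E"), (F[i - 1][j - 1], "F"))
            i, j = i - 1, j - 1
            state = prev[1]
        elif state == "E":
            cand = [(H[i][j - 1] + GAP_OPEN, "H"), (E[i][j - 1] + GAP_EXTEND, "E"),
                    (F[i][j - 1] + GAP_OPEN, "F")]
            state = max(cand)[1]
            j -= 1
        else:
            cand = [(H[i - 1][j] + GAP_OPEN, "H"), (F[i - 1][j] + GAP_EXTEND, "F"),
                    (E[i - 1][j] + GAP_OPEN, "E")]
            state = max(cand)[1]
            i -= 1
        if i == 0 and j == 0:
            break
        if i == 0:
            state = "E"
        elif j == 0:
            state = "F"
    return score, matches, cols


def _extend_ungapped(a: str, b: str, i: int, j: int, direction: int) -> tuple[int, int, int]:
    """X-drop ungapped extension; returns (length, matches, score) of the
    best extension starting one base beyond (i, j)."""
    best = (0, 0, 0)
    score = 0
    matches = 0
    step = 0
    while True:
        step += 1
        pi = i + direction * step
        pj = j + direction * step
        if not (0 <= pi < len(a) and 0 <= pj < len(b)):
            break
        if a[pi] == b[pj] and a[pi] != "N":
            score += MATCH
            matches += 1
        else:
            score += MISMATCH
        if score > best[2]:
            best = (step, matches, score)
        if best[2] - score > XDROP:
            break
    return best


@dataclass
class _Run:
    q: int
    s: int
    length: int

    @property
    def qend(self) -> int:
        return self.q + self.length

    @property
    def send(self) -> int:
        return self.s + self.length


def _anchor_runs(query: str, subject: str, k: int) -> list[_Run]:
    """Exact-match runs from shared k-mers, merged per diagonal."""
    index: dict[str, list[int]] = defaultdict(list)
    for j in range(len(subject) - k + 1):
        w = subject[j : j + k]
        if "N" not in w:
            index[w].append(j)
    by_diag: dict[int, list[int]] = defaultdict(list)
    for i in range(len(query) - k + 1):
        w = query[i : i + k]
        if "N" in w:
            continue
        for j in index.get(w, ()):
            by_diag[i - j].append(i)
    runs: list[_Run] = []
    for diag, qs in by_diag.items():
        qs.sort()
        start = prev = qs[0]
        for q in qs[1:]:
            if q <= prev + k:
                prev = q
            else:
                runs.append(_Run(start, start - diag, prev + k - start))
                start = prev = q
        runs.append(_Run(start, start - diag, prev + k - start))
    return runs


def _cluster_runs(runs: list[_Run], band: int = 30, join_gap: int = 300) -> list[list[_Run]]:
    """Group runs that plausibly belong to one local alignment."""
    runs = sorted(runs, key=lambda r: (r.q - r.s, r.q))
    clusters: list[list[_Run]] = []
    for run in runs:
        placed = False
        for cluster in clusters:
            last = cluster[-1]
            if (
                abs((run.q - run.s) - (last.q - last.s)) <= band
                and run.q <= last.qend + join_gap
                and run.q >= last.q - join_gap
            ):
                cluster.append(run)
                placed = True
                break
        if not placed:
            clusters.append([run])
    # clusters on adjacent diagonals may still be one alignment: merge by span
    merged: list[list[_Run]] = []
    for cluster in sorted(clusters, key=lambda c: min(r.q for r in c)):
        for m in merged:
            qlo = min(r.q for r in cluster)
            qhi = max(r.qend for r in cluster)
            mlo = min(r.q for r in m)
            mhi = max(r.qend for r in m)
            dm = np.median([r.q - r.s for r in m])
            dc = np.median([r.q - r.s for r in cluster])
            if abs(dc - dm) <= band and qlo <= mhi + join_gap and qhi >= mlo - join_gap:
                m.extend(cluster)
                break
        else:
            merged.append(list(cluster))
    return merged


def _chain(runs: list[_Run]) -> list[_Run]:
    """Max-weight collinear chain of runs (both coordinates increasing)."""
    runs = sorted(runs, key=lambda r: (r.q, r.s))
    n = len(runs)
    best = [r.length for r in runs]
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            # j strictly precedes i on both coordinates; small overlaps are
            # allowed here and trimmed below
            if (runs[j].q < runs[i].q and runs[j].s < runs[i].s
                    and runs[j].qend <= runs[i].qend
                    and runs[j].send <= runs[i].send):
                dq = max(runs[i].q - runs[j].qend, 0)
                ds = max(runs[i].s - runs[j].send, 0)
                # bridging a long unseeded stretch costs about what the DP
                # would lose there; keeps noise seeds out of real chains
                penalty = 0.6 * max(dq, ds)
                cand = best[j] + runs[i].length - penalty
                if cand > best[i]:
                    best[i] = cand
                    prev[i] = j
    end = int(np.argmax(best))
    chain = []
    while end != -1:
        chain.append(runs[end])
        end = prev[end]
    chain.reverse()
    # trim overlaps so successive runs are strictly collinear
    trimmed: list[_Run] = []
    for run in chain:
        if trimmed:
            last = trimmed[-1]
            overlap = max(last.qend - run.q, last.send - run.s, 0)
            if overlap >= run.length:
                continue
            if overlap > 0:
                run = _Run(run.q + overlap, run.s + overlap, run.length - overlap)
        trimmed.append(run)
    return trimmed


def _align_cluster(query: str, subject: str, cluster: list[_Run]) -> tuple | None:
    chain = _chain(cluster)
    if not chain:
        return None
    score = matches = cols = 0
    for run in chain:
        score += run.length * MATCH
        matches += run.length
        cols += run.length
    for a, b in zip(chain, chain[1:]):
        ga = query[a.qend : b.q]
        gb = subject[a.send : b.s]
        if len(ga) * len(gb) > MAX_GAP_CELLS:
            return None  # implausible chain; let smaller clusters stand alone
        s, m, c = _global_affine(ga, gb)
        score += s
        matches += m
        cols += c
    first, last = chain[0], chain[-1]
    ln, m, s = _extend_ungapped(query, subject, first.q, first.s, -1)
    q0, s0 = first.q - ln, first.s - ln
    score += s
    matches += m
    cols += ln
    ln, m, s = _extend_ungapped(query, subject, last.qend - 1, last.send - 1, +1)
    q1, s1 = last.qend + ln, last.send + ln
    score += s
    matches += m
    cols += ln
    return q0, q1, s0, s1, score, matches, cols


def local_align_segments(
    genome_a: SequenceRecord,
    genome_b: SequenceRecord,
    word_size: int = 7,
    min_len: int = 300,
    min_identity: float = 0.0,
    max_evalue: float = 1e-5,
) -> list[HomologySegment]:
    """Significant local alignments between two genomes, both strands.

    Segments are filtered by alignment length, identity and E-value, then
    reduced to a non-overlapping (on the query) best-scoring set, greedy by
    score with ties broken by leftmost query start.
    """
    if word_size < 4:
        raise ValueError("word_size must be >= 4")
    qseq = genome_a.seq
    m, n = len(qseq), len(genome_b.seq)
    if m == 0 or n == 0 or set(qseq) <= {"N"} or set(genome_b.seq) <= {"N"}:
        return []
    candidates: list[HomologySegment] = []
    for strand in "+-":
        sseq = genome_b.seq if strand == "+" else reverse_complement(genome_b.seq)
        runs = _anchor_runs(qseq, sseq, word_size)
        # drop bare-word noise seeds before clustering: a run only two bases
        # longer than the word is already ~16x rarer by chance, so real
        # segments keep plenty of seeds while random matches vanish
        runs = [r for r in runs if r.length >= word_size + 2]
        for cluster in _cluster_runs(runs):
            span = max(r.qend for r in cluster) - min(r.q for r in cluster)
            if span < min(min_len // 2, 50):
                continue
            res = _align_cluster(qseq, sseq, cluster)
            if res is None:
                continue
            q0, q1, s0, s1, score, matches, cols = res
            if cols == 0:
                continue
            log_e = math.log(KA_K * m * n) - KA_LAMBDA * score
            if log_e > 700:
                evalue = math.inf
            else:
                evalue = math.exp(log_e) if log_e > -700 else 0.0
            if strand == "+":
                subject_iv = (s0, s1)
            else:
                subject_iv = (n - s1, n - s0)
            candidates.append(
                HomologySegment(
                    query_iv=(q0, q1),
                    subject_iv=subject_iv,
                    strand=strand,
                    identity=matches / cols,
                    aln_len=cols,
                    matches=matches,
                    score=score,
                    evalue=evalue,
                )
            )
    candidates = [
        c
        for c in candidates
        if c.aln_len >= min_len and c.identity >= min_identity and c.evalue <= max_evalue
    ]
    candidates.sort(key=lambda c: (-c.score, c.query_iv[0]))
    kept: list[HomologySegment] = []
    for cand in candidates:
        overlap = 0
        for seg in kept:
            lo = max(cand.query_iv[0], seg.query_iv[0])
            hi = min(cand.query_iv[1], seg.query_iv[1])
            overlap = max(overlap, hi - lo)
        if overlap > 0.25 * (cand.query_iv[1] - cand.query_iv[0]):
            continue
        kept.append(cand)
    kept.sort(key=lambda c: c.query_iv[0])
    return kept


# ---------------------------------------------------------------------------
# plastid -> mitochondrion transfers

def detect_transfers(
    mt_record: SequenceRecord,
    cp_record: SequenceRecord,
    min_identity: float = 0.93,
    max_evalue: float = 1e-5,
    min_len: int = 300,
    word_size: int = 7,
) -> pd.DataFrame:
    """Chloroplast-derived segments in a mitogenome, sorted by mt start.

    The returned frame carries a ``summary`` attr with the segment count and
    the summed mitochondrial length.
    """
    segments = local_align_segments(
        mt_record,
        cp_record,
        word_size=word_size,
        min_len=min_len,
        min_identity=min_identity,
        max_evalue=max_evalue,
    )
    rows = [
        {
            "mt_start": seg.query_iv[0],
            "mt_end": seg.query_iv[1],
            "cp_start": seg.subject_iv[0],
            "cp_end": seg.subject_iv[1],
            "strand": seg.strand,
            "identity": round(seg.identity, 4),
            "aln_len": seg.aln_len,
            "evalue": seg.evalue,
        }
        for seg in segments
    ]
    frame = pd.DataFrame(
        rows,
        columns=["mt_start", "mt_end", "cp_start", "cp_end", "strand",
                 "identity", "aln_len", "evalue"],
    ).sort_values("mt_start", ignore_index=True) if rows else pd.DataFrame(
        columns=["mt_start", "mt_end", "cp_start", "cp_end", "strand",
                 "identity", "aln_len", "evalue"]
    )
    frame.attrs["summary"] = {
        "n_segments": len(frame),
        "total_mt_length": int((frame["mt_end"] - frame["mt_start"]).sum()) if len(frame) else 0,
    }
    return frame


# ---------------------------------------------------------------------------
# constitution: core / variable / specific

@dataclass
class FragmentClassMap:
    """Per-genome partition into core / variable / specific intervals."""

    genome_ids: list[str]
    intervals: dict[str, list[tuple[int, int, str]]]
    counts: dict[str, np.ndarray] = field(repr=False, default_factory=dict)

    def class_length(self, genome_id: str, label: str) -> int:
        return sum(e - s for s, e, lab in self.intervals[genome_id] if lab == label)

    def to_bed_rows(self, genome_id: str) -> list[tuple[int, int, str]]:
        return [(s, e, lab) for s, e, lab in self.intervals[genome_id]]


def _coverage_bools(
    genomes: list[SequenceRecord],
    evidence,
) -> dict[str, np.ndarray]:
    """genome id -> (N_genomes x genome_len) boolean coverage by each genome.

    Row g of its own matrix is True everywhere (self-coverage).
    Evidence is either a list of MAFBlock or a dict
    {(id_a, id_b): [HomologySegment]} from all-pairs alignment.
    """
    ids = [g.id for g in genomes]
    idx = {gid: i for i, gid in enumerate(ids)}
    cov = {
        g.id: np.zeros((len(genomes), g.length), dtype=bool) for g in genomes
    }
    for g in genomes:
        cov[g.id][idx[g.id], :] = True

    if isinstance(evidence, dict):
        for (ga, gb), segments in evidence.items():
            for seg in segments:
                q0, q1 = seg.query_iv
                s0, s1 = seg.subject_iv
                cov[ga][idx[gb], q0:q1] = True
                cov[gb][idx[ga], s0:s1] = True
    else:
        for block in evidence:
            segs = [s for s in block.segments if s.source in idx]
            for a in segs:
                for b in segs:
                    if a.source == b.source:
                        continue
                    lo, hi = a.interval
                    cov[a.source][idx[b.source], lo:hi] = True
    return cov


def classify_fragments(
    genomes: list[SequenceRecord],
    evidence,
) -> FragmentClassMap:
    """Label every base of every genome core / variable / specific.

    A base is core when every genome in the set has homologous sequence
    covering it, specific when only its own genome does, variable otherwise.
    The labeled intervals partition each genome exactly.
    """
    cov = _coverage_bools(genomes, evidence)
    n = len(genomes)
    intervals: dict[str, list[tuple[int, int, str]]] = {}
    counts: dict[str, np.ndarray] = {}
    for g in genomes:
        count = cov[g.id].sum(axis=0)
        counts[g.id] = count
        labels = np.where(count == n, 0, np.where(count == 1, 2, 1))
        ivs: list[tuple[int, int, str]] = []
        names = ("core", "variable", "specific")
        if g.length:
            boundaries = np.flatnonzero(np.diff(labels)) + 1
            starts = np.concatenate([[0], boundaries])
            ends = np.concatenate([boundaries, [g.length]])
            ivs = [(int(s), int(e), names[labels[s]]) for s, e in zip(starts, ends)]
        intervals[g.id] = ivs
    return FragmentClassMap(genome_ids=[g.id for g in genomes],
                            intervals=intervals, counts=counts)


def accumulation_curves(
    genomes: list[SequenceRecord],
    evidence,
    n_permutations: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Pan- and core-genome size versus number of genomes sampled.

    Genome orderings are drawn at random (up to ``n_permutations``); for a
    prefix of k genomes the core size is the bases of the first genome
    covered by all k, and the pan size accumulates only bases not homologous
    to an earlier genome, so each homologous block family is counted once.
    Reports mean, min and max over orderings for every k.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    cov = _coverage_bools(genomes, evidence)
    ids = [g.id for g in genomes]
    idx = {gid: i for i, gid in enumerate(ids)}
    rng = np.random.default_rng(seed)
    n = len(genomes)
    pan = np.zeros((n_permutations, n), dtype=np.int64)
    core = np.zeros((n_permutations, n), dtype=np.int64)
    for p in range(n_permutations):
        order = rng.permutation(n)
        ref = ids[order[0]]
        pan_total = 0
        for k, gi in enumerate(order):
            gid = ids[gi]
            if k == 0:
                new_bases = cov[gid].shape[1]
            else:
                earlier = [idx[ids[g]] for g in order[:k]]
                new_bases = int((~cov[gid][earlier, :].any(axis=0)).sum())
            pan_total += new_bases
            pan[p, k] = pan_total
            rows = [idx[ids[g]] for g in order[: k + 1]]
            core[p, k] = int(cov[ref][rows, :].all(axis=0).sum())
    return pd.DataFrame(
        {
            "k": np.arange(1, n + 1),
            "pan_mean": pan.mean(axis=0),
            "pan_min": pan.min(axis=0),
            "pan_max": pan.max(axis=0),
            "core_mean": core.mean(axis=0),
            "core_min": core.min(axis=0),
            "core_max": core.max(axis=0),
        }
    )


def gc_by_class(class_map: FragmentClassMap, genomes: list[SequenceRecord]) -> pd.DataFrame:
    """GC content of the concatenated bases of each class, per genome and mean.

    Classes with no bases in a genome are omitted from that genome's rows.
    """
    by_id = {g.id: g for g in genomes}
    rows = []
    for gid in class_map.genome_ids:
        seq = by_id[gid].seq
        for label in ("core", "variable", "specific"):
            parts = [seq[s:e] for s, e, lab in class_map.intervals[gid] if lab == label]
            text = "".join(parts)
            gcn = text.count("G") + text.count("C")
            atn = text.count("A") + text.count("T")
            if gcn + atn == 0:
                continue
            rows.append(
                {
                    "genome": gid,
                    "class": label,
                    "length": len(text),
                    "gc": gcn / (gcn + atn),
                }
            )
    frame = pd.DataFrame(rows, columns=["genome", "class", "length", "gc"])
    if len(frame):
        means = frame.groupby("class")["gc"].mean().rename("gc_mean")
        frame = frame.merge(means, on="class")
    return frame
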