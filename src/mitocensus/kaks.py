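"""Approximate Ka/Ks estimation: LWL site-class method plus the MLWL
transition/transversion-weighted modification.

Every codon position is classified by how many of its three possible point
changes are synonymous: 4-fold (all three), 0-fold (none), 2-fold otherwise.
Differences between aligned codons are decomposed over all orderings of
single-step changes that avoid stop codons, each stop-free pathway weighted
equally, and fractional transition/transversion counts accrue to the site
classes.  Per class the Kimura two-parameter correction gives transition
(A_i) and transversion (B_i) distances, combined as

    Ks = (L2*A2 + L4*(A4 + B4)) / (L2/3 + L4)
    Ka = (L0*(A0 + B0) + L2*B2) / (L0 + 2*L2/3)

MLWL replaces the fixed 1/3 synonymous share of 2-fold sites with
kappa/(kappa + 2), kappa being the transition/transversion rate ratio
estimated from the 4-fold sites, and weights the irregular arginine and
isoleucine sites (where the synonymous change is a transversion) by their
actual synonymous transition/transversion make-up.  With kappa forced to 1
the weighting collapses to 1/3 and MLWL reproduces LWL on sequences free of
those irregular codons.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd

from .composition import genetic_code
from .genome_io import reverse_complement  # noqa: F401  (re-export convenience)

logger = logging.getLogger(__name__)

__all__ = [
    "site_degeneracy",
    "CodonAlignment",
    "KaKsResult",
    "count_sites_and_differences",
    "kaks_pair",
    "kaks_matrix",
    "codon_align",
]

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
BASES = "ACGT"
TABLE_ID = 1


def _is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


@lru_cache(maxsize=None)
def _code() -> dict[str, str]:
    return genetic_code(TABLE_ID)


@lru_cache(maxsize=None)
def _site_profile(codon: str, position: int) -> tuple[int, int, int]:
    """(n_synonymous, n_syn_transitions, n_syn_transversions) for the three
    possible changes at ``position`` (1-based) of ``codon``.

    A change into a stop codon is never synonymous; stop codons themselves
    are not valid input.
    """
    code = _code()
    aa = code[codon]
    if aa == "*":
        raise ValueError(f"stop codon {codon} has no degeneracy class")
    p = position - 1
    n_syn = syn_ts = syn_tv = 0
    for alt in BASES:
        if alt == codon[p]:
            continue
        mutant = codon[:p] + alt + codon[p + 1 :]
        if code[mutant] == aa:
            n_syn += 1
            if _is_transition(codon[p], alt):
                syn_ts += 1
            else:
                syn_tv += 1
    return n_syn, syn_ts, syn_tv


def site_degeneracy(codon: str, position: int) -> int:
    """LWL degeneracy class (0, 2 or 4) of one codon position.

    4-fold when every change is synonymous, 0-fold when none is, 2-fold
    otherwise; position is 1-based.
    """
    if position not in (1, 2, 3):
        raise ValueError("position must be 1, 2 or 3")
    n_syn, _, _ = _site_profile(codon, position)
    return 4 if n_syn == 3 else (0 if n_syn == 0 else 2)


@dataclass
class CodonAlignment:
    """Gap- and stop-free aligned codon pairs for one gene and species pair."""

    pairs: list[tuple[str, str]]
    gene: str = ""
    species_pair: tuple[str, str] = ("", "")
    n_dropped: int = 0

    @classmethod
    def from_sequences(cls, seq_a: str, seq_b: str, gene: str = "",
                       species_pair: tuple[str, str] = ("", "")) -> "CodonAlignment":
        if len(seq_a) != len(seq_b):
            raise ValueError("aligned sequences must have equal length")
        code = _code()
        pairs = []
        dropped = 0
        usable = len(seq_a) - len(seq_a) % 3
        for i in range(0, usable, 3):
            ca, cb = seq_a[i : i + 3].upper(), seq_b[i : i + 3].upper()
            if set(ca + cb) - set(BASES):
                dropped += 1
                continue
            if code[ca] == "*" or code[cb] == "*":
                dropped += 1
                continue
            pairs.append((ca, cb))
        if dropped:
            logger.debug("%s: %d codon columns dropped (gaps/ambiguity/stops)",
                         gene or "pair", dropped)
        return cls(pairs=pairs, gene=gene, species_pair=species_pair, n_dropped=dropped)


@dataclass
class SiteCounts:
    L: dict[int, float] = field(default_factory=lambda: {0: 0.0, 2: 0.0, 4: 0.0})
    ts: dict[int, float] = field(default_factory=lambda: {0: 0.0, 2: 0.0, 4: 0.0})
    tv: dict[int, float] = field(default_factory=lambda: {0: 0.0, 2: 0.0, 4: 0.0})
    # synonymous capacity of the 2-fold sites under kappa weighting (MLWL);
    # accumulated as (n_syn_ts, n_syn_tv) per 2-fold site occurrence
    twofold_profiles: list[tuple[float, int, int]] = field(default_factory=list)


def _pathways(ca: str, cb: str) -> list[list[tuple[str, str, int]]]:
    """Stop-free single-step pathways from ca to cb, both directions.

    Each pathway is a list of (from_codon, to_codon, position) steps.
    """
    code = _code()
    diff = [p for p in range(3) if ca[p] != cb[p]]
    paths = []
    for start, target in ((ca, cb), (cb, ca)):
        for order in itertools.permutations(diff):
            cur = start
            steps = []
            ok = True
            for p in order:
                nxt = cur[:p] + target[p] + cur[p + 1 :]
                if code[nxt] == "*":
                    ok = False
                    break
                steps.append((cur, nxt, p))
                cur = nxt
            if ok:
                paths.append(steps)
    return paths


def count_sites_and_differences(aln: CodonAlignment) -> SiteCounts:
    """Site totals per degeneracy class and fractional ts/tv differences.

    L_i is averaged over the two sequences (each codon of each sequence
    contributes half a site per position).  A multi-difference codon pair is
    decomposed over all equally-weighted stop-free pathways; a step's class
    is the degeneracy of the changed position in the codon it starts from.
    Codon pairs whose every pathway passes through a stop are dropped whole.
    """
    if not aln.pairs:
        raise ValueError("empty codon alignment")
    counts = SiteCounts()
    for ca, cb in aln.pairs:
        diff = [p for p in range(3) if ca[p] != cb[p]]
        paths = _pathways(ca, cb) if diff else []
        if diff and not paths:
            logger.debug("codon pair %s/%s: all pathways hit stops; dropped", ca, cb)
            continue
        for pos in (1, 2, 3):
            for codon in (ca, cb):
                n_syn, syn_ts, syn_tv = _site_profile(codon, pos)
                cls = 4 if n_syn == 3 else (0 if n_syn == 0 else 2)
                counts.L[cls] += 0.5
                if cls == 2:
                    counts.twofold_profiles.append((0.5, syn_ts, syn_tv))
        if not diff:
            continue
        w = 1.0 / len(paths)
        for path in paths:
            for cur, nxt, p in path:
                cls = site_degeneracy(cur, p + 1)
                if _is_transition(cur[p], nxt[p]):
                    counts.ts[cls] += w
                else:
                    counts.tv[cls] += w
    return counts


@dataclass
class KaKsResult:
    L0: float
    L2: float
    L4: float
    P: dict[int, float]
    Q: dict[int, float]
    A: dict[int, float]
    B: dict[int, float]
    Ka: float
    Ks: float
    ratio: float
    kappa: float
    n_codons: int
    flags: list[str] = field(default_factory=list)


def _k2p_components(P: float, Q: float) -> tuple[float, float]:
    """(A, B): transition and transversion distances with K2P correction."""
    x = 1 - 2 * P - Q
    y = 1 - 2 * Q
    if x <= 0 or y <= 0:
        raise ValueError("saturated")
    A = 0.5 * math.log(1 / x) - 0.25 * math.log(1 / y)
    B = 0.5 * math.log(1 / y)
    return A, B


def estimate_kappa(counts: SiteCounts, floor: float = 0.5) -> float:
    """Transition/transversion rate ratio from the 4-fold sites.

    kappa = 2*A4/B4 under K2P; falls back to the pooled classes when the
    4-fold class is uninformative, and to 2.0 when nothing is.  Floored to
    avoid degenerate weighting.
    """
    for L, ts, tv in (
        (counts.L[4], counts.ts[4], counts.tv[4]),
        (sum(counts.L.values()), sum(counts.ts.values()), sum(counts.tv.values())),
    ):
        if L <= 0 or tv <= 0:
            continue
        try:
            A, B = _k2p_components(ts / L, tv / L)
        except ValueError:
            continue
        if B > 0:
            return max(2 * A / B, floor)
    return 2.0


def kaks_pair(
    cds_a: str,
    cds_b: str,
    variant: str = "MLWL",
    kappa: float | None = None,
    gene: str = "",
    species_pair: tuple[str, str] = ("", ""),
) -> KaKsResult:
    """Ka, Ks and their ratio for one aligned CDS pair.

    ``variant`` is LWL or MLWL; ``kappa`` overrides the data-driven estimate
    (MLWL with kappa=1 reduces to LWL away from the irregular Arg/Ile
    sites).  Saturation of any needed K2P log flags the result and leaves
    Ka/Ks as NaN; Ks == 0 with Ka > 0 flags the ratio infinite.
    """
    if variant not in ("LWL", "MLWL"):
        raise ValueError(f"unknown variant {variant!r}")
    aln = CodonAlignment.from_sequences(cds_a, cds_b, gene=gene,
                                        species_pair=species_pair)
    counts = count_sites_and_differences(aln)
    L = counts.L
    P = {i: (counts.ts[i] / L[i] if L[i] > 0 else 0.0) for i in (0, 2, 4)}
    Q = {i: (counts.tv[i] / L[i] if L[i] > 0 else 0.0) for i in (0, 2, 4)}
    A: dict[int, float] = {}
    B: dict[int, float] = {}
    flags: list[str] = []
    for i in (0, 2, 4):
        try:
            A[i], B[i] = _k2p_components(P[i], Q[i])
        except ValueError:
            A[i], B[i] = float("nan"), float("nan")
            if L[i] > 0:
                flags.append(f"saturated_L{i}")

    if variant == "MLWL":
        k = kappa if kappa is not None else estimate_kappa(counts)
        # synonymous share of each 2-fold site from its own syn ts/tv profile
        S2 = sum(w * (k * ts + tv) / (k + 2) for w, ts, tv in counts.twofold_profiles)
    else:
        k = 1.0
        S2 = L[2] / 3
    N2 = L[2] - S2

    if flags:
        ka = ks = ratio = float("nan")
    else:
        ks_num = L[2] * A[2] + L[4] * (A[4] + B[4])
        ka_num = L[0] * (A[0] + B[0]) + L[2] * B[2]
        ks_den = S2 + L[4]
        ka_den = L[0] + N2
        ks = ks_num / ks_den if ks_den > 0 else float("nan")
        ka = ka_num / ka_den if ka_den > 0 else float("nan")
        if ks != ks or ka != ka:
            flags.append("undefined_sites")
            ratio = float("nan")
        elif ks == 0 and ka == 0:
            flags.append("no_substitutions")
            ratio = float("nan")
        elif ks == 0:
            flags.append("ks_zero")
            ratio = float("inf")
        else:
            ratio = ka / ks
    return KaKsResult(
        L0=L[0], L2=L[2], L4=L[4], P=P, Q=Q, A=A, B=B,
        Ka=ka, Ks=ks, ratio=ratio, kappa=k,
        n_codons=len(aln.pairs), flags=flags,
    )


# ---------------------------------------------------------------------------
# codon-aware pairwise alignment for unaligned input

def codon_align(cds_a: str, cds_b: str) -> tuple[str, str]:
    """Codon-aware pairwise alignment: global alignment of the amino-acid
    translations back-mapped to codons, so gaps come in whole-codon units."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    code = _code()

    def translate(s: str) -> str:
        aas = []
        for i in range(0, len(s) - len(s) % 3, 3):
            codon = s[i : i + 3].upper()
            aas.append(code.get(codon, "X") if set(codon) <= set(BASES) else "X")
        return "".join(a if a != "*" else "X" for a in aas)

    pa, pb = translate(cds_a), translate(cds_b)
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    aligner.mode = "global"
    alignment = aligner.align(pa, pb)[0]
    out_a, out_b = [], []
    ia = ib = 0
    seq_a_str, seq_b_str = str(alignment[0]), str(alignment[1])
    for ca, cb in zip(seq_a_str, seq_b_str):
        if ca == "-":
            out_a.append("---")
        else:
            out_a.append(cds_a[3 * ia : 3 * ia + 3])
            ia += 1
        if cb == "-":
            out_b.append("---")
        else:
            out_b.append(cds_b[3 * ib : 3 * ib + 3])
            ib += 1
    return "".join(out_a), "".join(out_b)


def kaks_matrix(
    gene_sequences: dict[str, dict[str, str]],
    species_pairs: list[tuple[str, str]],
    variant: str = "MLWL",
    align: bool = True,
) -> pd.DataFrame:
    """Long-format Ka/Ks table over genes x species pairs.

    ``gene_sequences`` maps gene -> species -> CDS.  Missing genes in a
    species leave the cell absent (logged).  The frame carries a ``summary``
    attr counting ratios below vs at-or-above 1.
    """
    rows = []
    for gene, per_species in gene_sequences.items():
        for sp_a, sp_b in species_pairs:
            if sp_a not in per_species or sp_b not in per_species:
                logger.info("gene %s missing in %s or %s; cell absent", gene, sp_a, sp_b)
                continue
            a, b = per_species[sp_a], per_species[sp_b]
            if align:
                a, b = codon_align(a, b)
            res = kaks_pair(a, b, variant=variant, gene=gene,
                            species_pair=(sp_a, sp_b))
            rows.append(
                {
                    "gene": gene,
                    "pair": f"{sp_a}-{sp_b}",
                    "Ka": res.Ka,
                    "Ks": res.Ks,
                    "ratio": res.ratio,
                    "kappa": res.kappa,
                    "L0": res.L0,
                    "L2": res.L2,
                    "L4": res.L4,
                    "flags": ";".join(res.flags),
                }
            )
    frame = pd.DataFrame(
        rows, columns=["gene", "pair", "Ka", "Ks", "ratio", "kappa",
                       "L0", "L2", "L4", "flags"]
    )
    defined = frame["ratio"].dropna() if len(frame) else pd.Series(dtype=float)
    defined = defined[~defined.isin([float("inf")])] if len(defined) else defined
    frame.attrs["summary"] = {
        "n_purifying": int((defined < 1).sum()) if len(defined) else 0,
        "n_neutral_or_positive": int((defined >= 1).sum()) if len(defined) else 0,
    }
    return frame
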