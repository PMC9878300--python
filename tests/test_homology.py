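"""Local alignment, transfer detection and constitution analysis."""

import numpy as np
import pytest

from mitocensus.genome_io import MAFBlock, MAFSegment, SequenceRecord
from mitocensus.homology import (
    accumulation_curves,
    classify_fragments,
    detect_transfers,
    gc_by_class,
    local_align_segments,
)
from mitocensus.simulate import make_genome


def _mutate(seq: str, rate: float, seed: int) -> str:
    rng = np.random.default_rng(seed)
    out = list(seq)
    for i in rng.choice(len(seq), int(round(rate * len(seq))), replace=False):
        out[i] = next(b for b in "ACGT" if b != out[i])
    return "".join(out)


class TestLocalAlign:
    def test_identical_genomes_full_segment(self):
        a = make_genome(1000, 0.5, 3)
        b = SequenceRecord("b", a.seq)
        (seg,) = local_align_segments(a, b)
        assert seg.query_iv == (0, 1000)
        assert seg.subject_iv == (0, 1000)
        assert seg.identity == 1.0 and seg.strand == "+"

    def test_planted_diverged_copy_recovered(self):
        host = make_genome(10000, 0.44, 4)
        donor = make_genome(8000, 0.38, 5)
        insert = _mutate(donor.seq[1000:1500], 0.05, 6)
        mt = SequenceRecord("mt", host.seq[:3000] + insert + host.seq[3500:])
        (seg,) = local_align_segments(mt, donor, min_identity=0.90)
        assert abs(seg.query_iv[0] - 3000) <= 2
        assert abs(seg.query_iv[1] - 3500) <= 2
        assert seg.identity == pytest.approx(0.95, abs=0.02)

    def test_unrelated_genomes_yield_nothing(self):
        for seed in (7, 77, 777):
            g1 = make_genome(10000, 0.44, seed)
            g2 = make_genome(10000, 0.44, seed + 1)
            assert local_align_segments(g1, g2, min_identity=0.90) == []

    def test_reverse_strand_segment(self):
        from mitocensus.genome_io import reverse_complement

        host = make_genome(8000, 0.45, 8)
        donor = make_genome(6000, 0.40, 9)
        insert = reverse_complement(donor.seq[2000:2600])
        mt = SequenceRecord("mt", host.seq[:4000] + insert + host.seq[4600:])
        (seg,) = local_align_segments(mt, donor, min_identity=0.95)
        assert seg.strand == "-"
        assert abs(seg.subject_iv[0] - 2000) <= 2
        assert abs(seg.subject_iv[1] - 2600) <= 2

    def test_tightening_filters_is_monotone(self):
        host = make_genome(9000, 0.44, 10)
        donor = make_genome(7000, 0.42, 11)
        insert = _mutate(donor.seq[500:1200], 0.04, 12)
        mt = SequenceRecord("mt", host.seq[:2000] + insert + host.seq[2700:])
        loose = local_align_segments(mt, donor, min_identity=0.5, max_evalue=1e-3)
        tight = local_align_segments(mt, donor, min_identity=0.93, max_evalue=1e-20)
        keys = lambda segs: {(s.query_iv, s.strand) for s in segs}
        assert keys(tight) <= keys(loose)

    def test_agrees_with_smith_waterman_oracle(self):
        # independent oracle: Biopython's exact local aligner, same scoring
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.match_score = 1
        aligner.mismatch_score = -2
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -2

        host = make_genome(2000, 0.5, 13)
        donor = make_genome(2000, 0.5, 14)
        insert = _mutate(donor.seq[400:1000], 0.06, 15)
        a = SequenceRecord("a", host.seq[:700] + insert + host.seq[1300:])
        (seg,) = local_align_segments(a, donor, min_identity=0.85)
        best = aligner.align(a.seq, donor.seq)[0]
        q0, q1 = best.aligned[0][0][0], best.aligned[0][-1][1]
        s0, s1 = best.aligned[1][0][0], best.aligned[1][-1][1]
        assert abs(seg.query_iv[0] - q0) <= 2 and abs(seg.query_iv[1] - q1) <= 2
        assert abs(seg.subject_iv[0] - s0) <= 2 and abs(seg.subject_iv[1] - s1) <= 2
        matches = sum(
            1 for qa, qb in zip(str(best[0]), str(best[1])) if qa == qb != "-"
        )
        oracle_identity = matches / best.length
        assert seg.identity == pytest.approx(oracle_identity, abs=0.01)


class TestTransfers:
    def test_planted_transfer_found_at_coordinates(self):
        host = make_genome(12000, 0.45, 20)
        cp = make_genome(9000, 0.37, 21)
        insert = _mutate(cp.seq[4000:4700], 0.03, 22)
        mt = SequenceRecord("mt", host.seq[:5000] + insert + host.seq[5700:])
        frame = detect_transfers(mt, cp)
        assert len(frame) == 1
        row = frame.iloc[0]
        assert abs(row.mt_start - 5000) <= 2 and abs(row.mt_end - 5700) <= 2
        assert abs(row.cp_start - 4000) <= 2 and abs(row.cp_end - 4700) <= 2
        assert row.identity >= 0.93

    def test_duplicated_transfer_gives_two_mt_rows_one_cp_interval(self):
        host = make_genome(14000, 0.45, 23)
        cp = make_genome(9000, 0.37, 24)
        donor_piece = cp.seq[2000:2500]
        mt = SequenceRecord(
            "mt",
            host.seq[:3000] + donor_piece + host.seq[3500:9000]
            + donor_piece + host.seq[9500:],
        )
        frame = detect_transfers(mt, cp)
        assert len(frame) == 2
        assert frame.mt_start.iloc[0] < frame.mt_start.iloc[1]
        for _, row in frame.iterrows():
            assert abs(row.cp_start - 2000) <= 2 and abs(row.cp_end - 2500) <= 2

    def test_unrelated_genomes_no_transfers(self):
        mt = make_genome(10000, 0.45, 25)
        cp = make_genome(8000, 0.37, 26)
        frame = detect_transfers(mt, cp)
        assert len(frame) == 0
        assert frame.attrs["summary"]["n_segments"] == 0


def _family_with_structure(seed=30):
    """4 genomes: shared core, one block shared by two, one unique tract."""
    rng = np.random.default_rng(seed)
    core = "".join(rng.choice(list("ACGT"), size=4000))
    half = "".join(rng.choice(list("ACGT"), size=1500))
    uniq = ["".join(rng.choice(list("ACGT"), size=1000)) for _ in range(4)]
    genomes = [
        SequenceRecord("g0", core + half + uniq[0]),
        SequenceRecord("g1", core + half + uniq[1]),
        SequenceRecord("g2", core + uniq[2]),
        SequenceRecord("g3", core + uniq[3]),
    ]
    truth = {
        "g0": [(0, 4000, "core"), (4000, 5500, "variable"), (5500, 6500, "specific")],
        "g1": [(0, 4000, "core"), (4000, 5500, "variable"), (5500, 6500, "specific")],
        "g2": [(0, 4000, "core"), (4000, 5000, "specific")],
        "g3": [(0, 4000, "core"), (4000, 5000, "specific")],
    }
    return genomes, truth


def _all_pairs_evidence(genomes, **kwargs):
    evidence = {}
    for i in range(len(genomes)):
        for j in range(i + 1, len(genomes)):
            evidence[(genomes[i].id, genomes[j].id)] = local_align_segments(
                genomes[i], genomes[j], **kwargs
            )
    return evidence


class TestConstitution:
    def test_two_identical_genomes_all_core(self):
        a = make_genome(3000, 0.5, 31)
        b = SequenceRecord("b", a.seq)
        evidence = _all_pairs_evidence([a, b])
        cmap = classify_fragments([a, b], evidence)
        assert cmap.class_length("synth_31", "core") == 3000
        assert cmap.class_length("b", "core") == 3000

    def test_partition_is_exact_on_structured_family(self):
        genomes, _ = _family_with_structure()
        cmap = classify_fragments(genomes, _all_pairs_evidence(genomes))
        for g in genomes:
            total = sum(e - s for s, e, _ in cmap.intervals[g.id])
            assert total == g.length

    def test_planted_labels_recovered(self):
        genomes, truth = _family_with_structure()
        cmap = classify_fragments(genomes, _all_pairs_evidence(genomes))
        for g in genomes:
            want = np.empty(g.length, dtype=object)
            for s, e, lab in truth[g.id]:
                want[s:e] = lab
            got = np.empty(g.length, dtype=object)
            for s, e, lab in cmap.intervals[g.id]:
                got[s:e] = lab
            agreement = float(np.mean(want == got))
            assert agreement >= 0.99

    def test_maf_evidence_block_shared_by_two_of_three(self):
        rng = np.random.default_rng(33)
        seqs = {g: "".join(rng.choice(list("ACGT"), size=1000)) for g in ("x", "y", "z")}
        genomes = [SequenceRecord(g, s) for g, s in seqs.items()]
        block = MAFBlock(
            score=1.0,
            segments=[
                MAFSegment("x", 100, 300, "+", 1000, "A" * 300),
                MAFSegment("y", 200, 300, "+", 1000, "A" * 300),
            ],
        )
        cmap = classify_fragments(genomes, [block])
        assert cmap.class_length("x", "variable") == 300
        assert cmap.class_length("y", "variable") == 300
        assert cmap.class_length("z", "specific") == 1000

    def test_absent_genome_entirely_specific(self):
        genomes, _ = _family_with_structure()
        lonely = make_genome(2000, 0.5, 35)
        all_genomes = genomes + [lonely]
        evidence = _all_pairs_evidence(genomes)  # no evidence involving lonely
        cmap = classify_fragments(all_genomes, evidence)
        assert cmap.class_length(lonely.id, "specific") == lonely.length


class TestAccumulation:
    def test_identical_genomes_flat_curves(self):
        a = make_genome(2000, 0.5, 36)
        clones = [SequenceRecord(f"c{i}", a.seq) for i in range(3)]
        evidence = _all_pairs_evidence(clones)
        acc = accumulation_curves(clones, evidence, n_permutations=10, seed=1)
        assert (acc.pan_mean == 2000).all()
        assert (acc.core_mean == 2000).all()

    def test_monotone_and_pan_ge_core(self):
        genomes, _ = _family_with_structure()
        acc = accumulation_curves(genomes, _all_pairs_evidence(genomes),
                                  n_permutations=50, seed=2)
        assert (np.diff(acc.pan_min) >= 0).all() and (np.diff(acc.pan_mean) >= 0).all()
        assert (np.diff(acc.core_max) <= 0).all() and (np.diff(acc.core_mean) <= 0).all()
        assert (acc.pan_mean >= acc.core_mean).all()

    def test_final_sizes_match_planted_structure(self):
        genomes, _ = _family_with_structure()
        acc = accumulation_curves(genomes, _all_pairs_evidence(genomes),
                                  n_permutations=20, seed=3)
        # pan(4) = core + shared-by-two half + four unique tracts, counted once
        truth_pan = 4000 + 1500 + 4 * 1000
        truth_core = 4000
        assert acc.pan_mean.iloc[-1] == pytest.approx(truth_pan, rel=0.02)
        assert acc.core_mean.iloc[-1] == pytest.approx(truth_core, rel=0.02)

    def test_same_seed_reproducible(self):
        genomes, _ = _family_with_structure()
        ev = _all_pairs_evidence(genomes)
        a = accumulation_curves(genomes, ev, n_permutations=5, seed=9)
        b = accumulation_curves(genomes, ev, n_permutations=5, seed=9)
        assert a.equals(b)


class TestGCByClass:
    def test_identical_genomes_class_gc_equals_genome_gc(self):
        from mitocensus.composition import gc_content

        a = make_genome(2000, 0.5, 38)
        b = SequenceRecord("b", a.seq)
        cmap = classify_fragments([a, b], _all_pairs_evidence([a, b]))
        frame = gc_by_class(cmap, [a, b])
        row = frame[(frame.genome == "b") & (frame["class"] == "core")].iloc[0]
        assert row.gc == pytest.approx(gc_content(a.seq))
        # no specific bases anywhere: the class is absent from the table
        assert not (frame["class"] == "specific").any()

    def test_high_gc_core_tract_ranks_above_variable(self):
        rng = np.random.default_rng(39)
        core = "".join(rng.choice(list("ACGT"), p=[0.15, 0.35, 0.35, 0.15], size=3000))
        uniq = ["".join(rng.choice(list("ACGT"), p=[0.35, 0.15, 0.15, 0.35], size=1500))
                for _ in range(2)]
        g0 = SequenceRecord("g0", core + uniq[0])
        g1 = SequenceRecord("g1", core + uniq[1])
        cmap = classify_fragments([g0, g1], _all_pairs_evidence([g0, g1]))
        frame = gc_by_class(cmap, [g0, g1])
        core_gc = frame[frame["class"] == "core"].gc.mean()
        spec_gc = frame[frame["class"] == "specific"].gc.mean()
        assert core_gc > spec_gc
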