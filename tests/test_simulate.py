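"""Simulator: plan satisfaction, determinism, stall placement, bias, formats."""

from collections import Counter

import numpy as np
import pytest
from scipy import stats

from rg4kit.classify import scan_transcriptome
from rg4kit.io import read_bed, read_fastq
from rg4kit.simulate import (
    SimConfig,
    emit_truth,
    generate_transcriptome,
    reads_to_fastq,
    reads_to_frame,
    simulate_library,
)


def small_cfg(**kw) -> SimConfig:
    base = dict(
        seed=7,
        n_transcripts=10,
        length_range=(600, 900),
        motif_plan={"canonical": 5},
        depth=5000,
        complexity_per_ng=40.0,
    )
    base.update(kw)
    return SimConfig(**base)


class TestTranscriptome:
    def test_motif_plan_satisfied_exactly(self):
        tx = generate_transcriptome(small_cfg())
        assert Counter(m.klass for m in tx.planted) == {"canonical": 5}

    def test_deterministic_under_seed(self):
        cfg = small_cfg()
        assert generate_transcriptome(cfg) == generate_transcriptome(cfg)

    def test_planted_spans_within_transcripts_and_disjoint(self):
        tx = generate_transcriptome(SimConfig(seed=3))
        lengths = tx.lengths()
        by_tx = {}
        for m in tx.planted:
            assert 0 <= m.start < m.end <= lengths[m.transcript_id]
            by_tx.setdefault(m.transcript_id, []).append((m.start, m.end))
        for spans in by_tx.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_background_contains_no_class_match(self):
        # exhaustive scan of a motif-free transcriptome finds nothing:
        # background G-runs are capped below two
        tx = generate_transcriptome(small_cfg(motif_plan={}))
        assert scan_transcriptome(tx) == []
        for r in tx.records:
            assert "GG" not in r.sequence

    def test_planted_motifs_recovered_by_scan_with_identical_class(self):
        tx = generate_transcriptome(SimConfig(seed=11))
        found = {
            (c.transcript_id, c.motif_start, c.motif_end, c.klass)
            for c in scan_transcriptome(tx)
        }
        for m in tx.planted:
            assert (m.transcript_id, m.start, m.end, m.klass) in found

    def test_infeasible_plan_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            generate_transcriptome(
                small_cfg(n_transcripts=1, length_range=(200, 220),
                          motif_plan={"canonical": 10})
            )


class TestLibrary:
    def test_degenerate_probabilities_pin_stop_to_motif_end(self):
        cfg = small_cfg(
            epsilon_bg=0.0,
            theta_stop={"canonical": 1.0},
            p0_p1=(1.0, 0.0),
            fate_rates={},
        )
        tx = generate_transcriptome(cfg)
        motifs = {m.transcript_id: m for m in tx.planted}
        reads = simulate_library(tx, cfg, "K", 1)
        stalled = 0
        for r in reads:
            m = motifs.get(r.transcript_id)
            if m is None:
                continue
            # a fragment wholly containing the motif always stalls, so no
            # surviving read span may still contain the whole motif
            assert not (r.stop_pos <= m.start and m.end <= r.end_pos)
            if r.stop_pos == m.end - 1:
                stalled += 1
        assert stalled > 0

    def test_duplicates_share_umi_and_coordinates(self):
        cfg = small_cfg()
        tx = generate_transcriptome(cfg)
        df = reads_to_frame(simulate_library(tx, cfg, "K", 1))
        for _, grp in df.groupby("molecule_id"):
            assert grp["umi"].nunique() == 1
            assert grp["stop_pos"].nunique() == 1
            assert grp["end_pos"].nunique() == 1
            parents = grp["is_duplicate_of"]
            assert (parents == ".").sum() == 1

    def test_depth_zero_gives_empty_library(self):
        cfg = small_cfg(depth=0)
        tx = generate_transcriptome(cfg)
        assert simulate_library(tx, cfg, "K", 1) == []

    def test_unknown_condition_rejected(self):
        cfg = small_cfg()
        tx = generate_transcriptome(cfg)
        with pytest.raises(ValueError, match="condition"):
            simulate_library(tx, cfg, "Na", 1)

    def test_protocol_one_a_bias_near_65_percent(self):
        cfg = small_cfg(protocol="1.0", depth=50000, complexity_per_ng=500.0)
        tx = generate_transcriptome(cfg)
        df = reads_to_frame(simulate_library(tx, cfg, "Li", 1))
        seqs = {r.transcript_id: r.sequence for r in tx.records}
        bases = [seqs[r.transcript_id][r.stop_pos] for r in df.itertuples()]
        frac_a = np.mean([b == "A" for b in bases])
        assert frac_a == pytest.approx(0.65, abs=0.03)

    def test_protocol_two_a_bias_near_35_percent(self):
        cfg = small_cfg(protocol="2.0", depth=50000, complexity_per_ng=500.0)
        tx = generate_transcriptome(cfg)
        df = reads_to_frame(simulate_library(tx, cfg, "Li", 1))
        seqs = {r.transcript_id: r.sequence for r in tx.records}
        bases = [seqs[r.transcript_id][r.stop_pos] for r in df.itertuples()]
        assert np.mean([b == "A" for b in bases]) == pytest.approx(0.35, abs=0.03)

    def test_li_stops_at_motifs_indistinguishable_from_background(self):
        cfg = SimConfig(seed=5)
        tx = generate_transcriptome(cfg)
        df = reads_to_frame(simulate_library(tx, cfg, "Li", 1))
        df = df[df["fate"] == "usable"].drop_duplicates("molecule_id")
        motif_pos = {
            (m.transcript_id, p)
            for m in tx.planted
            for p in (m.end - 1, m.end)
        }
        stops_at_motif = stops_elsewhere = 0
        cov_at_motif = cov_elsewhere = 0
        lengths = tx.lengths()
        for tid, grp in df.groupby("transcript_id"):
            n = lengths[tid]
            stops = np.zeros(n, dtype=int)
            cov = np.zeros(n + 1, dtype=int)
            np.add.at(stops, grp["stop_pos"].to_numpy(), 1)
            np.add.at(cov, grp["stop_pos"].to_numpy(), 1)
            np.add.at(cov, grp["end_pos"].to_numpy(), -1)
            cov = np.cumsum(cov[:-1])
            is_motif = np.zeros(n, dtype=bool)
            for (t, p) in motif_pos:
                if t == tid and p < n:
                    is_motif[p] = True
            stops_at_motif += stops[is_motif].sum()
            cov_at_motif += cov[is_motif].sum()
            stops_elsewhere += stops[~is_motif].sum()
            cov_elsewhere += cov[~is_motif].sum()
        table = np.array(
            [
                [stops_at_motif, cov_at_motif - stops_at_motif],
                [stops_elsewhere, cov_elsewhere - stops_elsewhere],
            ]
        )
        p = stats.chi2_contingency(table)[1]
        assert p > 0.01

    def test_unique_molecule_count_increases_with_input(self):
        # library complexity scales with RNA input; duplicate fraction
        # rises as input falls
        uniques, dups = [], []
        for ng in (10.0, 100.0, 500.0):
            cfg = small_cfg(input_ng=ng, depth=4000)
            tx = generate_transcriptome(cfg)
            df = reads_to_frame(simulate_library(tx, cfg, "K", 1))
            uniques.append(df["molecule_id"].nunique())
            dups.append((df["is_duplicate_of"] != ".").mean())
        assert uniques[0] < uniques[1] < uniques[2]
        assert dups[0] > dups[1] > dups[2]

    def test_stops_within_transcript_bounds(self):
        cfg = small_cfg()
        tx = generate_transcriptome(cfg)
        lengths = tx.lengths()
        for r in simulate_library(tx, cfg, "K", 2):
            assert 0 <= r.stop_pos < r.end_pos <= lengths[r.transcript_id]


class TestEmission:
    def test_fastq_round_trip_reproduces_reads(self, tmp_path):
        cfg = small_cfg(depth=500)
        tx = generate_transcriptome(cfg)
        reads = simulate_library(tx, cfg, "K", 1)
        r1 = tmp_path / "R1.fastq.gz"
        r2 = tmp_path / "R2.fastq.gz"
        reads_to_fastq(reads, tx, cfg, r1, r2)
        seqs = tx.sequences()
        back = list(read_fastq(r1))
        assert len(back) == len(reads)
        for rec, r in zip(back, reads):
            assert rec.read_id == r.read_id
            assert rec.sequence[: cfg.umi_len] == r.umi
            insert = rec.sequence[cfg.umi_len :]
            assert seqs[r.transcript_id][r.stop_pos :].startswith(insert)

    def test_truth_bed_round_trip(self, tmp_path):
        cfg = small_cfg(depth=200)
        tx = generate_transcriptome(cfg)
        reads = simulate_library(tx, cfg, "K", 1)
        bed = tmp_path / "truth.bed"
        emit_truth(tx, reads, bed, tmp_path / "lineage.tsv")
        back = read_bed(bed)
        assert [(b.chrom, b.start, b.end, b.name) for b in back] == [
            (m.transcript_id, m.start, m.end, m.klass) for m in tx.planted
        ]

    def test_no_motifs_gives_empty_truth_bed(self, tmp_path):
        cfg = small_cfg(motif_plan={}, depth=100)
        tx = generate_transcriptome(cfg)
        bed = tmp_path / "truth.bed"
        emit_truth(tx, [], bed, tmp_path / "lineage.tsv")
        assert read_bed(bed) == []

    def test_library_deterministic_under_seed(self):
        cfg = small_cfg(depth=1000)
        tx = generate_transcriptome(cfg)
        a = simulate_library(tx, cfg, "Li", 1)
        b = simulate_library(tx, cfg, "Li", 1)
        assert a == b
        c = simulate_library(tx, cfg, "Li", 2)
        assert a != c
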