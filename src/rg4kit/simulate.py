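"""Ground-truthed simulator for rG4 stop-profiling libraries.

The simulator emulates the data-generating process the analysis assumes: a
polyadenylated transcriptome with log-normally distributed abundances and
planted quadruplex motifs of known class; random ~250-nt fragmentation;
reverse transcription that, under K+ (quadruplex-stabilising) conditions,
stalls at a planted motif's 3'-most G (offset 0) or its +1 flank, while under
Li+ the motif behaves like background; a low per-position background stall
rate in both conditions; UMI tagging; a finite library of unique molecules
whose size scales with RNA input, PCR-amplified and sequenced to a fixed
depth (which is what creates duplicate reads and saturation behaviour); a
protocol-dependent acceptance bias on the 5'-most nucleotide of the template
strand (the older hairpin-adapter protocol shows ~65% A at read 5' ends, the
dU-adapter protocol ~35%); and aligner fates (adapter-only, unalignable,
multimapped) injected at fixed rates so that yield accounting can be
exercised without shelling out to real trimmers/aligners.

Ground truth (planted motifs and per-read molecule lineage) is emitted
alongside the reads, sufficient to score sensitivity and false discovery
downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import ClassTaxonomy, DEFAULT_TAXONOMY, classify_window
from .io import BedRecord, FastqRead, write_bed, write_fastq, write_table

__all__ = [
    "SimConfig",
    "TranscriptRecord",
    "Transcriptome",
    "TruthMotif",
    "ReadRecord",
    "PROTOCOL_ABIAS",
    "generate_transcriptome",
    "simulate_library",
    "reads_to_frame",
    "frame_to_reads",
    "reads_to_fastq",
    "write_reads_table",
    "read_reads_table",
    "emit_truth",
]

READ_TABLE_COLUMNS = [
    "read_id",
    "transcript_id",
    "strand",
    "stop_pos",
    "end_pos",
    "umi",
    "condition",
    "replicate",
    "input_ng",
    "fate",
    "molecule_id",
    "is_duplicate_of",
]

# 5'-nucleotide acceptance weights: the hairpin-adapter protocol (1.0) shows a
# strong global A-bias (~65% A), the dU-adapter protocol (2.0) a mild one
# (~35% A, ~20% each T/C/G).
PROTOCOL_ABIAS: dict[str, dict[str, float]] = {
    "1.0": {"A": 0.65, "C": 0.35 / 3, "G": 0.35 / 3, "T": 0.35 / 3},
    "2.0": {"A": 0.35, "C": 0.65 / 3, "G": 0.65 / 3, "T": 0.65 / 3},
}

FATES = ("usable", "adapter_only", "unalignable", "multimapped")

_VARIANT_CLASSES = ("two_quartet", "g_triplex")


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the simulated study, reproducible from ``seed`` alone.

    theta_stop gives the per-fragment K+ stall probability at a planted motif
    by class: canonical quadruplexes stall most reliably (0.9), the
    non-canonical classes less so (0.7), and the structurally imperfect
    variant classes least and with extra replicate-to-replicate jitter (0.4).
    """

    seed: int = 0
    n_transcripts: int = 30
    length_range: tuple[int, int] = (1000, 1600)
    abundance_mu: float = 1.0  # log-normal over relative abundance
    abundance_sigma: float = 0.8
    motif_plan: Mapping[str, int] = field(
        default_factory=lambda: {
            "canonical": 10,
            "long_loop": 5,
            "bulge": 5,
            "two_quartet": 5,
            "g_triplex": 3,
        }
    )
    motif_min_gap: int = 80  # nt between planted motifs on one transcript
    frag_len_mean: float = 250.0  # target fragment size of the protocol
    frag_len_sd: float = 50.0
    theta_stop: Mapping[str, float] = field(
        default_factory=lambda: {
            "canonical": 0.9,
            "long_loop": 0.7,
            "bulge": 0.7,
            "two_quartet": 0.4,
            "g_triplex": 0.4,
        }
    )
    variant_theta_jitter: float = 0.05  # per-replicate sd on variant theta
    p0_p1: tuple[float, float] = (0.6, 0.4)  # stall at offset 0 vs +1
    epsilon_bg: float = 1e-3  # background per-position stall probability
    protocol: str = "2.0"
    abias_weights: Mapping[str, float] | None = None  # default per protocol
    umi_len: int = 10
    complexity_per_ng: float = 160.0  # unique library molecules per ng input
    dup_lambda: float = 1.0  # PCR copy dispersion at the reference 11 cycles
    pcr_cycles: int = 11
    input_ng: float = 100.0
    depth: int = 25000  # sequenced read pairs per library
    read_len: int = 150
    fate_rates: Mapping[str, float] = field(
        default_factory=lambda: {
            "adapter_only": 0.05,
            "unalignable": 0.10,
            "multimapped": 0.10,
        }
    )

    def resolved_abias(self) -> dict[str, float]:
        w = dict(self.abias_weights or PROTOCOL_ABIAS[self.protocol])
        total = sum(w.values())
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"abias weights must sum to 1, got {total}")
        return {b: w[b] / total for b in "ACGT"}

    def __post_init__(self) -> None:
        if self.n_transcripts <= 0 or self.depth < 0:
            raise ValueError("n_transcripts must be > 0 and depth >= 0")
        probs = [self.epsilon_bg, *self.p0_p1, *self.theta_stop.values()]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if not math.isclose(sum(self.p0_p1), 1.0, abs_tol=1e-9):
            raise ValueError("p0_p1 must sum to 1")
        self.resolved_abias()


@dataclass(frozen=True)
class TruthMotif:
    """A planted quadruplex motif: the simulator's ground truth."""

    transcript_id: str
    start: int  # 0-based half-open transcript coordinates
    end: int
    klass: str
    sequence: str


@dataclass(frozen=True)
class TranscriptRecord:
    transcript_id: str
    gene_id: str
    sequence: str
    tpm_true: float


@dataclass(frozen=True)
class Transcriptome:
    records: tuple[TranscriptRecord, ...]
    planted: tuple[TruthMotif, ...]

    def sequences(self) -> dict[str, str]:
        return {r.transcript_id: r.sequence for r in self.records}

    def lengths(self) -> dict[str, int]:
        return {r.transcript_id: len(r.sequence) for r in self.records}

    def by_id(self, transcript_id: str) -> TranscriptRecord:
        for r in self.records:
            if r.transcript_id == transcript_id:
                return r
        raise KeyError(transcript_id)


@dataclass(frozen=True)
class ReadRecord:
    """One sequenced molecule copy with its transcript alignment and fate."""

    read_id: str
    transcript_id: str
    stop_pos: int  # 0-based: the template-strand 5' base = RT stop
    end_pos: int  # half-open 3' bound of the fragment
    umi: str
    condition: str  # "K" or "Li"
    replicate: int
    input_ng: float
    fate: str
    molecule_id: str
    is_duplicate_of: str | None  # parent molecule id, None for the first copy

    def __post_init__(self) -> None:
        if not self.stop_pos < self.end_pos:
            raise ValueError("stop_pos must be < end_pos")
        if self.fate not in FATES:
            raise ValueError(f"unknown fate {self.fate!r}")


# ---------------------------------------------------------------------------
# Transcriptome generation
# ---------------------------------------------------------------------------

_NON_G = np.array(list("ACT"))
_BASES = np.array(list("ACGT"))


def _background(rng: np.random.Generator, n: int) -> np.ndarray:
    """Background sequence with G-runs capped below 2 (no GG anywhere), so
    the background can never satisfy any quadruplex/triplex class pattern."""
    out = np.empty(n, dtype="<U1")
    prev_g = True  # also forbid G at position 0 next to upstream motifs
    for i in range(n):
        if prev_g:
            base = _NON_G[rng.integers(0, 3)]
        else:
            base = _BASES[rng.integers(0, 4)]
        out[i] = base
        prev_g = base == "G"
    return out


def _loops(rng: np.random.Generator, n: int, lo: int, hi: int) -> list[str]:
    return [
        "".join(_NON_G[rng.integers(0, 3, rng.integers(lo, hi + 1))])
        for _ in range(n)
    ]


def _build_motif(klass: str, rng: np.random.Generator, tax: ClassTaxonomy) -> str:
    """Build one concrete motif instance of the requested class.

    Loop and bulge nucleotides are drawn from A/C/T so that the instance's
    class is unambiguous under the priority taxonomy.
    """
    g3 = "G" * tax.g_run_min
    lo, hi = tax.loop_min, tax.loop_max
    if klass == "canonical":
        loops = _loops(rng, 3, lo, hi)
        parts = [g3, loops[0], g3, loops[1], g3, loops[2], g3]
    elif klass == "long_loop":
        j = int(rng.integers(0, 3))
        loops = _loops(rng, 3, lo, hi)
        loops[j] = "".join(
            _NON_G[rng.integers(0, 3, rng.integers(tax.long_loop_min, tax.long_loop_max + 1))]
        )
        parts = [g3, loops[0], g3, loops[1], g3, loops[2], g3]
    elif klass == "bulge":
        j = int(rng.integers(0, 4))
        split = [(1, 2), (2, 1), (2, 2)][int(rng.integers(0, 3))]
        bulge = "".join(
            _NON_G[rng.integers(0, 3, rng.integers(tax.bulge_min, tax.bulge_max + 1))]
        )
        tracts = [g3] * 4
        tracts[j] = "G" * split[0] + bulge + "G" * split[1]
        loops = _loops(rng, 3, lo, hi)
        parts = [tracts[0], loops[0], tracts[1], loops[1], tracts[2], loops[2], tracts[3]]
    elif klass == "two_quartet":
        g2 = "G" * tax.two_quartet_g
        loops = _loops(rng, 3, lo, hi)
        parts = [g2, loops[0], g2, loops[1], g2, loops[2], g2]
    elif klass == "g_triplex":
        loops = _loops(rng, 2, lo, hi)
        parts = [g3, loops[0], g3, loops[1], g3]
    else:
        raise ValueError(f"unknown motif class {klass!r}")
    seq = "".join(parts)
    got = classify_window(seq, len(seq) - 1, tax)
    assert got is not None and got[0] == klass, (klass, seq, got)
    return seq


def generate_transcriptome(
    cfg: SimConfig, taxonomy: ClassTaxonomy = DEFAULT_TAXONOMY
) -> Transcriptome:
    """Generate a planted transcriptome satisfying ``cfg.motif_plan`` exactly.

    Deterministic under ``cfg.seed``.  Motifs are assigned to transcripts
    round-robin (after a seeded shuffle of the plan) and placed at random,
    pairwise separated by at least ``motif_min_gap`` nt and flanked by non-G
    bases so the planted span is exactly the maximal pattern match.

    Raises
    ------
    ValueError
        If the plan cannot be placed within the transcript lengths.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 101]))
    lo, hi = cfg.length_range
    lengths = rng.integers(lo, hi + 1, cfg.n_transcripts)
    abund = rng.lognormal(cfg.abundance_mu, cfg.abundance_sigma, cfg.n_transcripts)
    tpm = abund / abund.sum() * 1e6

    motifs = [k for k, n in sorted(cfg.motif_plan.items()) for _ in range(int(n))]
    rng.shuffle(motifs)

    # round-robin assignment keeps per-transcript motif counts feasible
    per_tx: list[list[str]] = [[] for _ in range(cfg.n_transcripts)]
    for i, k in enumerate(motifs):
        per_tx[i % cfg.n_transcripts].append(k)

    records: list[TranscriptRecord] = []
    planted: list[TruthMotif] = []
    for t in range(cfg.n_transcripts):
        tid = f"TX{t:04d}"
        n = int(lengths[t])
        seq = _background(rng, n)
        placed: list[tuple[int, int]] = []
        for klass in per_tx[t]:
            mseq = _build_motif(klass, rng, taxonomy)
            ok = False
            for _ in range(200):
                # keep 1-nt non-G flanks inside the transcript
                start = int(rng.integers(1, n - len(mseq) - 1))
                end = start + len(mseq)
                if all(
                    start - e >= cfg.motif_min_gap or s - end >= cfg.motif_min_gap
                    for s, e in placed
                ):
                    ok = True
                    break
            if not ok:
                raise ValueError(
                    f"motif plan infeasible: cannot place {klass!r} on {tid} "
                    f"(length {n}, {len(placed)} motifs already placed)"
                )
            seq[start:end] = list(mseq)
            # G-free flanks: a lone background G just upstream could seed a
            # bulged-tract match and extend the span beyond the planted motif
            for i in range(max(0, start - 12), start):
                if seq[i] == "G":
                    seq[i] = _NON_G[rng.integers(0, 3)]
            seq[end] = _NON_G[rng.integers(0, 3)]
            placed.append((start, end))
            planted.append(
                TruthMotif(
                    transcript_id=tid, start=start, end=end, klass=klass, sequence=mseq
                )
            )
        records.append(
            TranscriptRecord(
                transcript_id=tid,
                gene_id=f"GENE{t:04d}",
                sequence="".join(seq),
                tpm_true=float(tpm[t]),
            )
        )
    return Transcriptome(records=tuple(records), planted=tuple(planted))


# ---------------------------------------------------------------------------
# Library simulation
# ---------------------------------------------------------------------------


def _condition_code(condition: str) -> int:
    if condition == "K":
        return 1
    if condition == "Li":
        return 2
    raise ValueError(f"condition must be 'K' or 'Li', got {condition!r}")


def simulate_library(
    tx: Transcriptome,
    cfg: SimConfig,
    condition: str,
    replicate: int = 1,
) -> list[ReadRecord]:
    """Simulate one sequencing library of ``cfg.depth`` read pairs.

    The library is a finite pool of ``complexity_per_ng * input_ng`` unique
    cDNA molecules; each pool molecule receives a PCR weight of
    ``1 + Poisson(lambda)`` (``lambda = dup_lambda * pcr_cycles / 11``) and
    the sequencer draws ``depth`` reads multinomially over those weights.
    Reads of the same molecule share UMI and coordinates; saturation and
    duplicate fractions emerge from pool size versus depth.

    Molecule construction: a transcript is drawn proportional to
    ``tpm_true * length``, a fragment of ~N(frag_len_mean, frag_len_sd) nt is
    cut uniformly, and reverse transcription runs 3'->5' over the fragment.
    Under K+, each planted motif wholly contained in the fragment stalls RT
    with its class's ``theta_stop`` at motif 3' end + offset {0, +1}; under
    Li+ (and for non-stalled K+ fragments) only the background per-position
    stall rate ``epsilon_bg`` applies, else the read runs through to the
    fragment 5' end.  The molecule is accepted with probability proportional
    to the protocol's 5'-nucleotide bias weight at its stop position.
    """
    code = _condition_code(condition)
    if cfg.depth == 0:
        return []
    rng = np.random.default_rng(
        np.random.SeedSequence([cfg.seed, 211, code, int(replicate)])
    )
    weights_5p = cfg.resolved_abias()
    max_w = max(weights_5p.values())
    lam = cfg.dup_lambda * cfg.pcr_cycles / 11.0
    n_pool = max(1, int(round(cfg.complexity_per_ng * cfg.input_ng)))

    seqs = [r.sequence for r in tx.records]
    tids = [r.transcript_id for r in tx.records]
    tx_len = np.array([len(s) for s in seqs], dtype=float)
    w_tx = np.array([r.tpm_true for r in tx.records]) * tx_len
    w_tx = w_tx / w_tx.sum()
    motifs_by_tx: dict[int, list[TruthMotif]] = {}
    for m in tx.planted:
        motifs_by_tx.setdefault(tids.index(m.transcript_id), []).append(m)
    for ms in motifs_by_tx.values():
        ms.sort(key=lambda m: -m.end)  # RT meets the 3'-most motif first

    # per-replicate stochasticity of the structurally imperfect variant classes
    theta = dict(cfg.theta_stop)
    for k in _VARIANT_CLASSES:
        if k in theta and cfg.variant_theta_jitter > 0:
            jit = rng.normal(0.0, cfg.variant_theta_jitter)
            theta[k] = float(np.clip(theta[k] + jit, 0.0, 1.0))

    is_k = condition == "K"
    p0 = cfg.p0_p1[0]
    eps = cfg.epsilon_bg

    def make_molecule() -> tuple[int, int, int]:
        """Draw (tx_index, stop_pos, end_pos) for one accepted unique molecule."""
        while True:
            ti = int(rng.choice(len(seqs), p=w_tx))
            n = int(tx_len[ti])
            L = int(np.clip(rng.normal(cfg.frag_len_mean, cfg.frag_len_sd), 50, n))
            fs = int(rng.integers(0, n - L + 1))
            fe = fs + L
            stop = fs
            stalled = False
            if is_k:
                for m in motifs_by_tx.get(ti, ()):  # descending by end
                    if fs <= m.start and m.end <= fe and rng.random() < theta.get(m.klass, 0.0):
                        off = 0 if rng.random() < p0 else 1
                        cand = m.end - 1 + off
                        if cand < fe:
                            stop = cand
                            stalled = True
                        break
            if not stalled and eps > 0.0:
                # geometric scan from the fragment 3' end toward 5'
                k_fail = rng.geometric(eps)  # trials until first stall
                if k_fail <= L - 1:
                    stop = fe - k_fail
            base = seqs[ti][stop]
            if rng.random() < weights_5p.get(base, 0.0) / max_w:
                return ti, stop, fe

    umis = ["".join(_BASES[rng.integers(0, 4, cfg.umi_len)]) for _ in range(n_pool)]
    pool = [make_molecule() for _ in range(n_pool)]
    pcr_w = 1.0 + rng.poisson(lam, n_pool)
    counts = rng.multinomial(cfg.depth, pcr_w / pcr_w.sum())

    fate_names = list(cfg.fate_rates.keys())
    fate_p = np.array([cfg.fate_rates[f] for f in fate_names], dtype=float)
    p_usable = 1.0 - fate_p.sum()
    if p_usable < 0:
        raise ValueError("fate rates sum above 1")
    fate_choices = np.array(["usable", *fate_names])
    fate_probs = np.array([p_usable, *fate_p])

    reads: list[ReadRecord] = []
    lib = f"{condition}{replicate}"
    for j in range(n_pool):
        c = int(counts[j])
        if c == 0:
            continue
        ti, stop, fe = pool[j]
        mol_id = f"{lib}:M{j:06d}"
        for k in range(c):
            fate = str(fate_choices[rng.choice(len(fate_choices), p=fate_probs)])
            reads.append(
                ReadRecord(
                    read_id=f"{mol_id}.{k}",
                    transcript_id=tids[ti],
                    stop_pos=stop,
                    end_pos=fe,
                    umi=umis[j],
                    condition=condition,
                    replicate=int(replicate),
                    input_ng=cfg.input_ng,
                    fate=fate,
                    molecule_id=mol_id,
                    is_duplicate_of=None if k == 0 else mol_id,
                )
            )
    return reads


# ---------------------------------------------------------------------------
# Table and FASTQ emission
# ---------------------------------------------------------------------------


def reads_to_frame(reads: Sequence[ReadRecord]) -> pd.DataFrame:
    """The aligned-read table: the simulator's stand-in for trimmed, aligned
    reads (column order is part of the on-disk format)."""
    df = pd.DataFrame(
        [
            {
                "read_id": r.read_id,
                "transcript_id": r.transcript_id,
                "strand": "+",
                "stop_pos": r.stop_pos,
                "end_pos": r.end_pos,
                "umi": r.umi,
                "condition": r.condition,
                "replicate": r.replicate,
                "input_ng": r.input_ng,
                "fate": r.fate,
                "molecule_id": r.molecule_id,
                "is_duplicate_of": r.is_duplicate_of if r.is_duplicate_of else ".",
            }
            for r in reads
        ],
        columns=READ_TABLE_COLUMNS,
    )
    return df


def frame_to_reads(df: pd.DataFrame) -> list[ReadRecord]:
    return [
        ReadRecord(
            read_id=row.read_id,
            transcript_id=row.transcript_id,
            stop_pos=int(row.stop_pos),
            end_pos=int(row.end_pos),
            umi=row.umi,
            condition=row.condition,
            replicate=int(row.replicate),
            input_ng=float(row.input_ng),
            fate=row.fate,
            molecule_id=row.molecule_id,
            is_duplicate_of=None if row.is_duplicate_of == "." else row.is_duplicate_of,
        )
        for row in df.itertuples()
    ]


def write_reads_table(reads: Sequence[ReadRecord] | pd.DataFrame, path: str | Path) -> None:
    df = reads if isinstance(reads, pd.DataFrame) else reads_to_frame(reads)
    write_table(df, path)


def read_reads_table(path: str | Path) -> pd.DataFrame:
    from .io import read_table

    return read_table(path, dtype={"is_duplicate_of": str}, keep_default_na=False, na_values=[])


_COMP = str.maketrans("ACGTN", "TGCAN")


def reads_to_fastq(
    reads: Sequence[ReadRecord],
    tx: Transcriptome,
    cfg: SimConfig,
    r1_path: str | Path,
    r2_path: str | Path,
) -> None:
    """Write the paired FASTQ representation (Phred+33, fixed quality 'I').

    Mate 1 is the template-strand read: the UMI followed by transcript
    sequence from the stop position; mate 2 reads back from the fragment 3'
    end on the opposite strand.
    """
    seqs = tx.sequences()
    insert_len = cfg.read_len - cfg.umi_len
    r1, r2 = [], []
    for r in reads:
        s = seqs[r.transcript_id]
        fwd = s[r.stop_pos : min(r.stop_pos + insert_len, r.end_pos)]
        seq1 = r.umi + fwd
        start2 = max(r.end_pos - cfg.read_len, r.stop_pos)
        seq2 = s[start2 : r.end_pos][::-1].translate(_COMP)
        r1.append(FastqRead(r.read_id, seq1, "I" * len(seq1)))
        r2.append(FastqRead(r.read_id, seq2, "I" * len(seq2)))
    write_fastq(r1, r1_path)
    write_fastq(r2, r2_path)


def emit_truth(
    tx: Transcriptome,
    reads: Sequence[ReadRecord],
    bed_path: str | Path,
    lineage_path: str | Path,
) -> None:
    """Write ground truth: planted motifs as BED6 (name = class) and the
    per-read molecule lineage as TSV."""
    write_bed(
        [
            BedRecord(m.transcript_id, m.start, m.end, m.klass, 0.0, "+")
            for m in tx.planted
        ],
        bed_path,
    )
    lineage = pd.DataFrame(
        [
            {
                "read_id": r.read_id,
                "molecule_id": r.molecule_id,
                "is_duplicate_of": r.is_duplicate_of if r.is_duplicate_of else ".",
                "transcript_id": r.transcript_id,
                "stop_pos": r.stop_pos,
                "end_pos": r.end_pos,
                "umi": r.umi,
                "fate": r.fate,
            }
            for r in reads
        ],
        columns=[
            "read_id",
            "molecule_id",
            "is_duplicate_of",
            "transcript_id",
            "stop_pos",
            "end_pos",
            "umi",
            "fate",
        ],
    )
    write_table(lineage, lineage_path)
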