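"""UMI handling, duplicate collapse, yield accounting and depth subsampling.

Only a fraction of sequenced reads carries information usable for stall
detection: adapter-only reads are lost at trimming, unalignable and
multi-mapping reads at alignment, and PCR duplicates at UMI deduplication.
This module quantifies those losses stage by stage (the yield report), and
provides the uniform subsampling used to draw sequencing-saturation curves
(deduplicated molecule count as a function of depth).

Duplicate grouping is an exact match on the 4-tuple
(transcript, strand, stop position, UMI); no UMI-error tolerance is applied
because the simulator introduces none.  A 1-mismatch directional mode for
real data can be enabled via ``mismatch_tolerant=True``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io import FastqRead, read_fastq, write_fastq

__all__ = [
    "DEDUP_KEY",
    "STAGES",
    "YieldReport",
    "extract_umi",
    "extract_umi_fastq",
    "dedup",
    "subsample",
    "yield_report",
    "saturation_curve",
]

DEDUP_KEY = ["transcript_id", "strand", "stop_pos", "umi"]
STAGES = ("raw", "trimmed_usable", "uniquely_aligned", "deduplicated")


@dataclass(frozen=True)
class YieldReport:
    """Read counts and fraction-of-raw retained through the pipeline stages."""

    counts: dict[str, int]
    fractions: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": list(STAGES),
                "reads": [self.counts[s] for s in STAGES],
                "fraction_of_raw": [self.fractions[s] for s in STAGES],
            }
        )


# ---------------------------------------------------------------------------
# UMI extraction
# ---------------------------------------------------------------------------


def extract_umi(read: FastqRead, umi_len: int) -> tuple[str, FastqRead] | None:
    """Split the UMI off the 5' end of a mate-1 read.

    Returns ``(umi, trimmed_read)`` with the UMI appended to the read id
    after an underscore (the usual read-name annotation convention), or
    ``None`` if the read is too short to contain both UMI and insert.
    """
    if umi_len == 0:
        return "", read
    if len(read.sequence) <= umi_len:
        return None
    umi = read.sequence[:umi_len]
    return umi, FastqRead(
        read_id=f"{read.read_id}_{umi}",
        sequence=read.sequence[umi_len:],
        quality=read.quality[umi_len:],
    )


def extract_umi_fastq(
    r1_in: str | Path,
    r1_out: str | Path,
    umi_len: int,
) -> pd.DataFrame:
    """Extract UMIs from a mate-1 FASTQ file, writing trimmed reads.

    Returns a table of ``read_id``, ``umi`` and ``fate`` (``usable`` or
    ``too_short`` for discarded reads).
    """
    rows = []
    kept: list[FastqRead] = []
    for read in read_fastq(r1_in):
        res = extract_umi(read, umi_len)
        if res is None:
            rows.append({"read_id": read.read_id, "umi": ".", "fate": "too_short"})
            continue
        umi, trimmed = res
        kept.append(trimmed)
        rows.append({"read_id": read.read_id, "umi": umi, "fate": "usable"})
    write_fastq(kept, r1_out)
    return pd.DataFrame(rows, columns=["read_id", "umi", "fate"])


# ---------------------------------------------------------------------------
# Deduplication
# ---------------------------------------------------------------------------


def _directional_collapse(df: pd.DataFrame) -> pd.DataFrame:
    """1-mismatch directional UMI clustering within (transcript, strand, stop)
    groups, for real data with sequencing errors in UMIs."""
    out = []
    for _, grp in df.groupby(["transcript_id", "strand", "stop_pos"], sort=False):
        counts = grp.groupby("umi")["read_id"].count().sort_values(ascending=False)
        canonical: dict[str, str] = {}
        reps: list[str] = []
        for umi in counts.index:
            merged = False
            for rep in reps:
                if sum(a != b for a, b in zip(umi, rep)) == 1 and counts[rep] >= 2 * counts[umi] - 1:
                    canonical[umi] = rep
                    merged = True
                    break
            if not merged:
                reps.append(umi)
                canonical[umi] = umi
        g = grp.copy()
        g["umi"] = g["umi"].map(canonical)
        out.append(g)
    return pd.concat(out) if out else df


def dedup(
    reads: pd.DataFrame, mismatch_tolerant: bool = False
) -> tuple[pd.DataFrame, int]:
    """Collapse duplicate reads to one representative per dedup key.

    Reads must be usable (``fate == 'usable'``) and carry alignment
    coordinates and a UMI.  The representative of each
    (transcript, strand, stop, UMI) group is the read first in ``read_id``
    order (lexicographic).  Idempotent.

    Returns ``(unique_reads, n_duplicates_removed)``.

    Raises
    ------
    ValueError
        If any read lacks a UMI.
    """
    usable = reads[reads["fate"] == "usable"] if "fate" in reads.columns else reads
    if len(usable) == 0:
        return usable.copy(), 0
    if usable["umi"].isna().any() or (usable["umi"] == ".").any() or (usable["umi"] == "").any():
        raise ValueError("reads without UMI cannot be deduplicated")
    if mismatch_tolerant:
        usable = _directional_collapse(usable)
    unique = (
        usable.sort_values("read_id", kind="mergesort")
        .drop_duplicates(subset=DEDUP_KEY, keep="first")
        .sort_index()
    )
    return unique, len(usable) - len(unique)


# ---------------------------------------------------------------------------
# Subsampling
# ---------------------------------------------------------------------------


def subsample(reads: pd.DataFrame, target_depth: int, seed: int = 0) -> pd.DataFrame:
    """Uniform random subset of exactly ``target_depth`` reads, without
    replacement; if the target exceeds what is available the input is
    returned unchanged (no up-sampling).  Deterministic under ``seed``."""
    if target_depth < 0:
        raise ValueError("target_depth must be >= 0")
    n = len(reads)
    if target_depth >= n:
        return reads
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=target_depth, replace=False)
    return reads.iloc[np.sort(idx)]


# ---------------------------------------------------------------------------
# Yield accounting
# ---------------------------------------------------------------------------


def yield_report(reads: pd.DataFrame) -> YieldReport:
    """Stage-wise read yield from the fate flags of an aligned-read table.

    Stages: raw -> trimmed/usable (adapter-only reads lost) ->
    uniquely aligned (unalignable and multimapped lost) -> deduplicated.
    Counts are non-increasing by construction; fractions are of raw.
    """
    raw = len(reads)
    trimmed = reads[reads["fate"] != "adapter_only"]
    aligned = trimmed[~trimmed["fate"].isin(["unalignable", "multimapped"])]
    unique, _ = dedup(aligned)
    counts = {
        "raw": raw,
        "trimmed_usable": len(trimmed),
        "uniquely_aligned": len(aligned),
        "deduplicated": len(unique),
    }
    vals = [counts[s] for s in STAGES]
    if any(b > a for a, b in zip(vals, vals[1:])):
        raise ValueError("stage counts must be non-increasing")
    fractions = {s: (counts[s] / raw if raw else 0.0) for s in STAGES}
    return YieldReport(counts=counts, fractions=fractions)


# ---------------------------------------------------------------------------
# Saturation
# ---------------------------------------------------------------------------


def saturation_curve(
    reads: pd.DataFrame,
    fractions: Sequence[float] = tuple(np.arange(1, 11) / 10),
    seed: int = 0,
) -> pd.DataFrame:
    """Deduplicated molecule count as a function of subsampled raw depth.

    Raw reads are subsampled to each fraction of the library (default
    10%..100% in steps of 10%, mirroring depth titration at fixed
    multiples), then deduplicated.  Subsamples are nested — one seeded
    permutation, shallower depths are prefixes of deeper ones — so the
    curve is non-decreasing by construction, as with a real depth
    titration of one flowcell.  Returns a table with columns ``fraction``,
    ``depth`` and ``deduplicated``.
    """
    rows = []
    n = len(reads)
    order = np.random.default_rng(seed).permutation(n)
    for f in fractions:
        target = min(int(round(f * n)), n)
        sub = reads.iloc[np.sort(order[:target])]
        unique, _ = dedup(sub)
        rows.append({"fraction": f, "depth": target, "deduplicated": len(unique)})
    return pd.DataFrame(rows)
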