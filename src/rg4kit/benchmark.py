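"""Comparative analyses: reproducibility, coverage, nucleotide bias, input guidance.

These operations reproduce the evaluation layer of a stop-profiling study:

* intersection of RTS site lists between replicates or libraries, where two
  sites overlap when their spans are less than ``overlap_dist`` nt apart
  (strict, default < 5 nt);
* consensus (sites agreed across all replicate lists, anchored on the first
  list) and union (interval merge across libraries) site lists;
* ordinary least-squares regression of log10 site coverage between libraries
  (a slope near 1 with a small intercept means the libraries sample the same
  sites at proportional depth);
* 5'-nucleotide composition views that expose the protocol A-bias;
* the Alexander-Govern comparison of per-replicate A-fractions between
  protocols;
* TPM quantification from read counts, and the RNA-input guideline lookup
  keyed on post-enrichment parent-gene abundance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .calling import RTSSite

__all__ = [
    "BenchmarkConfig",
    "GuidelineTable",
    "DEFAULT_GUIDELINE",
    "intersect_sites",
    "consensus",
    "union",
    "coverage_regression",
    "nt_distributions",
    "compare_abias",
    "tpm_quantify",
    "recommend_input",
    "coverage_vs_tpm",
]


@dataclass(frozen=True)
class BenchmarkConfig:
    overlap_dist: int = 5  # sites agree when span distance < this (strict)
    subsample_grid: tuple[float, ...] = tuple(i / 10 for i in range(1, 11))

    def __post_init__(self) -> None:
        if self.overlap_dist < 1:
            raise ValueError("overlap_dist must be >= 1")


@dataclass(frozen=True)
class GuidelineTable:
    """Minimum post-enrichment RNA input by parent-gene abundance.

    The default bands: genes below 4 TPM are not recommended targets; 4-8 TPM
    needs at least 100 ng of post-enrichment RNA, 8-16 TPM at least 30 ng,
    and >= 16 TPM at least 10 ng.  Bands are half-open ``[lo, hi)`` so the
    printed shared endpoints (4-8, 8-16) resolve upward.
    """

    bands: tuple[tuple[float, float, float | None], ...] = (
        (0.0, 4.0, None),
        (4.0, 8.0, 100.0),
        (8.0, 16.0, 30.0),
        (16.0, float("inf"), 10.0),
    )

    def lookup(self, gene_tpm: float) -> float | None:
        if gene_tpm < 0:
            raise ValueError("TPM must be non-negative")
        for lo, hi, ng in self.bands:
            if lo <= gene_tpm < hi:
                return ng
        raise AssertionError("guideline bands must partition [0, inf)")


DEFAULT_GUIDELINE = GuidelineTable()


def recommend_input(
    gene_tpm: float, table: GuidelineTable = DEFAULT_GUIDELINE
) -> float | None:
    """Minimum RNA input (ng) for a target of the given parent-gene TPM;
    ``None`` means the target is not recommended (< 4 TPM post-enrichment)."""
    return table.lookup(gene_tpm)


# ---------------------------------------------------------------------------
# Site intersection / consensus / union
# ---------------------------------------------------------------------------


def _span_distance(a: RTSSite, b: RTSSite) -> int:
    """Minimum distance between two half-open spans; 0 if they overlap."""
    if a.transcript_id != b.transcript_id:
        raise ValueError("distance undefined across transcripts")
    return max(0, max(a.start - b.end, b.start - a.end))


def intersect_sites(
    A: Sequence[RTSSite],
    B: Sequence[RTSSite],
    cfg: BenchmarkConfig = BenchmarkConfig(),
) -> tuple[list[tuple[RTSSite, RTSSite]], list[RTSSite], list[RTSSite]]:
    """Pair up sites of two lists that lie within ``overlap_dist`` of each
    other (strict ``<``; span overlap counts as distance 0).

    Pairing is greedy nearest-first per transcript with each site used at
    most once.  Returns ``(agreed_pairs, only_A, only_B)``.
    """
    pairs: list[tuple[RTSSite, RTSSite]] = []
    used_a: set[int] = set()
    used_b: set[int] = set()
    by_tx_a: dict[str, list[int]] = {}
    by_tx_b: dict[str, list[int]] = {}
    for i, s in enumerate(A):
        by_tx_a.setdefault(s.transcript_id, []).append(i)
    for j, s in enumerate(B):
        by_tx_b.setdefault(s.transcript_id, []).append(j)
    for tid in sorted(set(by_tx_a) & set(by_tx_b)):
        cand = []
        for i in by_tx_a[tid]:
            for j in by_tx_b[tid]:
                d = _span_distance(A[i], B[j])
                if d < cfg.overlap_dist:
                    cand.append((d, A[i].start, B[j].start, i, j))
        for d, _, _, i, j in sorted(cand):
            if i not in used_a and j not in used_b:
                pairs.append((A[i], B[j]))
                used_a.add(i)
                used_b.add(j)
    only_a = [s for i, s in enumerate(A) if i not in used_a]
    only_b = [s for j, s in enumerate(B) if j not in used_b]
    return pairs, only_a, only_b


def consensus(
    site_lists: Sequence[Sequence[RTSSite]],
    cfg: BenchmarkConfig = BenchmarkConfig(),
) -> list[RTSSite]:
    """Sites of the first list that are agreed with by every other list.

    The first list is the basis (e.g. the highest-input library or the first
    replicate); iterative intersection against each further list keeps only
    basis sites rediscovered everywhere.
    """
    if not site_lists:
        raise ValueError("need at least one site list")
    base = list(site_lists[0])
    for other in site_lists[1:]:
        pairs, _, _ = intersect_sites(base, other, cfg)
        base = [a for a, _ in pairs]
    return base


def union(site_lists: Sequence[Sequence[RTSSite]]) -> list[RTSSite]:
    """Interval merge of all sites (same transcript, same strand) across
    libraries: overlapping or bookended spans coalesce by sweep."""
    all_sites = [s for lst in site_lists for s in lst]
    by_tx: dict[str, list[RTSSite]] = {}
    for s in all_sites:
        by_tx.setdefault(s.transcript_id, []).append(s)
    merged: list[RTSSite] = []
    for tid in sorted(by_tx):
        group = sorted(by_tx[tid], key=lambda s: (s.start, s.end))
        cur_start, cur_end = group[0].start, group[0].end
        members = [group[0]]

        def flush() -> None:
            merged.append(
                RTSSite(
                    transcript_id=tid,
                    start=cur_start,
                    end=cur_end,
                    positions=tuple(
                        sorted({p for m in members for p in m.positions})
                    ),
                    support_K=sum(m.support_K for m in members),
                    mean_cov=float(np.mean([m.mean_cov for m in members])),
                    score=max(m.score for m in members),
                )
            )

        for s in group[1:]:
            if s.start <= cur_end:  # overlap or bookended
                cur_end = max(cur_end, s.end)
                members.append(s)
            else:
                flush()
                cur_start, cur_end, members = s.start, s.end, [s]
        flush()
    return merged


# ---------------------------------------------------------------------------
# Coverage regression
# ---------------------------------------------------------------------------


def coverage_regression(
    pairs: Sequence[tuple[RTSSite, RTSSite]]
) -> tuple[float, float, float]:
    """OLS of log10(coverage in B) on log10(coverage in A) over agreed pairs.

    Returns ``(slope, intercept, r)``.  Coverage ratios between libraries of
    different input span orders of magnitude, so the fit lives in log space.

    Raises
    ------
    ValueError
        With fewer than 3 pairs, non-positive coverages, or degenerate
        (zero-variance) predictor.
    """
    if len(pairs) < 3:
        raise ValueError("need >= 3 agreed pairs for a regression")
    x = np.array([a.mean_cov for a, _ in pairs], dtype=float)
    y = np.array([b.mean_cov for _, b in pairs], dtype=float)
    if (x <= 0).any() or (y <= 0).any():
        raise ValueError("coverages must be positive for log regression")
    lx, ly = np.log10(x), np.log10(y)
    if np.ptp(lx) == 0:
        raise ValueError("degenerate predictor variance")
    import statsmodels.api as sm

    fit = sm.OLS(ly, sm.add_constant(lx)).fit()
    intercept, slope = fit.params
    r = float(np.corrcoef(lx, ly)[0, 1])
    return float(slope), float(intercept), r


# ---------------------------------------------------------------------------
# Nucleotide composition views
# ---------------------------------------------------------------------------


def _freqs(bases: Iterable[str]) -> dict[str, float]:
    s = pd.Series(list(bases))
    if len(s) == 0:
        return {b: 0.0 for b in "ACGT"}
    counts = s.value_counts()
    total = counts.sum()
    return {b: float(counts.get(b, 0)) / total for b in "ACGT"}


def nt_distributions(
    dedup_reads: pd.DataFrame,
    called_positions: pd.DataFrame,
    sequences: Mapping[str, str],
) -> dict[str, dict[str, float]]:
    """Three 5'-nucleotide composition views of a K+/Li+ library pair.

    ``read_5p``
        the transcript base under the 5' end (= RT stop) of every
        deduplicated template-strand read — the global protocol bias;
    ``rts_supporting_read_5p``
        the same, restricted to K+ reads whose 5' end falls on a called
        RT-stalled position — G-biased when stalls are quadruplex-driven;
    ``stalled_positions``
        the base at each called position, summarised as G vs non-G and the
        A/C/T shares within non-G.
    """
    base_at = lambda row: sequences[row.transcript_id][int(row.stop_pos)]
    read_bases = [base_at(r) for r in dedup_reads.itertuples()]
    view1 = _freqs(read_bases)

    called = called_positions[called_positions["called"]]
    called_set = {
        (r.transcript_id, int(r.pos)) for r in called.itertuples()
    }
    k_reads = dedup_reads[dedup_reads["condition"] == "K"]
    support_bases = [
        base_at(r)
        for r in k_reads.itertuples()
        if (r.transcript_id, int(r.stop_pos)) in called_set
    ]
    view2 = _freqs(support_bases)

    pos_bases = [
        sequences[r.transcript_id][int(r.pos)] for r in called.itertuples()
    ]
    pf = _freqs(pos_bases)
    non_g = pf["A"] + pf["C"] + pf["T"]
    view3 = {
        "G": pf["G"],
        "non_G": non_g,
        "A_of_non_G": pf["A"] / non_g if non_g else 0.0,
        "C_of_non_G": pf["C"] / non_g if non_g else 0.0,
        "T_of_non_G": pf["T"] / non_g if non_g else 0.0,
    }
    return {
        "read_5p": view1,
        "rts_supporting_read_5p": view2,
        "stalled_positions": view3,
    }


def compare_abias(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Alexander-Govern comparison of per-replicate A-fractions between two
    protocols/libraries.  Returns ``(statistic, p)``.

    Raises
    ------
    ValueError
        With fewer than 2 values per group or zero within-group variance.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need >= 2 values per group")
    if np.var(a) == 0 or np.var(b) == 0:
        raise ValueError("zero within-group variance")
    res = stats.alexandergovern(a, b)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Abundance
# ---------------------------------------------------------------------------


def tpm_quantify(
    counts: Mapping[str, int],
    lengths: Mapping[str, int],
    gene_of: Mapping[str, str] | None = None,
) -> tuple[pd.Series, pd.Series]:
    """Transcripts-per-million from read counts and transcript lengths.

    TPM_t = (c_t / l_t) / sum_j (c_j / l_j) * 1e6; gene abundances are sums
    of their transcripts' TPM.  All-zero counts yield all-zero TPM.
    """
    tids = sorted(lengths)
    length = np.array([lengths[t] for t in tids], dtype=float)
    if (length <= 0).any():
        raise ValueError("transcript lengths must be positive")
    c = np.array([counts.get(t, 0) for t in tids], dtype=float)
    rate = c / length
    denom = rate.sum()
    tpm = rate / denom * 1e6 if denom > 0 else np.zeros_like(rate)
    tpm_t = pd.Series(tpm, index=pd.Index(tids, name="transcript_id"), name="tpm")
    if gene_of is None:
        gene_of = {t: t for t in tids}
    genes = pd.Series({t: gene_of.get(t, t) for t in tids}, name="gene_id")
    tpm_g = tpm_t.groupby(genes).sum()
    tpm_g.index.name = "gene_id"
    return tpm_t, tpm_g


def coverage_vs_tpm(
    sites: Sequence[RTSSite],
    gene_tpm: Mapping[str, float],
    gene_of: Mapping[str, str],
) -> pd.DataFrame:
    """Per-site (mean coverage, parent-gene TPM) pairs.

    Sites whose transcript has no gene mapping or whose gene has no
    abundance are flagged ``unmapped`` and excluded from numeric summaries.
    """
    rows = []
    for s in sites:
        gid = gene_of.get(s.transcript_id)
        mapped = gid is not None and gid in gene_tpm
        rows.append(
            {
                "transcript_id": s.transcript_id,
                "start": s.start,
                "end": s.end,
                "mean_cov": s.mean_cov,
                "gene_id": gid if gid is not None else ".",
                "gene_tpm": float(gene_tpm[gid]) if mapped else np.nan,
                "unmapped": not mapped,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "start", "end", "mean_cov", "gene_id",
            "gene_tpm", "unmapped",
        ],
    )
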