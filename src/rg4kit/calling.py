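"""Calling RT-stalled positions and RTS sites from paired K+/Li+ libraries.

The statistical core of the pipeline.  Reverse transcription over a folded
quadruplex terminates prematurely under K+ (which stabilises the structure)
but reads through under Li+, so a transcript position harbouring a quadruplex
shows an excess of template-strand read 5' ends in the K+ library relative to
the Li+ control.  For every position with adequate K+ coverage the
stop/read-through contrast

    [stops_K, cov_K - stops_K; stops_Li, cov_Li - stops_Li]

is tested one-sided (K+ stop rate greater) with an exact conditional 2x2
test, p-values are Benjamini-Hochberg adjusted across all tested positions,
and positions passing the FDR level with the empirical rate in the right
direction are declared RT-stalled.  Adjacent stalled positions (a quadruplex
typically stalls at its 3'-most G and/or the +1 flank) are merged into RTS
sites; singletons form 1-nt sites.

The :class:`RTSModel` / :class:`RTSResults` pair is the primary interface:
build the model from deduplicated reads (or prebuilt stop profiles), ``fit``
it, and read the per-position table, the merged sites and ``summary()`` off
the results.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import BedRecord

__all__ = [
    "StopProfile",
    "CallerConfig",
    "RTSSite",
    "RTSModel",
    "RTSResults",
    "build_stop_profile",
    "build_stop_profiles",
    "test_position",
    "call_stalled_positions",
    "merge_positions",
    "sites_to_bed",
]


@dataclass
class StopProfile:
    """Per-position stop and coverage arrays for one transcript.

    ``stops_c[i]`` counts deduplicated template-strand reads whose 5' base is
    at i; ``cov_c[i]`` counts reads whose [stop, end) span contains i.
    """

    transcript_id: str
    stops_K: np.ndarray
    cov_K: np.ndarray
    stops_Li: np.ndarray
    cov_Li: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.stops_K)
        if not (len(self.cov_K) == len(self.stops_Li) == len(self.cov_Li) == n):
            raise ValueError("profile arrays must share the transcript length")
        if (self.stops_K > self.cov_K).any() or (self.stops_Li > self.cov_Li).any():
            raise ValueError("stops cannot exceed coverage")

    def __len__(self) -> int:
        return len(self.stops_K)


@dataclass(frozen=True)
class CallerConfig:
    """Caller parameters.

    min_cov
        Minimum K+ coverage for a position to be tested; encodes the
        detection limit of the assay (reliable calling needs roughly >=16x
        local coverage).
    alpha
        FDR level for the Benjamini-Hochberg adjustment.
    merge_gap
        Maximum coordinate gap (nt) between stalled positions merged into one
        site; 1 joins the typical 0/+1 stall pair.
    test
        Name of the two-sample count test ("fisher" is the one-sided exact
        conditional test; "barnard" and "boschloo" are exact unconditional
        alternatives).
    """

    min_cov: int = 16
    alpha: float = 0.05
    merge_gap: int = 1
    test: str = "fisher"

    def __post_init__(self) -> None:
        if self.min_cov < 1:
            raise ValueError("min_cov must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.test not in _TESTS:
            raise ValueError(f"unknown test {self.test!r}; choose from {sorted(_TESTS)}")


@dataclass(frozen=True)
class RTSSite:
    """A merged run of RT-stalled positions."""

    transcript_id: str
    start: int  # 0-based half-open span of the merged positions
    end: int
    positions: tuple[int, ...]
    support_K: int  # stalled-position-supporting K+ reads (sum of stops)
    mean_cov: float  # mean K+ coverage over the span
    score: float  # -log10 of the smallest adjusted p among positions
    replicate: int | None = None

    def __post_init__(self) -> None:
        if self.end - self.start < 1:
            raise ValueError("site span must cover at least one position")


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------


def build_stop_profile(
    reads: pd.DataFrame, transcript_id: str, length: int, condition: str
) -> tuple[np.ndarray, np.ndarray]:
    """Stop and coverage arrays for one transcript and condition.

    Reads must be deduplicated, usable and template-strand.  Coverage is
    computed by interval stabbing over [stop_pos, end_pos) with a difference
    array.
    """
    sel = reads[
        (reads["transcript_id"] == transcript_id) & (reads["condition"] == condition)
    ]
    if len(sel) and (
        (sel["stop_pos"].min() < 0) or (sel["end_pos"].max() > length)
    ):
        raise ValueError(f"reads outside transcript bounds for {transcript_id!r}")
    stops = np.zeros(length, dtype=np.int64)
    cov = np.zeros(length + 1, dtype=np.int64)
    if len(sel):
        np.add.at(stops, sel["stop_pos"].to_numpy(), 1)
        np.add.at(cov, sel["stop_pos"].to_numpy(), 1)
        np.add.at(cov, sel["end_pos"].to_numpy(), -1)
    return stops, np.cumsum(cov[:-1])


def build_stop_profiles(
    reads: pd.DataFrame, lengths: Mapping[str, int]
) -> dict[str, StopProfile]:
    """Profiles for every transcript in ``lengths`` from a deduplicated
    K+/Li+ read table.

    Raises
    ------
    KeyError
        If reads reference a transcript absent from ``lengths``.
    """
    unknown = set(reads["transcript_id"]) - set(lengths)
    if unknown:
        raise KeyError(f"reads on unknown transcripts: {sorted(unknown)[:5]}")
    profiles = {}
    for tid, n in lengths.items():
        sK, cK = build_stop_profile(reads, tid, n, "K")
        sLi, cLi = build_stop_profile(reads, tid, n, "Li")
        profiles[tid] = StopProfile(tid, sK, cK, sLi, cLi)
    return profiles


# ---------------------------------------------------------------------------
# Per-position test
# ---------------------------------------------------------------------------


def _fisher(sK: int, nK: int, sLi: int, nLi: int) -> float:
    table = [[sK, nK - sK], [sLi, nLi - sLi]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def _barnard(sK: int, nK: int, sLi: int, nLi: int) -> float:
    table = [[sK, nK - sK], [sLi, nLi - sLi]]
    return float(stats.barnard_exact(table, alternative="greater").pvalue)


def _boschloo(sK: int, nK: int, sLi: int, nLi: int) -> float:
    table = [[sK, nK - sK], [sLi, nLi - sLi]]
    return float(stats.boschloo_exact(table, alternative="greater").pvalue)


_TESTS: dict[str, Callable[[int, int, int, int], float]] = {
    "fisher": _fisher,
    "barnard": _barnard,
    "boschloo": _boschloo,
}


def test_position(sK: int, nK: int, sLi: int, nLi: int, test: str = "fisher") -> float:
    """One-sided p-value for H1: the K+ stop rate exceeds the Li+ stop rate.

    The default is the exact conditional (Fisher) test on the 2x2 table
    ``[[sK, nK-sK], [sLi, nLi-sLi]]``.

    Raises
    ------
    ValueError
        On inconsistent counts or zero coverage in either condition
        (positions without coverage are not testable).
    """
    if sK > nK or sLi > nLi or min(sK, sLi) < 0:
        raise ValueError("need 0 <= stops <= coverage in both conditions")
    if nK == 0 or nLi == 0:
        raise ValueError("zero coverage: position not testable")
    return _TESTS[test](sK, nK, sLi, nLi)


# ---------------------------------------------------------------------------
# Calling and merging
# ---------------------------------------------------------------------------


def call_stalled_positions(
    profiles: Mapping[str, StopProfile], cfg: CallerConfig = CallerConfig()
) -> pd.DataFrame:
    """Test every position with ``cov_K >= min_cov`` and BH-adjust across the
    whole run.

    Returns the per-position table with columns ``transcript_id``, ``pos``,
    ``stops_K``, ``cov_K``, ``stops_Li``, ``cov_Li``, ``p``, ``p_adj`` and
    ``called`` (adjusted p <= alpha and empirical K+ rate strictly above the
    Li+ rate).  Positions with zero Li+ coverage are skipped and flagged in
    ``skipped_zero_li`` rows (``p`` = NaN, never called).
    """
    rows = []
    test_fn = _TESTS[cfg.test]
    for tid in sorted(profiles):
        pr = profiles[tid]
        candidates = np.flatnonzero(pr.cov_K >= cfg.min_cov)
        for i in candidates:
            nK, sK = int(pr.cov_K[i]), int(pr.stops_K[i])
            nLi, sLi = int(pr.cov_Li[i]), int(pr.stops_Li[i])
            if nLi == 0:
                rows.append(
                    dict(
                        transcript_id=tid, pos=int(i), stops_K=sK, cov_K=nK,
                        stops_Li=sLi, cov_Li=nLi, p=np.nan, testable=False,
                    )
                )
                continue
            rows.append(
                dict(
                    transcript_id=tid, pos=int(i), stops_K=sK, cov_K=nK,
                    stops_Li=sLi, cov_Li=nLi, p=test_fn(sK, nK, sLi, nLi),
                    testable=True,
                )
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "pos", "stops_K", "cov_K", "stops_Li", "cov_Li",
            "p", "testable",
        ],
    )
    df["p_adj"] = np.nan
    df["called"] = False
    tested = df["testable"].to_numpy(dtype=bool)
    if tested.any():
        padj = multipletests(df.loc[tested, "p"], method="fdr_bh")[1]
        df.loc[tested, "p_adj"] = padj
        rate_K = df["stops_K"] / df["cov_K"]
        rate_Li = df["stops_Li"] / df["cov_Li"].replace(0, np.nan)
        df["called"] = (
            tested & (df["p_adj"] <= cfg.alpha) & (rate_K > rate_Li)
        ).fillna(False)
    return df


def merge_positions(
    positions: pd.DataFrame, cfg: CallerConfig = CallerConfig(), replicate: int | None = None
) -> list[RTSSite]:
    """Merge called stalled positions into RTS sites.

    Positions on one transcript whose coordinate difference is at most
    ``merge_gap`` join one site; singletons become 1-nt sites.  ``positions``
    is the table from :func:`call_stalled_positions` (only ``called`` rows
    are used).
    """
    sites: list[RTSSite] = []
    called = positions[positions["called"]]
    for tid, grp in called.groupby("transcript_id", sort=True):
        grp = grp.sort_values("pos")
        run: list[pd.Series] = []
        for _, row in grp.iterrows():
            if run and row["pos"] - run[-1]["pos"] > cfg.merge_gap:
                sites.append(_make_site(tid, run, replicate))
                run = []
            run.append(row)
        if run:
            sites.append(_make_site(tid, run, replicate))
    return sites


def _make_site(tid: str, run: list[pd.Series], replicate: int | None) -> RTSSite:
    pos = [int(r["pos"]) for r in run]
    return RTSSite(
        transcript_id=tid,
        start=pos[0],
        end=pos[-1] + 1,
        positions=tuple(pos),
        support_K=int(sum(r["stops_K"] for r in run)),
        mean_cov=float(np.mean([r["cov_K"] for r in run])),
        score=float(-np.log10(max(min(r["p_adj"] for r in run), 1e-300))),
        replicate=replicate,
    )


def sites_to_bed(sites: Iterable[RTSSite]) -> list[BedRecord]:
    """RTS sites as BED6 records, score = -log10 adjusted p."""
    return [
        BedRecord(
            chrom=s.transcript_id,
            start=s.start,
            end=s.end,
            name=f"RTS:{s.transcript_id}:{s.start}",
            score=round(s.score, 4),
            strand="+",
        )
        for s in sites
    ]


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


class RTSModel:
    """Differential RT-stop model for one K+/Li+ library pair.

    Parameters
    ----------
    profiles : mapping of transcript id -> StopProfile
        Per-transcript stop/coverage arrays for both conditions.
    config : CallerConfig
        Coverage gate, FDR level, merge gap and test choice.

    Use :meth:`from_reads` to build the profiles directly from a deduplicated
    aligned-read table.
    """

    def __init__(
        self, profiles: Mapping[str, StopProfile], config: CallerConfig = CallerConfig()
    ):
        self.profiles = dict(profiles)
        self.config = config

    @classmethod
    def from_reads(
        cls,
        reads: pd.DataFrame,
        lengths: Mapping[str, int],
        config: CallerConfig = CallerConfig(),
    ) -> "RTSModel":
        return cls(build_stop_profiles(reads, lengths), config)

    def fit(self, replicate: int | None = None) -> "RTSResults":
        """Run the per-position tests, BH adjustment and site merging."""
        table = call_stalled_positions(self.profiles, self.config)
        sites = merge_positions(table, self.config, replicate=replicate)
        return RTSResults(model=self, positions=table, sites=sites)


@dataclass
class RTSResults:
    """Fit results: the per-position test table and the merged RTS sites."""

    model: RTSModel
    positions: pd.DataFrame
    sites: list[RTSSite]

    @property
    def called_positions(self) -> pd.DataFrame:
        return self.positions[self.positions["called"]]

    @property
    def n_tested(self) -> int:
        return int(self.positions["testable"].sum())

    def sites_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "transcript_id": s.transcript_id,
                    "start": s.start,
                    "end": s.end,
                    "n_positions": len(s.positions),
                    "support_K": s.support_K,
                    "mean_cov": s.mean_cov,
                    "score": s.score,
                }
                for s in self.sites
            ],
            columns=[
                "transcript_id", "start", "end", "n_positions", "support_K",
                "mean_cov", "score",
            ],
        )

    def summary(self) -> str:
        cfg = self.model.config
        n_called = int(self.positions["called"].sum())
        lines = [
            "Differential RT-stop results (K+ vs Li+)",
            "=" * 44,
            f"test: one-sided {cfg.test} 2x2, BH FDR alpha={cfg.alpha}",
            f"coverage gate (K+): >= {cfg.min_cov}x   merge gap: {cfg.merge_gap} nt",
            f"transcripts profiled:    {len(self.model.profiles):7d}",
            f"positions tested:        {self.n_tested:7d}",
            f"RT-stalled positions:    {n_called:7d}",
            f"merged RTS sites:        {len(self.sites):7d}",
        ]
        if self.sites:
            widths = [s.end - s.start for s in self.sites]
            covs = [s.mean_cov for s in self.sites]
            lines += [
                f"mean site width (nt):    {np.mean(widths):10.2f}",
                f"median site coverage:    {np.median(covs):10.1f}",
            ]
        return "\n".join(lines)
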