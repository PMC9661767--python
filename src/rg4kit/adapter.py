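"""In-silico model of the 5' deoxyuridine (dU) adapter chemistry.

The library-preparation strategy modelled here replaces the hairpin 5' adapter
of earlier stop-profiling protocols with a single-stranded DNA adapter carrying
a deoxyuridine. After ligation to the cDNA, a USER II treatment creates an
abasic site at the dU and nicks the backbone, splitting the adapter portion off
the ligated product so that no gel purification is needed before PCR.

Three operations are modelled:

* :func:`cleave_at_du` — backbone scission immediately 5' of each dU
  (length-conserving nick; the dU stays on the 3' fragment),
* :func:`ligate` — single-stranded ligation of an upstream oligo with a free
  3'-OH to a downstream oligo carrying a 5' phosphate,
* :func:`gel_metrics` — the five densitometry ratios used to quantify
  cleavage, ligation efficiency, ligated-product reduction, column recovery
  and cleaved-adapter removal from gel band intensities.

Oligos are exchanged as FASTA where a dU is written as lowercase ``u`` in
place of ``T``; internally dU positions are kept as a 1-based position list.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

__all__ = [
    "Oligo",
    "GelBands",
    "GelMetrics",
    "NonCleavableError",
    "LigationError",
    "GelMetricError",
    "cleave_at_du",
    "ligate",
    "gel_metrics",
    "default_du_adapter",
    "n40_22_mimic",
    "read_oligos_fasta",
    "write_oligos_fasta",
]

_DNA = set("ACGTN")


class NonCleavableError(ValueError):
    """Substrate carries no dU and cannot be cleaved by USER II."""


class LigationError(ValueError):
    """Partners are not ligation-competent (3' block or missing 5' phosphate)."""


class GelMetricError(ValueError):
    """A metric's denominator is zero; the ratio is undefined."""


@dataclass(frozen=True)
class Oligo:
    """A DNA oligonucleotide with marked dU positions and end chemistry.

    Parameters
    ----------
    name : str
        Identifier, carried through cleavage/ligation with suffixes.
    sequence : str
        5'->3' DNA sequence over A/C/G/T/N.  A dU position holds the base
        ``T`` in the sequence; deoxyuridine identity lives in
        ``du_positions``.
    du_positions : tuple of int
        1-based positions (from the 5' end) carrying deoxyuridine.
    has_5p_phosphate : bool
        True if the 5' end is phosphorylated (required of the downstream
        ligation partner).
    has_3p_block : bool
        True if the 3' end carries a C3 spacer; a blocked oligo cannot serve
        as the upstream ligation partner (this is what prevents adapter
        self-oligomerisation).
    """

    name: str
    sequence: str
    du_positions: tuple[int, ...] = ()
    has_5p_phosphate: bool = False
    has_3p_block: bool = False

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _DNA
        if bad:
            raise ValueError(f"non-DNA characters in {self.name!r}: {sorted(bad)}")
        dus = tuple(sorted(set(int(p) for p in self.du_positions)))
        object.__setattr__(self, "du_positions", dus)
        for p in dus:
            if not 1 <= p <= len(seq):
                raise ValueError(
                    f"dU position {p} outside [1, {len(seq)}] in {self.name!r}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


def cleave_at_du(oligo: Oligo) -> list[Oligo]:
    """Cleave the backbone immediately 5' of every dU.

    A substrate with *k* dU positions yields ``k + 1`` fragments whose lengths
    sum to the substrate length (the nick model conserves nucleotides; the dU
    is retained at the 5' end of the 3'-side fragment).  The 44-nt adapter
    with its dU at position 24 therefore yields 23-nt and 21-nt fragments,
    and the 106-nt ligated product (dU at global position 86) yields 85-nt
    and 21-nt fragments.

    Raises
    ------
    NonCleavableError
        If the substrate carries no dU.
    """
    if not oligo.du_positions:
        raise NonCleavableError(f"{oligo.name!r} has no dU position to cleave")
    # cut points in 0-based string coordinates: 5' of each dU
    cuts = [p - 1 for p in oligo.du_positions]
    bounds = [0, *cuts, len(oligo)]
    fragments: list[Oligo] = []
    for i, (a, b) in enumerate(zip(bounds[:-1], bounds[1:])):
        dus = tuple(p - a for p in oligo.du_positions if a < p <= b)
        fragments.append(
            Oligo(
                name=f"{oligo.name}/frag{i + 1}",
                sequence=oligo.sequence[a:b],
                du_positions=dus,
                # the native 5' end keeps its phosphorylation state; new 5'
                # ends from USER scission are not ligation-competent here
                has_5p_phosphate=oligo.has_5p_phosphate if i == 0 else False,
                has_3p_block=oligo.has_3p_block if b == len(oligo) else False,
            )
        )
    assert sum(len(f) for f in fragments) == len(oligo)
    return fragments


def ligate(upstream: Oligo, downstream: Oligo) -> Oligo:
    """Single-stranded ligation of ``upstream`` (3'-OH) to ``downstream`` (5'-P).

    The product is the concatenated sequence with the downstream dU positions
    shifted by the upstream length.  Orientation follows the chemistry: the
    incoming cDNA provides the free 3'-OH, the dU adapter provides the 5'
    phosphate, so the adapter ends up 3' of the cDNA in the ligated product.

    An empty upstream is the identity (nothing to join).

    Raises
    ------
    LigationError
        If ``upstream`` is 3'-blocked (C3 spacer) or ``downstream`` lacks the
        5' phosphate.
    """
    if len(upstream) == 0:
        return downstream
    if upstream.has_3p_block:
        raise LigationError(
            f"upstream {upstream.name!r} is 3'-blocked (C3 spacer) and cannot ligate"
        )
    if not downstream.has_5p_phosphate:
        raise LigationError(
            f"downstream {downstream.name!r} lacks a 5' phosphate"
        )
    shift = len(upstream)
    return Oligo(
        name=f"{upstream.name}+{downstream.name}",
        sequence=upstream.sequence + downstream.sequence,
        du_positions=tuple(upstream.du_positions)
        + tuple(p + shift for p in downstream.du_positions),
        has_5p_phosphate=upstream.has_5p_phosphate,
        has_3p_block=downstream.has_3p_block,
    )


@dataclass(frozen=True)
class GelBands:
    """Background-corrected band intensities (arbitrary units).

    Band roles:

    A
        uncleaved adapter
    B
        cleaved adapter
    C
        cDNA-mimic template band
    D
        ligated product without USER II treatment
    E
        ligated product after USER II treatment
    F / G
        106-nt mimic without / with column purification
    H / I
        cleaved adapters before / after column purification

    Bands not relevant to a given experiment may be left ``None``; the
    corresponding metrics are then skipped.
    """

    A: float | None = None
    B: float | None = None
    C: float | None = None
    D: float | None = None
    E: float | None = None
    F: float | None = None
    G: float | None = None
    H: float | None = None
    I: float | None = None

    def __post_init__(self) -> None:
        for k in "ABCDEFGHI":
            v = getattr(self, k)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"band {k} must be a finite non-negative intensity")


@dataclass(frozen=True)
class GelMetrics:
    """The five densitometry percentages, each in [0, 100] (or None if not computed).

    ``clipped`` names metrics whose raw ratio fell outside [0, 100] because of
    noisy band intensities (e.g. E > D) and was clipped; the formulas assume
    ideal densitometry.
    """

    cleavage_rate: float | None = None
    ligation_efficiency: float | None = None
    reduction_rate: float | None = None
    recovery_rate: float | None = None
    removal_rate: float | None = None
    clipped: frozenset[str] = field(default_factory=frozenset)

    def as_dict(self) -> dict[str, float | None]:
        return {
            "cleavage_rate": self.cleavage_rate,
            "ligation_efficiency": self.ligation_efficiency,
            "reduction_rate": self.reduction_rate,
            "recovery_rate": self.recovery_rate,
            "removal_rate": self.removal_rate,
        }


def _ratio(name: str, num: float, den: float, clipped: set[str]) -> float:
    if den == 0:
        raise GelMetricError(f"{name}: zero denominator")
    val = num / den * 100.0
    if val < 0.0 or val > 100.0:
        clipped.add(name)
        val = min(max(val, 0.0), 100.0)
    return val


def gel_metrics(bands: GelBands) -> GelMetrics:
    """Evaluate the five gel-quantification ratios from band intensities.

    cleavage rate            = B / (A + B) * 100
    ligation efficiency      = D / (C + D) * 100
    reduction of ligated     = (1 - E / D) * 100
    column recovery          = G / F * 100
    cleaved-adapter removal  = (1 - I / H) * 100

    A metric is computed only when all of its bands are present.  Values that
    fall outside [0, 100] through measurement noise are clipped and flagged.

    Raises
    ------
    GelMetricError
        If a requested metric has a zero denominator.
    """
    clipped: set[str] = set()
    vals: dict[str, float | None] = {}

    def have(*keys: str) -> bool:
        return all(getattr(bands, k) is not None for k in keys)

    vals["cleavage_rate"] = (
        _ratio("cleavage_rate", bands.B, bands.A + bands.B, clipped)
        if have("A", "B")
        else None
    )
    vals["ligation_efficiency"] = (
        _ratio("ligation_efficiency", bands.D, bands.C + bands.D, clipped)
        if have("C", "D")
        else None
    )
    vals["reduction_rate"] = (
        _ratio("reduction_rate", bands.D - bands.E, bands.D, clipped)
        if have("D", "E")
        else None
    )
    vals["recovery_rate"] = (
        _ratio("recovery_rate", bands.G, bands.F, clipped) if have("F", "G") else None
    )
    vals["removal_rate"] = (
        _ratio("removal_rate", bands.H - bands.I, bands.H, clipped)
        if have("H", "I")
        else None
    )
    return GelMetrics(**vals, clipped=frozenset(clipped))


# ---------------------------------------------------------------------------
# Reference constructs
# ---------------------------------------------------------------------------

# Representative sequences: the real oligos' exact sequences are proprietary
# catalogue items; only their architecture (lengths, dU placement, end
# chemistry, N-regions) matters to the arithmetic modelled here.
_ADAPTER_5P = "ACACGACGCTCTTCCGATCTNNNNNNNNNNAGATCGGAAGAGCG"  # 44 nt, T at 24
_THREE_PRIME_ADAPTER = "TGGAATTCTCGGGTGCCAAGGC"  # 22 nt


def default_du_adapter() -> Oligo:
    """The 44-nt 5' dU adapter: dU at the 24th nucleotide from the 5' end,
    5'-phosphorylated, 3'-blocked with a C3 spacer."""
    assert len(_ADAPTER_5P) == 44 and _ADAPTER_5P[23] in "TN"
    seq = _ADAPTER_5P[:23] + "T" + _ADAPTER_5P[24:]
    return Oligo(
        name="5p_dU_adapter",
        sequence=seq,
        du_positions=(24,),
        has_5p_phosphate=True,
        has_3p_block=True,
    )


def n40_22_mimic(rng=None) -> Oligo:
    """The 62-nt cDNA mimic: 40 randomised nucleotides followed by the 22-nt
    3'-adapter sequence; free 3'-OH, no phosphate, no dU."""
    if rng is None:
        n40 = "N" * 40
    else:
        import numpy as np

        n40 = "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, 40)])
    return Oligo(name="N40+22", sequence=n40 + _THREE_PRIME_ADAPTER)


# ---------------------------------------------------------------------------
# FASTA I/O (dU written as lowercase "u")
# ---------------------------------------------------------------------------


def write_oligos_fasta(oligos: Iterable[Oligo], path: str | Path) -> None:
    """Write oligos as FASTA, encoding each dU as lowercase ``u`` and the end
    chemistry as ``[5P]`` / ``[3C3]`` tokens in the description."""
    path = Path(path)
    with path.open("w") as fh:
        for o in oligos:
            chars = list(o.sequence)
            for p in o.du_positions:
                chars[p - 1] = "u"
            tags = []
            if o.has_5p_phosphate:
                tags.append("[5P]")
            if o.has_3p_block:
                tags.append("[3C3]")
            header = " ".join([o.name, *tags])
            fh.write(f">{header}\n{''.join(chars)}\n")


def read_oligos_fasta(path: str | Path) -> list[Oligo]:
    """Read oligos from FASTA written by :func:`write_oligos_fasta`.

    Lowercase ``u`` (or ``U``) marks a dU and is stored as base ``T`` plus a
    1-based position entry.
    """
    from Bio import SeqIO

    oligos = []
    for rec in SeqIO.parse(str(path), "fasta"):
        raw = str(rec.seq)
        dus = tuple(i + 1 for i, c in enumerate(raw) if c in "uU")
        seq = "".join("T" if c in "uU" else c for c in raw)
        desc = rec.description
        oligos.append(
            Oligo(
                name=rec.id,
                sequence=seq,
                du_positions=dus,
                has_5p_phosphate="[5P]" in desc,
                has_3p_block="[3C3]" in desc,
            )
        )
    return oligos
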