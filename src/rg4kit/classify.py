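"""Structural classification of putative quadruplex sequences (PQS).

An RTS site marks where reverse transcription stalled; whether the stall was
caused by an RNA G-quadruplex is decided by inspecting the sequence
immediately 5' of the stall.  A quadruplex leaves its 3'-most G at the stall
position (offset 0) or one nucleotide upstream of it (the stall then sits on
the +1 flanking base), so classification anchors a pattern search at those two
offsets and scans a fixed window upstream.

The class taxonomy (tried in priority order, first match wins):

``canonical``
    four G-tracts of >=3 Gs, all loops 1-7 nt.
``long_loop``
    four G>=3 tracts, exactly one loop of 8-12 nt, the others 1-7 nt.
``bulge``
    four G-tracts where exactly one tract is interrupted by a 1-7 nt non-G
    bulge (the bulged tract still contributes >=3 Gs in total).
``two_quartet``
    four G-tracts of >=2 Gs, loops 1-7 nt (a two-quartet stack).
``g_triplex``
    three G>=3 tracts, loops 1-7 nt (a G-triplex intermediate).
``others``
    none of the above — the stall site does not meet the minimum sequence
    requirement for a quadruplex or triplex and is treated as a false
    positive detection.

For reporting, classes are grouped as canonical / non-canonical (long-loop
and bulged) / variant (two-quartet and G-triplex) / Others; the grouping map
is configuration, not biology, and can be overridden.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping

if TYPE_CHECKING:  # pragma: no cover
    from .calling import RTSSite
    from .simulate import Transcriptome

__all__ = [
    "ClassTaxonomy",
    "MotifCall",
    "DEFAULT_TAXONOMY",
    "classify_site",
    "classify_window",
    "flank_distribution",
    "scan_transcriptome",
    "scan_sequence",
]

CLASS_ORDER = ("canonical", "long_loop", "bulge", "two_quartet", "g_triplex")

DEFAULT_GROUPING: dict[str, str] = {
    "canonical": "canonical",
    "long_loop": "non-canonical",
    "bulge": "non-canonical",
    "two_quartet": "variant",
    "g_triplex": "variant",
    "others": "Others",
}


@dataclass(frozen=True)
class ClassTaxonomy:
    """Parameters of the PQS class patterns.

    All patterns are anchored so that their 3'-most G coincides with the
    search anchor.  ``window`` is how far upstream of the anchor the pattern
    may begin; ``anchor_offsets`` are the stall-position offsets tried
    (0 = stall on the 3'-most G, 1 = stall on the +1 flank).
    """

    g_run_min: int = 3
    two_quartet_g: int = 2
    loop_min: int = 1
    loop_max: int = 7
    long_loop_min: int = 8
    long_loop_max: int = 12
    bulge_min: int = 1
    bulge_max: int = 7
    window: int = 50
    anchor_offsets: tuple[int, ...] = (0, 1)
    grouping: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_GROUPING)
    )

    def group_of(self, cls: str) -> str:
        return self.grouping.get(cls, "Others")

    # --- compiled, end-anchored patterns -----------------------------------

    def _loop(self) -> str:
        return f"[ACGT]{{{self.loop_min},{self.loop_max}}}"

    def _long(self) -> str:
        return f"[ACGT]{{{self.long_loop_min},{self.long_loop_max}}}"

    def patterns(self) -> dict[str, re.Pattern[str]]:
        """Compile one end-anchored regex per class, in priority order."""
        g3 = f"G{{{self.g_run_min},}}"
        g2 = f"G{{{self.two_quartet_g},}}"
        loop, long_ = self._loop(), self._long()
        canonical = f"{g3}({loop}{g3}){{3}}"
        # exactly one long loop, at loop 1, 2 or 3
        long_loop = "|".join(
            g3
            + "".join(
                (long_ if i == j else loop) + g3 for i in range(3)
            )
            for j in range(3)
        )
        # one tract interrupted by a 1-7 nt non-G bulge; bulged tract keeps
        # >=3 Gs total (split 1+2, 2+1 or 2+2); other three tracts are intact
        bulge_tract = (
            f"(?:G{{2}}[ACT]{{{self.bulge_min},{self.bulge_max}}}G{{1,}}"
            f"|G{{1}}[ACT]{{{self.bulge_min},{self.bulge_max}}}G{{2,}})"
        )
        bulge = "|".join(
            "".join(
                (bulge_tract if i == j else g3) + (loop if i < 3 else "")
                for i in range(4)
            )
            for j in range(4)
        )
        two_quartet = f"{g2}({loop}{g2}){{3}}"
        g_triplex = f"{g3}({loop}{g3}){{2}}"
        return {
            "canonical": re.compile(f"(?:{canonical})$"),
            "long_loop": re.compile(f"(?:{long_loop})$"),
            "bulge": re.compile(f"(?:{bulge})$"),
            "two_quartet": re.compile(f"(?:{two_quartet})$"),
            "g_triplex": re.compile(f"(?:{g_triplex})$"),
        }


DEFAULT_TAXONOMY = ClassTaxonomy()


@dataclass(frozen=True)
class MotifCall:
    """Class assignment for one RTS site (or one scan anchor)."""

    transcript_id: str
    site_start: int
    site_end: int
    klass: str
    motif_start: int | None
    motif_end: int | None
    motif_sequence: str | None
    flank3: str | None  # base at motif position +1, None at transcript 3' end
    anchor_offset: int | None

    @property
    def group(self) -> str:
        return DEFAULT_GROUPING.get(self.klass, "Others")


def classify_window(
    sequence: str, anchor: int, taxonomy: ClassTaxonomy = DEFAULT_TAXONOMY
) -> tuple[str, int, int] | None:
    """Find the highest-priority class whose pattern ends exactly at ``anchor``.

    ``anchor`` is the 0-based index of the candidate 3'-most G.  Returns
    ``(class, motif_start, motif_end)`` with 0-based half-open coordinates,
    or None if no class matches.
    """
    if anchor < 0 or anchor >= len(sequence):
        return None
    if sequence[anchor] != "G":
        return None
    lo = max(0, anchor - taxonomy.window + 1)
    window = sequence[lo : anchor + 1]
    for cls, pat in taxonomy.patterns().items():
        m = pat.search(window)
        if m:
            return cls, lo + m.start(), anchor + 1
    return None


def classify_site(
    site: "RTSSite",
    sequence: str,
    taxonomy: ClassTaxonomy = DEFAULT_TAXONOMY,
) -> MotifCall:
    """Assign an rG4 structural class to a merged RTS site.

    For each anchor offset (0, then +1) the candidate motif 3' end is
    ``site.start - offset`` and the window upstream of it is searched for the
    highest-priority class pattern ending there.  The first success wins;
    with no success the site is labelled ``others`` (false positive).
    """
    for off in taxonomy.anchor_offsets:
        anchor = site.start - off
        hit = classify_window(sequence, anchor, taxonomy)
        if hit is not None:
            cls, mstart, mend = hit
            flank = sequence[mend] if mend < len(sequence) else None
            return MotifCall(
                transcript_id=site.transcript_id,
                site_start=site.start,
                site_end=site.end,
                klass=cls,
                motif_start=mstart,
                motif_end=mend,
                motif_sequence=sequence[mstart:mend],
                flank3=flank,
                anchor_offset=off,
            )
    return MotifCall(
        transcript_id=site.transcript_id,
        site_start=site.start,
        site_end=site.end,
        klass="others",
        motif_start=None,
        motif_end=None,
        motif_sequence=None,
        flank3=None,
        anchor_offset=None,
    )


def flank_distribution(calls: Iterable[MotifCall]) -> dict[str, int]:
    """Count the +1 flanking nucleotide over A/T/C/G across motif calls.

    Calls whose motif ends at the transcript 3' end (no flank) are skipped.
    """
    counts = {"A": 0, "C": 0, "G": 0, "T": 0}
    for c in calls:
        if c.flank3 in counts:
            counts[c.flank3] += 1
    return counts


def scan_sequence(
    sequence: str, taxonomy: ClassTaxonomy = DEFAULT_TAXONOMY
) -> list[tuple[str, int, int]]:
    """Exhaustively scan a sequence for class matches at every anchor.

    Returns ``(class, start, end)`` tuples for every position at which some
    class pattern ends, keeping only anchors that are not strictly inside a
    match already reported for the same or a higher-priority class 3' end
    (i.e. maximal matches per anchor).
    """
    out = []
    for i, base in enumerate(sequence):
        if base != "G":
            continue
        # only report anchors that end a G-run (maximal 3' end)
        if i + 1 < len(sequence) and sequence[i + 1] == "G":
            continue
        hit = classify_window(sequence, i, taxonomy)
        if hit is not None:
            out.append(hit)
    return out


def scan_transcriptome(
    tx: "Transcriptome", taxonomy: ClassTaxonomy = DEFAULT_TAXONOMY
) -> list[MotifCall]:
    """Scan every transcript for maximal class matches (simulator validation,
    union lists)."""
    calls = []
    for rec in tx.records:
        for cls, start, end in scan_sequence(rec.sequence, taxonomy):
            flank = rec.sequence[end] if end < len(rec.sequence) else None
            calls.append(
                MotifCall(
                    transcript_id=rec.transcript_id,
                    site_start=end - 1,
                    site_end=end,
                    klass=cls,
                    motif_start=start,
                    motif_end=end,
                    motif_sequence=rec.sequence[start:end],
                    flank3=flank,
                    anchor_offset=0,
                )
            )
    return calls
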