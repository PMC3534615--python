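"""Classification and filtering of paired-end ligation products.

Each mate of a sequenced pair engages one extremity of a restriction
fragment: a forward-strand mate reads toward the fragment's high-coordinate
(``+``) boundary, a reverse-strand mate toward its low-coordinate (``-``)
boundary.  The extremity pattern of a mate pair diagnoses the ligation
product: a self-circularized fragment joins its ``-`` to its ``+``
extremity, religation of two adjacent fragments joins the upstream ``+`` to
the downstream ``-`` (restoring the original sequence), while a loop over
two contiguous fragments joins the upstream ``-`` to the downstream ``+``.
Everything else is a long-range contact, the signal of interest.

Event classes
-------------
self_loop        one fragment circularized on itself
religation       adjacent fragments rejoined in original orientation
adjacent_loop    two contiguous fragments circularized together
long_range_intra non-adjacent same-chromosome contact
long_range_inter different-chromosome contact
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .restriction import MINUS, PLUS, FragmentTable

EVENT_CLASSES = (
    "self_loop",
    "religation",
    "adjacent_loop",
    "long_range_intra",
    "long_range_inter",
)

#: acceptable distances (bp) from read 5' start to the engaged RE1 cut,
#: per experimental condition (A/B differ in DNA concentration at ligation)
CONDITION_WINDOWS = {"A": (20, 21, 22), "B": (21, 22, 23)}

DEFAULT_MAPQ_MIN = 30


def mapq_from_error(p_error: float) -> int:
    """Phred-scaled mapping quality Q = -10*log10(p) for alignment error p."""
    if not 0.0 < p_error <= 1.0:
        raise ValueError("p_error must be in (0, 1]")
    return round(-10.0 * math.log10(p_error))


@dataclass(frozen=True)
class ReadMate:
    chrom: str
    pos: int  # 0-based 5' coordinate
    strand: str
    mapq: int


@dataclass(frozen=True)
class EndAssignment:
    fragment_id: int
    extremity: str
    dist_re1: int
    gc: float
    d_circle: int  # -1 when the fragment has no RE2 site


@dataclass(frozen=True)
class LigationEvent:
    end_a: EndAssignment
    end_b: EndAssignment
    event_class: str
    orientation: str
    genomic_distance: int  # bp between fragment midpoints; -1 for inter
    circle_length: int  # d_A + d_B; -1 when either arm undefined


class UnassignedError(ValueError):
    """Mate position falls outside every fragment."""


def assign_end(mate: ReadMate, frags: FragmentTable) -> EndAssignment:
    """Map a mate to the fragment extremity it engages.

    The engaged extremity is the fragment boundary in the mate's 3'
    direction; ``dist_re1`` is the distance from the 5' start to that
    boundary's cut site (expected ~20 bp by protocol design).
    """
    fid = frags.locate(mate.chrom, mate.pos)
    if fid < 0:
        raise UnassignedError(f"{mate.chrom}:{mate.pos} outside all fragments")
    if mate.strand == PLUS:
        extremity = PLUS
        dist = int(frags.col("end")[fid]) - mate.pos
        gc = float(frags.col("end_gc_plus")[fid])
        d = int(frags.col("d_plus")[fid])
    elif mate.strand == MINUS:
        extremity = MINUS
        dist = mate.pos - int(frags.col("start")[fid])
        gc = float(frags.col("end_gc_minus")[fid])
        d = int(frags.col("d_minus")[fid])
    else:
        raise ValueError(f"bad strand {mate.strand!r}")
    return EndAssignment(fid, extremity, dist, gc, d)


def classify_event(
    end_a: EndAssignment, end_b: EndAssignment, frags: FragmentTable
) -> LigationEvent:
    """Classify a pair of end assignments into one of the five event classes.

    Total over assigned pairs and invariant under swapping the mates: the
    orientation string always lists the lower-coordinate fragment first.
    """
    a, b = end_a, end_b
    # order by fragment coordinate, then '-' extremity before '+'
    def _key(e: EndAssignment) -> tuple[int, int]:
        return (e.fragment_id, 0 if e.extremity == MINUS else 1)

    if _key(b) < _key(a):
        a, b = b, a
    chrom = frags.col("chrom")
    same_chrom = chrom[a.fragment_id] == chrom[b.fragment_id]
    orientation = f"{a.extremity}/{b.extremity}"

    if a.fragment_id == b.fragment_id:
        cls = "self_loop"
    elif not same_chrom:
        cls = "long_range_inter"
    elif frags.adjacent(a.fragment_id, b.fragment_id):
        if orientation == "+/-":
            cls = "religation"
        elif orientation == "-/+":
            cls = "adjacent_loop"
        else:
            cls = "long_range_intra"
    else:
        cls = "long_range_intra"

    if same_chrom:
        starts, ends = frags.col("start"), frags.col("end")
        mid_a = (int(starts[a.fragment_id]) + int(ends[a.fragment_id])) // 2
        mid_b = (int(starts[b.fragment_id]) + int(ends[b.fragment_id])) // 2
        d_g = abs(mid_b - mid_a)
    else:
        d_g = -1
    if a.d_circle >= 0 and b.d_circle >= 0:
        circle = a.d_circle + b.d_circle
    else:
        circle = -1
    return LigationEvent(a, b, cls, orientation, d_g, circle)


@dataclass
class EventSummary:
    """Per-class counts of classified pairs and per-filter removal tallies."""

    class_counts: dict[str, int] = field(default_factory=lambda: dict.fromkeys(EVENT_CLASSES, 0))
    removed: dict[str, int] = field(
        default_factory=lambda: {
            "malformed": 0,
            "unassigned": 0,
            "mapq": 0,
            "dist_re1": 0,
            "re2_invalid": 0,
            "byproduct_class": 0,
        }
    )
    n_input: int = 0
    n_kept: int = 0

    @property
    def class_fractions(self) -> dict[str, float]:
        tot = sum(self.class_counts.values())
        if tot == 0:
            return dict.fromkeys(EVENT_CLASSES, 0.0)
        return {k: v / tot for k, v in self.class_counts.items()}

    def to_json(self, path: str | Path) -> None:
        payload = {
            "n_input": self.n_input,
            "n_kept": self.n_kept,
            "class_counts": self.class_counts,
            "class_fractions": self.class_fractions,
            "removed": self.removed,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_pairs_tsv(path: str | Path) -> Iterator[tuple[ReadMate, ReadMate]]:
    """Stream an 8-column pairs TSV: chrom1 pos1 strand1 mapq1 chrom2 pos2 strand2 mapq2.

    Lines starting with '#' are headers/comments.  Malformed rows yield None
    placeholders so the caller can tally them.
    """
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            try:
                m1 = ReadMate(parts[0], int(parts[1]), parts[2], int(parts[3]))
                m2 = ReadMate(parts[4], int(parts[5]), parts[6], int(parts[7]))
            except (IndexError, ValueError):
                yield None  # type: ignore[misc]
                continue
            yield m1, m2


def read_pairs_sam(path: str | Path) -> Iterator[tuple[ReadMate, ReadMate]]:
    """Extract mate pairs from a name-grouped SAM/BAM of paired alignments."""
    import pysam

    with pysam.AlignmentFile(str(path), check_sq=False) as sam:
        pending: dict[str, "pysam.AlignedSegment"] = {}
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            mate = pending.pop(rec.query_name, None)
            if mate is None:
                pending[rec.query_name] = rec
                continue
            yield tuple(
                ReadMate(
                    r.reference_name,
                    r.reference_end - 1 if r.is_reverse else r.reference_start,
                    MINUS if r.is_reverse else PLUS,
                    r.mapping_quality,
                )
                for r in (mate, rec)
            )


def _extremity_valid(frags: FragmentTable, end: EndAssignment) -> bool:
    col = "valid_minus" if end.extremity == MINUS else "valid_plus"
    return bool(frags.col(col)[end.fragment_id])


def filter_events(
    pairs: Iterable[tuple[ReadMate, ReadMate] | None],
    frags: FragmentTable,
    condition: str = "A",
    mapq_min: int = DEFAULT_MAPQ_MIN,
) -> tuple[list[LigationEvent], EventSummary]:
    """Run the full read-level filter cascade and classify what survives.

    Filters, in order, both mates each time:

    1. mapping quality >= ``mapq_min``;
    2. distance from read start to the engaged RE1 cut inside the
       condition's window (A: 20-22 bp, B: 21-23 bp);
    3. engaged extremity RE2-valid (site present, >= 20 bp from the cut);
    4. byproduct classes (self_loop, religation, adjacent_loop) dropped.

    Classification happens between (2) and (4) so the summary reports the
    class mixture of everything classifiable, mirroring the event census
    taken before byproduct removal.
    """
    if condition not in CONDITION_WINDOWS:
        raise ValueError(f"condition must be one of {set(CONDITION_WINDOWS)}")
    window = CONDITION_WINDOWS[condition]
    summary = EventSummary()
    kept: list[LigationEvent] = []
    for pair in pairs:
        summary.n_input += 1
        if pair is None:
            summary.removed["malformed"] += 1
            continue
        m1, m2 = pair
        if m1.mapq < mapq_min or m2.mapq < mapq_min:
            summary.removed["mapq"] += 1
            continue
        try:
            e1 = assign_end(m1, frags)
            e2 = assign_end(m2, frags)
        except UnassignedError:
            summary.removed["unassigned"] += 1
            continue
        if e1.dist_re1 not in window or e2.dist_re1 not in window:
            summary.removed["dist_re1"] += 1
            continue
        event = classify_event(e1, e2, frags)
        summary.class_counts[event.event_class] += 1
        if not (_extremity_valid(frags, e1) and _extremity_valid(frags, e2)):
            summary.removed["re2_invalid"] += 1
            continue
        if event.event_class in ("self_loop", "religation", "adjacent_loop"):
            summary.removed["byproduct_class"] += 1
            continue
        kept.append(event)
    summary.n_kept = len(kept)
    return kept, summary


def events_to_frame(events: Iterable[LigationEvent]) -> pd.DataFrame:
    rows = [
        (
            ev.end_a.fragment_id, ev.end_a.extremity, ev.end_a.dist_re1, ev.end_a.gc,
            ev.end_b.fragment_id, ev.end_b.extremity, ev.end_b.dist_re1, ev.end_b.gc,
            ev.event_class, ev.orientation, ev.genomic_distance, ev.circle_length,
        )
        for ev in events
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "frag_a", "extremity_a", "dist_re1_a", "gc_a",
            "frag_b", "extremity_b", "dist_re1_b", "gc_b",
            "event_class", "orientation", "genomic_distance", "circle_length",
        ],
    )


def build_contact_matrix(
    events: Iterable[LigationEvent], frags: FragmentTable, scope: str = "all"
):
    """Accumulate filtered events into a symmetric fragment x fragment count matrix.

    ``scope`` restricts to intra- or inter-chromosomal pairs; the two are
    normalized separately downstream.  Events touching fragments absent from
    the table are skipped and tallied.
    """
    from .normalize import ContactMatrix

    if scope not in ("intra", "inter", "all"):
        raise ValueError("scope must be intra, inter or all")
    n = len(frags)
    values = np.zeros((n, n))
    chrom = frags.df["chrom"].to_numpy()
    skipped = 0
    for ev in events:
        i, j = ev.end_a.fragment_id, ev.end_b.fragment_id
        if not (0 <= i < n and 0 <= j < n):
            skipped += 1
            continue
        same = chrom[i] == chrom[j]
        if scope == "intra" and not same:
            continue
        if scope == "inter" and same:
            continue
        values[i, j] += 1
        if i != j:
            values[j, i] += 1
    return ContactMatrix(
        values,
        index=frags.df["fragment_id"].to_numpy().copy(),
        scope=scope,
        metadata={"skipped_events": skipped},
    )
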