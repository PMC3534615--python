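"""Restriction-fragment map of a genome for a primary (RE1) and secondary (RE2) enzyme.

A genomic 3C library is anchored on the fragments produced by the primary
6-cutter (RE1, e.g. HindIII).  Each restriction fragment (RF) has two
extremities: the high-coordinate one is labelled ``+`` and the low-coordinate
one ``-``.  The secondary 4-cutter (RE2, e.g. MspI) re-digests ligation
products, so an extremity can only appear in the library if the fragment
carries an RE2 site at a workable distance from the RE1 cut.  This module
builds the fragment table and annotates everything downstream analysis needs:
RE2 sites, circularization arm lengths, end GC content and a mappability flag.

Coordinates are 0-based half-open (BED semantics) throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

MINUS = "-"
PLUS = "+"

#: distance (bp) below which an RE2 site is too close to the RE1 cut to
#: support re-circularization, so the extremity is unusable
DEFAULT_MIN_GAP = 20

#: flank width (bp) used for end GC content and for the mappability scan
DEFAULT_FLANK = 20


class NoRE2Error(ValueError):
    """Raised when a circle arm length is requested on a fragment without RE2 site."""


def n_possible_pairs(n_sites: int) -> int:
    """Size of the interaction universe: distinct unordered site pairs n(n-1)/2.

    For a genome cut ~830,000 times this exceeds 340 billion, which is why
    large-genome contact maps are binned before normalization.
    """
    if n_sites < 0:
        raise ValueError("site count must be nonnegative")
    return n_sites * (n_sites - 1) // 2


@dataclass
class FragmentTable:
    """Restriction fragments of a genome, one row per fragment.

    ``df`` columns: chrom, start, end, fragment_id, length, n_re2,
    end_gc_minus, end_gc_plus, mappable, valid_minus, valid_plus,
    d_minus, d_plus (circle arm lengths; -1 when no RE2 site).

    ``re2`` maps fragment_id to the sorted absolute coordinates of RE2
    sites inside the fragment.
    """

    df: pd.DataFrame
    re2: dict[int, np.ndarray] = field(default_factory=dict)
    re1_motif: str = ""
    re2_motif: str = ""

    def __post_init__(self) -> None:
        self._col_cache: dict[str, np.ndarray] = {}
        self._chrom_bounds: dict[str, tuple[int, int]] = {}
        self._boundaries: dict[str, np.ndarray] = {}
        for chrom, sub in self.df.groupby("chrom", sort=False):
            lo = int(sub["fragment_id"].iloc[0])
            hi = int(sub["fragment_id"].iloc[-1])
            self._chrom_bounds[chrom] = (lo, hi)
            self._boundaries[chrom] = np.append(
                sub["start"].to_numpy(), sub["end"].iloc[-1]
            )

    def __len__(self) -> int:
        return len(self.df)

    def col(self, name: str) -> np.ndarray:
        """Cached numpy view of a table column (hot path for per-read lookups)."""
        if name not in self._col_cache:
            self._col_cache[name] = self.df[name].to_numpy()
        return self._col_cache[name]

    @property
    def chroms(self) -> list[str]:
        return list(self._chrom_bounds)

    def locate(self, chrom: str, pos: int) -> int:
        """Fragment id containing ``pos``, or -1 when outside every fragment."""
        if chrom not in self._boundaries:
            return -1
        bounds = self._boundaries[chrom]
        if not (bounds[0] <= pos < bounds[-1]):
            return -1
        idx = int(np.searchsorted(bounds, pos, side="right")) - 1
        return self._chrom_bounds[chrom][0] + idx

    def locate_many(self, chroms: np.ndarray, pos: np.ndarray) -> np.ndarray:
        out = np.full(len(pos), -1, dtype=np.int64)
        for chrom in np.unique(chroms):
            m = chroms == chrom
            if str(chrom) not in self._boundaries:
                continue
            bounds = self._boundaries[str(chrom)]
            p = pos[m]
            idx = np.searchsorted(bounds, p, side="right") - 1
            ok = (p >= bounds[0]) & (p < bounds[-1])
            res = np.where(ok, self._chrom_bounds[str(chrom)][0] + idx, -1)
            out[m] = res
        return out

    def adjacent(self, i: int, j: int) -> bool:
        """True when fragments i and j are consecutive on the same chromosome."""
        if abs(i - j) != 1:
            return False
        ci = self.df["chrom"].iat[i]
        cj = self.df["chrom"].iat[j]
        return ci == cj

    def to_tsv(self, path: str | Path) -> None:
        cols = [
            "chrom", "start", "end", "fragment_id", "length", "n_re2",
            "end_gc_minus", "end_gc_plus", "mappable", "valid_minus", "valid_plus",
        ]
        self.df[cols].to_csv(path, sep="\t", index=False)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a (multi-record) FASTA into an ordered name -> uppercase sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def _find_motif(seq: str, motif: str) -> np.ndarray:
    """Start coordinates of every (possibly overlapping) motif occurrence."""
    hits = []
    i = seq.find(motif)
    while i != -1:
        hits.append(i)
        i = seq.find(motif, i + 1)
    return np.asarray(hits, dtype=np.int64)


def _check_motif(motif: str) -> None:
    if not motif or any(b not in "ACGT" for b in motif):
        raise ValueError(f"motif must be plain uppercase ACGT, got {motif!r}")


def digest_genome(
    sequences: Mapping[str, str], re1_motif: str, cut_offset: int = 1
) -> FragmentTable:
    """In-silico digest: cut every chromosome at each RE1 site.

    The cut coordinate is ``occurrence_start + cut_offset`` (default 1,
    matching HindIII A^AGCTT).  Fragments tile each chromosome: the first
    starts at 0 and the last ends at the chromosome length.  A chromosome
    without any site yields a single whole-chromosome fragment.
    """
    _check_motif(re1_motif)
    if not 0 <= cut_offset <= len(re1_motif):
        raise ValueError("cut_offset must lie within the motif")
    rows = []
    fid = 0
    for chrom, seq in sequences.items():
        if len(seq) == 0:
            raise ValueError(f"chromosome {chrom!r} is empty")
        cuts = _find_motif(seq, re1_motif) + cut_offset
        cuts = cuts[(cuts > 0) & (cuts < len(seq))]
        bounds = np.concatenate(([0], cuts, [len(seq)]))
        bounds = np.unique(bounds)
        for s, e in zip(bounds[:-1], bounds[1:]):
            rows.append((chrom, int(s), int(e), fid, int(e - s)))
            fid += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "fragment_id", "length"])
    df["n_re2"] = 0
    df["end_gc_minus"] = np.nan
    df["end_gc_plus"] = np.nan
    df["mappable"] = True
    df["valid_minus"] = False
    df["valid_plus"] = False
    df["d_minus"] = -1
    df["d_plus"] = -1
    return FragmentTable(df, re1_motif=re1_motif)


def annotate_re2(
    frags: FragmentTable,
    sequences: Mapping[str, str],
    re2_motif: str,
    min_gap: int = DEFAULT_MIN_GAP,
    cut_offset: int = 1,
) -> FragmentTable:
    """Locate RE2 sites inside each fragment and flag usable extremities.

    An extremity is valid when a same-fragment RE2 cut lies at least
    ``min_gap`` bp away from the RE1 boundary at that extremity; fragment
    level validity is the OR of the two.  Circle arm lengths (distance from
    each RE1 boundary to the nearest RE2 cut) are stored alongside.
    """
    _check_motif(re2_motif)
    if re2_motif == frags.re1_motif:
        raise ValueError("RE2 motif equals RE1 motif: degenerate protocol")
    df = frags.df
    re2_map: dict[int, np.ndarray] = {}
    n_re2 = np.zeros(len(df), dtype=np.int64)
    valid_minus = np.zeros(len(df), dtype=bool)
    valid_plus = np.zeros(len(df), dtype=bool)
    d_minus = np.full(len(df), -1, dtype=np.int64)
    d_plus = np.full(len(df), -1, dtype=np.int64)

    for chrom, sub in df.groupby("chrom", sort=False):
        seq = sequences[chrom]
        sites = _find_motif(seq, re2_motif) + cut_offset
        for row in sub.itertuples():
            inside = sites[(sites >= row.start) & (sites < row.end)]
            fid = row.fragment_id
            re2_map[fid] = inside
            n_re2[fid] = len(inside)
            if len(inside):
                d_minus[fid] = int(inside[0] - row.start)
                d_plus[fid] = int(row.end - inside[-1])
                valid_minus[fid] = d_minus[fid] >= min_gap
                valid_plus[fid] = d_plus[fid] >= min_gap
    df = df.copy()
    df["n_re2"] = n_re2
    df["valid_minus"] = valid_minus
    df["valid_plus"] = valid_plus
    df["d_minus"] = d_minus
    df["d_plus"] = d_plus
    out = FragmentTable(df, re2=re2_map, re1_motif=frags.re1_motif, re2_motif=re2_motif)
    out.df["end_gc_minus"] = frags.df["end_gc_minus"]
    out.df["end_gc_plus"] = frags.df["end_gc_plus"]
    out.df["mappable"] = frags.df["mappable"]
    return out


def gc_fraction(flank: str) -> float:
    """Fraction of G/C in a flank; non-ACGT characters count as non-GC."""
    if not flank:
        return 0.0
    gc = sum(1 for b in flank if b in "GC")
    if all(b == "N" for b in flank):
        logger.warning("all-N flank encountered; GC set to 0")
        return 0.0
    return gc / len(flank)


def end_gc(
    frags: FragmentTable, sequences: Mapping[str, str], flank: int = DEFAULT_FLANK
) -> FragmentTable:
    """GC fraction of the ``flank`` bp immediately interior to each extremity.

    This is the sequence a read engaging that extremity would cover; the
    flank is truncated for fragments shorter than ``flank``.
    """
    df = frags.df.copy()
    gcm = np.empty(len(df))
    gcp = np.empty(len(df))
    for row in df.itertuples():
        seq = sequences[row.chrom]
        w = min(flank, row.length)
        gcm[row.fragment_id] = gc_fraction(seq[row.start : row.start + w])
        gcp[row.fragment_id] = gc_fraction(seq[row.end - w : row.end])
    df["end_gc_minus"] = gcm
    df["end_gc_plus"] = gcp
    return FragmentTable(
        df, re2=frags.re2, re1_motif=frags.re1_motif, re2_motif=frags.re2_motif
    )


def annotate_mappability(
    frags: FragmentTable, sequences: Mapping[str, str], flank: int = DEFAULT_FLANK
) -> FragmentTable:
    """Flag fragments whose both end flanks occur more than once in the genome.

    Exact duplication of the ``flank`` bp end sequence is used as the
    ambiguity criterion; a fragment is unmappable when both extremities are
    ambiguous, mirroring the removal of repeat-embedded (subtelomeric)
    fragments.
    """
    counts: dict[str, int] = {}
    for seq in sequences.values():
        for i in range(0, max(0, len(seq) - flank + 1)):
            kmer = seq[i : i + flank]
            counts[kmer] = counts.get(kmer, 0) + 1
    df = frags.df.copy()
    mappable = np.ones(len(df), dtype=bool)
    for row in df.itertuples():
        seq = sequences[row.chrom]
        w = min(flank, row.length)
        left = seq[row.start : row.start + w]
        right = seq[row.end - w : row.end]
        amb_left = counts.get(left, 0) > 1
        amb_right = counts.get(right, 0) > 1
        if amb_left and amb_right:
            mappable[row.fragment_id] = False
    df["mappable"] = mappable
    return FragmentTable(
        df, re2=frags.re2, re1_motif=frags.re1_motif, re2_motif=frags.re2_motif
    )


def circle_arm_length(frags: FragmentTable, fragment_id: int, extremity: str) -> int:
    """Distance from the RE1 boundary at ``extremity`` to the nearest internal RE2 cut.

    This is one arm of the circle formed at the RE2 re-circularization step;
    the circle length of a ligation product is the sum of the two arms.
    """
    if extremity not in (MINUS, PLUS):
        raise ValueError(f"extremity must be '-' or '+', got {extremity!r}")
    col = "d_minus" if extremity == MINUS else "d_plus"
    d = int(frags.df[col].iat[fragment_id])
    if d < 0:
        raise NoRE2Error(f"fragment {fragment_id} carries no RE2 site")
    return d


def build_fragment_table(
    sequences: Mapping[str, str],
    re1_motif: str,
    re2_motif: str,
    cut_offset: int = 1,
    min_gap: int = DEFAULT_MIN_GAP,
    flank: int = DEFAULT_FLANK,
    mappability: bool = False,
) -> FragmentTable:
    """Digest + full annotation in one call."""
    frags = digest_genome(sequences, re1_motif, cut_offset=cut_offset)
    frags = annotate_re2(frags, sequences, re2_motif, min_gap=min_gap, cut_offset=cut_offset)
    frags = end_gc(frags, sequences, flank=flank)
    if mappability:
        frags = annotate_mappability(frags, sequences, flank=flank)
    return frags
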