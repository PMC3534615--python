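"""Shared fixtures: hand-built fragment tables and a reusable simulated library."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scn3c import events as ev
from scn3c.restriction import FragmentTable
from scn3c.simulate import SimConfig, simulate_library


def make_frag_table(
    chrom_fragments: dict[str, list[int]],
    d_minus: list[int] | None = None,
    d_plus: list[int] | None = None,
    gc_minus: list[float] | None = None,
    gc_plus: list[float] | None = None,
) -> FragmentTable:
    """Build a FragmentTable directly from per-chromosome fragment lengths.

    Arm lengths default to 30/40 bp (RE2-valid on both sides); GC defaults
    to 0.5 at every extremity.
    """
    rows = []
    fid = 0
    for chrom, lengths in chrom_fragments.items():
        pos = 0
        for L in lengths:
            rows.append((chrom, pos, pos + L, fid, L))
            pos += L
            fid += 1
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "fragment_id", "length"])
    n = len(df)
    df["n_re2"] = 1
    df["end_gc_minus"] = gc_minus if gc_minus is not None else [0.5] * n
    df["end_gc_plus"] = gc_plus if gc_plus is not None else [0.5] * n
    df["mappable"] = True
    df["d_minus"] = d_minus if d_minus is not None else [30] * n
    df["d_plus"] = d_plus if d_plus is not None else [40] * n
    df["valid_minus"] = df["d_minus"] >= 20
    df["valid_plus"] = df["d_plus"] >= 20
    return FragmentTable(df)


def make_event(
    frag_a: int,
    frag_b: int,
    cls: str = "long_range_intra",
    gc_a: float = 0.5,
    gc_b: float = 0.5,
    d_a: int = 30,
    d_b: int = 40,
    dg: int = 1000,
) -> ev.LigationEvent:
    end_a = ev.EndAssignment(frag_a, "+", 21, gc_a, d_a)
    end_b = ev.EndAssignment(frag_b, "-", 21, gc_b, d_b)
    circle = d_a + d_b if d_a >= 0 and d_b >= 0 else -1
    return ev.LigationEvent(end_a, end_b, cls, "+/-", dg, circle)


def mates_from_pairs(pairs: pd.DataFrame):
    return list(
        zip(
            map(ev.ReadMate, pairs.chrom1, pairs.pos1, pairs.strand1, pairs.mapq1),
            map(ev.ReadMate, pairs.chrom2, pairs.pos2, pairs.strand2, pairs.mapq2),
        )
    )


@pytest.fixture(scope="session")
def default_library():
    """A mid-size library under the default study conditions (all biases on)."""
    cfg = SimConfig(seed=123)
    genome, frags, prop, pairs = simulate_library(cfg, 60_000)
    return cfg, genome, frags, prop, pairs


@pytest.fixture(scope="session")
def default_filtered(default_library):
    cfg, genome, frags, prop, pairs = default_library
    kept, summary = ev.filter_events(mates_from_pairs(pairs), frags)
    return frags, pairs, kept, summary
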