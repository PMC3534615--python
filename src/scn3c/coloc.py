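"""Modified ROC test for 3D colocalization of genomic features.

The question asked is: among the strong interactions that touch a feature
(centromeres, telomeres, replication origins, tRNA genes, CTCF/PolII
sites), is there an enrichment of interactions whose *both* fragments carry
the feature?  Only pairs with at least one feature fragment enter the
ranking (by normalized interaction score, descending); a pair is positive
when both fragments carry the feature.  Traversing the ranking while
plotting cumulative percent negatives against cumulative percent positives
gives a curve whose excursion above the diagonal — and its trapezoidal AUC
— measures colocalization.

Working on a properly balanced map matters here: on a raw map, two
fragments that each interact more with the whole genome also interact more
with each other, which mimics colocalization without any spatial
proximity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .normalize import ContactMatrix
from .restriction import FragmentTable


@dataclass
class FeatureSet:
    """A named set of fragment ids carrying a genomic feature."""

    name: str
    fragment_ids: frozenset[int]

    def __post_init__(self) -> None:
        if not self.fragment_ids:
            raise ValueError(f"feature set {self.name!r} is empty")
        self.fragment_ids = frozenset(int(i) for i in self.fragment_ids)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Minimal BED reader: chrom, start, end (0-based half-open), optional name."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            name = parts[3].strip() if len(parts) > 3 else ""
            rows.append((parts[0], int(parts[1]), int(parts[2]), name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def features_from_bed(
    frags: FragmentTable, bed: pd.DataFrame | str | Path, name: str = "feature"
) -> FeatureSet:
    """Map BED intervals onto fragments: a fragment carries the feature iff
    the interval overlaps it by at least 1 bp."""
    if not isinstance(bed, pd.DataFrame):
        bed = read_bed(bed)
    hits: set[int] = set()
    df = frags.df
    for row in bed.itertuples():
        sub = df[df["chrom"] == row.chrom]
        overlap = sub[(sub["start"] < row.end) & (sub["end"] > row.start)]
        hits.update(int(i) for i in overlap["fragment_id"])
    return FeatureSet(name, frozenset(hits))


def telomere_features(frags: FragmentTable, n_terminal: int = 10) -> FeatureSet:
    """Telomeric fragments defined as the last ``n_terminal`` fragments of each arm."""
    ids: set[int] = set()
    for _, sub in frags.df.groupby("chrom", sort=False):
        fids = sub["fragment_id"].to_numpy()
        ids.update(int(i) for i in fids[:n_terminal])
        ids.update(int(i) for i in fids[-n_terminal:])
    return FeatureSet("telomeres", frozenset(ids))


@dataclass
class RocResult:
    """Ranked labeled interactions, the ROC curve and its AUC.

    Curve coordinates are percentages; the curve starts at (0,0) and ends
    at (100,100).  ``auc`` is in [0,1] (trapezoid rule); NaN when the
    ranking contains a single class.
    """

    ranked: pd.DataFrame  # columns: frag_i, frag_j, score, positive
    pct_negative: np.ndarray
    pct_positive: np.ndarray
    auc: float
    feature: str = ""

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.auc)

    def curve_to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"pct_negative": self.pct_negative, "pct_positive": self.pct_positive}
        ).to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "feature": self.feature,
                    "auc": None if self.degenerate else self.auc,
                    "n_positive": int(self.ranked["positive"].sum()),
                    "n_negative": int((~self.ranked["positive"]).sum()),
                },
                indent=2,
            )
            + "\n"
        )


def label_interactions(matrix: ContactMatrix, features: FeatureSet) -> pd.DataFrame:
    """All off-diagonal pairs touching the feature, ranked by score descending.

    Positive iff both fragments carry the feature.  Ties in score keep a
    stable (frag_i, frag_j) lexicographic order so the ranking is
    deterministic.
    """
    present = np.isin(matrix.index, list(features.fragment_ids))
    if not present.any():
        raise ValueError(
            f"no retained fragment carries feature {features.name!r}"
        )
    iu, ju = np.triu_indices(matrix.n, k=1)
    touch = present[iu] | present[ju]
    iu, ju = iu[touch], ju[touch]
    df = pd.DataFrame(
        {
            "frag_i": matrix.index[iu],
            "frag_j": matrix.index[ju],
            "score": matrix.values[iu, ju],
            "positive": present[iu] & present[ju],
        }
    )
    df = df.sort_values(
        ["score", "frag_i", "frag_j"], ascending=[False, True, True], kind="mergesort"
    ).reset_index(drop=True)
    return df


def roc_curve(ranked: pd.DataFrame, feature: str = "") -> RocResult:
    """ROC curve and trapezoidal AUC from a ranked labeled interaction list."""
    pos = ranked["positive"].to_numpy(dtype=bool)
    n_pos = int(pos.sum())
    n_neg = int((~pos).sum())
    cum_pos = np.concatenate(([0], np.cumsum(pos)))
    cum_neg = np.concatenate(([0], np.cumsum(~pos)))
    if n_pos == 0 or n_neg == 0:
        pct_pos = 100.0 * cum_pos / max(n_pos, 1)
        pct_neg = 100.0 * cum_neg / max(n_neg, 1)
        return RocResult(ranked, pct_neg, pct_pos, float("nan"), feature)
    pct_pos = 100.0 * cum_pos / n_pos
    pct_neg = 100.0 * cum_neg / n_neg
    auc = float(np.trapezoid(pct_pos, pct_neg) / (100.0 * 100.0))
    return RocResult(ranked, pct_neg, pct_pos, auc, feature)


def colocalization_roc(matrix: ContactMatrix, features: FeatureSet) -> RocResult:
    """Convenience wrapper: label, rank and score one feature set."""
    return roc_curve(label_interactions(matrix, features), feature=features.name)


def batch_roc(
    matrix: ContactMatrix, feature_sets: Iterable[FeatureSet]
) -> dict[str, RocResult]:
    return {fs.name: colocalization_roc(matrix, fs) for fs in feature_sets}
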