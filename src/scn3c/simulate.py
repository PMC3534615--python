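"""Synthetic 3C library generator with ground-truth labels.

The generator is a forward model of the protocol: a toy genome with planted
RE1/RE2 sites is digested in silico, ground-truth contact propensities are
laid down (distance decay within chromosomes, uniform background between
them, optional colocalization blocks and per-fragment coverage factors),
and paired-end tags are emitted by drawing an event class (self-loop,
religation, adjacent loop, long-range intra/inter), drawing the partner
fragments and extremities, and then accepting or rejecting the candidate
according to the modelled experimental biases:

* crosslink saturation with fragment length, f(L) = 1 - (1 - p_c)^L;
* Gaussian acceptance around an optimal end GC content;
* a log-normal-shaped circularization envelope over the circle length
  d_A + d_B, modulated by the helical-twist ripple
  (1 + alpha * cos(2*pi*L/T)).

Rejection sampling mimics the physical losses of the protocol rather than
reweighting counts.  Mate 5' positions are placed at protocol-like offsets
(20-22 bp) from the engaged RE1 cut sites with the correct strands, and
every emitted pair carries its generative truth label, so every downstream
estimator can be scored against the value that produced the data.

All randomness flows from a single integer seed; a given config is
byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .restriction import FragmentTable, build_fragment_table

BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimConfig:
    """Study conditions for one synthetic library.

    Defaults reproduce the regime the biases were characterized in: a
    6-cutter primary enzyme (~2 kb fragments), a 4-cutter secondary enzyme
    (~250 bp spacing), an event mixture with ~80% loops+religations,
    per-bp crosslink probability 0.004, GC optimum 45%, circularization
    optimum 500 bp with a 10.5 bp twist ripple.
    """

    chromosome_lengths: tuple[int, ...] = (300_000, 250_000, 200_000, 150_000)
    re1_motif: str = "AAGCTT"
    re2_motif: str = "CCGG"
    cut_offset: int = 1
    re1_spacing: int = 2_000
    re2_spacing: int = 250
    # event mixture over (self_loop, religation, adjacent_loop,
    # long_range_intra, long_range_inter); loops+religations = 0.8
    mixture: tuple[float, ...] = (0.45, 0.25, 0.10, 0.12, 0.08)
    decay_exponent: float = 1.5
    inter_base: float = 1.0  # relative propensity of any inter pair
    coloc_fragments: tuple[int, ...] = ()  # fragment ids of the planted block
    coloc_gamma: float = 1.0
    coverage_factors: dict[int, float] = field(default_factory=dict)
    length_bias: bool = True
    p_crosslink: float = 0.004  # per bp
    gc_bias: bool = True
    gc_optimum: float = 0.45
    gc_width: float = 0.08
    circ_bias: bool = True
    circ_optimum: float = 500.0  # bp
    # width of the log-normal-shaped envelope; circularization efficiency
    # (the J factor) falls off steeply away from the optimum, within a
    # length factor of ~1.5 either side
    circ_log_width: float = 0.35
    twist_period: float = 10.5  # bp
    twist_amplitude: float = 0.3
    no_re2_acceptance: float = 0.2  # depleted, not absent, as observed
    mate_offsets: tuple[int, ...] = (20, 21, 22)  # condition A window
    offset_probs: tuple[float, ...] = (1 / 3, 1 / 3, 1 / 3)
    mapq_high: int = 42
    low_mapq_fraction: float = 0.02
    mapq_low: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.mixture) - 1.0) > 1e-9:
            raise ValueError("event mixture must sum to 1")
        if not (0 <= self.twist_amplitude < 1):
            raise ValueError("twist amplitude must be in [0, 1)")
        if not (0 < self.p_crosslink < 1):
            raise ValueError("p_crosslink must be in (0, 1)")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        for key in ("chromosome_lengths", "mixture", "coloc_fragments",
                    "mate_offsets", "offset_probs"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# --------------------------------------------------------------- toy genome

def _scrub_motifs(seq: np.ndarray, motifs: Sequence[str], protected: set[int], rng) -> None:
    """Mutate bases until no motif occurs outside the protected plant ranges."""
    text = seq.tobytes().decode()
    for _ in range(200):
        dirty = False
        for motif in motifs:
            i = text.find(motif)
            while i != -1:
                positions = [p for p in range(i, i + len(motif)) if p not in protected]
                if positions:
                    dirty = True
                    p = positions[len(positions) // 2]
                    old = seq[p]
                    choices = BASES[BASES != old]
                    seq[p] = rng.choice(choices)
                i = text.find(motif, i + 1)
        if not dirty:
            return
        text = seq.tobytes().decode()
    raise RuntimeError("could not scrub accidental motif occurrences")


def make_toy_genome(config: SimConfig, rng: np.random.Generator | None = None) -> dict[str, str]:
    """Random background with RE1/RE2 motifs planted at randomized spacings.

    Accidental occurrences of either motif are scrubbed before planting, and
    plant-adjacent artifacts are scrubbed after, so the digest recovers
    exactly the planted site set.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    margin = max(len(config.re1_motif), len(config.re2_motif)) + 2
    genome: dict[str, str] = {}
    for c, length in enumerate(config.chromosome_lengths):
        if length < 4 * margin:
            raise ValueError("chromosome too short for motif planting")
        seq = rng.choice(BASES, size=length)

        def plant_positions(mean_spacing: int) -> list[int]:
            if mean_spacing <= 0:
                return []
            out, pos = [], 0
            while True:
                step = int(rng.uniform(0.5, 1.5) * mean_spacing)
                pos += max(step, margin)
                if pos >= length - margin:
                    return out
                out.append(pos)

        re1_pos = plant_positions(config.re1_spacing)
        taken = set()
        for p in re1_pos:
            taken.update(range(p - margin, p + margin))
        re2_pos = [
            p for p in plant_positions(config.re2_spacing) if p not in taken
        ]
        protected: set[int] = set()
        for p in re1_pos:
            protected.update(range(p, p + len(config.re1_motif)))
        for p in re2_pos:
            protected.update(range(p, p + len(config.re2_motif)))
        _scrub_motifs(seq, [config.re1_motif, config.re2_motif], protected, rng)
        for p in re1_pos:
            seq[p : p + len(config.re1_motif)] = np.frombuffer(
                config.re1_motif.encode(), dtype="S1"
            )
        for p in re2_pos:
            seq[p : p + len(config.re2_motif)] = np.frombuffer(
                config.re2_motif.encode(), dtype="S1"
            )
        _scrub_motifs(seq, [config.re1_motif, config.re2_motif], protected, rng)
        genome[f"chr{c + 1}"] = seq.tobytes().decode()
    return genome


def write_fasta(genome: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ------------------------------------------------------------- propensities

def crosslink_factor(lengths: np.ndarray, p_c: float) -> np.ndarray:
    """Probability a fragment is crosslinked at least once: 1 - (1 - p_c)^L."""
    return 1.0 - np.power(1.0 - p_c, lengths.astype(float))


def simulate_propensities(frags: FragmentTable, config: SimConfig) -> np.ndarray:
    """Ground-truth contact propensity matrix over fragments.

    Intra pairs decay as D_g^-beta of the midpoint separation; inter pairs
    share a uniform base.  Colocalization blocks multiply both-member pairs
    by gamma; fragment-level factors (crosslink saturation and any explicit
    coverage factors) enter as an outer product.
    """
    n = len(frags)
    starts = frags.col("start")
    ends = frags.col("end")
    chroms = frags.col("chrom")
    mids = (starts + ends) / 2.0
    same = chroms[:, None] == chroms[None, :]
    dg = np.abs(mids[:, None] - mids[None, :])
    with np.errstate(divide="ignore"):
        intra = np.power(np.maximum(dg, 1.0), -config.decay_exponent)
    prop = np.where(same, intra, config.inter_base)
    np.fill_diagonal(prop, 0.0)
    if config.coloc_fragments and config.coloc_gamma != 1.0:
        member = np.isin(np.arange(n), np.asarray(config.coloc_fragments))
        both = np.outer(member, member)
        prop = np.where(both, prop * config.coloc_gamma, prop)
    factors = np.ones(n)
    if config.length_bias:
        factors *= crosslink_factor(frags.col("length"), config.p_crosslink)
    for fid, fac in config.coverage_factors.items():
        factors[int(fid)] *= fac
    prop = prop * np.outer(factors, factors)
    np.fill_diagonal(prop, 0.0)
    return prop


# ---------------------------------------------------------------- emission

def circ_acceptance(length: np.ndarray, config: SimConfig) -> np.ndarray:
    """Circularization acceptance: log-normal-shaped envelope times twist ripple."""
    length = np.asarray(length, dtype=float)
    safe = np.maximum(length, 1.0)
    env = np.exp(
        -(np.log(safe / config.circ_optimum) ** 2) / (2.0 * config.circ_log_width**2)
    )
    ripple = (
        1.0 + config.twist_amplitude * np.cos(2.0 * np.pi * safe / config.twist_period)
    ) / (1.0 + config.twist_amplitude)
    return env * ripple


def gc_acceptance(gc_mean: np.ndarray, config: SimConfig) -> np.ndarray:
    """Gaussian acceptance around the optimal end GC content."""
    return np.exp(-((gc_mean - config.gc_optimum) ** 2) / (2.0 * config.gc_width**2))


class _Sampler:
    """Vectorized candidate-event sampler over a fragment table."""

    def __init__(self, frags: FragmentTable, prop: np.ndarray, config: SimConfig):
        self.frags = frags
        self.config = config
        n = len(frags)
        chroms = frags.col("chrom")
        same = chroms[:, None] == chroms[None, :]
        iu, ju = np.triu_indices(n, k=1)
        adjacent = same[iu, ju] & (ju - iu == 1)
        intra_lr = same[iu, ju] & (ju - iu > 1)
        inter = ~same[iu, ju]

        self.adj_pairs = np.stack([iu[adjacent], ju[adjacent]], axis=1)
        w = prop[iu, ju]

        def norm(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            pw = w[mask]
            tot = pw.sum()
            if tot <= 0:
                return np.empty((0, 2), dtype=int), np.empty(0)
            return np.stack([iu[mask], ju[mask]], axis=1), pw / tot

        self.intra_pairs, self.intra_p = norm(intra_lr)
        self.inter_pairs, self.inter_p = norm(inter)

        factors = np.ones(n)
        if config.length_bias:
            factors *= crosslink_factor(frags.col("length"), config.p_crosslink)
        for fid, fac in config.coverage_factors.items():
            factors[int(fid)] *= fac
        self.self_p = factors / factors.sum()
        aw = factors[self.adj_pairs[:, 0]] * factors[self.adj_pairs[:, 1]]
        self.adj_p = aw / aw.sum()

    def draw(self, m: int, rng: np.random.Generator):
        """Draw m candidate events; returns fragment ids, extremities (0='-',1='+')."""
        cfg = self.config
        cls = rng.choice(5, size=m, p=np.asarray(cfg.mixture))
        fa = np.empty(m, dtype=np.int64)
        fb = np.empty(m, dtype=np.int64)
        ea = np.empty(m, dtype=np.int8)
        eb = np.empty(m, dtype=np.int8)

        sel = cls == 0  # self_loop: '-' joined to '+' of one fragment
        k = int(sel.sum())
        if k:
            f = rng.choice(len(self.self_p), size=k, p=self.self_p)
            fa[sel], fb[sel] = f, f
            ea[sel], eb[sel] = 0, 1

        for code, (e_up, e_dn) in ((1, (1, 0)), (2, (0, 1))):
            # religation: upstream '+' to downstream '-'; adjacent loop: '-' to '+'
            sel = cls == code
            k = int(sel.sum())
            if k:
                if len(self.adj_pairs) == 0:
                    raise ValueError("no adjacent fragment pairs available")
                idx = rng.choice(len(self.adj_pairs), size=k, p=self.adj_p)
                fa[sel] = self.adj_pairs[idx, 0]
                fb[sel] = self.adj_pairs[idx, 1]
                ea[sel], eb[sel] = e_up, e_dn

        for code, pairs, p in ((3, self.intra_pairs, self.intra_p),
                               (4, self.inter_pairs, self.inter_p)):
            sel = cls == code
            k = int(sel.sum())
            if k:
                if len(pairs) == 0:
                    raise ValueError("no long-range pairs available for the mixture")
                idx = rng.choice(len(pairs), size=k, p=p)
                fa[sel] = pairs[idx, 0]
                fb[sel] = pairs[idx, 1]
                ea[sel] = rng.integers(0, 2, size=k)
                eb[sel] = rng.integers(0, 2, size=k)
        return cls, fa, fb, ea, eb


CLASS_NAMES = np.array(
    ["self_loop", "religation", "adjacent_loop", "long_range_intra", "long_range_inter"]
)


def emit_read_pairs(
    frags: FragmentTable,
    propensities: np.ndarray,
    config: SimConfig,
    n_pairs: int,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Emit ``n_pairs`` accepted paired-end tags with truth labels.

    Returns a frame with the 8 pairs-table columns (chrom/pos/strand/mapq per
    mate) plus truth columns: true_class, frag_a, frag_b, extremity_a/b,
    circle_length (-1 when undefined) and gc_mean.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sampler = _Sampler(frags, propensities, config)
    chrom_arr = frags.col("chrom")
    starts = frags.col("start")
    ends = frags.col("end")
    d_minus = frags.col("d_minus")
    d_plus = frags.col("d_plus")
    gc_minus = frags.col("end_gc_minus")
    gc_plus = frags.col("end_gc_plus")

    chunks: list[pd.DataFrame] = []
    got = 0
    attempted = 0
    ext_char = np.array(["-", "+"])
    while got < n_pairs:
        m = max(2 * (n_pairs - got), 10_000)
        attempted += m
        cls, fa, fb, ea, eb = sampler.draw(m, rng)
        da = np.where(ea == 1, d_plus[fa], d_minus[fa])
        db = np.where(eb == 1, d_plus[fb], d_minus[fb])
        gca = np.where(ea == 1, gc_plus[fa], gc_minus[fa])
        gcb = np.where(eb == 1, gc_plus[fb], gc_minus[fb])
        circle = np.where((da >= 0) & (db >= 0), da + db, -1)

        accept = np.ones(m)
        if config.gc_bias:
            accept *= gc_acceptance((gca + gcb) / 2.0, config)
        if config.circ_bias:
            factor = np.where(
                circle >= 0, circ_acceptance(circle, config), config.no_re2_acceptance
            )
            accept *= factor
        keep = rng.random(m) < accept
        if attempted > 1000 and keep.sum() < attempted * 0.001 and got == 0:
            raise RuntimeError(
                "acceptance rate below 0.1%: bias parameters are mis-configured"
            )
        cls, fa, fb, ea, eb = cls[keep], fa[keep], fb[keep], ea[keep], eb[keep]
        circle, gca, gcb = circle[keep], gca[keep], gcb[keep]
        k = len(fa)
        if k == 0:
            continue

        off_a = rng.choice(np.asarray(config.mate_offsets), size=k,
                           p=np.asarray(config.offset_probs))
        off_b = rng.choice(np.asarray(config.mate_offsets), size=k,
                           p=np.asarray(config.offset_probs))
        # '+' extremity -> forward mate ending at the cut; '-' -> reverse mate
        pos_a = np.where(ea == 1, ends[fa] - off_a, starts[fa] + off_a)
        pos_b = np.where(eb == 1, ends[fb] - off_b, starts[fb] + off_b)
        mapq_a = np.where(rng.random(k) < config.low_mapq_fraction,
                          config.mapq_low, config.mapq_high)
        mapq_b = np.where(rng.random(k) < config.low_mapq_fraction,
                          config.mapq_low, config.mapq_high)
        chunks.append(
            pd.DataFrame(
                {
                    "chrom1": chrom_arr[fa],
                    "pos1": pos_a,
                    "strand1": ext_char[ea],
                    "mapq1": mapq_a,
                    "chrom2": chrom_arr[fb],
                    "pos2": pos_b,
                    "strand2": ext_char[eb],
                    "mapq2": mapq_b,
                    "true_class": CLASS_NAMES[cls],
                    "frag_a": fa,
                    "frag_b": fb,
                    "extremity_a": ext_char[ea],
                    "extremity_b": ext_char[eb],
                    "circle_length": circle,
                    "gc_mean": (gca + gcb) / 2.0,
                }
            )
        )
        got += k
    out = pd.concat(chunks, ignore_index=True).iloc[:n_pairs].reset_index(drop=True)
    return out


PAIRS_COLUMNS = ["chrom1", "pos1", "strand1", "mapq1", "chrom2", "pos2", "strand2", "mapq2"]


def write_pairs_tsv(pairs: pd.DataFrame, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(PAIRS_COLUMNS) + "\n")
        pairs[PAIRS_COLUMNS].to_csv(fh, sep="\t", index=False, header=False)


def write_truth_tsv(pairs: pd.DataFrame, path: str | Path) -> None:
    cols = ["true_class", "frag_a", "frag_b", "extremity_a", "extremity_b",
            "circle_length", "gc_mean"]
    pairs[cols].to_csv(path, sep="\t", index=False)


def simulate_library(
    config: SimConfig, n_pairs: int
) -> tuple[dict[str, str], FragmentTable, np.ndarray, pd.DataFrame]:
    """Full generator pipeline: genome, fragment table, propensities, read pairs."""
    rng = np.random.default_rng(config.seed)
    genome = make_toy_genome(config, rng)
    frags = build_fragment_table(
        genome, config.re1_motif, config.re2_motif, cut_offset=config.cut_offset
    )
    prop = simulate_propensities(frags, config)
    pairs = emit_read_pairs(frags, prop, config, n_pairs, rng)
    return genome, frags, prop, pairs
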