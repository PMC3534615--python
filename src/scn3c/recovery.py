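"""Parameter-recovery studies: can the estimators find the values that made the data?

Each study generates data whose ground truth is known exactly — either from
the closed-form bias law or from the full synthetic-library generator — and
runs the corresponding estimator on it.  They are the package's validation
harness: the crosslink fit is checked against Poisson-noised saturation
curves, and the circularization-length optimum and helical-twist period are
checked against complete simulated libraries pushed through the regular
read-filtering and profile machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import biases, events as ev
from .biases import BiasProfile, CrosslinkFit, crosslink_curve
from .restriction import FragmentTable
from .simulate import SimConfig, simulate_library

#: genome used for the circularization studies: ~1200 fragments, enough
#: distinct arm-length pairs to populate the 1 bp circle-length bins
CIRC_STUDY_CHROMOSOMES = (800_000, 600_000, 500_000, 500_000)


def noisy_crosslink_profile(
    amplitude: float = 4000.0,
    p_crosslink: float = 0.004,
    seed: int = 0,
    bin_width: int = 100,
    length_range: tuple[int, int] = (100, 3000),
    fragments_per_bin: int = 25,
) -> BiasProfile:
    """Reads-per-fragment length profile sampled from the saturation law.

    Bin counts are Poisson around ``fragments_per_bin * f(midpoint)``; at
    the defaults every expected count is well above 100, the regime where
    the fit is meaningful.
    """
    rng = np.random.default_rng(seed)
    edges = np.arange(length_range[0], length_range[1] + bin_width, bin_width, dtype=float)
    mids = (edges[:-1] + edges[1:]) / 2
    expected = fragments_per_bin * crosslink_curve(mids, amplitude, p_crosslink)
    reads = rng.poisson(expected).astype(float)
    return BiasProfile(
        "fragment_length", edges, np.full(len(mids), fragments_per_bin, dtype=float), reads
    )


def crosslink_recovery(
    amplitude: float = 4000.0, p_crosslink: float = 0.004, seed: int = 0
) -> CrosslinkFit:
    """Refit (A, p_c) on a Poisson-noised profile generated at those values."""
    return biases.fit_crosslink(noisy_crosslink_profile(amplitude, p_crosslink, seed))


@dataclass
class CircularizationStudy:
    frags: FragmentTable
    kept: list
    profile: BiasProfile

    @property
    def mode(self) -> float:
        return biases.profile_mode(self.profile)

    def period(self) -> biases.PeriodEstimate:
        return biases.estimate_period(self.profile)


def circularization_study(
    seed: int,
    twist_amplitude: float,
    n_pairs: int = 1_200_000,
    circ_optimum: float = 500.0,
    twist_period: float = 10.5,
) -> CircularizationStudy:
    """Full-generator study of the circularization bias.

    Emits a complete library (default event mixture, ~80% byproducts) with
    the circularization acceptance env(L) * (1 + a*cos(2*pi*L/T)), runs the
    standard read filters, and bins the surviving long-range events into
    the 1 bp circle-length profile.  The GC acceptance is disabled so the
    measured profile reflects the circularization factor alone: RE2 sites
    close to a cut raise the flank GC (the recognition motif lies inside
    the 20 bp flank), which would otherwise couple the two biases.
    """
    cfg = SimConfig(
        seed=seed,
        chromosome_lengths=CIRC_STUDY_CHROMOSOMES,
        gc_bias=False,
        circ_optimum=circ_optimum,
        twist_period=twist_period,
        twist_amplitude=twist_amplitude,
    )
    _, frags, _, pairs = simulate_library(cfg, n_pairs)
    mates = zip(
        map(ev.ReadMate, pairs.chrom1, pairs.pos1, pairs.strand1, pairs.mapq1),
        map(ev.ReadMate, pairs.chrom2, pairs.pos2, pairs.strand2, pairs.mapq2),
    )
    kept, _ = ev.filter_events(mates, frags)
    profile = biases.circularization_profile(frags, kept)
    return CircularizationStudy(frags, kept, profile)
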