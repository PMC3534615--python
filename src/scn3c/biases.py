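"""Quantification of the experimental biases in a 3C library.

Three fragment-level covariates systematically modulate how often an
interaction is detected:

* **fragment length** — crosslinking probability grows with fragment size
  and saturates around 800 bp, modelled as f(x) = A(1 - (1 - p_c)^x) with
  p_c the per-basepair crosslink probability;
* **end GC content** — amplification and sequencing favour reads whose
  20 bp end flanks sit near 45% GC;
* **circularization length** — the re-circularization steps prefer circles
  (d_A + d_B) near 500 bp, with a ~10.5 bp ripple from the helical twist of
  DNA (ends ligate best when they meet in phase).

Every bias is expressed the same way: bin the covariate, count the possible
fragments or interactions per bin (N_i), the detected reads per bin (R_i),
and report the reads-per-possible-interaction ratio r_i = R_i / N_i.  The
same construction over genomic distance gives the contact-decay expectation
used for distance normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .events import LigationEvent
from .restriction import FragmentTable


@dataclass
class BiasProfile:
    """Binned (N_i, R_i, r_i) curve for one covariate.

    Bins with N_i = 0 have undefined ratio: r_i is NaN there and the bin is
    flagged in ``empty``, never silently zero.
    """

    covariate: str
    bin_edges: np.ndarray
    n_possible: np.ndarray  # N_i
    n_reads: np.ndarray  # R_i

    @property
    def ratio(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(self.n_possible > 0, self.n_reads / self.n_possible, np.nan)
        return r

    @property
    def empty(self) -> np.ndarray:
        return self.n_possible == 0

    @property
    def midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "N": self.n_possible,
                "R": self.n_reads,
                "r": self.ratio,
            }
        ).to_csv(path, sep="\t", index=False)


def _profile(
    covariate: str,
    possible: np.ndarray,
    observed: np.ndarray,
    bin_width: float,
    lo: float | None = None,
    hi: float | None = None,
) -> BiasProfile:
    lo = float(min(possible.min(), observed.min() if len(observed) else np.inf)) if lo is None else lo
    hi = float(max(possible.max(), observed.max() if len(observed) else -np.inf)) if hi is None else hi
    edges = np.arange(lo, hi + bin_width, bin_width)
    if len(edges) < 2:
        edges = np.array([lo, lo + bin_width])
    n_pos, _ = np.histogram(possible, bins=edges)
    n_obs, _ = np.histogram(observed, bins=edges)
    return BiasProfile(covariate, edges, n_pos, n_obs)


# -------------------------------------------------------------- length bias

def length_profile(
    frags: FragmentTable, events: Iterable[LigationEvent], bin_width: int = 100
) -> BiasProfile:
    """Reads per fragment as a function of fragment length (100 bp bins).

    N_i counts fragments whose length falls in the bin; R_i counts read
    ends landing on those fragments (each event contributes both of its
    ends).
    """
    lengths = frags.col("length").astype(float)
    ends = []
    for ev in events:
        ends.append(lengths[ev.end_a.fragment_id])
        ends.append(lengths[ev.end_b.fragment_id])
    return _profile("fragment_length", lengths, np.asarray(ends, dtype=float), bin_width, lo=0.0)


@dataclass
class CrosslinkFit:
    """Least-squares fit of the crosslink saturation curve f(x) = A(1-(1-p_c)^x)."""

    amplitude: float  # A, reads per fragment at saturation
    p_crosslink: float  # p_c, per-bp crosslink probability
    residual_norm: float
    degenerate: bool = False

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return crosslink_curve(np.asarray(x, dtype=float), self.amplitude, self.p_crosslink)


def crosslink_curve(x: np.ndarray, amplitude: float, p_c: float) -> np.ndarray:
    """Probability-of-at-least-one-crosslink saturation curve, scaled by ``amplitude``."""
    return amplitude * (1.0 - np.power(1.0 - p_c, x))


def fit_crosslink(profile: BiasProfile) -> CrosslinkFit:
    """Fit (A, p_c) to the occupied bins of a length profile.

    Unweighted least squares on bin midpoints.  A saturated profile (flat
    within numerical noise, the p_c -> 1 limit) cannot pin p_c down and is
    returned with ``degenerate=True``.
    """
    ok = ~profile.empty & np.isfinite(profile.ratio)
    x = profile.midpoints[ok]
    y = profile.ratio[ok]
    if len(x) < 3:
        raise ValueError("crosslink fit needs at least 3 occupied bins")
    a0 = float(y.max())
    half = y <= a0 / 2
    x_half = float(x[half].max()) if half.any() else float(x.min())
    p0 = min(max(np.log(2.0) / max(x_half, 1.0), 1e-6), 0.5)
    try:
        popt, _ = curve_fit(
            crosslink_curve,
            x,
            y,
            p0=(a0, p0),
            bounds=([0.0, 1e-12], [np.inf, 1.0 - 1e-12]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # non-convergence: surface, never silent
        raise RuntimeError(f"crosslink fit failed to converge: {exc}") from exc
    resid = float(np.linalg.norm(y - crosslink_curve(x, *popt)))
    # p_c -> 1 saturates f(x) = A for all x >= 1: the data cannot identify p_c
    degenerate = bool(popt[1] > 0.999 or np.ptp(crosslink_curve(x, *popt)) < 1e-9 * abs(popt[0]))
    return CrosslinkFit(float(popt[0]), float(popt[1]), resid, degenerate)


# ------------------------------------------------------------------ GC bias

def _valid_end_gc(frags: FragmentTable) -> np.ndarray:
    gcs = np.concatenate(
        [
            frags.col("end_gc_minus")[frags.col("valid_minus")],
            frags.col("end_gc_plus")[frags.col("valid_plus")],
        ]
    )
    return gcs[np.isfinite(gcs)]


def gc_profile(
    frags: FragmentTable, events: Iterable[LigationEvent], bin_width: float = 0.025
) -> BiasProfile:
    """Reads per possible interaction vs mean end GC of the pair (2.5% bins).

    The covariate of an event is the mean of the two engaged-end GC
    fractions.  N_i is the distribution of that mean over all RE2-valid
    extremity pairs, computed exactly by convolving the binned distribution
    of single-end GC values with itself.
    """
    gcs = _valid_end_gc(frags)
    if len(gcs) == 0:
        raise ValueError("no RE2-valid extremities with GC annotation")
    edges = np.arange(0.0, 1.0 + bin_width, bin_width)
    # distribution of pair means via self-convolution of the single-end
    # histogram: ends in bins i and j give a mean near (i + j) * w / 2, so
    # coarse mean-bin k collects sum-bins 2k and 2k+1
    h, _ = np.histogram(gcs, bins=edges)
    pair_sum = np.convolve(h, h).astype(float)  # ordered pairs; scale cancels in r_i
    n_pos = np.zeros(len(edges) - 1)
    for s, cnt in enumerate(pair_sum):
        n_pos[min(s // 2, len(n_pos) - 1)] += cnt
    means = np.array(
        [(ev.end_a.gc + ev.end_b.gc) / 2.0 for ev in events], dtype=float
    )
    n_obs, _ = np.histogram(means, bins=edges)
    return BiasProfile("mean_end_gc", edges, n_pos, n_obs)


# -------------------------------------------------- circularization bias

def possible_circle_lengths(frags: FragmentTable, max_length: int | None = None) -> np.ndarray:
    """Histogram of d_A + d_B over all valid extremity pairs (1 bp bins).

    Computed exactly as the self-convolution of the histogram of single-arm
    lengths d over valid extremities.
    """
    ds = np.concatenate(
        [
            frags.col("d_minus")[frags.col("valid_minus")],
            frags.col("d_plus")[frags.col("valid_plus")],
        ]
    ).astype(np.int64)
    ds = ds[ds >= 0]
    if len(ds) == 0:
        raise ValueError("no valid extremities with circle arm lengths")
    h = np.bincount(ds)
    conv = np.convolve(h, h)  # ordered pairs of arms; shape only matters
    if max_length is not None:
        conv = conv[: max_length + 1]
    return conv.astype(float)


def circularization_profile(
    frags: FragmentTable, events: Iterable[LigationEvent], bin_width: int = 1
) -> BiasProfile:
    """Reads per possible interaction vs circle length d_A + d_B (1 bp bins)."""
    circles = np.array(
        [ev.circle_length for ev in events if ev.circle_length >= 0], dtype=np.int64
    )
    n_pos_full = possible_circle_lengths(frags)
    hi = max(len(n_pos_full), (circles.max() + 1) if len(circles) else 1)
    if bin_width == 1:
        edges = np.arange(0, hi + 1, dtype=float)
        n_pos = np.zeros(hi)
        n_pos[: len(n_pos_full)] = n_pos_full
        n_obs = np.bincount(circles, minlength=hi).astype(float) if len(circles) else np.zeros(hi)
        return BiasProfile("circle_length", edges, n_pos, n_obs)
    edges = np.arange(0, hi + bin_width, bin_width, dtype=float)
    n_pos, _ = np.histogram(np.arange(len(n_pos_full)), bins=edges, weights=n_pos_full)
    n_obs, _ = np.histogram(circles, bins=edges)
    return BiasProfile("circle_length", edges, n_pos, n_obs)


def smooth_ratio(profile: BiasProfile, window: int = 21) -> np.ndarray:
    """Moving-average smoothing of r_i.

    R_i and N_i are each averaged over the window before dividing, which is
    the stable estimator where N_i is small (bins with few possible
    interactions otherwise dominate the raw ratio with noise).
    """
    kernel = np.ones(window)
    num = np.convolve(profile.n_reads.astype(float), kernel, mode="same")
    den = np.convolve(profile.n_possible.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def profile_mode(
    profile: BiasProfile,
    window: int = 21,
    min_support: float = 0.05,
    refine: bool = True,
) -> float:
    """Covariate value at the maximum of the smoothed r_i curve.

    Windows whose summed N_i falls below ``min_support`` times the best-
    supported window are excluded: the ratio estimate there is noise-
    dominated and would otherwise capture the argmax.  With ``refine`` the
    raw argmax is sharpened by fitting a parabola to log r over the region
    where the smoothed curve stays above half its peak and reporting the
    vertex — near its optimum a smooth efficiency peak is locally quadratic
    in log of the covariate, and the vertex uses the whole peak region
    instead of a single noisy bin.
    """
    sm = smooth_ratio(profile, window=window)
    den = np.convolve(profile.n_possible.astype(float), np.ones(window), mode="same")
    sm = np.where(den >= min_support * den.max(), sm, np.nan)
    if not np.isfinite(sm).any():
        raise ValueError("profile has no defined bins")
    k0 = int(np.nanargmax(sm))
    mids = profile.midpoints
    raw_mode = float(mids[k0])
    if not refine:
        return raw_mode
    peak = sm[k0]
    usable = np.isfinite(sm) & (sm >= 0.5 * peak) & (mids > 0)
    # contiguous run around the argmax only
    left = k0
    while left > 0 and usable[left - 1]:
        left -= 1
    right = k0
    while right < len(sm) - 1 and usable[right + 1]:
        right += 1
    sel = np.zeros_like(usable)
    sel[left : right + 1] = usable[left : right + 1]
    if sel.sum() < 10:
        return raw_mode
    x = np.log(mids[sel])
    y = np.log(sm[sel])
    a, b, _ = np.polyfit(x, y, 2)
    if a >= 0:
        return raw_mode
    vertex = float(np.exp(-b / (2 * a)))
    lo, hi = float(mids[left]), float(mids[right])
    return min(max(vertex, lo), hi)


@dataclass
class PeriodEstimate:
    period: float  # bp
    power_fraction: float
    significant: bool


def estimate_period(
    profile: BiasProfile,
    max_length: int = 500,
    band: tuple[float, float] = (5.0, 50.0),
    detrend_window: int = 21,
    zero_pad: int = 8,
    min_power_fraction: float = 0.02,
) -> PeriodEstimate:
    """Dominant oscillation period of the circularization-efficiency ripple.

    Restricts to circle lengths below ``max_length`` (where the helical
    modulation is visible), removes the smooth envelope with a
    ``detrend_window`` bp moving average, and takes the magnitude spectrum
    of the residual (zero-padded x``zero_pad`` for sub-bin period
    resolution).  Returns the period of the strongest peak in ``band`` and
    the fraction of in-band power it carries; below ``min_power_fraction``
    the profile is reported as having no significant periodicity.
    """
    r = profile.ratio
    mids = profile.midpoints
    region = mids < max_length
    if (region & np.isfinite(r)).sum() < 64:
        raise ValueError("need >=64 occupied 1 bp bins below max_length")
    y = r[region]
    defined = np.isfinite(y)
    # envelope = moving average over defined bins; residual carries the ripple
    kernel = np.ones(detrend_window)
    num = np.convolve(np.where(defined, y, 0.0), kernel, mode="same")
    den = np.convolve(defined.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        envelope = np.where(den > 0, num / den, 0.0)
    resid = np.where(defined, y - envelope, 0.0)
    resid = resid - resid[defined].mean() * defined
    n = len(resid)
    nfft = int(2 ** np.ceil(np.log2(n * zero_pad)))
    spec = np.abs(np.fft.rfft(resid, nfft)) ** 2
    freqs = np.fft.rfftfreq(nfft, d=1.0)  # cycles per bp at 1 bp binning
    in_band = (freqs >= 1.0 / band[1]) & (freqs <= 1.0 / band[0])
    total = spec[in_band].sum()
    if not in_band.any() or total <= 0:
        return PeriodEstimate(np.nan, 0.0, False)
    k = np.flatnonzero(in_band)[np.argmax(spec[in_band])]
    frac = float(spec[k] / total)
    # a real ripple concentrates power: require the peak to dominate the
    # in-band median by a wide margin as well as carrying min_power_fraction
    med = float(np.median(spec[in_band]))
    significant = bool(frac >= min_power_fraction and (med == 0 or spec[k] > 10 * med))
    return PeriodEstimate(float(1.0 / freqs[k]), frac, significant)


# --------------------------------------------------------- distance decay

@dataclass
class DistanceExpectation:
    """Polynomial fit of log10 r against log10 genomic distance.

    The expectation evaluator is clamped to strictly positive values by
    construction (it exponentiates the polynomial); outside the fitted
    domain it extends with the boundary value to stay monotone-safe.
    """

    bin_edges: np.ndarray
    n_possible: np.ndarray
    n_reads: np.ndarray
    coeffs: np.ndarray = field(default_factory=lambda: np.zeros(1))
    domain: tuple[float, float] = (1.0, 1.0)

    @property
    def ratio(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.n_possible > 0, self.n_reads / self.n_possible, np.nan)

    def evaluate(self, dg: np.ndarray) -> np.ndarray:
        dg = np.asarray(dg, dtype=float)
        lo, hi = self.domain
        x = np.log10(np.clip(dg, lo, hi))
        return np.power(10.0, np.polyval(self.coeffs, x))


def distance_expectation(
    matrix,
    frags: FragmentTable,
    n_bins: int = 50,
    degree: int = 8,
) -> DistanceExpectation:
    """Expected contacts per fragment pair as a function of genomic distance.

    For every intra-chromosomal pair the genomic distance is the midpoint
    separation; pairs are binned logarithmically, N_i counts pairs per bin,
    R_i sums their contacts, and a degree-``degree`` polynomial is fitted to
    log10(r_i) vs log10(D_g).  Heavy-tailed decay is poorly served by
    low-degree polynomials in linear space, hence log-log coordinates.
    """
    sub = frags.df.set_index("fragment_id").loc[matrix.index]
    mids = ((sub["start"] + sub["end"]) // 2).to_numpy()
    chroms = sub["chrom"].to_numpy()
    iu = np.triu_indices(len(mids), k=1)
    same = chroms[iu[0]] == chroms[iu[1]]
    if not same.any():
        raise ValueError("no intra-chromosomal pairs available")
    dg = np.abs(mids[iu[0]] - mids[iu[1]])[same].astype(float)
    counts = matrix.values[iu][same]
    dg = np.maximum(dg, 1.0)
    edges = np.logspace(0, np.log10(dg.max() + 1), n_bins + 1)
    n_pos, _ = np.histogram(dg, bins=edges)
    n_reads, _ = np.histogram(dg, bins=edges, weights=counts)
    # representative distance per bin = pair-weighted mean log distance;
    # using the geometric midpoint instead biases the fit near domain edges
    sum_logd, _ = np.histogram(dg, bins=edges, weights=np.log10(dg))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(n_pos > 0, n_reads / n_pos, np.nan)
        logd = np.where(n_pos > 0, sum_logd / n_pos, np.nan)
    ok = np.isfinite(r) & (r > 0)
    if ok.sum() < degree + 1:
        degree = max(1, int(ok.sum()) - 1)
    coeffs = np.polyfit(logd[ok], np.log10(r[ok]), degree)
    domain = (float(10.0 ** logd[ok].min()), float(10.0 ** logd[ok].max()))
    return DistanceExpectation(edges, n_pos, n_reads, coeffs, domain)
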