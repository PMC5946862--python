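"""Synthetic capillary-electrophoresis electropherograms with ground truth.

Emulates the signal the peak-fitting stage consumes: a sum of Gaussian peaks
riding on a constant baseline, one peak per cleavage fragment, with migration
position growing monotonically (slightly super-linearly) in fragment length
and peak width growing linearly with migration position.  Per-fragment
multiplicative amplitude jitter and per-sample additive Gaussian noise stand
in for instrument noise.  A deuterated variant reduces adenine peaks by the
kinetic isotope effect factor.

The per-position "intensity" of a SimSpec is the true cleavage extent and is
proportional to peak AREA (fragment abundance); amplitudes are derived as
``a = I / (w * sqrt(2*pi))`` so that the analytic area of each simulated peak
equals its true intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .core import DuplexSequence, Trace

SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class MigrationModel:
    """Data-point index of a fragment's peak apex as a function of length (nt).

    ``c(len) = p0 + p1*len + p2*len**2`` with a small positive quadratic term,
    mimicking the roughly regular but slowly stretching peak spacing of
    capillary electrophoresis.
    """

    p0: float = 100.0
    p1: float = 10.0
    p2: float = 0.002

    def __call__(self, length) -> np.ndarray | float:
        length = np.asarray(length, dtype=float)
        out = self.p0 + self.p1 * length + self.p2 * length**2
        return out if out.ndim else float(out)

    def validate(self, max_length: int) -> None:
        lens = np.arange(1, max_length + 1)
        if np.any(np.diff(self(lens)) <= 0):
            raise ValueError("migration model is not strictly increasing over range")


@dataclass(frozen=True)
class WidthModel:
    """Peak width parameter (data points) as a linear function of data point."""

    intercept: float = 2.0
    slope: float = 0.001

    def __call__(self, c) -> np.ndarray | float:
        c = np.asarray(c, dtype=float)
        out = self.intercept + self.slope * c
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class SimSpec:
    """Complete description of one simulated electrophoresis run.

    intensities map position (forward coordinate of the cleaved nucleotide on
    ``strand``) to true cleavage extent in arbitrary fluorescence*data-point
    units.  ``additive_noise`` is the per-sample Gaussian sd as a fraction of
    the median peak amplitude; ``amp_jitter`` is the sd of per-fragment
    multiplicative amplitude noise.  ``f_d`` is the deuterium isotope-effect
    factor applied at adenines of the labeled strand ("nearly a factor of
    two" means ~0.5).
    """

    sequence: DuplexSequence
    intensities: Mapping[int, float]
    seed: int
    strand: str = "forward"
    baseline: float = 50.0
    additive_noise: float = 0.01
    amp_jitter: float = 0.05
    f_d: float = 0.5
    migration: MigrationModel = field(default_factory=MigrationModel)
    width: WidthModel = field(default_factory=WidthModel)
    ladder: tuple[int, ...] = tuple(range(60, 441, 20))
    ladder_amplitude: float = 100.0

    def __post_init__(self) -> None:
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"unknown strand {self.strand!r}")
        if not 0.0 < self.f_d <= 1.0:
            raise ValueError("deuteration factor must be in (0, 1]")
        for pos, val in self.intensities.items():
            if val <= 0:
                raise ValueError(f"non-positive intensity at position {pos}")
            if not 1 <= pos <= self.sequence.length:
                raise ValueError(f"position {pos} outside sequence")

    def fragment_length(self, position: int) -> int:
        """Fragment length produced by cleavage at a labeled-strand position."""
        if self.strand == "forward":
            return position
        return self.sequence.length - position + 1

    def position_of_fragment(self, length: int) -> int:
        if self.strand == "forward":
            return length
        return self.sequence.length - length + 1


@dataclass(frozen=True)
class PeakTruth:
    fragment_length: int
    position: int  # forward coordinate of the cleaved nucleotide; 0 for ladder
    base: str
    amplitude: float  # includes jitter and deuteration
    center: float
    width: float

    @property
    def area(self) -> float:
        """Analytic area of the Gaussian peak."""
        return self.amplitude * self.width * SQRT_2PI


GroundTruth = list  # list[PeakTruth]


def gaussian_sum(x: np.ndarray, amplitudes, centers, widths,
                 baseline: float = 0.0) -> np.ndarray:
    """Evaluate ``b + sum_i a_i * exp(-0.5*((x - c_i)/w_i)^2)`` on ``x``."""
    x = np.asarray(x, dtype=float)
    a = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    c = np.atleast_1d(np.asarray(centers, dtype=float))
    w = np.atleast_1d(np.asarray(widths, dtype=float))
    out = np.full(x.shape, float(baseline))
    for ai, ci, wi in zip(a, c, w):
        out += ai * np.exp(-0.5 * ((x - ci) / wi) ** 2)
    return out


def _build_truth(spec: SimSpec, channel: str, deuterated: bool) -> GroundTruth:
    rng_jitter = np.random.default_rng([int(spec.seed), 17])
    truth: GroundTruth = []
    if channel == "ladder":
        for length in sorted(spec.ladder):
            c = float(spec.migration(length))
            w = float(spec.width(c))
            truth.append(PeakTruth(length, 0, "", spec.ladder_amplitude, c, w))
        return truth
    if channel != "cleavage":
        raise ValueError(f"unknown channel {channel!r}")
    positions = sorted(spec.intensities,
                       key=lambda p: spec.fragment_length(p))
    # one jitter draw per fragment, in fragment-length order, so normal and
    # deuterated runs built from the same seed share the identical stream
    jitter = (rng_jitter.normal(1.0, spec.amp_jitter, size=len(positions))
              if spec.amp_jitter > 0 else np.ones(len(positions)))
    jitter = np.clip(jitter, 0.05, None)
    for (pos, jit) in zip(positions, jitter):
        length = spec.fragment_length(pos)
        if length < 1 or length >= spec.sequence.length:
            raise ValueError(f"position {pos} yields invalid fragment length")
        base = spec.sequence.base(pos, spec.strand)
        c = float(spec.migration(length))
        w = float(spec.width(c))
        amp = spec.intensities[pos] / (w * SQRT_2PI) * jit
        if deuterated and base == "A":
            amp *= spec.f_d
        truth.append(PeakTruth(length, pos, base, amp, c, w))
    return truth


def _render(spec: SimSpec, truth: GroundTruth, channel: str) -> Trace:
    max_len = max((t.fragment_length for t in truth),
                  default=max(spec.ladder))
    spec.migration.validate(max(max_len, max(spec.ladder)))
    c_max = max(t.center for t in truth)
    w_max = max(t.width for t in truth)
    n = int(math.ceil(c_max + 6 * w_max + 20))
    x = np.arange(n)
    y = gaussian_sum(
        x,
        [t.amplitude for t in truth],
        [t.center for t in truth],
        [t.width for t in truth],
        baseline=spec.baseline,
    )
    if spec.additive_noise > 0:
        stream = 29 if channel == "ladder" else 31
        rng = np.random.default_rng([int(spec.seed), stream])
        scale = spec.additive_noise * float(
            np.median([t.amplitude for t in truth]))
        y = y + rng.normal(0.0, scale, size=n)
    return Trace(x, y, channel)


def simulate_trace(spec: SimSpec, channel: str = "cleavage"
                   ) -> tuple[Trace, GroundTruth]:
    """Render one channel of a run: the ladder or the cleavage signal."""
    truth = _build_truth(spec, channel, deuterated=False)
    return _render(spec, truth, channel), truth


def simulate_deuterated(spec: SimSpec) -> tuple[Trace, GroundTruth]:
    """Cleavage channel of the adenine-deuterated sample.

    Identical to :func:`simulate_trace` (same seed, same noise streams) except
    that amplitudes at adenine positions of the labeled strand are multiplied
    by ``spec.f_d``.
    """
    truth = _build_truth(spec, "cleavage", deuterated=True)
    return _render(spec, truth, "cleavage"), truth


def synthetic_intensities(seq: DuplexSequence, seed: int,
                          strand: str = "forward",
                          median: float = 100.0,
                          log_sd: float = 0.3) -> dict[int, float]:
    """Log-normal per-position cleavage extents for a whole strand.

    Cleavage after every position of the labeled strand yields fragments
    1..L-1, i.e. forward positions 1..L-1 (forward label) or 2..L (reverse).
    """
    rng = np.random.default_rng([int(seed), 5 if strand == "forward" else 7])
    length = seq.length
    if strand == "forward":
        positions = range(1, length)
    else:
        positions = range(2, length + 1)
    vals = median * np.exp(rng.normal(0.0, log_sd, size=length - 1))
    return {p: float(v) for p, v in zip(positions, vals)}


def truth_to_peakset(truth: GroundTruth):
    """Ground-truth peaks as a PeakSet with analytic areas.

    Lets downstream stages (normalization, adenine calling) run on exactly
    simulated peaks without the fitting step.
    """
    from .peakfit import GaussianPeak, PeakSet

    peaks = [GaussianPeak(t.fragment_length, t.amplitude, t.center, t.width,
                          area=t.area)
             for t in sorted(truth, key=lambda t: t.center)]
    return PeakSet(peaks)


def normalized_truth_profile(spec: SimSpec, norm_window: int = 50):
    """True intensities expressed in the pipeline's normalized cleavage units.

    Applies the same consecutive-block median normalization (blocks of
    ``norm_window`` nucleotides of fragment length) that the fitting stage
    applies to measured areas, so recovered and true profiles are directly
    comparable.  Returns a CleavageProfile keyed by forward coordinates.
    """
    from .core import CleavageProfile

    items = sorted(spec.intensities.items(),
                   key=lambda kv: spec.fragment_length(kv[0]))
    lengths = np.array([spec.fragment_length(p) for p, _ in items])
    vals = np.array([v for _, v in items], dtype=float)
    block = (lengths - lengths.min()) // norm_window
    out = vals.copy()
    for b in np.unique(block):
        m = np.median(vals[block == b])
        out[block == b] = vals[block == b] / m
    return CleavageProfile({p: float(v) for (p, _), v in zip(items, out)},
                           strand=spec.strand)


def make_sim_spec(seq: DuplexSequence, seed: int, strand: str = "forward",
                  **overrides) -> SimSpec:
    """Convenience SimSpec with log-normal intensities and a spanning ladder."""
    intensities = overrides.pop(
        "intensities", synthetic_intensities(seq, seed, strand))
    if "ladder" not in overrides:
        max_frag = seq.length - 1
        ladder = sorted({1, *range(20, max_frag, 20), max_frag})
        overrides["ladder"] = tuple(ladder)
    return SimSpec(sequence=seq, intensities=intensities, seed=seed,
                   strand=strand, **overrides)
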