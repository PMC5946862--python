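# Methods

This note documents the models, parameter choices and numerical decisions
behind `groovemap`, and what the synthetic-data tests do and do not
demonstrate about real instrument data.

## Signal model and coordinate conventions

A capillary-electrophoresis channel is modeled as a baseline plus a sum of
Gaussians, `G(x) = b + Σᵢ aᵢ exp(−½((x−cᵢ)/wᵢ)²)`, sampled at integer data
points. Fragment abundance is carried by peak *area*; amplitude and width
are nuisance shape parameters that vary with migration position.

All per-nucleotide quantities share one axis: 1-based forward-strand
positions, inclusive intervals. Reverse-strand values are keyed by the
forward coordinate of the paired base, which turns cross-strand averaging
into a pure index shift. A 5′-labeled fragment of length k places its
cleavage at strand position k; on the reverse strand that is forward
coordinate L−k+1. Missing positions are absent keys, never zeros.

## Peak fitting

- **Baseline**: the global minimum intensity is subtracted from every
  sample. The model's `b` is then held at 0 during window fits.
- **Ladder detection**: local maxima above `sensitivity × max` (default
  0.1), with a matching prominence requirement and a 10-sample minimum
  separation so that noise cannot split an apex or promote a shoulder bump;
  a 3-point parabolic interpolation refines each apex to sub-sample
  precision. Plateau maxima report their leftmost sample. Detected ladder
  peaks are fit jointly as a Gaussian sum and width is regressed on data
  point (ordinary least squares; a 95% prediction interval is used
  downstream). Fewer than 3 ladder peaks cannot support the regression and
  is an error.
- **Initialization**: one peak per expected fragment; centers linearly
  interpolated in fragment length between bracketing ladder centers (no
  extrapolation outside the ladder span), amplitude read off the trace at
  the nearest sample, width from the ladder regression.
- **Three passes** over sliding windows (600 points, step 300, defaults
  from the published scheme): (i) a, c, w free, after which the width
  regression and its 95% prediction interval are recomputed globally from
  all fitted peaks; (ii) a, c free with w bounded inside that interval;
  (iii) a, c free with w fixed. The solver is bounded trust-region least
  squares with an analytic Jacobian; a ≥ 0, w > 0, c constrained within
  half the inter-peak spacing of its current value; cost tolerance 1e−8,
  200 iterations per window. A window containing no peaks is skipped with a
  log entry; non-convergence raises an error naming the window.
- **Window merging**: within each window the first and last five fitted
  peaks are biased by tails of unmodeled peaks outside the window, so each
  peak keeps the estimate from the window in which it sits deepest inside
  the fitted peak list (ties broken toward the window co-fitting more
  peaks). Interior estimates therefore always beat edge estimates, and
  trace-end peaks — which are near an edge in every window — take their
  value from the fullest window covering them and are flagged `edge_only`.
  A naive "latest window wins" rule would hand trace-end peaks to a
  degenerate sliver window fitting one peak against data contaminated by
  its unmodeled neighbor; depth ranking avoids this.
- **Integration and normalization**: each final peak is integrated
  trapezoidally at unit step over c ± 6w truncated to the trace. Areas are
  normalized by the median within consecutive, non-overlapping 50-nt blocks
  of fragment length — the only reading under which the block median of
  normalized values is exactly 1.000 (a property asserted to 1e−12; the
  even-count median introduces at most one rounding).

## Adenine calling and sequence registration

Deuteration at the 5′ carbon slows hydroxyl-radical cleavage by close to a
factor of two, so the deuterated/normal ratio of normalized areas is ~0.5
at adenines and ~1.0 elsewhere; the calling threshold 0.75 is the midpoint.
Ratios use normalized (not raw) areas, making the comparison robust to
loading differences between the two separately prepared reactions.

One subtlety: the deuterated sample's own block medians are depressed by
its reduced adenine peaks, which inflates every raw ratio in a block by the
same factor (up to ~20% at 30% adenine content). Since non-adenines are the
block majority, the median ratio per 50-nt block estimates exactly this
distortion, so ratios are recentered by it (flag `recenter_window`, default
on). The assumption — adenines are a minority of each 50-nt block — holds
for natural sequences; for A-rich designed sequences the flag should be
disabled and the threshold reconsidered.

Sequence registration scores every offset within ±10 of the nominal
labeling-based registration by the fraction of peaks whose adenine call
matches the strand sequence, breaking ties toward fuller sequence overlap
and then the smaller shift; best agreement below 0.9 is an error. Remaining
peaks are labeled by reading the registered sequence.

## Cross-strand averaging and smoothing

In B-form geometry the minor-groove partner of forward position i sits
three nucleotides toward the 3′ end of the reverse strand. In shared
forward coordinates the reverse strand's 3′ direction is decreasing, so the
default pairing is `(fwd(i) + rev(i−3))/2`, i.e. `cross_strand_offset=−3`.
Which of the two symmetric pairings — (i, i−3) or (i, i+3) — a given
laboratory convention uses, and to which position the average is keyed, is
a convention rather than a physical fact; the offset is therefore fully
configurable and only the default is asserted. Positions lacking a partner
are absent from the output.

Smoothing is locally weighted linear regression: at each of `evaluation`
(default 300) equally spaced grid points, a degree-1 fit to the nearest
`max(4, ⌈span·n⌉)` points with tricube weights, mapped back to integer
positions by linear interpolation. Defaults span = 0.015, evaluation = 300
(chosen for ~300-nt profiles). Local linear regression reproduces straight
lines exactly and commutes with affine transforms of the values. Smoothing
is applied only after cross-strand averaging, never to single strands.

## Groove width from coordinates

Minor groove width is defined as the minimum cross-strand P–P distance
minus 5.8 Å (the sum of the opposing phosphate van der Waals radii),
clamped at 0. The search is restricted to ±5 bp of stagger around the
order-paired residue, which prevents spurious minima at duplex ends; each
minimum-distance pair contributes its width to the midpoint of the two
paired forward coordinates (round half down), and coincident contributions
are averaged. This is a deliberate geometric simplification of
curvilinear-axis groove analysis: it reproduces the distance-based
definition, not any particular reference program, and it computes no
helical parameters. The output is invariant under rigid-body transforms
and monotone in uniform strand separation (both tested).

The PDB reader is a minimal fixed-column ATOM-record parser (P atoms,
altloc blank or 'A', two named chains) that reports malformed records with
their line number; residues lacking a P atom (5′ termini) are omitted.

## Statistics

Spearman's ρ is the Pearson correlation of mid-ranks (ties averaged).
Significance uses `t = ρ√((n−2)/(1−ρ²))` on n−2 degrees of freedom,
two-sided by default (sidedness is configurable; the choice does not affect
ρ itself). Stars follow α = 0.1 (\*), 0.05 (\*\*), 0.01 (\*\*\*),
0.001 (\*\*\*\*) with significance at P ≤ α; |ρ| = 1 is reported as P = 0
with four stars and flagged degenerate. Site means are unweighted. No
multiple-testing correction is applied across sites. The affine scale
calibration (least squares of width on proxy) exists purely for overlays;
rank statistics are invariant to it, asserted by a regression test.

## Synthetic data generator

The generator emulates what the fitting stage consumes: migration position
`c(len) = 100 + 10·len + 0.002·len²` (strictly increasing, slightly
super-linear, ~10 data points between consecutive fragments, so a 600-point
window holds ~40–60 peaks), width `w(c) = 2 + 0.001·c`, a constant baseline
(default 50), per-fragment multiplicative amplitude jitter (default 5%),
per-sample additive Gaussian noise (default 1% of the median amplitude),
and a deuterated variant multiplying adenine amplitudes by f_D = 0.5
("nearly a factor of two"). Intensities are proportional to peak area
(fragment abundance), so the analytic area `a·w·√(2π)` of each simulated
peak equals its true intensity; default intensities are log-normal
(median 100, log-sd 0.3). All randomness derives from the SimSpec seed;
identical specs yield bit-identical traces, and the deuterated trace of the
same spec shares the same noise streams so that f_D = 1 reproduces the
normal trace exactly. Simulation studies that model two independent
reactions (normal vs deuterated) use two seeds.

What the generator does *not* model: dye mobility shifts between channels,
baseline drift and spikes, signal decay with fragment length, peak tailing,
off-ladder artifacts, or incomplete single-hit kinetics. Passing round-trip
tests therefore demonstrate correctness of the algorithmics (deconvolution,
normalization, calling, averaging) under the stated noise model, not
robustness to every instrument pathology.

Truth-vs-recovered comparisons express the truth in the pipeline's own
units by applying the identical 50-nt block-median normalization to the
true intensities before cross-strand averaging; raw truth differs only by
per-block scale factors.

## Problem sizes and defaults used in the test suite

Unit fitting tests use 60-nt duplexes; the round-trip and recovery studies
use 300-nt (or 200-peak) simulations, a 100-seed adenine-calling study, and
exhaustive rank-formula checks up to n = 6 — sizes at which every stated
tolerance (1e−3 parameter recovery, center RMSE < 0.5, ρ ≥ 0.99) is
exercised in seconds. The pentamer lookup bundled for tests is synthetic:
it follows the qualitative A/T-narrowing trend but is not derived from
simulation or experiment, and real predictions should load a published
table via `PentamerTable.from_tsv`.

## Known limitations

- The ladder-count contract is strict: detected peak count must equal the
  ladder definition; partial ladders require editing the definition.
- Sequence registration assumes the A-spacing pattern identifies the offset
  within ±10 positions; highly repetitive or A-free windows can fail the
  0.9 agreement floor by construction.
- The groove module's order-based pairing assumes two equal-register,
  antiparallel strands; nicked or mismatched duplexes are out of scope.
- Cleavage fragments outside the ladder span are not fit (no
  extrapolation); choose a ladder spanning the fragment range of interest.
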