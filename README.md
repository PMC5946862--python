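# groovemap

Nucleotide-resolution mapping of DNA minor groove width from hydroxyl
radical cleavage electropherograms.

## The problem

The minor groove of B-DNA narrows and widens along the sequence, and many
proteins read this shape directly (often by inserting arginines into narrow,
electronegative grooves). Crystallography gives groove geometry only for the
few sequences that have been solved. Hydroxyl radical footprinting offers a
solution-phase alternative: •OH abstracts deoxyribose hydrogens at a rate
that tracks the solvent accessibility of the backbone, so per-nucleotide
cleavage extents report on local minor groove width.

`groovemap` implements the full computational pipeline that turns raw
capillary-electrophoresis (CE) traces of cleavage ladders into a
per-nucleotide minor-groove proxy, and compares that pattern against groove
widths measured from co-crystal structures or predicted by pentamer lookup
models.

## The method

1. **Peak deconvolution** (`peakfit`). A cleavage trace is modeled as
   `G(x) = b + Σᵢ aᵢ·exp(−½((x−cᵢ)/wᵢ)²)`. After global-minimum baseline
   subtraction, size-standard ladder peaks are detected and fit jointly;
   peak width is regressed on migration position. One peak per expected
   fragment is initialized (centers interpolated between ladder peaks) and
   refined in three bounded nonlinear least-squares passes over sliding
   windows of 600 data points stepped by 300: (i) a, c, w free;
   (ii) w constrained inside the 95% prediction interval of the width
   regression; (iii) w fixed. The first/last five peaks of each window are
   discarded in favor of the overlapping window. Peaks are integrated
   trapezoidally and each area is divided by the median area within its
   50-nt block, which sets every block's median cleavage value to
   exactly 1.000.
2. **Adenine calling** (`assign`). A second sample, PCR-amplified with
   5′,5″-dideuterated dATP, cleaves ~2-fold slower at adenines. Peaks whose
   deuterated/normal normalized-area ratio falls below 0.75 are called A;
   the known sequence is registered onto the peak list via the called
   adenines and all peaks are labeled.
3. **Cross-strand averaging** (`orchid2`). The nucleotide directly across
   the minor groove from forward position *i* lies 3 nt toward the reverse
   strand's 3′ end, so the groove-width proxy is
   `ORChID2(i) = (fwd(i) + rev(i−3))/2`, optionally loess-smoothed
   (span 0.015, 300 evaluation points).
4. **Reference widths** (`groove`, `orchid2`). From a PDB structure, minor
   groove width is the minimum cross-strand phosphate–phosphate distance
   minus 5.8 Å of van der Waals radii, assigned to the midpoint nucleotide.
   Alternatively a sliding-pentamer lookup table predicts naked-DNA widths.
5. **Comparison** (`compare`). Profiles are compared over binding-site
   windows by Spearman's ρ with the t approximation
   `t = ρ√((n−2)/(1−ρ²))` on n−2 degrees of freedom and the star ladder
   α = 0.1 (\*), 0.05 (\*\*), 0.01 (\*\*\*), 0.001 (\*\*\*\*). An affine
   scale calibration maps proxy units to Å for overlays (rank correlations
   are unaffected).

A seeded synthetic-electropherogram generator (`simulate`) produces ladder
and cleavage channels with full ground truth, including the deuterated
variant, so the whole pipeline is testable without instrument data. The
399-bp study construct (BamHI … Drew–Dickerson dodecamer … HindIII) is
bundled as `groovemap.INSERT_399`.

## Worked example

```
$ groovemap simulate --length 120 --seed 42 --out-dir demo
wrote simulated run to demo
$ groovemap run --config demo/run.yaml --out-dir run
INFO groovemap: sequence registration: offset +0, agreement 1.000
INFO groovemap: sequence registration: offset +0, agreement 1.000
pipeline complete: stages fit_forward, fit_reverse, assign_forward, assign_reverse, orchid2
$ head -4 run/orchid2.tsv
position        value
5       0.8044875175998616
6       0.9612746711438287
7       0.9984837487556644
```

The run directory holds the fitted peak tables (`peaks_*.tsv`, with base
calls), single-strand cleavage profiles, the raw and smoothed ORChID2
profiles, and a manifest recording the seed and config hash. Comparing the
recovered profile with the one computed from the generator's true
intensities:

```python
import groovemap as gm
orchid = gm.read_profile("run/orchid2_raw.tsv", "orchid2")
truth = gm.exp_orchid2(
    gm.read_profile("demo/truth_forward.tsv", "cleavage", strand="forward"),
    gm.read_profile("demo/truth_reverse.tsv", "cleavage", strand="reverse"))
r = gm.compare_profiles(orchid, truth, name="demo")
print(f"n={r.n} rho={r.rho:.3f} t={r.t:.2f} P={r.p:.2e} stars={r.star_string}")
# n=115 rho=0.985 t=60.91 P=2.98e-88 stars=****
```

At the generator's default noise levels (1% additive, 5% amplitude jitter)
the recovered minor-groove proxy rank-correlates with the true cleavage
pattern at ρ = 0.985 over 115 positions — the per-position values are
dimensionless normalized cleavage extents, where 1.0 is the block median
and minima mark narrow minor grooves.

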