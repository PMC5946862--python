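"""Electropherogram peak deconvolution and integration.

The cleavage signal is modeled as ``G(x) = b + sum_i a_i*exp(-0.5*((x-c_i)/w_i)^2)``
with baseline ``b``, amplitudes ``a``, centers ``c`` and widths ``w``.  The
stages, in run order:

1. baseline subtraction (global minimum),
2. ladder peak detection and length assignment,
3. joint Gaussian fit of the ladder and a linear regression of width vs
   data point,
4. initialization of one peak per expected cleavage fragment (centers
   interpolated between ladder peaks, amplitudes read off the trace, widths
   from the regression),
5. three optimization passes over sliding windows (600 points, step 300):
   (i) a, c, w free, refreshing the width regression and its 95% prediction
   interval; (ii) a, c free with w constrained inside that interval;
   (iii) a, c free with w fixed.  The first and last five peaks of each
   window are discarded and retained from the overlapping window,
6. trapezoidal integration of each fitted peak,
7. normalization by the median area within consecutive 50-nt blocks, which
   sets each block's median cleavage value to exactly 1.000.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import statsmodels.api as sm
from scipy.optimize import least_squares
from scipy.signal import find_peaks

from .core import CleavageProfile, DuplexSequence, Trace

logger = logging.getLogger("groovemap")

W_FLOOR = 1e-2  # minimal admissible width parameter, data points


class FitError(RuntimeError):
    """Raised when a nonlinear fit fails to converge."""


class LadderError(ValueError):
    """Raised when ladder detection/assignment cannot proceed."""


@dataclass
class GaussianPeak:
    """One fitted Gaussian: amplitude, center (data points), width parameter."""

    fragment_length: int | None
    a: float
    c: float
    w: float
    area: float | None = None
    normalized_area: float | None = None
    base: str | None = None
    flag: str = ""

    def __post_init__(self) -> None:
        if self.a < 0:
            raise ValueError("negative amplitude")
        if self.w <= 0:
            raise ValueError("non-positive width")


@dataclass
class PeakSet:
    """Fitted peaks ordered by center."""

    peaks: list[GaussianPeak]

    def __post_init__(self) -> None:
        c = self.centers
        if c.size > 1 and np.any(np.diff(c) <= 0):
            raise ValueError("peak centers must be strictly increasing")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i: int) -> GaussianPeak:
        return self.peaks[i]

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([p.a for p in self.peaks])

    @property
    def centers(self) -> np.ndarray:
        return np.array([p.c for p in self.peaks])

    @property
    def widths(self) -> np.ndarray:
        return np.array([p.w for p in self.peaks])

    @property
    def fragment_lengths(self) -> list[int | None]:
        return [p.fragment_length for p in self.peaks]

    def by_fragment_length(self) -> dict[int, GaussianPeak]:
        out: dict[int, GaussianPeak] = {}
        for p in self.peaks:
            if p.fragment_length is not None:
                out[p.fragment_length] = p
        return out


PEAKSET_COLUMNS = ("fragment_length", "base", "a", "c", "w", "area",
                   "normalized_area", "flag")


def write_peakset(path: str | Path, peaks: PeakSet) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(PEAKSET_COLUMNS) + "\n")
        for p in peaks:
            fields = [
                "" if p.fragment_length is None else str(p.fragment_length),
                p.base or "",
                repr(float(p.a)), repr(float(p.c)), repr(float(p.w)),
                "" if p.area is None else repr(float(p.area)),
                "" if p.normalized_area is None else repr(float(p.normalized_area)),
                p.flag,
            ]
            fh.write("\t".join(fields) + "\n")


def read_peakset(path: str | Path) -> PeakSet:
    peaks: list[GaussianPeak] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            f = line.rstrip("\n").split("\t")

            def get(name: str) -> str:
                i = idx.get(name)
                return f[i] if i is not None and i < len(f) else ""

            try:
                peaks.append(GaussianPeak(
                    fragment_length=int(get("fragment_length")) if get("fragment_length") else None,
                    base=get("base") or None,
                    a=float(get("a")), c=float(get("c")), w=float(get("w")),
                    area=float(get("area")) if get("area") else None,
                    normalized_area=float(get("normalized_area")) if get("normalized_area") else None,
                    flag=get("flag"),
                ))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return PeakSet(peaks)


@dataclass(frozen=True)
class FitConfig:
    """Tunables of the fitting stage; defaults follow the published scheme."""

    window: int = 600          # data points per sliding fit window
    shift: int = 300           # window step
    edge_discard: int = 5      # peaks dropped at each window edge
    norm_window: int = 50      # nucleotides per normalization block
    ladder_sensitivity: float = 0.1  # fraction of global max for peak detection
    ci_alpha: float = 0.05     # width-regression prediction-interval level
    tol: float = 1e-8          # cost tolerance of the nonlinear solver
    max_iter: int = 200        # solver iteration cap per window

    def __post_init__(self) -> None:
        if self.shift > self.window:
            raise ValueError("shift must not exceed window")
        if self.edge_discard < 0:
            raise ValueError("edge_discard must be >= 0")


# ---------------------------------------------------------------------------
# Baseline and ladder
# ---------------------------------------------------------------------------


def subtract_baseline(trace: Trace) -> Trace:
    """Subtract the global minimum intensity from every sample."""
    if len(trace) == 0:
        raise ValueError("empty trace")
    return Trace(trace.data_point, trace.intensity - trace.intensity.min(),
                 trace.channel)


def detect_ladder_peaks(trace: Trace, sensitivity: float = 0.1,
                        min_distance: int = 10) -> np.ndarray:
    """Local maxima exceeding ``sensitivity * global max``, ordered by position.

    Plateau maxima report their leftmost sample; maxima closer than
    ``min_distance`` samples are merged into the higher one, suppressing
    noise-split apexes (ladder peaks are far wider apart than that).
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    y = trace.intensity
    height = sensitivity * y.max()
    idx, props = find_peaks(y, height=height, prominence=height,
                            plateau_size=1, distance=max(min_distance, 1))
    left = props["left_edges"]
    centers = trace.data_point[left].astype(float)
    # sub-sample apex refinement by a 3-point parabola; plateau maxima keep
    # their leftmost sample (the parabola is degenerate there)
    for k, i in enumerate(left):
        if 0 < i < y.size - 1 and y[i - 1] < y[i] > y[i + 1]:
            denom = y[i - 1] - 2 * y[i] + y[i + 1]
            if denom < 0:
                shift = 0.5 * (y[i - 1] - y[i + 1]) / denom
                if abs(shift) <= 0.5:
                    centers[k] += shift
    return centers


def assign_ladder(centers: Sequence[float],
                  lengths: Sequence[int]) -> dict[int, float]:
    """Pair the i-th smallest detected center with the i-th smallest length."""
    centers = sorted(float(c) for c in centers)
    lengths = sorted(int(l) for l in lengths)
    if len(centers) != len(lengths):
        raise LadderError(
            f"detected {len(centers)} ladder peaks but the ladder definition "
            f"has {len(lengths)} fragments"
        )
    return dict(zip(lengths, centers))


@dataclass(frozen=True)
class WidthRegression:
    """Linear regression of fitted peak width versus data point."""

    slope: float
    intercept: float
    _result: object = field(repr=False, compare=False, default=None)

    @classmethod
    def from_points(cls, centers: np.ndarray, widths: np.ndarray) -> "WidthRegression":
        centers = np.asarray(centers, dtype=float)
        widths = np.asarray(widths, dtype=float)
        if centers.size < 3:
            raise LadderError(
                f"width regression needs >= 3 peaks, got {centers.size}"
            )
        X = sm.add_constant(centers)
        res = sm.OLS(widths, X).fit()
        return cls(slope=float(res.params[1]), intercept=float(res.params[0]),
                   _result=res)

    def predict(self, c):
        return self.intercept + self.slope * np.asarray(c, dtype=float)

    def prediction_interval(self, c, alpha: float = 0.05
                            ) -> tuple[np.ndarray, np.ndarray]:
        """Prediction interval for a new peak's width at data point(s) ``c``."""
        c = np.atleast_1d(np.asarray(c, dtype=float))
        X = sm.add_constant(c, has_constant="add")
        frame = self._result.get_prediction(X).summary_frame(alpha=alpha)
        return frame["obs_ci_lower"].to_numpy(), frame["obs_ci_upper"].to_numpy()


# ---------------------------------------------------------------------------
# Nonlinear Gaussian-sum solver
# ---------------------------------------------------------------------------


def _solve_gaussians(x: np.ndarray, y: np.ndarray,
                     a0: np.ndarray, c0: np.ndarray, w0: np.ndarray,
                     c_lo: np.ndarray, c_hi: np.ndarray,
                     w_lo: np.ndarray, w_hi: np.ndarray,
                     fit_w: bool, cfg: FitConfig, label: str
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bounded nonlinear least squares for a sum of Gaussians on one window."""
    n = a0.size
    x = np.asarray(x, dtype=float)

    if fit_w:
        p0 = np.concatenate([a0, c0, np.clip(w0, w_lo, w_hi)])
        lb = np.concatenate([np.zeros(n), c_lo, w_lo])
        ub = np.concatenate([np.full(n, np.inf), c_hi, w_hi])
    else:
        p0 = np.concatenate([a0, c0])
        lb = np.concatenate([np.zeros(n), c_lo])
        ub = np.concatenate([np.full(n, np.inf), c_hi])
    w_fixed = w0

    def unpack(p):
        if fit_w:
            return p[:n], p[n:2 * n], p[2 * n:]
        return p[:n], p[n:], w_fixed

    def resid(p):
        a, c, w = unpack(p)
        model = np.zeros_like(x)
        for ai, ci, wi in zip(a, c, w):
            model += ai * np.exp(-0.5 * ((x - ci) / wi) ** 2)
        return model - y

    def jac(p):
        a, c, w = unpack(p)
        J = np.zeros((x.size, p.size))
        for i in range(n):
            z = (x - c[i]) / w[i]
            g = np.exp(-0.5 * z * z)
            J[:, i] = g
            J[:, n + i] = a[i] * g * z / w[i]
            if fit_w:
                J[:, 2 * n + i] = a[i] * g * z * z / w[i]
        return J

    res = least_squares(resid, p0, jac=jac, bounds=(lb, ub), method="trf",
                        ftol=cfg.tol, xtol=cfg.tol, gtol=None,
                        max_nfev=cfg.max_iter)
    if res.status == 0:
        raise FitError(
            f"{label}: solver did not converge within {cfg.max_iter} iterations "
            f"(residual norm {np.linalg.norm(res.fun):.3g})"
        )
    a, c, w = unpack(res.x)
    return np.asarray(a), np.asarray(c), np.asarray(w)


def _half_gaps(c: np.ndarray) -> np.ndarray:
    """Half the distance to the nearest neighboring center, per peak."""
    if c.size == 1:
        return np.array([np.inf])
    d = np.diff(c)
    left = np.concatenate([[d[0]], d])
    right = np.concatenate([d, [d[-1]]])
    return np.minimum(left, right) / 2.0


def _estimate_width(trace: Trace, center: float) -> float:
    """Crude width from the half-max extent around an apex."""
    x, y = trace.data_point, trace.intensity
    i0 = int(np.argmin(np.abs(x - center)))
    apex = y[i0]
    if apex <= 0:
        return 1.0
    half = apex / 2.0
    r = i0
    while r + 1 < y.size and y[r + 1] > half:
        r += 1
    l = i0
    while l - 1 >= 0 and y[l - 1] > half:
        l -= 1
    fwhm = max(x[r] - x[l], 1.0)
    return float(fwhm / 2.3548)


def fit_ladder(trace: Trace, centers: Sequence[float],
               cfg: FitConfig | None = None
               ) -> tuple[PeakSet, WidthRegression]:
    """Joint Gaussian-sum fit of the size-standard channel.

    Returns the fitted ladder peaks and the linear regression of fitted width
    versus data point used to seed cleavage peak widths.
    """
    cfg = cfg or FitConfig()
    centers = np.sort(np.asarray(centers, dtype=float))
    if centers.size == 0:
        raise LadderError("no ladder centers supplied")
    a0 = np.array([max(trace.value_at(c), 1e-6) for c in centers])
    w0 = np.array([_estimate_width(trace, c) for c in centers])
    gaps = _half_gaps(centers)
    gaps = np.where(np.isfinite(gaps), gaps, 6 * w0)
    a, c, w = _solve_gaussians(
        trace.data_point, trace.intensity, a0, centers, w0,
        centers - gaps, centers + gaps,
        np.full_like(w0, W_FLOOR), np.maximum(4 * w0, 2 * gaps),
        fit_w=True, cfg=cfg, label="ladder fit",
    )
    order = np.argsort(c)
    peaks = PeakSet([GaussianPeak(None, a[i], c[i], max(w[i], W_FLOOR))
                     for i in order])
    wreg = WidthRegression.from_points(c[order], w[order])
    return peaks, wreg


# ---------------------------------------------------------------------------
# Cleavage-channel initialization and three-pass fit
# ---------------------------------------------------------------------------


def initialize_peaks(trace: Trace, ladder_map: dict[int, float],
                     fragment_lengths: Sequence[int],
                     width_reg: WidthRegression) -> PeakSet:
    """One initial peak per expected fragment.

    Centers are linearly interpolated in fragment length between bracketing
    ladder peaks (no extrapolation); amplitudes are the trace intensity at the
    nearest sample; widths come from the ladder width regression.
    """
    lengths = sorted(int(l) for l in fragment_lengths)
    lad_len = np.array(sorted(ladder_map), dtype=float)
    lad_c = np.array([ladder_map[int(l)] for l in lad_len])
    lo, hi = lad_len[0], lad_len[-1]
    out = []
    for L in lengths:
        if not lo <= L <= hi:
            raise ValueError(
                f"fragment length {L} outside ladder span [{int(lo)}, {int(hi)}]"
            )
        c = float(np.interp(L, lad_len, lad_c))
        a = max(trace.value_at(c), 0.0)
        w = float(width_reg.predict(c))
        out.append(GaussianPeak(L, a, c, max(w, W_FLOOR)))
    return PeakSet(out)


def _sliding_pass(trace: Trace, a: np.ndarray, c: np.ndarray, w: np.ndarray,
                  w_lo: np.ndarray, w_hi: np.ndarray, fit_w: bool,
                  cfg: FitConfig, pass_name: str
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """One optimization pass over sliding windows.

    Each window fits the peaks whose current center falls inside it; the
    first/last ``edge_discard`` peaks of a window keep their values only if no
    overlapping window provides an interior estimate.
    """
    x, y = trace.data_point, trace.intensity
    n = a.size
    gaps = _half_gaps(c)
    gaps = np.where(np.isfinite(gaps), gaps, np.maximum(6 * w, 1.0))
    new = [a.copy(), c.copy(), w.copy()]
    # rank of the estimate kept so far: (depth inside the window's peak list,
    # number of co-fitted peaks); deeper placement means less edge bias
    best_rank: list[tuple[int, int] | None] = [None] * n
    got_any = np.zeros(n, dtype=bool)

    start = int(x[0])
    while start <= x[-1]:
        end = start + cfg.window
        sel = np.where((c >= start) & (c < end))[0]
        if sel.size == 0:
            logger.debug("%s: window [%d, %d) contains no peaks; skipped",
                         pass_name, start, end)
            start += cfg.shift
            continue
        mask = (x >= start) & (x < end)
        fa, fc, fw = _solve_gaussians(
            x[mask], y[mask], a[sel], c[sel], w[sel],
            c[sel] - gaps[sel], c[sel] + gaps[sel],
            w_lo[sel], w_hi[sel], fit_w, cfg,
            label=f"{pass_name}: window [{start}, {end})",
        )
        ed = cfg.edge_discard
        for local, g in enumerate(sel):
            depth = min(local, sel.size - 1 - local)
            rank = (min(depth, ed), sel.size)
            if best_rank[g] is None or rank > best_rank[g]:
                new[0][g], new[1][g], new[2][g] = fa[local], fc[local], fw[local]
                best_rank[g] = rank
            got_any[g] = True
        start += cfg.shift

    edge_only = got_any & np.array(
        [r is not None and r[0] < cfg.edge_discard for r in best_rank])
    return new[0], new[1], new[2], edge_only


def fit_peaks(trace: Trace, init: PeakSet, cfg: FitConfig | None = None
              ) -> tuple[PeakSet, WidthRegression]:
    """Three-pass sliding-window optimization of the cleavage peaks.

    Pass 1 frees (a, c, w) and refreshes the width-vs-data-point regression;
    pass 2 constrains w inside that regression's 95% prediction interval;
    pass 3 fixes w and refines (a, c).
    """
    cfg = cfg or FitConfig()
    if len(init) == 0:
        raise ValueError("empty initial PeakSet")
    a, c, w = init.amplitudes, init.centers, init.widths

    free_lo = np.full(len(init), W_FLOOR)
    free_hi = np.full(len(init), np.inf)
    a, c, w, _ = _sliding_pass(trace, a, c, w, free_lo, free_hi,
                               fit_w=True, cfg=cfg, pass_name="pass 1")

    try:
        wreg = WidthRegression.from_points(c, w)
        lo, hi = wreg.prediction_interval(c, alpha=cfg.ci_alpha)
        lo = np.maximum(lo, W_FLOOR)
        hi = np.maximum(hi, lo + 1e-9)  # keep the interval non-degenerate
    except LadderError:
        # too few peaks for a width regression: leave widths unconstrained
        logger.warning("width regression skipped (<3 peaks); passes 2-3 run "
                       "with free widths")
        wreg = None
        lo, hi = np.full(c.size, W_FLOOR), np.full(c.size, np.inf)
    w = np.clip(w, lo, hi)
    a, c, w, _ = _sliding_pass(trace, a, c, w, lo, hi,
                               fit_w=True, cfg=cfg, pass_name="pass 2")

    a, c, w, edge_only = _sliding_pass(trace, a, c, w, lo, hi,
                                       fit_w=False, cfg=cfg, pass_name="pass 3")

    order = np.argsort(c)
    peaks = []
    for i in order:
        peaks.append(GaussianPeak(
            init[i].fragment_length, max(a[i], 0.0), float(c[i]),
            max(float(w[i]), W_FLOOR),
            flag="edge_only" if edge_only[i] else "",
        ))
    return PeakSet(peaks), wreg


# ---------------------------------------------------------------------------
# Integration and normalization
# ---------------------------------------------------------------------------


def integrate_peaks(peaks: PeakSet, grid: Trace | tuple[float, float],
                    extent: float = 6.0) -> PeakSet:
    """Trapezoidal area of each single-peak model at unit grid step.

    Each peak is integrated over ``c +- extent*w`` truncated to the fitted
    range (the grid bounds).
    """
    if isinstance(grid, Trace):
        x_lo, x_hi = float(grid.data_point[0]), float(grid.data_point[-1])
    else:
        x_lo, x_hi = float(grid[0]), float(grid[1])
    out = []
    for p in peaks:
        lo = max(x_lo, math.floor(p.c - extent * p.w))
        hi = min(x_hi, math.ceil(p.c + extent * p.w))
        xs = np.arange(lo, hi + 1, dtype=float)
        ys = p.a * np.exp(-0.5 * ((xs - p.c) / p.w) ** 2)
        out.append(replace(p, area=float(np.trapezoid(ys, xs))))
    return PeakSet(out)


def normalize_areas(peaks: PeakSet, norm_window: int = 50) -> PeakSet:
    """Divide each area by the median area of its 50-nt block.

    Peaks are partitioned by fragment length into consecutive non-overlapping
    blocks of ``norm_window`` nucleotides (the last block may be short); the
    median normalized area within every block is then exactly 1.000 while the
    dynamic range of individual peaks is preserved.
    """
    if any(p.area is None for p in peaks):
        raise ValueError("areas must be computed before normalization")
    if any(p.fragment_length is None for p in peaks):
        raise ValueError("fragment lengths must be assigned before normalization")
    lengths = np.array([p.fragment_length for p in peaks])
    areas = np.array([p.area for p in peaks])
    block = (lengths - lengths.min()) // norm_window
    medians = {}
    for b in np.unique(block):
        m = float(np.median(areas[block == b]))
        if m == 0:
            raise ValueError(f"zero median area in normalization block {b}")
        medians[int(b)] = m
    out = [replace(p, normalized_area=float(p.area / medians[int(b)]))
           for p, b in zip(peaks, block)]
    return PeakSet(out)


def peaks_to_profile(peaks: PeakSet, strand: str,
                     seq: DuplexSequence) -> CleavageProfile:
    """Normalized areas keyed by forward coordinate of the cleaved nucleotide.

    With a 5'-labeled strand, a fragment of length k places the cleavage at
    strand position k; on the reverse strand that is forward coordinate
    ``L - k + 1``.
    """
    if strand not in ("forward", "reverse"):
        raise ValueError(f"unknown strand {strand!r}")
    L = seq.length
    values: dict[int, float] = {}
    for p in peaks:
        if p.fragment_length is None or p.normalized_area is None:
            raise ValueError("peaks must carry fragment lengths and normalized areas")
        pos = p.fragment_length if strand == "forward" else L - p.fragment_length + 1
        if pos in values:
            raise ValueError(f"duplicate cleavage position {pos}")
        values[pos] = p.normalized_area
    return CleavageProfile(values, strand=strand)


# ---------------------------------------------------------------------------
# Convenience: full channel processing
# ---------------------------------------------------------------------------


def fit_cleavage_run(cleavage: Trace, ladder: Trace,
                     ladder_lengths: Sequence[int],
                     fragment_lengths: Sequence[int],
                     cfg: FitConfig | None = None) -> PeakSet:
    """Run the whole fitting stage for one cleavage channel.

    Baseline-subtracts both channels, detects and fits the ladder, initializes
    one peak per expected fragment, runs the three-pass fit, integrates and
    normalizes.
    """
    cfg = cfg or FitConfig()
    clv = subtract_baseline(cleavage)
    lad = subtract_baseline(ladder)
    centers = detect_ladder_peaks(lad, cfg.ladder_sensitivity)
    lmap = assign_ladder(centers, ladder_lengths)
    lad_peaks, wreg = fit_ladder(lad, list(lmap.values()), cfg)
    lmap_fitted = dict(zip(sorted(lmap), lad_peaks.centers))
    init = initialize_peaks(clv, lmap_fitted, fragment_lengths, wreg)
    fitted, _ = fit_peaks(clv, init, cfg)
    fitted = integrate_peaks(fitted, clv)
    return normalize_areas(fitted, cfg.norm_window)
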