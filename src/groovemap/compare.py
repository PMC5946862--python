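"""Rank-correlation comparison of per-position profiles.

Two profiles (e.g. an experimental cross-strand cleavage average and a
crystallographic groove-width pattern) are compared over the positions they
share with Spearman's rank correlation rho.  Significance uses the standard
t approximation ``t = rho*sqrt((n-2)/(1-rho^2))`` on n-2 degrees of freedom,
two-sided by default, with the star ladder alpha = 0.1 (*), 0.05 (**),
0.01 (***), 0.001 (****).  Because rho is rank-based it is invariant to any
affine (or monotone) rescaling of either profile, so the overlay scale
calibration below never changes a correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .core import SiteAnnotation, _Profile, extract_site

logger = logging.getLogger("groovemap")

ALPHA_LADDER = (0.1, 0.05, 0.01, 0.001)


@dataclass(frozen=True)
class ComparisonResult:
    site: str
    n: int
    rho: float
    t: float
    p: float
    stars: int
    degenerate: bool = False

    @property
    def star_string(self) -> str:
        return "*" * self.stars


@dataclass(frozen=True)
class ScaleCalibration:
    """Affine map from dimensionless proxy units to Angstrom for overlays."""

    slope: float
    intercept: float
    residual_rms: float
    reference: str = ""

    def apply(self, profile: _Profile) -> dict[int, float]:
        return {p: self.slope * v + self.intercept for p, v in profile.items()}


def spearman_rho(x, y) -> float:
    """Spearman's rank correlation: Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 paired values")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("zero rank variance: all values tied")
    return float(stats.pearsonr(rx, ry).statistic)


def rho_significance(rho: float, n: int, two_sided: bool = True
                     ) -> tuple[float, float, int]:
    """t statistic, P-value and significance stars for a Spearman rho.

    P <= alpha is significant at that rung of the ladder; a perfect |rho| = 1
    is reported as P = 0 with four stars and flagged degenerate upstream.
    """
    if n < 3:
        raise ValueError("significance needs n >= 3")
    if abs(rho) >= 1.0:
        return math.inf if rho > 0 else -math.inf, 0.0, len(ALPHA_LADDER)
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    tail = stats.t.sf(abs(t), df=n - 2)
    p = 2.0 * tail if two_sided else (tail if t >= 0 else 1.0 - tail)
    stars = sum(p <= alpha for alpha in ALPHA_LADDER)
    return t, float(p), stars


def compare_profiles(a: _Profile, b: _Profile, name: str = "",
                     two_sided: bool = True) -> ComparisonResult:
    """ComparisonResult over the intersection of defined positions."""
    common = sorted(set(a.values) & set(b.values))
    if len(common) < 3:
        raise ValueError(
            f"site {name!r}: only {len(common)} common positions (need >= 3)"
        )
    x = [a[p] for p in common]
    y = [b[p] for p in common]
    rho = spearman_rho(x, y)
    degenerate = abs(rho) >= 1.0
    t, p, stars = rho_significance(rho, len(common), two_sided=two_sided)
    return ComparisonResult(name, len(common), rho, t, p, stars,
                            degenerate=degenerate)


def compare_sites(a: _Profile, b: _Profile, sites: list[SiteAnnotation],
                  two_sided: bool = True
                  ) -> tuple[list[ComparisonResult], float]:
    """Per-site comparisons and the unweighted mean rho across sites.

    Sites with fewer than 3 common positions are excluded with a warning.
    """
    results = []
    for site in sites:
        try:
            results.append(compare_profiles(
                extract_site(a, site), extract_site(b, site),
                name=site.name, two_sided=two_sided))
        except ValueError as exc:
            logger.warning("site %s excluded: %s", site.name, exc)
    if not results:
        raise ValueError("no site had enough common positions")
    mean_rho = float(np.mean([r.rho for r in results]))
    return results, mean_rho


def calibrate_scale(orchid: _Profile, groove: _Profile,
                    reference: str = "") -> ScaleCalibration:
    """Least-squares affine map from proxy units to Angstrom over a window.

    Fits ``groove ~ slope*orchid + intercept`` on the common positions of the
    two profiles; applying the map (see ScaleCalibration.apply) is a separate
    pure transform and cannot change any rank correlation.
    """
    common = sorted(set(orchid.values) & set(groove.values))
    if len(common) < 2:
        raise ValueError("calibration needs >= 2 paired positions")
    x = np.array([orchid[p] for p in common])
    y = np.array([groove[p] for p in common])
    if np.ptp(x) == 0:
        raise ValueError("zero variance in proxy values; cannot calibrate")
    slope, intercept = np.polyfit(x, y, deg=1)
    resid = y - (slope * x + intercept)
    return ScaleCalibration(float(slope), float(intercept),
                            float(np.sqrt(np.mean(resid ** 2))), reference)


def write_comparisons(path: str | Path, results: list[ComparisonResult],
                      mean_rho: float | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("site\tn\trho\tt\tP\tstars\n")
        for r in results:
            fh.write(f"{r.site}\t{r.n}\t{r.rho:.4f}\t{r.t:.4f}\t"
                     f"{r.p:.3e}\t{r.star_string}\n")
        if mean_rho is not None:
            fh.write(f"# mean_rho\t{mean_rho:.4f}\n")
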