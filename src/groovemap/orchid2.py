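"""Cross-strand averaging, loess smoothing, and pentamer-table prediction.

In B-form DNA the nucleotide directly across the minor groove from position i
of the forward strand sits three nucleotides toward the 3' end of the reverse
strand.  Averaging the two strands' normalized cleavage values over that
stagger yields the ORChID2 profile, a per-position proxy for minor groove
width.  Because the reverse strand's 3' direction runs toward decreasing
forward coordinates, the default pairing is ``(fwd(i) + rev(i - 3)) / 2``;
the sign and magnitude of the stagger are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (CleavageProfile, DuplexSequence, GrooveWidthProfile,
                   ORChID2Profile, reverse_complement)


@dataclass(frozen=True)
class Orchid2Config:
    cross_strand_offset: int = -3  # forward-coordinate shift applied to the reverse strand
    span: float = 0.015            # loess span (fraction of points per local window)
    evaluation: int = 300          # loess evaluation grid size

    def __post_init__(self) -> None:
        if not 0 < self.span <= 1:
            raise ValueError("span must be in (0, 1]")
        if self.evaluation < 2:
            raise ValueError("evaluation must be >= 2")


def exp_orchid2(fwd: CleavageProfile, rev: CleavageProfile,
                cfg: Orchid2Config | None = None) -> ORChID2Profile:
    """Average each forward value with its minor-groove partner on the reverse.

    ``value(i) = (fwd(i) + rev(i + offset)) / 2`` wherever both strands are
    defined; positions lacking a partner are absent from the output.
    """
    cfg = cfg or Orchid2Config()
    off = cfg.cross_strand_offset
    values = {}
    for i, v in fwd.items():
        j = i + off
        if j in rev:
            values[i] = 0.5 * (v + rev[j])
    if not values:
        raise ValueError("no overlap between strands at the configured offset")
    return ORChID2Profile(values)


def loess_smooth(profile: ORChID2Profile, span: float = 0.015,
                 evaluation: int = 300) -> ORChID2Profile:
    """Locally weighted linear regression smoothing.

    At each of ``evaluation`` equally spaced grid points over the position
    range, a degree-1 regression is fit to the nearest ``max(4, ceil(span*n))``
    points with tricube weights, and the grid values are mapped back to the
    integer positions by linear interpolation.
    """
    pos, val = profile.to_arrays()
    n = pos.size
    k = max(4, int(np.ceil(span * n)))
    if n < k:
        raise ValueError(f"need >= {k} points for span {span}, got {n}")
    x = pos.astype(float)
    grid = np.linspace(x[0], x[-1], evaluation)
    fitted = np.empty(evaluation)
    for m, g in enumerate(grid):
        d = np.abs(x - g)
        idx = np.argpartition(d, k - 1)[:k]
        dk = d[idx]
        dmax = dk.max()
        w = np.ones_like(dk) if dmax == 0 else (1 - (dk / dmax) ** 3) ** 3
        sw = w.sum()
        xm = (w * x[idx]).sum() / sw
        ym = (w * val[idx]).sum() / sw
        var = (w * (x[idx] - xm) ** 2).sum()
        slope = ((w * (x[idx] - xm) * (val[idx] - ym)).sum() / var
                 if var > 0 else 0.0)
        fitted[m] = ym + slope * (g - xm)
    smoothed = np.interp(x, grid, fitted)
    return ORChID2Profile(dict(zip(pos.tolist(), smoothed.tolist())),
                          smoothed=True)


# ---------------------------------------------------------------------------
# Pentamer lookup prediction
# ---------------------------------------------------------------------------


@dataclass
class PentamerTable:
    """Pentamer -> minor groove width (Angstrom) lookup.

    With ``strand_symmetric`` set, a pentamer and its reverse complement share
    one value and either key resolves.
    """

    values: dict[str, float]
    strand_symmetric: bool = False

    def __post_init__(self) -> None:
        for k, v in self.values.items():
            if len(k) != 5 or any(ch not in "ACGT" for ch in k):
                raise ValueError(f"invalid pentamer key {k!r}")
            if not np.isfinite(v):
                raise ValueError(f"non-finite value for pentamer {k}")
        if self.strand_symmetric:
            for k, v in list(self.values.items()):
                rc = reverse_complement(k)
                if rc in self.values and self.values[rc] != v:
                    raise ValueError(
                        f"strand-symmetric table disagrees on {k}/{rc}")
                self.values.setdefault(rc, v)

    def __getitem__(self, pentamer: str) -> float:
        if pentamer in self.values:
            return self.values[pentamer]
        raise KeyError(f"pentamer {pentamer} missing from table")

    @classmethod
    def from_tsv(cls, path: str | Path,
                 strand_symmetric: bool = False) -> "PentamerTable":
        values: dict[str, float] = {}
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                fields = line.split("\t")
                if lineno == 1 and fields[0].lower() in ("pentamer", "kmer"):
                    continue
                if len(fields) < 2:
                    raise ValueError(f"{path}: line {lineno}: expected 2 columns")
                values[fields[0].upper()] = float(fields[1])
        return cls(values, strand_symmetric=strand_symmetric)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("pentamer\tvalue\n")
            for k in sorted(self.values):
                fh.write(f"{k}\t{self.values[k]!r}\n")


def synthetic_pentamer_table() -> PentamerTable:
    """A synthetic stand-in lookup for tests and demos.

    Values follow the qualitative trend of B-DNA (A/T-rich pentamers have
    narrower minor grooves) but are NOT derived from simulation or experiment:
    width = 6.0 - 0.4*(A/T count) - 0.3*(central A/T count).  The construction
    is reverse-complement invariant, so the table is strand-symmetric.
    """
    values = {}
    bases = "ACGT"
    for i in range(4 ** 5):
        p = "".join(bases[(i // 4 ** j) % 4] for j in range(4, -1, -1))
        at = sum(ch in "AT" for ch in p)
        at_mid = sum(ch in "AT" for ch in p[1:4])
        values[p] = 6.0 - 0.4 * at - 0.3 * at_mid
    return PentamerTable(values, strand_symmetric=True)


def predict_pentamer_mgw(seq: DuplexSequence,
                         table: PentamerTable) -> GrooveWidthProfile:
    """Slide a pentamer window over the duplex; assign each table value to the
    central position.  Output covers positions 3..L-2."""
    if seq.length < 5:
        raise ValueError("sequence shorter than one pentamer")
    values = {}
    for start in range(seq.length - 4):
        pent = seq.forward[start:start + 5]
        values[start + 3] = table[pent]
    return GrooveWidthProfile(values)
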