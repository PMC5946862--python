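"""Minor groove width from 3D coordinates of a DNA duplex.

Width at a nucleotide is defined geometrically: the minimum distance between
phosphate atoms on opposite strands, minus 5.8 Angstrom for the two phosphate
van der Waals radii.  The search for the opposite-strand partner is capped at
a +-5 bp stagger around the paired residue to avoid spurious minima at duplex
ends, each minimum-distance pair contributes its width to the midpoint
nucleotide position (round half down), and contributions landing on the same
position are averaged.  This is a deliberate geometric simplification of
curvilinear-axis groove analysis; it reproduces the definition, not any
particular reference implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import GrooveWidthProfile

PHOSPHATE_VDW_SUM = 5.8  # Angstrom, sum of opposing phosphate vdW radii


@dataclass
class BackboneModel:
    """Ordered phosphate coordinates for the two strands of a duplex.

    Strands are listed 5'->3'; residue ``k`` (0-based list index) of strand A
    is taken to pair with residue ``n_b - 1 - k`` of strand B (antiparallel
    pairing by order).
    """

    strand_a: list[tuple[int, np.ndarray]]
    strand_b: list[tuple[int, np.ndarray]]

    def __post_init__(self) -> None:
        for name, strand in (("A", self.strand_a), ("B", self.strand_b)):
            resids = [r for r, _ in strand]
            if any(b <= a for a, b in zip(resids, resids[1:])):
                raise ValueError(f"strand {name}: residue indices must increase")
            for r, xyz in strand:
                if not np.all(np.isfinite(xyz)):
                    raise ValueError(f"strand {name}: non-finite coordinates "
                                     f"at residue {r}")

    def coords(self, which: str) -> np.ndarray:
        strand = self.strand_a if which == "a" else self.strand_b
        return np.array([xyz for _, xyz in strand], dtype=float)


@dataclass(frozen=True)
class GrooveParams:
    vdw_offset: float = PHOSPHATE_VDW_SUM  # Angstrom subtracted from P-P distance
    stagger: int = 5                       # bp searched around the paired residue
    clamp_at_zero: bool = True             # clip negative raw widths to 0

    def __post_init__(self) -> None:
        if self.vdw_offset <= 0:
            raise ValueError("vdw_offset must be positive")


def parse_structure(path: str | Path, chain_a: str, chain_b: str) -> BackboneModel:
    """Read phosphate (P) atoms of two chains from PDB-format ATOM records.

    Only altloc ' ' or 'A' atoms are kept; residues without a P atom (5'
    termini) are omitted.  Malformed ATOM records raise with the line number.
    """
    strands: dict[str, dict[int, np.ndarray]] = {chain_a: {}, chain_b: {}}
    seen_chains: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith("ATOM"):
                continue
            try:
                atom_name = line[12:16].strip()
                altloc = line[16]
                chain = line[21]
                resid = int(line[22:26])
                xyz = np.array([float(line[30:38]), float(line[38:46]),
                                float(line[46:54])])
            except (ValueError, IndexError) as exc:
                raise ValueError(
                    f"{path}: line {lineno}: malformed ATOM record ({exc})"
                ) from exc
            seen_chains.add(chain)
            if atom_name != "P" or altloc not in (" ", "A"):
                continue
            if chain in strands:
                strands[chain][resid] = xyz
    for chain in (chain_a, chain_b):
        if chain not in seen_chains:
            raise ValueError(f"{path}: chain {chain!r} not present")
        if not strands[chain]:
            raise ValueError(f"{path}: chain {chain!r} has no P atoms")
    return BackboneModel(
        strand_a=[(r, strands[chain_a][r]) for r in sorted(strands[chain_a])],
        strand_b=[(r, strands[chain_b][r]) for r in sorted(strands[chain_b])],
    )


def _round_half_down(x: float) -> int:
    return int(np.ceil(x - 0.5))


def minor_groove_width(model: BackboneModel,
                       params: GrooveParams | None = None) -> GrooveWidthProfile:
    """Per-nucleotide minor groove width along strand A (1-based positions).

    For each strand-A phosphate, the closest opposite-strand phosphate within
    the stagger window is found; the pair's width (distance minus the vdW
    offset, clamped at zero if enabled) is assigned to the midpoint position
    of the two paired forward coordinates, and coincident contributions are
    averaged.
    """
    params = params or GrooveParams()
    pa = model.coords("a")
    pb = model.coords("b")
    na, nb = len(pa), len(pb)
    if min(na, nb) < 2 * params.stagger:
        raise ValueError(
            f"need >= {2 * params.stagger} residues per strand, got {na} and {nb}"
        )
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    for k in range(na):
        paired = nb - 1 - k
        j_lo = max(0, paired - params.stagger)
        j_hi = min(nb - 1, paired + params.stagger)
        if j_lo > j_hi:
            continue
        d = np.linalg.norm(pb[j_lo:j_hi + 1] - pa[k], axis=1)
        j = j_lo + int(np.argmin(d))
        width = float(d[j - j_lo]) - params.vdw_offset
        if params.clamp_at_zero:
            width = max(width, 0.0)
        partner_fwd = nb - 1 - j  # forward coordinate of the partner's pair
        pos = _round_half_down((k + partner_fwd) / 2.0) + 1  # 1-based
        sums[pos] = sums.get(pos, 0.0) + width
        counts[pos] = counts.get(pos, 0) + 1
    values = {p: sums[p] / counts[p] for p in sums}
    return GrooveWidthProfile(values)
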