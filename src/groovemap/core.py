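"""Shared data model and tabular I/O for minor-groove mapping.

Coordinate convention
---------------------
All per-nucleotide quantities live on a single axis: 1-based positions on the
forward strand, intervals inclusive at both ends.  Reverse-strand quantities
are keyed by the forward coordinate of the paired base, so a cross-strand
operation is a pure index shift.  Missing positions are represented by an
absent key, never by zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
from Bio import SeqIO

logger = logging.getLogger("groovemap")

COMPLEMENT = str.maketrans("ACGT", "TGCA")
VALID_BASES = frozenset("ACGT")

#: Forward strand of the 399-bp study construct: a BamHI site, eleven
#: transcription-factor binding sites plus the Drew-Dickerson dodecamer
#: (CGCGAATTCGCG), and a terminal HindIII site.
INSERT_399 = (
    "GGATCCGGCTGAAGGTACAGACCCTTTAGTCAGTCTAGGATCATATGCCCAAACGGAACCCCAG"
    "CTGTGATTTATGGCGTGGTTACATGTAAAAATTTACATCTTAGACCCACATTTGAAAGGCAAATGG"
    "AGTACGTGTTTTTTAAAAAAATGTCCACGGGGGTCCTATAGAACTTTCCCACAGAGTATAGTACAA"
    "ACTTTCTTGTATATAACTCACTAATTGAAGGCGCGAATTCGCGGTATGCAAATAAGGGATGCGTCC"
    "TCATGTATATACATGAGGAAGCGTGTTAGCTGTCATAAAGTTGTCACGGAGCGCAATTACCTAA"
    "TAGGGAAATTTACACGCTAGGGACGCTATTATCGCTATTAGTATAGCACGATACACGAAAACGC"
    "AGGAAGCTT"
)


def _validate_bases(seq: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in VALID_BASES:
            raise ValueError(
                f"invalid base {ch!r} at position {i + 1}: only A/C/G/T accepted"
            )


def reverse_complement(seq: str) -> str:
    """Watson-Crick complement of ``seq``, reversed (5'->3' of the other strand)."""
    _validate_bases(seq)
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True)
class DuplexSequence:
    """A blunt double-stranded DNA molecule addressed on the forward strand.

    ``forward`` is the forward strand 5'->3'.  Position ``p`` (1-based) on the
    reverse strand means the base paired with forward position ``p``; the
    reverse strand read 5'->3' is the reverse complement, whose k-th base sits
    at forward coordinate ``L - k + 1``.
    """

    forward: str

    def __post_init__(self) -> None:
        _validate_bases(self.forward)
        if not self.forward:
            raise ValueError("empty sequence")

    @property
    def length(self) -> int:
        return len(self.forward)

    def __len__(self) -> int:
        return len(self.forward)

    @property
    def reverse(self) -> str:
        """Reverse strand, 5'->3'."""
        return reverse_complement(self.forward)

    def base(self, position: int, strand: str = "forward") -> str:
        """Base at a forward coordinate, on either strand."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside 1..{self.length}")
        b = self.forward[position - 1]
        if strand == "forward":
            return b
        if strand == "reverse":
            return b.translate(COMPLEMENT)
        raise ValueError(f"unknown strand {strand!r}")

    def strand_sequence(self, strand: str) -> str:
        if strand == "forward":
            return self.forward
        if strand == "reverse":
            return self.reverse
        raise ValueError(f"unknown strand {strand!r}")


@dataclass(frozen=True)
class SiteAnnotation:
    """A named interval on the forward strand, 1-based and inclusive."""

    name: str
    start: int
    end: int
    protein: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"site {self.name!r}: require 1 <= start <= end, got "
                f"[{self.start}, {self.end}]"
            )

    def validate_against(self, seq_length: int) -> None:
        if self.end > seq_length:
            raise ValueError(
                f"site {self.name!r} [{self.start}, {self.end}] exceeds sequence "
                f"length {seq_length}"
            )

    @property
    def positions(self) -> range:
        return range(self.start, self.end + 1)


# ---------------------------------------------------------------------------
# Per-position profiles
# ---------------------------------------------------------------------------


@dataclass
class _Profile:
    values: dict[int, float]

    def __post_init__(self) -> None:
        clean: dict[int, float] = {}
        for pos, val in self.values.items():
            p = int(pos)
            v = float(val)
            if p < 1:
                raise ValueError(f"position {p} < 1")
            if not math.isfinite(v):
                raise ValueError(f"non-finite value at position {p}")
            clean[p] = v
        self.values = dict(sorted(clean.items()))

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, position: int) -> float:
        return self.values[position]

    def __contains__(self, position: int) -> bool:
        return position in self.values

    def items(self) -> Iterator[tuple[int, float]]:
        return iter(self.values.items())

    @property
    def positions(self) -> np.ndarray:
        return np.fromiter(self.values.keys(), dtype=int)

    def to_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return self.positions, np.fromiter(self.values.values(), dtype=float)


@dataclass
class CleavageProfile(_Profile):
    """Median-normalized hydroxyl radical cleavage extents for one strand.

    Keyed by forward coordinates even for the reverse strand.
    """

    strand: str = "forward"

    def __post_init__(self) -> None:
        super().__post_init__()
        if self.strand not in ("forward", "reverse"):
            raise ValueError(f"unknown strand {self.strand!r}")
        for pos, val in self.values.items():
            if val < 0:
                raise ValueError(f"negative cleavage value at position {pos}")


@dataclass
class ORChID2Profile(_Profile):
    """Cross-strand averaged cleavage: a dimensionless minor-groove-width proxy."""

    smoothed: bool = False


@dataclass
class GrooveWidthProfile(_Profile):
    """Minor groove width per nucleotide position, in Angstrom."""

    def __post_init__(self) -> None:
        super().__post_init__()
        for pos, val in self.values.items():
            if val < 0:
                raise ValueError(f"negative groove width at position {pos}")


PROFILE_KINDS = {
    "cleavage": CleavageProfile,
    "orchid2": ORChID2Profile,
    "groove": GrooveWidthProfile,
}


def write_profile(path: str | Path, profile: _Profile) -> None:
    """Write a profile as two-column TSV (position, value), full precision."""
    with open(path, "w") as fh:
        fh.write("position\tvalue\n")
        for pos, val in profile.items():
            fh.write(f"{pos}\t{float(val)!r}\n")


def read_profile(path: str | Path, kind: str | type = "cleavage", **kwargs) -> _Profile:
    """Read a two-column TSV profile.

    ``kind`` selects the profile class ("cleavage", "orchid2", "groove" or the
    class itself); extra keyword arguments (e.g. ``strand``) are forwarded.
    Duplicate positions and non-numeric fields are rejected.
    """
    cls = PROFILE_KINDS[kind] if isinstance(kind, str) else kind
    values: dict[int, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            if lineno == 1 and fields[0].lower() in ("position", "pos"):
                continue
            try:
                pos = int(fields[0])
                val = float(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric field") from exc
            if pos in values:
                raise ValueError(f"{path}: line {lineno}: duplicate position {pos}")
            values[pos] = val
    return cls(values, **kwargs)


def extract_site(profile: _Profile, site: SiteAnnotation,
                 seq_length: int | None = None) -> _Profile:
    """Restrict a profile to the positions of ``site`` that it defines."""
    if seq_length is not None:
        site.validate_against(seq_length)
    sub = {p: v for p, v in profile.items() if site.start <= p <= site.end}
    return replace(profile, values=sub)


# ---------------------------------------------------------------------------
# Electropherogram traces
# ---------------------------------------------------------------------------


@dataclass
class Trace:
    """One fluorescence channel: intensity sampled at integer data points."""

    data_point: np.ndarray
    intensity: np.ndarray
    channel: str = ""

    def __post_init__(self) -> None:
        self.data_point = np.asarray(self.data_point, dtype=int)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.data_point.shape != self.intensity.shape:
            raise ValueError("data_point and intensity lengths differ")
        if self.data_point.size and np.any(np.diff(self.data_point) <= 0):
            raise ValueError("data points must be strictly increasing")

    def __len__(self) -> int:
        return self.data_point.size

    def value_at(self, x: float) -> float:
        """Intensity at the sample nearest to ``x``."""
        idx = int(np.clip(np.searchsorted(self.data_point, round(x)),
                          0, len(self) - 1))
        # searchsorted may land one past the closest sample
        if idx > 0 and abs(self.data_point[idx - 1] - x) <= abs(self.data_point[idx] - x):
            idx -= 1
        return float(self.intensity[idx])


def write_trace(path: str | Path, trace: Trace) -> None:
    with open(path, "w") as fh:
        fh.write("data_point\tintensity\n")
        for x, y in zip(trace.data_point, trace.intensity):
            fh.write(f"{int(x)}\t{float(y)!r}\n")


def read_trace(path: str | Path, channel: str = "") -> Trace:
    xs: list[int] = []
    ys: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() in ("data_point", "datapoint"):
                continue
            if len(fields) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            try:
                xs.append(int(fields[0]))
                ys.append(float(fields[1]))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric field") from exc
    return Trace(np.array(xs, dtype=int), np.array(ys, dtype=float), channel)


# ---------------------------------------------------------------------------
# Sequence and site readers
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> DuplexSequence:
    """First record of a FASTA file as a DuplexSequence."""
    for record in SeqIO.parse(str(path), "fasta"):
        return DuplexSequence(str(record.seq).upper())
    raise ValueError(f"{path}: no FASTA records found")


def write_fasta(path: str | Path, seq: DuplexSequence, name: str = "sequence") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, seq.length, 70):
            fh.write(seq.forward[i:i + 70] + "\n")


def read_sites(path: str | Path, fmt: str = "tsv",
               seq_length: int | None = None) -> list[SiteAnnotation]:
    """Read site annotations.

    ``fmt="tsv"``: native 1-based inclusive columns (name, start, end[, protein]).
    ``fmt="bed"``: BED 0-based half-open (chrom, start, end, name); converted to
    1-based inclusive on read and logged.
    """
    sites: list[SiteAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if fmt == "tsv":
                if lineno == 1 and fields[0].lower() == "name":
                    continue
                if len(fields) < 3:
                    raise ValueError(f"{path}: line {lineno}: expected >=3 columns")
                name, start, end = fields[0], int(fields[1]), int(fields[2])
                protein = fields[3] if len(fields) > 3 else ""
            elif fmt == "bed":
                if len(fields) < 3:
                    raise ValueError(f"{path}: line {lineno}: expected >=3 columns")
                start0, end0 = int(fields[1]), int(fields[2])
                start, end = start0 + 1, end0
                name = fields[3] if len(fields) > 3 else f"site{lineno}"
                protein = ""
                logger.info(
                    "BED interval [%d, %d) converted to 1-based inclusive [%d, %d]",
                    start0, end0, start, end,
                )
            else:
                raise ValueError(f"unknown site format {fmt!r}")
            site = SiteAnnotation(name, start, end, protein)
            if seq_length is not None:
                site.validate_against(seq_length)
            sites.append(site)
    return sites


def write_sites(path: str | Path, sites: list[SiteAnnotation]) -> None:
    with open(path, "w") as fh:
        fh.write("name\tstart\tend\tprotein\n")
        for s in sites:
            fh.write(f"{s.name}\t{s.start}\t{s.end}\t{s.protein}\n")
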