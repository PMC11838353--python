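"""Recombination maps and the uniform centiMorgan testing grid.

A genetic map gives, per chromosome, a monotone correspondence between
physical position (base pairs) and genetic position (centiMorgans).
Selection-scan statistics are evaluated on a grid of focal positions
spaced a constant genetic distance apart; this module reads the map,
interpolates between coordinate systems, and lays down that grid.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GeneticMap",
    "ScanGrid",
    "MapFormatError",
    "read_genetic_map",
    "uniform_map",
    "build_grid",
]


class MapFormatError(ValueError):
    """Raised when a recombination map file violates format invariants."""


class OutOfRangeError(ValueError):
    """Raised when a query position lies outside the mapped range."""


@dataclass
class GeneticMap:
    """Per-chromosome monotone (bp, cM) interpolation tables.

    ``tables`` maps chromosome id to a pair of arrays ``(bp, cm)`` with
    ``bp`` strictly increasing and ``cm`` non-decreasing.
    """

    tables: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.tables)

    def add_chromosome(self, chrom: str, bp, cm) -> None:
        bp = np.asarray(bp, dtype=float)
        cm = np.asarray(cm, dtype=float)
        if bp.size != cm.size:
            raise MapFormatError(f"chromosome {chrom}: bp/cm length mismatch")
        # collapse duplicate bp entries to one record each
        bp, idx = np.unique(bp, return_index=True)
        cm = cm[np.sort(idx)]
        if bp.size < 2:
            raise MapFormatError(
                f"chromosome {chrom}: fewer than 2 distinct map records"
            )
        if np.any(np.diff(cm) < 0):
            raise MapFormatError(f"chromosome {chrom}: cM column not non-decreasing")
        self.tables[chrom] = (bp, cm)

    def span_cm(self, chrom: str) -> tuple[float, float]:
        """Genetic start and end of a chromosome's mapped range."""
        _, cm = self.tables[chrom]
        return float(cm[0]), float(cm[-1])

    def length_cm(self, chrom: str) -> float:
        lo, hi = self.span_cm(chrom)
        return hi - lo

    def interpolate(self, chrom: str, query, direction: str = "bp_to_cm"):
        """Piecewise-linear interpolation between physical and genetic coordinates.

        Parameters
        ----------
        chrom : chromosome id present in the map.
        query : scalar or array of positions (bp or cM depending on direction).
        direction : ``"bp_to_cm"`` or ``"cm_to_bp"``.  The inverse direction
            uses the same piecewise-linear function; flat cM stretches (zero
            recombination) resolve deterministically to the leftmost bp knot.

        Raises
        ------
        OutOfRangeError : query lies outside the chromosome's mapped range.
        """
        if chrom not in self.tables:
            raise KeyError(f"chromosome {chrom!r} not in map")
        bp, cm = self.tables[chrom]
        q = np.asarray(query, dtype=float)
        scalar = q.ndim == 0
        q = np.atleast_1d(q)
        if direction == "bp_to_cm":
            x, y = bp, cm
        elif direction == "cm_to_bp":
            # np.interp on a non-decreasing x returns the value at the first
            # matching knot, i.e. flat stretches invert to the left knot.
            x, y = cm, bp
        else:
            raise ValueError(f"unknown direction {direction!r}")
        if np.any(q < x[0]) or np.any(q > x[-1]):
            raise OutOfRangeError(
                f"query outside mapped range [{x[0]}, {x[-1]}] on chromosome {chrom}"
            )
        out = np.interp(q, x, y)
        if direction == "cm_to_bp":
            # at cM values hit by several knots (flat stretch) np.interp
            # lands on the right knot; resolve to the leftmost bp instead
            idx = np.searchsorted(x, q, side="left")
            exact = (idx < x.size) & (x[np.minimum(idx, x.size - 1)] == q)
            out[exact] = y[idx[exact]]
        return float(out[0]) if scalar else out


def _open_text(path):
    with open(path, "rb") as raw:
        head = raw.read(2)
    if head == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return io.open(path, "rt")


def read_genetic_map(path, dialect: str = "plink") -> GeneticMap:
    """Read a recombination map file.

    Dialects
    --------
    ``plink`` : 4 whitespace-separated columns — chrom, id, cM, bp.
    ``tsv``   : 3 columns — chrom, bp, cM.

    Files may be gzip-compressed.  Records are grouped by chromosome; within
    each chromosome bp must be strictly increasing (duplicates collapsed) and
    cM non-decreasing.
    """
    if dialect not in ("plink", "tsv"):
        raise ValueError(f"unknown map dialect {dialect!r}")
    per_chrom: dict[str, list[tuple[float, float]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            try:
                if dialect == "plink":
                    chrom, _id, cm, bp = parts[0], parts[1], float(parts[2]), float(parts[3])
                else:
                    chrom, bp, cm = parts[0], float(parts[1]), float(parts[2])
            except (IndexError, ValueError) as exc:
                raise MapFormatError(f"{path}:{lineno}: cannot parse map record") from exc
            per_chrom.setdefault(chrom, []).append((bp, cm))
    gmap = GeneticMap()
    for chrom, recs in per_chrom.items():
        bp = np.array([r[0] for r in recs])
        cm = np.array([r[1] for r in recs])
        uniq_bp = np.unique(bp)
        if uniq_bp.size != bp.size:
            # collapse exact duplicate bp rows, keeping first occurrence
            _, first = np.unique(bp, return_index=True)
            keep = np.sort(first)
            bp, cm = bp[keep], cm[keep]
        if np.any(np.diff(bp) < 0):
            raise MapFormatError(f"chromosome {chrom}: bp column not increasing")
        gmap.add_chromosome(chrom, bp, cm)
    return gmap


def uniform_map(chrom_lengths_cm: dict[str, float] | list[float],
                bp_per_cm: float = 1e6) -> GeneticMap:
    """Build a constant-recombination-rate map (useful for simulation).

    ``chrom_lengths_cm`` may be a dict ``{chrom: length}`` or a list of
    lengths (chromosomes then named ``"1"``, ``"2"``, ...).
    """
    if not isinstance(chrom_lengths_cm, dict):
        chrom_lengths_cm = {str(i + 1): l for i, l in enumerate(chrom_lengths_cm)}
    gmap = GeneticMap()
    for chrom, length in chrom_lengths_cm.items():
        gmap.add_chromosome(chrom, [0.0, length * bp_per_cm], [0.0, length])
    return gmap


@dataclass
class ScanGrid:
    """Uniform-Δ grid of focal testing positions over all chromosomes.

    Attributes
    ----------
    delta_cm : grid spacing in cM.
    chrom_ids : chromosome of each grid point (length M).
    cm : genetic position of each grid point, in cM.
    bp : interpolated physical position of each grid point.
    offsets : dict chrom -> (start index, stop index) into the flat arrays.
    L_morgans : total genetic length of the genome in Morgans (untrimmed).
    """

    delta_cm: float
    chrom_ids: np.ndarray
    cm: np.ndarray
    bp: np.ndarray
    offsets: dict[str, tuple[int, int]]
    L_morgans: float

    @property
    def M(self) -> int:
        """Total number of grid points (hypothesis tests)."""
        return self.cm.size

    @property
    def C(self) -> int:
        """Number of chromosomes."""
        return len(self.offsets)

    @property
    def delta_morgans(self) -> float:
        return self.delta_cm / 100.0

    def chrom_slice(self, chrom: str) -> slice:
        a, b = self.offsets[chrom]
        return slice(a, b)

    def chrom_sizes(self) -> dict[str, int]:
        return {c: b - a for c, (a, b) in self.offsets.items()}


def build_grid(gmap: GeneticMap, delta_cm: float, trim_cm: float = 0.0) -> ScanGrid:
    """Lay down the uniform testing grid on a genetic map.

    Per chromosome, points run from ``start + trim_cm`` to ``end - trim_cm``
    in steps of ``delta_cm`` (both endpoints inclusive when they land on the
    grid).  Trimming by the segment detection threshold avoids focal
    positions near chromosome ends that no sufficiently long segment could
    fully flank.  ``L_morgans`` is the untrimmed total genetic length.
    """
    if delta_cm <= 0:
        raise ValueError("delta_cm must be positive")
    if trim_cm < 0:
        raise ValueError("trim_cm must be non-negative")
    chroms, cms, bps = [], [], []
    offsets: dict[str, tuple[int, int]] = {}
    total_cm = 0.0
    pos = 0
    for chrom in gmap.chromosomes:
        lo, hi = gmap.span_cm(chrom)
        total_cm += hi - lo
        span = (hi - lo) - 2.0 * trim_cm
        if span < 0:
            raise MapFormatError(
                f"chromosome {chrom}: mapped span {hi - lo:.3f} cM shorter than "
                f"2*trim ({2 * trim_cm:.3f} cM)"
            )
        # +1e-9 guards against float round-down at exact multiples of delta
        n_pts = int(np.floor(span / delta_cm + 1e-9)) + 1
        grid_cm = lo + trim_cm + delta_cm * np.arange(n_pts)
        grid_bp = gmap.interpolate(chrom, np.minimum(grid_cm, hi), "cm_to_bp")
        chroms.append(np.full(n_pts, chrom, dtype=object))
        cms.append(grid_cm)
        bps.append(np.asarray(grid_bp, dtype=float))
        offsets[chrom] = (pos, pos + n_pts)
        pos += n_pts
    return ScanGrid(
        delta_cm=float(delta_cm),
        chrom_ids=np.concatenate(chroms),
        cm=np.concatenate(cms),
        bp=np.concatenate(bps),
        offsets=offsets,
        L_morgans=total_cm / 100.0,
    )
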