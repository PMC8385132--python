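"""Coordinate algebra on linkage-disequilibrium-unit (LDU) genetic maps.

An LDU map is a per-chromosome, monotone correspondence between physical
position (bp, b37-style 1-based) and cumulative genetic distance measured in
additive linkage disequilibrium units.  Flat runs of the map ("blocks")
correspond to extended LD; steep rises ("steps") correspond to LD breakdown,
e.g. at recombination hotspots.  All colocalization decisions downstream are
taken in LDU, never in bp: two signals a few kb apart across a step are
genetically distant, while signals tens of kb apart inside a block are not.

The map is interpolated piecewise-linearly between anchors.  Positions outside
the anchored extent are an error rather than an extrapolation, because LD
structure cannot be extrapolated meaningfully.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "GeneticMap",
    "MapRangeError",
    "read_map_table",
    "kb_per_ldu_summary",
]


class MapRangeError(ValueError):
    """A physical position falls outside the anchored extent of a map."""


class GeneticMap:
    """Monotone bp -> cumulative-LDU correspondence for one chromosome.

    Parameters
    ----------
    chromosome
        Chromosome label, e.g. ``"13"``.
    positions
        Anchor physical positions in bp, strictly increasing.
    cum_ldu
        Cumulative LDU at each anchor, non-decreasing, first value >= 0.
    """

    __slots__ = ("chromosome", "positions", "cum_ldu")

    def __init__(self, chromosome: str, positions, cum_ldu):
        pos = np.asarray(positions, dtype=float)
        ldu = np.asarray(cum_ldu, dtype=float)
        if pos.ndim != 1 or pos.shape != ldu.shape:
            raise ValueError("positions and cum_ldu must be 1-D and equal length")
        if len(pos) < 2:
            raise ValueError("a genetic map needs at least two anchors")
        if not np.all(np.diff(pos) > 0):
            i = int(np.flatnonzero(np.diff(pos) <= 0)[0]) + 1
            raise ValueError(
                f"chr{chromosome}: anchor positions not strictly increasing "
                f"at anchor index {i} (pos {pos[i]:.0f})"
            )
        if not np.all(np.diff(ldu) >= 0):
            i = int(np.flatnonzero(np.diff(ldu) < 0)[0]) + 1
            raise ValueError(
                f"chr{chromosome}: cumulative LDU decreases at anchor index {i}"
            )
        if ldu[0] < 0:
            raise ValueError(f"chr{chromosome}: first anchor LDU is negative")
        self.chromosome = str(chromosome)
        self.positions = pos
        self.cum_ldu = ldu

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"GeneticMap(chr{self.chromosome}, {len(self.positions)} anchors, "
            f"[{self.start:.0f}, {self.end:.0f}] bp, {self.total_ldu:.2f} LDU)"
        )

    # -- basic extent -----------------------------------------------------

    @property
    def start(self) -> float:
        return float(self.positions[0])

    @property
    def end(self) -> float:
        return float(self.positions[-1])

    @property
    def total_ldu(self) -> float:
        return float(self.cum_ldu[-1] - self.cum_ldu[0])

    def contains(self, position: float) -> bool:
        return self.start <= position <= self.end

    def _check(self, position: float) -> None:
        if not self.contains(position):
            raise MapRangeError(
                f"position {position:.0f} outside chr{self.chromosome} map "
                f"extent [{self.start:.0f}, {self.end:.0f}]"
            )

    # -- interpolation ----------------------------------------------------

    def ldu_at(self, position: float) -> float:
        """Cumulative LDU at a physical position, by linear interpolation."""
        self._check(position)
        return float(np.interp(position, self.positions, self.cum_ldu))

    def ldu_at_many(self, positions) -> np.ndarray:
        """Vectorised :meth:`ldu_at`; every position must be in extent."""
        pos = np.asarray(positions, dtype=float)
        bad = (pos < self.start) | (pos > self.end)
        if bad.any():
            raise MapRangeError(
                f"{int(bad.sum())} position(s) outside chr{self.chromosome} "
                f"map extent [{self.start:.0f}, {self.end:.0f}]"
            )
        return np.interp(pos, self.positions, self.cum_ldu)

    def ldu_distance(self, pos_a: float, pos_b: float) -> float:
        """Metric genetic distance |LDU(a) - LDU(b)| along the chromosome.

        Zero iff the two positions coincide or share one flat LD block.
        """
        return abs(self.ldu_at(pos_a) - self.ldu_at(pos_b))

    # -- inversion --------------------------------------------------------

    def _bp_at_ldu_left(self, target: float) -> float:
        """Smallest position whose LDU is >= target (clamped to map start)."""
        pos, ldu = self.positions, self.cum_ldu
        if target <= ldu[0]:
            return float(pos[0])
        i = int(np.searchsorted(ldu, target, side="left"))
        # ldu[i-1] < target <= ldu[i]; the segment must be rising
        frac = (target - ldu[i - 1]) / (ldu[i] - ldu[i - 1])
        return float(pos[i - 1] + frac * (pos[i] - pos[i - 1]))

    def _bp_at_ldu_right(self, target: float) -> float:
        """Largest position whose LDU is <= target (clamped to map end)."""
        pos, ldu = self.positions, self.cum_ldu
        if target >= ldu[-1]:
            return float(pos[-1])
        j = int(np.searchsorted(ldu, target, side="right"))
        # ldu[j-1] <= target < ldu[j]; the segment must be rising
        frac = (target - ldu[j - 1]) / (ldu[j] - ldu[j - 1])
        return float(pos[j - 1] + frac * (pos[j] - pos[j - 1]))

    def bp_window(self, center: float, delta: float = 1.0) -> tuple[float, float]:
        """Physical interval spanning +/- ``delta`` LDU around ``center``.

        The interval is generally asymmetric about ``center``: inside a long
        LD block the window absorbs the whole block, while across a step it
        stops within a few bp.  Edges clamp to the map extent.
        """
        if delta <= 0:
            raise ValueError("delta must be positive")
        self._check(center)
        c = self.ldu_at(center)
        return (self._bp_at_ldu_left(c - delta), self._bp_at_ldu_right(c + delta))


def read_map_table(path_or_buf, chromosome: str | None = None) -> dict[str, GeneticMap]:
    """Load LDU maps from a TSV with columns ``chrom  pos_bp  cum_ldu``.

    Returns a dict keyed by chromosome label.  Invariant violations raise with
    the chromosome and offending anchor named.  If ``chromosome`` is given,
    only that chromosome is loaded.
    """
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos_bp", "cum_ldu"}
    if not required.issubset(df.columns):
        raise ValueError(f"map table must have columns {sorted(required)}")
    maps: dict[str, GeneticMap] = {}
    for chrom, grp in df.groupby("chrom", sort=False):
        if chromosome is not None and chrom != chromosome:
            continue
        maps[chrom] = GeneticMap(chrom, grp["pos_bp"].to_numpy(), grp["cum_ldu"].to_numpy())
    return maps


def write_map_table(maps: dict[str, GeneticMap], path) -> None:
    """Inverse of :func:`read_map_table`."""
    rows = []
    for chrom in maps:
        m = maps[chrom]
        rows.append(
            pd.DataFrame(
                {"chrom": chrom, "pos_bp": m.positions.astype(np.int64), "cum_ldu": m.cum_ldu}
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False, float_format="%.6f")


def kb_per_ldu_summary(gmap: GeneticMap, delta: float = 1.0) -> dict[str, float]:
    """Median/min/max physical width (kb) of +/-``delta``-LDU windows.

    Windows are evaluated at every anchor position — the only sampling scheme
    that does not impose an arbitrary bp grid on the map.  If the map spans
    less than ``delta`` LDU in total, every window is the whole chromosome;
    a warning is raised and the chromosome span returned for all three
    summaries.
    """
    if gmap.total_ldu < delta:
        warnings.warn(
            f"chr{gmap.chromosome}: total map extent {gmap.total_ldu:.3f} LDU "
            f"< {delta}; windows degenerate to the chromosome span",
            stacklevel=2,
        )
        span = (gmap.end - gmap.start) / 1e3
        return {"chromosome": gmap.chromosome, "median_kb": span, "min_kb": span, "max_kb": span}
    widths = np.array(
        [np.subtract(*reversed(gmap.bp_window(p, delta))) for p in gmap.positions]
    ) / 1e3
    return {
        "chromosome": gmap.chromosome,
        "median_kb": float(np.median(widths)),
        "min_kb": float(widths.min()),
        "max_kb": float(widths.max()),
    }
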