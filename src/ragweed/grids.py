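"""Regular-lattice rasters and the spatial primitives shared by all stages.

Every spatial quantity in the pipeline (seasonal pollen integral,
sensitisation rate, population, country code, beetle generations) lives on
the same kind of object: a :class:`RasterGrid`, a regular planar lattice of
cells with a nodata mask.  Station observations enter as
:class:`PointSample` lists and are brought onto the lattice by
inverse-distance-weighted interpolation; classified map legends use Jenks
natural breaks.
"""

from __future__ import annotations

import dataclasses
import io
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "GridSpec",
    "RasterGrid",
    "PointSample",
    "interpolate_idw",
    "natural_breaks",
    "classify",
    "mask_by_country",
    "read_raster",
    "write_raster",
    "read_points",
    "write_points",
]

#: CSV nodata token used by the gridded-CSV dialect.
NODATA_TOKEN = "NA"


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a regular raster: top-left origin, square cells, row-major.

    Cell ``(i, j)`` has its centre at
    ``(origin_x + (j + 0.5) * cell_size, origin_y - (i + 0.5) * cell_size)``:
    row 0 is the northernmost row.  ``crs`` is carried as an opaque tag
    (inputs are assumed already projected to metres) and never enters any
    distance computation.
    """

    origin_x: float
    origin_y: float
    n_rows: int
    n_cols: int
    cell_size: float = 10_000.0
    crs: str = "GCS_ETRS_1989"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """Arrays (xs, ys) of cell-centre coordinates, shape (n_rows, n_cols)."""
        j = np.arange(self.n_cols)
        i = np.arange(self.n_rows)
        xs = self.origin_x + (j + 0.5) * self.cell_size
        ys = self.origin_y - (i + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_of(self, x: float, y: float) -> tuple[int, int] | None:
        """Row/col of the cell containing planar point (x, y); None if outside."""
        j = int(np.floor((x - self.origin_x) / self.cell_size))
        i = int(np.floor((self.origin_y - y) / self.cell_size))
        if 0 <= i < self.n_rows and 0 <= j < self.n_cols:
            return i, j
        return None


@dataclass
class RasterGrid:
    """A lattice of values plus a nodata mask sharing one :class:`GridSpec`.

    Masked (nodata) cells are excluded from every reduction, and nodata
    propagates through arithmetic.
    """

    spec: GridSpec
    values: np.ndarray
    nodata_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.spec.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.spec.shape}"
            )
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.spec.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.spec.shape:
                raise ValueError("nodata mask shape does not match grid")

    # -- small algebra helpers; nodata is contagious ------------------------
    def _check_same_spec(self, other: "RasterGrid") -> None:
        if other.spec != self.spec:
            raise ValueError("grids have different GridSpecs")

    def copy(self) -> "RasterGrid":
        return RasterGrid(self.spec, self.values.copy(), self.nodata_mask.copy())

    def __mul__(self, other: "RasterGrid | float") -> "RasterGrid":
        if isinstance(other, RasterGrid):
            self._check_same_spec(other)
            return RasterGrid(
                self.spec,
                self.values * other.values,
                self.nodata_mask | other.nodata_mask,
            )
        return RasterGrid(self.spec, self.values * float(other), self.nodata_mask.copy())

    __rmul__ = __mul__

    def where_valid(self) -> np.ndarray:
        return ~self.nodata_mask

    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]

    def total(self) -> float:
        """Sum over non-nodata cells."""
        return float(self.values[~self.nodata_mask].sum())


@dataclass(frozen=True)
class PointSample:
    """A georeferenced station observation (e.g. a seasonal pollen integral)."""

    id: str
    x: float
    y: float
    value: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError(f"point {self.id!r}: non-finite coordinates")


# ---------------------------------------------------------------------------
# Interpolation
# ---------------------------------------------------------------------------

def interpolate_idw(
    points: Sequence[PointSample],
    spec: GridSpec,
    power: float = 2.0,
    k: int = 12,
) -> RasterGrid:
    """Inverse-distance-weighted interpolation of station values to a grid.

    Each cell centre takes the weight-averaged value of its ``k`` nearest
    stations with weights ``d**-power``.  A cell whose centre (numerically)
    coincides with a station takes that station's value exactly, so the
    interpolated field honours the calibration points.

    Parameters
    ----------
    points
        Station samples; must be nonempty.
    spec
        Target lattice.
    power
        Distance-decay exponent (> 0); default 2.
    k
        Number of nearest stations per cell; capped at ``len(points)``.
    """
    if len(points) == 0:
        raise ValueError("no calibration points")
    if power <= 0:
        raise ValueError("power must be > 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, len(points))

    coords = np.array([[p.x, p.y] for p in points])
    vals = np.array([p.value for p in points], dtype=float)
    xs, ys = spec.cell_centres()
    centres = np.column_stack([xs.ravel(), ys.ravel()])

    tree = cKDTree(coords)
    dist, idx = tree.query(centres, k=k)
    if k == 1:
        dist = dist[:, None]
        idx = idx[:, None]

    # exact-hit tolerance: a station within cell_size/1000 of the centre
    eps = spec.cell_size / 1000.0
    exact = dist[:, 0] < eps

    with np.errstate(divide="ignore", invalid="ignore"):
        w = dist ** (-power)
        out = np.einsum("ij,ij->i", w, vals[idx]) / w.sum(axis=1)
    out[exact] = vals[idx[exact, 0]]
    return RasterGrid(spec, out.reshape(spec.shape))


# ---------------------------------------------------------------------------
# Jenks natural breaks
# ---------------------------------------------------------------------------

def natural_breaks(values: Iterable[float], n_classes: int) -> list[float]:
    """Jenks natural-breaks class boundaries by dynamic programming.

    Minimises the total within-class sum of squared deviations over all
    partitions of the sorted data into ``n_classes`` contiguous, nonempty
    classes.  Ties in the dynamic programme are broken towards the smaller
    left class, which makes the partition deterministic.

    Returns the ``n_classes - 1`` interior boundaries as the upper value of
    each class except the last; boundaries are strictly increasing.
    """
    data = np.sort(np.asarray(list(values), dtype=float))
    n = data.size
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    n_distinct = np.unique(data).size
    if n_classes > n_distinct:
        raise ValueError(
            f"n_classes={n_classes} exceeds number of distinct values ({n_distinct})"
        )
    if n_classes == 1:
        return []

    # prefix sums for O(1) within-class SSD
    csum = np.concatenate([[0.0], np.cumsum(data)])
    csum2 = np.concatenate([[0.0], np.cumsum(data**2)])

    def ssd(lo: int, hi: int) -> float:
        """Within-class sum of squared deviations of data[lo:hi]."""
        m = hi - lo
        s = csum[hi] - csum[lo]
        s2 = csum2[hi] - csum2[lo]
        return s2 - s * s / m

    INF = float("inf")
    # cost[c][i]: best objective for first i points in c+1 classes
    cost = np.full((n_classes, n + 1), INF)
    split = np.zeros((n_classes, n + 1), dtype=int)
    for i in range(1, n + 1):
        cost[0][i] = ssd(0, i)
    for c in range(1, n_classes):
        for i in range(c + 1, n + 1):
            best, best_j = INF, -1
            for j in range(c, i):
                cand = cost[c - 1][j] + ssd(j, i)
                # strict improvement keeps the earliest split => smaller left classes
                if best_j < 0 or cand < best - 1e-12 * max(1.0, best):
                    best, best_j = cand, j
            cost[c][i] = best
            split[c][i] = best_j

    # walk back the split points
    bounds_idx = []
    i = n
    for c in range(n_classes - 1, 0, -1):
        j = split[c][i]
        bounds_idx.append(j)
        i = j
    bounds_idx.reverse()
    bounds = [float(data[j - 1]) for j in bounds_idx]
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise RuntimeError("non-increasing breaks; degenerate input")
    return bounds


def classify(grid: RasterGrid, breaks: Sequence[float]) -> RasterGrid:
    """Assign each valid cell the 0-based class index implied by ``breaks``."""
    cls = np.searchsorted(np.asarray(breaks, dtype=float), grid.values, side="left")
    return RasterGrid(grid.spec, cls.astype(float), grid.nodata_mask.copy())


# ---------------------------------------------------------------------------
# Masking
# ---------------------------------------------------------------------------

def mask_by_country(
    grid: RasterGrid, country_grid: RasterGrid, codes: Iterable[int]
) -> RasterGrid:
    """Set cells whose country code is not in ``codes`` to nodata."""
    grid._check_same_spec(country_grid)
    codeset = set(int(c) for c in codes)
    keep = np.isin(country_grid.values.astype(int), list(codeset)) if codeset else np.zeros(
        grid.spec.shape, dtype=bool
    )
    keep &= ~country_grid.nodata_mask
    out = grid.copy()
    out.nodata_mask |= ~keep
    return out


# ---------------------------------------------------------------------------
# Gridded-CSV raster I/O
# ---------------------------------------------------------------------------
# Dialect: header lines  "#origin_x=… #origin_y=… #cell_size=… #crs=…",
# then n_rows lines of n_cols comma-separated values, "NA" for nodata.

_HEADER_KEYS = ("origin_x", "origin_y", "cell_size", "crs")


def write_raster(grid: RasterGrid, path: str | os.PathLike) -> None:
    spec = grid.spec
    with open(path, "w") as fh:
        fh.write(f"#origin_x={spec.origin_x!r}\n")
        fh.write(f"#origin_y={spec.origin_y!r}\n")
        fh.write(f"#cell_size={spec.cell_size!r}\n")
        fh.write(f"#crs={spec.crs}\n")
        for i in range(spec.n_rows):
            row = [
                NODATA_TOKEN if grid.nodata_mask[i, j] else repr(float(grid.values[i, j]))
                for j in range(spec.n_cols)
            ]
            fh.write(",".join(row) + "\n")


def read_raster(path: str | os.PathLike) -> RasterGrid:
    header: dict[str, str] = {}
    rows: list[list[str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                m = re.match(r"#(\w+)=(.*)$", line)
                if not m:
                    raise ValueError(f"{path}: malformed header line {lineno}: {line!r}")
                header[m.group(1)] = m.group(2)
            else:
                rows.append(line.split(","))
    for key in ("origin_x", "origin_y", "cell_size"):
        if key not in header:
            raise ValueError(f"{path}: missing header field '{key}'")
    if not rows:
        raise ValueError(f"{path}: no data rows")
    n_cols = len(rows[0])
    values = np.zeros((len(rows), n_cols))
    mask = np.zeros((len(rows), n_cols), dtype=bool)
    for i, row in enumerate(rows):
        if len(row) != n_cols:
            raise ValueError(f"{path}: row {i} has {len(row)} columns, expected {n_cols}")
        for j, tok in enumerate(row):
            tok = tok.strip()
            if tok == NODATA_TOKEN:
                mask[i, j] = True
            else:
                try:
                    values[i, j] = float(tok)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}: non-numeric cell at row {i}, col {j}: {tok!r}"
                    ) from exc
    spec = GridSpec(
        origin_x=float(header["origin_x"]),
        origin_y=float(header["origin_y"]),
        n_rows=len(rows),
        n_cols=n_cols,
        cell_size=float(header["cell_size"]),
        crs=header.get("crs", ""),
    )
    return RasterGrid(spec, values, mask)


# ---------------------------------------------------------------------------
# Point CSV I/O (id,x,y,value)
# ---------------------------------------------------------------------------

def write_points(points: Sequence[PointSample], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("id,x,y,value\n")
        for p in points:
            fh.write(f"{p.id},{p.x!r},{p.y!r},{p.value!r}\n")


def read_points(path: str | os.PathLike) -> list[PointSample]:
    import pandas as pd

    df = pd.read_csv(path, dtype={"id": str})
    missing = {"id", "x", "y", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        PointSample(str(r.id), float(r.x), float(r.y), float(r.value))
        for r in df.itertuples(index=False)
    ]
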