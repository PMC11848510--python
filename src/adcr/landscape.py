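"""Raster landscapes: grid representation, synthetic patch generation, ESRI ASCII I/O.

The spatial domain is a rectangular grid of ``nx x ny`` square cells of side
``h``.  Cells are indexed 0-based with ``ix`` increasing eastwards and ``iy``
increasing northwards; the flat cell index is ``q = iy * nx + ix`` and the
cell centre sits at ``((ix + 0.5) h, (iy + 0.5) h)``.  All distances used by
the movement model and the estimators are centre-to-centre.

Landscape covariates (e.g. habitat class, water-surface ratio) are stored as
one or more per-cell layers; the permeability model is log-linear in them.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "Landscape",
    "PatchSpec",
    "generate_patch_landscape",
    "read_raster",
    "write_raster",
]


class RasterFormatError(ValueError):
    """Raised for malformed raster files."""


@dataclass(eq=False)
class Landscape:
    """A rectangular raster landscape with per-cell covariates.

    Parameters
    ----------
    nx, ny
        Number of cells along the x (east) and y (north) axes.
    h
        Cell side length in world distance units.
    covariates
        Array of shape ``(n_layers, ny, nx)`` (a single ``(ny, nx)`` layer is
        promoted).  Row index 0 is the *southern* row; rasters on disk are
        written north-up and flipped on read/write.
    """

    nx: int
    ny: int
    h: float = 1.0
    covariates: np.ndarray = field(default=None)
    origin: str = "south-west"  # internal row order marker; files are north-up

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell per axis")
        if self.h <= 0:
            raise ValueError("cell size h must be positive")
        if self.covariates is None:
            self.covariates = np.zeros((1, self.ny, self.nx))
        cov = np.asarray(self.covariates, dtype=float)
        if cov.ndim == 2:
            cov = cov[None, :, :]
        if cov.ndim != 3 or cov.shape[1:] != (self.ny, self.nx):
            raise ValueError(
                f"covariates must have shape (n_layers, {self.ny}, {self.nx})"
            )
        if not np.all(np.isfinite(cov)):
            raise ValueError("covariate layers must be finite everywhere")
        self.covariates = cov

    # -- geometry -----------------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.nx * self.ny

    @property
    def n_layers(self) -> int:
        return self.covariates.shape[0]

    @property
    def area(self) -> float:
        return self.n_cells * self.h ** 2

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) in world units."""
        return (0.0, self.nx * self.h, 0.0, self.ny * self.h)

    @property
    def cell_x(self) -> np.ndarray:
        """x coordinate of every cell centre, flat order."""
        return ((np.arange(self.nx) + 0.5) * self.h)[None, :].repeat(self.ny, 0).ravel()

    @property
    def cell_y(self) -> np.ndarray:
        return ((np.arange(self.ny) + 0.5) * self.h)[:, None].repeat(self.nx, 1).ravel()

    @property
    def cell_centers(self) -> np.ndarray:
        """(n_cells, 2) array of cell-centre coordinates."""
        return np.column_stack([self.cell_x, self.cell_y])

    @property
    def z(self) -> np.ndarray:
        """Covariates as an (n_cells, n_layers) matrix, flat cell order."""
        return self.covariates.reshape(self.n_layers, -1).T

    def cell_index(self, x, y) -> np.ndarray:
        """Flat index of the cell containing world point(s) (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.any(x < 0) or np.any(x > self.nx * self.h) or np.any(y < 0) or np.any(
            y > self.ny * self.h
        ):
            raise ValueError("point outside landscape extent")
        ix = np.minimum(np.floor(x / self.h).astype(int), self.nx - 1)
        iy = np.minimum(np.floor(y / self.h).astype(int), self.ny - 1)
        return iy * self.nx + ix

    def cell_center_of(self, q: int) -> tuple[float, float]:
        iy, ix = divmod(int(q), self.nx)
        return ((ix + 0.5) * self.h, (iy + 0.5) * self.h)

    def with_layers(self, layers: np.ndarray) -> "Landscape":
        return Landscape(self.nx, self.ny, self.h, np.asarray(layers, dtype=float))


@dataclass
class PatchSpec:
    """Specification for the random patch landscape generator.

    Patches are 4-connected clumps of cells carrying ``patch_value``; the rest
    of the grid carries ``background_value``.  Defaults mirror the simulation
    conditions used throughout: binary habitat contrast +/- 0.5 and five
    patches of 100-250 cells on a 50 x 50 grid.
    """

    n_patches: int = 5
    patch_area_range: tuple[int, int] = (100, 250)
    patch_value: float = 0.5
    background_value: float = -0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patches < 0:
            raise ValueError("n_patches must be >= 0")
        lo, hi = self.patch_area_range
        if lo <= 0 or hi < lo:
            raise ValueError("patch areas must be positive with min <= max")


_NEIGH = ((1, 0), (-1, 0), (0, 1), (0, -1))


def _grow_patch(free: np.ndarray, area: int, rng: np.random.Generator) -> list | None:
    """Grow one 4-connected patch of `area` cells on free cells, or None."""
    ny, nx = free.shape
    free_idx = np.flatnonzero(free)
    if len(free_idx) == 0:
        return None
    seed_q = int(rng.choice(free_idx))
    iy, ix = divmod(seed_q, nx)
    patch = [(iy, ix)]
    member = {(iy, ix)}
    frontier = []

    def push_neighbors(cy, cx):
        for dy, dx in _NEIGH:
            py, px = cy + dy, cx + dx
            if 0 <= py < ny and 0 <= px < nx and free[py, px] and (py, px) not in member:
                frontier.append((py, px))

    push_neighbors(iy, ix)
    while len(patch) < area:
        # drop frontier cells that were absorbed meanwhile
        while frontier:
            k = int(rng.integers(len(frontier)))
            cy, cx = frontier.pop(k)
            if (cy, cx) not in member and free[cy, cx]:
                break
        else:
            return None  # blocked before reaching the target area
        patch.append((cy, cx))
        member.add((cy, cx))
        push_neighbors(cy, cx)
    return patch


def generate_patch_landscape(nx: int, ny: int, spec: PatchSpec, *,
                             max_retries: int = 50) -> Landscape:
    """Generate a binary patch/background landscape by seeded random accretion.

    Each patch grows from a uniformly drawn free seed cell by repeatedly
    annexing a random free 4-neighbour of the current clump, so every patch is
    one 4-connected component.  Deterministic given ``spec.seed``.

    Raises
    ------
    ValueError
        If the requested total patch area cannot fit in the grid.
    RuntimeError
        If placement fails after ``max_retries`` restarts (no silent
        truncation of patch areas).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.patch_area_range
    if spec.n_patches * lo >= nx * ny:
        raise ValueError("requested total patch area does not fit in the grid")

    for _ in range(max_retries):
        areas = rng.integers(lo, hi + 1, size=spec.n_patches)
        if areas.sum() >= nx * ny:
            continue
        grid = np.full((ny, nx), spec.background_value, dtype=float)
        free = np.ones((ny, nx), dtype=bool)
        ok = True
        for area in areas:
            placed = None
            for _attempt in range(20):
                placed = _grow_patch(free, int(area), rng)
                if placed is not None:
                    break
            if placed is None:
                ok = False
                break
            for (py, px) in placed:
                grid[py, px] = spec.patch_value
                free[py, px] = False
        if ok:
            return Landscape(nx, ny, 1.0, grid)
    raise RuntimeError(
        f"failed to place {spec.n_patches} patches of area in {spec.patch_area_range} "
        f"on a {nx}x{ny} grid after {max_retries} retries"
    )


# ---------------------------------------------------------------------------
# ESRI ASCII grid / plain matrix I/O
# ---------------------------------------------------------------------------

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


def write_raster(landscape: Landscape, path, layer: int = 0,
                 xllcorner: float = 0.0, yllcorner: float = 0.0,
                 nodata: float = -9999.0) -> None:
    """Write one covariate layer as an ESRI ASCII grid (north-up row order)."""
    grid = landscape.covariates[layer]
    with open(path, "w") as fh:
        fh.write(f"ncols {landscape.nx}\n")
        fh.write(f"nrows {landscape.ny}\n")
        fh.write(f"xllcorner {xllcorner!r}\n")
        fh.write(f"yllcorner {yllcorner!r}\n")
        fh.write(f"cellsize {landscape.h!r}\n")
        fh.write(f"NODATA_value {nodata!r}\n")
        for iy in range(landscape.ny - 1, -1, -1):  # north-up
            fh.write(" ".join(repr(float(v)) for v in grid[iy]) + "\n")


def read_raster(path) -> Landscape:
    """Read an ESRI ASCII grid or a headerless numeric matrix into a Landscape.

    The file's first data row is the northern-most row.  NODATA values inside
    the domain are an error: the movement model needs a covariate everywhere.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise RasterFormatError("empty raster file")

    first_tok = lines[0].split()[0]
    is_headered = bool(re.match(r"^[A-Za-z]", first_tok))
    header: dict[str, float] = {}
    data_start = 0
    if is_headered:
        for i, ln in enumerate(lines):
            toks = ln.split()
            if re.match(r"^[A-Za-z]", toks[0]):
                if len(toks) != 2:
                    raise RasterFormatError(f"malformed header line: {ln!r}")
                try:
                    header[toks[0].lower()] = float(toks[1])
                except ValueError as exc:
                    raise RasterFormatError(f"malformed header line: {ln!r}") from exc
            else:
                data_start = i
                break
        else:
            raise RasterFormatError("raster has a header but no data rows")
        missing = [k for k in _HEADER_KEYS if k not in header]
        if missing:
            raise RasterFormatError(f"missing header keys: {missing}")
        nx = int(header["ncols"])
        ny = int(header["nrows"])
        h = float(header["cellsize"])
        if h <= 0:
            raise RasterFormatError("cellsize must be positive")
    rows = []
    for ln in lines[data_start:]:
        try:
            rows.append([float(t) for t in ln.split()])
        except ValueError as exc:
            raise RasterFormatError(f"non-numeric data row: {ln!r}") from exc
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise RasterFormatError("ragged data rows in raster")
    grid = np.asarray(rows, dtype=float)
    if is_headered:
        if grid.shape != (ny, nx):
            raise RasterFormatError(
                f"data shape {grid.shape} does not match header ({ny}, {nx})"
            )
        nodata = header.get("nodata_value")
        if nodata is not None and np.any(grid == nodata):
            raise RasterFormatError("NODATA values inside the domain")
    else:
        ny, nx = grid.shape
        h = 1.0
    return Landscape(nx, ny, h, grid[::-1])  # flip to south-first internal order
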