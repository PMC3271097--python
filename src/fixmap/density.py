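"""Spatial fixation-density maps on a regular grid.

Each fixation contributes an isotropic 2-D Gaussian (default sd 0.3
degrees of visual angle), evaluated at pixel centers and truncated at
4 sd for speed; fixations are weighted equally, never by duration. A
per-trial map therefore integrates (sum of values times cell area) to
the number of fixations it contains, up to the declared truncation
tolerance. Maps are averaged across trials within participant and then
across participants, so unbalanced cells stay well-defined.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

from .geometry import FaceGeometry, Rect, face_alignment

__all__ = [
    "GridSpec",
    "DensityMap",
    "DifferenceMap",
    "DEFAULT_SIGMA",
    "DEFAULT_TRUNCATE",
    "align_fixations",
    "density_map",
    "stamp_matrix",
    "group_average",
    "difference_map",
    "flip_for_inversion",
    "flip_fixations",
    "profile_plots",
    "save_map_tsv",
    "load_map_tsv",
    "save_map_png",
]

#: Gaussian kernel sd in degrees.
DEFAULT_SIGMA = 0.3
#: Kernel truncation radius in units of sigma.
DEFAULT_TRUNCATE = 4.0


@dataclass(frozen=True)
class GridSpec:
    """Regular raster over the aligned-face frame.

    Pixel (i, j) — column i, row j — has center
    ``(x_min + (i + 0.5) * cell, y_min + (j + 0.5) * cell)``.
    Values arrays are stored (n_y, n_x), image convention (row = y).
    """

    x_min: float
    y_min: float
    cell: float
    n_x: int
    n_y: int

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError("cell size must be positive")
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("grid must have at least one pixel per axis")

    @property
    def x_max(self) -> float:
        return self.x_min + self.n_x * self.cell

    @property
    def y_max(self) -> float:
        return self.y_min + self.n_y * self.cell

    @property
    def n_pixels(self) -> int:
        return self.n_x * self.n_y

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_y, self.n_x)

    @property
    def x_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.n_x) + 0.5) * self.cell

    @property
    def y_centers(self) -> np.ndarray:
        return self.y_min + (np.arange(self.n_y) + 0.5) * self.cell

    def region_mask(self, rect: Rect) -> np.ndarray:
        """Boolean (n_y, n_x) mask of pixel centers inside ``rect``."""
        inx = (self.x_centers >= rect.x_min) & (self.x_centers <= rect.x_max)
        iny = (self.y_centers >= rect.y_min) & (self.y_centers <= rect.y_max)
        return np.outer(iny, inx)

    @classmethod
    def from_bounds(
        cls, bounds: Rect, cell: float = 0.05, pad: float = 1.0
    ) -> "GridSpec":
        """Grid covering ``bounds`` padded by ``pad`` degrees each side."""
        x_min, y_min = bounds.x_min - pad, bounds.y_min - pad
        n_x = int(np.ceil((bounds.x_max + pad - x_min) / cell))
        n_y = int(np.ceil((bounds.y_max + pad - y_min) / cell))
        return cls(x_min, y_min, cell, n_x, n_y)

    def to_dict(self) -> dict:
        return {
            "x_min": self.x_min, "y_min": self.y_min, "cell": self.cell,
            "n_x": self.n_x, "n_y": self.n_y,
        }


@dataclass
class DensityMap:
    """Fixation density (per deg^2) over a grid, plus bookkeeping."""

    grid: GridSpec
    values: np.ndarray
    n_fixations: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def mass(self) -> float:
        """Integral of the map — the (effective) fixation count."""
        return float(self.values.sum() * self.grid.cell**2)


@dataclass
class DifferenceMap:
    """Signed participant-averaged A - B density contrast."""

    grid: GridSpec
    values: np.ndarray
    contrast: tuple[str, str]
    n_participants: int = 0
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# alignment of fixations into the common frame


def align_fixations(
    fixations: pd.DataFrame,
    face_geometries: dict[str, FaceGeometry],
    reference: np.ndarray,
) -> pd.DataFrame:
    """Translate each fixation by its face's alignment translation.

    Returns a copy with x/y replaced by aligned coordinates.
    """
    out = fixations.copy()
    for face_id, idx in fixations.groupby("face_id", sort=False).groups.items():
        t = face_alignment(face_geometries[str(face_id)], reference)
        out.loc[idx, "x"] = fixations.loc[idx, "x"] + t.dx
        out.loc[idx, "y"] = fixations.loc[idx, "y"] + t.dy
    return out


# ---------------------------------------------------------------------------
# rasterization


def _stamp_indices(
    x: np.ndarray, y: np.ndarray, grid: GridSpec, sigma: float, truncate: float
):
    """Per-fixation pixel windows and separable Gaussian factors.

    Returns (cols, rows, gx, gy, i0, j0) where gx/gy are (n, w) 1-D
    Gaussian pdf factors over the window columns/rows, cropped at grid
    edges via zero weights.
    """
    radius = truncate * sigma
    w = 2 * int(np.ceil(radius / grid.cell)) + 1
    # leftmost window pixel index per fixation
    i0 = np.floor((x - radius - grid.x_min) / grid.cell).astype(np.int64)
    j0 = np.floor((y - radius - grid.y_min) / grid.cell).astype(np.int64)
    offs = np.arange(w)
    cols = i0[:, None] + offs[None, :]          # (n, w)
    rows = j0[:, None] + offs[None, :]
    xc = grid.x_min + (cols + 0.5) * grid.cell
    yc = grid.y_min + (rows + 0.5) * grid.cell
    norm = 1.0 / (np.sqrt(2 * np.pi) * sigma)
    gx = norm * np.exp(-0.5 * ((xc - x[:, None]) / sigma) ** 2)
    gy = norm * np.exp(-0.5 * ((yc - y[:, None]) / sigma) ** 2)
    gx[(cols < 0) | (cols >= grid.n_x)] = 0.0
    gy[(rows < 0) | (rows >= grid.n_y)] = 0.0
    np.clip(cols, 0, grid.n_x - 1, out=cols)
    np.clip(rows, 0, grid.n_y - 1, out=rows)
    return cols, rows, gx, gy


def density_map(
    fixations: pd.DataFrame | np.ndarray,
    grid: GridSpec,
    sigma: float = DEFAULT_SIGMA,
    truncate: float = DEFAULT_TRUNCATE,
    meta: dict | None = None,
) -> DensityMap:
    """Sum of per-fixation isotropic Gaussians evaluated at pixel centers.

    ``fixations`` is a DataFrame with x/y columns (degrees, aligned
    frame, already clamped to the image) or an (n, 2) array. An empty
    input yields a zero map.
    """
    if isinstance(fixations, pd.DataFrame):
        xy = fixations[["x", "y"]].to_numpy(dtype=float)
    else:
        xy = np.atleast_2d(np.asarray(fixations, dtype=float))
        if xy.size == 0:
            xy = np.empty((0, 2))
    values = np.zeros(grid.shape)
    n = xy.shape[0]
    if n:
        cols, rows, gx, gy = _stamp_indices(xy[:, 0], xy[:, 1], grid, sigma, truncate)
        for k in range(n):
            values[np.ix_(rows[k], cols[k])] += np.outer(gy[k], gx[k])
    return DensityMap(grid, values, n_fixations=n, meta=meta or {})


def stamp_matrix(
    x: np.ndarray,
    y: np.ndarray,
    grid: GridSpec,
    sigma: float = DEFAULT_SIGMA,
    truncate: float = DEFAULT_TRUNCATE,
) -> sparse.csr_matrix:
    """Sparse (n_fixations, n_pixels) matrix of per-fixation Gaussian
    stamps (pixels flattened row-major).

    A density map for any weighting w of the fixations is ``w @ M``
    reshaped to the grid; the permutation engine exploits this, since
    relabelling conditions only changes w, never M.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n == 0:
        return sparse.csr_matrix((0, grid.n_pixels))
    cols, rows, gx, gy = _stamp_indices(x, y, grid, sigma, truncate)
    w = cols.shape[1]
    # outer products: (n, w_y, w_x)
    vals = gy[:, :, None] * gx[:, None, :]
    pix = rows[:, :, None] * grid.n_x + cols[:, None, :]
    indptr = np.arange(n + 1) * (w * w)
    m = sparse.csr_matrix(
        (vals.ravel(), pix.ravel(), indptr), shape=(n, grid.n_pixels)
    )
    m.sum_duplicates()  # edge-clipped windows may repeat a pixel with 0 weight
    return m


# ---------------------------------------------------------------------------
# averaging and contrasts


def group_average(
    per_trial_maps: Iterable[DensityMap],
    participant_of: Sequence,
) -> DensityMap:
    """Mean over trials within participant, then mean over participants."""
    maps = list(per_trial_maps)
    pids = list(participant_of)
    if len(maps) != len(pids) or not maps:
        raise ValueError("need one participant id per map, at least one map")
    grid = maps[0].grid
    by_p: dict = {}
    for m, p in zip(maps, pids):
        if m.grid != grid:
            raise ValueError("all maps must share one grid")
        by_p.setdefault(p, []).append(m)
    per_participant = [
        np.mean([m.values for m in ms], axis=0) for ms in by_p.values()
    ]
    values = np.mean(per_participant, axis=0)
    n_fix = float(np.mean(
        [np.mean([m.n_fixations for m in ms]) for ms in by_p.values()]
    ))
    return DensityMap(grid, values, n_fixations=n_fix,
                      meta={"n_participants": len(by_p)})


def difference_map(
    maps_a: dict, maps_b: dict, contrast: tuple[str, str] = ("A", "B")
) -> DifferenceMap:
    """Per-participant A - B, then across-participant mean.

    ``maps_a``/``maps_b`` map participant id -> per-participant
    DensityMap (already trial-averaged). Participants present in both
    dicts contribute; others are ignored.
    """
    shared = sorted(set(maps_a) & set(maps_b), key=str)
    if not shared:
        raise ValueError("no participant present in both conditions")
    grid = maps_a[shared[0]].grid
    diffs = [maps_a[p].values - maps_b[p].values for p in shared]
    return DifferenceMap(grid, np.mean(diffs, axis=0), contrast,
                         n_participants=len(shared))


def flip_for_inversion(obj, axis_y: float | None = None):
    """Reflect a map (or fixation table) about a horizontal axis.

    For a :class:`DensityMap`/:class:`DifferenceMap` the rows are
    reversed, i.e. reflection about the grid's vertical midline
    (axis_y is implied by the grid and must be None or match it).
    For a DataFrame of fixations, y -> 2*axis_y - y.
    """
    if isinstance(obj, pd.DataFrame):
        if axis_y is None:
            raise ValueError("axis_y required to flip fixations")
        return flip_fixations(obj, axis_y)
    grid_axis = obj.grid.y_min + 0.5 * obj.grid.n_y * obj.grid.cell
    if axis_y is not None and abs(axis_y - grid_axis) > 1e-9:
        raise ValueError(
            f"grid supports reflection about y={grid_axis:g} only, got {axis_y:g}"
        )
    out = type(obj)(**{**obj.__dict__, "values": obj.values[::-1].copy()})
    return out


def flip_fixations(fixations: pd.DataFrame, axis_y: float) -> pd.DataFrame:
    out = fixations.copy()
    out["y"] = 2 * axis_y - fixations["y"]
    return out


def profile_plots(density: DensityMap | DifferenceMap):
    """Marginal profiles: summation of the map across each dimension.

    Returns (x_profile, y_profile); each integrates to the map mass
    (sum of profile times cell equals sum of values times cell^2).
    """
    cell = density.grid.cell
    x_profile = density.values.sum(axis=0) * cell
    y_profile = density.values.sum(axis=1) * cell
    return x_profile, y_profile


# ---------------------------------------------------------------------------
# IO


def save_map_tsv(density, path: str | Path) -> None:
    """Numeric grid as TSV plus a JSON sidecar with the GridSpec."""
    path = Path(path)
    np.savetxt(path, density.values, delimiter="\t")
    sidecar = {"grid": density.grid.to_dict()}
    if isinstance(density, DensityMap):
        sidecar["n_fixations"] = density.n_fixations
    if isinstance(density, DifferenceMap):
        sidecar["contrast"] = list(density.contrast)
        sidecar["n_participants"] = density.n_participants
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def load_map_tsv(path: str | Path) -> DensityMap | DifferenceMap:
    path = Path(path)
    values = np.atleast_2d(np.loadtxt(path, delimiter="\t"))
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    grid = GridSpec(**sidecar["grid"])
    if "contrast" in sidecar:
        return DifferenceMap(grid, values, tuple(sidecar["contrast"]),
                             sidecar.get("n_participants", 0))
    return DensityMap(grid, values, sidecar.get("n_fixations", float(np.nan)))


def save_map_png(
    density, path: str | Path, signed: bool | None = None, dpi: int = 120
) -> None:
    """Heatmap PNG with zero rendered transparent; signed maps use a
    red/blue diverging scale, plain densities a sequential one scaled
    from zero to the observed maximum."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = density.values
    if signed is None:
        signed = isinstance(density, DifferenceMap) or (values < 0).any()
    g = density.grid
    extent = (g.x_min, g.x_max, g.y_max, g.y_min)  # y down
    masked = np.ma.masked_where(values == 0, values)
    fig, ax = plt.subplots(figsize=(g.n_x / 40 + 1.5, g.n_y / 40 + 1.5))
    if signed:
        vmax = float(np.abs(values).max()) or 1.0
        im = ax.imshow(masked, extent=extent, cmap="bwr", vmin=-vmax, vmax=vmax)
    else:
        vmax = float(values.max()) or 1.0
        im = ax.imshow(masked, extent=extent, cmap="hot", vmin=0, vmax=vmax)
    fig.colorbar(im, ax=ax, shrink=0.85)
    ax.set_xlabel("x (deg)")
    ax.set_ylabel("y (deg)")
    fig.savefig(path, dpi=dpi, transparent=True)
    plt.close(fig)
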