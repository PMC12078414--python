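"""Ramachandran grids: histogramming, coarsening, Jensen-Shannon comparison.

Grids follow one convention throughout the package: bin centers at
-180 + resolution/2 + k*resolution on the half-open domain [-180, 180),
phi on the first axis, psi on the second.  Divergences between a predicted
and a reference distribution are reported at 10 degree graining with the
binary-logarithm Jensen-Shannon divergence, which is symmetric and bounded
between 0 (identical) and 1 (disjoint supports).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .physmodel import grid_centers

__all__ = [
    "RamachandranGrid",
    "DihedralSeries",
    "wrap_angles",
    "ramachandran_histogram",
    "coarsen",
    "js_divergence",
    "save_grids",
    "load_grids",
]


def wrap_angles(a):
    """Map angles (deg) onto [-180, 180); +180 wraps to -180."""
    return (np.asarray(a, dtype=float) + 180.0) % 360.0 - 180.0


@dataclass
class RamachandranGrid:
    """Discrete probability distribution over (phi, psi) bins."""

    resolution: float
    probabilities: np.ndarray  # (n, n)

    def __post_init__(self):
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        n = int(round(360.0 / self.resolution))
        if self.probabilities.shape != (n, n):
            raise ValueError("grid shape does not match its resolution")
        if np.any(self.probabilities < 0):
            raise ValueError("probabilities must be nonnegative")
        if abs(self.probabilities.sum() - 1.0) > 1e-10:
            raise ValueError("probabilities must sum to 1 within 1e-10")

    @classmethod
    def from_values(cls, resolution: float, values) -> "RamachandranGrid":
        """Normalize nonnegative values into a grid."""
        v = np.asarray(values, dtype=float)
        s = v.sum()
        if s <= 0:
            raise ValueError("cannot normalize an all-zero grid")
        return cls(resolution, v / s)

    @classmethod
    def uniform(cls, resolution: float) -> "RamachandranGrid":
        n = int(round(360.0 / resolution))
        return cls(resolution, np.full((n, n), 1.0 / (n * n)))

    @property
    def centers(self) -> np.ndarray:
        return grid_centers(self.resolution)

    def max_bin(self) -> float:
        return float(self.probabilities.max())

    def region_mass(self, phi_range, psi_range) -> float:
        """Probability mass in a [phi_lo, phi_hi] x [psi_lo, psi_hi] window."""
        c = self.centers
        mi = (c >= phi_range[0]) & (c <= phi_range[1])
        mj = (c >= psi_range[0]) & (c <= psi_range[1])
        return float(self.probabilities[np.ix_(mi, mj)].sum())


@dataclass
class DihedralSeries:
    """(phi, psi) time series (deg) for one residue."""

    phi: np.ndarray
    psi: np.ndarray
    dt: float  # s

    def __post_init__(self):
        self.phi = wrap_angles(self.phi)
        self.psi = wrap_angles(self.psi)
        if self.phi.shape != self.psi.shape or self.phi.ndim != 1:
            raise ValueError("phi and psi must be 1-D arrays of equal length")

    def __len__(self) -> int:
        return len(self.phi)

    def strided(self, step: int) -> "DihedralSeries":
        """Coarser time graining (e.g. 100 ps from a 1 ps series)."""
        return DihedralSeries(self.phi[::step], self.psi[::step],
                              self.dt * step)


def ramachandran_histogram(series: DihedralSeries,
                           resolution: float = 10.0) -> RamachandranGrid:
    """Normalized 2-D histogram of a dihedral series."""
    if len(series) == 0:
        raise ValueError("empty dihedral series")
    n = int(round(360.0 / resolution))
    i = np.floor((series.phi + 180.0) / resolution).astype(int)
    j = np.floor((series.psi + 180.0) / resolution).astype(int)
    counts = np.zeros((n, n))
    np.add.at(counts, (i, j), 1.0)
    return RamachandranGrid.from_values(resolution, counts)


def coarsen(grid: RamachandranGrid, target_resolution: float
            ) -> RamachandranGrid:
    """Block-sum a grid to a coarser resolution (probability conserving)."""
    factor = target_resolution / grid.resolution
    if abs(factor - round(factor)) > 1e-9 or factor < 1:
        raise ValueError(
            f"target resolution {target_resolution} incompatible with "
            f"{grid.resolution}")
    f = int(round(factor))
    n = grid.probabilities.shape[0] // f
    blocks = grid.probabilities.reshape(n, f, n, f).sum(axis=(1, 3))
    return RamachandranGrid(target_resolution, blocks)


def js_divergence(p: RamachandranGrid, r: RamachandranGrid) -> float:
    """Jensen-Shannon divergence (log base 2, in [0, 1]) between two grids.

    Zero bins follow the convention 0 * log2(0 / x) = 0.
    """
    if p.resolution != r.resolution:
        raise ValueError("grids must share a resolution")
    pv = p.probabilities.ravel()
    rv = r.probabilities.ravel()
    m = 0.5 * (pv + rv)
    out = 0.0
    mask = pv > 0
    out += np.sum(pv[mask] * np.log2(pv[mask] / m[mask]))
    mask = rv > 0
    out += np.sum(rv[mask] * np.log2(rv[mask] / m[mask]))
    return float(np.clip(0.5 * out, 0.0, 1.0))


def render_comparison(ref: RamachandranGrid, pred: RamachandranGrid,
                      path, residue: int | None = None) -> None:
    """Side-by-side Ramachandran heat maps: reference left, prediction right.

    Both panels share the color scale defined by the reference range;
    predicted bins exceeding it are flagged with a hatched overlay.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ref.resolution != pred.resolution:
        raise ValueError("grids must share a resolution")
    vmax = ref.probabilities.max()
    extent = (-180, 180, -180, 180)
    fig, axes = plt.subplots(1, 2, figsize=(8, 4), sharey=True)
    for ax, grid, title in ((axes[0], ref, "reference"),
                            (axes[1], pred, "prediction")):
        im = ax.imshow(grid.probabilities.T, origin="lower", extent=extent,
                       vmin=0.0, vmax=vmax, cmap="viridis", aspect="equal")
        ax.set_xlabel("phi (deg)")
        ax.set_title(title if residue is None else f"{title} res {residue}")
    over = pred.probabilities.T > vmax
    if over.any():
        axes[1].contourf(pred.centers, pred.centers, over.astype(float),
                         levels=[0.5, 1.5], colors="red", alpha=0.35)
    axes[0].set_ylabel("psi (deg)")
    fig.colorbar(im, ax=axes, shrink=0.8, label="probability")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_grid(path, grid: RamachandranGrid) -> None:
    """Write a single (residue-independent) grid, e.g. a prior."""
    save_grids(path, {-1: grid})


def load_grid(path) -> RamachandranGrid:
    grids = load_grids(path)
    if len(grids) != 1:
        raise ValueError(f"{path} holds {len(grids)} grids, expected one")
    return next(iter(grids.values()))


def save_grids(path, grids: dict[int, RamachandranGrid]) -> None:
    """Write per-residue grids to an HDF5 container (group res_<i>)."""
    import h5py

    with h5py.File(path, "w") as h5:
        for res, g in grids.items():
            grp = h5.create_group(f"res_{res}")
            d = grp.create_dataset("values", data=g.probabilities)
            d.attrs["resolution_deg"] = g.resolution
            d.attrs["residue"] = res


def load_grids(path) -> dict[int, RamachandranGrid]:
    import h5py

    out = {}
    with h5py.File(path, "r") as h5:
        for name in h5:
            d = h5[name]["values"]
            out[int(d.attrs["residue"])] = RamachandranGrid(
                float(d.attrs["resolution_deg"]), d[...])
    return out
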