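"""Synthetic conformational ensembles with known ground truth.

The generator emulates the statistical structure of a disordered-protein
trajectory without any force-field physics: per-residue dihedral dynamics
as a continuous-time Markov jump process between Ramachandran basins
(alpha, beta, polyproline-II, left-handed helix) with wrapped-Gaussian
intra-basin jitter relaxing on its own time scale, a rigid-internal-
coordinate chain build per frame, and isotropic global tumbling as a
rotational-diffusion random walk.  Every stochastic operation is
reproducible from (spec, seed), and the "true" per-residue Ramachandran
grid is the analytic basin mixture, so recovery targets are independent of
sampling noise.

Defaults: 1 ps frames, 1e6 frames (1 us), 5 ns basin exchange, 3 ns
tumbling, 15 degree basin spread -- sized so the correlation functions
converge well inside a 10 ns integration bound.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import lfilter

from .physmodel import (BackboneGeometry, RateSurface, _nerf, grid_centers)
from .gridmetrics import DihedralSeries, RamachandranGrid, wrap_angles

__all__ = [
    "Basin",
    "EnsembleSpec",
    "CANONICAL_BASINS",
    "sample_dihedral_series",
    "true_grid",
    "chain_coordinates",
    "apply_tumbling",
    "synthetic_rates",
    "standin_coil_prior",
    "save_chain",
    "load_chain",
]


@dataclass(frozen=True)
class Basin:
    """One Ramachandran basin: center (deg), angular spread (deg, s.d.), weight."""

    phi: float
    psi: float
    spread: float
    weight: float


# canonical basin centers used for disordered-chain defaults
CANONICAL_BASINS = {
    "alpha": (-63.0, -43.0),
    "beta": (-135.0, 135.0),
    "ppii": (-75.0, 150.0),
    "alphaL": (60.0, 45.0),
}


@dataclass
class EnsembleSpec:
    """Generative description of a synthetic dihedral ensemble.

    ``basins`` holds one basin list per residue (weights sum to 1 per
    residue).  Exchange between basins happens at ``exchange_time``;
    intra-basin jitter is an Ornstein-Uhlenbeck deviation with the basin's
    spread as stationary s.d. and ``jitter_time`` as relaxation time.
    """

    basins: list[list[Basin]]
    exchange_time: float = 5e-9
    jitter_time: float = 50e-12
    tau_rot: float = 3e-9
    n_frames: int = 1_000_000
    dt: float = 1e-12
    seed: int = 0

    def __post_init__(self):
        for res_basins in self.basins:
            w = sum(b.weight for b in res_basins)
            if any(b.weight < 0 for b in res_basins) or abs(w - 1.0) > 1e-9:
                raise ValueError("basin weights must be >= 0 and sum to 1")
        for name in ("exchange_time", "jitter_time", "tau_rot", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def n_residues(self) -> int:
        return len(self.basins)

    @classmethod
    def disordered_chain(cls, n_residues: int, seed: int = 0,
                         spread: float = 15.0, **kw) -> "EnsembleSpec":
        """Four-basin mixtures with per-residue weight variation.

        Weights are drawn once (from the seed) around a coil-like
        composition so every residue is disordered yet distinguishable.
        """
        rng = np.random.default_rng(seed)
        base = np.array([0.30, 0.25, 0.35, 0.10])  # alpha, beta, ppii, alphaL
        centers = [CANONICAL_BASINS[k] for k in
                   ("alpha", "beta", "ppii", "alphaL")]
        basins = []
        for _ in range(n_residues):
            w = base * rng.uniform(0.4, 1.6, size=4)
            w = w / w.sum()
            basins.append([Basin(c[0], c[1], spread, wi)
                           for c, wi in zip(centers, w)])
        return cls(basins, seed=seed, **kw)


def _ou_series(rng, n, sigma, rho):
    """Stationary AR(1) (discretized Ornstein-Uhlenbeck) series."""
    noise = rng.standard_normal(n) * (sigma * np.sqrt(1.0 - rho * rho))
    x = lfilter([1.0], [1.0, -rho], noise)
    decay = rho ** np.arange(n)
    return x + rng.standard_normal() * sigma * decay


def sample_dihedral_series(spec: EnsembleSpec, residue: int = 0,
                           truth_resolution: float = 1.0
                           ) -> tuple[DihedralSeries, RamachandranGrid]:
    """Simulate one residue's (phi, psi) series and its analytic truth grid."""
    basins = spec.basins[residue]
    rng = np.random.default_rng(np.random.SeedSequence((spec.seed, residue)))
    n = spec.n_frames
    weights = np.array([b.weight for b in basins])
    # Markov jumps: exponential waiting times, destination drawn from the
    # stationary weights, giving stationary occupancies equal to the weights
    p_jump = -np.expm1(-spec.dt / spec.exchange_time)
    jump = rng.random(n) < p_jump
    jump[0] = True
    draws = rng.choice(len(basins), size=n, p=weights)
    idx_of_last_jump = np.maximum.accumulate(
        np.where(jump, np.arange(n), -1))
    basin_idx = draws[idx_of_last_jump]
    centers_phi = np.array([b.phi for b in basins])[basin_idx]
    centers_psi = np.array([b.psi for b in basins])[basin_idx]
    spreads = np.array([b.spread for b in basins])
    if np.ptp(spreads) > 1e-12:
        raise ValueError("per-residue basins must share one spread value")
    sigma = spreads[0]
    rho = float(np.exp(-spec.dt / spec.jitter_time))
    if sigma > 0:
        dphi = _ou_series(rng, n, sigma, rho)
        dpsi = _ou_series(rng, n, sigma, rho)
    else:
        dphi = dpsi = np.zeros(n)
    series = DihedralSeries(centers_phi + dphi, centers_psi + dpsi, spec.dt)
    return series, true_grid(basins, truth_resolution)


def _wrapped_gaussian(centers, mu, sigma):
    if sigma <= 0:
        dens = np.zeros_like(centers)
        dens[np.argmin(np.abs(wrap_angles(centers - mu)))] = 1.0
        return dens
    acc = np.zeros_like(centers)
    for k in (-1, 0, 1):
        acc += np.exp(-0.5 * ((centers - mu + 360.0 * k) / sigma) ** 2)
    return acc


def true_grid(basins: Sequence[Basin], resolution: float = 1.0
              ) -> RamachandranGrid:
    """Analytic wrapped-Gaussian basin mixture on the standard grid."""
    centers = grid_centers(resolution)
    total = np.zeros((len(centers), len(centers)))
    for b in basins:
        fphi = _wrapped_gaussian(centers, b.phi, b.spread)
        fpsi = _wrapped_gaussian(centers, b.psi, b.spread)
        total += b.weight * np.outer(fphi / fphi.sum(), fpsi / fpsi.sum())
    return RamachandranGrid.from_values(resolution, total)


# ---------------------------------------------------------------------------
# Chain coordinates
# ---------------------------------------------------------------------------

ChainPositions = dict[tuple[int, str], np.ndarray]  # (residue, atom) -> (n, 3)


def chain_coordinates(series: Sequence[DihedralSeries],
                      geometry: BackboneGeometry | None = None
                      ) -> ChainPositions:
    """Internal-to-Cartesian chain build, one frame per time step.

    Residues are indexed 0..R-1; a dummy carbonyl (residue -1) precedes the
    chain so that residue 0 can apply its phi like any other.  All internal
    coordinates other than the supplied (phi_i, psi_i) are rigid, omega
    trans.  Atom names: N, H, CA, HA, C, O.
    """
    g = geometry or BackboneGeometry()
    n = len(series[0])
    for s in series:
        if len(s) != n:
            raise ValueError("all residues must have the same number of frames")
    pos: ChainPositions = {}
    shape = (n, 3)
    pos[(0, "N")] = np.zeros(shape)
    pos[(-1, "C")] = np.broadcast_to([g.r_c_n, 0.0, 0.0], shape).copy()
    a = np.radians(g.ang_c_n_ca)
    pos[(0, "CA")] = np.broadcast_to(
        [g.r_n_ca * np.cos(a), g.r_n_ca * np.sin(a), 0.0], shape).copy()
    pos[(-1, "O")] = _nerf(pos[(0, "CA")], pos[(0, "N")], pos[(-1, "C")],
                           g.r_c_o, g.ang_o_c_n, 0.0)
    for i, s in enumerate(series):
        phi, psi = s.phi, s.psi
        pos[(i, "H")] = _nerf(pos[(i - 1, "O")], pos[(i - 1, "C")],
                              pos[(i, "N")], g.r_NH, g.ang_c_n_h, 180.0)
        pos[(i, "C")] = _nerf(pos[(i - 1, "C")], pos[(i, "N")],
                              pos[(i, "CA")], g.r_ca_c, g.ang_n_ca_c, phi)
        pos[(i, "HA")] = _nerf(pos[(i - 1, "C")], pos[(i, "N")],
                               pos[(i, "CA")], g.r_CaHa, g.ang_n_ca_ha,
                               phi + 120.0)
        pos[(i + 1, "N")] = _nerf(pos[(i, "N")], pos[(i, "CA")],
                                  pos[(i, "C")], g.r_c_n, g.ang_ca_c_n, psi)
        pos[(i, "O")] = _nerf(pos[(i, "N")], pos[(i, "CA")], pos[(i, "C")],
                              g.r_c_o, g.ang_ca_c_o, psi + 180.0)
        pos[(i + 1, "CA")] = _nerf(pos[(i, "CA")], pos[(i, "C")],
                                   pos[(i + 1, "N")], g.r_n_ca, g.ang_c_n_ca,
                                   g.omega)
    r = len(series)
    pos[(r, "H")] = _nerf(pos[(r - 1, "O")], pos[(r - 1, "C")],
                          pos[(r, "N")], g.r_NH, g.ang_c_n_h, 180.0)
    return pos


# ---------------------------------------------------------------------------
# Tumbling
# ---------------------------------------------------------------------------

def _quat_multiply(q1, q2):
    w1, x1, y1, z1 = q1[..., 0], q1[..., 1], q1[..., 2], q1[..., 3]
    w2, x2, y2, z2 = q2[..., 0], q2[..., 1], q2[..., 2], q2[..., 3]
    return np.stack([
        w1 * w2 - x1 * x2 - y1 * y2 - z1 * z2,
        w1 * x2 + x1 * w2 + y1 * z2 - z1 * y2,
        w1 * y2 - x1 * z2 + y1 * w2 + z1 * x2,
        w1 * z2 + x1 * y2 - y1 * x2 + z1 * w2,
    ], axis=-1)


def _quat_to_matrix(q):
    w, x, y, z = q[..., 0], q[..., 1], q[..., 2], q[..., 3]
    return np.stack([
        np.stack([1 - 2 * (y * y + z * z), 2 * (x * y - w * z),
                  2 * (x * z + w * y)], axis=-1),
        np.stack([2 * (x * y + w * z), 1 - 2 * (x * x + z * z),
                  2 * (y * z - w * x)], axis=-1),
        np.stack([2 * (x * z - w * y), 2 * (y * z + w * x),
                  1 - 2 * (x * x + y * y)], axis=-1),
    ], axis=-2)


def tumbling_matrices(n_frames: int, dt: float, tau_rot: float,
                      rng) -> np.ndarray:
    """Rotation matrices R(t) of an isotropic rotational-diffusion walk.

    Small-step quaternion increments with diffusion coefficient
    D_r = 1 / (6 tau_rot); R(0) is the identity.  The cumulative
    composition is evaluated with a vectorized prefix scan.
    """
    if np.isinf(tau_rot):
        return np.broadcast_to(np.eye(3), (n_frames, 3, 3))
    sigma = np.sqrt(2.0 * dt / (6.0 * tau_rot))
    rotvec = rng.standard_normal((n_frames, 3)) * sigma
    rotvec[0] = 0.0
    half = 0.5 * np.linalg.norm(rotvec, axis=1)
    axis = np.zeros_like(rotvec)
    nz = half > 0
    axis[nz] = rotvec[nz] / (2.0 * half[nz][:, None])
    q = np.empty((n_frames, 4))
    q[:, 0] = np.cos(half)
    q[:, 1:] = axis * np.sin(half)[:, None]
    # Hillis-Steele inclusive prefix product (composition is associative)
    shift = 1
    while shift < n_frames:
        prev = q.copy()
        q[shift:] = _quat_multiply(prev[:-shift], prev[shift:])
        q /= np.linalg.norm(q, axis=1, keepdims=True)
        shift *= 2
    return _quat_to_matrix(q)


def apply_tumbling(traj, tau_rot: float, seed=None, dt: float | None = None,
                   rng=None):
    """Rigid-rotate every frame of a trajectory by a diffusive tumbling walk.

    ``traj`` is either a ChainPositions mapping (dt optional, frames taken
    from the arrays) or a plain (n, ..., 3) array.  Internal geometry is
    untouched; tau_rot = inf returns the input unchanged.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if isinstance(traj, dict):
        n = next(iter(traj.values())).shape[0]
        rot = tumbling_matrices(n, dt if dt is not None else 1e-12,
                                tau_rot, rng)
        return {k: np.einsum("tij,tj->ti", rot, v) for k, v in traj.items()}
    traj = np.asarray(traj)
    rot = tumbling_matrices(traj.shape[0], dt if dt is not None else 1e-12,
                            tau_rot, rng)
    return np.einsum("tij,t...j->t...i", rot, traj)


# ---------------------------------------------------------------------------
# Forward rate generation and the stand-in prior
# ---------------------------------------------------------------------------

def rigid_ensemble_rate_sets(conformers, n_frames: int, dt: float,
                             tau_rot: float, seed: int,
                             upper_bound: float,
                             geometry: BackboneGeometry | None = None,
                             constants=None, csa_map=None):
    """Rate sets of frozen conformers sharing one tumbling realization.

    ``conformers`` is a list of per-residue (phi, psi); every residue is a
    rigid fragment whose dynamics is the common isotropic tumbling walk
    (uniform dynamics by construction).  Equivalent to a frozen chain --
    a constant rotation between fragments drops out of every correlation
    function -- but processes one residue at a time with bounded memory.
    """
    from . import rateasm
    from .physmodel import build_fragment
    from .tcfcore import TcfEngine

    rng = np.random.default_rng(seed)
    rot = tumbling_matrices(n_frames, dt, tau_rot, rng)
    sets = {}
    for i, (phi, psi) in enumerate(conformers):
        frag = build_fragment(float(phi), float(psi), geometry)
        chain = {(i + off, name): np.einsum("tij,j->ti", rot, xyz)
                 for (name, off), xyz in frag.items()}
        engine = TcfEngine(n_frames, dt, upper_bound)
        sets[i] = rateasm.compute_residue_rates(
            chain, i, dt, upper_bound, constants, geometry, csa_map, engine)
        engine.clear_cache()
    known = rateasm.KnownAmplitudes.from_model(constants, geometry, csa_map)
    rateasm.attach_proxies(sets, known)
    return sets


def synthetic_rates(p: RamachandranGrid, taus: Mapping[str, float],
                    surfaces: Mapping[str, RateSurface],
                    noise_sigma: float = 0.0, seed=None, rng=None
                    ) -> tuple[dict[str, float], dict[str, float]]:
    """Forward-generate rates Gamma_j = tau_j * sum(p * A_j) + noise.

    Returns (rates, true amplitudes); ground truth taus are the inputs.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rates, amps = {}, {}
    for rid, surf in surfaces.items():
        if surf.resolution != p.resolution:
            raise ValueError(f"surface {rid} resolution mismatch with p")
        a = float(np.sum(p.probabilities * surf.values))
        amps[rid] = a
        rates[rid] = taus[rid] * a + noise_sigma * rng.standard_normal()
    return rates, amps


def standin_coil_prior(resolution: float = 1.0, uniform_floor: float = 0.05
                       ) -> RamachandranGrid:
    """Synthetic stand-in for a residue-generic random-coil prior.

    A broad four-basin mixture (alpha, beta, polyproline-II, left-handed
    helix) blended with a uniform floor so the prior is strictly positive
    everywhere.  It is NOT the published coil library grid -- it is a
    weakly informative synthetic surrogate with the same role.
    """
    basins = [
        Basin(*CANONICAL_BASINS["alpha"], spread=25.0, weight=0.30),
        Basin(*CANONICAL_BASINS["beta"], spread=25.0, weight=0.25),
        Basin(*CANONICAL_BASINS["ppii"], spread=25.0, weight=0.35),
        Basin(*CANONICAL_BASINS["alphaL"], spread=20.0, weight=0.10),
    ]
    mixture = true_grid(basins, resolution).probabilities
    n = mixture.shape[0]
    values = (1.0 - uniform_floor) * mixture + uniform_floor / (n * n)
    return RamachandranGrid.from_values(resolution, values)


def export_pdb(path, positions: ChainPositions, frames=range(0, 1)) -> None:
    """Minimal multi-frame PDB export for interoperability with MD tooling.

    Backbone atoms only, residue name GLY-like placeholder; intended for
    visual inspection, not round-tripping.
    """
    order = ["N", "H", "CA", "HA", "C", "O"]
    residues = sorted({r for (r, _) in positions if r >= 0})
    with open(path, "w") as fh:
        for m, t in enumerate(frames, start=1):
            fh.write(f"MODEL     {m:4d}\n")
            serial = 1
            for res in residues:
                for name in order:
                    key = (res, name)
                    if key not in positions:
                        continue
                    x, y, z = positions[key][t]
                    el = name[0]
                    fh.write(f"ATOM  {serial:5d} {name:^4s} GLY A"
                             f"{res + 1:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                             f"  1.00  0.00          {el:>2s}\n")
                    serial += 1
            fh.write("ENDMDL\n")
        fh.write("END\n")


def save_chain(path, positions: ChainPositions, dt: float, seed: int) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        h5.attrs["dt_ps"] = dt * 1e12
        h5.attrs["seed"] = seed
        for (res, name), arr in positions.items():
            h5.create_dataset(f"r{res}/{name}", data=arr)


def load_chain(path) -> tuple[ChainPositions, float, int]:
    import h5py

    pos: ChainPositions = {}
    with h5py.File(path, "r") as h5:
        dt = float(h5.attrs["dt_ps"]) * 1e-12
        seed = int(h5.attrs["seed"])
        for rkey in h5:
            res = int(rkey[1:])
            for name in h5[rkey]:
                pos[(res, name)] = h5[rkey][name][...]
    return pos, dt, seed
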