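"""Time correlation functions and zero-frequency spectral densities.

The cross TCF of two unit-vector series is C(t) = <P2(a(0) . b(t))>,
averaged over time origins.  P2 of a dot product decomposes into the six
symmetric outer products of each vector, so the TCF is computed as a sum of
channel cross-correlations evaluated with FFTs (zero-padded, unbiased: each
lag divided by its number of contributing origins).  Sampling quality is
improved by also correlating the two series in reversed order and averaging
the two estimates.

Optionally the correlated quantity is P2 weighted by r_a(0)^-3 r_b(t)^-3
for dipoles whose instantaneous length fluctuates.

J(0) is the trapezoidal integral of the TCF up to a configurable bound
(defaults 10 ns for disordered, 20 ns for folded systems); the effective
correlation time is the same integral after normalizing the amplitude to 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.fft import next_fast_len, rfft, irfft

__all__ = [
    "VectorTrajectory",
    "Tcf",
    "TcfEngine",
    "cross_tcf",
    "csa_weighted_tcf",
    "integrate_tcf",
    "correlation_time",
    "TruncationError",
    "UPPER_BOUND_DISORDERED_S",
    "UPPER_BOUND_FOLDED_S",
    "save_vector_trajectory",
    "load_vector_trajectory",
]

UPPER_BOUND_DISORDERED_S = 10e-9
UPPER_BOUND_FOLDED_S = 20e-9

# channel index pairs of the symmetric second-moment decomposition
_CHANNELS = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))
_CHANNEL_WEIGHTS = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])


class TruncationError(ValueError):
    """Requested integration bound exceeds the available lag range."""


@dataclass
class VectorTrajectory:
    """Unit-vector time series with optional instantaneous distances (A)."""

    vectors: np.ndarray  # (n, 3)
    dt: float  # s
    distances: np.ndarray | None = None  # (n,), Angstrom

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != 3:
            raise ValueError("vectors must have shape (n, 3)")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("vectors must be unit length within 1e-8")
        if self.distances is not None:
            self.distances = np.asarray(self.distances, dtype=float)
            if self.distances.shape != (len(self.vectors),):
                raise ValueError("distances must match the number of frames")
            if np.any(self.distances <= 0):
                raise ValueError("distances must be positive")

    def __len__(self) -> int:
        return len(self.vectors)

    @property
    def span(self) -> float:
        return (len(self.vectors) - 1) * self.dt

    @property
    def mean_distance(self) -> float | None:
        if self.distances is None:
            return None
        return float(self.distances.mean())


@dataclass
class Tcf:
    """Correlation function sampled at lags 0, dt, 2*dt, ..."""

    values: np.ndarray
    dt: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def amplitude(self) -> float:
        return float(self.values[0])

    @property
    def max_lag(self) -> float:
        return (len(self.values) - 1) * self.dt

    def normalized(self) -> "Tcf":
        if self.amplitude == 0:
            raise ZeroDivisionError("zero-amplitude TCF cannot be normalized")
        return Tcf(self.values / self.amplitude, self.dt)


class TcfEngine:
    """FFT cross-correlator with cached per-trajectory channel spectra.

    One rate assembly touches the same vector series many times (a dipole
    against both CSA axes, the reverse-order average, several rates sharing
    a bond vector); caching the channel FFTs makes the per-pair cost a
    single inverse transform.
    """

    def __init__(self, n_frames: int, dt: float, max_lag: float):
        if max_lag > (n_frames - 1) * dt + 1e-15:
            raise ValueError("max_lag exceeds the trajectory span")
        self.n = n_frames
        self.dt = dt
        self.n_lags = int(round(max_lag / dt)) + 1
        self.nfft = next_fast_len(self.n + self.n_lags)
        self._cache: dict[tuple[int, bool], np.ndarray] = {}

    def spectra(self, vt: VectorTrajectory, weighted: bool) -> np.ndarray:
        """rfft of the 6 tensor channels plus the scalar (r^-3) channel."""
        key = (id(vt), weighted)
        hit = self._cache.get(key)
        if hit is not None:
            return hit[1]
        if len(vt) != self.n or vt.dt != self.dt:
            raise ValueError("trajectory length/dt mismatch with engine")
        v = vt.vectors
        if weighted:
            if vt.distances is None:
                raise ValueError("distance weighting requires distances")
            scalar = vt.distances ** -3
        else:
            scalar = np.ones(self.n)
        chans = np.empty((7, self.n))
        for k, (i, j) in enumerate(_CHANNELS):
            chans[k] = v[:, i] * v[:, j] * scalar
        chans[6] = scalar
        sp = rfft(chans, n=self.nfft, axis=1)
        # hold a reference to vt: the key is its id(), which must stay unique
        self._cache[key] = (vt, sp)
        return sp

    def clear_cache(self) -> None:
        self._cache.clear()

    def cross(self, a: VectorTrajectory, b: VectorTrajectory,
              distance_weighting: bool = False,
              weight_a: bool | None = None,
              weight_b: bool | None = None) -> Tcf:
        """Cross TCF; ``weight_a``/``weight_b`` control per-side r^-3 weighting
        (both default to ``distance_weighting``)."""
        if len(a) != len(b) or a.dt != b.dt:
            raise ValueError("trajectories must share length and dt")
        wa = distance_weighting if weight_a is None else weight_a
        wb = distance_weighting if weight_b is None else weight_b
        sa = self.spectra(a, wa)
        sb = self.spectra(b, wb)
        w = 1.5 * _CHANNEL_WEIGHTS
        spec = np.einsum("c,cf->f", w, np.conj(sa[:6]) * sb[:6])
        spec -= 0.5 * np.conj(sa[6]) * sb[6]
        full = irfft(spec, n=self.nfft)
        L = self.n_lags
        fwd = full[:L]
        rev = np.empty(L)
        rev[0] = full[0]
        rev[1:] = full[self.nfft - 1:self.nfft - L:-1]
        counts = self.n - np.arange(L)
        return Tcf(0.5 * (fwd + rev) / counts, self.dt)


def cross_tcf(a: VectorTrajectory, b: VectorTrajectory, max_lag: float,
              distance_weighting: bool = False,
              weight_a: bool | None = None,
              weight_b: bool | None = None) -> Tcf:
    """C(t) = <P2(a(0) . b(t))> (optionally r^-3-weighted), origin-averaged.

    Computed with the FFT convolution theorem and symmetrized as the mean
    of the forward and reversed-order correlations; unbiased at every lag.
    """
    engine = TcfEngine(len(a), a.dt, max_lag)
    return engine.cross(a, b, distance_weighting, weight_a, weight_b)


def csa_weighted_tcf(component_tcfs: Mapping, csa, csa2=None) -> Tcf:
    """Linear combination of component TCFs with CSA anisotropy weights.

    For a DD/CSA interference pass components keyed "x", "y" (weights
    sigma_kk - sigma_zz, in ppm); for CSA/CSA pass keys ("x","x"), ("x","y"),
    ("y","x"), ("y","y") and the second tensor, giving the double sum.
    """
    deltas = {"x": csa.delta_x, "y": csa.delta_y}
    if csa2 is None:
        keys = ["x", "y"]
        weights = [deltas[k] for k in keys]
    else:
        d2 = {"x": csa2.delta_x, "y": csa2.delta_y}
        keys = [(k, l) for k in ("x", "y") for l in ("x", "y")]
        weights = [deltas[k] * d2[l] for k, l in keys]
    acc = None
    dt = None
    for key, w in zip(keys, weights):
        if key not in component_tcfs:
            raise KeyError(f"missing component TCF for {key!r}")
        t = component_tcfs[key]
        if dt is None:
            dt = t.dt
            acc = w * t.values
        else:
            if t.dt != dt or len(t.values) != len(acc):
                raise ValueError("component TCFs must share dt and length")
            acc = acc + w * t.values
    return Tcf(acc, dt)


def integrate_tcf(tcf: Tcf, upper_bound: float) -> float:
    """Trapezoidal J(0) = integral of C(t) from 0 to upper_bound (s)."""
    if upper_bound > tcf.max_lag + 1e-15:
        raise TruncationError(
            f"upper bound {upper_bound} s exceeds max lag {tcf.max_lag} s")
    k = int(round(upper_bound / tcf.dt))
    return float(np.trapezoid(tcf.values[:k + 1], dx=tcf.dt))


def correlation_time(tcf: Tcf, upper_bound: float) -> float:
    """Effective correlation time: J(0) of the amplitude-normalized TCF."""
    amp = tcf.amplitude
    if amp == 0 or not np.isfinite(amp):
        raise ZeroDivisionError("correlation time undefined for zero amplitude")
    return integrate_tcf(tcf, upper_bound) / amp


def save_vector_trajectory(path, vt: VectorTrajectory, *, atom_pair: str = "",
                           residue: int = -1) -> None:
    import h5py

    with h5py.File(path, "w") as h5:
        d = h5.create_dataset("vectors", data=vt.vectors)
        if vt.distances is not None:
            h5.create_dataset("distances", data=vt.distances)
        d.attrs["dt_ps"] = vt.dt * 1e12
        d.attrs["atom_pair"] = atom_pair
        d.attrs["residue"] = residue


def load_vector_trajectory(path) -> VectorTrajectory:
    import h5py

    with h5py.File(path, "r") as h5:
        vec = h5["vectors"][...]
        dist = h5["distances"][...] if "distances" in h5 else None
        dt = float(h5["vectors"].attrs["dt_ps"]) * 1e-12
    return VectorTrajectory(vec, dt, dist)
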