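"""Physical model of backbone cross-correlated relaxation (CCR) amplitudes.

A CCR rate between two relaxation mechanisms (dipole-dipole or chemical
shift anisotropy) factorizes into a structural amplitude ``A`` -- set by the
second Legendre polynomial of the projection angle between the two
interaction vectors -- and an effective correlation time.  With a rigid
model backbone whose only conformational degrees of freedom are the
dihedrals (phi, psi) of the central residue, the amplitude becomes a
surface ``A(phi, psi)`` that can be tabulated once and reused in both the
forward prediction of rates and the inversion of measured rates into a
Ramachandran distribution.

This module holds the physical constants, the rigid peptide geometry, the
CSA tensor frames, the declarative registry of the ten CCR interferences
(eight remote rates plus the two known-amplitude rates used as dynamical
proxies), and the computation of amplitude surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PhysicalConstants",
    "CsaTensor",
    "BackboneGeometry",
    "Dipole",
    "CsaSite",
    "RateKind",
    "RateSurface",
    "RATE_REGISTRY",
    "REMOTE_RATE_IDS",
    "KNOWN_RATE_IDS",
    "MAGIC_ANGLE_DEG",
    "p2",
    "default_csa_map",
    "build_fragment",
    "csa_frame",
    "prefactor",
    "structural_amplitude",
    "build_rate_surface",
    "build_rate_surfaces",
    "grid_centers",
    "save_surfaces",
    "load_surfaces",
    "DegenerateFrameError",
    "UnknownAtomError",
]

MAGIC_ANGLE_DEG = np.degrees(np.arccos(1.0 / np.sqrt(3.0)))  # 54.7356...


def p2(x):
    """Second Legendre polynomial P2(x) = 1.5 x^2 - 0.5."""
    x = np.asarray(x)
    return 1.5 * x * x - 0.5


class DegenerateFrameError(ValueError):
    """Plane-defining bonds of a CSA frame are (numerically) colinear."""


class UnknownAtomError(KeyError):
    """An interaction references an atom the fragment builder does not place."""


# ---------------------------------------------------------------------------
# Constants and tensors
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhysicalConstants:
    """Gyromagnetic ratios (rad s-1 T-1, signed), field and SI constants.

    ``B0`` defaults to the field of an 800 MHz (proton operational
    frequency) spectrometer.
    """

    gamma_H: float = 2.6752218744e8
    gamma_C: float = 6.728284e7
    gamma_N: float = -2.7116e7
    mu0: float = 4.0e-7 * np.pi
    hbar: float = 1.054571817e-34
    B0: float = 2.0 * np.pi * 800.0e6 / 2.6752218744e8

    def __post_init__(self):
        if not (self.gamma_N < 0 < self.gamma_C < self.gamma_H):
            raise ValueError("expected gamma_N < 0 < gamma_C < gamma_H")
        if self.B0 <= 0:
            raise ValueError("B0 must be positive")

    @classmethod
    def at_proton_mhz(cls, mhz: float) -> "PhysicalConstants":
        c = cls()
        return replace(c, B0=2.0 * np.pi * mhz * 1e6 / c.gamma_H)

    def gamma(self, atom_name: str) -> float:
        el = atom_name[0]
        if el == "H":
            return self.gamma_H
        if el == "C":
            return self.gamma_C
        if el == "N":
            return self.gamma_N
        raise KeyError(f"no gyromagnetic ratio for atom {atom_name!r}")


@dataclass(frozen=True)
class CsaTensor:
    """Chemical shift anisotropy tensor: principal values and in-plane frame.

    ``alpha`` is the angle (degrees) between the reference bond and the xx
    eigenvector, measured in the peptide plane toward the second
    plane-defining bond.  ``frame_rule`` names the two bonds whose span
    defines the plane; zz is the plane normal.
    """

    sigma_xx: float  # ppm
    sigma_yy: float
    sigma_zz: float
    alpha: float  # deg
    frame_rule: str

    def __post_init__(self):
        if not (self.sigma_xx >= self.sigma_yy >= self.sigma_zz):
            raise ValueError("principal values must be ordered xx >= yy >= zz")

    @property
    def delta_x(self) -> float:
        """sigma_xx - sigma_zz in ppm."""
        return self.sigma_xx - self.sigma_zz

    @property
    def delta_y(self) -> float:
        """sigma_yy - sigma_zz in ppm."""
        return self.sigma_yy - self.sigma_zz


# Average backbone tensors.  The amide-nitrogen tensor is effectively axial
# (sigma_xx - sigma_zz ~ sigma_xx - sigma_yy = 170 ppm, i.e. yy ~ zz), so it
# is stored through its principal-value differences (170, 0) ppm.
C_PRIME_CSA = CsaTensor(249.4, 191.1, 87.9, alpha=37.0, frame_rule="C'N/C'O")
N_CSA = CsaTensor(170.0, 0.0, 0.0, alpha=20.0, frame_rule="NH/NC'")


def default_csa_map() -> dict[str, CsaTensor]:
    """Per-element average CSA tensors used throughout."""
    return {"C": C_PRIME_CSA, "N": N_CSA}


@dataclass(frozen=True)
class BackboneGeometry:
    """Rigid internal coordinates of the model backbone.

    Lengths in Angstrom, angles in degrees.  The peptide torsion omega is
    fixed (trans); phi and psi of the central residue are the only
    conformational degrees of freedom.  Amide and alpha proton distances
    default to 1.01 and 1.09 A (trajectory-average values).
    """

    r_n_ca: float = 1.458
    r_ca_c: float = 1.525
    r_c_n: float = 1.329
    r_c_o: float = 1.231
    r_NH: float = 1.01
    r_CaHa: float = 1.09
    ang_n_ca_c: float = 111.0
    ang_ca_c_n: float = 116.2
    ang_c_n_ca: float = 121.7
    ang_ca_c_o: float = 120.8
    ang_o_c_n: float = 123.0
    ang_c_n_h: float = 119.15
    ang_n_ca_ha: float = 109.5
    omega: float = 180.0

    def __post_init__(self):
        for name in ("r_n_ca", "r_ca_c", "r_c_n", "r_c_o", "r_NH", "r_CaHa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def mean_distance(self, a: "Atom", b: "Atom") -> float | None:
        """Mean bond length (A) for a dipole, or None if not a fixed bond."""
        pair = frozenset([(a[0], 0), (b[0], b[1] - a[1])])
        table = {
            frozenset([("N", 0), ("H", 0)]): self.r_NH,
            frozenset([("CA", 0), ("HA", 0)]): self.r_CaHa,
            frozenset([("C", 0), ("CA", 0)]): self.r_ca_c,
            frozenset([("N", 0), ("CA", 0)]): self.r_n_ca,
        }
        return table.get(pair)


# ---------------------------------------------------------------------------
# Rate registry
# ---------------------------------------------------------------------------

Atom = tuple[str, int]  # (atom name, residue offset relative to residue i)


@dataclass(frozen=True)
class Dipole:
    """A dipolar interaction between two nuclei.

    ``distance_mode`` is "fixed-mean" for bonded pairs (trajectory-mean
    distance enters the prefactor) or "instantaneous" when r(t)^-3 is kept
    inside the correlation function.
    """

    a: Atom
    b: Atom
    distance_mode: str = "fixed-mean"


@dataclass(frozen=True)
class CsaSite:
    """A CSA relaxation mechanism located on one nucleus."""

    nucleus: Atom


Interaction = Dipole | CsaSite


@dataclass(frozen=True)
class RateKind:
    """Declarative description of one CCR interference."""

    rate_id: str
    mechanism_class: str  # "dd_dd" | "dd_csa" | "csa_csa"
    interactions: tuple[Interaction, Interaction]
    amplitude_known: bool = False

    def involves_hn(self) -> bool:
        """True if any dipole of this kind involves an amide proton."""
        for ia in self.interactions:
            if isinstance(ia, Dipole):
                if ia.a[0] == "H" or ia.b[0] == "H":
                    return True
        return False


# The ten registered interferences.  Atoms are named (PDB-style) with the
# residue offset relative to the central residue i.  Eight remote rates (no
# shared spin between the two mechanisms) probe phi_i/psi_i through the
# relative orientation of interaction vectors in the i-1..i+1 fragment; the
# two known-amplitude rates live inside one rigid peptide plane, so their
# amplitude is conformation-independent and their measured rate yields a
# correlation time directly.
RATE_REGISTRY: dict[str, RateKind] = {}


def _register(kind: RateKind) -> None:
    RATE_REGISTRY[kind.rate_id] = kind


_register(RateKind("NHN_CAHA", "dd_dd",
                   (Dipole(("N", 0), ("H", 0)), Dipole(("CA", 0), ("HA", 0)))))
_register(RateKind("CAHA_NHN1", "dd_dd",
                   (Dipole(("CA", 0), ("HA", 0)), Dipole(("N", 1), ("H", 1)))))
_register(RateKind("NHN_NHN1", "dd_dd",
                   (Dipole(("N", 0), ("H", 0)), Dipole(("N", 1), ("H", 1)))))
_register(RateKind("HAHN1_C", "dd_csa",
                   (Dipole(("HA", 0), ("H", 1), distance_mode="instantaneous"),
                    CsaSite(("C", 0)))))
_register(RateKind("NHN_C", "dd_csa",
                   (Dipole(("N", 0), ("H", 0)), CsaSite(("C", 0)))))
_register(RateKind("CAHA_Cm1", "dd_csa",
                   (Dipole(("CA", 0), ("HA", 0)), CsaSite(("C", -1)))))
_register(RateKind("CAHA_C", "dd_csa",
                   (Dipole(("CA", 0), ("HA", 0)), CsaSite(("C", 0)))))
_register(RateKind("Cm1_C", "csa_csa",
                   (CsaSite(("C", -1)), CsaSite(("C", 0)))))
# Known-amplitude (proxy) rates: N-CSA with the NH dipole of the same
# peptide plane, and C'-CSA with the C'CA dipole of the same plane.
_register(RateKind("N_NHN", "dd_csa",
                   (Dipole(("N", 0), ("H", 0)), CsaSite(("N", 0))),
                   amplitude_known=True))
_register(RateKind("C_CCA", "dd_csa",
                   (Dipole(("C", 0), ("CA", 0)), CsaSite(("C", 0))),
                   amplitude_known=True))

REMOTE_RATE_IDS = tuple(k for k, v in RATE_REGISTRY.items() if not v.amplitude_known)
KNOWN_RATE_IDS = tuple(k for k, v in RATE_REGISTRY.items() if v.amplitude_known)
assert len(REMOTE_RATE_IDS) == 8 and len(KNOWN_RATE_IDS) == 2


# ---------------------------------------------------------------------------
# Internal-to-Cartesian fragment construction
# ---------------------------------------------------------------------------

def _unit(v, axis=-1):
    n = np.linalg.norm(v, axis=axis, keepdims=True)
    return v / n


def _nerf(a, b, c, bond, angle_deg, torsion_deg):
    """Place atom d at |cd| = bond, angle(b,c,d), torsion(a,b,c,d).

    Natural-extension-reference-frame placement; all arguments broadcast
    over leading dimensions.
    """
    theta = np.radians(angle_deg)
    chi = np.radians(torsion_deg)
    bc = _unit(c - b)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n, axis=-1, keepdims=True)
    if np.any(nn < 1e-10):
        raise ValueError("colinear reference atoms in internal-coordinate build")
    n = n / nn
    m = np.cross(n, bc)
    theta = np.broadcast_to(np.asarray(theta)[..., None], bc.shape[:-1] + (1,))
    chi = np.broadcast_to(np.asarray(chi)[..., None], bc.shape[:-1] + (1,))
    d = (-np.cos(theta) * bc
         + np.sin(theta) * np.cos(chi) * m
         + np.sin(theta) * np.sin(chi) * n)
    return c + bond * d


def dihedral_angle(p0, p1, p2, p3):
    """Signed dihedral (deg, in [-180, 180)) of four points (broadcasts)."""
    b0 = p0 - p1
    b1 = _unit(p2 - p1)
    b2 = p3 - p2
    v = b0 - np.sum(b0 * b1, axis=-1, keepdims=True) * b1
    w = b2 - np.sum(b2 * b1, axis=-1, keepdims=True) * b1
    x = np.sum(v * w, axis=-1)
    y = np.sum(np.cross(b1, v) * w, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    return np.where(ang >= 180.0, ang - 360.0, ang)


def bond_angle(p0, p1, p2):
    """Angle (deg) at p1."""
    u = _unit(p0 - p1)
    v = _unit(p2 - p1)
    return np.degrees(np.arccos(np.clip(np.sum(u * v, axis=-1), -1.0, 1.0)))


def build_fragment(phi, psi, geometry: BackboneGeometry | None = None
                   ) -> dict[Atom, np.ndarray]:
    """Cartesian coordinates of the i-1..i+1 fragment at dihedrals (phi, psi).

    Returns a mapping (atom name, residue offset) -> positions with shape
    ``np.broadcast(phi, psi).shape + (3,)``.  Only phi_i and psi_i are
    variable; every other internal coordinate is fixed with omega trans.
    """
    g = geometry or BackboneGeometry()
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    shape = np.broadcast(phi, psi).shape
    phi = np.broadcast_to(phi, shape)
    psi = np.broadcast_to(psi, shape)

    def const(xyz):
        return np.broadcast_to(np.asarray(xyz, dtype=float), shape + (3,))

    f: dict[Atom, np.ndarray] = {}
    f[("N", 0)] = const([0.0, 0.0, 0.0])
    f[("C", -1)] = const([g.r_c_n, 0.0, 0.0])
    a = np.radians(g.ang_c_n_ca)
    f[("CA", 0)] = const([g.r_n_ca * np.cos(a), g.r_n_ca * np.sin(a), 0.0])
    # torsion(CA_i - N_i - C'_{i-1} - O_{i-1}) = 0 (O cis to CA_i, in plane)
    f[("O", -1)] = _nerf(f[("CA", 0)], f[("N", 0)], f[("C", -1)],
                         g.r_c_o, g.ang_o_c_n, 0.0)
    # amide proton trans to the carbonyl oxygen of the same plane
    f[("H", 0)] = _nerf(f[("O", -1)], f[("C", -1)], f[("N", 0)],
                        g.r_NH, g.ang_c_n_h, 180.0)
    f[("C", 0)] = _nerf(f[("C", -1)], f[("N", 0)], f[("CA", 0)],
                        g.r_ca_c, g.ang_n_ca_c, phi)
    # L-amino-acid convention: HA at phi + 120 about the N-CA bond
    f[("HA", 0)] = _nerf(f[("C", -1)], f[("N", 0)], f[("CA", 0)],
                         g.r_CaHa, g.ang_n_ca_ha, phi + 120.0)
    f[("N", 1)] = _nerf(f[("N", 0)], f[("CA", 0)], f[("C", 0)],
                        g.r_c_n, g.ang_ca_c_n, psi)
    f[("O", 0)] = _nerf(f[("N", 0)], f[("CA", 0)], f[("C", 0)],
                        g.r_c_o, g.ang_ca_c_o, psi + 180.0)
    f[("H", 1)] = _nerf(f[("CA", 0)], f[("C", 0)], f[("N", 1)],
                        g.r_NH, g.ang_c_n_h, 0.0)
    f[("CA", 1)] = _nerf(f[("CA", 0)], f[("C", 0)], f[("N", 1)],
                         g.r_n_ca, g.ang_c_n_ca, g.omega)
    return f


def fragment_atom(coords: Mapping[Atom, np.ndarray], atom: Atom) -> np.ndarray:
    try:
        return coords[atom]
    except KeyError:
        raise UnknownAtomError(f"atom {atom!r} not present in fragment") from None


# ---------------------------------------------------------------------------
# CSA frames
# ---------------------------------------------------------------------------

def csa_frame(coords: Mapping[Atom, np.ndarray], nucleus: Atom,
              tensor: CsaTensor) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal (xx, yy, zz) principal axes of the CSA at ``nucleus``.

    zz is the normal of the plane spanned by the two frame bonds; xx lies in
    the plane at ``tensor.alpha`` degrees from the reference bond, rotated
    toward the second bond; yy completes a right-handed triad.
    """
    name, off = nucleus
    if name == "C":
        origin = fragment_atom(coords, ("C", off))
        ref = fragment_atom(coords, ("N", off + 1)) - origin
        sec = fragment_atom(coords, ("O", off)) - origin
    elif name == "N":
        origin = fragment_atom(coords, ("N", off))
        ref = fragment_atom(coords, ("H", off)) - origin
        sec = fragment_atom(coords, ("C", off - 1)) - origin
    else:
        raise UnknownAtomError(f"no CSA frame rule for nucleus {nucleus!r}")
    e1 = _unit(ref)
    normal = np.cross(e1, sec)
    nn = np.linalg.norm(normal, axis=-1, keepdims=True)
    if np.any(nn < 1e-8):
        raise DegenerateFrameError(
            f"plane-defining bonds for {nucleus!r} are colinear")
    zz = normal / nn
    e2 = _unit(sec - np.sum(sec * e1, axis=-1, keepdims=True) * e1)
    al = np.radians(tensor.alpha)
    xx = np.cos(al) * e1 + np.sin(al) * e2
    yy = np.cross(zz, xx)
    return xx, yy, zz


# ---------------------------------------------------------------------------
# Prefactors and amplitudes
# ---------------------------------------------------------------------------

_ANGSTROM = 1e-10
_PPM = 1e-6


def prefactor(kind: RateKind, constants: PhysicalConstants | None = None,
              geometry: BackboneGeometry | None = None,
              csa_map: Mapping[str, CsaTensor] | None = None,
              distances: Mapping[int, float] | None = None) -> np.ndarray:
    """Component prefactors (s-2 when multiplied with P2 and divided by s).

    Returns one value per correlated component: a single scalar for DD/DD,
    the (x, y) pair for DD/CSA and the (xx, xy, yx, yy) quadruple for
    CSA/CSA.  Mean dipolar distances come from the geometry; ``distances``
    (A, keyed by interaction position) overrides them, which is also the
    only way to supply a distance for an instantaneous-mode dipole whose
    r(t)^-3 is handled inside the correlation function (pass 1.0 there and
    scale externally).
    """
    c = constants or PhysicalConstants()
    g = geometry or BackboneGeometry()
    csa_map = csa_map if csa_map is not None else default_csa_map()
    kdd = (2.0 / 5.0) * (c.mu0 * c.hbar / (4.0 * np.pi)) ** 2
    kdc = (4.0 / 15.0) * (c.mu0 * c.hbar / (4.0 * np.pi))
    kcc = 8.0 / 45.0

    def dipole_part(idx: int, dip: Dipole) -> float:
        r = None
        if distances is not None and idx in distances:
            r = distances[idx]
        elif dip.distance_mode == "fixed-mean":
            r = g.mean_distance(dip.a, dip.b)
        if r is None:
            raise ValueError(
                f"no mean distance for dipole {dip.a}-{dip.b}; supply one")
        return c.gamma(dip.a[0]) * c.gamma(dip.b[0]) / (r * _ANGSTROM) ** 3

    def csa_part(site: CsaSite) -> tuple[float, np.ndarray]:
        try:
            t = csa_map[site.nucleus[0]]
        except KeyError:
            raise ValueError(
                f"missing CSA tensor for nucleus {site.nucleus!r}") from None
        return c.gamma(site.nucleus[0]), np.array([t.delta_x, t.delta_y]) * _PPM

    ia, ib = kind.interactions
    if kind.mechanism_class == "dd_dd":
        return np.array([kdd * dipole_part(0, ia) * dipole_part(1, ib)])
    if kind.mechanism_class == "dd_csa":
        dip, site = (ia, ib) if isinstance(ia, Dipole) else (ib, ia)
        idx = 0 if isinstance(ia, Dipole) else 1
        gu, deltas = csa_part(site)
        return kdc * dipole_part(idx, dip) * gu * c.B0 * deltas
    if kind.mechanism_class == "csa_csa":
        gu, du = csa_part(ia)
        gv, dv = csa_part(ib)
        return kcc * gu * gv * c.B0 ** 2 * np.outer(du, dv).ravel()
    raise ValueError(f"unknown mechanism class {kind.mechanism_class!r}")


def _interaction_axes(interaction: Interaction,
                      coords: Mapping[Atom, np.ndarray],
                      csa_map: Mapping[str, CsaTensor]):
    """Unit vectors (list) of one interaction; dipoles also return r (A)."""
    if isinstance(interaction, Dipole):
        va = fragment_atom(coords, interaction.a)
        vb = fragment_atom(coords, interaction.b)
        d = vb - va
        r = np.linalg.norm(d, axis=-1)
        return [d / r[..., None]], r
    xx, yy, _ = csa_frame(coords, interaction.nucleus,
                          csa_map[interaction.nucleus[0]])
    return [xx, yy], None


def structural_amplitude(kind: RateKind, phi, psi,
                         geometry: BackboneGeometry | None = None,
                         constants: PhysicalConstants | None = None,
                         csa_map: Mapping[str, CsaTensor] | None = None,
                         coords: Mapping[Atom, np.ndarray] | None = None):
    """Structural amplitude A(phi, psi) in s-2 (rate per unit correlation time).

    Sums prefactor * P2(cos theta) over the correlated components of the
    interference.  For an instantaneous-distance dipole the conformation's
    own r(phi, psi) enters the prefactor.  For the two known-amplitude kinds
    the result is independent of (phi, psi) by construction.
    """
    g = geometry or BackboneGeometry()
    c = constants or PhysicalConstants()
    csa_map = csa_map if csa_map is not None else default_csa_map()
    if coords is None:
        coords = build_fragment(phi, psi, g)
    ia, ib = kind.interactions
    axes_a, r_a = _interaction_axes(ia, coords, csa_map)
    axes_b, r_b = _interaction_axes(ib, coords, csa_map)
    dist_override: dict[int, float] = {}
    for idx, inter in enumerate((ia, ib)):
        if isinstance(inter, Dipole) and inter.distance_mode == "instantaneous":
            dist_override[idx] = 1.0  # r (A) folded in below, per conformation
    pref = prefactor(kind, c, g, csa_map, distances=dist_override or None)
    total = 0.0
    i = 0
    for ua in axes_a[: (1 if isinstance(ia, Dipole) else 2)]:
        for ub in axes_b[: (1 if isinstance(ib, Dipole) else 2)]:
            total = total + pref[i] * p2(np.sum(ua * ub, axis=-1))
            i += 1
    # prefactor already carries the Angstrom-to-meter conversion for r = 1 A,
    # so only the dimensionless (r / 1 A)^3 remains per instantaneous dipole
    for idx, r in ((0, r_a), (1, r_b)):
        if idx in dist_override:
            total = total / r ** 3
    return total


# ---------------------------------------------------------------------------
# Surfaces
# ---------------------------------------------------------------------------

def grid_centers(resolution: float) -> np.ndarray:
    """Bin centers -180 + res/2 + k*res on the half-open domain [-180, 180)."""
    if abs(360.0 / resolution - round(360.0 / resolution)) > 1e-9:
        raise ValueError("360 must be divisible by the resolution")
    n = int(round(360.0 / resolution))
    return -180.0 + resolution / 2.0 + resolution * np.arange(n)


@dataclass
class RateSurface:
    """Tabulated structural amplitude A(phi, psi) for one rate kind.

    ``values[i, j]`` is the amplitude at phi = centers[i], psi = centers[j];
    the surface is 360-degree periodic.
    """

    rate_id: str
    resolution: float
    values: np.ndarray  # (n, n), s-2

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = int(round(360.0 / self.resolution))
        if self.values.shape != (n, n):
            raise ValueError("surface shape does not match its resolution")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("surface contains non-finite values")

    @property
    def centers(self) -> np.ndarray:
        return grid_centers(self.resolution)

    def at(self, phi: float, psi: float) -> float:
        """Nearest-bin lookup (wrapping into [-180, 180))."""
        res = self.resolution
        i = int(np.floor(((phi + 180.0) % 360.0) / res))
        j = int(np.floor(((psi + 180.0) % 360.0) / res))
        return float(self.values[i, j])


def build_rate_surfaces(kinds: Sequence[RateKind] | None = None,
                        resolution: float = 1.0,
                        geometry: BackboneGeometry | None = None,
                        constants: PhysicalConstants | None = None,
                        csa_map: Mapping[str, CsaTensor] | None = None
                        ) -> dict[str, RateSurface]:
    """Tabulate amplitude surfaces for several kinds on one shared fragment grid."""
    if kinds is None:
        kinds = list(RATE_REGISTRY.values())
    g = geometry or BackboneGeometry()
    c = constants or PhysicalConstants()
    csa_map = csa_map if csa_map is not None else default_csa_map()
    centers = grid_centers(resolution)
    pp, ss = np.meshgrid(centers, centers, indexing="ij")
    coords = build_fragment(pp.ravel(), ss.ravel(), g)
    out = {}
    for kind in kinds:
        vals = structural_amplitude(kind, None, None, g, c, csa_map,
                                    coords=coords)
        vals = np.broadcast_to(vals, pp.size).reshape(pp.shape)
        out[kind.rate_id] = RateSurface(kind.rate_id, resolution,
                                        np.array(vals, dtype=float))
    return out


def build_rate_surface(kind: RateKind, resolution: float = 1.0,
                       geometry: BackboneGeometry | None = None,
                       constants: PhysicalConstants | None = None,
                       csa_map: Mapping[str, CsaTensor] | None = None
                       ) -> RateSurface:
    return build_rate_surfaces([kind], resolution, geometry, constants,
                               csa_map)[kind.rate_id]


def well_conditioned_conformer(surfaces: Mapping[str, RateSurface]
                               ) -> tuple[float, float]:
    """(phi, psi) maximizing the smallest normalized amplitude magnitude.

    Relative accuracy of a rate estimated from a finite trajectory diverges
    where its amplitude crosses a magic-angle zero; rigid-conformer
    benchmarks therefore use the grid point whose weakest rate (relative
    to that rate's own maximum magnitude) is strongest.  Deterministic
    given the surfaces.
    """
    stack = np.stack([np.abs(s.values) / np.abs(s.values).max()
                      for s in surfaces.values()])
    worst = stack.min(axis=0)
    i, j = np.unravel_index(int(np.argmax(worst)), worst.shape)
    centers = next(iter(surfaces.values())).centers
    return float(centers[i]), float(centers[j])


def save_surfaces(path, surfaces: Mapping[str, RateSurface],
                  constants: PhysicalConstants | None = None) -> None:
    """Write surfaces to an HDF5 container (one group per rate id)."""
    import h5py

    c = constants or PhysicalConstants()
    with h5py.File(path, "w") as h5:
        for rid, s in surfaces.items():
            grp = h5.create_group(rid)
            d = grp.create_dataset("values", data=s.values)
            d.attrs["rate_id"] = rid
            d.attrs["resolution_deg"] = s.resolution
            d.attrs["B0_T"] = c.B0


def load_surfaces(path) -> dict[str, RateSurface]:
    import h5py

    out = {}
    with h5py.File(path, "r") as h5:
        for rid in h5:
            d = h5[rid]["values"]
            out[rid] = RateSurface(rid, float(d.attrs["resolution_deg"]),
                                   d[...])
    return out
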