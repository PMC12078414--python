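"""Assembly of per-residue CCR rates, dynamical proxies and amplitude recovery.

A measured remote rate is the product of a structural amplitude and an
effective correlation time.  The two known-amplitude rates of the
encompassing peptide planes (N-CSA/NH and C'-CSA/C'CA, whose interaction
geometry is rigid) give direct access to local correlation times; dividing
each remote rate by such a dynamical proxy approximates its structural
component, which is what the Ramachandran inversion consumes.

Proxy choices: "nnh" (amide plane), "ccca" (carbonyl plane, the better
approximation for typical backbone dynamics), or "opt", a fixed
0.7 * tau_CCCA + 0.3 * tau_NNH blend applied to remote rates that involve
the amide proton (others keep tau_CCCA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import tcfcore
from .physmodel import (Atom, BackboneGeometry, CsaTensor, Dipole,
                        PhysicalConstants, RATE_REGISTRY, REMOTE_RATE_IDS,
                        RateKind, csa_frame, default_csa_map, prefactor,
                        structural_amplitude)
from .tcfcore import (Tcf, TcfEngine, VectorTrajectory, correlation_time,
                      integrate_tcf)

__all__ = [
    "ResidueRateSet",
    "KnownAmplitudes",
    "OPT_PROXY_WEIGHTS",
    "CONVERGENCE_TAIL_FRACTION",
    "interaction_vectors",
    "compute_rate",
    "compute_residue_rates",
    "assemble_rate_sets",
    "proxy_tau_nnh",
    "proxy_tau_ccca",
    "proxy_tau_opt",
    "proxy_tau",
    "normalize_rates",
    "proxy_diagnostic",
    "rate_sets_to_table",
    "save_rate_table",
    "load_rate_table",
]

log = logging.getLogger(__name__)

# blend weights for the optimal proxy (carbonyl-plane, amide-plane)
OPT_PROXY_WEIGHTS = (0.7, 0.3)

# a TCF is flagged non-converged when its tail retains more than this
# fraction of the initial correlation
CONVERGENCE_TAIL_FRACTION = 0.01


@dataclass
class ResidueRateSet:
    """The ten rates of one residue plus proxy and (optional) truth columns."""

    residue: int
    rates: dict[str, float]
    tau_nnh: float | None = None
    tau_ccca: float | None = None
    tau_opt: float | None = None
    true_tau: dict[str, float] | None = None   # simulation-only diagnostics
    true_amp: dict[str, float] | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self):
        for tau in (self.tau_nnh, self.tau_ccca, self.tau_opt):
            if tau is not None and tau <= 0:
                raise ValueError("proxy correlation times must be positive")

    def proxy(self, choice: str, rate_id: str | None = None) -> float:
        return proxy_tau(self, choice, rate_id)


@dataclass(frozen=True)
class KnownAmplitudes:
    """Conformation-independent amplitudes of the two proxy rates (s-2)."""

    a_nnh: float
    a_ccca: float

    @classmethod
    def from_model(cls, constants: PhysicalConstants | None = None,
                   geometry: BackboneGeometry | None = None,
                   csa_map: Mapping[str, CsaTensor] | None = None
                   ) -> "KnownAmplitudes":
        a_nnh = float(structural_amplitude(
            RATE_REGISTRY["N_NHN"], 0.0, 0.0, geometry, constants, csa_map))
        a_ccca = float(structural_amplitude(
            RATE_REGISTRY["C_CCA"], 0.0, 0.0, geometry, constants, csa_map))
        return cls(a_nnh, a_ccca)


# ---------------------------------------------------------------------------
# Vector extraction from a coordinate trajectory
# ---------------------------------------------------------------------------

def _positions(chain: Mapping, residue: int, atom: Atom) -> np.ndarray:
    key = (residue + atom[1], atom[0])
    try:
        return chain[key]
    except KeyError:
        raise KeyError(
            f"trajectory lacks atom {atom[0]!r} of residue {key[0]}") from None


def interaction_vectors(chain: Mapping, residue: int, interaction,
                        dt: float,
                        csa_map: Mapping[str, CsaTensor] | None = None
                        ) -> dict[str, VectorTrajectory]:
    """Unit-vector series of one interaction at one residue.

    Dipoles return {"d": trajectory-with-distances}; CSA sites return the
    in-plane principal axes {"x": ..., "y": ...} built frame by frame.
    """
    csa_map = csa_map if csa_map is not None else default_csa_map()
    if isinstance(interaction, Dipole):
        pa = _positions(chain, residue, interaction.a)
        pb = _positions(chain, residue, interaction.b)
        d = pb - pa
        r = np.linalg.norm(d, axis=-1)
        return {"d": VectorTrajectory(d / r[:, None], dt, distances=r)}
    # CSA: rebuild the frame rule on absolute residue indices
    name, off = interaction.nucleus
    if name == "C":
        atoms = (("C", off), ("N", off + 1), ("O", off))
    else:
        atoms = (("N", off), ("H", off), ("C", off - 1))
    coords = {a: _positions(chain, residue, a) for a in atoms}
    xx, yy, _ = csa_frame(coords, interaction.nucleus, csa_map[name])
    return {"x": VectorTrajectory(xx, dt),
            "y": VectorTrajectory(yy, dt)}


# ---------------------------------------------------------------------------
# Rate computation
# ---------------------------------------------------------------------------

def _component_pairs(kind: RateKind, va: dict, vb: dict):
    """(key, trajectory_a, trajectory_b) per correlated component, ordered
    to match the prefactor components of the kind."""
    ia, ib = kind.interactions
    if kind.mechanism_class == "dd_dd":
        return [(("d", "d"), va["d"], vb["d"])]
    if kind.mechanism_class == "dd_csa":
        if isinstance(ia, Dipole):
            return [(("d", k), va["d"], vb[k]) for k in ("x", "y")]
        return [((k, "d"), va[k], vb["d"]) for k in ("x", "y")]
    return [((k, l), va[k], vb[l]) for k in ("x", "y") for l in ("x", "y")]


def compute_rate(chain: Mapping, residue: int, kind: RateKind,
                 dt: float, upper_bound: float,
                 constants: PhysicalConstants | None = None,
                 geometry: BackboneGeometry | None = None,
                 csa_map: Mapping[str, CsaTensor] | None = None,
                 engine: TcfEngine | None = None,
                 vectors: Mapping | None = None
                 ) -> tuple[float, float, float, bool]:
    """One CCR rate from a coordinate trajectory.

    Returns (Gamma in s-1, effective correlation time tau in s, structural
    component A = Gamma / tau in s-2, converged flag).  Instantaneous
    inter-nuclear distances enter the TCF denominator only for the
    Halpha_i-HN_{i+1} dipole; all other dipoles use trajectory-mean
    distances in the prefactor.
    """
    c = constants or PhysicalConstants()
    g = geometry or BackboneGeometry()
    csa_map = csa_map if csa_map is not None else default_csa_map()
    ia, ib = kind.interactions
    if vectors is None:
        vectors = {}
    va = vectors.get(ia) or interaction_vectors(chain, residue, ia, dt,
                                                csa_map)
    vb = vectors.get(ib) or interaction_vectors(chain, residue, ib, dt,
                                                csa_map)
    n = len(next(iter(va.values())))
    if engine is None:
        engine = TcfEngine(n, dt, upper_bound)

    # distances: trajectory means for fixed-mean dipoles, unity (handled in
    # the correlation function, in Angstrom) for instantaneous ones
    distances: dict[int, float] = {}
    weighted: dict[int, bool] = {}
    for idx, (inter, v) in enumerate(((ia, va), (ib, vb))):
        if isinstance(inter, Dipole):
            if inter.distance_mode == "instantaneous":
                distances[idx] = 1.0
                weighted[idx] = True
            else:
                distances[idx] = v["d"].mean_distance
                weighted[idx] = False
    pref = prefactor(kind, c, g, csa_map, distances=distances or None)

    pairs = _component_pairs(kind, va, vb)
    wa = weighted.get(0, False)
    wb = weighted.get(1, False)
    tcfs = []
    for _, ta, tb in pairs:
        tcfs.append(engine.cross(ta, tb, weight_a=wa, weight_b=wb))
    gamma = 0.0
    weighted_values = None
    for p, t in zip(pref, tcfs):
        gamma += p * integrate_tcf(t, upper_bound)
        contrib = p * t.values
        weighted_values = contrib if weighted_values is None \
            else weighted_values + contrib
    total = Tcf(weighted_values, dt)
    if total.amplitude == 0.0:
        return 0.0, float("nan"), 0.0, True
    tau = correlation_time(total, upper_bound)
    amp = gamma / tau
    k = int(round(upper_bound / dt))
    tail = abs(total.values[k]) / abs(total.amplitude)
    converged = tail < CONVERGENCE_TAIL_FRACTION
    if not converged:
        log.warning("TCF tail of %s at residue %d retains %.2f%% of C(0)",
                    kind.rate_id, residue, 100 * tail)
    return gamma, tau, amp, converged


def compute_residue_rates(chain: Mapping, residue: int, dt: float,
                          upper_bound: float = tcfcore.UPPER_BOUND_DISORDERED_S,
                          constants: PhysicalConstants | None = None,
                          geometry: BackboneGeometry | None = None,
                          csa_map: Mapping[str, CsaTensor] | None = None,
                          engine: TcfEngine | None = None,
                          keep_truth: bool = True) -> ResidueRateSet:
    """All ten registered rates of one residue (no proxies yet)."""
    rates, taus, amps, flags = {}, {}, {}, []
    n = len(next(iter(chain.values())))
    if engine is None:
        engine = TcfEngine(n, dt, upper_bound)
    # extract each distinct physical interaction once; several rates share
    # bond vectors and CSA frames
    vectors = {}
    for kind in RATE_REGISTRY.values():
        for inter in kind.interactions:
            if inter not in vectors:
                vectors[inter] = interaction_vectors(chain, residue, inter,
                                                     dt, csa_map)
    for rid, kind in RATE_REGISTRY.items():
        gamma, tau, amp, conv = compute_rate(
            chain, residue, kind, dt, upper_bound, constants, geometry,
            csa_map, engine, vectors)
        rates[rid] = gamma
        taus[rid] = tau
        amps[rid] = amp
        if not conv:
            flags.append(f"nonconverged:{rid}")
    return ResidueRateSet(residue, rates,
                          true_tau=taus if keep_truth else None,
                          true_amp=amps if keep_truth else None,
                          flags=flags)


# ---------------------------------------------------------------------------
# Dynamical proxies
# ---------------------------------------------------------------------------

def proxy_tau_nnh(gamma_i: float | None, gamma_ip1: float | None,
                  a_nnh: float) -> tuple[float, bool]:
    """Average amide-plane correlation time of the two encompassing planes.

    Returns (tau, flagged); flagged is True when only one plane was
    available (terminal residues).
    """
    vals = [g for g in (gamma_i, gamma_ip1) if g is not None]
    if not vals:
        raise ValueError("no amide-plane rate available for the proxy")
    return sum(vals) / (len(vals) * a_nnh), len(vals) < 2


def proxy_tau_ccca(gamma_im1: float | None, gamma_i: float | None,
                   a_ccca: float) -> tuple[float, bool]:
    """Average carbonyl-plane correlation time of the two encompassing planes."""
    vals = [g for g in (gamma_im1, gamma_i) if g is not None]
    if not vals:
        raise ValueError("no carbonyl-plane rate available for the proxy")
    return sum(vals) / (len(vals) * a_ccca), len(vals) < 2


def proxy_tau_opt(tau_ccca: float, tau_nnh: float,
                  weights: tuple[float, float] = OPT_PROXY_WEIGHTS) -> float:
    """Fixed-weight blend of the two proxies (default 0.7/0.3)."""
    return weights[0] * tau_ccca + weights[1] * tau_nnh


def attach_proxies(rate_sets: Mapping[int, ResidueRateSet],
                   known: KnownAmplitudes) -> None:
    """Fill tau_nnh / tau_ccca / tau_opt of every set in place.

    Neighbouring residues supply the second peptide plane; boundary
    residues fall back to the single available plane and are flagged.
    """
    def rate_of(res: int, rid: str) -> float | None:
        rs = rate_sets.get(res)
        return None if rs is None else rs.rates.get(rid)

    for res, rs in rate_sets.items():
        g_n_i = rate_of(res, "N_NHN")
        g_n_ip1 = rate_of(res + 1, "N_NHN")
        g_c_im1 = rate_of(res - 1, "C_CCA")
        g_c_i = rate_of(res, "C_CCA")
        rs.tau_nnh, flag_n = proxy_tau_nnh(g_n_i, g_n_ip1, known.a_nnh)
        rs.tau_ccca, flag_c = proxy_tau_ccca(g_c_im1, g_c_i, known.a_ccca)
        rs.tau_opt = proxy_tau_opt(rs.tau_ccca, rs.tau_nnh)
        if flag_n or flag_c:
            rs.flags.append("single-plane-proxy")


def assemble_rate_sets(chain: Mapping, residues: Sequence[int], dt: float,
                       upper_bound: float = tcfcore.UPPER_BOUND_DISORDERED_S,
                       constants: PhysicalConstants | None = None,
                       geometry: BackboneGeometry | None = None,
                       csa_map: Mapping[str, CsaTensor] | None = None,
                       keep_truth: bool = True
                       ) -> dict[int, ResidueRateSet]:
    """Rates plus proxies for a set of residues of one trajectory."""
    n = len(next(iter(chain.values())))
    out = {}
    for res in residues:
        # fresh engine per residue keeps the spectra cache bounded
        engine = TcfEngine(n, dt, upper_bound)
        out[res] = compute_residue_rates(chain, res, dt, upper_bound,
                                         constants, geometry, csa_map,
                                         engine, keep_truth)
        engine.clear_cache()
    known = KnownAmplitudes.from_model(constants, geometry, csa_map)
    attach_proxies(out, known)
    return out


def proxy_tau(rate_set: ResidueRateSet, choice: str,
              rate_id: str | None = None) -> float:
    """The proxy correlation time for one remote rate of one residue.

    With the blended "opt" choice, only remote kinds involving the amide
    proton receive the blend; the rest keep the carbonyl-plane proxy.
    """
    if choice == "nnh":
        tau = rate_set.tau_nnh
    elif choice == "ccca":
        tau = rate_set.tau_ccca
    elif choice == "opt":
        if rate_id is not None and not RATE_REGISTRY[rate_id].involves_hn():
            tau = rate_set.tau_ccca
        else:
            tau = rate_set.tau_opt
    elif choice == "true":
        if rate_set.true_tau is None or rate_id is None:
            raise ValueError("true per-rate taus only exist in simulation mode")
        tau = rate_set.true_tau[rate_id]
    else:
        raise ValueError(f"unknown proxy choice {choice!r}")
    if tau is None:
        raise ValueError(f"proxy {choice!r} not computed for residue "
                         f"{rate_set.residue}")
    return tau


def normalize_rates(rate_set: ResidueRateSet, proxy_choice: str = "ccca"
                    ) -> dict[str, float]:
    """Approximate structural components Gamma / tau_proxy per remote rate."""
    out = {}
    for rid in REMOTE_RATE_IDS:
        tau = proxy_tau(rate_set, proxy_choice, rid)
        if tau <= 0:
            raise ValueError(f"nonpositive proxy correlation time for "
                             f"residue {rate_set.residue}")
        out[rid] = rate_set.rates[rid] / tau
    return out


def proxy_diagnostic(rate_sets: Sequence[ResidueRateSet],
                     proxy_choice: str = "ccca") -> tuple[float, float]:
    """(R^2, slope-through-origin) of approximated vs. true amplitudes.

    Pools the remote rates of all residues; requires simulation-truth
    amplitudes.  The slope is the least-squares fit constrained through
    (0, 0); R^2 is the squared Pearson correlation of the cloud.
    """
    xs, ys = [], []
    for rs in rate_sets:
        if rs.true_amp is None:
            raise ValueError("proxy diagnostic requires simulation truth")
        approx = normalize_rates(rs, proxy_choice)
        for rid in REMOTE_RATE_IDS:
            xs.append(rs.true_amp[rid])
            ys.append(approx[rid])
    x = np.asarray(xs)
    y = np.asarray(ys)
    if len(x) < 2:
        raise ValueError("need at least two points for the diagnostic")
    slope = float(np.sum(x * y) / np.sum(x * x))
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r), slope


# ---------------------------------------------------------------------------
# Rate table round-trip
# ---------------------------------------------------------------------------

def rate_sets_to_table(rate_sets: Mapping[int, ResidueRateSet],
                       proxy_choice: str = "ccca"):
    """Long-format table: residue, rate_id, gamma_per_s, sigma, tau_proxy_ns."""
    import pandas as pd

    rows = []
    for res in sorted(rate_sets):
        rs = rate_sets[res]
        for rid, gamma in rs.rates.items():
            tau = None
            if rid in REMOTE_RATE_IDS:
                try:
                    tau = proxy_tau(rs, proxy_choice, rid) * 1e9
                except ValueError:
                    tau = None
            rows.append({"residue": res, "rate_id": rid,
                         "gamma_per_s": gamma, "sigma": 1.0,
                         "tau_proxy_ns": tau})
    return pd.DataFrame(rows)


def save_rate_table(path, rate_sets: Mapping[int, ResidueRateSet],
                    proxy_choice: str = "ccca") -> None:
    rate_sets_to_table(rate_sets, proxy_choice).to_csv(path, index=False)


def load_rate_table(path) -> dict[int, dict]:
    """Read a rate table back into {residue: {rates, tau_proxy_s, sigma}}."""
    import pandas as pd

    df = pd.read_csv(path)
    out: dict[int, dict] = {}
    for res, sub in df.groupby("residue"):
        rates = dict(zip(sub["rate_id"], sub["gamma_per_s"]))
        sigma = dict(zip(sub["rate_id"], sub["sigma"]))
        taus = {rid: t * 1e-9 for rid, t in
                zip(sub["rate_id"], sub["tau_proxy_ns"]) if np.isfinite(t)}
        out[int(res)] = {"rates": rates, "sigma": sigma, "tau_proxy_s": taus}
    return out
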