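"""Command-line interface, configuration and pipeline plumbing.

Subcommands mirror the stages of the method: ``simulate`` (synthetic
ensemble with ground truth), ``surfaces`` (structural-amplitude tables),
``rates`` (per-residue CCR rates and dynamical proxies from a trajectory),
``infer`` (MaxEnt Ramachandran inversion) and ``compare`` (Jensen-Shannon
tables against a reference).  Units at user-facing boundaries: degrees for
angles, ns for times, s-1 for rates; everything internal is SI.

Every run writes a provenance sidecar (config hash, package version,
seed) next to its output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import click
import numpy as np

from . import __version__
from . import gridmetrics, maxent, physmodel, rateasm, synthgen
from .gridmetrics import RamachandranGrid, coarsen, js_divergence
from .maxent import InversionProblem, MaxEntResult, maxent_map, l_curve
from .physmodel import (BackboneGeometry, CsaTensor, PhysicalConstants,
                        REMOTE_RATE_IDS, build_rate_surfaces,
                        default_csa_map)
from .rateasm import ResidueRateSet, assemble_rate_sets, proxy_tau

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "invert_rate_sets", "invert_rate_table",
           "compare_grid_sets", "load_md_trajectory", "main"]


@dataclass
class RunConfig:
    """Run parameters with the method's defaults."""

    b0_mhz: float = 800.0
    tmax_ns: float = 10.0
    proxy: str = "ccca"  # nnh | ccca | opt
    temperature: float = maxent.DEFAULT_TEMPERATURE
    lcurve: tuple[float, float, int] | None = None
    resolution: float = 1.0
    report_resolution: float = 10.0
    seed: int = 0
    geometry: BackboneGeometry = field(default_factory=BackboneGeometry)
    csa: dict[str, CsaTensor] = field(default_factory=default_csa_map)

    @property
    def constants(self) -> PhysicalConstants:
        return PhysicalConstants.at_proton_mhz(self.b0_mhz)

    @property
    def upper_bound_s(self) -> float:
        return self.tmax_ns * 1e-9

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Read a TOML config; sections [run], [geometry], [csa.C], [csa.N]."""
        with open(path, "rb") as fh:
            raw = tomllib.load(fh)
        kw = dict(raw.get("run", {}))
        if "lcurve" in kw:
            kw["lcurve"] = tuple(kw["lcurve"])
        geom = BackboneGeometry(**raw.get("geometry", {}))
        csa = default_csa_map()
        for nuc, vals in raw.get("csa", {}).items():
            csa[nuc] = CsaTensor(**vals)
        return cls(geometry=geom, csa=csa, **kw)

    def provenance(self, command: str) -> dict:
        blob = json.dumps(
            {"command": command,
             "config": dataclasses.asdict(self)},
            default=str, sort_keys=True)
        return {"command": command,
                "config_hash": hashlib.sha256(blob.encode()).hexdigest(),
                "version": __version__,
                "seed": self.seed}


def _write_provenance(out_path, config: RunConfig, command: str) -> None:
    side = Path(str(out_path) + ".provenance.json")
    side.write_text(json.dumps(config.provenance(command), indent=1))


# ---------------------------------------------------------------------------
# Pipeline helpers (the library surface behind the CLI)
# ---------------------------------------------------------------------------

def invert_rate_sets(rate_sets: dict[int, ResidueRateSet],
                     surfaces, prior: RamachandranGrid,
                     config: RunConfig | None = None
                     ) -> tuple[dict[int, MaxEntResult], dict]:
    """MaxEnt inversion per residue; failures are isolated per residue."""
    cfg = config or RunConfig()
    remote = {rid: surfaces[rid] for rid in REMOTE_RATE_IDS}
    results: dict[int, MaxEntResult] = {}
    failures: dict[int, str] = {}
    for res in sorted(rate_sets):
        rs = rate_sets[res]
        try:
            rates = {rid: rs.rates[rid] for rid in REMOTE_RATE_IDS}
            taus = {rid: proxy_tau(rs, cfg.proxy, rid)
                    for rid in REMOTE_RATE_IDS}
            problem = InversionProblem(rates, remote, taus, prior,
                                       temperature=cfg.temperature)
            if cfg.lcurve is not None:
                tmin, tmax, ntemp = cfg.lcurve
                temps = np.geomspace(tmin, tmax, int(ntemp))
                points, t_sel = l_curve(problem, temps)
                problem = dataclasses.replace(problem, temperature=t_sel)
            results[res] = maxent_map(problem)
        except Exception as exc:  # one residue must not abort the batch
            log.error("inversion failed for residue %d: %s", res, exc)
            failures[res] = str(exc)
    return results, failures


def invert_rate_table(table: dict[int, dict], surfaces,
                      prior: RamachandranGrid,
                      config: RunConfig | None = None):
    """Inversion from a loaded rate table (rates plus proxy taus)."""
    cfg = config or RunConfig()
    remote = {rid: surfaces[rid] for rid in REMOTE_RATE_IDS}
    results, failures = {}, {}
    for res in sorted(table):
        entry = table[res]
        try:
            rates = {rid: entry["rates"][rid] for rid in REMOTE_RATE_IDS}
            taus = {rid: entry["tau_proxy_s"][rid]
                    for rid in REMOTE_RATE_IDS}
            sigmas = {rid: entry["sigma"][rid] for rid in REMOTE_RATE_IDS}
            results[res] = maxent_map(InversionProblem(
                rates, remote, taus, prior, sigmas=sigmas,
                temperature=cfg.temperature))
        except Exception as exc:
            log.error("inversion failed for residue %d: %s", res, exc)
            failures[res] = str(exc)
    return results, failures


def compare_grid_sets(pred: dict[int, RamachandranGrid],
                      ref: dict[int, RamachandranGrid],
                      resolution: float = 10.0) -> dict[int, float]:
    """Per-residue Jensen-Shannon divergence at the reporting resolution."""
    common = sorted(set(pred) & set(ref))
    if not common:
        raise ValueError("no residues in common between prediction and "
                         "reference")
    out = {}
    for res in common:
        p = pred[res] if pred[res].resolution == resolution \
            else coarsen(pred[res], resolution)
        r = ref[res] if ref[res].resolution == resolution \
            else coarsen(ref[res], resolution)
        out[res] = js_divergence(p, r)
    return out


def load_md_trajectory(topology, trajectory=None, dt: float | None = None):
    """Adapter: read backbone positions from standard MD formats.

    Uses MDAnalysis; returns (ChainPositions keyed by (residue index from
    0, atom name), dt in seconds).  Atom naming follows the PDB backbone
    convention (N, H/HN, CA, HA, C, O).
    """
    import MDAnalysis as mda

    u = mda.Universe(topology) if trajectory is None \
        else mda.Universe(topology, trajectory)
    prot = u.select_atoms("protein")
    if len(prot) == 0:
        raise ValueError("empty protein selection in trajectory")
    names = {"N": "N", "H": ("H", "HN"), "CA": "CA", "HA": "HA",
             "C": "C", "O": "O"}
    index_of = {}
    for i, res in enumerate(prot.residues):
        for ours, theirs in names.items():
            cands = (theirs,) if isinstance(theirs, str) else theirs
            for cand in cands:
                sel = res.atoms.select_atoms(f"name {cand}")
                if len(sel) == 1:
                    index_of[(i, ours)] = sel[0].ix
                    break
    n_frames = len(u.trajectory)
    pos = {key: np.empty((n_frames, 3)) for key in index_of}
    for t, _ in enumerate(u.trajectory):
        frame = u.atoms.positions
        for key, ix in index_of.items():
            pos[key][t] = frame[ix]
    if dt is None:
        dt = u.trajectory.dt * 1e-12  # MDAnalysis reports ps
    return pos, dt


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _config_from_options(geometry, b0_mhz, tmax_ns, proxy, temperature,
                         lcurve, resolution, seed) -> RunConfig:
    cfg = RunConfig.from_file(geometry) if geometry else RunConfig()
    cfg.b0_mhz = b0_mhz
    cfg.tmax_ns = tmax_ns
    cfg.proxy = proxy
    cfg.temperature = temperature
    if lcurve:
        cfg.lcurve = (lcurve[0], lcurve[1], int(lcurve[2]))
    cfg.resolution = resolution
    cfg.seed = seed
    return cfg


_shared = [
    click.option("--geometry", type=click.Path(exists=True), default=None,
                 help="TOML config with geometry/CSA/run overrides."),
    click.option("--b0-mhz", default=800.0, show_default=True,
                 help="Proton operational frequency."),
    click.option("--tmax-ns", default=10.0, show_default=True,
                 help="TCF integration upper bound."),
    click.option("--proxy", default="ccca", show_default=True,
                 type=click.Choice(["nnh", "ccca", "opt"])),
    click.option("--temperature", default=1.0, show_default=True),
    click.option("--lcurve", nargs=3, type=float, default=None,
                 help="TMIN TMAX N: select T on an L-curve."),
    click.option("--resolution", default=1.0, show_default=True,
                 help="Surface/grid resolution (deg)."),
    click.option("--seed", default=0, show_default=True, type=int),
]


def _with_shared(f):
    for opt in reversed(_shared):
        f = opt(f)
    return f


@click.group()
@click.version_option(__version__)
def main():
    """Ramachandran distributions from cross-correlated relaxation rates."""
    logging.basicConfig(level=logging.INFO, stream=sys.stderr,
                        format="%(levelname)s %(name)s: %(message)s")


@main.command()
@_with_shared
@click.option("--out", required=True, type=click.Path())
def surfaces(geometry, b0_mhz, tmax_ns, proxy, temperature, lcurve,
             resolution, seed, out):
    """Tabulate structural-amplitude surfaces for all registered rates."""
    cfg = _config_from_options(geometry, b0_mhz, tmax_ns, proxy,
                               temperature, lcurve, resolution, seed)
    surf = build_rate_surfaces(resolution=cfg.resolution,
                               geometry=cfg.geometry,
                               constants=cfg.constants, csa_map=cfg.csa)
    physmodel.save_surfaces(out, surf, cfg.constants)
    _write_provenance(out, cfg, "surfaces")
    click.echo(f"wrote {len(surf)} surfaces at {cfg.resolution} deg to {out}")


@main.command()
@_with_shared
@click.option("--traj", required=True, type=click.Path(exists=True),
              help="Internal HDF5 chain container (or topology file).")
@click.option("--md-traj", type=click.Path(exists=True), default=None,
              help="MD trajectory file read through MDAnalysis.")
@click.option("--residues", default=None,
              help="Residue range like 1-8 (default: all with full planes).")
@click.option("--out", required=True, type=click.Path())
def rates(geometry, b0_mhz, tmax_ns, proxy, temperature, lcurve, resolution,
          seed, traj, md_traj, residues, out):
    """Per-residue CCR rates and dynamical proxies from a trajectory."""
    cfg = _config_from_options(geometry, b0_mhz, tmax_ns, proxy,
                               temperature, lcurve, resolution, seed)
    if md_traj is not None or not str(traj).endswith(".h5"):
        chain, dt = load_md_trajectory(traj, md_traj)
    else:
        chain, dt, _ = synthgen.load_chain(traj)
    res_avail = sorted({r for (r, a) in chain if a == "CA"})
    if residues:
        lo, hi = (int(x) for x in residues.split("-"))
        scored = list(range(lo, hi + 1))
    else:
        scored = res_avail[:-1] if res_avail else []
    if not scored:
        raise click.ClickException("empty residue selection")
    n_frames = len(next(iter(chain.values())))
    ub = cfg.upper_bound_s
    if ub > (n_frames - 1) * dt:
        ub = (n_frames - 1) * dt
        log.warning("integration bound clamped to the trajectory span "
                    "(%.3g ns)", ub * 1e9)
    sets = assemble_rate_sets(chain, scored, dt, ub,
                              cfg.constants, cfg.geometry, cfg.csa)
    rateasm.save_rate_table(out, sets, cfg.proxy)
    _write_provenance(out, cfg, "rates")
    click.echo(f"wrote rates for {len(sets)} residues to {out}")


@main.command()
@_with_shared
@click.option("--rates", "rates_path", required=True,
              type=click.Path(exists=True))
@click.option("--prior", type=click.Path(exists=True), default=None,
              help="Prior grid file (default: built-in synthetic coil prior).")
@click.option("--surfaces", "surfaces_path", type=click.Path(exists=True),
              default=None, help="Surface file (default: build at runtime).")
@click.option("--out", required=True, type=click.Path())
@click.option("--diagnostics", type=click.Path(), default=None)
def infer(geometry, b0_mhz, tmax_ns, proxy, temperature, lcurve, resolution,
          seed, rates_path, prior, surfaces_path, out, diagnostics):
    """Invert a rate table into per-residue Ramachandran distributions."""
    cfg = _config_from_options(geometry, b0_mhz, tmax_ns, proxy,
                               temperature, lcurve, resolution, seed)
    table = rateasm.load_rate_table(rates_path)
    q = gridmetrics.load_grid(prior) if prior \
        else synthgen.standin_coil_prior(cfg.resolution)
    surf = physmodel.load_surfaces(surfaces_path) if surfaces_path \
        else build_rate_surfaces(resolution=cfg.resolution,
                                 geometry=cfg.geometry,
                                 constants=cfg.constants, csa_map=cfg.csa)
    results, failures = invert_rate_table(table, surf, q, cfg)
    gridmetrics.save_grids(out, {r: v.grid for r, v in results.items()})
    if diagnostics:
        with open(diagnostics, "w") as fh:
            fh.write("residue\tchi2\tdkl\tconverged\n")
            for r, v in sorted(results.items()):
                fh.write(f"{r}\t{v.chi2:.6e}\t{v.dkl:.6e}\t{v.converged}\n")
    _write_provenance(out, cfg, "infer")
    click.echo(f"inverted {len(results)} residues "
               f"({len(failures)} failures) to {out}")


@main.command()
@click.option("--pred", required=True, type=click.Path(exists=True))
@click.option("--ref", required=True, type=click.Path(exists=True))
@click.option("--resolution", default=10.0, show_default=True)
@click.option("--out", required=True, type=click.Path())
def compare(pred, ref, resolution, out):
    """Jensen-Shannon divergence table between two grid sets."""
    p = gridmetrics.load_grids(pred)
    r = gridmetrics.load_grids(ref)
    js = compare_grid_sets(p, r, resolution)
    with open(out, "w") as fh:
        fh.write("residue\tjs\n")
        for res, v in sorted(js.items()):
            fh.write(f"{res}\t{v:.6f}\n")
        fh.write(f"mean\t{float(np.mean(list(js.values()))):.6f}\n")
    click.echo(f"mean JS over {len(js)} residues: "
               f"{float(np.mean(list(js.values()))):.4f}")


@main.command()
@click.option("--spec", "spec_path", type=click.Path(exists=True),
              default=None, help="TOML ensemble spec.")
@click.option("--n-residues", default=10, show_default=True)
@click.option("--n-frames", default=1_000_000, show_default=True)
@click.option("--tau-rot-ns", default=3.0, show_default=True)
@click.option("--exchange-ns", default=5.0, show_default=True)
@click.option("--seed", default=0, show_default=True, type=int)
@click.option("--out", required=True, type=click.Path())
@click.option("--truth", type=click.Path(), default=None,
              help="Write the analytic per-residue truth grids here.")
def simulate(spec_path, n_residues, n_frames, tau_rot_ns, exchange_ns, seed,
             out, truth):
    """Generate a synthetic disordered-chain trajectory with ground truth."""
    if spec_path:
        with open(spec_path, "rb") as fh:
            raw = tomllib.load(fh)
        spec = synthgen.EnsembleSpec.disordered_chain(
            raw.get("n_residues", n_residues),
            seed=raw.get("seed", seed),
            n_frames=raw.get("n_frames", n_frames),
            tau_rot=raw.get("tau_rot_ns", tau_rot_ns) * 1e-9,
            exchange_time=raw.get("exchange_ns", exchange_ns) * 1e-9)
    else:
        spec = synthgen.EnsembleSpec.disordered_chain(
            n_residues, seed=seed, n_frames=n_frames,
            tau_rot=tau_rot_ns * 1e-9, exchange_time=exchange_ns * 1e-9)
    series, truths = [], {}
    for i in range(spec.n_residues):
        s, tg = synthgen.sample_dihedral_series(spec, i)
        series.append(s)
        truths[i] = tg
    pos = synthgen.chain_coordinates(series)
    pos = synthgen.apply_tumbling(pos, spec.tau_rot, seed=spec.seed + 1000,
                                  dt=spec.dt)
    synthgen.save_chain(out, pos, spec.dt, spec.seed)
    if truth:
        gridmetrics.save_grids(truth, truths)
    cfg = RunConfig(seed=spec.seed)
    _write_provenance(out, cfg, "simulate")
    click.echo(f"simulated {spec.n_residues} residues x {spec.n_frames} "
               f"frames to {out}")


if __name__ == "__main__":
    main()
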