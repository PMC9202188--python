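"""End-to-end workflow orchestration.

Runs the eight-stage chain for every cycloadduct and every competing
reactive site: site detection, retro transformation, 3D embedding,
constrained-scan job, pseudo-guess selection, guess-TS cleanup, TS
refinement with vibrational check, and IRC — followed, on request, by
the reaction-force and decomposition analyses.

Each (adduct, site) pair is an independent track named
``sys_<adduct>_<site>`` with its own working folder; a failure in one
track never aborts the others.  Progress persists in a JSON state file,
so re-running with the same workdir skips completed tracks.  Rejected
stationary points and unparseable outputs are copied into ERROR_FILES
with a manifest entry.

With the synthetic backend the whole chain runs without any QM
software; with the "gaussian" dialect the pipeline emits job files and
stops at each stage that would need a real backend run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import qm_io, rfa, rfd, retro_da
from .config import AnalysisConfig, Config
from .geometry import (
    EmbedParams,
    Geometry,
    build_pseudo_guess_constraints,
    embed_with_retry,
    set_distance,
    synchronicity_index,
    write_xyz,
)
from .rfa import IRCPath

logger = logging.getLogger(__name__)

__all__ = ["SyntheticBackend", "PipelineState", "run_pipeline", "run_analysis"]

STAGES = (
    "sites_found",
    "retro_done",
    "embedded",
    "pseudo_guess",
    "guess_ts",
    "refined_ts",
    "ts_validated",
    "irc_done",
    "rfa_done",
    "rfd_done",
)


class SyntheticBackend:
    """A deterministic stand-in backend producing self-consistent outputs.

    Every job file the pipeline writes is answered with a plausible
    Gaussian-style output: scans interpolate the constrained distances
    toward their targets with monotonically rising energies, TS
    optimizations land the forming bonds at prescribed distances,
    frequency sections carry a single imaginary mode unless a failure is
    injected, and IRC outputs are analytic paths with exactly
    self-consistent forces.

    Parameters
    ----------
    seed : int
        Controls nothing random at present but is recorded for parity
        with real backends.
    refine_distances : (float, float)
        Forming-bond lengths (Angstrom) of the refined TS; unequal
        values emulate an asynchronous reaction.
    freq_override : dict
        Map system label -> frequency list, to inject vibrational-check
        failures for specific tracks.
    """

    def __init__(
        self,
        seed: int = 42,
        refine_distances: tuple[float, float] = (2.20, 2.20),
        freq_override: dict | None = None,
        barrier_a: float = 0.01,
    ) -> None:
        self.seed = seed
        self.refine_distances = refine_distances
        self.freq_override = freq_override or {}
        self.barrier_a = barrier_a

    # -- individual job handlers ------------------------------------------

    def run_scan(self, spec: qm_io.JobSpec, out_path, n_points: int) -> Path:
        geom = spec.geometry
        constraints = spec.constraints.distance_constraints
        configs = []
        start = [geom.distance(c.atom_i, c.atom_j) for c in constraints]
        for k in range(n_points):
            frac = k / (n_points - 1)
            coords = geom.coords.copy()
            for c, d0 in zip(constraints, start):
                target = d0 + frac * (c.target_A - d0)
                coords = set_distance(coords, c.atom_i, c.atom_j, target)
            g = Geometry(list(geom.elements), coords, geom.charge, geom.multiplicity, "scan_point")
            # stretching toward the two-fragment configuration costs energy
            energy = -230.0 + 0.05 * frac
            configs.append((g, energy))
        return qm_io.write_gaussian_scan_log(configs, out_path)

    def run_ts_opt(self, spec: qm_io.JobSpec, out_path, site, distances, system: str) -> Path:
        geom = spec.geometry
        coords = geom.coords.copy()
        (d1, e1), (d4, e2) = site.forming_bonds
        coords = set_distance(coords, d1, e1, distances[0])
        coords = set_distance(coords, d4, e2, distances[1])
        g = Geometry(list(geom.elements), coords, geom.charge, geom.multiplicity, "refined_ts")
        n_modes = max(1, 3 * geom.n_atoms - 6)
        freqs = self.freq_override.get(
            system, [-520.0] + [100.0 + 25.0 * k for k in range(n_modes - 1)]
        )
        return qm_io.write_gaussian_opt_log(g, -230.04, out_path, frequencies=freqs)

    def run_irc(self, spec: qm_io.JobSpec, out_path, site) -> Path:
        """Analytic IRC: the forming bonds stretch with xi on the product->
        reactant axis; forces are solved for exact consistency."""
        ts = spec.geometry
        n = spec.irc_points_per_direction
        step = spec.irc_step_size
        xi = step * np.arange(-n, n + 1, dtype=float)
        P = len(xi)
        a = self.barrier_a
        energy = -230.04 - a * xi**2  # inverted parabola, TS on top
        (d1, e1), (d4, e2) = site.forming_bonds
        # motion: the dienophile-side atoms drift along the forming-bond axes
        moving = {}
        for i, j in ((d1, e1), (d4, e2)):
            u = ts.coords[j] - ts.coords[i]
            u = u / np.linalg.norm(u)
            moving[j] = 0.15 * u  # Angstrom per xi unit
        coords = np.repeat(ts.coords[None], P, axis=0)
        for j, vel in moving.items():
            coords[:, j, :] += xi[:, None] * vel[None]
        from .units import ANGSTROM_TO_BOHR

        tangents = np.zeros((P, ts.n_atoms, 3))
        for j, vel in moving.items():
            tangents[:, j, :] = vel * ANGSTROM_TO_BOHR
        tnorm2 = np.einsum("pax,pax->p", tangents, tangents)
        e_prime = -2.0 * a * xi
        g_factor = -e_prime / tnorm2
        forces = g_factor[:, None, None] * tangents
        geometries = [
            Geometry(list(ts.elements), coords[i], ts.charge, ts.multiplicity, "irc_point")
            for i in range(P)
        ]
        path = IRCPath(xi=xi, energy=energy, geometries=geometries, forces=forces)
        return qm_io.write_gaussian_irc_log(path, out_path)


@dataclasses.dataclass
class PipelineState:
    """Per-track stage markers persisted as JSON in the workdir."""

    tracks: dict = dataclasses.field(default_factory=dict)

    def mark(self, system: str, stage: str, **meta) -> None:
        rec = self.tracks.setdefault(system, {})
        rec["stage"] = stage
        rec.update(meta)

    def fail(self, system: str, reason: str) -> None:
        rec = self.tracks.setdefault(system, {})
        rec["stage"] = "failed"
        rec["reason"] = reason

    def stage(self, system: str) -> str | None:
        return self.tracks.get(system, {}).get("stage")

    def summary(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for rec in self.tracks.values():
            counts[rec["stage"]] = counts.get(rec["stage"], 0) + 1
        return counts

    def save(self, workdir: Path) -> None:
        (Path(workdir) / "state.json").write_text(json.dumps(self.tracks, indent=1))

    @classmethod
    def load(cls, workdir: Path) -> "PipelineState":
        f = Path(workdir) / "state.json"
        if f.exists():
            return cls(json.loads(f.read_text()))
        return cls()


def _run_track(config: Config, backend, adduct, site, idx, sidx, workdir, error_dir, state):
    system = f"sys_{idx}_{sidx}"
    sysdir = workdir / system
    sysdir.mkdir(parents=True, exist_ok=True)
    state.mark(
        system,
        "sites_found",
        smiles=adduct.smiles,
        diene_atoms=list(site.diene_atoms),
        dienophile_atoms=list(site.dienophile_atoms),
    )

    # retro transformation (round-trip validated)
    products = retro_da.retro_transform(adduct, site)
    if not retro_da.forward_check(products, adduct):
        raise RuntimeError("retro products fail the forward-reaction round trip")
    (sysdir / "retro.json").write_text(
        json.dumps(
            {
                "adduct": adduct.smiles,
                "diene": products.diene_smiles,
                "dienophile": products.dienophile_smiles,
                "combined": products.combined_smiles,
                "intramolecular": products.intramolecular,
            },
            indent=1,
        )
    )
    state.mark(system, "retro_done", retro=products.combined_smiles,
               intramolecular=products.intramolecular)

    # 3D embedding (heavy-atom indices are preserved by AddHs, so the
    # site indices remain valid in the embedded geometry)
    geom = embed_with_retry(adduct, EmbedParams(random_seed=config.seed))
    write_xyz(geom, sysdir / "embedded.xyz", comment=f"{system} UFF-relaxed")
    state.mark(system, "embedded")

    # constrained scan toward the two-fragment pseudo-guess
    constraints = build_pseudo_guess_constraints(site, config.separation_A)
    scan_spec = qm_io.JobSpec("constrained_scan", config.theory_guess, geom, constraints)
    scan_job = qm_io.write_job(scan_spec, sysdir / "scan.gjf")
    if config.backend == "gaussian":
        state.mark(system, "embedded", note="job files emitted; awaiting external backend")
        return
    scan_out = backend.run_scan(scan_spec, sysdir / "scan.log", config.scan_points)
    scan = qm_io.parse_scan_output(scan_out)
    pseudo = qm_io.select_pseudo_guess(scan)
    write_xyz(pseudo, sysdir / "pseudo_guess.xyz", comment=f"{system} pseudo-guess")
    state.mark(system, "pseudo_guess")

    # guess-TS cleanup at the semi-empirical level
    guess_spec = qm_io.JobSpec("ts_opt_semiempirical", config.theory_guess, pseudo)
    qm_io.write_job(guess_spec, sysdir / "guess_ts.gjf")
    guess_out = backend.run_ts_opt(
        guess_spec, sysdir / "guess_ts.log", site,
        (config.separation_A, config.separation_A), system,
    )
    guess_geom, _ = qm_io.parse_opt_output(guess_out)
    guess_geom.provenance = "guess_ts"
    state.mark(system, "guess_ts")

    # refinement at the target QM level, with the frequency check
    refine_spec = qm_io.JobSpec("ts_opt_qm", config.theory_refine, guess_geom)
    qm_io.write_job(refine_spec, sysdir / "refine_ts.gjf")
    refine_out = backend.run_ts_opt(
        refine_spec, sysdir / "refine_ts.log", site, backend.refine_distances, system
    )
    ts_geom, _ = qm_io.parse_opt_output(refine_out)
    ts_geom.provenance = "refined_ts"
    state.mark(system, "refined_ts")

    freqs = qm_io.parse_freq_output(refine_out)
    verdict = qm_io.vibrational_check(freqs)
    if verdict != "true_ts":
        qm_io.route_failure(refine_out, f"vibrational check: {verdict}", error_dir, stage="refined_ts")
        state.fail(system, verdict)
        return
    write_xyz(ts_geom, sysdir / "ts.xyz", comment=f"{system} refined TS")
    s_index = synchronicity_index(ts_geom, site)
    state.mark(system, "ts_validated", synchronicity_A=round(s_index, 6))

    # optional reactant/product optimization jobs
    if config.rc_flag:
        for tag, smi in (("diene", products.diene_smiles), ("dienophile", products.dienophile_smiles)):
            if not smi:
                continue
            frag = retro_da.Cycloadduct.from_smiles(smi)
            frag_geom = embed_with_retry(frag, EmbedParams(random_seed=config.seed))
            frag_spec = qm_io.JobSpec("frequency", config.theory_refine, frag_geom,
                                      title=f"{system} {tag} opt")
            qm_io.write_job(frag_spec, sysdir / f"{tag}_opt.gjf")

    # intrinsic reaction coordinate
    irc_spec = qm_io.JobSpec(
        "irc", config.theory_refine, ts_geom,
        irc_points_per_direction=config.irc_points, irc_step_size=config.irc_step,
    )
    qm_io.write_job(irc_spec, sysdir / "irc.gjf")
    irc_out = backend.run_irc(irc_spec, sysdir / "irc.log", site)
    path = qm_io.parse_irc_output(irc_out, name=system)
    qm_io.write_path_file(path, sysdir / "irc.ircpath")
    state.mark(system, "irc_done", irc_points=path.n_points, has_forces=path.has_forces,
               synchronicity_A=round(s_index, 6))


def run_pipeline(config: Config, backend: SyntheticBackend | None = None) -> PipelineState:
    """Run the TS-prediction chain for every adduct and competing site.

    Returns the final state; per-track failures are contained and
    recorded with a reason, config-level problems raise ConfigError.
    """
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    error_dir = workdir / "ERROR_FILES"
    state = PipelineState.load(workdir)
    if backend is None and config.backend == "synthetic":
        backend = SyntheticBackend(seed=config.seed)

    adducts = retro_da.parse_smiles_file(config.smiles_path)
    for idx, adduct in enumerate(adducts):
        sites = retro_da.find_reactive_sites(adduct)
        if not sites:
            system = f"sys_{idx}_0"
            state.fail(system, "no cyclohexene reactive site found")
            note = workdir / f"{system}_no_site.txt"
            note.write_text(f"{adduct.smiles}: not recognised as a Diels-Alder adduct\n")
            qm_io.route_failure(note, "no reactive site", error_dir, stage="sites_found")
            continue
        for sidx, site in enumerate(sites):
            system = f"sys_{idx}_{sidx}"
            done = state.stage(system)
            if done in ("irc_done", "ts_validated", "rfa_done", "rfd_done"):
                logger.info("%s already at %s; skipping", system, done)
                continue
            try:
                _run_track(config, backend, adduct, site, idx, sidx, workdir, error_dir, state)
            except Exception as exc:  # per-track containment
                logger.warning("%s failed: %s", system, exc)
                state.fail(system, str(exc))
            state.save(workdir)
    state.save(workdir)
    summary = state.summary()
    logger.info("pipeline summary: %s", summary)
    return state


def run_analysis(config: Config, analysis: AnalysisConfig) -> dict[str, dict]:
    """Reaction-force (and, when enabled, decomposition) analysis of IRC data.

    Honors the RFA/RFD flags of the main configuration: nothing runs
    when RFA_FLAG is 0, and the decomposition additionally needs
    RFD_FLAG plus per-atom forces in the IRC data.  Returns a per-system
    report dict; per-system problems are recorded, not raised.
    """
    if not config.rfa_flag:
        logger.warning("RFA_FLAG is not set to 1; analysis request ignored")
        return {}
    workdir = Path(config.workdir)
    state = PipelineState.load(workdir)
    if analysis.systems == ["all"]:
        systems = [s for s, rec in sorted(state.tracks.items()) if rec.get("stage") == "irc_done"]
    else:
        systems = analysis.systems
    results: dict[str, dict] = {}
    for system in systems:
        report: dict = {}
        results[system] = report
        path_file = workdir / system / "irc.ircpath"
        if not path_file.exists():
            report["error"] = "no IRC data for this system"
            logger.warning("%s: %s", system, report["error"])
            continue
        path = qm_io.parse_path_file(path_file, name=system)
        profile = rfa.rfa_profile(path)
        table = rfa.write_rfa_table(profile, workdir / system / "rfa.tsv", kcal=analysis.kcal)
        report["rfa_table"] = str(table)
        if analysis.plots:
            report["rfa_plot"] = str(rfa.plot_rfa(profile, workdir / system / "rfa.png"))
        if not config.rfd_flag:
            continue
        if not path.has_forces:
            report["rfd_error"] = "IRC data lacks per-atom forces; decomposition unavailable"
            logger.warning("%s: %s", system, report["rfd_error"])
            continue
        dec = rfd.atomic_force_decomposition(path)
        dec = rfd.atomic_kappa_decomposition(dec, path)
        if analysis.fragments == "pairs":
            rec = state.tracks.get(system, {})
            if "diene_atoms" in rec:
                d = rec["diene_atoms"]
                e = rec["dienophile_atoms"]
                rfd.fragment_aggregate(dec, {"pair1": (d[0], e[0]), "pair2": (d[3], e[1])})
        atoms = tuple(analysis.atoms) if analysis.atoms is not None else None
        table = rfd.write_decomposition_table(dec, workdir / system / "rfd.tsv", atoms=atoms)
        report["rfd_table"] = str(table)
    return results
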