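"""Electronic-structure job files and output parsing.

The workflow delegates all quantum chemistry to an external backend and
only ever touches text files: it writes job inputs for each stage
(constrained scan, guess-TS cleanup, TS refinement, frequency, IRC),
parses the corresponding outputs, applies the vibrational check, and
routes rejected files into an ERROR_FILES folder with a manifest.

Two output dialects are supported:

* a simplified Gaussian-style log dialect (``*.log``) with the familiar
  landmarks — ``Input orientation:`` coordinate tables, ``SCF Done:``
  energies, ``Frequencies --`` rows, IRC point blocks with a signed
  direction and a net reaction coordinate, ``Forces (Hartrees/Bohr)``
  tables, and a ``Normal termination`` trailer;
* the package's own plain-text path format (``*.ircpath``): a header
  with the atom and point counts, then per point one ``xi`` line, one
  ``energy`` line, and N ``element x y z [fx fy fz]`` lines.

Both are emitted by the synthetic backend, so every parser is exercised
without any QM software.  Atom indices are 1-based inside job files
(dialect convention) and 0-based everywhere else.
"""

from __future__ import annotations

import dataclasses
import shutil
from pathlib import Path

import numpy as np

from .geometry import ConstraintSpec, Geometry
from .rfa import IRCPath
from .units import IRC_STEPSIZE_DIALECT_FACTOR

__all__ = [
    "JobSpec",
    "FrequencySet",
    "ScanResult",
    "ParseFailure",
    "InsufficientScan",
    "write_job",
    "parse_scan_output",
    "parse_opt_output",
    "parse_freq_output",
    "select_pseudo_guess",
    "vibrational_check",
    "route_failure",
    "parse_irc_output",
    "write_path_file",
    "parse_path_file",
    "write_gaussian_scan_log",
    "write_gaussian_opt_log",
    "write_gaussian_freq_log",
    "write_gaussian_irc_log",
]

JOB_TYPES = ("constrained_scan", "ts_opt_semiempirical", "ts_opt_qm", "frequency", "irc")

#: Diagnostic substrings that mark a failed backend run.  Config-extensible.
DEFAULT_ERROR_PATTERNS = (
    "Error termination",
    "Convergence failure",
    "basis set not found",
)


class ParseFailure(RuntimeError):
    """Backend output is truncated, failed, or not in the expected dialect."""


class InsufficientScan(RuntimeError):
    """A scan produced fewer than two configurations."""


@dataclasses.dataclass
class JobSpec:
    """One electronic-structure job to be written for the backend."""

    job_type: str
    theory: str
    geometry: Geometry
    constraints: ConstraintSpec | None = None
    irc_points_per_direction: int | None = None
    irc_step_size: float | None = None  # amu^(1/2)*bohr
    resources: tuple[str, ...] = ()
    title: str = "daforge job"

    def __post_init__(self) -> None:
        if self.job_type not in JOB_TYPES:
            raise ValueError(f"unknown job type {self.job_type!r}")
        if not self.theory:
            raise ValueError("theory level must be non-empty")
        if self.job_type == "irc":
            if not self.irc_points_per_direction or self.irc_points_per_direction < 1:
                raise ValueError("irc jobs need irc_points_per_direction >= 1")
            if not self.irc_step_size or self.irc_step_size <= 0:
                raise ValueError("irc jobs need a positive irc_step_size")


@dataclasses.dataclass
class FrequencySet:
    """Harmonic frequencies in cm^-1; negative entries are imaginary modes."""

    frequencies: list[float]

    def __post_init__(self) -> None:
        if not self.frequencies:
            raise ValueError("frequency set must be non-empty")

    @property
    def n_imaginary(self) -> int:
        return sum(1 for f in self.frequencies if f < 0)


@dataclasses.dataclass
class ScanResult:
    """Ordered optimized configurations of a constrained scan."""

    configurations: list[tuple[Geometry, float]]  # (geometry, energy in Hartree)

    def __len__(self) -> int:
        return len(self.configurations)


# ---------------------------------------------------------------------------
# job input writing


def _route_line(spec: JobSpec) -> str:
    if spec.job_type == "constrained_scan":
        return f"#p opt=modredundant {spec.theory}"
    if spec.job_type in ("ts_opt_semiempirical", "ts_opt_qm"):
        # single-ended eigenvector-following (Berny) saddle search + freq check
        return f"#p opt=(ts,berny,calcfc,noeigen) freq {spec.theory}"
    if spec.job_type == "frequency":
        return f"#p freq {spec.theory}"
    # irc: both directions, per-direction point count; dialect step size is
    # an integer in units of 0.01 amu^(1/2)*bohr
    step_int = int(round(spec.irc_step_size * IRC_STEPSIZE_DIALECT_FACTOR))
    return (
        f"#p irc=(maxpoints={spec.irc_points_per_direction},"
        f"stepsize={step_int},calcfc,both) {spec.theory}"
    )


def write_job(spec: JobSpec, path) -> Path:
    """Write a Gaussian-style job input file for a JobSpec.

    Constrained scans get one frozen-distance line per constraint in the
    redundant-coordinate section (``B i j target F``, 1-based indices).
    """
    path = Path(path)
    g = spec.geometry
    lines = list(spec.resources)
    lines += [_route_line(spec), "", spec.title, "", f"{g.charge} {g.multiplicity}"]
    for el, (x, y, z) in zip(g.elements, g.coords):
        lines.append(f" {el:<3s} {x:13.6f} {y:13.6f} {z:13.6f}")
    lines.append("")
    if spec.job_type == "constrained_scan":
        if spec.constraints is None:
            raise ValueError("constrained_scan jobs need a ConstraintSpec")
        for c in spec.constraints.distance_constraints:
            flag = "F" if c.frozen else "B"
            lines.append(f"B {c.atom_i + 1} {c.atom_j + 1} {c.target_A:.4f} {flag}")
        lines.append("")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Gaussian-style log writing (used by the synthetic backend)

_ORIENT_HEADER = [
    "                         Input orientation:",
    " ---------------------------------------------------------------------",
    " Center     Symbol              Coordinates (Angstroms)",
    " Number                    X           Y           Z",
    " ---------------------------------------------------------------------",
]


def _orientation_block(geom: Geometry) -> list[str]:
    lines = list(_ORIENT_HEADER)
    for i, (el, (x, y, z)) in enumerate(zip(geom.elements, geom.coords), start=1):
        lines.append(f" {i:6d}     {el:<3s}      {x:12.6f}{y:12.6f}{z:12.6f}")
    lines.append(" ---------------------------------------------------------------------")
    return lines


def _forces_block(elements, forces_point: np.ndarray) -> list[str]:
    lines = [
        " ***** Axes restored to original set *****",
        "       Forces (Hartrees/Bohr)",
        " Number  Symbol          Fx          Fy          Fz",
        " -------------------------------------------------------------------",
    ]
    for i, (el, (fx, fy, fz)) in enumerate(zip(elements, forces_point), start=1):
        lines.append(f" {i:6d}   {el:<3s}   {fx:14.9f}{fy:14.9f}{fz:14.9f}")
    lines.append(" -------------------------------------------------------------------")
    return lines


def _scf_line(energy: float, theory: str = "R") -> str:
    return f" SCF Done:  E({theory}) = {energy:18.9f}     A.U. after   11 cycles"


def write_gaussian_scan_log(configurations, path) -> Path:
    """Emit a scan log: per optimized point an orientation block, an SCF
    energy and an 'Optimization completed.' marker."""
    lines = [" Entering Gaussian-style scan output (synthetic)"]
    for geom, energy in configurations:
        lines += _orientation_block(geom)
        lines.append(_scf_line(energy))
        lines.append(" Optimization completed.")
    lines.append(" Normal termination of backend run.")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def write_gaussian_opt_log(geom: Geometry, energy: float, path, frequencies=None) -> Path:
    """Emit an optimization log with a single final structure (plus an
    optional frequency section, as produced by opt+freq jobs)."""
    lines = [" Entering Gaussian-style optimization output (synthetic)"]
    lines += _orientation_block(geom)
    lines.append(_scf_line(energy))
    lines.append(" Optimization completed.")
    if frequencies is not None:
        lines += _frequency_lines(frequencies)
    lines.append(" Normal termination of backend run.")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def _frequency_lines(frequencies) -> list[str]:
    lines = [" Harmonic frequencies (cm**-1):"]
    freqs = list(frequencies)
    for k in range(0, len(freqs), 3):
        chunk = freqs[k : k + 3]
        lines.append(" Frequencies --  " + "".join(f"{f:12.4f}" for f in chunk))
    return lines


def write_gaussian_freq_log(frequencies, path) -> Path:
    """Emit a frequency log with 'Frequencies --' rows, three per line."""
    lines = [" Entering Gaussian-style frequency output (synthetic)"]
    lines += _frequency_lines(frequencies)
    lines.append(" Normal termination of backend run.")
    Path(path).write_text("\n".join(lines) + "\n")
    return Path(path)


def write_gaussian_irc_log(path_obj: IRCPath, path) -> Path:
    """Emit a two-direction IRC log for a path whose TS sits at xi = 0.

    The TS record is written in both direction blocks (as real IRC runs
    do); parsers must deduplicate it.
    """
    p = Path(path)
    ts_idx = int(np.argmin(np.abs(path_obj.xi)))
    lines = [" Entering Gaussian-style IRC output (synthetic)"]

    def point_block(i: int, direction: str, number: int) -> list[str]:
        block = [
            f" Point Number: {number:3d}          Path direction: {direction}",
            f" NET REACTION COORDINATE UP TO THIS POINT = {abs(path_obj.xi[i]):12.5f}",
        ]
        block += _orientation_block(path_obj.geometries[i])
        block.append(_scf_line(path_obj.energy[i]))
        if path_obj.has_forces:
            block += _forces_block(path_obj.geometries[i].elements, path_obj.forces[i])
        return block

    for number, i in enumerate(range(ts_idx, len(path_obj.xi))):
        lines += point_block(i, "FORWARD", number)
    for number, i in enumerate(range(ts_idx, -1, -1)):
        lines += point_block(i, "REVERSE", number)
    lines.append(" Normal termination of backend run.")
    p.write_text("\n".join(lines) + "\n")
    return p


# ---------------------------------------------------------------------------
# parsing

def _check_terminated(text: str, path, error_patterns=DEFAULT_ERROR_PATTERNS) -> None:
    for pat in error_patterns:
        if pat in text:
            raise ParseFailure(f"{path}: backend reported failure ({pat!r})")
    if "Normal termination" not in text:
        raise ParseFailure(f"{path}: output truncated (no termination line)")


def _parse_orientation(lines: list[str], start: int):
    """Parse one orientation block starting at its 'Input orientation:' line."""
    i = start + 5  # skip the header rows
    elements: list[str] = []
    coords: list[list[float]] = []
    while i < len(lines) and not lines[i].strip().startswith("---"):
        parts = lines[i].split()
        elements.append(parts[1])
        coords.append([float(v) for v in parts[2:5]])
        i += 1
    return elements, np.array(coords), i


def _parse_forces(lines: list[str], start: int):
    i = start + 3  # 'Forces' line + column header + rule
    rows: list[list[float]] = []
    while i < len(lines) and not lines[i].strip().startswith("---"):
        parts = lines[i].split()
        rows.append([float(v) for v in parts[2:5]])
        i += 1
    return np.array(rows), i


def parse_scan_output(path, error_patterns=DEFAULT_ERROR_PATTERNS) -> ScanResult:
    """Parse a constrained-scan log into its ordered optimized points."""
    path = Path(path)
    text = path.read_text()
    _check_terminated(text, path, error_patterns)
    lines = text.splitlines()
    configs: list[tuple[Geometry, float]] = []
    cur_geom: Geometry | None = None
    cur_energy: float | None = None
    i = 0
    while i < len(lines):
        line = lines[i]
        if "Input orientation:" in line:
            elements, coords, i = _parse_orientation(lines, i)
            cur_geom = Geometry(elements, coords, provenance="scan_point")
            continue
        if "SCF Done:" in line:
            cur_energy = float(line.split("=")[1].split()[0])
        elif "Optimization completed" in line:
            if cur_geom is None or cur_energy is None:
                raise ParseFailure(f"{path}: optimization marker without geometry/energy")
            configs.append((cur_geom, cur_energy))
        i += 1
    if not configs:
        raise ParseFailure(f"{path}: no optimized configurations found")
    return ScanResult(configs)


def parse_opt_output(path, error_patterns=DEFAULT_ERROR_PATTERNS):
    """Parse an optimization log; returns (final Geometry, final energy)."""
    scan = parse_scan_output(path, error_patterns)
    geom, energy = scan.configurations[-1]
    return geom, energy


def parse_freq_output(path, error_patterns=DEFAULT_ERROR_PATTERNS) -> FrequencySet:
    """Collect every 'Frequencies --' row of a frequency log."""
    path = Path(path)
    text = path.read_text()
    _check_terminated(text, path, error_patterns)
    freqs: list[float] = []
    for line in text.splitlines():
        if "Frequencies --" in line:
            freqs.extend(float(v) for v in line.split("--")[1].split())
    if not freqs:
        raise ParseFailure(f"{path}: no frequencies found")
    return FrequencySet(freqs)


def select_pseudo_guess(scan: ScanResult) -> Geometry:
    """Pick the pseudo-guess TS: the highest-energy scan configuration.

    For intermolecular cycloadditions this is the stretched two-fragment
    structure.  Energy ties break toward the later scan index (closer to
    the stretched configuration).
    """
    if len(scan) < 2:
        raise InsufficientScan(f"scan has {len(scan)} configuration(s); need at least 2")
    energies = [e for _, e in scan.configurations]
    best = max(range(len(energies)), key=lambda i: (energies[i], i))
    geom = scan.configurations[best][0].copy()
    geom.provenance = "guess_ts"
    return geom


def vibrational_check(freqs: FrequencySet) -> str:
    """Classify a stationary point by its imaginary-mode count.

    Exactly one imaginary (negative) frequency marks a true transition
    state; none marks a minimum; more marks a higher-order saddle.
    """
    n = freqs.n_imaginary
    if n == 0:
        return "minimum"
    if n == 1:
        return "true_ts"
    return "higher_order_saddle"


def route_failure(path, reason: str, error_dir, stage: str = "unknown") -> Path:
    """Copy a rejected file into the ERROR_FILES folder and log the reason.

    The original file is left in place.  Name collisions get a numeric
    suffix.  A tab-separated ``manifest.tsv`` (filename, stage, reason)
    is appended per routed file.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cannot route missing file {path}")
    error_dir = Path(error_dir)
    error_dir.mkdir(parents=True, exist_ok=True)
    dest = error_dir / path.name
    k = 1
    while dest.exists():
        dest = error_dir / f"{path.stem}_{k}{path.suffix}"
        k += 1
    shutil.copy2(path, dest)
    manifest = error_dir / "manifest.tsv"
    with manifest.open("a") as fh:
        fh.write(f"{dest.name}\t{stage}\t{reason}\n")
    return dest


def parse_irc_output(path, error_patterns=DEFAULT_ERROR_PATTERNS, name: str | None = None) -> IRCPath:
    """Parse an IRC output (either dialect) into an IRCPath.

    Gaussian-style logs carry unsigned net reaction coordinates per
    direction; the reverse branch is negated (reactant side), the
    forward branch kept positive, and the duplicate TS record dropped.
    Points come back sorted by ascending xi.  If any point lacks a
    forces table the whole path is flagged force-less.
    """
    path = Path(path)
    if path.suffix == ".ircpath":
        return parse_path_file(path, name=name)
    text = path.read_text()
    _check_terminated(text, path, error_patterns)
    lines = text.splitlines()
    records: list[dict] = []
    current: dict | None = None
    i = 0
    while i < len(lines):
        line = lines[i]
        if "Point Number:" in line:
            if current is not None:
                records.append(current)
            direction = "REVERSE" if "REVERSE" in line else "FORWARD"
            current = {"direction": direction}
        elif "NET REACTION COORDINATE" in line and current is not None:
            value = float(line.split("=")[1])
            current["xi"] = -value if current["direction"] == "REVERSE" else value
        elif "Input orientation:" in line and current is not None:
            elements, coords, i = _parse_orientation(lines, i)
            current["geom"] = Geometry(elements, coords, provenance="irc_point")
            continue
        elif "SCF Done:" in line and current is not None:
            current["energy"] = float(line.split("=")[1].split()[0])
        elif "Forces (Hartrees/Bohr)" in line and current is not None:
            forces, i = _parse_forces(lines, i)
            current["forces"] = forces
            continue
        i += 1
    if current is not None:
        records.append(current)
    if not records:
        raise ParseFailure(f"{path}: no IRC points found")
    for rec in records:
        if "xi" not in rec or "geom" not in rec or "energy" not in rec:
            raise ParseFailure(f"{path}: incomplete IRC point record")
    # deduplicate on xi (the TS appears once per direction block)
    seen: dict[float, dict] = {}
    for rec in records:
        key = round(rec["xi"], 9)
        seen.setdefault(key, rec)
    ordered = [seen[k] for k in sorted(seen)]
    has_forces = all("forces" in r for r in ordered)
    forces = np.stack([r["forces"] for r in ordered]) if has_forces else None
    return IRCPath(
        xi=np.array([r["xi"] for r in ordered]),
        energy=np.array([r["energy"] for r in ordered]),
        geometries=[r["geom"] for r in ordered],
        forces=forces,
        name=name or path.stem,
    )


# ---------------------------------------------------------------------------
# the package's own plain-text path format


def write_path_file(path_obj: IRCPath, path) -> Path:
    """Serialize an IRCPath in the plain path format (round-trip exact to
    the printed precision, 1e-9)."""
    p = Path(path)
    lines = [
        "# daforge irc path format v1",
        f"# name {path_obj.name}",
        f"natoms {path_obj.n_atoms}",
        f"npoints {path_obj.n_points}",
        f"has_forces {1 if path_obj.has_forces else 0}",
    ]
    for i in range(path_obj.n_points):
        g = path_obj.geometries[i]
        lines.append(f"point {i}")
        lines.append(f"xi {path_obj.xi[i]:.9f}")
        lines.append(f"energy {path_obj.energy[i]:.12f}")
        for a, el in enumerate(g.elements):
            row = f"{el:<3s} " + " ".join(f"{v:16.9f}" for v in g.coords[a])
            if path_obj.has_forces:
                row += " " + " ".join(f"{v:16.9f}" for v in path_obj.forces[i, a])
            lines.append(row)
    lines.append("end")
    p.write_text("\n".join(lines) + "\n")
    return p


def parse_path_file(path, name: str | None = None) -> IRCPath:
    """Parse the plain path format back into an IRCPath."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or "daforge irc path" not in lines[0]:
        raise ParseFailure(f"{path}: not a daforge path file")
    if lines[-1].strip() != "end":
        raise ParseFailure(f"{path}: truncated path file")
    header: dict[str, str] = {}
    body_start = 0
    file_name = None
    for i, line in enumerate(lines):
        if line.startswith("# name"):
            file_name = line.split(None, 2)[2]
            continue
        if line.startswith("#"):
            continue
        key = line.split()[0]
        if key == "point":
            body_start = i
            break
        header[key] = line.split()[1]
    n_atoms = int(header["natoms"])
    n_points = int(header["npoints"])
    has_forces = bool(int(header.get("has_forces", "0")))
    xi, energy, geometries, forces = [], [], [], []
    i = body_start
    try:
        for _ in range(n_points):
            assert lines[i].startswith("point")
            xi.append(float(lines[i + 1].split()[1]))
            energy.append(float(lines[i + 2].split()[1]))
            elements, coords, frc = [], [], []
            for a in range(n_atoms):
                parts = lines[i + 3 + a].split()
                elements.append(parts[0])
                coords.append([float(v) for v in parts[1:4]])
                if has_forces:
                    frc.append([float(v) for v in parts[4:7]])
            geometries.append(Geometry(elements, np.array(coords), provenance="irc_point"))
            if has_forces:
                forces.append(frc)
            i += 3 + n_atoms
    except (IndexError, AssertionError, ValueError) as exc:
        raise ParseFailure(f"{path}: malformed path file ({exc})")
    return IRCPath(
        xi=np.array(xi),
        energy=np.array(energy),
        geometries=geometries,
        forces=np.array(forces) if has_forces else None,
        name=name or file_name or path.stem,
    )
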