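"""INI configuration handling for the workflow.

Two files drive the pipeline, mirroring the classic layout of this kind
of tool: a main configuration (``da.ini``) with the job-level settings
and stage flags, and an analysis configuration (``analysis.ini``)
selecting the systems and atoms for the post-IRC analyses.

Main file keywords (all optional; defaults shown):

    [main]      smiles_file=SMILES.txt  workdir=.  seed=42
    [theory]    guess=PM6  refine=B3LYP/6-31G(d)
    [geometry]  separation_A=2.15
    [scan]      n_points=16
    [irc]       points=60  step=0.8
    [flags]     RC_FLAG=0  RFA_FLAG=0  RFD_FLAG=0
    [backend]   dialect=synthetic        # or: gaussian (emit job files only)

Unknown keys warn rather than fail; malformed INI syntax is fatal with a
line diagnostic.
"""

from __future__ import annotations

import configparser
import dataclasses
import logging
from pathlib import Path

logger = logging.getLogger(__name__)

__all__ = ["Config", "AnalysisConfig", "ConfigError", "load_config", "load_analysis_config"]


class ConfigError(RuntimeError):
    """Fatal configuration problem (missing or malformed file, bad value)."""


_KNOWN_KEYS = {
    "main": {"smiles_file", "workdir", "seed"},
    "theory": {"guess", "refine"},
    "geometry": {"separation_a"},
    "scan": {"n_points"},
    "irc": {"points", "step"},
    "flags": {"rc_flag", "rfa_flag", "rfd_flag"},
    "backend": {"dialect"},
}


@dataclasses.dataclass
class Config:
    """Validated main configuration with defaults applied."""

    smiles_path: Path = Path("SMILES.txt")
    workdir: Path = Path(".")
    seed: int = 42
    theory_guess: str = "PM6"
    theory_refine: str = "B3LYP/6-31G(d)"
    separation_A: float = 2.15
    scan_points: int = 16
    irc_points: int = 60
    irc_step: float = 0.8
    rc_flag: int = 0
    rfa_flag: int = 0
    rfd_flag: int = 0
    backend: str = "synthetic"

    def __post_init__(self) -> None:
        for name in ("rc_flag", "rfa_flag", "rfd_flag"):
            if getattr(self, name) not in (0, 1):
                raise ConfigError(f"{name.upper()} must be 0 or 1")
        for name in ("separation_A", "irc_step"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        for name in ("scan_points", "irc_points"):
            if getattr(self, name) < 2:
                raise ConfigError(f"{name} must be at least 2")
        if self.backend not in ("synthetic", "gaussian"):
            raise ConfigError(f"unknown backend dialect {self.backend!r}")


def _read_ini(path) -> configparser.ConfigParser:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    parser = configparser.ConfigParser()
    try:
        parser.read(path)
    except configparser.Error as exc:
        raise ConfigError(f"malformed INI file {path}: {exc}")
    return parser


def _warn_unknown(parser: configparser.ConfigParser, known: dict, label: str) -> None:
    for section in parser.sections():
        sec = section.lower()
        if sec not in known:
            logger.warning("%s: unknown section [%s] ignored", label, section)
            continue
        for key in parser[section]:
            if key.lower() not in known[sec]:
                logger.warning("%s: unknown key %s.%s ignored", label, section, key)


def load_config(path) -> Config:
    """Load and validate the main configuration file."""
    parser = _read_ini(path)
    _warn_unknown(parser, _KNOWN_KEYS, str(path))

    def get(section, key, default):
        return parser.get(section, key, fallback=default)

    try:
        return Config(
            smiles_path=Path(get("main", "smiles_file", "SMILES.txt")),
            workdir=Path(get("main", "workdir", ".")),
            seed=int(get("main", "seed", "42")),
            theory_guess=get("theory", "guess", "PM6"),
            theory_refine=get("theory", "refine", "B3LYP/6-31G(d)"),
            separation_A=float(get("geometry", "separation_A", "2.15")),
            scan_points=int(get("scan", "n_points", "16")),
            irc_points=int(get("irc", "points", "60")),
            irc_step=float(get("irc", "step", "0.8")),
            rc_flag=int(get("flags", "RC_FLAG", "0")),
            rfa_flag=int(get("flags", "RFA_FLAG", "0")),
            rfd_flag=int(get("flags", "RFD_FLAG", "0")),
            backend=get("backend", "dialect", "synthetic"),
        )
    except ValueError as exc:
        raise ConfigError(f"bad value in {path}: {exc}")


@dataclasses.dataclass
class AnalysisConfig:
    """Selection of systems/atoms for the reaction-force analyses.

    ``systems`` is a list of system labels (``sys_<adduct>_<site>``) or
    ["all"]; ``atoms`` restricts the per-atom decomposition report;
    ``fragments`` of "pairs" aggregates the two forming-bond pairs.
    """

    systems: list[str] = dataclasses.field(default_factory=lambda: ["all"])
    atoms: list[int] | None = None  # None = all atoms
    fragments: str = "pairs"
    kcal: bool = True
    plots: bool = False


def load_analysis_config(path) -> AnalysisConfig:
    """Load the analysis configuration file."""
    parser = _read_ini(path)
    known = {"systems": {"select"}, "decomposition": {"atoms", "fragments", "plots", "kcal"}}
    _warn_unknown(parser, known, str(path))
    select = parser.get("systems", "select", fallback="all")
    systems = [s.strip() for s in select.split(",") if s.strip()]
    atoms_raw = parser.get("decomposition", "atoms", fallback="all").strip()
    atoms = None if atoms_raw.lower() == "all" else [int(a) for a in atoms_raw.split(",")]
    return AnalysisConfig(
        systems=systems or ["all"],
        atoms=atoms,
        fragments=parser.get("decomposition", "fragments", fallback="pairs"),
        kcal=parser.getboolean("decomposition", "kcal", fallback=True),
        plots=parser.getboolean("decomposition", "plots", fallback=False),
    )
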