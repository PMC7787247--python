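"""Config parsing, validation, deterministic seeding and CSV/JSON writers.

Config files are YAML (JSON is a subset) with one block per subcommand
plus an optional global ``seed`` and ``log_level``.  Validation walks the
whole document and reports *every* violation with its path, not just the
first; unknown keys are rejected.

One global seed spawns an independent substream per module (via
numpy.random.SeedSequence keyed on the module name), so adding a module
never perturbs another module's random draws.
"""

from __future__ import annotations

import json
import logging
import sys
import zlib
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version as _pkg_version
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError

__all__ = [
    "RunConfig",
    "parse_and_validate",
    "derive_seed",
    "write_csv",
    "write_json",
    "read_csv",
    "get_logger",
    "package_version",
]


def package_version() -> str:
    try:
        return _pkg_version("inm")
    except PackageNotFoundError:
        return "unknown"


def get_logger(level: str = "INFO") -> logging.Logger:
    """Package logger writing ISO-timestamped records to stderr."""
    logger = logging.getLogger("inm")
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter(
            "%(asctime)s %(levelname)s %(name)s: %(message)s",
            datefmt="%Y-%m-%dT%H:%M:%S"))
        logger.addHandler(handler)
    logger.setLevel(level.upper())
    return logger


def derive_seed(global_seed: int, module: str) -> int:
    """Deterministic per-module substream seed from the global seed."""
    key = zlib.crc32(module.encode())
    ss = np.random.SeedSequence([int(global_seed), key])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# schema: block -> field -> (type, default, constraint predicate, message)
# default None and no-predicate fields are required.

def _pos(x):
    return x > 0


def _nonneg(x):
    return x >= 0


_SCHEMA: dict[str, dict[str, tuple]] = {
    "ising": {
        "n_channels": (int, 100, lambda x: x >= 2, "n_channels must be >= 2"),
        "coupling": (float, 1.0, _pos,
                     "coupling must be > 0 (ferromagnetic J > 0)"),
        "beta": (float, 1.0, _pos, "beta must be > 0"),
        "phi": (list, [0.0], None, ""),
        "beta_grid": (list, None, None, ""),
        "coupling_grid": (list, None, None, ""),
        "g_max": (float, 36.0, _pos, "g_max must be > 0"),
    },
    "gating": {
        "n_channels": (int, 100, lambda x: x >= 2, "n_channels must be >= 2"),
        "coupling": (float, 1.0, _pos,
                     "coupling must be > 0 (ferromagnetic J > 0)"),
        "beta": (float, 1.0, _pos, "beta must be > 0"),
        "phi": (float, 0.5, None, ""),
        "flip_rate": (float, 1.0, _pos, "flip_rate must be > 0"),
        "dt": (float, 0.1, _pos, "dt must be > 0"),
        "duration": (float, 100.0, _pos, "duration must be > 0"),
        "unit_current": (float, 6.6, _pos, "unit_current must be > 0"),
    },
    "congruence": {
        "phi_min": (float, -100.0, None, ""),
        "phi_max": (float, 100.0, None, ""),
        "n_points": (int, 101, lambda x: x >= 5, "need >= 5 grid points"),
        "a1": (float, 1.0, _pos, "A1 must be > 0"),
        "a2": (float, 1.5, _pos, "A2 must be > 0"),
        "b1": (float, -2.0, None, ""),
        "b2": (float, 0.0, None, ""),
        "phi_t": (float, 25.0, _pos, "phi_T must be > 0"),
    },
    "circuit": {
        "c_m": (float, 1.0, _pos, "c_m must be > 0"),
        "g_leak": (float, 0.3, _nonneg, "g_leak must be >= 0"),
        "e_leak": (float, -54.4, None, ""),
        "e_na": (float, 50.0, None, ""),
        "e_k": (float, -77.0, None, ""),
        "g_max_na": (float, 120.0, _nonneg, "g_max_na must be >= 0"),
        "g_max_k": (float, 9.0, _nonneg, "g_max_k must be >= 0"),
        "n_channels": (int, 10000, lambda x: x >= 2, "n_channels must be >= 2"),
        "coupling_na": (float, 0.25, _pos,
                        "coupling must be > 0 (ferromagnetic J > 0)"),
        "coupling_k": (float, 0.25, _pos,
                       "coupling must be > 0 (ferromagnetic J > 0)"),
        "beta_na": (float, 0.022, _pos, "beta_na must be > 0"),
        "beta_k": (float, 0.03, _pos, "beta_k must be > 0"),
        "flip_rate_na": (float, 8.0, _pos, "flip_rate_na must be > 0"),
        "flip_rate_k": (float, 0.25, _pos, "flip_rate_k must be > 0"),
        "dt": (float, 0.01, _pos, "dt must be > 0"),
        "duration": (float, 60.0, _pos, "duration must be > 0"),
        "v_init": (float, -70.0, None, ""),
        "stimulus": (list, [[20.0, 21.0, 250.0]], None, ""),
    },
    "cable": {
        "a1_um": (float, 0.6, _pos, "a1 must be > 0"),
        "a2_um": (float, 1.0, _pos, "a2 must be > 0"),
        "length_um": (float, 100.0, _pos, "length must be > 0"),
        "lamella_thickness_nm": (float, 10.0, _pos, "d_m must be > 0"),
        "c_m_area": (float, 1.0, _pos, "c_m must be > 0"),
        "r_l": (float, 100.0, _pos, "r_L must be > 0"),
        "velocity_reference_a2_um": (float, 1.0, _pos, "reference a2 must be > 0"),
        "velocity_reference_m_s": (float, 150.0, _pos,
                                   "reference velocity must be > 0"),
        "a2_scan_um": (list, [0.25, 0.5, 1.0, 2.0, 4.0], None, ""),
    },
    "nuon": {
        "n_sections": (int, 100, _pos, "n_sections must be > 0"),
        "section_length_um": (float, 100.0, _pos, "section length must be > 0"),
        "node_gap_um": (float, 1.0, _pos, "node gap must be > 0"),
        "loss_coefficients": (list, None, None, ""),
        "target_velocity_m_s": (float, 150.0, _pos,
                                "target velocity must be > 0"),
        "effective_mass": (float, 1e-20, _pos, "effective mass must be > 0"),
        "effective_charge": (float, 1.602176634e-19, _pos,
                             "effective charge must be > 0"),
    },
}

_GLOBAL_FIELDS = {"seed": (int, 0), "log_level": (str, "INFO")}


@dataclass
class RunConfig:
    """Validated configuration: per-module blocks plus global settings."""

    seed: int = 0
    log_level: str = "INFO"
    blocks: dict = field(default_factory=dict)

    def block(self, name: str) -> dict:
        """The named block with all defaults filled in."""
        merged = {k: spec[1] for k, spec in _SCHEMA[name].items()}
        merged.update(self.blocks.get(name, {}))
        return merged


def parse_and_validate(config_text: str) -> RunConfig:
    """Parse a YAML/JSON config document, reporting every violation.

    Raises :class:`ValidationError` whose message lists all offending
    paths; otherwise returns a :class:`RunConfig` with defaults filled.
    """
    try:
        doc = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:
        raise ValidationError(f"config is not valid YAML/JSON: {exc}") from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValidationError("config root must be a mapping")

    problems: list[str] = []
    cfg = RunConfig()
    for key, value in doc.items():
        if key in _GLOBAL_FIELDS:
            typ, _default = _GLOBAL_FIELDS[key]
            if typ is int and (not isinstance(value, int)
                              or isinstance(value, bool)):
                problems.append(f"{key}: must be an integer")
            elif typ is str and not isinstance(value, str):
                problems.append(f"{key}: must be a string")
            else:
                setattr(cfg, key, value)
        elif key in _SCHEMA:
            if not isinstance(value, dict):
                problems.append(f"{key}: block must be a mapping")
                continue
            block_schema = _SCHEMA[key]
            parsed = {}
            for fname, fval in value.items():
                if fname not in block_schema:
                    problems.append(f"{key}.{fname}: unknown key")
                    continue
                typ, _default, pred, msg = block_schema[fname]
                if typ in (int, float):
                    if isinstance(fval, bool) or not isinstance(
                            fval, (int, float)):
                        problems.append(f"{key}.{fname}: must be a number")
                        continue
                    if typ is int and int(fval) != fval:
                        problems.append(f"{key}.{fname}: must be an integer")
                        continue
                    fval = typ(fval)
                elif typ is list and not isinstance(fval, list):
                    problems.append(f"{key}.{fname}: must be a list")
                    continue
                if pred is not None and typ in (int, float) \
                        and not pred(fval):
                    problems.append(f"{key}.{fname}: {msg} (got {fval})")
                    continue
                parsed[fname] = fval
            cfg.blocks[key] = parsed
        else:
            problems.append(f"{key}: unknown top-level key")
    if cfg.seed < 0:
        problems.append("seed: must be >= 0")
    if problems:
        raise ValidationError(
            "invalid configuration:\n  " + "\n  ".join(problems))
    return cfg


# ---------------------------------------------------------------------------
# writers

def _provenance_lines(params: dict, seed: int | None) -> list[str]:
    lines = [f"# inm version {package_version()}"]
    if seed is not None:
        lines.append(f"# seed {seed}")
    for k, v in params.items():
        lines.append(f"# {k} = {v}")
    return lines


def write_csv(path, columns: dict[str, np.ndarray],
              params: dict | None = None, seed: int | None = None) -> None:
    """CSV with '#'-prefixed provenance header, comma-separated, '.' decimal."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = list(columns)
    arrays = [np.asarray(columns[n]) for n in names]
    n = arrays[0].size
    with open(path, "w") as fh:
        for line in _provenance_lines(params or {}, seed):
            fh.write(line + "\n")
        fh.write(",".join(names) + "\n")
        for i in range(n):
            fh.write(",".join(format(a[i], ".17g") if a.dtype.kind == "f"
                              else str(a[i]) for a in arrays) + "\n")


def write_json(path, payload: dict, params: dict | None = None,
               seed: int | None = None) -> None:
    """JSON report with an embedded provenance object."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {"provenance": {"package": "inm", "version": package_version(),
                          "seed": seed, "parameters": params or {}}}
    doc.update(payload)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=float)
        fh.write("\n")


def read_csv(path):
    """Reload a package-written CSV (skipping provenance comments)."""
    import pandas as pd

    return pd.read_csv(path, comment="#")
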