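"""Pipeline configuration: YAML parsing, defaults, validation.

A single YAML file configures both the analysis pipeline (top-level keys)
and the synthetic-genome generator (under the ``simulate`` key). Unknown
keys are rejected with a nearest-key suggestion; all type and range
violations are reported together.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, fields
from pathlib import Path

import yaml

from .synthetic_data import SimConfig


class ConfigError(ValueError):
    """One or more configuration problems, all listed in the message."""


@dataclass(frozen=True)
class PipelineParams:
    min_codons: int = 400            # env screen: ORFs of >= 400 codons
    e_threshold: float = 1e-10       # profile-HMM screening E-value
    flank: int = 10_000              # bp of context either side of an env ORF
    min_ltr_len: int = 100
    max_ltr_len: int = 3_000
    min_ltr_identity: float = 80.0   # percent
    seed_k: int = 12
    band: int = 32
    min_residue_fraction: float = 0.6  # MSA column trim ('rm_gap 60')
    family_identity_threshold: float = 80.0  # percent aa identity
    rate: float = 2.6e-3             # subs/site/MY
    convention: str = "one_lineage"        # LTR dating convention
    min_tail: int = 80               # aa downstream of the furin site
    provirus_orf_min_nt: int = 300   # structure-map ORF fill threshold


_RANGES = {
    "min_codons": (1, None),
    "e_threshold": (0.0, None),
    "flank": (0, None),
    "min_ltr_len": (1, None),
    "max_ltr_len": (1, None),
    "min_ltr_identity": (0.0, 100.0),
    "seed_k": (4, 64),
    "band": (0, None),
    "min_residue_fraction": (0.0, 1.0),
    "family_identity_threshold": (0.0, 100.0),
    "rate": (0.0, None),
    "min_tail": (0, None),
    "provirus_orf_min_nt": (0, None),
}


def _check_fields(section: str, data: dict, cls, errors: list[str]) -> dict:
    valid = {f.name: f.type for f in fields(cls)}
    clean: dict = {}
    for key, value in data.items():
        if key not in valid:
            hint = difflib.get_close_matches(key, valid, n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            errors.append(f"{section}: unknown key {key!r}{suffix}")
            continue
        clean[key] = value
    return clean


def validate_config(
    path: str | Path | None = None, data: dict | None = None
) -> tuple[PipelineParams, SimConfig]:
    """Load, default-fill and validate a configuration.

    Returns (pipeline parameters, simulation config); raises ConfigError
    listing every problem at once.
    """
    if data is None:
        data = {}
        if path is not None:
            loaded = yaml.safe_load(Path(path).read_text())
            if loaded is not None:
                if not isinstance(loaded, dict):
                    raise ConfigError("config file must contain a YAML mapping")
                data = loaded
    data = dict(data)
    errors: list[str] = []
    sim_data = data.pop("simulate", {}) or {}
    if not isinstance(sim_data, dict):
        errors.append("simulate: must be a mapping")
        sim_data = {}
    pipe_clean = _check_fields("pipeline", data, PipelineParams, errors)
    sim_clean = _check_fields("simulate", sim_data, SimConfig, errors)
    for key in ("copies_per_family", "age_grid"):
        if key in sim_clean and isinstance(sim_clean[key], list):
            sim_clean[key] = tuple(sim_clean[key])

    for key, (lo, hi) in _RANGES.items():
        if key in pipe_clean:
            value = pipe_clean[key]
            if not isinstance(value, (int, float)) or isinstance(value, bool):
                errors.append(f"pipeline: {key} must be numeric, got {value!r}")
                continue
            if (lo is not None and value < lo) or (hi is not None and value > hi):
                errors.append(
                    f"pipeline: {key}={value!r} outside allowed range "
                    f"[{lo}, {'inf' if hi is None else hi}]"
                )
    if "convention" in pipe_clean and pipe_clean["convention"] not in (
        "one_lineage",
        "two_lineage",
    ):
        errors.append(
            f"pipeline: convention must be 'one_lineage' or 'two_lineage', "
            f"got {pipe_clean['convention']!r}"
        )
    if errors:
        raise ConfigError("\n".join(errors))
    try:
        params = PipelineParams(**pipe_clean)
        sim = SimConfig(**sim_clean)
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    return params, sim
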