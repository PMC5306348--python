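"""Configuration and table I/O.

All tables are plain comma-separated text with a header row, UTF-8, '.'
decimal — the tabular style of GeneMapper-like exports.  Configs are
YAML with keys mirroring the ProcessParams / CEParams field names;
unknown keys are rejected so typos cannot silently revert a parameter to
its default.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .core import CEParams, ConfigError, EPG, KitDef, LocusDef, ProcessParams
from .degradation import QuantPair

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "write_epg_table",
    "read_epg_table",
    "read_quant_pairs",
    "write_kit_table",
    "read_kit_table",
    "file_digest",
]

EPG_COLUMNS = [
    "sample_id", "locus", "allele", "is_stutter",
    "size_bp", "molecules", "height_rfu", "detected",
]
QUANT_COLUMNS = ["sample_id", "kit_label", "c_small", "c_large", "x_small", "x_large"]
KIT_COLUMNS = ["locus", "dye", "repeat_bp", "allele", "size_bp"]

_CE_PRESETS = {"identity": CEParams.identity, "3500xl": CEParams.calibration_3500xl,
               "3130xl": CEParams.calibration_3130xl}


@dataclass
class RunConfig:
    """Fully validated simulation run configuration."""

    process: ProcessParams
    ce: CEParams
    p_deg: float = 0.0
    cells: float = 1.0
    cell_mode: str = "fixed"
    ploidy: str = "diploid"
    replicates: int = 1
    seed: int = 0
    kit: dict = field(default_factory=lambda: {"n_loci": 4, "size_range": [70, 450]})

    def to_dict(self) -> dict:
        d = {
            "process": asdict(self.process),
            "ce": asdict(self.ce),
            "p_deg": self.p_deg,
            "cells": self.cells,
            "cell_mode": self.cell_mode,
            "ploidy": self.ploidy,
            "replicates": self.replicates,
            "seed": self.seed,
            "kit": dict(self.kit),
        }
        return d


_PROCESS_DEFAULTS = {
    "extraction_efficiency": 1.0,
    "pcr_aliquot": 1.0,
    "pcr_cycles": 28,
    "pcr_efficiency": 0.90,
    "stutter_probability": 0.005,
    "ce_aliquot": 1.0,
}


def _build_section(name: str, data: dict, defaults: dict, cls):
    unknown = set(data) - set(defaults)
    if unknown:
        raise ConfigError(f"unknown key(s) in '{name}': {sorted(unknown)}")
    merged = {**defaults, **data}
    return cls(**merged)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Missing process keys take the standard crime-stain defaults
    (pcr_e = 0.90, stutter_p = 0.005, all transfer fractions 1.0,
    28 cycles).  ``ce`` may be a preset name (identity | 3500xl |
    3130xl), optionally with an ``ldt`` override, or a full field map.
    Any unknown key raises :class:`ConfigError` naming the key.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    known_top = {"process", "ce", "p_deg", "cells", "cell_mode", "ploidy",
                 "replicates", "seed", "kit"}
    unknown = set(raw) - known_top
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {sorted(unknown)}")

    process = _build_section("process", raw.get("process", {}) or {}, _PROCESS_DEFAULTS, ProcessParams)

    ce_raw = raw.get("ce", "identity")
    if isinstance(ce_raw, str):
        if ce_raw.lower() not in _CE_PRESETS:
            raise ConfigError(f"unknown ce preset {ce_raw!r}; options: {sorted(_CE_PRESETS)}")
        ce = _CE_PRESETS[ce_raw.lower()]()
    elif isinstance(ce_raw, dict):
        preset = ce_raw.pop("preset", None)
        if preset is not None:
            base = _CE_PRESETS[preset.lower()]()
            allowed = {"ldt"}
            unknown = set(ce_raw) - allowed
            if unknown:
                raise ConfigError(f"unknown key(s) in 'ce' with preset: {sorted(unknown)}")
            ce = CEParams(**{**asdict(base), **ce_raw})
        else:
            ce_defaults = asdict(CEParams())
            ce = _build_section("ce", ce_raw, ce_defaults, CEParams)
    else:
        raise ConfigError("'ce' must be a preset name or a mapping")

    p_deg = float(raw.get("p_deg", 0.0))
    if not (0.0 <= p_deg < 1.0):
        raise ConfigError(f"p_deg must be in [0, 1), got {p_deg!r}")
    cfg = RunConfig(
        process=process,
        ce=ce,
        p_deg=p_deg,
        cells=float(raw.get("cells", 1.0)),
        cell_mode=str(raw.get("cell_mode", "fixed")),
        ploidy=str(raw.get("ploidy", "diploid")),
        replicates=int(raw.get("replicates", 1)),
        seed=int(raw.get("seed", 0)),
        kit=dict(raw.get("kit", {"n_loci": 4, "size_range": [70, 450]})),
    )
    if cfg.cell_mode not in ("fixed", "poisson"):
        raise ConfigError(f"cell_mode must be fixed|poisson, got {cfg.cell_mode!r}")
    if cfg.ploidy not in ("diploid", "haploid"):
        raise ConfigError(f"ploidy must be diploid|haploid, got {cfg.ploidy!r}")
    if cfg.replicates < 1:
        raise ConfigError("replicates must be >= 1")
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False), encoding="utf-8")


def write_epg_table(epgs: dict[str, EPG] | list[EPG], path: str | Path) -> None:
    """Write EPGs as one tidy CSV (stable column order, lossless numerics)."""
    if isinstance(epgs, list):
        epgs = {f"s{i + 1}": e for i, e in enumerate(epgs)}
    frames = [epg.to_frame(sample_id) for sample_id, epg in epgs.items()]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=EPG_COLUMNS)
    df.to_csv(path, index=False)


def read_epg_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"locus": str, "allele": str})
    missing = set(EPG_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"EPG table {path} missing column(s): {sorted(missing)}")
    return df[EPG_COLUMNS]


def read_quant_pairs(path: str | Path) -> list[tuple[str, str, QuantPair]]:
    """Read dual-target quant pairs from CSV.

    Returns (sample_id, kit_label, QuantPair) triples; a malformed row is
    reported with its line number (header = line 1).
    """
    df = pd.read_csv(path)
    missing = set(QUANT_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"quant table {path} missing column(s): {sorted(missing)}")
    out = []
    for i, row in df.iterrows():
        try:
            pair = QuantPair(
                c_small=float(row["c_small"]),
                c_large=float(row["c_large"]),
                x_small=float(row["x_small"]),
                x_large=float(row["x_large"]),
            )
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"quant table {path}, line {i + 2}: {exc}") from exc
        out.append((str(row["sample_id"]), str(row["kit_label"]), pair))
    return out


def write_kit_table(kit: KitDef, path: str | Path) -> None:
    rows = [
        {"locus": locus.name, "dye": locus.dye, "repeat_bp": locus.repeat_bp,
         "allele": allele, "size_bp": size}
        for locus in kit
        for allele, size in locus.alleles.items()
    ]
    pd.DataFrame(rows, columns=KIT_COLUMNS).to_csv(path, index=False)


def read_kit_table(path: str | Path, name: str | None = None) -> KitDef:
    df = pd.read_csv(path)
    missing = set(KIT_COLUMNS) - set(df.columns)
    if missing:
        raise ConfigError(f"kit table {path} missing column(s): {sorted(missing)}")
    loci = []
    for locus_name, g in df.groupby("locus", sort=False):
        loci.append(
            LocusDef(
                name=str(locus_name),
                dye=str(g["dye"].iloc[0]),
                repeat_bp=int(g["repeat_bp"].iloc[0]),
                alleles={str(a): int(s) for a, s in zip(g["allele"], g["size_bp"])},
            )
        )
    return KitDef(name=name or Path(path).stem, loci=tuple(loci))


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file, for run manifests."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
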