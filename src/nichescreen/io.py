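"""File I/O: multi-page TIFF fields, CSV tables, YAML config, provenance.

Images travel as one multi-page TIFF per field (page order given by the
channel map, default nuclear/stemness/fibroblast = pages 0/1/2, values
clipped to 16-bit unsigned).  All tables are UTF-8 CSV with a header row.
"""

from __future__ import annotations

import hashlib
import json
import platform
import sys
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import CellRecord, ColonyRecord, FieldImage, ScoringParams, WellPhenotype

__all__ = [
    "ConfigError",
    "DataError",
    "RunConfig",
    "load_config",
    "write_field_tiff",
    "read_field_tiff",
    "write_phenotypes",
    "read_phenotypes",
    "cells_to_frame",
    "colonies_to_frame",
    "write_dilution_csv",
    "read_dilution_csv",
    "provenance_record",
]

DEFAULT_CHANNEL_MAP = {"nuclear": 0, "stemness": 1, "fibroblast": 2}
# stain aliases accepted in configs
_CHANNEL_ALIASES = {"hoechst": "nuclear", "nanog": "stemness", "cd90": "fibroblast"}


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration (exit code 2)."""


class DataError(ValueError):
    """Missing or corrupt input data (exit code 3)."""


@dataclass
class RunConfig:
    """Run configuration shared by the CLI commands."""

    channel_map: dict[str, int] = dc_field(default_factory=lambda: dict(DEFAULT_CHANNEL_MAP))
    scoring: ScoringParams = dc_field(default_factory=ScoringParams)
    seed: int = 0
    verbosity: int = 1
    raw: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(DEFAULT_CHANNEL_MAP) - set(self.channel_map)
        if missing:
            raise ConfigError(f"channel map lacks channels: {sorted(missing)}")


def load_config(path: str | Path | None) -> RunConfig:
    """Load a YAML/JSON config; a missing path gives the defaults."""
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    cm = dict(DEFAULT_CHANNEL_MAP)
    for key, idx in (raw.get("channel_map") or {}).items():
        name = _CHANNEL_ALIASES.get(key.lower(), key.lower())
        if name not in DEFAULT_CHANNEL_MAP:
            raise ConfigError(f"unknown channel '{key}'")
        cm[name] = int(idx)
    try:
        scoring = ScoringParams(**(raw.get("scoring") or {}))
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"bad scoring parameters: {exc}") from exc
    return RunConfig(
        channel_map=cm,
        scoring=scoring,
        seed=int(raw.get("seed", 0)),
        verbosity=int(raw.get("verbosity", 1)),
        raw=raw,
    )


def write_field_tiff(path: str | Path, field: FieldImage,
                     channel_map: dict[str, int] | None = None) -> None:
    """Write one field as a 16-bit multi-page TIFF (one page per channel)."""
    channel_map = channel_map or DEFAULT_CHANNEL_MAP
    order = sorted(channel_map, key=channel_map.get)
    pages = np.stack([
        np.clip(np.asarray(getattr(field, name)), 0, 65535).astype(np.uint16)
        for name in order
    ])
    meta = {
        "channel_order": order,
        "pixel_size_um": field.pixel_size_um,
        "field_index": field.field_index,
    }
    tifffile.imwrite(path, pages, photometric="minisblack",
                     description=json.dumps(meta))


def read_field_tiff(
    path: str | Path,
    channel_map: dict[str, int] | None = None,
    pixel_size_um: float | None = None,
    field_index: int | None = None,
) -> FieldImage:
    """Read a multi-page TIFF back into a FieldImage.

    The pixel size and field index fall back to the JSON metadata written
    by :func:`write_field_tiff`; a channel index outside the available
    pages raises :class:`DataError`.
    """
    channel_map = channel_map or DEFAULT_CHANNEL_MAP
    try:
        with tifffile.TiffFile(path) as tif:
            pages = tif.asarray()
            desc = tif.pages[0].description
    except Exception as exc:  # unreadable/corrupt file
        raise DataError(f"cannot read TIFF {path}: {exc}") from exc
    if pages.ndim == 2:
        pages = pages[None]
    meta = {}
    if desc:
        try:
            meta = json.loads(desc)
        except (TypeError, json.JSONDecodeError):
            meta = {}
    if pixel_size_um is None:
        pixel_size_um = float(meta.get("pixel_size_um", 1.0))
    if field_index is None:
        field_index = int(meta.get("field_index", 0))
    channels = {}
    for name, idx in channel_map.items():
        if idx >= len(pages):
            raise DataError(
                f"{path}: channel '{name}' mapped to page {idx} but file has "
                f"{len(pages)} page(s)"
            )
        channels[name] = pages[idx].astype(np.float64)
    return FieldImage(
        channels["nuclear"], channels["stemness"], channels["fibroblast"],
        pixel_size_um=pixel_size_um, field_index=field_index,
    )


def write_phenotypes(path: str | Path, rows: list[tuple[str, WellPhenotype]]) -> None:
    df = pd.DataFrame([{"well": w, **p.as_dict()} for w, p in rows])
    df.to_csv(path, index=False)


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"well", *WellPhenotype.PARAMETERS} - set(df.columns)
    if missing:
        raise DataError(f"phenotype table lacks columns: {sorted(missing)}")
    return df


def cells_to_frame(cells: list[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "cell_id": c.cell_id, "x": c.centroid_x, "y": c.centroid_y,
            "area_px": c.area_px, "equivalent_width_px": c.equivalent_width_px,
            "mean_nuclear": c.mean_nuclear, "mean_stemness": c.mean_stemness,
            "mean_fibroblast": c.mean_fibroblast,
            "nanog_pos": c.nanog_pos, "cd90_pos": c.cd90_pos,
        }
        for c in cells
    ])


def colonies_to_frame(colonies: list[ColonyRecord]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "colony_id": c.colony_id, "x": c.centroid_x, "y": c.centroid_y,
            "area_um2": c.area_um2, "form_factor": c.form_factor,
            "nanog_pos_count": c.nanog_pos_count,
            "nanog_neg_count": c.nanog_neg_count,
            "stemness_intensity_sd": c.stemness_intensity_sd,
            "members": ";".join(str(i) for i in c.member_cell_ids),
        }
        for c in colonies
    ])


def write_dilution_csv(path: str | Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)


def read_dilution_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"dose", "tested", "responding"} - set(df.columns)
    if missing:
        raise DataError(f"dilution table lacks columns: {sorted(missing)}")
    return df


def provenance_record(config: RunConfig, seed: int, extra: dict | None = None) -> dict:
    """Machine-readable record sufficient to reproduce deterministic stages."""
    from . import __version__

    cfg_text = json.dumps(
        {"channel_map": config.channel_map, "scoring": asdict(config.scoring),
         "raw": config.raw},
        sort_keys=True, default=str,
    )
    return {
        "config_sha256": hashlib.sha256(cfg_text.encode()).hexdigest(),
        "seed": seed,
        "nichescreen_version": __version__,
        "python": sys.version.split()[0],
        "platform": platform.platform(),
        "numpy": np.__version__,
        **(extra or {}),
    }
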