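"""Tooth-measurement CSV reading, run-configuration loading, and reports.

The tooth CSV schema has one row per measured tooth:

    site, specimen_id, tooth_position, crown_height_mm

Only anterior positions (A1, A2, a1, a2) enter the analysis by default; a
``column_map`` option adapts externally deposited files whose headers differ.
Run configurations are YAML/JSON documents with blocks ``sites``,
``demography``, ``dispersal``, ``growth``, ``allometry``, ``grid`` and
``shedding``; omitted blocks and fields fall back to the package defaults, and
printed per-second demographic rates may be given as ``r_per_sec`` /
``mu_per_sec`` (converted to day^-1 at load, and echoed in the log).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .allometry import AllometryParams
from .environment import GrowthParams, SiteEnvironment
from .simulate import (
    SECONDS_PER_DAY,
    DemographyParams,
    DispersalParams,
    RunConfig,
    SheddingModel,
    SimGrid,
)

__all__ = [
    "ANTERIOR_SET",
    "REQUIRED_COLUMNS",
    "SchemaError",
    "ToothMeasurementSet",
    "read_tooth_csv",
    "load_config",
    "write_config",
]

logger = logging.getLogger("dentdist.io")

ANTERIOR_SET = frozenset({"A1", "A2", "a1", "a2"})
REQUIRED_COLUMNS = ("site", "specimen_id", "tooth_position", "crown_height_mm")
MAX_CROWN_MM = 100.0


class SchemaError(ValueError):
    """Input file does not match the documented schema."""


@dataclass
class ToothMeasurementSet:
    """Validated per-tooth records for one locality, plus a filter report."""

    site: str
    records: pd.DataFrame  # columns: specimen_id, tooth_position, crown_height_mm
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def crown_heights(self) -> np.ndarray:
        return self.records["crown_height_mm"].to_numpy(dtype=float)

    def to_distribution(self):
        from .shapes import DentalDistribution

        return DentalDistribution(values=self.crown_heights, site_label=self.site)


def read_tooth_csv(path, anterior_only: bool = True,
                   column_map: dict[str, str] | None = None) -> ToothMeasurementSet:
    """Read and validate a tooth-measurement CSV.

    ``column_map`` maps external header names onto the documented schema,
    e.g. ``{"locality": "site"}``.  Rows with non-anterior positions (when
    ``anterior_only``) or invalid heights are dropped; every drop is counted
    in the returned ``provenance`` filter report so that
    input n = kept + dropped.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    n_input = len(df)
    report: dict = {"source": str(path), "n_input": n_input,
                    "dropped_non_anterior": 0, "dropped_bad_height": 0,
                    "bad_rows": [], "duplicates": 0}

    heights = pd.to_numeric(df["crown_height_mm"], errors="coerce")
    bad = heights.isna() | (heights <= 0) | (heights >= MAX_CROWN_MM)
    if bad.any():
        report["dropped_bad_height"] = int(bad.sum())
        report["bad_rows"] = [
            {"row": int(i), "crown_height_mm": df["crown_height_mm"].iloc[i]}
            for i in np.nonzero(bad.to_numpy())[0]
        ]
        logger.warning("%s: dropped %d row(s) with invalid crown height",
                       path, bad.sum())
    df = df.loc[~bad].assign(crown_height_mm=heights[~bad])

    if anterior_only:
        anterior = df["tooth_position"].isin(ANTERIOR_SET)
        report["dropped_non_anterior"] = int((~anterior).sum())
        df = df.loc[anterior]

    dup = df.duplicated(subset=["specimen_id", "tooth_position"])
    report["duplicates"] = int(dup.sum())  # re-measurements are kept, counted

    report["n_kept"] = len(df)
    sites = df["site"].unique()
    site = str(sites[0]) if len(sites) == 1 else ",".join(map(str, sites))
    records = df[["specimen_id", "tooth_position", "crown_height_mm"]].reset_index(drop=True)
    return ToothMeasurementSet(site=site, records=records, provenance=report)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

def _build(cls, block: dict, rename: dict[str, str] | None = None):
    """Instantiate a params dataclass from a config block, keeping defaults."""
    block = dict(block or {})
    if rename:
        for old, new in rename.items():
            if old in block:
                block[new] = block.pop(old)
    names = {f.name for f in dc_fields(cls)}
    unknown = set(block) - names
    if unknown:
        raise SchemaError(f"{cls.__name__}: unknown field(s) {sorted(unknown)}")
    coerced = {}
    for k, v in block.items():
        coerced[k] = tuple(v) if isinstance(v, list) else v
    return cls(**coerced)


def load_config(path) -> RunConfig:
    """Load and validate a YAML/JSON run configuration.

    All dataclass invariants are enforced at construction; violations raise
    with the offending field named.  Printed per-second rates are converted
    to day^-1 here.
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}

    demo_block = dict(doc.get("demography") or {})
    for sec_key, day_key in (("r_per_sec", "r"), ("mu_per_sec", "mu")):
        if sec_key in demo_block:
            per_day = float(demo_block.pop(sec_key)) * SECONDS_PER_DAY
            demo_block[day_key] = per_day
            logger.info("converted %s to %s = %.6g day^-1", sec_key, day_key, per_day)

    growth = _build(GrowthParams, doc.get("growth"))

    sites = doc.get("sites") or {}
    defaults = RunConfig()
    site_j = (_build(SiteEnvironment, sites.get("juvenile"))
              if sites.get("juvenile") else defaults.site_juvenile)
    site_a = (_build(SiteEnvironment, sites.get("adult"))
              if sites.get("adult") else defaults.site_adult)

    grid_block = dict(doc.get("grid") or {})
    if "mass_bin_edges" in grid_block:
        grid = _build(SimGrid, grid_block)
    else:
        grid = SimGrid.log_spaced(growth, **grid_block)

    cfg = RunConfig(
        site_juvenile=site_j,
        site_adult=site_a,
        demography=_build(DemographyParams, demo_block),
        dispersal=_build(DispersalParams, doc.get("dispersal")),
        growth=growth,
        allometry=_build(AllometryParams, doc.get("allometry")),
        grid=grid,
        shedding=_build(SheddingModel, doc.get("shedding")),
        initial_abundance=float(doc.get("initial_abundance", defaults.initial_abundance)),
    )
    logger.info("loaded config %s (hash %s)", path, cfg.config_hash())
    return cfg


def write_config(cfg: RunConfig, path) -> Path:
    """Serialise a run configuration to YAML (round-trips via load_config)."""
    path = Path(path)
    doc = cfg.as_dict()
    doc["sites"] = {"juvenile": doc.pop("site_juvenile"),
                    "adult": doc.pop("site_adult")}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
    return path


def write_json(obj: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)
    return path


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
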