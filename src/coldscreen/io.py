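"""Reading and writing panels, configs and result tables.

Panel CSV dialect: header ``genotype,trial,replicate,treatment,trait,value``
(name-based, any column order), UTF-8, decimal point, one observation per
row, treatment in {control, cold} (case normalized with a warning).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .panel import PANEL_COLUMNS, TREATMENTS, PanelConfig, validate_panel

log = logging.getLogger(__name__)

__all__ = ["read_panel", "write_panel", "load_config", "config_to_dict", "write_matrices_json"]


class PanelParseError(ValueError):
    pass


def read_panel(path) -> pd.DataFrame:
    """Read and validate a long-format panel CSV.

    Accepts any column order (name-based), normalizes treatment case, and
    raises ``PanelParseError`` with line numbers for malformed headers,
    non-numeric values or duplicate observation keys.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise PanelParseError(f"{path}: malformed header, missing columns {missing}")
    df = df[PANEL_COLUMNS].copy()

    value = pd.to_numeric(df["value"], errors="coerce")
    bad = value.isna() & df["value"].notna()
    if bad.any():
        lines = (np.flatnonzero(bad) + 2)[:5].tolist()  # +2: header + 1-based
        raise PanelParseError(f"{path}: non-numeric value at line(s) {lines}")
    if value.isna().any():
        lines = (np.flatnonzero(value.isna()) + 2)[:5].tolist()
        raise PanelParseError(f"{path}: empty value at line(s) {lines}")
    df["value"] = value
    df["replicate"] = pd.to_numeric(df["replicate"], errors="coerce")
    if df["replicate"].isna().any():
        lines = (np.flatnonzero(df["replicate"].isna()) + 2)[:5].tolist()
        raise PanelParseError(f"{path}: non-numeric replicate at line(s) {lines}")
    df["replicate"] = df["replicate"].astype(int)

    norm = df["treatment"].str.strip().str.lower()
    changed = norm != df["treatment"]
    if changed.any():
        log.warning("%s: %d treatment labels normalized to lower case",
                    path, int(changed.sum()))
    df["treatment"] = norm
    unknown = set(df["treatment"].unique()) - set(TREATMENTS)
    if unknown:
        raise PanelParseError(f"{path}: unknown treatment labels {sorted(unknown)}")

    key_cols = ["genotype", "trial", "replicate", "treatment", "trait"]
    dup = df.duplicated(subset=key_cols, keep=False)
    if dup.any():
        lines = (np.flatnonzero(df.duplicated(subset=key_cols)) + 2)[:5].tolist()
        raise PanelParseError(f"{path}: duplicate observation keys at line(s) {lines}")
    validate_panel(df)
    return df


def write_panel(panel: pd.DataFrame, path) -> None:
    panel[PANEL_COLUMNS].to_csv(path, index=False)


def load_config(path) -> PanelConfig:
    """Load a PanelConfig from YAML or JSON; keys mirror the dataclass fields."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a mapping")
    if "traits" in data:
        data["traits"] = tuple(data["traits"])
    if "bounds" in data and data["bounds"] is not None:
        data["bounds"] = {t: tuple(None if v is None else float(v) for v in pair)
                          for t, pair in data["bounds"].items()}
    return PanelConfig(**data)


def config_to_dict(config: PanelConfig) -> dict:
    return {
        "n_genotypes": config.n_genotypes,
        "n_trials": config.n_trials,
        "n_replicates": config.n_replicates,
        "traits": list(config.traits),
        "control_means": dict(config.control_means),
        "cold_shift": dict(config.cold_shift),
        "G_cov": np.asarray(config.G_cov).tolist(),
        "E_cov": np.asarray(config.E_cov).tolist(),
        "trial_sd": config.trial_sd,
        "control_attenuation": config.control_attenuation,
        "control_noise_scale": config.control_noise_scale,
        "seed": config.seed,
        "bounds": {t: list(v) for t, v in config.bounds.items()},
        "round_li": config.round_li,
    }


def write_matrices_json(M, path) -> None:
    payload = {
        "traits": list(M.traits),
        "P": np.asarray(M.P).tolist(),
        "G": np.asarray(M.G).tolist(),
        "r": int(M.r),
        "condition_number": float(M.condition_number),
        "ill_conditioned": bool(M.ill_conditioned),
    }
    Path(path).write_text(json.dumps(payload, indent=2))
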