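"""File I/O helpers: tidy tables, NIfTI volumes, YAML/JSON config, provenance."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml


def load_config(path) -> dict:
    """Read a YAML or JSON configuration file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text) or {}


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_provenance(path, config: dict, seed: int) -> None:
    """Sidecar metadata: config hash, seed, package version."""
    from gaitbrain import __version__

    meta = {"config_hash": config_hash(config), "seed": int(seed), "version": __version__}
    Path(path).write_text(json.dumps(meta, indent=2) + "\n")


def write_steps_csv(steps: pd.DataFrame, path) -> None:
    steps.to_csv(path, index=False)


def read_steps_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_covariates_tsv(covariates: pd.DataFrame, path) -> None:
    covariates.to_csv(path, sep="\t", index=False)


def read_covariates_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_nifti(vol: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float64), affine), str(path))


def save_mask_nifti(mask: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine
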