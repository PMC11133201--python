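"""File I/O: covariance CSVs, model specs (YAML/JSON), registries, reports.

Covariance dialect: comma-separated, one header row of indicator labels,
full symmetric numeric body, '.' decimal.  Mild asymmetry (below 1e-8) is
symmetrized by averaging; anything larger is an error.  A sidecar file
``<name>.meta.json`` may carry ``{"n": ...}``; an explicit ``n`` argument
wins.

Model spec schema (YAML or JSON)::

    latents: [xi1, xi2, eta]
    blocks: {xi1: [x11, x12, x13], ...}
    loadings: {x11: 1.0, ...}
    error_variances: {x11: 1.0, ...}
    structural: [{from: xi1, to: eta, coef: 0.25}, ...]
    exo_cov: [[1.0, -0.667], [-0.667, 1.0]]
    disturbance_variances: {eta: 1.0}

Registry JSON: a list of ``{cov_csv, n, model_yaml, label}`` entries.
JSON outputs carry a provenance header (package version, config hash,
seed) so seeded runs are byte-reproducible.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .model import CovarianceInput, PopulationModel

__all__ = ["read_cov_csv", "write_cov_csv", "parse_model_config",
           "write_model_config", "read_registry", "provenance", "dump_json"]


def read_cov_csv(path, n: int | None = None) -> CovarianceInput:
    """Read a labelled symmetric covariance matrix from CSV."""
    path = Path(path)
    df = pd.read_csv(path, header=0, float_precision="round_trip")
    labels = [str(c) for c in df.columns]
    if any(lab.replace(".", "", 1).replace("-", "", 1).isdigit() for lab in labels):
        raise ValueError(f"{path}: first row must be a header of indicator "
                         "labels, found numeric values")
    try:
        m = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in covariance body") from exc
    if m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: body is {m.shape[0]}x{m.shape[1]}, "
                         "expected a square matrix")
    asym = float(np.max(np.abs(m - m.T), initial=0.0))
    if asym >= 1e-8:
        raise ValueError(f"{path}: matrix asymmetric by {asym:.3g} (>= 1e-8)")
    if n is None:
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        if not sidecar.exists():
            sidecar = path.parent / (path.name + ".meta.json")
        if sidecar.exists():
            n = json.loads(sidecar.read_text()).get("n")
    return CovarianceInput((m + m.T) / 2.0, n, labels)


def write_cov_csv(path, cov: CovarianceInput) -> None:
    df = pd.DataFrame(cov.matrix, columns=list(cov.labels))
    df.to_csv(path, index=False, float_format="%.17g")
    if cov.n is not None:
        meta = Path(str(path) + ".meta.json")
        meta.write_text(json.dumps({"n": cov.n}) + "\n")


def parse_model_config(path) -> PopulationModel:
    """Parse and validate a model specification file (YAML or JSON)."""
    path = Path(path)
    try:
        doc = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ValueError(f"{path}: malformed YAML/JSON ({exc})") from exc
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: top level must be a mapping")
    required = ["latents", "blocks", "loadings", "error_variances",
                "structural", "exo_cov", "disturbance_variances"]
    missing = [k for k in required if k not in doc]
    if missing:
        raise ValueError(f"{path}: missing keys {missing}")
    structural = []
    for i, edge in enumerate(doc["structural"]):
        try:
            structural.append((edge["from"], edge["to"], float(edge["coef"])))
        except (KeyError, TypeError) as exc:
            raise ValueError(f"{path}: structural edge #{i} needs keys "
                             "'from', 'to', 'coef'") from exc
    try:
        return PopulationModel(
            latent_names=doc["latents"], blocks=doc["blocks"],
            loadings=doc["loadings"], error_variances=doc["error_variances"],
            structural=tuple(structural), exo_cov=np.array(doc["exo_cov"]),
            disturbance_variances=doc["disturbance_variances"])
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_model_config(path, model: PopulationModel) -> None:
    doc = {
        "latents": list(model.latent_names),
        "blocks": {k: list(v) for k, v in model.blocks.items()},
        "loadings": dict(model.loadings),
        "error_variances": dict(model.error_variances),
        "structural": [{"from": s, "to": d, "coef": c}
                       for s, d, c in model.structural],
        "exo_cov": model.exo_cov.tolist(),
        "disturbance_variances": dict(model.disturbance_variances),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_registry(path):
    """Read a registry JSON into (label, CovarianceInput, PopulationModel)."""
    path = Path(path)
    entries = json.loads(path.read_text())
    if not isinstance(entries, list):
        raise ValueError(f"{path}: registry must be a JSON list")
    out = []
    for e in entries:
        cov = read_cov_csv(path.parent / e["cov_csv"], n=e.get("n"))
        model = parse_model_config(path.parent / e["model_yaml"])
        out.append((e.get("label", e["cov_csv"]), cov, model))
    return out


def provenance(config: dict, seed: int | None = None) -> dict:
    """Provenance header for output files: version, config hash, seed."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return {"package": "compositebias", "version": __version__,
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "seed": seed, "schema": 1}


def dump_json(path, payload: dict) -> None:
    """Deterministic JSON writer (sorted keys, fixed float formatting)."""
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=2,
                                     default=float) + "\n")
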