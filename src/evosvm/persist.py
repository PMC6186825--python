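"""Self-describing JSON persistence for fitted ensembles.

The container records the resolved config, master seed, per-member feature
indices, subject splits, weights and the explicit decision-function state
(support vectors, dual coefficients, intercept).  Because members predict
from exactly these arrays, and JSON round-trips Python floats exactly, a
loaded ensemble reproduces the fitted one's predictions bit for bit.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .ensemble import BaseClassifier, WeightedEnsemble
from .exceptions import PersistenceError

__all__ = ["save_ensemble", "load_ensemble", "FORMAT_VERSION"]

FORMAT_VERSION = 1


def _member_to_dict(member: BaseClassifier) -> dict:
    return {
        "feature_subset": [int(j) for j in member.feature_subset],
        "train_indices": [int(i) for i in member.train_indices],
        "validation_indices": [int(i) for i in member.validation_indices],
        "sigma": float(member.sigma),
        "C": float(member.C),
        "weight": float(member.weight),
        "support_vectors": [[float(v) for v in row] for row in member.support_vectors],
        "dual_coef": [float(v) for v in member.dual_coef],
        "intercept": float(member.intercept),
        "classes": [int(c) for c in member.classes],
    }


def _member_from_dict(d: dict, index: int) -> BaseClassifier:
    try:
        member = BaseClassifier(
            feature_subset=np.asarray(d["feature_subset"], dtype=int),
            train_indices=np.asarray(d["train_indices"], dtype=int),
            validation_indices=np.asarray(d["validation_indices"], dtype=int),
            sigma=float(d["sigma"]),
            C=float(d["C"]),
        )
        member.weight = float(d["weight"])
        member.support_vectors = np.asarray(d["support_vectors"], dtype=float)
        member.dual_coef = np.asarray(d["dual_coef"], dtype=float)
        member.intercept = float(d["intercept"])
        member.classes = np.asarray(d["classes"], dtype=int)
    except (KeyError, TypeError, ValueError) as exc:
        raise PersistenceError(
            f"member {index}: missing or malformed field ({exc})"
        ) from exc
    return member


def save_ensemble(
    ensemble: WeightedEnsemble,
    path,
    *,
    config: dict | None = None,
    seed: int | None = None,
    scaler: tuple[np.ndarray, np.ndarray] | None = None,
    metadata: dict | None = None,
) -> None:
    """Write the fitted ensemble (plus provenance) as versioned JSON."""
    doc = {
        "format": "evosvm-ensemble",
        "version": FORMAT_VERSION,
        "region_count": int(ensemble.region_count),
        "evolution_index": int(ensemble.evolution_index),
        "feature_pool": [int(j) for j in ensemble.feature_pool],
        "config": config,
        "seed": None if seed is None else int(seed),
        "scaler": None
        if scaler is None
        else {
            "mean": [float(v) for v in scaler[0]],
            "scale": [float(v) for v in scaler[1]],
        },
        "metadata": metadata or {},
        "members": [_member_to_dict(m) for m in ensemble.members],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def load_ensemble(path) -> tuple[WeightedEnsemble, dict]:
    """Load an ensemble written by :func:`save_ensemble`.

    Returns ``(ensemble, container)`` where ``container`` holds config,
    seed, scaler and metadata exactly as stored.
    """
    path = Path(path)
    if not path.exists():
        raise PersistenceError(f"ensemble file not found: {path}")
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise PersistenceError(f"{path}: not valid JSON ({exc})") from exc
    if doc.get("format") != "evosvm-ensemble":
        raise PersistenceError(
            f"{path}: field 'format' is {doc.get('format')!r}, "
            "expected 'evosvm-ensemble'"
        )
    if doc.get("version") != FORMAT_VERSION:
        raise PersistenceError(
            f"{path}: field 'version' is {doc.get('version')!r}, this build "
            f"reads version {FORMAT_VERSION}"
        )
    for key in ("region_count", "feature_pool", "members"):
        if key not in doc:
            raise PersistenceError(f"{path}: missing field {key!r}")
    members = [_member_from_dict(m, i) for i, m in enumerate(doc["members"])]
    ensemble = WeightedEnsemble(
        members=members,
        feature_pool=np.asarray(doc["feature_pool"], dtype=int),
        region_count=int(doc["region_count"]),
        evolution_index=int(doc.get("evolution_index", 0)),
    )
    if doc.get("scaler") is not None:
        doc["scaler"] = (
            np.asarray(doc["scaler"]["mean"], dtype=float),
            np.asarray(doc["scaler"]["scale"], dtype=float),
        )
    return ensemble, doc
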