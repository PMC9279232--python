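"""JSON persistence for fitted models.

The artifact records everything needed to re-apply a fitted model to new
z-scored visits: the event grid, subtype sequences and mixture fractions,
noise scales, MCMC sequence samples if drawn (positional variance diagrams
are derived from them), hyperparameters, the random seed and the software
version.  Serialization is canonical (sorted keys, fixed separators) so
write -> read -> write is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import __version__
from .sustain import EventGrid, SuStaInModel

FORMAT_VERSION = 1


class ArtifactError(ValueError):
    pass


def model_to_dict(model: SuStaInModel) -> dict:
    d = {
        "format_version": FORMAT_VERSION,
        "software_version": __version__,
        "grid": {
            "biomarkers": list(model.grid.biomarkers),
            "levels": [list(lv) for lv in model.grid.levels],
            "z_max": list(model.grid.z_max),
        },
        "n_subtypes": model.n_subtypes,
        "sequences": [np.asarray(s).tolist() for s in model.sequences],
        "fractions": model.fractions.tolist(),
        "sigma": model.sigma.tolist(),
        "log_likelihood": model.log_likelihood,
        "seed": model.seed,
        "hyperparameters": model.hyperparameters,
    }
    if model.mcmc_samples is not None:
        d["mcmc_samples"] = [np.asarray(s).tolist() for s in model.mcmc_samples]
    return d


def write_model(model: SuStaInModel, path) -> None:
    payload = json.dumps(model_to_dict(model), sort_keys=True, separators=(",", ":"), allow_nan=False)
    Path(path).write_text(payload + "\n", encoding="utf-8")


def read_model(path) -> SuStaInModel:
    try:
        d = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise ArtifactError(f"cannot parse model artifact {path}: {exc}") from exc
    if not isinstance(d, dict) or "format_version" not in d:
        raise ArtifactError(f"{path} is not a model artifact")
    if d["format_version"] != FORMAT_VERSION:
        raise ArtifactError(
            f"artifact format version {d['format_version']} != supported {FORMAT_VERSION}"
        )
    grid = EventGrid(
        tuple(d["grid"]["biomarkers"]),
        tuple(tuple(lv) for lv in d["grid"]["levels"]),
        tuple(d["grid"]["z_max"]),
    )
    return SuStaInModel(
        grid=grid,
        sequences=[np.asarray(s, dtype=int) for s in d["sequences"]],
        fractions=np.asarray(d["fractions"], dtype=float),
        sigma=np.asarray(d["sigma"], dtype=float),
        log_likelihood=float(d["log_likelihood"]),
        seed=d.get("seed"),
        hyperparameters=d.get("hyperparameters", {}),
        mcmc_samples=[np.asarray(s, dtype=int) for s in d["mcmc_samples"]] if "mcmc_samples" in d else None,
    )


def roundtrip_bytes(model: SuStaInModel) -> bytes:
    """Canonical byte representation (for round-trip identity checks)."""
    return (json.dumps(model_to_dict(model), sort_keys=True, separators=(",", ":")) + "\n").encode()
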