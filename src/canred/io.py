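"""Model-file round-tripping and the bundled three-gene example.

Models are stored as plain JSON (schema ``canred-model-v1``): a ``formalism``
tag ("gma" | "ssystem" | "normalized_ssystem" | "glv"), the variable names,
and the defining matrices as nested row-major arrays.  Numbers are written
as JSON numbers; Python's shortest-round-trip float representation makes
write -> read bit-identical.  Unknown top-level fields are preserved in the
model's ``metadata`` and written back on export.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from .models import (
    GLVModel,
    ModelError,
    NormalizedSSystem,
    PowerLawModel,
    SSystem,
)

__all__ = ["SCHEMA_VERSION", "read_model", "write_model", "make_toy_model",
           "model_hash", "matrix_to_csv", "matrix_from_csv"]

SCHEMA_VERSION = "canred-model-v1"

_FIELDS = {
    "gma": ("N", "gamma", "F"),
    "ssystem": ("alpha", "beta", "G", "H"),
    "normalized_ssystem": ("f", "G", "H"),
    "glv": ("lambda", "A", "B"),
}
_KNOWN_KEYS = {"schema", "formalism", "variables", "metadata"} | {
    k for fields in _FIELDS.values() for k in fields
} | {"steady_state_raw"}


def _get(doc: dict, key: str) -> np.ndarray:
    if key not in doc:
        raise ModelError(f"missing field at /{key}")
    try:
        arr = np.asarray(doc[key], dtype=float)
    except (TypeError, ValueError) as exc:
        raise ModelError(f"field /{key} is not a numeric array: {exc}") from None
    if not np.all(np.isfinite(arr)):
        raise ModelError(f"field /{key} contains non-finite values")
    return arr


def read_model(path):
    """Load a model from a ``canred-model-v1`` JSON file."""
    path = Path(path)
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("schema") != SCHEMA_VERSION:
        raise ModelError(
            f"/schema: expected {SCHEMA_VERSION!r}, got {doc.get('schema')!r}"
        )
    formalism = doc.get("formalism")
    if formalism not in _FIELDS:
        raise ModelError(f"/formalism: unknown formalism {formalism!r}")
    names = doc.get("variables")
    metadata = dict(doc.get("metadata", {}))
    extra = {k: doc[k] for k in doc if k not in _KNOWN_KEYS}
    if extra:
        metadata["_extra"] = extra
    try:
        if formalism == "gma":
            model = PowerLawModel(_get(doc, "N"), _get(doc, "gamma"),
                                  _get(doc, "F"), names)
        elif formalism == "ssystem":
            model = SSystem(_get(doc, "alpha"), _get(doc, "beta"),
                            _get(doc, "G"), _get(doc, "H"), names)
        elif formalism == "normalized_ssystem":
            ss = doc.get("steady_state_raw")
            model = NormalizedSSystem(_get(doc, "f"), _get(doc, "G"),
                                      _get(doc, "H"),
                                      steady_state_raw=None if ss is None
                                      else np.asarray(ss, float),
                                      var_names=names)
        else:
            model = GLVModel(_get(doc, "lambda"), _get(doc, "A"),
                             _get(doc, "B"), names)
    except ModelError as exc:
        raise ModelError(f"{path.name}: {exc}") from None
    model.metadata.update(metadata)
    return model


def _doc_for(model) -> dict:
    if isinstance(model, PowerLawModel):
        body = {"formalism": "gma", "N": model.N, "gamma": model.gamma, "F": model.F}
    elif isinstance(model, NormalizedSSystem):
        body = {"formalism": "normalized_ssystem", "f": model.f,
                "G": model.G, "H": model.H,
                "steady_state_raw": model.steady_state_raw}
    elif isinstance(model, SSystem):
        body = {"formalism": "ssystem", "alpha": model.alpha, "beta": model.beta,
                "G": model.G, "H": model.H}
    elif isinstance(model, GLVModel):
        body = {"formalism": "glv", "lambda": model.lam, "A": model.A, "B": model.B}
    else:
        raise ModelError(f"cannot serialize {type(model).__name__}")
    doc = {"schema": SCHEMA_VERSION, "formalism": body.pop("formalism"),
           "variables": list(model.var_names)}
    doc.update({k: np.asarray(v).tolist() for k, v in body.items()})
    meta = dict(model.metadata)
    extra = meta.pop("_extra", {})
    if meta:
        doc["metadata"] = meta
    doc.update(extra)
    return doc


def write_model(model, path) -> None:
    """Write a model as ``canred-model-v1`` JSON."""
    doc = _doc_for(model)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def model_hash(model) -> str:
    """Stable short hash of the serialized model (for logging)."""
    payload = json.dumps(_doc_for(model), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def matrix_to_csv(matrix, path, var_names=None) -> None:
    """Write a single matrix as CSV with a header row of variable names."""
    import pandas as pd

    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    cols = var_names or [f"x{i}" for i in range(1, matrix.shape[1] + 1)]
    pd.DataFrame(matrix, columns=cols).to_csv(path, index=False)


def matrix_from_csv(path) -> tuple[np.ndarray, list[str]]:
    """Read a matrix written by :func:`matrix_to_csv`; returns (matrix, names)."""
    import pandas as pd

    df = pd.read_csv(path)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def make_toy_model() -> SSystem:
    """The bundled three-gene regulatory network.

    Gene 1 induces itself (kinetic order 1.1) and is inhibited by gene 3
    (order 0.48); gene 1 induces gene 2 (order 0.3) and gene 2 induces
    gene 3 (order 0.7).  All rate constants are 1, degradation is first
    order, and the steady state is x = (1, 1, 1).
    """
    G = np.array([
        [1.1, 0.0, -0.48],
        [0.3, 0.0, 0.0],
        [0.0, 0.7, 0.0],
    ])
    H = np.eye(3)
    model = SSystem(np.ones(3), np.ones(3), G, H, ["x1", "x2", "x3"])
    model.metadata["name"] = "three-gene toy network"
    return model
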