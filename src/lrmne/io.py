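"""Serialization of datasets, models, and subspaces.

Datasets travel as HDF5 (datasets ``stimuli`` and ``responses``) or as
a pair of delimited text files for small fixtures.  Models are stored
as a JSON header (scalars, shapes, signs, regularization) next to an
``.npz`` with the weight arrays.  Subspaces go to HDF5.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .models import LowRankFactors, MNEModel, StimulusResponseSet
from .subspace import Subspace


def save_dataset_h5(path, data: StimulusResponseSet, attrs=None):
    with h5py.File(path, "w") as f:
        f.create_dataset("stimuli", data=data.stimuli, dtype="float64")
        f.create_dataset("responses", data=data.responses, dtype="float64")
        for key, val in (attrs or {}).items():
            f.attrs[key] = val


def load_dataset_h5(path) -> StimulusResponseSet:
    with h5py.File(path, "r") as f:
        return StimulusResponseSet(f["stimuli"][...], f["responses"][...])


def save_dataset_text(prefix, data: StimulusResponseSet):
    """Two delimited text files: <prefix>_stimuli.tsv, <prefix>_responses.tsv."""
    prefix = str(prefix)
    np.savetxt(prefix + "_stimuli.tsv", data.stimuli, delimiter="\t")
    np.savetxt(prefix + "_responses.tsv", data.responses, delimiter="\t")


def load_dataset_text(prefix) -> StimulusResponseSet:
    prefix = str(prefix)
    return StimulusResponseSet(
        np.loadtxt(prefix + "_stimuli.tsv", delimiter="\t", ndmin=2),
        np.loadtxt(prefix + "_responses.tsv", delimiter="\t"),
    )


def save_model(path, model: MNEModel, factors: LowRankFactors | None = None):
    """JSON header + npz arrays; ``path`` is the .json path."""
    path = Path(path)
    header = {
        "a": model.a,
        "D": model.dim,
        "has_J": model.J is not None,
        "factored": factors is not None,
    }
    arrays = {"h": model.h}
    if factors is not None:
        header["r"] = factors.rank
        header["signs"] = factors.signs.tolist()
        header["reg_params"] = factors.reg_params.tolist()
        arrays["U"] = factors.U
        arrays["V"] = factors.V
    elif model.J is not None:
        arrays["J"] = model.J
    path.write_text(json.dumps(header, indent=1))
    np.savez(path.with_suffix(".npz"), **arrays)


def load_model(path):
    """Returns ``(model, factors-or-None)``."""
    path = Path(path)
    header = json.loads(path.read_text())
    arrays = np.load(path.with_suffix(".npz"))
    factors = None
    if header["factored"]:
        factors = LowRankFactors(
            arrays["U"],
            arrays["V"],
            np.asarray(header["signs"]),
            np.asarray(header["reg_params"]),
        )
        J = factors.U @ factors.V.T
    elif header["has_J"]:
        J = arrays["J"]
    else:
        J = None
    return MNEModel(header["a"], arrays["h"], J), factors


def save_subspace_h5(path, sub: Subspace):
    with h5py.File(path, "w") as f:
        f.create_dataset("basis", data=sub.basis, dtype="float64")
        f.create_dataset("eigenvalues", data=sub.eigenvalues, dtype="float64")


def load_subspace_h5(path) -> Subspace:
    with h5py.File(path, "r") as f:
        return Subspace(f["basis"][...], f["eigenvalues"][...])


def write_json_report(path, report: dict):
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"not serializable: {type(o)}")

    Path(path).write_text(json.dumps(report, indent=1, default=_default))
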