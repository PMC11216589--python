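"""HDF5 / TSV persistence for activations, responses and score tables."""

from __future__ import annotations

import h5py
import numpy as np

from .features import ReferenceProjection
from .synthetic import ActivationSet, NeuralSessionData

__all__ = [
    "write_activations",
    "read_activations",
    "write_sessions",
    "read_sessions",
    "write_basis",
    "read_basis",
]

_STR = h5py.string_dtype(encoding="utf-8")


def write_activations(path, acts: dict[str, ActivationSet]) -> None:
    """Layout: /layers/<name>/activations, /stimuli/ids, /stimuli/domain."""
    first = next(iter(acts.values()))
    with h5py.File(path, "w") as f:
        f.create_dataset("stimuli/ids", data=np.asarray(first.stimulus_ids, dtype=_STR))
        f.create_dataset("stimuli/domain", data=np.asarray(first.domains, dtype=_STR))
        for name, a in acts.items():
            f.create_dataset(f"layers/{name}/activations", data=a.X, dtype="float64")
        f.attrs["layer_order"] = list(acts)


def read_activations(path) -> dict[str, ActivationSet]:
    with h5py.File(path, "r") as f:
        ids = f["stimuli/ids"].asstr()[:]
        domains = f["stimuli/domain"].asstr()[:]
        order = list(f.attrs["layer_order"])
        return {
            name: ActivationSet(name, ids.copy(), domains.copy(), f[f"layers/{name}/activations"][:])
            for name in order
        }


def write_sessions(path, sessions: dict[str, NeuralSessionData]) -> None:
    """One group per domain holding /responses [rep x stim x site] and ids."""
    with h5py.File(path, "w") as f:
        for domain, sess in sessions.items():
            g = f.create_group(domain)
            g.create_dataset("responses", data=sess.responses, dtype="float64")
            g.create_dataset("stimuli/ids", data=np.asarray(sess.stimulus_ids, dtype=_STR))
            g.create_dataset("sites/ids", data=np.asarray(sess.site_ids, dtype=_STR))
            g.attrs["animal"] = sess.animal
            g.attrs["session"] = sess.session


def read_sessions(path) -> dict[str, NeuralSessionData]:
    out = {}
    with h5py.File(path, "r") as f:
        for domain in f:
            g = f[domain]
            out[domain] = NeuralSessionData(
                animal=g.attrs["animal"],
                session=g.attrs["session"],
                site_ids=list(g["sites/ids"].asstr()[:]),
                stimulus_ids=g["stimuli/ids"].asstr()[:],
                domain=domain,
                responses=g["responses"][:],
            )
    return out


def write_basis(path, bases: dict[str, ReferenceProjection]) -> None:
    with h5py.File(path, "w") as f:
        for name, b in bases.items():
            g = f.create_group(f"basis/{name}")
            g.create_dataset("means", data=b.unit_means)
            g.create_dataset("components", data=b.components)
            g.create_dataset("explained_variance", data=b.explained_variance)


def read_basis(path) -> dict[str, ReferenceProjection]:
    out = {}
    with h5py.File(path, "r") as f:
        for name in f["basis"]:
            g = f[f"basis/{name}"]
            out[name] = ReferenceProjection(
                layer=name,
                unit_means=g["means"][:],
                components=g["components"][:],
                explained_variance=g["explained_variance"][:],
            )
    return out
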