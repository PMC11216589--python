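"""Reference-set principal-component basis for layer activations.

High-dimensional layer activations are reduced with PCA before regression.
The basis is fitted once on a *reference* activation set (emulating random
natural images distinct from the experimental stimuli) and then reused for
every stimulus set, so all analyses of a layer share a single coordinate
system.  A no-projection bypass is available at the pipeline level for
checking that the reduction itself does not drive the results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .synthetic import ActivationSet

__all__ = ["ReferenceProjection", "fit_reference_basis", "project"]

DEFAULT_MAX_COMPONENTS = 500


class DegenerateReferenceError(ValueError):
    """Raised when the reference activations carry no variance at all."""


@dataclass
class ReferenceProjection:
    layer: str
    unit_means: np.ndarray  # (n_units,)
    components: np.ndarray  # (n_units, k), columnwise orthonormal
    explained_variance: np.ndarray  # (k,), nonincreasing

    @property
    def k(self) -> int:
        return self.components.shape[1]


def fit_reference_basis(
    reference: ActivationSet, k: int | None = None
) -> ReferenceProjection:
    """Fit a PCA basis on centered reference activations.

    ``k`` defaults to min(n_reference - 1, n_units, 500); values exceeding
    the attainable rank are truncated with a warning.  Centering only — no
    variance scaling.  Component signs are fixed by forcing the
    largest-magnitude loading of each component positive.
    """
    X = reference.X
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 reference stimuli")
    if np.allclose(X.std(axis=0), 0.0):
        raise DegenerateReferenceError(
            f"reference activations for layer {reference.layer!r} are constant"
        )
    k_max = min(n - 1, p)
    if k is None:
        k_eff = min(k_max, DEFAULT_MAX_COMPONENTS)
    else:
        if k < 1:
            raise ValueError("k must be >= 1")
        k_eff = min(k, k_max)
        if k_eff < k:
            warnings.warn(
                f"requested k={k} exceeds attainable rank {k_max}; truncating",
                stacklevel=2,
            )
    pca = PCA(n_components=k_eff, svd_solver="full")
    pca.fit(X)
    components = pca.components_.T.copy()  # (p, k)
    signs = np.sign(components[np.abs(components).argmax(axis=0), np.arange(k_eff)])
    signs[signs == 0] = 1.0
    components *= signs
    return ReferenceProjection(
        layer=reference.layer,
        unit_means=pca.mean_.copy(),
        components=components,
        explained_variance=pca.explained_variance_.copy(),
    )


def project(activations: ActivationSet, basis: ReferenceProjection) -> ActivationSet:
    """Project activations into the reference basis: (X - means) @ components."""
    if activations.n_units != basis.components.shape[0]:
        raise ValueError(
            f"activation width {activations.n_units} does not match basis "
            f"width {basis.components.shape[0]}"
        )
    Xp = (activations.X - basis.unit_means) @ basis.components
    return ActivationSet(
        activations.layer, activations.stimulus_ids, activations.domains, Xp
    )
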