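"""Synthetic stimulus sets, feature hierarchies and trial-structured neural responses.

Everything downstream of this module (basis fitting, cross-validated PLS
scoring, reliability and ensemble analyses) operates on the containers
defined here.  The generator emulates the structure of a visual
electrophysiology experiment: stimuli from two domains (an in-distribution,
"naturalistic"-like domain used for fitting, and an out-of-distribution
domain used for generalization testing), a multi-layer nonlinear feature
hierarchy standing in for a pretrained network, and neuronal sites whose
mean responses are noisy linear readouts of one hidden layer.  Because the
generating layer, readout weights and noise scale are returned as explicit
ground truth, parameter-recovery and gap analyses can be tested exactly.

Two independent out-of-distribution mechanisms are provided:

* a *latent distribution shift* (mean offset and/or covariance scaling of
  the OOD latents) — covariate shift with a correct model;
* a *readout change* (weight perturbation, or generation from a different
  layer altogether) — model misspecification, which is what produces an
  asymmetric transfer between domains.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DomainShift",
    "StimulusSet",
    "FeatureHierarchy",
    "ActivationSet",
    "TruthConfig",
    "SyntheticGroundTruth",
    "NeuralSessionData",
    "generate_stimuli",
    "generate_hierarchy",
    "compute_activations",
    "generate_sessions",
    "noise_sd_for_reliability",
]

ID_DOMAIN = "ID"
OOD_DOMAIN = "OOD"

_NONLINEARITIES = {
    "relu": lambda z: np.maximum(z, 0.0),
    "tanh": np.tanh,
    "identity": lambda z: z,
}


@dataclass(frozen=True)
class DomainShift:
    """Latent-distribution change of the OOD domain relative to ID.

    ID latents are standard multivariate normal; OOD latents are
    ``N(offset, cov_scale * I)``.  ``cov_scale`` < 1 makes the OOD domain
    *narrower* than ID (the regime in which regression models fitted on
    OOD extrapolate poorly to ID).
    """

    offset: np.ndarray | float = 0.0
    cov_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.cov_scale <= 0:
            raise ValueError(f"cov_scale must be positive, got {self.cov_scale}")

    def offset_vector(self, d_z: int) -> np.ndarray:
        off = np.asarray(self.offset, dtype=float)
        if off.ndim == 0:
            return np.full(d_z, float(off))
        if off.shape != (d_z,):
            raise ValueError(f"offset has shape {off.shape}, expected ({d_z},)")
        return off


@dataclass
class StimulusSet:
    """Stimuli identified by string ids, each with a domain label and a latent vector."""

    stimulus_ids: np.ndarray  # (n,) str
    domains: np.ndarray  # (n,) str, each ID_DOMAIN or OOD_DOMAIN
    latents: np.ndarray  # (n, d_z) float

    def __post_init__(self) -> None:
        self.stimulus_ids = np.asarray(self.stimulus_ids, dtype=object)
        self.domains = np.asarray(self.domains, dtype=object)
        self.latents = np.asarray(self.latents, dtype=float)
        if len(set(self.stimulus_ids)) != len(self.stimulus_ids):
            raise ValueError("stimulus ids must be unique")
        if not set(self.domains) <= {ID_DOMAIN, OOD_DOMAIN}:
            raise ValueError("domains must be 'ID' or 'OOD'")
        if self.latents.ndim != 2 or self.latents.shape[0] != len(self.stimulus_ids):
            raise ValueError("latents must be (n_stimuli, d_z)")

    @property
    def n(self) -> int:
        return len(self.stimulus_ids)

    @property
    def d_z(self) -> int:
        return self.latents.shape[1]

    def mask(self, domain: str) -> np.ndarray:
        return self.domains == domain

    def subset(self, domain: str) -> "StimulusSet":
        m = self.mask(domain)
        return StimulusSet(self.stimulus_ids[m], self.domains[m], self.latents[m])


@dataclass
class ActivationSet:
    """Unit activations of one layer: a stimuli x units matrix with id/domain labels."""

    layer: str
    stimulus_ids: np.ndarray
    domains: np.ndarray
    X: np.ndarray  # (n_stimuli, n_units)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.stimulus_ids):
            raise ValueError("activation matrix must be (n_stimuli, n_units)")

    @property
    def n_units(self) -> int:
        return self.X.shape[1]

    def subset(self, domain: str) -> "ActivationSet":
        m = np.asarray(self.domains) == domain
        return ActivationSet(
            self.layer,
            np.asarray(self.stimulus_ids)[m],
            np.asarray(self.domains)[m],
            self.X[m],
        )


@dataclass
class FeatureHierarchy:
    """Deterministic multi-layer nonlinear feature map.

    Layer ``l`` computes ``f(A_l @ h_{l-1} + b_l)`` where ``h_0`` is the
    latent vector and ``f`` is a fixed elementwise nonlinearity.  The
    mixing matrices are standardized at construction so every unit's
    pre-activation has approximately zero mean and unit variance on
    standard-normal latents, keeping post-activation variances well inside
    [0.1, 10] for all supported nonlinearities.
    """

    layer_names: list[str]
    weights: list[np.ndarray]  # A_l, (units_l, units_{l-1})
    biases: list[np.ndarray]  # b_l, (units_l,)
    nonlinearity: str
    d_z: int

    def __post_init__(self) -> None:
        if not self.layer_names:
            raise ValueError("hierarchy must have at least one layer")
        if self.nonlinearity not in _NONLINEARITIES:
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")

    @property
    def units_per_layer(self) -> list[int]:
        return [w.shape[0] for w in self.weights]

    def layer_index(self, name: str) -> int:
        try:
            return self.layer_names.index(name)
        except ValueError:
            raise KeyError(f"layer {name!r} not in hierarchy {self.layer_names}") from None

    def forward(self, latents: np.ndarray) -> list[np.ndarray]:
        """Activations of every layer for a (n, d_z) latent matrix."""
        latents = np.asarray(latents, dtype=float)
        if latents.ndim != 2 or latents.shape[1] != self.d_z:
            raise ValueError(
                f"latents have dimension {latents.shape[1:]}, hierarchy expects d_z={self.d_z}"
            )
        f = _NONLINEARITIES[self.nonlinearity]
        out = []
        h = latents
        for A, b in zip(self.weights, self.biases):
            h = f(h @ A.T + b)
            out.append(h)
        return out


def generate_stimuli(
    n_id: int,
    n_ood: int,
    d_z: int,
    shift: DomainShift | None = None,
    seed: int = 0,
) -> StimulusSet:
    """Draw a two-domain stimulus set.

    ID latents come from a standard multivariate normal; OOD latents from
    the shifted/scaled normal described by ``shift``.  Deterministic given
    the seed.
    """
    if n_id < 2 or n_ood < 2:
        raise ValueError("need at least 2 stimuli per domain")
    shift = shift or DomainShift()
    rng = np.random.default_rng(seed)
    z_id = rng.standard_normal((n_id, d_z))
    z_ood = shift.offset_vector(d_z) + np.sqrt(shift.cov_scale) * rng.standard_normal(
        (n_ood, d_z)
    )
    ids = np.array(
        [f"id_{i:04d}" for i in range(n_id)] + [f"ood_{i:04d}" for i in range(n_ood)],
        dtype=object,
    )
    domains = np.array([ID_DOMAIN] * n_id + [OOD_DOMAIN] * n_ood, dtype=object)
    return StimulusSet(ids, domains, np.vstack([z_id, z_ood]))


def generate_hierarchy(
    d_z: int,
    units_per_layer: list[int],
    nonlinearity: str = "relu",
    seed: int = 0,
) -> FeatureHierarchy:
    """Construct a random feature hierarchy with calibrated activation scale.

    Raw mixing matrices are Gaussian; a calibration pass on seeded
    standard-normal latents folds an empirical standardization of each
    unit's pre-activation into (A_l, b_l), so the transform remains a pure
    deterministic function of the stored parameters.
    """
    if not units_per_layer:
        raise ValueError("units_per_layer must be nonempty")
    if any(u < 1 for u in units_per_layer):
        raise ValueError("all layer widths must be >= 1")
    rng = np.random.default_rng(seed)
    n_calib = 2000
    h = rng.standard_normal((n_calib, d_z))
    f = _NONLINEARITIES.get(nonlinearity)
    if f is None:
        raise ValueError(f"unknown nonlinearity {nonlinearity!r}")
    weights, biases = [], []
    fan_in = d_z
    for width in units_per_layer:
        A = rng.standard_normal((width, fan_in)) / np.sqrt(fan_in)
        b = 0.1 * rng.standard_normal(width)
        z = h @ A.T + b
        mu, sd = z.mean(axis=0), z.std(axis=0)
        sd = np.where(sd < 1e-12, 1.0, sd)
        A = A / sd[:, None]
        b = (b - mu) / sd
        weights.append(A)
        biases.append(b)
        h = f(h @ A.T + b)
        fan_in = width
    names = [f"layer{i + 1}" for i in range(len(units_per_layer))]
    return FeatureHierarchy(names, weights, biases, nonlinearity, d_z)


def compute_activations(
    hierarchy: FeatureHierarchy, stimuli: StimulusSet
) -> dict[str, ActivationSet]:
    """Per-layer activation matrices for a stimulus set, in stimulus order."""
    acts = hierarchy.forward(stimuli.latents)
    return {
        name: ActivationSet(name, stimuli.stimulus_ids, stimuli.domains, X)
        for name, X in zip(hierarchy.layer_names, acts)
    }


def noise_sd_for_reliability(
    target: float, n_reps: int, signal_sd: float = 1.0
) -> float:
    """Trial-noise SD that yields a target Spearman-Brown corrected reliability.

    Split-half reliability of trial-averaged responses with ``n`` repetitions,
    signal variance s^2 and trial-noise variance sigma^2 has expected
    half-half correlation c = s^2 / (s^2 + 2 sigma^2 / n) and corrected value
    2c/(1+c); this inverts that closed form.
    """
    if not 0 < target < 1:
        raise ValueError("target reliability must be in (0, 1)")
    c = target / (2.0 - target)
    return float(signal_sd * np.sqrt(n_reps * (1.0 / c - 1.0) / 2.0))


@dataclass
class TruthConfig:
    """How site ground truth is drawn.

    ``true_layers`` may be an explicit per-site list of layer names or
    ``None`` (sites spread evenly across layers).  Weights are sparse
    Gaussian and rescaled so the signal SD of ``w . h(s)`` over the ID
    stimuli is ``signal_sd``, which makes ``noise_sd`` directly comparable
    to the reliability closed form.  ``baseline`` is added to every mean
    response to keep firing rates positive despite rectification.
    """

    true_layers: list[str] | None = None
    weight_sparsity: float = 0.5  # fraction of zero weights
    signal_sd: float = 1.0
    noise_sd: float | np.ndarray = 1.0
    baseline: float = 5.0
    ood_readout_perturbation: float = 0.0
    ood_layer_override: str | list[str | None] | None = None
    ood_override_mix: float = 1.0  # weight of the override-layer component

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight_sparsity < 1.0:
            raise ValueError("weight_sparsity must be in [0, 1)")
        if np.any(np.asarray(self.noise_sd) < 0):
            raise ValueError("noise_sd must be nonnegative")
        if self.ood_readout_perturbation < 0:
            raise ValueError("ood_readout_perturbation must be nonnegative")
        if not 0.0 <= self.ood_override_mix <= 1.0:
            raise ValueError("ood_override_mix must be in [0, 1]")


@dataclass
class SyntheticGroundTruth:
    """Per-site generating parameters returned alongside simulated sessions."""

    site_ids: list[str]
    true_layer: list[str]
    readout_weights: list[np.ndarray]
    noise_sd: np.ndarray
    baseline: np.ndarray
    ood_readout_perturbation: float
    ood_layer_override: list[str | None]
    ood_weights: list[np.ndarray | None] = field(default_factory=list)
    ood_override_mix: float = 1.0

    def to_json(self, path) -> None:
        obj = {
            "site_ids": self.site_ids,
            "true_layer": self.true_layer,
            "readout_weights": [w.tolist() for w in self.readout_weights],
            "noise_sd": self.noise_sd.tolist(),
            "baseline": self.baseline.tolist(),
            "ood_readout_perturbation": self.ood_readout_perturbation,
            "ood_layer_override": self.ood_layer_override,
            "ood_weights": [None if w is None else w.tolist() for w in self.ood_weights],
            "ood_override_mix": self.ood_override_mix,
        }
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "SyntheticGroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            site_ids=obj["site_ids"],
            true_layer=obj["true_layer"],
            readout_weights=[np.asarray(w) for w in obj["readout_weights"]],
            noise_sd=np.asarray(obj["noise_sd"]),
            baseline=np.asarray(obj["baseline"]),
            ood_readout_perturbation=obj["ood_readout_perturbation"],
            ood_layer_override=obj["ood_layer_override"],
            ood_weights=[None if w is None else np.asarray(w) for w in obj["ood_weights"]],
            ood_override_mix=obj.get("ood_override_mix", 1.0),
        )


@dataclass
class NeuralSessionData:
    """Trial-level responses of one session: a repetition x stimulus x site tensor."""

    animal: str
    session: str
    site_ids: list[str]
    stimulus_ids: np.ndarray
    domain: str
    responses: np.ndarray  # (n_rep, n_stim, n_site), nonnegative

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 3:
            raise ValueError("responses must be (rep, stimulus, site)")
        if self.responses.shape[1] != len(self.stimulus_ids):
            raise ValueError("stimulus axis does not match stimulus_ids")
        if self.responses.shape[2] != len(self.site_ids):
            raise ValueError("site axis does not match site_ids")
        if len(set(self.site_ids)) != len(self.site_ids):
            raise ValueError("site ids must be unique within a session")

    @property
    def n_repetitions(self) -> int:
        return self.responses.shape[0]

    def trial_mean(self) -> np.ndarray:
        """Across-repetition mean response, (n_stim, n_site)."""
        return self.responses.mean(axis=0)

    def site_matrix(self, site_id: str) -> np.ndarray:
        """Repetition x stimulus matrix for one site."""
        return self.responses[:, :, self.site_ids.index(site_id)]


def _draw_weights(rng: np.random.Generator, width: int, sparsity: float) -> np.ndarray:
    w = rng.standard_normal(width)
    if sparsity > 0:
        n_zero = int(round(sparsity * width))
        n_zero = min(n_zero, width - 1)  # keep at least one active unit
        zero_idx = rng.choice(width, size=n_zero, replace=False)
        w[zero_idx] = 0.0
    return w


def _normalize_signal(w: np.ndarray, H: np.ndarray, signal_sd: float) -> np.ndarray:
    sd = (H @ w).std()
    if sd < 1e-12:
        raise ValueError("degenerate readout: zero signal variance on ID stimuli")
    return w * (signal_sd / sd)


def generate_sessions(
    hierarchy: FeatureHierarchy,
    stimuli: StimulusSet,
    n_sites: int,
    truth: TruthConfig | None = None,
    rep_range: tuple[int, int] = (31, 51),
    seed: int = 0,
    animal: str = "A",
    session: str = "S1",
) -> tuple[dict[str, NeuralSessionData], SyntheticGroundTruth]:
    """Simulate trial-structured responses for both stimulus domains.

    Each site's mean response to stimulus s is ``w . h_L(s) + baseline``
    where L is the site's true layer; for OOD stimuli the configured
    perturbation or layer override replaces the readout.  Trials are the
    mean plus independent Gaussian noise, rectified at zero.  The
    repetition count is drawn once per domain, uniformly in ``rep_range``.
    """
    truth = truth or TruthConfig()
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    lo, hi = rep_range
    if not (2 <= lo <= hi <= 200):
        raise ValueError("rep_range must lie within [2, 200]")
    rng = np.random.default_rng(seed)

    layers = truth.true_layers
    if layers is None:
        layers = [
            hierarchy.layer_names[i * len(hierarchy.layer_names) // n_sites]
            for i in range(n_sites)
        ]
    if len(layers) != n_sites:
        raise ValueError("true_layers must have one entry per site")
    for name in layers:
        hierarchy.layer_index(name)  # raises KeyError if absent

    override = truth.ood_layer_override
    if override is None or isinstance(override, str):
        override = [override] * n_sites
    for name in override:
        if name is not None:
            hierarchy.layer_index(name)

    acts = compute_activations(hierarchy, stimuli)
    id_mask = stimuli.mask(ID_DOMAIN)
    noise_sd = np.broadcast_to(np.asarray(truth.noise_sd, dtype=float), (n_sites,)).copy()
    site_ids = [f"{animal}-{session}-site{j:03d}" for j in range(n_sites)]

    weights: list[np.ndarray] = []
    ood_weights: list[np.ndarray | None] = []
    mean_id = np.empty((int(id_mask.sum()), n_sites))
    mean_ood = np.empty((int((~id_mask).sum()), n_sites))
    for j in range(n_sites):
        H = acts[layers[j]].X
        w = _normalize_signal(
            _draw_weights(rng, H.shape[1], truth.weight_sparsity), H[id_mask], truth.signal_sd
        )
        weights.append(w)

        mean_id[:, j] = H[id_mask] @ w + truth.baseline
        if override[j] is not None:
            H_over = acts[override[j]].X
            v = _normalize_signal(
                _draw_weights(rng, H_over.shape[1], truth.weight_sparsity),
                H_over[id_mask],
                truth.signal_sd,
            )
            mix = truth.ood_override_mix
            signal = (1.0 - mix) * (H @ w) + mix * (H_over @ v)
            sd = signal[id_mask].std()
            if sd < 1e-12:
                raise ValueError("degenerate mixed OOD readout")
            signal *= truth.signal_sd / sd
            mean_ood[:, j] = signal[~id_mask] + truth.baseline
            ood_weights.append(v)
        elif truth.ood_readout_perturbation > 0:
            delta = rng.standard_normal(len(w))
            delta *= np.linalg.norm(w) / np.linalg.norm(delta)
            w_ood = _normalize_signal(
                w + truth.ood_readout_perturbation * delta, H[id_mask], truth.signal_sd
            )
            mean_ood[:, j] = H[~id_mask] @ w_ood + truth.baseline
            ood_weights.append(w_ood)
        else:
            mean_ood[:, j] = H[~id_mask] @ w + truth.baseline
            ood_weights.append(None)

    sessions: dict[str, NeuralSessionData] = {}
    for domain, means, mask in (
        (ID_DOMAIN, mean_id, id_mask),
        (OOD_DOMAIN, mean_ood, ~id_mask),
    ):
        n_rep = int(rng.integers(lo, hi + 1))
        trials = means[None, :, :] + noise_sd[None, None, :] * rng.standard_normal(
            (n_rep, means.shape[0], n_sites)
        )
        np.maximum(trials, 0.0, out=trials)
        sessions[domain] = NeuralSessionData(
            animal=animal,
            session=session,
            site_ids=site_ids,
            stimulus_ids=stimuli.stimulus_ids[mask],
            domain=domain,
            responses=trials,
        )

    gt = SyntheticGroundTruth(
        site_ids=site_ids,
        true_layer=list(layers),
        readout_weights=weights,
        noise_sd=noise_sd,
        baseline=np.full(n_sites, float(truth.baseline)),
        ood_readout_perturbation=float(truth.ood_readout_perturbation),
        ood_layer_override=list(override),
        ood_weights=ood_weights,
        ood_override_mix=float(truth.ood_override_mix),
    )
    if truth.baseline < 5 * np.max(noise_sd, initial=0.0):
        warnings.warn(
            "baseline below 5x noise SD: rectification may distort responses",
            stacklevel=2,
        )
    return sessions, gt
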