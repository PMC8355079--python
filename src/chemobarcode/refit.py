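"""Signature refitting: reconstruct a catalogue as known-signature activity.

``fit_exposures`` expresses a sample's normalized SBS96 profile as a convex
combination of a fixed signature set (non-negative least squares on the
simplex), iteratively dropping signatures whose weight falls below a floor
— the convention of the deconstructSigs family of refitting tools, which
suppresses "signature bleeding" of tiny spurious activities.
``assign_mutations_ml`` then attributes each individual mutation to the
signature maximizing activity x channel probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .catalog import MutationRecord, SBS96Catalogue, classify_sbs96
from .signatures import SignatureProfile, SignatureSet, cosine_similarity

#: Weight of the sum-to-one constraint row in the augmented NNLS system.
_SIMPLEX_PENALTY = 100.0


@dataclass
class ExposureVector:
    """Per-signature activities (mutation counts) for one sample."""

    sample_id: str
    activities: dict[str, float]
    residual: float  # cosine of reconstructed vs observed profile
    total_mutations: float = 0.0

    def activity(self, name: str) -> float:
        return self.activities.get(name, 0.0)

    def as_array(self, names: list[str]) -> np.ndarray:
        return np.array([self.activities.get(n, 0.0) for n in names])


def _simplex_nnls(signature_matrix: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Non-negative weights approximately on the simplex minimizing ||Sw - p||."""
    k = signature_matrix.shape[1]
    augmented = np.vstack([signature_matrix, np.full((1, k), _SIMPLEX_PENALTY)])
    rhs = np.concatenate([target, [_SIMPLEX_PENALTY]])
    weights, _ = nnls(augmented, rhs)
    total = weights.sum()
    return weights / total if total > 0 else weights


def fit_exposures(
    profile_counts: np.ndarray,
    signatures: SignatureSet,
    weight_floor: float = 0.06,
    sample_id: str = "sample",
) -> ExposureVector:
    """Least-squares convex refit of a 96-channel count vector.

    Returns activities = weight x total mutation count per signature.
    Signatures with fitted weight below ``weight_floor`` are dropped and
    the remainder refit, repeating until all surviving weights clear the
    floor. If nothing survives, an all-zero exposure is returned with a
    warning.
    """
    counts = np.asarray(profile_counts, dtype=float)
    if counts.shape != (96,):
        raise ValueError(f"expected a 96-channel count vector, got {counts.shape}")
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot refit an empty profile (zero total count)")
    target = counts / total

    names = list(signatures.names)
    matrix = signatures.matrix()
    active = list(range(len(names)))
    weights = np.zeros(len(names))
    while active:
        sub = _simplex_nnls(matrix[:, active], target)
        if sub.min() >= weight_floor or len(active) == 1:
            if len(active) == 1 and sub[0] < weight_floor:
                active = []  # even alone it cannot clear the floor
                break
            weights[:] = 0.0
            for i, w in zip(active, sub):
                weights[i] = w
            break
        # drop the weakest signature and refit the rest
        drop = active[int(np.argmin(sub))]
        active = [i for i in active if i != drop]
    if not active or weights.sum() == 0:
        warnings.warn(f"{sample_id}: no signature survives the weight floor; zero exposures")
        return ExposureVector(sample_id, {n: 0.0 for n in names}, residual=0.0,
                              total_mutations=total)

    weights = weights / weights.sum()
    reconstruction = matrix @ weights
    residual = cosine_similarity(reconstruction, target)
    activities = {n: float(w * total) for n, w in zip(names, weights)}
    return ExposureVector(sample_id, activities, residual=residual, total_mutations=total)


def fit_exposures_catalogue(
    catalogue: SBS96Catalogue, signatures: SignatureSet, weight_floor: float = 0.06
) -> list[ExposureVector]:
    """fit_exposures for every sample of a catalogue (zero rows get zero exposures)."""
    out = []
    for sample, row in zip(catalogue.sample_ids, catalogue.counts):
        if row.sum() == 0:
            out.append(ExposureVector(sample, {n: 0.0 for n in signatures.names},
                                      residual=1.0, total_mutations=0.0))
        else:
            out.append(fit_exposures(row, signatures, weight_floor, sample_id=sample))
    return out


def assign_channels_ml(
    channels: np.ndarray, exposures: ExposureVector, signatures: SignatureSet
) -> list[str]:
    """Maximum-likelihood signature label per mutation channel.

    For a mutation in channel c the label is argmax_s activity_s x P_s(c);
    ties break by signature order. If every product is zero the mutation
    is labeled ``"unassigned"`` (excluded from downstream proportions).
    """
    matrix = signatures.matrix()  # (96, k)
    act = exposures.as_array(signatures.names)  # (k,)
    scores = matrix * act[None, :]  # (96, k)
    labels = []
    for c in np.asarray(channels, dtype=int):
        row = scores[c]
        if row.max() <= 0:
            labels.append("unassigned")
        else:
            labels.append(signatures.names[int(np.argmax(row))])
    return labels


def assign_mutations_ml(
    records: list[MutationRecord],
    exposures: ExposureVector,
    signatures: SignatureSet,
    reference=None,
    channels: np.ndarray | None = None,
) -> list[str]:
    """Label each mutation record with its maximum-likelihood signature.

    Channels may be passed precomputed; otherwise a reference genome
    accessor is required to classify each record. Labels are also written
    onto ``record.signature``.
    """
    if channels is None:
        if reference is None:
            raise ValueError("need either precomputed channels or a reference genome")
        channels = np.array([classify_sbs96(r, reference) for r in records])
    labels = assign_channels_ml(channels, exposures, signatures)
    for rec, label in zip(records, labels):
        rec.signature = label
    return labels


class SignatureRefitter:
    """sklearn-style transformer: catalogue counts -> exposure matrix.

    Parameters mirror :func:`fit_exposures`. ``transform`` maps an
    (n_samples, 96) count array to (n_samples, k) activities against the
    fixed signature set.
    """

    def __init__(self, signatures: SignatureSet, weight_floor: float = 0.06):
        self.signatures = signatures
        self.weight_floor = weight_floor

    def get_params(self, deep: bool = True) -> dict:
        return {"signatures": self.signatures, "weight_floor": self.weight_floor}

    def set_params(self, **params) -> "SignatureRefitter":
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, X, y=None) -> "SignatureRefitter":
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 96:
            raise ValueError(f"X must be (n_samples, 96), got {X.shape}")
        self.n_features_in_ = 96
        self.signature_names_ = list(self.signatures.names)
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "signature_names_"):
            self.fit(X)
        X = np.asarray(X, dtype=float)
        rows = []
        for i, row in enumerate(X):
            if row.sum() == 0:
                rows.append(np.zeros(len(self.signatures)))
                continue
            ev = fit_exposures(row, self.signatures, self.weight_floor, sample_id=f"s{i}")
            rows.append(ev.as_array(self.signature_names_))
        return np.vstack(rows)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).transform(X)
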