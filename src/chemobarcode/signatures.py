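"""Mutational signature profiles: containers, similarity, derivation, fixtures.

A signature is a probability distribution over the 96 SBS channels.
Signature sets are read and written in the COSMIC wide format: a channel
label column followed by one column per signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from .catalog import CHANNELS96, SBS96Catalogue

_SUM_TOL = 1e-9


@dataclass
class SignatureProfile:
    """A named probability vector over the 96 channels."""

    name: str
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (96,):
            raise ValueError(f"profile must have 96 channels, got {self.probs.shape}")
        if (self.probs < 0).any():
            raise ValueError(f"{self.name}: negative channel probability")
        total = self.probs.sum()
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"{self.name}: probabilities sum to {total}, not 1")

    @classmethod
    def from_counts(cls, name: str, counts: np.ndarray) -> "SignatureProfile":
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total <= 0:
            raise ValueError(f"{name}: cannot normalize an all-zero vector")
        return cls(name=name, probs=counts / total)


class SignatureSet:
    """Ordered collection of uniquely named signature profiles."""

    def __init__(self, profiles: Iterable[SignatureProfile]):
        self.profiles = list(profiles)
        if not self.profiles:
            raise ValueError("a signature set needs at least one member")
        names = [p.name for p in self.profiles]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate signature names in {names}")

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.profiles]

    def __len__(self) -> int:
        return len(self.profiles)

    def __iter__(self) -> Iterator[SignatureProfile]:
        return iter(self.profiles)

    def __getitem__(self, key: int | str) -> SignatureProfile:
        if isinstance(key, str):
            for p in self.profiles:
                if p.name == key:
                    return p
            raise KeyError(key)
        return self.profiles[key]

    def matrix(self) -> np.ndarray:
        """Column-stochastic (96, k) matrix, one column per signature."""
        return np.column_stack([p.probs for p in self.profiles])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {p.name: p.probs for p in self.profiles}, index=list(CHANNELS96)
        )

    def to_tsv(self, path: str | Path) -> None:
        frame = self.to_dataframe()
        frame.index.name = "channel"
        frame.to_csv(path, sep="\t", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SignatureSet":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        if sorted(frame.index) != sorted(CHANNELS96):
            raise ValueError(f"{path}: channel labels are not the SBS96 set")
        frame = frame.reindex(list(CHANNELS96))
        return cls(
            SignatureProfile.from_counts(str(col), frame[col].to_numpy())
            for col in frame.columns
        )


def cosine_similarity(a: SignatureProfile | np.ndarray, b: SignatureProfile | np.ndarray) -> float:
    """dot(a,b)/(|a||b|); raises on a zero vector."""
    va = a.probs if isinstance(a, SignatureProfile) else np.asarray(a, dtype=float)
    vb = b.probs if isinstance(b, SignatureProfile) else np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity of a zero vector is undefined")
    return float(np.dot(va, vb) / (na * nb))


def derive_mean_signature(catalogue: SBS96Catalogue, name: str = "HSC") -> SignatureProfile:
    """Mean per-channel count across samples, normalized by the mean total.

    This is the count-space average used to derive the hematopoietic stem
    cell (HSC) signature from healthy-blood catalogues: identical to
    pooling all samples' mutations and normalizing once, so high-burden
    samples weigh proportionally more than low-burden ones.
    """
    if catalogue.n_samples == 0 or catalogue.counts.sum() == 0:
        raise ValueError("cannot derive a signature from an empty/all-zero catalogue")
    mean_counts = catalogue.counts.mean(axis=0)
    return SignatureProfile(name=name, probs=mean_counts / mean_counts.sum())


# ---------------------------------------------------------------------------
# Parametric fixture signatures
# ---------------------------------------------------------------------------
# Templates emulate the *character* of the processes the package analyses
# without shipping reference data: a platinum-adduct-like profile (C>T and
# C>A peaks with a 5' C, the SBS31 character), a 5FU-like profile (T>G
# peaks in NpTpT context, the SBS17b character) and a broad clock-like
# HSC/SBS5-like background. Profiles are Dirichlet-perturbed around the
# template so different seeds give distinct but same-shaped signatures.

def _template(weights: dict[str, float], baseline: float) -> np.ndarray:
    probs = np.full(96, baseline, dtype=float)
    for label, weight in weights.items():
        probs[CHANNELS96.index(label)] = weight
    return probs / probs.sum()


def _platinum_template() -> np.ndarray:
    weights = {
        "C[C>T]A": 0.10, "C[C>T]C": 0.14, "C[C>T]G": 0.05, "C[C>T]T": 0.12,
        "A[C>T]A": 0.03, "A[C>T]C": 0.04, "A[C>T]G": 0.02, "A[C>T]T": 0.03,
        "C[C>A]A": 0.05, "C[C>A]C": 0.06, "C[C>A]G": 0.02, "C[C>A]T": 0.05,
        "T[C>A]A": 0.02, "T[C>A]C": 0.02,
    }
    return _template(weights, baseline=0.001)


def _fivefu_template() -> np.ndarray:
    weights = {
        "A[T>G]T": 0.12, "C[T>G]T": 0.20, "G[T>G]T": 0.08, "T[T>G]T": 0.25,
        "C[T>G]C": 0.03, "A[T>A]T": 0.03, "C[T>A]T": 0.04,
    }
    return _template(weights, baseline=0.002)


def _hsc_template() -> np.ndarray:
    # Broad, clock-like: mass spread over all channels with mild
    # substitution-class tilts and a CpG>TpG bump.
    class_weight = {"C>A": 0.8, "C>G": 0.5, "C>T": 1.5, "T>A": 0.6, "T>C": 1.8, "T>G": 0.5}
    probs = np.empty(96)
    for i, label in enumerate(CHANNELS96):
        sub = label[2:5]
        w = class_weight[sub]
        if sub == "C>T" and label[6] == "G":
            w *= 1.6  # CpG context
        if sub == "T>C" and label[0] == "A":
            w *= 1.4
        probs[i] = w
    return probs / probs.sum()


_FIXTURE_TEMPLATES = {
    "platinum_like": _platinum_template,
    "fivefu_like": _fivefu_template,
    "hsc_like": _hsc_template,
}


def fixture_signatures(kind: str, seed: int = 0, concentration: float = 2000.0) -> SignatureProfile:
    """Deterministic parametric stand-in signatures for tests and simulations.

    ``flat`` is exactly uniform (1/96). The other kinds draw a Dirichlet
    sample around their template with the given concentration, so the same
    (kind, seed) always yields the same profile.
    """
    if kind == "flat":
        return SignatureProfile(name="flat", probs=np.full(96, 1.0 / 96.0))
    if kind not in _FIXTURE_TEMPLATES:
        raise ValueError(
            f"unknown fixture kind {kind!r}; expected one of "
            f"{sorted(_FIXTURE_TEMPLATES) + ['flat']}"
        )
    import zlib

    template = _FIXTURE_TEMPLATES[kind]()
    rng = np.random.default_rng([zlib.crc32(kind.encode()), seed])
    probs = rng.dirichlet(template * concentration)
    probs = np.maximum(probs, 1e-12)
    return SignatureProfile(name=kind, probs=probs / probs.sum())
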