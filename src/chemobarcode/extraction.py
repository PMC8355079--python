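"""De novo signature extraction by bootstrapped KL-NMF.

The factorization minimizes the generalized Kullback-Leibler divergence
(Poisson likelihood) between the catalogue and W @ H with multiplicative
updates, the algorithm family behind the reference signature-extraction
tools. Stability is assessed by resampling each sample's catalogue
(multinomial, totals preserved), factorizing each replicate from several
random initializations, pooling all solutions, clustering them by cosine
similarity, and reporting per-signature mean silhouette scores. Final
exposures are refit against the cluster centroids on the original,
un-resampled catalogue.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_samples

from .catalog import SBS96Catalogue
from .refit import fit_exposures
from .signatures import SignatureProfile, SignatureSet, cosine_similarity

logger = logging.getLogger(__name__)

_EPS = 1e-12


@dataclass
class ExtractionResult:
    signatures: SignatureSet
    exposures: np.ndarray  # (n_samples, k), mutation-count scale
    stability: np.ndarray  # per-signature mean silhouette, in [-1, 1]
    reconstruction_error: np.ndarray  # per-sample relative L2 error
    sample_ids: list[str]

    def exposures_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.exposures, index=self.sample_ids,
                            columns=self.signatures.names)


def _kl_divergence(V: np.ndarray, WH: np.ndarray) -> float:
    WH = np.maximum(WH, _EPS)
    mask = V > 0
    div = np.where(mask, V * np.log(np.maximum(V, _EPS) / WH), 0.0) - V + WH
    return float(div.sum())


def nmf_factorize(
    counts: np.ndarray,
    k: int,
    seed: int = 0,
    max_iter: int = 10_000,
    tol: float = 1e-8,
    track_objective: bool = False,
):
    """KL-NMF of a catalogue matrix by multiplicative updates.

    ``counts`` is the (n_samples, 96) catalogue; returns ``(W, H)`` with W
    a column-stochastic (96, k) profile matrix and H the (k, n_samples)
    exposure matrix (so counts.T ~= W @ H). Convergence when the relative
    objective change drops below ``tol`` or after ``max_iter`` updates;
    the generalized KL objective is non-increasing across iterations.
    With ``track_objective`` the per-check objective values are returned
    as a third element.
    """
    V = np.asarray(counts, dtype=float).T  # (96, n_samples)
    if V.ndim != 2 or V.shape[0] != 96:
        raise ValueError(f"counts must be (n_samples, 96), got {np.shape(counts)}")
    if (V < 0).any():
        raise ValueError("negative counts")
    if V.sum() == 0:
        raise ValueError("cannot factorize an all-zero catalogue")
    n = V.shape[1]
    if not (1 <= k <= min(96, n)):
        raise ValueError(f"k={k} outside 1..min(96, n_samples={n})")

    rng = np.random.default_rng(seed)
    scale = V.sum() / (96 * n * k)
    W = rng.uniform(0.5, 1.5, size=(96, k)) * np.sqrt(scale)
    H = rng.uniform(0.5, 1.5, size=(k, n)) * np.sqrt(scale)

    objective = _kl_divergence(V, W @ H)
    trace = [objective]
    check_every = 10
    for it in range(max_iter):
        WH = np.maximum(W @ H, _EPS)
        H *= W.T @ (V / WH) / np.maximum(W.sum(axis=0)[:, None], _EPS)
        WH = np.maximum(W @ H, _EPS)
        W *= (V / WH) @ H.T / np.maximum(H.sum(axis=1)[None, :], _EPS)
        if (it + 1) % check_every == 0 or it == max_iter - 1:
            new_objective = _kl_divergence(V, W @ H)
            trace.append(new_objective)
            if abs(objective - new_objective) <= tol * max(abs(objective), 1.0):
                objective = new_objective
                break
            objective = new_objective

    # normalize W columns to sum 1, compensate in H
    col_sums = np.maximum(W.sum(axis=0), _EPS)
    W = W / col_sums
    H = H * col_sums[:, None]
    if track_objective:
        return W, H, trace
    return W, H


def _best_of_inits(V_rows: np.ndarray, k: int, seeds: list[int], max_iter: int, tol: float):
    best = None
    for s in seeds:
        W, H = nmf_factorize(V_rows, k, seed=s, max_iter=max_iter, tol=tol)
        obj = _kl_divergence(V_rows.T.astype(float), W @ H)
        if best is None or obj < best[0]:
            best = (obj, W, H)
    return best[1], best[2]


def _bootstrap_counts(counts: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(counts)
    for i, row in enumerate(counts):
        total = int(row.sum())
        if total == 0:
            out[i] = 0
        else:
            out[i] = rng.multinomial(total, row / total)
    return out


def extract_signatures(
    catalogue: SBS96Catalogue,
    k: int,
    n_bootstraps: int = 100,
    n_inits: int = 10,
    seed: int = 0,
    max_iter: int = 10_000,
    tol: float = 1e-8,
) -> ExtractionResult:
    """Bootstrap-NMF extraction with solution clustering and stability scores.

    Every bootstrap replicate resamples each sample's counts (multinomial,
    total preserved) and keeps the best-objective factorization over
    ``n_inits`` initializations. The k signatures of every replicate are
    matched to running cluster centroids by greedy best-cosine assignment;
    centroids (renormalized member means) are the reported signatures.
    Stability is the mean cosine-distance silhouette per cluster; any
    negative value is logged as unstable but not fatal. Exposures are
    least-squares refits of the centroids on the original catalogue.
    """
    counts = catalogue.counts
    seed_seq = np.random.SeedSequence(seed)
    boot_rng = np.random.default_rng(seed_seq.spawn(1)[0])

    solutions: list[np.ndarray] = []  # each (k, 96), row-stochastic profiles
    for b in range(n_bootstraps):
        resampled = _bootstrap_counts(counts, boot_rng)
        if resampled.sum() == 0:
            raise ValueError("all-zero bootstrap catalogue")
        init_seeds = [int(s.generate_state(1)[0] % (2**31))
                      for s in np.random.SeedSequence((seed, 1, b)).spawn(n_inits)]
        W, _ = _best_of_inits(resampled, k, init_seeds, max_iter, tol)
        solutions.append(W.T)  # k rows of 96-profiles

    members, labels = _cluster_solutions(solutions, k)
    centroids = np.vstack([
        _normalize(members[labels == c].mean(axis=0)) for c in range(k)
    ])

    # order clusters by total centroid-matched exposure later; keep stable order:
    stability = _cluster_silhouette(members, labels, k)
    for c in range(k):
        if stability[c] < 0:
            logger.warning("extraction cluster %d is unstable (silhouette %.3f)", c, stability[c])

    sig_set = SignatureSet(
        SignatureProfile(name=f"extracted_{c}", probs=centroids[c]) for c in range(k)
    )
    exposures = np.zeros((catalogue.n_samples, k))
    recon_err = np.zeros(catalogue.n_samples)
    for i, row in enumerate(counts):
        total = row.sum()
        if total == 0:
            recon_err[i] = 0.0
            continue
        ev = fit_exposures(row, sig_set, weight_floor=0.0, sample_id=catalogue.sample_ids[i])
        exposures[i] = ev.as_array(sig_set.names)
        recon = sig_set.matrix() @ (exposures[i] / total)
        recon_err[i] = float(np.linalg.norm(recon - row / total) / np.linalg.norm(row / total))

    return ExtractionResult(
        signatures=sig_set,
        exposures=exposures,
        stability=stability,
        reconstruction_error=recon_err,
        sample_ids=list(catalogue.sample_ids),
    )


def _normalize(v: np.ndarray) -> np.ndarray:
    return v / max(v.sum(), _EPS)


def _cluster_solutions(solutions: list[np.ndarray], k: int):
    """Greedy best-cosine matching of each solution's signatures to running centroids."""
    centroids = solutions[0].copy()  # (k, 96)
    counts = np.ones(k)
    members = [solutions[0]]
    labels = [np.arange(k)]
    for sol in solutions[1:]:
        sims = sol @ centroids.T / (
            np.linalg.norm(sol, axis=1)[:, None] * np.linalg.norm(centroids, axis=1)[None, :]
        )
        assign = -np.ones(k, dtype=int)
        used_rows, used_cols = set(), set()
        flat = [(-sims[i, j], i, j) for i in range(k) for j in range(k)]
        for _, i, j in sorted(flat):
            if i in used_rows or j in used_cols:
                continue
            assign[i] = j
            used_rows.add(i)
            used_cols.add(j)
        for i in range(k):
            j = assign[i]
            centroids[j] = (centroids[j] * counts[j] + sol[i]) / (counts[j] + 1)
            counts[j] += 1
        members.append(sol)
        labels.append(assign)
    member_matrix = np.vstack(members)
    label_vector = np.concatenate(labels)
    return member_matrix, label_vector


def _cluster_silhouette(members: np.ndarray, labels: np.ndarray, k: int) -> np.ndarray:
    if k == 1 or len(set(labels.tolist())) < 2:
        # silhouette undefined for a single cluster; report mean cosine to centroid
        centroid = _normalize(members.mean(axis=0))
        sims = [cosine_similarity(m, centroid) for m in members]
        return np.array([float(np.mean(sims))] * k)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        samples = silhouette_samples(members, labels, metric="cosine")
    return np.array([float(samples[labels == c].mean()) for c in range(k)])


def match_to_reference(result: ExtractionResult, reference: SignatureSet) -> pd.DataFrame:
    """Best-cosine reference match per extracted signature (ties by reference order)."""
    rows = []
    for profile in result.signatures:
        sims = [cosine_similarity(profile, ref) for ref in reference]
        best = int(np.argmax(sims))  # argmax takes the first maximum: reference order
        rows.append((profile.name, reference.names[best], sims[best]))
    return pd.DataFrame(rows, columns=["extracted", "reference", "cosine"])


def rank_sweep(
    catalogue: SBS96Catalogue,
    ks: list[int],
    n_bootstraps: int = 20,
    n_inits: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Helper sweeping k: mean silhouette and mean reconstruction error per rank."""
    rows = []
    for k in ks:
        res = extract_signatures(catalogue, k, n_bootstraps=n_bootstraps,
                                 n_inits=n_inits, seed=seed)
        rows.append((k, float(res.stability.mean()), float(res.reconstruction_error.mean())))
    return pd.DataFrame(rows, columns=["k", "mean_silhouette", "mean_reconstruction_error"])


class SignatureExtractor:
    """sklearn-style estimator facade over :func:`extract_signatures`.

    ``fit(X)`` on an (n_samples, 96) count matrix sets ``components_``
    (k x 96 profiles), ``exposures_``, ``stability_`` and
    ``reconstruction_error_``; ``transform`` refits exposures of new
    catalogues against the fitted components.
    """

    def __init__(self, n_signatures: int = 2, n_bootstraps: int = 100,
                 n_inits: int = 10, random_state: int = 0):
        self.n_signatures = n_signatures
        self.n_bootstraps = n_bootstraps
        self.n_inits = n_inits
        self.random_state = random_state

    def get_params(self, deep: bool = True) -> dict:
        return {
            "n_signatures": self.n_signatures,
            "n_bootstraps": self.n_bootstraps,
            "n_inits": self.n_inits,
            "random_state": self.random_state,
        }

    def set_params(self, **params) -> "SignatureExtractor":
        for key, value in params.items():
            setattr(self, key, value)
        return self

    def fit(self, X, y=None) -> "SignatureExtractor":
        X = np.asarray(X)
        catalogue = SBS96Catalogue(
            sample_ids=[f"s{i}" for i in range(X.shape[0])], counts=X
        )
        result = extract_signatures(
            catalogue, self.n_signatures, n_bootstraps=self.n_bootstraps,
            n_inits=self.n_inits, seed=self.random_state,
        )
        self.result_ = result
        self.components_ = np.vstack([p.probs for p in result.signatures])
        self.exposures_ = result.exposures
        self.stability_ = result.stability
        self.reconstruction_error_ = result.reconstruction_error
        self.n_features_in_ = 96
        return self

    def transform(self, X) -> np.ndarray:
        from .refit import SignatureRefitter

        return SignatureRefitter(self.result_.signatures, weight_floor=0.0).fit_transform(X)

    def fit_transform(self, X, y=None) -> np.ndarray:
        return self.fit(X).exposures_
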