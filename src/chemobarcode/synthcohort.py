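"""Synthetic-data engine for the chemotherapy-barcode analyses.

Generates cohorts of SBS96 catalogues emulating the study conditions:
blood samples with tens-to-low-hundreds of mutations and an HSC-like
background; AML-like catalogues with ~1000 background mutations plus
optional injected chemotherapy-signature mutations; VAF distributions with
clonal and subclonal peaks under stated purity and copy number; and
clinical covariate tables for the detectability logistic model. The
injection machinery drives the limit-of-detection experiment: spike known
numbers of foreign-signature mutations into every sample and ask at which
level the cohort's reconstructed foreign exposure distribution separates
from baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import MutationRecord, SBS96Catalogue
from .detect import test_catalogue
from .signatures import SignatureProfile, SignatureSet, fixture_signatures


@dataclass
class CohortSpec:
    """Conditions for one synthetic cohort.

    ``burden_model`` is either an explicit list of per-sample totals
    (resampled/cycled in order) or ``("nbinom", mean, size)``. The default
    mirrors a blood cohort with a median burden of about 100 mutations.
    ``background`` is a mixture of signature profiles with weights summing
    to 1.
    """

    n_samples: int = 100
    burden_model: tuple | list = ("nbinom", 100.0, 2.0)
    background: list[tuple[SignatureProfile, float]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not self.background:
            self.background = [(fixture_signatures("hsc_like", seed=0), 1.0)]
        weights = np.array([w for _, w in self.background], dtype=float)
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValueError(f"background weights sum to {weights.sum()}, not 1")

    def mixture_probs(self) -> np.ndarray:
        probs = np.zeros(96)
        for profile, weight in self.background:
            probs += weight * profile.probs
        return probs / probs.sum()


def _draw_burdens(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    model = spec.burden_model
    if isinstance(model, (list, np.ndarray)):
        totals = np.asarray(model, dtype=int)
        reps = int(np.ceil(spec.n_samples / len(totals)))
        return np.tile(totals, reps)[: spec.n_samples]
    kind, mean, size = model
    if kind != "nbinom":
        raise ValueError(f"unknown burden model {kind!r}")
    if mean <= 0:
        raise ValueError("negative-binomial mean must be positive")
    # numpy parameterization: n = size, p = size/(size+mean)
    return rng.negative_binomial(size, size / (size + mean), size=spec.n_samples)


def generate_cohort(spec: CohortSpec) -> SBS96Catalogue:
    """Draw per-sample totals from the burden model and channels multinomially."""
    rng = np.random.default_rng(spec.seed)
    burdens = _draw_burdens(spec, rng)
    probs = spec.mixture_probs()
    counts = np.vstack([rng.multinomial(int(t), probs) for t in burdens])
    ids = [f"synth_{i:03d}" for i in range(spec.n_samples)]
    return SBS96Catalogue(sample_ids=ids, counts=counts)


def inject_signature(
    catalogue: SBS96Catalogue, foreign: SignatureProfile, k: int, seed: int = 0
) -> SBS96Catalogue:
    """Add exactly k multinomial draws from ``foreign`` to every sample's row."""
    if k < 0:
        raise ValueError("injection count must be >= 0")
    rng = np.random.default_rng(seed)
    counts = catalogue.counts.copy()
    if k > 0:
        for i in range(counts.shape[0]):
            counts[i] += rng.multinomial(k, foreign.probs)
    return SBS96Catalogue(sample_ids=list(catalogue.sample_ids), counts=counts)


def cohort_empirical_test(
    baseline_exposures,
    injected_exposures,
    n_perm: int = 1000,
    seed: int = 0,
    statistic: str = "mean",
) -> float:
    """One-tailed empirical p for injected exposures exceeding baseline.

    Statistic is stat(injected) - stat(baseline) (mean by default, median
    behind the flag); the null is built by permuting pooled group labels;
    p = (1 + #{perm >= observed}) / (n_perm + 1), so never below
    1/(n_perm+1).
    """
    a = np.asarray(baseline_exposures, dtype=float)
    b = np.asarray(injected_exposures, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both exposure lists must be non-empty")
    stat = np.mean if statistic == "mean" else np.median
    observed = stat(b) - stat(a)
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if stat(perm[a.size:]) - stat(perm[: a.size]) >= observed:
            count += 1
    return (1 + count) / (n_perm + 1)


def ks_compare(exposures_a, exposures_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value."""
    a = np.asarray(exposures_a, dtype=float)
    b = np.asarray(exposures_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class InjectionExperimentResult:
    levels: list[int]
    baseline_exposures: np.ndarray
    exposures_by_level: dict[int, np.ndarray]
    p_by_level: dict[int, float]
    smallest_significant_level: int | None
    alpha: float
    n_permutations: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "levels": list(self.levels),
            "p_by_level": {str(k): v for k, v in self.p_by_level.items()},
            "smallest_significant_level": self.smallest_significant_level,
            "alpha": self.alpha,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


DEFAULT_LEVELS = [1, 3, 5, 7, 10, 15, 20]


def detection_limit_experiment(
    spec: CohortSpec,
    foreign: SignatureProfile,
    levels: list[int] | None = None,
    background_for_fit: SignatureSet | None = None,
    n_perm: int = 1000,
    seed: int = 0,
    dispersion: float = 10.0,
    alpha: float = 0.01,
) -> InjectionExperimentResult:
    """Limit-of-detection experiment for a foreign signature.

    Generates the baseline cohort from ``spec``, runs the NB presence test
    per sample to obtain reconstructed foreign exposures, then for each
    injection level k spikes k foreign mutations into every sample,
    re-runs the test, and compares the injected exposure distribution to
    baseline with the one-tailed empirical permutation test. Reports the
    per-level p-values and the smallest level with p < alpha.
    """
    levels = sorted(levels if levels is not None else DEFAULT_LEVELS)
    if any(k < 0 for k in levels):
        raise ValueError("levels must be non-negative")
    if background_for_fit is None:
        background_for_fit = SignatureSet([p for p, _ in spec.background])

    baseline = generate_cohort(spec)
    base_results = test_catalogue(baseline, background_for_fit, foreign,
                                  dispersion=dispersion, seed=seed)
    base_exposures = np.array([r.foreign_exposure for r in base_results])

    exposures_by_level: dict[int, np.ndarray] = {}
    p_by_level: dict[int, float] = {}
    smallest = None
    for j, k in enumerate(levels):
        if k == 0:
            exposures_by_level[0] = base_exposures.copy()
            p_by_level[0] = cohort_empirical_test(
                base_exposures, base_exposures, n_perm=n_perm, seed=seed + 7919
            )
            continue
        injected = inject_signature(baseline, foreign, k, seed=seed + 101 * (j + 1))
        results = test_catalogue(injected, background_for_fit, foreign,
                                 dispersion=dispersion, seed=seed)
        exposures = np.array([r.foreign_exposure for r in results])
        exposures_by_level[k] = exposures
        p_by_level[k] = cohort_empirical_test(
            base_exposures, exposures, n_perm=n_perm, seed=seed + 7919 + j
        )
        if smallest is None and p_by_level[k] < alpha:
            smallest = k
    return InjectionExperimentResult(
        levels=levels,
        baseline_exposures=base_exposures,
        exposures_by_level=exposures_by_level,
        p_by_level=p_by_level,
        smallest_significant_level=smallest,
        alpha=alpha,
        n_permutations=n_perm,
        seed=seed,
    )


def generate_taml_cohort(
    n_samples: int,
    hsc_profile: SignatureProfile,
    noise_weight: float = 0.1,
    injected: tuple[SignatureProfile, float, float] | None = None,
    background_burden: int = 1000,
    seed: int = 0,
) -> SBS96Catalogue:
    """AML-like synthetic samples: HSC background + flat noise + injected signature.

    Each sample draws ``background_burden`` mutations from the HSC profile
    admixed with a flat profile at ``noise_weight``; if ``injected`` is
    given as (signature, mean, sd), a normal(mean, sd) draw (rounded,
    floored at 0) of additional mutations follows that signature's channel
    probabilities — the design of the synthetic treatment-related AML
    samples (e.g. 279 +- 71 5FU-like mutations).
    """
    if injected is not None and (injected[1] < 0 or injected[2] < 0):
        raise ValueError("injected mean and sd must be >= 0")
    rng = np.random.default_rng(seed)
    flat = np.full(96, 1.0 / 96.0)
    probs = (1 - noise_weight) * hsc_profile.probs + noise_weight * flat
    probs = probs / probs.sum()
    counts = np.zeros((n_samples, 96), dtype=np.int64)
    for i in range(n_samples):
        counts[i] = rng.multinomial(background_burden, probs)
        if injected is not None:
            profile, mean, sd = injected
            n_inj = max(0, int(round(rng.normal(mean, sd)))) if sd > 0 else int(round(mean))
            if n_inj > 0:
                counts[i] += rng.multinomial(n_inj, profile.probs)
    ids = [f"taml_{i:02d}" for i in range(n_samples)]
    return SBS96Catalogue(sample_ids=ids, counts=counts)


def generate_clonal_cohort(
    n_mut: int,
    clonal_fraction: float,
    purity: float,
    depth_model: int | tuple = 100,
    signature_assignment_truth: dict[str, float] | None = None,
    seed: int = 0,
    sample_id: str = "clonal_synth",
) -> list[MutationRecord]:
    """Mutation records with known clonal/subclonal and signature truth labels.

    Clonal mutations have expected VAF purity/2 (diploid, multiplicity 1);
    subclonal mutations have expected VAF purity*u/2 with the subclone
    cancer-cell fraction u drawn uniformly on (0.1, 0.6). Alt reads are
    binomial at the sampled depth. Truth labels are stored on the records'
    ``clonality`` and ``signature`` fields.
    """
    if not (0.0 <= clonal_fraction <= 1.0):
        raise ValueError("clonal_fraction must be in [0, 1]")
    if not (0.0 < purity <= 1.0):
        raise ValueError("purity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if isinstance(depth_model, tuple):
        kind, mean = depth_model
        if kind != "poisson":
            raise ValueError(f"unknown depth model {kind!r}")
        depths = np.maximum(1, rng.poisson(mean, size=n_mut))
    else:
        depths = np.full(n_mut, int(depth_model))
    sig_names, sig_weights = None, None
    if signature_assignment_truth:
        sig_names = list(signature_assignment_truth)
        sig_weights = np.array([signature_assignment_truth[n] for n in sig_names], dtype=float)
        sig_weights = sig_weights / sig_weights.sum()

    records = []
    for i in range(n_mut):
        is_clonal = rng.random() < clonal_fraction
        ccf = 1.0 if is_clonal else rng.uniform(0.1, 0.6)
        expected_vaf = purity * ccf / 2.0
        alt = rng.binomial(depths[i], expected_vaf)
        sig = sig_names[rng.choice(len(sig_names), p=sig_weights)] if sig_names else None
        records.append(
            MutationRecord(
                sample_id=sample_id, chrom="chr1", pos=1000 + 10 * i, ref="C", alt="T",
                alt_reads=int(alt), depth=int(depths[i]),
                signature=sig, clonality="clonal" if is_clonal else "subclonal",
            )
        )
    return records


def generate_clinical_table(
    n_samples: int,
    coefficients: dict[str, float] | None = None,
    tumor_types: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Clinical covariate table with a logistic detectability outcome.

    Covariates: time_treatment and time_since_end (days, exponential with
    realistic scales, standardized internally when modeling), tumor_type
    (categorical), distal (binary metastasis-site flag). ``coefficients``
    give the log-odds effects on the standardized covariates (plus
    'intercept'); the detected flag is Bernoulli under that model.
    """
    coefficients = coefficients or {
        "intercept": -0.5, "time_treatment": 0.0, "time_since_end": 1.0, "distal": 1.0,
    }
    tumor_types = tumor_types or ["breast", "colorectal", "ovary", "urinary_tract"]
    rng = np.random.default_rng(seed)
    time_treatment = rng.exponential(180, size=n_samples)
    time_since_end = rng.exponential(365, size=n_samples)
    distal = rng.integers(0, 2, size=n_samples)
    types = rng.choice(tumor_types, size=n_samples)

    def z(v):
        return (v - v.mean()) / v.std()

    logit = (
        coefficients.get("intercept", 0.0)
        + coefficients.get("time_treatment", 0.0) * z(time_treatment)
        + coefficients.get("time_since_end", 0.0) * z(time_since_end)
        + coefficients.get("distal", 0.0) * distal
    )
    for t in tumor_types:
        key = f"tumor_type[{t}]"
        if key in coefficients:
            logit = logit + coefficients[key] * (types == t)
    detected = rng.random(n_samples) < 1.0 / (1.0 + np.exp(-logit))
    return pd.DataFrame(
        {
            "sample": [f"donor_{i:04d}" for i in range(n_samples)],
            "time_treatment": time_treatment,
            "time_since_end": time_since_end,
            "tumor_type": types,
            "distal": distal.astype(int),
            "detected": detected.astype(int),
        }
    )
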