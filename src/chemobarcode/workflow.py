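"""Config-driven orchestration of the end-to-end analyses.

A single YAML config names one analysis block (detection_limit,
taml_signatures, clonality_timing or cohort_stats) plus its inputs and a
seed; every artifact written is stamped with the package version, the
seed and a hash of the config so reruns are byte-identical (timestamps
are kept out of the artifacts for that reason) and provenance is
explicit.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .catalog import SBS96Catalogue
from .clonality import classify_records, clonal_fraction, timing_summary
from .extraction import extract_signatures, match_to_reference
from .refit import fit_exposures_catalogue
from .signatures import SignatureSet, fixture_signatures
from .synthcohort import (
    CohortSpec,
    detection_limit_experiment,
    generate_clonal_cohort,
    generate_taml_cohort,
)

logger = logging.getLogger(__name__)

ANALYSES = ("detection_limit", "taml_signatures", "clonality_timing", "cohort_stats")


@dataclass
class RunConfig:
    analysis: str
    seed: int = 0
    output_dir: str = "chemobarcode_out"
    paths: dict = field(default_factory=dict)
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.analysis not in ANALYSES:
            raise ValueError(f"unknown analysis {self.analysis!r}; expected one of {ANALYSES}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        if "analysis" not in raw:
            raise ValueError(f"{path}: config is missing the required field 'analysis'")
        return cls(
            analysis=raw["analysis"],
            seed=int(raw.get("seed", 0)),
            output_dir=raw.get("output_dir", "chemobarcode_out"),
            paths=raw.get("paths", {}) or {},
            params=raw.get("params", {}) or {},
        )

    def digest(self) -> str:
        payload = json.dumps(
            {"analysis": self.analysis, "seed": self.seed,
             "paths": self.paths, "params": self.params},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _stamp(config: RunConfig) -> dict:
    return {"package_version": __version__, "seed": config.seed, "config_hash": config.digest()}


def run(config: RunConfig) -> dict:
    """Execute the configured analysis; returns the result payload.

    Artifacts (result JSON, TSVs, run log) land in ``config.output_dir``.
    A stage failure aborts with the stage name; artifacts already written
    are preserved.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = []

    def log(stage: str, message: str, start: float) -> None:
        line = f"stage={stage} seed={config.seed} elapsed={time.perf_counter() - start:.2f}s {message}"
        logger.info(line)
        log_lines.append(line)

    stage = config.analysis
    start = time.perf_counter()
    try:
        payload = dict(_stamp(config))
        if config.analysis == "detection_limit":
            payload.update(_run_detection_limit(config, out))
        elif config.analysis == "taml_signatures":
            payload.update(_run_taml_signatures(config, out))
        elif config.analysis == "clonality_timing":
            payload.update(_run_clonality_timing(config))
        elif config.analysis == "cohort_stats":
            payload.update(_run_cohort_stats(config))
        log(stage, "completed", start)
    except Exception as exc:
        log(stage, f"FAILED: {exc}", start)
        (out / "run.log").write_text("\n".join(log_lines) + "\n")
        raise RuntimeError(f"analysis stage {stage!r} failed: {exc}") from exc

    (out / "result.json").write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return payload


def _load_catalogue(config: RunConfig, key: str = "catalogue") -> SBS96Catalogue:
    if key not in config.paths:
        raise ValueError(f"config is missing the required path {key!r}")
    return SBS96Catalogue.from_tsv(config.paths[key])


def _background_set(config: RunConfig) -> SignatureSet:
    if "signatures" in config.paths:
        return SignatureSet.from_tsv(config.paths["signatures"])
    return SignatureSet([fixture_signatures("hsc_like", seed=0)])


def _run_detection_limit(config: RunConfig, out: Path) -> dict:
    p = config.params
    spec = CohortSpec(
        n_samples=int(p.get("n_samples", 100)),
        burden_model=("nbinom", float(p.get("burden_mean", 100.0)), float(p.get("burden_size", 2.0))),
        seed=config.seed,
    )
    foreign = fixture_signatures(p.get("foreign", "platinum_like"), seed=0)
    result = detection_limit_experiment(
        spec,
        foreign,
        levels=[int(k) for k in p.get("levels", [1, 3, 5, 7, 10, 15, 20])],
        background_for_fit=_background_set(config),
        n_perm=int(p.get("n_perm", 1000)),
        seed=config.seed,
        dispersion=float(p.get("dispersion", 10.0)),
        alpha=float(p.get("alpha", 0.01)),
    )
    rows = ["level\texposure"]
    for level, exposures in result.exposures_by_level.items():
        rows.extend(f"{level}\t{e:.6g}" for e in exposures)
    (out / "exposures_by_level.tsv").write_text("\n".join(rows) + "\n")
    return {"detection_limit": result.to_dict()}


def _run_taml_signatures(config: RunConfig, out: Path) -> dict:
    p = config.params
    hsc = fixture_signatures("hsc_like", seed=0)
    injected_sig = fixture_signatures(p.get("injected", "fivefu_like"), seed=0)
    taml = generate_taml_cohort(
        n_samples=int(p.get("n_taml", 3)),
        hsc_profile=hsc,
        noise_weight=float(p.get("noise_weight", 0.1)),
        injected=(injected_sig, float(p.get("injected_mean", 279.0)), float(p.get("injected_sd", 71.0))),
        background_burden=int(p.get("background_burden", 1000)),
        seed=config.seed,
    )
    background_spec = CohortSpec(
        n_samples=int(p.get("n_background", 29)),
        burden_model=("nbinom", float(p.get("burden_mean", 1000.0)), 5.0),
        seed=config.seed + 1,
    )
    from .synthcohort import generate_cohort

    pooled_counts = np.vstack([generate_cohort(background_spec).counts, taml.counts])
    pooled = SBS96Catalogue(
        sample_ids=[f"aml_{i:02d}" for i in range(background_spec.n_samples)] + taml.sample_ids,
        counts=pooled_counts,
    )
    result = extract_signatures(
        pooled, k=int(p.get("k", 2)),
        n_bootstraps=int(p.get("n_bootstraps", 30)),
        n_inits=int(p.get("n_inits", 5)), seed=config.seed,
    )
    reference = SignatureSet([hsc, injected_sig])
    matches = match_to_reference(result, reference)
    result.signatures.to_tsv(out / "extracted_signatures.tsv")
    result.exposures_frame().to_csv(out / "exposures.tsv", sep="\t")
    return {
        "taml_signatures": {
            "matches": matches.to_dict(orient="records"),
            "stability": [float(s) for s in result.stability],
        }
    }


def _run_clonality_timing(config: RunConfig) -> dict:
    p = config.params
    truth = p.get("signature_truth", {"platinum_like": 0.3, "hsc_like": 0.7})
    records = generate_clonal_cohort(
        n_mut=int(p.get("n_mut", 2000)),
        clonal_fraction=float(p.get("clonal_fraction", 0.75)),
        purity=float(p.get("purity", 0.9)),
        depth_model=int(p.get("depth", 100)),
        signature_assignment_truth=truth,
        seed=config.seed,
    )
    labels = classify_records(records, purity=float(p.get("purity", 0.9)))
    assignments = [r.signature for r in records]
    focal = p.get("focal", "platinum_like")
    summary = timing_summary(assignments, labels, focal_signature=focal)
    return {
        "clonality_timing": {
            "clonal_fraction_focal": clonal_fraction(assignments, labels, focal),
            "fold_change_focal": summary.fold_change,
            "table": summary.table.reset_index().to_dict(orient="records"),
        }
    }


def _run_cohort_stats(config: RunConfig) -> dict:
    import pandas as pd

    from .cohortstats import detectability_logistic

    p = config.params
    if "clinical" in config.paths:
        clinical = pd.read_csv(config.paths["clinical"], sep="\t")
    else:
        from .synthcohort import generate_clinical_table

        clinical = generate_clinical_table(int(p.get("n_samples", 500)), seed=config.seed)
    candidates = [tuple(m) for m in p.get(
        "candidate_models",
        [[], ["time_since_end"], ["distal"], ["time_since_end", "distal"],
         ["time_treatment", "time_since_end", "distal"]],
    )]
    reports = detectability_logistic(
        clinical.drop(columns=[c for c in ("sample", "detected") if c in clinical]),
        clinical["detected"].to_numpy(),
        candidate_models=candidates,
        n_randomizations=int(p.get("n_randomizations", 100)),
        seed=config.seed,
    )
    return {
        "cohort_stats": [
            {
                "formula": list(r.formula), "bic": r.bic, "cv_auroc": r.cv_auroc,
                "selected": r.selected, "coefficients": r.coefficients,
            }
            for r in reports
        ]
    }
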