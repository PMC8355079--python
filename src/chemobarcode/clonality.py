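"""Cancer cell fraction estimation and clonal/subclonal signature timing.

The timing readout uses chemotherapy mutations as a barcode: if treatment
preceded the clonal expansion, the chemotherapy signature's mutations ride
along in (essentially) every cell and are classified clonal. The CCF of a
mutation is obtained from its VAF corrected for tumor purity, local total
copy number and mutation multiplicity; a mutation is called subclonal when
the upper bound of the CCF 95% confidence interval falls below 1 — a
simplified two-state version of the cancer-cell-fraction classifiers used
for tumor mutation timing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import MutationRecord


@dataclass
class CCFEstimate:
    ccf: float
    ci_low: float
    ci_high: float
    label: str | None  # "clonal" | "subclonal", set by classify_clonality
    vaf: float
    depth: int
    purity: float
    total_cn: int
    multiplicity: int
    flagged: bool = False  # point estimate implausibly high (> 2)


def _binomial_ci(alt_reads: int, depth: int, level: float, method: str) -> tuple[float, float]:
    if method == "clopper-pearson":
        lo = 0.0 if alt_reads == 0 else stats.beta.ppf((1 - level) / 2, alt_reads, depth - alt_reads + 1)
        hi = 1.0 if alt_reads == depth else stats.beta.ppf(1 - (1 - level) / 2, alt_reads + 1, depth - alt_reads)
        return float(lo), float(hi)
    if method == "wilson":
        z = stats.norm.ppf(1 - (1 - level) / 2)
        p = alt_reads / depth
        denom = 1 + z**2 / depth
        center = (p + z**2 / (2 * depth)) / denom
        half = z * np.sqrt(p * (1 - p) / depth + z**2 / (4 * depth**2)) / denom
        return float(max(0.0, center - half)), float(min(1.0, center + half))
    raise ValueError(f"unknown interval method {method!r}")


def estimate_ccf(
    vaf: float,
    depth: int,
    purity: float,
    total_cn: int = 2,
    multiplicity: int = 1,
    alt_reads: int | None = None,
    ci_method: str = "clopper-pearson",
    level: float = 0.95,
) -> CCFEstimate:
    """CCF = vaf * (purity*total_cn + 2*(1-purity)) / (purity*multiplicity).

    The 95% CI transforms the binomial (alt_reads, depth) interval for the
    VAF (Clopper-Pearson exact by default, Wilson behind the flag) through
    the same affine map. A point estimate above 2 is flagged, not fatal.
    """
    if not (0.0 < purity <= 1.0):
        raise ValueError("purity must be in (0, 1]")
    if total_cn < 1 or multiplicity < 1:
        raise ValueError("total_cn and multiplicity must be >= 1")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    if alt_reads is None:
        alt_reads = int(round(vaf * depth))
    factor = (purity * total_cn + 2.0 * (1.0 - purity)) / (purity * multiplicity)
    ccf = vaf * factor
    lo, hi = _binomial_ci(alt_reads, depth, level, ci_method)
    return CCFEstimate(
        ccf=float(ccf), ci_low=float(lo * factor), ci_high=float(hi * factor),
        label=None, vaf=float(vaf), depth=int(depth), purity=float(purity),
        total_cn=int(total_cn), multiplicity=int(multiplicity),
        flagged=bool(ccf > 2.0),
    )


def classify_clonality(estimate: CCFEstimate) -> str:
    """Subclonal iff the CCF CI upper bound is below 1; clonal otherwise."""
    estimate.label = "subclonal" if estimate.ci_high < 1.0 else "clonal"
    return estimate.label


def classify_records(
    records: list[MutationRecord],
    purity: float,
    total_cn: int = 2,
    multiplicity: int = 1,
    ci_method: str = "clopper-pearson",
) -> list[str]:
    """Estimate CCF and classify each record; labels written to record.clonality."""
    labels = []
    for rec in records:
        est = estimate_ccf(
            rec.vaf, rec.depth, purity, total_cn, multiplicity,
            alt_reads=rec.alt_reads, ci_method=ci_method,
        )
        labels.append(classify_clonality(est))
        rec.clonality = labels[-1]
    return labels


@dataclass
class TimingSummary:
    table: pd.DataFrame  # per-signature n_clonal, n_subclonal, proportions
    focal_signature: str
    fold_change: float
    pseudocount: float


def timing_summary(
    assignments: list[str],
    labels: list[str],
    focal_signature: str,
    pseudocount: float = 0.5,
) -> TimingSummary:
    """Clonal-vs-subclonal relative activity per signature, and the focal fold change.

    Proportions within each clonality stratum are pseudocounted
    (Haldane-Anscombe, 0.5) so the fold change
    prop_clonal(focal)/prop_subclonal(focal) stays finite when the focal
    signature is absent from a stratum. ``"unassigned"`` mutations are
    excluded.
    """
    if len(assignments) != len(labels):
        raise ValueError("assignments and clonality labels must align per mutation")
    pairs = [(a, l) for a, l in zip(assignments, labels) if a != "unassigned"]
    if not pairs:
        raise ValueError("no assigned mutations to summarize")
    signatures = sorted({a for a, _ in pairs})
    if focal_signature not in signatures:
        signatures.append(focal_signature)
    n_clonal = {s: 0 for s in signatures}
    n_subclonal = {s: 0 for s in signatures}
    for a, l in pairs:
        (n_clonal if l == "clonal" else n_subclonal)[a] += 1
    tot_c = sum(n_clonal.values()) + pseudocount * len(signatures)
    tot_s = sum(n_subclonal.values()) + pseudocount * len(signatures)
    rows = []
    for s in signatures:
        pc = (n_clonal[s] + pseudocount) / tot_c
        ps = (n_subclonal[s] + pseudocount) / tot_s
        rows.append((s, n_clonal[s], n_subclonal[s], pc, ps, pc / ps))
    table = pd.DataFrame(
        rows,
        columns=["signature", "n_clonal", "n_subclonal",
                 "prop_clonal_activity", "prop_subclonal_activity", "fold_change"],
    ).set_index("signature")
    return TimingSummary(
        table=table,
        focal_signature=focal_signature,
        fold_change=float(table.loc[focal_signature, "fold_change"]),
        pseudocount=pseudocount,
    )


def clonal_fraction(assignments: list[str], labels: list[str], focal_signature: str) -> float:
    """Fraction of the focal signature's mutations that are clonal."""
    n_c = sum(1 for a, l in zip(assignments, labels) if a == focal_signature and l == "clonal")
    n_s = sum(1 for a, l in zip(assignments, labels) if a == focal_signature and l == "subclonal")
    if n_c + n_s == 0:
        raise ValueError(f"no mutations assigned to {focal_signature!r}")
    return n_c / (n_c + n_s)
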