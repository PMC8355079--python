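"""Somatic SNV handling and SBS96 mutational catalogues.

Single-base substitutions are classified into the 96 trinucleotide channels
of the pyrimidine-centered convention: the mutated base is reported as C or
T (purine-reference mutations are reverse-complemented), flanked by its 5'
and 3' neighbours. Channel order is substitution-major (C>A, C>G, C>T, T>A,
T>C, T>G) with flanks in alphabetical order — the order used by the COSMIC
signature files — and is fixed package-wide.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PYRIMIDINES = ("C", "T")
BASES = ("A", "C", "G", "T")
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: The 96 channel labels, e.g. ``"A[C>A]A"``, in fixed COSMIC order.
CHANNELS96: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)
CHANNEL_INDEX: dict[str, int] = {label: i for i, label in enumerate(CHANNELS96)}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


@dataclass
class MutationRecord:
    """One somatic single-nucleotide variant in one sample.

    Positions are 1-based (VCF convention). ``vaf`` is alt_reads/depth when
    read counts are present. ``signature`` and ``clonality`` are optional
    downstream annotations (also used as ground-truth labels by the
    synthetic generators).
    """

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    alt_reads: int = 0
    depth: int = 0
    filter_flag: str = "PASS"
    vaf: float = field(default=np.nan)
    signature: str | None = None
    clonality: str | None = None

    def __post_init__(self) -> None:
        self.ref = self.ref.upper()
        self.alt = self.alt.upper()
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt ({self.ref}) at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError(f"1-based position must be >= 1, got {self.pos}")
        if np.isnan(self.vaf) and self.depth > 0:
            self.vaf = self.alt_reads / self.depth
        if not np.isnan(self.vaf) and not (0.0 <= self.vaf <= 1.0):
            raise ValueError(f"VAF {self.vaf} outside [0, 1] at {self.chrom}:{self.pos}")

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1 and self.ref in BASES and self.alt in BASES


_RECORD_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt", "alt_reads", "depth", "vaf",
    "filter", "signature", "clonality",
]


def records_to_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    rows = [
        (r.sample_id, r.chrom, r.pos, r.ref, r.alt, r.alt_reads, r.depth, r.vaf,
         r.filter_flag, r.signature or "", r.clonality or "")
        for r in records
    ]
    return pd.DataFrame(rows, columns=_RECORD_COLUMNS)


def write_records_tsv(records: Iterable[MutationRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def read_records_tsv(path: str | Path) -> list[MutationRecord]:
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            MutationRecord(
                sample_id=str(row.sample), chrom=str(row.chrom), pos=int(row.pos),
                ref=str(row.ref), alt=str(row.alt), alt_reads=int(row.alt_reads),
                depth=int(row.depth),
                vaf=float(row.vaf) if str(row.vaf) != "" else np.nan,
                filter_flag=str(getattr(row, "filter", "PASS") or "PASS"),
                signature=str(row.signature) or None,
                clonality=str(row.clonality) or None,
            )
        )
    return out


def read_mutations(
    path: str | Path, format: str = "tsv", sample_id: str | None = None
) -> tuple[list[MutationRecord], list[MutationRecord]]:
    """Read somatic variants; return ``(snv_records, other_records)``.

    ``other_records`` collects indels and multi-nucleotide rows — they are
    counted by callers but never context-classified. VCF input uses the
    per-sample AD (and DP) fields for read support; multi-allelic records
    are split into one record per ALT allele. TSV input needs columns
    sample, chrom, pos, ref, alt and either alt_reads+depth or vaf.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "vcf":
        return _read_vcf(path, sample_id)
    if format == "tsv":
        return _read_tsv(path)
    raise ValueError(f"unknown format {format!r} (expected 'vcf' or 'tsv')")


def _read_vcf(path: Path, sample_id: str | None) -> tuple[list[MutationRecord], list[MutationRecord]]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples) or [sample_id or path.stem]
    snvs: list[MutationRecord] = []
    others: list[MutationRecord] = []
    for variant in vcf:
        alts = variant.ALT or []
        ad = variant.format("AD") if vcf.samples else None
        dp = variant.format("DP") if vcf.samples else None
        for alt_ix, alt in enumerate(alts):
            for s_ix, sample in enumerate(samples):
                if ad is not None:
                    row = np.asarray(ad[s_ix]).ravel()
                    alt_reads = int(row[alt_ix + 1]) if len(row) > alt_ix + 1 else 0
                    if dp is not None:
                        depth = int(np.asarray(dp[s_ix]).ravel()[0])
                    else:
                        depth = int(row[row >= 0].sum())
                else:
                    alt_reads, depth = 0, 0
                if ad is not None and alt_reads <= 0 and len(samples) > 1:
                    continue  # multi-sample VCF: keep only carriers
                rec = MutationRecord(
                    sample_id=sample_id or sample,
                    chrom=str(variant.CHROM), pos=int(variant.POS),
                    ref=str(variant.REF), alt=str(alt),
                    alt_reads=alt_reads, depth=depth,
                    filter_flag=variant.FILTER or "PASS",
                )
                (snvs if rec.is_snv else others).append(rec)
    return snvs, others


def _read_tsv(path: Path) -> tuple[list[MutationRecord], list[MutationRecord]]:
    snvs: list[MutationRecord] = []
    others: list[MutationRecord] = []
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"sample", "chrom", "pos", "ref", "alt"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: TSV must carry columns {sorted(required)}")
        has_reads = {"alt_reads", "depth"}.issubset(reader.fieldnames)
        has_vaf = "vaf" in (reader.fieldnames or [])
        if not has_reads and not has_vaf:
            raise ValueError(f"{path}: need alt_reads+depth columns or a vaf column")
        for line_no, row in enumerate(reader, start=2):
            try:
                rec = MutationRecord(
                    sample_id=row["sample"], chrom=row["chrom"], pos=int(row["pos"]),
                    ref=row["ref"], alt=row["alt"],
                    alt_reads=int(row["alt_reads"]) if has_reads else 0,
                    depth=int(row["depth"]) if has_reads else 0,
                    vaf=float(row["vaf"]) if has_vaf and row.get("vaf") else np.nan,
                    filter_flag=row.get("filter", "PASS") or "PASS",
                )
            except (KeyError, ValueError) as exc:
                raise ValueError(f"{path}: malformed row at line {line_no}: {exc}") from exc
            (snvs if rec.is_snv else others).append(rec)
    return snvs, others


def fetch_context(reference, chrom: str, pos: int) -> str:
    """Trinucleotide context [pos-1, pos+1] (1-based) as an upper-case string.

    Accepts a pyfaidx ``Fasta``, a pysam ``FastaFile`` or a plain mapping
    of chromosome name to sequence string.
    """
    start0, end0 = pos - 2, pos + 1
    if isinstance(reference, Mapping):
        seq = reference[chrom][start0:end0]
    elif hasattr(reference, "fetch"):  # pysam
        seq = reference.fetch(chrom, start0, end0)
    else:  # pyfaidx
        seq = str(reference[chrom][start0:end0])
    return str(seq).upper()


def classify_sbs96(record: MutationRecord, reference) -> int:
    """Channel index (0..95) for an SNV, or raise/skip per the error rules.

    Purine-reference mutations are reverse-complemented to the
    pyrimidine-centered convention. A reference-base mismatch raises; an
    ambiguous base (N) in the context raises ``AmbiguousContextError`` so
    callers can skip the record with a warning.
    """
    if not record.is_snv:
        raise ValueError(f"not an SNV: {record.ref}>{record.alt}")
    context = fetch_context(reference, record.chrom, record.pos)
    if len(context) != 3:
        raise ValueError(f"reference does not cover {record.chrom}:{record.pos}+-1")
    if context[1] != record.ref:
        raise ValueError(
            f"reference mismatch at {record.chrom}:{record.pos}: "
            f"genome has {context[1]}, record says {record.ref}"
        )
    return channel_of(context, record.alt)


class AmbiguousContextError(ValueError):
    """Context contains an N; the record should be skipped, not fatal."""


def channel_of(context: str, alt: str) -> int:
    """Channel index from a raw trinucleotide context and alt base."""
    context = context.upper()
    alt = alt.upper()
    if "N" in context or alt == "N":
        raise AmbiguousContextError(f"ambiguous base in context {context}>{alt}")
    ref = context[1]
    if ref not in PYRIMIDINES:
        context = reverse_complement(context)
        alt = _COMPLEMENT[alt]
        ref = context[1]
    label = f"{context[0]}[{ref}>{alt}]{context[2]}"
    return CHANNEL_INDEX[label]


@dataclass
class SBS96Catalogue:
    """Samples x 96 count matrix over the fixed channel order."""

    sample_ids: list[str]
    counts: np.ndarray  # shape (n_samples, 96), non-negative ints

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[1] != 96:
            raise ValueError(f"counts must be (n_samples, 96), got {self.counts.shape}")
        if len(self.sample_ids) != self.counts.shape[0]:
            raise ValueError("sample_ids length does not match counts")
        if (self.counts < 0).any():
            raise ValueError("negative counts")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        """COSMIC orientation: 96 rows (channel labels) x one column per sample."""
        return pd.DataFrame(self.counts.T, index=list(CHANNELS96), columns=self.sample_ids)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="channel")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "SBS96Catalogue":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        if list(frame.index) != list(CHANNELS96):
            frame = frame.reindex(list(CHANNELS96))
            if frame.isna().any().any():
                raise ValueError(f"{path}: channel labels do not match the SBS96 set")
        return cls(sample_ids=[str(c) for c in frame.columns], counts=frame.to_numpy().T)


def build_catalogue(records: Sequence[MutationRecord], reference) -> SBS96Catalogue:
    """Count each sample's SNVs into the 96 channels (sample order = first appearance).

    Records whose context contains an N are skipped (collected into the
    catalogue's warning tally), matching the convention that ambiguous
    contexts are unclassifiable rather than fatal.
    """
    sample_ids: list[str] = []
    index: dict[str, int] = {}
    rows: list[np.ndarray] = []
    skipped = 0
    for rec in records:
        if rec.sample_id not in index:
            index[rec.sample_id] = len(sample_ids)
            sample_ids.append(rec.sample_id)
            rows.append(np.zeros(96, dtype=np.int64))
        try:
            channel = classify_sbs96(rec, reference)
        except AmbiguousContextError:
            skipped += 1
            continue
        rows[index[rec.sample_id]][channel] += 1
    counts = np.vstack(rows) if rows else np.zeros((0, 96), dtype=np.int64)
    catalogue = SBS96Catalogue(sample_ids=sample_ids, counts=counts)
    catalogue.skipped_ambiguous = skipped  # type: ignore[attr-defined]
    return catalogue


def count_dbs(records: Sequence[MutationRecord]) -> dict[str, int]:
    """Per-sample double-base-substitution counts from adjacent SNV pairs.

    Two SNVs of one sample at positions (pos, pos+1) form one DBS; a run of
    L adjacent SNVs contributes floor(L/2) DBS, pairing left to right. The
    result is invariant to input order.
    """
    by_sample: dict[str, dict[str, list[int]]] = {}
    for rec in records:
        if rec.is_snv:
            by_sample.setdefault(rec.sample_id, {}).setdefault(rec.chrom, []).append(rec.pos)
    out: dict[str, int] = {}
    for sample, chroms in by_sample.items():
        total = 0
        for positions in chroms.values():
            positions = sorted(set(positions))
            i = 0
            while i < len(positions) - 1:
                if positions[i + 1] == positions[i] + 1:
                    total += 1
                    i += 2
                else:
                    i += 1
        out[sample] = total
    return out


@dataclass
class FilterParams:
    """Thresholds for the blood-somatic filter."""

    min_alt_reads: int = 2
    max_vaf: float = 0.5  # exclusive
    burden_percentile: float = 97.5
    pon_max_freq: float = 0.0  # blacklist variants seen above this frequency


@dataclass
class Rejection:
    record: MutationRecord
    reason: str  # exactly one primary reason


def filter_blood_somatic(
    records: Sequence[MutationRecord],
    panel_of_normals: Mapping[tuple[str, int, str, str], float] | None = None,
    region_blacklist: Sequence[tuple[str, int, int]] | None = None,
    params: FilterParams | None = None,
) -> tuple[list[MutationRecord], list[Rejection]]:
    """Blood somatic-mutation filter.

    Applied in order: caller PASS flag; read support (>= min_alt_reads);
    VAF strictly below max_vaf; panel-of-normals blacklist; region
    blacklist (1-based inclusive intervals); finally whole samples whose
    surviving burden exceeds the cohort's burden_percentile are dropped as
    unreliable. Each rejection carries its first failing reason.
    """
    params = params or FilterParams()
    kept: list[MutationRecord] = []
    rejected: list[Rejection] = []
    for rec in records:
        if rec.filter_flag != "PASS":
            rejected.append(Rejection(rec, "filter"))
        elif rec.alt_reads < params.min_alt_reads:
            rejected.append(Rejection(rec, "support"))
        elif not (rec.vaf < params.max_vaf):
            rejected.append(Rejection(rec, "vaf"))
        elif (
            panel_of_normals is not None
            and panel_of_normals.get((rec.chrom, rec.pos, rec.ref, rec.alt), -1.0)
            > params.pon_max_freq
        ):
            rejected.append(Rejection(rec, "blacklist"))
        elif region_blacklist is not None and any(
            rec.chrom == chrom and start <= rec.pos <= end
            for chrom, start, end in region_blacklist
        ):
            rejected.append(Rejection(rec, "region"))
        else:
            kept.append(rec)

    burdens: dict[str, int] = {}
    for rec in kept:
        burdens[rec.sample_id] = burdens.get(rec.sample_id, 0) + 1
    if not burdens:
        raise ValueError("no samples survive the per-variant filters; cannot take a burden percentile")
    threshold = float(np.percentile(list(burdens.values()), params.burden_percentile))
    dropped_samples = {s for s, b in burdens.items() if b > threshold}
    final = [r for r in kept if r.sample_id not in dropped_samples]
    rejected.extend(Rejection(r, "burden") for r in kept if r.sample_id in dropped_samples)
    return final, rejected
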