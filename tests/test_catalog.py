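"""Catalogue building: channel classification, DBS pairing, somatic filtering."""

import numpy as np
import pytest

from chemobarcode.catalog import (
    CHANNELS96,
    FilterParams,
    MutationRecord,
    SBS96Catalogue,
    build_catalogue,
    channel_of,
    classify_sbs96,
    count_dbs,
    filter_blood_somatic,
    read_mutations,
    reverse_complement,
)

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


def test_channel_order_is_substitution_major():
    assert CHANNELS96[0] == "A[C>A]A"
    assert CHANNELS96[15] == "T[C>A]T"
    assert CHANNELS96[95] == "T[T>G]T"
    assert len(set(CHANNELS96)) == 96


@pytest.mark.parametrize(
    "context, alt, label",
    [
        ("ACA", "A", "A[C>A]A"),
        ("TGT", "T", "A[C>A]A"),  # purine ref, reverse-complemented
        ("CAT", "G", "A[T>C]G"),  # A>G becomes T>C on the other strand
    ],
)
def test_channel_examples(context, alt, label):
    assert CHANNELS96[channel_of(context, alt)] == label


def test_classification_is_strand_involution_consistent():
    """All 192 raw (context, alt) descriptions collapse onto the 96 channels:
    a mutation and its reverse-complement description share a channel."""
    seen = set()
    for five in BASES:
        for ref in BASES:
            for three in BASES:
                for alt in BASES:
                    if alt == ref:
                        continue
                    context = five + ref + three
                    forward = channel_of(context, alt)
                    backward = channel_of(reverse_complement(context), COMPLEMENT[alt])
                    assert forward == backward
                    seen.add(forward)
    assert seen == set(range(96))


def test_classify_sbs96_checks_reference_base(toy_genome):
    pos = 101
    genome_ref = toy_genome["chr1"][pos - 1]
    wrong = next(b for b in BASES if b != genome_ref)
    alt = next(b for b in BASES if b not in (genome_ref, wrong))
    good = MutationRecord("s", "chr1", pos, genome_ref, alt, 5, 10)
    assert 0 <= classify_sbs96(good, toy_genome) < 96
    bad = MutationRecord("s", "chr1", pos, wrong, alt, 5, 10)
    with pytest.raises(ValueError, match="mismatch"):
        classify_sbs96(bad, toy_genome)


def test_build_catalogue_row_sums_match_snv_counts(toy_genome):
    rng = np.random.default_rng(5)
    records = []
    per_sample = {"a": 100, "b": 37}
    for sample, n in per_sample.items():
        positions = rng.choice(np.arange(2, 19_999), size=n, replace=False)
        for pos in positions:
            ref = toy_genome["chr1"][pos - 1]
            alt = rng.choice([b for b in BASES if b != ref])
            records.append(MutationRecord(sample, "chr1", int(pos), ref, alt, 5, 10))
    catalogue = build_catalogue(records, toy_genome)
    assert catalogue.sample_ids == ["a", "b"]
    assert catalogue.row_totals().tolist() == [100, 37]


def test_build_catalogue_empty_and_ambiguous():
    empty = build_catalogue([], {"chr1": "ACGT"})
    assert empty.n_samples == 0
    # N in the context: record skipped, not fatal
    genome = {"chr1": "ANCAT"}
    rec = MutationRecord("s", "chr1", 3, "C", "T", 5, 10)
    catalogue = build_catalogue([rec], genome)
    assert catalogue.row_totals().tolist() == [0]
    assert catalogue.skipped_ambiguous == 1


@pytest.mark.parametrize(
    "positions, expected",
    [
        ([100, 101], 1),
        ([100, 102], 0),
        ([100, 101, 102], 1),  # run of 3 pairs left-to-right
        ([100, 101, 102, 103], 2),
        ([100, 101, 103, 104, 200], 2),
    ],
)
def test_count_dbs_adjacency_pairing(positions, expected):
    records = [MutationRecord("s", "chr1", p, "C", "T", 5, 10) for p in positions]
    assert count_dbs(records)["s"] == expected
    # invariant to input order
    assert count_dbs(records[::-1])["s"] == expected


def test_count_dbs_does_not_pair_across_samples_or_chroms():
    records = [
        MutationRecord("a", "chr1", 100, "C", "T", 5, 10),
        MutationRecord("b", "chr1", 101, "C", "T", 5, 10),
        MutationRecord("a", "chr2", 101, "C", "T", 5, 10),
    ]
    assert count_dbs(records) == {"a": 0, "b": 0}


def test_tsv_reading_splits_snvs_from_indels(tmp_path):
    rows = ["sample\tchrom\tpos\tref\talt\talt_reads\tdepth"]
    for i in range(5):
        rows.append(f"s1\tchr1\t{100 + i}\tC\tT\t4\t20")
    rows.append("s1\tchr1\t300\tCT\tC\t4\t20")   # deletion
    rows.append("s1\tchr1\t400\tCT\tAA\t4\t20")  # MNV row: not an SNV
    path = tmp_path / "muts.tsv"
    path.write_text("\n".join(rows) + "\n")
    snvs, others = read_mutations(path, format="tsv")
    assert len(snvs) == 5 and len(others) == 2
    assert all(r.vaf == pytest.approx(0.2) for r in snvs)


def test_tsv_malformed_row_reports_line_number(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("sample\tchrom\tpos\tref\talt\tvaf\ns1\tchr1\tnotanint\tC\tT\t0.1\n")
    with pytest.raises(ValueError, match="line 2"):
        read_mutations(path, format="tsv")


VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    '##contig=<ID=chr1,length=20000>\n'
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
)


def test_vcf_reading_ad_arithmetic_and_multiallelic_split(tmp_path):
    body = (
        "chr1\t100\t.\tC\tA\t.\tPASS\t.\tAD:DP\t3,7:10\n"
        "chr1\t200\t.\tG\tA,T\t.\tPASS\t.\tAD:DP\t2,5,3:10\n"
        "chr1\t300\t.\tCT\tC\t.\tPASS\t.\tAD:DP\t6,4:10\n"
    )
    path = tmp_path / "muts.vcf"
    path.write_text(VCF_HEADER + body)
    snvs, others = read_mutations(path, format="vcf")
    assert len(snvs) == 3  # one SNV + the split multi-allelic pair
    assert len(others) == 1
    first = snvs[0]
    assert (first.alt_reads, first.depth) == (7, 10)
    assert first.vaf == pytest.approx(0.7)
    multi = {(r.alt, r.alt_reads) for r in snvs if r.pos == 200}
    assert multi == {("A", 5), ("T", 3)}


def _rec(sample, vaf=0.2, alt_reads=4, flag="PASS", pos=100):
    depth = max(1, int(round(alt_reads / vaf))) if vaf > 0 else 20
    return MutationRecord(sample, "chr1", pos, "C", "T", alt_reads, depth, filter_flag=flag)


def test_filter_rules_and_reasons():
    records = [
        _rec("s1", vaf=0.6, alt_reads=12),           # vaf >= 0.5 -> rejected
        MutationRecord("s1", "chr1", 101, "C", "T", 1, 10),  # 1 supporting read
        _rec("s1", flag="LowQual"),
        _rec("s1", pos=500),                          # blacklisted variant
        _rec("s1", pos=900),                          # blacklisted region
        _rec("s1", pos=110),
        _rec("s2", pos=120),
    ]
    pon = {("chr1", 500, "C", "T"): 0.3}
    kept, rejected = filter_blood_somatic(
        records, panel_of_normals=pon, region_blacklist=[("chr1", 890, 910)]
    )
    reasons = [r.reason for r in rejected]
    assert reasons == ["vaf", "support", "filter", "blacklist", "region"]
    assert len(kept) == 2
    assert len(kept) + len(rejected) == len(records)


def test_filter_vaf_is_strictly_exclusive():
    records = [
        MutationRecord("s1", "chr1", 100, "C", "T", 10, 20),  # vaf exactly 0.5
        MutationRecord("s1", "chr1", 110, "C", "T", 9, 20),
    ]
    kept, rejected = filter_blood_somatic(records)
    assert [r.reason for r in rejected] == ["vaf"]
    assert len(kept) == 1


def test_filter_drops_hypermutated_sample_at_percentile():
    records = []
    for i in range(39):
        for j in range(4):  # modest burden
            records.append(_rec(f"s{i:02d}", pos=100 + 10 * j))
    for j in range(40):  # one sample at 10x the median burden
        records.append(_rec("s_outlier", pos=100 + 10 * j))
    kept, rejected = filter_blood_somatic(records)
    burdens = [4] * 39 + [40]
    assert 40 > float(np.percentile(burdens, 97.5))  # the oracle for the drop
    assert all(r.sample_id != "s_outlier" for r in kept)
    assert sum(1 for r in rejected if r.reason == "burden") == 40


def test_catalogue_tsv_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    counts = rng.integers(0, 20, size=(3, 96))
    catalogue = SBS96Catalogue(["x", "y", "z"], counts)
    path = tmp_path / "catalogue.tsv"
    catalogue.to_tsv(path)
    back = SBS96Catalogue.from_tsv(path)
    assert back.sample_ids == ["x", "y", "z"]
    np.testing.assert_array_equal(back.counts, counts)
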