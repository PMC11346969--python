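"""Variable-region extraction, counting, enrichment and ranking."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from riboswivel.enrichment import (
    ExtractionSpec, ReadRecord, compute_enrichment, count_variants,
    extract_pool, extract_variable_region, read_fastq,
)
from riboswivel.synthetic import SyntheticPoolSpec, make_fastq_pools

UP = "TCAGGCATTC"
DOWN = "GATCCTAGGC"
SPEC = ExtractionSpec(upstream=UP, downstream=DOWN, n=8)


def _read(seq, phred=38, override=None):
    q = np.full(len(seq), phred)
    if override:
        for pos, v in override.items():
            q[pos] = v
    return ReadRecord("r", seq, q)


def test_extraction_happy_path():
    region = "ACGTTGCA"
    read = _read("GGG" + UP + region + DOWN + "TT")
    variant, reason = extract_variable_region(read, SPEC)
    assert (variant, reason) == (region, "accepted")


def test_phred_below_30_in_region_rejects():
    region = "ACGTTGCA"
    seq = "GGG" + UP + region + DOWN + "TT"
    bad_pos = 3 + len(UP) + 2  # inside the variable region
    variant, reason = extract_variable_region(_read(seq, override={bad_pos: 29}), SPEC)
    assert variant is None and reason == "low_quality"
    # phred 30 exactly is kept
    variant, reason = extract_variable_region(_read(seq, override={bad_pos: 30}), SPEC)
    assert reason == "accepted"
    # low quality outside the extracted span is ignored under region scope
    variant, reason = extract_variable_region(_read(seq, override={0: 2}), SPEC)
    assert reason == "accepted"
    variant, reason = extract_variable_region(
        _read(seq, override={0: 2}), SPEC, quality_scope="read")
    assert reason == "low_quality"


def test_missing_flank_and_bad_length():
    assert extract_variable_region(_read("GGG" + UP + "ACGTTGCA" + "TTTT"), SPEC)[1] == "no_flank"
    assert extract_variable_region(_read("ACGTTGCA" + DOWN), SPEC)[1] == "no_flank"
    short = _read("G" + UP + "ACGTT" + DOWN + "AA")
    assert extract_variable_region(short, SPEC)[1] == "bad_length"


def test_n_bases_always_rejected_in_region():
    seq = "GGG" + UP + "ACGNTGCA" + DOWN + "TT"
    assert extract_variable_region(_read(seq), SPEC)[1] == "low_quality"


def test_count_variants_abundances():
    df = count_variants(["AA", "AA", "AC", "AG"])
    by = dict(zip(df.sequence, df.abundance))
    assert by == pytest.approx({"AA": 0.5, "AC": 0.25, "AG": 0.25})
    assert df.abundance.sum() == pytest.approx(1.0, abs=1e-12)
    single = count_variants(["AA"])
    assert single.abundance.iloc[0] == 1.0
    with pytest.raises(ValueError):
        count_variants([])


@settings(max_examples=20, derandomize=True)
@given(st.lists(st.sampled_from(["AA", "AC", "AG", "AT", "CC"]), min_size=1, max_size=50))
def test_abundances_always_sum_to_one(seqs):
    assert count_variants(seqs).abundance.sum() == pytest.approx(1.0, abs=1e-12)


def test_enrichment_values_and_ranking_match_sort_oracle():
    inp = count_variants(["A"] * 5 + ["B"] * 20 + ["C"] * 25 + ["D"] * 25 + ["E"] * 25)
    out = count_variants(["A"] * 20 + ["B"] * 20 + ["C"] * 30 + ["D"] * 5 + ["E"] * 25)
    table = compute_enrichment(inp, out)
    by = dict(zip(table.sequence, table.enrichment))
    assert by["A"] == pytest.approx(4.0)
    assert by["B"] == pytest.approx(1.0)
    # brute-force ranking oracle: sort by (enrichment, output abundance, seq)
    expect = sorted(by, key=lambda s: (-by[s],
                                       -float(table.set_index("sequence").output_abundance[s]),
                                       s))
    assert list(table.sequence) == expect
    assert list(table["rank"]) == list(range(1, len(table) + 1))


def test_variant_absent_from_input_is_flagged():
    inp = count_variants(["A"] * 10)
    out = count_variants(["A"] * 5 + ["Z"] * 5)
    table = compute_enrichment(inp, out).set_index("sequence")
    assert bool(table.loc["Z", "absent_from_input"])
    assert np.isnan(table.loc["Z", "enrichment"])


def test_planted_pool_recovery_and_rejection_partition(tmp_path):
    spec = SyntheticPoolSpec(depth=10_000, seed=7)
    truth = make_fastq_pools(spec, tmp_path / "in.fq", tmp_path / "out.fq")
    es = ExtractionSpec(spec.upstream, spec.downstream, len(spec.variants[0]))
    in_reads = read_fastq(tmp_path / "in.fq")
    accepted, tally = extract_pool(in_reads, es)
    # rejection reasons partition the pool
    assert sum(tally.values()) == len(in_reads)
    assert tally["accepted"] == len(accepted)
    counts = count_variants(accepted).set_index("sequence")
    for v, info in truth["variants"].items():
        p = info["input_freq"]
        se = np.sqrt(p * (1 - p) / spec.depth)
        assert counts.loc[v, "abundance"] == pytest.approx(p, abs=4 * se)


def test_planted_enrichment_recovered(tmp_path):
    spec = SyntheticPoolSpec(depth=10_000, seed=8)
    truth = make_fastq_pools(spec, tmp_path / "in.fq", tmp_path / "out.fq")
    from riboswivel.enrichment import enrichment_from_fastq

    es = ExtractionSpec(spec.upstream, spec.downstream, len(spec.variants[0]))
    table, _ = enrichment_from_fastq(tmp_path / "in.fq", tmp_path / "out.fq", es)
    by = dict(zip(table.sequence, table.enrichment))
    for v, info in truth["variants"].items():
        assert by[v] == pytest.approx(info["expected_enrichment"], rel=0.1)


def test_enrichment_sharpens_with_depth(tmp_path):
    """Estimated enrichment converges to the planted frequency ratio."""
    errs = {}
    for depth in (1000, 100_000):
        spec = SyntheticPoolSpec(depth=depth, seed=5)
        truth = make_fastq_pools(spec, tmp_path / f"in{depth}.fq", tmp_path / f"out{depth}.fq")
        from riboswivel.enrichment import enrichment_from_fastq

        es = ExtractionSpec(spec.upstream, spec.downstream, len(spec.variants[0]))
        table, _ = enrichment_from_fastq(tmp_path / f"in{depth}.fq",
                                         tmp_path / f"out{depth}.fq", es)
        by = dict(zip(table.sequence, table.enrichment))
        errs[depth] = max(abs(by[v] - info["expected_enrichment"])
                          for v, info in truth["variants"].items())
    assert errs[100_000] < errs[1000]
    assert errs[100_000] < 0.05


def test_phred_contamination_rejection_rate(tmp_path):
    rate = 0.05
    spec = SyntheticPoolSpec(depth=10_000, seed=9, contamination_rate=rate)
    make_fastq_pools(spec, tmp_path / "in.fq", tmp_path / "out.fq")
    es = ExtractionSpec(spec.upstream, spec.downstream, len(spec.variants[0]))
    _, tally = extract_pool(read_fastq(tmp_path / "in.fq"), es)
    se = np.sqrt(rate * (1 - rate) / spec.depth)
    assert tally["low_quality"] / spec.depth == pytest.approx(rate, abs=4 * se)
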