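"""CDS assembly/filtering, codon counting, positional statistics, RSCU, ENC."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastocub.codon_usage import (
    CodingSequence,
    CodonUsageTable,
    assemble_cds,
    codon_counts,
    enc,
    filter_cds,
    gene_cub_metrics,
    rscu,
)
from plastocub.genetics import AA_TO_CODONS, SENSE_CODONS, STOP_CODONS
from plastocub.io import GeneFeature, PlastomeRecord


def _cds(dna, name="g", species="sp", trans=False):
    return CodingSequence(name, species, dna, is_trans_spliced=trans)


# ---------------------------------------------------------------- assembly

def test_assemble_deduplicates_ir_copies():
    gene = "ATG" + "GCT" * 20 + "TAA"
    record = PlastomeRecord(
        "x", "org", gene + "T" * 20 + gene + "AT" * 10,
        features=[
            GeneFeature("dup", "CDS", "+", ((1, 66),)),
            GeneFeature("dup", "CDS", "+", ((87, 152),)),
            GeneFeature("other", "CDS", "+", ((1, 66),)),
        ],
    )
    out = assemble_cds(record)
    assert [c.gene_name for c in out] == ["dup", "other"]


def test_assembled_minus_strand_cds_starts_with_start_codon(plastome):
    record, _ = plastome
    by_name = {c.gene_name: c for c in assemble_cds(record)}
    assert by_name["psbA"].dna.startswith("ATG")
    assert by_name["psbA"].dna[-3:] in STOP_CODONS


def test_assemble_pre_filter_count_matches_annotation(plastome):
    record, _ = plastome
    assert len(assemble_cds(record)) == len(record.features_of_kind("CDS"))


# ---------------------------------------------------------------- filtering

def test_filter_rule_by_rule():
    seqs = [
        _cds(("ATG" + "GCT" * 98 + "TAA")[:299], "a299"),       # 299 bp
        _cds("ATG" + "GCT" * 98 + "TAA", "b300_atg"),           # 300 bp, ATG
        _cds("ATG" + "GCT" * 40 + "TAA" + "GCT" * 58 + "TAA", "c_internal"),
        _cds("GTG" + "GCT" * 98 + "TAA", "d300_gtg"),           # 300 bp, GTG
        _cds(("ATG" + "GCT" * 98 + "TAAA")[:301], "e301"),      # 301 bp
    ]
    result = filter_cds(seqs, min_len=300, start_policy="table11")
    assert [c.gene_name for c in result.retained] == ["b300_atg", "d300_gtg"]
    assert result.reasons() == {"too_short": 1, "internal_stop": 1, "not_triplet": 1}
    # the stricter policy also drops the GTG start
    strict = filter_cds(seqs, min_len=300, start_policy="atg_only")
    assert [c.gene_name for c in strict.retained] == ["b300_atg"]
    assert strict.reasons()["bad_start"] == 1


def test_filter_clean_minimal_cds_retained():
    cds = _cds("ATG" + "GCT" * 98 + "TAA")
    assert len(cds.dna) == 300
    result = filter_cds([cds])
    assert result.retained == [cds] and not result.rejected


@pytest.mark.parametrize(
    "dna,trans,reason",
    [
        ("ATG" + "GCT" * 98 + "GCT", False, "no_stop"),
        ("ATG" + "GCT" * 98 + "TAA", True, "trans_spliced"),
    ],
)
def test_filter_single_reasons(dna, trans, reason):
    result = filter_cds([_cds(dna, trans=trans)])
    assert result.reasons() == {reason: 1}


def test_filter_flags_repeated_identical_copies():
    cds = _cds("ATG" + "GCT" * 98 + "TAA")
    result = filter_cds([cds, cds])
    assert len(result.retained) == 1
    assert result.reasons() == {"duplicate_ir_copy": 1}


def test_filter_is_idempotent(plastome):
    record, _ = plastome
    first = filter_cds(assemble_cds(record))
    second = filter_cds(first.retained)
    assert second.retained == first.retained and not second.rejected


def test_filter_accounting_invariant(plastome):
    record, _ = plastome
    cds = assemble_cds(record)
    result = filter_cds(cds)
    assert len(result.retained) + len(result.rejected) == len(cds)


# ---------------------------------------------------------------- counting

def test_codon_counts_examples():
    table = codon_counts(_cds("ATGGCGTAA"))
    assert table.counts == {"ATG": 1, "GCG": 1, "TAA": 1}
    assert table.n_codons == 3

    doubled = codon_counts([_cds("ATGGCGTAA"), _cds("ATGGCGTAA")], pool=True)
    assert doubled.counts == {"ATG": 2, "GCG": 2, "TAA": 2}


def test_codon_counts_pooled_equals_sum_of_per_gene(plastome):
    record, _ = plastome
    retained = filter_cds(assemble_cds(record)).retained
    per_gene = codon_counts(retained, pool=False)
    pooled = codon_counts(retained, pool=True)
    summed = {}
    for t in per_gene:
        for codon, x in t.counts.items():
            summed[codon] = summed.get(codon, 0) + x
    assert pooled.counts == summed


def test_codon_counts_skips_n_codons_and_rejects_frameshift():
    table = codon_counts(_cds("ATGNNNGCG"))
    assert table.counts == {"ATG": 1, "GCG": 1} and table.n_skipped == 1
    with pytest.raises(ValueError, match="multiple of 3"):
        codon_counts(_cds("ATGG"))


# ---------------------------------------------------------------- metrics

def test_gene_metrics_hand_example():
    m = gene_cub_metrics(_cds("ATGGCGTTTTAA"))
    assert m.gc1 == pytest.approx(100 / 3)
    assert m.gc2 == pytest.approx(100 / 3)
    assert m.gc3 == pytest.approx(200 / 3)
    assert (m.p1, m.p2, m.p3, m.p12) == (0.5, 0.5, 0.5, 0.5)
    assert (m.a3s, m.t3s, m.c3s, m.g3s) == (0.0, 0.5, 0.0, 0.5)
    assert m.gc3s == 0.5


def test_gene_metrics_all_gc_third_positions():
    m = gene_cub_metrics(_cds("ATG" + "GCGGCCCTGACC" * 10 + "TAA"))
    assert m.gc3 == 100.0
    assert m.p3 == 1.0


@given(
    st.lists(st.sampled_from(SENSE_CODONS), min_size=1, max_size=120),
    st.sampled_from(list(STOP_CODONS)),
)
@settings(max_examples=60, deadline=None)
def test_exclusion_sets_by_brute_force_recount(codons, stop):
    """Each statistic uses exactly its own codon-exclusion set."""
    m = gene_cub_metrics(_cds("".join(codons) + stop))
    p_set = [c for c in codons if c not in {"ATG", "ATA", "TGG"} | STOP_CODONS]
    x_set = [
        c for c in codons
        if c not in {"ATG", "ATT", "ATC", "ATA", "TGG"} | STOP_CODONS
    ]
    gc3s_set = [c for c in codons if c not in {"ATG", "TGG"} | STOP_CODONS]
    if p_set:
        assert m.p3 == pytest.approx(
            sum(c[2] in "GC" for c in p_set) / len(p_set)
        )
    else:
        assert math.isnan(m.p3)
    if x_set:
        assert m.a3s + m.t3s + m.c3s + m.g3s == pytest.approx(1.0)
        assert m.t3s == pytest.approx(sum(c[2] == "T" for c in x_set) / len(x_set))
    else:
        assert math.isnan(m.a3s)
    if gc3s_set:
        assert m.gc3s == pytest.approx(
            sum(c[2] in "GC" for c in gc3s_set) / len(gc3s_set)
        )
    assert m.gc1 == pytest.approx(100 * sum(c[0] in "GC" for c in codons) / len(codons))


# ---------------------------------------------------------------- RSCU

def test_rscu_uniform_family_is_unbiased():
    table = CodonUsageTable({"GCT": 5, "GCC": 5, "GCA": 5, "GCG": 5}, 20)
    prof = rscu(table)
    assert all(prof.rscu[c] == 1.0 for c in ("GCT", "GCC", "GCA", "GCG"))


def test_rscu_ala_example_and_conventions():
    prof = rscu(CodonUsageTable({"GCT": 3, "GCC": 1, "ATG": 2}, 6))
    assert [prof.rscu[c] for c in ("GCT", "GCC", "GCA", "GCG")] == [3.0, 1.0, 0.0, 0.0]
    assert prof.rscu["ATG"] == 1.0  # Met by convention
    assert math.isnan(prof.rscu["TTT"])  # unobserved family


@given(
    st.dictionaries(st.sampled_from(SENSE_CODONS), st.integers(0, 50), max_size=40)
)
@settings(max_examples=80, deadline=None)
def test_rscu_family_sums_equal_family_size(counts):
    counts = {c: x for c, x in counts.items() if x > 0}
    prof = rscu(CodonUsageTable(counts, sum(counts.values())))
    for aa, fam in AA_TO_CODONS.items():
        if len(fam) == 1:
            continue
        if sum(counts.get(c, 0) for c in fam) > 0:
            assert sum(prof.rscu[c] for c in fam) == pytest.approx(len(fam))
        else:
            assert all(math.isnan(prof.rscu[c]) for c in fam)


# ---------------------------------------------------------------- ENC

def test_enc_is_20_at_maximal_bias():
    counts = {fam[0]: 10 for fam in AA_TO_CODONS.values()}
    assert enc(CodonUsageTable(counts, sum(counts.values()))) == pytest.approx(20.0)


def test_enc_is_38_for_three_one_family_counts():
    counts = {}
    for fam in AA_TO_CODONS.values():
        if len(fam) == 1:
            counts[fam[0]] = 4
        else:
            counts[fam[0]] = 3
            counts[fam[1]] = 1
    # every degenerate family: n=4, sum p^2 = 0.625, F = (4*0.625-1)/3 = 0.5
    assert enc(CodonUsageTable(counts, sum(counts.values()))) == pytest.approx(38.0)


def test_enc_near_61_under_uniform_usage():
    import numpy as np

    rng = np.random.default_rng(17)
    draws = rng.choice(SENSE_CODONS, size=5000)
    counts = {}
    for c in draws:
        counts[str(c)] = counts.get(str(c), 0) + 1
    value = enc(CodonUsageTable(counts, 5000))
    assert abs(value - 61.0) <= 0.5


def test_enc_undefined_on_empty_and_tiny_tables():
    assert math.isnan(enc(CodonUsageTable({}, 0)))
    # a single two-fold family cannot define the four- and six-fold classes
    assert math.isnan(enc(CodonUsageTable({"TTT": 3, "TTC": 1}, 4)))


@given(
    st.dictionaries(
        st.sampled_from(SENSE_CODONS), st.integers(1, 30), min_size=25, max_size=61
    )
)
@settings(max_examples=60, deadline=None)
def test_enc_bounds_whenever_defined(counts):
    value = enc(CodonUsageTable(counts, sum(counts.values())))
    if not math.isnan(value):
        assert 20.0 <= value <= 61.0
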