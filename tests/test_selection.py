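"""NG86 Ka/Ks: codon alignment, site/difference counting, classification."""

import math
from itertools import permutations

import numpy as np
import pytest

from plastocub.codon_usage import CodingSequence
from plastocub.genetics import SENSE_CODONS, STOP_CODONS, translate_codon
from plastocub.selection import (
    CodonAlignment,
    PairwiseKaKs,
    align_codons,
    classify_selection,
    kaks_scan,
    ng86,
    pathway_differences,
    synonymous_sites,
)
from plastocub.simulate import simulate_codon_pair

def _cds(dna, name="g", species="sp"):
    return CodingSequence(name, species, dna)


# ---------------------------------------------------------------- alignment

def test_align_identical_sequences_drops_terminal_stop():
    a = _cds("ATGAAATTTTAA")
    aln = align_codons(a, _cds("ATGAAATTTTAA", species="sp2"))
    assert aln.n_codon_pairs == 3  # 4 codons minus the stop
    assert all(x == y for x, y in aln.codon_pairs)


def test_align_with_indel_drops_gapped_codon_column():
    # MK* vs MDK*: the D codon is unmatched and dropped
    aln = align_codons(_cds("ATGAAATAA"), _cds("ATGGATAAATAA"))
    assert aln.codon_pairs == [("ATG", "ATG"), ("AAA", "AAA")]


def test_align_rejects_frameshift_and_internal_stop():
    with pytest.raises(ValueError, match="multiple of 3"):
        align_codons(_cds("ATGAA"), _cds("ATGAAATAA"))
    with pytest.raises(ValueError, match="codon 2"):
        align_codons(_cds("ATGTAAAAATAA"), _cds("ATGAAAAAATAA"))


# ---------------------------------------------------------------- NG86 counts

def test_ng86_identical_sequences():
    result = ng86(align_codons(_cds("ATGAAATTTTAA"), _cds("ATGAAATTTTAA", species="x")))
    assert result.Ka == 0.0 and result.Ks == 0.0
    assert result.omega_flag == "undefined_Ks0"
    assert classify_selection(result) == "undetermined"


def test_ng86_worked_example_ttt_tta():
    """One nonsynonymous difference; TTA's position 2 has two stop neighbours,
    so S = (1/3 + 2/3)/2 = 0.5 and pN = 1/2.5 = 0.4."""
    result = ng86(CodonAlignment("x", ("a", "b"), [("TTT", "TTA")]))
    assert result.S == pytest.approx(0.5)
    assert result.N == pytest.approx(2.5)
    assert (result.Nd, result.Sd) == (1.0, 0.0)
    assert result.pN == pytest.approx(0.4)
    assert result.Ka == pytest.approx(0.5716, abs=1e-4)
    assert result.Ks == 0.0


def test_ng86_worked_example_glycine():
    result = ng86(
        CodonAlignment("x", ("a", "b"), [("GGG", "GGA"), ("GGG", "GGG")])
    )
    assert result.S == pytest.approx(2.0)
    assert (result.Nd, result.Sd) == (0.0, 1.0)
    assert result.pS == pytest.approx(0.5)
    assert result.Ks == pytest.approx(0.8240, abs=1e-4)
    assert result.Ka == 0.0
    assert result.omega == 0.0


def test_ng86_is_symmetric():
    rng = np.random.default_rng(3)
    for rep in range(10):
        a, b = simulate_codon_pair(40, 0.5, 0.25, seed=rep)
        fwd = ng86(align_codons(a, b))
        rev = ng86(align_codons(b, a))
        assert (fwd.S, fwd.N, fwd.Nd, fwd.Sd) == (rev.S, rev.N, rev.Nd, rev.Sd)


def _oracle_pathways(ca, cb):
    """Independent re-enumeration of stop-avoiding minimum pathways."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    results = []
    for order in permutations(diff):
        cur, nd, sd, ok = ca, 0, 0, True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if translate_codon(cur) == translate_codon(nxt):
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            results.append((nd, sd))
    return results


def test_difference_counts_match_pathway_oracle_on_random_pairs():
    rng = np.random.default_rng(11)
    total_checked = 0
    for _ in range(30):
        codons_a = rng.choice(SENSE_CODONS, size=30)
        codons_b = rng.choice(SENSE_CODONS, size=30)
        nd = sd = 0.0
        blocked = 0
        for ca, cb in zip(codons_a, codons_b):
            paths = _oracle_pathways(str(ca), str(cb))
            if not paths:
                blocked += 1
                continue
            nd += sum(p[0] for p in paths) / len(paths)
            sd += sum(p[1] for p in paths) / len(paths)
        aln = CodonAlignment("x", ("a", "b"), list(zip(map(str, codons_a), map(str, codons_b))))
        result = ng86(aln)
        assert result.Nd + result.Sd == pytest.approx(nd + sd, abs=1e-9)
        assert result.Nd == pytest.approx(nd, abs=1e-9)
        assert result.n_blocked == blocked
        total_checked += 1
    assert total_checked == 30


def test_site_counts_sum_to_three_per_codon_without_stop_neighbours():
    stop_neighbour = {
        c
        for c in SENSE_CODONS
        if any(
            c[:i] + b + c[i + 1 :] in STOP_CODONS
            for i in range(3)
            for b in "ACGT"
        )
    }
    clean = [c for c in SENSE_CODONS if c not in stop_neighbour]
    pairs = [(a, b) for a, b in zip(clean, reversed(clean))]
    aln = CodonAlignment("x", ("a", "b"), pairs)
    result = ng86(aln)
    assert result.S + result.N == pytest.approx(3 * len(pairs))


def test_synonymous_sites_examples():
    assert synonymous_sites("TTT") == pytest.approx(1 / 3)
    assert synonymous_sites("TTA") == pytest.approx(2 / 3)
    assert synonymous_sites("GGG") == pytest.approx(1.0)
    # Met has no synonymous change at any position
    assert synonymous_sites("ATG") == 0.0


def test_stop_crossing_pathways_are_excluded_not_counted():
    # TGG -> TAT: mutating position 2 first passes through the stop TAG, so
    # only the order via TGT (Cys) survives and both steps are nonsynonymous
    assert pathway_differences("TGG", "TAT") == (2.0, 0.0)
    # under the plastid code every sense-codon pair keeps at least one
    # stop-free pathway, so a fully blocked pair cannot arise from valid CDS
    assert all(
        _oracle_pathways(ca, cb)
        for ca in SENSE_CODONS
        for cb in SENSE_CODONS
        if ca != cb
    )


# ---------------------------------------------------------------- omega

def test_classification_thresholds():
    def result(omega, flag=None):
        return PairwiseKaKs(
            "g", ("a", "b"), 100, 50, 1, 1, 0.01, 0.02, 0.01, 0.02,
            omega, flag, 50,
        )

    assert classify_selection(result(1.3)) == "positive"
    assert classify_selection(result(0.2)) == "purifying"
    assert classify_selection(result(1.0)) == "neutral"
    assert classify_selection(result(math.nan, "saturated")) == "undetermined"


def test_omega_recovery_on_simulated_pairs():
    """Median estimated omega within 20% of truth and >= 90% coverage of
    [0.5x, 2x] at Ks ~ 0.3, 500 codons, 50 replicates per omega."""
    for true_omega in (0.1, 0.5, 1.0):
        estimates = []
        for rep in range(50):
            a, b = simulate_codon_pair(500, true_omega, 0.3, seed=1000 * rep + int(true_omega * 10))
            estimates.append(ng86(align_codons(a, b)).omega)
        estimates = np.asarray(estimates)
        assert abs(np.median(estimates) - true_omega) <= 0.2 * true_omega
        coverage = np.mean(
            (estimates >= 0.5 * true_omega) & (estimates <= 2.0 * true_omega)
        )
        assert coverage >= 0.9


def test_kaks_scan_matches_orthologues_by_name(plastome, diverged):
    from plastocub.codon_usage import assemble_cds, filter_cds

    record, _ = plastome
    derived, dspec = diverged
    a = filter_cds(assemble_cds(record)).retained
    b = filter_cds(assemble_cds(derived)).retained
    scan = kaks_scan(a, b)
    assert [r.gene_name for r, _ in scan] == sorted({c.gene_name for c in a})
    for result, klass in scan:
        assert klass in {"positive", "purifying", "neutral", "undetermined"}
        if not math.isnan(result.Ka):
            assert result.Ka >= 0
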