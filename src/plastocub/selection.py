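"""Pairwise Ka/Ks by the Nei-Gojobori counting method (NG86).

Orthologous CDS pairs are aligned at the protein level (global
Needleman-Wunsch, BLOSUM62, gap open -10 / extend -0.5), back-translated to a
codon alignment, and scored: synonymous site fractions are counted per codon
position over non-stop single-base changes, differences are averaged over all
minimum-length mutational pathways that avoid stop codons, and the raw
proportions are corrected for multiple hits with the Jukes-Cantor formula
d = -(3/4) ln(1 - 4p/3). omega = Ka/Ks classifies genes as under positive
(>1), purifying (<1) or neutral (~1) selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .codon_usage import CodingSequence
from .genetics import BASES, STOP_CODONS, codons_of, translate_codon

NAN = float("nan")


@dataclass
class CodonAlignment:
    gene_name: str
    pair: tuple[str, str]
    codon_pairs: list[tuple[str, str]]

    @property
    def n_codon_pairs(self) -> int:
        return len(self.codon_pairs)


@dataclass
class PairwiseKaKs:
    gene_name: str
    pair: tuple[str, str]
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    Ka: float
    Ks: float
    omega: float
    omega_flag: str | None  # None | undefined_Ks0 | saturated | undefined
    n_codon_pairs: int
    n_blocked: int = 0  # codon pairs whose every pathway crosses a stop


def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _translate_or_report(cds: CodingSequence) -> tuple[tuple[str, ...], str]:
    codons = codons_of(cds.dna)
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    aas = []
    for i, codon in enumerate(codons):
        aa = translate_codon(codon)
        if aa == "*":
            raise ValueError(
                f"{cds.gene_name}: internal stop codon {codon} at codon {i + 1}"
            )
        aas.append(aa)
    return codons, "".join(aas)


def align_codons(cds_a: CodingSequence, cds_b: CodingSequence) -> CodonAlignment:
    """Protein-guided codon alignment of two CDS.

    Terminal stops are removed; gapped codon columns are dropped so every
    retained column is a gap-free codon pair.
    """
    codons_a, prot_a = _translate_or_report(cds_a)
    codons_b, prot_b = _translate_or_report(cds_b)
    pairs: list[tuple[str, str]] = []
    if prot_a and prot_b:
        alignment = _protein_aligner().align(prot_a, prot_b)[0]
        ia = ib = 0
        for col_a, col_b in zip(alignment[0], alignment[1]):
            if col_a != "-" and col_b != "-":
                pairs.append((codons_a[ia], codons_b[ib]))
            if col_a != "-":
                ia += 1
            if col_b != "-":
                ib += 1
    return CodonAlignment(
        gene_name=cds_a.gene_name,
        pair=(cds_a.species_label, cds_b.species_label),
        codon_pairs=pairs,
    )


@lru_cache(maxsize=None)
def synonymous_sites(codon: str) -> float:
    """NG86 synonymous site count of one codon: at each position, synonymous
    single-base changes / non-stop single-base changes; a position whose every
    change creates a stop contributes 0."""
    aa = translate_codon(codon)
    total = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for b in BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            valid += 1
            if translate_codon(alt) == aa:
                syn += 1
        if valid:
            total += syn / valid
    return total


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float] | None:
    """(nonsynonymous, synonymous) difference counts between two codons,
    averaged over all minimum-length mutational pathways that avoid stop
    codons. None when every pathway crosses a stop codon."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    nd_total = sd_total = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        current = codon_a
        nd = sd = 0
        ok = True
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if translate_codon(current) == translate_codon(nxt):
                sd += 1
            else:
                nd += 1
            current = nxt
        if ok:
            nd_total += nd
            sd_total += sd
            n_paths += 1
    if n_paths == 0:
        return None
    return nd_total / n_paths, sd_total / n_paths


def _jukes_cantor(p: float) -> tuple[float, str | None]:
    if math.isnan(p):
        return NAN, "undefined"
    if p == 0:
        return 0.0, None
    if p >= 0.75:
        return NAN, "saturated"
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0), None


def ng86(alignment: CodonAlignment) -> PairwiseKaKs:
    """Nei-Gojobori Ka/Ks with Jukes-Cantor correction for one codon alignment.

    Site counts are averaged between the two sequences; codon pairs whose
    every mutational pathway crosses a stop codon are excluded from both site
    and difference counts and tallied in ``n_blocked``.
    """
    if alignment.n_codon_pairs < 1:
        raise ValueError(f"{alignment.gene_name}: empty codon alignment")
    s_a = s_b = nd = sd = 0.0
    n_used = 0
    n_blocked = 0
    for ca, cb in alignment.codon_pairs:
        if ca in STOP_CODONS or cb in STOP_CODONS:
            raise ValueError(f"stop codon in alignment: {ca}/{cb}")
        diffs = pathway_differences(ca, cb)
        if diffs is None:
            n_blocked += 1
            continue
        s_a += synonymous_sites(ca)
        s_b += synonymous_sites(cb)
        nd += diffs[0]
        sd += diffs[1]
        n_used += 1

    S = (s_a + s_b) / 2.0
    N = 3.0 * n_used - S
    pN = nd / N if N > 0 else NAN
    pS = sd / S if S > 0 else NAN
    ka, flag_a = _jukes_cantor(pN)
    ks, flag_s = _jukes_cantor(pS)

    omega = NAN
    flag = flag_a or flag_s
    if flag is None:
        if ks == 0:
            flag = "undefined_Ks0"
        else:
            omega = ka / ks
    return PairwiseKaKs(
        gene_name=alignment.gene_name,
        pair=alignment.pair,
        N=N,
        S=S,
        Nd=nd,
        Sd=sd,
        pN=pN,
        pS=pS,
        Ka=ka,
        Ks=ks,
        omega=omega,
        omega_flag=flag,
        n_codon_pairs=alignment.n_codon_pairs,
        n_blocked=n_blocked,
    )


def classify_selection(
    result: PairwiseKaKs, neutral_band: tuple[float, float] = (0.95, 1.05)
) -> str:
    """positive / purifying / neutral / undetermined from omega and the band."""
    if result.omega_flag is not None or math.isnan(result.omega):
        return "undetermined"
    low, high = neutral_band
    if result.omega > high:
        return "positive"
    if result.omega < low:
        return "purifying"
    return "neutral"


def kaks_scan(
    cds_a: Sequence[CodingSequence],
    cds_b: Sequence[CodingSequence],
    neutral_band: tuple[float, float] = (0.95, 1.05),
) -> list[tuple[PairwiseKaKs, str]]:
    """NG86 over the orthologue intersection (matched by gene name) of two
    filtered CDS sets, sorted by gene name."""
    by_name_a = {c.gene_name: c for c in cds_a}
    by_name_b = {c.gene_name: c for c in cds_b}
    out = []
    for name in sorted(set(by_name_a) & set(by_name_b)):
        result = ng86(align_codons(by_name_a[name], by_name_b[name]))
        out.append((result, classify_selection(result, neutral_band)))
    return out
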