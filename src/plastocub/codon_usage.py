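"""Codon-usage-bias statistics for plastid protein-coding genes.

CDS assembly and filtering (start-codon policy under the plastid genetic code,
length >= 300 bp, no internal stops), codon counting, per-gene positional GC
statistics (GC1/2/3, P1/P2/P3, A3s/T3s/C3s/G3s, GC3s), relative synonymous
codon usage (RSCU) and Wright's effective number of codons (ENC).

Each positional statistic is computed over its own codon-exclusion set:

* GC1/GC2/GC3 — all sense codons (stops excluded), reported in percent;
* P1/P2/P3   — additionally excluding ATG, ATA and TGG, as fractions;
* A3s/T3s/C3s/G3s — excluding ATG, ATT, ATC, ATA, TGG and stops;
* GC3s       — third positions of synonymous codons (Met, Trp, stops excluded).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .genetics import (
    AA_TO_CODONS,
    START_CODONS_TABLE11,
    STOP_CODONS,
    codons_of,
)
from .io import PlastomeRecord, extract_feature_sequence

NAN = float("nan")

P_EXCLUDED = frozenset({"ATG", "ATA", "TGG"}) | STOP_CODONS
X3S_EXCLUDED = frozenset({"ATG", "ATT", "ATC", "ATA", "TGG"}) | STOP_CODONS
GC3S_EXCLUDED = frozenset({"ATG", "TGG"}) | STOP_CODONS

#: the 8 four-fold degenerate codon boxes (first two bases); within a box the
#: third base is fully synonymous, so strand-parity (A=T, G=C) is exact under
#: unbiased mutation — the classical PR2 site restriction
FOURFOLD_BOXES = frozenset({"CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG"})

REJECT_REASONS = (
    "bad_start",
    "too_short",
    "internal_stop",
    "not_triplet",
    "no_stop",
    "duplicate_ir_copy",
    "trans_spliced",
)


@dataclass(frozen=True)
class CodingSequence:
    """An in-frame coding-strand CDS with provenance."""

    gene_name: str
    species_label: str
    dna: str
    provenance: tuple = ()
    is_trans_spliced: bool = False

    @property
    def length_bp(self) -> int:
        return len(self.dna)


@dataclass
class CdsFilterResult:
    retained: list[CodingSequence]
    rejected: list[tuple[str, str]]  # (gene_name, reason)

    def reasons(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for _, reason in self.rejected:
            out[reason] = out.get(reason, 0) + 1
        return out


@dataclass
class CodonUsageTable:
    counts: dict[str, int]
    n_codons: int
    n_skipped: int = 0  # codons containing N

    def __post_init__(self) -> None:
        if sum(self.counts.values()) != self.n_codons:
            raise ValueError("counts must sum to n_codons")


@dataclass
class GeneCUBMetrics:
    gene_name: str
    species_label: str
    gc1: float  # percent
    gc2: float
    gc3: float
    p1: float  # fractions
    p2: float
    p3: float
    p12: float
    a3s: float
    t3s: float
    c3s: float
    g3s: float
    gc3s: float
    enc: float
    n_codons: int
    # third-base fractions over four-fold degenerate boxes only
    a3f: float = NAN
    t3f: float = NAN
    c3f: float = NAN
    g3f: float = NAN


@dataclass
class RSCUProfile:
    rscu: dict[str, float]
    n_codons: int


def assemble_cds(record: PlastomeRecord) -> list[CodingSequence]:
    """One CodingSequence per CDS feature; identical IR-duplicated copies are
    collapsed to one. Malformed CDS pass through for filter_cds to reject."""
    out: list[CodingSequence] = []
    seen: set[tuple[str, str]] = set()
    for feat in record.features_of_kind("CDS"):
        dna = extract_feature_sequence(record, feat)
        key = (feat.gene_name, dna)
        if key in seen:
            continue  # second IR copy
        seen.add(key)
        out.append(
            CodingSequence(
                gene_name=feat.gene_name,
                species_label=record.organism or record.identifier,
                dna=dna,
                provenance=(record.identifier, feat.segments),
                is_trans_spliced=feat.is_trans_spliced,
            )
        )
    return out


def filter_cds(
    cds_list: Sequence[CodingSequence],
    min_len: int = 300,
    start_policy: Literal["table11", "atg_only"] = "table11",
) -> CdsFilterResult:
    """Screen CDS for codon-usage analysis; every rejection carries a reason.

    Retained CDS have a valid start codon under ``start_policy`` (table11:
    ATG/GTG/TTG), length >= ``min_len`` and a multiple of 3, a terminal stop,
    and no internal stop codons. Trans-spliced genes and repeated identical
    IR copies are rejected.
    """
    starts = {"ATG"} if start_policy == "atg_only" else set(START_CODONS_TABLE11)
    retained: list[CodingSequence] = []
    rejected: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    for cds in cds_list:
        key = (cds.gene_name, cds.dna)
        if key in seen:
            rejected.append((cds.gene_name, "duplicate_ir_copy"))
            continue
        seen.add(key)
        if cds.is_trans_spliced:
            rejected.append((cds.gene_name, "trans_spliced"))
        elif cds.length_bp < min_len:
            rejected.append((cds.gene_name, "too_short"))
        elif cds.length_bp % 3:
            rejected.append((cds.gene_name, "not_triplet"))
        elif cds.dna[:3] not in starts:
            rejected.append((cds.gene_name, "bad_start"))
        elif cds.dna[-3:] not in STOP_CODONS:
            rejected.append((cds.gene_name, "no_stop"))
        elif any(c in STOP_CODONS for c in codons_of(cds.dna)[:-1]):
            rejected.append((cds.gene_name, "internal_stop"))
        else:
            retained.append(cds)
    return CdsFilterResult(retained=retained, rejected=rejected)


def codon_counts(
    cds_set: Iterable[CodingSequence] | CodingSequence, pool: bool = True
) -> CodonUsageTable | list[CodonUsageTable]:
    """Codon counts over non-overlapping triplets; codons containing N are
    skipped and tallied in ``n_skipped``. Pooled or one table per gene."""
    if isinstance(cds_set, CodingSequence):
        cds_set = [cds_set]
    tables = []
    for cds in cds_set:
        counts: dict[str, int] = {}
        skipped = 0
        for codon in codons_of(cds.dna):
            if "N" in codon:
                skipped += 1
            else:
                counts[codon] = counts.get(codon, 0) + 1
        tables.append(
            CodonUsageTable(counts=counts, n_codons=sum(counts.values()), n_skipped=skipped)
        )
    if not pool:
        return tables
    pooled: dict[str, int] = {}
    skipped = 0
    for t in tables:
        skipped += t.n_skipped
        for codon, x in t.counts.items():
            pooled[codon] = pooled.get(codon, 0) + x
    return CodonUsageTable(counts=pooled, n_codons=sum(pooled.values()), n_skipped=skipped)


def _strip_terminal_stop(codons: tuple[str, ...]) -> tuple[str, ...]:
    if codons and codons[-1] in STOP_CODONS:
        return codons[:-1]
    return codons


def _gc_fraction_at(codons: list[str], position: int) -> float:
    if not codons:
        return NAN
    return sum(1 for c in codons if c[position] in "GC") / len(codons)


def gene_cub_metrics(cds: CodingSequence) -> GeneCUBMetrics:
    """All per-gene codon-position statistics and ENC for one CDS.

    The terminal stop codon is removed first; codons containing N are ignored.
    A statistic whose eligible codon set is empty is NaN; the others are still
    computed.
    """
    codons = [
        c for c in _strip_terminal_stop(codons_of(cds.dna)) if "N" not in c
    ]
    gc_set = [c for c in codons if c not in STOP_CODONS]
    p_set = [c for c in codons if c not in P_EXCLUDED]
    x3s_set = [c for c in codons if c not in X3S_EXCLUDED]
    gc3s_set = [c for c in codons if c not in GC3S_EXCLUDED]

    p1 = _gc_fraction_at(p_set, 0)
    p2 = _gc_fraction_at(p_set, 1)

    if x3s_set:
        third = [c[2] for c in x3s_set]
        a3s, t3s, c3s, g3s = (third.count(b) / len(third) for b in "ATCG")
    else:
        a3s = t3s = c3s = g3s = NAN

    ff_third = [c[2] for c in codons if c[:2] in FOURFOLD_BOXES]
    if ff_third:
        a3f, t3f, c3f, g3f = (ff_third.count(b) / len(ff_third) for b in "ATCG")
    else:
        a3f = t3f = c3f = g3f = NAN

    table = codon_counts(
        CodingSequence(cds.gene_name, cds.species_label, "".join(gc_set))
    )
    return GeneCUBMetrics(
        gene_name=cds.gene_name,
        species_label=cds.species_label,
        gc1=100 * _gc_fraction_at(gc_set, 0),
        gc2=100 * _gc_fraction_at(gc_set, 1),
        gc3=100 * _gc_fraction_at(gc_set, 2),
        p1=p1,
        p2=p2,
        p3=_gc_fraction_at(p_set, 2),
        p12=(p1 + p2) / 2,
        a3s=a3s,
        t3s=t3s,
        c3s=c3s,
        g3s=g3s,
        gc3s=_gc_fraction_at(gc3s_set, 2),
        enc=enc(table),
        n_codons=len(codons),
        a3f=a3f,
        t3f=t3f,
        c3f=c3f,
        g3f=g3f,
    )


def rscu(table: CodonUsageTable) -> RSCUProfile:
    """Relative synonymous codon usage under the plastid code.

    RSCU_c = X_c / (family mean of X); an unobserved family is NaN throughout;
    Met and Trp are reported as 1.0 by convention when observed. Stop codons
    are excluded.
    """
    values: dict[str, float] = {}
    for aa, fam in AA_TO_CODONS.items():
        total = sum(table.counts.get(c, 0) for c in fam)
        k = len(fam)
        for c in fam:
            if total == 0:
                values[c] = NAN
            elif k == 1:
                values[c] = 1.0
            else:
                values[c] = table.counts.get(c, 0) * k / total
    return RSCUProfile(rscu=values, n_codons=table.n_codons)


#: Wright's degeneracy classes under the plastid code: (class size count, weight)
_ENC_CLASSES = {2: 9, 3: 1, 4: 5, 6: 3}


def enc(table: CodonUsageTable) -> float:
    """Wright's effective number of codons, in [20, 61], NaN when undefined.

    Per amino-acid family with n observed codons and usage frequencies p_i,
    F = (n * sum(p_i^2) - 1) / (n - 1); class means use families with n >= 2
    and F > 0. A missing three-fold class mean is imputed as the average of
    the two- and four-fold means; a missing two-, four- or six-fold class mean
    makes ENC undefined.
    """
    f_by_class: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, fam in AA_TO_CODONS.items():
        k = len(fam)
        if k == 1:
            continue
        counts = [table.counts.get(c, 0) for c in fam]
        n = sum(counts)
        if n < 2:
            continue
        f_hat = (n * sum((x / n) ** 2 for x in counts) - 1) / (n - 1)
        if f_hat > 0:
            f_by_class[k].append(f_hat)

    means = {k: sum(v) / len(v) for k, v in f_by_class.items() if v}
    if not all(k in means for k in (2, 4, 6)):
        return NAN
    if 3 not in means:
        means[3] = (means[2] + means[4]) / 2
    value = 2 + sum(_ENC_CLASSES[k] / means[k] for k in (2, 3, 4, 6))
    return min(value, 61.0)


def metrics_table(metrics: Sequence[GeneCUBMetrics]):
    """Per-gene metrics as a pandas DataFrame (column order is stable)."""
    import pandas as pd

    cols = [
        "species_label", "gene_name", "n_codons", "gc1", "gc2", "gc3",
        "p1", "p2", "p3", "p12", "a3s", "t3s", "c3s", "g3s", "gc3s", "enc",
    ]
    return pd.DataFrame([{c: getattr(m, c) for c in cols} for m in metrics])[cols]
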