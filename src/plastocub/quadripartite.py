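"""Quadripartite structure: inverted-repeat detection, regions and junctions.

A plastid genome is modelled as a circle carrying two exactly
reverse-complementary repeat copies (IRb/IRa) that separate a large and a
small single-copy region (LSC/SSC). Detection is exact-match seed-and-extend
on k-mers of the reverse complement; the canonical linearization starts at
LSC base 1 and reads LSC -> IRb -> SSC -> IRa, with the four junctions
JLB/JSB/JSA/JLA placed on the last base of the upstream region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .genetics import reverse_complement, complement_base
from .io import GeneFeature, PlastomeRecord, rotate_record

REGIONS = ("LSC", "IRb", "SSC", "IRa")
JUNCTIONS = ("JLB", "JSB", "JSA", "JLA")
#: IR copy on the repeat side of each junction
IR_SIDE = {"JLB": "IRb", "JSB": "IRb", "JSA": "IRa", "JLA": "IRa"}


@dataclass
class QuadripartitePartition:
    """LSC/IRb/SSC/IRa intervals on the canonical linearization.

    ``rotation_offset`` is the 0-based index, on the input linearization, of
    canonical base 1 (the first LSC base).
    """

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    junctions: dict[str, int]
    ir_length: int
    genome_length: int
    rotation_offset: int = 0
    region_length: dict[str, int] = field(default_factory=dict)
    region_gc: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {
            "LSC": self.lsc[1] - self.lsc[0] + 1,
            "IRb": self.irb[1] - self.irb[0] + 1,
            "SSC": self.ssc[1] - self.ssc[0] + 1,
            "IRa": self.ira[1] - self.ira[0] + 1,
        }
        if lengths["IRb"] != lengths["IRa"] or lengths["IRb"] != self.ir_length:
            raise ValueError("IR copies must have equal length == ir_length")
        if sum(lengths.values()) != self.genome_length:
            raise ValueError("regions must tile the genome exactly once")
        if not self.region_length:
            self.region_length = lengths

    def interval(self, region: str) -> tuple[int, int]:
        return {"LSC": self.lsc, "IRb": self.irb, "SSC": self.ssc, "IRa": self.ira}[region]

    def to_canonical(self, pos: int) -> int:
        """Map a 1-based input-linearization position to canonical coordinates."""
        return (pos - 1 - self.rotation_offset) % self.genome_length + 1

    def canonical_record(self, record: PlastomeRecord) -> PlastomeRecord:
        """The record rotated so the canonical linearization starts at base 1."""
        if self.rotation_offset == 0:
            return record
        return rotate_record(record, self.rotation_offset)


@dataclass(frozen=True)
class JunctionGeneReport:
    junction: str
    gene_name: str
    relation: str  # spans | upstream | downstream
    overlap_bp: int
    distance_bp: int


def _gc_percent(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return float("nan")
    return 100.0 * (seq.count("G") + seq.count("C")) / acgt


def _circular_overlap(a: tuple[int, int], b: tuple[int, int], n: int) -> bool:
    """Do two 0-based circular intervals (start, length) share a position?"""
    sa, la = a
    sb, lb = b
    # relative start of b w.r.t. a
    rel = (sb - sa) % n
    return rel < la or (sa - sb) % n < lb


def detect_inverted_repeats(
    sequence: str,
    min_len: int = 1000,
    *,
    seed_k: int | None = None,
) -> QuadripartitePartition | None:
    """Locate the maximal pair of disjoint, exactly reverse-complementary
    repeats of length >= ``min_len`` on a circular sequence.

    Returns ``None`` when no such pair exists ("no quadripartite structure");
    ties between equally long non-nested candidates are broken towards the
    smallest start on the given linearization, with a warning.
    """
    seq = sequence.upper()
    n = len(seq)
    if min_len < 1:
        raise ValueError("min_len must be positive")
    if n < 2 * min_len:
        return None
    k = seed_k or min(min_len, 21)
    ext = seq + seq[: k - 1]  # circular k-mers

    index: dict[str, list[int]] = {}
    for p in range(n):
        index.setdefault(ext[p : p + k], []).append(p)

    visited: set[tuple[int, int]] = set()
    candidates: list[tuple[int, int, int]] = []  # (length, start_a, start_b)

    def base(i: int) -> str:
        return seq[i % n]

    max_len = n // 2
    for a0 in range(n):
        rk = reverse_complement(ext[a0 : a0 + k])
        for b0 in index.get(rk, ()):  # seq[b0:b0+k] == rc(seq[a0:a0+k])
            # the seed's first base pairs with the last base of its partner
            if (a0, (b0 + k - 1) % n) in visited:
                continue
            a, b, length = a0, b0, k
            if _circular_overlap((a, length), (b, length), n):
                continue
            # grow left of A / right of B
            while length < max_len:
                na = (a - 1) % n
                if base(na) != complement_base(base(b + length)):
                    break
                if _circular_overlap((na, length + 1), (b, length + 1), n):
                    break
                a, length = na, length + 1
            # grow right of A / left of B
            while length < max_len:
                nb = (b - 1) % n
                if base(a + length) != complement_base(base(nb)):
                    break
                if _circular_overlap((a, length + 1), (nb, length + 1), n):
                    break
                b, length = nb, length + 1
            for t in range(length):
                pa = (a + t) % n
                pb = (b + length - 1 - t) % n
                visited.add((pa, pb))
                visited.add((pb, pa))
            if length >= min_len:
                candidates.append((length, min(a, b) % n, max(a, b) % n))

    if not candidates:
        return None
    best_len = max(c[0] for c in candidates)
    best = sorted({c for c in candidates if c[0] == best_len})
    if len(best) > 1:
        warnings.warn(
            f"{len(best)} equally long inverted-repeat candidates of {best_len} bp; "
            "keeping the one with the smallest start"
        )
    length, a, b = best[0][0], best[0][1], best[0][2]

    # single-copy arcs between the repeats (0-based starts)
    arc1_start = (a + length) % n
    arc1_len = (b - arc1_start) % n
    arc2_start = (b + length) % n
    arc2_len = (a - arc2_start) % n
    if arc1_len == 0 or arc2_len == 0:
        return None  # repeats adjacent: no quadripartite structure
    if arc1_len >= arc2_len:
        lsc_start, lsc_len, ssc_len = arc1_start, arc1_len, arc2_len
        irb_start = b
    else:
        lsc_start, lsc_len, ssc_len = arc2_start, arc2_len, arc1_len
        irb_start = a

    jlb = lsc_len
    jsb = jlb + length
    jsa = jsb + ssc_len
    part = QuadripartitePartition(
        lsc=(1, jlb),
        irb=(jlb + 1, jsb),
        ssc=(jsb + 1, jsa),
        ira=(jsa + 1, n),
        junctions={"JLB": jlb, "JSB": jsb, "JSA": jsa, "JLA": n},
        ir_length=length,
        genome_length=n,
        rotation_offset=lsc_start,
    )
    canon = seq[lsc_start:] + seq[:lsc_start]
    part.region_gc = {
        r: _gc_percent(canon[part.interval(r)[0] - 1 : part.interval(r)[1]])
        for r in REGIONS
    }
    return part


def region_statistics(
    record: PlastomeRecord, partition: QuadripartitePartition
) -> tuple[dict[str, int], dict[str, float]]:
    """Region lengths (bp) and GC content (%, N excluded) on the canonical
    linearization. GC is reported to full precision; round to 1 decimal for
    display."""
    if partition.genome_length != len(record.sequence):
        raise ValueError(
            f"partition length {partition.genome_length} != genome length "
            f"{len(record.sequence)}"
        )
    canon = partition.canonical_record(record).sequence
    lengths, gc = {}, {}
    for region in REGIONS:
        start, end = partition.interval(region)
        lengths[region] = end - start + 1
        gc[region] = _gc_percent(canon[start - 1 : end])
    partition.region_length = lengths
    partition.region_gc = gc
    return lengths, gc


def _canonical_gene_spans(
    record: PlastomeRecord, partition: QuadripartitePartition
) -> list[tuple[str, int, int]]:
    """(gene, canonical start, canonical end) for junction reporting.

    Uses 'gene' features when present (real GenBank annotations), otherwise all
    annotated features. A span crossing the canonical origin is reported with
    end > genome length (unwrapped) so interval logic stays linear.
    """
    n = partition.genome_length
    feats = record.features_of_kind("gene") or record.features
    spans = []
    for feat in feats:
        pts = []
        for s, e in feat.segments:
            pts.append(partition.to_canonical(s))
            pts.append(partition.to_canonical(e))
        start, end = min(pts), max(pts)
        if end - start > n // 2:  # crosses the canonical origin
            over = [p for p in pts if p <= n // 2]
            under = [p for p in pts if p > n // 2]
            start, end = min(under), max(over) + n
        spans.append((feat.gene_name, start, end))
    return spans


def junction_report(
    record: PlastomeRecord, partition: QuadripartitePartition
) -> list[JunctionGeneReport]:
    """Genes spanning each junction (with bp on the IR side) and the nearest
    non-spanning gene on each flank."""
    n = partition.genome_length
    spans = _canonical_gene_spans(record, partition)
    reports: list[JunctionGeneReport] = []
    for junction in JUNCTIONS:
        j = partition.junctions[junction]
        ir_lo, ir_hi = partition.interval(IR_SIDE[junction])
        spanning = []
        for name, start, end in spans:
            # spans the boundary between j and j+1 iff it contains both,
            # i.e. start <= j <= end-1 (also testing the wrapped image j+n)
            covers = start <= j <= end - 1 or start <= j + n <= end - 1
            if covers:
                overlap = _interval_intersection(start, end, ir_lo, ir_hi, n)
                spanning.append((name, overlap))
        for name, overlap in spanning:
            reports.append(
                JunctionGeneReport(junction, name, "spans", overlap, 0)
            )
        span_names = {name for name, _ in spanning}
        up_best = down_best = None
        for name, start, end in spans:
            if name in span_names:
                continue
            d_up = (j - end) % n
            d_down = (start - (j + 1)) % n
            if up_best is None or d_up < up_best[1]:
                up_best = (name, d_up)
            if down_best is None or d_down < down_best[1]:
                down_best = (name, d_down)
        if up_best:
            reports.append(
                JunctionGeneReport(junction, up_best[0], "upstream", 0, up_best[1])
            )
        if down_best:
            reports.append(
                JunctionGeneReport(junction, down_best[0], "downstream", 0, down_best[1])
            )
    return reports


def _interval_intersection(s1: int, e1: int, s2: int, e2: int, n: int) -> int:
    """Intersection length of [s1,e1] (possibly unwrapped past n) with [s2,e2]."""
    total = max(0, min(e1, e2) - max(s1, s2) + 1)
    if e1 > n:  # also test the wrapped image
        total += max(0, min(e1 - n, e2) - max(s1 - n, s2) + 1)
    return total


def extract_lsc_irb_ssc(
    record: PlastomeRecord, partition: QuadripartitePartition
) -> str:
    """The phylogeny-ready LSC+IRb+SSC sequence (IRa excluded)."""
    if partition.genome_length != len(record.sequence):
        raise ValueError("partition does not match record")
    if partition.ir_length <= 0:
        raise ValueError("degenerate partition: no inverted repeat")
    canon = partition.canonical_record(record).sequence
    return canon[: partition.junctions["JSA"]]
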