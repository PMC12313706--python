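"""Synthetic plastome generator with known ground truth for every stage.

Everything is a pure function of (spec, seed): a quadripartite genome with a
planted inverted-repeat pair and annotated CDS (controllable per-position
codon composition), a divergence process with per-gene omega and GC-biased
mutation that keeps the IR copies exactly reverse-complementary, and smaller
generators for Ka/Ks recovery (codon pairs at a target synonymous divergence)
and for neutrality-plot calibration (gene sets whose third and first/second
codon positions share a gene-specific mutational GC pressure to a tunable
degree).

Default composition mimics an AT-rich plastid genome: intergenic GC ~ 0.28,
IR GC ~ 0.46 and third-position GC ~ 0.18.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .codon_usage import CodingSequence
from .genetics import BASES, STOP_CODONS, complement_base, reverse_complement, translate_codon
from .io import GeneFeature, PlastomeRecord
from .quadripartite import QuadripartitePartition, _gc_percent

_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class CodonModel:
    """Per-codon-position base weights (each position sums to 1)."""

    w1: dict[str, float]
    w2: dict[str, float]
    w3: dict[str, float]

    def __post_init__(self) -> None:
        for w in (self.w1, self.w2, self.w3):
            if set(w) != set(BASES) or abs(sum(w.values()) - 1.0) > 1e-9:
                raise ValueError("weights must cover A/C/G/T and sum to 1")

    def probs(self, position: int) -> np.ndarray:
        w = (self.w1, self.w2, self.w3)[position]
        return np.array([w[b] for b in BASES])


def _gc_weights(gc: float) -> dict[str, float]:
    return {"A": (1 - gc) / 2, "T": (1 - gc) / 2, "G": gc / 2, "C": gc / 2}


#: positional GC roughly 0.43 / 0.37 / 0.18, as in AT-rich plastomes
DEFAULT_CODON_MODEL = CodonModel(
    w1=_gc_weights(0.43), w2=_gc_weights(0.37), w3=_gc_weights(0.18)
)

UNIFORM_CODON_MODEL = CodonModel(
    w1=_gc_weights(0.5), w2=_gc_weights(0.5), w3=_gc_weights(0.5)
)


@dataclass(frozen=True)
class GeneSpec:
    name: str
    region: str  # LSC | SSC
    strand: str  # + | -
    n_codons: int  # total codons including start and stop
    junction: str | None = None  # JLB | JSB | JSA
    junction_overlap_bp: int = 0

    @property
    def length_bp(self) -> int:
        return 3 * self.n_codons

    def __post_init__(self) -> None:
        if self.region not in ("LSC", "SSC"):
            raise ValueError("genes are planted in LSC or SSC")
        if self.n_codons < 4:
            raise ValueError("a gene needs at least 4 codons")
        if self.junction not in (None, "JLB", "JSB", "JSA"):
            raise ValueError("supported junctions: JLB, JSB, JSA")
        if self.junction and not 0 < self.junction_overlap_bp < self.length_bp:
            raise ValueError("junction overlap must be inside the gene")


@dataclass(frozen=True)
class SyntheticPlastomeSpec:
    seed: int
    lsc_len: int = 12000
    ir_len: int = 2500
    ssc_len: int = 6000
    genes: tuple[GeneSpec, ...] = ()
    codon_model: CodonModel = DEFAULT_CODON_MODEL
    intergenic_gc: float = 0.28
    ir_gc: float = 0.46

    def __post_init__(self) -> None:
        if min(self.lsc_len, self.ir_len, self.ssc_len) <= 0:
            raise ValueError("region lengths must be positive")
        if self.lsc_len <= self.ssc_len:
            raise ValueError("LSC must be longer than SSC (canonical naming)")


@dataclass(frozen=True)
class DivergenceSpec:
    seed: int
    omega: dict[str, float] = field(default_factory=dict)
    default_omega: float = 0.2
    coding_rate: float = 0.01
    noncoding_rate: float = 0.04
    beta: float = 0.25  # probability a substitution lands on G or C
    constraint: float = 0.0  # fraction of codon positions 1-2 immune


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return bytes(rng.choice(_BASE_ARR, size=length, p=probs)).decode()


def _sample_codons(
    rng: np.random.Generator, count: int, model: CodonModel
) -> list[str]:
    """``count`` sense codons from the per-position weights (stops resampled)."""
    cols = [rng.choice(_BASE_ARR, size=count, p=model.probs(i)) for i in range(3)]
    codons = [bytes((a, b, c)).decode() for a, b, c in zip(*cols)]
    bad = [i for i, codon in enumerate(codons) if codon in STOP_CODONS]
    while bad:
        redraw = [rng.choice(_BASE_ARR, size=len(bad), p=model.probs(i)) for i in range(3)]
        for j, i in enumerate(bad):
            codons[i] = bytes((redraw[0][j], redraw[1][j], redraw[2][j])).decode()
        bad = [i for i in bad if codons[i] in STOP_CODONS]
    return codons


def generate_cds(
    rng: np.random.Generator, n_codons: int, model: CodonModel
) -> str:
    """ATG + (n_codons - 2) stop-free codons from the model + TAA."""
    return "ATG" + "".join(_sample_codons(rng, n_codons - 2, model)) + "TAA"


def _place_genes(
    spec: SyntheticPlastomeSpec,
) -> list[tuple[GeneSpec, int, int]]:
    """Assign (start, end) canonical coordinates to every gene, pinning
    junction-spanning genes and spacing the rest evenly in their region."""
    jlb = spec.lsc_len
    jsb = jlb + spec.ir_len
    jsa = jsb + spec.ssc_len
    placed: list[tuple[GeneSpec, int, int]] = []
    bounds = {"LSC": [1, jlb], "SSC": [jsb + 1, jsa]}
    free: dict[str, list[GeneSpec]] = {"LSC": [], "SSC": []}
    for g in spec.genes:
        if g.junction is None:
            free[g.region].append(g)
            continue
        ov = g.junction_overlap_bp
        if g.junction == "JLB":
            start, end = jlb - (g.length_bp - ov) + 1, jlb + ov
            bounds["LSC"][1] = min(bounds["LSC"][1], start - 1)
        elif g.junction == "JSB":
            start, end = jsb - ov + 1, jsb - ov + g.length_bp
            bounds["SSC"][0] = max(bounds["SSC"][0], end + 1)
        else:  # JSA
            start, end = jsa - (g.length_bp - ov) + 1, jsa + ov
            bounds["SSC"][1] = min(bounds["SSC"][1], start - 1)
        placed.append((g, start, end))
    for region, genes in free.items():
        lo, hi = bounds[region]
        total = sum(g.length_bp for g in genes)
        gap = (hi - lo + 1 - total) // (len(genes) + 1) if genes else 0
        if genes and gap < 20:
            names = [g.name for g in genes]
            raise ValueError(f"genes do not fit in {region}: {names}")
        cursor = lo + gap
        for g in genes:
            placed.append((g, cursor, cursor + g.length_bp - 1))
            cursor += g.length_bp + gap
    return sorted(placed, key=lambda t: t[1])


def _break_boundary_extension(
    genome: bytearray, coding: bytearray, pairs: list[tuple[int, int]]
) -> bool:
    """Ensure genome[p] != complement(genome[q]) for each boundary pair by
    rewriting an intergenic member; False when both members are coding."""
    for p, q in pairs:
        if chr(genome[p]) != complement_base(chr(genome[q])):
            continue
        if not coding[p]:
            target, other = p, q
        elif not coding[q]:
            target, other = q, p
        else:
            return False
        forbidden = complement_base(chr(genome[other]))
        # prefer an A<->T swap so extreme-composition genomes stay extreme
        genome[target] = ord(next(b for b in "ATGC" if b != forbidden))
    return True


def simulate_plastome(
    spec: SyntheticPlastomeSpec,
) -> tuple[PlastomeRecord, QuadripartitePartition]:
    """A circular LSC+IRb+SSC+IRa genome with IRa the exact reverse complement
    of IRb, annotated CDS with valid starts/stops and no internal stops, and
    the planted partition as ground truth. Deterministic given the spec."""
    rng = np.random.default_rng(spec.seed)
    n = spec.lsc_len + 2 * spec.ir_len + spec.ssc_len
    jlb = spec.lsc_len
    jsb = jlb + spec.ir_len
    jsa = jsb + spec.ssc_len

    backbone = bytearray(
        (
            _random_seq(rng, spec.lsc_len, spec.intergenic_gc)
            + _random_seq(rng, spec.ir_len, spec.ir_gc)
            + _random_seq(rng, spec.ssc_len, spec.intergenic_gc)
        ).encode()
    )
    backbone += reverse_complement(backbone[jlb:jsb].decode()).encode()

    placements = _place_genes(spec)
    coding = bytearray(n)
    for _, start, end in placements:
        for p in range(start - 1, end):
            coding[p] = 1
    features = [
        GeneFeature(
            gene_name=g.name, feature_kind="CDS", strand=g.strand,
            segments=((start, end),),
        )
        for g, start, end in placements
    ]

    # Genes spanning JSB and JSA share mirrored inverted-repeat sequence, so
    # independently sampled genes can conflict after mirroring (an induced
    # internal stop). Resample until every planted CDS survives mirroring;
    # the loop draws from the same stream, so the result is seed-deterministic.
    from .codon_usage import assemble_cds, filter_cds

    record = None
    for _ in range(100):
        genome = bytearray(backbone)
        ira_written: list[int] = []  # 0-based gene positions inside IRa
        for gene, start, end in placements:
            seq = generate_cds(rng, gene.n_codons, spec.codon_model)
            if gene.strand == "-":
                seq = reverse_complement(seq)
            genome[start - 1 : end] = seq.encode()
            ira_written.extend(p for p in range(start - 1, end) if p >= jsa)
        # mirror gene bases written inside IRa back into IRb, then rebuild
        # IRa from IRb so the repeat pair is exactly reverse-complementary
        for p in ira_written:
            t = p - jsa
            genome[jlb + (spec.ir_len - 1 - t)] = ord(
                complement_base(chr(genome[p]))
            )
        genome[jsa:n] = reverse_complement(genome[jlb:jsb].decode()).encode()
        # make the planted repeat maximal: seed-and-extend must stop exactly
        # at the four junctions, so the base just outside each IR end must not
        # be reverse-complementary to its counterpart outside the other copy
        if not _break_boundary_extension(genome, coding, [(jlb - 1, 0), (jsb, jsa - 1)]):
            continue  # both boundary bases inside genes and complementary: resample
        candidate = PlastomeRecord(
            identifier=f"SYNP{spec.seed:05d}",
            organism=f"Plastoma simulatum s{spec.seed}",
            sequence=genome.decode(),
            is_circular=True,
            features=features,
        )
        min_len = min((g.length_bp for g in spec.genes), default=300)
        if not filter_cds(assemble_cds(candidate), min_len=min(300, min_len)).rejected:
            record = candidate
            break
    if record is None:
        raise RuntimeError("could not build a conflict-free genome in 100 attempts")

    sequence = record.sequence
    partition = QuadripartitePartition(
        lsc=(1, jlb),
        irb=(jlb + 1, jsb),
        ssc=(jsb + 1, jsa),
        ira=(jsa + 1, n),
        junctions={"JLB": jlb, "JSB": jsb, "JSA": jsa, "JLA": n},
        ir_length=spec.ir_len,
        genome_length=n,
        rotation_offset=0,
    )
    partition.region_gc = {
        r: _gc_percent(sequence[partition.interval(r)[0] - 1 : partition.interval(r)[1]])
        for r in ("LSC", "IRb", "SSC", "IRa")
    }
    return record, partition


def _draw_base(rng: np.random.Generator, beta: float) -> str:
    """G/C with probability beta (split evenly), A/T otherwise."""
    if rng.random() < beta:
        return "G" if rng.random() < 0.5 else "C"
    return "A" if rng.random() < 0.5 else "T"


def diverge_genome(
    record: PlastomeRecord,
    dspec: DivergenceSpec,
    partition: QuadripartitePartition | None = None,
) -> PlastomeRecord:
    """A derived genome: i.i.d. substitutions at the noncoding rate outside
    genes, proposal/acceptance substitutions inside genes, and IR copies
    co-mutated so they remain exact reverse complements.

    Per-gene omega sets the relative fixation probability of nonsynonymous vs
    synonymous proposals: synonymous changes are accepted with min(1, 1/omega)
    and nonsynonymous with min(1, omega), so omega > 1 genuinely favours
    amino-acid change. Stops are never created; start and stop codons are left
    untouched so derived CDS stay filter-valid.
    """
    from .quadripartite import detect_inverted_repeats

    if partition is None:
        partition = detect_inverted_repeats(record.sequence)
    if partition is not None and partition.rotation_offset != 0:
        raise ValueError("diverge_genome expects a canonically linearized record")
    rng = np.random.default_rng(dspec.seed)
    genome = bytearray(record.sequence.encode())
    n = len(genome)

    coding_mask = bytearray(n)
    for feat in record.features_of_kind("CDS"):
        for s, e in feat.segments:
            for p in range(s - 1, e):
                coding_mask[p] = 1

    ira_lo = partition.ira[0] - 1 if partition else n  # 0-based
    irb_lo = partition.irb[0] - 1 if partition else None
    ir_len = partition.ir_length if partition else 0

    # coding sites whose mirror image in the other IR copy is also coding
    # belong to two genes at once; freeze them so co-mutation cannot break
    # either gene's reading frame
    frozen: set[int] = set()
    for p in range(ira_lo, ira_lo + ir_len):
        q = irb_lo + (ir_len - 1 - (p - ira_lo))
        if coding_mask[p] and coding_mask[q]:
            frozen.add(p)
            frozen.add(q)

    changed_in_ira: list[int] = []

    def write(p: int, base: str) -> None:
        genome[p] = ord(base)
        if p >= ira_lo:
            changed_in_ira.append(p)

    # coding sites, gene by gene on the coding strand
    for feat in record.features_of_kind("CDS"):
        omega = dspec.omega.get(feat.gene_name, dspec.default_omega)
        p_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
        p_nonsyn = min(1.0, omega)
        (s, e), strand = feat.segments[0], feat.strand
        length = e - s + 1

        def genome_pos(i: int) -> int:
            return (s - 1 + i) if strand == "+" else (e - 1 - i)

        def coding_base(i: int) -> str:
            b = chr(genome[genome_pos(i)])
            return b if strand == "+" else complement_base(b)

        for ci in range(1, length // 3 - 1):  # skip start and stop codons
            for pos in range(3):
                if pos < 2 and rng.random() < dspec.constraint:
                    continue
                if rng.random() >= dspec.coding_rate:
                    continue
                i = 3 * ci + pos
                if genome_pos(i) in frozen:
                    continue
                new = _draw_base(rng, dspec.beta)
                if new == coding_base(i):
                    continue
                codon = "".join(coding_base(3 * ci + k) for k in range(3))
                alt = codon[:pos] + new + codon[pos + 1 :]
                if alt in STOP_CODONS:
                    continue
                accept = (
                    p_nonsyn
                    if translate_codon(alt) != translate_codon(codon)
                    else p_syn
                )
                if rng.random() >= accept:
                    continue
                write(genome_pos(i), new if strand == "+" else complement_base(new))

    # noncoding sites (IRa handled by mirroring from IRb)
    for p in range(ira_lo):
        if coding_mask[p]:
            continue
        if rng.random() < dspec.noncoding_rate:
            write(p, _draw_base(rng, dspec.beta))

    if partition is not None:
        for p in changed_in_ira:
            t = p - ira_lo
            genome[irb_lo + (ir_len - 1 - t)] = ord(complement_base(chr(genome[p])))
        genome[ira_lo : ira_lo + ir_len] = reverse_complement(
            genome[irb_lo : irb_lo + ir_len].decode()
        ).encode()

    return PlastomeRecord(
        identifier=f"{record.identifier}.d{dspec.seed}",
        organism=f"{record.organism} der. {dspec.seed}",
        sequence=genome.decode(),
        is_circular=record.is_circular,
        features=list(record.features),
    )


def simulate_codon_pair(
    n_codons: int,
    omega: float,
    target_ks: float,
    seed: int,
    model: CodonModel = DEFAULT_CODON_MODEL,
) -> tuple[CodingSequence, CodingSequence]:
    """An ancestor/descendant CDS pair at expected synonymous divergence
    ~``target_ks`` and nonsynonymous/synonymous rate ratio ``omega``.

    Proposals are uniform over sites and alternative bases (Jukes-Cantor-like);
    synonymous proposals fix with probability min(1, 1/omega) and nonsynonymous
    ones with min(1, omega), so omega > 1 favours amino-acid change. The
    proposal count is scaled so the accepted synonymous divergence per
    synonymous site stays ~target_ks; stop codons are never created.
    """
    if n_codons <= 0 or target_ks < 0 or omega < 0:
        raise ValueError("n_codons must be positive; target_ks and omega non-negative")
    rng = np.random.default_rng(seed)
    ancestor = _sample_codons(rng, n_codons, model)
    derived = list(ancestor)
    p_syn = min(1.0, 1.0 / omega) if omega > 0 else 1.0
    p_nonsyn = min(1.0, omega)
    for _ in range(round(3 * n_codons * target_ks / p_syn)):
        ci = int(rng.integers(n_codons))
        pos = int(rng.integers(3))
        codon = derived[ci]
        new = BASES[int(rng.integers(4))]
        if new == codon[pos]:
            continue
        alt = codon[:pos] + new + codon[pos + 1 :]
        if alt in STOP_CODONS:
            continue
        accept = (
            p_nonsyn if translate_codon(alt) != translate_codon(codon) else p_syn
        )
        if rng.random() >= accept:
            continue
        derived[ci] = alt
    label = f"pair{seed}"
    return (
        CodingSequence(label, "ancestor", "".join(ancestor)),
        CodingSequence(label, "derived", "".join(derived)),
    )


def simulate_neutrality_geneset(
    n_genes: int,
    beta: float = 0.5,
    constraint: float = 0.0,
    n_codons: int = 300,
    seed: int = 0,
    spread: float = 0.2,
) -> list[CodingSequence]:
    """Gene set for neutrality-plot calibration.

    Each gene draws its own mutational GC pressure g around ``beta``; the
    third codon position always follows g, while positions 1-2 follow
    constraint * beta + (1 - constraint) * g — so constraint=0 makes P12 track
    P3 (slope ~1) and constraint=1 freezes positions 1-2 at the global
    composition (slope ~0).
    """
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(n_genes):
        g = float(np.clip(rng.uniform(beta - spread, beta + spread), 0.05, 0.95))
        g12 = constraint * beta + (1.0 - constraint) * g
        model = CodonModel(w1=_gc_weights(g12), w2=_gc_weights(g12), w3=_gc_weights(g))
        genes.append(
            CodingSequence(
                gene_name=f"gene{i + 1:03d}",
                species_label="neutrality-sim",
                dna=generate_cds(rng, n_codons, model),
            )
        )
    return genes


def simulate_gc3_geneset(
    n_genes: int,
    n_codons: int = 2000,
    seed: int = 0,
    gc3_range: tuple[float, float] = (0.1, 0.9),
) -> list[CodingSequence]:
    """Genes whose codon usage is driven only by third-position GC content
    (positions 1-2 uniform; within-family parity A=T, G=C) — the regime in
    which observed ENC should trace Wright's expected curve."""
    rng = np.random.default_rng(seed)
    genes = []
    for i in range(n_genes):
        s = float(rng.uniform(*gc3_range))
        model = CodonModel(w1=_gc_weights(0.5), w2=_gc_weights(0.5), w3=_gc_weights(s))
        genes.append(
            CodingSequence(
                gene_name=f"mut{i + 1:03d}",
                species_label="gc3-sim",
                dna=generate_cds(rng, n_codons, model),
            )
        )
    return genes


def simulate_selection_geneset(
    n_genes: int,
    n_codons: int = 500,
    seed: int = 0,
    preference: float = 0.85,
) -> list[CodingSequence]:
    """Genes under strong translational selection: within every synonymous
    family one fixed preferred codon is used with probability ``preference``.
    Observed ENC falls well below the expected curve (positive deviations)."""
    from .genetics import AA_TO_CODONS

    rng = np.random.default_rng(seed)
    preferred = {aa: fam[int(rng.integers(len(fam)))] for aa, fam in AA_TO_CODONS.items()}
    aas = sorted(AA_TO_CODONS)
    genes = []
    for i in range(n_genes):
        codons = []
        for _ in range(n_codons - 2):
            aa = aas[int(rng.integers(len(aas)))]
            fam = AA_TO_CODONS[aa]
            if rng.random() < preference:
                codons.append(preferred[aa])
            else:
                codons.append(fam[int(rng.integers(len(fam)))])
        genes.append(
            CodingSequence(
                gene_name=f"sel{i + 1:03d}",
                species_label="selection-sim",
                dna="ATG" + "".join(codons) + "TAA",
            )
        )
    return genes


def default_gene_roster() -> tuple[GeneSpec, ...]:
    """A desk-scale plastome gene roster: LSC and SSC genes plus the two
    junction-spanning genes seen at plastid IR borders (an ndhF-like gene
    reaching 64 bp into IRb and a chlL-like gene reaching 5 bp into IRa)."""
    return (
        GeneSpec("psbA", "LSC", "-", 240),
        GeneSpec("matK", "LSC", "+", 300),
        GeneSpec("atpA", "LSC", "+", 260),
        GeneSpec("rbcL", "LSC", "+", 320),
        GeneSpec("petB", "LSC", "+", 150),
        GeneSpec("rpoB", "LSC", "+", 360),
        GeneSpec("psbD", "LSC", "+", 200),
        GeneSpec("ycf66", "LSC", "-", 140),
        GeneSpec("clpP", "LSC", "-", 130),
        GeneSpec("ndhF", "SSC", "-", 250, junction="JSB", junction_overlap_bp=64),
        GeneSpec("ndhD", "SSC", "+", 170),
        GeneSpec("ycf1", "SSC", "+", 400),
        GeneSpec("ndhA", "SSC", "-", 120),
        GeneSpec("chlL", "SSC", "+", 110, junction="JSA", junction_overlap_bp=5),
    )
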