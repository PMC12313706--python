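"""Reading and writing annotated plastid genomes.

The shared data model is :class:`PlastomeRecord`: an (optionally circular)
DNA sequence plus an ordered list of :class:`GeneFeature` annotations with
1-based inclusive coordinates, the GenBank convention. GenBank flat files are
parsed with Biopython; compound ``join``/``complement`` locations are resolved
into ordered segments, ``order(...)`` and mixed-strand locations are flagged
as trans-spliced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .genetics import reverse_complement

VALID_BASES = frozenset("ACGTN")
FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "gene")


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature in genome coordinates (1-based inclusive)."""

    gene_name: str
    feature_kind: str  # CDS | tRNA | rRNA | gene
    strand: str  # '+' | '-'
    segments: tuple[tuple[int, int], ...]
    is_trans_spliced: bool = False
    transl_table: int = 11
    wraps_origin: bool = False

    def __post_init__(self) -> None:
        if self.feature_kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.feature_kind!r}")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.segments:
            raise ValueError("feature needs at least one segment")
        for start, end in self.segments:
            if start < 1 or end < start:
                raise ValueError(f"bad segment ({start}, {end})")

    @property
    def span(self) -> tuple[int, int]:
        """(min start, max end) over all segments."""
        return (min(s for s, _ in self.segments), max(e for _, e in self.segments))

    @property
    def length(self) -> int:
        return sum(e - s + 1 for s, e in self.segments)


@dataclass
class PlastomeRecord:
    """A circular annotated plastid genome."""

    identifier: str
    organism: str
    sequence: str
    is_circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.identifier}: empty sequence")
        seq = self.sequence.upper()
        if set(seq) - VALID_BASES:
            bad = sorted(set(seq) - VALID_BASES)
            warnings.warn(
                f"{self.identifier}: ambiguity codes {bad} normalized to N"
            )
            seq = "".join(c if c in VALID_BASES else "N" for c in seq)
        self.sequence = seq
        for feat in self.features:
            _, end = feat.span
            if end > len(seq) and not (self.is_circular and feat.wraps_origin):
                raise ValueError(
                    f"{self.identifier}: feature {feat.gene_name} exceeds genome "
                    f"length {len(seq)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def features_of_kind(self, kind: str) -> list[GeneFeature]:
        return [f for f in self.features if f.feature_kind == kind]


def _location_to_segments(location) -> tuple[tuple[tuple[int, int], ...], str, bool]:
    """Convert a Biopython location to 1-based segments + strand + trans flag."""
    parts = location.parts if isinstance(location, CompoundLocation) else [location]
    strands = {p.strand for p in parts}
    trans = isinstance(location, CompoundLocation) and (
        location.operator == "order" or len(strands) > 1
    )
    strand = "-" if location.strand == -1 else "+"
    segments = tuple((int(p.start) + 1, int(p.end)) for p in parts)
    if strand == "-":
        # complement(join(...)) reads 3'->5' of the genome; store segments in
        # ascending genomic order so extraction is rc(concatenation).
        segments = tuple(sorted(segments))
    return segments, strand, trans


def _feature_name(feat: SeqFeature) -> str:
    for key in ("gene", "product", "locus_tag"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return "unknown"


def read_genbank(path: str | Path) -> list[PlastomeRecord]:
    """Parse a GenBank flat file into one :class:`PlastomeRecord` per entry.

    A record without sequence is a hard error; a feature whose location cannot
    be interpreted is skipped with a warning, never silently.
    """
    records = []
    for rec in SeqIO.parse(str(path), "genbank"):
        try:
            seq = str(rec.seq)
        except Exception as exc:  # undefined sequence
            raise ValueError(f"{rec.id}: GenBank record has no sequence") from exc
        if not seq:
            raise ValueError(f"{rec.id}: GenBank record has no sequence")
        organism = rec.annotations.get("organism", "")
        circular = rec.annotations.get("topology", "linear") == "circular"
        features: list[GeneFeature] = []
        for feat in rec.features:
            if feat.type not in FEATURE_KINDS:
                continue
            try:
                segments, strand, trans = _location_to_segments(feat.location)
                table = int(feat.qualifiers.get("transl_table", [11])[0])
                trans = trans or "trans_splicing" in feat.qualifiers
                features.append(
                    GeneFeature(
                        gene_name=_feature_name(feat),
                        feature_kind=feat.type,
                        strand=strand,
                        segments=segments,
                        is_trans_spliced=trans,
                        transl_table=table,
                    )
                )
            except Exception as exc:
                warnings.warn(
                    f"{rec.id}: skipping feature with unparseable location "
                    f"({feat.type} {feat.location}): {exc}"
                )
        records.append(
            PlastomeRecord(
                identifier=rec.id,
                organism=organism,
                sequence=seq,
                is_circular=circular,
                features=features,
            )
        )
    return records


def extract_feature_sequence(record: PlastomeRecord, feature: GeneFeature) -> str:
    """Feature sequence, 5'->3' on the coding strand.

    Segments are concatenated in annotation order; minus-strand features return
    the reverse complement of the concatenation.
    """
    n = len(record.sequence)
    chunks = []
    for start, end in feature.segments:
        if end > n:
            if not record.is_circular:
                raise ValueError(
                    f"{feature.gene_name}: segment ({start}, {end}) out of bounds "
                    f"on linear record of length {n}"
                )
            # wrap past the origin
            chunks.append(record.sequence[start - 1 :] + record.sequence[: end - n])
        else:
            chunks.append(record.sequence[start - 1 : end])
    seq = "".join(chunks)
    return reverse_complement(seq) if feature.strand == "-" else seq


def write_fasta(sequences: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write (label, sequence) pairs as FASTA wrapped at 70 columns."""
    labels = [label for label, _ in sequences]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise ValueError(f"duplicate FASTA labels: {dupes}")
    with open(path, "w") as fh:
        for label, seq in sequences:
            fh.write(f">{label}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as (label, uppercase sequence) pairs."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def _segments_to_location(feature: GeneFeature):
    parts = []
    strand = -1 if feature.strand == "-" else 1
    segs = feature.segments if strand == 1 else tuple(reversed(feature.segments))
    for start, end in segs:
        parts.append(SimpleLocation(start - 1, end, strand=strand))
    if len(parts) == 1:
        return parts[0]
    return CompoundLocation(parts, operator="order" if feature.is_trans_spliced else "join")


def write_genbank(records: Iterable[PlastomeRecord], path: str | Path) -> None:
    """Write records as a GenBank flat file (round-trips with read_genbank)."""
    out = []
    for rec in records:
        sr = SeqRecord(
            Seq(rec.sequence),
            id=rec.identifier,
            name=rec.identifier.replace(".", "_")[:16],
            description=rec.organism,
            annotations={
                "molecule_type": "DNA",
                "topology": "circular" if rec.is_circular else "linear",
                "organism": rec.organism,
            },
        )
        for feat in rec.features:
            qualifiers = {"gene": [feat.gene_name]}
            if feat.feature_kind == "CDS":
                qualifiers["transl_table"] = [str(feat.transl_table)]
            if feat.is_trans_spliced:
                qualifiers["trans_splicing"] = [""]
            sr.features.append(
                SeqFeature(
                    _segments_to_location(feat),
                    type=feat.feature_kind,
                    qualifiers=qualifiers,
                )
            )
        out.append(sr)
    SeqIO.write(out, str(path), "genbank")


def rotate_record(record: PlastomeRecord, offset: int) -> PlastomeRecord:
    """Rotate a circular record left by ``offset`` bases (new origin at offset+1).

    Features crossing the new origin are split into two segments and flagged
    ``wraps_origin``.
    """
    if not record.is_circular:
        raise ValueError("can only rotate a circular record")
    n = len(record.sequence)
    offset %= n
    seq = record.sequence[offset:] + record.sequence[:offset]
    features = []
    for feat in record.features:
        segments: list[tuple[int, int]] = []
        wraps = False
        for start, end in feat.segments:
            s = (start - 1 - offset) % n + 1
            e = (end - 1 - offset) % n + 1
            if s <= e:
                segments.append((s, e))
            else:  # crosses the new origin
                segments.append((s, n))
                segments.append((1, e))
                wraps = True
        # re-merge segments that were split by a previous rotation
        merged = [segments[0]]
        for s, e in segments[1:]:
            if s == merged[-1][1] + 1:
                merged[-1] = (merged[-1][0], e)
            else:
                merged.append((s, e))
        segments = merged
        if feat.strand == "-" and not wraps:
            segments.sort()
        features.append(
            replace(feat, segments=tuple(segments), wraps_origin=wraps)
        )
    return PlastomeRecord(
        identifier=record.identifier,
        organism=record.organism,
        sequence=seq,
        is_circular=True,
        features=features,
    )
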