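"""Sliding-window nucleotide diversity over a multiple-genome alignment.

Nucleotide diversity pi is the mean proportion of differing sites over all
sequence pairs. Within each window, alignment columns containing any gap or N
are excluded entirely (from numerator and denominator), following common
DnaSP practice; windows are defined on alignment coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import combinations
from typing import Sequence

import numpy as np

from .io import PlastomeRecord

NAN = float("nan")

_CODES = {b: i for i, b in enumerate("ACGT")}


@dataclass
class AlignmentMatrix:
    labels: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.rows):
            raise ValueError("one label per row required")
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 sequences")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def n(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def to_array(self) -> np.ndarray:
        """(n, L) int8 matrix; A/C/G/T -> 0..3, gap/N/other -> -1."""
        arr = np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype=np.uint8
        ).reshape(self.n, self.length)
        out = np.full(arr.shape, -1, dtype=np.int8)
        for base, code in _CODES.items():
            out[arr == ord(base)] = code
        return out


@dataclass
class WindowDiversity:
    start: int  # 1-based inclusive, alignment coordinates
    end: int
    midpoint: int
    usable_sites: int
    pi: float
    truncated: bool = False
    label: str | None = None


def _pi_from_array(arr: np.ndarray) -> tuple[float, int]:
    n = arr.shape[0]
    usable = (arr >= 0).all(axis=0)
    m = int(usable.sum())
    if m == 0:
        return NAN, 0
    sub = arr[:, usable]
    total = 0.0
    for i, j in combinations(range(n), 2):
        total += np.count_nonzero(sub[i] != sub[j]) / m
    return 2.0 * total / (n * (n - 1)), m


def nucleotide_diversity(
    alignment: AlignmentMatrix, start: int = 1, end: int | None = None
) -> tuple[float, int]:
    """pi and the usable-site count over alignment columns [start, end]
    (1-based inclusive). Columns with any gap or N are excluded; zero usable
    sites gives (NaN, 0)."""
    end = alignment.length if end is None else end
    arr = alignment.to_array()[:, start - 1 : end]
    return _pi_from_array(arr)


def sliding_windows(
    alignment: AlignmentMatrix, window: int = 600, step: int = 200
) -> list[WindowDiversity]:
    """Windows at starts 1, 1+step, ... while the full window fits.

    A window longer than the alignment collapses to a single truncated window
    covering everything.
    """
    if not window >= step >= 1:
        raise ValueError("require window >= step >= 1")
    length = alignment.length
    arr = alignment.to_array()
    out: list[WindowDiversity] = []
    if window > length:
        pi, usable = _pi_from_array(arr)
        return [
            WindowDiversity(1, length, (1 + length) // 2, usable, pi, truncated=True)
        ]
    start = 1
    while start + window - 1 <= length:
        end = start + window - 1
        pi, usable = _pi_from_array(arr[:, start - 1 : end])
        out.append(WindowDiversity(start, end, (start + end) // 2, usable, pi))
        start += step
    return out


def diversity_summary(windows: Sequence[WindowDiversity]) -> dict[str, float]:
    """Genome-wide mean pi over windows with usable sites, and the maximum."""
    defined = [w for w in windows if w.usable_sites > 0]
    if not defined:
        return {"mean_pi": NAN, "max_pi": NAN, "n_windows": 0.0}
    best = max(defined, key=lambda w: w.pi)
    return {
        "mean_pi": sum(w.pi for w in defined) / len(defined),
        "max_pi": best.pi,
        "max_window_start": float(best.start),
        "max_window_end": float(best.end),
        "n_windows": float(len(defined)),
    }


def column_to_position_map(alignment: AlignmentMatrix, ref_label: str) -> list[int | None]:
    """Map each alignment column (0-based) to a 1-based position in the
    reference genome, or None where the reference row has a gap."""
    try:
        row = alignment.rows[alignment.labels.index(ref_label)]
    except ValueError:
        raise ValueError(f"reference label {ref_label!r} not in alignment") from None
    out: list[int | None] = []
    pos = 0
    for ch in row:
        if ch == "-":
            out.append(None)
        else:
            pos += 1
            out.append(pos)
    return out


def label_windows(
    windows: Sequence[WindowDiversity],
    record: PlastomeRecord,
    column_map: Sequence[int | None],
) -> list[WindowDiversity]:
    """Annotate each window by the gene(s) at its mapped midpoint, the
    flanking pair "upstream~downstream" for intergenic midpoints, or
    "unaligned" when the reference is gapped there."""
    genes = []
    feats = record.features_of_kind("gene") or record.features
    for feat in feats:
        start, end = feat.span
        genes.append((start, end, feat.gene_name))
    genes.sort()
    out = []
    for w in windows:
        pos = column_map[w.midpoint - 1]
        if pos is None:
            label = "unaligned"
        else:
            hits = [name for s, e, name in genes if s <= pos <= e]
            if hits:
                label = "/".join(dict.fromkeys(hits))
            else:
                label = f"{_nearest_flank(genes, pos, len(record))}"
        out.append(replace(w, label=label))
    return out


def _nearest_flank(
    genes: list[tuple[int, int, str]], pos: int, genome_len: int
) -> str:
    if not genes:
        return "intergenic"
    up = min(genes, key=lambda g: (pos - g[1]) % genome_len)
    down = min(genes, key=lambda g: (g[0] - pos) % genome_len)
    return f"{up[2]}~{down[2]}"
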