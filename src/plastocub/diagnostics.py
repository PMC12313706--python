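"""Inferential codon-usage diagnostics: ENC-GC3s, PR2 and the neutrality plot.

These three analyses separate mutation pressure from selection as drivers of
codon usage bias. Genes shaped by mutation alone fall on Wright's expected
ENC curve, sit at the PR2 parity point (0.5, 0.5), and give a neutrality
regression (P12 on P3) with slope near 1; selection pulls ENC below the
curve, displaces PR2 points, and flattens the neutrality slope towards 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

from scipy import stats

from .codon_usage import GeneCUBMetrics

NAN = float("nan")


@dataclass(frozen=True)
class EncGc3sPoint:
    gene_name: str
    gc3s: float
    enc_observed: float
    enc_expected: float
    deviation: float  # (expected - observed) / expected


@dataclass(frozen=True)
class Pr2Point:
    gene_name: str
    x: float  # G3s / (G3s + C3s)
    y: float  # A3s / (A3s + T3s)
    quadrant: str


@dataclass(frozen=True)
class NeutralityRegressionResult:
    slope: float
    intercept: float
    pearson_r: float
    p_value: float
    n_genes: int
    mutation_share: float  # slope as percent


def expected_enc(gc3s: float) -> float:
    """Wright's expected ENC under mutation pressure alone at synonymous
    third-position GC content ``s``: 2 + s + 29 / (s^2 + (1-s)^2)."""
    if not 0.0 <= gc3s <= 1.0:
        raise ValueError(f"gc3s must be in [0, 1], got {gc3s}")
    return 2.0 + gc3s + 29.0 / (gc3s**2 + (1.0 - gc3s) ** 2)


def enc_gc3s_analysis(
    metrics: Sequence[GeneCUBMetrics],
) -> tuple[list[EncGc3sPoint], dict[str, float]]:
    """Per-gene ENC-GC3s points with relative deviation from the expected
    curve; genes with undefined ENC or GC3s are skipped and counted."""
    points: list[EncGc3sPoint] = []
    skipped = 0
    for m in metrics:
        if math.isnan(m.enc) or math.isnan(m.gc3s):
            skipped += 1
            continue
        exp = expected_enc(m.gc3s)
        points.append(
            EncGc3sPoint(m.gene_name, m.gc3s, m.enc, exp, (exp - m.enc) / exp)
        )
    if points:
        mean_dev = sum(p.deviation for p in points) / len(points)
        frac_below = sum(p.enc_observed < p.enc_expected for p in points) / len(points)
    else:
        mean_dev = frac_below = NAN
    summary = {
        "n_genes": float(len(points)),
        "n_skipped": float(skipped),
        "mean_deviation": mean_dev,
        "mean_abs_deviation": (
            sum(abs(p.deviation) for p in points) / len(points) if points else NAN
        ),
        "fraction_below_curve": frac_below,
    }
    return points, summary


def _quadrant(x: float, y: float) -> str:
    if x == 0.5 or y == 0.5:
        return "center"
    horiz = "right" if x > 0.5 else "left"
    vert = "upper" if y > 0.5 else "lower"
    return f"{vert}-{horiz}"


def pr2_analysis(
    metrics: Sequence[GeneCUBMetrics],
    fourfold_only: bool = False,
) -> tuple[list[Pr2Point], dict[str, int]]:
    """PR2 bias coordinates y = A3s/(A3s+T3s) vs x = G3s/(G3s+C3s), with
    quadrant counts relative to the parity point (0.5, 0.5).

    With ``fourfold_only`` the axes are computed over the 8 four-fold
    degenerate codon boxes instead of the default A3s/T3s/G3s/C3s exclusion
    set. The default set keeps 15 T-ending and 15 C-ending but only 13 A- and
    13 G-ending codons eligible, so even unbiased usage sits slightly
    lower-left of (0.5, 0.5); four-fold boxes make parity exact.
    """
    points: list[Pr2Point] = []
    counts = {
        "upper-left": 0, "upper-right": 0, "lower-left": 0,
        "lower-right": 0, "center": 0, "skipped": 0,
    }
    for m in metrics:
        if fourfold_only:
            a, t, g, c = m.a3f, m.t3f, m.g3f, m.c3f
        else:
            a, t, g, c = m.a3s, m.t3s, m.g3s, m.c3s
        at = a + t
        gc = g + c
        if not at > 0 or not gc > 0 or math.isnan(at) or math.isnan(gc):
            counts["skipped"] += 1
            continue
        x = g / gc
        y = a / at
        quad = _quadrant(x, y)
        counts[quad] += 1
        points.append(Pr2Point(m.gene_name, x, y, quad))
    return points, counts


def neutrality_regression(
    metrics: Sequence[GeneCUBMetrics],
) -> NeutralityRegressionResult:
    """Ordinary least squares of P12 on P3 across genes, with Pearson r and
    its exact two-sided t-test p-value (n - 2 degrees of freedom)."""
    xy = [
        (m.p3, m.p12)
        for m in metrics
        if not (math.isnan(m.p3) or math.isnan(m.p12))
    ]
    if len(xy) < 3:
        raise ValueError(
            f"neutrality regression needs >= 3 genes with defined P12 and P3, got {len(xy)}"
        )
    x = [p for p, _ in xy]
    y = [q for _, q in xy]
    if max(x) == min(x):
        raise ValueError("neutrality regression undefined: variance of P3 is zero")
    fit = stats.linregress(x, y)
    return NeutralityRegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        n_genes=len(xy),
        mutation_share=float(fit.slope) * 100.0,
    )
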