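"""ENC-GC3s curve, PR2 parity coordinates and the neutrality regression."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from plastocub.codon_usage import GeneCUBMetrics, gene_cub_metrics
from plastocub.diagnostics import (
    enc_gc3s_analysis,
    expected_enc,
    neutrality_regression,
    pr2_analysis,
)
from plastocub.simulate import (
    simulate_gc3_geneset,
    simulate_neutrality_geneset,
    simulate_selection_geneset,
)

NAN = float("nan")


def _metrics(**kw):
    base = dict(
        gene_name="g", species_label="s", gc1=NAN, gc2=NAN, gc3=NAN,
        p1=NAN, p2=NAN, p3=NAN, p12=NAN, a3s=NAN, t3s=NAN, c3s=NAN, g3s=NAN,
        gc3s=NAN, enc=NAN, n_codons=0,
    )
    base.update(kw)
    return GeneCUBMetrics(**base)


# ---------------------------------------------------------------- expected ENC

def test_expected_enc_closed_form_values():
    assert expected_enc(0.0) == pytest.approx(31.0)
    assert expected_enc(0.5) == pytest.approx(60.5)
    assert expected_enc(0.1804) == pytest.approx(43.36, abs=0.01)
    with pytest.raises(ValueError):
        expected_enc(1.2)


@given(st.floats(0.0, 1.0))
@settings(max_examples=100, deadline=None)
def test_expected_enc_symmetric_up_to_linear_term(s):
    assert expected_enc(s) - s == pytest.approx(expected_enc(1 - s) - (1 - s))


# ---------------------------------------------------------------- ENC-GC3s

def test_gene_on_curve_has_zero_deviation():
    m = _metrics(gc3s=0.3, enc=expected_enc(0.3))
    points, summary = enc_gc3s_analysis([m])
    assert points[0].deviation == pytest.approx(0.0)
    assert summary["n_skipped"] == 0


def test_undefined_enc_is_skipped_and_counted():
    points, summary = enc_gc3s_analysis([_metrics(gc3s=0.3, enc=NAN)])
    assert not points and summary["n_skipped"] == 1


def test_mutation_only_genes_trace_the_expected_curve():
    genes = simulate_gc3_geneset(30, n_codons=2000, seed=3)
    _, summary = enc_gc3s_analysis([gene_cub_metrics(g) for g in genes])
    assert summary["mean_abs_deviation"] < 0.05


def test_selected_genes_fall_below_the_curve():
    genes = simulate_selection_geneset(20, n_codons=500, seed=3)
    points, summary = enc_gc3s_analysis([gene_cub_metrics(g) for g in genes])
    assert summary["fraction_below_curve"] == 1.0
    assert all(p.deviation > 0 for p in points)


# ---------------------------------------------------------------- PR2

def test_pr2_parity_and_arithmetic():
    center = _metrics(a3s=0.2, t3s=0.2, g3s=0.3, c3s=0.3)
    points, counts = pr2_analysis([center])
    assert (points[0].x, points[0].y) == (0.5, 0.5)
    assert points[0].quadrant == "center" and counts["center"] == 1

    # third-base tallies A=10, T=30, G=20, C=40 (fractions /100)
    m = _metrics(a3s=0.1, t3s=0.3, g3s=0.2, c3s=0.4)
    points, counts = pr2_analysis([m])
    assert points[0].y == pytest.approx(0.25)
    assert points[0].x == pytest.approx(1 / 3)
    assert points[0].quadrant == "lower-left"


def test_pr2_skips_genes_with_empty_denominators():
    _, counts = pr2_analysis([_metrics(a3s=0.0, t3s=0.0, g3s=0.5, c3s=0.5)])
    assert counts["skipped"] == 1


def test_pr2_quadrants_uniform_under_unbiased_mutation():
    """With parity mutation (A=T, G=C) the four-fold-box PR2 coordinates
    scatter symmetrically: quadrant counts are uniform (chi-square, alpha=0.01,
    200 genes)."""
    genes = simulate_gc3_geneset(200, n_codons=300, seed=9, gc3_range=(0.5, 0.5))
    metrics = [gene_cub_metrics(g) for g in genes]
    _, counts = pr2_analysis(metrics, fourfold_only=True)
    observed = [counts[q] for q in ("upper-left", "upper-right", "lower-left", "lower-right")]
    assert stats.chisquare(observed).pvalue > 0.01


def test_pr2_default_axes_shift_lower_left_under_uniform_usage():
    """The default exclusion set keeps more T/C- than A/G-ending codons, so
    uniform usage sits slightly below-left of parity."""
    genes = simulate_gc3_geneset(200, n_codons=300, seed=9, gc3_range=(0.5, 0.5))
    points, _ = pr2_analysis([gene_cub_metrics(g) for g in genes])
    assert np.mean([p.x for p in points]) < 0.5
    assert np.mean([p.y for p in points]) < 0.5


# ---------------------------------------------------------------- neutrality

def test_neutrality_identity_regression():
    ms = [_metrics(p3=v, p12=v) for v in (0.1, 0.3, 0.5, 0.7)]
    fit = neutrality_regression(ms)
    assert fit.slope == pytest.approx(1.0)
    assert fit.pearson_r == pytest.approx(1.0)
    assert fit.mutation_share == pytest.approx(100.0)


def test_neutrality_hand_ols():
    ms = [
        _metrics(p3=0.1, p12=0.30),
        _metrics(p3=0.2, p12=0.32),
        _metrics(p3=0.3, p12=0.34),
    ]
    fit = neutrality_regression(ms)
    assert fit.slope == pytest.approx(0.2)
    assert fit.intercept == pytest.approx(0.28)
    assert fit.pearson_r == pytest.approx(1.0)
    assert fit.n_genes == 3


def test_neutrality_degenerate_inputs_raise():
    with pytest.raises(ValueError, match=">= 3 genes"):
        neutrality_regression([_metrics(p3=0.1, p12=0.2)] * 2)
    with pytest.raises(ValueError, match="variance of P3"):
        neutrality_regression([_metrics(p3=0.5, p12=v) for v in (0.1, 0.2, 0.3)])


def test_neutrality_ols_matches_normal_equations_oracle():
    rng = np.random.default_rng(21)
    for _ in range(25):
        n = int(rng.integers(3, 30))
        x = rng.random(n)
        y = 0.3 * x + rng.normal(0, 0.05, n)
        if np.ptp(x) == 0:
            continue
        ms = [_metrics(p3=float(a), p12=float(b)) for a, b in zip(x, y)]
        fit = neutrality_regression(ms)
        xm, ym = x.mean(), y.mean()
        slope = float(((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum())
        intercept = ym - slope * xm
        assert fit.slope == pytest.approx(slope, abs=1e-10)
        assert fit.intercept == pytest.approx(intercept, abs=1e-10)


def test_neutrality_slope_recovery_under_known_constraint():
    slopes = {}
    for constraint in (0.0, 0.5, 1.0):
        genes = simulate_neutrality_geneset(
            200, beta=0.5, constraint=constraint, n_codons=300, seed=42
        )
        fit = neutrality_regression([gene_cub_metrics(g) for g in genes])
        slopes[constraint] = fit.slope
    assert 0.8 <= slopes[0.0] <= 1.2
    assert -0.1 <= slopes[1.0] <= 0.1
    assert slopes[0.0] > slopes[0.5] > slopes[1.0]
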