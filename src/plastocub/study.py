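"""The synthetic comparative study: one ancestor plastome and three derived
genomes under fixed, documented conditions.

These conditions emulate a four-congener plastome comparison at desk scale:
a 23 kb quadripartite genome (12 kb LSC, 2.5 kb IRs, 6 kb SSC) carrying 14
genes including the two junction-spanning ones (an ndhF-like gene 64 bp into
IRb, a chlL-like gene 5 bp into IRa); AT-biased mutation pressure
(beta = 0.25); noncoding sites diverging faster than coding sites; strong
purifying selection on most genes with two genes (ycf66, ndhD) under positive
selection. Divergence is substitution-only, so whole genomes align
column-for-column without an external aligner.
"""

from __future__ import annotations

from .io import PlastomeRecord
from .quadripartite import QuadripartitePartition
from .simulate import (
    DivergenceSpec,
    SyntheticPlastomeSpec,
    default_gene_roster,
    diverge_genome,
    simulate_plastome,
)

#: genes planted under positive selection, with their omega
POSITIVE_GENES = {"ycf66": 2.0, "ndhD": 1.8}


def study_divergence_spec(seed: int) -> DivergenceSpec:
    return DivergenceSpec(
        seed=seed,
        omega=dict(POSITIVE_GENES),
        default_omega=0.15,
        coding_rate=0.02,
        noncoding_rate=0.06,
        beta=0.25,
    )


def build_study(
    seed: int, n_derived: int = 3
) -> tuple[list[PlastomeRecord], QuadripartitePartition]:
    """The ancestor plus ``n_derived`` independently diverged genomes, and the
    planted partition (shared by all: divergence is substitution-only)."""
    spec = SyntheticPlastomeSpec(seed=seed % 2**31, genes=default_gene_roster())
    ancestor, truth = simulate_plastome(spec)
    genomes = [ancestor]
    for i in range(1, n_derived + 1):
        dseed = (seed + 7919 * i) % 2**31
        genomes.append(diverge_genome(ancestor, study_divergence_spec(dseed), truth))
    return genomes, truth
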