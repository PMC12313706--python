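import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")

from plastocub.simulate import (
    DivergenceSpec,
    GeneSpec,
    SyntheticPlastomeSpec,
    default_gene_roster,
    diverge_genome,
    simulate_plastome,
)


def small_spec(seed: int) -> SyntheticPlastomeSpec:
    """A fast desk-scale genome (12 kb, 1.5 kb IRs) for seed-sweep tests."""
    return SyntheticPlastomeSpec(
        seed=seed,
        lsc_len=6000,
        ir_len=1500,
        ssc_len=3000,
        genes=(
            GeneSpec("psbA", "LSC", "-", 150),
            GeneSpec("rbcL", "LSC", "+", 200),
            GeneSpec("ndhF", "SSC", "-", 160, junction="JSB", junction_overlap_bp=64),
            GeneSpec("chlL", "SSC", "+", 110, junction="JSA", junction_overlap_bp=5),
        ),
    )


@pytest.fixture(scope="session")
def plastome():
    """The default synthetic plastome (23 kb, 14 genes) plus planted truth."""
    return simulate_plastome(SyntheticPlastomeSpec(seed=7, genes=default_gene_roster()))


@pytest.fixture(scope="session")
def diverged(plastome):
    """A genome diverged from the fixture with two genes under positive
    selection and deep enough coding divergence for countable substitutions."""
    record, truth = plastome
    dspec = DivergenceSpec(
        seed=11,
        omega={"ycf66": 2.0, "ndhD": 1.8},
        default_omega=0.15,
        coding_rate=0.05,
        noncoding_rate=0.12,
        beta=0.25,
    )
    return diverge_genome(record, dspec, truth), dspec
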