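import numpy as np
import pytest

from translocross.genome import (
    TranslocationKind,
    TranslocationSpec,
    make_homokaryon,
)


@pytest.fixture
def it_spec():
    """Insertional translocation, no interstitial crossovers."""
    return TranslocationSpec(TranslocationKind.INSERTIONAL, donor_chrom=5, recipient_chrom=6)


@pytest.fixture
def it_spec_x():
    """Insertional translocation with crossover intervals on both chromosomes."""
    return TranslocationSpec(
        TranslocationKind.INSERTIONAL, donor_chrom=5, recipient_chrom=6,
        interstitial_xover_prob={5: 0.05, 6: 0.05},
    )


@pytest.fixture
def rt_spec():
    return TranslocationSpec(TranslocationKind.RECIPROCAL, donor_chrom=1, recipient_chrom=2)


@pytest.fixture
def qt_spec():
    return TranslocationSpec(TranslocationKind.QUASI_TERMINAL, donor_chrom=3, recipient_chrom=4)


@pytest.fixture
def qt_undefined_b_spec():
    """Quasi-terminal architecture whose B junction is not sequenced."""
    return TranslocationSpec(
        TranslocationKind.QUASI_TERMINAL, donor_chrom=3, recipient_chrom=4, junctions={"A"}
    )


@pytest.fixture
def t_parent():
    return make_homokaryon("Tnt", "a", translocation=True)


@pytest.fixture
def n_parent():
    return make_homokaryon("85", "A")


@pytest.fixture
def e_parent():
    return make_homokaryon("85E", "A", eight_spore=True)


@pytest.fixture
def zygote(t_parent, n_parent):
    return (t_parent.nuclei[0], n_parent.nuclei[0])


@pytest.fixture
def rng():
    return np.random.default_rng(20160617)
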