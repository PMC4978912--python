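"""The drive and maturation-insufficiency models and self-crosses."""

from collections import Counter

import numpy as np
import pytest

from translocross.genome import ConfigurationError, GenotypeClass, ParentGenotype, make_homokaryon
from translocross.ascus import package_tetrasperma
from translocross.meiosis import simulate_meiosis
from translocross.viability import (
    DriveElement,
    DriveModelParams,
    MaturationModelParams,
    apply_drive_model,
    apply_maturation_model,
    mature_all,
    self_cross,
)

AUX_CHROM = {"drvR": 6, "drvD": 5}


@pytest.fixture
def drive_parents():
    """The drive scenario: one element on the rearranged recipient chromosome
    (from the translocation parent), one on the normal homolog of the donor
    (from the tester)."""
    pt = make_homokaryon("Tnt", "a", translocation=True, aux_loci={"drvR": True, "drvD": False})
    pn = make_homokaryon("85", "A", aux_loci={"drvR": False, "drvD": True})
    return pt.nuclei[0], pn.nuclei[0]


@pytest.fixture
def drive_params():
    return DriveModelParams(
        elements=(DriveElement("drvR", 6, "Tnt"), DriveElement("drvD", 5, "85")),
        kill_prob=1.0,
    )


def eight_spored(zygote, spec, rng, mode, aux_chromosomes=AUX_CHROM):
    octad = simulate_meiosis(zygote, spec, rng, forced_mode=mode, aux_chromosomes=aux_chromosomes)
    return package_tetrasperma(octad, spec, 1.0, rng)


def test_drive_kills_alt_homokaryons_but_spares_adj_dp(it_spec, drive_parents, drive_params, rng):
    alt = apply_drive_model(eight_spored(drive_parents, it_spec, rng, "ALT"), drive_params, rng)
    mature_all(alt)
    # each T spore lacks the donor-homolog element, each N spore the recipient one
    assert alt.black_count == 0
    adj = apply_drive_model(eight_spored(drive_parents, it_spec, rng, "ADJ"), drive_params, rng)
    mature_all(adj)
    survivors = [s.nuclei[0].genotype_class(it_spec) for s in adj.spores if s.is_black]
    assert survivors == [GenotypeClass.DP] * 4  # both elements unite in Dp


def test_drive_rescues_heterokaryotic_spores(it_spec, drive_parents, drive_params, rng):
    for mode in ("ALT", "ADJ"):
        octad = simulate_meiosis(drive_parents, it_spec, rng, forced_mode=mode,
                                 aux_chromosomes=AUX_CHROM)
        asc = package_tetrasperma(octad, it_spec, 0.0, rng)
        mature_all(apply_drive_model(asc, drive_params, rng))
        assert asc.black_count == 4  # one nucleus covers each element


def test_drive_zero_kill_prob_is_identity(it_spec, drive_parents, rng):
    params = DriveModelParams(elements=(DriveElement("drvR", 6, "Tnt"),), kill_prob=0.0)
    asc = eight_spored(drive_parents, it_spec, rng, "ALT")
    before = [s.viable for s in asc.spores]
    apply_drive_model(asc, params, rng)
    assert [s.killed_by_drive for s in asc.spores] == [False] * 8
    assert [s.viable for s in asc.spores] == before


def test_drive_refutation_when_elements_sit_on_the_wrong_chromosomes(it_spec, rng):
    """With the donor chromosome as the element carrier on the tester side
    reversed - the configuration forced by a rearrangement whose recipient is
    the postulated carrier chromosome - the model kills the Dp progeny, the
    opposite of what is observed."""
    pt = make_homokaryon("Tnt", "a", translocation=True, aux_loci={"drv": False})
    pn = make_homokaryon("E", "A", aux_loci={"drv": True})
    # single element on the tester's homolog of the *recipient* chromosome
    params = DriveModelParams(elements=(DriveElement("drv", 6, "E"),), kill_prob=1.0)
    asc = eight_spored((pt.nuclei[0], pn.nuclei[0]), it_spec, rng, "ADJ",
                       aux_chromosomes={"drv": 6})
    apply_drive_model(asc, params, rng)
    mature_all(asc)
    dead_dp = [s for s in asc.spores
               if s.nuclei[0].genotype_class(it_spec) is GenotypeClass.DP and not s.is_black]
    assert len(dead_dp) == 4


def test_drive_missing_locus_errors(it_spec, zygote, rng):
    asc = package_tetrasperma(simulate_meiosis(zygote, it_spec, rng), it_spec, 0.0, rng)
    params = DriveModelParams(elements=(DriveElement("nowhere", 3, "Tnt"),))
    with pytest.raises(ConfigurationError):
        apply_drive_model(asc, params, rng)


def test_maturation_strict_blocks_over_four_viable(it_spec, zygote, rng):
    params = MaturationModelParams()  # threshold 4, failure 1.0
    # 8 viable homokaryotic spores after alternate segregation: none mature
    alt = eight_spored(zygote, it_spec, rng, "ALT")
    apply_maturation_model(alt, params, rng)
    assert alt.viable_count == 8 and alt.black_count == 0
    # adjacent-1 makes only 4 viable: all mature
    adj = eight_spored(zygote, it_spec, rng, "ADJ")
    apply_maturation_model(adj, params, rng)
    assert adj.viable_count == 4 and adj.black_count == 4
    matured = [s.nuclei[0].genotype_class(it_spec) for s in adj.spores if s.is_black]
    assert matured == [GenotypeClass.DP] * 4
    # heterokaryotic asci (4 binucleate viable) are unaffected
    het = package_tetrasperma(simulate_meiosis(zygote, it_spec, rng, forced_mode="ALT"),
                              it_spec, 0.0, rng)
    apply_maturation_model(het, params, rng)
    assert het.black_count == 4


def test_maturation_failure_prob_zero_is_identity(it_spec, zygote, rng):
    alt = eight_spored(zygote, it_spec, rng, "ALT")
    apply_maturation_model(alt, MaturationModelParams(failure_prob=0.0), rng)
    assert alt.black_count == 8


def test_maturation_per_spore_mode(it_spec, zygote, rng):
    params = MaturationModelParams(failure_prob=0.5, per_spore=True)
    blacks = [
        apply_maturation_model(eight_spored(zygote, it_spec, rng, "ALT"), params, rng).black_count
        for _ in range(200)
    ]
    # independent per-spore failure: intermediate counts appear
    assert min(blacks) < 4 < max(blacks)


def test_self_cross_interconverts_heterokaryon_classes(it_spec, rng):
    pt = make_homokaryon("Tnt", "a", translocation=True)
    pn = make_homokaryon("85", "A")
    het_tn = ParentGenotype("[T+N]", (pt.nuclei[0], pn.nuclei[0]))
    ds = self_cross(het_tn, it_spec, 400, rng, replacement_prob=0.0)
    classes = Counter(ds.progeny[ds.progeny.self_fertile == 1].true_genotype)
    assert set(classes) == {"[N+T]", "[Df+Dp]"}
    ratio = classes["[N+T]"] / classes["[Df+Dp]"]
    assert 0.7 < ratio < 1.4
    # a [Dp+Df] heterokaryon produces the same two ascus classes
    from translocross.genome import Nucleus
    het_dpdf = ParentGenotype("[Dp+Df]", (
        Nucleus("A", donor=("N", "N"), recipient=("T", "T")),   # Dp
        Nucleus("a", donor=("T", "T"), recipient=("N", "N")),   # Df
    ))
    ds2 = self_cross(het_dpdf, it_spec, 400, rng, replacement_prob=0.0)
    classes2 = set(ds2.progeny[ds2.progeny.self_fertile == 1].true_genotype)
    assert classes2 == {"[N+T]", "[Df+Dp]"}
    with pytest.raises(ConfigurationError):
        self_cross(pt, it_spec, 10, rng)  # homokaryon: self-sterile


def test_param_validation():
    with pytest.raises(ConfigurationError):
        MaturationModelParams(viable_threshold=0)
    with pytest.raises(ConfigurationError):
        MaturationModelParams(failure_prob=1.5)
    with pytest.raises(ConfigurationError):
        DriveModelParams(elements=(), kill_prob=-0.1)
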