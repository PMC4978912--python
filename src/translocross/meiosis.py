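"""Chromatid-resolution simulation of one meiosis in a translocation heterozygote.

One meiosis is modeled as: bivalent formation (four chromatids per homolog
pair), at most one interstitial crossover per configured interval, meiosis-I
centromere disjunction (alternate or adjacent-1, equally likely when the cross
is heterozygous for the rearrangement), meiosis II, and one postmeiotic
mitosis.  The result is an ordered octad of eight haploid nuclei.

Canonical octad geometry
------------------------
Mitotic sisters sit adjacent at positions (1,2)(3,4)(5,6)(7,8), and the two
meiosis-I poles interleave along the ascus: positions 1-2 and 5-6 descend from
one pole, 3-4 and 7-8 from the other.  With first-division segregation of
mating type this places nonsister nuclei of opposite mating type at positions
(1,3), (2,4), (5,7), (6,8) - the pairs a four-spored ascus packages together.

``enumerate_octads`` is the exact combinatorial oracle for the simulator: it
enumerates disjunction modes and chromatid choices with rational
probabilities.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np

from .genome import (
    ConfigurationError,
    GenotypeClass,
    Nucleus,
    TranslocationKind,
    TranslocationSpec,
)

ALT = "ALT"
ADJ = "ADJ"
NA = "NA"

#: Nonsister spore-pairing positions of the canonical octad (0-based).
NONSISTER_PAIRS = ((0, 2), (1, 3), (4, 6), (5, 7))


@dataclass
class Octad:
    """Eight nuclei in canonical linear order plus meiosis provenance."""

    nuclei: list[Nucleus]
    segregation_mode: str
    n_interstitial_xovers: int = 0

    def classes(self, spec: TranslocationSpec) -> list[GenotypeClass]:
        return [nuc.genotype_class(spec) for nuc in self.nuclei]

    def class_multiset(self, spec: TranslocationSpec) -> tuple[tuple[str, int], ...]:
        counts = Counter(c.value for c in self.classes(spec))
        return tuple(sorted(counts.items()))


@dataclass(frozen=True)
class OctadClass:
    """Black:white ascospore class of an octad (black = non-deficiency)."""

    black: int
    white: int

    def __post_init__(self) -> None:
        if self.black + self.white != 8:
            raise ValueError("an octad holds exactly eight nuclei")

    @property
    def label(self) -> str:
        return f"{self.black}:{self.white}"


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    if isinstance(rng, (int, np.integer)):
        return np.random.default_rng(int(rng))
    raise ConfigurationError(f"rng must be a numpy Generator or integer seed, got {type(rng).__name__}")


def _pure_allele(nucleus: Nucleus, role: str) -> str:
    cen, arm = getattr(nucleus, role)
    if cen != arm:
        raise ConfigurationError("zygote nuclei must carry non-recombinant chromosomes")
    return cen


def _locus_chromosome(locus: str, aux_chromosomes: dict[str, int] | None) -> int | None:
    if aux_chromosomes and locus in aux_chromosomes:
        return aux_chromosomes[locus]
    if locus.startswith("chr") and locus[3:].isdigit():
        return int(locus[3:])
    if locus == "E":
        return 6  # the Eight-spore locus segregates with chromosome 6
    return None


def simulate_meiosis(
    zygote: tuple[Nucleus, Nucleus],
    spec: TranslocationSpec,
    rng,
    *,
    forced_mode: str | None = None,
    mat_sds_prob: float = 0.0,
    aux_chromosomes: dict[str, int] | None = None,
) -> Octad:
    """Simulate one meiosis plus postmeiotic mitosis of a zygote.

    Parameters
    ----------
    zygote:
        The two parental nuclei, one of each mating type.
    rng:
        ``numpy.random.Generator`` or an integer seed.
    forced_mode:
        Pin the meiosis-I disjunction to ``"ALT"`` or ``"ADJ"`` (only
        meaningful for a rearrangement heterozygote); default draws each with
        probability 1/2.
    mat_sds_prob:
        Probability that the mating-type locus shows second-division
        segregation; the default 0 is first-division segregation throughout.
    aux_chromosomes:
        Chromosome assignment for auxiliary loci whose name does not encode
        one (``chrK`` and ``E`` are recognized automatically).
    """
    rng = _as_rng(rng)
    if not 0.0 <= mat_sds_prob <= 1.0:
        raise ConfigurationError("mat_sds_prob must lie in [0,1]")
    mats = {nuc.mating_type for nuc in zygote}
    if mats != {"A", "a"}:
        raise ConfigurationError("zygote nuclei must have opposite mating types")
    parents = tuple(zygote)

    donor_alleles = tuple(_pure_allele(p, "donor") for p in parents)
    recip_alleles = tuple(_pure_allele(p, "recipient") for p in parents)
    donor_het = set(donor_alleles) == {"T", "N"}
    recip_het = set(recip_alleles) == {"T", "N"}
    if spec.kind is TranslocationKind.NONE:
        if donor_het or recip_het:
            raise ConfigurationError("rearranged chromosomes in an isosequential (kind='none') cross")
        heterozygous = False
    else:
        if donor_het != recip_het:
            raise ConfigurationError(
                "cross heterozygous for only one of the two rearranged chromosomes is inconsistent with the spec"
            )
        heterozygous = donor_het

    if heterozygous:
        if forced_mode is None:
            mode = ALT if rng.random() < 0.5 else ADJ
        elif forced_mode in (ALT, ADJ):
            mode = forced_mode
        else:
            raise ConfigurationError(f"forced_mode must be 'ALT' or 'ADJ', got {forced_mode!r}")
    else:
        if forced_mode not in (None, NA):
            raise ConfigurationError("segregation mode applies only to rearrangement heterozygotes")
        mode = NA

    # Bivalents: chromatids [cen_allele, arm_allele, parent_index]; the first
    # two chromatids belong to parent 0, the last two to parent 1.
    def bivalent(role: str, alleles: tuple[str, str]) -> tuple[list[list], int]:
        chromatids = [[alleles[p], alleles[p], p] for p in (0, 0, 1, 1)]
        chrom = spec.donor_chrom if role == "donor" else spec.recipient_chrom
        p_x = spec.interstitial_xover_prob.get(chrom, 0.0)
        n_x = 0
        if p_x and rng.random() < p_x:
            i = int(rng.integers(2))
            j = 2 + int(rng.integers(2))
            chromatids[i][1], chromatids[j][1] = chromatids[j][1], chromatids[i][1]
            n_x = 1
        return chromatids, n_x

    donor_chromatids, nx_d = bivalent("donor", donor_alleles)
    recip_chromatids, nx_r = bivalent("recipient", recip_alleles)

    # Meiosis I: homologous centromeres disjoin, so each parent's two
    # chromatids of a bivalent travel together.  The disjunction mode fixes
    # the relative orientation of the two bivalents.
    if mode == NA:
        pole_of_p0_donor = int(rng.integers(2))
        pole_of_p0_recip = int(rng.integers(2))
    else:
        t_parent = donor_alleles.index("T")
        pole_of_t = int(rng.integers(2))
        pole_of_p0_donor = pole_of_t if t_parent == 0 else 1 - pole_of_t
        pole_of_t_recip = pole_of_t if mode == ALT else 1 - pole_of_t
        t_parent_r = recip_alleles.index("T")
        pole_of_p0_recip = pole_of_t_recip if t_parent_r == 0 else 1 - pole_of_t_recip

    def at_pole(chromatids: list[list], p0_pole: int) -> list[list[list]]:
        poles: list[list[list]] = [[], []]
        for c in chromatids:
            poles[p0_pole if c[2] == 0 else 1 - p0_pole].append(c)
        return poles

    donor_poles = at_pole(donor_chromatids, pole_of_p0_donor)
    recip_poles = at_pole(recip_chromatids, pole_of_p0_recip)

    # Meiosis II: the two chromatids at a pole separate into the pole's two
    # products; which chromatid enters which product is random.
    for poles in (donor_poles, recip_poles):
        for pole in poles:
            if rng.random() < 0.5:
                pole.reverse()

    # Mating type: first-division segregation sends both mat-A products to one
    # pole; second-division segregation splits each pole one A, one a.
    mat_of_p0 = parents[0].mating_type
    mat_of_p1 = parents[1].mating_type
    if rng.random() < mat_sds_prob:
        order0 = [mat_of_p0, mat_of_p1] if rng.random() < 0.5 else [mat_of_p1, mat_of_p0]
        order1 = [mat_of_p0, mat_of_p1] if rng.random() < 0.5 else [mat_of_p1, mat_of_p0]
        mat_table = [order0, order1]
        mat_pole_origin = None
    else:
        pole_of_p0_mat = int(rng.integers(2))
        mat_table = [None, None]
        mat_table[pole_of_p0_mat] = [mat_of_p0, mat_of_p0]
        mat_table[1 - pole_of_p0_mat] = [mat_of_p1, mat_of_p1]
        mat_pole_origin = pole_of_p0_mat

    # Auxiliary loci are centromere-linked: each locus follows the parental
    # origin of its chromosome's centromere.  The two rearranged chromosomes
    # follow the disjunction; every other chromosome assorts independently.
    loci = sorted(set(parents[0].aux_loci) | set(parents[1].aux_loci))
    pole_origin: dict[int, int] = {}
    for locus in loci:
        chrom = _locus_chromosome(locus, aux_chromosomes)
        if chrom is None:
            raise ConfigurationError(f"auxiliary locus {locus!r} has no chromosome assignment")
        if chrom not in pole_origin:
            if chrom == spec.donor_chrom and spec.kind is not TranslocationKind.NONE:
                pole_origin[chrom] = pole_of_p0_donor
            elif chrom == spec.recipient_chrom and spec.kind is not TranslocationKind.NONE:
                pole_origin[chrom] = pole_of_p0_recip
            else:
                pole_origin[chrom] = int(rng.integers(2))

    def product_nucleus(pole: int, prod: int) -> Nucleus:
        d = donor_poles[pole][prod]
        r = recip_poles[pole][prod]
        aux: dict[str, object] = {}
        for locus in loci:
            chrom = _locus_chromosome(locus, aux_chromosomes)
            origin = 0 if pole_origin[chrom] == pole else 1
            aux[locus] = parents[origin].aux_loci.get(locus)
        return Nucleus(
            mating_type=mat_table[pole][prod],
            donor=(d[0], d[1]),
            recipient=(r[0], r[1]),
            aux_loci=aux,
        )

    # Postmeiotic mitosis and the canonical pole-interleaved linear order:
    # [p0-prod0, p0-prod0, p1-prod0, p1-prod0, p0-prod1, p0-prod1, p1-prod1, p1-prod1]
    nuclei: list[Nucleus] = []
    for prod in (0, 1):
        for pole in (0, 1):
            template = product_nucleus(pole, prod)
            nuclei.append(template)
            nuclei.append(template.copy())
    return Octad(nuclei, mode, nx_d + nx_r)


def classify_octad(octad: Octad, spec: TranslocationSpec) -> OctadClass:
    """Black:white class: black nuclei are everything except deficiencies."""
    white = sum(1 for c in octad.classes(spec) if c is GenotypeClass.DF)
    return OctadClass(black=8 - white, white=white)


def enumerate_octads(
    spec: TranslocationSpec,
    xover_count: int = 0,
    interval: str | int | None = None,
) -> list[tuple[tuple[tuple[str, int], ...], Fraction]]:
    """Exact octad genotype-multiset distribution over disjunction modes and
    chromatid choices.

    Supports 0 or 1 interstitial crossovers (the two-strand single-crossover
    model); ``interval`` names the chromosome carrying the crossover, by role
    (``"donor"``/``"recipient"``) or chromosome number, defaulting to the
    donor.  Probabilities are exact rationals summing to 1.
    """
    if xover_count not in (0, 1):
        raise ConfigurationError("enumerate_octads supports 0 or 1 interstitial crossovers")
    if spec.kind is TranslocationKind.NONE:
        if xover_count:
            raise ConfigurationError("interstitial crossovers are undefined for an isosequential cross")
        return [(((GenotypeClass.N.value, 8),), Fraction(1))]

    if interval is None:
        role_x = "donor"
    elif interval in ("donor", "recipient"):
        role_x = str(interval)
    else:
        role_x = spec.role_of(int(interval))
        if role_x is None:
            raise ConfigurationError(f"chromosome {interval} carries no interstitial interval under this spec")

    def chromatids(role: str, with_x: bool, i: int = 0, j: int = 0) -> list[tuple[str, str]]:
        cs = [["T", "T"], ["T", "T"], ["N", "N"], ["N", "N"]]
        if with_x:
            cs[i][1], cs[2 + j][1] = cs[2 + j][1], cs[i][1]
        return [tuple(c) for c in cs]

    outcomes: dict[tuple[tuple[str, int], ...], Fraction] = {}

    def add(multiset: tuple[tuple[str, int], ...], p: Fraction) -> None:
        outcomes[multiset] = outcomes.get(multiset, Fraction(0)) + p

    xover_choices: list[tuple[int, int, Fraction]]
    if xover_count == 1:
        xover_choices = [(i, j, Fraction(1, 4)) for i in (0, 1) for j in (0, 1)]
    else:
        xover_choices = [(0, 0, Fraction(1))]

    for mode in (ALT, ADJ):
        p_mode = Fraction(1, 2)
        for i, j, p_x in xover_choices:
            donor_cs = chromatids("donor", xover_count == 1 and role_x == "donor", i, j)
            recip_cs = chromatids("recipient", xover_count == 1 and role_x == "recipient", i, j)
            # Pole 0 receives the T centromeres of the donor bivalent;
            # orientation is symmetric so it carries no probability.
            donor_poles = ([c for c in donor_cs if c[0] == "T"], [c for c in donor_cs if c[0] == "N"])
            if mode == ALT:
                recip_poles = ([c for c in recip_cs if c[0] == "T"], [c for c in recip_cs if c[0] == "N"])
            else:
                recip_poles = ([c for c in recip_cs if c[0] == "N"], [c for c in recip_cs if c[0] == "T"])
            # Meiosis II pairing of donor with recipient chromatids per pole.
            for m0 in (0, 1):
                for m1 in (0, 1):
                    p = p_mode * p_x * Fraction(1, 4)
                    classes: list[str] = []
                    for pole, m in ((0, m0), (1, m1)):
                        dpair = donor_poles[pole]
                        rpair = recip_poles[pole] if m == 0 else recip_poles[pole][::-1]
                        for d, r in zip(dpair, rpair):
                            nuc = Nucleus("A", donor=d, recipient=r)
                            classes.extend([nuc.genotype_class(spec).value] * 2)
                    add(tuple(sorted(Counter(classes).items())), p)

    assert sum(outcomes.values()) == 1
    return sorted(outcomes.items())


def octad_class_distribution(
    spec: TranslocationSpec, xover_count: int = 0, interval: str | int | None = None
) -> dict[str, Fraction]:
    """Exact black:white class-label distribution from :func:`enumerate_octads`."""
    dist: dict[str, Fraction] = {}
    for multiset, p in enumerate_octads(spec, xover_count, interval):
        white = dict(multiset).get(GenotypeClass.DF.value, 0)
        label = f"{8 - white}:{white}"
        dist[label] = dist.get(label, Fraction(0)) + p
    return dist
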