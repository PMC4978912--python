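"""Translocation architectures, chromosome variants, and nuclear genotype classes.

A chromosomal translocation heterozygote carries, for each of the two
chromosomes involved, one rearranged and one normal-sequence homolog.  This
module represents the rearrangement abstractly: each chromosome variant is a
set of segment identifiers, and the viability-relevant genotype class of a
haploid nucleus (``T`` translocation, ``N`` normal, ``Dp`` duplication, ``Df``
deficiency) is a pure function of which segments the nucleus carries.

Three rearrangement kinds are supported:

* **insertional** -- an interior donor-chromosome segment is inserted into a
  recipient chromosome, creating junctions A (donor) and B, C (recipient,
  proximal and distal);
* **quasi_terminal** -- a distal donor segment is moved to the tip of a
  recipient chromosome (junctions A and B), with the recipient losing nothing;
* **reciprocal** -- terminal segments of the two chromosomes are exchanged
  (junctions A and B).

Base-pair coordinates are deliberately absent: segment presence/absence is all
the downstream viability and genotyping logic needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from types import MappingProxyType
from typing import Mapping


class ConfigurationError(ValueError):
    """Raised when a cross or translocation configuration is inconsistent."""


class TranslocationKind(str, Enum):
    INSERTIONAL = "insertional"
    QUASI_TERMINAL = "quasi_terminal"
    RECIPROCAL = "reciprocal"
    NONE = "none"


class GenotypeClass(str, Enum):
    T = "T"
    N = "N"
    DP = "Dp"
    DF = "Df"


#: Abstract segment identifiers.  Proximal segments are centromere-linked and
#: shared by the rearranged and normal variant of a chromosome; everything that
#: differs between variants lies distal to the interstitial region.
SEG_DONOR_PROX = "donor-proximal"
SEG_DONOR_DIST = "donor-distal"
SEG_TRANS = "translocated-segment"
SEG_RECIP_PROX = "recipient-proximal"
SEG_RECIP_DIST = "recipient-distal"

#: Junctions each kind of rearrangement creates.
CANONICAL_JUNCTIONS: Mapping[TranslocationKind, frozenset[str]] = MappingProxyType({
    TranslocationKind.INSERTIONAL: frozenset({"A", "B", "C"}),
    TranslocationKind.QUASI_TERMINAL: frozenset({"A", "B"}),
    TranslocationKind.RECIPROCAL: frozenset({"A", "B"}),
    TranslocationKind.NONE: frozenset(),
})

#: Distal-arm segment content per (kind, chromosome role, arm allele).
#: ``"T"`` = rearranged-sequence arm, ``"N"`` = normal-sequence arm.
_ARM_DISTAL: dict[tuple[TranslocationKind, str], dict[str, frozenset[str]]] = {
    (TranslocationKind.INSERTIONAL, "donor"): {
        "N": frozenset({SEG_TRANS, SEG_DONOR_DIST}),
        "T": frozenset({SEG_DONOR_DIST}),
    },
    (TranslocationKind.INSERTIONAL, "recipient"): {
        "N": frozenset({SEG_RECIP_DIST}),
        "T": frozenset({SEG_TRANS, SEG_RECIP_DIST}),
    },
    (TranslocationKind.QUASI_TERMINAL, "donor"): {
        "N": frozenset({SEG_DONOR_DIST}),
        "T": frozenset(),
    },
    (TranslocationKind.QUASI_TERMINAL, "recipient"): {
        "N": frozenset({SEG_RECIP_DIST}),
        "T": frozenset({SEG_RECIP_DIST, SEG_DONOR_DIST}),
    },
    (TranslocationKind.RECIPROCAL, "donor"): {
        "N": frozenset({SEG_DONOR_DIST}),
        "T": frozenset({SEG_RECIP_DIST}),
    },
    (TranslocationKind.RECIPROCAL, "recipient"): {
        "N": frozenset({SEG_RECIP_DIST}),
        "T": frozenset({SEG_DONOR_DIST}),
    },
    (TranslocationKind.NONE, "donor"): {
        "N": frozenset({SEG_DONOR_DIST}),
        "T": frozenset({SEG_DONOR_DIST}),
    },
    (TranslocationKind.NONE, "recipient"): {
        "N": frozenset({SEG_RECIP_DIST}),
        "T": frozenset({SEG_RECIP_DIST}),
    },
}

_PROXIMAL = {"donor": frozenset({SEG_DONOR_PROX}), "recipient": frozenset({SEG_RECIP_PROX})}

VARIANT_LABELS = ("T_D", "T_R", "N_D", "N_R")


class _FrozenProbMap(dict):
    """Read-only-by-convention probability map; hashable so specs can key caches."""

    def __hash__(self) -> int:  # type: ignore[override]
        return hash(tuple(sorted(self.items())))


@dataclass(frozen=True)
class TranslocationSpec:
    """Architecture of a rearrangement heterozygous in a cross.

    Parameters
    ----------
    kind:
        One of ``insertional``, ``quasi_terminal``, ``reciprocal``, ``none``.
    donor_chrom, recipient_chrom:
        Chromosome numbers (1-7) of the two chromosomes involved.
    junctions:
        The *defined* breakpoint junctions, i.e. those for which a junction
        PCR assay exists.  Defaults to the full canonical set for the kind; a
        proper subset models an architecture whose remaining junctions are not
        yet sequenced (e.g. a quasi-terminal rearrangement with only the A
        junction defined, for which the genotyper cannot separate N from Dp).
    interstitial_xover_prob:
        Per-chromosome probability, per meiosis, of a single crossover in the
        interstitial region between the centromere and the breakpoint.
    """

    kind: TranslocationKind
    donor_chrom: int = 1
    recipient_chrom: int = 2
    junctions: frozenset[str] | None = None
    interstitial_xover_prob: Mapping[int, float] = field(default_factory=dict)
    name: str = ""

    def __post_init__(self) -> None:
        kind = TranslocationKind(self.kind)
        object.__setattr__(self, "kind", kind)
        canonical = CANONICAL_JUNCTIONS[kind]
        junctions = canonical if self.junctions is None else frozenset(self.junctions)
        if not junctions <= canonical:
            raise ConfigurationError(
                f"junctions {sorted(junctions)} not a subset of the canonical "
                f"{sorted(canonical)} for kind={kind.value}"
            )
        if kind is not TranslocationKind.NONE and "A" not in junctions:
            raise ConfigurationError("the A junction must be defined for any rearrangement")
        object.__setattr__(self, "junctions", junctions)
        if kind is not TranslocationKind.NONE and self.donor_chrom == self.recipient_chrom:
            raise ConfigurationError("donor and recipient chromosomes must differ")
        for chrom, p in dict(self.interstitial_xover_prob).items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"interstitial crossover probability {p} for chromosome {chrom} not in [0,1]")
        object.__setattr__(self, "interstitial_xover_prob", _FrozenProbMap(self.interstitial_xover_prob))

    @property
    def undefined_junctions(self) -> frozenset[str]:
        return CANONICAL_JUNCTIONS[self.kind] - self.junctions

    def role_of(self, chrom: int) -> str | None:
        if chrom == self.donor_chrom:
            return "donor"
        if chrom == self.recipient_chrom:
            return "recipient"
        return None


def chromatid_segments(kind: TranslocationKind, role: str, arm_allele: str) -> frozenset[str]:
    """Segment set of one chromatid given its distal-arm allele ('T' or 'N')."""
    if role not in ("donor", "recipient"):
        raise ConfigurationError(f"unknown chromosome role {role!r}")
    if arm_allele not in ("T", "N"):
        raise ConfigurationError(f"unknown arm allele {arm_allele!r}")
    return _PROXIMAL[role] | _ARM_DISTAL[(TranslocationKind(kind), role)][arm_allele]


def _parse_variant(label: str) -> tuple[str, str]:
    if label not in VARIANT_LABELS:
        raise ConfigurationError(f"unknown chromosome variant label {label!r}")
    allele, role_code = label.split("_")
    return ({"D": "donor", "R": "recipient"}[role_code], allele)


def variant_segments(kind: TranslocationKind, label: str) -> frozenset[str]:
    """Segment content of a non-recombinant chromosome variant (T_D/T_R/N_D/N_R)."""
    role, allele = _parse_variant(label)
    return chromatid_segments(kind, role, allele)


@dataclass(frozen=True)
class ChromosomeVariant:
    label: str
    segments: frozenset[str]


def segment_inventory(spec: TranslocationSpec) -> dict[str, ChromosomeVariant]:
    """The four chromosome variants of a heterozygote and their segment sets."""
    if spec.kind is TranslocationKind.NONE:
        raise ConfigurationError("segment inventory is undefined for kind='none'")
    return {lab: ChromosomeVariant(lab, variant_segments(spec.kind, lab)) for lab in VARIANT_LABELS}


def full_genome(kind: TranslocationKind) -> frozenset[str]:
    """Union of the normal-sequence variants: the complete segment complement."""
    return chromatid_segments(kind, "donor", "N") | chromatid_segments(kind, "recipient", "N")


@dataclass
class Nucleus:
    """One haploid meiotic product.

    ``donor`` and ``recipient`` are ``(centromere_allele, arm_allele)`` pairs
    with alleles ``'T'``/``'N'``; an interstitial crossover makes the two
    alleles differ.  ``aux_loci`` carries centromere-linked auxiliary alleles
    (one marker per chromosome, the Eight-spore locus, drive-element presence
    flags).  The genotype class is always derived, never stored.
    """

    mating_type: str
    donor: tuple[str, str] = ("N", "N")
    recipient: tuple[str, str] = ("N", "N")
    aux_loci: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mating_type not in ("A", "a"):
            raise ConfigurationError(f"mating type must be 'A' or 'a', got {self.mating_type!r}")

    def segments(self, spec: TranslocationSpec) -> frozenset[str]:
        return (chromatid_segments(spec.kind, "donor", self.donor[1])
                | chromatid_segments(spec.kind, "recipient", self.recipient[1]))

    def genotype_class(self, spec: TranslocationSpec) -> GenotypeClass:
        return classify_nucleus(self, spec)

    @property
    def variant_labels(self) -> tuple[str, str]:
        """Chromosome variant labels; recombinant chromatids are suffixed '*'."""
        def lab(role_code: str, pair: tuple[str, str]) -> str:
            cen, arm = pair
            return f"{arm}_{role_code}" + ("" if cen == arm else "*")
        return (lab("D", self.donor), lab("R", self.recipient))

    def copy(self) -> "Nucleus":
        return Nucleus(self.mating_type, self.donor, self.recipient, dict(self.aux_loci))


def classify_nucleus(nucleus: Nucleus, spec: TranslocationSpec) -> GenotypeClass:
    """Genotype class from segment coverage.

    Deficiency (missing segment) takes precedence over duplication, so both
    adjacent-1 products of a reciprocal rearrangement classify as Df even
    though each also duplicates a segment.  A balanced nucleus is T when both
    chromosomes carry rearranged-sequence arms, N when both are normal.
    """
    if spec.kind is TranslocationKind.NONE:
        return GenotypeClass.N
    donor_segs = chromatid_segments(spec.kind, "donor", nucleus.donor[1])
    recip_segs = chromatid_segments(spec.kind, "recipient", nucleus.recipient[1])
    if full_genome(spec.kind) - (donor_segs | recip_segs):
        return GenotypeClass.DF
    if donor_segs & recip_segs:
        return GenotypeClass.DP
    if (nucleus.donor[1], nucleus.recipient[1]) == ("T", "T"):
        return GenotypeClass.T
    return GenotypeClass.N


def derive_genotype_class(variant_pair: tuple[str, str], spec: TranslocationSpec) -> GenotypeClass:
    """Genotype class of a nucleus holding the given (donor, recipient) variants.

    Total over all four combinations of non-recombinant variant labels.
    """
    roles = {}
    for label in variant_pair:
        role, allele = _parse_variant(label)
        if role in roles:
            raise ConfigurationError(f"variant pair {variant_pair} holds two {role} chromosomes")
        roles[role] = allele
    if set(roles) != {"donor", "recipient"}:
        raise ConfigurationError(f"variant pair {variant_pair} must hold one donor and one recipient homolog")
    nucleus = Nucleus("A", donor=(roles["donor"],) * 2, recipient=(roles["recipient"],) * 2)
    return classify_nucleus(nucleus, spec)


@dataclass(frozen=True)
class ParentGenotype:
    """A cross parent: one nuclear template (homokaryon) or two of opposite
    mating type (self-fertile heterokaryon, e.g. [T + N] or [Dp + Df])."""

    label: str
    nuclei: tuple[Nucleus, ...]

    def __post_init__(self) -> None:
        if len(self.nuclei) not in (1, 2):
            raise ConfigurationError("a parent holds one or two nuclear templates")
        if len(self.nuclei) == 2 and self.nuclei[0].mating_type == self.nuclei[1].mating_type:
            raise ConfigurationError("heterokaryotic parents need constituent nuclei of opposite mating type")
        for nuc in self.nuclei:
            if nuc.donor[0] != nuc.donor[1] or nuc.recipient[0] != nuc.recipient[1]:
                raise ConfigurationError("parental nuclei must carry non-recombinant chromosomes")

    @property
    def is_heterokaryotic(self) -> bool:
        return len(self.nuclei) == 2

    def nucleus_of_mating_type(self, mating_type: str) -> Nucleus:
        for nuc in self.nuclei:
            if nuc.mating_type == mating_type:
                return nuc
        raise ConfigurationError(f"parent {self.label!r} has no mat {mating_type} nucleus")


def make_homokaryon(label: str, mating_type: str, *, translocation: bool = False,
                    eight_spore: bool = False, aux_loci: Mapping[str, object] | None = None,
                    n_chromosomes: int = 7) -> ParentGenotype:
    """Convenience constructor for a homokaryotic parent strain.

    Installs one centromere-linked marker allele per chromosome (the allele
    value is the strain label) and the Eight-spore locus on chromosome 6.
    """
    allele = "T" if translocation else "N"
    aux: dict[str, object] = {f"chr{k}": label for k in range(1, n_chromosomes + 1)}
    aux["E"] = "E" if eight_spore else "+"
    if aux_loci:
        aux.update(aux_loci)
    nucleus = Nucleus(mating_type, donor=(allele, allele), recipient=(allele, allele), aux_loci=aux)
    return ParentGenotype(label, (nucleus,))
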