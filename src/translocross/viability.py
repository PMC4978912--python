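"""The two competing explanations for transmission ratio distortion.

Model 1 (meiotic drive): nucleus-autonomous drive elements kill spores in
which no nucleus carries them.  With one element on the translocation
recipient chromosome and one on the normal homolog of the donor chromosome,
alternate segregation separates the elements into the T and N products
(killing both as homokaryotic spores), while adjacent-1 unites them in the
Dp product, which survives.  A heterokaryotic spore is rescued whenever
either of its nuclei carries each element.

Model 2 (maturation-factor insufficiency, a hybrid-incompatibility effect):
an ascus holding more than four viable ascospores fails to mature any of
them ("tragedy of the commons").  Since adjacent-1 segregation never yields
more than four viable spores, while alternate segregation yields four to
eight, the strict form of this model reproduces both the max-4- ascus
phenotype and the deficit of T and N homokaryotic progeny.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ascus import Ascus
from .genome import ConfigurationError, ParentGenotype, TranslocationSpec
from .meiosis import _as_rng


@dataclass(frozen=True)
class DriveElement:
    """A drive locus: aux-locus id, chromosome it rides on, and which parent
    of the cross contributes it (by parent label)."""

    locus: str
    chromosome: int
    parent_of_origin: str


@dataclass(frozen=True)
class DriveModelParams:
    elements: tuple[DriveElement, ...]
    kill_prob: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.kill_prob <= 1.0:
            raise ConfigurationError("kill probability must lie in [0,1]")
        object.__setattr__(self, "elements", tuple(self.elements))


@dataclass(frozen=True)
class MaturationModelParams:
    viable_threshold: int = 4
    failure_prob: float = 1.0
    per_spore: bool = False

    def __post_init__(self) -> None:
        if self.viable_threshold < 1:
            raise ConfigurationError("viable threshold must be at least 1")
        if not 0.0 <= self.failure_prob <= 1.0:
            raise ConfigurationError("failure probability must lie in [0,1]")


def apply_drive_model(ascus: Ascus, params: DriveModelParams, rng) -> Ascus:
    """Mark spores not covered by every drive element as maturation failures.

    A spore survives iff, for every configured element, at least one of its
    nuclei carries the element's locus.  Deterministic at kill_prob=1.
    Mutates and returns the ascus.
    """
    rng = _as_rng(rng)
    for spore in ascus.spores:
        for element in params.elements:
            carried = False
            for nucleus in spore.nuclei:
                if element.locus not in nucleus.aux_loci:
                    raise ConfigurationError(
                        f"drive locus {element.locus!r} missing from nuclear genotypes"
                    )
                if nucleus.aux_loci[element.locus]:
                    carried = True
            if not carried and rng.random() < params.kill_prob:
                spore.killed_by_drive = True
                spore.matured = False
                break
    return ascus


def apply_maturation_model(ascus: Ascus, params: MaturationModelParams, rng) -> Ascus:
    """Apply the maturation-insufficiency model to a packaged ascus.

    If the viable-spore count exceeds the threshold then, with probability
    ``failure_prob``, maturation fails - ascus-wide by default (no spore in
    the ascus matures), or independently per viable spore when
    ``per_spore=True``.  Otherwise every viable spore matures.  Mutates and
    returns the ascus.
    """
    rng = _as_rng(rng)
    over = ascus.viable_count > params.viable_threshold
    if over and not params.per_spore and rng.random() < params.failure_prob:
        for spore in ascus.spores:
            spore.matured = False
        return ascus
    for spore in ascus.spores:
        if spore.viable and not spore.killed_by_drive:
            if over and params.per_spore and rng.random() < params.failure_prob:
                spore.matured = False
            else:
                spore.matured = True
    return ascus


def mature_all(ascus: Ascus) -> Ascus:
    """No-model default: every viable spore matures."""
    for spore in ascus.spores:
        if spore.viable and not spore.killed_by_drive:
            spore.matured = True
    return ascus


def self_cross(
    heterokaryon: ParentGenotype,
    spec: TranslocationSpec,
    n_asci: int,
    rng,
    *,
    maturation: MaturationModelParams | None = None,
    drive: DriveModelParams | None = None,
    replacement_prob: float | None = None,
    species: str = "tetrasperma",
    primer_failure_prob: float = 0.0,
    aux_chromosomes: dict[str, int] | None = None,
):
    """Self-cross of a self-fertile heterokaryon: its two constituent nuclei
    form the zygote and the full meiosis -> packaging -> viability chain runs.

    Both [T + N] and [Dp + Df] heterokaryons interconvert through self-crosses;
    with the models off their progeny show the two heterokaryon classes in
    roughly equal numbers.  Returns a :class:`~translocross.simulate.CrossDataset`.
    """
    if not heterokaryon.is_heterokaryotic:
        raise ConfigurationError("a homokaryon is self-sterile and cannot self-cross")
    from .genome import ParentGenotype as _PG  # local alias for clarity
    from .simulate import SimulationConfig, generate_cross

    parents = tuple(
        _PG(f"{heterokaryon.label}[{nuc.mating_type}]", (nuc,))
        for nuc in heterokaryon.nuclei
    )
    config = SimulationConfig(
        spec=spec,
        parents=parents,
        n_asci=n_asci,
        species=species,
        maturation=maturation,
        drive=drive,
        replacement_prob=replacement_prob,
        primer_failure_prob=primer_failure_prob,
        aux_chromosomes=aux_chromosomes,
    )
    return generate_cross(config, _as_rng(rng))
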