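"""Synthetic crosses: asci, progeny isolates, PCR profiles, marker matrices.

``generate_cross`` composes the whole forward pipeline - meiosis, spore
packaging, viability models, junction-PCR profiling with primer-failure
noise, marker assortment - and emits tidy tables with the statistical
structure the inference layer assumes.  Every matured black spore becomes a
progeny isolate; a ``true_genotype`` column carries ground truth for testing
and is never consumed by inference.

Default parameters quantify the study conditions of the motivating crosses:
interstitial crossover probability 0.05 per interval, binucleate-spore
replacement 0.08 (0.5 with the dominant Eight-spore mutant), strict
(all-or-none) maturation failure above four viable spores when the
maturation model is enabled, deterministic drive kills when drive elements
are configured, and a 1% primer-site failure rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .ascus import Ascus, package_crassa, package_tetrasperma, replacement_rate
from .genome import (
    ConfigurationError,
    GenotypeClass,
    Nucleus,
    ParentGenotype,
    TranslocationKind,
    TranslocationSpec,
    make_homokaryon,
)
from .genotyping import ASSAYS, assays_available, simulate_profile
from .meiosis import _as_rng, simulate_meiosis
from .segstats import CrossCounts
from .viability import (
    DriveModelParams,
    MaturationModelParams,
    apply_drive_model,
    apply_maturation_model,
    mature_all,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything needed to simulate one cross.

    ``parents`` is a pair of homokaryotic parents of opposite mating type (a
    self-cross of a heterokaryon is configured through
    :func:`translocross.viability.self_cross`).  Model switches default off;
    ``replacement_prob`` overrides the Eight-spore-derived rate when set.
    """

    spec: TranslocationSpec
    parents: tuple[ParentGenotype, ParentGenotype]
    n_asci: int = 1000
    species: str = "tetrasperma"
    r_base: float = 0.08
    r_eight_spore: float = 0.5
    replacement_prob: float | None = None
    maturation: MaturationModelParams | None = None
    drive: DriveModelParams | None = None
    germling_t_loss: float = 0.0
    primer_failure_prob: float = 0.01
    mat_sds_prob: float = 0.0
    aux_chromosomes: Mapping[str, int] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        errors: list[str] = []
        if self.n_asci < 1:
            errors.append("n_asci must be at least 1")
        if self.species not in ("tetrasperma", "crassa"):
            errors.append(f"unknown species {self.species!r}")
        for name in ("r_base", "r_eight_spore", "germling_t_loss", "primer_failure_prob", "mat_sds_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                errors.append(f"{name}={v} not in [0,1]")
        if self.replacement_prob is not None and not 0.0 <= self.replacement_prob <= 1.0:
            errors.append(f"replacement_prob={self.replacement_prob} not in [0,1]")
        if len(self.parents) != 2:
            errors.append("a cross needs exactly two parents")
        else:
            mats = [p.nuclei[0].mating_type for p in self.parents if not p.is_heterokaryotic]
            if any(p.is_heterokaryotic for p in self.parents):
                errors.append("cross parents must be homokaryotic (use self_cross for heterokaryons)")
            elif mats[0] == mats[1]:
                errors.append("parents must have opposite mating types")
        if errors:
            raise ConfigurationError("; ".join(errors))

    @property
    def eight_spore_present(self) -> bool:
        return any(nuc.aux_loci.get("E") == "E" for p in self.parents for nuc in p.nuclei)

    def effective_replacement_prob(self) -> float:
        if self.replacement_prob is not None:
            return self.replacement_prob
        return replacement_rate(self.eight_spore_present, self.r_base, self.r_eight_spore)

    def provenance(self) -> dict:
        return {
            "translocation": {
                "kind": self.spec.kind.value,
                "name": self.spec.name,
                "donor_chrom": self.spec.donor_chrom,
                "recipient_chrom": self.spec.recipient_chrom,
                "junctions": sorted(self.spec.junctions),
                "interstitial_xover_prob": {str(k): v for k, v in self.spec.interstitial_xover_prob.items()},
            },
            "parents": [p.label for p in self.parents],
            "species": self.species,
            "n_asci": self.n_asci,
            "eight_spore_present": self.eight_spore_present,
            "replacement_prob": self.effective_replacement_prob(),
            "maturation": None if self.maturation is None else {
                "viable_threshold": self.maturation.viable_threshold,
                "failure_prob": self.maturation.failure_prob,
                "per_spore": self.maturation.per_spore,
            },
            "drive": None if self.drive is None else {
                "kill_prob": self.drive.kill_prob,
                "elements": [
                    {"locus": e.locus, "chromosome": e.chromosome, "parent_of_origin": e.parent_of_origin}
                    for e in self.drive.elements
                ],
            },
            "germling_t_loss": self.germling_t_loss,
            "primer_failure_prob": self.primer_failure_prob,
            "mat_sds_prob": self.mat_sds_prob,
            "seed": self.seed,
        }


@dataclass
class CrossDataset:
    """Simulated cross: ascus table, progeny table, marker matrix, provenance.

    ``progeny['true_genotype']`` is ground truth for validation only; the
    genotyping and statistics layers must see only the assay columns.
    """

    asci: pd.DataFrame
    progeny: pd.DataFrame
    markers: pd.DataFrame
    provenance: dict
    ascus_objects: list[Ascus] = field(default_factory=list)


def _truth_label(classes: list[GenotypeClass]) -> str:
    if len(classes) == 1:
        return classes[0].value
    return "[" + "+".join(sorted(c.value for c in classes)) + "]"


def generate_cross(config: SimulationConfig, rng=None) -> CrossDataset:
    """Run the full forward pipeline for one cross."""
    if rng is None:
        if config.seed is None:
            raise ConfigurationError("a seed (or an explicit rng) is required for simulation")
        rng = np.random.default_rng(config.seed)
    rng = _as_rng(rng)
    spec = config.spec
    zygote = (config.parents[0].nuclei[0], config.parents[1].nuclei[0])
    r = config.effective_replacement_prob()
    available = assays_available(spec)
    aux_chrom = dict(config.aux_chromosomes) if config.aux_chromosomes else None

    ascus_rows, progeny_rows, marker_rows = [], [], []
    ascus_objects: list[Ascus] = []
    isolate_counter = 0
    for ascus_idx in range(config.n_asci):
        octad = simulate_meiosis(zygote, spec, rng, mat_sds_prob=config.mat_sds_prob,
                                 aux_chromosomes=aux_chrom)
        if config.species == "tetrasperma":
            ascus = package_tetrasperma(octad, spec, r, rng)
        else:
            ascus = package_crassa(octad, spec)
        if config.drive is not None:
            apply_drive_model(ascus, config.drive, rng)
        if config.maturation is not None:
            apply_maturation_model(ascus, config.maturation, rng)
        else:
            mature_all(ascus)
        ascus_id = f"asc{ascus_idx:05d}"
        ascus_rows.append({
            "ascus_id": ascus_id,
            "spore_count": ascus.spore_count,
            "black": ascus.black_count,
            "white": ascus.white_count,
            "class_label": ascus.bw_label,
            "segregation_mode": ascus.segregation_mode,
            "n_interstitial_xovers": ascus.n_interstitial_xovers,
        })
        ascus_objects.append(ascus)

        for spore in ascus.spores:
            if not spore.is_black:
                continue
            nuclei = list(spore.nuclei)
            classes = [n.genotype_class(spec) for n in nuclei]
            # post-germination loss of the T nucleus from [T+N] heterokaryons
            if (config.germling_t_loss and len(nuclei) == 2
                    and set(classes) == {GenotypeClass.T, GenotypeClass.N}
                    and rng.random() < config.germling_t_loss):
                keep = classes.index(GenotypeClass.N)
                nuclei, classes = [nuclei[keep]], [classes[keep]]
            mats = "".join(sorted({n.mating_type for n in nuclei}))
            self_fertile = len(mats) == 2
            profile = simulate_profile(nuclei, spec, config.primer_failure_prob, rng)
            isolate_id = f"iso{isolate_counter:06d}"
            isolate_counter += 1
            row = {
                "isolate_id": isolate_id,
                "ascus_id": ascus_id,
                "self_fertile": int(self_fertile),
                "mating_types": mats,
                "true_genotype": _truth_label(classes),
            }
            for assay in ASSAYS:
                row[assay] = int(profile.amplified[assay]) if assay in available else pd.NA
            progeny_rows.append(row)
            if not self_fertile and len(nuclei) == 1:
                nucleus = nuclei[0]
                marker_rows.append({
                    "isolate_id": isolate_id,
                    **{f"chr{k}": nucleus.aux_loci.get(f"chr{k}") for k in range(1, 8)},
                })

    asci_df = pd.DataFrame(ascus_rows)
    progeny_cols = ["isolate_id", "ascus_id", "self_fertile", "mating_types",
                    *ASSAYS, "true_genotype"]
    progeny_df = pd.DataFrame(progeny_rows, columns=progeny_cols)
    markers_df = pd.DataFrame(marker_rows, columns=["isolate_id", *(f"chr{k}" for k in range(1, 8))])
    return CrossDataset(asci_df, progeny_df, markers_df, config.provenance(), ascus_objects)


def generate_marker_progeny(
    n: int,
    rng,
    *,
    parent_alleles: tuple[str, str] = ("E", "+"),
    phenotype_chromosome: int | None = None,
    recombination_fraction: float = 0.0,
) -> pd.DataFrame:
    """Marker matrix of ``n`` homokaryotic progeny under independent assortment.

    Each of the seven chromosome markers draws a parental allele with
    probability 1/2, independently.  When ``phenotype_chromosome`` is set, a
    binary ``phenotype`` column cosegregates with that chromosome's marker at
    the given recombination fraction (0 = complete linkage) - emulating a
    dominant locus such as Eight-spore pinned to chromosome 6.
    """
    if n < 1:
        raise ConfigurationError("n must be at least 1")
    if not 0.0 <= recombination_fraction <= 0.5:
        raise ConfigurationError("recombination fraction must lie in [0, 0.5]")
    rng = _as_rng(rng)
    draws = rng.integers(2, size=(n, 7))
    data = {f"chr{k}": [parent_alleles[d] for d in draws[:, k - 1]] for k in range(1, 8)}
    frame = pd.DataFrame(data)
    if phenotype_chromosome is not None:
        if not 1 <= phenotype_chromosome <= 7:
            raise ConfigurationError("phenotype chromosome must be 1-7")
        linked = draws[:, phenotype_chromosome - 1].copy()
        flips = rng.random(n) < recombination_fraction
        linked[flips] = 1 - linked[flips]
        frame["phenotype"] = [parent_alleles[d] for d in linked]
    return frame


#: The six translocation-by-normal cross count rows used for regression tests:
#: (T, N, Dp) homokaryon tallies with progeny totals and self-sterile counts.
_TABLE_ROWS = (
    ("EB4", "85", 129, 31, 11, 11, 9),
    ("EB4", "E", 60, 40, 7, 15, 17),
    ("IBj5", "85", 133, 25, 1, 1, 23),
    ("IBj5", "E", 82, 33, 0, 2, 28),
    ("B362i", "85", 163, 59, 0, 3, 48),
    ("B362i", "E", 77, 61, 0, 27, 14),
)


def table4_fixture() -> list[CrossCounts]:
    """Published homokaryon tallies of the six insertional-translocation
    crosses, for regression tests of the distortion statistics."""
    return [
        CrossCounts(strain=s, tester=tst, n_progeny=np_, n_self_sterile=ss, t=t, n=n, dp=dp)
        for s, tst, np_, ss, t, n, dp in _TABLE_ROWS
    ]


def default_insertional_spec(xover_prob: float = 0.05, donor: int = 5, recipient: int = 6,
                             name: str = "IT") -> TranslocationSpec:
    """An insertional-translocation spec with interstitial crossover intervals
    on both involved chromosomes."""
    return TranslocationSpec(
        kind=TranslocationKind.INSERTIONAL,
        donor_chrom=donor,
        recipient_chrom=recipient,
        interstitial_xover_prob={donor: xover_prob, recipient: xover_prob},
        name=name,
    )


def default_cross_config(
    *,
    eight_spore_tester: bool = False,
    maturation_on: bool = False,
    xover_prob: float = 0.05,
    n_asci: int = 1000,
    seed: int | None = None,
    **overrides,
) -> SimulationConfig:
    """Convenience builder: an introgressed insertional translocation strain
    crossed to a normal-sequence tester (optionally carrying Eight-spore),
    with the maturation model optionally enabled in its strict form."""
    spec = overrides.pop("spec", default_insertional_spec(xover_prob))
    parent_t = make_homokaryon("Tnt", "a", translocation=True)
    parent_n = make_homokaryon("85E" if eight_spore_tester else "85", "A",
                               eight_spore=eight_spore_tester)
    return SimulationConfig(
        spec=spec,
        parents=(parent_t, parent_n),
        n_asci=n_asci,
        maturation=MaturationModelParams() if maturation_on else None,
        seed=seed,
        **overrides,
    )
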