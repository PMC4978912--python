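"""Packaging an octad into ascospores and assigning color/viability.

Two species rules are implemented.  *N. crassa* partitions the eight nuclei
into eight uninucleate ascospores.  *N. tetrasperma* makes four initially
binucleate ascospores, each receiving a pair of nonsister nuclei of opposite
mating type; with some probability a binucleate position is instead replaced
by a pair of smaller uninucleate (homokaryotic) ascospores - the event whose
frequency the dominant Eight-spore (E) mutant raises.

A spore is viable (and black) when the union of its nuclear segment sets
covers the full genome: a [Dp + Df] dikaryotic spore is therefore black even
though its Df nucleus alone would make a white spore.  This complementation
is what lets four-spored asci mask a rearrangement entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import ConfigurationError, Nucleus, TranslocationSpec, full_genome, TranslocationKind
from .meiosis import NONSISTER_PAIRS, Octad, _as_rng


@dataclass
class Spore:
    """One ascospore holding one or two nuclei.

    ``color``/``viable`` reflect segment coverage at packaging time;
    ``matured`` is set later by the viability models (``None`` = no model
    applied yet).  A spore is scored black only if it is viable and has not
    failed maturation.
    """

    nuclei: tuple[Nucleus, ...]
    viable: bool
    color: str
    matured: bool | None = None
    killed_by_drive: bool = False

    @property
    def is_black(self) -> bool:
        return self.viable and not self.killed_by_drive and self.matured is not False

    @property
    def is_binucleate(self) -> bool:
        return len(self.nuclei) == 2

    @property
    def mating_types(self) -> str:
        return "".join(sorted({n.mating_type for n in self.nuclei}))


@dataclass
class Ascus:
    """A packaged ascus of 4-8 spores holding the eight octad nuclei."""

    spores: list[Spore]
    segregation_mode: str = "NA"
    n_interstitial_xovers: int = 0
    replaced: tuple[bool, ...] = ()

    @property
    def spore_count(self) -> int:
        return len(self.spores)

    @property
    def black_count(self) -> int:
        return sum(1 for s in self.spores if s.is_black)

    @property
    def white_count(self) -> int:
        return self.spore_count - self.black_count

    @property
    def bw_label(self) -> str:
        return f"{self.black_count}:{self.white_count}"

    @property
    def viable_count(self) -> int:
        """Viable spores before any maturation verdict (drive kills excluded)."""
        return sum(1 for s in self.spores if s.viable and not s.killed_by_drive)

    def nuclei(self) -> list[Nucleus]:
        return [n for s in self.spores for n in s.nuclei]


def _make_spore(nuclei: tuple[Nucleus, ...], spec: TranslocationSpec) -> Spore:
    if spec.kind is TranslocationKind.NONE:
        viable = True
    else:
        covered: frozenset[str] = frozenset().union(*(n.segments(spec) for n in nuclei))
        viable = not (full_genome(spec.kind) - covered)
    return Spore(nuclei=nuclei, viable=viable, color="black" if viable else "white")


def package_crassa(octad: Octad, spec: TranslocationSpec) -> Ascus:
    """Eight uninucleate ascospores in octad order (*N. crassa* rule)."""
    spores = [_make_spore((nuc,), spec) for nuc in octad.nuclei]
    return Ascus(spores, octad.segregation_mode, octad.n_interstitial_xovers)


def package_tetrasperma(
    octad: Octad,
    spec: TranslocationSpec,
    replacement_prob: float,
    rng,
) -> Ascus:
    """Four nonsister binucleate ascospores, each independently replaced by a
    pair of uninucleate spores with probability ``replacement_prob``
    (*N. tetrasperma* rule).  Spore count is 4 + number of replacements.
    """
    if not 0.0 <= replacement_prob <= 1.0:
        raise ConfigurationError("replacement probability must lie in [0,1]")
    rng = _as_rng(rng)
    spores: list[Spore] = []
    replaced: list[bool] = []
    for i, j in NONSISTER_PAIRS:
        pair = (octad.nuclei[i], octad.nuclei[j])
        hit = bool(rng.random() < replacement_prob)
        replaced.append(hit)
        if hit:
            spores.append(_make_spore((pair[0],), spec))
            spores.append(_make_spore((pair[1],), spec))
        else:
            spores.append(_make_spore(pair, spec))
    return Ascus(spores, octad.segregation_mode, octad.n_interstitial_xovers, tuple(replaced))


def replacement_rate(eight_spore_present: bool, r_base: float = 0.08, r_eight_spore: float = 0.5) -> float:
    """Binucleate-spore replacement probability for a cross.

    ``r_base`` applies when neither parent carries the dominant Eight-spore
    mutation; ``r_eight_spore`` (which must exceed ``r_base``) when any does.
    """
    if not 0.0 <= r_base <= 1.0 or not 0.0 <= r_eight_spore <= 1.0:
        raise ConfigurationError("replacement rates must lie in [0,1]")
    if r_eight_spore <= r_base:
        raise ConfigurationError("the Eight-spore replacement rate must exceed the base rate")
    return r_eight_spore if eight_spore_present else r_base
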