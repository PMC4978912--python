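"""Breakpoint-junction PCR genotyping: profiles from genotypes and back.

Five assays exist: amplification across the rearrangement junctions A, B and
C, and two positive controls ND and NR that amplify normal-sequence regions
of the donor and recipient chromosomes - regions disrupted in the rearranged
chromosomes, so they amplify only from the N-derived homologs.  Junction A
rides on the rearranged donor chromosome (T_D), junctions B and C on the
rearranged recipient (T_R); ND reports the normal donor homolog (N_D) and NR
the normal recipient (N_R).  A heterokaryon amplifies the union of its
constituent nuclei's profiles.

Which assays are available follows from the architecture: junction assays
exist only for defined junctions, and NR does not exist for quasi-terminal
rearrangements (tip capping disrupts no recipient sequence).  For a
quasi-terminal spec whose B junction is undefined, N and Dp therefore produce
identical profiles and only T is positively identifiable.

``call_genotype`` inverts the forward map over single genotypes and
two-genotype heterokaryon unions; unmatched profiles are explained by the
minimal number of primer-site mutations (a positive assay can only be lost,
never gained).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from itertools import combinations
from typing import Iterable, Mapping

from .genome import (
    ConfigurationError,
    GenotypeClass,
    Nucleus,
    TranslocationKind,
    TranslocationSpec,
)
from .meiosis import _as_rng

ASSAYS = ("A", "B", "C", "ND", "NR")

#: The chromosome variant each assay detects.
_ASSAY_VARIANT = {"A": "T_D", "B": "T_R", "C": "T_R", "ND": "N_D", "NR": "N_R"}

#: Variants carried by each homokaryotic genotype class.
_CLASS_VARIANTS = {
    GenotypeClass.T: frozenset({"T_D", "T_R"}),
    GenotypeClass.N: frozenset({"N_D", "N_R"}),
    GenotypeClass.DP: frozenset({"N_D", "T_R"}),
    GenotypeClass.DF: frozenset({"T_D", "N_R"}),
}


class CallResult(str, Enum):
    T = "T"
    N = "N"
    DP = "Dp"
    HET_TN_OR_DPDF = "HET[T+N]or[Dp+Df]"
    HET_NDP = "HET[N+Dp]"
    AMBIGUOUS = "AMBIGUOUS"


@dataclass(frozen=True)
class JunctionProfile:
    """Amplification booleans over the assays available under a spec."""

    amplified: Mapping[str, bool]
    assays_available: frozenset[str]

    def __post_init__(self) -> None:
        amplified = dict(self.amplified)
        extra = set(amplified) - set(self.assays_available)
        if extra:
            raise ConfigurationError(f"profile reports unavailable assays: {sorted(extra)}")
        object.__setattr__(self, "amplified", amplified)

    def key(self) -> tuple[tuple[str, bool], ...]:
        return tuple((a, bool(self.amplified.get(a, False))) for a in ASSAYS if a in self.assays_available)

    def positives(self) -> frozenset[str]:
        return frozenset(a for a, v in self.amplified.items() if v)


@dataclass(frozen=True)
class GenotypeCall:
    call: CallResult
    candidates: frozenset
    note: str = ""
    excluded_from_counts: bool = False


def assays_available(spec: TranslocationSpec) -> frozenset[str]:
    """Assays that exist for a given rearrangement architecture."""
    if spec.kind is TranslocationKind.NONE:
        return frozenset()
    available = set(spec.junctions) | {"ND"}
    if spec.kind is not TranslocationKind.QUASI_TERMINAL:
        available.add("NR")
    return frozenset(available)


def _variants_of(source) -> frozenset[str]:
    if isinstance(source, GenotypeClass):
        return _CLASS_VARIANTS[source]
    if isinstance(source, Nucleus):
        return frozenset({f"{source.donor[1]}_D", f"{source.recipient[1]}_R"})
    if isinstance(source, str):
        return _CLASS_VARIANTS[GenotypeClass(source)]
    if isinstance(source, Iterable):
        members = list(source)
        if not members:
            raise ConfigurationError("cannot derive a profile from an empty genotype set")
        out: frozenset[str] = frozenset()
        for member in members:
            out = out | _variants_of(member)
        return out
    raise ConfigurationError(f"cannot derive a junction profile from {source!r}")


def expected_profile(source, spec: TranslocationSpec) -> JunctionProfile:
    """Noiseless junction profile of a genotype class, nucleus, or collection
    thereof (a heterokaryon amplifies the union)."""
    available = assays_available(spec)
    carried = _variants_of(source)
    amplified = {a: _ASSAY_VARIANT[a] in carried for a in available}
    return JunctionProfile(amplified, available)


def simulate_profile(source, spec: TranslocationSpec, primer_failure_prob: float, rng) -> JunctionProfile:
    """Forward simulation with primer-site-failure noise: each positive assay
    independently drops to negative with the given probability; negatives
    never flip positive."""
    if not 0.0 <= primer_failure_prob <= 1.0:
        raise ConfigurationError("primer failure probability must lie in [0,1]")
    rng = _as_rng(rng)
    exp = expected_profile(source, spec)
    amplified = {
        a: bool(v and not (primer_failure_prob and rng.random() < primer_failure_prob))
        for a, v in exp.amplified.items()
    }
    return JunctionProfile(amplified, exp.assays_available)


_SINGLE_CLASSES = (GenotypeClass.T, GenotypeClass.N, GenotypeClass.DP)
_HET_PAIRS = tuple(frozenset(p) for p in combinations(
    (GenotypeClass.T, GenotypeClass.N, GenotypeClass.DP, GenotypeClass.DF), 2))
_TN = frozenset({GenotypeClass.T, GenotypeClass.N})
_DPDF = frozenset({GenotypeClass.DP, GenotypeClass.DF})
_NDP = frozenset({GenotypeClass.N, GenotypeClass.DP})


@lru_cache(maxsize=None)
def _decision_table(spec: TranslocationSpec):
    singles = {g: expected_profile(g, spec).key() for g in _SINGLE_CLASSES}
    pairs = {p: expected_profile(p, spec).key() for p in _HET_PAIRS}
    return singles, pairs


def _fmt(candidate) -> str:
    if isinstance(candidate, frozenset):
        return "[" + "+".join(sorted(g.value for g in candidate)) + "]"
    return candidate.value


def call_genotype(
    profile: JunctionProfile,
    spec: TranslocationSpec,
    mating_types: str | None = None,
) -> GenotypeCall:
    """Decision-table inversion of :func:`expected_profile`.

    Resolution order: unique single-genotype match; heterokaryon-union match
    (the all-positive profile matches both [T+N] and [Dp+Df] and is called as
    that ambiguity class); otherwise the profile is explained as a candidate
    genotype with the minimal number of primer-site mutations.  Mating-type
    evidence is advisory: a heterokaryon call with a single observed mating
    type is flagged ``excluded_from_counts`` (same-mating-type heterokaryons
    are left out of segregation tallies).
    """
    available = assays_available(spec)
    if not set(profile.amplified) <= available:
        raise ConfigurationError("profile reports assays unavailable under this spec")
    obs = tuple((a, bool(profile.amplified.get(a, False))) for a in ASSAYS if a in available)
    singles, pairs = _decision_table(spec)

    single_matches = [g for g, key in singles.items() if key == obs]
    if len(single_matches) == 1:
        g = single_matches[0]
        return GenotypeCall(CallResult(g.value), frozenset({g}))
    if len(single_matches) > 1:
        names = "/".join(sorted(g.value for g in single_matches))
        return GenotypeCall(
            CallResult.AMBIGUOUS,
            frozenset(single_matches),
            note=f"{names} indistinguishable under the available assays",
        )

    pair_matches = [p for p, key in pairs.items() if key == obs]
    if pair_matches:
        matched = set(pair_matches)
        if matched == {_TN, _DPDF}:
            return GenotypeCall(
                CallResult.HET_TN_OR_DPDF,
                frozenset({_TN, _DPDF}),
                note="[T+N] or [Dp+Df] heterokaryon",
                excluded_from_counts=mating_types in ("A", "a"),
            )
        if matched == {_NDP}:
            return GenotypeCall(
                CallResult.HET_NDP,
                frozenset({_NDP}),
                note="[N+Dp] heterokaryon",
                excluded_from_counts=mating_types in ("A", "a"),
            )
        names = " or ".join(_fmt(p) for p in sorted(pair_matches, key=_fmt))
        return GenotypeCall(
            CallResult.AMBIGUOUS,
            frozenset(pair_matches),
            note=f"heterokaryon profile: {names}",
            excluded_from_counts=mating_types in ("A", "a"),
        )

    # No exact match: explain by primer-site mutations (positives lost only).
    def compatible(key) -> int | None:
        expected = dict(key)
        flips = 0
        for assay, seen in obs:
            if seen and not expected[assay]:
                return None  # would need a gained positive: impossible
            if expected[assay] and not seen:
                flips += 1
        return flips

    best: list = []
    best_flips: int | None = None
    for cand, key in list(singles.items()) + list(pairs.items()):
        flips = compatible(key)
        if flips is None:
            continue
        # prefer single genotypes over heterokaryon pairs at equal flips
        rank = (flips, 0 if isinstance(cand, GenotypeClass) else 1)
        if best_flips is None or rank < best_flips:
            best, best_flips = [cand], rank
        elif rank == best_flips:
            best.append(cand)
    if not best:  # pragma: no cover - the all-positive union is always compatible
        return GenotypeCall(CallResult.AMBIGUOUS, frozenset(), note="profile inconsistent with every genotype")
    names = " or ".join(_fmt(c) for c in sorted(best, key=_fmt))
    n_mut = best_flips[0]
    return GenotypeCall(
        CallResult.AMBIGUOUS,
        frozenset(best),
        note=f"may be {names} with {n_mut} mutated primer site(s)",
    )
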