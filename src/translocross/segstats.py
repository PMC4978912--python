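"""Segregation statistics: ALT:ADJ estimation, distortion tests, exact
binomial linkage thresholds, pairwise independence tables, and ascus-type
tabulation.

The ALT:ADJ estimator rests on one observation: alternate segregation yields
T and N homokaryons, adjacent-1 yields Dp and Df, and Df spores never
germinate - so the adjacent-1 count is estimated as twice the observed Dp
count.  Deviation of ALT:ADJ from 1:1 is tested by chi-square with one
degree of freedom (no continuity correction by default).

Linkage verdicts use the classical exact device: for n progeny scored at two
loci, the parental:recombinant split under independence is Binomial(n, 1/2),
and the smallest count m with P[X >= m] <= alpha (one direction) is the
linkage threshold - 21 of 28 and 19 of 24 at the 1% level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations
from math import comb

import pandas as pd
from scipy import stats

from .ascus import Ascus
from .genome import ConfigurationError

logger = logging.getLogger(__name__)


class NoTestError(ValueError):
    """Raised when the requested test is undefined for the given data."""


@dataclass(frozen=True)
class CrossCounts:
    """Genotype tallies of one cross's progeny (heterokaryons and ambiguous
    calls are recorded but never enter ratio estimates)."""

    strain: str = ""
    tester: str = ""
    n_progeny: int = 0
    n_self_sterile: int = 0
    t: int = 0
    n: int = 0
    dp: int = 0
    het: int = 0
    ambiguous: int = 0

    def __post_init__(self) -> None:
        if min(self.t, self.n, self.dp, self.het, self.ambiguous) < 0:
            raise ConfigurationError("genotype counts cannot be negative")
        if self.n_self_sterile and self.t + self.n + self.dp > self.n_self_sterile:
            raise ConfigurationError("T+N+Dp cannot exceed the self-sterile count")


#: Phenotype classes of a translocation-by-normal cross.
PHENO_EQUAL = "T=N=Dp"
PHENO_TN_LL_DP = "T,N<<Dp"
PHENO_T_LL_NDP = "T<<N,Dp"
PHENO_UNDETERMINED = "UNDETERMINED"


@dataclass(frozen=True)
class AltAdjEstimate:
    alt: int
    adj: int
    chi_square: float
    p_value: float
    significant: bool
    alpha: float

    @property
    def ratio(self) -> str:
        return f"{self.alt}:{self.adj}"


def alt_adj_estimate(counts: CrossCounts | tuple[int, int, int], alpha: float = 0.01,
                     yates: bool = False) -> AltAdjEstimate:
    """ALT:ADJ estimate and 1:1 chi-square test from (T, N, Dp) homokaryon counts.

    ``alt = T + N``; ``adj = 2 * Dp`` (doubling Dp stands in for the inviable
    Df complement).
    """
    if isinstance(counts, CrossCounts):
        t, n, dp = counts.t, counts.n, counts.dp
    else:
        t, n, dp = counts
    if min(t, n, dp) < 0:
        raise ConfigurationError("counts cannot be negative")
    alt, adj = t + n, 2 * dp
    total = alt + adj
    if total == 0:
        raise NoTestError("all genotype counts are zero; the 1:1 test is undefined")
    dev = abs(alt - adj)
    if yates:
        dev = max(dev - 1.0, 0.0)
    chi_sq = dev * dev / total
    p = float(stats.chi2.sf(chi_sq, df=1))
    return AltAdjEstimate(alt, adj, chi_sq, p, p < alpha, alpha)


def classify_phenotype(counts: CrossCounts | tuple[int, int, int], alpha: float = 0.01) -> str:
    """Phenotype class of a cross from its homokaryon counts.

    Primary test: ALT:ADJ vs 1:1 (chi-square).  Significant deficit of ALT
    products -> ``T,N<<Dp``.  If ALT:ADJ is Mendelian, a secondary
    one-direction exact binomial test of T against N (expected 1:1 among
    ALT products) flags ``T<<N,Dp``.  The secondary rule is this package's
    formalization of a phenotype the source data report without a stated
    test.
    """
    if isinstance(counts, CrossCounts):
        t, n, dp = counts.t, counts.n, counts.dp
    else:
        t, n, dp = counts
    est = alt_adj_estimate((t, n, dp), alpha=alpha)
    if est.significant:
        if est.adj > est.alt:
            return PHENO_TN_LL_DP
        return PHENO_UNDETERMINED
    if t + n > 0:
        p_low = float(stats.binom.cdf(t, t + n, 0.5))
        if p_low <= alpha and t < n:
            return PHENO_T_LL_NDP
    return PHENO_EQUAL


def binomial_threshold(n: int, alpha: float = 0.01) -> int | None:
    """Smallest m with P[X >= m] <= alpha for X ~ Binomial(n, 1/2), by exact
    tail summation; ``None`` when even m = n is not significant.

    This is the one-direction 1% deviation threshold of the classical
    linkage tables: 21 (of 28) and 19 (of 24) at alpha = 0.01.
    """
    if n < 1:
        raise ConfigurationError("n must be at least 1")
    if not 0.0 < alpha < 1.0:
        raise ConfigurationError("alpha must lie in (0,1)")
    alpha_frac = Fraction(alpha).limit_denominator(10**9)
    denom = 1 << n
    tail = 0
    # accumulate the upper tail from m = n downward; stop at the last m that
    # keeps P[X >= m] <= alpha
    for m in range(n, -1, -1):
        tail += comb(n, m)
        if Fraction(tail, denom) > alpha_frac:
            return m + 1 if m < n else None
    return 0


@dataclass(frozen=True)
class SegPairResult:
    pair: tuple[str, str]
    parental: int
    recombinant: int
    n: int
    threshold: int | None
    independent: bool | None

    @property
    def ratio(self) -> str:
        return f"{self.parental}:{self.recombinant}"


def _pair_result(pair: tuple[str, str], parental: int, recombinant: int, alpha: float) -> SegPairResult:
    n = parental + recombinant
    if n == 0:
        return SegPairResult(pair, 0, 0, 0, None, None)
    m = binomial_threshold(n, alpha)
    independent: bool | None
    if m is None:
        independent = None  # sample too small for any verdict at this alpha
    else:
        independent = not (parental >= m or recombinant >= m)
    return SegPairResult(pair, parental, recombinant, n, m, independent)


def pairwise_segregation(markers: pd.DataFrame, alpha: float = 0.01) -> list[SegPairResult]:
    """Independence verdicts for every pair of marker columns.

    Each column must be biallelic with alleles coded identically across
    columns by parent of origin (the parental classes are the two same-parent
    diagonal genotypes).  Rows missing either genotype of a pair are excluded
    (logged).  alpha is per comparison: no family-wise correction.
    """
    cols = [c for c in markers.columns if c.lower().startswith("chr")] or list(markers.columns)
    results = []
    for x, y in combinations(cols, 2):
        sub = markers[[x, y]].dropna()
        dropped = len(markers) - len(sub)
        if dropped:
            logger.info("pair (%s,%s): excluded %d rows with missing genotypes", x, y, dropped)
        alleles = set(sub[x]) | set(sub[y])
        if len(alleles) > 2:
            raise ConfigurationError(
                f"markers must share one biallelic parent coding; saw {sorted(map(str, alleles))}"
            )
        parental = int((sub[x] == sub[y]).sum())
        recombinant = len(sub) - parental
        results.append(_pair_result((x, y), parental, recombinant, alpha))
    return results


def linkage_to_phenotype(markers: pd.DataFrame, phenotype, alpha: float = 0.01) -> list[SegPairResult]:
    """Marker-versus-phenotype cosegregation with the same threshold machinery.

    ``phenotype`` is a binary vector (e.g. eight-spore vs four-spore cross
    outcome).  For each marker column the cosegregation count is the larger
    diagonal of the 2x2 table; a chromosome is flagged (non-independent) when
    it reaches the one-direction binomial threshold.
    """
    pheno = pd.Series(phenotype, index=markers.index)
    levels = sorted(set(pheno.dropna()), key=str)
    if len(levels) < 2:
        raise NoTestError("phenotype is constant; cosegregation is untestable")
    if len(levels) > 2:
        raise ConfigurationError("phenotype must be binary")
    cols = [c for c in markers.columns if c.lower().startswith("chr")] or list(markers.columns)
    results = []
    for col in cols:
        sub = pd.DataFrame({"m": markers[col], "p": pheno}).dropna()
        m_levels = sorted(set(sub["m"]), key=str)
        is_first = sub["m"] == m_levels[0]
        is_case = sub["p"] == levels[0]
        agree = int((is_first == is_case).sum())
        cosegregating = max(agree, len(sub) - agree)
        results.append(_pair_result((col, "phenotype"), cosegregating, len(sub) - cosegregating, alpha))
    return results


def linked_chromosomes(results: list[SegPairResult]) -> list[str]:
    return [r.pair[0] for r in results if r.independent is False]


ASCUS_TABLE_COLUMNS = ["N", "4", "5", "6", "7", "8:0", "6:2", "4:4", "2:6", "0:8"]


def tabulate_asci(asci: list[Ascus]) -> pd.DataFrame:
    """Ascus-type spectrum: percentages of 4- to 7-spored asci, with
    eight-spored asci split by matured-black:white class.

    Returns a one-row DataFrame in the layout of the published spectra
    (percentages of the total ascus count N).
    """
    if not asci:
        raise NoTestError("no asci to tabulate")
    total = len(asci)
    counts: dict[str, int] = {c: 0 for c in ASCUS_TABLE_COLUMNS if c != "N"}
    for ascus in asci:
        if ascus.spore_count < 8:
            key = str(ascus.spore_count)
        else:
            key = ascus.bw_label
        counts[key] = counts.get(key, 0) + 1
    row: dict[str, float] = {"N": total}
    ordered = ASCUS_TABLE_COLUMNS + [k for k in counts if k not in ASCUS_TABLE_COLUMNS]
    for key in ordered:
        if key == "N":
            continue
        row[key] = 100.0 * counts.get(key, 0) / total
    return pd.DataFrame([row], columns=ordered)


def count_progeny_genotypes(progeny: pd.DataFrame, spec, alpha: float = 0.01,
                            strain: str = "", tester: str = "") -> tuple[pd.DataFrame, CrossCounts]:
    """Call every self-sterile isolate's genotype from its assay columns and
    tally the cross.

    Returns the progeny table with a ``genotype_call`` column appended, and a
    :class:`CrossCounts` in which only self-sterile T/N/Dp calls enter the
    tallies; heterokaryon profiles and ambiguous calls are counted separately
    and same-mating-type heterokaryon profiles are excluded.
    """
    from .genotyping import ASSAYS, CallResult, JunctionProfile, assays_available, call_genotype

    available = assays_available(spec)
    calls: list[str] = []
    tally = {"t": 0, "n": 0, "dp": 0, "het": 0, "ambiguous": 0}
    n_self_sterile = 0
    for _, row in progeny.iterrows():
        amplified = {}
        for assay in ASSAYS:
            if assay not in available:
                continue
            value = row.get(assay)
            if pd.isna(value):
                raise ConfigurationError(
                    f"isolate {row.get('isolate_id', '?')}: assay {assay} is available "
                    "under this spec but missing from the table"
                )
            amplified[assay] = bool(int(value))
        call = call_genotype(JunctionProfile(amplified, available), spec,
                             mating_types=row.get("mating_types"))
        calls.append(call.call.value)
        if int(row.get("self_fertile", 0)):
            continue
        n_self_sterile += 1
        if call.call is CallResult.T:
            tally["t"] += 1
        elif call.call is CallResult.N:
            tally["n"] += 1
        elif call.call is CallResult.DP:
            tally["dp"] += 1
        elif call.call in (CallResult.HET_TN_OR_DPDF, CallResult.HET_NDP):
            tally["het"] += 1
        else:
            tally["ambiguous"] += 1
    annotated = progeny.copy()
    annotated["genotype_call"] = calls
    counts = CrossCounts(strain=strain, tester=tester, n_progeny=len(progeny),
                         n_self_sterile=n_self_sterile, **tally)
    return annotated, counts


def estimate_interstitial_xover_prob(class_labels, n_intervals: int = 1) -> float:
    """Recover the per-interval interstitial crossover probability from the
    frequency of the 6:2 octad class.

    Exactly one interstitial crossover makes an octad of the 6:2 class
    whatever the disjunction mode (the exact enumeration oracle gives
    P(6:2 | one crossover) = 1 for a nonreciprocal heterozygote), so with m
    independently sampled intervals P(6:2) = 1 - (1 - c)^m up to O(c^2)
    double-crossover terms.  Inverts that relation.
    """
    if n_intervals < 1:
        raise ConfigurationError("n_intervals must be at least 1")
    labels = list(class_labels)
    if not labels:
        raise NoTestError("no octad classes supplied")
    freq = sum(1 for lab in labels if lab == "6:2") / len(labels)
    if freq >= 1.0:
        return 1.0
    return 1.0 - (1.0 - freq) ** (1.0 / n_intervals)
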