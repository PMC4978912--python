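# Methods

## Scope and model overview

`translocross` models one meiosis of a fungal translocation heterozygote at
chromatid resolution and everything downstream of it: ascospore packaging in
*N. crassa* and *N. tetrasperma*, two competing ascospore-viability models,
junction-PCR genotyping with a noise model, and the segregation statistics
used to detect transmission ratio distortion (TRD).  Rearrangements are
represented abstractly as segment sets; base-pair coordinates, primer
sequences and wet-lab protocols are out of scope.

## Meiosis engine

Each of the two rearranged chromosomes forms a bivalent of four chromatids,
two per parent.  A chromatid is `(centromere allele, distal-arm allele)`
with alleles T (rearranged sequence) or N (normal); everything that
distinguishes the variants lies distal to the interstitial region, so a
single interstitial crossover is an arm-allele swap between one chromatid of
each homolog (two-strand single crossover, at most one per interval per
meiosis, probability `interstitial_xover_prob[chromosome]`).  We adopt the
single-crossover model because a single interstitial exchange is necessary
and sufficient to generate the 6:2 ascus class, which is the only
recombination signal the downstream statistics consume.

Meiosis I disjoins homologous centromeres; when the cross is heterozygous
for the rearrangement the joint orientation of the two bivalents is
**alternate** (T centromeres together) or **adjacent-1** (mixed) with
probability ½ each.  Adjacent-2 disjunction (homologous centromeres to the
same pole) is excluded from the model.  Meiosis II separates the two
chromatids at each pole into that pole's two products at random; a
postmeiotic mitosis duplicates each product.

**Octad geometry.**  The canonical linear octad interleaves the two
meiosis-I poles: positions (1,2) and (5,6) are the mitotic sister pairs of
pole 0's two products, (3,4) and (7,8) of pole 1's.  Binucleate ascospores
pair positions (1,3), (2,4), (5,7), (6,8): each spore joins one member of a
sister pair with a nonsister nucleus from the adjacent meiosis-II spindle.
With first-division segregation of mating type (the default, and the
classical drawing for this system) this puts one *mat A* and one *mat a*
nucleus in every binucleate spore, and makes the two spore genotypes after
ALT and ADJ exactly [T+N] and [Dp+Df].  A non-interleaved order would pair
same-mating-type nuclei and is therefore not offered as a default; the
pairing positions are a module constant (`NONSISTER_PAIRS`) for sensitivity
analysis.  An option sets the frequency of second-division segregation of
mating type.

**Auxiliary loci.**  Markers (one per chromosome), the *Eight-spore* locus
(chromosome 6) and drive-element flags are modeled as centromere-linked:
each follows the parental origin of its chromosome's centromere, which for
the two rearranged chromosomes is dictated by the disjunction and for all
others is an independent coin flip per meiosis.  This is a simplification -
no map distances - adequate because every downstream test consumes only
cosegregation counts.

**Exact oracle.**  `enumerate_octads` enumerates disjunction modes,
crossover chromatid choices and meiosis-II pairings with rational
probabilities (0 or 1 crossovers; more raise an explicit error).  Key exact
results: an insertional heterozygote gives {4T+4N} and {4Dp+4Df} with
probability ½ each; one interstitial crossover in either interval gives a
6:2 octad with probability 1 under both modes; a reciprocal heterozygote
gives 8:0 / 0:8 at ½ each and 4:4 under one crossover.  The Monte-Carlo
engine is tested against these distributions by goodness of fit.

## Ascospore packaging and viability

A spore is viable (black) iff the union of its nuclear segment sets covers
the genome - so [Dp+Df] spores are black by complementation, and the
masking of rearrangements by *N. tetrasperma* development is an emergent
property rather than a special case.  Replacement of a binucleate position
by two uninucleate spores is independent per position with probability
`r`, giving the shifted-binomial spore-count distribution
P(4+k spores) = C(4,k) r^k (1-r)^(4-k).

## Viability models

* **Drive (model 1).**  Elements are aux loci with a chromosome and parent
  of origin.  A spore survives iff for every element some constituent
  nucleus carries it; otherwise it fails to mature with probability `k`
  (default 1, deterministic).  With elements on the rearranged recipient
  chromosome and the normal donor homolog, ALT kills the T and N
  homokaryotic spores, ADJ unites both elements in Dp, and heterokaryotic
  spores are rescued.  The model's known refutation is reproducible: when
  the postulated carrier is the *recipient* chromosome of the rearrangement,
  the model kills the Dp progeny, contrary to observation.
* **Maturation insufficiency (model 2).**  If an ascus holds more than
  `viable_threshold` (default 4) viable spores, maturation fails with
  probability `f` (default 1) for the whole ascus - all-or-none, because
  whole-ascus failure is what the observed 0:8 ascus class implies.  A
  per-spore variant is available behind a flag for exploration.  Strict
  model 2 makes two exact predictions the tests assert: no ascus matures
  more than four black spores, and every matured homokaryon from an
  eight-spored ascus is Dp.
* **Germling T-loss.**  A second incompatibility that would convert
  [T+N] heterokaryotic germlings into N homokaryons is modeled as a
  post-germination event with probability `g` (default 0); it produces the
  T ≪ N, Dp phenotype.

## PCR genotyping

Junction A rides the rearranged donor chromosome, B and C the rearranged
recipient; control assays ND and NR amplify normal-sequence regions
disrupted in the rearranged chromosomes.  Because a quasi-terminal
rearrangement disrupts no recipient sequence, NR does not exist for that
architecture; with its B junction additionally undefined, N and Dp give
identical profiles and only T is positively identifiable - the genotyper
degrades to an explicit two-candidate ambiguity rather than guessing.
Profile inversion proceeds: unique single match → that call; union match →
heterokaryon call (the all-positive profile is inherently [T+N]-or-[Dp+Df]);
otherwise the minimal-mutation explanation, since primer-site mutations can
only turn positives negative.  Noise model: each positive drops out
independently with probability `mu`.

## Segregation statistics

* ALT:ADJ: alt = T+N, adj = 2·Dp; χ² = (alt−adj)²/(alt+adj), df 1, no
  continuity correction (Yates available as an option).
* Phenotype rule: significant deficit of ALT products → T,N≪Dp; otherwise a
  one-direction exact binomial test of T against N (expected 1:1 among ALT
  products) flags T≪N,Dp.  The secondary rule is this package's
  formalization of a phenotype reported without a stated test; it reproduces
  the published classifications of all six reference count rows.
* `binomial_threshold(n, alpha)` computes the exact smallest m with
  P[X ≥ m] ≤ α, X ~ Binomial(n, ½), by `Fraction` tail summation (no normal
  approximation; α is rationalized before comparison).  Pairwise marker
  tables and marker-phenotype cosegregation both apply this threshold per
  comparison, with no family-wise correction, matching the referenced
  threshold-table practice.
* `estimate_interstitial_xover_prob` inverts P(6:2) = 1 − (1−c)^m over m
  configured intervals; exact for m = 1 by the enumeration oracle, with an
  O(c²) bias for m = 2 (double-crossover octads are not always 6:2).

## Synthetic-data generator

`generate_cross` composes meiosis → packaging → viability → profiling and
emits tidy tables (asci, progeny, homokaryon marker matrix, provenance).
Defaults quantify the study conditions: c = 0.05 per interstitial interval,
r = 0.08 base replacement and 0.5 with *Eight-spore* (calibrated so the
no-*E* spore-count spectrum is dominated by four-spored asci, as observed),
f = 1, k = 1, g = 0, primer failure mu = 0.01.  All randomness flows from a
single seeded generator recorded in provenance; identical config + seed give
byte-identical tables.  The `true_genotype` column is ground truth for
validation and is dropped before inference in every test that closes the
loop.

What the generator does *not* emulate: ascospore-size dimorphism,
germination kinetics, the extra postmeiotic mitoses hypothesized to explain
anomalous genotypes in rare >4-black asci, meiotic silencing in Dp crosses,
and real marker maps (markers are centromere-linked).  Passing tests
therefore validate the segregation/viability logic and the inference layer,
not these finer biological features.

## Numerical and design notes

* Deficiency takes precedence over duplication when classifying a nucleus,
  so both adjacent-1 products of a reciprocal exchange classify Df.
* Problem sizes in the test suite: 10,000 meioses for oracle goodness-of-fit
  and model-property checks, 20,000 for crossover-rate recovery - sizes at
  which binomial error is well inside the asserted tolerances.
* With c = 0.05, crossover octads let an occasional T or N homokaryon mature
  under strict model 2 (a [T+Df] spore replaced in an ascus left with
  exactly four viable spores), so Dp dominance is overwhelming but not
  literally 100% across all ascus sizes; the exact invariants asserted are
  the max-4⁻ bound and Dp-purity of eight-spored survivors.
* Exit codes in the CLI: 0 success, 1 data/runtime error, 2 configuration
  error.  Simulation without a seed is an error, never a silent default.

## Known limitations

Adjacent-2 disjunction, multi-crossover interference and chromatid
interference are not modeled; the enumeration oracle stops at one
crossover; drive elements are centromere-linked rather than mapped;
phenotype classification of crosses with very small counts follows the
stated rule without small-sample correction beyond the exact binomial.
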