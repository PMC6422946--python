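# Methods

## The scientific setting

Methanogenic degradation of organic matter in anoxic soil slurries is
carried out by a web of guilds: fermenting bacteria supply acetate and
H₂/CO₂; acetoclastic methanogens (Methanosarcinaceae,
Methanotrichaceae) split acetate to CH₄; hydrogenotrophic methanogens
reduce CO₂ with H₂; and at elevated temperature syntrophic acetate
oxidizers (Thermoanaerobacteraceae) can replace the acetoclastic route
by oxidizing acetate to H₂/CO₂ for a hydrogenotrophic partner.
Incubation temperature reorganises both the taxonomic structure (who is
there) and the functional routing (which pathway makes the CH₄), and
the two are coupled: the carbon isotope fractionation between CO₂ and
CH₄, α_app = (δ¹³CO₂ + 10³)/(δ¹³CH₄ + 10³), sits near 1.08 when CH₄
comes exclusively from CO₂ and near 1.04 when acetoclastic
methanogenesis contributes.

The pipeline analyses factorial temperature-shift experiments: soils
pre-incubated at 25/35/45 °C, then shifted to each of the three
temperatures with replicate vessels.  Because real datasets of this
design are large (hundreds of thousands of reads per sample), the
package ships a synthetic generator that reproduces the *statistical
structure* such experiments exhibit, at desk scale, with full ground
truth.

## The synthetic community model

**Thermal niches.**  Every OTU has a Gaussian thermal response
`response(T) = exp(-(T - optimum)² / (2·width²))`.  The default
blueprint plants three temperature assemblages — optima 25, 35 and
45 °C — with overlapping mesophilic niches (width 7 °C) and a narrow
thermophilic niche (width 3 °C).  Acetoclastic methanogens are strictly
mesophilic (optimum 25 °C, width 5 °C).  Default sizes: 60 bacterial +
30 archaeal OTUs split evenly over the assemblages; depths 10 000
bacterial and 2 000 archaeal reads per sample.  These are deliberate
desk-scale study conditions; field-scale depths (281 947 / 10 162) are
a config change away.

**Pre-incubation legacy.**  Pre-incubation samples sit at thermal
equilibrium, `baseline · response(T_pre)`.  Shift samples are
*legacy-dominated*:

    w = baseline · max(response(T_pre), floor) · response(T_inc)^γ

with γ = 0.5 and floor = 0.05.  The rationale: the pre-incubation is an
order of magnitude longer than the shift phase, so a few weeks at the
new temperature modulate rather than replace the established
community.  The floor is a rare-biosphere seed — it lets thermophiles
bloom after an up-shift to 45 °C even though they were undetectable at
25 °C.  A pure current-temperature response (γ = 1, no legacy term) was
tried first and rejected: it makes the incubation temperature, not the
pre-incubation temperature, the dominant axis of Bray–Curtis variation,
which contradicts the behaviour this design is meant to emulate.

**Hysteresis.**  OTUs carry a hysteresis flag; flagged OTUs have their
expectation forced to zero in every sample pre-incubated at 45 °C,
whatever the later shift.  Defaults: all mesophilic Archaea are
hysteretic (archaeal diversity, once lost at 45 °C, does not recover),
as are mesophilic Bacteria except two "recoverer" OTUs per mesophilic
assemblage.  Recovery must be coherent across domains: if bacteria
recover after a down-shift while archaea do not (or vice versa), the
within-domain renormalisation of read counts decorrelates thermophilic
Bacteria from thermophilic Archaea and splits the 45 °C co-occurrence
module by domain — an artifact of compositional data, not biology.

**Ecotypes.**  A per-soil override table changes an OTU's niche,
hysteresis flag or baseline without changing its label, emulating
thermal ecotypes.  The three default soils differ functionally:

* Soil I ("Italian-like"): one acetoclastic OTU is non-hysteretic, so
  the acetoclastic pathway (and low α_app) returns after a down-shift;
  syntrophic acetate oxidizers handle acetate at 45 °C.
* Soil P ("Philippines-like"): acetoclasts have broad (width 15 °C),
  non-hysteretic niches — the mixed pathway operates at every
  temperature.
* Soil U ("Utah-like"): syntrophic acetate oxidizers are effectively
  absent and nothing recovers after 45 °C, so 45 °C-pre-incubated
  vessels lose both acetate-consuming guilds and acetate accumulates
  (~70 mM versus a ~0.5 mM baseline).  One fermenter is a thermophilic
  ecotype here (same OTU label, different thermal optimum).

A few bacterial OTUs carry a fixed cross-soil baseline so that the
shared-OTU report has planted positives; all other baselines are
lognormal(0, σ=1.5), drawn independently per soil, so each soil's
abundant community is largely its own.

**Counts.**  Within each domain, expected weights are normalised and
reads drawn by a single multinomial at the domain depth (column sums
equal the depth exactly).  Per-sample lognormal replicate noise
(σ_rep = 0.8 on the log scale) is applied before normalisation.  σ_rep
is the one deliberately calibrated constant: it sets where
within-assemblage Spearman correlations across the 36 samples of one
soil land, and 0.8 centres them in the 0.8–0.9 band that the network
stage uses — smaller values push correlations above the band's upper
bound, larger ones below the lower bound.  Overdispersion beyond this
(Dirichlet-multinomial) is not modelled.

**Isotopes.**  Each sample's hydrogenotrophic exclusivity is
`f = clip(1 − A_aceto / threshold, 0, 1)`, where A_aceto is the
expected within-archaea relative abundance of the acetoclastic guild
and the activity threshold is 1 %.  The true fractionation mixes the
endmembers linearly, `α = f·1.08 + (1−f)·1.04`.  This mapping is a
modelling choice — endmember values alone do not identify the
activity→α function; it is saturating so that any appreciable
acetoclastic activity yields the mixed-regime value.  Time series relax
exponentially (τ = 5 d) from the pre-incubation state's α to the
sample's equilibrium α; δ¹³CO₂ is drawn around −10 ‰ (SD 0.5 ‰) and
δ¹³CH₄ follows from the α_app identity plus 1 ‰ measurement noise.
CH₄/CO₂ amounts accumulate linearly, scaled down where methanogenesis
has stalled (acetate-accumulating vessels).

**Ancillary data.**  qPCR copy numbers are lognormal around 10⁹ g⁻¹
(Archaea) with a 10× bacterial:archaeal ratio; acetate is ~0.5 mM
except where neither acetoclastic methanogens nor syntrophic acetate
oxidizers are active (both below the 1 % activity threshold), where it
is ~70 mM.

**Randomness.**  All draws flow from one seed through named substreams
(baselines, counts, isotopes, ancillary), so regenerating one output
never perturbs the others; identical seeds give byte-identical files.

## Analysis stages and numerical choices

* **Rarefaction** — multivariate hypergeometric subsampling (without
  replacement) per sample; samples below depth are dropped with a
  warning.  The pipeline rarefies each domain to
  min(configured depth, smallest library).
* **Alpha diversity** — natural logs throughout; Chao1 in the
  bias-corrected form S + F₁(F₁−1)/(2(F₂+1)) (defined when F₂ = 0; the
  classic form is a flag away); Fisher's α solved from
  S = α·ln(1 + N/α) by Brent root-finding (tolerance 10⁻¹²); J =
  H′/ln S.  Diversity uses tables *with* singletons; ordination and
  networks use singleton-free tables.
* **Letters** — Kruskal–Wallis omnibus gate, then Dunn tie-corrected
  pairwise z-tests with Benjamini–Hochberg adjustment; Duncan's
  multiple range test uses studentized-range quantiles at the
  protection level α_p = 1 − (1−α)^(p−1) and the harmonic mean n for
  unbalanced groups.  Both feed an insert-and-absorb compact letter
  display; the highest mean always carries "a".
* **NMDS** — non-metric SMACOF (monotone regression), k = 2, 20 random
  restarts, eps 10⁻¹², best Kruskal stress-1 kept along with every
  restart's final stress.
* **PCA selection** — Hellinger transform, column-centred, unscaled
  (the common default; scaling is not used because Hellinger values
  share a scale).  Loadings are unit-norm right singular vectors; signs
  are arbitrary and only absolute values are used.  Ties at the k-th
  largest |loading| are all included.
* **Network** — abundance filter keeps OTUs *at* the threshold
  ("less than … filtered out"); the correlation band is inclusive on
  both ends (0.8 ≤ ρ ≤ 0.9) and q strictly < 0.01.  The upper bound
  discards the very strongest correlations; it is retained verbatim as
  part of the published filter rather than reinterpreted.  Spearman p
  values use the t approximation with n − 2 df (exact permutation is
  impractical at n = 36 and unnecessary given the q-threshold
  regime).  The FDR family is all OTU pairs of one soil surviving the
  abundance filter, Bacteria and Archaea combined.  All 36 samples of a
  soil (both phases) enter the correlations.  Louvain runs 10 seeded
  restarts keeping the max-Q partition; Q is always re-evaluated from
  the definitional formula on the stored partition.  A "major" module
  holds ≥ 10 % of network nodes (threshold configurable).  Module
  temperature labels are the argmax of the module's mean member
  relative abundance over pre-incubation-temperature sample groups;
  ties go to the lower temperature with a warning.
* **Pathway classification** — terminal mean over the last 5 time
  points, threshold 1.06 (midpoint of the anchors), boundary assigned
  hydrogenotrophic-dominant.  The window is a documented choice; time
  courses do not come with a canonical reduction.
* **VFA flags** — acetate accumulation is flagged against 10× the
  cross-treatment median; the pipeline evaluates this over all soils at
  once because a per-soil median is itself inflated when half of that
  soil's treatments accumulate.

## What the generator does and does not show

Passing tests demonstrate that every stage recovers planted structure
under the generator's assumptions: Gaussian niches, clean guild
memberships, multinomial sampling, a single legacy mechanism.  Real
amplicon data add overdispersion beyond multinomial, compositional
interactions among hundreds to thousands of OTUs, chimeras and
taxonomy errors, and environmental drivers other than temperature;
module recovery there will be correspondingly weaker.  The generator is
a validity check for the machinery and a sandbox for effect sizes, not
evidence about any particular soil.

## Known limitations

* Positive-correlation networks only; no SparCC-style compositional
  correction of the correlations themselves.
* The activity→α mapping is linear between two endmembers; open-system
  isotope effects and CH₄ oxidation are not modelled (the latter is
  absent in anoxic slurries by design).
* Dunn post-hoc at n = 3 replicates has little power; letter displays
  on the default design mostly separate only extreme treatments.
* NMDS stress near zero (perfectly embeddable configurations) is
  reported as computed; stress-based dimensionality diagnostics are not
  implemented.
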