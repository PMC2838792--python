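# Methods

This note records the models implemented in `cladelink`, the choices made
where the method leaves room, and what the synthetic studies do and do not
demonstrate.

## Behavioral networks by parsimony

Individuals are leaves of an unrooted tree; every behavioral symptom is a
character. Dichotomous symptoms are scored as unordered binary characters
(Fitch): one unit per gain (0→1) or loss (1→0). Four-state severity scales
(absent / minimal / moderate / severe) are scored as ordered characters with
cost |i−j| (Wagner), because severity is a natural ordering; a switch
(`ordered_ordinal=False`) treats them as unordered instead. Missing states
are free — they are assigned whatever state minimizes tree length and never
contribute cost, and they are likewise excluded from all prevalence counts
and likelihood-ratio tallies.

Tree search is a Nixon-style parsimony ratchet: hill-climb on a matrix in
which a random 25% of characters are doubled in weight, then hill-climb on
the original weights, keeping every distinct minimal tree found (default 200
iterations, capped at 1000 trees deduplicated by bipartition set). Climbs
use first-improvement rearrangement with SPR neighborhoods up to 16 leaves
and NNI neighborhoods beyond, where SPR enumeration becomes the bottleneck;
the separate `spr_refine` step always uses full SPR and is intended for
re-analysis within a single clade. Identical symptom profiles are collapsed
to one leaf during search and re-expanded as a polytomy afterwards, which
provably leaves the score unchanged and shrinks realistic inputs (hundreds
of individuals, dozens of distinct profiles) to tractable size. The
change-counting inner loop (set-Fitch for unordered, Farris intervals for
ordered characters) is JIT-compiled with numba; the public
`parsimony_score` is an independent vectorized Sankoff dynamic program that
also handles multifurcating trees, and the two paths cross-check each other
in the tests. Exhaustive enumeration (≤8 leaves) with a third, recursive
scorer lives in `cladelink.reference` as the oracle.

Consensus keeps exactly the bipartitions present in more than 51% of the
equally parsimonious trees (strict majority guarantees pairwise
compatibility, so the consensus always exists); unresolved regions stay
multifurcating.

## Nesting and affection coding

The network is rooted at an artificial all-zero "asymptomatic"
pseudo-individual added before the search and removed after rooting —
asymptomatic relatives cluster at one end of the network, so this anchors
the direction of increasing symptom load. Every internal node of the rooted
consensus with ≥2 descendant leaves is a clade. Levels are depth ranks
numbered downward (the root's children carry the maximum level, leafward
clades smaller numbers); indices enumerate clades within a level in
preorder. Labels are `level_index`. The family filter (default: members from
≥40 distinct families) is applied before any linkage test, as an a priori
multiplicity control. A clade's affection coding marks members affected,
their symptom-scored relatives unaffected, unscored relatives unknown
(unscored is not asymptomatic), and drops families with no members from that
clade's analysis.

## Pedigree likelihoods, LOD, and HLOD

Two-point likelihoods are exact Elston–Stewart peeling over joint
disease–marker genotypes. An individual's state is an ordered pair of
haplotypes (disease allele × marker allele), so a marker with m alleles
gives (2m)² states. Founders carry Hardy–Weinberg priors at both loci under
linkage equilibrium, with marker allele frequencies taken from the map file
or estimated by counting typed founders. Transmission recombines with
probability θ (sex-averaged); penetrance applies to the affection status
(unknown contributes a factor 1, the standard convention); untyped marker
genotypes are summed over. Messages are batched over the model and θ grids
and rescaled against underflow. Pedigrees with loops are rejected with an
explicit error rather than approximated. The default θ grid is
{0, 0.01, 0.05, 0.10, …, 0.50}; LOD(0.5) = 0 holds exactly by construction.

A family–model combination whose likelihood is zero at every θ (e.g. an
unaffected child of two affected parents under a fully penetrant recessive
model) is excluded from that model with a warning; a family inconsistent
under *every* model has a genotype error and is excluded from the marker.
LOD(0) = −∞ for obligate recombinants is kept — it is meaningful and handled
by the admixture score.

The heterogeneity statistic is the admixture HLOD jointly over (α, θ),
compared against "no linkage, no heterogeneity": a 0.01-step α grid followed
by bounded scalar refinement around the grid optimum. At α = 1 the HLOD
equals the homogeneity LOD sum, and its maximum is never below
max(0, homogeneity LOD). The reported per-clade `Z_max` maximizes over the
four genetic models and both analysis schemes (LOD and HLOD). The four
models are: Dom-1 (penetrances 0/1/1, q = 0.01), Rec-1 (0/0/1, q = 0.09),
Dom-2 (0.0005/0.55/0.55, q = 0.01), Rec-2 (0.0005/0.0005/0.55, q = 0.09).

`cladelink.reference.brute_force_family_loglik` materializes the full joint
genotype table (feasible to 6 members × 2 marker alleles) as the oracle for
the peeling engine; agreement is asserted to 1e-10 relative.

## Four-group LRT and permutation p-values

For a clade and a diagnostic category, the scored cohort partitions into
group 4 (intersection), group 3 (clade only), group 2 (category only), and
group 1 (the rest). Per-trait presence means state ≥1 (any severity);
missing states drop out of both numerator and denominator. The null pools
the non-empty groups among {2, 3, 4} into one binomial rate; the alternative
frees group 2 against the pooled clade groups {3, 4}. At the boundaries the
comparison degenerates to the two informative groups (2 vs 4 under
containment, 2 vs 3 under disjointness); with fewer than two non-empty
groups the test is undefined and flagged, never reported as p = 1. Group 1
multiplies both likelihoods identically and cancels. The statistic is
2(lnL_A − lnL_0) at closed-form plug-in MLEs, validated against grid-search
maximization at 1e-6 resolution.

The permutation null shuffles clade membership across the scored cohort,
holding the clade size and all diagnostic labels fixed — the minimal
exchangeable null for the hypothesis — with the (hits+1)/(n+1) convention
(default 10,000 permutations). Family structure is not preserved under
permutation; symptom correlation between relatives therefore makes these
p-values anti-conservative to a degree the test does not correct.
Significance is reported unadjusted at 0.05; a Benjamini–Hochberg column is
available as a convenience. Clade profiles list traits present in strictly
more than 70% of scored members.

## Gene-dropping empirical p-values

Replicate genotype datasets keep the pedigree, map, and missingness pattern
fixed and redraw founder genotypes from the marker allele frequencies
(linkage equilibrium), transmitting with recombination from the Haldane map
function on the cM gaps (Kosambi available as an option). Clades and
phenotypes are never re-derived — only genotypes are randomized, so the
replicates embody "no linkage between this phenotype and anything". p_M
compares a clade's observed maximum (over models and markers, LOD and HLOD)
with each replicate's same maximum; p_G compares against replicate maxima
across all analyzed clades as well. Both use (hits+1)/(R+1); the default
R = 100 gives a floor of ≈0.01. The p_G denominator includes only the clades
that passed the family filter.

## Synthetic family studies

The generator emulates the architecture of the GAW14 KPD simulation; the
exact GAW14 generating tables are not public, so all quantitative settings
are this package's own, chosen once to be realistic and documented here:

* Three populations (Aipotu, Karangar, Danacaa; default 100 families each,
  two founders + four children) ascertained by redrawing each family until
  ≥2 members carry a qualifying latent phenotype (any of P1–P3; P2/P3; P1
  respectively).
* Latent phenotypes from epistatic two-locus predicates: P1 = carrier at D1
  and D2; P2 = homozygous D2 and carrier D3; P3 = carrier D2 and homozygous
  D3 (P2 and P3 differ only by trait *b*). Base penetrance 0.95;
  multiple satisfied predicates resolve in priority order P1 > P2 > P3.
* D4 carriers have full P2/P3 penetrance, non-carriers ×0.6 — D4 adds
  linkage signal to those clades. Modifier loci D5/D6 multiply penetrance by
  0.85 each when carried. D2 alone expresses traits {e, f, h} in otherwise
  unaffected carriers with probability 0.20 (a dominant sub-clinical
  effect).
* Disease allele frequencies 0.12 (D1), 0.18 (D2, D3), 0.20 (D4–D6). Common
  disease alleles put carriers on both parental sides and visibly dilute
  two-point linkage information; these values keep ascertainment feasible
  while preserving a localizable signal.
* Traits: P1 → {b,e,f,h}; P2 → {c..h}; P3 → {b..h}, expressed with
  probability 1; every trait is additionally present at a background rate of
  0.02 in everyone, producing the symptom continuum into unaffected
  relatives.
* Marker panel: 416 microsatellites, 7.5 cM spacing, 10 chromosomes, 4
  alleles with Dirichlet(2) frequencies. `KPDConfig.scaled()` is the
  desk-scale design used throughout the tests: 3 × 30 families, 4
  chromosomes × 8 markers, loci D1–D3 on chromosomes 1–3, D4 distal on
  chromosome 3, chromosome 4 free of any locus as the unlinked control, and
  a proportionally scaled family filter (12 of 90 families ≈ the 40 of 300
  default).

What the generator does **not** emulate: diagnostic misclassification,
variable family structures and marriage loops, marker genotyping error,
linkage disequilibrium between markers, and trait–trait correlation beyond
what the latent phenotypes induce. Passing the end-to-end tests therefore
shows that the pipeline recovers a clean epistatic architecture from
symptoms alone at realistic sample sizes — not that it is robust to every
artifact of real clinical data.

Truth recovery is judged against either locus of the causal pair (D1 or D2
for a P1-enriched clade): with epistatic determination both loci are causal,
and which one dominates the two-point signal varies by ascertainment and
chance. A run counts as localized when the maximum-HLOD marker lies within
15 cM (two marker intervals) of a causal locus.

## Problem sizes and numerical choices

The validation suite uses sizes chosen for exactness of the oracles:
exhaustive tree enumeration to 7 leaves (945 topologies), brute-force
pedigree likelihood to 6 members × 2 alleles (16⁶ joint states), 1e-6 grid
resolution for the LRT oracle, 200-study calibration runs at R = 25
replicates, and 20 seeded end-to-end studies at the scaled design. Message
rescaling keeps likelihoods in range for families far deeper than any used
here. Ties in the change-count backtrace prefer the parent state, then the
smallest state; tree-set deduplication and all enumeration orders are
deterministic, so every search, simulation, permutation, and replicate
stream is exactly reproducible from its seed.

## Known limitations

* Two-point linkage only; no multipoint or identity-by-descent statistics.
* Loop-free pedigrees only; loops are rejected, not broken.
* Autosomal markers, sex-averaged recombination.
* The LRT and permutation null treat individuals as exchangeable, ignoring
  familial correlation of symptoms.
* Clade labels reproduce the structural semantics (level = inclusiveness,
  index = traversal order), not any particular program's node numbering.
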