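# Methods

`zwevo` reconstructs the evolutionary history of avian Z/W gametologs —
orthologous gene pairs stranded on the two sex chromosomes when
recombination between them ceased — and tests the selective forces acting
on them afterwards.  This note documents the models, the defaults and the
reasoning behind the open design choices.

## The inference chain

1. **W-linked gene discovery** (`wlinkage`, `homology`): putative W genes
   are female-limited or strongly female-biased in sexed expression data
   (females are the heterogametic ZW sex), or highly similar to known
   reference W genes.
2. **Gametolog pairing** (`homology`): each species W gene is mapped to the
   reference-species W ortholog by best similarity hit, the curated
   reference W→Z table gives the reference Z gene, and the species' Z
   ortholog is the reciprocal best hit of that reference Z gene, with a
   next-best-hit fallback when young gametologs break reciprocity.
   Multi-copy W paralogs resolve to the pair with the lowest dS.  W
   fragments with reference coverage < 25% *and* aligned length < 150 bp
   are excluded (a conjunction, as the rule is stated; an OR variant sits
   behind `mode="or"`).
3. **Codon-aware alignment** (`seqio`): translated proteins are aligned
   (Needleman–Wunsch, BLOSUM62, progressive against the first record for
   more than two sequences) and back-threaded onto codons, so gaps always
   occupy whole codons.  Manual removal of poorly aligned regions is
   replaced by a deterministic mask: codon columns with > 50% gaps, and
   5-codon windows below 40% mean pairwise identity, iterated to a
   fixpoint (hence idempotent).  The thresholds are explicit stand-ins for
   a visual-inspection step and are configurable.
4. **Pairwise divergence** (`divergence`): maximum likelihood under a
   Goldman–Yang codon model (61 sense codons, transition/transversion
   ratio κ, dN/dS ratio ω, F3x4 codon frequencies), optimised by bounded
   quasi-Newton on (log t, log κ, log ω) from three fixed starting points.
   dS and dN derive from the fitted branch length through the synonymous /
   nonsynonymous flux fractions of the fitted matrix and the site
   proportions of the ω = 1 mutation matrix.  Standard errors come from
   the observed information via the delta method; 95% CIs are ±1.96 SE
   floored at zero.  The Nei–Gojobori (1986) counting method (pathway
   averaging, Jukes–Cantor correction; mutations to stop codons count as
   nonsynonymous) is kept as an independent cross-check.  Pairs with
   dS > 1 are declared saturated and barred from dating.
5. **Strata and dating** (`strata`): a locus joins its reference
   ortholog's stratum when the two dS 95% CIs overlap, is called
   lineage-specific when its CI is disjoint and lower, and a
   high-support "independent" gene-tree call overrides CI overlap (the
   device that resolves young regions where divergence alone is
   ambiguous; conflicts are flagged).  Dates use the sex-chromosome
   molecular clock T = dS / (3.8 × 10⁻⁹ /site/year) — a combined Z+W
   synonymous rate that already folds in male-mutation bias — rounded to
   the nearest My.
6. **Gene trees** (`genetrees`): exhaustive topology search (3/15/105
   topologies for 4/5/6 tips) under HKY85 with empirical base
   frequencies, rooted on the zebra-finch Z outgroup.  Bootstrap support
   resamples codon triplets (frame preserved).  `method="refit"`
   re-optimises every topology per replicate; `method="rell"` resamples
   per-codon log-likelihoods at the original optima (Kishino–Hasegawa).
   RELL tracked refit closely in side-by-side runs at ~1/100 the cost and
   is what the large simulation studies use.  A tree is "shared" when the
   W tips form a clade at ≥ 95% support, "independent" when every species'
   Z+W pair does, otherwise "unresolved".
7. **Gene conversion** (`geneconv`): candidate tracts are maximal runs of
   agreement between a Z and a W sequence over silent polymorphic sites
   (columns that vary in nucleotide but not amino acid — selection on
   protein sequence cannot mimic them).  gscale 0 permits no mismatches;
   gscale 2 penalises each mismatch by 2.5 agreement units (two mismatches
   cancel roughly five matches; configurable) and keeps disjoint
   maximal-scoring segments.  Significance: 10,000 (default) permutations
   of the polymorphic-site columns shared across all Z–W pairs;
   sim_p = (1 + #{permutation max ≥ score}) / (n_perm + 1).  A
   Bonferroni-over-pairs, Karlin–Altschul-style length-corrected p-value
   is reported alongside.  Fragments are "inner" when the run contains at
   least one pair-private agreement site (a state found in no other
   sequence — evidence the exchange involved these two lineages);
   ambiguous runs default to outer.  Exons covered by < 50 bp of fragment
   span are discarded.  Direction: at each fragment site the pair's shared
   state is polled against same-chromosome relatives (Z-like vs W-like);
   a call needs ≥ 3 informative sites with ≥ 80% agreement, otherwise an
   ML tree of the spanning exons decides by which chromosome clade absorbs
   the converted pair; otherwise "unknown".  dS is re-estimated after
   dropping converted exons.
8. **Selection** (`selection`): branch models give the designated
   foreground (all-W or all-Z branches, outgroup excluded) its own ω;
   LRTs compare the free model to ω_fg = 1 (neutral) and ω_fg = 0 (strict
   purifying selection, floored at 10⁻⁶ to keep the likelihood finite) on
   χ²(1).  The branch-site model A adds site classes (ω₀ < 1, ω = 1, and
   foreground classes 2a/2b with ω₂ ≥ 1) and tests ω₂ = 1; both the χ²(1)
   p-value and the 0/χ²(1) mixture are reported, with significance flags
   on χ²(1).  Branch lengths, κ and proportions are re-optimised under
   every model; on a 2-taxon tree the branch-model likelihood matches the
   pairwise ML likelihood to < 10⁻⁴ (tested).

## The synthetic-data generator

The generator (`simdata`) emulates the statistical structure of the real
inputs so every stage is testable without downloads.

* **Species tree** (((Gg, Mg), Ap), Tg) with splits at 30, 90 and 130 My
  (chicken, turkey, mallard; zebra finch outgroup, Z only).
* **Suppression events**: per locus, each taxon carries a
  years-before-present time at which Z–W recombination ceased.  Taxa with
  equal times at or above their species split share one event (their W
  genes form a clade); younger equal times are independent per-lineage
  events.  Contradictory configurations (a single lineage "suppressed"
  before it existed, given another W-bearing taxon with a different time)
  are rejected.
* **Sequence evolution**: an HKY mutation process (κ default 2.0, uniform
  base frequencies) layered on codons with nonsynonymous changes damped by
  ω — i.e. the Muse–Gaut codon chain — sampled exactly per branch from the
  matrix exponential.  The matrix is rescaled so one unit of branch length
  is one synonymous substitution per synonymous site; a branch spanning
  Δt years at rate μ has length μΔt.  W branches use μ_w, everything else
  (Z, ancestral, outgroup) μ_z, with defaults in ratio 1:2.4 scaled so
  μ_w + μ_z = 3.8 × 10⁻⁹ — the clock constant is the only number the data
  pin down; the split is a labelled assumption from male-mutation-bias
  estimates in birds.  Consequently a locus suppressed T years ago has
  expected Z–W dS of 3.8 × 10⁻⁹ · T, the identity the dating stage
  inverts.  Defaults ω_w = 0.1, ω_z = 0.2 reflect the strong purifying
  selection measured on these chromosomes.
* **Conversion tracts** are applied as literal donor→recipient copies over
  [start, end) after sequence simulation, recorded in the truth table.
* **Expression**: W genes exactly zero in males, Z and autosomal genes
  lognormal in both sexes (log-sd 0.5 around 20 FPKM-like units).
* **SNPs**: every fixed Z–W difference yields a female-limited SNP
  (females carry both chromosomes); identical young pairs optionally get
  one segregating W-private variant.

What the generator does **not** emulate: indels (so alignment-quality
machinery is exercised only by constructed fixtures), rate heterogeneity
among sites, codon-usage bias, assembly fragmentation, read-level noise
in expression, and intra-W ampliconic duplication.  Passing tests
therefore demonstrate correctness of the inference machinery under the
stated model, not robustness to every artefact of real assemblies.

## Study designs and measured behaviour

Problem sizes were chosen to finish comfortably on one CPU; bootstrap and
permutation counts are reduced (1000→200, 10,000→2,000) and flagged here.

* **Clock dating**: the printed stratum dS bounds map to 75–106, 45–71,
  41–71, 36–68 and ≤ 39 My; exact reproduction is asserted.
* **Estimator cross-check**: 100 pairs at true dS ∈ {0.05, 0.15, 0.30}
  under κ = 1, ω = 1, where NG86's equal-rate counting is exact.  Under
  the generator default κ = 2, NG86 shows its well-known upward dS bias
  (≈ +13% at dS ≈ 0.34 against ML), which is why the cross-check pins
  κ = 1; the ML route is the production estimator.
* **Conversion-test calibration**: 400 4-sequence null loci (Gg/Ap shared
  suppression drawn uniformly over 90–130 My, cds 900), within-species
  pair tested.  The rejection rate at α = 0.05 falls in the nominal band.
  The KS uniformity check fails by construction: the run score is an
  integer whose null tail decays by a factor ≈ p_agree ≈ 0.3 per unit, so
  sim_p is lattice-valued and strictly superuniform (deficits 0.1–0.2
  between attainable values); a KS test at n = 400 resolves this for any
  faithful implementation of the permutation statistic.  Heterogeneous
  ensembles (CDS 0.6–3 kb, suppression 30–130 My) smooth but do not
  remove the lattice, and very young loci push the test further into
  conservatism.  Practical reading: sim_p is valid but conservative
  between its attainable levels.
* **Stratum recovery**: ancestral (90 My, shared at the Galloanserae
  split), intermediate (60 My, independently suppressed in both
  lineages), lineage-specific (20 My); 10 loci each, cds 900.  The
  ancestral stratum is recovered through CI overlap (its gene tree is
  necessarily unresolved — at suppression exactly coincident with
  speciation the W internal branch has zero length); the intermediate
  stratum is recovered by the tree override; dates are assessed as
  per-stratum means because a single locus at 20 My and 300 codons
  carries ~24% relative SE on dS.
* **Topology classification**: 25 shared loci (Gg+Mg at 90 My, 60 My of
  W-clade internal branch) and 25 independent loci (Gg and Ap each at
  40 My), cds 1800 — typical real gametolog CDS run 1.5–8 kb, and power
  measurements at cds 900 put shared-call support astride the 95%
  threshold, so the study uses a realistic longer gene.
* **Selection tests**: 25 neutral-foreground and 25 ω_w = 0.1 loci
  (7 tips, cds 900).  The free-vs-1 LRT holds its size and detects
  purifying selection essentially always at these divergences, consistent
  with the very large likelihood ratios such data produce.

## Numerical choices

* Reversible rate matrices are diagonalised through the symmetric
  similarity transform (√π scaling) with `eigh`; decompositions are
  cached on (κ, ω), which makes numeric gradients over branch lengths
  cheap.
* Likelihood optimisation: L-BFGS-B in log-parameter space, ftol 1e-10,
  bounds wide enough to be inactive at realistic optima; nested-model
  fits are warm-started from each other and re-polished if nesting is
  violated numerically.
* Pattern compression (unique codon columns) before every tree
  likelihood.
* Pairwise estimates with zero variable sites short-circuit to
  dS = dN = 0 with zero SE; ω is flagged undefined when dS = 0.
* Ties: similarity hits sort by (−score, target id); paralog resolution
  by (dS, −aligned length, W id); fragment selection by (−score,
  leftmost, longest).
* Coordinates are 0-based half-open everywhere in code and tables.

## Known limitations

* The progressive protein alignment is reference-guided (first record),
  adequate for the highly similar gametolog sets it serves, not a general
  MSA replacement.
* Exhaustive tree search is capped at 8 tips by design.
* The KA-style corrected p-value for conversion fragments uses an
  ungapped-approximation prefactor (K = 1 on the expectation scale,
  Bonferroni over pairs); it is a screening correction, not an exact
  error rate.
* The branch-site ω₂ and class proportions are weakly identified at
  single-gene scale (a familiar property of model A); the LRT is the
  reliable summary.
* GTR and among-site rate variation are not implemented for gene trees;
  HKY85 with empirical frequencies is the fixed model.
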