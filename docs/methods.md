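# Methods

This note documents the statistical model behind `episig`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic test
bed does and does not establish.

## Differential methylation model

Methylation fractions (beta values) are variance-stabilised to M-values,
M = log2(β′/(1−β′)) with β′ clipped to [ε, 1−ε], ε = 1e-6. For each probe
*g* an ordinary least-squares fit of M on [intercept, case indicator,
cell-proportion covariates] yields the group coefficient, residual
variance s²_g and residual degrees of freedom d_g. Because cell
proportions lie on the simplex, the last proportion column is dropped to
keep the design full rank.

The per-probe variances are shrunk by an empirical-Bayes prior: assuming
s²_g | σ²_g ~ σ²_g χ²_{d_g}/d_g with a scaled inverse chi-square prior on
σ²_g, the hyperparameters (d₀, s₀²) are fitted by the method of moments on
e_g = log s²_g − ψ(d_g/2) + log(d_g/2): the excess of var(e) over
ψ′(d_g/2) determines d₀ through the trigamma inverse (Newton iteration;
monotone and convex, converges in a handful of steps), and mean(e) gives
s₀². When the excess is non-positive d₀ = ∞ and every probe is tested
against s₀² with a normal tail. An exactly-degenerate variance vector
(all s²_g identical — impossible with continuous data, reachable in
constructed fixtures) short-circuits to d₀ = ∞ with s₀² equal to the
common variance, so the moderated statistic coincides with the ordinary t.
The moderated statistic is t_g = β̂_g / (s_post,g · v) with d₀ + d_g
degrees of freedom, v the unscaled coefficient SE. The test suite verifies
the whole machinery against limma (via Rscript) to ≤1e-6 relative error
and against an independent bisection solver of the same moment equations.

Effect sizes are reported on the beta scale (mean case β − mean control β
over the matched cohort), where the 10% threshold is meaningful; test
statistics live on the M scale.

## The selection funnel

Probes meeting the differential criteria (|Δβ| > 0.10 strictly, BH q <
0.01 strictly) form the funnel's universe. This effect/FDR prefilter is a
deliberate design choice: the probes that survive the downstream funnel
are exactly the differential probes, which keeps the selected signature
interpretable and makes its direction composition reflect the biology
rather than the tail behaviour of null probes. Without it, whenever the
true differential set is smaller than the ROC budget the remaining slots
fill with direction-symmetric null probes. The prefilter can be disabled
(`dmp_prefilter: false`) to obtain the unconditional funnel.

Stages, each deterministic with documented tie-breaks:

1. **Ranking product.** score = |Δβ| · (−log₁₀ p), descending; ties broken
   by smaller p, then probe id. Raw p is used by default
   (`rank_uses_adjusted_p` switches to q). Top 1000 kept.
2. **ROC selection.** Per-probe AUC by the rank-sum identity with midrank
   tie handling, using raw betas as scores; probes ranked by
   max(AUC, 1−AUC) so hypo- and hypermethylated probes compete
   symmetrically; ties preserve the incoming rank order. Top 500 kept.
3. **Correlation pruning.** Greedy scan in rank order; a probe is kept iff
   its Pearson |r| with every already-kept probe is ≤ 0.9, computed across
   all training samples on the beta scale. Constant probes (undefined r)
   are kept with a warning. Greedy rank-order pruning, not a graph-optimal
   independent set, because it is deterministic and order-faithful.

The final probes' case and control training medians are stored in the
model for concordance scoring.

## Matched controls

Sex is matched exactly and age by nearest neighbour, 7 controls per case,
sampled without replacement; cases are processed in lexicographic id order
and age ties break by lexicographic control id, making the procedure fully
deterministic and invariant to pool row order. Propensity-score machinery
is intentionally not reproduced: sex and age are the only matching
variables the workflow uses.

## MVP classifier

Features are betas at the signature probes. The training set is every case
plus 75% of controls and 75% of each confounder-disorder pool (seeded,
stratified by pool); the binary target is case vs rest. A linear-kernel
SVM (C = 1) provides the decision function; a one-dimensional logistic fit
on the training decision values (lightly regularised so the map stays
finite on separable data) provides the calibrated probability. The
calibration pair (A, B) and the hyperplane (w, b) serialise to plain JSON,
so a saved model reproduces scores to ≤1e-10 without any fitted library
object. The 0.5 label in reports is a convenience only — no diagnostic
claim is made, and a low score does not rule out pathogenicity.

Leave-one-out validation re-derives the signature from the remaining
cases with freshly matched controls, embeds training cases, controls and
the held-out sample by classical MDS, and assigns the held-out sample to
the nearer group centroid — an algorithmic version of reading membership
off an ordination plot.

## DMR calling

A transparent seed-and-extend rule replaces kernel-based region testers:
maximal runs of probes with inter-probe gaps ≤ 1000 bp on one chromosome,
with ≥ 5 CpGs, region mean Δβ (unweighted over members) of at least 10%,
and Fisher-combined member p-values BH-adjusted *across all candidate
runs* strictly below 0.01. The Fisher statistic X = −2Σ ln p is compared
to χ²_{2k}; underflow is floored at the smallest normal double. Stouffer's
Z = Σz_i/√k is reported alongside. Region coordinates are 0-based
half-open, [first probe, last probe + 1].

Whether the 10% threshold applies to the region mean or to every member is
not uniquely determined by the criteria as printed; the region mean is
used (the per-member reading is a one-line config change downstream of the
probe statistics).

## Enrichment

All three analyses share one Fisher 2×2 core (sample OR with 0/∞
sentinels; two-tailed p by hypergeometric enumeration, verified against an
exhaustive oracle for all margins ≤ 30).

* **Probe categories:** signature membership × category membership against
  the analyzed-probe background. Significance tiers (\*, \*\*, \*\*\* at
  0.01 / 1e-3 / 1e-6) annotate the raw p; BH-adjusted q across categories
  is reported alongside.
* **DMRs vs feature tracks:** a DMR hits a track iff strictly more than
  50% of its length is covered. The null is 1000 seeded, length-matched
  intervals placed uniformly (chromosomes weighted by length) — a
  documented, reproducible stand-in for partition-based nulls whose exact
  margins are tool internals. Tiers at 0.05 / 0.01 / 0.001.
* **Combo score:** a = query intervals overlapping the reference (≥1 bp),
  b = remaining query, c = non-overlapped reference intervals, d fills the
  table to genome extent / mean interval length (both sets pooled).
  combo = sign(ln OR) · |log₂ OR| · (−log₁₀ p); an OR of exactly 1 scores
  0; zero cells use the Haldane-corrected OR for the magnitude while the
  raw direction sets the sign. p is floored at 1e-300 before the log.
* **Chromatin states:** one combo score per state per epigenome (absent
  states score 0), pairwise two-sided Wilcoxon rank-sum across states
  (exact enumeration below 50 combined tie-free observations, otherwise
  the midrank normal approximation with tie correction) with BH
  adjustment.

## The synthetic cohort generator

The generator's defaults are the study conditions used throughout the test
suite and the acceptance script: 20,000 probes on two synthetic
chromosomes, 8 cases, a 200-control pool (7:1 matching then yields 56),
two confounder pools of 20, 300 signal probes with Δβ ~ U(0.10, 0.20),
100% hypermethylating, logit noise sd 0.15, six blood cell types.

What it emulates:

* **Probe geography** — CpG-island-like clusters (5–12 probes, 50–500 bp
  gaps) carrying promoter categories, isolated probes (>2 kb apart)
  carrying Body/3'UTR/IGR, with marginal category frequencies matching the
  configured EPIC-like composition; a configurable fraction of probes
  carries QC flags.
* **Bimodal baselines** — promoter probes mostly near β ≈ 0.1, gene-body
  and intergenic probes mostly near β ≈ 0.85.
* **Cell-composition confounding** — per-cell-type logit offsets (larger
  on a 10% highly-variable subset), Dirichlet mixtures per sample, and a
  mean composition shift for cases, which makes the covariate adjustment
  of the discovery stage consequential.
* **Planted truth** — about half the signal probes are whole promoter
  clusters (each recorded as a planted region; members share a direction),
  the rest scattered with promoter-category probes upweighted 5×. Effects
  are anchored to the expected control-group mixture beta and
  feasibility-checked so the realized |Δβ| never falls below the
  configured minimum. Sample betas follow
  expit(logit(mixture) + effect + N(0, sd)), which keeps values strictly
  inside (0, 1). Confounder signatures are scattered on probes disjoint
  from the case's and from each other's, so specificity failures are
  attributable to the classifier.
* **Chromatin states** — each synthetic epigenome partitions every
  chromosome exactly; promoter clusters get an Active TSS core
  (probability 0.75, else a bivalent/flanking promoter state) with
  Flanking Active TSS shoulders; the remainder is quiescent-dominated
  2–20 kb segments. The default of 127 epigenomes mirrors the reference
  compendium; tests and the acceptance pipeline use 8 per cohort, which is
  enough to rank state medians stably at this genome size.

What it does not emulate: raw intensities and normalisation artefacts,
chip/batch effects, SNP-driven outlier probes, age- or sex-dependent
methylation drift, correlated (rather than independent) probe noise, and
real blood reference panels (the cell profiles are synthetic). Passing
tests therefore demonstrate that the pipeline recovers known truth under
realistic array-like statistics — not that any particular clinical
signature would be recovered from real arrays.

The optional `background_shift` parameter can impose a small global
methylation offset outside the planted signature; its default is 0 because
the magnitude of such shifts in real cohorts is not well quantified.

## Problem sizes and determinism

Unit fixtures are tiny and constructed; end-to-end checks run ten seeded
cohorts at the default geometry (about 8 s of compute per cohort for
simulation, discovery, DMR calling and state profiling together). Every
stochastic step is driven by explicit seeds through numpy Generator
streams; identical (config, seed) reproduce bit-identical cohorts, probe
lists and scores. `scripts/acceptance.py` derives its per-cohort seeds
from the single `--seed` argument.

## Known limitations

* The MVP calibration is fitted on the training decision values rather
  than cross-validated; with the small case counts this workflow targets,
  held-out calibration curves would be too noisy to be meaningful, and the
  score should be read as a ranking with a convenience threshold.
* Correlation pruning at |r| ≤ 0.9 on 8-vs-56 cohorts removes many
  genuinely differential probes (strong group separation alone pushes
  pairwise r near the threshold), so final signatures here are smaller
  than the candidate DMP set; this mirrors the funnel's behaviour on real
  cohorts.
* The DMR rule is deliberately simpler than kernel-smoothing testers;
  regions whose probe spacing straddles the 1 kb gap threshold can split.
* Interval enrichment uses in-memory interval lists; it is not an indexed
  search engine and is not intended for thousands of query tracks.
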