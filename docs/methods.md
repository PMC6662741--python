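# Methods

## Experimental model

The pipeline analyses a 4-plex isobaric-tag (iTRAQ) experiment in which a
pooled control is labeled with reporter channel 114 and three tumor grades
with 115 (grade II), 116 (grade III) and 117 (grade IV / GBM). Each
peptide-spectrum match (PSM) carries four reporter intensities; the
tumor/control intensity ratio within a PSM estimates the relative abundance
of its parent protein for that grade. Quantitation is therefore pairwise per
grade: a PSM may be quantifiable for one grade and not another, depending on
which channels clear the signal-to-noise gate.

## Identification filters

* **Peptide-level target-decoy FDR.** PSMs are collapsed to the
  best-scoring PSM per peptide sequence (the common convention when an FDR
  is controlled "at the peptide level"), ranked by decreasing score, and
  the raw FDR at rank *k* is (#decoys ≤ *k*)/(#targets ≤ *k*). Q-values are
  the running minimum from the bottom of the list, capped at 1. Targets
  with q ≤ 0.01 are retained; decoys are removed. On a score tie the decoy
  is counted first, which is the conservative choice. Calibration is
  checked empirically: over 200 simulated score sets (correct targets
  Normal(μ, 1); incorrect targets and decoys Normal(μ − 4, 1), emulating an
  equal-size decoy database), the mean realized false-discovery proportion
  at nominal 1% stays near 1%.
* **Reporter quality.** A PSM is quantifiable for a grade iff the control
  channel and that grade's channel both have S/N ≥ 1.5 and positive
  intensity. The pairwise (control + grade channel) reading was chosen over
  an all-four-channels rule because each grade is quantified against the
  control independently; this is a documented design choice, not the only
  defensible one.
* **Uniqueness.** Only PSMs mapping to a single protein accession enter
  fold-change calculation; shared PSMs are kept in an identification-only
  set.
* **Both-runs rule.** Quantified proteins must be identified in both
  replicate runs; runs are pooled afterwards for quantitation (no per-run
  averaging step is defined).

## The fold-change curation cascade

Per grade and protein: (1) the provisional fold change is the arithmetic
mean of all quantifiable unique-PSM ratios, gated at 1.3-fold (≤ 1/1.3 for
down-regulation); (2) within surviving proteins, only PSMs whose own ratio
passes the same 1.3-fold rule *in the protein's direction* are retained —
a 0.6 ratio cannot support an up-call; (3) the fold change and percent CV
(100 × sample SD / mean, n−1 denominator, ratio scale) are recomputed from
the retained PSMs; (4) the final call requires the recomputed fold change
at or beyond 1.5-fold in the protein's direction, at least 2 retained PSMs,
and CV < 40%. A single retained ratio makes the CV not assessable (reported
as missing); such proteins cannot pass the ≥ 2-PSM rule anyway. The mean
(rather than a median of peptide-level summaries) is used because the CV
gate is conventionally defined about the mean. Every protein records the
stage at which it exited, so the funnel is auditable.

Two consequences of this design are worth knowing. Stage 2 censors the
ratio distribution toward the call direction, so recomputed fold changes of
proteins near the 1.3 gate are biased away from 1 (up to ~8% for true fold
changes around 1.5–1.7 at 15% reporter noise); for strongly changed
proteins the bias is negligible. And the cascade is deliberately
monotone: raising the final fold-change threshold or lowering the CV
ceiling can only remove calls, never add them (verified by property tests).

## Synthetic data

The generator emulates the data regime the pipeline is meant for, with
every planted quantity recorded for recovery checks.

* **Fold changes.** Per (protein, grade), differential with probability
  0.3; differential fold changes are log-uniform on [1.5, 8.0] with equal
  odds of inversion to the reciprocal (down-regulation); null fold changes
  are log-uniform on [1/1.2, 1.2] — unchanged proteins drift but stay
  under the 1.3 curation gate, which is what "not differentially
  expressed" means operationally here.
* **Reporter intensities.** Each PSM draws a control intensity log-uniform
  on [10³, 10⁶]; each channel's intensity is control × true fold change ×
  independent log-normal noise with CV 0.15 by default (multiplicative
  noise matches MS reporter statistics). In the zero-noise limit every PSM
  ratio equals the planted fold change exactly. S/N is intensity over a
  constant noise floor (940), placing ~5% of PSMs below the 1.5 gate.
* **Support.** 1–6 peptides per protein, 1–4 PSMs per peptide per run, two
  runs; a protein misses one run with probability 0.1 (exercising the
  both-runs rule) and a peptide is shared between two accessions with
  probability 0.05 (exercising the uniqueness rule).
* **Scores.** Targets Normal(8, 1); decoys Normal(8 − 4, 1) at a 10% decoy
  share — the simplest calibratable target-decoy model.
* **Companion tables.** Transcript records match each DE protein's
  direction with probability 0.65, otherwise flipped or absent with equal
  odds; each DE protein at grade IV receives one validated miRNA regulator
  whose direction is inverse with probability 0.8; the PPI background is
  Erdős–Rényi over 200 proteins at edge probability 0.05 with a planted
  10-node module at 0.8 among DE-up grade-IV proteins, scores uniform in
  [400, 999].

What the generator does *not* emulate: peptide-detectability and
abundance-dependent missingness, channel cross-talk (isotope impurity),
ratio compression from co-isolation, shared-peptide homology structure,
and degree-heterogeneous (scale-free) interactomes. Passing recovery tests
therefore demonstrate the correctness and calibration of the *procedures*,
not the field performance of the instruments or databases.

## Statistics

* **Over-representation.** One-sided hypergeometric tail (equivalently
  Fisher's exact test, greater), BH-adjusted across sets; the background
  universe defaults to all identified proteins, standard ORA practice in
  proteomics. This module is a generic stand-in for commercial pathway
  tools: no proprietary knowledge base or causal scoring is reproduced.
* **Edge enrichment.** The analytical network p-value of STRING-like
  services is replaced by a permutation test: draw |query| nodes uniformly
  without replacement from the background graph, count induced edges, and
  report p = (1 + #{null ≥ observed})/(1 + permutations). The add-one
  pseudocount makes p ∈ (0, 1]. Because the statistic (an edge count) is
  discrete, p-values under the null are slightly conservative for small
  query sets where ties at 0–3 edges dominate; calibration is checked at
  query size 30 on a 200-node background, where the discreteness is mild.
  Degree-preserving sampling is intentionally not the default — the simple
  uniform null matches the question "are these nodes more connected than a
  random set of the same size".
* **Bridging-TF ranking.** In the merged TF × invasion subnetwork, edges
  are partitioned (TF–TF if both endpoints are TFs, else
  invasion–invasion if both are invasion entities, else cross) and TFs are
  ranked by cross-degree, tie-broken by total induced degree then name.

## Concordance and the 2-D map

Concordance is direction-only (no magnitude or p-value threshold by
default; an optional transcript p-value gate exists but is off). Because
the denominator of a "percent concordant" statement is ambiguous when the
transcript resource is incomplete, both rates are always reported: over all
DE proteins, and over the matched subset. The miRNA cascade map enforces
three-layer agreement — transcript direction = protein direction, miRNA
direction inverse — and reports both the miRNA-side and entity-side
conformance fractions for the same reason. Pairs referencing unknown
identifiers are dropped and counted rather than raised: database joins are
lossy by nature.

## Problem sizes and determinism

The default study (and the acceptance script) uses 500 proteins, two runs,
~9,000–10,000 PSMs, a 200-node interactome, 10,000 permutations for the
planted-module p-value, 200 score sets for FDR calibration and 400
replicates at 199 permutations for the null-uniformity check; these sizes
give stable estimates (binomial standard errors of a few percent) while
running in seconds. All randomness flows through numpy Generators seeded
from a single integer; a fixed seed reproduces every output file
byte-identically, and the run manifest records parameters, seeds and
SHA-256 checksums.

## Interpretation notes on recovery metrics

Fold-change recovery is summarized as the mean absolute relative error over
DE-called proteins with ≥ 4 curated PSMs: with 15% reporter noise the
standard error of a 4-PSM mean is itself ~10%, so a per-protein hard bound
would conflate estimator correctness with sampling noise. DE sensitivity is
computed among planted strongly-changed proteins *observed in both runs*,
because proteins dropped from a run are undetectable by the both-runs rule
by design, not by failure of the cascade. The end-to-end conforming-miRNA
fraction is attenuated by the transcript concordance rate (a conforming
miRNA whose target lacks a concordant transcript produces no cascade), so
generator-rate recovery is assessed on the inverse-pair rule directly.
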