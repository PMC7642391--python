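# Methods

This document describes the statistical model behind each pipeline stage,
the default parameter choices and why they were made, what the synthetic
data does and does not emulate, and known limitations.

Notation: the *case* condition is the perturbed/disease state, *control*
the reference. All mutual information (MI) values are in nats.

## 1. Ligand screen (`ligand_screen`)

Input is a label-free mass-spectrometry abundance table (log2 intensities,
proteins × replicates) contrasting a case secretome with a control
secretome. Missing values encode non-detection and are treated
categorically rather than imputed:

* **both** — detected in ≥ `min_detect` replicates of each condition;
  screened by fold change, selected when `2**log2_fc ≥ fc_min`
  (`log2_fc = mean(case) − mean(control)`).
* **case_only** — detected in ≥ `min_detect` case replicates and in *zero*
  control replicates; selected outright (the fold-change ratio is
  undefined, and all-or-nothing detection is itself strong evidence).
* **other** — everything else; never selected.

Defaults `fc_min = 1.5`, `min_detect = 2` are conventional screening cuts
for triplicate label-free MS: 1.5-fold is roughly the smallest change
reliably quantified at typical replicate CVs, and requiring two detections
guards against single-replicate artifacts.

## 2. PPI prior (`ppi_prior`)

Each protein carries precomputed interaction-probability scores in [0, 1]
against its annotated partners (a structural/contextual PPI prior of the
PrePPI kind, supplied as a flat table). For a candidate pair (L, R) with
score *s*:

* ligand-side p: add-one empirical p-value of *s* against L's scores with
  all of its other partners, `p = (1 + #{x ≥ s}) / (1 + |null|)`;
* receptor-side p: likewise for R;
* pair p: `max(p_L, p_R)` by default — the interaction must look
  exceptional from *both* proteins' perspectives, which de-prioritizes
  promiscuously sticky proteins. A Fisher combination is available
  (`pair_combination="fisher"`) but is anti-conservative when one side is
  unremarkable.

The add-one convention keeps p in (0, 1] and is the standard bias-safe
estimate for permutation-style nulls. Benjamini–Hochberg q-values are
attached for reporting; the downstream aggregation consumes only the rank
order.

## 3. Regulon inference (`regulon_net`)

An ARACNe-style reverse-engineering of a receptor-centered network:

**MI estimator.** Adaptive partitioning on copula-transformed data
(ranks/n): starting from the unit square, a cell is recursively split into
four quadrants at the in-cell marginal medians while it holds at least
`4 × min_subcell_points = 16` points; the estimate is
`Σ_cells (n_c/n) · ln[(n_c/n)/area_c]`. A chi-squared uniformity gate on
the quadrant counts (`alpha_split < 1`) is implemented but **off by
default**: with realistic sample sizes the gate stalls the recursion in
small cells (the df = 3 test has little power at n ≈ 30–60) and
underestimates strong dependence by up to 0.35 nats at ρ = 0.9, n = 1000.
The ungated estimator has a small positive bias on independent data
(≈ +0.06 nats at n = 1000) and a small negative bias under strong
dependence (≈ −0.10 nats at ρ = 0.9); both are within the accuracy targets
of the acceptance suite, and the positive null bias is absorbed by the
permutation threshold below, which is computed with the *same* estimator.

**Edge significance.** The threshold is the (1 − `alpha_mi`) quantile of
MI over `n_perm` randomly permuted gene pairs (one profile shuffled,
destroying dependence while preserving marginals). The pipeline default is
`alpha_mi = 0.001` with `n_perm = 2000` — the finest quantile resolvable
at that permutation budget. A per-edge level of 0.05 is far too liberal at
genome scale: with ~10³ genes it admits ~5% of all non-targets into every
regulon, and those false targets actively break the downstream modulator
screen (they dilute the conditional-MI retention statistic until all
modulators score alike). Published ARACNe practice uses per-edge
significance around 10⁻⁸ for ~20k-gene compendia; 10⁻³ plays the same role
at the ~10²–10³-gene problem sizes this package targets.

**DPI pruning.** In every fully connected triple the strictly weakest edge
is removed (tolerance optional); removal decisions are computed on the
input graph and applied simultaneously, so the result is independent of
triangle visiting order. This suppresses indirect regulator→target edges
that are mediated by a third gene.

**Regulons.** Regulators keeping ≥ `min_targets = 25` targets form the
interactome. Per target, *mode* = Spearman correlation with the regulator
(sign and confidence of the regulation direction) and *weight* = edge MI
normalized by the regulon's strongest edge. The size floor exists because
enrichment NES values over very small regulons are noisy; 25 is the
conventional floor in regulon-based activity inference.

## 4. Receptor activity (`receptor_activity`)

The case-vs-control signature assigns each gene a z-statistic: Welch
t-test p-value mapped through the normal quantile, signed by the direction
of change. Receptor activity is a two-component weighted enrichment of its
regulon in that signature (the aREA/VIPER scheme):

* rank-quantile scores: `z_i = Φ⁻¹((r_i − 0.5)/n)` over the signed stats,
  and `z*_i = Φ⁻¹(0.5 + (r|stat|_i − 0.5)/(2n))` over the magnitudes;
* directed part `D = Σ w m z` (activated targets high, repressed targets
  low), magnitude part `T = Σ w (1 − |m|) z*` (engaged when the mode is
  uncertain);
* `NES = (D + T) / sqrt(Σ(wm)² + Σ(w(1−|m|))²)`, standard normal under a
  random signature (verified by permutation in the acceptance suite);
  `p_activation = 1 − Φ(NES)`.

The default ranking is one-sided (activation): the biological question is
which receptor is *activated* by an extracellular ligand in the case
condition. `two_sided=True` is available when loss of activity is equally
interesting.

## 5. Modulator screen (`modulator_cmi`)

A receptor that transmits the ligand signal should change the operating
point of the downstream transcription factor (TF): the dependence between
the TF and its targets varies with the receptor's state. For every
(modulator M, TF, target T) triplet the conditional MI `I(TF; T | M)` is
estimated by splitting samples into `n_bins_z = 3` equal-frequency strata
of M's expression and averaging within-stratum MI (sample-weighted).
Three strata is the coarsest split that can reveal non-monotone modulation
while keeping ≥ 60–70 samples per stratum at the intended compendium
sizes.

A triplet is *retained* when its CMI is at or above the mean over all
computed triplets; a modulator with k of n triplets retained gets the
binomial tail p-value `P(Bin(n, p₀) ≥ k)` with p₀ the global retention
rate. Retention-vs-mean is a self-calibrating cut: it needs no absolute
CMI scale, but it presumes the triplet set is dominated by *genuine*
TF targets — which is why the strict edge threshold of stage 3 matters.

## 6. Evidence integration (`evidence_integration`)

Receptor-level rankings (activity, modulation) are lifted to pair level by
rank inheritance; entities absent from a ranking get the worst rank 1.0,
so missing evidence penalizes rather than silently favors a pair. For
each pair with normalized ranks r₁…r_k (k = 3 sources), under the null
that ranks are independent Uniform(0, 1) the j-th smallest rank follows
Beta(j, k−j+1); the aggregation statistic is
`rho = min_j BetaCDF(r_(j); j, k−j+1)` and the reported score is the
Bonferroni-corrected `min(1, k·rho)`. Pairs with score ≤ `alpha = 0.01`
are called significant — the convention under which the bundled published
ranking yields exactly three significant pairs. Rank aggregation is used
instead of p-value combination because the three sources' p-values are
computed under incommensurable null models.

## 7. Synthetic data (`synthetic_data`)

The generators produce desk-scale versions of all four inputs with one
planted pair (`L_ENR1`, `REC00`) recoverable by every evidence source:

* **Proteome** — baseline log2 intensities N(20, 2), replicate noise
  N(0, 0.2); enriched proteins gain `log2_effect` in case replicates;
  case-only proteins are undetected in all control replicates.
* **Expression** — receptor activity `A_R ~ N(shift·1{case}, 1)` with
  observed receptor mRNA `A_R + ε`. The TF transcript is N(2, 1),
  *independent* of the receptor; each TF target follows
  `m_t · β · c(A_R) · x_TF + ε` with the post-translational gate
  `c(A_R) = 2·sigmoid(3γ·A_R)`. The gate is the point of the design: the
  TF→target transfer strength *depends on the receptor state*, which is
  exactly the alternative hypothesis of the conditional-MI screen, and —
  through the TF's positive mean — also shifts target means between
  conditions so the inferred receptor regulon responds to the contrast.
  (A naive linear chain `A_TF = γ·A_R + ε` would make the true modulator
  score *worst* in the screen: conditioning on the upstream driver removes
  the shared variance it explains.) Decoy receptors drive equally sized
  regulons from independent latents; unstructured noise genes complete the
  matrix. Setting `condition_shift = 0` and `modulation = 0` (the
  `--no-signals` fixture) severs every expression-side signal while
  keeping all entities present and rankable.
* **PPI prior** — i.i.d. Beta(1, 9) background scores (high-confidence
  interactions rare), symmetric by construction, with the planted pair's
  score set to 0.95 on both sides.

What the synthetic data does **not** emulate: MS intensity-dependent
missingness, batch structure or confounding in the expression compendium,
scale-free network topology, overlapping/correlated regulons, or the
id-mapping step between species (an orthology id map hook exists in the
pipeline but the generators use one namespace).

## 8. Problem sizes and runtime

Default fixture: 20 proteins, ~1k genes × 200 samples, 121 PPI universe →
full pipeline ≈ 25 s (dominated by the ~2000 permutation MI calls and the
~10³ regulator–gene MI calls; one MI call at n = 200 is ≈ 0.8 ms).
Reduced fixture (60 + 60 samples, 8 decoys): ≈ 2 s per run, used for the
50-seed null calibration sweep. The study-scale pair space (65 × 298) is
handled directly; the expression compendium is the scaling bottleneck
(MI cost is linear in samples after an O(n log n) rank transform, and
quadratic-ish in genes for a joint network build).

## 9. Limitations

* The MI permutation threshold assumes roughly exchangeable marginals
  across genes; heavy-tailed or multimodal genes can make the null
  slightly anti-conservative (mitigated by the strict `alpha_mi`).
* The modulator screen's mean-retention cut loses discrimination when the
  TF regulon is contaminated with non-targets (see §3) or when the TF's
  *transcript* is itself strongly driven by the modulator — conditional MI
  cannot distinguish "modulates the TF's activity" from "shares an
  upstream driver with the TF".
* Pair-level aggregation inherits receptor-level evidence identically for
  every ligand of that receptor; discrimination *between* ligands of the
  same receptor comes only from the abundance screen and the PPI prior.
* Empirical p-values are bounded below by 1/(1 + |null|); with small PPI
  partner sets the ligand side saturates and the max-combination is
  conservative.
* The final Bonferroni factor k = 3 treats the three evidence sources as
  independent; they are computed from disjoint data types, but a shared
  latent confounder (e.g. sample-size artifacts in the compendium) would
  violate this.
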