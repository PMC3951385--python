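# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `refstab`. Everything stated here is computed by the
package's tests or scripts; nothing is quoted from external runs.

## 1. Quantification model

A SYBR-green amplification trace is modelled as exponential growth of
product fluorescence saturating at a plateau. For a well with starting
fluorescence R0 and per-cycle efficiency E (E = 1 is perfect doubling),
the underlying signal at cycle c is G(c) = R0·(1+E)^c, and quantification
inverts this through three quantities:

* **Ct** — the fractional cycle where the baseline-subtracted trace first
  reaches the detection threshold, by linear interpolation between the
  bracketing cycles. A trace that never reaches the threshold is a
  "no amplification" error; a threshold below the cycle-1 signal is a
  "threshold below baseline" error (the crossing would be extrapolated).
* **E** — from a log-linear regression of log fluorescence on cycle over
  a sliding window restricted to strictly positive, growing
  baseline-subtracted values; the window maximizing R² is taken as the
  exponential phase and E = exp(slope) − 1.
* **R0** = R_Ct·(1+E)^(−Ct), with R_Ct the threshold fluorescence. The
  identity is preserved exactly in every `AmplificationFit` (checked to
  1e−9 relative).

Tunable parameters, with defaults and rationale:

| parameter | default | meaning / rationale |
|---|---|---|
| threshold | 10% of the plate's median plateau | plateau = max of the baseline-subtracted trace; a plate-wide threshold keeps Ct comparable across wells, and 10% sits safely above baseline noise yet inside the near-exponential region |
| baseline window | cycles 3–8 | mean fluorescence over early cycles, before detectable product in realistic designs; subtracted prior to both Ct and E estimation |
| fit window length | 4 cycles | short enough to sit inside the exponential phase, long enough for a stable slope |
| outlier alpha | 0.05 | level of the replicate-efficiency screen |
| outlier min_effect | 0.02 (per-cycle gain) | a member is only flagged if it deviates from its replicate group by more than the typical uncertainty of a log-linear efficiency fit; protects near-noiseless data, where meaningless scatter otherwise produces huge test statistics |

**Outlier screening.** Amplification efficiency is a primer property, so
replicate groups are screened per gene. Within-group comparability uses an
iterative externally studentized residual test: each well's efficiency is
compared with the mean of its group's other members, scaled by the pooled
within-group SD with the candidate excluded, against a t critical value
Bonferroni-adjusted over all wells — the familywise false-flag rate under a
single-normal null is approximately alpha (measured 0.048 at alpha = 0.05
over 500 null panels in the test suite). Between-group equivalence of mean
efficiencies is a separate one-way ANOVA (`efficiency_equivalence`). A pure
omnibus ANOVA cannot serve as the outlier trigger: a single discordant well
inflates the within-group mean square and can leave F near 1 precisely when
an outlier is present.

**Aggregation.** Technical replicates are aggregated by the geometric mean
of R0 (multiplicative noise model); biological replicates stay separate as
samples for the stability analysis. Relative quantities divide each gene by
its maximum across samples (calibrator convention), so values lie in (0, 1].
When the input is a Ct table plus per-primer efficiencies instead of traces,
R0 is computed with unit R_Ct; the constant cancels in every within-gene
ratio, hence in M, V, ρ and all normalized profiles.

## 2. Pairwise-variation stability (M and V)

For genes j, k with relative quantities a·j, a·k, the pairwise variation is
the sample SD (n−1) of log₂(a_j/a_k) over shared samples; M_j is the mean of
these over all k ≠ j. Iterative elimination removes the highest-M gene and
recomputes until two genes remain; the final two are reported as a tied pair
(a symmetric pairwise SD cannot order them). All logs are base 2.

Normalization factors NFₙ are per-sample geometric means of the n most
stable genes; V(n, n+1) is the SD over samples of log₂(NFₙ/NFₙ₊₁); the
recommended count is the smallest n with V ≤ cutoff (default 0.15, with ≤ so
a series like (0.213, 0.15) recommends three genes); if nothing qualifies,
the full panel is returned with an explicit exceeds-cutoff flag.

Numerical conventions: missing values restrict pairwise SDs to shared
samples, and an NF is undefined for a sample missing any member gene; exact
M ties during elimination remove the gene later in input order and are
recorded on the result. M and V are invariant to per-gene rescaling (they
are built from log ratios) and to sample permutation.

## 3. Variance-decomposition stability (ρ)

On a complete log₂ matrix y (genes × samples) with a sample → group design
(G groups, sizes n_g, L genes):

1. per-sample centering z_ij = y_ij − mean_i(y_ij) absorbs template-amount
   and global-expression effects;
2. d_ig = mean_{j∈g}(z_ij) − (n_g-weighted mean over groups) estimates the
   inter-group shift; σ²_ig = Var_{j∈g}(z_ij) · L/(L−1) the intra-group
   variance (the L/(L−1) factor undoes the centering shrinkage);
3. γ² = max(0, Var_{i,g}(d_ig) − mean_{i,g}(σ²_ig/n_g)) is a
   method-of-moments estimate of the between-gene dispersion of true
   shifts (sample variance with n−1 over all (gene, group) cells);
4. shrinkage d*_ig = d_ig · γ²/(γ² + σ²_ig/n_g) (zero when γ² = 0), and
   ρ_i = (1/G) Σ_g (|d*_ig| + √(σ²_ig/n_g)). Lower ρ = more stable.

With a single group, ρ_i = √(σ²_i) computed over all samples — ranking by
within-set variance of z. The best pair minimizes the ρ of the pseudo-gene
with d_pair = (d_i + d_k)/2 and σ²_pair = (σ²_i + σ²_k)/4 over all pairs
(exhaustive search; lexicographic tie-break, ties recorded). Group means
are weighted by n_g so balanced designs are unaffected and unbalanced ones
lean on the better-estimated groups; σ² and γ² are floored at zero.

This estimator is fixed as the package's documented, self-consistent
definition of the intra/inter-group decomposition; numeric agreement with
any particular spreadsheet implementation of the same idea is not claimed.
Its tests assert equivalence with an independent literal recomputation of
the formulas above plus parameter recovery on simulated ground truth. Note
that only *relative* group shifts are identifiable: the per-sample centering
subtracts the panel-mean shift, so a gene shifting exactly with the panel
average looks stable. The recovery tests therefore use zero-mean shift
panels.

## 4. Normalization comparison

`compare_normalizations` reports 100·(max−min)/max per shared sample —
oriented to the larger NF, symmetric, bounded in [0, 100). This equals the
relative change a switch of normalization factors induces in every
normalized target value. Reporting summaries over biological replicates use
mean ± SD per condition. `run_validation` repeats the whole
ranking → best/worst NF → normalization → comparison loop over named sample
subsets (all / abiotic / tissue / leaf-stem in the default design),
skipping subsets with fewer than 3 samples.

## 5. Synthetic experiments and what they do (not) show

The generator emulates the validation study's design: 10 conditions
(leaf, stem, rachis, root; drought, salt, cold, heat, wounding, flooding)
× 3 biological replicates, 3 technical replicates, 11 candidate reference
genes and 7 CesA-family targets.

* **Biological variation**: one N(0, σ_g) log₂ deviation per
  (gene, sample). Default per-gene σ span 0.25–1.2 log₂ units, mapping the
  published per-gene Ct ranges (0.88–5.10 cycles over 30 samples) through
  the expected range of 30 normal draws (≈ 4.1 σ). Baseline Cts span
  21–27 (UBQ6/SAMDC near 21, eIF-4a at 27); primer efficiencies are the
  published per-primer values (0.967–1.079), within a declared envelope of
  [0.96, 1.10].
* **Condition effects** are additive in log₂. Default reference genes
  carry none (their instability is pure dispersion, matching the envelope
  above); the targets carry tissue- and stress-biased effects (e.g. CesA7
  up in stem/root/flooding) that normalization should recover.
* **Technical variation**: N(0, 0.15) cycles of Ct noise per well.
* **Traces**: G(c) = R0·(1+E)^c saturating smoothly as
  F = baseline + plateau·(1 − exp(−G/plateau)), cycles 1–40. The smooth
  saturation keeps the 10%-of-plateau threshold crossing within ≈ 0.08
  cycles of the ideal exponential crossing (≈ 0.02 in log₁₀ R0), so
  round-trip recovery tolerances (E ± 0.02, log₁₀ R0 ± 0.05) are
  meaningful rather than vacuous.

Because deviations are Gaussian, simulated Ct values cannot be *guaranteed*
inside the printed 19.6–27.1 envelope; the envelope test instead requires
≥ 99% of reference-gene Ct draws within [19, 28] over 20 seeded runs (and
all within [17.5, 29.5]). The generator does not model PCR inhibitors,
primer-dimer artifacts, multi-plate batch effects, probe chemistries or
non-Gaussian biological tails — passing tests demonstrate correctness of
the estimators under the stated noise model, not robustness to every
instrument pathology.

A deliberate consequence of the envelope: with n = 30 samples, the sample
SD of a gene with true σ = 1.2 fluctuates by ≈ 13%, so that gene's M value
(expected ≈ 1.31 against this panel) exceeds the conventional 1.5
acceptability cutoff in roughly one replicate in ten. Any single simulated
panel therefore usually satisfies "all M < 1.5", while the *maximum* M over
20 independent replicates typically lands near 1.5–1.65. The acceptance
script reports exactly that maximum, computed fresh each run.

## 6. Problem sizes

Default test and script sizes are chosen to keep the whole suite
desk-scale: stability analyses run on 30 × 11 matrices (seconds), oracle
equivalence uses ≥ 50 small random matrices per estimator, recovery suites
use 20 seeded replicates, and the trace-level round trip quantifies one
full 1 620-well plate. Seeds are fixed in tests and derived from `--seed`
in scripts; identical seeds give byte-identical artifacts.

## 7. Known limitations

* The final two genes of the elimination ranking are inherently unordered;
  downstream code must treat them as a pair.
* Ungrouped (single-group) designs reduce ρ to a plain variance ranking;
  inter-group interpretability is lost.
* The V ≤ 0.15 rule is a heuristic; for panels where no n qualifies the
  result carries an explicit flag rather than a silent recommendation.
* Efficiency estimation assumes a visible exponential phase above baseline;
  very late amplification (Ct near the last cycles) shortens the usable
  window and degrades E.
* Missing-value support covers pairwise statistics and NF definition, but
  the variance-decomposition path requires a complete matrix (impute or
  drop upstream).
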