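# Methods

## Overview

`framefilter` implements a frame-selection framework for time-varying
functional connectivity: it deconstructs FC into edge time series, selects
frame subsets by similarity between a binary node template and each frame's
activity bipartition, rebuilds connectivity components from the selected
frames, relates component edges to behavioral scores across subjects, and
optimizes the template per behavior by simulated annealing. Temporal nulls
and profile clustering characterize where in time and across behaviors the
information lives.

## Model and conventions

**Z-scoring and edge time series.** Each node's series is standardized with
the sample standard deviation (denominator `T − 1`). The eTS entry for edge
`(i, j)` at frame `t` is `z_i(t)·z_j(t)`; with the `T − 1` divisor its time
mean equals the Pearson correlation exactly, and the package asserts this
identity to 1e-12. Edge vectorization is fixed everywhere: strict upper
triangle, `i < j`, lexicographic, 0-based. Frame indices are 0-based in
`[0, T)`. A connectivity component from a proper frame subset is the plain
mean over selected frames; the full frame set uses `T − 1` so it reproduces
FC exactly (the subset/full distinction is deliberate and documented in the
API).

**Bipartitions.** The z-scored series is thresholded at zero; exact zeros
map to 0, making the rule total and deterministic (the convention matters
only for measure-zero inputs). The agreement component over `l` selected
frames subtracts the scalar permutation null
`P_null = (1/l) Σ_k Σ_s (|C_ks|/N)((|C_ks|−1)/(N−1))` uniformly from every
entry. Agreement is computed per run from that run's selected frames; the
subject-level component is the unweighted mean across runs. The diagonal is
excluded from all edge vectorizations.

**Template matching.** Similarity between a template and a frame is the
mutual information of the 2×2 label contingency, normalized as
`2·MI/(H(M)+H(M′))` — symmetric, bounded in [0, 1], and invariant to
complementation of either argument, so a pattern and its inversion select
identical frames. Zero-entropy partitions (an all-1/all-0 frame or
template) score 0 rather than NaN, so degenerate frames are simply never
selected. Selection takes the `round(fraction·T)` highest-scoring frames
per run (minimum 1), with ties broken toward earlier frames by a stable
sort; nearest rounding makes a 10% selection of an 1,100-frame run exactly
110 frames. MI logs are natural-base (the normalization cancels the base).

**Brain–behavior maps.** Behavior scores are residualized on confounds by
OLS with an intercept, refit separately inside every subject group the map
is computed on (train and test groups each get their own fit; nothing is
carried across). Per edge, Spearman correlation (average ranks) relates the
component edge across subjects to the residualized behavior; constant edges
yield ρ = 0 with a warning so the optimizer's cost stays defined. The
scalar objective is `D = mean(|ρ|)` over edges. Transfer between groups is
the Spearman correlation of their maps; signed-edge transfer averages test
ρ within the train map's positive and negative edge sets separately.

**Annealing.** Proposals flip 1, 2, or 3 distinct uniformly chosen nodes
with probabilities (0.68, 0.27, 0.04) renormalized to sum one. A proposal
is accepted if it does not worsen `D`, otherwise with probability
`exp(−ΔD/Temp)` under the geometric schedule `Temp = T0·Texp^h`. The chain
compares against the last *accepted* cost; the global best is tracked
separately and returned, so the reported best-so-far trace is
non-decreasing by construction. Defaults `T0 = 0.05`, `Texp = 0.996`
(configurable): the starting temperature sits on the scale of typical early
cost differences of the mean-|ρ| objective (a few hundredths), and the
schedule reaches a near-greedy regime within roughly a thousand iterations.
A substantially colder chain behaves greedily from the first iteration and
tends to freeze on sampling-noise local optima of the cost surface, which
measurably hurts template recovery on synthetic data. Each
cross-validation split regenerates its initial random template from its own
seed; all randomness flows through seeded generators and identical seeds
reproduce results bit-identically.

**Temporal nulls.** Null framesets rigidly rotate each cross-validation's
selected frames by an independent uniform circular offset, preserving
cardinality and the multiset of circular gaps while randomizing position.
Per-frame consistency p-values use the conservative
`(1 + #{null ≥ obs})/(1 + n_iter)` convention, which never returns zero.
Default `α = 0.01` (with 0.001 available), 10,000 null iterations at full
scale. Framewise-displacement-style nuisance summaries are optional inputs
and degrade gracefully when absent (synthetic data has none).

**Profile clustering.** Behavior × RSS-decile profiles of mean |BB| are
compared by Spearman correlation; the resulting signed similarity matrix is
clustered by a two-phase Louvain maximizing
`Q(γ) = Σ_{r≠s}[S_rs − γP_rs]δ(σ_r,σ_s)` over ordered pairs with the
constant Potts null `P_rs = 1` (the null is isolated behind one function so
other null models can be swapped in). Sweep default: 1,000 γ values over
`[0, max S]`, finer re-sweeps are a user parameter. The partition ensemble
becomes a co-classification matrix, reclustered iteratively (minus the
ensemble's chance co-assignment rate) until unanimous. Louvain ties break
toward the first best-improving move in seeded sweep order; correctness is
validated against exhaustive partition enumeration at small sizes.

## Synthetic cohort

The generator emulates the data regime the method targets: `S` subjects ×
`R` runs of `T` frames over `N` nodes, with

1. a **modular baseline** — `n_systems` blocks with within-system
   correlation `rho_within`, AR(1)-smoothed (`ar1_phi`), passed through a
   subject-specific random mixing matrix (`subject_var`) that plants
   behavior-*unrelated* individual differences in baseline connectivity,
   as real cohorts show;
2. **template-locked events** — at rate `event_rate`, a shared latent
   amplitude (`event_amp`, per-event jitter) is added positively on
   template-1 nodes and negatively on template-0 nodes, scaled by
   `max(0, 1 + coupling_beta·b_s)` with `b_s` the subject's behavior score:
   the brain–behavior relationship is expressed *only* at event frames,
   through how cleanly their bipartitions realize the template;
3. **global events** — rare (`global_event_rate`), high-amplitude
   (`global_event_amp`), uniform-sign frames: high-RSS moments carrying no
   behavioral or template information (their single-group bipartitions
   score zero entropy and are never selected);
4. white measurement noise (`noise_sd`).

Ground truth (template, per-run event frames, coupling) is recorded
exactly, and a null behavior is drawn independently of all series.

**Defaults and why.** `S = 60`, `R = 2`, `T = 400`, `N = 40`,
`n_systems = 4` size a cohort that exercises every pipeline stage in
minutes on one CPU. `event_rate = 0.35` with `event_amp = 1.3` makes the
planted pattern a *recurring moderate-amplitude motif* rather than a rare
extreme: events outnumber the 10% selection capacity, so filtering is a
cleanness-ranked competition among event frames and every template error
degrades the selected set — this is what makes the planted template the
actual optimum of the mean-|ρ| objective. (With rare, very strong events
the objective is instead maximized by *partial* templates whose selection
count acts as a behavior readout — a genuine property of
selection-based objectives worth knowing about; the default conditions are
chosen so that recovery is well-posed.) `coupling_beta = 0.5` gives a
strong but non-saturating coupling; `subject_var = 1.6` injects enough
baseline connectome variability that full-data components do not trivially
carry the planted signal, matching the method's motivating regime where
filtering beats full FC. `rho_within = 0.35`, `ar1_phi = 0.3`,
`noise_sd = 0.25` keep the baseline realistic (coherent systems, smooth
signals) and make background bipartitions competitive in the matching
score, which sharpens template discrimination.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: no hemodynamic forward model, no
physiological or scanner noise, no head motion (an FD-like column is
optional and synthetic), no spatial geometry, and events are idealized
additive sign-patterned latents rather than empirically characterized
co-fluctuation structures. Results on this cohort validate the machinery
and its statistical behavior, not effect sizes on any real dataset.

## Validation strategy

Three layers: (i) exact identities (eTS time mean vs. FC; full-frame
component vs. FC; NMI of a template with itself and its complement);
(ii) independent brute-force oracles — contingency-table NMI, double-loop
modularity, exhaustive set-partition maxima at ≤ 8 behaviors — and
null-model calibration (type-I rates of the circshift test and the
edgewise Spearman maps); (iii) planted-truth recovery: components built
from true event frames must beat full-connectivity maps for the coupled
behavior (permutation test) and not for the null behavior; a 1,000-iteration
anneal must recover the planted template (NMI ≥ 0.5, inversion-invariant)
in most seeds; and optimized templates must transfer across subject splits
better than full-connectivity baselines. Problem sizes in the test suite
(e.g., 10 cross-validation splits at 400 iterations; 2,000-iteration nulls)
are desk-scale choices that keep the full suite in the ten-minute range
while leaving each statistical check comfortably powered.

## Known limitations

- The mean-|ρ| objective rewards any monotone behavior channel; on data
  where frame *selectability* covaries with behavior, the optimizer can
  prefer behavior-thresholding templates over the generative one. The
  synthetic defaults avoid that regime by design; real-data users should
  inspect selection-count–behavior correlations before interpreting an
  optimized template's anatomy.
- The Louvain implementation is dense-matrix (suitable for tens to
  hundreds of behaviors, not large graphs).
- P-values are uncorrected by default, mirroring the per-frame reporting
  convention; multiple-comparison control across frames is the caller's
  responsibility.
- Residualization assumes linear confound effects.
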