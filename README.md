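# framefilter

Template-based frame filtering of edge time series for behavior-specific
functional connectivity.

## The problem

Functional connectivity (FC) — the matrix of Pearson correlations between
regional activity time series — averages an entire recording into one
network, even though the co-fluctuations that build it are highly
non-stationary: a minority of moments carries most of the structure, and
different moments may carry different behavioral information. `framefilter`
implements a frame-selection framework for asking *which moments in time
carry a given brain–behavior relationship*, and for optimizing that
selection per behavior.

The core quantities:

- **Edge time series (eTS).** With z-scored regional signals `z_i(t)`, the
  co-fluctuation of regions *i, j* at frame *t* is `r_ij(t) = z_i(t)·z_j(t)`.
  Its time mean with divisor `T − 1` is exactly the Pearson FC
  `r_ij = (1/(T−1)) Σ_t z_i(t) z_j(t)`; averaging over any frame subset
  yields a *connectivity component* (FCc).
- **RSS amplitude.** `RSS(t) = sqrt(Σ_{i<j} r_ij(t)²)` measures global
  co-fluctuation strength per frame; sorting frames into RSS deciles probes
  how behavioral associations distribute across amplitude.
- **Bipartitions and agreement components (AGc).** Thresholding z-scored
  activity at zero splits each frame's nodes into above-/below-mean groups.
  The agreement matrix over selected frames (fraction of frames in which two
  nodes share a group, minus the permutation null
  `P_null = (1/l) Σ_k Σ_s (|C_ks|/N)((|C_ks|−1)/(N−1))`) is a cheap,
  amplitude-free FC surrogate for arbitrary frame subsets.
- **Template filtering.** A binary node template selects the top fraction
  (default 10%) of frames whose bipartitions have the highest normalized
  mutual information `2·MI/(H+H′)` with it — a score invariant to global
  sign inversion, so a pattern and its mirror select the same frames.
- **Behavior optimization.** Per-edge Spearman correlations between
  component edges and a confound-residualized behavior score across
  subjects give a brain–behavior map; its mean absolute value
  `D = mean(|BB|)` is maximized over templates by simulated annealing
  (1/2/3-node flips with probabilities 0.68/0.27/0.04, Metropolis
  acceptance `exp(−ΔD/Temp) > R(0,1)`, cooling `Temp = T0·Texp^h`), inside
  repeated 80/20 train/test subject splits.
- **Temporal nulls.** Selected framesets are compared across
  cross-validations and behaviors against circular-shift surrogates that
  preserve set size and spacing, with per-frame p-values
  `(1 + #{null ≥ obs})/(1 + n_iter)`.
- **Behavior clustering.** RSS-decile profiles of mean |BB| per behavior
  are clustered by Louvain modularity maximization with a constant Potts
  null (`Q(γ) = Σ_{r≠s} [S_rs − γ]δ(σ_r,σ_s)`), a resolution sweep, and
  multiresolution consensus.

Because suitable recordings are restricted-access, the package ships a
seeded synthetic cohort generator that plants a ground-truth template whose
event expression covaries with a behavior score — so the whole pipeline can
be exercised and validated end to end against known truth.

## Worked example

Run the end-to-end synthetic demo (generate a 60-subject cohort, anneal a
template for the coupled behavior over 1,000 iterations, compare against the
full-data component, and score recovery of the planted template):

```bash
framefilter pipeline --seed 7 --iters 1000 --out demo/
```

prints

```
optimized mean |rho| 0.7221 vs full 0.3910; template recovery NMI 0.758
```

meaning: the optimized template's filtered agreement components reach a mean
absolute edgewise brain–behavior correlation of 0.72 across the cohort,
versus 0.39 for components built from all frames — frame selection roughly
doubles the measurable association — and the recovered template matches the
planted ground truth with normalized mutual information 0.76 (1.0 would be
exact recovery up to inversion).

Other subcommands (`simulate`, `ets`, `filter`, `bin-rss`, `behavior-map`,
`optimize`, `temporal-null`, `cluster-profiles`) expose the individual
stages on delimited-text inputs; see `framefilter --help`.

Library use mirrors the CLI:

```python
from framefilter import (SyntheticConfig, generate, zscore_series,
                         edge_time_series, rss_amplitude)

ds = generate(SyntheticConfig(seed=7))
ts = ds.series[ds.subject_ids[0]][0]
ets = edge_time_series(zscore_series(ts))
rss = rss_amplitude(ets)          # per-frame co-fluctuation amplitude
```

## Documentation

`docs/methods.md` describes the model, the synthetic cohort's generative
structure and its limitations, parameter defaults, and numerical choices.
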