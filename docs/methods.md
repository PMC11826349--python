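# Methods

## The problem

A structural connectome is a weighted, undirected graph: nodes are cortical
regions (84 in the Desikan–Killiany parcellation this package defaults to),
and the weight of edge (i, j) is the number of tractography streamlines
joining regions i and j. Graph-theoretic summaries of this network —
modularity, efficiency, rich-club organization, and so on — are widely used
as biomarkers of aging and neurodegeneration, but they inherit systematic,
non-biological *site effects* from scanner hardware, acquisition protocol
and processing choices. Pooling connectomes across sites without correction
confounds site with biology.

`connharm` removes site effects at the level of the connectome itself. It
learns a latent representation of the connectome that is minimally
informative of site but maximally informative of biology (age, sex, and the
network measures), then reconstructs every connectome under a *single*
user-chosen site label, yielding measures expressed in one common
acquisition domain.

## Model

The model is a variational autoencoder with a site-conditional decoder.

* **Encoder** `x → Linear → ReLU → Linear → ReLU → (μ_z, log σ_z²)`, where
  `x` is the vectorized strict upper triangle of the connectome
  (`n(n−1)/2` features; 3486 for n = 84), transformed `log(1 + w)` and
  z-scored per feature on the training set. The encoder is *not* given the
  site label.
* **Latent code** `z = μ_z + σ_z ⊙ ε`, `ε ~ N(0, I)` during training; at
  test time the deterministic mean `μ_z` is used.
* **Decoder** takes `[z, onehot(c)]` through two linear layers (ReLU
  between) back to the feature space. Because the decoder receives the
  site label `c`, the latent code never needs to store it.
* **Prediction heads**: age and sex are affine maps of `z` alone — biology
  must be decodable without knowing the site. The network-measures head is
  affine in `[z, onehot(c)]`, because its training targets (the 12 measures
  of the raw connectome) are themselves site-biased.

The loss is

```
ℓ_total = w_recon·MSE(x̂_c, x) + w_kl·KL[q(z|x) ‖ N(0, I)]
        + w_age·MSE(â, a) + w_sex·BCE(ŝ, s) + w_B·MSE(B̂_c, B)
```

with all targets standardized on the training set (ages z-scored; each
measure z-scored; undefined measures masked out of the mean). Minimizing
the conditional reconstruction error while pushing the posterior toward a
standard normal bounds the mutual information between `z` and the site
variable: the reconstruction can be site-accurate only through the decoder
condition, and the KL term denies `z` the capacity to duplicate it. Sex is
encoded female = 1, male = 0.

Two training schemes are supported. *Co-learning* trains one model whose
measures head predicts all 12 network measures simultaneously;
*individual learning* trains 12 separate models, one per measure. The
co-learning latent space is shaped by all twelve targets at once, which in
practice regularizes it and matches or beats the per-measure models.

### Implementation

The network is implemented directly in NumPy: forward pass, hand-derived
backpropagation, and an Adam optimizer. Gradients are verified against
central finite differences in the test suite (relative tolerance 1e-4 on a
small network). Training is bitwise deterministic given the configuration
seed, which drives initialization, minibatch shuffling, the input
corruption, and the reparameterization draws through a single
`numpy.random.Generator`.

### Denoising criterion

During training the encoder input is corrupted with Gaussian noise
(`input_noise_sd`, default 1.0 on the standardized feature scale) while
the reconstruction target stays clean. This makes the latent code — and
therefore every reconstruction — invariant to edge-level measurement
noise, which matters downstream: graph measures recomputed from
reconstructions otherwise inherit each subject's idiosyncratic edge noise,
and for measures with little biological variance that noise dominates the
between-site effect-size estimate. Optional KL annealing
(`kl_anneal_epochs`) and linear learning-rate decay (`lr_final_fraction`)
are available but off by default; on the default study they bought
nothing, and KL weights above ~1.5 visibly destroyed the age signal.

### Hyperparameters

| parameter | default | rationale |
| --- | --- | --- |
| hidden_dim | 256 | two-layer MLPs on 3486 features; minutes-scale CPU training |
| latent_dim | 32 | enough for age/sex/measure signal, small enough for the KL to bind |
| w_recon, w_kl, w_age, w_B | 1.0 | the plain unweighted composite loss |
| w_sex | 4.0 | the sex task is a single binary logit competing with a 3486-dimensional reconstruction; at weight 1 its gradient is too dilute for the encoder to retain the sex direction, a standard multi-task balancing issue |
| input_noise_sd | 1.0 | denoising corruption (see above), in standardized feature units |
| learning rate | 1e-3 | Adam default regime |
| epochs | 400 | composite loss plateaus by ~300 on the default study size; much longer training starts re-memorizing site detail |
| batch size | 32 | — |

All are configurable through `ModelConfig`; the defaults are tuned to the
default synthetic study size (300 training subjects) and train in roughly
three minutes on one CPU core.

## The 12 network measures

All measures operate on validated, thresholded connectomes and follow
Brain Connectivity Toolbox conventions for weighted undirected graphs:

1. **modularity** — best-of-10 seeded Louvain runs (resolution 1.0); the
   reported Q is re-evaluated from the returned partition with the weighted
   Newman formula.
2. **avg_betweenness** — mean raw Brandes betweenness on lengths 1/w;
   tied shortest paths are counted fractionally.
3. **assortativity** — Pearson correlation of *binary* degrees over edge
   endpoints (both orientations); undefined (NaN) for regular graphs.
4. **avg_participation** — mean participation coefficient computed with
   strengths, using the Louvain partition from (1).
5. **avg_clustering** — mean Onnela coefficient on max-normalized weights.
6. **avg_strength** — mean row sum.
7. **avg_local_efficiency** — mean efficiency of each node's
   neighbor-induced subgraph.
8. **global_efficiency** — mean inverse shortest-path distance.
9. **density** — fraction of possible edges present.
10. **rich_club** — weighted rich-club curve φ_w(k); the scalar summary is
    the mean over defined k (configurable: mean | max-k | fixed-k).
11. **char_path_length** — mean shortest-path distance over connected
    pairs, lengths 1/w.
12. **edge_count** — mean hop count of those same shortest paths; among
    tied shortest paths the minimal hop count is used (a deterministic
    tie-break implemented with a lexicographic Floyd–Warshall).

Numerical choices worth knowing:

* **Lengths.** Shortest-path measures use ℓ = 1/w. Streamline-count
  connectomes carry no physical edge lengths, so path lengths are in
  inverse-count units, not millimeters.
* **Efficiency normalization.** Global and local efficiency first divide
  weights by the matrix maximum (the BCT `weight_conversion` convention),
  so both lie in [0, 1]. Characteristic path length and betweenness use the
  raw weights.
* **Disconnection.** Infinite-distance pairs contribute 0 to efficiency
  and are excluded from the path-length/edge-count means; a measure is NaN
  ("undefined") only when no finite pair exists. No measure raises on a
  disconnected or empty graph.
* **Edge filter.** Edges lighter than a configurable fraction (default
  1e-7, i.e. 0.00001%) of the total streamline count (default 10 million)
  are removed before analysis; the comparison is strict (`< cutoff`
  removed, equality retained) and the filter is idempotent.

The entire battery is verified against brute-force enumeration oracles
(exhaustive path and triangle enumeration, explicit formula evaluation) on
random small graphs (n ≤ 8, integer weights ≤ 3) to 1e-9.

## Harmonization and evaluation

At test time, every connectome is encoded to `μ_z` and decoded under one
common site label. Decoded features are mapped back through the inverse
feature transform, clipped to be non-negative, and reassembled into a
symmetric zero-diagonal matrix. Decoded weights below one streamline are
zeroed by default (`edge_floor=1.0`): the decoder is continuous, but a
fraction of a streamline is not a meaningful count, and such vanishing
edges destabilize the binary-topology measures (density, assortativity,
rich club) of the reconstruction. Two measure routes are reported side by
side for every subject: the model's site-conditional measures head
(*predicted*) and the 12 measures recomputed from the reconstructed
connectome (*recomputed*). Neither is privileged; evaluation reports both.

Between-site disparity is quantified on a demographically matched test set
(1:1 cross-site pairs, same sex, ages within ±1 year, found by maximum
bipartite matching rather than greedily) with Cohen's d (pooled SD) and
the two-sided Mann–Whitney U test (midranks, tie-corrected normal
approximation with continuity correction; appropriate at the n ≈ 60–80 per
site this package targets). Successful harmonization reduces
medium-to-large effects (|d| > 0.5) to small ones (|d| < 0.2) and removes
significance (p ≥ 0.05) wherever it was present before. No
multiple-testing correction is applied across the 12 measures; p-values
are reported raw, per measure. Training stability is assessed by
bootstrap: repeated retraining on random 80% subsamples (without
replacement) against a fixed test set, summarized as mean ± SD.

## Synthetic cohorts

Because no public multi-site connectome cohort can ship with the package,
the `simulate` module generates two-site cohorts with known ground truth.
A shared template graph (two hemisphere blocks; intra-hemispheric edges
denser than inter-hemispheric; log-normal streamline counts) is perturbed
per subject by multiplicative effects:

* **site**: an intra-hemispheric weight bias (SITE2 ×1.25) plus a global
  gain (SITE2 ×1.10) — site differences in real multi-site studies
  concentrate in intra-hemispheric connections;
* **age**: a 1.2%/year decline of all weights (ages uniform 55–85);
* **sex**: ×1.20 on a fixed random 20% subset of template edges for
  female subjects;
* **noise**: per-edge log-normal noise (σ = 0.15), then rounding to
  integer streamline counts.

All effects are multiplicative because counts are positive and
heavy-tailed; rounding lets weak edges drop out, so site effects also reach
the binary topology (density, degree structure). The default effect sizes
were calibrated once so that the raw two-site cohort shows
medium-to-large (|d| > 0.5) between-site differences on at least half of
the 12 measures, which is the regime the harmonization claim addresses.

What the generator does *not* emulate: realistic regional topology beyond
the two-block hemisphere structure, distance-dependent connection
probability, site-by-age interactions, longitudinal repeat scans, or
disease effects. Passing the synthetic battery therefore demonstrates that
the method removes multiplicative, topology-reaching site effects while
preserving smooth covariate signal — not that it harmonizes any particular
real scanner pair.

## Default study size

The shipped study conditions are 150 training subjects per site and 60
matched test pairs at 84 nodes. This is large enough for stable effect-size
estimates (the standard error of Cohen's d at n = 60 per group is ≈ 0.18)
while keeping a full generate–measure–train–project–evaluate cycle in the
single-digit minutes on one CPU core. The real cohorts the method is aimed
at (hundreds of subjects per site) are reachable by raising
`GeneratorConfig.n_per_site`.

### Statistical resolution of the effect-size benchmark

A between-site Cohen's d estimated from 60 pairs has a standard error of
roughly `sqrt(2/60) ≈ 0.18` times the fraction of measure variance not
explained by biology. For measures whose between-subject variance is
mostly idiosyncratic noise, the *maximum* |d| across 12 measures therefore
fluctuates around 0.2–0.35 even when no site effect exists at all — on the
default study, regenerating the matched test set with *identical* site
effects yields a raw max |d| of ≈ 0.35. Post-harmonization effect sizes at
this test-set size should be read with that floor in mind: values of
≈ 0.2 on the recomputed route are compatible with complete site removal,
and the head-predicted route (which is almost fully denoised) is the
sharper instrument for detecting *residual* site signal.

## Known limitations

* Under the synthetic generator, co-learning does not show a
  measure-prediction advantage over the twelve per-measure models: most
  generated measures have almost no biologically learnable variance (head
  error ≈ 1 SD), so the scheme comparison reduces to noise-level ties,
  and the specialized models win the few predictable measures by
  concentrating capacity. Both schemes harmonize equally well here; any
  co-learning advantage would have to come from covariance structure among
  measures that this generator does not produce.
* The decoder reconstructs each edge independently from a 32-dimensional
  code, so reconstructed connectomes are smoother than raw ones; absolute
  levels of noise-sensitive measures (e.g. clustering of weak edges) can
  shift between the raw and reconstructed domains even though *between-site
  differences* within the reconstructed domain are removed. Compare
  harmonized values only with harmonized values.
* Under individual learning the 12 models share no latent space, so the
  reconstructed connectome route is defined per model; only the measure
  head outputs are meaningfully comparable across the 12 models.
* The Mann–Whitney p-value uses the asymptotic normal approximation; for
  very small test sets (n < ~10 per site) an exact method would be
  preferable.
* Age and sex heads are linear in `z`; strongly non-linear covariate
  effects would require deeper heads.
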