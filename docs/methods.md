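# Methods

## Problem and approach

Quantitative ultrasound of the liver needs a per-image binary mask of a
field of interest inside the parenchyma. Hand-configured encoder–decoder
segmentation networks are sensitive to architecture choices, so `evoseg`
searches the architecture space with an island-model genetic algorithm:
one subpopulation per network depth, evolved in parallel and coupled only
through periodic migration, with Dice-coefficient fitness and a
depth-penalized score for comparing architectures across depths.

## Genome and constraint system

A genome is the 4-tuple (dropout rate `p_d`, filter list `F = f_1..f_d`,
depth `d`, skip flag `u_s`). Constraints: `len(F) == d`, each
`f_i ∈ [f_min, f_max]` (defaults 8 and 1024), `p_d ∈ [0, 0.5]`, and `d`
in a configurable depth set. The default depth set is `{3, 4, 5, 6}`,
matching the depths of the shipped filter catalog; a narrower set such as
`[2, 5]` is expressible through `GenomeBounds(depth_set=...)`. Violations
are reported (not raised) by `validate_genome`; `clip_to_bounds` is the
projection onto the legal box and is idempotent.

Filter lists in the catalog are strictly increasing, but nothing enforces
a funnel shape after mutation: only box bounds are applied. An optional
`snap_pow2` mode rounds mutated filter counts to the nearest in-bounds
power of two; the default leaves the literal ±8 arithmetic untouched.

## Operators

* **Fitness** — best validation Dice of the genome's trained network,
  `2|A∩B| / (|A|+|B|+ε)` with ε = 1e-6 (configurable) guarding the
  empty-mask case.
* **Selection** — each subpopulation keeps its ⌈N/2⌉ fittest genomes
  (never emptying a lineage at odd N). Ties break on the canonical JSON
  serialization of the genome, so runs are reproducible bit for bit.
* **Crossover** — dropout rates, depths and aligned filter entries are
  averaged (integers rounded half-up); the skip flag is a fair coin
  between the parents. Partners share a depth by construction (they come
  from one subpopulation); a permissive `cross_depth="align"` mode
  averages over the shallow `min(d1, d2)` levels and fills the child's
  deeper levels from the deeper parent.
* **Mutation** — one 10 % coin perturbs dropout by U(−0.05, 0.05); an
  independent 10 % coin per filter entry adds U(−8, 8) rounded to the
  nearest integer. Results are clipped. The per-event reading (rather
  than one coin for all filters jointly) follows the operator's
  description of each filter size being adjusted independently.
* **Adjusted score** — `dice / (d · p)` with penalty factor `p = 0.1` by
  default. The score is a *ranking device across depths*, not a
  probability (it exceeds 1); within a subpopulation selection uses raw
  Dice, which orders identically. The alternative reading
  `dice · (1 − d·p)` is available as `penalty_mode="linear"`.
* **Convergence** — stop when the all-population average fitness changes
  by less than `ε_c` (default 1e-3) between consecutive generations, or
  at the generation cap.

## Migration

Every `interval` generations (default 3) each depth's top performer
exports its dropout rate and skip flag to every other depth. Because
filter lists are depth-specific, a migrant's filters are regenerated by
sampling the catalog entry of the target depth. Its dropout is the blend
`(1 − r)·mean(target dropouts) + r·source_top` with migration rate
`r = 0.2` by default; blending against the target population's mean (a
population-level quantity) was chosen because migrants are new
individuals, not overwrites of any particular incumbent. Migrants carry
the source top's fitness as a *provisional* score until they are next
trained. After the exchange each depth truncates to `retain_after = 3`
members. Truncation is elitist: the depth's own top performer always
survives, so a migrant with an optimistic provisional score can never
evict the best solution a depth has found — without this guarantee the
per-depth best could regress across generations.

## Two-phase protocol

**Phase 1 (coarse search).** Subpopulations of `N = 6` genomes per depth
(4 at desk scale) seeded from the catalog; when `N` is at least the
number of catalog rows for a depth, every row appears at least once, so
small exhaustive searches cover the catalog in generation one. Each
generation: train every not-yet-scored genome for `phase1_epochs` epochs
on an 80/20 split, select the top half, refill to `N` by crossover of
random retained parents plus mutation, and migrate on schedule. Retained
genomes keep their cached fitness rather than being retrained — this
avoids stochastic fitness drift and makes the elitism property exactly
testable. Per-genome training seeds are a SHA-256 hash of (run seed,
genome serialization), so results do not depend on worker scheduling.

**Phase 2 (refinement).** An elite-of-one lineage starts from the
phase-1 winner (argmax of adjusted score over every evaluation). Each of
`phase2_generations` rounds spawns one mutant and one crossover child
(incumbent × mutant), trains them long (`phase2_epochs`, early stopping
on validation loss with patience 10 and best-weight restoration), and
replaces the incumbent only on strict improvement. The final genome is
scored by seeded k-fold cross-validation (default 3 folds), reporting
per-fold Dice, mean and population standard deviation.

## Network and training

The genome realizes the canonical U-Net reading: two 3×3 convolutions
with ReLU per level, 2×2 max pooling between encoder levels, learned 2×2
stride-2 transposed-convolution upsampling, skip concatenation when
`u_s`, dropout once per level after its convolutions, and a 1×1 sigmoid
head. Input sides must divide by `2^(d−1)`. Layers are NumPy float32
with explicit reverse-mode gradients (im2col + BLAS matmul convolutions);
the optimizer is Adam at learning rate 1e-4 (default). The loss is mean
per-pixel binary cross-entropy with probabilities floored at 1e-7;
validation Dice is computed on predictions binarized at 0.5. The output
bias is initialized to the logit of the training foreground fraction,
which skips the early epochs a sigmoid head otherwise spends learning
the base rate — this matters for the very short trainings used as
phase-1 fitness evaluations.

## Synthetic phantoms

The generator emulates the three B-mode statistics the task depends on:

* a piecewise echogenicity map — background 1.0 and one contiguous blob
  at contrast 1.6 (a randomly oriented ellipse, area fraction 0.15 of
  the image, with a low-frequency radial perturbation of its contour
  emulating a smooth manual field-of-interest boundary; star-shaped, so
  always one 4-connected region);
* multiplicative speckle: `1 + s·(R − 1)` with `R` Rayleigh-distributed
  with unit mean and amplitude `s = 0.7` by default (`s = 0` is the
  noise-free two-level limit used as a geometric-alignment oracle);
* per-row depth attenuation (0.4 %/row) and, with probability 0.2, a
  shadow wedge widening with depth at 0.45× intensity.

Pixels are independent: the generator does **not** model spatially
correlated speckle, probe geometry, point-spread functions, or
harmonic-mode differences, and its blob is brighter and better separated
than real parenchyma boundaries. Passing tests therefore certify the
*pipeline* — operators, search dynamics, training mechanics — not
clinical segmentation accuracy; clinical-scale Dice claims require real
annotated scans.

## Problem sizes

Defaults mirror the full-scale protocol (depths 3–6, 627-image-scale
datasets at 256×256, 30/300-epoch trainings, 10 generations) which is a
multi-GPU-hour workload. The shipped `presets.desk_config` is the
package's CPU-scale counterpart used by the test suite: 200 phantoms at
64×64, depths {3, 4} with a small-filter catalog (first-level widths
kept at 8 because wide shallow levels dominate CPU convolution cost),
four genomes per depth, three generations of 3-epoch evaluations, two
refinement rounds of 15-epoch early-stopped training, 3-fold CV, and
Adam at 1e-2 (short trainings need the larger step; the 1e-4 default is
tuned for 300-epoch refinement). On one CPU core this two-phase run
takes roughly 10–15 minutes (the exact time depends on which
architecture wins phase 1) and reaches cross-validated Dice ≈ 0.93 on
the default phantoms.

## Numerical and design notes

* Integer rounding is half-up everywhere (crossover means, mutation
  deltas), avoiding Python's banker's rounding for reproducibility.
* Dropout masks draw from the network's own generator; training is
  bit-reproducible for a fixed `TrainConfig.seed`.
* `kfold_cv` uses seeded shuffled `KFold`; the reported spread is the
  population standard deviation.
* Offspring counts: the population is refilled to `N` after selection
  (and after migration truncation on migration generations); offspring
  are generated before migration, and trimmed or topped up afterwards so
  the next generation is exactly `N` per depth.
* A failing fitness evaluation is retried once, then aborts naming the
  genome's serialization.
* Known limitations: no batch normalization (unneeded at these depths on
  [0,1] inputs); single-channel grayscale only; all-to-all migration
  topology only; the evolutionary operators treat depth as fixed within
  a subpopulation, so depth changes only occur through migration.
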