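# Methods

## What the simulator emulates

The generative model reproduces the statistical skeleton of a
serial-multiplex immunogold experiment on serial-section TEM material:

* **Geometry.** A stack of `n_sections` ultrathin sections (40 nm each;
  z = index × thickness) crossed by neurite profiles whose (x, y)
  centroids random-walk gently from section to section. With the bilateral
  layout (default), profiles come in left/right pairs mirrored exactly
  about the x = 0 midline and sharing their peptide content, emulating the
  bilaterally symmetric ventral-nerve-cord population. IDs follow the
  `n<k>`/`N<k>` convention for first/second series.
* **DCV occupancy.** Dense-core vesicles are not spread uniformly along an
  axon: occupancy is bursty and some sections carry none. We model the
  per-section DCV count as a two-state Markov chain — off → on with
  probability `dcv_on_rate`, on → off with `dcv_off_rate`, initial state
  stationary — with Poisson(`dcv_mean`) counts in the on state and exactly
  zero in the off state. Off-run lengths are geometric with parameter
  `dcv_on_rate`; the stationary on-fraction is
  `dcv_on_rate / (dcv_on_rate + dcv_off_rate)`. Both closed forms are used
  as test oracles.
* **Labeling design.** `paired-grids`: each antibody gets ≥ 2 runs of 4–6
  consecutive sections (configurable up to the 4–18 range that fits on one
  EM grid), with run starts ~50 sections apart — blocks of one run per
  antibody are laid back-to-back, and the second block is offset by the
  spacing. `whole-body`: 1–6-section runs scattered over a long
  (thousands-of-sections) series. Runs are pairwise disjoint half-open
  ranges.
* **Gold deposition.** Thinned Poisson, linear in DCV count:
  `raw ~ Poisson(α·D·maxₚS[a,p] + λ_bg·A)`, then `Binomial(raw, p_enh)`.
  Cross-reactivity takes the *max* over the neurite's expressed peptides
  (an antibody binds its best-matching epitope), not the sum, avoiding
  double counting. Counts exist only for (labeled section × intersecting
  neurite) cells; elsewhere they are absent, which the gold table keeps
  distinct from zero. Thinning a Poisson yields a Poisson, so mean and
  variance both equal `p_enh·(α·D·S + λ_bg·A)` — the oracle the deposition
  tests check at 10⁴ replicates.
* **Synapses.** Peptidergic presynapses sample vesicle diameters from a
  normal truncated at zero (63 ± 8.4 nm, the measured dense-core law);
  classical presynapses from a smaller clear-vesicle law (35 ± 5 nm; no
  measured clear-vesicle diameter is available, 35 nm is a typical small
  clear vesicle). At 63/8.4 the truncation is numerically irrelevant
  (the zero bound is 7.5 SDs below the mean).
* **Image stacks.** `render_if_stacks` stands in for whole-body confocal
  scans of sibling specimens: one smooth blobby ground-truth pattern
  (center-of-mass centered), viewed per stack through a random small
  affine (in-plane rotation ~4°, ~3% scale, ~1.5-voxel offsets), a smooth
  low-frequency deformation (coarse control grid, ~1 voxel), and Gaussian
  noise. True transforms are retained so registration can be scored
  against them.

## Default parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| `section_thickness_nm` | 40 | nm | standard ultrathin section |
| `n_sections` | 200 | — | one trunk-segment series |
| `dcv_on_rate` / `dcv_off_rate` | 0.2 / 0.1 | per section | on-fraction 2/3, mean burst ~10 sections (~0.4 µm), mean gap ~5 sections — bursty with visible zero-runs |
| `dcv_mean` | 4 | vesicles/section | a few DCVs per profile per section |
| `gold_per_dcv` (α) | 1 | particles/DCV | specific signal α·E[D|on] = 4 per labeled section |
| `background_rate` (λ_bg) | 0.02 | particles/µm² | controls show essentially zero background in traced neurites; kept small but nonzero so specificity is testable |
| `enhancement_prob` (p_enh) | 0.5 | — | silver enhancement misses a substantial fraction of ultra-small particles |
| `vesicle_diam_mean_nm` / `sd` | 63 / 8.4 | nm | dense-core vesicle measurement (n = 100) |
| `clear_diam_mean_nm` / `sd` | 35 / 5 | nm | typical clear synaptic vesicle |
| `peptidergic_fraction` | 0.25 | — | a minority of profiles carry peptides |
| `coexpression_prob` | 0.1 | — | occasional two-peptide neurons |

Identity-calling thresholds: `min_gold = 2` (the candidate rule),
`min_runs = 2`, `min_total = 5`. "Strong labeling" has no published
numerical definition; we operationalize *confirmed* as ≥ min_gold on
≥ min_runs independently stained runs OR total ≥ min_total, which lets a
neuron whose paired run happens to lack DCVs still be confirmed through
its cumulative signal (these cases carry an explicit
`dcv_absence_false_negative` flag when DCV tracks are available).

Cross-reactive-group flagging uses Jaccard ≥ 0.5 between
confirmed-positive sets — well above chance overlap at realistic
positive-set sizes. In the power analysis, hits mediated by *partial*
recognition (0 < S < 1) are reported separately and count as neither true
nor false positives, mirroring how partially characterized antibodies are
treated as family-level markers rather than errors.

## Numerical and design choices

* **RNG.** One root seed; every component (neurites, per-neurite DCV
  tracks, design, gold, synapses) draws from its own child stream keyed by
  a stable CRC of the component name, so adding neurites never perturbs
  existing draws and identical (config, seed) gives byte-identical
  serializations.
* **Table semantics.** Row totals, column totals and the grand total
  ignore absent cells; the double-counting identity (Σ rows = Σ columns)
  is enforced by construction and property-tested. Shade bins default to
  {0}, {1}, {2–4}, {5–9}, {≥10}; published figures show shades without
  printing edges, so the edges are package defaults.
* **Control transect.** Default endpoints are the widest chord of the
  convex hull of profile centroids; the walk takes `per_step = 2` nearest
  not-yet-sampled profiles per 1-µm step, warns (never raises) when
  profiles run out, and never samples a profile twice.
* **Registration.** Similarity is normalized cross-correlation. The
  affine is parametrized about the grid center and optimized by greedy
  per-coordinate line search with multiscale step shrinking (deterministic,
  derivative-free, never accepts a worse value). The deformable part is a
  coarse control-point displacement grid (default 2×3×3) upsampled
  trilinearly via a precomputed sparse operator, optimized the same way,
  with displacements clipped to 15% of the field of view. Stage sequence
  defaults to affine, then two affine+deformable rounds (the published
  description of the cycle count is ambiguous; three total averaging
  rounds is the default and is configurable). Each stage re-registers the
  *original* oriented stacks (warm-started from the previous stage's
  transform), ranks by NCC, and averages the top `k_keep = 24` of 36 in
  canonical stack-id order — which makes the build bit-for-bit invariant
  to input ordering. Desk-scale default stacks are 64×64×8 voxels.
* **Circuits.** Polyadic connectors contribute one synaptic pair per
  postsynaptic target (the CATMAID convention). Edge display width is
  √weight. The vesicle-class cut is 45 nm, the midpoint between the two
  modeled diameter means, so the per-synapse misclassification rate
  follows in closed form from the two truncated-normal tails. The midline
  is the x = 0 plane; laterality uses the soma side (root-node side, with
  a warning, when no soma is marked).
* **Degenerate inputs.** Empty neurite lists, zero-synapse requests and
  per_step = 0 transects return empty results; all-zero image stacks,
  singular affines, cyclic SWC parent links and design/table mismatches
  raise typed errors naming the offender.

## Problem sizes

Tests and drivers run at desk scale by choice: 200-neurite stacks,
10⁴-replicate deposition oracles, 20-replicate power sweeps, 36-stack
64×64×8 template cohorts. These sizes give 3-σ Monte-Carlo resolution on
every oracle the suite asserts while keeping the full pipeline fast on a
single CPU.

## What passing tests do and do not show

The generator reproduces the *statistical* structure the method relies on
— bursty vesicle occupancy, sparse disjoint labeling runs, Poisson gold
with background and incomplete enhancement, mirrored geometry — not real
micrographs. It contains no segmentation or particle-detection noise, no
section loss or folds, no antibody-specific affinity differences, and its
cross-reactivity matrix is an input rather than an estimate. Passing the
recovery criteria therefore shows the *inference rules* behave correctly
under the assumed generative law (e.g. precision is driven by the
background rate, recall by run length × occupancy), not that any
particular wet-lab series achieves those numbers. Results that depend on
a full EM volume (total traced-neuron counts, maximum synapse convergence
in a real circuit) are out of reach of the packaged data and are treated
as context, not reproduced quantities.
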