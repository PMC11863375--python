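# Methods

## Model overview

`confdiff` generates molecular conformers with a denoising diffusion
probabilistic model (DDPM) over atomic coordinates. A fixed forward
process corrupts a conformation X_0 with Gaussian noise over T steps;
a learned noise predictor drives the reverse process, iteratively
denoising a sample drawn from an isotropic Gaussian prior into a
conformation consistent with the molecule's bond graph.

### Forward process and schedule

The per-step noise magnitudes follow a sigmoidal schedule: T values
s_t are linearly spaced on [-6, 6] and

    beta_t = beta_min + logistic(s_t) * (beta_max - beta_min),

with defaults T = 5000, beta_min = 1e-7, beta_max = 2e-3. With
alpha_t = 1 - beta_t and alpha_bar_t = prod_{s<=t} alpha_s, the t-step
marginal has the closed form

    X_t = sqrt(alpha_bar_t) X_0 + sqrt(1 - alpha_bar_t) eps,
    eps ~ N(0, I),

and at the defaults alpha_bar_T ~ 6.7e-3: the terminal state is close
to the prior. A degenerate T = 1 schedule takes the left endpoint of
the span.

The reverse update is the standard eps-parameterized posterior mean

    X_{t-1} = (X_t - beta_t / sqrt(1 - alpha_bar_t) * eps_hat)
              / sqrt(alpha_t) + sigma_t z,

with fixed posterior variance
sigma_t^2 = beta_t (1 - alpha_bar_{t-1}) / (1 - alpha_bar_t) (so
sigma_1 = 0; the final step is noise-free). The training objective is
the simple denoising MSE (loss weight gamma_t = 1, configurable).

**Zero center of mass.** Coordinates and injected noise are
centroid-subtracted at every forward and reverse step. Translations
are an unconstrained flat direction of the process; removing them
keeps the sampled distribution proper and makes equivariance
statements exact (rotation equivariance with translations quotiented
out).

### Graph construction

Two directed edge sets drive the encoders, with a fixed type
vocabulary {0 single, 1 double, 2 triple, 3 aromatic, 4 two-hop,
5 three-hop, 6 spatial}:

* **local** — covalent bonds typed by bond order, plus auxiliary edges
  joining atoms at covalent-graph distance 2 or 3 (breadth-first
  search on the bond graph only; a pair reachable at several depths
  takes the smallest, and covalent bonds are never re-typed);
* **spatial** — every remaining atom pair within 10 Å (inclusive at
  the boundary), rebuilt from the *current* coordinates at every
  denoising step, since proximity changes as atoms move.

Hydrogens are retained as graph atoms. Indexing is 0-based throughout;
conversions happen at file boundaries (SDF/SMILES/XYZ via RDKit).

### Encoders

* **Edge encoder** — a linear layer expands the scalar edge length,
  the result is concatenated with a learned edge-type embedding,
  passed through a GeLU MLP, recombined with the type embedding by
  element-wise multiplication, and mapped by a second MLP. A Gaussian
  radial-basis expansion of the length is available as a config
  option; the default is the plain linear expansion.
* **Global encoder** — an attention-enhanced continuous-filter
  convolution (CFConv) network over all edges. Each interaction block
  runs two parallel CFConv pathways with separate filter networks
  (128 and 64 filters by default): the wider pathway targets
  long-range, higher-order structure, the narrower one coarser
  patterns. Their concatenation passes through a learnable shifted
  softplus — softplus(x - s) * c with per-channel learnable shift and
  scale (initialized s = 0, c = 1) — then an attention gate (a linear
  layer to half width with ReLU, a second linear layer, sigmoid) that
  rescales features atom-wise, then a linear projection back to the
  128-wide residual stream. An adaptive feature-scaling module runs
  after every block: channel scales 2*sigmoid(MLP(context)) computed
  from the mean-pooled node features (near-identity at
  initialization). Distances enter only through edge lengths, so node
  features are rigid-motion invariant by construction.
* **CFConv details** — node features are projected to the filter
  width and LeakyReLU-activated before message passing; per-edge
  messages are the sender features gated element-wise by the filter
  network's output and by a distance weight; messages are
  sum-aggregated per receiver; batch normalization stabilizes the
  aggregated feature maps before an atom-wise output layer. Placing
  the normalization after aggregation (the figure-level description
  leaves the exact ordering open) keeps the message path alive for
  single-element molecules, whose pre-aggregation node rows are
  identical and would otherwise be annihilated by batch statistics.
* **Distance weighting** — a Gaussian envelope exp(-d^2 / (2 sigma^2))
  with sigma = d_cutoff = 10 Å, hard-zeroed for d > d_cutoff,
  multiplied element-wise by the output of a small learnable network
  of the distance (sigmoid-bounded per filter channel).
* **Local encoder** — a GIN-style stack over local edges:
  h_i' = MLP((1 + eps) h_i + sum_j ReLU(h_j + e_ij)), with batch
  normalization and ReLU after every layer but the last, residual
  recombination, and a final two-layer ReLU MLP. Linear layers that
  feed a normalization drop their bias (it is absorbed exactly).

### Scores and equivariant gradients

Per-stream MLPs map the symmetric endpoint combination
[h_i + h_j, e_ij] to one scalar score per directed edge, guaranteeing
score(i, j) = score(j, i). Scores become per-atom vectors along
interatomic displacement directions:

    g_i = sum_j s_ij (x_i - x_j) / ||x_i - x_j||,

centered to zero mean; edges with coincident endpoints
(length < 1e-8) contribute zero. Built this way the prediction
rotates with the input exactly, which the tests verify end to end to
1e-4.

Training computes a separate denoising loss per stream
(L = L_global + lambda L_local, lambda = 1 by default); inference
mixes the two fields as w_g eps_g + w_l eps_l. Because both streams
are trained against the full noise target, the default mixing weights
are w_g = w_l = 0.5 — an equal-weight *average* — so the mixed
prediction matches the training target's scale; an equal-weight sum
would double the predicted noise magnitude and destabilize sampling.
All three constants are config options.

**Time conditioning** uses a sinusoidal embedding of the raw step
index t passed through a small MLP and added to the node embeddings
of both streams. Embedding the raw index rather than t/T preserves
resolution between adjacent steps, which measurably improves
training at short schedules.

### Normalization statistics at inference

Batch-normalization layers learn affine parameters against the
statistics of their training batches. At inference the package
defaults to normalizing by the current graph's own statistics
(`norm_eval_stats="batch"`): this is a deterministic function of the
input — identical molecules embed identically — and stays consistent
with the statistics the affine parameters were trained under even
when training batches are small. Running-average statistics
(`"running"`) are tracked and available; at desk-scale batch sizes
they drift far from any single batch's statistics and degrade
sampling badly (measured: 0/20 successful toy conformers versus 16/20
with current-graph statistics). Single-row inputs always fall back to
the running estimates.

## Training procedure

Adam with learning rate 1e-3, moment coefficients (0.95, 0.999), no
weight decay. Each iteration samples a batch of molecules with
replacement, draws t uniformly on [1, T] and eps ~ N(0, I) per
molecule, accumulates the two-stream loss, clips the global gradient
norm (presets: 10,000 small-molecule / 30,000 drug-like, with batch
sizes 64 / 32), and steps. The validation objective — the training
loss under a fixed noise seed, so values are comparable across calls
— is evaluated every 5,000 iterations by default; a plateau scheduler
multiplies the learning rate by 0.6 after 10 consecutive
non-improving validations (strict comparison, floor 1e-6). t is
sampled per molecule; no exponential moving average of weights is
kept. Checkpoints carry model parameters, optimizer moments,
scheduler state and the RNG state, and resume bit-exactly.

## Synthetic data

The toy generator builds exact idealized geometries with matching
bond graphs: a tetrahedral center (all angles arccos(-1/3)), a
straight chain, a planar regular ring (optionally aromatic), and a
zig-zag torsion chain with tetrahedral bond angles and user-specified
dihedrals placed by internal coordinates. Elements default to carbon;
bond lengths default to 1.54 Å. Reference ensembles are seeded
Gaussian jitters of the ideal geometry.

These templates emulate *rigid single-conformer* molecules. They
exercise graph construction, equivariance, the diffusion machinery
and the metrics without any external data, but they do not probe
multi-basin torsional landscapes, chemistry-dependent bond lengths,
or dataset-scale diversity — passing tests demonstrate mechanism
correctness, not benchmark-level accuracy on real conformer
ensembles.

### Desk-scale study conditions

The end-to-end check trains a deliberately tiny model (width 32,
interaction blocks 2, GIN depth 2, T = 100) on a single rigid
5-heavy-atom molecule (the all-carbon tetrahedral star — a 5-atom
molecule with only one heavy atom would make the heavy-atom RMSD
check vacuous) for at most 2,000 iterations at batch 64, then draws
20 conformers and measures heavy-atom, symmetry-corrected RMSD to the
reference. For the short schedule the terminal signal retention is
matched to the default schedule's by scaling beta_max to 0.1
(preserving sum(beta) ~ 5, hence alpha_bar_T ~ 6.7e-3), so the prior
remains a valid starting point. The toy preset enables the edge
encoder's Gaussian-RBF length expansion: with a single rigid target,
final-step precision is limited by the network's distance resolution
at bond scale, and the radial basis raises the fraction of sampled
conformers within 0.3 Å of the reference from roughly 85% to 95% in
our measurements.

One genuine ceiling of this setting: an equivariant denoiser cannot
pin the absolute orientation of the target at high noise levels, so
the optimal achievable objective is bounded away from zero — the
measured validation loss flattens near that floor rather than near
zero. RMSD after optimal superposition is unaffected.

## Evaluation metrics

Minimal RMSD uses Kabsch superposition (proper rotations only,
translations removed) after optional hydrogen exclusion, minimized
over bond-graph automorphisms (element- and bond-order-preserving,
enumerated via VF2 with a cap of 10^4; beyond the cap the identity
mapping is used and the report flags the fallback). Coverage and
matching:

    COV-R = % of reference conformers whose nearest generated
            RMSD <= delta,
    MAT-R = mean nearest-generated RMSD over references,

with COV-P / MAT-P swapping the two roles. delta defaults to 0.5 Å
(small molecules) or 1.25 Å (drug-like); the evaluation driver
generates 2x|reference| conformers by default. Best-k lists the k
smallest per-generated-frame minima (ties broken by frame index).
Property correlations are Pearson coefficients against a
caller-supplied property table (constant columns reported as
missing). Torsions use the standard atan2 construction with angles in
(-180, 180]; the (phi, psi) density is a Gaussian KDE fitted on the
3x3 periodic tiling of the samples, evaluated on a 180x180
cell-center grid (Scott's rule bandwidth unless overridden) and
normalized to integrate to 1 — the symmetric kernel makes the density
exactly continuous across the ±180° seam.

## Numerical and degenerate-input choices

* Spatial cutoff comparisons are inclusive (d <= 10 Å).
* Coincident atoms: zero edge length is valid input to the edge
  encoder; score-to-gradient conversion guards lengths < 1e-8.
* Sampling aborts with the offending step index if any coordinate
  exceeds 1e3 Å or turns non-finite.
* Kabsch on collinear/planar point sets: the optimal rotation may be
  non-unique but the residual is well-defined; the implementation
  uses the residual only.
* All randomness flows through named NumPy generators; per-molecule
  sampling seeds derive from (run seed, molecule index, draw index).

## Known limitations

* No stereochemistry or chirality handling: reflections of a chiral
  target are not penalized by design anywhere in the model.
* Benchmark-scale evaluation (tens of thousands of molecules,
  GPU-scale training) is out of desk-scale reach; the package's
  evidence is mechanism-level correctness plus the rigid-toy
  end-to-end loop.
* Property computation (TPSA, logP, ...) is delegated: the
  correlation routine consumes a precomputed table.
* The tensor engine is deliberately minimal (float64, CPU, no
  broadcasting beyond NumPy semantics); it is sized for the toy
  problems the tests run, not for production training.
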