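# Methods

## Model

`plcdiff` models the joint distribution of the 3D coordinates of a protein's
Cα atoms and a ligand's heavy atoms with a variance-preserving (VP)
diffusion generative model that is equivariant under rigid motions. The
modeled entity is a token sequence: one token per residue followed by one
token per ligand heavy atom; conditioning information is the amino-acid
sequence (optionally augmented by a per-residue embedding matrix from an
external protein language model, supplied as a file) and the ligand
molecular graph. No protein structure is used as input in the default
variant; a structure-conditioned variant accepts a backbone Cα template
through its distance matrix only.

### Forward process and schedule

All distributions live on the linear subspace of point clouds with centroid
at the origin (`N_x`), which removes global translation from the model. The
forward process is

    q(z_t | x) = N_x(alpha_t x, sigma_t^2 I),   t in [0, 1],

with alpha_t^2 + sigma_t^2 = 1. The schedule is parameterized by
gamma(t) = -log SNR(t), linear between `gamma_min = -13.3` and
`gamma_max = 5.0` (both configurable, dimensionless). These endpoints give
sigma_0^2 ≈ 1.7e-6 (z_0 is the data to visual precision) and
alpha_1^2 ≈ 6.7e-3 (z_1 is the prior to statistical precision); the
constructor rejects schedules with sigma_0^2 ≥ 1e-4 or alpha_1^2 ≥ 1e-2.
All schedule quantities are evaluated in log/sigmoid space, and the
transition variance uses `expm1` so that sigma_{t|s}^2 stays accurate and
non-negative as s → t.

The literature this family of schedules comes from does not fix endpoint
values; the linear form is the simplest shape satisfying smoothness, strict
monotonicity and the endpoint behaviour, and is deliberately not learned.

### Coordinate scaling

Coordinates in Angstrom are multiplied by `coord_scale = 0.1` before
diffusion and divided by it after sampling, so a typical complex has
order-one extent under the unit-variance prior. Variance matching of this
kind materially affects training; the value is a config constant, not a
learned quantity.

### Noise predictor

The noise prediction network eps_hat(z_t; t) has three stages:

1. **Input featurization.** Single representation: learned amino-acid
   embeddings (plus a LayerNorm + linear map of the optional PLM matrix,
   added to protein rows only) and summed embeddings of nine per-atom
   ligand features (atomic number, chirality, degree, formal charge,
   hydrogen count, radical electrons, hybridization, aromaticity, ring
   membership). Pair representation: relative-position embeddings of the
   residue-index offset clipped at ±32 for protein–protein pairs (pairs
   involving a ligand token use a dedicated "not applicable" bucket),
   block-type embeddings distinguishing protein–ligand and unbonded
   ligand–ligand pairs, and summed embeddings of three bond features on
   bonded ligand pairs (applied symmetrically). Gaussian radial-basis
   embeddings of the current inter-token distances (64 centers spanning
   0–30 Å) and a sinusoidal embedding of diffusion time (32 dimensions,
   frequencies geometric from 1 to 1000) are added to the representations
   at every denoising call, so the coordinate-dependent features track the
   latent state through the reverse process.
2. **Residual trunk.** `n_blocks` blocks, each applying pair-biased
   multi-head self-attention over tokens, a 4× transition MLP on the single
   representation, an outer-product update of the pair representation from
   the single representation, an optional triangular multiplicative update
   (outgoing edges) on the pair representation, and a 4× pair transition —
   all residual. Every branch's output projection is zero-initialized, so a
   freshly built block is the identity map; training grows the update away
   from zero. Desk-scale defaults: 2 blocks, c_s = 64, c_p = 32, 4 heads.
   The published-scale depth (12 blocks) is a configuration choice, not a
   separate code path.
3. **Equivariant head.** The final pair tensor is symmetrized as
   (P + Pᵀ)/2 over the token axes, mapped by LayerNorm → linear → ReLU →
   linear to a scalar weight matrix W (diagonal zeroed), and the noise
   prediction is the weighted sum of unit relative-difference vectors,

       eps_hat_i = sum_{j != i} W_ij / max(||z_i - z_j||, eps_d) (z_i - z_j),

   followed by centroid removal. `eps_d` (default 0.01 Å, converted to
   latent units) floors the denominator; coincident atoms occur routinely
   at high noise and produce a zero direction vector rather than a division
   by zero. W sees coordinates only through distances, so rotating and
   translating z rotates eps_hat exactly; the test suite holds this to a
   relative error of 1e-8 at float64 (measured ~1e-15).

Time conditioning enters once, additively, at featurization (not per
block). The template variant adds radial-basis embeddings of the template
Cα distance matrix to the protein–protein pair block; conditioning through
distances keeps the variant invariant to rigid motion of the template and
means two templates with equal distance matrices condition identically.

### NumPy implementation

The network, a small reverse-mode autodiff engine, Adam and EMA tracking
are implemented directly on NumPy float64 arrays (`plcdiff.nn`). The engine
supports exactly the operations the model needs (broadcast arithmetic,
fused LayerNorm/softmax, two-operand einsum contractions, embedding
lookup); gradients are verified against central finite differences in the
test suite. Double precision throughout is what makes the 1e-8
equivariance bound meaningful.

## Objective

Training minimizes the Monte Carlo estimator of the continuous-time
diffusion loss

    L = 1/2 E_{t ~ U(0,1), eps ~ N_x(0,I)} [ gamma'(t) ||eps - eps_hat(z_t; t)||^2 ],

with z_t = alpha_t x + sigma_t eps; gamma'(t) is constant for the linear
schedule. The squared error sums over x/y/z and averages over atoms, so
systems of different sizes weight equally in a mixed batch (a convention
choice; the source formulation does not state one). The discrete T-step
loss uses per-interval weights exp(gamma(t) - gamma(s)) - 1 — the sign that
makes each term equal the closed-form Gaussian KL divergence between the
true and model reverse transitions, an identity the tests verify term by
term at 1e-6 relative error.

One discretization property is worth recording: for a linear gamma the
discrete loss exceeds its continuous limit by the exact model-independent
factor (e^h - 1)/h with h = (gamma_max - gamma_min)/T — about 3.6% at
T = 256 for the default endpoints. The bias vanishes only as T grows or the
gamma range shrinks, and any schedule satisfying the endpoint contract has
gamma range > 13.8, i.e. at least a 2.7% bias at T = 256.

Prior KL and reconstruction NLL terms of the variational bound are
available in closed form on the 3(n-1)-dimensional subspace as diagnostics;
they contain no learnable parameter and are never backpropagated.

## Training protocol

Adam (beta1 = 0.9, beta2 = 0.999, eps = 1e-8) with the learning rate ramped
linearly from zero over the first 1000 steps; an exponential moving average
of the parameters with decay 0.999 is updated after every step, and the EMA
snapshot with the best validation loss is the set used at inference.
Validation noise and times are fixed at loop start (stratified t, seeded
eps) so model selection is not dominated by estimator variance. Diffusion
times within a training batch are stratified across [0, 1] by default
(`stratify_time`), a pure variance reduction of the same Monte Carlo
objective. Default mini-batch size is 4 at desk scale (the published-scale
value of 24 is a config field) and the default base learning rate is the
full-scale value 4e-4; the packaged desk-scale experiment raises it to
3e-3, which at toy problem size converges several times faster within the
same wall-clock budget (selected by validation loss among candidate rates
at a fixed short budget). Training is bit-reproducible given the config
seed.

## Sampling

Ancestral sampling discretizes time uniformly into T steps (default 250),
starts from the subspace prior and iterates

    z_s = z_t / alpha_{t|s} - (sigma_{t|s}^2 / (alpha_{t|s} sigma_t)) eps_hat(z_t; t)
          + sigma_{t->s} xi,

with xi a fresh subspace draw. The returned structure is the mean
z_0 / alpha_0 of the reconstruction distribution: its standard deviation
(sigma_0/alpha_0 ≈ 0.0013 latent units ≈ 0.013 Å) is negligible, and
returning the mean makes each frame a deterministic function of its seed.
Ensemble frames use independent child seeds spawned from the ensemble seed
and are exchangeable; per-frame seeds are recorded in the output manifest.

## Evaluation metrics

* **TM-score** on same-length Cα traces with correspondence by index
  (generated and reference proteins share the sequence, so no alignment
  step is needed — the reason a sequence-alignment dependency was dropped).
  d0 = 1.24 (L-15)^(1/3) - 1.8, clamped to ≥ 0.5 Å, which keeps the formula
  positive for chains of ≲ 21 residues. The maximization over
  superpositions seeds rigid fits from contiguous fragments (lengths L,
  L/2, L/4 and 4, all offsets) and refines each by iteratively re-weighted
  least-squares superposition with weights (1 + (d_i/d0)^2)^-2; because the
  TM kernel is convex in d^2 this iteration ascends the score monotonically
  to a fixed point. An exhaustive mode enumerating every fragment of length
  ≥ 4 serves as the oracle in tests.
* **L-rms**: the predicted frame is superposed on the reference using
  protein Cα atoms only, and the plain heavy-atom RMSD of the ligand is
  reported. No graph-automorphism correction is applied by default (the
  benchmark definition followed here does not mention one); atom
  correspondence is by index.
* Cohort curves report, per threshold, the fraction of complexes whose
  best ensemble frame passes (TM above / L-rms below), and
  subsample-performance curves average success over random k-subsets of
  frames at 2 Å and 5 Å cutoffs. Stratified summaries group per-complex
  success by a user-supplied annotation column.

## Synthetic data

The toy generator builds a rigid bead-chain protein — ideal helix (rise
1.5 Å, radius 2.3 Å, 100°/residue) or extended chain (3.8 Å spacing) — and
a small chain or ring ligand with exact 1.5 Å bonds anchored 4 Å outside a
designated mid-chain pocket residue. The only source of conformational
variability is a rigid isotropic Gaussian displacement of the ligand with
configurable standard deviation ("pocket jitter"), so the ground-truth
ensemble statistics (e.g. the ligand-centroid-to-pocket-residue distance, a
scaled noncentral-chi variable) are known and trained models can be scored
against them. Draws producing interatomic distances below 0.5 Å are
rejected and redrawn.

What the generator does **not** emulate: side chains, secondary-structure
variety, protein flexibility, chemically valid torsion sampling, or the
size and diversity of a curated complex database. Passing the recovery
tests therefore demonstrates that the training/sampling machinery can learn
a known joint distribution at desk scale — not that the desk-scale model
generalizes to real complexes.

## Problem sizes and numerical choices

The packaged experiments run on a single CPU in double precision. The
recovery experiment trains the desk-scale model (2 blocks, c_s 64, c_p 32)
on 2000 conformers of a 12-residue helix with a 4-atom ligand and jitter
1.0 Å, for 24 epochs of the 1600-conformer training split (9600 Adam steps,
roughly seven minutes on one CPU), then generates 200 frames with 100
sampler steps; the equivariance
suite uses 50 systems of 5–50 tokens; loss identities use T = 64 (KL
equality) and T = 256 (discretization bias); the point-mass sampler oracle
uses T = 250. Tie-breaks and degenerate cases: Kabsch always returns a
proper rotation (the smallest singular direction is flipped when the
optimum is a reflection); a single-token system lives in the trivial
subspace {0} and samples the origin; PDB altloc selection is by occupancy.

## Known limitations

* Desk-scale training on the toy task recovers local geometry tightly and
  the global fold only partially (ensembles remain more diverse than the
  generating distribution); published-scale depth, width and data are
  configuration away but not exercised here.
* Single protein chain and single ligand per complex; multi-chain input is
  an explicit error.
* Ligand L-rms uses index correspondence; symmetry-equivalent atom
  renumbering is not corrected.
* Likelihood estimation and binding-pose confidence scoring are out of
  scope.
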