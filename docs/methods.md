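# Methods

## The model

`pocketdiff` generates 3D ligands for a fixed protein pocket with a hybrid
denoising diffusion model whose reverse process is steered by a learned
binding-affinity "expert".

A molecule is an atom cloud M = [x, z] with coordinates x ∈ R^{N×3} (Å) and
type rows z ∈ R^{N×K} over a K = 8 element vocabulary
({C, N, O, F, P, S, Cl} plus a catch-all class). The pocket
P is a fixed typed atom cloud; no operation anywhere in the package moves a
protein coordinate.

**Forward corruption.** Coordinates follow a Gaussian chain with marginal
q(x_t|x_0) = N(√ᾱ_t x_0, (1−ᾱ_t)I); atom types follow a categorical chain with
uniform transitions (keep a label with probability α_t^cat, else resample
uniformly), giving the marginal ᾱ_t^cat z_0 + (1−ᾱ_t^cat)/K. Both chains are
defined in the pocket-centered frame produced by `center_complex`.

**Network.** A shared SE(3)-equivariant trunk φ_ω embeds the joint
pocket+ligand graph: invariant features h are updated additively with
attention-weighted messages f_h(d_ij, h_i, h_j, e_ij); coordinates are updated
additively along relative vectors (x_i − x_j) scaled by a learned scalar gate,
masked so only ligand atoms move. e_ij is one of four message-direction kinds
(ligand/protein × ligand/protein). On top of the trunk sit two heads: a
softmax type head producing ẑ_0 and a sigmoid affinity head whose per-atom
scores average into v̂ = (1/N) Σ σ(MLP(h_i)) ∈ [0,1]. Because every input to
h is invariant (distances, type embeddings, edge kinds, sinusoidal time
embedding), v̂ and ẑ_0 are SE(3)-invariant and x̂_0 is equivariant by
construction; the test suite asserts this at random initializations, not just
trained weights.

**The distillation target.** Ground-truth affinity is a self-contained
empirical oracle in the AutoDock-Vina family: five pairwise terms of the
surface distance d_s = ‖x_i−x_j‖ − R_i − R_j (two Gaussians, quadratic
repulsion for d_s < 0, a hydrophobic ramp and a hydrogen-bond ramp, gated by
element-level flags), summed over ligand–protein pairs within an 8 Å cutoff
with the published Vina weights, divided by (1 + 0.05846 · N_rot) where N_rot
counts single acyclic bonds between non-terminal heavy atoms. The raw score
is mapped to v ∈ [0,1] by a clipped affine min–max normalization (strictly
decreasing: larger v = stronger binding). Chemistry flags are element-level,
not environment-aware — the oracle is a distillation target and ranking
signal, not a docking replacement.

**Joint loss.**

    L = ‖x_0 − x̂_0‖² + γ·KL(q(z_{t−1}|z_t,z_0) ‖ q(z_{t−1}|z_t,ẑ_0)) + λ(v − v̂)²

with γ = 100, λ = 1 by default. With λ = 0 the affinity head receives exactly
zero gradient and the model reduces to a plain pocket-conditioned denoiser;
this degeneracy is asserted in the tests.

**Guided sampling.** At each reverse step the affinity prediction is treated
as a classifier probability p(bind|x_t, z_t, t, P) := v̂ and one backward pass
yields both guidance signals:

* coordinates: x_{t−1} ~ N(μ̃_t + s·β̃_t·∇_{x_t} log v̂, β̃_t I) — the standard
  classifier-guided mean shift on the DDPM posterior;
* types: z′_t = (z_t + δ)·exp(r·∇_{z_t} v̂) elementwise, then z_{t−1} is
  sampled from the categorical posterior evaluated with z′_t in place of z_t.
  The δ > 0 offset lets gradient signal reach the zero entries of a one-hot
  row, and z′_t stays strictly positive by construction.

The asymmetry — log-gradient for coordinates, raw probability gradient for
types — is deliberate and the literal form of the guidance scheme;
`NetworkConfig.log_type_grad` harmonizes them if desired. With s = r = 0 the
sampler is bit-identical to the unguided reverse process under a shared seed:
guidance never consumes random draws. Within one step, type guidance is
applied before the coordinate step; both reuse a single network evaluation at
the incoming state.

**Choosing the guidance scales.** Defaults are s = 0.3 with the coordinate
gradient scaled to unit RMS (`normalize_grad=True`), r = 10, δ = 0.01.
Normalization gives the mean shift fixed displacement semantics — each step
moves atoms by at most s·β̃ Å along the expert's uphill direction — which
matters because the raw gradient magnitude of a trained expert varies
several-fold between training runs; a raw scale tuned for one model
overshoots for another. The scale itself was calibrated on development
pocket sets disjoint from the benchmark protocol's: predicted affinity v̂
rises monotonically with guidance strength, but the *oracle* score of the
generated molecules peaks at a moderate total displacement and collapses
beyond it, where the cumulative shift drags atoms into steric clash (the
distilled expert inherits the "more protein neighbors = better" pattern of
its labels, and strong guidance drives states off-distribution where that
pattern stops being true). This is the standard classifier-guidance strength
trade-off; re-calibrate when the expert, the corpus or the chain length
changes. `normalize_grad=False` recovers the literal unnormalized shift.

## Numerical and engineering choices

* **Autodiff.** The network, training and guidance gradients run on a small
  in-house reverse-mode engine over float64 numpy arrays (`autodiff.py`).
  Activations are smooth (SiLU/tanh/sigmoid) throughout, so analytic
  gradients agree with central finite differences (step 1e-4) to better than
  1e-3 relative error, which the acceptance suite checks directly.
* **Graph.** k-nearest-neighbor graph (k = 16 full scale, 12 desk scale),
  symmetrized, ties broken by atom index; neighbor lists are frozen at the
  input geometry for stability while distances are recomputed every layer.
  Distances use a 1e-10 floor inside the square root; coordinate gates divide
  by (d + 1) to bound per-step displacements.
* **Noise schedule.** Sigmoid β ramp for coordinates and cosine-style
  keep-probabilities for the categorical chain, T = 1000 by default. The ramp
  is calibrated so Σβ ≈ 5, i.e. ᾱ_T ≈ 7·10⁻³ < 0.01 — the terminal marginal
  must be essentially the standard normal the sampler initializes from. For
  shorter chains the β ramp is rescaled ∝ 1000/T so this property is
  T-independent.
* **Posterior edge cases.** β̃_1 = 0 exactly (the t = 1 reverse step is
  deterministic and guidance has no effect there); categorical posteriors
  normalize soft ẑ_0 internally and reject zero-mass rows; KL floors the
  second argument at 1e-12. Type-guidance exponents are clipped at |50| to
  prevent overflow, with a logged warning.
* **Determinism.** All stochastic operations take an explicit
  `numpy.random.Generator`; training is bit-reproducible for a fixed seed on
  one thread, and checkpoints serialize parameters, schedule and vocabulary
  together so sampling is reproducible from a checkpoint alone.
* **Bond reconstruction.** Generated atom clouds get bonds by a
  covalent-radius rule (bond if d < r_i + r_j + 0.45 Å) accepted
  shortest-first under per-element valence caps, so over-coordinated atoms
  shed their longest bonds. Disconnected outputs are allowed but logged.

## The synthetic data generator

Real training corpora (docked protein–ligand complexes) are far beyond a
desk-scale test budget, so every experiment here runs on synthetic complexes:
pocket atoms sampled on a spherical-cap shell (radius 8 Å ± 0.75, covering a
`concavity` fraction of the solid angle, default 0.75), and a ligand grown as
a 1.5 Å-step random walk from the cavity center, rejection-sampled to stay
≥ 3.2 Å from every pocket atom — the van der Waals contact regime where the
oracle's attractive terms dominate. Datasets jitter pocket size (24–72
atoms), cavity radius (±~25 %), concavity and ligand size (4–11 atoms) so the
oracle labels vary for real geometric reasons; a 1-NN regressor on mean
ligand–pocket distance alone reaches Pearson r > 0.3 on the labels, which the
tests assert as a floor on learnable signal.

Because these toy complexes score about −2..0 kcal/mol (an order of magnitude
weaker than real complexes), the fixture label normalizer uses bounds
(lo, hi) = (−2.5, 0) matched to that range; the general-purpose default
(−12, 0) sized for experimental score ranges would compress all labels into a
few percent of [0,1].

The generator can also emit *decoy* poses (`decoy_fraction` /
`decoy_contact`): the finished ligand is slid into the shell until its
closest pocket contact reaches 1.8–3.0 Å, yielding clashed, near-zero-labeled
complexes like the poor poses of docked corpora. This is off by default: in
desk-scale experiments decoys halved the label variance the expert could
actually predict across noise levels (pose-dependent label variance is
unrecoverable from heavily corrupted states) without measurably teaching the
network the repulsive wall, so the standard corpus contains only comfortable
poses and clash avoidance is handled by the guidance-scale calibration above.

What the fixtures do **not** emulate: residue chemistry, protonation,
torsional strain, realistic element frequencies at binding sites. Passing
tests therefore demonstrate that the machinery — distillation, invariances,
guidance — works as specified, not that the model attains publication-scale
affinity on real proteins.

## Desk-scale study conditions

The benchmark protocol (`pocketdiff.benchmark`, also run by
`scripts/acceptance.py`) uses sizes chosen for statistical resolution at a
few minutes of single-CPU runtime:

* corpus: 50 labeled complexes; network: L = 2 layers, D = 64, k = 12,
  T = 100; training: 200 epochs, Adam lr 1e-3, clip norm 10, seed-fixed.
* expert evaluation: each complex corrupted to 10 equally spaced timesteps
  across the chain; Pearson correlation of v̂ against v over all pairs.
* guidance evaluation: 32 fresh pockets, 2 guided + 2 unguided samples per
  pocket with a shared per-pocket seed (paired design), mean per-pocket
  oracle scores compared by a one-sided sign test; the pocket's own fixture
  ligand provides the reference score for the high-affinity fraction.

## Known limitations

* The expert is trained and evaluated on the same synthetic corpus — the
  protocol measures whether joint training can distill the oracle across
  noise levels at this scale, not out-of-distribution generalization.
* The atom-count prior for generation (shifted Poisson, mean 0.08 per pocket
  atom, clamped to [4, 60]) is a stand-in; nothing calibrates it to real
  ligand-size distributions.
* Uniform-transition categorical diffusion ignores chemically informed
  transition structure; coordinates and types are corrupted independently.
* The oracle's element-level chemistry flags cannot express directional
  hydrogen bonds, salt bridges or π-stacking.
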