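# Methods

`stmalign` models how an embodied agent can bootstrap a grounded,
cross-modal representation system while learning to act — without any
extrinsic reward or pre-given semantics. This note documents the model,
its assumptions, the numerical choices, and what the tests do and do not
establish.

## The model

### Topological maps and the shared internal space

Each modality (retinal vision, touch, proprioception, and the motor
*policy* space) is represented by a grid of K = G² prototype vectors,
the nodes of which sit on the integer lattice {0..G−1}² — the 2-D
*internal space* common to all maps. The unsupervised objective is the
classic self-organizing-map energy

    L = 1/2 Σᵢ Σⱼ φᵢⱼ ‖xᵢ − cⱼ‖²,   φᵢⱼ = exp(−‖gⱼ − g_{r(i)}‖² / 2σ_r²),

with r(i) the winning (nearest-prototype) node of pattern i and g the
node positions. The supervised variant multiplies φ by a second radial
factor centred on an externally supplied *anchor* position tᵢ,

    φᵢⱼ = exp(−‖gⱼ − g_{r(i)}‖² / 2σ_r²) · exp(−‖gⱼ − tᵢ‖² / 2σ_t²),

which confines where in the grid a pattern may be represented. Training
several maps with a shared anchor per tuple of co-occurring patterns
aligns their manifolds: afterwards one internal point simultaneously
indexes a visual state, a touch state, a posture and the policy that
produces them.

Prototypes are updated with the batched delta rule (the gradient of L
with respect to cⱼ, normalized per node):

    cⱼ ← cⱼ + η · Σᵢ wᵢ φᵢⱼ (xᵢ − cⱼ) / max(Σᵢ wᵢ φᵢⱼ, 1e−8),

where wᵢ ∈ [0, 1] are per-sample weights (see the intrinsic signal).

A pattern is summarized in the internal space two ways: the full grid
activation aⱼ = exp(−‖gⱼ − g_winner‖²/2σ_r²), and a single continuous
point — the activation-weighted centroid of the node positions. The
inverse mapping regenerates a modality pattern from any internal point
as the radial-basis weighted average of prototypes around it; this one
primitive serves both policy generation and sensory re-enactment.

### The intrinsic signal

At every timestep of an episode the agent computes the mean Euclidean
distance ξ̂ between the internal points of its three sensory modalities
plus the executed policy, and the point encoding the policy *selected*
at the episode start:

    ξ̂ = (Σᵢ ‖x_sᵢ − x̂_π‖ + ‖x_π − x̂_π‖) / (N_s + 1),
    ξ = exp(−ξ̂² / 2σ_ξ),     δ_t = ξ_t − ξ_{t−1},
    ψ_t = ξ_t if δ_t > th_δ else 0.

ψ fires only when representations have just *converged* — read as
evidence that the current policy is causally responsible for the sensory
change (a motor-sensory contingency). ψ_t·(1−c_k) is the sample weight
of that timestep's patterns in the map update. Note that σ_ξ enters the
exponent unsquared; this follows the defining expression as stated, and
σ_ξ is exposed in the configuration. At t = 0 there is no predecessor,
so δ₀ := 0 and ψ₀ = 0.

### Competence

A logistic regressor over quadratic features (x, y, x², y², xy, 1) of an
internal point predicts the probability that the policy encoded there
reproduces its sensory effects. Coordinates are rescaled by the grid
extent to [0, 1] before the feature expansion so plain gradient steps
remain well-conditioned. Its per-episode training target is the best
radial closeness reached during the episode (max_t ξ_t by default;
mean ξ and mean ψ are available via `target_stat`).

Competence modulates learning three ways:

* **global**: C_tot, the mean prediction over all policy-map nodes,
  sets the epoch learning rate η = η_max − C_tot (η_max − η_min);
* **local**: episode k's samples are scaled by (1 − c_k), focusing
  learning where competence is still low;
* **exploration**: the executed policy is π̂ plus Gaussian noise of
  standard deviation σ_explore (1 − c_k) per parameter, so mastered
  policies are exploited verbatim.

The predictor's bias is initialized to −2 (predicting ≈ 0.12): a fresh
agent predicts low success probability until experience indicates
otherwise. A zero-weight logistic (0.5 everywhere) is not a neutral
prior for a success probability and would pin the early competence curve
to 0.5.

### The world

A planar 3-joint arm (links 0.4/0.3/0.2 in a [−1,1]² workspace) ends in
a two-fingered gripper whose fingers mirror one shared (opening, curl)
command — 5 controlled degrees of freedom. Joints servo toward commanded
angles at most 0.2 rad per step. One object per episode, from three
categories: *fixed* (small blue-dominant quadrilateral; never moves),
*movable* (big red-dominant triangle; pushed on contact, never grasped),
*graspable* (small green-dominant quadrilateral; pushed, and locked to
the gripper when both fingers' inner sensors touch it while closing).
Sensing: 5 normalized joint angles; 40 binary touch sensors (5 per
phalanx side, inner and outer, both fingers; contact tolerance 0.01);
a 10×10×3 retina cropped (window 0.3) around the saliency argmax; a
20×20 saliency map with a Gaussian blob (σ = 0.1) at the object centroid
or, with no object, the gripper tip. Dynamics are kinematic and fully
deterministic: no forces, friction or inertia. The three category
affordances — which is what drives learning — are preserved exactly.

### Control and the training loop

A policy is the 515-dimensional weight vector of the online controller:
45 inputs (proprioception + touch) → 10 tanh hidden units → 5 outputs.
The gripper joints are driven entirely by the network; the arm command
is a hardwired reach target (damped-least-squares inverse kinematics
toward the salient point, seeded at the current posture) plus a network
correction bounded to ±0.2 rad. This separates learning to manipulate
from learning to reach. The retina does not feed the online controller;
discriminative vision acts through the offline layer at policy
selection.

The maps operate on a unit-box image of the policy space; raw weights
are the fixed affine image (pattern − ½)·gain with gain 2.0. The gain is
chosen so that policies span the behavioural repertoire: much smaller
gains leave every network's tanh pre-activations near zero, all policies
then command the same mid-range gripper posture, and no grasp can occur.

Each epoch: measure C_tot, run 24 episodes of T = 50 steps with frozen
maps (per episode: forward-map the initial retina, inverse-map that
point through the policy map to select π̂, add competence-scaled noise,
execute), then update all four maps — sensory maps with all timesteps'
patterns, weights ψ_t (1 − c_k) and the selected policy's point x̂_π as
anchor; the policy map with the 24 executed policies, anchored the same
way, weighted by the episode-mean ψ · (1 − c_k), since the policy
contributes one pattern per episode rather than one per timestep —
and finally refresh the predictor (30 gradient steps on the 24
episode outcomes).

## Parameters

| parameter | default | meaning |
|---|---|---|
| G | 10 (tests: 6) | grid side; internal space is [0, G−1]² |
| σ_t | 1.5 grid units | anchor width of the supervised factor |
| σ_r | G/2 → 0.8 | update neighborhood width, annealed |
| anneal_fraction | 0.25 | fraction of epochs spent annealing σ_r; the rest fine-tunes at 0.8 |
| σ_readout | 0.8 | width used when reading maps during episodes |
| σ_ξ | 0.5 | radial width of ξ (distances in grid units) |
| th_δ | 0.01 | increment threshold of the contingency gate |
| η_min, η_max | 0.02, 0.5 | learning-rate endpoints vs C_tot |
| σ_explore | 0.15 | exploration noise scale (policy-pattern units) |
| episodes/epoch, T | 24, 50 | epoch structure |
| epochs | 300 (tests: 40) | training length |

Two widths deserve comment. The annealed σ_r is a *training* parameter
(Kohonen's ordering-then-convergence schedule: the long convergence
phase at small σ_r is what differentiates prototypes within an anchor
region; without it they remain near-clones and winner selection within a
region is arbitrary). The *representation* read out during episodes uses
the fixed σ_readout = final σ_r: with the annealed width, the
activation-weighted centroid compresses every point toward the grid
centre early in training, which would make internal distances (and so ξ
and competence) artifacts of the schedule rather than measurements of
alignment.

All sensory channels are natively bounded in [0, 1] (normalized angles,
binary touch, color values), so patterns enter the maps with those fixed
bounds; a running min-max scaler is available for inputs without known
bounds. Cross-modal commensurability does not depend on this: only
internal-space distances (grid units) are ever compared across
modalities.

## Numerical choices

* Winner ties break to the lowest node index (determinism).
* Per-node update normalization floor 1e−8; activations below 1e−12 are
  treated as zero in centroid and inverse mapping; a fully underflowed
  inverse query returns the nearest node's prototype with a degenerate
  flag.
* Internal points are validated to lie in the closed grid box.
* k-means (k = 5) uses 10 restarts with a seeded state; PCA-RGB
  rescales each of the first three components to [0, 1]; a
  zero-variance map renders mid-gray with a flag.
* One seeded generator threads through map init, environment sampling
  and exploration noise; identical seeds reproduce runs bitwise.

## What the synthetic generators emulate

`fixtures.make_paired_dataset` produces paired observations of a known
2-D latent through smooth injective embeddings (affine + bounded
sinusoidal warp) plus Gaussian noise — a stand-in for
environment-generated multimodal experience with ground truth attached.
It captures the geometric core of the alignment problem (several
modalities driven by one latent cause) but none of the temporal,
behavioural or contact structure of real interaction: no policies, no
contingency gating, no category affordances. Tests passing on it show
the supervised-map machinery aligns manifolds when a shared latent
exists; they do not show that the full closed-loop system discovers such
latents — that is what the manipulation-world runs are for.

## Scaled-down study conditions

The test suite and analyses run the manipulation world at G = 6,
40 epochs × 24 episodes × 50 steps, three seeds (the full-scale profile
is G = 10, 300 epochs). At this scale, the expected signatures are: the
global competence curve rises from its pessimistic prior and flattens;
per-map change decays to a small fraction of its peak (touch is the
least stable, as its effective dataset — timesteps with contact — is the
smallest); episodes of the three object categories occupy separable
regions of the internal space; and re-enacted visual prototypes
round-trip through their own node. The measured competence gain at this
scale reflects both the predictor learning the achievable closeness
level and a modest improvement of that level itself; desk-scale runs are
too short for the strong late-stage convergence a full-scale run can
exhibit.

## Known limitations

* The kinematic contact model resolves pushes with a fixed displacement
  per contacted step along the centroid direction; glancing contacts and
  torque are not modelled, and object orientation never changes from
  pushing.
* Proprioception carries the arm posture, which depends on object
  *position* (not category); its representations therefore converge more
  slowly than touch or vision, and a residual distance floor remains.
* The cross-modal cluster composition (k-means over concatenated one-hot
  per-map cluster indicators) is one reasonable construction of a
  "linear composition" of per-map clusterings; alternatives (e.g.
  clustering stacked prototype features) would be defensible too.
* Goal selection is exogenous (stimulus-tied) only; curiosity-driven
  endogenous goal sampling is out of scope.
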