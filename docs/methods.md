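# Methods

## The model

The arm is a planar two-link chain (shoulder, elbow) moving in the
para-sagittal plane under gravity, with the shoulder at the origin of an
(x, z) frame: x antero-posterior, z vertical.  Joint angles are measured
counterclockwise, q1 from the +x axis to the upper arm and q2 from the
upper-arm extension to the forearm.  Rigid-body dynamics take the
manipulator form

    M(q) q̈ + C(q, q̇) q̇ + G(q) + B q̇ = τ,

with the standard two-link closed forms for the inertia matrix M, the
Coriolis matrix C (in the convention that makes Ṁ − 2C skew-symmetric),
the gravity vector G, and a constant symmetric viscosity matrix B.
Torques are generated smoothly by muscle contraction, modeled as a
double integrator on each joint torque: the control is the torque
acceleration, u = τ̈, and the state is (q, q̇, τ, τ̇).

Anthropometric defaults follow Winter-style regressions from body mass
70 kg and stature 1.75 m (segment masses 0.028·Mb and 0.022·Mb, lengths
0.186·H and 0.254·H, COM fractions 0.436 / 0.682, gyration-radius
fractions 0.322 / 0.468; the distal segment lumps forearm and hand).
Viscosity defaults to B = [[0.05, 0.025], [0.025, 0.05]] N·m·s/rad, a
common arm-model value.  All parameters are configurable; joint limits
default to q1 ∈ [−π/2, π], q2 ∈ [0, 2.8] rad and the command bound to
|u| ≤ 10⁴ N·m/s², enforced as soft penalties in the solver.

## Movement costs

Eight candidate cost functionals from the motor-control literature are
integrated over the fixed movement duration T: squared fingertip jerk
(hand smoothness), squared joint jerk and squared joint acceleration
(joint smoothness), squared torque change, squared torque, the geodesic
path length √(q̇ᵀM(q)q̇) under the kinetic-energy metric, the total
absolute work Σᵢ|τᵢ q̇ᵢ| (mechanical energy actually spent), and the
squared neural command ‖u‖².  Composites are non-negative weighted sums
Σ αᵢ sᵢ Cᵢ, where s is a fixed re-scaling vector making the
differently-dimensioned costs commensurate (sᵢ = 1/median single-cost
optimum over a reference task set, so rescaled single-cost optima are
O(1)).

The two nonsmooth integrands are regularized: √(·+ε) for the geodesic
and √((·)²+ε²) per joint for the absolute work.  Both converge to the
exact value from above as ε → 0; the solver anneals ε over the schedule
10⁻² → 10⁻⁴ → 10⁻⁶ (SI-scaled) with warm starts, and reported costs use
the final ε.

## Direct optimal control

The task: steer the arm from a rest posture q0 to the vertical bar at
horizontal distance d (85% of arm length by default) in fixed time T
(default 0.7 s), at rest on arrival, minimizing the composite cost.
Rest means zero velocity and zero acceleration — equivalently τ = G(q) —
at both ends; the torque rate τ̇ is left free at both ends, since the
target manifold constrains only velocity and acceleration.  The endpoint
height on the bar is free (the task redundancy), bounded by the
intersection of the bar with the shoulder-centred circle of radius
L = l1+l2.

Because the control is u = τ̈, the system is differentially flat in the
joint path: q(t) and its derivatives up to fourth order determine every
state and the control through the inverse dynamics and its first two
time derivatives (implemented in closed form and verified against
finite-difference oracles).  The solver therefore parametrizes each
joint angle directly on s = t/T:

    qᵢ(s) = q0ᵢ + (qTᵢ − q0ᵢ) h(s) + Σₖ cᵢₖ s³(1−s)³ Lₖ(2s−1),

with h the quintic smoothstep and Lₖ Legendre polynomials
(k = 0 … K−1, default K = 8).  Every coefficient vector satisfies the
dynamics exactly and meets the rest boundary conditions by construction,
so the OCP becomes a smooth bound-constrained minimization over
(c, z_f) — z_f being the endpoint height for bar targets, mapped to the
terminal posture by inverse kinematics.  Costs are integrated by
Gauss–Legendre quadrature at `nodes` points (default 40); gradients are
forward differences evaluated in a single batched call; the optimizer is
L-BFGS-B with multi-start (3 perturbed initial guesses) on failure.  The
initial guess is the joint-space smoothstep to the bar point at the
start height.

Numerical behaviour worth knowing:

- The quadratic costs are quadrature-converged to well below 0.1% at
  40 nodes; the absolute-work integrand has kinks at power zero
  crossings and converges more slowly (≈0.4% change when doubling nodes
  from 40), and possesses families of near-equivalent optima (timing
  along the path is weakly determined), so cold starts at different
  resolutions may land in slightly different minima.
- Near the workspace boundary (endpoints approaching full arm
  extension) the finite joint-space basis cannot represent the
  inverse-kinematic image of straight Cartesian paths; endpoint-sweep
  costs within ~20% of the region edge carry extra representation
  error.
- The hand-jerk point-to-point solution reproduces the analytic quintic
  (720·D²/T⁵, peak/mean speed 15/8) to <0.1% in cost and <1 mm in path
  at default settings — the solver's primary oracle.

## Inverse optimal control

Given per-posture reference trajectories (trial-averaged and
time-normalized to 200 samples), the bi-level fit searches the weight
vector whose optimal trajectories best match the references.  Since
scaling all weights leaves the optima unchanged, one component is
anchored at 1 — the angle-acceleration weight by default.  The path
metric is

    metric(sim, ref) = mean‖p_sim − p_ref‖ + λc·|sIPC_sim − sIPC_ref|·chord,

i.e. mean Cartesian fingertip distance plus a curvature-mismatch term
scaled to metres (λc = 1 by default); the fit objective Φ sums the
metric over postures.  Φ is an inner optimum obtained numerically, hence
noisy and possibly non-differentiable in the weights; the outer search
uses COBYQA, a bound-constrained derivative-free trust-region method
with quadratic local models, with the trust region floored at 10⁻³ of
the weight scale, a budget of inner solves per restart (default 150),
and restarts from all-ones plus random non-negative points.  Inner
solves are warm-started from neighbouring outer iterates; the reported Φ
is recomputed from scratch at the returned weights.

Weight identifiability has a known degeneracy: different weight mixtures
(notably within the torque/torque-change/effort family) can produce
near-identical trajectories, so Φ has flat valleys.  Two measures
address it.  First, a sparsification pass after the search: components
are tentatively zeroed (smallest first) and the zero is kept whenever Φ
does not worsen beyond inner-solver noise (2% relative + 10⁻⁵ m) — an
Occam tie-break among path-equivalent weight vectors, mirroring the
observation that irrelevant weights end exactly at the lower bound.
Second, a flag is raised when a fitted weight ends at the upper bound,
the signature of an inappropriate anchor choice (the anchored cost being
absent from the true composite); the remedy is to re-run with a
different anchor.  Even so, recovery of a *pure* non-anchored cost from
path data alone is not always unique — the package's tests therefore
validate exact recovery for the anchored cost and joint
energy+smoothness recovery for the hybrid composite, and treat
torque-family mixtures as the documented identifiability limit.

## Motion analysis

Recorded (or synthesized) fingertip series are low-pass filtered with a
zero-phase 5th-order Butterworth at 10 Hz (forward-backward, so the
effective attenuation order doubles), windowed between the first upward
and last downward crossing of 5% of peak tangential speed (robust to
multiple crossings), and resampled to 200 points with cubic splines.
Note the 5% window systematically trims the slow tails of bell-shaped
profiles (a quintic loses ~14% of its nominal duration); all
duration-dependent features are defined on the windowed movement.

Features: movement duration, peak and mean speed and their ratio (1.875
for the quintic), relative time to peak, curvilinear distance
(integrated on the filtered grid), reached point normalized by arm
length, movement-vector angle (counterclockwise from horizontal), the
signed index of path curvature (max chord deviation / chord length,
positive above the chord; the side convention uses the chord normal with
positive z component), constant and variable endpoint errors, the
endpoint consistency index (endpoint z SD / reachable-region length),
and shoulder-elbow coupling (R² of the linear elbow-on-shoulder fit on
the normalized window).  The area between two paths is estimated by
Monte-Carlo point-in-polygon sampling over the joint bounding box
(deterministic given a seed, standard error reported), with endpoint
gaps below 1 cm closed by straight segments.

## Synthetic data

The generator emulates the study protocol: five rest postures spanning
start points below, level with and above the shoulder; bar at 85% of arm
length; 0.7 s movements sampled at 100 Hz; 20 trials per posture.
Trial-to-trial structure: endpoint jitter on the bar with vertical SD
0.03 m and antero-posterior SD 0.01 m (the empirical 3:1 anisotropy),
either re-solving the fixed-endpoint OCP per trial or smoothly warping
the nominal solution (cheaper); smooth within-trial joint perturbations
on sine half-waves vanishing at both ends (amplitude scaled to ~5 mm at
the fingertip); duration scaling with CV 0.1.  The reference per posture
is the trial average after time normalization.

What the generator does *not* emulate: measurement noise spectra of
motion capture, marker soft-tissue artifacts, out-of-plane motion,
muscle-level variability, and any trial-to-trial learning.  Passing
recovery tests on these data therefore demonstrates the correctness and
self-consistency of the pipeline — generator, solver, metric, fit — not
that the same weights would be recovered from real recordings.

## Problem sizes used in tests and scripts

Tests and analysis scripts run at 25–30 quadrature nodes and basis size
6 (solution quality changes by <0.5% versus the 40-node default), with
inverse-fit budgets of 100–150 inner solves and 2–3 restarts, and
Monte-Carlo areas at 4×10⁴–10⁵ samples.  These sizes were chosen so the
full pipeline — including two bi-level fits — completes on a single CPU
in minutes while leaving every tested property comfortably resolved.
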