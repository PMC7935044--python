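# Methods

This note records the models the package implements, the defaults that
matter, what the synthetic generators do and do not emulate, and the
numerical choices made where the design was genuinely open.

## Generative model

All machinery addresses the linear stochastic differential equation

```
dx/dt = J x + C u + omega_x,     E[omega_x(t) omega_x(s)'] = 2 Gamma delta(t-s),
y     = k * x + omega_y,
```

with `J` the N x N Jacobian (directed effective connectivity, Hz), `Gamma`
a diagonal diffusion amplitude, `C` the effect of exogenous inputs `u`,
`k` a linear convolution kernel (hemodynamic-like), and white observation
noise `omega_y`, sampled at a repetition time TR.

The diffusion convention `2 Gamma delta` is fixed so that a scalar
Ornstein–Uhlenbeck process has stationary variance `Gamma/kappa`
(variance proportional to the characteristic time constant) and the
equilibrium identity `J = -Gamma Pi` holds exactly for symmetric `J`.

## Jacobian estimation

With matrix derivative and convolution operators `D` and `K` that commute,
the model linearizes to `D y = y J' + omega` with
`cov(omega) = gamma_1 K K' + gamma_2 D D' + gamma_3 I`. Each row of `J`
(one state's incoming couplings) is fit independently: an exact Gaussian
conditional posterior given the noise hyperparameters, alternating with
Fisher-scoring updates of log-hyperparameters under log-normal priors,
maximizing a variational free-energy bound (accepted steps only, so the
bound is nondecreasing; convergence at 0.01 nats or 64 iterations).

Numerical and statistical choices, each load-bearing:

* **Circulant operators.** `D` and the kernel matrices are periodic
  (circulant), so they commute exactly and are jointly diagonal in the
  discrete Fourier basis; the per-row scheme costs O(T N^2) per iteration
  instead of O(T^3). Interior rows of `D` equal ordinary finite
  differences.
* **Forward difference.** `D` is one-sided, `(y[t+1]-y[t])/TR`. A centered
  difference regressed on its midpoint estimates only the irreversible
  part of the drift — its conditional expectation given `y[t]` is
  `(e^{J dt} - Sigma e^{J' dt} Sigma^{-1})/2dt` — and is therefore blind
  to the time-symmetric component of `J`. The forward difference is the
  Euler/Ito drift estimator and identifiable.
* **Flat moment equations.** The reported posterior uses unweighted
  time-domain moments with the fitted marginal noise variance. Because the
  design contains the process's own past, only the flat weighting
  preserves the exactness of the one-step drift moment; frequency-domain
  whitening correlates the effective design with the process noise and
  measurably biases null couplings. The weighted variational scheme still
  supplies hyperparameters, free energy and convergence, and on noiseless
  data both posteriors coincide with generalized least squares.
* **Indefinite kernel cross-terms.** The cross components
  `kappa_i kappa_j K_i K_j'` are replaced by the positive-semidefinite
  stack `{K_i K_i', (sum K_i)(sum K_i)'}` with independent nonnegative
  (log-normal) hyperparameters, spanning the same space while keeping
  every component a valid covariance.
* **Priors.** Couplings: Gaussian, mean 0 (diagonal -0.5 Hz,
  stability-encouraging), variance 4 (sd 2 Hz, weakly informative).  The
  prior width is the reference measure of the Bayesian-model-reduction
  Occam factor: with a much tighter prior the fixed 3-nat rule cannot
  discriminate null from true couplings at desk-scale information.
  Log-hyperparameters: mean -2, variance 4.
* **Discretization.** The forward-difference GLM estimates
  `(e^{J TR} - I)/TR`; an optional matrix-log correction inverts this map
  but is off by default because it amplifies estimation noise through the
  near-singular directions of the transition matrix more than it removes
  path bias.

Sparsification then proceeds by closed-form Bayesian model reduction:
couplings beyond a hard 32-mm mirrored distance are excluded a priori
(homologous pairs exempt; homology = mirrored distance under one voxel
spacing); reciprocal pairs are removed when the summed evidence gain for
removing both directions reaches 3 nats (a 20:1 odds ratio), decisions
evaluated against the unpruned posterior so they are order-independent;
and a sweep of distance-limited models reports an evidence profile over
radii, the winner being the smallest radius within 0.5 nats of the best
(Occam preference among ties).

## Particular partition

The adjacency convention is `A_ij = 1` iff `|J_ij| > 1e-6` Hz off the
diagonal, i.e. `j -> i`, matching `J_ij = d(dx_i/dt)/dx_j`; self-decay is
not an edge. The blanket-forming matrix `B = A + A' + A'A` marks parents,
children and co-parents (the moral-graph neighborhood). Particles are
grown greedily:

1. Among *eligible* states — those whose entire B-row is still
   unassigned — seed with the largest graph-Laplacian degree
   (`W = |J| + |J|'`, ties to the lowest index).
2. Grow the internal set up to `n_internal` with eligible states whose
   coupling to the seed exceeds the median of the seed's nonzero
   couplings.
3. The blanket is the union of the internal set's B-rows, restricted to
   unassigned states.
4. Repeat; when no eligible internal candidate remains, leftover states
   (necessarily blanket members of earlier particles' neighborhoods) form
   blanket-only particles, one per connected component.

The eligibility rule resolves an ambiguity in the grouping procedure in
favor of correctness: every internal-bearing particle satisfies the
blanket condition *by construction*, which is what the brute-force
Gaussian oracle verifies (zero partial correlation between internal and
external states given the blanket, computed from the stationary
precision). Blanket states are sensory iff they receive an edge from
outside their particle, else active; labeling is idempotent and
permutation-equivariant.

## Renormalization group

One blocking step composes grouping (the particular partition) with
reduction: internal states are eliminated (they do not couple particles),
each particle's blanket Jacobian is eigendecomposed, and modes with
`Re(lambda) > -1` Hz are retained (decay slower than a second — the
adiabatic approximation), capped at `max_modes` without ever splitting a
complex-conjugate pair; if nothing qualifies the slowest mode is kept.
Eigenvector phase is fixed by making each column's largest-modulus entry
real positive (eigensolvers are phase-arbitrary; this makes reruns
bit-identical). The left inverse is the pseudo-inverse, so
`xi^- J(b,b) xi = diag(lambda)` holds to machine precision on retained
modes. Because only slow modes survive, the mean decay rate is
nondecreasing in scale; the model records this and warns if violated.

Eigenmodes chain back to the base scale (`nu = xi^(1) xi^(2) ... `),
giving each coarse eigenstate a voxel-space pattern. Particle centers are
probability-weighted positions under `softmax(|nu|/temperature)`
(temperature defaults to the std of `|nu|`; a constant mode gives the
uniform distribution, the zero-temperature limit the argmax voxel), and
homologous distances fold the hemisphere axis about the mid-plane.

Per scale, `sigma_tau` is the mean time constant `-1/Re(lambda)` over
retained stable modes (unstable modes stay in the model but are excluded
from the mean and counted), and `sigma_ell` the mean effective linear
extent `(voxel_volume x participation ratio of |nu|^2)^(1/3)`; a
`|nu|`-weighted caliper width is available as an alternative since the
dispersion measure is not uniquely determined by the flow. Ordinary least
squares of `ln sigma_tau` on `ln sigma_ell` gives the scaling exponent
`alpha`; per-step geometric factors anchor the extrapolation
`sigma(i) = sigma(0) f^i` to unmeasured scales.

Voxel-level series are reduced to first-scale states by greedy
variance-ranked grouping: the largest-variance unassigned voxel seeds a
group of all unassigned voxels within 4 mm; the group's first
eigenvariate (SVD, sign fixed positive on the seed voxel) becomes the
state and its loading the base eigenmode.

## Steady-state dynamics

For stable `J`: transfer functions `T(f) = (2 pi i f - lambda)^{-1}` per
mode; stationary covariance from the Lyapunov equation
`J Sigma + Sigma J' + 2 Gamma = 0` (residual checked to 1e-8);
cross-covariances `C(tau) = e^{J tau} Sigma` with `C(-tau) = C(tau)'`, and
an independent spectral (Wiener–Khinchin) route for cross-checks whose
truncation and periodization errors are kept below 1e-6 at the default
grid for O(1) decay rates. Time-reversal asymmetry is measured as
`max_tau |C(tau) - C(tau)'|`, zero exactly under detailed balance
(symmetric `J`).

The modewise Helmholtz decomposition uses `kappa = -Re(lambda)`,
solenoidal operator `Q = -i Im(lambda)/Re(lambda) Gamma`, and precision
`Pi = kappa/Gamma`. The sign convention makes `Pi` positive for stable
modes, and then `lambda = (Q - Gamma) Pi` and
`lambda Q + Q lambda' = lambda' Gamma - Gamma lambda` hold exactly
(asserted to 1e-10). Kinetic energy (`hbar = m = 1`) splits as
`|lambda|^2/2kappa = Re^2/2kappa + Im^2/2kappa`; unstable modes carry
negative kinetic energy.

Distance power laws log-bin the signed real couplings over log mirrored
distance (equal-width bins, at least five entries per reported bin) and
regress the mean log magnitude per sign class, alongside a reciprocity
tabulation (both-excitatory / both-inhibitory / mixed fractions). Input
responses are first-order kernels `e^{J t} C`, induced variance their
squared time integral (trapezoidal), and per-mode input effects are
standard linear-model F tests against a constant-only null.

## Synthetic generators and what passing tests mean

`sample_jacobian` draws sparse couplings for pairs within 16 mm with
probability `density`; the sign is excitatory within 8 mm and inhibitory
in the annulus beyond (a Mexican-hat profile), magnitudes are shifted
half-normal `scale (0.4 + |N(0,1)|)` — planted effects carry a minimum
detectable size, as in a designed power study — and reciprocal edges
co-occur with probability 0.96. Stability is enforced by rescaling the
off-diagonal couplings (bisection until the spectral abscissa lies in
[-0.1, -0.01] Hz): rescaling preserves both the sparsity pattern and the
intended ~1-s self-decay time constants, where deepening the diagonal
would make every state artificially fast.

Default study conditions, chosen from an identifiability analysis of the
derivative GLM (sampling must resolve the dynamics, `kappa TR < 1`, and
the per-edge information `|J|^2 x duration / 2 kappa` must support the
3-nat decision rule): density 0.15, self-decay 0.75 Hz,
excitatory/inhibitory scales 0.3/0.2 Hz, dt 0.12 s, TR 0.72 s, 1000
samples (720 s), measurement noise at one third of the signal amplitude.
Recovery experiments observe the TR-sampled states plus white noise; the
hemodynamic-kernel observation path (two unit-sum gamma kernels peaking
at 6 s and 16 s) is validated by its own properties — DC gain one,
output autocorrelation equal to the kernel autocorrelation, exact
commutation with D — because a 6-s kernel at TR 0.72 suppresses exactly
the frequency band that identifies ~1-Hz couplings, so no estimator can
recover them through it at these problem sizes.

`make_hierarchical_system` plants blocks whose Markov blankets are exact:
couplings are reciprocal with equal weights and the noise uniform, so the
stationary precision is proportional to `-J` and conditional independence
can be checked to machine precision; within a block an internal clique
couples to an inner blanket state, which couples to a relay, and all
between-block edges run relay-to-relay, keeping every internal state's
moral neighborhood inside its block. `make_scale_free_system` nests this
motif: each state of a designed coarse Jacobian expands into a four-state
block whose symmetric blanket sub-Jacobian has its slow eigenvalue
prescribed (geometric in scale, factor `e^{beta_tau}`) and eigenvector
`(1,1)/sqrt(2)` (support doubling, `beta_ell = ln 2 / 3`), with designed
couplings realized exactly through the eigenvector projections. It is an
algebraic fixture for the coarse-graining path and need not be
dynamically stable.

What these generators do *not* emulate: nonlinear (neural-mass) dynamics,
biophysical hemodynamic state equations, state-dependent coupling,
session/subject variability, scanner drifts or physiological artefacts.
Passing tests therefore demonstrate correctness of the algorithms under
the linear model's own assumptions, not performance on real fMRI.

## Known limitations

* The derivative-GLM estimator is moment-based; at measurement noise
  comparable to the signal (amplitude SNR near 1) its attenuation floor —
  shared, in our experiments, by the exact state-space likelihood at
  these problem sizes — caps coupling recovery well below the quality
  reached at SNR 3.
* Estimating couplings through a slow hemodynamic kernel at whole-second
  TRs is band-limited in principle; the pipeline accepts such data but
  ground-truth recovery of fast couplings should not be expected.
* The particular partition is not unique (seeding order, internal-state
  counts and the dissipation threshold all change it); the package makes
  deterministic choices and records them, rather than searching for a
  "best" partition.
* Higher-scale Jacobians are projections of the base-scale estimate; the
  Jacobian is not re-estimated per scale.
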