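"""Spatially embedded linear stochastic systems for testing the pipeline.

Everything downstream of this module (Jacobian inference, particular
partitions, renormalization, steady-state characterization) operates on a
linear stochastic differential equation

    dx/dt = J x + C u + omega,   E[omega(t) omega(s)'] = 2 Gamma delta(t - s),

observed through a linear convolution kernel (a hemodynamic-like basis) with
additive measurement noise, sampled at a repetition time TR.  This module
builds such systems: mirror-symmetric geometries, sparse Mexican-hat coupling
(short-range excitation with an inhibitory penumbra), Euler--Maruyama
simulation, convolved noisy observation, and block-structured systems whose
Markov-blanket partition is known by construction.

The diffusion convention is E[omega omega'] = 2*Gamma*delta, so a scalar
Ornstein--Uhlenbeck process dx = -kappa x dt + sqrt(2 gamma) dW has
stationary variance gamma / kappa (variance proportional to the
characteristic time constant).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _signal

__all__ = [
    "GridGeometry",
    "LinearStochasticSystem",
    "ObservationModel",
    "TimeSeriesMatrix",
    "gamma_kernel_basis",
    "make_geometry",
    "sample_jacobian",
    "simulate_latent",
    "observe",
    "make_hierarchical_system",
    "make_scale_free_system",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GridGeometry:
    """Anatomical embedding of the states.

    positions : (N, 3) array of coordinates in mm.
    voxel_volume : volume represented by one state, mm^3.
    hemisphere_axis : index of the coordinate axis mirrored when computing
        homologous ("mirrored") distances, i.e. the axis orthogonal to the
        sagittal plane.
    """

    positions: np.ndarray
    voxel_volume: float = 1.0
    hemisphere_axis: int = 0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must be an (N, 3) array")
        if self.positions.shape[0] < 2:
            raise ValueError("need at least two positions")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.voxel_volume <= 0:
            raise ValueError("voxel_volume must be positive")

    @property
    def n_states(self) -> int:
        return self.positions.shape[0]

    def distances(self) -> np.ndarray:
        """Plain Euclidean distance matrix (mm)."""
        d = self.positions[:, None, :] - self.positions[None, :, :]
        return np.sqrt((d ** 2).sum(-1))

    def mirrored_positions(self) -> np.ndarray:
        """Positions folded across the mid-sagittal plane.

        The mirrored coordinate is replaced by its absolute value (measured
        from the mid-plane of the ensemble), superimposing homologous
        locations in the two hemispheres.
        """
        pos = self.positions.copy()
        ax = self.hemisphere_axis
        mid = 0.5 * (pos[:, ax].max() + pos[:, ax].min())
        pos[:, ax] = np.abs(pos[:, ax] - mid)
        return pos

    def mirrored_distances(self) -> np.ndarray:
        """Euclidean distances after projecting across the sagittal plane."""
        pos = self.mirrored_positions()
        d = pos[:, None, :] - pos[None, :, :]
        return np.sqrt((d ** 2).sum(-1))


@dataclass
class LinearStochasticSystem:
    """A linear SDE dx = (J x + C u) dt + sqrt(2 Gamma) dW with geometry."""

    jacobian: np.ndarray
    noise_amplitude: np.ndarray
    geometry: GridGeometry
    input_matrix: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.jacobian = np.asarray(self.jacobian, dtype=float)
        self.noise_amplitude = np.atleast_1d(
            np.asarray(self.noise_amplitude, dtype=float))
        n = self.jacobian.shape[0]
        if self.jacobian.shape != (n, n):
            raise ValueError("jacobian must be square")
        if not np.all(np.isfinite(self.jacobian)):
            raise ValueError("jacobian must be finite")
        if self.noise_amplitude.size == 1:
            self.noise_amplitude = np.full(n, float(self.noise_amplitude[0]))
        if np.any(self.noise_amplitude < 0):
            raise ValueError("noise amplitudes must be nonnegative")
        if self.input_matrix is not None:
            self.input_matrix = np.asarray(self.input_matrix, dtype=float)
            if self.input_matrix.shape[0] != n:
                raise ValueError("input_matrix must have one row per state")

    @property
    def n_states(self) -> int:
        return self.jacobian.shape[0]

    @property
    def is_stable(self) -> bool:
        return bool(np.max(np.linalg.eigvals(self.jacobian).real) < 0)


@dataclass
class ObservationModel:
    """Linear convolution observation y = (sum_k kappa_k K_k) * x + noise."""

    kernel_basis: list
    kernel_coefficients: np.ndarray
    observation_noise: float
    tr: float

    def __post_init__(self) -> None:
        if len(self.kernel_basis) < 1:
            raise ValueError("need at least one basis kernel")
        self.kernel_basis = [np.asarray(k, dtype=float)
                             for k in self.kernel_basis]
        for k in self.kernel_basis:
            if k.size < 1:
                raise ValueError("kernels must have length >= 1")
        self.kernel_coefficients = np.asarray(
            self.kernel_coefficients, dtype=float)
        if self.kernel_coefficients.size != len(self.kernel_basis):
            raise ValueError("one coefficient per basis kernel")
        if self.observation_noise < 0:
            raise ValueError("observation noise variance must be >= 0")
        if self.tr <= 0:
            raise ValueError("TR must be positive")

    def kernel(self) -> np.ndarray:
        """The composite kernel K = sum_k kappa_k K_k (finest-dt samples)."""
        length = max(k.size for k in self.kernel_basis)
        out = np.zeros(length)
        for coef, k in zip(self.kernel_coefficients, self.kernel_basis):
            out[: k.size] += coef * k
        return out


@dataclass
class TimeSeriesMatrix:
    """A T x N multivariate series with its sampling interval (s)."""

    values: np.ndarray
    sampling_interval: float
    channel_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a T x N matrix")
        if self.values.shape[0] < 3:
            raise ValueError("need at least 3 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series contains non-finite values")
        if self.sampling_interval <= 0:
            raise ValueError("sampling interval must be positive")
        if not self.channel_ids:
            self.channel_ids = [f"s{i}" for i in range(self.values.shape[1])]

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------

def gamma_kernel_basis(dt: float, peaks=(6.0, 16.0), length: float = 32.0):
    """Two gamma-shaped unit-sum kernels mimicking a hemodynamic basis.

    Each kernel is a gamma density t^(a-1) exp(-t/b) with mode at the
    requested peak time (s), sampled at dt and normalized to unit sum so
    DC gain is one.
    """
    t = np.arange(0.0, length, dt) + dt / 2.0
    basis = []
    for peak in peaks:
        shape = 6.0
        scale = peak / (shape - 1.0)
        k = t ** (shape - 1.0) * np.exp(-t / scale)
        basis.append(k / k.sum())
    return basis


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def make_geometry(n_per_hemisphere: int, spacing: float,
                  layout: str = "grid", seed: int = 0,
                  hemisphere_axis: int = 0) -> GridGeometry:
    """Mirror-symmetric state positions for two hemispheres.

    ``n_per_hemisphere`` positions are laid out in one hemisphere (grid: a
    near-cubic lattice; random: uniform in a cube of the matching extent),
    offset from the mid-plane by one spacing, then mirrored across
    ``hemisphere_axis``.  Deterministic for fixed seed.
    """
    if n_per_hemisphere < 1:
        raise ValueError("n_per_hemisphere must be >= 1")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    rng = np.random.default_rng(seed)
    if layout == "grid":
        side = int(np.ceil(n_per_hemisphere ** (1.0 / 3.0)))
        grid = np.stack(np.meshgrid(*[np.arange(side)] * 3,
                                    indexing="ij"), axis=-1)
        pts = grid.reshape(-1, 3)[:n_per_hemisphere].astype(float) * spacing
    elif layout == "random":
        extent = spacing * max(n_per_hemisphere ** (1.0 / 3.0), 1.0)
        pts = rng.uniform(0.0, extent, size=(n_per_hemisphere, 3))
    else:
        raise ValueError(f"unknown layout {layout!r}")
    ax = hemisphere_axis
    right = pts.copy()
    right[:, ax] = right[:, ax] + spacing / 2.0    # offset from mid-plane
    left = right.copy()
    left[:, ax] = -left[:, ax]
    positions = np.vstack([right, left])
    return GridGeometry(positions=positions, voxel_volume=spacing ** 3,
                        hemisphere_axis=ax)


_DEFAULT_COUPLING = dict(excit_scale=0.3, inhib_scale=0.2,
                         excit_range=8.0, inhib_range=16.0,
                         density=0.15, self_decay=0.75)


def sample_jacobian(geometry: GridGeometry, coupling: dict | None = None,
                    seed: int = 0, reciprocity: float = 0.96,
                    noise_amplitude: float = 1.0,
                    stability_margin: float = 0.01,
                    max_shift_iter: int = 50) -> LinearStochasticSystem:
    """Sparse, distance-dependent Mexican-hat Jacobian.

    Off-diagonal couplings are drawn for pairs closer than ``inhib_range``
    with probability ``density``; sign is set by distance (excitatory within
    ``excit_range``, inhibitory in the annulus beyond), magnitudes are
    half-normal with the per-sign scale (Hz).  Reciprocal edges co-occur with
    probability ``reciprocity``.  The diagonal starts at -self_decay and is
    shifted uniformly until max Re(eig(J)) <= -stability_margin, preserving
    the off-diagonal sparsity pattern.
    """
    cfg = dict(_DEFAULT_COUPLING)
    if coupling:
        cfg.update(coupling)
    if cfg["self_decay"] <= 0:
        raise ValueError("self_decay must be positive")
    if cfg["excit_range"] <= 0 or cfg["inhib_range"] <= 0:
        raise ValueError("coupling ranges must be positive")
    if not (0 <= cfg["density"] <= 1):
        raise ValueError("density must lie in (0, 1]")

    rng = np.random.default_rng(seed)
    n = geometry.n_states
    dist = geometry.distances()
    max_range = max(cfg["excit_range"], cfg["inhib_range"])
    jac = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dist[i, j]
            if d > max_range or rng.random() >= cfg["density"]:
                continue
            if d <= cfg["excit_range"]:
                sign, scale = 1.0, cfg["excit_scale"]
            else:
                sign, scale = -1.0, cfg["inhib_scale"]
            # shifted half-normal magnitudes: planted couplings carry a
            # minimum effect size of 0.4*scale rather than clustering at 0
            w_ij = sign * scale * (0.4 + abs(rng.standard_normal()))
            w_ji = sign * scale * (0.4 + abs(rng.standard_normal()))
            if rng.random() < reciprocity:
                jac[i, j], jac[j, i] = w_ij, w_ji
            elif rng.random() < 0.5:
                jac[i, j] = w_ij
            else:
                jac[j, i] = w_ji
    np.fill_diagonal(jac, -cfg["self_decay"])

    # Stabilize by scaling the off-diagonal couplings (sparsity- and
    # time-constant-preserving); deepening the diagonal instead would make
    # every state decay faster than the intended self_decay.
    off = jac - np.diag(np.diag(jac))
    diag = np.diag(np.diag(jac))

    def abscissa(scale):
        return float(np.max(np.linalg.eigvals(diag + scale * off).real))

    if abscissa(1.0) > -stability_margin:
        lo, hi = 0.0, 1.0
        for _ in range(max_shift_iter):
            mid = 0.5 * (lo + hi)
            a_mid = abscissa(mid)
            # accept anywhere inside [-10*margin, -margin]: hugging the
            # margin exactly would plant an artificially critical mode
            if -10.0 * stability_margin <= a_mid <= -stability_margin:
                lo = mid
                break
            if a_mid <= -stability_margin:
                lo = mid
            else:
                hi = mid
        jac = diag + lo * off
        if abscissa(lo) > -stability_margin + 1e-9:
            raise RuntimeError("could not stabilize Jacobian by coupling "
                               "rescale")

    return LinearStochasticSystem(jacobian=jac,
                                  noise_amplitude=noise_amplitude,
                                  geometry=geometry)


def simulate_latent(system: LinearStochasticSystem, duration: float,
                    dt: float = 0.12, seed: int = 0,
                    inputs: np.ndarray | None = None,
                    x0: np.ndarray | None = None,
                    burn_in: float | None = None,
                    allow_unstable: bool = False) -> TimeSeriesMatrix:
    """Euler--Maruyama integration of the latent SDE.

    Noise increments are sqrt(2 Gamma dt) times standard normals, matching
    the E[omega omega'] = 2 Gamma delta convention.  A burn-in of ten
    characteristic times of the slowest mode (default) is simulated and
    discarded so the retained samples are effectively stationary.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < 10 * dt:
        raise ValueError("duration must be at least 10*dt")
    eigs = np.linalg.eigvals(system.jacobian)
    if np.max(eigs.real) >= 0 and not allow_unstable:
        raise ValueError("system is unstable; pass allow_unstable=True "
                         "to integrate anyway")
    if burn_in is None:
        slowest = np.min(-eigs.real[eigs.real < 0], initial=np.inf)
        burn_in = 0.0 if not np.isfinite(slowest) else min(10.0 / slowest,
                                                           10.0 * duration)
    n = system.n_states
    n_burn = int(round(burn_in / dt))
    n_keep = int(round(duration / dt))
    rng = np.random.default_rng(seed)
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    amp = np.sqrt(2.0 * system.noise_amplitude * dt)
    jac = system.jacobian
    cin = system.input_matrix
    if inputs is not None:
        inputs = np.asarray(inputs, dtype=float)
        if cin is None:
            raise ValueError("system has no input matrix but inputs given")
        if inputs.shape[0] < n_keep:
            raise ValueError("inputs shorter than simulation")
    out = np.empty((n_keep, n))
    for step in range(n_burn + n_keep):
        drift = jac @ x
        if inputs is not None and step >= n_burn:
            drift = drift + cin @ inputs[step - n_burn]
        x = x + dt * drift + amp * rng.standard_normal(n)
        if not np.all(np.isfinite(x)):
            raise FloatingPointError(
                f"simulation blew up at step {step} (t={step * dt:.2f}s)")
        if step >= n_burn:
            out[step - n_burn] = x
    return TimeSeriesMatrix(values=out, sampling_interval=dt)


def observe(latent: TimeSeriesMatrix, model: ObservationModel,
            seed: int = 0) -> TimeSeriesMatrix:
    """Convolve, decimate to TR and add white observation noise."""
    dt = latent.sampling_interval
    step = model.tr / dt
    if abs(step - round(step)) > 1e-9:
        raise ValueError("TR must be an integer multiple of the latent dt")
    step = int(round(step))
    kernel = model.kernel()
    if latent.n_samples < kernel.size:
        raise ValueError("latent series shorter than the kernel")
    conv = _signal.lfilter(kernel, [1.0], latent.values, axis=0)
    sampled = conv[::step]
    if model.observation_noise > 0:
        rng = np.random.default_rng(seed)
        sampled = sampled + rng.normal(
            0.0, np.sqrt(model.observation_noise), size=sampled.shape)
    return TimeSeriesMatrix(values=sampled, sampling_interval=model.tr,
                            channel_ids=list(latent.channel_ids))


def make_hierarchical_system(block_sizes, within_strength: float = 1.0,
                             between_strength: float = 0.2, seed: int = 0,
                             self_decay: float = 1.0,
                             noise_amplitude: float = 1.0,
                             spacing: float = 4.0):
    """Block-structured system whose particular partition is known.

    Each block hosts ``size - 2`` internal states plus two designated
    blanket states: an inner one (s) coupled to every internal state, and a
    relay (a) coupled to s only.  All between-block edges run between
    relays (ring order), so an internal state's moral neighborhood (direct
    neighbors plus two-step co-parents) never leaves its block.  All
    couplings are reciprocal with equal weights and the noise amplitude is
    uniform, so the stationary precision is proportional to -J and the
    planted blankets are *exactly* verifiable by zero partial correlations.

    Returns (system, partition) where partition is a
    :class:`blanketrg.partition.Partition` ground truth.
    """
    from .partition import Particle, Partition, adjacency, classify_blanket

    block_sizes = list(block_sizes)
    if len(block_sizes) < 2:
        raise ValueError("need at least 2 blocks")
    if any(s < 3 for s in block_sizes):
        raise ValueError("blocks must have size >= 3 "
                         "(internal + two blanket states)")
    if not between_strength < within_strength:
        raise ValueError("between_strength must be < within_strength")

    rng = np.random.default_rng(seed)
    n = sum(block_sizes)
    jac = np.zeros((n, n))
    particles = []
    offset = 0
    relays = []      # a-state per block
    for size in block_sizes:
        idx = list(range(offset, offset + size))
        internal = idx[: size - 2]
        s_node, a_node = idx[size - 2], idx[size - 1]
        w = within_strength
        for i in internal:
            for j in internal:
                if i < j:
                    wij = w * (1.5 + 0.5 * rng.random())
                    jac[i, j] = jac[j, i] = wij
        for i in internal:
            jac[i, s_node] = jac[s_node, i] = w
        jac[s_node, a_node] = jac[a_node, s_node] = 0.4 * w
        particles.append(Particle(internal=frozenset(internal),
                                  sensory=frozenset([s_node]),
                                  active=frozenset([a_node])))
        relays.append(a_node)
        offset += size

    if between_strength > 0:
        nb = len(block_sizes)
        for b in range(nb):
            a_here, a_next = relays[b], relays[(b + 1) % nb]
            if a_here != a_next:
                jac[a_here, a_next] = jac[a_next, a_here] = between_strength

    # stabilize: diagonal dominates row sums of |couplings|
    row_sums = np.abs(jac).sum(axis=1)
    diag = -(row_sums + self_decay)
    np.fill_diagonal(jac, diag)

    n_per_hemi = (n + 1) // 2
    geometry = make_geometry(n_per_hemi, spacing, layout="grid", seed=seed)
    geometry = GridGeometry(positions=geometry.positions[:n],
                            voxel_volume=geometry.voxel_volume,
                            hemisphere_axis=geometry.hemisphere_axis)
    system = LinearStochasticSystem(jacobian=jac,
                                    noise_amplitude=noise_amplitude,
                                    geometry=geometry)
    partition = Partition(particles=particles, n_states=n)
    partition = classify_blanket(partition, adjacency(jac))
    return system, partition


def make_scale_free_system(n_levels: int = 3, kappa0: float = 1.0,
                           factor_tau: float = 2.0, seed: int = 0,
                           jitter: float = 0.01, spacing: float = 2.0):
    """Nested blanket motif with prescribed renormalization-group flow.

    Builds a 4**n_levels-state Jacobian whose recursive particular
    partition and adiabatic reduction (two internal states per particle,
    one retained mode) yield, by construction, mean decay rates that fall
    geometrically by ``factor_tau`` per scale while the eigenmode support
    doubles per scale.  The implied beta functions are therefore

        beta_tau = ln(factor_tau),   beta_ell = ln(2) / 3,

    so the spatiotemporal scaling exponent is alpha = 3 ln(factor_tau)/ln 2.

    Construction is top-down: the designed Jacobian at scale i+1 is
    realized at scale i by expanding every state into a 4-state block
    [int1, int2, s, a] whose symmetric blanket sub-Jacobian
    [[-kappa_i, w], [w, -kappa_i]] has slow eigenvalue -kappa_{i+1}
    (w = kappa_i - kappa_{i+1}, retained eigenvector (1,1)/sqrt(2), hence
    support doubling), and every designed coupling between states maps to
    the four blanket-to-blanket edges that induce it exactly under the
    eigenvector projections.  Internal couplings are sized to dominate the
    graph-Laplacian degree so the partition recovers the blocks; they are
    eliminated by the reduction and do not affect the flow (the system is
    an algebraic fixture and need not be dynamically stable).

    Returns (system, info) where info holds the kappa schedule, the beta
    factors, the implied alpha and the RG configuration to use
    (n_internal=2, max_modes=1).
    """
    if n_levels < 1:
        raise ValueError("need at least one level")
    if factor_tau <= 1:
        raise ValueError("factor_tau must exceed 1 (slowing)")
    rng = np.random.default_rng(seed)
    kappas = kappa0 / factor_tau ** np.arange(n_levels + 1)
    jac = np.array([[-kappas[n_levels]]])
    for level in range(n_levels, 0, -1):
        kap_lo, kap_hi = kappas[level - 1], kappas[level]
        w_base = kap_lo - kap_hi
        g_attach = 0.5 * w_base
        n_hi = jac.shape[0]
        off = jac - np.diag(np.diag(jac))
        load = 2.0 * w_base + g_attach + float(
            (np.abs(off).sum(axis=1) + np.abs(off).sum(axis=0)).max())
        c_int = load + w_base + 0.1
        n_lo = 4 * n_hi
        lo = np.zeros((n_lo, n_lo))
        blanket = []    # (s, a) per block
        for b in range(n_hi):
            i1, i2, s, a = 4 * b, 4 * b + 1, 4 * b + 2, 4 * b + 3
            cb = c_int * (1.0 + jitter * rng.random())
            lo[i1, i2] = lo[i2, i1] = cb
            lo[i1, s] = g_attach          # s -> int1
            lo[i2, a] = g_attach          # a -> int2
            wb = w_base * (1.0 + jitter * (2.0 * rng.random() - 1.0))
            lo[s, a] = lo[a, s] = wb
            for k in (i1, i2, s, a):
                lo[k, k] = -kap_lo
            blanket.append((s, a))
        for nidx in range(n_hi):
            for midx in range(n_hi):
                if nidx == midx or jac[nidx, midx] == 0:
                    continue
                v = jac[nidx, midx] / 2.0
                s_n, a_n = blanket[nidx]
                s_m, a_m = blanket[midx]
                for tgt in (s_n, a_n):
                    for src in (s_m, a_m):
                        lo[tgt, src] += v
        jac = lo

    n = jac.shape[0]
    side = int(np.ceil(n ** (1.0 / 3.0)))
    grid = np.stack(np.meshgrid(*[np.arange(side)] * 3,
                                indexing="ij"), axis=-1)
    positions = grid.reshape(-1, 3)[:n].astype(float) * spacing
    geometry = GridGeometry(positions=positions, voxel_volume=spacing ** 3,
                            hemisphere_axis=0)
    system = LinearStochasticSystem(jacobian=jac, noise_amplitude=1.0,
                                    geometry=geometry)
    info = {
        "kappas": kappas,
        "beta_tau": float(np.log(factor_tau)),
        "beta_ell": float(np.log(2.0) / 3.0),
        "alpha": float(3.0 * np.log(factor_tau) / np.log(2.0)),
        "n_scales": n_levels + 1,
        "rg_config": {"n_internal": 2, "max_modes": 1,
                      "dissipation_threshold": 1.0},
    }
    return system, info
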