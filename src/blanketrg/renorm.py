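"""Renormalization-group coarse-graining of particular partitions.

One RG step composes a grouping operator G (the particular partition of the
current states, :mod:`blanketrg.partition`) with a reduction operator R
(adiabatic elimination): internal states are dropped -- they do not couple
particles -- and each particle's blanket Jacobian J(b, b) is
eigendecomposed, retaining only the slow eigenmodes (Re(lambda) above a
dissipation threshold).  The retained eigenstates become the states of the
next scale, with intrinsic coupling diag(lambda) and extrinsic coupling

    lambda_nm = xi_n^- J(b_n, b_m) xi_m ,

where xi are the retained eigenvector columns and xi^- the pseudo-inverse.
Because only slow modes survive, the mean decay rate can only fall with
scale (progressive critical slowing).  Chaining the eigenvector blocks back
to the base scale yields a voxel-space eigenmode per eigenstate, from which
spatial extents, particle centers and the spatiotemporal scaling exponent
(log time constant vs log spatial extent) are measured.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .partition import Partition, particular_partition
from .synthgen import GridGeometry, TimeSeriesMatrix

__all__ = [
    "ParticleEigen",
    "Scale",
    "MultiscaleModel",
    "ScalingFit",
    "RGConfig",
    "seed_particles_from_voxels",
    "adiabatic_reduce",
    "coarse_grain",
    "run_rg",
    "project_eigenmodes",
    "particle_centers",
    "mirrored_center_distances",
    "scale_summaries",
    "fit_scaling",
    "extrapolate_scales",
]


@dataclass
class ParticleEigen:
    """Retained eigenstructure of one particle's blanket Jacobian."""

    eigenvalues: np.ndarray     # complex, sorted by descending real part
    eigenvectors: np.ndarray    # (blanket_dim, retained) complex
    left_inverse: np.ndarray    # pinv(eigenvectors), (retained, blanket_dim)

    @property
    def n_retained(self) -> int:
        return self.eigenvalues.size


@dataclass
class Scale:
    """One level of the multiscale model."""

    index: int
    jacobian: np.ndarray                 # (states, states) complex
    partition: Partition | None         # partition of the scale below
    particles: list                      # ParticleEigen per particle
    particle_of_state: np.ndarray        # particle index per state
    eigenmodes: np.ndarray | None = None   # (voxels, states) complex
    centers: np.ndarray | None = None      # (states, 3) mm

    @property
    def n_states(self) -> int:
        return self.jacobian.shape[0]

    def intrinsic_eigenvalues(self) -> np.ndarray:
        return np.concatenate([p.eigenvalues for p in self.particles])


@dataclass
class MultiscaleModel:
    scales: list
    geometry: GridGeometry | None
    provenance: dict = field(default_factory=dict)

    @property
    def n_scales(self) -> int:
        return len(self.scales)

    def mean_decay_rates(self) -> np.ndarray:
        """Mean Re(lambda) per scale; nondecreasing under the RG flow."""
        return np.array([s.intrinsic_eigenvalues().real.mean()
                         for s in self.scales])


@dataclass
class ScalingFit:
    sigma_tau: np.ndarray        # per-scale temporal constants, s
    sigma_ell: np.ndarray        # per-scale spatial constants, mm
    alpha: float                 # log-log slope
    gamma: float                 # exp(intercept)
    factor_tau: float            # geometric-mean per-step e^{beta_tau}
    factor_ell: float            # geometric-mean per-step e^{beta_ell}
    step_factors_tau: np.ndarray = field(default_factory=lambda: np.array([]))
    step_factors_ell: np.ndarray = field(default_factory=lambda: np.array([]))
    residuals: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class RGConfig:
    """Knobs of the blocking transformation.

    n_internal may be an int or a per-scale list; dissipation_threshold is
    in Hz (modes with Re(lambda) <= -threshold dissipate within
    1/threshold seconds and are dropped); max_modes caps the retained
    eigenstates per particle (conjugate pairs are never split).
    """

    n_internal: int | list = 1
    dissipation_threshold: float = 1.0
    max_modes: int = 8
    tol: float = 1e-6
    temperature: float | None = None
    extent_method: str = "participation"

    def n_internal_at(self, scale_index: int) -> int:
        if isinstance(self.n_internal, (list, tuple, np.ndarray)):
            i = min(scale_index, len(self.n_internal) - 1)
            return int(self.n_internal[i])
        return int(self.n_internal)


# ---------------------------------------------------------------------------
# voxels -> first-scale states
# ---------------------------------------------------------------------------

def seed_particles_from_voxels(voxel_series, voxel_positions,
                               radius: float = 4.0, n_target: int = 1024):
    """Greedy variance-ranked grouping of voxels into first-level particles.

    Repeatedly: take the unassigned voxel of largest variance, group all
    unassigned voxels within ``radius`` of it, record the first eigenvariate
    (SVD of the group's series, sign fixed so the seed voxel loads
    positively) and its spatial loading; remove the group.  Stops at
    ``n_target`` particles or exhaustion.

    Returns (eigenvariates T x P, loadings voxels x P, groups).
    """
    values = voxel_series.values if isinstance(voxel_series,
                                               TimeSeriesMatrix) \
        else np.asarray(voxel_series, dtype=float)
    if values.size == 0:
        raise ValueError("empty series")
    positions = np.asarray(voxel_positions, dtype=float)
    n_vox = values.shape[1]
    if positions.shape[0] != n_vox:
        raise ValueError("one position per voxel required")
    variances = values.var(axis=0)
    unassigned = np.ones(n_vox, dtype=bool)
    eigenvariates, loadings, groups = [], [], []
    while unassigned.any() and len(groups) < n_target:
        cand = np.flatnonzero(unassigned)
        seed = cand[np.argmax(variances[cand])]
        d = np.linalg.norm(positions - positions[seed], axis=1)
        group = np.flatnonzero(unassigned & (d <= radius))
        sub = values[:, group]
        sub_c = sub - sub.mean(axis=0)
        u, s, vt = np.linalg.svd(sub_c, full_matrices=False)
        load = vt[0]
        seed_pos = int(np.flatnonzero(group == seed)[0])
        if load[seed_pos] < 0:
            load, u = -load, u.copy()
            u[:, 0] = -u[:, 0]
        eigenvariates.append(u[:, 0] * s[0])
        full_load = np.zeros(n_vox)
        full_load[group] = load
        loadings.append(full_load)
        groups.append(group)
        unassigned[group] = False
    return (np.column_stack(eigenvariates), np.column_stack(loadings),
            groups)


# ---------------------------------------------------------------------------
# adiabatic reduction
# ---------------------------------------------------------------------------

def _phase_fix(vec: np.ndarray) -> np.ndarray:
    """Make the largest-modulus component of each column real positive."""
    out = vec.copy()
    for k in range(out.shape[1]):
        idx = int(np.argmax(np.abs(out[:, k])))
        pivot = out[idx, k]
        if np.abs(pivot) > 0:
            out[:, k] = out[:, k] * (np.conj(pivot) / np.abs(pivot))
    return out


def adiabatic_reduce(j_blanket: np.ndarray,
                     dissipation_threshold: float = 1.0,
                     max_modes: int = 8) -> ParticleEigen:
    """Retain the slow eigenmodes of a blanket Jacobian.

    Eigenmodes with Re(lambda) > -dissipation_threshold survive (they decay
    more slowly than 1/threshold seconds); the rest are eliminated.  If no
    mode qualifies the single slowest one is kept, and a conjugate pair is
    never split by the ``max_modes`` cap (the cap is relaxed by one
    instead).
    """
    jac = np.asarray(j_blanket)
    if jac.ndim != 2 or jac.shape[0] != jac.shape[1]:
        raise ValueError("blanket Jacobian must be square")
    if jac.shape[0] == 0:
        raise ValueError("empty blanket Jacobian")
    lam, vec = np.linalg.eig(jac)
    cond = np.linalg.cond(vec)
    if cond > 1e12:
        warnings.warn("near-defective blanket Jacobian "
                      f"(eigenvector condition {cond:.2e}); regularizing",
                      stacklevel=2)
        jitter = 1e-8 * max(np.abs(jac).max(), 1.0)
        lam, vec = np.linalg.eig(
            jac + jitter * np.diag(np.arange(1, jac.shape[0] + 1)))
    order = np.lexsort((np.arange(lam.size), -np.abs(lam.imag),
                        -lam.real))
    lam, vec = lam[order], vec[:, order]

    keep = int(np.sum(lam.real > -dissipation_threshold))
    if keep == 0:
        keep = 1
    if keep > max_modes:
        keep = max_modes
        # never split a conjugate pair at the cap
        if keep < lam.size and lam[keep - 1].imag != 0 and \
                np.isclose(lam[keep], np.conj(lam[keep - 1])):
            keep += 1
    lam, vec = lam[:keep], vec[:, :keep]
    vec = _phase_fix(vec)
    left = np.linalg.pinv(vec)
    return ParticleEigen(eigenvalues=lam, eigenvectors=vec,
                         left_inverse=left)


def coarse_grain(jacobian: np.ndarray, partition: Partition,
                 config: RGConfig | None = None):
    """One application of the reduction operator R.

    Internal states are eliminated; each particle's blanket Jacobian is
    reduced adiabatically, and the next-scale Jacobian is assembled with
    diagonal intrinsic blocks diag(lambda) and extrinsic blocks
    xi_n^- J(b_n, b_m) xi_m.

    Returns (next_jacobian, particle_eigens, blanket_indices,
    particle_of_state).
    """
    config = config or RGConfig()
    jac = np.asarray(jacobian)
    blankets, eigens = [], []
    for particle in partition.particles:
        b = sorted(particle.blanket) if particle.blanket \
            else sorted(particle.internal)     # isolated particle
        blankets.append(np.array(b, dtype=int))
        eigens.append(adiabatic_reduce(
            jac[np.ix_(b, b)],
            dissipation_threshold=config.dissipation_threshold,
            max_modes=config.max_modes))
    sizes = [e.n_retained for e in eigens]
    offsets = np.concatenate([[0], np.cumsum(sizes)])
    dim = int(offsets[-1])
    nxt = np.zeros((dim, dim), dtype=complex)
    particle_of_state = np.empty(dim, dtype=int)
    for n, (e_n, b_n) in enumerate(zip(eigens, blankets)):
        sl_n = slice(offsets[n], offsets[n + 1])
        particle_of_state[sl_n] = n
        nxt[sl_n, sl_n] = np.diag(e_n.eigenvalues)
        for m, (e_m, b_m) in enumerate(zip(eigens, blankets)):
            if m == n:
                continue
            block = jac[np.ix_(b_n, b_m)]
            if np.any(block):
                sl_m = slice(offsets[m], offsets[m + 1])
                nxt[sl_n, sl_m] = \
                    e_n.left_inverse @ block @ e_m.eigenvectors
    return nxt, eigens, blankets, particle_of_state


# ---------------------------------------------------------------------------
# the full RG flow
# ---------------------------------------------------------------------------

def run_rg(system_or_jacobian, geometry: GridGeometry | None = None,
           n_scales: int = 4, config: RGConfig | None = None,
           base_modes: np.ndarray | None = None) -> MultiscaleModel:
    """Alternate particular partition (G) and adiabatic reduction (R).

    Accepts a LinearStochasticSystem or a raw Jacobian (+ geometry).  The
    base scale treats every state as a particle with a single eigenstate
    whose eigenvalue is the state's self-coupling J_nn.  Iterates until
    ``n_scales`` scales are recorded or a single irreducible particle
    remains.  The progressive-slowing property (mean Re(lambda)
    nondecreasing across scales) is checked and logged in the provenance.
    """
    from .synthgen import LinearStochasticSystem
    if isinstance(system_or_jacobian, LinearStochasticSystem):
        jac = system_or_jacobian.jacobian
        geometry = geometry or system_or_jacobian.geometry
    else:
        jac = np.asarray(system_or_jacobian)
    if n_scales < 1:
        raise ValueError("n_scales must be >= 1")
    config = config or RGConfig()

    n = jac.shape[0]
    if base_modes is None:
        base_modes = np.eye(n, dtype=complex)
    base = Scale(
        index=1, jacobian=jac.astype(complex), partition=None,
        particles=[ParticleEigen(eigenvalues=np.array([jac[k, k]],
                                                      dtype=complex),
                                 eigenvectors=np.ones((1, 1), dtype=complex),
                                 left_inverse=np.ones((1, 1), dtype=complex))
                   for k in range(n)],
        particle_of_state=np.arange(n),
        eigenmodes=np.asarray(base_modes, dtype=complex))
    scales = [base]
    while len(scales) < n_scales:
        current = scales[-1]
        if current.n_states < 2:
            break
        part = particular_partition(
            current.jacobian,
            n_internal=config.n_internal_at(len(scales) - 1),
            tol=config.tol)
        nxt_jac, eigens, blankets, pos = coarse_grain(
            current.jacobian, part, config)
        if nxt_jac.shape[0] >= current.n_states:
            break      # no further reduction possible
        # Eq. 9 chain: next modes = previous modes over blanket cols @ xi
        modes_cols = []
        for e, b in zip(eigens, blankets):
            modes_cols.append(current.eigenmodes[:, b] @ e.eigenvectors)
        nxt_modes = np.concatenate(modes_cols, axis=1)
        scales.append(Scale(index=len(scales) + 1, jacobian=nxt_jac,
                            partition=part, particles=eigens,
                            particle_of_state=pos, eigenmodes=nxt_modes))
        if part.n_particles == 1:
            break
    model = MultiscaleModel(scales=scales, geometry=geometry,
                            provenance={"config": config})
    if geometry is not None:
        for scale in model.scales:
            scale.centers = particle_centers(
                scale.eigenmodes, geometry.positions,
                temperature=config.temperature)
    rates = model.mean_decay_rates()
    slowing_ok = bool(np.all(np.diff(rates) >= -1e-10))
    model.provenance["mean_decay_rates"] = rates
    model.provenance["progressive_slowing"] = slowing_ok
    if not slowing_ok:
        warnings.warn("mean Re(lambda) decreased across a scale; the "
                      "adiabatic reduction did not slow the dynamics",
                      stacklevel=2)
    return model


def project_eigenmodes(model: MultiscaleModel) -> list:
    """Per-scale voxel-space eigenmodes (chained eigenvector products)."""
    out = []
    for scale in model.scales:
        if scale.eigenmodes is None:
            raise ValueError(f"scale {scale.index} has no eigenmodes")
        out.append(scale.eigenmodes)
    return out


# ---------------------------------------------------------------------------
# centers and spatiotemporal summaries
# ---------------------------------------------------------------------------

def particle_centers(modes: np.ndarray, positions: np.ndarray,
                     temperature: float | None = None) -> np.ndarray:
    """Expected anatomical location of each eigenmode.

    The probability over voxels is a softmax of |mode| / temperature
    (default temperature: the std of |mode|); the center is the
    probability-weighted mean position.  As temperature -> 0 the center
    approaches the argmax voxel.
    """
    modes = np.atleast_2d(np.asarray(modes))
    if modes.shape[0] == np.asarray(positions).shape[0]:
        pass
    positions = np.asarray(positions, dtype=float)
    if modes.shape[0] != positions.shape[0]:
        raise ValueError("modes must have one row per voxel")
    centers = np.empty((modes.shape[1], positions.shape[1]))
    for k in range(modes.shape[1]):
        w = np.abs(modes[:, k])
        if not w.any():
            raise ValueError(f"eigenmode {k} is identically zero")
        temp = temperature if temperature is not None else w.std()
        if temp <= 0 and np.ptp(w) == 0:
            p = np.full_like(w, 1.0 / w.size)   # constant mode: uniform
        elif temp <= 0:
            p = np.zeros_like(w)
            p[np.argmax(w)] = 1.0
        else:
            z = w / temp
            z = z - z.max()
            p = np.exp(z)
            p /= p.sum()
        centers[k] = p @ positions
    return centers


def mirrored_center_distances(centers: np.ndarray, positions: np.ndarray,
                              hemisphere_axis: int = 0) -> np.ndarray:
    """Pairwise distances after folding centers across the sagittal plane."""
    centers = np.asarray(centers, dtype=float).copy()
    ax = hemisphere_axis
    mid = 0.5 * (np.asarray(positions)[:, ax].max()
                 + np.asarray(positions)[:, ax].min())
    centers[:, ax] = np.abs(centers[:, ax] - mid)
    diff = centers[:, None, :] - centers[None, :, :]
    return np.sqrt((diff ** 2).sum(-1))


def _participation_extent(mode: np.ndarray, voxel_volume: float) -> float:
    w = np.abs(mode) ** 2
    pr = w.sum() ** 2 / (w ** 2).sum()
    return (voxel_volume * pr) ** (1.0 / 3.0)


def _caliper_extent(mode: np.ndarray, positions: np.ndarray) -> float:
    w = np.abs(mode)
    w = w / w.sum()
    centroid = w @ positions
    var = w @ ((positions - centroid) ** 2).sum(axis=1)
    return 2.0 * np.sqrt(var)


def scale_summaries(model: MultiscaleModel,
                    extent_method: str | None = None):
    """Characteristic temporal and spatial constants per scale.

    sigma_tau(i): mean time constant -1/Re(lambda) over retained
    eigenstates with Re(lambda) < 0 (unstable modes are kept in the model
    but excluded from the mean, and logged).  sigma_ell(i): mean effective
    linear extent of the eigenmodes -- (voxel_volume x participation
    ratio)^(1/3) by default, or the |mode|-weighted caliper width.
    """
    cfg = model.provenance.get("config") or RGConfig()
    method = extent_method or cfg.extent_method
    voxvol = model.geometry.voxel_volume if model.geometry else 1.0
    sigma_tau, sigma_ell, excluded = [], [], []
    for scale in model.scales:
        lam = scale.intrinsic_eigenvalues()
        stable = lam.real < 0
        excluded.append(int((~stable).sum()))
        if not stable.any():
            raise ValueError(
                f"scale {scale.index} has no stable modes; lower the "
                "dissipation threshold or inspect the Jacobian")
        sigma_tau.append(float((-1.0 / lam.real[stable]).mean()))
        modes = scale.eigenmodes
        if method == "participation":
            ext = [_participation_extent(modes[:, k], voxvol)
                   for k in range(modes.shape[1])]
        elif method == "caliper":
            if model.geometry is None:
                raise ValueError("caliper extent needs geometry")
            ext = [_caliper_extent(modes[:, k], model.geometry.positions)
                   for k in range(modes.shape[1])]
        else:
            raise ValueError(f"unknown extent method {method!r}")
        sigma_ell.append(float(np.mean(ext)))
    return np.array(sigma_tau), np.array(sigma_ell), excluded


def fit_scaling(sigma_tau, sigma_ell) -> ScalingFit:
    """OLS of ln sigma_tau on ln sigma_ell: slope alpha, exp-intercept gamma."""
    tau = np.asarray(sigma_tau, dtype=float)
    ell = np.asarray(sigma_ell, dtype=float)
    if tau.size != ell.size or tau.size < 2:
        raise ValueError("need >= 2 scales with matching summaries")
    if np.any(tau <= 0) or np.any(ell <= 0):
        raise ValueError("summaries must be positive")
    lt, le = np.log(tau), np.log(ell)
    slope, intercept = np.polyfit(le, lt, 1)
    resid = lt - (slope * le + intercept)
    step_tau = tau[1:] / tau[:-1]
    step_ell = ell[1:] / ell[:-1]
    return ScalingFit(sigma_tau=tau, sigma_ell=ell, alpha=float(slope),
                      gamma=float(np.exp(intercept)),
                      factor_tau=float(np.exp(np.mean(np.log(step_tau)))),
                      factor_ell=float(np.exp(np.mean(np.log(step_ell)))),
                      step_factors_tau=step_tau, step_factors_ell=step_ell,
                      residuals=resid)


def extrapolate_scales(fit: ScalingFit, scale_indices):
    """Geometric extrapolation from the scale-0 anchors.

    sigma_tau(i) = sigma_tau(0) * factor_tau^i and likewise for the spatial
    constant; negative indices extrapolate downwards.
    """
    idx = np.atleast_1d(np.asarray(scale_indices, dtype=float))
    tau0, ell0 = fit.sigma_tau[0], fit.sigma_ell[0]
    return (ell0 * fit.factor_ell ** idx, tau0 * fit.factor_tau ** idx)
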