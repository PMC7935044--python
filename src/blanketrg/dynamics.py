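"""Closed-form characterization of linear stochastic dynamics at any scale.

For dx = J x dt + sqrt(2 Gamma) dW with stable J:

* transfer functions T(f) = (2*pi*i*f - lambda)^-1 per eigenmode (Lorentzian
  spectra; the peak frequency is Im(lambda)/2pi);
* the stationary covariance solves the Lyapunov equation
  J Sigma + Sigma J' + 2 Gamma = 0;
* lagged cross-covariances C(tau) = expm(J tau) Sigma (tau >= 0), with an
  independent spectral (Wiener--Khinchin) route for cross-checks;
* the Helmholtz decomposition of the steady-state flow into dissipative
  (gradient) and solenoidal components, modewise: kappa = -Re(lambda),
  Q = -i Im(lambda)/Re(lambda) * Gamma, Pi = kappa/Gamma, with the kinetic
  energy split lambda'lambda/(2 kappa) = Re^2/(2 kappa) + Im^2/(2 kappa);
* distance power laws of signed couplings (log-binned regression) and
  reciprocity tabulation;
* first-order (impulse response) kernels exp(J t) C of exogenous inputs and
  per-state F tests of input effects.

Sign conventions: stable modes have Re(lambda) < 0; the precision of a mode
is Pi = kappa / Gamma > 0, and lambda = (Q - Gamma) Pi holds exactly.
Detailed balance (symmetric J) gives Q = 0 and time-symmetric
cross-covariances.  Units are Hz for rates, seconds for lags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg as sla

__all__ = [
    "TransferFunction",
    "StationaryCovariance",
    "CrossCovariance",
    "HelmholtzSummary",
    "DistancePowerLaw",
    "InducedResponse",
    "transfer_functions",
    "stationary_covariance",
    "cross_covariance",
    "cross_covariance_spectral",
    "helmholtz",
    "distance_power_law",
    "induced_responses",
]


@dataclass
class TransferFunction:
    frequencies: np.ndarray          # Hz
    gains: np.ndarray                # (modes, freqs) complex
    power: np.ndarray                # (modes, freqs) |T|^2 * 2*Gamma
    eigenvalues: np.ndarray

    def peak_frequency(self, mode: int) -> float:
        """Frequency of maximal gain: Im(lambda)/2pi for underdamped modes."""
        lam = self.eigenvalues[mode]
        return max(lam.imag / (2.0 * np.pi), 0.0)


@dataclass
class StationaryCovariance:
    sigma: np.ndarray
    precision: np.ndarray
    residual: float                  # |J S + S J' + 2 Gamma|_F

    def surprisal(self, x: np.ndarray) -> float:
        """Gaussian surprisal 0.5 x' Pi x (up to the log-partition const)."""
        x = np.asarray(x, dtype=float)
        return 0.5 * float(x @ self.precision @ x)


@dataclass
class CrossCovariance:
    lags: np.ndarray                 # s, symmetric about 0
    values: np.ndarray               # (lags, N, N)

    def peak_lag(self, i: int, j: int) -> float:
        k = int(np.argmax(np.abs(self.values[:, i, j])))
        return float(self.lags[k])

    def asymmetry(self) -> float:
        """Max |C(tau) - C(tau)'| over positive lags.

        At stationarity C(-tau) = C(tau)', so time-reversal symmetry
        (detailed balance) is equivalent to C(tau) being symmetric at
        every lag; solenoidal flow makes this nonzero.
        """
        out = 0.0
        for k in np.flatnonzero(self.lags > 0):
            c = self.values[k]
            out = max(out, float(np.max(np.abs(c - c.T))))
        return out


@dataclass
class HelmholtzSummary:
    eigenvalues: np.ndarray          # complex, per mode
    gamma: np.ndarray                # real diffusion per mode
    kappa: np.ndarray                # -Re(lambda)
    q: np.ndarray                    # imaginary solenoidal operator
    precision: np.ndarray            # kappa / gamma
    energy_dissipative: np.ndarray   # Re(lambda)^2 / (2 kappa)
    energy_solenoidal: np.ndarray    # Im(lambda)^2 / (2 kappa)
    energy_total: np.ndarray         # |lambda|^2 / (2 kappa)
    identity_residual: float
    constraint_residual: float


@dataclass
class DistancePowerLaw:
    bin_centers_excitatory: np.ndarray
    bin_means_excitatory: np.ndarray
    bin_centers_inhibitory: np.ndarray
    bin_means_inhibitory: np.ndarray
    exponent_excitatory: float | None
    exponent_inhibitory: float | None
    reciprocity: dict = field(default_factory=dict)


@dataclass
class InducedResponse:
    t_grid: np.ndarray
    kernels: np.ndarray              # (time, states, inputs)
    induced_variance: np.ndarray     # (states, inputs)
    f_stats: np.ndarray | None = None
    p_values: np.ndarray | None = None
    df: tuple | None = None


# ---------------------------------------------------------------------------

def transfer_functions(eigenvalues, freq_grid,
                       noise_amplitude: float = 1.0) -> TransferFunction:
    """Per-eigenstate Lorentzian gains T(f) = 1/(2*pi*i*f - lambda).

    A full Jacobian may be passed instead of eigenvalues; modal gains are
    then computed in its eigenbasis.
    """
    arr = np.asarray(eigenvalues)
    if arr.ndim == 2:
        arr = np.linalg.eigvals(arr)
    freq = np.asarray(freq_grid, dtype=float)
    if freq.ndim != 1 or np.any(np.diff(freq) <= 0) or np.any(freq < 0):
        raise ValueError("frequency grid must be nonnegative and ascending")
    omega = 2.0 * np.pi * freq
    denom = 1j * omega[None, :] - arr[:, None]
    if np.any(np.abs(denom) < 1e-12):
        raise ZeroDivisionError(
            "infinite gain: a purely oscillatory eigenvalue coincides "
            "with a grid frequency")
    gains = 1.0 / denom
    power = (np.abs(gains) ** 2) * 2.0 * noise_amplitude
    return TransferFunction(frequencies=freq, gains=gains, power=power,
                            eigenvalues=arr)


def stationary_covariance(jacobian: np.ndarray,
                          gamma) -> StationaryCovariance:
    """Solve J Sigma + Sigma J' + 2 Gamma = 0 for the steady state."""
    jac = np.asarray(jacobian, dtype=float)
    n = jac.shape[0]
    g = np.atleast_1d(np.asarray(gamma, dtype=float))
    gmat = np.diag(np.full(n, float(g[0]))) if g.size == 1 else (
        np.diag(g) if g.ndim == 1 else g)
    if np.max(np.linalg.eigvals(jac).real) >= 0:
        raise ValueError("Jacobian is not stable: no stationary state")
    sigma = sla.solve_continuous_lyapunov(jac, -2.0 * gmat)
    sigma = 0.5 * (sigma + sigma.T)
    residual = float(np.linalg.norm(jac @ sigma + sigma @ jac.T
                                    + 2.0 * gmat))
    precision = np.linalg.inv(sigma)
    return StationaryCovariance(sigma=sigma, precision=precision,
                                residual=residual)


def cross_covariance(jacobian: np.ndarray, gamma, lag_grid) -> CrossCovariance:
    """Matrix-exponential route: C(tau) = expm(J tau) Sigma, C(-tau)=C(tau)'."""
    lags = np.asarray(lag_grid, dtype=float)
    if np.any(lags < 0):
        raise ValueError("lag grid must be nonnegative; negative lags are "
                         "filled by stationarity")
    sigma = stationary_covariance(jacobian, gamma).sigma
    jac = np.asarray(jacobian, dtype=float)
    pos = np.stack([sla.expm(jac * tau) @ sigma for tau in lags])
    full_lags = np.concatenate([-lags[::-1][:-1], lags])
    neg = np.stack([c.T for c in pos[1:][::-1]]) if len(lags) > 1 else \
        np.empty((0,) + sigma.shape)
    values = np.concatenate([neg, pos]) if len(neg) else pos
    return CrossCovariance(lags=full_lags, values=values)


def cross_covariance_spectral(jacobian: np.ndarray, gamma,
                              n_freq: int = 2 ** 21,
                              domega: float = 0.6) -> CrossCovariance:
    """Wiener--Khinchin route, independent of the matrix exponential.

    The spectral density S(omega) = (i omega I - J)^-1 2 Gamma
    (-i omega I - J')^-1 is sampled on a uniform grid and inverse-FFT'd.
    Sampling the spectrum periodizes C, and truncating the grid at
    W = n_freq*domega/2 leaves a tail error of order 2 Gamma/(pi W); the
    defaults keep both below ~1e-6 for O(1) decay rates.
    """
    jac = np.asarray(jacobian, dtype=float)
    n = jac.shape[0]
    g = np.atleast_1d(np.asarray(gamma, dtype=float))
    gmat = np.diag(np.full(n, float(g[0]))) if g.size == 1 else (
        np.diag(g) if g.ndim == 1 else g)
    lam, vec = np.linalg.eig(jac)
    if np.max(lam.real) >= 0:
        raise ValueError("Jacobian is not stable: no stationary state")
    vinv = np.linalg.inv(vec)
    omega = (np.arange(n_freq) - n_freq // 2) * domega
    # (i w I - J)^-1 = V diag(1/(i w - lam)) V^-1, vectorized over w
    resolvent = 1.0 / (1j * omega[:, None] - lam[None, :])    # (F, n)
    left = np.einsum("ij,fj,jk->fik", vec, resolvent, vinv @ (2.0 * gmat))
    spec = np.einsum("fik,fjk->fij", left,
                     np.conj(np.einsum("ij,fj,jk->fik", vec, resolvent,
                                       vinv)))
    # C(tau_m) = (domega/2pi) sum_f S(w_f) exp(i w_f tau_m)
    spec = np.fft.ifftshift(spec, axes=0)
    ctau = np.fft.ifft(spec, axis=0) * (n_freq * domega / (2.0 * np.pi))
    lags = np.fft.fftfreq(n_freq, d=domega / (2.0 * np.pi))
    order = np.argsort(lags)
    return CrossCovariance(lags=lags[order], values=ctau[order].real)


def helmholtz(eigenvalues, gamma) -> HelmholtzSummary:
    """Modewise solenoidal/dissipative decomposition at steady state.

    For each eigenvalue lambda with diffusion Gamma: kappa = -Re(lambda),
    Q = -i Im(lambda)/Re(lambda) Gamma, Pi = kappa/Gamma.  Asserts the
    steady-state identities lambda = (Q - Gamma) Pi and
    lambda Q + Q lambda' = lambda' Gamma - Gamma lambda, and splits the
    kinetic energy lambda'lambda/(2 kappa) into dissipative Re^2/(2 kappa)
    and solenoidal Im^2/(2 kappa) parts (hbar = m = 1 units).
    """
    lam = np.atleast_1d(np.asarray(eigenvalues, dtype=complex))
    g = np.broadcast_to(np.atleast_1d(np.asarray(gamma, dtype=float)),
                        lam.shape).astype(float)
    if np.any(lam.real == 0):
        raise ZeroDivisionError(
            "a mode has Re(lambda) = 0: the steady-state decomposition "
            "requires nonzero dissipation; perturb the eigenvalue or drop "
            "the mode")
    kappa = -lam.real
    q = -1j * lam.imag / lam.real * g
    precision = kappa / g
    e_diss = lam.real ** 2 / (2.0 * kappa)
    e_sol = lam.imag ** 2 / (2.0 * kappa)
    e_tot = (lam.conj() * lam).real / (2.0 * kappa)
    identity_residual = float(np.max(np.abs(lam - (q - g) * precision)))
    constraint_residual = float(np.max(np.abs(
        lam * q + q * lam.conj() - (lam.conj() * g - g * lam))))
    return HelmholtzSummary(eigenvalues=lam, gamma=g, kappa=kappa, q=q,
                            precision=precision,
                            energy_dissipative=e_diss,
                            energy_solenoidal=e_sol, energy_total=e_tot,
                            identity_residual=identity_residual,
                            constraint_residual=constraint_residual)


def _fit_loglog(dist: np.ndarray, coup: np.ndarray, n_bins: int,
                min_per_bin: int = 5):
    """Log-bin |coupling| over log-distance and regress bin means."""
    logd = np.log(dist)
    edges = np.linspace(logd.min(), logd.max() + 1e-12, n_bins + 1)
    centers, means = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        mask = (logd >= lo) & (logd < hi)
        if mask.sum() >= min_per_bin:
            centers.append(0.5 * (lo + hi))
            means.append(np.log(np.abs(coup[mask])).mean())
    centers, means = np.array(centers), np.array(means)
    if centers.size < 2:
        return centers, means, None
    slope = np.polyfit(centers, means, 1)[0]
    return centers, means, float(slope)


def distance_power_law(jacobian: np.ndarray, mirrored_distances: np.ndarray,
                       n_bins: int = 8, tol: float = 1e-9,
                       min_per_bin: int = 5) -> DistancePowerLaw:
    """Distance scaling of excitatory and inhibitory couplings.

    Separates positive and negative real off-diagonal couplings, log-bins
    them over log mirrored distance and regresses the mean log-magnitude on
    log distance per sign class.  Also tabulates reciprocity: fractions of
    reciprocal pairs that are ++ (both excitatory), -- (both inhibitory) or
    mixed-sign.
    """
    jac = np.asarray(jacobian)
    dist = np.asarray(mirrored_distances, dtype=float)
    n = jac.shape[0]
    iu = ~np.eye(n, dtype=bool)
    coup = jac.real
    mask = iu & (np.abs(coup) > tol) & (dist > 0)
    exc = mask & (coup > 0)
    inh = mask & (coup < 0)
    ce, me, slope_e = _fit_loglog(dist[exc], coup[exc], n_bins,
                                  min_per_bin) if exc.sum() >= 2 else \
        (np.array([]), np.array([]), None)
    ci, mi, slope_i = _fit_loglog(dist[inh], coup[inh], n_bins,
                                  min_per_bin) if inh.sum() >= 2 else \
        (np.array([]), np.array([]), None)
    both = mask & mask.T
    pp = mm = pm = 0
    for i in range(n):
        for j in range(i + 1, n):
            if both[i, j]:
                si, sj = np.sign(coup[i, j]), np.sign(coup[j, i])
                if si > 0 and sj > 0:
                    pp += 1
                elif si < 0 and sj < 0:
                    mm += 1
                else:
                    pm += 1
    total = max(pp + mm + pm, 1)
    reciprocity = {"excitatory": pp / total, "inhibitory": mm / total,
                   "mixed": pm / total, "n_pairs": pp + mm + pm}
    return DistancePowerLaw(
        bin_centers_excitatory=np.exp(ce), bin_means_excitatory=me,
        bin_centers_inhibitory=np.exp(ci), bin_means_inhibitory=mi,
        exponent_excitatory=slope_e, exponent_inhibitory=slope_i,
        reciprocity=reciprocity)


def induced_responses(jacobian: np.ndarray, input_matrix: np.ndarray,
                      t_grid, series: np.ndarray | None = None,
                      design: np.ndarray | None = None) -> InducedResponse:
    """First-order kernels exp(J t) C, induced variance and input F tests.

    ``series`` (T x modes) and ``design`` (T x inputs, including a constant
    column) are optional: when given, each mode is regressed on the design
    and the input block is F-tested against the constant-only null.
    """
    jac = np.asarray(jacobian, dtype=float)
    cmat = np.asarray(input_matrix, dtype=float)
    if cmat.ndim == 1:
        cmat = cmat[:, None]
    t_grid = np.asarray(t_grid, dtype=float)
    eigs = np.linalg.eigvals(jac)
    stable = eigs.real < 0
    if stable.any():
        slowest = 1.0 / np.min(-eigs.real[stable])
        if t_grid[-1] < 5.0 * slowest:
            import warnings
            warnings.warn("t_grid does not cover five slowest time "
                          "constants; induced variance is truncated",
                          stacklevel=2)
    kernels = np.stack([sla.expm(jac * t) @ cmat for t in t_grid])
    induced = np.trapezoid(kernels ** 2, t_grid, axis=0)

    f_stats = p_values = df = None
    if series is not None and design is not None:
        from scipy import stats as sstats
        y = np.asarray(series, dtype=float)
        x = np.asarray(design, dtype=float)
        const_cols = np.all(np.isclose(x, x[0:1, :]), axis=0)
        if not const_cols.any():
            raise ValueError("design must include a constant column")
        t_n, k = x.shape
        p_full = k
        p_null = int(const_cols.sum())
        beta, *_ = np.linalg.lstsq(x, y, rcond=None)
        rss_full = ((y - x @ beta) ** 2).sum(axis=0)
        xn = x[:, const_cols]
        beta0, *_ = np.linalg.lstsq(xn, y, rcond=None)
        rss_null = ((y - xn @ beta0) ** 2).sum(axis=0)
        df1, df2 = p_full - p_null, t_n - p_full
        with np.errstate(divide="ignore", invalid="ignore"):
            f_stats = ((rss_null - rss_full) / df1) / (rss_full / df2)
        p_values = sstats.f.sf(f_stats, df1, df2)
        df = (df1, df2)
    return InducedResponse(t_grid=t_grid, kernels=kernels,
                           induced_variance=induced, f_stats=f_stats,
                           p_values=p_values, df=df)
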