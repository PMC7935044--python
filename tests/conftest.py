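import numpy as np
import pytest

from blanketrg import dynamics, synthgen


@pytest.fixture(scope="session")
def small_geometry():
    return synthgen.make_geometry(10, 4.0, "grid", seed=1)


@pytest.fixture(scope="session")
def default_system(small_geometry):
    return synthgen.sample_jacobian(small_geometry, seed=2)


def max_partial_correlation(system, partition):
    """Largest |partial correlation| between any internal state and any
    state outside its particle, conditioned on the particle's blanket;
    computed brute-force from the stationary Gaussian."""
    cov = dynamics.stationary_covariance(
        system.jacobian, system.noise_amplitude).sigma
    n = system.n_states
    worst = 0.0
    for particle in partition.particles:
        mu, b = sorted(particle.internal), sorted(particle.blanket)
        if not mu or not b:
            continue
        ext = sorted(set(range(n)) - set(mu) - set(b))
        if not ext:
            continue
        s_bb = cov[np.ix_(b, b)]
        s_mb = cov[np.ix_(mu, b)]
        s_eb = cov[np.ix_(ext, b)]
        cross = cov[np.ix_(mu, ext)] - s_mb @ np.linalg.solve(s_bb, s_eb.T)
        v_m = np.diag(cov[np.ix_(mu, mu)]
                      - s_mb @ np.linalg.solve(s_bb, s_mb.T))
        v_e = np.diag(cov[np.ix_(ext, ext)]
                      - s_eb @ np.linalg.solve(s_bb, s_eb.T))
        r = cross / np.sqrt(np.outer(np.maximum(v_m, 1e-300),
                                     np.maximum(v_e, 1e-300)))
        worst = max(worst, float(np.abs(r).max()))
    return worst


def support_scores(posterior, system):
    """(F1, on-support correlation) of a Jacobian posterior against truth."""
    true = system.jacobian
    on = np.abs(true - np.diag(np.diag(true))) > 1e-9
    est = posterior.support.copy()
    np.fill_diagonal(est, False)
    tp = int((est & on).sum())
    fp = int((est & ~on).sum())
    fn = int((~est & on).sum())
    precision = tp / max(tp + fp, 1)
    recall = tp / max(tp + fn, 1)
    f1 = 2 * precision * recall / max(precision + recall, 1e-12)
    corr = float(np.corrcoef(posterior.mean[on], true[on])[0, 1])
    return f1, corr


def noisy_observation(system, seed, n_samples=1000, dt=0.12, decimate=6,
                      snr=3.0):
    """TR-sampled latent states plus white measurement noise at the given
    amplitude SNR (signal sd / noise sd)."""
    tr = dt * decimate
    latent = synthgen.simulate_latent(system, n_samples * tr, dt=dt,
                                      seed=seed)
    values = latent.values[::decimate][:n_samples]
    rng = np.random.default_rng(seed + 10_000)
    noisy = values + rng.normal(0.0, values.std() / snr, values.shape)
    return synthgen.TimeSeriesMatrix(values=noisy, sampling_interval=tr)
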