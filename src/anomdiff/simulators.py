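"""Trajectory generators for the five anomalous-diffusion models.

All generators draw from a single ``numpy.random.Generator`` in a documented
order, so runs are bitwise reproducible under a fixed seed and individual
draws can be stubbed in tests.

Conventions
-----------
* Trajectories start at the origin at time 0 and are resampled on the unit
  grid t = 0, 1, ..., L-1 (``regularize``), so index and time coincide.
* CTRW and LW first produce an :class:`~anomdiff.models.EventTrajectory`
  (irregular event times); ATTM, SBM and FBM are generated directly on the
  regular grid.
* In 2D, ATTM/CTRW/FBM/SBM are compositions of independent 1D motions; in
  3D the same holds for FBM/SBM, while ATTM/CTRW (3D) and LW (2D/3D) map
  the 1D step length onto a uniformly random direction on the circle or
  sphere.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erfcinv

from .models import (
    EventTrajectory,
    Interpolation,
    InvalidParameterError,
    Model,
    ModelConstraintError,
    ModelSpec,
    RegularTrajectory,
)

__all__ = [
    "sample_powerlaw",
    "simulate_ctrw",
    "simulate_fbm",
    "simulate_lw",
    "simulate_attm",
    "simulate_sbm",
    "regularize",
    "lift_dimension",
    "random_directions",
    "simulate",
    "fractional_gaussian_noise",
]

_WAIT_CHUNK = 32  # waiting/flight times are drawn in chunks of this size

def _as_generator(rng) -> np.random.Generator:
    """Accept a Generator (or duck-typed stub), a seed, or None."""
    if hasattr(rng, "standard_normal"):
        return rng
    return np.random.default_rng(rng)



def sample_powerlaw(exponent: float, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` times from the Pareto density psi(t) ~ t^-exponent on t >= 1.

    Inverse-CDF sampling: t = (1 - u)^(-1 / (exponent - 1)) with u uniform
    on [0, 1).  Requires ``exponent > 1`` for normalizability.
    """
    if exponent <= 1:
        raise InvalidParameterError(
            f"power-law tail exponent must exceed 1, got {exponent}"
        )
    if n < 0:
        raise InvalidParameterError("n must be non-negative")
    if n == 0:
        return np.empty(0)
    u = rng.random(n)
    return (1.0 - u) ** (-1.0 / (exponent - 1.0))


def _draw_event_times(
    tail_exponent: float, horizon: float, rng: np.random.Generator
) -> np.ndarray:
    """Cumulative power-law event times continued until the horizon is covered."""
    waits: list[np.ndarray] = []
    total = 0.0
    while total < horizon:
        chunk = sample_powerlaw(tail_exponent, _WAIT_CHUNK, rng)
        waits.append(chunk)
        total += float(chunk.sum())
    times = np.cumsum(np.concatenate(waits))
    stop = int(np.searchsorted(times, horizon))  # first index with time >= horizon
    return times[: stop + 1]


def simulate_ctrw(
    spec: ModelSpec, horizon: float, rng: np.random.Generator, dim: int = 1
) -> EventTrajectory:
    """Continuous-time random walk: power-law waits, Gaussian jumps.

    Waiting times follow psi(t) ~ t^-sigma with sigma = alpha + 1; at each
    event the tracer jumps by a Gaussian displacement of s.d. sqrt(D) and
    holds its position until the next event.  For alpha = 1 the waiting time
    is fixed at 1 (the narrow limit of the one-sided stable density).
    ``dim`` = 3 draws a uniform random direction per jump; 2D CTRW is built
    by axis composition in :func:`simulate`.
    """
    if spec.model is not Model.CTRW:
        raise ModelConstraintError("spec.model must be CTRW")
    if spec.alpha > 1:
        raise ModelConstraintError("CTRW is strictly subdiffusive (alpha <= 1)")
    if horizon <= 0:
        raise InvalidParameterError("horizon must be positive")
    if spec.alpha == 1.0:
        times = np.arange(1.0, np.floor(horizon) + 1.0)
        if times.size == 0 or times[-1] < horizon:
            times = np.append(times, times[-1] + 1.0 if times.size else 1.0)
    else:
        times = _draw_event_times(spec.sigma, horizon, rng)
    n = times.size
    step_sd = np.sqrt(spec.diffusivity)
    if dim == 1:
        steps = step_sd * rng.standard_normal(n)[None, :]
    else:
        lengths = np.abs(step_sd * rng.standard_normal(n))
        steps = lift_dimension(Model.CTRW, dim, lengths, rng)
    positions = np.cumsum(steps, axis=1)
    return EventTrajectory(times, positions, Interpolation.HOLD)


def simulate_lw(
    spec: ModelSpec, horizon: float, rng: np.random.Generator, dim: int = 1
) -> EventTrajectory:
    """Levy walk: constant-speed flights with power-law durations.

    Flight times follow psi(t) ~ t^-(sigma+1); each flight covers a distance
    v * t_i in a random sense (+/- in 1D, uniform direction in 2D/3D), with
    the speed v drawn once per trajectory uniformly from (0, 10] unless
    fixed in the spec.  The exponent map is alpha = 3 - sigma for
    1 < sigma < 2, and alpha = 2 (ballistic) for 0 < sigma < 1.
    """
    if spec.model is not Model.LW:
        raise ModelConstraintError("spec.model must be LW")
    if spec.alpha < 1:
        raise ModelConstraintError("LW is superdiffusive (alpha >= 1)")
    if horizon <= 0:
        raise InvalidParameterError("horizon must be positive")
    speed = spec.speed if spec.speed is not None else 10.0 * (1.0 - rng.random())
    times = _draw_event_times(spec.sigma + 1.0, horizon, rng)
    flights = np.diff(times, prepend=0.0)
    lengths = speed * flights
    if dim == 1:
        signs = 1.0 - 2.0 * rng.integers(0, 2, times.size)  # (-1)^r, r in {0,1}
        steps = (signs * lengths)[None, :]
    else:
        steps = lift_dimension(Model.LW, dim, lengths, rng)
    positions = np.cumsum(steps, axis=1)
    return EventTrajectory(times, positions, Interpolation.LINEAR)


# ---------------------------------------------------------------------------
# fractional Gaussian noise


def _fgn_autocovariance(hurst: float, n: int) -> np.ndarray:
    """Autocovariance gamma(k), k = 0..n, of unit-variance fGn."""
    k = np.arange(n + 1, dtype=float)
    h2 = 2.0 * hurst
    return 0.5 * ((k + 1) ** h2 - 2 * k**h2 + np.abs(k - 1) ** h2)


def _fgn_davies_harte(
    hurst: float, n: int, rng: np.random.Generator, size: int
) -> np.ndarray | None:
    """Exact fGn by circulant embedding; ``None`` if the embedding fails."""
    gamma = _fgn_autocovariance(hurst, n)
    row = np.concatenate([gamma, gamma[-2:0:-1]])  # length 2n
    eig = np.fft.fft(row).real
    if np.min(eig) < -1e-9 * np.max(eig):
        return None
    eig = np.clip(eig, 0.0, None)
    m = 2 * n
    gn = rng.standard_normal((size, m))
    w = np.zeros((size, m), dtype=complex)
    w[:, 0] = np.sqrt(eig[0] / m) * gn[:, 0]
    idx = np.arange(1, n)
    w[:, idx] = np.sqrt(eig[idx] / (2 * m)) * (gn[:, 2 * idx - 1] + 1j * gn[:, 2 * idx])
    w[:, n] = np.sqrt(eig[n] / m) * gn[:, m - 1]
    w[:, m - idx] = np.conjugate(w[:, idx])
    return np.fft.fft(w, axis=1)[:, :n].real


def _fgn_hosking(
    hurst: float, n: int, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Exact fGn by the Durbin–Levinson (Hosking) recursion, O(n^2)."""
    gamma = _fgn_autocovariance(hurst, n)
    out = np.empty((size, n))
    z = rng.standard_normal((size, n))
    phi = np.zeros(n)
    prev = np.zeros(n)
    v = 1.0
    out[:, 0] = z[:, 0]
    for i in range(1, n):
        prev, phi = phi, prev
        phi[i - 1] = (gamma[i] - prev[: i - 1] @ gamma[i - 1 : 0 : -1]) / v
        phi[: i - 1] = prev[: i - 1] - phi[i - 1] * prev[: i - 1][::-1]
        v *= 1.0 - phi[i - 1] ** 2
        out[:, i] = out[:, :i] @ phi[:i][::-1] + np.sqrt(v) * z[:, i]
    return out


def fractional_gaussian_noise(
    hurst: float,
    n: int,
    rng: np.random.Generator,
    size: int = 1,
    method: str = "auto",
) -> np.ndarray:
    """``size`` independent series of ``n`` unit-variance fGn increments.

    ``method``: "auto" tries the Davies–Harte circulant embedding and falls
    back to the Hosking recursion when the embedding is not nonnegative
    definite; "davies-harte" and "hosking" force a method.
    """
    if not (0 < hurst < 1):
        raise InvalidParameterError("Hurst exponent must lie in (0, 1)")
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    if method not in ("auto", "davies-harte", "hosking"):
        raise InvalidParameterError(f"unknown fGn method {method!r}")
    if method in ("auto", "davies-harte"):
        out = _fgn_davies_harte(hurst, n, rng, size)
        if out is not None:
            return out
        if method == "davies-harte":
            raise InvalidParameterError("circulant embedding not nonnegative definite")
    return _fgn_hosking(hurst, n, rng, size)


def simulate_fbm(
    spec: ModelSpec,
    length: int,
    dim: int = 1,
    rng: np.random.Generator | None = None,
) -> RegularTrajectory:
    """Fractional Brownian motion: cumulative sums of exact fGn per axis.

    Components along orthogonal axes are independent.  With diffusivity K_H
    the ensemble MSD per axis is 2 K_H t^(2H), H = alpha/2.
    """
    if spec.model is not Model.FBM:
        raise ModelConstraintError("spec.model must be FBM")
    if spec.alpha >= 2:
        raise ModelConstraintError("FBM cannot reach the ballistic limit alpha = 2")
    rng = _as_generator(rng)
    fgn = fractional_gaussian_noise(spec.hurst, length - 1, rng, size=dim)
    increments = np.sqrt(2.0 * spec.diffusivity) * fgn
    positions = np.concatenate(
        [np.zeros((dim, 1)), np.cumsum(increments, axis=1)], axis=1
    )
    return RegularTrajectory(positions, spec=spec)


# ---------------------------------------------------------------------------
# ATTM / SBM


def _attm_parameters(alpha: float, rng: np.random.Generator) -> tuple[float, float]:
    """Draw (sigma, gamma) with sigma uniform on (0, 3] until sigma < gamma < sigma+1."""
    while True:
        sigma = 3.0 * (1.0 - rng.random())
        gamma = sigma / alpha
        if sigma < gamma < sigma + 1.0:
            return sigma, gamma


def simulate_attm(
    spec: ModelSpec,
    horizon: float,
    dt: float = 1.0,
    rng: np.random.Generator | None = None,
    dim: int = 1,
) -> RegularTrajectory:
    """Annealed transient time motion: Brownian segments with random diffusivity.

    Diffusivities follow P(D) ~ D^(sigma-1) on (0, 1] and each segment lasts
    t_i = D_i^(-gamma) with gamma = sigma/alpha, (sigma, gamma) accepted in
    the subdiffusive regime sigma < gamma < sigma + 1.  Brownian increments
    within a segment have variance 2 D_i dt.  ``alpha = 1`` degenerates to
    plain Brownian motion with a single random diffusivity.  ``dim`` = 3
    maps per-step displacement lengths to random directions on the sphere;
    2D ATTM is built by axis composition in :func:`simulate`.
    """
    if spec.model is not Model.ATTM:
        raise ModelConstraintError("spec.model must be ATTM")
    if spec.alpha > 1:
        raise ModelConstraintError("ATTM is strictly subdiffusive (alpha <= 1)")
    rng = _as_generator(rng)
    n_steps = int(round(horizon / dt))
    if spec.alpha == 1.0:
        # rejection condition sigma < gamma is unsatisfiable at alpha = 1
        d = rng.random()
        sds = np.full(n_steps, np.sqrt(2.0 * d * dt))
    else:
        sigma, gamma = _attm_parameters(spec.alpha, rng)
        sds = np.empty(n_steps)
        done = 0
        while done < n_steps:
            d = rng.random() ** (1.0 / sigma)  # inverse CDF of P(D) ~ D^(sigma-1)
            # duration D^-gamma can overflow for tiny D; only the part of the
            # segment inside the horizon is ever realized
            with np.errstate(divide="ignore", over="ignore"):
                duration = float(np.exp(-gamma * np.log(d))) if d > 0 else np.inf
            seg = n_steps - done
            if duration / dt < seg:
                seg = max(1, int(round(duration / dt)))
            sds[done : done + seg] = np.sqrt(2.0 * d * dt)
            done += seg
    if dim == 1:
        steps = (sds * rng.standard_normal(n_steps))[None, :]
    else:
        lengths = np.abs(sds * rng.standard_normal(n_steps))
        steps = lift_dimension(Model.ATTM, dim, lengths, rng)
    positions = np.concatenate([np.zeros((dim, 1)), np.cumsum(steps, axis=1)], axis=1)
    return RegularTrajectory(positions, spec=spec)


def _sbm_increments(
    alpha: float,
    length: int,
    diffusivity: float,
    rng: np.random.Generator,
    size: int = 1,
) -> np.ndarray:
    """SBM displacement batch of shape (size, length-1).

    Increment i has variance 2 K_a (i^alpha - (i-1)^alpha); the Gaussian
    deviate is realized as sqrt(2) * erfcinv(2u) applied to uniform draws.
    """
    i = np.arange(1, length, dtype=float)
    dvar = 2.0 * diffusivity * (i**alpha - (i - 1.0) ** alpha)
    u = rng.random((size, length - 1))
    z = np.sqrt(2.0) * erfcinv(np.clip(2.0 * u, 1e-16, 2.0 - 1e-16))
    return np.sqrt(dvar) * z


def simulate_sbm(
    spec: ModelSpec,
    length: int,
    rng: np.random.Generator | None = None,
    dim: int = 1,
) -> RegularTrajectory:
    """Scaled Brownian motion: Gaussian increments with diffusivity K(t) ~ t^(alpha-1).

    Axes are always independent (2D and 3D alike); the ensemble MSD per axis
    is 2 K_a t^alpha exactly on the sampling grid.
    """
    if spec.model is not Model.SBM:
        raise ModelConstraintError("spec.model must be SBM")
    rng = _as_generator(rng)
    increments = _sbm_increments(spec.alpha, length, spec.diffusivity, rng, size=dim)
    positions = np.concatenate(
        [np.zeros((dim, 1)), np.cumsum(increments, axis=1)], axis=1
    )
    return RegularTrajectory(positions, spec=spec)


# ---------------------------------------------------------------------------
# resampling and dimension lifting


def regularize(
    traj: EventTrajectory, horizon: float, dt: float = 1.0, spec: ModelSpec | None = None
) -> RegularTrajectory:
    """Resample an event trajectory at uniform times 0, dt, ..., horizon.

    ``hold`` keeps the last event position (CTRW: the tracer waits between
    jumps); ``linear`` interpolates along the current flight (LW).  Before
    the first event the tracer sits at the origin.
    """
    if dt <= 0:
        raise InvalidParameterError("dt must be positive")
    if traj.times.size == 0 or traj.times[-1] < horizon:
        raise InvalidParameterError("event trajectory does not cover the horizon")
    grid = np.arange(int(np.floor(horizon / dt)) + 1, dtype=float) * dt
    times = np.concatenate([[0.0], traj.times])
    padded = np.concatenate([np.zeros((traj.dim, 1)), traj.positions], axis=1)
    if traj.interpolation is Interpolation.HOLD:
        idx = np.searchsorted(times, grid, side="right") - 1
        positions = padded[:, idx]
    else:
        positions = np.vstack([np.interp(grid, times, padded[d]) for d in range(traj.dim)])
    return RegularTrajectory(positions, spec=spec)


def random_directions(dim: int, n: int, rng: np.random.Generator) -> np.ndarray:
    """``n`` unit vectors uniform on the circle (dim=2) or sphere (dim=3), shape (dim, n)."""
    if dim == 2:
        theta = 2.0 * np.pi * rng.random(n)
        return np.vstack([np.cos(theta), np.sin(theta)])
    if dim == 3:
        # uniform on the sphere: z uniform on [-1, 1], azimuth uniform
        z = 2.0 * rng.random(n) - 1.0
        theta = 2.0 * np.pi * rng.random(n)
        r = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
        return np.vstack([r * np.cos(theta), r * np.sin(theta), z])
    raise InvalidParameterError("dim must be 2 or 3 for random directions")


def lift_dimension(
    model: Model,
    dim: int,
    lengths_or_components: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Map per-event 1D step lengths onto random directions in ``dim`` dimensions.

    ``dim`` = 1 passes the input through unchanged (as a (1, n) array).  Used
    for ATTM/CTRW in 3D and LW in 2D/3D, where the 1D step length sets the
    radius of the circle/sphere on which the step ends.
    """
    if dim == 1:
        return np.atleast_2d(np.asarray(lengths_or_components, dtype=float))
    if dim not in (2, 3):
        raise InvalidParameterError("dim must be 1, 2 or 3")
    lengths = np.asarray(lengths_or_components, dtype=float)
    return lengths * random_directions(dim, lengths.size, rng)


# ---------------------------------------------------------------------------
# dispatcher


def _simulate_1d(
    spec: ModelSpec, length: int, rng: np.random.Generator
) -> RegularTrajectory:
    horizon = float(length - 1)
    if spec.model is Model.CTRW:
        return regularize(simulate_ctrw(spec, horizon, rng), horizon, spec=spec)
    if spec.model is Model.LW:
        return regularize(simulate_lw(spec, horizon, rng), horizon, spec=spec)
    if spec.model is Model.FBM:
        return simulate_fbm(spec, length, dim=1, rng=rng)
    if spec.model is Model.ATTM:
        return simulate_attm(spec, horizon, rng=rng)
    return simulate_sbm(spec, length, rng=rng)


def simulate(
    model: Model | str,
    alpha: float,
    length: int,
    dim: int = 1,
    rng: np.random.Generator | int | None = None,
    diffusivity: float = 1.0,
) -> RegularTrajectory:
    """Generate one trajectory of exactly ``length`` points per dimension.

    Dispatches to the model-specific generator, lifts to 2D/3D following
    each model's recipe, and resamples on the unit grid.  Deterministic
    given an integer seed or a seeded generator.
    """
    spec = ModelSpec.create(model, alpha, diffusivity=diffusivity)
    if length < 2:
        raise InvalidParameterError("length must be >= 2")
    if dim not in (1, 2, 3):
        raise InvalidParameterError("dim must be 1, 2 or 3")
    rng = _as_generator(rng)
    horizon = float(length - 1)

    if dim == 1:
        return _simulate_1d(spec, length, rng)
    if spec.model in (Model.FBM, Model.SBM):
        if spec.model is Model.FBM:
            return simulate_fbm(spec, length, dim=dim, rng=rng)
        return simulate_sbm(spec, length, rng=rng, dim=dim)
    if spec.model is Model.LW:
        return regularize(simulate_lw(spec, horizon, rng, dim=dim), horizon, spec=spec)
    if spec.model is Model.CTRW:
        if dim == 2:  # composition of independent 1D motions
            parts = [_simulate_1d(spec, length, rng) for _ in range(2)]
            return RegularTrajectory(
                np.vstack([p.positions for p in parts]), spec=spec
            )
        return regularize(simulate_ctrw(spec, horizon, rng, dim=3), horizon, spec=spec)
    # ATTM
    if dim == 2:
        parts = [_simulate_1d(spec, length, rng) for _ in range(2)]
        return RegularTrajectory(np.vstack([p.positions for p in parts]), spec=spec)
    return simulate_attm(spec, horizon, rng=rng, dim=3)
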