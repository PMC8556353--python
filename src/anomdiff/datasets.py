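"""Assembly of benchmark labeled datasets for the three tasks.

Pipeline applied to every raw trajectory (simulated at full length L=1000
for tasks 1 and 2, two length-200 segments for task 3):

1. standardize: divide by the pooled standard deviation of unit-lag
   displacements, so sigma_D = 1;
2. corrupt with localization noise, i.i.d. Gaussian of s.d. sigma_noise
   per coordinate (sigma_noise in {0.1, 0.5, 1} => SNR in {10, 2, 1});
3. scale by |z|, z ~ N(0, 1), emulating a random effective diffusion
   coefficient (applied after the noise so the recorded SNR levels are
   exact ratios);
4. cut to the target length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import (
    ChangepointLabel,
    DegenerateTrajectoryError,
    InvalidParameterError,
    LabeledDataset,
    Model,
    RegularTrajectory,
    Task,
    compatible_models,
)
from .simulators import simulate

__all__ = [
    "NoiseConfig",
    "DatasetConfig",
    "standardize",
    "scale_diffusivity",
    "add_noise",
    "compute_snr",
    "build_task1",
    "build_task2",
    "build_task3",
    "build_dataset",
    "ALPHA_GRID",
]

# anomalous-exponent grid for task 1 balancing: 0.05, 0.10, ..., 2.00
ALPHA_GRID = np.round(np.arange(1, 41) * 0.05, 2)

DEFAULT_NOISE_LEVELS = (0.1, 0.5, 1.0)


@dataclass(frozen=True)
class NoiseConfig:
    """Per-axis localization-noise amplitude and the SNR it implies."""

    sigma_noise: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.sigma_noise):
            raise InvalidParameterError("sigma_noise must be positive")

    @property
    def snr(self) -> float:
        """SNR of a standardized trajectory (sigma_D = 1): mean of 1/sigma per axis."""
        return float(np.mean([1.0 / s for s in self.sigma_noise]))


@dataclass(frozen=True)
class DatasetConfig:
    """Knobs of the dataset builders; defaults are the benchmark conditions."""

    noise_levels: tuple[float, ...] = DEFAULT_NOISE_LEVELS
    length_range: tuple[int, int] = (10, 1000)
    raw_length: int = 1000        # simulation length before cutting (T1/T2)
    segment_length: int = 200     # total length of task-3 trajectories
    scale_diffusivity: bool = True


def _displacement_sd(positions: np.ndarray) -> float:
    """Population s.d. of unit-lag displacements pooled over all axes."""
    disp = np.diff(positions, axis=1).ravel()
    return float(np.std(disp))


def standardize(traj: RegularTrajectory) -> RegularTrajectory:
    """Rescale so the pooled unit-lag displacement s.d. equals 1 exactly.

    One scale per trajectory (pooled over axes), preserving isotropy.
    Raises :class:`DegenerateTrajectoryError` for immobile trajectories.
    """
    if traj.length < 3:
        raise InvalidParameterError("standardize needs at least 3 samples")
    sd = _displacement_sd(traj.positions)
    if sd == 0.0 or not np.isfinite(sd):
        raise DegenerateTrajectoryError("zero displacement s.d. (immobile trajectory)")
    return RegularTrajectory(
        traj.positions / sd,
        spec=traj.spec,
        noise_sigma=traj.noise_sigma,
        scale=traj.scale,
        snr=traj.snr,
    )


def scale_diffusivity(
    traj: RegularTrajectory, rng: np.random.Generator
) -> RegularTrajectory:
    """Multiply all coordinates by |z|, z ~ N(0, 1); the scale is recorded.

    The absolute value avoids sign flips (irrelevant for a centered path)
    and the degenerate zero scale.
    """
    z = abs(float(rng.standard_normal()))
    return RegularTrajectory(
        traj.positions * z,
        spec=traj.spec,
        noise_sigma=traj.noise_sigma,
        scale=z,
        snr=traj.snr,
    )


def compute_snr(traj_clean: RegularTrajectory, sigma_noise) -> float:
    """Overall SNR: arithmetic mean over axes of sigma_D(axis) / sigma_noise(axis)."""
    sigma_noise = np.broadcast_to(
        np.asarray(sigma_noise, dtype=float), (traj_clean.dim,)
    )
    if np.any(sigma_noise <= 0):
        raise InvalidParameterError("SNR undefined for sigma_noise <= 0")
    disp = np.diff(traj_clean.positions, axis=1)
    per_axis = np.std(disp, axis=1) / sigma_noise
    return float(np.mean(per_axis))


def add_noise(
    traj: RegularTrajectory, noise: NoiseConfig, rng: np.random.Generator
) -> RegularTrajectory:
    """Add i.i.d. Gaussian localization noise to every coordinate.

    Per-axis amplitudes may differ (2D/3D); the overall SNR relative to the
    clean input is recorded in the metadata.
    """
    sigma = np.broadcast_to(np.asarray(noise.sigma_noise, dtype=float), (traj.dim,))
    snr = compute_snr(traj, sigma)
    noisy = traj.positions + sigma[:, None] * rng.standard_normal(traj.positions.shape)
    return RegularTrajectory(
        noisy, spec=traj.spec, noise_sigma=sigma.copy(), scale=traj.scale, snr=snr
    )


def _draw_noise(
    dim: int, levels: tuple[float, ...], rng: np.random.Generator
) -> NoiseConfig:
    """Independent noise level per axis, drawn from the configured set."""
    idx = rng.integers(0, len(levels), size=dim)
    return NoiseConfig(tuple(float(levels[i]) for i in idx))


def _postprocess(
    traj: RegularTrajectory,
    length: int,
    config: DatasetConfig,
    rng: np.random.Generator,
) -> RegularTrajectory:
    """standardize -> noise -> |z| scale -> cut, per the dataset recipe."""
    out = standardize(traj)
    out = add_noise(out, _draw_noise(traj.dim, config.noise_levels, rng), rng)
    if config.scale_diffusivity:
        out = scale_diffusivity(out, rng)
    return RegularTrajectory(
        out.positions[:, :length],
        spec=out.spec,
        noise_sigma=out.noise_sigma,
        scale=out.scale,
        snr=out.snr,
    )


def _simulate_valid(
    model: Model, alpha: float, length: int, dim: int, rng: np.random.Generator
) -> RegularTrajectory:
    """Simulate, regenerating on the rare immobile draw (zero displacement s.d.)."""
    while True:
        traj = simulate(model, alpha, length, dim=dim, rng=rng)
        if _displacement_sd(traj.positions) > 0:
            return traj


def build_task1(
    n: int,
    dim: int = 1,
    seed: int | np.random.Generator | None = None,
    config: DatasetConfig | None = None,
) -> LabeledDataset:
    """Exponent-inference dataset: balanced in alpha, not in model.

    alpha is drawn uniformly over the grid {0.05, 0.10, ..., 2.0}; the model
    is drawn uniformly among those compatible with the drawn alpha.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    config = config or DatasetConfig()
    rng = np.random.default_rng(seed)
    ds = LabeledDataset(task=Task.T1)
    lo, hi = config.length_range
    for _ in range(n):
        alpha = float(ALPHA_GRID[rng.integers(0, ALPHA_GRID.size)])
        models = compatible_models(alpha)
        model = models[rng.integers(0, len(models))]
        length = int(rng.integers(lo, hi + 1))
        traj = _simulate_valid(model, alpha, config.raw_length, dim, rng)
        ds.trajectories.append(_postprocess(traj, length, config, rng))
        ds.labels.append(alpha)
    return ds


def _draw_alpha(model: Model, rng: np.random.Generator) -> float:
    """Uniform alpha on the model's admissible sub-grid of {0.05, ..., 2.0}."""
    grid = [a for a in ALPHA_GRID if model in compatible_models(float(a))]
    return float(grid[rng.integers(0, len(grid))])


def build_task2(
    n: int,
    dim: int = 1,
    seed: int | np.random.Generator | None = None,
    config: DatasetConfig | None = None,
) -> LabeledDataset:
    """Model-classification dataset: equal counts per model (within 1)."""
    if n < 5:
        raise InvalidParameterError("n must be >= 5 (one per model)")
    config = config or DatasetConfig()
    rng = np.random.default_rng(seed)
    ds = LabeledDataset(task=Task.T2)
    lo, hi = config.length_range
    counts = np.full(5, n // 5)
    counts[: n % 5] += 1
    for model, count in zip(Model, counts):
        for _ in range(int(count)):
            alpha = _draw_alpha(model, rng)
            length = int(rng.integers(lo, hi + 1))
            traj = _simulate_valid(model, alpha, config.raw_length, dim, rng)
            ds.trajectories.append(_postprocess(traj, length, config, rng))
            ds.labels.append(model)
    return ds


def _concat_segments(
    seg1: RegularTrajectory, seg2: RegularTrajectory, changepoint: int
) -> np.ndarray:
    """Join two standardized segments at ``changepoint`` with no jump.

    Indices 0..changepoint come from segment 1; segment 2 is translated so
    its origin coincides with segment 1's position at the changepoint and
    fills indices changepoint..L-1.
    """
    length = seg1.length
    out = np.empty_like(seg1.positions)
    out[:, : changepoint + 1] = seg1.positions[:, : changepoint + 1]
    anchor = seg1.positions[:, changepoint : changepoint + 1]
    tail = seg2.positions[:, 1 : length - changepoint] - seg2.positions[:, :1]
    out[:, changepoint + 1 :] = anchor + tail
    return out


def build_task3(
    n: int,
    dim: int = 1,
    seed: int | np.random.Generator | None = None,
    config: DatasetConfig | None = None,
) -> LabeledDataset:
    """Segmentation dataset: length-200 trajectories with one changepoint.

    The two segments' (model, alpha) pairs are redrawn until they differ in
    at least one feature; the changepoint index is uniform on {1, ..., 199}.
    Segments are standardized independently, joined continuously, then noise
    and the |z| scale are applied to the concatenated trajectory.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    config = config or DatasetConfig()
    rng = np.random.default_rng(seed)
    ds = LabeledDataset(task=Task.T3)
    length = config.segment_length
    for _ in range(n):
        while True:
            a1 = float(ALPHA_GRID[rng.integers(0, ALPHA_GRID.size)])
            m1 = compatible_models(a1)[rng.integers(0, len(compatible_models(a1)))]
            a2 = float(ALPHA_GRID[rng.integers(0, ALPHA_GRID.size)])
            m2 = compatible_models(a2)[rng.integers(0, len(compatible_models(a2)))]
            if (m1, a1) != (m2, a2):
                break
        t_cp = int(rng.integers(1, length))
        seg1 = standardize(_simulate_valid(m1, a1, length, dim, rng))
        seg2 = standardize(_simulate_valid(m2, a2, length, dim, rng))
        joined = RegularTrajectory(
            _concat_segments(seg1, seg2, t_cp), spec=seg1.spec
        )
        out = add_noise(joined, _draw_noise(dim, config.noise_levels, rng), rng)
        if config.scale_diffusivity:
            out = scale_diffusivity(out, rng)
        ds.trajectories.append(out)
        ds.labels.append(ChangepointLabel(t_cp, m1, a1, m2, a2))
    return ds


def build_dataset(
    task: Task | int,
    n: int,
    dim: int = 1,
    seed: int | np.random.Generator | None = None,
    config: DatasetConfig | None = None,
) -> LabeledDataset:
    """Dispatch to the task-specific builder."""
    task = Task(task) if not isinstance(task, Task) else task
    builder = {Task.T1: build_task1, Task.T2: build_task2, Task.T3: build_task3}[task]
    return builder(n, dim=dim, seed=seed, config=config)
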