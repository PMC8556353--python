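"""Domain types shared across the toolkit.

The five diffusion models and their exponent constraints:

========  =========================  =====================================
model     anomalous exponent range   derived parameters
========  =========================  =====================================
ATTM      0.05 <= alpha <= 1         sigma, gamma drawn with alpha = sigma/gamma
CTRW      0.05 <= alpha <= 1         waiting-time tail sigma = alpha + 1
FBM       0.05 <= alpha < 2          Hurst exponent H = alpha / 2
LW        1 <= alpha <= 2            flight-time tail sigma = 3 - alpha
SBM       0.05 <= alpha <= 2         diffusivity K(t) = alpha * K_a * t^(alpha-1)
========  =========================  =====================================
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

ALPHA_MIN = 0.05
ALPHA_MAX = 2.0


class Model(enum.Enum):
    """Diffusion model identity, in the fixed (alphabetical) index order."""

    ATTM = 0
    CTRW = 1
    FBM = 2
    LW = 3
    SBM = 4

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


MODELS = tuple(Model)


class InvalidParameterError(ValueError):
    """A parameter outside its mathematically valid range."""


class ModelConstraintError(ValueError):
    """An (model, alpha) combination the model cannot realize."""


class DegenerateTrajectoryError(ValueError):
    """A trajectory on which the requested operation is undefined (e.g. immobile)."""


def alpha_bounds(model: Model) -> tuple[float, float]:
    """Inclusive-ish bounds of the anomalous exponent for ``model``.

    FBM's upper bound is exclusive (no ballistic limit); all others inclusive.
    """
    if model in (Model.CTRW, Model.ATTM):
        return ALPHA_MIN, 1.0
    if model is Model.LW:
        return 1.0, ALPHA_MAX
    if model is Model.FBM:
        return ALPHA_MIN, ALPHA_MAX  # alpha < 2 enforced in compatible()
    return ALPHA_MIN, ALPHA_MAX


def compatible(model: Model, alpha: float) -> bool:
    """Whether ``model`` can produce anomalous exponent ``alpha``."""
    if not (ALPHA_MIN <= alpha <= ALPHA_MAX):
        return False
    if model in (Model.CTRW, Model.ATTM) and alpha > 1:
        return False
    if model is Model.LW and alpha < 1:
        return False
    if model is Model.FBM and alpha >= ALPHA_MAX:
        return False
    return True


def compatible_models(alpha: float) -> tuple[Model, ...]:
    """All models able to produce exponent ``alpha``, in fixed order."""
    return tuple(m for m in MODELS if compatible(m, alpha))


@dataclass(frozen=True)
class ModelSpec:
    """A diffusion model plus its exponent and derived parameters.

    Parameters not meaningful for a model are left ``None`` (e.g. ``hurst``
    for CTRW).  ATTM's ``sigma``/``gamma`` pair is drawn stochastically at
    simulation time, so the spec carries only the exponent.
    """

    model: Model
    alpha: float
    sigma: float | None = None
    gamma: float | None = None
    hurst: float | None = None
    speed: float | None = None
    diffusivity: float = 1.0

    @classmethod
    def create(
        cls,
        model: Model | str,
        alpha: float,
        diffusivity: float = 1.0,
        speed: float | None = None,
    ) -> "ModelSpec":
        """Validate ``(model, alpha)`` and fill the derived parameters."""
        if isinstance(model, str):
            model = Model[model.upper()]
        alpha = float(alpha)
        if not (ALPHA_MIN <= alpha <= ALPHA_MAX):
            raise ModelConstraintError(
                f"alpha={alpha} outside the admissible range [{ALPHA_MIN}, {ALPHA_MAX}]"
            )
        if not compatible(model, alpha):
            raise ModelConstraintError(
                f"{model.name} cannot realize alpha={alpha}: "
                f"CTRW/ATTM are strictly subdiffusive (alpha <= 1), "
                f"LW is superdiffusive (alpha >= 1), FBM excludes alpha = 2"
            )
        if diffusivity <= 0:
            raise InvalidParameterError("diffusivity must be positive")
        sigma = gamma = hurst = None
        if model is Model.CTRW:
            sigma = alpha + 1.0
        elif model is Model.LW:
            # flight-time tail: alpha = 3 - sigma for 1 < sigma < 2; any
            # sigma in (0, 1) yields the ballistic alpha = 2.
            sigma = 3.0 - alpha if alpha < 2 else 0.5
        elif model is Model.FBM:
            hurst = alpha / 2.0
        if speed is not None and not (0 < speed <= 10):
            raise InvalidParameterError("LW speed must lie in (0, 10]")
        return cls(
            model=model,
            alpha=alpha,
            sigma=sigma,
            gamma=gamma,
            hurst=hurst,
            speed=speed,
            diffusivity=float(diffusivity),
        )


class Interpolation(enum.Enum):
    HOLD = "hold"      # tracer waits at its position between jumps (CTRW)
    LINEAR = "linear"  # constant-velocity flight between turning points (LW)


@dataclass
class EventTrajectory:
    """Irregularly sampled path: positions attained at strictly increasing times.

    The tracer starts at the origin at time 0; ``positions[:, i]`` is the
    position reached at ``times[i]``.
    """

    times: np.ndarray            # shape (n_events,)
    positions: np.ndarray        # shape (dim, n_events)
    interpolation: Interpolation

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.times.ndim != 1 or self.positions.shape[1] != self.times.size:
            raise InvalidParameterError("times and positions shapes disagree")
        if self.times.size and (np.any(np.diff(self.times) <= 0) or self.times[0] <= 0):
            raise InvalidParameterError("event times must be strictly increasing and > 0")

    @property
    def dim(self) -> int:
        return self.positions.shape[0]


@dataclass
class RegularTrajectory:
    """Uniformly sampled positions (unit time step) with provenance metadata."""

    positions: np.ndarray              # shape (dim, L)
    spec: ModelSpec | None = None
    noise_sigma: np.ndarray | None = None  # per-axis localization noise s.d.
    scale: float | None = None             # |z| diffusivity scale factor
    snr: float | None = None               # mean per-axis SNR recorded at noise time

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        if self.positions.shape[1] < 2:
            raise InvalidParameterError("a trajectory needs at least 2 samples")
        if not np.all(np.isfinite(self.positions)):
            raise InvalidParameterError("non-finite coordinates")

    @property
    def dim(self) -> int:
        return self.positions.shape[0]

    @property
    def length(self) -> int:
        return self.positions.shape[1]


class Task(enum.Enum):
    """The three benchmark tasks."""

    T1 = 1  # anomalous-exponent inference
    T2 = 2  # model classification
    T3 = 3  # changepoint segmentation


@dataclass(frozen=True)
class ChangepointLabel:
    """Ground truth for one segmented trajectory."""

    changepoint: int
    model_1: Model
    alpha_1: float
    model_2: Model
    alpha_2: float


@dataclass
class LabeledDataset:
    """Trajectories plus per-trajectory ground truth for one task."""

    task: Task
    trajectories: list[RegularTrajectory] = field(default_factory=list)
    labels: list = field(default_factory=list)  # float | Model | ChangepointLabel

    def __len__(self) -> int:
        return len(self.trajectories)
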