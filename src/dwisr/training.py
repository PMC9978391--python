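"""Training-pair construction, b-value grouping, the AdaGrad/MSE loop, and
product-based checkpoint selection — plus a model/results front end.

The restoration network is trained separately per b-value group because the
signal level and contrast of diffusion-weighted volumes change strongly with
the diffusion weighting: the unweighted b = 0 volumes are trained together
with the b = 1000 shell, while b = 1500 and b = 2000 each get their own
model.  Batch size is fixed at 1 (one volume pair per step) and the
optimizer is AdaGrad with per-parameter accumulated squared gradients:

    acc += g^2;   theta -= lr * g / sqrt(acc + eps)

with lr = 5e-4 and eps = 1e-8 by default.  The loss is the mean (not sum)
squared error over voxels so volumes of different sizes are comparable.

:class:`SuperResolution3D` wraps all of this in a fit-style interface: build
the model from a cohort of high-resolution volumes, call :meth:`fit`, and
get a :class:`SuperResolutionResults` carrying the per-group weights, loss
logs, checkpoints and a ``summary()`` table.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Optional, Sequence

import numpy as np

from . import metrics
from .io import DWIVolume
from .network import ModelState, SRCNNSpec, forward_backward, init_model
from .resample import ResampleSpec, downsample, interpolate_up, normalize_range

__all__ = [
    "TrainingSpec",
    "TrainingPair",
    "BValueGroup",
    "TrainingLog",
    "ConfigError",
    "DEFAULT_GROUPING",
    "build_pairs",
    "group_by_bvalue",
    "AdaGrad",
    "train",
    "select_best_checkpoint",
    "SuperResolution3D",
    "SuperResolutionResults",
]

# Canonical shell grouping: b = 0 is trained together with the b = 1000 shell.
DEFAULT_GROUPING = (
    ("b0b1000", frozenset({0.0, 1000.0})),
    ("b1500", frozenset({1500.0})),
    ("b2000", frozenset({2000.0})),
)


class ConfigError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class TrainingSpec:
    learning_rate: float = 5e-4
    optimizer: str = "adagrad"
    batch_size: int = 1
    epochs: int = 1
    max_iterations: Optional[int] = None
    checkpoint_interval: int = 5000
    loss: str = "mse"
    epsilon: float = 1e-8
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.batch_size != 1:
            raise ValueError("batch_size is fixed at 1")
        if self.checkpoint_interval < 1:
            raise ValueError("checkpoint_interval must be >= 1")
        if self.optimizer.lower() != "adagrad":
            raise ConfigError(f"unsupported optimizer {self.optimizer!r}")
        if self.loss.lower() != "mse":
            raise ConfigError(f"unsupported loss {self.loss!r}")


@dataclasses.dataclass
class TrainingPair:
    source: np.ndarray  # interpolated low-resolution volume, HR grid
    target: np.ndarray  # high-resolution volume
    bval: float
    subject: object = 0
    gradient_index: int = 0


@dataclasses.dataclass
class BValueGroup:
    label: str
    member_bvals: frozenset
    pairs: list


@dataclasses.dataclass
class TrainingLog:
    """Per-iteration losses, per-subject aggregates and checkpoint states."""

    iterations: list = dataclasses.field(default_factory=list)  # (it, subject, loss)
    subject_losses: list = dataclasses.field(default_factory=list)  # (subject, epoch, mean)
    checkpoints: list = dataclasses.field(default_factory=list)  # (it, ModelState)

    @property
    def losses(self):
        return [loss for _, _, loss in self.iterations]

    def epoch_losses(self):
        """Mean of the per-subject aggregated losses, per epoch (ascending).

        Single-pair losses fluctuate with whichever volume was presented;
        the per-epoch mean is the stable curve the training actually drives
        down.
        """
        by_epoch = {}
        for _subject, epoch, loss in self.subject_losses:
            by_epoch.setdefault(epoch, []).append(loss)
        return [float(np.mean(by_epoch[e])) for e in sorted(by_epoch)]

    def checkpoint_ids(self):
        return [it for it, _ in self.checkpoints]


def _pad_to_multiple(grid: np.ndarray, factor: int) -> np.ndarray:
    """Zero-pad trailing edges so every spatial dim divides by ``factor``.

    Zeros are background in brain DWI, so padding does not disturb tissue
    statistics; the loss runs over the padded grid.
    """
    pad = [(0, (-s) % factor) for s in grid.shape]
    if not any(p[1] for p in pad):
        return grid
    return np.pad(grid, pad)


def build_pairs(vol: DWIVolume, resample_spec: ResampleSpec = ResampleSpec(),
                subject=0) -> list:
    """One (interpolated source, high-resolution target) pair per gradient.

    target = the zero-padded high-resolution grid; source = the target after
    the degrade/restore cycle (block ×1/3 downsample, interpolation back up,
    range renormalization against the target).  Source and target always
    share dims.
    """
    f = resample_spec.factor
    pairs = []
    for g in range(vol.n_gradients):
        target = _pad_to_multiple(vol.data[..., g], f)
        low = downsample(target, f)
        source = interpolate_up(low, f, resample_spec.method)
        if resample_spec.renormalize and target.max() > target.min():
            source = normalize_range(source, target)
        pairs.append(
            TrainingPair(source=source, target=target, bval=float(vol.bvals[g]),
                         subject=subject, gradient_index=g)
        )
    return pairs


def group_by_bvalue(pairs: Sequence[TrainingPair],
                    grouping=DEFAULT_GROUPING) -> list:
    """Partition pairs into the three per-shell training groups.

    b = 0 is merged into the b = 1000 group; a b-value outside the configured
    shells raises :class:`ConfigError` naming the value.
    """
    groups = [BValueGroup(label, members, []) for label, members in grouping]
    for pair in pairs:
        for group in groups:
            if pair.bval in group.member_bvals:
                group.pairs.append(pair)
                break
        else:
            known = sorted(b for _, m in grouping for b in m)
            raise ConfigError(
                f"b-value {pair.bval} is not in the configured shells {known}"
            )
    return groups


class AdaGrad:
    """Per-parameter AdaGrad with zero initial accumulator."""

    def __init__(self, params, learning_rate: float, epsilon: float = 1e-8):
        self.params = list(params)
        self.lr = float(learning_rate)
        self.eps = float(epsilon)
        self.acc = [np.zeros_like(p) for p in self.params]

    def step(self, grads):
        for p, g, a in zip(self.params, grads, self.acc):
            a += g * g
            p -= self.lr * g / np.sqrt(a + self.eps)


def train(group: BValueGroup, model: ModelState, spec: TrainingSpec):
    """Run the batch-1 AdaGrad/MSE loop over one b-value group.

    Pairs are presented subject-by-subject, with the subject order and the
    gradient order within each subject reshuffled every epoch from the run
    seed.  The loss is recorded every iteration and aggregated per subject;
    the model state is checkpointed every ``checkpoint_interval`` iterations
    and once more at the end.  Deterministic given seed and pair list.
    """
    if not group.pairs:
        raise ValueError(f"group {group.label!r} has no training pairs")
    model = model.copy()
    log = TrainingLog()
    rng = np.random.default_rng(spec.seed)
    params = model.weights + model.biases
    opt = AdaGrad(params, spec.learning_rate, spec.epsilon)

    subjects = sorted({p.subject for p in group.pairs}, key=repr)
    by_subject = {s: [p for p in group.pairs if p.subject == s] for s in subjects}
    iteration = 0
    stop = False
    for epoch in range(spec.epochs):
        order = [subjects[i] for i in rng.permutation(len(subjects))]
        for subject in order:
            pairs = list(by_subject[subject])
            pairs = [pairs[i] for i in rng.permutation(len(pairs))]
            subject_losses = []
            for pair in pairs:
                loss, gw, gb, _ = forward_backward(model, pair.source, pair.target)
                if not np.isfinite(loss):
                    raise FloatingPointError(
                        f"training diverged at iteration {iteration + 1} "
                        f"(group {group.label!r}, loss {loss})"
                    )
                opt.step(gw + gb)
                iteration += 1
                model.iteration_count = iteration
                log.iterations.append((iteration, subject, loss))
                subject_losses.append(loss)
                if iteration % spec.checkpoint_interval == 0:
                    log.checkpoints.append((iteration, model.copy()))
                if spec.max_iterations is not None and iteration >= spec.max_iterations:
                    stop = True
                    break
            if subject_losses:
                log.subject_losses.append(
                    (subject, epoch, float(np.mean(subject_losses)))
                )
            if stop:
                break
        if stop:
            break
    if not log.checkpoints or log.checkpoints[-1][0] != iteration:
        log.checkpoints.append((iteration, model.copy()))
    model.check_finite()
    return model, log


def select_best_checkpoint(log: TrainingLog, test_reports) -> int:
    """Pick the checkpoint maximizing the normalized three-index product.

    ``test_reports`` holds one summary (or averaged MetricReport) per
    checkpoint in ``log``; ties break toward the earlier checkpoint.
    Returns the checkpoint's iteration id.
    """
    ids = log.checkpoint_ids()
    if not ids:
        raise ValueError("no checkpoints recorded")
    if len(test_reports) != len(ids):
        raise ValueError(
            f"{len(test_reports)} metric reports for {len(ids)} checkpoints"
        )
    scores = metrics.product_score(test_reports)
    best = 0
    for i in range(1, len(scores)):
        if scores[i] > scores[best]:
            best = i
    return ids[best]


# ---------------------------------------------------------------------------
# Fit-style front end


class SuperResolution3D:
    """Super-resolution restoration model over a cohort of DWI volumes.

    Parameters
    ----------
    volumes : sequence of DWIVolume
        High-resolution training volumes (one per subject).
    resample_spec, srcnn_spec, training_spec : configuration blocks;
        defaults reproduce the reference pipeline (factor 3, tricubic
        restoration, 9/3/5 kernels with 32/16/1 channels, AdaGrad at 5e-4).
    """

    def __init__(self, volumes: Sequence[DWIVolume],
                 resample_spec: ResampleSpec = ResampleSpec(),
                 srcnn_spec: SRCNNSpec = SRCNNSpec(),
                 training_spec: TrainingSpec = TrainingSpec(),
                 grouping=DEFAULT_GROUPING):
        self.volumes = list(volumes)
        self.resample_spec = resample_spec
        self.srcnn_spec = srcnn_spec
        self.training_spec = training_spec
        self.grouping = grouping
        pairs = []
        for subject, vol in enumerate(self.volumes):
            pairs.extend(build_pairs(vol, resample_spec, subject=subject))
        all_groups = group_by_bvalue(pairs, grouping)
        for g in all_groups:
            if not g.pairs:
                warnings.warn(
                    f"no training data for b-value group {g.label!r}; "
                    "no model will be trained for it",
                    stacklevel=2,
                )
        self.groups = [g for g in all_groups if g.pairs]

    def fit(self) -> "SuperResolutionResults":
        models, logs = {}, {}
        for group in self.groups:
            state = init_model(self.srcnn_spec)
            state, log = train(group, state, self.training_spec)
            models[group.label] = state
            logs[group.label] = log
        return SuperResolutionResults(self, models, logs)


class SuperResolutionResults:
    """Fitted per-group models with their training diagnostics."""

    def __init__(self, model: SuperResolution3D, models: dict, logs: dict):
        self.model = model
        self.models = models
        self.logs = logs

    @classmethod
    def from_checkpoints(cls, states: dict,
                         resample_spec: ResampleSpec = ResampleSpec(),
                         grouping=DEFAULT_GROUPING) -> "SuperResolutionResults":
        """Assemble a prediction-only results object from saved checkpoints.

        ``states`` maps group labels (e.g. ``"b0b1000"``) to ModelState.
        """
        shell = SuperResolution3D.__new__(SuperResolution3D)
        shell.grouping = grouping
        shell.resample_spec = resample_spec
        shell.volumes = []
        shell.groups = []
        return cls(shell, dict(states), {})

    @property
    def group_labels(self):
        return list(self.models)

    def model_for_bval(self, bval: float) -> ModelState:
        for label, members in self.model.grouping:
            if bval in members and label in self.models:
                return self.models[label]
        raise ConfigError(f"no trained model covers b-value {bval}")

    def predict(self, lr_vol: DWIVolume) -> DWIVolume:
        from .pipeline import predict as _predict

        return _predict(self, lr_vol, self.model.resample_spec)

    def final_losses(self):
        return {label: log.losses[-1] for label, log in self.logs.items()}

    def initial_losses(self):
        return {label: log.losses[0] for label, log in self.logs.items()}

    def summary(self) -> str:
        """Plain-text table of the fit, one row per b-value group."""
        lines = [
            "3-D super-resolution CNN fit (AdaGrad, batch size 1, MSE loss)",
            f"kernels {self.model.srcnn_spec.kernel_edges}  "
            f"channels {self.model.srcnn_spec.channels}  "
            f"residual weight {self.model.srcnn_spec.residual_weight}",
            f"learning rate {self.model.training_spec.learning_rate}  "
            f"epochs {self.model.training_spec.epochs}",
            "",
            f"{'group':>10} {'pairs':>6} {'iters':>7} {'first loss':>12} "
            f"{'last loss':>12} {'ckpts':>6}",
        ]
        group_sizes = {g.label: len(g.pairs) for g in self.model.groups}
        for label, log in self.logs.items():
            lines.append(
                f"{label:>10} {group_sizes[label]:>6d} "
                f"{len(log.iterations):>7d} {log.losses[0]:>12.5g} "
                f"{log.losses[-1]:>12.5g} {len(log.checkpoints):>6d}"
            )
        return "\n".join(lines)
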