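"""Fine-motor-impairment indices from keystroke dynamics.

A 1-D convolutional autoencoder learns an unsupervised representation of the
padded hold-time/flight-time sequences (two channels, length 100).  The
encoder is two convolutional layers (16 filters, kernel 5, same padding, no
pooling); the decoder mirrors it back to the input shape.  Pretraining
minimises mean squared reconstruction error with RMSprop on an 80/20
train/validation split.

For severity estimation a two-layer fully-connected head (50 hidden units)
replaces the decoder and the whole network is fine-tuned end-to-end against
clinician-style 0–4 item scores, one independent regressor per symptom:
rigidity (R), bradykinesia (B) and alternate finger tapping (AFT).
Generalisation is assessed with leave-one-subject-out (LOSO) cross
validation; predictions are clipped to the [0, 4] score range.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import spearmanr

from . import nn
from .keystroke import DynamicsSeries, stack_padded

logger = logging.getLogger(__name__)

SYMPTOMS = ("rigidity", "bradykinesia", "aft")
SCORE_MIN, SCORE_MAX = 0.0, 4.0


@dataclass(frozen=True)
class EncoderSpec:
    """Architecture of the convolutional encoder."""

    input_length: int = 100
    channels: int = 2
    conv_layers: int = 2
    kernel_size: int = 5
    filters_per_layer: int = 16


@dataclass(frozen=True)
class TrainingConfig:
    """Optimisation settings for pretraining and fine-tuning."""

    pretrain_epochs: int = 50
    pretrain_batch: int = 64
    lr: float = 1e-3
    val_fraction: float = 0.2
    finetune_epochs: int = 50
    finetune_batch: int = 32
    head_hidden: int = 50
    seed: int = 0


@dataclass(frozen=True)
class SeveritySample:
    """One padded typing session with its three 0–4 symptom scores."""

    dynamics: DynamicsSeries
    subject_id: str
    scores: tuple[int, int, int]  # (rigidity, bradykinesia, aft)

    def __post_init__(self):
        if not all(SCORE_MIN <= s <= SCORE_MAX for s in self.scores):
            raise ValueError(f"scores must lie in [0, 4], got {self.scores}")


@dataclass(frozen=True)
class FMIIndices:
    """Per-session severity estimates, clipped to the 0–4 scale."""

    session_id: str
    subject_id: str
    r_index: float
    b_index: float
    aft_index: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.r_index, self.b_index, self.aft_index)


@dataclass
class PretrainResult:
    encoder_weights: list[np.ndarray]
    train_curve: list[float] = field(default_factory=list)
    val_curve: list[float] = field(default_factory=list)
    spec: EncoderSpec = field(default_factory=EncoderSpec)
    cfg: TrainingConfig = field(default_factory=TrainingConfig)
    n_parameters: int = 0


#: Training arithmetic runs in single precision (ample for 0-4 targets).
DTYPE = np.float32


def build_encoder(spec: EncoderSpec, rng: np.random.Generator) -> nn.Sequential:
    layers: list[nn.Layer] = []
    ch = spec.channels
    for _ in range(spec.conv_layers):
        layers += [nn.Conv1D(ch, spec.filters_per_layer, spec.kernel_size, rng,
                             dtype=DTYPE),
                   nn.ReLU()]
        ch = spec.filters_per_layer
    return nn.Sequential(*layers)


def build_decoder(spec: EncoderSpec, rng: np.random.Generator) -> nn.Sequential:
    # mirror of the encoder: back down to the input channel count, linear output
    return nn.Sequential(
        nn.Conv1D(spec.filters_per_layer, spec.filters_per_layer,
                  spec.kernel_size, rng, dtype=DTYPE),
        nn.ReLU(),
        nn.Conv1D(spec.filters_per_layer, spec.channels, spec.kernel_size, rng,
                  dtype=DTYPE),
    )


def build_regressor(
    spec: EncoderSpec, cfg: TrainingConfig, rng: np.random.Generator,
    encoder_weights: list[np.ndarray] | None = None,
) -> nn.Sequential:
    """Encoder + flatten + 50-unit hidden layer + linear scalar output."""
    encoder = build_encoder(spec, rng)
    if encoder_weights is not None:
        encoder.set_weights(encoder_weights)
    flat = spec.filters_per_layer * spec.input_length
    return nn.Sequential(
        encoder, nn.Flatten(),
        nn.Dense(flat, cfg.head_hidden, rng, dtype=DTYPE), nn.ReLU(),
        nn.Dense(cfg.head_hidden, 1, rng, dtype=DTYPE),
    )


def _check_finite(loss: float, context: str) -> None:
    if not np.isfinite(loss):
        raise FloatingPointError(f"non-finite loss during {context}: {loss}")


def _train(model, x, y, epochs, batch, lr, rng, context, x_val=None, y_val=None):
    opt = nn.RMSprop(model, lr=lr)
    train_curve, val_curve = [], []
    for epoch in range(epochs):
        losses = []
        for idx in nn.iterate_minibatches(len(x), batch, rng):
            pred = model.forward(x[idx], train=True)
            loss, grad = nn.mse_loss(pred, y[idx])
            _check_finite(loss, context)
            model.backward(grad)
            opt.step()
            losses.append(loss)
        train_curve.append(float(np.mean(losses)))
        if x_val is not None:
            val_loss, _ = nn.mse_loss(model.forward(x_val), y_val)
            _check_finite(val_loss, context)
            val_curve.append(val_loss)
    return train_curve, val_curve


def pretrain_autoencoder(
    sessions: list[DynamicsSeries],
    spec: EncoderSpec = EncoderSpec(),
    cfg: TrainingConfig = TrainingConfig(),
) -> PretrainResult:
    """Unsupervised reconstruction pretraining of the encoder.

    Uses an 80/20 train/validation split; the held-out reconstruction loss is
    reported per epoch and must improve over the initial value.
    """
    if len(sessions) < 100:
        raise ValueError(f"need >= 100 padded sessions, got {len(sessions)}")
    x = stack_padded(sessions).astype(DTYPE)
    rng = np.random.default_rng(cfg.seed)
    n_val = max(1, int(round(cfg.val_fraction * len(x))))
    perm = rng.permutation(len(x))
    x_val, x_train = x[perm[:n_val]], x[perm[n_val:]]

    encoder = build_encoder(spec, rng)
    model = nn.Sequential(encoder, build_decoder(spec, rng))
    init_val, _ = nn.mse_loss(model.forward(x_val), x_val)
    train_curve, val_curve = _train(
        model, x_train, x_train, cfg.pretrain_epochs, cfg.pretrain_batch,
        cfg.lr, rng, "autoencoder pretraining", x_val, x_val,
    )
    if val_curve[-1] >= init_val:
        logger.warning(
            "pretraining did not improve held-out reconstruction "
            "(%.4g -> %.4g)", init_val, val_curve[-1],
        )
    return PretrainResult(
        encoder_weights=encoder.get_weights(),
        train_curve=train_curve,
        val_curve=[init_val] + val_curve,
        spec=spec, cfg=cfg,
        n_parameters=model.n_parameters(),
    )


@dataclass
class FinetuneResult:
    models: dict[str, nn.Sequential]            # final models, fit on all data
    loso_predictions: "np.ndarray"              # (n_samples, 3), clipped
    true_scores: "np.ndarray"                   # (n_samples, 3)
    subject_ids: list[str]
    session_ids: list[str]
    spearman: dict[str, float]
    spec: EncoderSpec = field(default_factory=EncoderSpec)
    cfg: TrainingConfig = field(default_factory=TrainingConfig)


def _fit_regressor(x, y, spec, cfg, encoder_weights, seed):
    rng = np.random.default_rng(seed)
    model = build_regressor(spec, cfg, rng, encoder_weights)
    _train(model, x.astype(DTYPE), y[:, None].astype(DTYPE),
           cfg.finetune_epochs, cfg.finetune_batch, cfg.lr, rng,
           "severity fine-tuning")
    return model


def finetune_regressors(
    pretrained: PretrainResult,
    samples: list[SeveritySample],
    cfg: TrainingConfig | None = None,
) -> FinetuneResult:
    """Fine-tune one regressor per symptom, with LOSO out-of-fold estimates.

    Each fold re-initialises the head, loads the pretrained encoder weights,
    and trains end-to-end (the encoder is not frozen) on all subjects but
    one; the held-out subject's sessions get out-of-fold predictions.  After
    the folds, a final model per symptom is fit on all samples for deployment.
    """
    cfg = cfg or pretrained.cfg
    spec = pretrained.spec
    subjects = sorted({s.subject_id for s in samples})
    if len(subjects) < 3:
        raise ValueError(f"need samples from >= 3 subjects, got {len(subjects)}")
    x = stack_padded([s.dynamics for s in samples]).astype(DTYPE)
    y = np.array([s.scores for s in samples], dtype=np.float64)
    subj = np.array([s.subject_id for s in samples])

    preds = np.full_like(y, np.nan)
    for fold, held_out in enumerate(subjects):
        test = subj == held_out
        for j in range(3):
            model = _fit_regressor(
                x[~test], y[~test, j], spec, cfg, pretrained.encoder_weights,
                seed=cfg.seed + 1000 * (fold + 1) + j,
            )
            preds[test, j] = np.clip(
                model.forward(x[test])[:, 0], SCORE_MIN, SCORE_MAX
            )

    spearman = {}
    for j, name in enumerate(SYMPTOMS):
        rho = spearmanr(y[:, j], preds[:, j]).statistic
        spearman[name] = float(rho)
        logger.info("LOSO Spearman rho (%s): %.3f", name, rho)

    models = {
        name: _fit_regressor(x, y[:, j], spec, cfg, pretrained.encoder_weights,
                             seed=cfg.seed + j)
        for j, name in enumerate(SYMPTOMS)
    }
    return FinetuneResult(
        models=models,
        loso_predictions=preds,
        true_scores=y,
        subject_ids=[s.subject_id for s in samples],
        session_ids=[s.dynamics.session_id for s in samples],
        spearman=spearman,
        spec=spec, cfg=cfg,
    )


def predict_indices(
    models: dict[str, nn.Sequential], series: DynamicsSeries,
    input_length: int = 100,
) -> FMIIndices:
    """Severity indices for one padded session; deterministic, clipped to [0,4]."""
    if series.padded_ht is None or len(series.padded_ht) != input_length:
        raise ValueError(
            f"series must be padded to length {input_length} "
            f"(got {None if series.padded_ht is None else len(series.padded_ht)})"
        )
    x = np.stack([series.padded_ht, series.padded_ft])[None].astype(DTYPE)
    vals = {
        name: float(np.clip(models[name].forward(x)[0, 0], SCORE_MIN, SCORE_MAX))
        for name in SYMPTOMS
    }
    return FMIIndices(
        session_id=series.session_id, subject_id=series.subject_id,
        r_index=vals["rigidity"], b_index=vals["bradykinesia"],
        aft_index=vals["aft"],
    )


def predict_indices_batch(
    models: dict[str, nn.Sequential], series: list[DynamicsSeries],
    input_length: int = 100,
) -> list[FMIIndices]:
    if not series:
        return []
    x = stack_padded(series).astype(DTYPE)
    if x.shape[2] != input_length:
        raise ValueError(f"series must be padded to length {input_length}")
    cols = {
        name: np.clip(models[name].forward(x)[:, 0], SCORE_MIN, SCORE_MAX)
        for name in SYMPTOMS
    }
    return [
        FMIIndices(
            session_id=s.session_id, subject_id=s.subject_id,
            r_index=float(cols["rigidity"][i]),
            b_index=float(cols["bradykinesia"][i]),
            aft_index=float(cols["aft"][i]),
        )
        for i, s in enumerate(series)
    ]


def aggregate_subject_indices(indices: list[FMIIndices]) -> dict[str, float]:
    """Subject feature row: mean index per symptom over the subject's sessions."""
    if not indices:
        raise ValueError("no session indices to aggregate")
    arr = np.array([ix.as_tuple() for ix in indices])
    means = arr.mean(axis=0)
    return {
        "R": float(means[0]), "B": float(means[1]), "AFT": float(means[2]),
        "n_sessions": len(indices),
    }


def save_models(result: FinetuneResult, out_dir) -> None:
    """One archive per symptom: weights + architecture spec + seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, model in result.models.items():
        payload = {
            "symptom": name,
            "spec": result.spec,
            "cfg": result.cfg,
            "weights": model.get_weights(),
        }
        with open(out / f"{name}.pkl", "wb") as fh:
            pickle.dump(payload, fh)


def load_models(model_dir) -> dict[str, nn.Sequential]:
    models = {}
    for name in SYMPTOMS:
        with open(Path(model_dir) / f"{name}.pkl", "rb") as fh:
            payload = pickle.load(fh)
        rng = np.random.default_rng(0)
        model = build_regressor(payload["spec"], payload["cfg"], rng)
        model.set_weights(payload["weights"])
        models[name] = model
    return models
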