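"""Multitask quantile glucose forecaster.

A sequence-to-sequence LSTM predicts the last 20 min (four 5-min steps) of the
glucose trajectory at three quantiles (default 0.025 / 0.5 / 0.975).  The
encoder consumes the history of (CGM glucose, delivered insulin, announced
carbs); the decoder consumes the exogenous (insulin, carbs) of the forecast
window, so the most recent 20 min of CGM are never shown to the model.  The
three heads share the encoder and decoder and are trained jointly with a
uniformly weighted pinball loss.

Training follows a two-stage protocol: a population model fitted on pooled
subject data (learning rate 1e-3), then per-subject fine-tuning at 1e-4.  The
fine-tuned model's validation MAE is the deviation threshold used downstream
by the meal-size estimator.
"""

from __future__ import annotations

import copy
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from . import _qlstm
from .scenario_sim import GlucoseTimeline

DECODER_STEPS = 4  # 20 min at 5-min sampling


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def pinball_loss(y, y_hat, tau: float) -> float:
    """Mean pinball (tilted) loss at quantile ``tau``.

    tau*(y - y_hat) where the model under-predicts, (1-tau)*(y_hat - y) where
    it over-predicts; non-negative, zero iff y == y_hat.  At tau = 0.5 this is
    half the mean absolute error.
    """
    if not 0 < tau < 1:
        raise ValueError("tau must lie in (0, 1)")
    diff = np.asarray(y, dtype=float) - np.asarray(y_hat, dtype=float)
    return float(np.mean(np.where(diff > 0, tau * diff, (tau - 1.0) * diff)))


def total_loss(loss_lb: float, loss_m: float, loss_ub: float) -> float:
    """Uniformly weighted multitask objective: the mean of the three losses."""
    return (loss_lb + loss_m + loss_ub) / 3.0


# ---------------------------------------------------------------------------
# windows and normalisation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormStats:
    """Per-feature min-max normalisation, frozen at population-training time.

    Feature order: glucose (mg/dL), insulin per step (U), carbs per step (g).
    """

    offset: np.ndarray  # [3] feature minima
    scale: np.ndarray   # [3] feature ranges (>= small positive)

    def norm_enc(self, enc: np.ndarray) -> np.ndarray:
        return (enc - self.offset) / self.scale

    def norm_dec(self, dec: np.ndarray) -> np.ndarray:
        return (dec - self.offset[1:]) / self.scale[1:]

    def norm_glucose(self, g: np.ndarray) -> np.ndarray:
        return (g - self.offset[0]) / self.scale[0]

    def denorm_glucose(self, g: np.ndarray) -> np.ndarray:
        return g * self.scale[0] + self.offset[0]

    def to_dict(self) -> dict:
        return {"offset": self.offset.tolist(), "scale": self.scale.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormStats":
        return cls(offset=np.asarray(d["offset"], dtype=float),
                   scale=np.asarray(d["scale"], dtype=float))


def compute_norm_stats(enc_arrays: Sequence[np.ndarray]) -> NormStats:
    """Min-max stats over the pooled (training-split) encoder features."""
    flat = np.concatenate([a.reshape(-1, a.shape[-1]) for a in enc_arrays], axis=0)
    lo = flat.min(axis=0)
    hi = flat.max(axis=0)
    scale = np.where(hi - lo > 1e-9, hi - lo, 1.0)
    return NormStats(offset=lo, scale=scale)


@dataclass
class WindowBatch:
    """Sliding forecast windows over a timeline, in raw physical units.

    ``enc`` [N, enc_len, 3] carries (glucose, insulin, carbs); ``dec``
    [N, 4, 2] carries (insulin, carbs); ``targets`` [N, 4] are the CGM values
    of the decoder window.  ``stats`` holds the normalisation applied on the
    way into the model.
    """

    enc: np.ndarray
    dec: np.ndarray
    targets: np.ndarray
    stats: NormStats | None = None

    def __post_init__(self) -> None:
        if self.dec.shape[1:] != (DECODER_STEPS, 2):
            raise ValueError("decoder window must be 4 steps of (insulin, carbs)")
        if not np.all(np.isfinite(self.targets)):
            raise ValueError("targets must be finite")

    def __len__(self) -> int:
        return self.enc.shape[0]

    def normalised(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        if self.stats is None:
            raise ValueError("WindowBatch has no normalisation stats attached")
        return (self.stats.norm_enc(self.enc).astype(_qlstm.DTYPE),
                self.stats.norm_dec(self.dec).astype(_qlstm.DTYPE),
                self.stats.norm_glucose(self.targets).astype(_qlstm.DTYPE))

    def subset(self, idx) -> "WindowBatch":
        return WindowBatch(self.enc[idx], self.dec[idx], self.targets[idx], self.stats)


def build_windows(timeline: GlucoseTimeline, enc_len: int,
                  stats: NormStats | None = None) -> WindowBatch:
    """Stride-1 sliding windows: ``enc_len`` encoder steps + 4 decoder steps.

    A timeline of exactly enc_len + 4 steps yields one window; shorter
    timelines yield an empty batch with a warning.
    """
    span = enc_len + DECODER_STEPS
    n = len(timeline) - span + 1
    if n <= 0:
        warnings.warn("timeline shorter than one forecast window; no windows built")
        return WindowBatch(np.empty((0, enc_len, 3)), np.empty((0, DECODER_STEPS, 2)),
                           np.empty((0, DECODER_STEPS)), stats)
    feats = np.stack([timeline.glucose, timeline.insulin_per_step,
                      timeline.announced_carbs], axis=1)  # [L, 3]
    idx = np.arange(n)[:, None]
    enc = feats[idx + np.arange(enc_len)[None, :]]
    dec_rows = idx + enc_len + np.arange(DECODER_STEPS)[None, :]
    dec = feats[dec_rows][:, :, 1:]
    targets = timeline.glucose[dec_rows]
    return WindowBatch(enc=enc, dec=dec, targets=targets, stats=stats)


# ---------------------------------------------------------------------------
# configuration / bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainingConfig:
    lstm_cells: int = 64
    pretrain_lr: float = 1e-3
    finetune_lr: float = 1e-4
    batch_size: int = 128
    max_epochs: int = 100
    patience: int = 20
    min_delta: float = 1e-4
    split: float = 0.8
    quantiles: tuple[float, float, float] = (0.025, 0.5, 0.975)
    enc_len: int = 24          # 2 h of history
    grad_clip: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lb, m, ub = self.quantiles
        if not 0 < lb < 0.5 <= m <= 0.5 < ub < 1:
            raise ValueError("quantiles must satisfy 0 < lb < 0.5 < ub < 1 with median 0.5")
        if not 0 < self.split < 1:
            raise ValueError("split must lie in (0, 1)")


@dataclass
class QuantileForecast:
    """Lower/median/upper glucose forecast over the 4-step decoder window."""

    lower: np.ndarray
    median: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        for a in (self.lower, self.median, self.upper):
            if len(a) != DECODER_STEPS or not np.all(np.isfinite(a)):
                raise ValueError("forecast must be finite and span the decoder window")


@dataclass
class ModelBundle:
    """Trained weights + everything needed to reuse them consistently."""

    weights: dict[str, np.ndarray]
    config: TrainingConfig
    stats: NormStats
    validation_mae: float     # mg/dL, median head at the final decoder step
    history: list[float] = field(default_factory=list)  # per-epoch val loss

    def copy(self) -> "ModelBundle":
        return ModelBundle(weights={k: v.copy() for k, v in self.weights.items()},
                           config=self.config, stats=self.stats,
                           validation_mae=self.validation_mae,
                           history=list(self.history))


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _forward_chunked(weights: dict, xe: np.ndarray, xd: np.ndarray,
                     chunk: int = 4096) -> np.ndarray:
    outs = []
    for a in range(0, len(xe), chunk):
        y, _ = _qlstm.forward(weights, xe[a:a + chunk], xd[a:a + chunk])
        outs.append(y)
    return np.concatenate(outs, axis=0) if outs else np.empty((0, DECODER_STEPS, 3))


def _val_loss(weights: dict, xe, xd, y, taus) -> float:
    pred = _forward_chunked(weights, xe, xd)
    loss, _ = _qlstm.pinball_loss_and_dy(y, pred, taus)
    return loss


def _fit(weights: dict, train: tuple, val: tuple, lr: float,
         config: TrainingConfig, rng: np.random.Generator) -> tuple[dict, list[float]]:
    """Minibatch Adam with early stopping on validation total loss."""
    xe, xd, y = train
    taus = np.asarray(config.quantiles)
    opt = _qlstm.Adam(weights, lr)
    best = {k: v.copy() for k, v in weights.items()}
    best_loss = _val_loss(weights, *val, taus)
    history = [best_loss]
    wait = 0
    n = len(xe)
    for _epoch in range(config.max_epochs):
        order = rng.permutation(n)
        for a in range(0, n, config.batch_size):
            sel = order[a:a + config.batch_size]
            pred, cache = _qlstm.forward(weights, xe[sel], xd[sel], keep_cache=True)
            loss, dy = _qlstm.pinball_loss_and_dy(y[sel], pred, taus)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite training loss at epoch {_epoch}; aborting")
            grads = _qlstm.backward(weights, cache, dy)
            _qlstm.clip_grads(grads, config.grad_clip)
            opt.step(weights, grads)
        vloss = _val_loss(weights, *val, taus)
        history.append(vloss)
        if best_loss - vloss > config.min_delta:
            best_loss = vloss
            best = {k: v.copy() for k, v in weights.items()}
            wait = 0
        else:
            wait += 1
            if wait >= config.patience:
                break
    return best, history


def _chronological_split(wb: WindowBatch, split: float) -> tuple[WindowBatch, WindowBatch]:
    n_train = int(np.floor(split * len(wb)))
    return wb.subset(slice(0, n_train)), wb.subset(slice(n_train, len(wb)))


def _median_final_mae(weights: dict, wb: WindowBatch) -> float:
    xe, xd, _ = wb.normalised()
    pred = _forward_chunked(weights, xe, xd)
    med = wb.stats.denorm_glucose(pred[:, -1, 1])
    return float(np.mean(np.abs(wb.targets[:, -1] - med)))


def train_population(data: Sequence[GlucoseTimeline], config: TrainingConfig) -> ModelBundle:
    """Stage one: fit a generalised model on pooled per-subject windows.

    Each subject's windows are split 80/20 in time order; normalisation stats
    are computed on the pooled training split and frozen into the bundle.
    """
    if len(data) < 1:
        raise ValueError("need at least one timeline")
    raw = [build_windows(tl, config.enc_len) for tl in data]
    splits = [_chronological_split(wb, config.split) for wb in raw]
    stats = compute_norm_stats([tr.enc for tr, _ in splits if len(tr)])
    for wb, (tr, va) in zip(raw, splits):
        wb.stats = tr.stats = va.stats = stats
    train_n = [tr.normalised() for tr, _ in splits if len(tr)]
    val_n = [va.normalised() for _, va in splits if len(va)]
    train = tuple(np.concatenate(parts) for parts in zip(*train_n))
    val = tuple(np.concatenate(parts) for parts in zip(*val_n))
    rng = np.random.default_rng(config.seed)
    weights = _qlstm.init_weights(3, 2, config.lstm_cells, 3, rng)
    weights, history = _fit(weights, train, val, config.pretrain_lr, config, rng)
    pooled_val = WindowBatch(np.concatenate([va.enc for _, va in splits]),
                             np.concatenate([va.dec for _, va in splits]),
                             np.concatenate([va.targets for _, va in splits]), stats)
    return ModelBundle(weights=weights, config=config, stats=stats,
                       validation_mae=_median_final_mae(weights, pooled_val),
                       history=history)


def finetune_individual(bundle: ModelBundle, data: GlucoseTimeline,
                        config: TrainingConfig | None = None) -> ModelBundle:
    """Stage two: fine-tune the population model on one subject's data.

    Normalisation stats are frozen from the population stage.  The returned
    bundle's ``validation_mae`` (median head, final decoder step, on this
    subject's chronological validation split) is the threshold used by the
    carbohydrate estimator.
    """
    config = bundle.config if config is None else config
    wb = build_windows(data, config.enc_len, stats=bundle.stats)
    tr, va = _chronological_split(wb, config.split)
    weights = {k: v.copy() for k, v in bundle.weights.items()}
    history: list[float] = []
    if config.max_epochs > 0 and len(tr):
        rng = np.random.default_rng(config.seed + 1)
        weights, history = _fit(weights, tr.normalised(), va.normalised(),
                                config.finetune_lr, config, rng)
    return ModelBundle(weights=weights, config=config, stats=bundle.stats,
                       validation_mae=_median_final_mae(weights, va),
                       history=history)


# ---------------------------------------------------------------------------
# inference
# ---------------------------------------------------------------------------

def predict_batch(bundle: ModelBundle, windows: WindowBatch) -> np.ndarray:
    """De-normalised forecasts [N, 4, 3] with heads ordered (lower, median, upper)."""
    if windows.enc.shape[-1] != 3 or windows.dec.shape[-1] != 2:
        raise ValueError("window feature dimensions do not match the model")
    if windows.stats is None:
        windows = WindowBatch(windows.enc, windows.dec, windows.targets, bundle.stats)
    xe, xd, _ = windows.normalised()
    pred = _forward_chunked(bundle.weights, xe, xd)
    return bundle.stats.denorm_glucose(pred)


def predict_quantiles(bundle: ModelBundle, window: WindowBatch) -> QuantileForecast:
    """Forecast for a single window (a batch of length one)."""
    if len(window) != 1:
        raise ValueError("predict_quantiles expects a single window; use predict_batch")
    pred = predict_batch(bundle, window)[0]
    return QuantileForecast(lower=pred[:, 0], median=pred[:, 1], upper=pred[:, 2])


def interval_coverage(bundle: ModelBundle, windows: WindowBatch) -> dict[str, float]:
    """Empirical PI coverage and quantile-crossing rate at the final step."""
    pred = predict_batch(bundle, windows)
    y = windows.targets[:, -1]
    lo, up = pred[:, -1, 0], pred[:, -1, 2]
    inside = (y >= np.minimum(lo, up)) & (y <= np.maximum(lo, up))
    crossing = np.mean(np.any(pred[:, :, 2] < pred[:, :, 0], axis=1))
    return {"coverage_pct": float(100.0 * inside.mean()),
            "crossing_rate": float(crossing),
            "n": int(len(y))}


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def save_bundle(bundle: ModelBundle, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savez(directory / "weights.npz", **bundle.weights)
    sidecar = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in bundle.config.__dict__.items()},
        "stats": bundle.stats.to_dict(),
        "validation_mae": bundle.validation_mae,
        "history": bundle.history,
    }
    (directory / "bundle.json").write_text(json.dumps(sidecar, indent=2))


def load_bundle(directory: str | Path) -> ModelBundle:
    directory = Path(directory)
    with np.load(directory / "weights.npz") as z:
        weights = {k: z[k].copy() for k in z.files}
    sidecar = json.loads((directory / "bundle.json").read_text())
    cfg = dict(sidecar["config"])
    cfg["quantiles"] = tuple(cfg["quantiles"])
    return ModelBundle(weights=weights, config=TrainingConfig(**cfg),
                       stats=NormStats.from_dict(sidecar["stats"]),
                       validation_mae=sidecar["validation_mae"],
                       history=sidecar.get("history", []))
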