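"""Training, prediction and benchmarking.

Models are trained with a mixed MS-SSIM + L1 objective,
``alpha * (1 - MS-SSIM) + (1 - alpha) * L1_G``, where ``L1_G`` is the
Gaussian-window-weighted mean absolute error and ``alpha`` defaults to
0.84.  Benchmarking scores model output and a bilinear-upscaling control
against ground truth with PSNR and SSIM on every image, then compares
the two with paired t-tests.

All metrics operate on the normalized [0, 1] scale with
``data_range = 1`` so bit depth never enters the numbers.
"""

from __future__ import annotations

import json
import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import PairedSample, TiledDataset, TileRecord, stitch
from .model_zoo import ResUNet, bilinear_control, save_checkpoint
from .nn import Adam, Tensor
from .nn import functional as F

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "MetricsRecord", "msssim_l1_loss", "psnr", "ssim",
           "train", "predict", "benchmark", "paired_ttest", "relative_uplift"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 20
    batch_size: int = 4
    learning_rate: float = 1e-3
    loss_alpha: float = 0.84
    seed: int = 0
    checkpoint_path: str | None = None
    device: str = "cpu"

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not 0.0 <= self.loss_alpha <= 1.0:
            raise ValueError("loss_alpha must lie in [0, 1]")
        if self.device != "cpu":
            raise ValueError("only cpu execution is supported")


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def msssim_l1_loss(pred: np.ndarray | Tensor, target: np.ndarray | Tensor,
                   alpha: float = 0.84, data_range: float = 1.0) -> float | Tensor:
    """Mixed MS-SSIM + Gaussian-weighted L1 loss.

    Accepts NCHW Tensors (differentiable, used in training) or plain 2-D
    arrays (returns a float).  Zero when ``pred == target``.
    """
    if isinstance(pred, Tensor):
        return F.msssim_l1(pred, target, alpha=alpha, data_range=data_range)
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.ndim == 2:
        pred, target = pred[None, None], target[None, None]
    out = F.msssim_l1(Tensor(pred), Tensor(target), alpha=alpha,
                      data_range=data_range)
    return float(out.data)


def psnr(pred: np.ndarray, target: np.ndarray, data_range: float = 1.0) -> float:
    """Peak signal-to-noise ratio, 10*log10(range^2 / MSE), in dB.

    Identical images return the ``+inf`` sentinel.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    if data_range <= 0:
        raise ValueError("data_range must be positive")
    mse = float(np.mean((pred - target) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(data_range * data_range / mse)


def ssim(pred: np.ndarray, target: np.ndarray, data_range: float = 1.0) -> float:
    """Single-scale SSIM with an 11x11 Gaussian window (sigma 1.5) and the
    standard stabilizers K1 = 0.01, K2 = 0.03."""
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    ssim_map, _ = F.ssim_parts(Tensor(pred[None, None]),
                               Tensor(target[None, None]), data_range)
    return float(ssim_map.data.mean())


def paired_ttest(a, b) -> tuple[float, float]:
    """Two-sided paired t-test on the differences ``a - b``.

    All-zero differences are the degenerate case: returns ``(0.0, 1.0)``
    with a warning so report generation keeps a total ordering.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and equal length")
    if a.size < 2:
        raise ValueError("at least two pairs are required")
    diff = a - b
    if np.all(diff == diff[0]):
        if diff[0] == 0.0:
            warnings.warn("all paired differences are zero; reporting "
                          "t = 0, p = 1", stacklevel=2)
            return 0.0, 1.0
        return math.copysign(math.inf, diff[0]), 0.0
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def relative_uplift(uplift_method: float, uplift_baseline: float) -> float:
    """(method - baseline) / baseline; fractional relative increase.

    A zero baseline has no relative scale — raise, and report the
    absolute difference instead.
    """
    if uplift_baseline == 0.0:
        raise ZeroDivisionError(
            "baseline uplift is zero; report the absolute difference "
            f"{uplift_method} instead")
    return (uplift_method - uplift_baseline) / uplift_baseline


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _batch_tensor(images: list[np.ndarray]) -> Tensor:
    return Tensor(np.stack(images)[:, None, :, :])


def train(model: ResUNet, dataset: TiledDataset,
          train_records: list[TileRecord],
          val_records: list[TileRecord] | None,
          config: TrainConfig) -> tuple[ResUNet, dict[str, list[float]]]:
    """Minibatch Adam training on the MS-SSIM + L1 loss.

    Every epoch reshuffles the records and re-crappifies each tile with a
    fresh intensity and noise draw; the whole run is reproducible from
    ``config.seed``.  When validation records are given, the best-
    validation checkpoint is kept (and written to
    ``config.checkpoint_path`` if set).
    """
    if not train_records:
        raise ValueError("empty training set")
    ss = np.random.SeedSequence(config.seed)
    shuffle_ss, crap_ss, val_ss = ss.spawn(3)
    shuffle_rng = np.random.default_rng(shuffle_ss)
    crap_rng = np.random.default_rng(crap_ss)
    val_seed = val_ss.generate_state(1)[0]

    optimizer = Adam(model.parameters(), lr=config.learning_rate)
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": []}
    best_val = math.inf
    best_state = None

    for epoch in range(config.epochs):
        model.train_mode()
        order = np.array(train_records, dtype=object)
        shuffle_rng.shuffle(order)
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch = order[start:start + config.batch_size]
            samples = [dataset.get_train_sample(r, crap_rng) for r in batch]
            x = _batch_tensor([s.lr for s in samples])
            y = _batch_tensor([s.hr for s in samples])
            pred = model(x)
            loss = F.msssim_l1(pred, y, alpha=config.loss_alpha)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch starting with "
                    f"record {samples[0].record}")
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            losses.append(float(loss.data))
        history["train_loss"].append(float(np.mean(losses)))

        if val_records:
            # fixed seed every epoch: the validation degradation is
            # identical across epochs, so the metric is comparable
            val_rng = np.random.default_rng(val_seed)
            model.eval_mode()
            vlosses = []
            for start in range(0, len(val_records), config.batch_size):
                batch = val_records[start:start + config.batch_size]
                samples = [dataset.get_train_sample(r, val_rng, validation=True)
                           for r in batch]
                x = _batch_tensor([s.lr for s in samples])
                y = _batch_tensor([s.hr for s in samples])
                vlosses.append(float(F.msssim_l1(
                    model(x), y, alpha=config.loss_alpha).data))
            vloss = float(np.mean(vlosses))
            history["val_loss"].append(vloss)
            if vloss < best_val:
                best_val = vloss
                best_state = model.state_dict()
        logger.info("epoch %d: train %.5f%s", epoch,
                    history["train_loss"][-1],
                    f" val {history['val_loss'][-1]:.5f}" if val_records else "")

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval_mode()
    if config.checkpoint_path is not None:
        save_checkpoint(model, config.checkpoint_path)
    return model, history


# ---------------------------------------------------------------------------
# prediction and benchmarking
# ---------------------------------------------------------------------------

def predict(model: ResUNet, samples: list[PairedSample],
            stitch_spec: dict | None = None
            ) -> list[np.ndarray] | np.ndarray:
    """Restore LR samples in evaluation mode; outputs are clipped to
    [0, 1].  With ``stitch_spec = {"out_shape": ..., "stride": ...}`` the
    tiles are reassembled into one frame."""
    outputs = [(s.record, model.predict_array(s.lr)) for s in samples]
    if stitch_spec is None:
        return [out for _, out in outputs]
    return stitch(outputs, tuple(stitch_spec["out_shape"]),
                  int(stitch_spec["stride"]))


@dataclass
class MetricsRecord:
    """Per-image and aggregate PSNR/SSIM for method and control."""

    per_image: pd.DataFrame  # id, psnr_method, psnr_control, ssim_method, ssim_control
    summary: dict[str, float]
    uplift: dict[str, float]
    t_statistic: dict[str, float]
    p_value: dict[str, float]
    degenerate: dict[str, bool]

    def to_csv(self, path: str | Path) -> None:
        self.per_image.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        payload = {"summary": self.summary, "uplift": self.uplift,
                   "t_statistic": self.t_statistic, "p_value": self.p_value,
                   "degenerate": self.degenerate}
        Path(path).write_text(json.dumps(payload, indent=2))

    def summary_text(self) -> str:
        lines = ["Benchmark (method vs bilinear control)"]
        for metric in ("psnr", "ssim"):
            lines.append(
                f"  {metric.upper()}: method {self.summary[f'{metric}_method_mean']:.4f} "
                f"control {self.summary[f'{metric}_control_mean']:.4f} "
                f"uplift {self.uplift[metric]:+.4f} "
                f"(t = {self.t_statistic[metric]:.3f}, "
                f"p = {self.p_value[metric]:.3g})")
        return "\n".join(lines)


def benchmark(model: ResUNet, dataset_or_pairs, scale: int) -> MetricsRecord:
    """Score the model and the bilinear control on real HR/LR pairs.

    Accepts a benchmark-mode :class:`TiledDataset` or an explicit list of
    :class:`PairedSample` with both ``hr`` and ``lr`` set.  No crappifier
    runs anywhere on this path.
    """
    if isinstance(dataset_or_pairs, TiledDataset):
        ds = dataset_or_pairs
        pairs = [ds.get_benchmark_pair(r) for r in ds.records]
    else:
        pairs = list(dataset_or_pairs)
    if not pairs:
        raise ValueError("empty benchmark pair list")

    rows = []
    for i, s in enumerate(pairs):
        if s.hr is None:
            raise ValueError(f"benchmark pair {i} lacks an HR image")
        image_id = f"{s.record.source_id}/f{s.record.frame}" \
                   f"/r{s.record.row}c{s.record.col}"
        pred = model.predict_array(s.lr)
        ctrl = bilinear_control(s.lr, scale)
        rows.append({
            "id": image_id,
            "psnr_method": psnr(pred, s.hr),
            "psnr_control": psnr(ctrl, s.hr),
            "ssim_method": ssim(pred, s.hr),
            "ssim_control": ssim(ctrl, s.hr),
        })
    table = pd.DataFrame(rows)

    summary: dict[str, float] = {}
    uplift: dict[str, float] = {}
    t_stat: dict[str, float] = {}
    p_val: dict[str, float] = {}
    degenerate: dict[str, bool] = {}
    for metric in ("psnr", "ssim"):
        m = table[f"{metric}_method"].to_numpy()
        c = table[f"{metric}_control"].to_numpy()
        summary[f"{metric}_method_mean"] = float(m.mean())
        summary[f"{metric}_method_std"] = float(m.std(ddof=1)) if len(m) > 1 else 0.0
        summary[f"{metric}_control_mean"] = float(c.mean())
        summary[f"{metric}_control_std"] = float(c.std(ddof=1)) if len(c) > 1 else 0.0
        uplift[metric] = float(m.mean() - c.mean())
        if len(m) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t, p = paired_ttest(m, c)
        else:
            t, p = math.nan, math.nan
        t_stat[metric] = t
        p_val[metric] = p
        degenerate[metric] = bool(np.all((m - c) == 0.0))

    return MetricsRecord(per_image=table, summary=summary, uplift=uplift,
                         t_statistic=t_stat, p_value=p_val,
                         degenerate=degenerate)
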