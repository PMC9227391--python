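"""Performance metrics and robustness experiments.

Covers three jobs:

* confusion counts and the derived metrics — accuracy ACC = (TP+TN)/n,
  sensitivity TPR = TP/(TP+FN) and false-positive rate FPR = FP/(TN+FP);
* a hyperparameter scan that retrains the classifier over a grid of
  configurations on one fixed train/validation split;
* the chemical-shift robustness experiment: mixture spectra are translated
  along the ppm axis over a symmetric offset grid (±0.052 ppm by default,
  35 offsets) while the pure-compound spectra stay put, and the trained
  model's prediction is tracked across offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .augment import AugmentationConfig, SpectralPair, substream, superpose
from .model import ModelConfig, PSCNN, predict_pair, train
from .spectra import SpectralLibrary, Spectrum, normalize_max

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ShiftScanResult",
    "ShiftVariationStats",
    "UndefinedMetricError",
    "confusion_counts",
    "metrics",
    "evaluate_dataset",
    "hyperparameter_scan",
    "shift_spectrum",
    "shift_offset_grid",
    "invariance_scan",
    "build_invariance_pairs",
    "shift_variation_stats",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero (e.g. TPR with no positives)."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """ACC/TPR/FPR on [0, 1] plus the counts they were computed from."""

    acc: float
    tpr: float
    fpr: float
    counts: ConfusionCounts


def confusion_counts(
    probabilities: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
) -> ConfusionCounts:
    """Count TP/TN/FP/FN comparing ``probability > threshold`` to the labels."""
    p = np.asarray(probabilities, dtype=np.float64)
    y = np.asarray(labels)
    if p.shape != y.shape:
        raise ValueError(f"{p.size} probabilities but {y.size} labels")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    pred = p > threshold
    actual = y == 1
    return ConfusionCounts(
        tp=int(np.sum(pred & actual)),
        tn=int(np.sum(~pred & ~actual)),
        fp=int(np.sum(pred & ~actual)),
        fn=int(np.sum(~pred & actual)),
    )


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """ACC, TPR and FPR from confusion counts; undefined ratios raise."""
    if counts.total == 0:
        raise UndefinedMetricError("no samples: ACC undefined")
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("no positive samples: TPR undefined")
    if counts.tn + counts.fp == 0:
        raise UndefinedMetricError("no negative samples: FPR undefined")
    return MetricsReport(
        acc=(counts.tp + counts.tn) / counts.total,
        tpr=counts.tp / (counts.tp + counts.fn),
        fpr=counts.fp / (counts.tn + counts.fp),
        counts=counts,
    )


def evaluate_dataset(
    model: PSCNN,
    pairs: Sequence[SpectralPair] | tuple[np.ndarray, np.ndarray, np.ndarray],
    threshold: float = 0.5,
) -> MetricsReport:
    """Predict every pair and compute the metrics at ``threshold``."""
    if isinstance(pairs, tuple):
        xp, xm, y = pairs
    else:
        xp = np.stack([p.pure.intensities for p in pairs]).astype(np.float32)
        xm = np.stack([p.mixture.intensities for p in pairs]).astype(np.float32)
        y = np.array([p.label for p in pairs])
    if xp.shape[0] == 0:
        raise ValueError("empty evaluation set")
    probs = model.predict(xp, xm)
    return metrics(confusion_counts(probs, np.asarray(y, dtype=int), threshold))


# ---------------------------------------------------------------------------
# hyperparameter scan


def hyperparameter_scan(
    library: SpectralLibrary,
    data_config: AugmentationConfig,
    grid: Sequence[ModelConfig],
    verbose: bool = False,
) -> pd.DataFrame:
    """Train one model per config on an identical split; report validation ACC.

    Returns one row per config, in grid order, with the best row flagged —
    comparable because every run sees the same data and the same split.
    """
    if len(grid) == 0:
        raise ValueError("empty hyperparameter grid")
    from .augment import build_dataset, split_dataset  # local import avoids cycle

    dataset = split_dataset(build_dataset(library, data_config))
    train_arrays = dataset.arrays("train")
    val_arrays = dataset.arrays("val")
    rows = []
    for i, cfg in enumerate(grid):
        model = PSCNN(cfg, input_length=train_arrays[0].shape[1])
        train(model, train_arrays, val_arrays, verbose=verbose)
        rows.append(
            {
                "name": f"M{i + 1}",
                "epochs": cfg.epochs,
                "n_conv_layers": cfg.n_conv_layers,
                "learning_rate": cfg.learning_rate,
                "val_acc": model.history["val_acc"][-1],
            }
        )
    table = pd.DataFrame(rows)
    table["best"] = table["val_acc"] == table["val_acc"].max()
    return table


# ---------------------------------------------------------------------------
# chemical-shift robustness


def shift_spectrum(spectrum: Spectrum, delta: float) -> Spectrum:
    """Translate all peaks by ``delta`` ppm on the fixed grid.

    A peak at p moves to p + delta; intensities are linearly interpolated
    back onto the original grid and vacated edges fill with 0.
    """
    span = abs(spectrum.ppm[0] - spectrum.ppm[-1])
    if abs(delta) >= span:
        raise ValueError(f"|delta|={abs(delta)} exceeds the spectrum's ppm span")
    if delta == 0.0:
        return spectrum.copy()
    x_asc = spectrum.ppm[::-1]
    y_asc = spectrum.intensities[::-1]
    query = x_asc - delta  # y_new(x) = y_old(x - delta)
    out = np.interp(query, x_asc, y_asc, left=0.0, right=0.0)
    out = np.where((query < x_asc[0]) | (query > x_asc[-1]), 0.0, out)
    return Spectrum(
        spectrum.ppm.copy(), out[::-1], name=spectrum.name, meta=dict(spectrum.meta)
    )


def shift_offset_grid(max_shift: float = 0.052, step: float = 0.003) -> np.ndarray:
    """Symmetric ppm offsets {−k·step, …, 0, …, +k·step}, k = ⌊max/step⌋.

    The defaults scan ±0.052 ppm in 0.003-ppm steps, producing 35 offsets.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    if max_shift < 0:
        raise ValueError("max_shift must be non-negative")
    k = int(np.floor(max_shift / step + 1e-12))
    return np.arange(-k, k + 1) * step


@dataclass
class ShiftScanResult:
    """Predicted probability vs. applied mixture shift for one base pair.

    ``pass_window`` is the widest symmetric contiguous offset interval
    around zero with every probability > 0.5, or None if the unshifted pair
    is already misclassified.
    """

    offsets: np.ndarray
    probabilities: np.ndarray
    pass_window: tuple[float, float] | None = field(init=False)

    def __post_init__(self) -> None:
        o, p = np.asarray(self.offsets), np.asarray(self.probabilities)
        if o.shape != p.shape:
            raise ValueError("offsets and probabilities must align")
        center = int(np.argmin(np.abs(o)))
        if not p[center] > 0.5:
            self.pass_window = None
            return
        j = 0
        while (
            center - (j + 1) >= 0
            and center + (j + 1) < o.size
            and p[center - (j + 1)] > 0.5
            and p[center + (j + 1)] > 0.5
        ):
            j += 1
        self.pass_window = (float(o[center - j]), float(o[center + j]))


def invariance_scan(
    model: PSCNN, base_pair: SpectralPair, offsets: np.ndarray
) -> ShiftScanResult:
    """Predict the base pair under every mixture shift; pure spectrum unshifted."""
    offsets = np.asarray(offsets, dtype=np.float64)
    xm = np.stack(
        [shift_spectrum(base_pair.mixture, float(d)).intensities for d in offsets]
    ).astype(np.float32)
    xp = np.broadcast_to(
        base_pair.pure.intensities.astype(np.float32), xm.shape
    ).copy()
    probs = model.predict(xp, xm)
    return ShiftScanResult(offsets=offsets, probabilities=probs)


def build_invariance_pairs(
    library: SpectralLibrary,
    config: AugmentationConfig,
    component_counts: Sequence[int] = (2, 2, 3, 3, 4, 4, 5, 5),
) -> list[SpectralPair]:
    """Mixture-with-own-component pairs for the robustness experiment.

    Augments one mixture per entry of ``component_counts`` (default: two
    mixtures each of 2, 3, 4 and 5 components → 8 mixtures) and pairs every
    mixture with each of its components; the default yields 28 base pairs,
    all labeled 1.  Crossing them with the default 35-offset grid defines
    the 980 varied pairs of the full experiment.
    """
    if len(library) < max(component_counts):
        raise ValueError("library smaller than the largest requested mixture")
    seeds = substream(config.seed, "invariance").spawn(len(component_counts))
    pairs: list[SpectralPair] = []
    for count, seed in zip(component_counts, seeds):
        rng = np.random.default_rng(seed)
        chosen = rng.choice(len(library), size=count, replace=False)
        ratios = rng.uniform(config.ratio_range[0], config.ratio_range[1], size=count)
        mixture = normalize_max(
            superpose(
                [library[int(i)] for i in chosen], ratios, config.noise_sigma, rng
            )
        )
        composition = [(int(i), float(r)) for i, r in zip(chosen, ratios)]
        for idx in chosen:
            pairs.append(
                SpectralPair(
                    pure=library[int(idx)],
                    mixture=mixture,
                    label=1,
                    pure_index=int(idx),
                    composition=composition,
                )
            )
    return pairs


@dataclass
class ShiftVariationStats:
    """Mean ± 1.5·sd summary of observed peak-position deviations (ppm)."""

    deviations: np.ndarray
    ddof: int = 1
    mean: float = field(init=False)
    sd: float = field(init=False)
    interval: tuple[float, float] = field(init=False)
    coverage: float = field(init=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.deviations, dtype=np.float64)
        if d.size == 0:
            raise ValueError("need at least one deviation")
        self.deviations = d
        self.mean = float(d.mean())
        self.sd = float(d.std(ddof=self.ddof)) if d.size > self.ddof else 0.0
        half = 1.5 * self.sd
        self.interval = (self.mean - half, self.mean + half)
        inside = (d >= self.interval[0]) & (d <= self.interval[1])
        self.coverage = float(inside.mean())


def shift_variation_stats(deviations: Sequence[float], ddof: int = 1) -> ShiftVariationStats:
    """Summarize peak-position deviations: mean, sd, mean ± 1.5·sd, coverage.

    ``ddof=1`` (sample standard deviation) by default; pass ``ddof=0`` for
    the population convention.
    """
    return ShiftVariationStats(deviations=np.asarray(deviations, dtype=float), ddof=ddof)
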