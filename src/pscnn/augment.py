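"""Spectral-pair data augmentation.

NMR intensities are additive, so realistic mixture spectra can be
synthesized as ratio-weighted sums of pure-compound spectra plus noise.
Each training example is a pair (pure spectrum, mixture spectrum) labeled 1
if the mixture contains the pure compound and 0 otherwise.  Positive pairs
superpose the target compound with several others; negative pairs superpose
the same number of compounds while excluding the target.

Defaults follow the augmentation protocol used to train the classifier:
22,000 pairs at mixing ratios 0.2–1.0, split 18,000/2,000/2,000 into
train/validation/test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence
from zlib import crc32

import h5py
import numpy as np

from .spectra import (
    SpectralLibrary,
    Spectrum,
    SpectrumFormatError,
    mask_regions,
    normalize_max,
)

__all__ = [
    "AugmentationConfig",
    "SpectralPair",
    "AugmentedDataset",
    "superpose",
    "make_pair",
    "build_dataset",
    "split_dataset",
    "save_dataset",
    "load_dataset",
]

PARTITIONS = ("train", "val", "test")

#: solvent windows (ppm) zeroed when masking is on: DMSO-d6 2.50, HDO 3.33
SOLVENT_WINDOWS = ((2.45, 2.55), (3.28, 3.38))


def substream(seed: int, label: str) -> np.random.SeedSequence:
    """Named, independent random substream derived from one master seed."""
    return np.random.SeedSequence([int(seed), crc32(label.encode())])


@dataclass
class AugmentationConfig:
    """Protocol parameters for pair generation.

    noise_sigma is the standard deviation of the additive Gaussian noise
    relative to unit-max component spectra.  mask_windows lists ppm windows
    zeroed in every mixture (off by default; synthetic libraries have no
    solvent signal).
    """

    n_pairs: int = 22_000
    ratio_range: tuple[float, float] = (0.2, 1.0)
    components_range: tuple[int, int] = (2, 5)
    noise_sigma: float = 0.005
    positive_fraction: float = 0.5
    split_sizes: tuple[int, int, int] = (18_000, 2_000, 2_000)
    mask_windows: tuple[tuple[float, float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.ratio_range
        if not (0 < lo <= hi):
            raise ValueError("ratio_range must satisfy 0 < low <= high")
        if self.components_range[0] < 2 or self.components_range[1] < self.components_range[0]:
            raise ValueError("components_range must be an ordered range with min >= 2")
        if not (0 < self.positive_fraction < 1):
            raise ValueError("positive_fraction must be in (0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if sum(self.split_sizes) != self.n_pairs:
            raise ValueError(
                f"split_sizes {self.split_sizes} must sum to n_pairs={self.n_pairs}"
            )


@dataclass
class SpectralPair:
    """(pure spectrum, mixture spectrum, label) — the classifier's input unit.

    ``composition`` records the (library index, ratio) actually superposed;
    it is empty for experimental mixtures whose true content is unknown.
    """

    pure: Spectrum
    mixture: Spectrum
    label: int
    pure_index: int = -1
    composition: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label not in (0, 1):
            raise ValueError("label must be 0 or 1")
        if not self.pure.same_grid(self.mixture):
            raise ValueError("pure and mixture spectra must share one grid")
        if self.composition:
            present = any(i == self.pure_index for i, _ in self.composition)
            if present != bool(self.label):
                raise ValueError(
                    "label inconsistent with composition: target "
                    f"{self.pure_index} present={present}, label={self.label}"
                )


@dataclass
class AugmentedDataset:
    """All generated pairs plus (after splitting) their partition tags."""

    pairs: list[SpectralPair]
    config: AugmentationConfig
    partition: np.ndarray | None = None  # str tags, same length as pairs

    def subset(self, tag: str) -> list[SpectralPair]:
        if self.partition is None:
            raise ValueError("dataset has not been split; call split_dataset first")
        if tag not in PARTITIONS:
            raise ValueError(f"unknown partition {tag!r}")
        return [p for p, t in zip(self.pairs, self.partition) if t == tag]

    def arrays(self, tag: str | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Model-ready float32 arrays (pure, mixture, labels) for a partition."""
        pairs = self.pairs if tag is None else self.subset(tag)
        x_pure = np.stack([p.pure.intensities for p in pairs]).astype(np.float32)
        x_mix = np.stack([p.mixture.intensities for p in pairs]).astype(np.float32)
        y = np.array([p.label for p in pairs], dtype=np.float32)
        return x_pure, x_mix, y

    def __len__(self) -> int:
        return len(self.pairs)


def superpose(
    components: Sequence[Spectrum],
    ratios: Sequence[float],
    noise_sigma: float = 0.0,
    seed: int | np.random.SeedSequence | np.random.Generator = 0,
) -> Spectrum:
    """Pointwise Σ ratio·intensity plus i.i.d. Gaussian noise of sd noise_sigma.

    Deterministic given the seed.  The result is NOT renormalized here;
    callers that need unit-max mixtures normalize afterwards.
    """
    if len(components) != len(ratios):
        raise ValueError(
            f"{len(components)} components but {len(ratios)} ratios"
        )
    if len(components) == 0:
        raise ValueError("need at least one component")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    ref = components[0]
    total = np.zeros(len(ref), dtype=np.float64)
    for spec, ratio in zip(components, ratios):
        if not ref.same_grid(spec):
            raise ValueError(f"component {spec.name!r} not on the shared grid")
        if ratio <= 0:
            raise ValueError("ratios must be positive")
        total += float(ratio) * spec.intensities
    if noise_sigma > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        total = total + rng.normal(0.0, noise_sigma, size=total.shape)
    names = "+".join(s.name for s in components)
    return Spectrum(ref.ppm.copy(), total, name=f"mix({names})", meta={})


def make_pair(
    library: SpectralLibrary,
    target_index: int,
    positive: bool,
    config: AugmentationConfig,
    seed: int | np.random.SeedSequence,
) -> SpectralPair:
    """One labeled pair for ``target_index``.

    Positive pairs mix the target with k−1 other distinct compounds; negative
    pairs mix k distinct compounds, none of them the target; k is drawn from
    ``config.components_range`` and every mixing ratio i.i.d. uniform from
    ``config.ratio_range``.  The mixture is noise-corrupted, optionally
    solvent-masked, and re-normalized to unit maximum.
    """
    n = len(library)
    if not 0 <= target_index < n:
        raise IndexError(f"target_index {target_index} out of range for {n} entries")
    if n < config.components_range[1] + 1:
        raise ValueError(
            f"library of {n} entries is too small for up to "
            f"{config.components_range[1]} components plus a held-out target"
        )
    rng = np.random.default_rng(seed)
    k = int(rng.integers(config.components_range[0], config.components_range[1] + 1))
    others = [i for i in range(n) if i != target_index]
    if positive:
        chosen = [target_index] + list(
            rng.choice(others, size=k - 1, replace=False)
        )
    else:
        chosen = list(rng.choice(others, size=k, replace=False))
    ratios = rng.uniform(config.ratio_range[0], config.ratio_range[1], size=k)
    mixture = superpose(
        [library[int(i)] for i in chosen], ratios, config.noise_sigma, rng
    )
    if config.mask_windows:
        mixture = mask_regions(mixture, config.mask_windows)
    mixture = normalize_max(mixture)
    pure = library[target_index]
    if config.mask_windows:
        pure = normalize_max(mask_regions(pure, config.mask_windows))
    return SpectralPair(
        pure=pure,
        mixture=mixture,
        label=1 if positive else 0,
        pure_index=target_index,
        composition=[(int(i), float(r)) for i, r in zip(chosen, ratios)],
    )


def build_dataset(library: SpectralLibrary, config: AugmentationConfig) -> AugmentedDataset:
    """Generate the full pair set: n_pairs pairs, balanced per positive_fraction.

    Target compounds are cycled over the library so every entry appears as
    the pure side.  Each pair draws from its own spawned substream, so the
    dataset is a pure function of (library, config).
    """
    n = config.n_pairs
    n_pos = int(round(config.positive_fraction * n))
    labels = np.zeros(n, dtype=bool)
    labels[:n_pos] = True
    seeds = substream(config.seed, "augmentation").spawn(n)
    pairs = [
        make_pair(library, i % len(library), bool(labels[i]), config, seeds[i])
        for i in range(n)
    ]
    return AugmentedDataset(pairs=pairs, config=config)


def split_dataset(dataset: AugmentedDataset, config: AugmentationConfig | None = None) -> AugmentedDataset:
    """Tag each pair train/val/test by a uniformly random disjoint partition."""
    config = config or dataset.config
    sizes = config.split_sizes
    if sum(sizes) != len(dataset):
        raise ValueError(
            f"split sizes {sizes} do not sum to dataset size {len(dataset)}"
        )
    rng = np.random.default_rng(substream(config.seed, "split"))
    order = rng.permutation(len(dataset))
    tags = np.empty(len(dataset), dtype=object)
    start = 0
    for tag, size in zip(PARTITIONS, sizes):
        tags[order[start : start + size]] = tag
        start += size
    return AugmentedDataset(pairs=dataset.pairs, config=dataset.config, partition=tags)


# ---------------------------------------------------------------------------
# persistence


def save_dataset(dataset: AugmentedDataset, path: str | Path) -> None:
    """Write pairs, labels, composition and partition tags to HDF5."""
    path = Path(path)
    n = len(dataset)
    with h5py.File(path, "w") as fh:
        fh.attrs["container"] = "pscnn-augmented-dataset"
        fh.attrs["config"] = json.dumps(
            {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in vars(dataset.config).items()
            }
        )
        if n == 0:
            return
        grid = dataset.pairs[0].pure.ppm
        fh.create_dataset("grid", data=grid)
        fh.create_dataset(
            "pure", data=np.stack([p.pure.intensities for p in dataset.pairs])
        )
        fh.create_dataset(
            "mixture",
            data=np.stack([p.mixture.intensities for p in dataset.pairs]),
        )
        fh.create_dataset("label", data=np.array([p.label for p in dataset.pairs], dtype=np.int8))
        fh.create_dataset(
            "pure_index", data=np.array([p.pure_index for p in dataset.pairs], dtype=np.int32)
        )
        fh.create_dataset(
            "composition",
            data=np.array(
                [json.dumps(p.composition) for p in dataset.pairs],
                dtype=h5py.string_dtype(),
            ),
        )
        fh.create_dataset(
            "pure_name",
            data=np.array([p.pure.name for p in dataset.pairs], dtype=h5py.string_dtype()),
        )
        if dataset.partition is not None:
            fh.create_dataset(
                "partition",
                data=np.array(list(dataset.partition), dtype=h5py.string_dtype()),
            )


def load_dataset(path: str | Path) -> AugmentedDataset:
    path = Path(path)
    with h5py.File(path, "r") as fh:
        if fh.attrs.get("container") != "pscnn-augmented-dataset":
            raise SpectrumFormatError(f"{path}: not an augmented-dataset container")
        raw_cfg = json.loads(fh.attrs["config"])
        cfg = AugmentationConfig(
            **{k: tuple(map(tuple, v)) if k == "mask_windows" else tuple(v) if isinstance(v, list) else v
               for k, v in raw_cfg.items()}
        )
        if "grid" not in fh:
            return AugmentedDataset(pairs=[], config=cfg)
        grid = fh["grid"][()]
        pure = fh["pure"][()]
        mix = fh["mixture"][()]
        labels = fh["label"][()]
        pure_idx = fh["pure_index"][()]
        comps = [json.loads(c) for c in fh["composition"][()]]
        names = [n.decode() if isinstance(n, bytes) else n for n in fh["pure_name"][()]]
        partition = None
        if "partition" in fh:
            partition = np.array(
                [t.decode() if isinstance(t, bytes) else t for t in fh["partition"][()]],
                dtype=object,
            )
    pairs = [
        SpectralPair(
            pure=Spectrum(grid.copy(), pure[i], name=names[i]),
            mixture=Spectrum(grid.copy(), mix[i], name=f"mixture-{i}"),
            label=int(labels[i]),
            pure_index=int(pure_idx[i]),
            composition=[(int(a), float(b)) for a, b in comps[i]],
        )
        for i in range(len(labels))
    ]
    return AugmentedDataset(pairs=pairs, config=cfg, partition=partition)
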