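"""Microarray-like synthetic data with a planted informative-feature set.

Real expression matrices in this problem regime have far more features than
samples (thousands of probes, tens to a few hundred arrays) and only a small
set of class-discriminative features.  The generator emulates exactly that:
noise features are i.i.d. standard Gaussians; each informative feature j gets a
class-dependent mean shift

    mean(j, class k) = effect_size * (k - (c - 1) / 2) * sign_j

with unit-variance Gaussian noise, where sign_j alternates between +1 and -1
across informative features so up- and down-regulated markers both occur.  The
class levels are evenly spaced, so every pair of classes differs by at least
``effect_size`` noise standard deviations on every informative feature.  For
two classes this is the classic two-group mean-shift model with separation
``effect_size``.

Labels are allocated to requested class proportions by largest remainder
(exact to within one sample) and shuffled.  The matrix is min-max scaled onto
[0, 1] before being returned, matching what the downstream filter scorers
expect.  Everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_preprocess import Dataset, minmax_scale, write_dataset

__all__ = ["SyntheticSpec", "generate", "write_synthetic"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one generated dataset.

    Defaults describe a small binary-class expression experiment: 100 samples,
    200 features of which 5 are informative with a 2-standard-deviation class
    separation — few enough samples and a sparse enough signal to be honest
    about the m >> n regime while remaining quick to score exhaustively.
    """

    n_samples: int = 100
    n_features: int = 200
    n_informative: int = 5
    n_classes: int = 2
    effect_size: float = 2.0
    class_proportions: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2 or self.n_features < 1:
            raise ValueError("need n_samples >= 2 and n_features >= 1")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must be within [0, n_features]")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        props = self.proportions
        if len(props) != self.n_classes:
            raise ValueError("class_proportions length must equal n_classes")
        if abs(sum(props) - 1.0) > 1e-9 or any(p <= 0 for p in props):
            raise ValueError("class_proportions must be positive and sum to 1")
        if min(props) * self.n_samples < 1:
            raise ValueError("a class has zero expected samples")

    @property
    def proportions(self) -> tuple[float, ...]:
        if self.class_proportions is not None:
            return tuple(self.class_proportions)
        return tuple([1.0 / self.n_classes] * self.n_classes)


def _allocate_counts(n: int, proportions: tuple[float, ...]) -> np.ndarray:
    """Largest-remainder apportionment: exact to within one sample per class."""
    raw = np.asarray(proportions) * n
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1
    if np.any(counts == 0):
        raise ValueError("a class received zero samples; increase n_samples")
    return counts


def generate(spec: SyntheticSpec) -> tuple[Dataset, list[str]]:
    """Draw one dataset; returns it with the informative feature names."""
    rng = np.random.default_rng(spec.seed)
    n, m, c = spec.n_samples, spec.n_features, spec.n_classes

    counts = _allocate_counts(n, spec.proportions)
    y = np.repeat(np.arange(c), counts)
    rng.shuffle(y)

    width = len(str(m))
    names = [f"gene{j + 1:0{width}d}" for j in range(m)]
    informative_idx = np.sort(rng.choice(m, size=spec.n_informative, replace=False))

    values = rng.standard_normal((n, m))
    offsets = np.arange(c) - (c - 1) / 2.0
    for rank, j in enumerate(informative_idx):
        sign = 1.0 if rank % 2 == 0 else -1.0
        values[:, j] += spec.effect_size * sign * offsets[y]

    data = Dataset(
        values=values,
        feature_names=names,
        labels=np.array([f"class{k}" for k in y]),
    )
    return minmax_scale(data), [names[j] for j in informative_idx]


def write_synthetic(spec: SyntheticSpec, path: str, truth_path: str | None = None):
    """Generate and write the dataset (and the ground-truth sidecar)."""
    data, informative = generate(spec)
    write_dataset(data, path)
    if truth_path is not None:
        with open(truth_path, "w", encoding="utf-8") as fh:
            fh.write("\n".join(informative) + "\n")
    return data, informative
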