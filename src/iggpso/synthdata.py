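"""Synthetic high-dimensional, small-sample expression data.

Mimics the regime of public cancer gene-expression benchmarks — thousands
of features, at most a couple of hundred samples, 2-4 classes — with three
planted feature roles:

* *informative*: class-shifted Gaussians, class means spaced ``effect_size``
  within-class standard deviations apart (a per-feature random permutation
  decides which class sits at which mean, so informative features do not all
  point the same way);
* *redundant*: a randomly chosen informative feature plus Gaussian noise,
  so redundancy is detectable by simple correlation;
* *irrelevant*: standard Gaussians independent of the class.

Feature columns are shuffled so the planted structure is not positional,
and the ground-truth role of every feature is returned alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import ExpressionDataset

__all__ = ["SyntheticSpec", "generate", "paper_shape_presets"]

ROLE_INFORMATIVE = "informative"
ROLE_REDUNDANT = "redundant"
ROLE_IRRELEVANT = "irrelevant"


@dataclass
class SyntheticSpec:
    """Recipe for one synthetic dataset."""

    n_samples: int = 100
    n_features: int = 2000
    n_informative: int = 20
    n_redundant: int = 30
    n_classes: int = 2
    effect_size: float = 1.5
    redundancy_noise_sd: float = 0.5
    class_proportions: tuple[float, ...] | None = None
    seed: int = 0
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_informative + self.n_redundant > self.n_features:
            raise ValueError("planted features exceed n_features")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.redundancy_noise_sd < 0:
            raise ValueError("redundancy_noise_sd must be >= 0")
        if self.n_redundant > 0 and self.n_informative == 0:
            raise ValueError("redundant features need informative parents")
        if self.class_proportions is None:
            self.class_proportions = tuple(1.0 / self.n_classes for _ in range(self.n_classes))
        if len(self.class_proportions) != self.n_classes:
            raise ValueError("one proportion per class required")
        if abs(sum(self.class_proportions) - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        if self.n_samples < self.n_classes:
            raise ValueError("need at least one sample per class")


def _apportion(n: int, proportions: tuple[float, ...]) -> np.ndarray:
    """Largest-remainder apportionment of n samples over the classes."""
    quotas = np.array(proportions) * n
    counts = np.floor(quotas).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(quotas - counts), kind="stable")
    counts[order[:remainder]] += 1
    # guarantee every class at least one sample
    while counts.min() == 0:
        counts[np.argmin(counts)] += 1
        counts[np.argmax(counts)] -= 1
    return counts


def generate(spec: SyntheticSpec) -> tuple[ExpressionDataset, np.ndarray]:
    """Build the dataset; returns (dataset, per-feature role labels)."""
    rng = np.random.default_rng(spec.seed)
    counts = _apportion(spec.n_samples, spec.class_proportions)
    labels = np.repeat(np.arange(spec.n_classes), counts)

    n_irr = spec.n_features - spec.n_informative - spec.n_redundant
    informative = rng.standard_normal((spec.n_samples, spec.n_informative))
    for j in range(spec.n_informative):
        class_means = rng.permutation(spec.n_classes) * spec.effect_size
        informative[:, j] += class_means[labels]
    if spec.n_redundant > 0:
        parents = rng.integers(spec.n_informative, size=spec.n_redundant)
        redundant = informative[:, parents] + rng.normal(
            0.0, spec.redundancy_noise_sd, (spec.n_samples, spec.n_redundant)
        )
    else:
        redundant = np.empty((spec.n_samples, 0))
    irrelevant = rng.standard_normal((spec.n_samples, n_irr))

    matrix = np.hstack([informative, redundant, irrelevant])
    roles = np.array(
        [ROLE_INFORMATIVE] * spec.n_informative
        + [ROLE_REDUNDANT] * spec.n_redundant
        + [ROLE_IRRELEVANT] * n_irr
    )
    perm = rng.permutation(spec.n_features)
    matrix = matrix[:, perm]
    roles = roles[perm]

    dataset = ExpressionDataset(
        expression=matrix,
        labels=labels,
        feature_ids=[f"g{j:05d}" for j in range(spec.n_features)],
        sample_ids=[f"s{i:04d}" for i in range(spec.n_samples)],
        class_names=[f"class{c}" for c in range(spec.n_classes)],
    )
    return dataset, roles


def paper_shape_presets() -> list[SyntheticSpec]:
    """Four presets matching well-known benchmark shapes.

    (features, samples, classes) = (5966, 102, 2), (5748, 171, 4),
    (4434, 50, 4) and (325, 73, 4) — the prostate, toxicogenomics, glioma
    and discrete-lung expression benchmark shapes — with the default
    planted-structure parameters.
    """
    shapes = [
        ("prostate_like", 5966, 102, 2),
        ("tox_like", 5748, 171, 4),
        ("glioma_like", 4434, 50, 4),
        ("lung_like", 325, 73, 4),
    ]
    presets = []
    for name, n_features, n_samples, n_classes in shapes:
        presets.append(
            SyntheticSpec(
                n_samples=n_samples,
                n_features=n_features,
                n_informative=20,
                n_redundant=30,
                n_classes=n_classes,
                name=name,
            )
        )
    return presets
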