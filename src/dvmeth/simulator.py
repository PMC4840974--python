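"""Synthetic beta-value datasets with known differential-variability structure.

The generator draws a features x samples matrix of beta values for a
two-phenotype design (normal vs disease, equal group sizes).  Null CpGs are
unmethylated in both phenotypes, Beta(a1, b1) with defaults (10, 90): mean
0.1, sd ~0.03.  True differentially variable CpGs (DVCs) have some or all
disease samples redrawn from Beta(a2, b2) with defaults (6, 4): mean 0.6,
sd ~0.15, i.e. an average methylation gain of ~0.5 in altered samples.

Three DV types are generated, with a fixed number of true CpGs per type:

* ``type1a`` -- every disease sample is altered: a mean-dominated shift.
* ``type1b`` -- a subset (default 20 of 50) of disease samples is altered:
  differential variance is the key signal, but a mean shift remains.
* ``type2``  -- only a few outlier disease samples (default 3 of 50) are
  altered: no significant mean difference, variance only.

A ``type3`` pattern (bidirectional, discoordinated outliers) can be
requested explicitly; it is off by default and uses a mid-methylated base
so that outliers can deviate in both directions.

Only hypermethylation is simulated by default; because the beta scale is
symmetric under b -> 1 - b there is no loss of generality, and a
``direction="hypo"`` flag generates the mirrored datasets for testing
direction handling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import MethylationDataset

__all__ = ["SimConfig", "SimulatedDataset", "simulate_dataset", "theoretical_moments"]

TRUTH_LABELS = ("null", "type1a", "type1b", "type2")


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the standard benchmark conditions."""

    n_features: int = 6000
    n_samples_per_group: int = 50
    n_true_per_type: int = 200
    a1: float = 10.0
    b1: float = 90.0
    a2: float = 6.0
    b2: float = 4.0
    n_altered_type1b: int = 20
    n_altered_type2: int = 3
    seed: int = 0
    direction: str = "hyper"
    n_true_type3: int = 0

    def validate(self) -> None:
        if min(self.a1, self.b1, self.a2, self.b2) <= 0:
            raise ValueError("beta shape parameters must be positive")
        if self.n_true_per_type < 0 or self.n_true_type3 < 0:
            raise ValueError("true-positive counts must be non-negative")
        if 3 * self.n_true_per_type + self.n_true_type3 > self.n_features:
            raise ValueError("more true DVCs requested than features")
        if not (
            0 <= self.n_altered_type2 <= self.n_altered_type1b <= self.n_samples_per_group
        ):
            raise ValueError(
                "need n_altered_type2 <= n_altered_type1b <= n_samples_per_group"
            )
        if self.direction not in ("hyper", "hypo"):
            raise ValueError("direction must be 'hyper' or 'hypo'")
        if self.n_samples_per_group < 2:
            raise ValueError("need at least 2 samples per group")


@dataclass
class SimulatedDataset:
    """A generated dataset plus per-feature ground truth.

    ``truth`` holds one label per feature in {null, type1a, type1b, type2}
    (plus type3 when requested); ``altered_samples`` maps each true feature's
    id to the disease-sample indices (within the disease group) that were
    drawn from the altered distribution.
    """

    dataset: MethylationDataset
    truth: np.ndarray
    altered_samples: dict = field(default_factory=dict)
    config: SimConfig | None = None

    def truth_index(self, label: str) -> np.ndarray:
        return np.where(self.truth == label)[0]


def theoretical_moments(a: float, b: float) -> tuple[float, float]:
    """Mean and standard deviation of a Beta(a, b) distribution."""
    if a <= 0 or b <= 0:
        raise ValueError("shape parameters must be positive")
    mean = a / (a + b)
    sd = np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1.0)))
    return float(mean), float(sd)


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate one dataset under ``config``; deterministic given the seed.

    Features are laid out as the type-1a block, then type-1b, then type-2
    (then type-3 if requested), then nulls; the altered-sample subset of
    every partially altered feature is drawn independently per feature.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_per_group = config.n_samples_per_group
    n_samples = 2 * n_per_group
    k = config.n_true_per_type

    # group 0 = normal in columns 0..n-1, group 1 = disease in columns n..2n-1
    values = rng.beta(config.a1, config.b1, size=(config.n_features, n_samples))

    truth = np.array(["null"] * config.n_features, dtype=object)
    truth[0:k] = "type1a"
    truth[k : 2 * k] = "type1b"
    truth[2 * k : 3 * k] = "type2"
    n_type3 = config.n_true_type3
    if n_type3:
        truth[3 * k : 3 * k + n_type3] = "type3"

    altered: dict[str, np.ndarray] = {}
    feature_ids = np.array(
        [f"cg{i:06d}" for i in range(config.n_features)], dtype=object
    )

    def _alter(row: int, n_altered: int) -> None:
        subset = np.sort(rng.choice(n_per_group, size=n_altered, replace=False))
        values[row, n_per_group + subset] = rng.beta(config.a2, config.b2, size=n_altered)
        altered[feature_ids[row]] = subset

    for row in range(0, k):
        _alter(row, n_per_group)
    for row in range(k, 2 * k):
        _alter(row, config.n_altered_type1b)
    for row in range(2 * k, 3 * k):
        _alter(row, config.n_altered_type2)

    if n_type3:
        # Bidirectional outliers need headroom on both sides, so type-3
        # features sit on a mid-methylated base; twice the type-2 outlier
        # count, each deviating up or down with equal probability.
        n_out = min(2 * config.n_altered_type2, n_per_group)
        for row in range(3 * k, 3 * k + n_type3):
            values[row, :] = rng.beta(50, 50, size=n_samples)
            subset = np.sort(rng.choice(n_per_group, size=n_out, replace=False))
            up = rng.random(n_out) < 0.5
            draws = rng.beta(45, 5, size=n_out)
            draws[~up] = 1.0 - draws[~up]
            values[row, n_per_group + subset] = draws
            altered[feature_ids[row]] = subset

    if config.direction == "hypo":
        values = 1.0 - values

    group = np.concatenate([np.zeros(n_per_group, int), np.ones(n_per_group, int)])
    sample_ids = np.array(
        [f"N{i:03d}" for i in range(n_per_group)]
        + [f"D{i:03d}" for i in range(n_per_group)],
        dtype=object,
    )
    ds = MethylationDataset(
        values=values, feature_ids=feature_ids, sample_ids=sample_ids, group=group
    )
    return SimulatedDataset(dataset=ds, truth=truth, altered_samples=altered, config=config)


def null_config(config: SimConfig | None = None, seed: int | None = None) -> SimConfig:
    """A copy of ``config`` with every feature null (no true DVCs)."""
    config = config or SimConfig()
    updates: dict = {"n_true_per_type": 0, "n_true_type3": 0}
    if seed is not None:
        updates["seed"] = seed
    return replace(config, **updates)
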