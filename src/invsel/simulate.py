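"""Synthetic data with known group structure and noisy classifications.

The generator emulates the benchmark setting the package is built for: a
numeric feature matrix (samples x features) in which a minority of features
carries a true group structure of ``n_groups`` normal populations with
equidistant means and a common standard deviation, together with an observed
classification that is a corrupted version of the truth.

Two corruption schemes are supported:

* binary (two true groups): each sample's observed 0/1 label is drawn from a
  Bernoulli whose success probability depends on the true group — ``prob1``
  for true group 0 and ``prob2`` for true group 1.  ``prob1=0, prob2=1`` is
  the error-free corner; ``prob1=prob2`` destroys all label information.
* semi-quantitative (graded): the true rating on an ordered integer scale is
  perturbed by subtracting a Bernoulli(``prob1``) draw and taking the absolute
  value, so category 0 flips up to 1 and every category c >= 1 drops to c-1.

Ground-truth group labels are kept alongside the observed ones so that a
downstream evaluation can score models against the truth the rater never saw.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InvalidConfigError, InvalidInputError

__all__ = [
    "SimulationConfig",
    "SimulatedDataset",
    "balanced_group_sizes",
    "sample_informative_mask",
    "generate_features",
    "inject_binary_error",
    "inject_binomial_rating",
    "inject_graded_error",
    "simulate_dataset",
    "write_dataset",
]

# fixed spawn keys so each stage of the generator can be reproduced on its own
_STAGE_MASK = 0
_STAGE_FEATURES = 1
_STAGE_ERRORS = 2


@dataclass
class SimulationConfig:
    """Parameters of one simulated condition.

    Attributes
    ----------
    n_samples, n_features : int
        Size of the feature matrix.
    n_groups : int
        Number of true underlying populations (>= 2).
    frac_informative : float
        Probability that a feature is associated with the grouping (~0.10
        in the benchmark conditions).
    mean_diff : float
        Difference between the means of adjacent populations (constant
        across the scale — equidistant groups).
    sd : float
        Common standard deviation of every population.
    prob1, prob2 : float
        Corruption parameters; see module docstring.  ``prob2`` is only used
        by the binary scheme.
    encoding : {"binary", "semiquant"}
        Observed-label scheme.
    n_categories : int
        Number of categories of the observed semi-quantitative scale; when it
        differs from ``n_groups`` the true grouping is re-expressed on this
        scale before errors are applied (a rater using a finer or coarser
        scale than the underlying structure).  Ignored for binary encoding.
    base : float
        Mean of the lowest population and of non-informative features.
    seed : int
        Master seed; per-stage sub-streams are derived from it.
    """

    n_samples: int = 50
    n_features: int = 100
    n_groups: int = 2
    frac_informative: float = 0.10
    mean_diff: float = 2.0
    sd: float = 1.0
    prob1: float = 0.1
    prob2: float = 0.9
    encoding: str = "binary"
    n_categories: int | None = None
    base: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.n_features < 1:
            raise InvalidConfigError("n_samples and n_features must be positive")
        if self.n_groups < 2:
            raise InvalidConfigError("n_groups must be >= 2")
        if self.n_groups > self.n_samples:
            raise InvalidConfigError("n_groups cannot exceed n_samples")
        if not 0.0 <= self.frac_informative <= 1.0:
            raise InvalidConfigError("frac_informative must lie in [0, 1]")
        if self.sd <= 0:
            raise InvalidConfigError("sd must be positive")
        for name in ("prob1", "prob2"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InvalidConfigError(f"{name} must lie in [0, 1]")
        if self.encoding not in ("binary", "semiquant"):
            raise InvalidConfigError("encoding must be 'binary' or 'semiquant'")
        if self.encoding == "binary" and self.n_groups != 2:
            raise InvalidConfigError("binary encoding requires n_groups == 2")
        if self.n_categories is None:
            self.n_categories = 2 if self.encoding == "binary" else self.n_groups
        if self.encoding == "semiquant" and self.n_categories < 2:
            raise InvalidConfigError("n_categories must be >= 2")


@dataclass
class SimulatedDataset:
    """A generated condition: features plus true and observed labels."""

    features: np.ndarray  # (n_samples, n_features)
    true_labels: np.ndarray  # true group index, 0..n_groups-1
    observed_labels: np.ndarray  # noisy rating on the observed scale
    informative_idx: np.ndarray  # sorted feature indices carrying signal
    true_ratings: np.ndarray  # error-free rating on the observed scale
    config: SimulationConfig = field(repr=False)

    @property
    def feature_ids(self) -> list[str]:
        width = len(str(self.features.shape[1] - 1))
        return [f"f{j:0{width}d}" for j in range(self.features.shape[1])]

    @property
    def sample_ids(self) -> list[str]:
        width = len(str(self.features.shape[0] - 1))
        return [f"s{i:0{width}d}" for i in range(self.features.shape[0])]


def _rng(seed: int, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(stage,)))


def balanced_group_sizes(n_samples: int, n_groups: int) -> np.ndarray:
    """Split ``n_samples`` into ``n_groups`` balanced groups.

    When an even split is impossible the remainder is absorbed entirely by
    the highest-ranked group, so the first ``n_groups - 1`` entries all equal
    ``n_samples // n_groups``.
    """
    if n_groups < 1:
        raise InvalidConfigError("n_groups must be >= 1")
    if n_samples < n_groups:
        raise InvalidConfigError("need at least one sample per group")
    base = n_samples // n_groups
    sizes = np.full(n_groups, base, dtype=int)
    sizes[-1] += n_samples - base * n_groups
    return sizes


def sample_informative_mask(n_features: int, frac: float, seed: int) -> np.ndarray:
    """Independently mark each feature informative with probability ``frac``.

    Returns the sorted array of informative feature indices.  Implemented as
    a uniform draw per feature compared against ``frac`` (so the set size is
    Binomial(n_features, frac), not fixed).
    """
    if not 0.0 <= frac <= 1.0:
        raise InvalidConfigError("frac must lie in [0, 1]")
    rng = _rng(seed, _STAGE_MASK)
    u = rng.uniform(size=n_features)
    return np.flatnonzero(u < frac)


def generate_features(
    sizes: np.ndarray,
    informative_idx: np.ndarray,
    mean_diff: float,
    sd: float,
    n_features: int,
    seed: int,
    base: float = 0.0,
) -> np.ndarray:
    """Draw the (n_samples, n_features) matrix given group sizes and the mask.

    Informative feature j for a sample in group g is Normal(base + g*mean_diff,
    sd); non-informative features are Normal(base, sd) for every sample, so
    the difficulty of the selection problem is governed purely by the
    mean_diff/sd ratio.
    """
    if sd <= 0:
        raise InvalidConfigError("sd must be positive")
    sizes = np.asarray(sizes, dtype=int)
    n_samples = int(sizes.sum())
    rng = _rng(seed, _STAGE_FEATURES)
    X = rng.normal(loc=base, scale=sd, size=(n_samples, n_features))
    groups = np.repeat(np.arange(sizes.size), sizes)
    informative_idx = np.asarray(informative_idx, dtype=int)
    if informative_idx.size:
        shift = np.outer(groups.astype(float) * mean_diff, np.ones(informative_idx.size))
        X[:, informative_idx] += shift
    return X


def inject_binary_error(
    true_labels: np.ndarray, prob1: float, prob2: float, seed: int
) -> np.ndarray:
    """Observed 0/1 labels: Bernoulli(prob1) for true 0, Bernoulli(prob2) for true 1."""
    true_labels = np.asarray(true_labels)
    if not np.isin(true_labels, (0, 1)).all():
        raise InvalidInputError("binary error injection requires 0/1 true labels")
    rng = _rng(seed, _STAGE_ERRORS)
    u = rng.uniform(size=true_labels.shape)
    p = np.where(true_labels == 0, prob1, prob2)
    return (u < p).astype(int)


def inject_binomial_rating(
    true_labels: np.ndarray, n_categories: int, prob1: float, prob2: float, seed: int
) -> np.ndarray:
    """Semi-quantitative rating of a two-group truth: per-group binomial redraw.

    A rater using a ``n_categories``-point scale on samples from two
    underlying groups: the observed rating is Binomial(n_categories - 1, p)
    with p = ``prob1`` for true group 0 and ``prob2`` for true group 1 — the
    direct c-category generalisation of the binary per-group Bernoulli
    scheme (which is the special case n_categories = 2).  ``prob1 = prob2``
    destroys all label information; a larger scale concentrates the rating
    around (c-1)*p and therefore carries *more* information for unequal
    probabilities.
    """
    true_labels = np.asarray(true_labels)
    if not np.isin(true_labels, (0, 1)).all():
        raise InvalidInputError("binomial rating requires 0/1 true group labels")
    if n_categories < 2:
        raise InvalidConfigError("n_categories must be >= 2")
    rng = _rng(seed, _STAGE_ERRORS)
    p = np.where(true_labels == 0, prob1, prob2)
    return rng.binomial(n_categories - 1, p)


def inject_graded_error(true_labels: np.ndarray, prob1: float, seed: int) -> np.ndarray:
    """Graded corruption: observed = |true - e| with e ~ Bernoulli(prob1).

    Category 0 flips up to 1; every category c >= 1 drops to c - 1.
    """
    true_labels = np.asarray(true_labels)
    if (true_labels < 0).any():
        raise InvalidInputError("graded error injection requires nonnegative labels")
    rng = _rng(seed, _STAGE_ERRORS)
    e = (rng.uniform(size=true_labels.shape) < prob1).astype(int)
    return np.abs(true_labels - e)


def _ratings_on_scale(true_labels: np.ndarray, n_groups: int, n_categories: int) -> np.ndarray:
    """Re-express the true grouping on the observed rating scale.

    With matching cardinality the rating is the group index itself.  Otherwise
    the ordered samples are partitioned into ``n_categories`` balanced blocks
    (same expansion rule as the groups), so low ratings line up with low
    groups — the rater grades the same ordering on a different resolution.
    """
    if n_categories == n_groups:
        return true_labels.copy()
    sizes = balanced_group_sizes(true_labels.size, n_categories)
    order = np.argsort(true_labels, kind="stable")
    ratings = np.empty(true_labels.size, dtype=int)
    ratings[order] = np.repeat(np.arange(n_categories), sizes)
    return ratings


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full condition from a :class:`SimulationConfig`.

    Bit-reproducible for a fixed seed; the mask, feature and error stages use
    independent sub-streams of the master seed.
    """
    sizes = balanced_group_sizes(config.n_samples, config.n_groups)
    true_labels = np.repeat(np.arange(config.n_groups), sizes)
    informative_idx = sample_informative_mask(
        config.n_features, config.frac_informative, config.seed
    )
    X = generate_features(
        sizes,
        informative_idx,
        config.mean_diff,
        config.sd,
        config.n_features,
        config.seed,
        base=config.base,
    )
    if config.encoding == "binary":
        true_ratings = true_labels.copy()
        observed = inject_binary_error(true_labels, config.prob1, config.prob2, config.seed)
    elif config.n_groups == 2 and config.n_categories != 2:
        # two-group truth rated on a finer scale: per-group binomial redraw
        true_ratings = true_labels * (config.n_categories - 1)
        observed = inject_binomial_rating(
            true_labels, config.n_categories, config.prob1, config.prob2, config.seed
        )
    else:
        true_ratings = _ratings_on_scale(true_labels, config.n_groups, config.n_categories)
        observed = inject_graded_error(true_ratings, config.prob1, config.seed)
    return SimulatedDataset(
        features=X,
        true_labels=true_labels,
        observed_labels=observed,
        informative_idx=informative_idx,
        true_ratings=true_ratings,
        config=config,
    )


def write_dataset(dataset: SimulatedDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a dataset as features.tsv / meta.tsv / config.json.

    features.tsv holds features in rows and samples in columns (feature IDs in
    the first column, sample IDs in the header); meta.tsv holds one row per
    sample with true_label, observed_label and true_rating columns.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    feat = pd.DataFrame(
        dataset.features.T, index=dataset.feature_ids, columns=dataset.sample_ids
    )
    feat.index.name = "feature_id"
    meta = pd.DataFrame(
        {
            "true_label": dataset.true_labels,
            "observed_label": dataset.observed_labels,
            "true_rating": dataset.true_ratings,
        },
        index=dataset.sample_ids,
    )
    meta.index.name = "sample_id"
    paths = {
        "features": out_dir / "features.tsv",
        "meta": out_dir / "meta.tsv",
        "config": out_dir / "config.json",
    }
    feat.to_csv(paths["features"], sep="\t")
    meta.to_csv(paths["meta"], sep="\t")
    paths["config"].write_text(json.dumps(asdict(dataset.config), indent=2) + "\n")
    return paths
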