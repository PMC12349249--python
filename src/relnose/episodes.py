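"""N-way K-shot episode construction.

An episode is one few-shot task: ``n_way`` classes are drawn from a bundle,
``k_shot`` labeled support samples are taken from each, and up to
``query_per_class`` further samples per class (disjoint from the support
set) form the queries to classify.  The relation-target matrix encodes, for
every (class, query) pair, whether the query truly belongs to that class —
the regression target of the relation-scoring model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import DatasetBundle, Sample


@dataclass(frozen=True)
class EpisodeSpec:
    """Task shape: N-way, K-shot, with P queries per class."""

    n_way: int = 4
    k_shot: int = 1
    query_per_class: int = 20

    def __post_init__(self) -> None:
        if self.n_way < 2:
            raise ValueError("n_way must be >= 2")
        if self.k_shot < 1 or self.query_per_class < 1:
            raise ValueError("k_shot and query_per_class must be >= 1")


@dataclass
class Episode:
    """Support samples grouped by class plus a flat query list."""

    support: list[list[Sample]]       # [n_way][k_shot]
    query: list[Sample]
    class_order: list[str] = field(default_factory=list)

    @property
    def n_way(self) -> int:
        return len(self.support)

    @property
    def k_shot(self) -> int:
        return len(self.support[0])

    def support_array(self) -> np.ndarray:
        """[N, K, T, C] stacked support matrices."""
        return np.stack([np.stack([s.matrix for s in row]) for row in self.support])

    def query_array(self) -> np.ndarray:
        """[n_query, T, C] stacked query matrices."""
        return np.stack([s.matrix for s in self.query])

    def query_class_indices(self) -> np.ndarray:
        index = {c: i for i, c in enumerate(self.class_order)}
        return np.array([index[s.label] for s in self.query])


def sample_episode(bundle: DatasetBundle, spec: EpisodeSpec,
                   rng: np.random.Generator) -> Episode:
    """Draw one episode without replacement.

    Each selected class contributes exactly ``k_shot`` support samples and
    ``min(query_per_class, remaining)`` queries, so small classes (e.g. an
    8-sample breath category) are clipped rather than rejected.
    """
    by_class = bundle.by_class()
    eligible = [c for c in bundle.classes if len(by_class[c]) >= spec.k_shot + 1]
    if len(eligible) < spec.n_way:
        raise ValueError(
            f"need {spec.n_way} classes with >= {spec.k_shot + 1} samples, "
            f"have {len(eligible)}")
    chosen = list(rng.choice(eligible, size=spec.n_way, replace=False))
    support: list[list[Sample]] = []
    query: list[Sample] = []
    for cls in chosen:
        pool = by_class[cls]
        order = rng.permutation(len(pool))
        support.append([pool[i] for i in order[:spec.k_shot]])
        n_query = min(spec.query_per_class, len(pool) - spec.k_shot)
        query.extend(pool[i] for i in order[spec.k_shot:spec.k_shot + n_query])
    return Episode(support=support, query=query, class_order=[str(c) for c in chosen])


def relation_targets(episode: Episode) -> np.ndarray:
    """0/1 matrix [n_way, n_query]: entry (i, j) is 1 iff query j belongs to
    class i.  Every query column sums to exactly 1."""
    q_idx = episode.query_class_indices()
    targets = np.zeros((episode.n_way, len(episode.query)))
    targets[q_idx, np.arange(len(episode.query))] = 1.0
    return targets
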