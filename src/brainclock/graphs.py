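"""From connectivity matrices to model-ready graph samples.

Each subject's normalized O-information matrix becomes a weighted graph:
the matrix is the adjacency, and node i's feature vector is row i of the
same matrix. The module also provides NaN filtering, age-stratified
train/test splitting with 5-fold cross-validation folds, and the
age-interpolation augmentation M_t = (1 - alpha) M_1 + alpha M_2 with
alpha = (a_t - a_1) / (a_2 - a_1), applied between age-adjacent training
subjects within each stratum. Augmented samples are flagged and are never
eligible for validation or test sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .errors import ContractError
from .hoi import OmegaMatrix
from .synthetic import SubjectRecord

logger = logging.getLogger(__name__)


@dataclass
class GraphSample:
    """Weighted graph with per-node features and a target age."""

    sample_id: str
    adjacency: np.ndarray
    node_features: np.ndarray
    target_age: float
    record: SubjectRecord | None = None
    augmented: bool = False
    parent_ids: tuple[str, str] | None = None

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


@dataclass
class SplitPlan:
    """Hold-out split plus cross-validation folds over the training ids."""

    train_ids: list[str]
    test_ids: list[str]
    folds: list[tuple[list[str], list[str]]]
    strata: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        fold_of = {}
        for k, (_, val) in enumerate(self.folds):
            for sid in val:
                fold_of[sid] = k
        for sid in self.train_ids:
            rows.append(
                {
                    "subject_id": sid,
                    "role": "train",
                    "fold": fold_of.get(sid, -1),
                    "stratum": self.strata.get(sid, -1),
                }
            )
        for sid in self.test_ids:
            rows.append(
                {"subject_id": sid, "role": "test", "fold": -1,
                 "stratum": self.strata.get(sid, -1)}
            )
        return pd.DataFrame(rows)


def build_graph(m: OmegaMatrix, record: SubjectRecord) -> GraphSample:
    """Adjacency = the Omega matrix; node i's features = row i; target = age."""
    v = np.asarray(m.values, dtype=float)
    return GraphSample(
        sample_id=m.subject_id,
        adjacency=v,
        node_features=v.copy(),
        target_age=float(record.age),
        record=record,
    )


def filter_invalid(samples: Sequence[GraphSample]) -> tuple[list[GraphSample], list[str]]:
    """Drop samples with non-finite features, adjacency or target."""
    kept, removed = [], []
    for s in samples:
        ok = (
            np.all(np.isfinite(s.adjacency))
            and np.all(np.isfinite(s.node_features))
            and np.isfinite(s.target_age)
        )
        (kept if ok else removed).append(s if ok else s.sample_id)
    if removed:
        logger.warning("filtered %d invalid graph samples: %s", len(removed), removed)
    return kept, removed


def stratified_split(
    samples: Sequence[GraphSample],
    test_fraction: float = 0.20,
    n_bins: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Age-stratified hold-out split plus 5-fold CV folds on the training part."""
    if len(samples) < n_bins:
        raise ContractError(f"need at least {n_bins} samples")
    ids = [s.sample_id for s in samples]
    ages = np.array([s.target_age for s in samples])
    # equal-width age bins over the observed range
    edges = np.linspace(ages.min(), ages.max(), n_bins + 1)[1:-1]
    labels = np.digitize(ages, edges)
    counts = np.bincount(labels, minlength=n_bins)
    stratify: np.ndarray | None = labels
    if counts[counts > 0].min() < 2:
        logger.warning("too few samples per age bin; falling back to unstratified split")
        stratify = None
    train_ids, test_ids = train_test_split(
        ids, test_size=test_fraction, random_state=seed, stratify=stratify
    )
    strata = dict(zip(ids, (int(b) for b in labels)))
    train_labels = np.array([strata[i] for i in train_ids])
    n_folds = 5
    if stratify is not None and np.bincount(train_labels).min() >= n_folds:
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        fold_iter = skf.split(np.zeros(len(train_ids)), train_labels)
    else:
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(train_ids))
        chunks = np.array_split(perm, n_folds)
        fold_iter = (
            (np.setdiff1d(perm, c, assume_unique=True), c) for c in chunks
        )
    folds = [
        ([train_ids[i] for i in tr], [train_ids[i] for i in va])
        for tr, va in fold_iter
    ]
    return SplitPlan(train_ids=list(train_ids), test_ids=list(test_ids),
                     folds=folds, strata=strata)


def interpolate_matrices(
    M1: np.ndarray, a1: float, M2: np.ndarray, a2: float, a_t: float
) -> np.ndarray:
    """Linear age interpolation between two connectivity matrices."""
    M1 = np.asarray(M1, dtype=float)
    M2 = np.asarray(M2, dtype=float)
    if M1.shape != M2.shape:
        raise ContractError("matrices must share a shape")
    if a1 == a2:
        raise ContractError("parent ages must differ")
    alpha = (a_t - a1) / (a2 - a1)
    if not 0.0 <= alpha <= 1.0:
        raise ContractError(f"target age {a_t} outside parent ages [{a1}, {a2}]")
    return (1.0 - alpha) * M1 + alpha * M2


def augment_training_set(
    train: Sequence[GraphSample],
    n_augment: int = 500,
    strata_field: str = "region_group",
    seed: int = 0,
) -> list[GraphSample]:
    """Interpolation augmentation, split equally across strata.

    Within each stratum, subjects are sorted by age; each augmented sample
    interpolates an age-adjacent pair (sampled with replacement) at a target
    age drawn uniformly strictly between the pair's ages.
    """
    rng = np.random.default_rng(seed)
    groups: dict[str, list[GraphSample]] = {}
    for s in train:
        key = getattr(s.record, strata_field, "all") if s.record else "all"
        groups.setdefault(str(key), []).append(s)
    usable = {k: sorted(v, key=lambda s: s.target_age)
              for k, v in groups.items()}
    for k in list(usable):
        if len(usable[k]) < 2:
            logger.warning("stratum %r has < 2 subjects; skipped for augmentation", k)
            del usable[k]
    if not usable:
        return []
    keys = sorted(usable)
    per = n_augment // len(keys)
    quota = {k: per for k in keys}
    for k in keys[: n_augment - per * len(keys)]:
        quota[k] += 1
    out: list[GraphSample] = []
    for k in keys:
        members = usable[k]
        pairs = [
            (members[i], members[i + 1])
            for i in range(len(members) - 1)
            if members[i].target_age < members[i + 1].target_age
        ]
        if not pairs:
            logger.warning("stratum %r has no age-distinct adjacent pairs; skipped", k)
            continue
        for q in range(quota[k]):
            p1, p2 = pairs[rng.integers(len(pairs))]
            a1, a2 = p1.target_age, p2.target_age
            a_t = float(rng.uniform(a1, a2))
            while not (a1 < a_t < a2):  # guard against endpoint draws
                a_t = float(rng.uniform(a1, a2))
            adj = interpolate_matrices(p1.adjacency, a1, p2.adjacency, a2, a_t)
            out.append(
                GraphSample(
                    sample_id=f"aug_{k}_{q:04d}",
                    adjacency=adj,
                    node_features=adj.copy(),
                    target_age=a_t,
                    record=p1.record,
                    augmented=True,
                    parent_ids=(p1.sample_id, p2.sample_id),
                )
            )
    return out
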