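"""Decoupling surgeons into experience groups.

Surgeon similarity is the token-level Levenshtein distance between preference
sequences (tokens are indicator ids, not characters of their printed names).
Agglomerative clustering with average linkage on the resulting distance matrix,
cut at two clusters, separates surgeons whose difficulty drivers form a small
stable core from those still sensitive to many indicators.  A Gaussian-mixture
partitioner over per-surgeon summary vectors is provided as the conventional
comparison baseline, and a pooled-variance two-sample t-test quantifies the
operative-time difference between the two groups.

The Levenshtein DP is implemented here rather than taken from a string library
because the alphabet is the set of indicator ids (arbitrary hashables), and the
average-linkage loop is hand-rolled so the merge tie-break (lowest id-ordered
pair first) is an explicit part of the contract.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator
from sklearn.mixture import GaussianMixture

from .exceptions import ValidationError
from .records import normalize_durations
from .schema import Dataset, SurgicalRecord
from .trajectory import PreferenceSequence

__all__ = [
    "levenshtein",
    "pairwise_distances",
    "DistanceMatrix",
    "Partition",
    "SequencePartitioner",
    "GMMPartitioner",
    "cluster_surgeons",
    "assign_surgeon",
    "assign_sample",
    "gmm_partition",
    "group_duration_test",
]


def _tokens(seq) -> tuple:
    return tuple(seq.tokens) if isinstance(seq, PreferenceSequence) else tuple(seq)


def levenshtein(a, b) -> int:
    """Minimum unit-cost edits (insert/delete/substitute) between token sequences."""
    ta, tb = _tokens(a), _tokens(b)
    if len(ta) < len(tb):
        ta, tb = tb, ta
    prev = list(range(len(tb) + 1))
    for i, x in enumerate(ta, start=1):
        cur = [i] + [0] * len(tb)
        for j, y in enumerate(tb, start=1):
            cur[j] = min(
                prev[j] + 1,  # deletion
                cur[j - 1] + 1,  # insertion
                prev[j - 1] + (x != y),  # substitution / match
            )
        prev = cur
    return prev[-1]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric non-negative distances over an ordered list of surgeon ids."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValidationError("distance matrix shape mismatch")
        if (v < 0).any() or not np.allclose(v, v.T) or np.any(np.diag(v) != 0):
            raise ValidationError(
                "distance matrix must be symmetric, non-negative, zero-diagonal"
            )


def pairwise_distances(seqs: list[PreferenceSequence]) -> DistanceMatrix:
    """All-pairs Levenshtein distances between surgeons' preference sequences."""
    if len(seqs) < 2:
        raise ValidationError("need >= 2 sequences")
    ids = tuple(s.surgeon_id for s in seqs)
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate surgeon ids in sequence list")
    n = len(seqs)
    D = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = levenshtein(seqs[i], seqs[j])
    return DistanceMatrix(ids=ids, values=D)


@dataclass(frozen=True)
class Partition:
    """surgeon_id -> cluster id (1-based), plus the agglomerative merge history.

    ``merges`` lists ``(height, members_a, members_b)`` tuples in merge order
    (empty for non-hierarchical partitioners).  Cluster 1 is the cluster
    containing the lexicographically smallest surgeon id.
    """

    assignment: dict[str, int]
    merges: tuple = ()

    def members(self, cluster: int) -> tuple[str, ...]:
        return tuple(sorted(s for s, c in self.assignment.items() if c == cluster))

    @property
    def clusters(self) -> tuple[int, ...]:
        return tuple(sorted(set(self.assignment.values())))


def _linkage_distance(D: np.ndarray, a: list[int], b: list[int], linkage: str) -> float:
    block = D[np.ix_(a, b)]
    if linkage == "average":
        return float(block.mean())
    if linkage == "complete":
        return float(block.max())
    if linkage == "single":
        return float(block.min())
    raise ValidationError(f"unknown linkage {linkage!r}")


class SequencePartitioner(BaseEstimator):
    """Hierarchical decoupler over preference sequences.

    fit() computes pairwise Levenshtein distances, agglomerates with the chosen
    linkage, and cuts the tree at ``k`` clusters.  Exact distance ties are broken
    by merging the pair of clusters whose (sorted) smallest member indices are
    lexicographically lowest, which makes the tree deterministic and invariant to
    input order up to relabeling.
    """

    def __init__(self, k: int = 2, linkage: str = "average"):
        self.k = k
        self.linkage = linkage

    def fit(self, sequences: list[PreferenceSequence], distance: DistanceMatrix | None = None):
        if distance is None:
            distance = pairwise_distances(sequences)
        ids, D = distance.ids, distance.values
        n = len(ids)
        if self.k > n:
            raise ValidationError(f"k={self.k} exceeds number of surgeons ({n})")

        clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
        merges = []
        cut: dict[int, list[int]] | None = (
            {c: list(m) for c, m in clusters.items()} if n == self.k else None
        )
        while len(clusters) > 1:
            best = None
            for a in clusters:
                for b in clusters:
                    if a >= b:
                        continue
                    d = _linkage_distance(D, clusters[a], clusters[b], self.linkage)
                    # a cluster's dict key equals its smallest member index, so
                    # (d, a, b) realizes the lowest-id-ordered-pair tie rule
                    key = (d, a, b)
                    if best is None or key < best[0]:
                        best = (key, a, b)
            (height, _, _), a, b = best
            merges.append(
                (
                    float(height),
                    tuple(ids[i] for i in sorted(clusters[a])),
                    tuple(ids[i] for i in sorted(clusters[b])),
                )
            )
            clusters[a] = sorted(clusters[a] + clusters[b])
            del clusters[b]
            if len(clusters) == self.k:
                cut = {c: list(m) for c, m in clusters.items()}

        if cut is None:  # k == n handled above; k > n raised earlier
            raise ValidationError("failed to cut tree")  # pragma: no cover

        # label clusters 1..k: cluster 1 contains the lexicographically smallest id
        groups = sorted(
            (sorted(ids[i] for i in members) for members in cut.values()),
            key=lambda g: g[0],
        )
        assignment = {sid: c + 1 for c, g in enumerate(groups) for sid in g}
        self.ids_ = ids
        self.distance_ = distance
        self.labels_ = np.array([assignment[s] for s in ids])
        self.partition_ = Partition(assignment=assignment, merges=tuple(merges))
        self.sequences_ = list(sequences) if sequences else []
        return self

    def predict(self, seq: PreferenceSequence) -> int:
        """Assign a new surgeon's sequence to the nearest fitted cluster."""
        return assign_surgeon(seq, self.partition_, self.sequences_)


def cluster_surgeons(
    D: DistanceMatrix, k: int = 2, linkage: str = "average"
) -> Partition:
    """Cut an average-linkage tree over a precomputed distance matrix at k clusters."""
    est = SequencePartitioner(k=k, linkage=linkage)
    est.fit([], distance=D)
    return est.partition_


def assign_surgeon(
    seq: PreferenceSequence,
    partition: Partition,
    member_seqs: list[PreferenceSequence],
) -> int:
    """Cluster minimizing the mean Levenshtein distance to its member sequences."""
    by_id = {s.surgeon_id: s for s in member_seqs}
    best = None
    for c in partition.clusters:
        members = [by_id[sid] for sid in partition.members(c) if sid in by_id]
        if not members:
            raise ValidationError(f"cluster {c} has no member sequences")
        mean_d = float(np.mean([levenshtein(seq, m) for m in members]))
        if best is None or (mean_d, c) < best:
            best = (mean_d, c)
    return best[1]


def _standardization_stats(train: Dataset) -> tuple[np.ndarray, np.ndarray]:
    X = train.codes
    if np.isnan(X).any():
        raise ValidationError("training data contains missing values; impute first")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    return mu, np.where(sd > 0, sd, 1.0)


def assign_sample(
    record: SurgicalRecord,
    partition: Partition,
    train: Dataset,
    mode: str = "surgeon",
) -> int:
    """Route one record to a cluster.

    ``mode='surgeon'`` (default): a record whose surgeon is in the partition goes
    to that surgeon's cluster; unknown surgeons fall back to the nearest training
    cluster centroid in standardized feature space.  ``mode='feature'`` always uses
    the centroid rule.  Centroid ties go to the lower cluster id.
    """
    if mode not in ("surgeon", "feature"):
        raise ValidationError(f"unknown assignment mode {mode!r}")
    if mode == "surgeon" and record.surgeon_id in partition.assignment:
        return partition.assignment[record.surgeon_id]

    mu, sd = _standardization_stats(train)
    x = (np.asarray(record.levels, dtype=float) - mu) / sd
    surgeons = np.asarray(train.surgeon_of_record)
    Xs = (train.codes - mu) / sd
    best = None
    for c in partition.clusters:
        members = set(partition.members(c))
        sel = np.isin(surgeons, list(members))
        if not sel.any():
            raise ValidationError(f"cluster {c} has no training records")
        centroid = Xs[sel].mean(axis=0)
        d = float(np.linalg.norm(x - centroid))
        if best is None or (d, c) < best:
            best = (d, c)
    return best[1]


class GMMPartitioner(BaseEstimator):
    """Gaussian-mixture baseline: cluster per-surgeon summary vectors.

    Each surgeon is summarized by the mean of their standardized indicator codes
    concatenated with the mean and SD of their globally standardized operative
    times (per-surgeon z-scores would be identically (0, 1) and carry no signal).
    Full-covariance mixture, seeded k-means initialization; deterministic given
    the seed.
    """

    def __init__(self, k: int = 2, random_state: int = 0, reg_covar: float = 1e-3):
        self.k = k
        self.random_state = random_state
        self.reg_covar = reg_covar

    @staticmethod
    def summary_vectors(ds: Dataset) -> tuple[tuple[str, ...], np.ndarray]:
        mu, sd = _standardization_stats(ds)
        d = ds.durations
        dz = (d - d.mean()) / (d.std() if d.std() > 0 else 1.0)
        ids = ds.surgeon_ids
        surgeons = np.asarray(ds.surgeon_of_record)
        rows = []
        for sid in ids:
            sel = surgeons == sid
            feats = ((ds.codes[sel] - mu) / sd).mean(axis=0)
            rows.append(np.concatenate([feats, [dz[sel].mean(), dz[sel].std()]]))
        return ids, np.asarray(rows)

    def fit(self, ds: Dataset):
        ids, V = self.summary_vectors(ds)
        if self.k > len(ids):
            raise ValidationError(f"k={self.k} exceeds number of surgeons")
        try:
            gm = GaussianMixture(
                n_components=self.k,
                covariance_type="full",
                random_state=self.random_state,
                reg_covar=self.reg_covar,
                n_init=1,
            )
            raw = gm.fit_predict(V)
        except Exception as exc:  # singular covariance and friends
            raise ValidationError(
                f"GMM fit failed ({exc}); try increasing reg_covar"
            ) from exc
        # relabel so cluster 1 holds the smallest surgeon id, preserving grouping
        order: dict[int, int] = {}
        for sid, lab in sorted(zip(ids, raw)):
            if lab not in order:
                order[lab] = len(order) + 1
        assignment = {sid: order[lab] for sid, lab in zip(ids, raw)}
        self.ids_ = ids
        self.labels_ = np.array([assignment[s] for s in ids])
        self.partition_ = Partition(assignment=assignment)
        return self


def gmm_partition(ds: Dataset, k: int = 2, seed: int = 0) -> Partition:
    """Comparison baseline: GMM clustering of per-surgeon summary vectors."""
    return GMMPartitioner(k=k, random_state=seed).fit(ds).partition_


@dataclass(frozen=True)
class GroupDurationTest:
    t: float
    p: float
    group_means: dict[int, float]


def group_duration_test(ds: Dataset, partition: Partition) -> GroupDurationTest:
    """Two-sided pooled-variance (Student) t-test on raw durations between groups."""
    clusters = partition.clusters
    if len(clusters) != 2:
        raise ValidationError("duration test requires exactly 2 clusters")
    samples = []
    for c in clusters:
        members = set(partition.members(c))
        d = ds.subset(lambda r: r.surgeon_id in members).durations
        if d.size < 2:
            raise ValidationError(f"cluster {c} has fewer than 2 records")
        samples.append(d)
    a, b = samples
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        raise ValidationError("zero pooled variance; t statistic undefined")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupDurationTest(
        t=float(t),
        p=float(p),
        group_means={c: float(d.mean()) for c, d in zip(clusters, samples)},
    )
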