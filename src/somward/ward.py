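"""Ward agglomerative clustering and the SOM-Ward variant.

Classic Ward agglomeration starts from singletons and repeatedly merges
the pair of clusters with the smallest Ward distance

    d_rs = n_r * n_s / (n_r + n_s) * ||xbar_r - xbar_s||^2,

which equals the increase in total within-cluster sum of squares caused
by the merge.  The merged centroid is the cardinality-weighted mean and
cardinalities add (the Lance–Williams centroid update).

The SOM-Ward variant runs the same agglomeration over the neuron
prototypes of a trained self-organizing map, but treats the distance
between clusters that are not lattice-adjacent ("non-associated") as
infinite: only clusters containing at least one pair of neighboring
neurons may merge.  Cutting the resulting dendrogram at k clusters and
assigning each student to the cluster of its best matching unit yields
the two-level clustering of the data.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .som import SOMap, bmu_indices


@dataclass(frozen=True)
class ClusterState:
    """A cluster: member point ids, centroid, and total weight."""

    members: frozenset[int]
    centroid: np.ndarray
    cardinality: float

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("cluster must have at least one member")
        if self.cardinality <= 0:
            raise ValueError("cardinality must be positive")


def ward_distance(r: ClusterState, s: ClusterState) -> float:
    """Ward merge cost: increase in within-cluster SSE if r and s merge."""
    diff = r.centroid - s.centroid
    nr, ns = r.cardinality, s.cardinality
    return float(nr * ns / (nr + ns) * np.dot(diff, diff))


def merge(r: ClusterState, s: ClusterState) -> ClusterState:
    """Weighted-mean centroid update; cardinalities add; members union."""
    if r.members & s.members:
        raise ValueError(f"clusters overlap on members {sorted(r.members & s.members)}")
    n = r.cardinality + s.cardinality
    centroid = (r.cardinality * r.centroid + s.cardinality * s.centroid) / n
    return ClusterState(members=r.members | s.members, centroid=centroid,
                        cardinality=n)


@dataclass
class Merge:
    left: int
    right: int
    distance: float
    cardinality: float


@dataclass
class MergeTrace:
    """Ordered record of agglomerative merges (a dendrogram).

    Initial clusters carry ids 0..n_initial-1; the cluster created by
    merge t gets id n_initial + t.  complete is False when a constrained
    run stopped early because the remaining clusters were disconnected.
    """

    n_initial: int
    weights: np.ndarray
    merges: list[Merge] = field(default_factory=list)
    complete: bool = True

    def __len__(self) -> int:
        return len(self.merges)

    def distances(self) -> np.ndarray:
        return np.array([m.distance for m in self.merges])

    def write_csv(self, path: str | Path) -> None:
        """Linkage-style CSV: left, right, distance, size."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["left", "right", "distance", "size"])
            for m in self.merges:
                w.writerow([m.left, m.right, repr(m.distance), repr(m.cardinality)])


def _singletons(points: np.ndarray, weights: np.ndarray) -> dict[int, ClusterState]:
    return {
        i: ClusterState(members=frozenset([i]), centroid=points[i].copy(),
                        cardinality=float(weights[i]))
        for i in range(len(points))
    }


def _as_weights(n: int, weights: Sequence[float] | None) -> np.ndarray:
    if weights is None:
        return np.ones(n)
    w = np.asarray(weights, dtype=float)
    if w.shape != (n,) or np.any(w <= 0):
        raise ValueError("weights must be positive, one per point")
    return w


def agglomerate(
    points: np.ndarray, weights: Sequence[float] | None = None
) -> MergeTrace:
    """Unconstrained Ward agglomeration from singletons to one cluster.

    Ties on distance are broken by the lexicographically smallest
    (left id, right id) pair, left < right.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n = len(points)
    if n < 1:
        raise ValueError("need at least one point")
    w = _as_weights(n, weights)
    trace = MergeTrace(n_initial=n, weights=w)
    active = _singletons(points, w)
    next_id = n
    while len(active) > 1:
        best: tuple[float, int, int] | None = None
        ids = sorted(active)
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                a, b = ids[ai], ids[bi]
                d = ward_distance(active[a], active[b])
                if best is None or (d, a, b) < best:
                    best = (d, a, b)
        d, a, b = best
        merged = merge(active.pop(a), active.pop(b))
        active[next_id] = merged
        trace.merges.append(Merge(a, b, d, merged.cardinality))
        next_id += 1
    return trace


def somward_agglomerate(
    m: SOMap, neuron_weights: Sequence[float] | None = None
) -> MergeTrace:
    """Ward agglomeration over SOM prototypes restricted to associated
    (lattice-adjacent) clusters.

    Two clusters are associated when some neuron of one is an immediate
    lattice neighbor of some neuron of the other.  On a connected
    lattice this yields exactly n_neurons - 1 merges; a disconnected
    lattice stops at one cluster per component (trace flagged
    incomplete).  Default neuron weight is 1 (prototypes as points).
    """
    points = m.weights
    n = m.n_neurons
    w = _as_weights(n, neuron_weights)
    trace = MergeTrace(n_initial=n, weights=w)
    active = _singletons(points, w)
    adjacency: dict[int, set[int]] = {
        i: set(map(int, nbrs)) for i, nbrs in enumerate(m.lattice_neighbors())
    }
    pair_dist: dict[tuple[int, int], float] = {}
    for a, nbrs in adjacency.items():
        for b in nbrs:
            if a < b:
                pair_dist[(a, b)] = ward_distance(active[a], active[b])
    next_id = n
    while len(active) > 1 and pair_dist:
        (a, b), d = min(pair_dist.items(), key=lambda kv: (kv[1], kv[0]))
        merged = merge(active.pop(a), active.pop(b))
        active[next_id] = merged
        trace.merges.append(Merge(a, b, d, merged.cardinality))
        del pair_dist[(a, b)]
        new_nbrs = (adjacency.pop(a) | adjacency.pop(b)) - {a, b}
        for c in new_nbrs:
            adjacency[c].discard(a)
            adjacency[c].discard(b)
            adjacency[c].add(next_id)
            pair_dist.pop((min(a, c), max(a, c)), None)
            pair_dist.pop((min(b, c), max(b, c)), None)
            pair_dist[(c, next_id)] = ward_distance(active[c], active[next_id])
        adjacency[next_id] = new_nbrs
        next_id += 1
    if len(active) > 1:
        trace.complete = False
    return trace


def cut(trace: MergeTrace, k: int) -> np.ndarray:
    """Labels (1..k) for the initial items after undoing the last k-1 merges.

    Label 1 is the heaviest cluster (total weight), descending; ties are
    broken by the smallest member id.
    """
    n = trace.n_initial
    if not 1 <= k <= n:
        raise ValueError(f"k={k} outside 1..{n}")
    n_merges = n - k
    if n_merges > len(trace.merges):
        raise ValueError(
            f"trace has only {len(trace.merges)} merges; cannot cut at k={k}"
        )
    parent = list(range(n + len(trace.merges)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for t in range(n_merges):
        mg = trace.merges[t]
        new = n + t
        parent[find(mg.left)] = new
        parent[find(mg.right)] = new
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    order = sorted(
        groups.values(),
        key=lambda ms: (-float(trace.weights[ms].sum()), min(ms)),
    )
    labels = np.zeros(n, dtype=int)
    for lab, ms in enumerate(order, start=1):
        labels[ms] = lab
    return labels


def merge_distance_curve(trace: MergeTrace) -> list[tuple[int, float]]:
    """(k, distance) of the merge that reduces k+1 clusters to k.

    For unconstrained Ward these distances are non-decreasing along the
    trace; the lattice-constrained variant may violate monotonicity.
    """
    if trace.n_initial < 1:
        raise ValueError("empty trace")
    n = trace.n_initial
    return [(n - t - 1, mg.distance) for t, mg in enumerate(trace.merges)]


@dataclass
class ClusterSolution:
    """A k-cluster solution with neuron labels, student labels and stats."""

    k: int
    neuron_labels: np.ndarray
    student_ids: list[str]
    student_labels: np.ndarray
    percentages: dict[int, float]
    profile: pd.DataFrame  # index: cluster label, columns: variable labels

    def to_json(self, path: str | Path) -> None:
        doc = {
            "k": self.k,
            "neuron_labels": self.neuron_labels.tolist(),
            "students": {
                sid: int(lab)
                for sid, lab in zip(self.student_ids, self.student_labels)
            },
            "percentages": {str(c): p for c, p in self.percentages.items()},
            "profile": {
                str(c): {v: (None if pd.isna(x) else float(x))
                         for v, x in row.items()}
                for c, row in self.profile.iterrows()
            },
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    def write_assignments_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, lineterminator="\n")
            w.writerow(["student_id", "cluster"])
            for sid, lab in zip(self.student_ids, self.student_labels):
                w.writerow([sid, int(lab)])

    def write_profile_csv(self, path: str | Path) -> None:
        out = self.profile.copy()
        out.insert(0, "percent", [self.percentages[c] for c in out.index])
        out.round(2).to_csv(path, index_label="cluster")


def assign_students(
    m: SOMap,
    neuron_labels: np.ndarray,
    student_ids: Sequence[str],
    data: np.ndarray,
    variable_labels: Sequence[str] | None = None,
) -> ClusterSolution:
    """Map each student to the cluster of its BMU; tabulate shares and
    per-cluster per-variable means over students."""
    neuron_labels = np.asarray(neuron_labels, dtype=int)
    if neuron_labels.shape != (m.n_neurons,):
        raise ValueError("neuron labels must cover every neuron")
    data = np.asarray(data, dtype=float)
    k = int(neuron_labels.max())
    bmus = bmu_indices(m, data)
    student_labels = neuron_labels[bmus]
    n = len(student_ids)
    if variable_labels is None:
        variable_labels = [f"x{i + 1}" for i in range(data.shape[1])]
    percentages: dict[int, float] = {}
    rows = []
    for c in range(1, k + 1):
        mask = student_labels == c
        percentages[c] = 100.0 * mask.sum() / n if n else 0.0
        rows.append(
            data[mask].mean(axis=0) if mask.any()
            else np.full(data.shape[1], np.nan)
        )
    profile = pd.DataFrame(rows, index=pd.Index(range(1, k + 1), name="cluster"),
                           columns=list(variable_labels))
    return ClusterSolution(
        k=k, neuron_labels=neuron_labels, student_ids=list(student_ids),
        student_labels=student_labels, percentages=percentages, profile=profile,
    )


def relabel_by_variable(
    solution: ClusterSolution, variable: str | int
) -> ClusterSolution:
    """Relabel clusters 1..k in decreasing order of a profile variable.

    Convention used for naming the aliveness clusters: sorting on the
    human variable descending puts the anthropocentric cluster first.
    """
    prof = solution.profile
    col = prof.columns[variable] if isinstance(variable, int) else variable
    order = prof[col].sort_values(ascending=False, kind="stable").index
    mapping = {int(old): new for new, old in enumerate(order, start=1)}
    remap = np.vectorize(lambda c: mapping[int(c)])
    new_profile = prof.rename(index=mapping).sort_index()
    return ClusterSolution(
        k=solution.k,
        neuron_labels=remap(solution.neuron_labels),
        student_ids=solution.student_ids,
        student_labels=remap(solution.student_labels),
        percentages={mapping[c]: p for c, p in solution.percentages.items()},
        profile=new_profile,
    )
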