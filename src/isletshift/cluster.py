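"""Hierarchical clustering with squared-Euclidean distances and Ward linkage.

Distances are computed over the complete-case proteins (quantified in every
sample; no imputation) on log2 values by default, with optional per-protein
median centering. Ward agglomeration uses the Lance-Williams recurrence on
squared-Euclidean input; ties are broken by the lowest-index pair so the
merge order is deterministic across platforms.

Height convention: the merge height is the Ward distance on squared-
Euclidean input, i.e. twice the increase in within-cluster sum of squares
caused by the merge. Two singletons therefore merge at exactly their
squared-Euclidean distance, and heights equal the squares of the heights
reported by Euclidean-metric Ward implementations.

The same machinery also yields a condition-to-reference proximity summary:
squared-Euclidean distances between condition centroids and the reference
centroid, computed from the pairwise sample distances alone via the standard
centroid identity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError, VocabularyError
from .io import AbundanceMatrix, SampleAnnotation


def sample_distance_matrix(
    matrix: AbundanceMatrix,
    transform: str = "log2",
    centering: str = "none",
    axis: str = "samples",
) -> pd.DataFrame:
    """Pairwise squared-Euclidean distances between samples (or proteins).

    d(i, j) = sum over complete-case proteins of (x_pi - x_pj)^2. Requires at
    least two complete-case proteins. ``axis='proteins'`` clusters the other
    axis with the same conventions (complete-case restriction unchanged).
    """
    if transform not in ("log2", "none"):
        raise VocabularyError(f"transform must be 'log2' or 'none', got {transform!r}")
    if centering not in ("none", "protein_median"):
        raise VocabularyError(
            f"centering must be 'none' or 'protein_median', got {centering!r}"
        )
    if axis not in ("samples", "proteins"):
        raise VocabularyError(f"axis must be 'samples' or 'proteins', got {axis!r}")
    values = matrix.log2() if transform == "log2" else matrix.data.astype(float)
    complete = values.dropna(axis=0, how="any")
    if len(complete) < 2:
        raise ValidationError(
            f"need >= 2 complete-case proteins for distances, got {len(complete)}"
        )
    if centering == "protein_median":
        complete = complete.sub(complete.median(axis=1), axis=0)
    points = complete.to_numpy().T if axis == "samples" else complete.to_numpy()
    labels = list(complete.columns) if axis == "samples" else list(complete.index)
    sq = np.sum(points**2, axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * (points @ points.T)
    d = np.maximum(d, 0.0)
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    return pd.DataFrame(d, index=labels, columns=labels)


@dataclass(frozen=True)
class LinkageTree:
    """Agglomeration record: leaves 0..n-1, merge k creates node n+k.

    ``merges`` is an ordered list of (node_a, node_b, height) with heights
    non-negative and non-decreasing; ``labels`` names the leaves.
    """

    labels: tuple[str, ...]
    merges: tuple[tuple[int, int, float], ...]

    def __post_init__(self):
        n = len(self.labels)
        if len(self.merges) != n - 1:
            raise ValidationError(f"{n} leaves need {n - 1} merges, got {len(self.merges)}")
        used: set[int] = set()
        last = 0.0
        for a, b, h in self.merges:
            if a in used or b in used:
                raise ValidationError("a node may be merged at most once")
            used.update((a, b))
            if h < -1e-12 or h < last - 1e-9:
                raise ValidationError("merge heights must be non-negative, non-decreasing")
            last = max(last, h)

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_sets(self) -> dict[int, frozenset[int]]:
        """Leaf indices under every node (leaves and internal)."""
        n = len(self.labels)
        sets: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
        for k, (a, b, _h) in enumerate(self.merges):
            sets[n + k] = sets[a] | sets[b]
        return sets

    def cophenetic_matrix(self) -> pd.DataFrame:
        """Height at which each leaf pair first shares a cluster."""
        n = len(self.labels)
        coph = np.zeros((n, n))
        sets = {i: frozenset([i]) for i in range(n)}
        for k, (a, b, h) in enumerate(self.merges):
            for i in sets[a]:
                for j in sets[b]:
                    coph[i, j] = coph[j, i] = h
            sets[n + k] = sets[a] | sets[b]
            del sets[a], sets[b]
        return pd.DataFrame(coph, index=self.labels, columns=self.labels)

    def to_json_dict(self) -> dict:
        return {
            "leaves": list(self.labels),
            "merges": [[int(a), int(b), float(h)] for a, b, h in self.merges],
        }

    def to_newick(self) -> str:
        """Newick with branch lengths = height differences (leaves at 0)."""
        n = len(self.labels)
        height = {i: 0.0 for i in range(n)}
        text = {i: self.labels[i] for i in range(n)}
        for k, (a, b, h) in enumerate(self.merges):
            node = n + k
            height[node] = h
            text[node] = (
                f"({text[a]}:{h - height[a]:.12g},{text[b]}:{h - height[b]:.12g})"
            )
        return text[n + len(self.merges) - 1] + ";"

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)
            fh.write("\n")


def ward_linkage(distances: pd.DataFrame | np.ndarray, labels=None) -> LinkageTree:
    """Ward agglomeration of a squared-Euclidean distance grid.

    Greedy minimum-merge-cost agglomeration with the Lance-Williams Ward
    update d(ij,k) = ((ni+nk) d(i,k) + (nj+nk) d(j,k) - nk d(i,j)) / (ni+nj+nk).
    Ties pick the lowest-index pair.
    """
    if isinstance(distances, pd.DataFrame):
        if labels is None:
            labels = list(distances.index)
        d = distances.to_numpy(dtype=float).copy()
    else:
        d = np.asarray(distances, dtype=float).copy()
        if labels is None:
            labels = [f"sample_{i}" for i in range(d.shape[0])]
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValidationError(f"distance grid must be square, got shape {d.shape}")
    if not np.allclose(d, d.T, atol=1e-9):
        raise ValidationError("distance grid must be symmetric")
    if (np.diag(d) != 0).any() or (d < -1e-12).any():
        raise ValidationError("distances must be non-negative with zero diagonal")
    n = d.shape[0]
    if n < 2:
        raise ValidationError("need >= 2 items to cluster")

    node_id = list(range(n))  # current node id per active slot
    size = np.ones(n)
    active = np.ones(n, dtype=bool)
    merges: list[tuple[int, int, float]] = []
    big = np.inf
    work = d.copy()
    np.fill_diagonal(work, big)
    for step in range(n - 1):
        idx = np.flatnonzero(active)
        sub = work[np.ix_(idx, idx)]
        np.fill_diagonal(sub, big)
        # lowest-index tie-break: flat argmin of the row-major scan
        flat = np.argmin(sub)
        i_loc, j_loc = divmod(flat, sub.shape[0])
        if i_loc > j_loc:
            i_loc, j_loc = j_loc, i_loc
        i, j = idx[i_loc], idx[j_loc]
        h = work[i, j]
        merges.append((node_id[i], node_id[j], float(h)))
        ni, nj = size[i], size[j]
        for k in idx:
            if k in (i, j):
                continue
            nk = size[k]
            new = ((ni + nk) * work[i, k] + (nj + nk) * work[j, k] - nk * h) / (
                ni + nj + nk
            )
            work[i, k] = work[k, i] = new
        size[i] = ni + nj
        node_id[i] = n + step
        active[j] = False
    return LinkageTree(tuple(labels), tuple(merges))


def condition_proximity_to_reference(
    distances: pd.DataFrame,
    annotation: SampleAnnotation,
    reference: str = "ISLET",
) -> list[tuple[str, float]]:
    """Squared distance of each condition centroid to the reference centroid.

    Computed from the pairwise squared-Euclidean sample distances via
    ||cA - cB||^2 = mean d(A,B) - mean d(A,A)/2 - mean d(B,B)/2. Returned
    ascending (nearest condition first); ties are ordered by condition name.
    The reference itself (distance 0) is excluded.
    """
    sample_conditions = dict(
        zip(annotation.entries["sample_id"], annotation.entries["condition"])
    )
    by_condition: dict[str, list[str]] = {}
    for sid in distances.index:
        cond = sample_conditions.get(sid)
        if cond is not None:
            by_condition.setdefault(cond, []).append(sid)
    if reference not in by_condition:
        raise ValidationError(f"reference condition {reference!r} absent from distances")

    def mean_block(rows, cols):
        return float(distances.loc[rows, cols].to_numpy().mean())

    ref = by_condition[reference]
    intra_ref = mean_block(ref, ref) / 2.0
    out = []
    for cond, samples in by_condition.items():
        if cond == reference:
            continue
        dist = mean_block(samples, ref) - mean_block(samples, samples) / 2.0 - intra_ref
        out.append((cond, max(dist, 0.0)))
    out.sort(key=lambda item: (item[1], item[0]))
    return out
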