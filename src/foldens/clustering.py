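"""RMSD-radius Cartesian clustering with centroid-nearest representatives.

Leader clustering: frames are scanned in order and assigned to the first
cluster whose (incrementally updated) centroid lies within the radius, after
optimal superposition; otherwise they open a new cluster. An optional
refinement pass reassigns every frame to its nearest centroid until stable,
which also restores order-independence for well separated basins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import Ensemble, kabsch_superpose

__all__ = ["ClusterSet", "cluster_ensemble", "representatives"]


@dataclass
class ClusterSet:
    assignments: np.ndarray        # cluster id per frame, 0-based
    radius: float
    representatives: np.ndarray    # frame index per cluster
    populations: np.ndarray        # fraction per cluster
    centroid_coords: np.ndarray    # (n_clusters, n_sel_atoms, 3)
    atom_selection: np.ndarray     # indices of atoms used for the RMSD

    @property
    def n_clusters(self) -> int:
        return len(self.populations)


def _aligned_rmsd(coords: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    return kabsch_superpose(coords, target)


def cluster_ensemble(ens: Ensemble, radius: float, algorithm: str = "leader",
                     selection: str = "ca", max_refine: int = 50,
                     seed: int | None = None) -> ClusterSet:
    """Cluster an ensemble by pairwise-superposed RMSD with a fixed radius.

    ``algorithm='leader'`` does a single ordered scan; ``'kmedoid_refine'``
    follows it with nearest-centroid reassignment passes until stable. The
    RMSD uses C-alpha atoms by default (``selection='all'`` for every atom).
    Deterministic for a given frame order (the seed is accepted for interface
    symmetry with stochastic generators but the algorithm itself is exact).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if algorithm not in ("leader", "kmedoid_refine"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if selection == "ca":
        sel = np.nonzero(ens.topology.ca_mask())[0]
        if len(sel) < 3:
            sel = np.arange(ens.topology.n_atoms)
    elif selection == "all":
        sel = np.arange(ens.topology.n_atoms)
    else:
        raise ValueError(f"unknown selection {selection!r}")

    frames = ens.frames[:, sel, :]
    n = len(frames)
    assignments = np.full(n, -1, dtype=int)
    centroids: list[np.ndarray] = []
    members: list[list[int]] = []

    for k in range(n):
        best_c, best_d = -1, np.inf
        for c, cen in enumerate(centroids):
            _, d = _aligned_rmsd(frames[k], cen)
            if d < best_d:
                best_c, best_d = c, d
        if best_c >= 0 and best_d <= radius:
            assignments[k] = best_c
            members[best_c].append(k)
            # incremental centroid update in the centroid's frame
            aligned, _ = _aligned_rmsd(frames[k], centroids[best_c])
            m = len(members[best_c])
            centroids[best_c] = centroids[best_c] + (aligned - centroids[best_c]) / m
        else:
            assignments[k] = len(centroids)
            centroids.append(frames[k].copy())
            members.append([k])

    if algorithm == "kmedoid_refine":
        for _ in range(max_refine):
            new_assign = np.empty(n, dtype=int)
            for k in range(n):
                dists = [_aligned_rmsd(frames[k], cen)[1] for cen in centroids]
                new_assign[k] = int(np.argmin(dists))
            if np.array_equal(new_assign, assignments):
                break
            assignments = new_assign
            keep = [c for c in range(len(centroids)) if np.any(assignments == c)]
            remap = {c: i for i, c in enumerate(keep)}
            assignments = np.array([remap[a] for a in assignments])
            centroids = [
                _mean_aligned(frames[assignments == i], centroids[c])
                for i, c in zip(range(len(keep)), keep)
            ]

    n_clusters = len(centroids)
    populations = np.array([(assignments == c).sum() / n for c in range(n_clusters)])
    reps = np.empty(n_clusters, dtype=int)
    for c in range(n_clusters):
        idx = np.nonzero(assignments == c)[0]
        dists = np.array([_aligned_rmsd(frames[k], centroids[c])[1] for k in idx])
        reps[c] = idx[int(np.argmin(dists))]  # argmin ties break on lowest frame index
    return ClusterSet(assignments, radius, reps, populations,
                      np.asarray(centroids), sel)


def _mean_aligned(member_frames: np.ndarray, reference: np.ndarray) -> np.ndarray:
    aligned = np.array([kabsch_superpose(f, reference)[0] for f in member_frames])
    return aligned.mean(axis=0)


def representatives(cs: ClusterSet, ens: Ensemble) -> list[int]:
    """Frame index per cluster: the member closest (superposed RMSD) to the
    cluster centroid, ties broken by lowest frame index."""
    frames = ens.frames[:, cs.atom_selection, :]
    out = []
    for c in range(cs.n_clusters):
        idx = np.nonzero(cs.assignments == c)[0]
        assert len(idx) > 0, "empty cluster"
        dists = np.array([_aligned_rmsd(frames[k], cs.centroid_coords[c])[1] for k in idx])
        out.append(int(idx[int(np.argmin(dists))]))
    return out
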