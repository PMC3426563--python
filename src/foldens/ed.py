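"""Essential dynamics: Cartesian covariance analysis of aligned ensembles and
subspace-similarity metrics.

Three metrics quantify how similar the dominant deformation spaces of two
ensembles are:

* ``hess_similarity`` (gamma): mean squared inner product between two sets of
  n orthonormal modes; 1 for identical subspaces, ~n/3N for random ones.
* ``relative_similarity`` (kappa): gamma between two ensembles normalised by
  their split-half self-similarities, correcting for sampling noise.
* ``overlap`` (Ov): norm of the projection of a unit transition vector onto
  the top-n modes of an essential space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structures import Ensemble, align_to_reference, iterative_mean_align

__all__ = [
    "EssentialSpace",
    "SimilarityResult",
    "TransitionVector",
    "covariance_matrix",
    "essential_space",
    "hess_similarity",
    "relative_similarity",
    "transition_vector",
    "overlap",
    "random_subspace_gamma",
]


@dataclass
class EssentialSpace:
    """Orthonormal deformation modes (columns) with descending variances."""

    eigenvectors: np.ndarray      # (3N, m), orthonormal columns
    eigenvalues: np.ndarray       # (m,), descending, >= 0 (A^2)
    n_atoms: int

    def __post_init__(self) -> None:
        self.eigenvectors = np.asarray(self.eigenvectors, dtype=float)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        v = self.eigenvectors
        if v.ndim != 2 or v.shape[0] != 3 * self.n_atoms:
            raise ValueError("eigenvector matrix must be (3N, m)")
        if self.eigenvalues.shape != (v.shape[1],):
            raise ValueError("one eigenvalue per mode required")
        if np.any(np.diff(self.eigenvalues) > 1e-9):
            raise ValueError("eigenvalues must be sorted descending")
        if np.any(self.eigenvalues < -1e-9):
            raise ValueError("negative eigenvalue")
        gram = v.T @ v
        if np.max(np.abs(gram - np.eye(v.shape[1]))) > 1e-8:
            raise ValueError("eigenvector columns are not orthonormal")

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[1]

    @property
    def variance_explained(self) -> np.ndarray:
        """Cumulative variance fraction per mode, relative to the retained total
        (equals the full-trace fraction when all modes are kept)."""
        total = self.eigenvalues.sum()
        if total <= 0:
            return np.zeros(self.n_modes)
        return np.cumsum(self.eigenvalues) / total


@dataclass
class SimilarityResult:
    gamma: float
    kappa: float
    gamma_self_a: float
    gamma_self_b: float
    n_modes: int


@dataclass
class TransitionVector:
    r: np.ndarray               # unit 3N vector
    source: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float).ravel()
        norm = np.linalg.norm(self.r)
        if abs(norm - 1.0) > 1e-10:
            raise ValueError(f"transition vector norm {norm} != 1")


def _aligned_displacements(ens: Ensemble, selection: np.ndarray | None,
                           reference: np.ndarray | None) -> np.ndarray:
    """Superpose frames (iterative-mean protocol, or onto a fixed reference),
    subtract the ensemble mean, flatten to (F, 3n_sel)."""
    if reference is None:
        aligned, _ = iterative_mean_align(ens.frames, ens.align_mask)
    else:
        aligned = align_to_reference(ens.frames, reference, ens.align_mask)
    if selection is not None:
        sel = np.asarray(selection)
        if sel.dtype == bool:
            sel = np.nonzero(sel)[0]
        aligned = aligned[:, sel, :]
    flat = aligned.reshape(len(aligned), -1)
    return flat - flat.mean(axis=0)


def covariance_matrix(ens: Ensemble, selection: np.ndarray | None = None,
                      reference: np.ndarray | None = None) -> np.ndarray:
    """3N x 3N Cartesian covariance of the aligned ensemble.

    Normalised by the number of frames so that the trace equals the summed
    per-coordinate variances (and 3/(8 pi^2) times the summed B-factors).
    """
    if ens.n_frames < 2:
        raise ValueError("covariance needs at least 2 frames")
    x = _aligned_displacements(ens, selection, reference)
    return x.T @ x / len(x)


def essential_space(cov: np.ndarray, n_modes: int | None = None,
                    variance_target: float | None = None) -> EssentialSpace:
    """Diagonalise a covariance matrix and keep the top modes.

    Exactly one of ``n_modes`` / ``variance_target`` selects the dimension;
    with ``variance_target`` the smallest m whose cumulative variance fraction
    reaches the target is kept.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ValueError("covariance must be square")
    if np.max(np.abs(cov - cov.T)) > 1e-8 * max(1.0, np.abs(cov).max()):
        raise ValueError("covariance must be symmetric")
    dim = cov.shape[0]
    if dim % 3:
        raise ValueError("covariance dimension must be 3N")
    if (n_modes is None) == (variance_target is None):
        raise ValueError("give exactly one of n_modes or variance_target")
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    if n_modes is not None:
        if not 1 <= n_modes <= dim:
            raise ValueError(f"n_modes must be in [1, {dim}]")
        m = n_modes
    else:
        total = evals.sum()
        if total <= 0:
            m = 1
        else:
            m = int(np.searchsorted(np.cumsum(evals) / total, variance_target) + 1)
            m = min(m, dim)
    return EssentialSpace(evecs[:, :m], evals[:m], dim // 3)


def hess_similarity(a: EssentialSpace, b: EssentialSpace, n: int = 50) -> float:
    """Subspace similarity gamma = (1/n) sum_ij (v_i^A . v_j^B)^2 over the
    first n modes of each space; in [0, 1], symmetric."""
    if a.eigenvectors.shape[0] != b.eigenvectors.shape[0]:
        raise ValueError("essential spaces live in different dimensions")
    if a.n_modes < n or b.n_modes < n:
        raise ValueError(f"both spaces need >= {n} modes")
    dots = a.eigenvectors[:, :n].T @ b.eigenvectors[:, :n]
    return float(np.sum(dots**2) / n)


def _split_frames(n_frames: int, split: str) -> tuple[np.ndarray, np.ndarray]:
    idx = np.arange(n_frames)
    if split == "halves":
        return idx[: n_frames // 2], idx[n_frames // 2:]
    if split == "odd_even":
        return idx[::2], idx[1::2]
    raise ValueError(f"unknown split {split!r}")


def relative_similarity(ens_a: Ensemble, ens_b: Ensemble, n: int = 50,
                        split: str = "halves", reference: np.ndarray | None = None,
                        normalisation: str = "arithmetic") -> SimilarityResult:
    """Noise-corrected subspace similarity.

    gamma_AB is computed between the full ensembles; each ensemble's
    self-similarity is the gamma between essential spaces of its two split
    parts; kappa = 2 gamma_AB / (gamma_self_A + gamma_self_B) (or the
    geometric-mean variant). All covariances use a common reference frame
    (default: the iteratively aligned mean of ensemble A).
    """
    if ens_a.n_frames < 4 or ens_b.n_frames < 4:
        raise ValueError("need >= 4 frames per ensemble to split")
    if reference is None:
        _, reference = iterative_mean_align(ens_a.frames, ens_a.align_mask)

    def space_of(ens: Ensemble, frame_idx: np.ndarray | None = None) -> EssentialSpace:
        sub = ens if frame_idx is None else ens.subset(frame_idx)
        return essential_space(covariance_matrix(sub, reference=reference), n_modes=n)

    gamma_ab = hess_similarity(space_of(ens_a), space_of(ens_b), n)
    ia1, ia2 = _split_frames(ens_a.n_frames, split)
    ib1, ib2 = _split_frames(ens_b.n_frames, split)
    gamma_a = hess_similarity(space_of(ens_a, ia1), space_of(ens_a, ia2), n)
    gamma_b = hess_similarity(space_of(ens_b, ib1), space_of(ens_b, ib2), n)
    if normalisation == "arithmetic":
        kappa = 2.0 * gamma_ab / (gamma_a + gamma_b)
    elif normalisation == "geometric":
        kappa = gamma_ab / np.sqrt(gamma_a * gamma_b)
    else:
        raise ValueError(f"unknown normalisation {normalisation!r}")
    return SimilarityResult(gamma_ab, float(kappa), gamma_a, gamma_b, n)


def transition_vector(ens_a: Ensemble, ens_b: Ensemble, seed: int | None = None,
                      reference: np.ndarray | None = None) -> TransitionVector:
    """Unit first principal component of the meta-ensemble built by pooling an
    equal number of snapshots from both ensembles (the larger one is
    downsampled without replacement, seeded)."""
    if ens_a.topology.n_atoms != ens_b.topology.n_atoms:
        raise ValueError("ensembles have incompatible topologies")
    rng = np.random.default_rng(seed)
    n = min(ens_a.n_frames, ens_b.n_frames)

    def draw(ens: Ensemble) -> Ensemble:
        if ens.n_frames == n:
            return ens
        return ens.subset(np.sort(rng.choice(ens.n_frames, size=n, replace=False)))

    a, b = draw(ens_a), draw(ens_b)
    if reference is None:
        _, reference = iterative_mean_align(a.frames, a.align_mask)
    meta = Ensemble(a.topology, np.concatenate([a.frames, b.frames]),
                    align_mask=a.align_mask)
    space = essential_space(covariance_matrix(meta, reference=reference), n_modes=1)
    r = space.eigenvectors[:, 0]
    return TransitionVector(r / np.linalg.norm(r))


def overlap(space: EssentialSpace, r: TransitionVector, n: int) -> float:
    """Ov = sqrt(sum_i (r . v_i)^2) over the first n modes; in [0, 1]."""
    if len(r.r) != space.eigenvectors.shape[0]:
        raise ValueError("transition vector dimension mismatch")
    if n > space.n_modes:
        raise ValueError(f"requested {n} modes, space has {space.n_modes}")
    proj = space.eigenvectors[:, :n].T @ r.r
    return float(min(1.0, np.sqrt(np.sum(proj**2))))


def random_subspace_gamma(dim: int, n: int, n_draws: int = 200,
                          seed: int | None = None) -> np.ndarray:
    """Monte-Carlo null distribution of gamma between independent random
    n-dimensional subspaces of R^dim (expectation n/dim). Useful to judge
    whether an observed gamma is significant."""
    rng = np.random.default_rng(seed)
    out = np.empty(n_draws)
    for k in range(n_draws):
        qa, _ = np.linalg.qr(rng.standard_normal((dim, n)))
        qb, _ = np.linalg.qr(rng.standard_normal((dim, n)))
        out[k] = np.sum((qa.T @ qb) ** 2) / n
    return out
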