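"""Structure/ensemble data model and per-conformer geometric descriptors.

All coordinates are in Angstrom. A :class:`Structure` is a flat list of atoms
with residue bookkeeping; an :class:`Ensemble` is an ordered stack of
coordinate frames sharing one topology plus an alignment mask that defines
the common reference frame (typically the conformationally conserved core).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "BONDI_RADII",
    "BACKBONE_ATOMS",
    "Structure",
    "Ensemble",
    "ContactMap",
    "SASAResult",
    "FlexibilityProfile",
    "kabsch_superpose",
    "rmsd",
    "tm_score",
    "radius_of_gyration",
    "iterative_mean_align",
    "b_factors",
    "contact_map",
    "residue_min_distances",
    "sasa",
]

#: van der Waals radii (Bondi 1964), Angstrom. Unknown elements raise.
BONDI_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
}

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT", "H", "HA", "H1", "H2", "H3"}


def vdw_radius(element: str) -> float:
    key = element.strip().upper()
    if key not in BONDI_RADII:
        raise ValueError(f"unknown element {element!r}: no van der Waals radius tabulated")
    return BONDI_RADII[key]


@dataclass
class Structure:
    """A single conformation: atoms, residue bookkeeping and vdW radii."""

    atom_names: list[str]
    residue_index: np.ndarray          # 1-based, per atom
    residue_name: list[str]            # 3-letter code, per atom
    coords: np.ndarray                 # (n_atoms, 3), Angstrom
    elements: list[str]
    radii: np.ndarray                  # (n_atoms,), Angstrom
    b_column: np.ndarray | None = None # optional crystal B-factors, A^2

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.radii = np.asarray(self.radii, dtype=float)
        n = len(self.atom_names)
        if n < 1:
            raise ValueError("Structure needs at least one atom")
        if self.coords.shape != (n, 3):
            raise ValueError(f"coords shape {self.coords.shape} != ({n}, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if self.radii.shape != (n,) or np.any(self.radii <= 0):
            raise ValueError("radii must be positive, one per atom")
        if len(self.residue_name) != n or self.residue_index.shape != (n,):
            raise ValueError("residue metadata length mismatch")
        if np.any(np.diff(self.residue_index) < 0):
            raise ValueError("residue_index must be non-decreasing along the chain")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def residue_ids(self) -> np.ndarray:
        """Unique residue indices in chain order."""
        return np.unique(self.residue_index)

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    def ca_mask(self) -> np.ndarray:
        return np.array([name.strip() == "CA" for name in self.atom_names])

    def heavy_mask(self) -> np.ndarray:
        return np.array([el.strip().upper() != "H" for el in self.elements])

    def residue_name_of(self, residue: int) -> str:
        pos = np.nonzero(self.residue_index == residue)[0]
        if len(pos) == 0:
            raise KeyError(f"no residue {residue}")
        return self.residue_name[pos[0]]

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(
            atom_names=self.atom_names,
            residue_index=self.residue_index.copy(),
            residue_name=list(self.residue_name),
            coords=np.asarray(coords, dtype=float),
            elements=list(self.elements),
            radii=self.radii.copy(),
            b_column=None if self.b_column is None else self.b_column.copy(),
        )


@dataclass
class Ensemble:
    """Ordered conformer stack sharing one topology."""

    topology: Structure
    frames: np.ndarray                     # (n_frames, n_atoms, 3)
    frame_labels: list[str] | None = None
    align_mask: np.ndarray | None = None   # bool per atom; default: all atoms
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise ValueError("frames must be a non-empty (n_frames, n_atoms, 3) array")
        if self.frames.shape[1:] != (self.topology.n_atoms, 3):
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology {self.topology.n_atoms}"
            )
        if self.align_mask is None:
            self.align_mask = np.ones(self.topology.n_atoms, dtype=bool)
        else:
            self.align_mask = np.asarray(self.align_mask, dtype=bool)
            if self.align_mask.shape != (self.topology.n_atoms,):
                raise ValueError("align_mask must have one entry per atom")
            if not self.align_mask.any():
                raise ValueError("align_mask is empty")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])

    def subset(self, frame_indices: Sequence[int]) -> "Ensemble":
        idx = np.asarray(frame_indices, dtype=int)
        labels = None
        if self.frame_labels is not None:
            labels = [self.frame_labels[i] for i in idx]
        return Ensemble(self.topology, self.frames[idx], labels, self.align_mask.copy())


@dataclass
class ContactMap:
    """Residue-residue contacts (stored once, i < j) and per-residue counts."""

    pairs: set[tuple[int, int]]
    per_residue_counts: dict[int, int]
    cutoff: float
    min_seq_sep: int
    mode: str = "heavy_atom"

    def __post_init__(self) -> None:
        for i, j in self.pairs:
            if not i < j:
                raise ValueError(f"pair ({i}, {j}) not stored with i < j")
            if j - i < self.min_seq_sep:
                raise ValueError(f"pair ({i}, {j}) violates min_seq_sep {self.min_seq_sep}")
        counts: dict[int, int] = dict(self.per_residue_counts)
        recount: dict[int, int] = {r: 0 for r in counts}
        for i, j in self.pairs:
            recount[i] = recount.get(i, 0) + 1
            recount[j] = recount.get(j, 0) + 1
        for r, c in recount.items():
            if counts.get(r, 0) != c:
                raise ValueError(f"per_residue_counts inconsistent at residue {r}")

    @property
    def n_contacts(self) -> int:
        return len(self.pairs)


@dataclass
class SASAResult:
    per_atom_area: np.ndarray     # A^2
    per_residue_area: dict[int, float]
    trp_area: float               # summed Trp side-chain area, A^2
    probe_radius: float
    n_points: int

    @property
    def total_area(self) -> float:
        return float(self.per_atom_area.sum())


@dataclass
class FlexibilityProfile:
    residue_ids: np.ndarray
    per_residue_b: np.ndarray     # A^2
    mean_structure: np.ndarray    # coordinates used as fluctuation reference


# ---------------------------------------------------------------------------
# superposition

def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    The optimal proper rotation is found on the masked atom subset and applied
    to all atoms. Returns the transformed coordinates and the masked RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape:
        raise ValueError("coordinate shapes differ")
    if mask is None:
        mask = np.ones(len(mobile), dtype=bool)
    mask = np.asarray(mask)
    if mask.dtype == bool:
        idx = np.nonzero(mask)[0]
    else:
        idx = np.asarray(mask, dtype=int)
    if len(idx) < 3:
        raise ValueError("superposition mask needs >= 3 atoms")

    m = mobile[idx]
    r = reference[idx]
    mc = m.mean(axis=0)
    rc = r.mean(axis=0)
    h = (m - mc).T @ (r - rc)
    u, svals, vt = np.linalg.svd(h)
    # degenerate (collinear or coincident) point sets leave the rotation
    # under-determined about an axis
    if svals[1] < 1e-10 * max(svals[0], 1.0):
        raise ValueError("degenerate superposition mask (collinear or coincident points)")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    moved = (mobile - mc) @ rot.T + rc
    return moved, rmsd(moved[idx], reference[idx])


# ---------------------------------------------------------------------------
# TM-score

def _tm_d0(n_res: int) -> float:
    return 1.24 * (n_res - 15) ** (1.0 / 3.0) - 1.8


def _tm_of_alignment(model: np.ndarray, reference: np.ndarray, idx: np.ndarray,
                     d0: float, max_iter: int = 30) -> float:
    """Superpose on ``idx``, score all residues, shrink to close residues, repeat."""
    best = 0.0
    current = np.asarray(idx, dtype=int)
    seen: set[bytes] = set()
    for _ in range(max_iter):
        try:
            moved, _ = kabsch_superpose(model, reference, current)
        except ValueError:
            break
        d = np.linalg.norm(moved - reference, axis=1)
        score = float(np.mean(1.0 / (1.0 + (d / d0) ** 2)))
        best = max(best, score)
        close = np.nonzero(d < d0)[0]
        if len(close) < 4:
            close = np.argsort(d)[:4]
        close = np.sort(close)
        key = close.tobytes()
        if key in seen:
            break
        seen.add(key)
        current = close
    return best


def tm_score(model: np.ndarray, reference: np.ndarray) -> float:
    """Template-modelling score on C-alpha coordinates, maximised over
    fragment-seeded superpositions (seed lengths L, L/2, L/4 and 4)."""
    model = np.asarray(model, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if model.shape != reference.shape:
        raise ValueError("model/reference residue counts differ")
    n = len(model)
    if n <= 15:
        raise ValueError("TM-score normalisation undefined for length <= 15")
    d0 = _tm_d0(n)
    best = 0.0
    for seed_len in sorted({n, max(4, n // 2), max(4, n // 4), 4}, reverse=True):
        for start in range(0, n - seed_len + 1):
            idx = np.arange(start, start + seed_len)
            best = max(best, _tm_of_alignment(model, reference, idx, d0))
    return best


# ---------------------------------------------------------------------------
# size and flexibility

def radius_of_gyration(coords: np.ndarray, masses: np.ndarray | None = None) -> float:
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 2 or len(coords) < 1:
        raise ValueError("need at least one atom")
    if masses is None:
        masses = np.ones(len(coords))
    masses = np.asarray(masses, dtype=float)
    if np.any(masses < 0):
        raise ValueError("negative masses")
    total = masses.sum()
    if total <= 0:
        raise ValueError("all masses are zero")
    com = (masses[:, None] * coords).sum(axis=0) / total
    return float(np.sqrt((masses * np.sum((coords - com) ** 2, axis=1)).sum() / total))


def iterative_mean_align(
    frames: np.ndarray,
    mask: np.ndarray | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Superpose all frames onto their running mean until the mean is stable.

    Returns (aligned frames, mean structure). Convergence: RMSD between
    successive mean structures on the mask < ``tol`` Angstrom.
    """
    frames = np.asarray(frames, dtype=float)
    if mask is None:
        mask = np.ones(frames.shape[1], dtype=bool)
    ref = frames[0]
    aligned = frames.copy()
    for _ in range(max_iter):
        for k in range(len(frames)):
            aligned[k], _ = kabsch_superpose(frames[k], ref, mask)
        mean = aligned.mean(axis=0)
        if rmsd(mean[mask], ref[mask]) < tol:
            return aligned, mean
        ref = mean
    return aligned, mean


def align_to_reference(frames: np.ndarray, reference: np.ndarray,
                       mask: np.ndarray | None = None) -> np.ndarray:
    """Single-pass superposition of every frame onto a fixed reference."""
    frames = np.asarray(frames, dtype=float)
    out = np.empty_like(frames)
    for k in range(len(frames)):
        out[k], _ = kabsch_superpose(frames[k], reference, mask)
    return out


def b_factors(ens: Ensemble, per: str = "residue", ca_only: bool = False) -> FlexibilityProfile:
    """Isotropic B-factors B_i = (8 pi^2 / 3) <|dr_i|^2> about the iteratively
    aligned ensemble mean. ``per='residue'`` averages over member atoms."""
    if ens.n_frames < 2:
        raise ValueError("B-factors need at least 2 frames")
    if per not in ("residue", "atom"):
        raise ValueError("per must be 'residue' or 'atom'")
    aligned, mean = iterative_mean_align(ens.frames, ens.align_mask)
    msf = np.mean(np.sum((aligned - mean) ** 2, axis=2), axis=0)  # per atom
    b_atom = (8.0 * np.pi**2 / 3.0) * msf
    if per == "atom":
        return FlexibilityProfile(np.arange(ens.topology.n_atoms), b_atom, mean)
    top = ens.topology
    sel = top.ca_mask() if ca_only else np.ones(top.n_atoms, dtype=bool)
    res_ids = top.residue_ids
    vals = np.empty(len(res_ids))
    for k, r in enumerate(res_ids):
        members = (top.residue_index == r) & sel
        if not members.any():
            members = top.residue_index == r
        vals[k] = b_atom[members].mean()
    return FlexibilityProfile(res_ids, vals, mean)


# ---------------------------------------------------------------------------
# contacts

def _contact_atom_selection(s: Structure, mode: str) -> np.ndarray:
    if mode == "heavy_atom":
        return np.nonzero(s.heavy_mask())[0]
    if mode == "cbeta":
        # CB per residue, CA fallback (glycine / bead models)
        keep = []
        for r in s.residue_ids:
            members = np.nonzero(s.residue_index == r)[0]
            names = [s.atom_names[i].strip() for i in members]
            if "CB" in names:
                keep.append(members[names.index("CB")])
            elif "CA" in names:
                keep.append(members[names.index("CA")])
            else:
                keep.append(members[0])
        return np.asarray(keep, dtype=int)
    raise ValueError(f"unknown contact mode {mode!r}")


def residue_min_distances(coords: np.ndarray, residue_of_atom: np.ndarray,
                          residue_ids: np.ndarray) -> np.ndarray:
    """Minimum inter-residue atom distance matrix for a given atom selection."""
    n_res = len(residue_ids)
    pos = {r: k for k, r in enumerate(residue_ids)}
    grp = np.array([pos[r] for r in residue_of_atom])
    d = cdist(coords, coords)
    out = np.full((n_res, n_res), np.inf)
    np.minimum.at(out, (grp[:, None].repeat(len(grp), 1), grp[None, :].repeat(len(grp), 0)), d)
    return out


def contact_map(s: Structure, cutoff: float = 5.5, min_seq_sep: int = 2,
                mode: str = "heavy_atom") -> ContactMap:
    """Native-contact map: residues i, j (|i-j| >= min_seq_sep) are in contact
    iff their minimum inter-atom distance (per ``mode``) is <= cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if min_seq_sep < 1:
        raise ValueError("min_seq_sep must be >= 1")
    sel = _contact_atom_selection(s, mode)
    res_ids = s.residue_ids
    dmin = residue_min_distances(s.coords[sel], s.residue_index[sel], res_ids)
    pairs: set[tuple[int, int]] = set()
    counts = {int(r): 0 for r in res_ids}
    for a in range(len(res_ids)):
        for b in range(a + 1, len(res_ids)):
            i, j = int(res_ids[a]), int(res_ids[b])
            if j - i < min_seq_sep:
                continue
            if dmin[a, b] <= cutoff:
                pairs.add((i, j))
                counts[i] += 1
                counts[j] += 1
    return ContactMap(pairs, counts, cutoff, min_seq_sep, mode)


# ---------------------------------------------------------------------------
# solvent accessible surface (Shrake-Rupley quadrature)

def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n)
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    theta = np.pi * (3.0 - np.sqrt(5.0)) * i
    return np.column_stack([r * np.cos(theta), r * np.sin(theta), z])


def sasa(s: Structure, probe_radius: float = 1.4, n_points: int = 960,
         trp_sidechain_only: bool = True) -> SASAResult:
    """Solvent-accessible surface area by uniform sphere quadrature.

    A quadrature point on atom i's expanded sphere (r_i + probe) is exposed
    iff it lies strictly outside every other expanded sphere; exactly
    coincident spheres therefore each keep their full area (deterministic).
    ``trp_area`` sums side-chain atoms of TRP residues; bead models whose Trp
    residues carry no side-chain atoms fall back to all atoms of the residue.
    """
    if n_points < 60:
        raise ValueError("n_points must be >= 60 for a usable quadrature")
    pts = _fibonacci_sphere(n_points)
    expanded = s.radii + probe_radius
    coords = s.coords
    n = s.n_atoms
    d = cdist(coords, coords)
    per_atom = np.zeros(n)
    eps = 1e-9
    for i in range(n):
        neighbours = np.nonzero((d[i] < expanded[i] + expanded) & (np.arange(n) != i))[0]
        sphere = coords[i] + expanded[i] * pts
        if len(neighbours) == 0:
            exposed = n_points
        else:
            dist2 = cdist(sphere, coords[neighbours])
            buried = (dist2 < expanded[neighbours][None, :] - eps).any(axis=1)
            exposed = int((~buried).sum())
        per_atom[i] = 4.0 * np.pi * expanded[i] ** 2 * exposed / n_points

    per_res: dict[int, float] = {}
    for r in s.residue_ids:
        per_res[int(r)] = float(per_atom[s.residue_index == r].sum())

    trp = 0.0
    for r in s.residue_ids:
        members = np.nonzero(s.residue_index == r)[0]
        if s.residue_name[members[0]].strip().upper() != "TRP":
            continue
        if trp_sidechain_only:
            side = [i for i in members if s.atom_names[i].strip() not in BACKBONE_ATOMS]
            if not side:
                side = list(members)  # C-alpha bead models
        else:
            side = list(members)
        trp += float(per_atom[side].sum())

    return SASAResult(per_atom, per_res, trp, probe_radius, n_points)
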