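"""Contact-fraction phi-value prediction and accumulated error versus an
experimental profile.

phi_i of a conformation is the fraction of residue i's native contacts that
are retained (new non-native contacts are ignored). Residues without native
contacts have undefined phi (NaN) and are excluded from error sums.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .structures import (ContactMap, Ensemble, Structure,
                         _contact_atom_selection, residue_min_distances)

__all__ = ["PhiProfile", "PhiErrorReport", "phi_calc", "phi_ensemble", "phi_error"]


@dataclass
class PhiProfile:
    residue_index: np.ndarray     # 1-based
    phi: np.ndarray               # NaN where undefined (no native contacts)
    n_native: np.ndarray | None = None
    source: str = "calculated"

    def __post_init__(self) -> None:
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.phi = np.asarray(self.phi, dtype=float)
        if self.phi.shape != self.residue_index.shape:
            raise ValueError("phi/residue_index length mismatch")
        defined = ~np.isnan(self.phi)
        if np.any(self.phi[defined] < 0):
            raise ValueError("phi values must be >= 0")
        if self.n_native is not None:
            self.n_native = np.asarray(self.n_native, dtype=int)
            if self.n_native.shape != self.phi.shape:
                raise ValueError("n_native length mismatch")

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.phi)


@dataclass
class PhiErrorReport:
    signed_sum: float
    abs_sum: float
    per_residue_abs_sum: float
    included_residues: np.ndarray
    n_included: int


def _retained_native_pairs(coords: np.ndarray, s: Structure, native: ContactMap,
                           cutoff: float) -> set[tuple[int, int]]:
    sel = _contact_atom_selection(s, native.mode)
    res_ids = s.residue_ids
    pos = {int(r): k for k, r in enumerate(res_ids)}
    dmin = residue_min_distances(coords[sel], s.residue_index[sel], res_ids)
    kept = set()
    for (i, j) in native.pairs:
        if dmin[pos[i], pos[j]] <= cutoff:
            kept.add((i, j))
    return kept


def phi_calc(snapshot: Structure, native: ContactMap,
             cutoff_tolerance: float = 1.0) -> PhiProfile:
    """Per-residue fraction of native contacts retained in ``snapshot``.

    A native pair (i, j) counts as retained when the snapshot's minimum
    inter-residue distance is <= native cutoff * ``cutoff_tolerance``
    (1.0 = same cutoff as the native map; >1 adds hysteresis).
    """
    res_ids = snapshot.residue_ids
    native_residues = set(native.per_residue_counts)
    if {int(r) for r in res_ids} != native_residues:
        raise ValueError("snapshot residue set does not match the native contact map")
    cutoff = native.cutoff * cutoff_tolerance
    kept = _retained_native_pairs(snapshot.coords, snapshot, native, cutoff)
    kept_count = {int(r): 0 for r in res_ids}
    for i, j in kept:
        kept_count[i] += 1
        kept_count[j] += 1
    n_nat = np.array([native.per_residue_counts.get(int(r), 0) for r in res_ids])
    phi = np.full(len(res_ids), np.nan)
    for k, r in enumerate(res_ids):
        if n_nat[k] > 0:
            phi[k] = kept_count[int(r)] / n_nat[k]
    return PhiProfile(res_ids, phi, n_nat, source="calculated")


def phi_ensemble(ens: Ensemble, native: ContactMap,
                 cutoff_tolerance: float = 1.0) -> tuple[PhiProfile, np.ndarray]:
    """Ensemble-mean phi profile plus the (n_frames, n_residues) per-frame
    phi matrix (NaN where undefined)."""
    per_frame = []
    for k in range(ens.n_frames):
        per_frame.append(phi_calc(ens.frame_structure(k), native, cutoff_tolerance).phi)
    mat = np.asarray(per_frame)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN residues stay NaN
        mean = np.nanmean(mat, axis=0)
    res_ids = ens.topology.residue_ids
    n_nat = np.array([native.per_residue_counts.get(int(r), 0) for r in res_ids])
    return PhiProfile(res_ids, mean, n_nat, source="calculated"), mat


def phi_error(calc: PhiProfile, exp: PhiProfile,
              exclude: np.ndarray | None = None) -> PhiErrorReport:
    """Accumulated difference between a calculated and an experimental profile.

    Residues are included when the experimental phi is defined and < 1, the
    calculated phi is defined, and the residue is not in ``exclude`` (e.g. a
    helix whose experimental determinations are unreliable). Sign convention:
    calculated more native-like than experiment -> positive.
    """
    if not np.array_equal(calc.residue_index, exp.residue_index):
        raise ValueError("profiles use different residue indexing")
    include = exp.defined & (exp.phi < 1.0) & calc.defined
    if exclude is not None:
        excl = np.isin(calc.residue_index, np.asarray(exclude, dtype=int))
        include &= ~excl
    if not include.any():
        raise ValueError("no residues left after exclusions")
    diff = calc.phi[include] - exp.phi[include]
    signed = float(diff.sum())
    return PhiErrorReport(
        signed_sum=signed,
        abs_sum=abs(signed),
        per_residue_abs_sum=float(np.abs(diff).sum()),
        included_residues=calc.residue_index[include],
        n_included=int(include.sum()),
    )
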