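"""File I/O: multi-model PDB, multi-frame XYZ, SAXS curve text files,
phi-value tables and spectra matrices.

The PDB reader is a deliberately small fixed-column parser covering the
ATOM/HETATM/MODEL/ENDMDL subset this package needs; it reports parse errors
with line numbers, prefers altloc 'A', keeps the first chain by default and
skips HETATM records unless whitelisted.
"""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd

from .structures import Ensemble, Structure, vdw_radius

__all__ = [
    "read_structure",
    "read_ensemble",
    "write_structure",
    "write_ensemble",
    "read_saxs_curve",
    "write_saxs_curve",
    "read_phi_table",
    "write_phi_table",
    "read_spectra_csv",
    "write_spectra_csv",
]


class PDBParseError(ValueError):
    pass


_ELEMENT_FROM_NAME = {
    "CA": "C", "CB": "C", "CG": "C", "CD": "C", "CE": "C", "CZ": "C",
    "N": "N", "C": "C", "O": "O", "S": "S",
}


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if name in _ELEMENT_FROM_NAME:
        return _ELEMENT_FROM_NAME[name]
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    raise ValueError(f"cannot infer element for atom name {atom_name!r}")


def _parse_pdb_models(
    path: str,
    first_chain_only: bool = True,
    hetatm_whitelist: Sequence[str] = (),
):
    """Parse ATOM records into per-model atom lists. Returns
    (models, atom_names, residue_index, residue_name, elements, b_column)."""
    models: list[list[tuple[float, float, float]]] = []
    current: list[tuple[float, float, float]] = []
    meta_done = False
    atom_names: list[str] = []
    res_idx: list[int] = []
    res_name: list[str] = []
    elements: list[str] = []
    bvals: list[float] = []
    chain_kept: str | None = None
    in_model = False

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            rec = raw[:6].strip()
            if rec == "MODEL":
                if current:
                    models.append(current)
                    meta_done = True
                current = []
                in_model = True
                continue
            if rec == "ENDMDL":
                if current:
                    models.append(current)
                    meta_done = True
                current = []
                in_model = False
                continue
            if rec not in ("ATOM", "HETATM"):
                continue
            line = raw.rstrip("\n")
            if len(line) < 54:
                raise PDBParseError(f"{path}:{lineno}: truncated {rec} record")
            try:
                name = line[12:16]
                altloc = line[16]
                resname = line[17:20].strip()
                chain = line[21]
                resseq = int(line[22:26])
                x = float(line[30:38])
                y = float(line[38:46])
                z = float(line[46:54])
                bfac = float(line[60:66]) if len(line) >= 66 and line[60:66].strip() else 0.0
                element = line[76:78].strip() if len(line) >= 78 else ""
            except ValueError as exc:
                raise PDBParseError(f"{path}:{lineno}: malformed {rec} record: {exc}") from exc
            if rec == "HETATM" and resname not in hetatm_whitelist:
                continue
            if altloc not in (" ", "", "A"):
                continue
            if first_chain_only:
                if chain_kept is None:
                    chain_kept = chain
                elif chain != chain_kept:
                    continue
            current.append((x, y, z))
            if not meta_done:
                atom_names.append(name)
                res_idx.append(resseq)
                res_name.append(resname)
                try:
                    elements.append(element.upper() if element else _guess_element(name))
                except ValueError as exc:
                    raise PDBParseError(f"{path}:{lineno}: {exc}") from exc
                bvals.append(bfac)
    if current:
        models.append(current)
    if not models:
        raise PDBParseError(f"{path}: no ATOM records found")
    for k, m in enumerate(models):
        if len(m) != len(models[0]):
            raise PDBParseError(
                f"{path}: frame {k + 1} has {len(m)} atoms, expected {len(models[0])}"
            )
    return models, atom_names, res_idx, res_name, elements, bvals


def _structure_from_meta(coords, atom_names, res_idx, res_name, elements, bvals) -> Structure:
    radii = np.array([vdw_radius(el) for el in elements])
    return Structure(
        atom_names=[n.strip() for n in atom_names],
        residue_index=np.asarray(res_idx, dtype=int),
        residue_name=list(res_name),
        coords=np.asarray(coords, dtype=float),
        elements=list(elements),
        radii=radii,
        b_column=np.asarray(bvals, dtype=float),
    )


def _detect_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    ext = os.path.splitext(path)[1].lower()
    return "xyz" if ext == ".xyz" else "pdb"


def read_structure(path: str, format: str | None = None,
                   hetatm_whitelist: Sequence[str] = ()) -> Structure:
    """Read a single-conformation structure from PDB or XYZ."""
    fmt = _detect_format(path, format)
    if fmt == "xyz":
        frames, elements = _parse_xyz(path)
        if len(frames) > 1:
            raise ValueError(f"{path}: {len(frames)} frames; use read_ensemble for trajectories")
        return _structure_from_xyz(frames[0], elements)
    models, *meta = _parse_pdb_models(path, hetatm_whitelist=hetatm_whitelist)
    if len(models) > 1:
        raise ValueError(f"{path}: {len(models)} models; use read_ensemble for multi-model files")
    return _structure_from_meta(models[0], *meta)


def read_ensemble(path: str, format: str | None = None,
                  align_mask: np.ndarray | None = None) -> Ensemble:
    """Read a multi-model PDB or multi-frame XYZ file into an Ensemble
    (frames in file order; topology taken from the first frame)."""
    fmt = _detect_format(path, format)
    if fmt == "xyz":
        frames, elements = _parse_xyz(path)
        top = _structure_from_xyz(frames[0], elements)
        return Ensemble(top, np.asarray(frames), align_mask=align_mask)
    models, *meta = _parse_pdb_models(path)
    top = _structure_from_meta(models[0], *meta)
    return Ensemble(top, np.asarray(models), align_mask=align_mask)


def _parse_xyz(path: str):
    frames: list[list[list[float]]] = []
    elements: list[str] = []
    with open(path) as fh:
        lines = fh.readlines()
    pos = 0
    frame_no = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        frame_no += 1
        try:
            n = int(lines[pos].split()[0])
        except ValueError as exc:
            raise ValueError(f"{path}:{pos + 1}: expected atom count") from exc
        if pos + 1 + n >= len(lines) + 1:
            raise ValueError(f"{path}: frame {frame_no} truncated")
        block = lines[pos + 2: pos + 2 + n]
        if len(block) < n:
            raise ValueError(f"{path}: frame {frame_no} has fewer than {n} atom lines")
        coords = []
        els = []
        for k, ln in enumerate(block):
            parts = ln.split()
            if len(parts) < 4:
                raise ValueError(f"{path}:{pos + 3 + k}: malformed XYZ atom line")
            els.append(parts[0])
            coords.append([float(parts[1]), float(parts[2]), float(parts[3])])
        if frames and len(coords) != len(frames[0]):
            raise ValueError(
                f"{path}: frame {frame_no} has {len(coords)} atoms, expected {len(frames[0])}"
            )
        if not frames:
            elements = els
        frames.append(coords)
        pos += 2 + n
    if not frames:
        raise ValueError(f"{path}: empty XYZ file")
    return frames, elements


def _structure_from_xyz(coords, elements) -> Structure:
    n = len(coords)
    radii = np.array([vdw_radius(el) for el in elements])
    return Structure(
        atom_names=["CA"] * n,
        residue_index=np.arange(1, n + 1),
        residue_name=["UNK"] * n,
        coords=np.asarray(coords, dtype=float),
        elements=list(elements),
        radii=radii,
    )


_PDB_ATOM = (
    "ATOM  {serial:>5d} {name:<4s}{altloc:1s}{resname:<3s} {chain:1s}"
    "{resseq:>4d}    {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{b:6.2f}          {element:>2s}\n"
)


def _format_atom_name(name: str) -> str:
    name = name.strip()
    return f" {name:<3s}" if len(name) < 4 else name


def _write_model(fh, s: Structure, coords: np.ndarray) -> None:
    b = s.b_column if s.b_column is not None else np.zeros(s.n_atoms)
    for i in range(s.n_atoms):
        fh.write(_PDB_ATOM.format(
            serial=i + 1,
            name=_format_atom_name(s.atom_names[i]),
            altloc=" ",
            resname=s.residue_name[i][:3],
            chain="A",
            resseq=int(s.residue_index[i]),
            x=coords[i, 0], y=coords[i, 1], z=coords[i, 2],
            occ=1.0, b=float(b[i]),
            element=s.elements[i][:2].upper(),
        ))


def write_structure(path: str, s: Structure) -> None:
    with open(path, "w") as fh:
        _write_model(fh, s, s.coords)
        fh.write("END\n")


def write_ensemble(path: str, ens: Ensemble) -> None:
    with open(path, "w") as fh:
        for k in range(ens.n_frames):
            fh.write(f"MODEL     {k + 1:>4d}\n")
            _write_model(fh, ens.topology, ens.frames[k])
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# SAXS curves: whitespace-delimited 2-3 column text (s [1/A], I, sigma)

def read_saxs_curve(path: str):
    from .saxs import SAXSCurve

    data = np.loadtxt(path, comments="#")
    if data.ndim == 1:
        data = data[None, :]
    if data.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 columns (s, I)")
    sigma = data[:, 2] if data.shape[1] >= 3 else None
    return SAXSCurve(data[:, 0], data[:, 1], sigma)


def write_saxs_curve(path: str, curve) -> None:
    cols = [curve.s, curve.intensity]
    if curve.sigma is not None:
        cols.append(curve.sigma)
    np.savetxt(path, np.column_stack(cols), fmt="%.8e",
               header="s[1/A] I(s)" + (" sigma" if curve.sigma is not None else ""))


# ---------------------------------------------------------------------------
# phi-value tables: TSV (residue_index, phi[, stderr])

def read_phi_table(path: str):
    from .phi import PhiProfile

    df = pd.read_csv(path, sep="\t")
    if "residue_index" not in df.columns or "phi" not in df.columns:
        raise ValueError(f"{path}: expected columns residue_index, phi")
    return PhiProfile(
        residue_index=df["residue_index"].to_numpy(dtype=int),
        phi=df["phi"].to_numpy(dtype=float),
        n_native=df["n_native"].to_numpy(dtype=int) if "n_native" in df.columns else None,
        source="experimental",
    )


def write_phi_table(path: str, profile) -> None:
    cols = {"residue_index": profile.residue_index, "phi": profile.phi}
    if profile.n_native is not None:
        cols["n_native"] = profile.n_native
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# spectra series: CSV matrix, rows = wavelengths (nm), columns = temperatures (K)

def read_spectra_csv(path: str):
    from .spectra import SpectraSeries

    df = pd.read_csv(path, index_col=0)
    wavelengths = df.index.to_numpy(dtype=float)
    temperatures = np.array([float(c) for c in df.columns])
    return SpectraSeries(wavelengths, temperatures, df.to_numpy(dtype=float))


def write_spectra_csv(path: str, series) -> None:
    df = pd.DataFrame(series.Y, index=series.wavelengths,
                      columns=[f"{t:.2f}" for t in series.temperatures])
    df.index.name = "wavelength_nm"
    df.to_csv(path, float_format="%.8g")
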