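"""Synthetic fixtures with planted ground truth.

Everything the analysis pipeline consumes can be generated here: C-alpha bead
"proteins" with a rigid core and flexible loops, correlated-Gaussian
ensembles with planted deformation modes, loop-disordered ensembles with
prescribed native-contact retention, noisy three-component SAXS temperature
series and three-state absorbance series. All generators are deterministic
per seed and record their ground truth in metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .saxs import SAXSCurve, SAXSDataset, debye_curve
from .spectra import SpectraSeries, ThreeStateModel, populations
from .structures import Ensemble, Structure

__all__ = [
    "ToySpec",
    "make_toy_protein",
    "sample_gaussian_ensemble",
    "make_disordered_ensemble",
    "make_saxs_mixture",
    "make_spectra_series",
    "reference_components",
    "make_three_population_ensemble",
]

_BOND = 3.8  # consecutive C-alpha spacing, A


@dataclass
class ToySpec:
    n_residues: int
    core_ranges: list[tuple[int, int]]
    loop_ranges: list[tuple[int, int]] = field(default_factory=list)
    trp_positions: list[int] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 3:
            raise ValueError("need at least 3 residues")
        if not self.core_ranges:
            raise ValueError("need at least one core range")
        seen: set[int] = set()
        for lo, hi in list(self.core_ranges) + list(self.loop_ranges):
            if not (1 <= lo <= hi <= self.n_residues):
                raise ValueError(f"range ({lo}, {hi}) outside [1, {self.n_residues}]")
            span = set(range(lo, hi + 1))
            if span & seen:
                raise ValueError("core/loop ranges overlap")
            seen |= span
        for t in self.trp_positions:
            if not 1 <= t <= self.n_residues:
                raise ValueError(f"trp position {t} out of range")

    def loop_mask(self) -> np.ndarray:
        mask = np.zeros(self.n_residues, dtype=bool)
        for lo, hi in self.loop_ranges:
            mask[lo - 1: hi] = True
        return mask


def _helix_template(m: int) -> np.ndarray:
    """Ideal C-alpha helix trace, steps renormalised to exactly _BOND."""
    t = np.arange(m)
    radius, rise, turn = 2.3, 1.5, np.deg2rad(100.0)
    pts = np.column_stack([radius * np.cos(turn * t), radius * np.sin(turn * t), rise * t])
    out = [np.zeros(3)]
    for k in range(1, m):
        step = pts[k] - pts[k - 1]
        out.append(out[-1] + _BOND * step / np.linalg.norm(step))
    return np.asarray(out)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _build_chain(spec: ToySpec, rng: np.random.Generator) -> np.ndarray:
    loop = spec.loop_mask()
    coords = np.zeros((spec.n_residues, 3))
    direction = np.array([1.0, 0.0, 0.0])
    i = 0
    while i < spec.n_residues:
        j = i
        while j < spec.n_residues and loop[j] == loop[i]:
            j += 1
        m = j - i
        if not loop[i]:
            template = _helix_template(m) @ _random_rotation(rng).T
            start = coords[i - 1] + _BOND * direction if i > 0 else np.zeros(3)
            seg = template - template[0] + start
            coords[i:j] = seg
            if m > 1:
                direction = seg[-1] - seg[-2]
                direction /= np.linalg.norm(direction)
        else:
            centroid = coords[:i].mean(axis=0) if i > 0 else np.zeros(3)
            p = coords[i - 1] if i > 0 else np.zeros(3)
            d = direction.copy()
            for k in range(i, j):
                pull = centroid - p
                norm = np.linalg.norm(pull)
                if norm > 1e-9:
                    pull /= norm
                # propose steps until one stays clash-free (best effort)
                placed = coords[:k] if k > 0 else coords[:1]
                best_step, best_clearance = None, -np.inf
                for _ in range(30):
                    cand = d + 0.9 * rng.standard_normal(3) + 0.55 * pull
                    cand /= np.linalg.norm(cand)
                    q = p + _BOND * cand
                    clearance = np.min(np.linalg.norm(placed - q, axis=1)) if k > 0 else np.inf
                    if clearance > best_clearance:
                        best_step, best_clearance = cand, clearance
                    if clearance >= 2.2:
                        break
                d = best_step
                p = p + _BOND * d
                coords[k] = p
            direction = d
        i = j
    return coords


def make_toy_protein(spec: ToySpec, max_retries: int = 25) -> Structure:
    """Deterministic C-alpha bead chain: compact helical core segments joined
    by curved loop arcs, consecutive bead spacing exactly 3.8 A, minimum
    bead-bead distance >= 2 A (retried with fresh sub-seeds, then error)."""
    for attempt in range(max_retries):
        rng = np.random.default_rng([spec.seed, attempt])
        coords = _build_chain(spec, rng)
        d = cdist(coords, coords)
        np.fill_diagonal(d, np.inf)
        if d.min() >= 2.0:
            break
    else:
        raise ValueError("could not build a clash-free toy protein for this spec")
    names = ["TRP" if (k + 1) in spec.trp_positions else "ALA"
             for k in range(spec.n_residues)]
    return Structure(
        atom_names=["CA"] * spec.n_residues,
        residue_index=np.arange(1, spec.n_residues + 1),
        residue_name=names,
        coords=coords,
        elements=["C"] * spec.n_residues,
        radii=np.full(spec.n_residues, 1.7),
    )


def _rigid_subspace(coords: np.ndarray) -> np.ndarray:
    """Orthonormal basis of infinitesimal rigid motions (3 translations +
    3 rotations) around the centred reference, as 3N columns."""
    n = len(coords)
    centred = coords - coords.mean(axis=0)
    cols = []
    for k in range(3):
        t = np.zeros((n, 3))
        t[:, k] = 1.0
        cols.append(t.ravel())
    for axis in np.eye(3):
        cols.append(np.cross(np.broadcast_to(axis, (n, 3)), centred).ravel())
    q, _ = np.linalg.qr(np.column_stack(cols))
    return q


def sample_gaussian_ensemble(ref: Structure, mode_spec: list[tuple[np.ndarray, float]],
                             isotropic_noise: float, n_frames: int,
                             seed: int | None = None) -> Ensemble:
    """Frames = ref + sum_k z_k v_k + eps with z_k ~ N(0, var_k) along
    orthonormalised planted directions and isotropic Gaussian jitter eps.

    Planted directions are first projected off the rigid-body (translation +
    rotation) subspace so that downstream superposition leaves them intact;
    the modes actually used are recorded in ``metadata``.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    rng = np.random.default_rng(seed)
    dim = 3 * ref.n_atoms
    x0 = ref.coords.ravel()
    if mode_spec:
        dirs = np.column_stack([np.asarray(v, dtype=float).ravel() for v, _ in mode_spec])
        if dirs.shape[0] != dim:
            raise ValueError("mode directions must be 3N vectors")
        rigid = _rigid_subspace(ref.coords)
        dirs = dirs - rigid @ (rigid.T @ dirs)
        q, _ = np.linalg.qr(dirs)
        modes = q[:, : dirs.shape[1]]
        variances = np.array([var for _, var in mode_spec], dtype=float)
        z = rng.standard_normal((n_frames, len(variances))) * np.sqrt(variances)
        disp = z @ modes.T
    else:
        modes = np.zeros((dim, 0))
        variances = np.zeros(0)
        disp = np.zeros((n_frames, dim))
    noise = isotropic_noise * rng.standard_normal((n_frames, dim))
    frames = (x0 + disp + noise).reshape(n_frames, ref.n_atoms, 3)
    return Ensemble(ref, frames,
                    metadata={"modes": modes, "variances": variances,
                              "isotropic_noise": isotropic_noise, "seed": seed})


def _measure_retention(frames: np.ndarray, native_coords: np.ndarray,
                       cutoff: float, min_seq_sep: int):
    """Per-residue mean native-contact retention, counted directly on bead
    distances (independent of the phi module's code path)."""
    d0 = cdist(native_coords, native_coords)
    n = len(native_coords)
    iu, ju = np.triu_indices(n, k=min_seq_sep)
    native_pairs = (d0[iu, ju] <= cutoff)
    pi, pj = iu[native_pairs], ju[native_pairs]
    n_nat = np.zeros(n)
    np.add.at(n_nat, pi, 1)
    np.add.at(n_nat, pj, 1)
    kept_sum = np.zeros(n)
    for f in frames:
        df = np.linalg.norm(f[pi] - f[pj], axis=1)
        kept = df <= cutoff
        np.add.at(kept_sum, pi, kept)
        np.add.at(kept_sum, pj, kept)
    with np.errstate(invalid="ignore", divide="ignore"):
        retention = kept_sum / (n_nat * len(frames))
    retention[n_nat == 0] = np.nan
    return retention, n_nat


def make_disordered_ensemble(native: Structure, loop_ranges: list[tuple[int, int]],
                             retention, amplitude: float, n_frames: int,
                             seed: int | None = None, core_jitter: float = 0.1,
                             cutoff: float = 5.5, min_seq_sep: int = 2) -> Ensemble:
    """Loop-disordered / core-intact ensemble.

    Core beads are jittered (sigma ``core_jitter`` <= 0.5 A); each loop bead
    independently stays near its native position with its retention
    probability, otherwise it is swept onto a chain-correlated random
    excursion of scale ``amplitude``. The realised per-residue native-contact
    retention (measured post hoc at the given contact definition) is recorded
    as ground truth in ``metadata['realized_retention']``.
    """
    n_res = native.n_atoms
    p = np.asarray(retention, dtype=float) * np.ones(n_res)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("retention probabilities must lie in [0, 1]")
    loop_mask = np.zeros(n_res, dtype=bool)
    for lo, hi in loop_ranges:
        loop_mask[lo - 1: hi] = True
    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, n_res, 3))
    for f in range(n_frames):
        coords = native.coords + core_jitter * rng.standard_normal((n_res, 3))
        broken = loop_mask & (rng.random(n_res) >= p)
        if broken.any():
            # chain-correlated displacement directions give arc-like excursions
            u = np.empty((n_res, 3))
            prev = rng.standard_normal(3)
            prev /= np.linalg.norm(prev)
            for k in range(n_res):
                prev = prev + 0.7 * rng.standard_normal(3)
                prev /= np.linalg.norm(prev)
                u[k] = prev
            scale = amplitude * (0.75 + 0.5 * rng.random(n_res))
            coords[broken] += scale[broken, None] * u[broken]
        frames[f] = coords
    realized, n_nat = _measure_retention(frames, native.coords, cutoff, min_seq_sep)
    align_mask = ~loop_mask
    if align_mask.sum() < 3:
        align_mask = np.ones(n_res, dtype=bool)
    return Ensemble(
        native, frames, align_mask=align_mask,
        metadata={
            "realized_retention": realized,
            "n_native_contacts": n_nat,
            "planted_retention": p,
            "loop_mask": loop_mask,
            "contact_cutoff": cutoff,
            "min_seq_sep": min_seq_sep,
            "amplitude": amplitude,
            "seed": seed,
        },
    )


def make_saxs_mixture(components: list[SAXSCurve], population_model: ThreeStateModel,
                      temperatures: np.ndarray, noise_frac: float = 0.0,
                      seed: int | None = None) -> SAXSDataset:
    """Noisy temperature series of three-state mixtures of known components.

    Rows are sum_i X_i(T) S_i(s) times multiplicative Gaussian noise; the
    population matrix and pure curves are stored as ground truth.
    """
    if len(components) != 3:
        raise ValueError("need exactly 3 component curves")
    grid = components[0].s
    for c in components[1:]:
        if not np.array_equal(c.s, grid):
            raise ValueError("components must share one s grid")
    if noise_frac < 0:
        raise ValueError("noise_frac must be >= 0")
    temperatures = np.asarray(temperatures, dtype=float)
    x = populations(population_model, temperatures)
    s_true = np.vstack([c.intensity for c in components])
    d = x @ s_true
    rng = np.random.default_rng(seed)
    if noise_frac > 0:
        d = d * (1.0 + noise_frac * rng.standard_normal(d.shape))
    d = np.clip(d, 0.0, None)
    return SAXSDataset(d, temperatures, grid,
                       metadata={"C_true": x, "S_true": s_true, "seed": seed,
                                 "noise_frac": noise_frac})


def make_spectra_series(pure_spectra: np.ndarray, wavelengths: np.ndarray,
                        model: ThreeStateModel, temperatures: np.ndarray,
                        noise: float = 0.0, seed: int | None = None):
    """Absorbance series Y = states @ X^T + Gaussian noise.

    ``pure_spectra`` is (n_wavelengths, 3) ordered N, I, U. Returns
    (SpectraSeries, ground_truth dict)."""
    pure_spectra = np.asarray(pure_spectra, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    temperatures = np.asarray(temperatures, dtype=float)
    if pure_spectra.shape != (len(wavelengths), 3):
        raise ValueError("pure_spectra must be (n_wavelengths, 3)")
    x = populations(model, temperatures)
    y = pure_spectra @ x.T
    rng = np.random.default_rng(seed)
    if noise > 0:
        y = y + noise * rng.standard_normal(y.shape)
    series = SpectraSeries(wavelengths, temperatures, y)
    truth = {"pure_spectra": pure_spectra, "populations": x, "seed": seed, "noise": noise}
    return series, truth


def reference_components(grid: np.ndarray, seed: int = 0):
    """Bundled three-state SAXS component set: Debye curves of a compact
    (native-like), a mildly expanded (intermediate-like) and an extended
    (coil-like) toy conformation, each normalised to I(0) = 1.

    Returns (curves, structures) ordered native, intermediate, unfolded.
    """
    grid = np.asarray(grid, dtype=float)
    spec = ToySpec(n_residues=60, core_ranges=[(1, 20), (41, 60)],
                   loop_ranges=[(21, 40)], trp_positions=[8, 15, 47, 54], seed=seed)
    native = make_toy_protein(spec)
    intermediate = native.with_coords(
        native.coords.mean(axis=0) + 1.35 * (native.coords - native.coords.mean(axis=0)))
    rng = np.random.default_rng(seed)
    # extended coil: persistent random walk, step 3.8
    coords = [np.zeros(3)]
    d = np.array([1.0, 0.0, 0.0])
    for _ in range(native.n_atoms - 1):
        d = d + 0.25 * rng.standard_normal(3)
        d /= np.linalg.norm(d)
        coords.append(coords[-1] + _BOND * d)
    unfolded = native.with_coords(np.asarray(coords))
    curves = []
    structures = [native, intermediate, unfolded]
    for st in structures:
        c = debye_curve(st, grid)
        i0 = c.intensity[0] if grid[0] == 0 else debye_curve(st, np.array([0.0])).intensity[0]
        curves.append(SAXSCurve(grid, c.intensity / i0))
    return curves, structures


def make_three_population_ensemble(native: Structure, loop_ranges: list[tuple[int, int]],
                                   fractions: tuple[float, float, float],
                                   n_frames: int, seed: int | None = None,
                                   intermediate_retention: float = 0.15,
                                   unfolded_retention: float = 0.0,
                                   intermediate_amplitude: float = 12.0,
                                   unfolded_amplitude: float = 30.0):
    """Mixed ensemble of native-like, loop-disordered intermediate-like and
    globally disordered unfolded-like frames with planted state labels.

    Returns (Ensemble, labels) with labels in {0: native, 1: intermediate,
    2: unfolded}; label order is shuffled deterministically per seed.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    rng = np.random.default_rng(seed)
    counts = np.round(np.asarray(fractions) * n_frames).astype(int)
    counts[-1] = n_frames - counts[:-1].sum()
    all_ranges = [(1, native.n_atoms)]
    nat = make_disordered_ensemble(native, loop_ranges, 1.0, 0.0, max(2, counts[0]),
                                   seed=int(rng.integers(2**31)))
    inter = make_disordered_ensemble(native, loop_ranges, intermediate_retention,
                                     intermediate_amplitude, max(2, counts[1]),
                                     seed=int(rng.integers(2**31)))
    unf = make_disordered_ensemble(native, all_ranges, unfolded_retention,
                                   unfolded_amplitude, max(2, counts[2]),
                                   seed=int(rng.integers(2**31)), core_jitter=0.3)
    frames = np.concatenate([nat.frames[: counts[0]], inter.frames[: counts[1]],
                             unf.frames[: counts[2]]])
    labels = np.concatenate([np.zeros(counts[0], int), np.ones(counts[1], int),
                             np.full(counts[2], 2, int)])
    order = rng.permutation(n_frames)
    loop_mask = inter.metadata["loop_mask"]
    align_mask = ~loop_mask if (~loop_mask).sum() >= 3 else np.ones(native.n_atoms, bool)
    ens = Ensemble(native, frames[order], align_mask=align_mask,
                   metadata={"labels": labels[order], "fractions": tuple(fractions),
                             "seed": seed,
                             "intermediate_metadata": inter.metadata})
    return ens, labels[order]
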