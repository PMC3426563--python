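"""Small-angle X-ray scattering analysis.

``debye_curve`` computes vacuum Debye scattering from coordinates with
per-bead effective scattering factors (no hydration shell or excluded-volume
terms: the pipeline uses chi-based ranking, for which relative curve shape is
what matters). ``guinier_fit`` extracts I(0) and Rg from the low-angle
regime, ``chi_fit`` scores a computed curve against an experimental one, and
``mcr_als`` resolves a temperature-stacked dataset into non-negative
component curves and concentration profiles by alternating least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.spatial.distance import pdist

from .structures import Structure

__all__ = [
    "SAXSCurve",
    "GuinierResult",
    "ChiFit",
    "SAXSDataset",
    "MCRResult",
    "debye_curve",
    "guinier_fit",
    "chi_fit",
    "pca_rank",
    "mcr_als",
    "match_components",
]

#: uniform fractional error applied when an experimental curve carries no
#: per-point sigmas (the convention used for deconvoluted intermediate curves)
DEFAULT_FRACTIONAL_ERROR = 0.07


@dataclass
class SAXSCurve:
    s: np.ndarray                  # momentum transfer, 1/A, strictly increasing
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.s.ndim != 1 or self.s.shape != self.intensity.shape:
            raise ValueError("s and intensity must be matching 1-D arrays")
        if np.any(self.s < 0) or np.any(np.diff(self.s) <= 0):
            raise ValueError("s grid must be non-negative and strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("negative intensities")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.s.shape or np.any(self.sigma <= 0):
                raise ValueError("sigma must be positive, one per point")

    def effective_sigma(self, fractional_error: float = DEFAULT_FRACTIONAL_ERROR) -> np.ndarray:
        if self.sigma is not None:
            return self.sigma
        return fractional_error * self.intensity


@dataclass
class GuinierResult:
    I0: float
    Rg: float                      # A
    s_range_used: tuple[float, float]
    n_points_used: int
    r2: float


@dataclass
class ChiFit:
    chi: float
    scale: float
    n_points: int


@dataclass
class SAXSDataset:
    """Temperature-stacked SAXS data matrix (rows = temperatures)."""

    D: np.ndarray
    temperatures: np.ndarray
    s: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.s = np.asarray(self.s, dtype=float)
        if self.D.shape != (len(self.temperatures), len(self.s)):
            raise ValueError("D must be (n_temperatures, n_s)")
        if not np.all(np.isfinite(self.D)):
            raise ValueError("D contains non-finite values")


@dataclass
class MCRResult:
    C: np.ndarray                  # (n_temperatures, n_components)
    S: np.ndarray                  # (n_components, n_s)
    R: np.ndarray                  # residuals, D - C @ S
    lack_of_fit: float             # ||R||_F / ||D||_F
    n_iterations: int
    converged: bool
    lof_history: np.ndarray


# ---------------------------------------------------------------------------
# forward computation

def debye_curve(s_obj: Structure, grid: np.ndarray,
                representation: str = "residue_bead",
                scattering_factors: dict[str, float] | None = None) -> SAXSCurve:
    """Debye-formula scattering curve I(s) = sum_ij f_i f_j sinc(s r_ij).

    ``residue_bead`` places one scatterer per residue (first CA if present,
    else the residue centroid); ``heavy_atom`` uses all non-hydrogen atoms.
    Effective scattering factors default to 1 per bead and may be overridden
    per residue name (residue_bead) or element (heavy_atom).
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 0) or np.any(grid > 1.0):
        raise ValueError("grid must lie within [0, 1] 1/A")
    if s_obj.n_atoms < 1:
        raise ValueError("empty structure")

    if representation == "residue_bead":
        coords = []
        keys = []
        for r in s_obj.residue_ids:
            members = np.nonzero(s_obj.residue_index == r)[0]
            names = [s_obj.atom_names[i].strip() for i in members]
            if "CA" in names:
                coords.append(s_obj.coords[members[names.index("CA")]])
            else:
                coords.append(s_obj.coords[members].mean(axis=0))
            keys.append(s_obj.residue_name[members[0]].strip())
        coords = np.asarray(coords)
    elif representation == "heavy_atom":
        mask = s_obj.heavy_mask()
        coords = s_obj.coords[mask]
        keys = [el for el, keep in zip(s_obj.elements, mask) if keep]
    else:
        raise ValueError(f"unknown representation {representation!r}")

    table = scattering_factors or {}
    f = np.array([table.get(k, 1.0) for k in keys], dtype=float)

    n = len(coords)
    intensity = np.empty(len(grid))
    self_term = float(np.sum(f**2))
    if n == 1:
        intensity[:] = self_term
        return SAXSCurve(grid, intensity)
    r = pdist(coords)
    iu, ju = np.triu_indices(n, k=1)
    ff = f[iu] * f[ju]
    for k, s in enumerate(grid):
        x = s * r
        intensity[k] = self_term + 2.0 * np.sum(ff * np.sinc(x / np.pi))
    return SAXSCurve(grid, np.clip(intensity, 0.0, None))


# ---------------------------------------------------------------------------
# Guinier analysis

def guinier_fit(curve: SAXSCurve, limit_factor: float = 1.3,
                max_iter: int = 50) -> GuinierResult:
    """I(0) and Rg from the low-angle linearisation ln I = ln I0 - (Rg^2/3) s^2.

    The admissible range s < limit_factor / Rg is enforced by iterating the
    linear fit until the point selection is self-consistent.
    """
    s, intensity = curve.s, curve.intensity
    n = len(s)
    # seed the iteration from the lowest-angle points only
    use = np.zeros(n, dtype=bool)
    use[: min(n, max(5, n // 10))] = True
    for _ in range(max_iter):
        if use.sum() < 5:
            raise ValueError("fewer than 5 points in the Guinier range")
        if np.any(intensity[use] <= 0):
            raise ValueError("non-positive intensities in the Guinier range")
        x = s[use] ** 2
        y = np.log(intensity[use])
        slope, intercept = np.polyfit(x, y, 1)
        if slope >= 0:
            raise ValueError("non-decreasing low-angle intensity: no Guinier regime")
        rg = float(np.sqrt(-3.0 * slope))
        new_use = s < limit_factor / rg
        if np.array_equal(new_use, use):
            break
        use = new_use
    else:
        raise ValueError("Guinier range iteration did not converge")
    yhat = intercept + slope * x
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return GuinierResult(
        I0=float(np.exp(intercept)),
        Rg=rg,
        s_range_used=(float(s[use].min()), float(s[use].max())),
        n_points_used=int(use.sum()),
        r2=r2,
    )


# ---------------------------------------------------------------------------
# chi fitting

def chi_fit(calc: SAXSCurve, exp: SAXSCurve,
            fractional_error: float = DEFAULT_FRACTIONAL_ERROR,
            ddof: int = 0) -> ChiFit:
    """Error-weighted goodness of fit between a computed and an experimental
    curve: chi = sqrt( min_c sum_i ((I_exp - c I_calc)/sigma)^2 / (n - ddof) ).

    The computed curve is linearly interpolated onto the experimental grid
    restricted to the overlapping s-range (no extrapolation); curves with
    disjoint ranges raise. Experimental curves without sigmas get a uniform
    fractional error (default 7%).
    """
    lo = max(calc.s[0], exp.s[0])
    hi = min(calc.s[-1], exp.s[-1])
    if lo >= hi:
        raise ValueError("curves have disjoint s-ranges")
    keep = (exp.s >= lo) & (exp.s <= hi)
    if keep.sum() < 2:
        raise ValueError("fewer than 2 overlapping grid points")
    s = exp.s[keep]
    i_exp = exp.intensity[keep]
    sigma = exp.effective_sigma(fractional_error)[keep]
    i_calc = np.interp(s, calc.s, calc.intensity)

    w = 1.0 / sigma**2
    denom = float(np.sum(w * i_calc**2))
    if denom == 0:
        raise ValueError("computed curve is zero on the overlap range")
    c = float(np.sum(w * i_exp * i_calc) / denom)
    resid = (i_exp - c * i_calc) / sigma
    n = len(s)
    chi = float(np.sqrt(np.sum(resid**2) / (n - ddof)))
    return ChiFit(chi=chi, scale=c, n_points=n)


# ---------------------------------------------------------------------------
# matrix decomposition

def pca_rank(dataset: SAXSDataset, threshold: float = 0.995) -> int:
    """Number of components needed to reach ``threshold`` cumulative explained
    variance of the (uncentered) data matrix's singular spectrum."""
    d = dataset.D
    if d.shape[0] < 2:
        raise ValueError("need at least 2 temperature rows")
    svals = np.linalg.svd(d, compute_uv=False)
    var = svals**2
    frac = np.cumsum(var) / var.sum()
    return int(np.searchsorted(frac, threshold) + 1)


def _nnls_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Solve min ||a x - b_col|| with x >= 0 for every column of b."""
    out = np.empty((a.shape[1], b.shape[1]))
    for j in range(b.shape[1]):
        out[:, j], _ = nnls(a, b[:, j])
    return out


def _lstsq(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    sol, _, rank, _ = np.linalg.lstsq(a, b, rcond=None)
    if rank < a.shape[1]:
        warnings.warn("rank-deficient least-squares step in MCR-ALS", RuntimeWarning)
    return sol


def _purest_rows(d: np.ndarray, k: int) -> np.ndarray:
    """Indices of k mutually most dissimilar rows (largest residual after
    projecting out the span of the rows already chosen); a SIMPLISMA-style
    pure-variable initialisation."""
    norms = np.linalg.norm(d, axis=1)
    norms[norms == 0] = 1.0
    rows = d / norms[:, None]
    chosen = [int(np.argmax(np.linalg.norm(d, axis=1)))]
    basis = rows[chosen[0]][None, :]
    for _ in range(1, k):
        q, _ = np.linalg.qr(basis.T)
        resid = rows - (rows @ q) @ q.T
        scores = np.linalg.norm(resid, axis=1)
        scores[chosen] = -1.0
        nxt = int(np.argmax(scores))
        chosen.append(nxt)
        basis = np.vstack([basis, rows[nxt]])
    return np.asarray(chosen)


def mcr_als(dataset: SAXSDataset, n_components: int,
            nonneg_C: bool = True, nonneg_S: bool = True, closure_C: bool = True,
            init: str | np.ndarray = "purest", tol: float = 1e-10,
            max_iter: int = 500, seed: int | None = None) -> MCRResult:
    """Multivariate curve resolution by alternating least squares.

    Factorises D ~= C @ S with optional non-negativity on either factor and a
    closure constraint normalising each concentration row to unit sum.
    ``init`` is ``"purest"`` (default: the k mutually most dissimilar data
    rows seed S, which anchors the rotation when near-pure rows exist),
    ``"svd"`` (non-negative projection of the leading singular structure,
    with a seeded random fallback for degenerate rows) or an explicit initial
    S matrix (n_components x n_s). Iteration stops when the relative
    lack-of-fit change drops below ``tol``; non-convergence is flagged on the
    result, not raised.
    """
    d = dataset.D
    n_t, n_s = d.shape
    if not 1 <= n_components <= min(n_t, n_s):
        raise ValueError("n_components must be <= min(n_temperatures, n_s)")
    rng = np.random.default_rng(seed)

    if isinstance(init, np.ndarray):
        s_mat = np.asarray(init, dtype=float).copy()
        if s_mat.shape != (n_components, n_s):
            raise ValueError("provided init must be (n_components, n_s)")
    elif init == "purest":
        s_mat = d[_purest_rows(d, n_components)].copy()
        if nonneg_S:
            s_mat = np.clip(s_mat, 0.0, None)
        for k in range(n_components):
            if not s_mat[k].any():
                s_mat[k] = rng.random(n_s)
    elif init == "svd":
        u, svals, vt = np.linalg.svd(d, full_matrices=False)
        s_mat = vt[:n_components] * svals[:n_components, None]
        # fix sign so each component is predominantly positive, then project
        signs = np.sign(np.sum(s_mat, axis=1))
        signs[signs == 0] = 1.0
        s_mat *= signs[:, None]
        if nonneg_S:
            s_mat = np.clip(s_mat, 0.0, None)
        for k in range(n_components):
            if not s_mat[k].any():
                s_mat[k] = rng.random(n_s)
    else:
        raise ValueError(f"unknown init {init!r}")

    d_norm = np.linalg.norm(d)
    lof_hist: list[float] = []
    converged = False
    c_mat = np.zeros((n_t, n_components))
    it = 0
    for it in range(1, max_iter + 1):
        # solve C given S
        if nonneg_C:
            c_mat = _nnls_rows(s_mat.T, d.T).T
        else:
            c_mat = _lstsq(s_mat.T, d.T).T
        if closure_C:
            row_sums = c_mat.sum(axis=1)
            row_sums[row_sums <= 0] = 1.0
            c_mat = c_mat / row_sums[:, None]
        # solve S given C
        if nonneg_S:
            s_mat = _nnls_rows(c_mat, d)
        else:
            s_mat = _lstsq(c_mat, d)
        resid = d - c_mat @ s_mat
        lof = float(np.linalg.norm(resid) / d_norm)
        lof_hist.append(lof)
        if lof < 1e-14 or (
            len(lof_hist) > 1
            and abs(lof_hist[-2] - lof) <= tol * max(lof_hist[-2], 1e-300)
        ):
            converged = True
            break
    resid = d - c_mat @ s_mat
    return MCRResult(
        C=c_mat,
        S=s_mat,
        R=resid,
        lack_of_fit=float(np.linalg.norm(resid) / d_norm),
        n_iterations=it,
        converged=converged,
        lof_history=np.asarray(lof_hist),
    )


def match_components(estimated: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Permutation of estimated component rows best matching ``truth`` rows by
    cosine similarity (used to resolve MCR permutation ambiguity in tests)."""
    from itertools import permutations

    k = truth.shape[0]

    def unit(m):
        n = np.linalg.norm(m, axis=1, keepdims=True)
        n[n == 0] = 1.0
        return m / n

    e, t = unit(estimated), unit(truth)
    sim = t @ e.T
    best, best_score = None, -np.inf
    for perm in permutations(range(k)):
        score = sum(sim[i, perm[i]] for i in range(k))
        if score > best_score:
            best, best_score = perm, score
    return np.asarray(best)
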