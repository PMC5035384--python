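"""Generalized Procrustes analysis, semilandmark sliding, relative warps
and thin-plate-spline deformation grids for 2-D landmark configurations.

The alignment removes position, orientation and scale (partial
Procrustes: every configuration is scaled to unit centroid size), with
rotations restricted to proper rotations — specimens are assumed to be
digitized in a consistent orientation, so reflections are disallowed.

Semilandmarks, when a slider table is supplied, slide along the chord
between their neighbouring landmarks so as to minimize the bending
energy of the thin-plate spline mapping the consensus onto each
specimen; sliding and re-superimposition are interleaved until the
consensus stabilizes.

Relative warps are computed with weighting exponent alpha = 0 and the
uniform (affine) component included, which makes them exactly the
principal components of the Procrustes-aligned coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import LandmarkSet, SliderTable

__all__ = [
    "centroid_size",
    "GeneralizedProcrustes",
    "ProcrustesResults",
    "ShapeScores",
    "relative_warps",
    "bending_energy_matrix",
    "bending_energy",
    "tps_deformation_grid",
    "shape_at_score",
]


def centroid_size(config: np.ndarray) -> float | np.ndarray:
    """Centroid size: sqrt of summed squared landmark distances from the
    configuration centroid.

    Accepts a single (k, 2) configuration or a stack (n, k, 2); returns
    a scalar or a length-n vector accordingly. Translation- and
    rotation-invariant; scales linearly with the configuration.
    """
    config = np.asarray(config, dtype=float)
    single = config.ndim == 2
    if single:
        config = config[None]
    centered = config - config.mean(axis=1, keepdims=True)
    cs = np.sqrt((centered**2).sum(axis=(1, 2)))
    if np.any(cs <= 0):
        raise ValueError("degenerate configuration: all landmarks coincident")
    return float(cs[0]) if single else cs


def _optimal_rotation(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Proper rotation R minimizing ||x @ R - y||_F for centered x, y."""
    h = x.T @ y
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, d]) @ vt


def _center_and_scale(configs: np.ndarray) -> np.ndarray:
    centered = configs - configs.mean(axis=1, keepdims=True)
    cs = np.sqrt((centered**2).sum(axis=(1, 2), keepdims=True))
    if np.any(cs <= 0):
        raise ValueError("degenerate specimen: zero centroid size")
    return centered / cs


@dataclass
class ProcrustesResults:
    """Output of a generalized Procrustes fit.

    Attributes
    ----------
    aligned : ndarray, shape (n, k, 2)
        Superimposed configurations at unit centroid size.
    consensus : ndarray, shape (k, 2)
        Mean configuration, centred at the origin with centroid size 1.
    centroid_sizes : ndarray, shape (n,)
        Original per-specimen centroid sizes (digitizer units).
    n_iterations : int
        GPA iterations used in the final superimposition pass.
    converged : bool
    slid : bool
        Whether semilandmark sliding was applied.
    """

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    n_iterations: int
    converged: bool
    slid: bool = False
    specimen_ids: list | None = None

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def k(self) -> int:
        return self.aligned.shape[1]

    def procrustes_variance(self) -> float:
        """Total summed squared deviation from the consensus / (n - 1)."""
        dev = self.aligned - self.consensus
        return float((dev**2).sum() / (self.n_specimens - 1))

    def relative_warps(self) -> "ShapeScores":
        return relative_warps(self)


class GeneralizedProcrustes:
    """Generalized Procrustes superimposition model.

    Parameters
    ----------
    landmarks : LandmarkSet or ndarray (n, k, 2)
    sliders : SliderTable, optional
        Semilandmark definitions; when given, sliding steps that
        minimize thin-plate-spline bending energy against the consensus
        are interleaved with re-superimposition.

    Examples
    --------
    >>> fit = GeneralizedProcrustes(landmark_set, sliders).fit()
    >>> scores = fit.relative_warps()
    """

    def __init__(self, landmarks, sliders: SliderTable | None = None):
        if isinstance(landmarks, LandmarkSet):
            self.coords = np.asarray(landmarks.coords, dtype=float)
            self.specimen_ids = list(landmarks.specimen_ids)
        else:
            self.coords = np.asarray(landmarks, dtype=float)
            self.specimen_ids = None
        if self.coords.ndim != 3 or self.coords.shape[2] != 2:
            raise ValueError("landmarks must have shape (n, k, 2)")
        if self.coords.shape[0] < 1:
            raise ValueError("need at least one specimen")
        self.sliders = sliders
        if sliders is not None:
            sliders.validate(self.coords.shape[1])

    def fit(
        self,
        tol: float = 1e-8,
        max_iter: int = 100,
        slide_cycles: int = 5,
        slide_tol: float = 1e-6,
    ) -> ProcrustesResults:
        """Run the superimposition (and sliding, if sliders were given).

        The plain GPA iterates centre/scale/rotate-to-consensus and
        consensus updates until the relative change of the consensus
        falls below ``tol`` (cap ``max_iter``). With sliders, up to
        ``slide_cycles`` slide/re-superimpose cycles run, stopping when
        the consensus moves by less than ``slide_tol`` between cycles.
        """
        cs = centroid_size(self.coords)
        cs = np.atleast_1d(cs)
        aligned, consensus, n_iter, converged = _gpa(self.coords, tol, max_iter)
        slid = False
        if self.sliders is not None and self.sliders.n_sliders > 0:
            for _ in range(slide_cycles):
                prev = consensus
                aligned = _slide_semilandmarks(aligned, consensus, self.sliders)
                aligned, consensus, n_iter, converged = _gpa(aligned, tol, max_iter)
                slid = True
                if np.linalg.norm(consensus - prev) < slide_tol:
                    break
        return ProcrustesResults(
            aligned=aligned,
            consensus=consensus,
            centroid_sizes=cs,
            n_iterations=n_iter,
            converged=converged,
            slid=slid,
            specimen_ids=self.specimen_ids,
        )


def _gpa(configs: np.ndarray, tol: float, max_iter: int):
    """Core GPA loop. Returns (aligned, consensus, n_iter, converged)."""
    x = _center_and_scale(configs)
    n = x.shape[0]
    if n == 1:
        return x, x[0].copy(), 0, True
    consensus = x[0].copy()
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for i in range(n):
            x[i] = x[i] @ _optimal_rotation(x[i], consensus)
        new_consensus = x.mean(axis=0)
        new_consensus -= new_consensus.mean(axis=0)
        new_consensus /= np.sqrt((new_consensus**2).sum())
        change = np.linalg.norm(new_consensus - consensus)
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"generalized Procrustes did not converge in {max_iter} iterations "
            f"(last consensus change {change:.3e})"
        )
    # final rotation pass, then fix the output convention: consensus is
    # the mean of the aligned configurations, rescaled (together with
    # the configurations) so the consensus has exactly unit centroid
    # size. Specimen CS then sits within O(shape variance) of 1.
    for i in range(n):
        x[i] = x[i] @ _optimal_rotation(x[i], consensus)
    mean_config = x.mean(axis=0)
    c = np.sqrt((mean_config**2).sum())
    x /= c
    consensus = mean_config / c
    return x, consensus, it, converged


# ---------------------------------------------------------------------------
# Thin-plate spline machinery (shared by sliding, deformation grids and
# the bending-energy quadratic form)
# ---------------------------------------------------------------------------


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r^2, with U(0) = 0 (2-D biharmonic kernel)."""
    out = np.zeros_like(r2)
    pos = r2 > 0
    out[pos] = r2[pos] * np.log(r2[pos])
    return out


def _tps_system(points: np.ndarray) -> np.ndarray:
    """Full (k+3, k+3) TPS system matrix [[K, P], [P^T, 0]]."""
    k = points.shape[0]
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    kmat = _tps_kernel(d2)
    p = np.column_stack([np.ones(k), points])
    full = np.zeros((k + 3, k + 3))
    full[:k, :k] = kmat
    full[:k, k:] = p
    full[k:, :k] = p.T
    return full


def bending_energy_matrix(reference: np.ndarray) -> np.ndarray:
    """Bending-energy matrix of a reference configuration.

    The upper-left k x k block of the inverse TPS system matrix. For a
    displacement field v (per coordinate axis), v^T B v is proportional
    to the integral bending energy of the thin-plate spline carrying
    the reference onto reference + v. B annihilates affine fields.
    """
    reference = np.asarray(reference, dtype=float)
    k = reference.shape[0]
    full = _tps_system(reference)
    try:
        inv = np.linalg.inv(full)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular TPS system: coincident landmarks in reference"
        ) from exc
    b = inv[:k, :k]
    return (b + b.T) / 2.0


def bending_energy(reference: np.ndarray, target: np.ndarray) -> float:
    """Bending energy of the TPS deformation reference -> target."""
    b = bending_energy_matrix(reference)
    v = np.asarray(target, dtype=float) - np.asarray(reference, dtype=float)
    return float(v[:, 0] @ b @ v[:, 0] + v[:, 1] @ b @ v[:, 1])


def _slide_semilandmarks(
    aligned: np.ndarray, consensus: np.ndarray, sliders: SliderTable
) -> np.ndarray:
    """Slide each specimen's semilandmarks along neighbour chords to
    minimize bending energy relative to the consensus."""
    n, k, _ = aligned.shape
    b = bending_energy_matrix(consensus)
    e = np.zeros((2 * k, 2 * k))
    e[:k, :k] = b
    e[k:, k:] = b
    out = aligned.copy()
    idx_before = sliders.triples[:, 0]
    idx_slider = sliders.triples[:, 1]
    idx_after = sliders.triples[:, 2]
    s = sliders.n_sliders
    for i in range(n):
        spec = out[i]
        chords = spec[idx_after] - spec[idx_before]
        norms = np.linalg.norm(chords, axis=1)
        norms[norms == 0] = 1.0
        tangents = chords / norms[:, None]
        u = np.zeros((2 * k, s))
        u[idx_slider, np.arange(s)] = tangents[:, 0]
        u[k + idx_slider, np.arange(s)] = tangents[:, 1]
        v = np.concatenate([spec[:, 0] - consensus[:, 0], spec[:, 1] - consensus[:, 1]])
        a = u.T @ e @ u
        rhs = -u.T @ e @ v
        t = np.linalg.solve(a + 1e-12 * np.eye(s), rhs)
        spec = spec.copy()
        spec[idx_slider, 0] += t * tangents[:, 0]
        spec[idx_slider, 1] += t * tangents[:, 1]
        out[i] = spec
    return out


# ---------------------------------------------------------------------------
# Relative warps
# ---------------------------------------------------------------------------


@dataclass
class ShapeScores:
    """Relative-warp (principal component) decomposition of aligned shapes.

    ``scores[i, j]`` is specimen i's score on relative warp j (RW1 is
    column 0). ``loadings[j]`` is the j-th component direction in the
    flattened 2k-dimensional shape space (x, y interleaved per
    landmark); reshape to (k, 2) for a landmark-wise displacement field.
    """

    scores: np.ndarray  # (n, c)
    eigenvalues: np.ndarray  # (c,)
    pct_variance: np.ndarray  # (c,)
    loadings: np.ndarray  # (c, 2k)
    consensus: np.ndarray  # (k, 2)

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    def n_nondegenerate(self, rtol: float = 1e-9) -> int:
        """Components whose variance exceeds rtol x the largest.

        For k 2-D landmarks after Procrustes alignment this is at most
        2k - 4 (translation, rotation and scale are removed).
        """
        if self.eigenvalues.size == 0:
            return 0
        return int(np.sum(self.eigenvalues > rtol * self.eigenvalues[0]))


def _similarity_basis(consensus: np.ndarray) -> np.ndarray:
    """Orthonormal basis (4, 2k) of the similarity directions at the
    consensus: x/y translation, infinitesimal rotation, and scaling."""
    k = consensus.shape[0]
    tx = np.tile([1.0, 0.0], k)
    ty = np.tile([0.0, 1.0], k)
    rot = np.column_stack([-consensus[:, 1], consensus[:, 0]]).ravel()
    scl = consensus.ravel()
    basis = np.array([tx, ty, rot, scl])
    q, _ = np.linalg.qr(basis.T)
    return q.T


def relative_warps(fit: ProcrustesResults) -> ShapeScores:
    """Principal components of the Procrustes-aligned coordinates.

    Uniform and non-uniform shape variation enter together (alpha = 0),
    so relative warps coincide with ordinary PCA about the consensus.
    Component signs are fixed by making each loading's largest-magnitude
    entry positive; eigenvalues (score variances, n-1 denominator) are
    sorted in decreasing order.
    """
    n, k, _ = fit.aligned.shape
    if n < 3:
        raise ValueError("relative warps require at least 3 specimens")
    flat = fit.aligned.reshape(n, 2 * k)
    centered = flat - flat.mean(axis=0)
    # project into the shape tangent space at the consensus: aligned
    # configurations sit on the unit-size/rotation-aligned manifold, so
    # second-order leakage into the 4 similarity directions remains
    # after superimposition; removing it leaves exactly 2k - 4 dims
    basis = _similarity_basis(fit.consensus)
    centered = centered - (centered @ basis.T) @ basis
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    # deterministic sign: largest-|loading| entry positive
    for j in range(vt.shape[0]):
        jmax = np.argmax(np.abs(vt[j]))
        if vt[j, jmax] < 0:
            vt[j] = -vt[j]
            u[:, j] = -u[:, j]
    scores = u * s
    total = eigenvalues.sum()
    pct = 100.0 * eigenvalues / total if total > 0 else np.zeros_like(eigenvalues)
    return ShapeScores(
        scores=scores,
        eigenvalues=eigenvalues,
        pct_variance=pct,
        loadings=vt,
        consensus=fit.consensus.copy(),
    )


def shape_at_score(
    scores: ShapeScores, component: int, score_value: float
) -> np.ndarray:
    """Synthetic configuration at a given score along one relative warp:
    consensus + score x loading, reshaped to (k, 2). Used for the
    positive/negative deformation insets on score histograms."""
    if not 0 <= component < scores.n_components:
        raise IndexError(
            f"component {component} out of range [0, {scores.n_components})"
        )
    k = scores.consensus.shape[0]
    displacement = score_value * scores.loadings[component]
    return scores.consensus + displacement.reshape(k, 2)


def tps_deformation_grid(
    consensus: np.ndarray,
    target: np.ndarray,
    grid_size: int = 24,
    margin: float = 0.15,
):
    """Thin-plate-spline deformation grid mapping consensus -> target.

    Solves the exact-interpolation TPS (one spline per coordinate axis)
    and evaluates it on a rectangular grid spanning the consensus
    bounding box (padded by ``margin`` of its extent).

    Returns
    -------
    (grid_x, grid_y) : ndarrays, shape (grid_size, grid_size)
        Warped grid-line positions, suitable for pcolormesh/line plots.
    """
    consensus = np.asarray(consensus, dtype=float)
    target = np.asarray(target, dtype=float)
    if consensus.shape != target.shape:
        raise ValueError("consensus and target must share the same landmarks")
    k = consensus.shape[0]
    full = _tps_system(consensus)
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = target
    try:
        coefs = np.linalg.solve(full, rhs)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular TPS system: coincident landmarks in consensus"
        ) from exc
    lo = consensus.min(axis=0)
    hi = consensus.max(axis=0)
    pad = margin * (hi - lo)
    gx, gy = np.meshgrid(
        np.linspace(lo[0] - pad[0], hi[0] + pad[0], grid_size),
        np.linspace(lo[1] - pad[1], hi[1] + pad[1], grid_size),
    )
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    warped = _tps_evaluate(consensus, coefs, pts)
    return warped[:, 0].reshape(gx.shape), warped[:, 1].reshape(gy.shape)


def _tps_evaluate(
    knots: np.ndarray, coefs: np.ndarray, points: np.ndarray
) -> np.ndarray:
    d2 = ((points[:, None, :] - knots[None, :, :]) ** 2).sum(-1)
    kmat = _tps_kernel(d2)
    p = np.column_stack([np.ones(points.shape[0]), points])
    k = knots.shape[0]
    return kmat @ coefs[:k] + p @ coefs[k:]
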