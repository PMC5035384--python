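"""Nonparametric fitness-surface visualization.

Penalized thin-plate-spline smoothing of relative fitness over pairs of
canonical axes (or any two predictors), with the smoothing parameter
chosen by generalized cross-validation:

    GCV(lam) = n * RSS(lam) / (n - tr(H(lam)))^2

where H is the smoother ("hat") matrix. The surfaces are descriptive —
perspective plots of where fitness is high or low over the axes of
strongest nonlinear selection — and carry no inference.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .morphometry import _tps_kernel

__all__ = ["SmoothSurface", "fit_tps_surface", "surface_plot", "evaluate_surface"]


@dataclass
class SmoothSurface:
    """A fitted penalized thin-plate-spline surface over two predictors."""

    knots: np.ndarray  # (m, 2) unique predictor points
    c: np.ndarray  # kernel coefficients (m,)
    d: np.ndarray  # affine coefficients (3,)
    smoothing: float
    gcv: float
    gcv_path: np.ndarray | None  # (n_lambda, 2): lambda, GCV
    fitted: np.ndarray  # fitted values at knots
    grid_x: np.ndarray
    grid_y: np.ndarray
    grid_z: np.ndarray

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return evaluate_surface(self, points)


def evaluate_surface(surface: SmoothSurface, points: np.ndarray) -> np.ndarray:
    points = np.atleast_2d(np.asarray(points, dtype=float))
    d2 = ((points[:, None, :] - surface.knots[None, :, :]) ** 2).sum(-1)
    kmat = _tps_kernel(d2)
    p = np.column_stack([np.ones(points.shape[0]), points])
    return kmat @ surface.c + p @ surface.d


def _aggregate_duplicates(x: np.ndarray, w: np.ndarray):
    """Average fitness over duplicated predictor points (multiplicity-
    weighted mean); returns unique points and their mean response."""
    uniq, inverse = np.unique(x, axis=0, return_inverse=True)
    if uniq.shape[0] == x.shape[0]:
        return x, w
    sums = np.zeros(uniq.shape[0])
    counts = np.zeros(uniq.shape[0])
    np.add.at(sums, inverse, w)
    np.add.at(counts, inverse, 1)
    return uniq, sums / counts


def fit_tps_surface(
    x: np.ndarray,
    w: np.ndarray,
    smoothing="gcv",
    n_lambda: int = 40,
    lambda_span: tuple[float, float] = (1e-6, 1e3),
    grid_size: int = 30,
) -> SmoothSurface:
    """Fit a penalized thin-plate spline of fitness over two predictors.

    Parameters
    ----------
    x : (n, 2) predictor scores (e.g. two canonical axes).
    w : (n,) relative fitness.
    smoothing : "gcv" or a non-negative float.
        With "gcv", ``n_lambda`` log-spaced candidates spanning
        ``lambda_span`` times a data-scale normalization are searched
        and the GCV minimizer kept. 0 gives exact interpolation.
    grid_size : resolution of the evaluation grid for plotting.

    Notes
    -----
    Solves (K + n*lam*I) c + P d = w, P'c = 0 via a null-space QR
    reduction and a single eigendecomposition, so the whole GCV path
    costs one O(m^3) factorization. Duplicate predictor points are
    replaced by their multiplicity-weighted mean fitness first.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("x must be (n, 2)")
    if x.shape[0] != w.shape[0]:
        raise ValueError("x and w length mismatch")
    x, w = _aggregate_duplicates(x, w)
    m = x.shape[0]
    if m < 6:
        raise ValueError(f"need at least 6 distinct points, got {m}")

    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
    kmat = _tps_kernel(d2)
    pmat = np.column_stack([np.ones(m), x])
    if np.linalg.matrix_rank(pmat) < 3:
        raise ValueError("all points collinear; surface is degenerate")

    # null-space reduction: c = Q2 g with P' Q2 = 0
    q, _ = np.linalg.qr(pmat, mode="complete")
    q2 = q[:, 3:]
    b = q2.T @ kmat @ q2
    b = (b + b.T) / 2.0
    evals, evecs = np.linalg.eigh(b)
    evals = np.clip(evals, 0.0, None)  # conditionally PSD kernel; clip rounding
    rhs = evecs.T @ (q2.T @ w)

    scale = max(evals.mean(), np.finfo(float).tiny)

    def solve(lam_abs: float):
        g = evecs @ (rhs / (evals + lam_abs))
        c = q2 @ g
        # residual identity: w - fitted = lam_abs * c
        resid = lam_abs * c
        rss = float(resid @ resid)
        edf_resid = lam_abs * np.sum(1.0 / (evals + lam_abs))  # tr(I - H)
        return c, rss, edf_resid

    gcv_path = None
    if isinstance(smoothing, str):
        if smoothing != "gcv":
            raise ValueError("smoothing must be 'gcv' or a float")
        lams = np.geomspace(lambda_span[0], lambda_span[1], n_lambda) * scale
        best = None
        path = []
        for lam in lams:
            _, rss, tr_imh = solve(m * lam)
            gcv = m * rss / tr_imh**2 if tr_imh > 0 else np.inf
            path.append((lam, gcv))
            if best is None or gcv < best[1]:
                best = (lam, gcv)
        lam_sel, gcv_sel = best
        gcv_path = np.array(path)
        c, rss, tr_imh = solve(m * lam_sel)
    else:
        lam_sel = float(smoothing)
        if lam_sel < 0:
            raise ValueError("smoothing must be non-negative")
        if lam_sel == 0:
            # exact interpolation
            full = np.zeros((m + 3, m + 3))
            full[:m, :m] = kmat
            full[:m, m:] = pmat
            full[m:, :m] = pmat.T
            rhs_full = np.concatenate([w, np.zeros(3)])
            sol = np.linalg.solve(full, rhs_full)
            c, d = sol[:m], sol[m:]
            fitted = kmat @ c + pmat @ d
            surface = SmoothSurface(
                knots=x, c=c, d=d, smoothing=0.0, gcv=0.0, gcv_path=None,
                fitted=fitted, grid_x=np.empty(0), grid_y=np.empty(0),
                grid_z=np.empty(0),
            )
            _attach_grid(surface, grid_size)
            return surface
        c, rss, tr_imh = solve(m * lam_sel)
        gcv_sel = m * rss / tr_imh**2 if tr_imh > 0 else np.inf

    # affine part: P d = w - (K + m*lam*I) c, solved in least squares
    d, _, _, _ = np.linalg.lstsq(pmat, w - kmat @ c - m * lam_sel * c, rcond=None)
    fitted = kmat @ c + pmat @ d
    surface = SmoothSurface(
        knots=x, c=c, d=d, smoothing=float(lam_sel), gcv=float(gcv_sel),
        gcv_path=gcv_path, fitted=fitted,
        grid_x=np.empty(0), grid_y=np.empty(0), grid_z=np.empty(0),
    )
    _attach_grid(surface, grid_size)
    return surface


def _attach_grid(surface: SmoothSurface, grid_size: int) -> None:
    lo = surface.knots.min(axis=0)
    hi = surface.knots.max(axis=0)
    gx, gy = np.meshgrid(
        np.linspace(lo[0], hi[0], grid_size), np.linspace(lo[1], hi[1], grid_size)
    )
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    gz = evaluate_surface(surface, pts).reshape(gx.shape)
    surface.grid_x, surface.grid_y, surface.grid_z = gx, gy, gz


def surface_plot(
    surface: SmoothSurface,
    path: str,
    xlabel: str = "axis 1",
    ylabel: str = "axis 2",
    zlabel: str = "relative fitness",
    elev: float = 30.0,
    azim: float = -60.0,
    cmap: str = "viridis",
) -> None:
    """Perspective-view rendering of a fitted surface, written to file."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="3d")
    ax.plot_surface(
        surface.grid_x, surface.grid_y, surface.grid_z,
        cmap=cmap, linewidth=0.2, edgecolor="k", alpha=0.9,
    )
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.set_zlabel(zlabel)
    ax.view_init(elev=elev, azim=azim)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
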