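"""Canonical analysis of the nonlinear selection gradient matrix.

The symmetric gamma matrix is rotated to its eigenbasis (the M matrix,
rows m_i), locating the major axes of nonlinear selection: lambda_i
(the eigenvalue) measures curvature along m_i (negative = stabilizing,
positive = disruptive) and theta_i measures directional selection along
the same axis.

theta_i and regression-based lambda_i come from a "double regression":
the standardized traits are rotated into canonical scores y = z M' and
relative fitness is regressed on all y_i and y_i^2 jointly (no
cross-products of distinct canonical axes — gamma is diagonal in this
frame by construction). Eigenvalue significance uses a rank-matched
permutation procedure: every shuffled replicate re-estimates and
re-diagonalizes its own gamma, and the observed i-th ranked eigenvalue
is referred to the permutation distribution of i-th ranked eigenvalues,
so the order-statistic extremity of the leading and trailing axes is
built into the null (see eigen_permutation_test).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .selection import DEFAULT_N_PERM, _ols, _permute_columns, quadratic_design

__all__ = [
    "canonical_decompose",
    "double_regression",
    "eigen_permutation_test",
    "CanonicalAnalysis",
    "CanonicalResults",
]


def canonical_decompose(gamma: np.ndarray, atol: float = 1e-8):
    """Eigendecomposition of gamma with deterministic conventions.

    Returns (M, lam): rows of M are unit eigenvectors m_i ordered by
    decreasing signed eigenvalue, each with its largest-magnitude
    loading made positive. M @ gamma @ M.T is diagonal with entries lam,
    and lam sums to trace(gamma).
    """
    gamma = np.asarray(gamma, dtype=float)
    if gamma.ndim != 2 or gamma.shape[0] != gamma.shape[1]:
        raise ValueError("gamma must be square")
    if not np.allclose(gamma, gamma.T, atol=atol):
        raise ValueError("gamma is not symmetric within tolerance")
    gamma = (gamma + gamma.T) / 2.0
    lam, vec = np.linalg.eigh(gamma)
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    m = vec[:, order].T
    for i in range(m.shape[0]):
        jmax = np.argmax(np.abs(m[i]))
        if m[i, jmax] < 0:
            m[i] = -m[i]
    return m, lam


def _canonical_design(z: np.ndarray, m: np.ndarray):
    """Design for the double regression: [1, y_1..y_p, y_1^2..y_p^2]."""
    y = z @ m.T
    return np.column_stack([np.ones(z.shape[0]), y, y**2])


def double_regression(z: np.ndarray, w: np.ndarray, m: np.ndarray):
    """Per-axis linear (theta) and quadratic (lambda) gradients.

    Fits relative fitness on the canonical scores and their squares
    jointly. Returns (theta, lam_reg, theta_se, lam_se); quadratic
    coefficients and their SEs are doubled, matching the gamma
    convention, so lam_reg equals the eigenvalues of the fitted gamma
    when the fitness surface is exactly quadratic.
    """
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    m = np.asarray(m, dtype=float)
    if m.shape[1] != z.shape[1]:
        raise ValueError("M and traits dimension mismatch")
    p = m.shape[0]
    x = _canonical_design(z, m)
    coefs, se, _ = _ols(x, w)
    theta = coefs[1 : 1 + p]
    lam_reg = 2.0 * coefs[1 + p :]
    return theta, lam_reg, se[1 : 1 + p], 2.0 * se[1 + p :]


def _gamma_from_second_order(coefs: np.ndarray, p: int) -> np.ndarray:
    gamma = np.zeros((p, p))
    np.fill_diagonal(gamma, 2.0 * coefs[1 + p : 1 + 2 * p])
    pos = 1 + 2 * p
    for j in range(p):
        for l in range(j + 1, p):
            gamma[j, l] = gamma[l, j] = coefs[pos]
            pos += 1
    return gamma


def eigen_permutation_test(
    z: np.ndarray,
    w: np.ndarray,
    m: np.ndarray | None = None,
    n_perm: int = DEFAULT_N_PERM,
    seed=None,
):
    """Rank-matched permutation p-values for each lambda_i (and theta_i).

    Fitness is shuffled across individuals and, for every replicate,
    the full second-order model is refitted, the replicate's gamma
    matrix rebuilt and re-diagonalized, and its ORDERED eigenvalues
    (with the per-axis rotated linear gradients) retained. The observed
    i-th ranked eigenvalue is then compared with the permutation
    distribution of i-th ranked eigenvalues. Rank matching is essential
    for size: the extreme eigenvalues of an estimated gamma are extreme
    order statistics even under no selection, so comparing them against
    fixed-axis permuted coefficients (rotation held fixed) grossly
    inflates the type-I error of the leading/trailing axes.

    Two-tailed p with the add-one correction, as in
    selection.permutation_test. Returns (p_lambda, p_theta).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    n, p = z.shape
    x2, _ = quadratic_design(z)
    piv = np.linalg.pinv(x2)
    obs_coefs = piv @ w
    gamma_obs = _gamma_from_second_order(obs_coefs, p)
    m_obs, lam_obs = canonical_decompose(gamma_obs)
    theta_obs = m_obs @ obs_coefs[1 : 1 + p]

    rng = np.random.default_rng(seed)
    r_le_lam = np.zeros(p)
    r_ge_lam = np.zeros(p)
    r_le_th = np.zeros(p)
    r_ge_th = np.zeros(p)
    for wm in _permute_columns(w, n_perm, rng):
        perm_coefs = piv @ wm  # (q, block)
        for b in range(perm_coefs.shape[1]):
            gamma_b = _gamma_from_second_order(perm_coefs[:, b], p)
            m_b, lam_b = canonical_decompose(gamma_b)
            theta_b = m_b @ perm_coefs[1 : 1 + p, b]
            r_le_lam += lam_b <= lam_obs
            r_ge_lam += lam_b >= lam_obs
            r_le_th += theta_b <= theta_obs
            r_ge_th += theta_b >= theta_obs

    def two_tailed(r_le, r_ge):
        return np.minimum(
            2.0 * np.minimum(r_le + 1, r_ge + 1) / (n_perm + 1), 1.0
        )

    return two_tailed(r_le_lam, r_ge_lam), two_tailed(r_le_th, r_ge_th)


@dataclass
class CanonicalResults:
    """Canonical rotation of gamma with per-axis gradients.

    ``m[i]`` is the i-th eigenvector (loadings over the original
    traits); ``lam`` the eigenvalues of gamma (reported lambda);
    ``lam_reg`` the double-regression re-estimates; ``theta`` the
    linear gradient along each axis.
    """

    trait_names: list[str]
    m: np.ndarray
    lam: np.ndarray
    theta: np.ndarray
    theta_se: np.ndarray
    lam_reg: np.ndarray
    lam_se: np.ndarray
    p_lambda: np.ndarray | None
    p_theta: np.ndarray | None
    n: int
    n_perm: int
    ordering: str = "descending-eigenvalue"

    @property
    def n_axes(self) -> int:
        return self.m.shape[0]

    def table(self) -> pd.DataFrame:
        """M-matrix layout: one row per axis with loadings, theta, lambda."""
        df = pd.DataFrame(
            self.m,
            index=[f"m{i + 1}" for i in range(self.n_axes)],
            columns=self.trait_names,
        )
        df["theta"] = self.theta
        df["lambda"] = self.lam
        if self.p_theta is not None:
            df["p_theta"] = self.p_theta
            df["p_lambda"] = self.p_lambda
        return df

    def summary(self) -> str:
        def stars(pv):
            if pv is None or np.isnan(pv):
                return ""
            return "***" if pv < 0.001 else "**" if pv < 0.01 else "*" if pv < 0.05 else ""

        title = "Canonical analysis of gamma"
        lines = [title, "=" * len(title), f"n = {self.n}, permutations = {self.n_perm}", ""]
        header = f"{'axis':>5}" + "".join(f"{t:>9}" for t in self.trait_names)
        header += f"{'theta':>9}{'lambda':>9}"
        lines.append(header)
        for i in range(self.n_axes):
            row = f"{'m' + str(i + 1):>5}"
            row += "".join(f"{v:>9.3f}" for v in self.m[i])
            st = stars(self.p_theta[i]) if self.p_theta is not None else ""
            sl = stars(self.p_lambda[i]) if self.p_lambda is not None else ""
            row += f"{self.theta[i]:>8.3f}{st:<1}{self.lam[i]:>8.3f}{sl:<1}"
            lines.append(row)
        lines.append("")
        lines.append(f"sum(lambda) = {self.lam.sum():.3f} = trace(gamma)")
        if self.p_lambda is not None:
            lines.append("(* p<0.05, ** p<0.01, *** p<0.001; permutation test)")
        return "\n".join(lines)


class CanonicalAnalysis:
    """Canonical analysis model: rotate gamma, then double regression.

    Parameters
    ----------
    z, w : standardized traits and relative fitness.
    gamma : the estimated gamma matrix. If None it is re-estimated from
        (z, w) via the full second-order model.
    """

    def __init__(self, z, w, gamma=None, trait_names=None):
        self.z = np.asarray(z, dtype=float)
        self.w = np.asarray(w, dtype=float)
        if gamma is None:
            from .selection import quadratic_gradients

            gamma, _, _ = quadratic_gradients(self.z, self.w)
        self.gamma = np.asarray(gamma, dtype=float)
        p = self.z.shape[1]
        self.trait_names = (
            list(trait_names) if trait_names is not None
            else [f"z{j + 1}" for j in range(p)]
        )

    def fit(self, n_perm: int = DEFAULT_N_PERM, seed=None) -> CanonicalResults:
        m, lam = canonical_decompose(self.gamma)
        theta, lam_reg, theta_se, lam_se = double_regression(self.z, self.w, m)
        p_lambda = p_theta = None
        if n_perm and n_perm > 0:
            p_lambda, p_theta = eigen_permutation_test(
                self.z, self.w, m, n_perm=n_perm, seed=seed
            )
        return CanonicalResults(
            trait_names=self.trait_names,
            m=m,
            lam=lam,
            theta=theta,
            theta_se=theta_se,
            lam_reg=lam_reg,
            lam_se=lam_se,
            p_lambda=p_lambda,
            p_theta=p_theta,
            n=self.z.shape[0],
            n_perm=n_perm if n_perm else 0,
        )
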