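"""Lande–Arnold selection-gradient estimation with permutation inference.

Directional selection gradients (beta) come from the first-order
regression of relative fitness on standardized traits; quadratic and
correlational gradients (gamma) come from the full second-order model
fitted jointly, with the quadratic coefficients doubled so the diagonal
of gamma is on the stabilizing/disruptive scale (fitness surface
w = a + beta'z + 1/2 z'gamma z).

Significance is assessed by randomization: fitness values are shuffled
across individuals, the model refitted, and a two-tailed p-value per
coefficient computed with the add-one small-sample correction. Ordinary
least squares is used throughout, including for binary mating success —
the gradients of the Lande–Arnold framework are OLS quantities; a
logistic fit is available as a diagnostic only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "standardize",
    "relative_fitness",
    "quadratic_design",
    "linear_gradients",
    "quadratic_gradients",
    "permutation_test",
    "logistic_diagnostic",
    "SelectionGradientModel",
    "SelectionGradientResults",
]

DEFAULT_N_PERM = 9999


def standardize(traits, ddof: int = 1):
    """Centre each trait to mean 0 and scale to unit variance.

    Uses the sample standard deviation (n-1 denominator) by default.
    Idempotent; leaves the trait correlation matrix unchanged.
    """
    if isinstance(traits, pd.DataFrame):
        arr = traits.to_numpy(dtype=float)
        sd = arr.std(axis=0, ddof=ddof)
        zero = np.flatnonzero(sd == 0)
        if zero.size:
            names = [traits.columns[j] for j in zero]
            raise ValueError(f"zero-variance trait(s), cannot standardize: {names}")
        z = (arr - arr.mean(axis=0)) / sd
        return pd.DataFrame(z, index=traits.index, columns=traits.columns)
    arr = np.asarray(traits, dtype=float)
    one_d = arr.ndim == 1
    if one_d:
        arr = arr[:, None]
    sd = arr.std(axis=0, ddof=ddof)
    if np.any(sd == 0):
        raise ValueError(f"zero-variance trait column(s): {np.flatnonzero(sd == 0)}")
    z = (arr - arr.mean(axis=0)) / sd
    return z[:, 0] if one_d else z


def relative_fitness(raw, episode=None) -> np.ndarray:
    """Divide fitness by its (per-episode) mean so mean relative fitness is 1.

    ``episode``, if given, is a label per individual; relativization is
    then done within episode, as fitness is only comparable within a
    selective bout.
    """
    raw = np.asarray(raw, dtype=float)
    if np.any(raw < 0):
        raise ValueError("fitness must be non-negative")
    if episode is None:
        mean = raw.mean()
        if mean <= 0:
            raise ValueError("mean fitness is zero; cannot relativize")
        return raw / mean
    episode = np.asarray(episode)
    w = np.empty_like(raw)
    for label in np.unique(episode):
        mask = episode == label
        mean = raw[mask].mean()
        if mean <= 0:
            raise ValueError(f"mean fitness is zero in episode {label!r}")
        w[mask] = raw[mask] / mean
    return w


def quadratic_design(z: np.ndarray, include_cross: bool = True):
    """Design matrix of the second-order fitness model.

    Columns: intercept, the p linear terms, the p squared terms, and
    (optionally) the p(p-1)/2 pairwise products, in that order.

    Returns (X, names) where names label the non-intercept columns.
    """
    z = np.asarray(z, dtype=float)
    n, p = z.shape
    cols = [np.ones(n), *[z[:, j] for j in range(p)]]
    names = ["const"] + [f"z{j + 1}" for j in range(p)]
    for j in range(p):
        cols.append(z[:, j] ** 2)
        names.append(f"z{j + 1}^2")
    if include_cross:
        for j in range(p):
            for l in range(j + 1, p):
                cols.append(z[:, j] * z[:, l])
                names.append(f"z{j + 1}*z{l + 1}")
    return np.column_stack(cols), names


def _ols(x: np.ndarray, y: np.ndarray):
    """Least-squares fit; returns (coefs, se, residuals, rank check)."""
    n, q = x.shape
    coefs, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    if rank < q:
        raise ValueError(
            "rank-deficient design: collinear traits or insufficient data "
            f"(rank {rank} < {q} parameters)"
        )
    resid = y - x @ coefs
    dof = n - q
    if dof > 0:
        sigma2 = float(resid @ resid) / dof
        xtx_inv = np.linalg.inv(x.T @ x)
        se = np.sqrt(np.clip(sigma2 * np.diag(xtx_inv), 0, None))
    else:
        se = np.full(q, np.nan)
    return coefs, se, resid


def linear_gradients(z: np.ndarray, w: np.ndarray):
    """Directional gradients beta from the first-order model.

    Returns (beta, se): OLS coefficients (and standard errors) of
    relative fitness on the standardized traits, intercept excluded.
    """
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    n, p = z.shape
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (= {p + 1}) individuals, got {n}")
    x = np.column_stack([np.ones(n), z])
    coefs, se, _ = _ols(x, w)
    return coefs[1:], se[1:]


def quadratic_gradients(z: np.ndarray, w: np.ndarray):
    """Gamma matrix from the full second-order model.

    All linear, squared, and pairwise-product terms are fitted jointly;
    the squared-term coefficients are doubled onto the gamma diagonal
    and the product coefficients become the symmetric off-diagonals.

    Returns (gamma, gamma_se, linear2): the gamma matrix, matching
    standard errors (diagonal SEs also doubled), and the second-order
    model's linear coefficients (which differ from beta in general).
    """
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    n, p = z.shape
    n_par = 1 + p + p * (p + 1) // 2
    if n <= n_par:
        raise ValueError(
            f"need n > {n_par} individuals for the full second-order model, got {n}"
        )
    x, _ = quadratic_design(z)
    coefs, se, _ = _ols(x, w)
    return _coefs_to_gamma(coefs, se, p)


def _coefs_to_gamma(coefs: np.ndarray, se: np.ndarray, p: int):
    gamma = np.zeros((p, p))
    gamma_se = np.zeros((p, p))
    quad = coefs[1 + p : 1 + 2 * p]
    quad_se = se[1 + p : 1 + 2 * p]
    np.fill_diagonal(gamma, 2.0 * quad)
    np.fill_diagonal(gamma_se, 2.0 * quad_se)
    pos = 1 + 2 * p
    for j in range(p):
        for l in range(j + 1, p):
            gamma[j, l] = gamma[l, j] = coefs[pos]
            gamma_se[j, l] = gamma_se[l, j] = se[pos]
            pos += 1
    return gamma, gamma_se, coefs[1 : 1 + p]


def _permute_columns(w: np.ndarray, n_perm: int, rng: np.random.Generator,
                     block: int = 2000):
    """Yield blocks of permuted fitness vectors as (n, block) matrices."""
    n = w.shape[0]
    done = 0
    while done < n_perm:
        b = min(block, n_perm - done)
        mat = np.tile(w, (b, 1))
        mat = rng.permuted(mat, axis=1)
        yield mat.T
        done += b


def permutation_test(
    z: np.ndarray,
    w: np.ndarray,
    order: str = "first",
    n_perm: int = DEFAULT_N_PERM,
    seed=None,
) -> np.ndarray:
    """Randomization p-values for every coefficient of one model order.

    Fitness values are shuffled across individuals ``n_perm`` times and
    the model refitted each time (traits are standardized once on the
    observed sample and held fixed; only fitness is permuted). The
    two-tailed p-value for a coefficient is
    ``min(1, 2 * min((r_le + 1), (r_ge + 1)) / (n_perm + 1))`` where
    r_le / r_ge count pseudo-estimates at or below / at or above the
    observed estimate; the add-one correction keeps p > 0.

    Parameters
    ----------
    order : "first" or "second"
        First-order model (p-values for beta) or full second-order model
        (p-values for the linear, squared and product coefficients).

    Returns
    -------
    ndarray of p-values, one per non-intercept coefficient in design
    order. Identical seeds give identical p-values.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    z = np.asarray(z, dtype=float)
    w = np.asarray(w, dtype=float)
    n, p = z.shape
    if order == "first":
        x = np.column_stack([np.ones(n), z])
    elif order == "second":
        x, _ = quadratic_design(z)
    else:
        raise ValueError("order must be 'first' or 'second'")
    piv = np.linalg.pinv(x)
    obs = piv @ w
    rng = np.random.default_rng(seed)
    q = x.shape[1]
    r_le = np.zeros(q)
    r_ge = np.zeros(q)
    for wm in _permute_columns(w, n_perm, rng):
        perm_coefs = piv @ wm  # (q, block)
        r_le += (perm_coefs <= obs[:, None]).sum(axis=1)
        r_ge += (perm_coefs >= obs[:, None]).sum(axis=1)
    p_two = 2.0 * np.minimum(r_le + 1, r_ge + 1) / (n_perm + 1)
    return np.minimum(p_two, 1.0)[1:]  # drop intercept


def logistic_diagnostic(z: np.ndarray, y: np.ndarray):
    """Optional logistic-regression diagnostic for binary fitness.

    Never used for the reported gradients; offered to sanity-check the
    direction of effects under a link suited to 0/1 outcomes. Returns a
    fitted statsmodels Logit results object.
    """
    import statsmodels.api as sm

    z = np.asarray(z, dtype=float)
    x = sm.add_constant(z)
    return sm.Logit(np.asarray(y, dtype=float), x).fit(disp=False)


@dataclass
class SelectionGradientResults:
    """Fitted selection gradients for one selective episode.

    Attributes
    ----------
    beta, beta_se : directional gradients (first-order model) and SEs.
    gamma, gamma_se : symmetric gamma matrix (doubled diagonal) and SEs.
    linear2 : linear coefficients of the second-order model (reported
        for completeness; beta is taken from the first-order model).
    p_beta : permutation p-values for beta.
    p_gamma : symmetric matrix of permutation p-values for gamma.
    """

    trait_names: list[str]
    beta: np.ndarray
    beta_se: np.ndarray
    gamma: np.ndarray
    gamma_se: np.ndarray
    linear2: np.ndarray
    p_beta: np.ndarray | None
    p_gamma: np.ndarray | None
    n: int
    n_perm: int
    episode: str | None = None
    _z: np.ndarray | None = field(default=None, repr=False)
    _w: np.ndarray | None = field(default=None, repr=False)

    def canonical(self, n_perm: int | None = None, seed=None):
        """Canonical analysis of this episode's gamma matrix.

        Rotates the traits onto the eigenvectors of gamma and
        re-estimates the per-axis linear (theta) and quadratic (lambda)
        gradients by double regression, with the eigenvalue permutation
        test when ``n_perm`` is truthy.
        """
        from .canonical import CanonicalAnalysis

        if self._z is None or self._w is None:
            raise ValueError("data were not retained; refit with keep_data=True")
        if n_perm is None:
            n_perm = self.n_perm
        return CanonicalAnalysis(self._z, self._w, gamma=self.gamma,
                                 trait_names=self.trait_names).fit(
            n_perm=n_perm, seed=seed
        )

    def gamma_table(self) -> pd.DataFrame:
        """Lower-triangle gamma layout with beta as the leading column."""
        p = len(self.trait_names)
        tri = np.full((p, p), np.nan)
        idx = np.tril_indices(p)
        tri[idx] = self.gamma[idx]
        df = pd.DataFrame(tri, index=self.trait_names, columns=self.trait_names)
        df.insert(0, "beta", self.beta)
        return df

    def summary(self) -> str:
        lines = []
        title = "Selection gradient estimates"
        if self.episode:
            title += f" ({self.episode} episode)"
        lines.append(title)
        lines.append("=" * len(title))
        lines.append(f"n = {self.n}, permutations = {self.n_perm}")
        lines.append("")
        lines.append(f"{'trait':>8} {'beta':>9} {'SE':>8} {'p':>8}")
        for j, name in enumerate(self.trait_names):
            pv = f"{self.p_beta[j]:.4f}" if self.p_beta is not None else "   --"
            lines.append(
                f"{name:>8} {self.beta[j]:>9.4f} {self.beta_se[j]:>8.4f} {pv:>8}"
            )
        lines.append("")
        lines.append("gamma (lower triangle; diagonal doubled):")
        p = len(self.trait_names)
        header = " " * 8 + "".join(f"{t:>9}" for t in self.trait_names)
        lines.append(header)
        for j in range(p):
            row = f"{self.trait_names[j]:>8}"
            for l in range(p):
                if l <= j:
                    star = ""
                    if self.p_gamma is not None:
                        pv = self.p_gamma[j, l]
                        star = "*" if pv < 0.05 else ""
                    row += f"{self.gamma[j, l]:>8.3f}{star:<1}"
                else:
                    row += " " * 9
            lines.append(row)
        if self.p_gamma is not None:
            lines.append("(* permutation p < 0.05)")
        return "\n".join(lines)


class SelectionGradientModel:
    """Lande–Arnold selection analysis for one selective episode.

    Parameters
    ----------
    traits : DataFrame or ndarray (n, p)
        Phenotypic traits (e.g. body size, genital centroid size,
        relative-warp scores). Standardized internally unless
        ``standardize=False``.
    fitness : array-like
        Raw fitness (binary success or offspring count); relativized to
        mean 1 internally unless ``relativize=False``.
    episode : str, optional
        Label carried through to summaries ("mating"/"fertilization").
    """

    def __init__(
        self,
        traits,
        fitness,
        episode: str | None = None,
        standardize_traits: bool = True,
        relativize: bool = True,
    ):
        if isinstance(traits, pd.DataFrame):
            self.trait_names = [str(c) for c in traits.columns]
            z = traits.to_numpy(dtype=float)
        else:
            z = np.asarray(traits, dtype=float)
            self.trait_names = [f"z{j + 1}" for j in range(z.shape[1])]
        if z.ndim != 2:
            raise ValueError("traits must be 2-D (individuals x traits)")
        fitness = np.asarray(fitness, dtype=float)
        if fitness.shape[0] != z.shape[0]:
            raise ValueError("traits and fitness length mismatch")
        self.z = standardize(z) if standardize_traits else z
        self.w = relative_fitness(fitness) if relativize else fitness
        self.episode = episode

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, trait_columns, fitness_column: str = "fitness",
        episode: str | None = None,
    ) -> "SelectionGradientModel":
        """Build from a tidy per-specimen table (see io.read_trait_table)."""
        if episode is not None and "episode" in df.columns:
            df = df[df["episode"] == episode]
        return cls(df[list(trait_columns)], df[fitness_column], episode=episode)

    def fit(
        self,
        n_perm: int = DEFAULT_N_PERM,
        seed=None,
        keep_data: bool = True,
    ) -> SelectionGradientResults:
        """Estimate beta and gamma; run permutation tests if n_perm > 0.

        Separate randomizations are run for the first- and second-order
        models (the same shuffles are not recycled across orders).
        """
        beta, beta_se = linear_gradients(self.z, self.w)
        gamma, gamma_se, linear2 = quadratic_gradients(self.z, self.w)
        p = self.z.shape[1]
        p_beta = p_gamma = None
        if n_perm and n_perm > 0:
            rng = np.random.default_rng(seed)
            s1, s2 = rng.integers(0, 2**31 - 1, size=2)
            p_beta = permutation_test(self.z, self.w, "first", n_perm, int(s1))
            p_all = permutation_test(self.z, self.w, "second", n_perm, int(s2))
            p_gamma = np.zeros((p, p))
            np.fill_diagonal(p_gamma, p_all[p : 2 * p])
            pos = 2 * p
            for j in range(p):
                for l in range(j + 1, p):
                    p_gamma[j, l] = p_gamma[l, j] = p_all[pos]
                    pos += 1
        return SelectionGradientResults(
            trait_names=self.trait_names,
            beta=beta,
            beta_se=beta_se,
            gamma=gamma,
            gamma_se=gamma_se,
            linear2=linear2,
            p_beta=p_beta,
            p_gamma=p_gamma,
            n=self.z.shape[0],
            n_perm=n_perm if n_perm else 0,
            episode=self.episode,
            _z=self.z if keep_data else None,
            _w=self.w if keep_data else None,
        )
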