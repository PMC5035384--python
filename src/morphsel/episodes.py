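"""Sequential model building: partial F-tests comparing the form of
selection between two selective episodes.

Observations from both episodes (each standardized and relativized
within its own episode) are pooled with an episode indicator, and
episode x term interactions are tested block by block:

1. linear block     — do the directional gradients differ?
2. quadratic block  — do the quadratic gradients differ?
3. correlational    — do the correlational gradients differ?

Blocks are cumulative: interactions from earlier blocks stay in the
model when a later block is tested, so with pooled n and p traits the
denominator dfs are n - (2 + 2p), n - (2 + 4p) and
n - (2 + 4p + p(p-1)), e.g. 996, 986 and 966 for n = 1008, p = 5.
Per-trait quadratic differences are assessed by single-interaction-term
deletion from the quadratic-block full model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .selection import relative_fitness, standardize

__all__ = ["EpisodeComparison", "ComparisonResult", "sequential_model_comparison"]


@dataclass
class ComparisonResult:
    """Partial-F comparison of selection between two episodes."""

    blocks: pd.DataFrame  # index: linear/quadratic/correlational; F, df1, df2, p
    per_trait_quadratic: pd.DataFrame  # index: trait; F, df1, df2, p
    n_pooled: int
    trait_names: list[str]

    def summary(self) -> str:
        title = "Sequential model building: episode comparison"
        lines = [title, "=" * len(title), f"pooled n = {self.n_pooled}", ""]
        for name, row in self.blocks.iterrows():
            lines.append(
                f"{name:>13} block: F_{int(row.df1)},{int(row.df2)} = "
                f"{row.F:.3f}, P = {row.p:.3f}"
            )
        lines.append("")
        lines.append("per-trait quadratic differences (single-term deletion):")
        for name, row in self.per_trait_quadratic.iterrows():
            lines.append(
                f"{name:>13}: F_{int(row.df1)},{int(row.df2)} = "
                f"{row.F:.3f}, P = {row.p:.3f}"
            )
        return "\n".join(lines)


def _sse(x: np.ndarray, y: np.ndarray) -> float:
    coefs, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ coefs
    return float(r @ r)


def _partial_f(sse_red: float, sse_full: float, df_num: int, df_den: int):
    if df_den <= 0:
        raise ValueError("insufficient pooled sample size for this block")
    f = max(sse_red - sse_full, 0.0) / df_num / (sse_full / df_den)
    p = float(stats.f.sf(f, df_num, df_den))
    return f, p


def sequential_model_comparison(
    z1: np.ndarray,
    w1: np.ndarray,
    z2: np.ndarray,
    w2: np.ndarray,
    trait_names=None,
) -> ComparisonResult:
    """Partial F-tests on episode x term interactions, block by block.

    ``z1, w1`` and ``z2, w2`` must already be standardized / relativized
    within their episode (use EpisodeComparison for the full workflow).
    """
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    if z1.shape[1] != z2.shape[1]:
        raise ValueError("episodes have different trait sets")
    p = z1.shape[1]
    if trait_names is None:
        trait_names = [f"z{j + 1}" for j in range(p)]
    z = np.vstack([z1, z2])
    w = np.concatenate([np.asarray(w1, float), np.asarray(w2, float)])
    n = z.shape[0]
    e = np.concatenate([np.zeros(len(w1)), np.ones(len(w2))])

    lin = z
    quad = z**2
    cross_cols = [z[:, j] * z[:, l] for j in range(p) for l in range(j + 1, p)]
    cross = np.column_stack(cross_cols) if cross_cols else np.empty((n, 0))

    ones = np.ones((n, 1))
    ecol = e[:, None]

    def inter(block):
        return block * ecol

    # cumulative design blocks
    base_lin = np.hstack([ones, ecol, lin])
    full_lin = np.hstack([base_lin, inter(lin)])
    base_quad = np.hstack([full_lin, quad])
    full_quad = np.hstack([base_quad, inter(quad)])
    base_cross = np.hstack([full_quad, cross])
    full_cross = np.hstack([base_cross, inter(cross)])

    rows = []
    specs = [
        ("linear", base_lin, full_lin, p),
        ("quadratic", base_quad, full_quad, p),
        ("correlational", base_cross, full_cross, p * (p - 1) // 2),
    ]
    sse_full_quad = None
    for name, reduced, full, df_num in specs:
        if df_num == 0:
            continue
        df_den = n - full.shape[1]
        sse_r = _sse(reduced, w)
        sse_f = _sse(full, w)
        if name == "quadratic":
            sse_full_quad = sse_f
        f, pv = _partial_f(sse_r, sse_f, df_num, df_den)
        rows.append({"block": name, "F": f, "df1": df_num, "df2": df_den, "p": pv})
    blocks = pd.DataFrame(rows).set_index("block")

    # per-trait quadratic interaction deletion from the quadratic-block model
    df_den_quad = n - full_quad.shape[1]
    per_rows = []
    quad_inter = inter(quad)
    for j in range(p):
        keep = [l for l in range(p) if l != j]
        reduced = np.hstack([base_quad, quad_inter[:, keep]])
        sse_r = _sse(reduced, w)
        f, pv = _partial_f(sse_r, sse_full_quad, 1, df_den_quad)
        per_rows.append(
            {"trait": trait_names[j], "F": f, "df1": 1, "df2": df_den_quad, "p": pv}
        )
    per_trait = pd.DataFrame(per_rows).set_index("trait")

    return ComparisonResult(
        blocks=blocks,
        per_trait_quadratic=per_trait,
        n_pooled=n,
        trait_names=list(trait_names),
    )


class EpisodeComparison:
    """Compare selection between two episodes from raw traits and fitness.

    Traits are standardized and fitness relativized WITHIN each episode
    before pooling, since fitness scales and trait distributions are
    episode-specific.

    Parameters
    ----------
    traits : DataFrame or ndarray (n, p), both episodes stacked.
    fitness : raw fitness per individual.
    episode : label per individual; exactly two distinct labels.
    """

    def __init__(self, traits, fitness, episode):
        if isinstance(traits, pd.DataFrame):
            self.trait_names = [str(c) for c in traits.columns]
            traits = traits.to_numpy(dtype=float)
        else:
            traits = np.asarray(traits, dtype=float)
            self.trait_names = [f"z{j + 1}" for j in range(traits.shape[1])]
        episode = np.asarray(episode)
        labels = np.unique(episode)
        if len(labels) != 2:
            raise ValueError(f"need exactly two episodes, got {list(labels)}")
        self.labels = labels
        fitness = np.asarray(fitness, dtype=float)
        self._parts = []
        for label in labels:
            mask = episode == label
            self._parts.append(
                (standardize(traits[mask]), relative_fitness(fitness[mask]))
            )

    def fit(self, n_perm: int = 0, seed=None) -> ComparisonResult:
        """Run the block comparisons.

        By default p-values come from the F distribution. With
        ``n_perm`` > 0 the block p-values are replaced by a label
        permutation test: episode labels are shuffled across the pooled
        individuals (each shuffled episode re-standardized and
        re-relativized), the block F recomputed, and
        p = (#{F_perm >= F_obs} + 1)/(n_perm + 1).
        """
        (z1, w1), (z2, w2) = self._parts
        result = sequential_model_comparison(z1, w1, z2, w2, self.trait_names)
        if n_perm and n_perm > 0:
            result = self._label_permutation(result, n_perm, seed)
        return result

    def _label_permutation(
        self, observed: ComparisonResult, n_perm: int, seed
    ) -> ComparisonResult:
        (z1, w1), (z2, w2) = self._parts
        z = np.vstack([z1, z2])
        w = np.concatenate([w1, w2])
        n1 = len(w1)
        n = len(w)
        rng = np.random.default_rng(seed)
        exceed = np.zeros(len(observed.blocks))
        f_obs = observed.blocks["F"].to_numpy()
        for _ in range(n_perm):
            perm = rng.permutation(n)
            a, b = perm[:n1], perm[n1:]
            res = sequential_model_comparison(
                standardize(z[a]), relative_fitness(w[a]),
                standardize(z[b]), relative_fitness(w[b]),
                self.trait_names,
            )
            exceed += res.blocks["F"].to_numpy() >= f_obs
        blocks = observed.blocks.copy()
        blocks["p"] = (exceed + 1) / (n_perm + 1)
        return ComparisonResult(
            blocks=blocks,
            per_trait_quadratic=observed.per_trait_quadratic,
            n_pooled=observed.n_pooled,
            trait_names=observed.trait_names,
        )
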