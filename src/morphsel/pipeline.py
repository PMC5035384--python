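"""End-to-end orchestration of the two-episode selection analysis.

The pipeline aligns ALL specimens together (both episodes pooled) so
centroid size and the relative warps live in one geometric space and
the two episodes' gradients are directly comparable; it then estimates
per-episode selection gradients and canonical solutions, compares the
episodes by sequential model building, and renders fitness surfaces
over the major canonical axes.

Everything is a pure function of (inputs, config, seeds); outputs carry
the config hash and per-stage log lines record seeds and wall time.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .canonical import CanonicalResults
from .episodes import ComparisonResult, EpisodeComparison
from .io import LandmarkSet, SliderTable, read_sliders, read_tps, read_trait_table
from .morphometry import GeneralizedProcrustes, ProcrustesResults, centroid_size
from .selection import SelectionGradientModel, SelectionGradientResults
from .surfaces import fit_tps_surface, surface_plot

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "select_rw_count"]


def select_rw_count(pct_variance, threshold: float = 80.0) -> int:
    """Smallest number of leading relative warps whose cumulative
    percent variance exceeds the threshold (default 80%)."""
    pct = np.asarray(pct_variance, dtype=float)
    if pct.size == 0:
        raise ValueError("empty percent-variance vector")
    cum = np.cumsum(pct)
    above = np.flatnonzero(cum > threshold)
    if above.size == 0:
        return int(pct.size)
    return int(above[0] + 1)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Either ``tps_path``/``trait_path`` (with optional ``slider_path``)
    for real data, or ``synthetic=True`` to generate a study from the
    built-in truth (optionally overridden via ``truth_overrides``).
    """

    tps_path: str | None = None
    slider_path: str | None = None
    trait_path: str | None = None
    synthetic: bool = False
    truth_overrides: dict = field(default_factory=dict)
    n_perm: int = 9999
    seed: int = 0
    rw_threshold: float = 80.0
    max_rws: int | None = None  # cap on retained RWs (None = rule only)
    out_dir: str | None = None
    pooled_alignment: bool = True  # per-episode alignment only behind this flag
    make_figures: bool = True

    def __post_init__(self) -> None:
        if self.n_perm and self.n_perm < 99:
            raise ValueError("n_perm must be at least 99 (or 0 to skip)")
        if not self.synthetic:
            for path in (self.tps_path, self.trait_path):
                if path is None:
                    raise ValueError(
                        "tps_path and trait_path are required unless synthetic=True"
                    )
                if not Path(path).exists():
                    raise FileNotFoundError(path)
            if self.slider_path is not None and not Path(self.slider_path).exists():
                raise FileNotFoundError(self.slider_path)

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    config: RunConfig
    alignment: ProcrustesResults
    pct_variance: np.ndarray
    n_rws_retained: int
    traits: pd.DataFrame  # pooled per-specimen trait table
    gradients: dict[str, SelectionGradientResults]
    canonical: dict[str, CanonicalResults]
    comparison: ComparisonResult | None
    log: list[str]

    def summary(self) -> str:
        parts = [
            f"pipeline run (config {self.config.config_hash()}, "
            f"seed {self.config.seed})",
            f"specimens aligned: {self.alignment.n_specimens}; "
            f"RWs retained: {self.n_rws_retained} "
            f"(cumulative {self.pct_variance[: self.n_rws_retained].sum():.2f}%)",
            "",
        ]
        for episode, res in self.gradients.items():
            parts.append(res.summary())
            parts.append("")
            parts.append(self.canonical[episode].summary())
            parts.append("")
        if self.comparison is not None:
            parts.append(self.comparison.summary())
        return "\n".join(parts)


def _stage(log: list[str], name: str, start: float, **values) -> None:
    elapsed = time.perf_counter() - start
    kv = " ".join(f"{k}={v}" for k, v in values.items())
    log.append(f"stage={name} elapsed={elapsed:.2f}s {kv}".rstrip())


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis; see module docstring for the stages."""
    log: list[str] = [f"config_hash={config.config_hash()} seed={config.seed}"]
    rng = np.random.default_rng(config.seed)

    t0 = time.perf_counter()
    if config.synthetic:
        from .simulate import default_truth, generate_study

        truth = default_truth(**config.truth_overrides)
        gen_seed = int(rng.integers(0, 2**31 - 1))
        mating, fert = generate_study(truth, seed=gen_seed)
        coords = np.concatenate(
            [mating.landmarks.coords, fert.landmarks.coords], axis=0
        )
        ids = mating.landmarks.specimen_ids + fert.landmarks.specimen_ids
        landmarks = LandmarkSet(coords=coords, specimen_ids=ids)
        trait_df = pd.concat([mating.traits, fert.traits], ignore_index=True)
        trait_df["fitness"] = np.concatenate([mating.fitness, fert.fitness])
        sliders = None
        _stage(log, "simulate", t0, n=len(ids), gen_seed=gen_seed)
    else:
        landmarks = read_tps(config.tps_path)
        sliders = (
            read_sliders(config.slider_path, k=landmarks.k)
            if config.slider_path
            else None
        )
        trait_df = read_trait_table(config.trait_path)
        order = {sid: i for i, sid in enumerate(landmarks.specimen_ids)}
        missing = set(trait_df["specimen_id"]) - set(order)
        if missing:
            raise ValueError(
                f"trait table specimens missing from TPS file: {sorted(missing)[:5]}"
            )
        trait_df = trait_df.sort_values(
            "specimen_id", key=lambda s: s.map(order)
        ).reset_index(drop=True)
        _stage(log, "load", t0, n=landmarks.n_specimens)

    # morphometrics on the pooled specimen set (single shape space)
    t0 = time.perf_counter()
    if not config.pooled_alignment:
        raise NotImplementedError(
            "per-episode alignment is intentionally unsupported in the "
            "standard pipeline; align episodes separately by hand if needed"
        )
    fit = GeneralizedProcrustes(landmarks, sliders).fit()
    scores = fit.relative_warps()
    n_rws = select_rw_count(scores.pct_variance, config.rw_threshold)
    if config.max_rws is not None:
        n_rws = min(n_rws, config.max_rws)
    cs = centroid_size(landmarks.coords)
    _stage(log, "morphometry", t0, iterations=fit.n_iterations, rws=n_rws)

    traits = trait_df.copy()
    traits["cs"] = cs
    for j in range(n_rws):
        traits[f"rw{j + 1}"] = scores.scores[:, j]
    trait_cols = ["pw", "cs"] + [f"rw{j + 1}" for j in range(n_rws)]

    gradients: dict[str, SelectionGradientResults] = {}
    canonical: dict[str, CanonicalResults] = {}
    episodes = list(pd.unique(traits["episode"]))
    for episode in episodes:
        t0 = time.perf_counter()
        sub = traits[traits["episode"] == episode]
        model = SelectionGradientModel(
            sub[trait_cols], sub["fitness"], episode=episode
        )
        seed_g = int(rng.integers(0, 2**31 - 1))
        res = model.fit(n_perm=config.n_perm, seed=seed_g)
        gradients[episode] = res
        seed_c = int(rng.integers(0, 2**31 - 1))
        canonical[episode] = res.canonical(n_perm=config.n_perm, seed=seed_c)
        _stage(log, f"gradients[{episode}]", t0, n=res.n, seed=seed_g)

    comparison = None
    if len(episodes) == 2:
        t0 = time.perf_counter()
        comparison = EpisodeComparison(
            traits[trait_cols], traits["fitness"], traits["episode"]
        ).fit()
        _stage(log, "comparison", t0, n=comparison.n_pooled)

    result = PipelineResult(
        config=config,
        alignment=fit,
        pct_variance=scores.pct_variance,
        n_rws_retained=n_rws,
        traits=traits,
        gradients=gradients,
        canonical=canonical,
        comparison=comparison,
        log=log,
    )

    if config.out_dir is not None:
        _write_outputs(result, scores, config)
    return result


def _write_outputs(result: PipelineResult, scores, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = config.config_hash()
    result.traits.to_csv(out / f"traits_{tag}.csv", index=False)
    for episode, res in result.gradients.items():
        res.gamma_table().to_csv(out / f"gradients_{episode}_{tag}.csv")
        result.canonical[episode].table().to_csv(out / f"canonical_{episode}_{tag}.csv")
    if result.comparison is not None:
        result.comparison.blocks.to_csv(out / f"comparison_blocks_{tag}.csv")
        result.comparison.per_trait_quadratic.to_csv(
            out / f"comparison_per_trait_{tag}.csv"
        )
    if config.make_figures:
        for episode, res in result.gradients.items():
            can = result.canonical[episode]
            if res._z is None or can.n_axes < 2:
                continue
            # surface over the two axes of strongest curvature
            order = np.argsort(can.lam)
            ax_pair = (order[0], order[1])
            y = res._z @ can.m.T
            surf = fit_tps_surface(y[:, list(ax_pair)], res._w, smoothing="gcv")
            surface_plot(
                surf,
                str(out / f"surface_{episode}_{tag}.png"),
                xlabel=f"m{ax_pair[0] + 1}",
                ylabel=f"m{ax_pair[1] + 1}",
            )
    (out / f"run_{tag}.log").write_text("\n".join(result.log) + "\n")
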