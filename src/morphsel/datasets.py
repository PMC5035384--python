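"""Published worked-example gradient estimates for the broad-horned
flour beetle (Gnatocerus cornutus) genital-shape selection study.

These are the printed standardized selection gradients for body size
(pronotum width, PW), genital centroid size (CS) and three relative
warps (RW1-RW3) in two selective episodes — mating success (binary,
n = 500) and fertilization success (offspring counts, n = 508) — and
the published canonical eigenvalues for the mating episode. They serve
as worked-example inputs: the canonical machinery can be exercised on
the mating gamma matrix and checked against the published
eigendecomposition without access to the raw specimen data.

Note: the published fertilization gamma contains the entry
gamma(RW1, PW) = -1.533, which is irreconcilable with the published
fertilization eigenvalues (their sum matches the gamma trace, but no
symmetric matrix with that off-diagonal entry has those eigenvalues;
back-solving suggests a value near -0.07, consistent with a
transcription artefact). The fertilization matrix is therefore provided
as printed, flagged, and not suitable as an eigendecomposition check.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "TRAIT_NAMES",
    "mating_beta",
    "mating_gamma",
    "mating_eigenvalues",
    "fertilization_beta",
    "fertilization_gamma",
    "fertilization_eigenvalues",
    "gradient_table",
]

TRAIT_NAMES = ["PW", "CS", "RW1", "RW2", "RW3"]

_MATING_BETA = np.array([-0.014, -0.017, -0.117, 0.005, -0.052])

# lower triangle as printed; diagonal already doubled
_MATING_GAMMA_LOWER = [
    [-0.146],
    [-0.016, -0.214],
    [-0.058, 0.201, -0.196],
    [0.048, 0.077, 0.100, -0.146],
    [0.061, -0.180, 0.159, 0.012, -0.142],
]

# published canonical eigenvalues (lambda_1..lambda_5), mating episode
_MATING_EIGENVALUES = np.array([0.072, 0.014, -0.117, -0.257, -0.557])

_FERT_BETA = np.array([0.081, -0.195, 0.020, 0.074, -0.104])

# contains the flagged -1.533 entry; see module docstring
_FERT_GAMMA_LOWER = [
    [-0.086],
    [0.178, -0.340],
    [-1.533, 0.139, -0.048],
    [0.003, -0.028, 0.072, 0.078],
    [0.177, -0.131, 0.064, 0.014, -0.190],
]

_FERT_EIGENVALUES = np.array([0.118, 0.061, -0.023, -0.144, -0.600])


def _symmetrize(lower: list[list[float]]) -> np.ndarray:
    p = len(lower)
    g = np.zeros((p, p))
    for i, row in enumerate(lower):
        for j, v in enumerate(row):
            g[i, j] = g[j, i] = v
    return g


def mating_beta() -> np.ndarray:
    """Directional gradients (PW, CS, RW1, RW2, RW3), mating episode."""
    return _MATING_BETA.copy()


def mating_gamma() -> np.ndarray:
    """Symmetric gamma matrix, mating episode (diagonal doubled)."""
    return _symmetrize(_MATING_GAMMA_LOWER)


def mating_eigenvalues() -> np.ndarray:
    """Published canonical eigenvalues of the mating gamma."""
    return _MATING_EIGENVALUES.copy()


def fertilization_beta() -> np.ndarray:
    return _FERT_BETA.copy()


def fertilization_gamma() -> np.ndarray:
    """Symmetric gamma matrix, fertilization episode, as printed.

    Carries the flagged gamma(RW1, PW) = -1.533 entry (see module
    docstring); do not use as an eigendecomposition reference.
    """
    return _symmetrize(_FERT_GAMMA_LOWER)


def fertilization_eigenvalues() -> np.ndarray:
    return _FERT_EIGENVALUES.copy()


def gradient_table(episode: str = "mating") -> pd.DataFrame:
    """Beta + lower-triangle gamma in the published table layout."""
    if episode == "mating":
        beta, gamma = mating_beta(), mating_gamma()
    elif episode == "fertilization":
        beta, gamma = fertilization_beta(), fertilization_gamma()
    else:
        raise ValueError("episode must be 'mating' or 'fertilization'")
    p = len(TRAIT_NAMES)
    tri = np.full((p, p), np.nan)
    idx = np.tril_indices(p)
    tri[idx] = gamma[idx]
    df = pd.DataFrame(tri, index=TRAIT_NAMES, columns=TRAIT_NAMES)
    df.insert(0, "beta", beta)
    return df
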