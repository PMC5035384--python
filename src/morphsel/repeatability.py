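"""Measurement repeatability as an intraclass correlation.

One-way ANOVA ICC for balanced repeated measurements (here: two
independent digitizations of the same specimen):

    R = (MSB - MSW) / (MSB + (m - 1) * MSW)

with the exact F-distribution confidence interval for the balanced
one-way design. Negative point estimates are reported as computed (the
variance-component estimator is unbiased; truncation would not be).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["RepeatabilityEstimate", "icc_repeatability"]


@dataclass
class RepeatabilityEstimate:
    trait: str
    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    n_measurements: int  # per subject
    ms_between: float
    ms_within: float

    def summary(self) -> str:
        return (
            f"{self.trait}: R = {self.icc:.3f}, "
            f"95% CI = ({self.ci_low:.3f}, {self.ci_high:.3f}), "
            f"{self.n_subjects} subjects x {self.n_measurements} measurements"
        )


def icc_repeatability(
    measurements,
    subjects=None,
    trait: str = "trait",
    conf: float = 0.95,
) -> RepeatabilityEstimate:
    """One-way ANOVA intraclass correlation with exact-F CI.

    Parameters
    ----------
    measurements : (n_subjects, m) array, or 1-D values with ``subjects``
        giving a subject label per value. The design must be balanced
        with at least 2 subjects and 2 measurements per subject.
    conf : confidence level for the interval (default 0.95).

    Notes
    -----
    With F = MSB/MSW, n subjects and m measurements each, the interval
    bounds are (FL - 1)/(FL + m - 1) and (FU - 1)/(FU + m - 1) where
    FL = F / F_{1-a/2; n-1, n(m-1)} and FU = F * F_{1-a/2; n(m-1), n-1}.
    """
    if subjects is not None:
        values = np.asarray(measurements, dtype=float)
        subjects = np.asarray(subjects)
        groups = [values[subjects == s] for s in np.unique(subjects)]
        sizes = {len(g) for g in groups}
        if len(sizes) != 1:
            raise ValueError("unbalanced design: unequal measurements per subject")
        data = np.vstack(groups)
    else:
        data = np.asarray(measurements, dtype=float)
        if data.ndim != 2:
            raise ValueError("measurements must be (n_subjects, m) or use subjects=")
    n, m = data.shape
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if m < 2:
        raise ValueError("need at least 2 measurements per subject")

    subject_means = data.mean(axis=1)
    grand = data.mean()
    ssb = m * ((subject_means - grand) ** 2).sum()
    ssw = ((data - subject_means[:, None]) ** 2).sum()
    if ssb + ssw == 0:
        raise ValueError("zero total variance; repeatability undefined")
    df_b = n - 1
    df_w = n * (m - 1)
    msb = ssb / df_b
    msw = ssw / df_w

    if msw == 0:
        icc, lo, hi = 1.0, 1.0, 1.0
    else:
        icc = (msb - msw) / (msb + (m - 1) * msw)
        f_obs = msb / msw
        alpha = 1.0 - conf
        fl = f_obs / stats.f.ppf(1 - alpha / 2, df_b, df_w)
        fu = f_obs * stats.f.ppf(1 - alpha / 2, df_w, df_b)
        lo = (fl - 1) / (fl + m - 1)
        hi = (fu - 1) / (fu + m - 1)

    return RepeatabilityEstimate(
        trait=trait,
        icc=float(icc),
        ci_low=float(lo),
        ci_high=float(hi),
        n_subjects=n,
        n_measurements=m,
        ms_between=float(msb),
        ms_within=float(msw),
    )
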