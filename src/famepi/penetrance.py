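"""Multiplex-family risk: P(at least k cases) by joint carrier status.

From a fitted log-link Poisson model, the probability that a family
reaches k or more cases is the upper tail of the Poisson distribution at
the fitted rate, ``P(Y >= k) = 1 - F(k - 1; lambda)``.  Profiles over the
2 x 2 carrier grid quantify how much more likely a double-carrier family
is to be highly multiplex than a double-noncarrier family; both the risk
difference and the risk ratio of the two extreme combinations are
reported.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import glm
from .epistasis import AGE, INTERCEPT, _interaction_label


def prob_at_least_k(mean: float | np.ndarray, k: int) -> float | np.ndarray:
    """Poisson upper-tail probability P(Y >= k) at rate ``mean``.

    ``k = 0`` returns 1 exactly; a nonpositive rate is a domain error.
    """
    lam = np.asarray(mean, dtype=float)
    if (lam <= 0).any():
        raise ValueError("Poisson rate must be positive")
    if k < 0 or int(k) != k:
        raise ValueError("k must be a nonnegative integer")
    out = np.ones_like(lam) if k == 0 else stats.poisson.sf(k - 1, lam)
    return float(out) if np.isscalar(mean) else out


def penetrance_profile(
    fit: glm.GlmFit,
    snp1: str,
    snp2: str,
    k: int = 4,
    age: float | None = None,
) -> pd.DataFrame:
    """P(Y >= k) for every carrier combination of two loci.

    ``age`` must be supplied when the fit is age-adjusted (callers
    typically pass the cohort mean age).  The result frame carries the
    double-carrier minus double-noncarrier risk difference and their
    ratio in ``.attrs`` — the "how much higher is the multiplex risk for
    double carriers" contrast.
    """
    if fit.link != "log":
        raise glm.GlmError("penetrance profiles require a log-link fit")
    labels = list(fit.labels)
    for needed in (snp1, snp2):
        if needed not in labels:
            raise glm.GlmError(f"fit has no coefficient for {needed!r}")
    if AGE in labels and age is None:
        raise glm.GlmError("fit is age-adjusted; supply the age setting")

    inter = _interaction_label(snp1, snp2)
    rows = []
    for g1 in (0, 1):
        for g2 in (0, 1):
            x = np.zeros(len(labels))
            x[labels.index(INTERCEPT)] = 1.0
            x[labels.index(snp1)] = g1
            x[labels.index(snp2)] = g2
            if inter in labels:
                x[labels.index(inter)] = g1 * g2
            if AGE in labels:
                x[labels.index(AGE)] = age
            lam = float(fit.predict_mean(x)[0])
            rows.append(
                {
                    snp1: g1,
                    snp2: g2,
                    "rate": lam,
                    "prob_at_least_k": prob_at_least_k(lam, k),
                }
            )
    prof = pd.DataFrame(rows)
    p11 = float(prof.loc[(prof[snp1] == 1) & (prof[snp2] == 1), "prob_at_least_k"].iloc[0])
    p00 = float(prof.loc[(prof[snp1] == 0) & (prof[snp2] == 0), "prob_at_least_k"].iloc[0])
    prof.attrs["k"] = k
    prof.attrs["risk_difference"] = p11 - p00
    prof.attrs["risk_ratio"] = p11 / p00 if p00 > 0 else np.inf
    return prof


def plot_profile(profile: pd.DataFrame, path: str | Path) -> None:
    """Bar chart of the carrier-combination tail probabilities."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    snp1, snp2 = profile.columns[:2]
    labels = [
        f"{snp1}={'+' if r[snp1] else '-'}\n{snp2}={'+' if r[snp2] else '-'}"
        for _, r in profile.iterrows()
    ]
    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.bar(labels, profile["prob_at_least_k"], color="#4878b0")
    ax.set_ylabel(f"P(>= {profile.attrs.get('k', '?')} cases in family)")
    ax.set_xlabel("carrier status")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
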