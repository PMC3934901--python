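"""Two-locus model ladder, LRT/AIC comparison and epistasis classification.

The ladder fits, on a common complete-case subject set:

* intercept-only,
* each single-locus model (dominant-coded carrier status),
* the two-locus main-effects model ("additive" in the source's usage),
* the two-locus model with the product interaction term ("multiplicative"),

optionally with a linear age term, and compares nested pairs by
likelihood-ratio tests and all models by AIC.  Stratified rate ratios
(one locus fitted within carrier/noncarrier strata of the other) expose
effect modification, and the interaction is classified per scale:
multiplicative-scale epistasis from the sign of the interaction
coefficient gated by its LRT, additive (risk)-scale epistasis from
contrasts of fitted means.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from . import glm
from .aggregation import dominant_codes, family_outcome
from .io import Cohort

INTERCEPT = "intercept"
AGE = "age"


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """One model in the ladder."""

    endpoint: str = "all"
    snps: tuple[str, ...] = ()
    interaction: bool = False
    adjust_age: bool = False

    def __post_init__(self) -> None:
        if self.interaction and len(self.snps) != 2:
            raise ValueError("an interaction term requires exactly two SNPs")
        if len(self.snps) > 2:
            raise ValueError("at most two SNPs are supported")


def _interaction_label(snp1: str, snp2: str) -> str:
    return f"{snp1}:{snp2}"


def build_design(
    cohort: Cohort, spec: ModelSpec, family_level: bool = False
) -> glm.DesignResponse:
    """Assemble the design matrix and per-subject outcome for one model.

    Outcome: the family's endpoint-specific case count, attributed to
    every member (the source's Table-1 convention).  Covariates: dominant
    carrier codes for each SNP, their product if ``interaction``, and age
    if ``adjust_age``.  Subjects missing any required covariate are
    dropped (complete case); the surviving positional row indices are
    recorded in ``kept_rows`` so sample sizes stay auditable.

    ``family_level=True`` collapses to one row per family using the
    family's modal carrier status per SNP (ties resolve to carrier) — the
    correct observational unit when genotypes are family-shared, used by
    the calibration/recovery studies.
    """
    outcome = family_outcome(cohort, spec.endpoint)
    y = cohort.data["family_id"].map(outcome).to_numpy(dtype=float)
    n = len(y)

    cols: dict[str, np.ndarray] = {INTERCEPT: np.ones(n)}
    for s in spec.snps:
        cols[s] = dominant_codes(cohort, s)
    if spec.interaction:
        s1, s2 = spec.snps
        cols[_interaction_label(s1, s2)] = cols[s1] * cols[s2]
    if spec.adjust_age:
        cols[AGE] = cohort.data["age"].to_numpy(dtype=float)

    X = np.column_stack(list(cols.values()))
    keep = ~np.isnan(X).any(axis=1)
    kept_rows = np.flatnonzero(keep)
    X = X[keep]
    yk = y[keep]
    fam = cohort.data["family_id"].to_numpy()[keep]

    if family_level:
        df = pd.DataFrame(X, columns=list(cols))
        df["_y"] = yk
        df["_fam"] = fam
        agg = {c: "mean" for c in cols}
        agg["_y"] = "first"
        g = df.groupby("_fam", sort=False).agg(agg)
        for s in spec.snps:
            g[s] = (g[s] >= 0.5).astype(float)  # modal status, ties -> carrier
        if spec.interaction:
            s1, s2 = spec.snps
            g[_interaction_label(s1, s2)] = g[s1] * g[s2]
        X = g[list(cols)].to_numpy()
        yk = g["_y"].to_numpy()
        fam = g.index.to_numpy()
        kept_rows = np.arange(len(yk))

    return glm.DesignResponse(
        X=X, y=yk, labels=tuple(cols), kept_rows=kept_rows, groups=fam
    )


#: ladder model names in fitting order
LADDER_MODELS = ("intercept", "snp1_only", "snp2_only", "additive", "multiplicative")


@dataclasses.dataclass
class EpistasisReport:
    """All fits and comparisons for one endpoint / age setting."""

    endpoint: str
    snps: tuple[str, str]
    adjust_age: bool
    fits: Mapping[str, glm.GlmFit]
    lrts: pd.DataFrame
    aic_table: pd.DataFrame
    stratified: pd.DataFrame
    classification: Mapping[str, object]
    n_obs: int
    kept_rows: np.ndarray

    @property
    def best_model(self) -> str:
        return str(self.aic_table.loc[self.aic_table["aic"].idxmin(), "model"])

    def interaction_lrt(self) -> glm.LrtResult:
        row = self.lrts[
            (self.lrts["nested"] == "additive")
            & (self.lrts["full"] == "multiplicative")
        ].iloc[0]
        return glm.LrtResult(chi2=row["chi2"], df=int(row["df"]), p=row["p"])


def run_ladder(
    cohort: Cohort,
    snp1: str,
    snp2: str,
    endpoint: str = "all",
    adjust_age: bool = False,
    alpha: float = 0.05,
    bonferroni: int = 1,
    robust: bool = False,
) -> EpistasisReport:
    """Fit the full model ladder and assemble the epistasis report.

    All five models are fitted on the common complete-case rows of the
    most complete (interaction) design, so every likelihood-ratio test is
    between models of the same observations.  ``bonferroni`` divides the
    classification alpha (default 1: no multiple-testing correction,
    matching the source's practice).  Non-converged fits are flagged in
    the AIC table, never hidden.
    """
    full_spec = ModelSpec(
        endpoint=endpoint, snps=(snp1, snp2), interaction=True, adjust_age=adjust_age
    )
    full = build_design(cohort, full_spec)
    inter = _interaction_label(snp1, snp2)
    age_cols = [AGE] if adjust_age else []
    columns = {
        "intercept": [INTERCEPT] + age_cols,
        "snp1_only": [INTERCEPT, snp1] + age_cols,
        "snp2_only": [INTERCEPT, snp2] + age_cols,
        "additive": [INTERCEPT, snp1, snp2] + age_cols,
        "multiplicative": [INTERCEPT, snp1, snp2, inter] + age_cols,
    }
    fits = {
        name: glm.fit_poisson(full.subset(cols), robust=robust)
        for name, cols in columns.items()
    }

    pairs = [
        ("intercept", "snp1_only"),
        ("intercept", "snp2_only"),
        ("snp1_only", "additive"),
        ("snp2_only", "additive"),
        ("additive", "multiplicative"),
    ]
    lrt_rows = []
    for a, b in pairs:
        res = glm.lrt(fits[a], fits[b])
        lrt_rows.append(
            {"nested": a, "full": b, "chi2": res.chi2, "df": res.df, "p": res.p}
        )
    lrts = pd.DataFrame(lrt_rows)

    aics = pd.DataFrame(
        {
            "model": list(fits),
            "k": [f.n_params for f in fits.values()],
            "loglik": [f.loglik for f in fits.values()],
            "aic": [f.aic for f in fits.values()],
            "converged": [f.converged for f in fits.values()],
        }
    )
    aics["delta_aic"] = aics["aic"] - aics["aic"].min()
    aics["best"] = aics["aic"] == aics["aic"].min()

    strat = pd.concat(
        [
            stratified_rate_ratio(
                cohort, snp2, snp1, endpoint=endpoint, adjust_age=adjust_age
            ),
            stratified_rate_ratio(
                cohort, snp1, snp2, endpoint=endpoint, adjust_age=adjust_age
            ),
        ],
        ignore_index=True,
    )

    report = EpistasisReport(
        endpoint=endpoint,
        snps=(snp1, snp2),
        adjust_age=adjust_age,
        fits=fits,
        lrts=lrts,
        aic_table=aics,
        stratified=strat,
        classification={},
        n_obs=full.X.shape[0],
        kept_rows=full.kept_rows,
    )
    report.classification = classify_epistasis(
        report, alpha=alpha / max(1, bonferroni)
    )
    return report


def stratified_rate_ratio(
    cohort: Cohort,
    target_snp: str,
    stratifier_snp: str,
    endpoint: str = "all",
    adjust_age: bool = False,
    level: float = 0.95,
) -> pd.DataFrame:
    """Single-locus rate ratio of ``target_snp`` within each stratum of
    ``stratifier_snp`` carrier status.

    A stratum whose target column is constant (or empty) is reported with
    ``estimable=False`` and NaN estimates rather than silently dropped;
    under positive interaction the carrier-stratum ratio exceeds the
    noncarrier-stratum ratio.
    """
    strat_codes = dominant_codes(cohort, stratifier_snp)
    rows = []
    for label, code in (("carrier", 1.0), ("noncarrier", 0.0)):
        sub = Cohort(
            data=cohort.data[strat_codes == code].reset_index(drop=True),
            snps=cohort.snps,
        )
        rec = {
            "target": target_snp,
            "stratifier": stratifier_snp,
            "stratum": label,
            "n": sub.n_subjects,
            "estimable": False,
            "rate_ratio": np.nan,
            "lower": np.nan,
            "upper": np.nan,
            "p": np.nan,
        }
        if sub.n_subjects > 0:
            spec = ModelSpec(
                endpoint=endpoint, snps=(target_snp,), adjust_age=adjust_age
            )
            try:
                design = build_design(sub, spec)
                fit = glm.fit_poisson(design)
                rr = glm.rate_ratio(fit, target_snp, level=level)
            except glm.GlmError:
                rows.append(rec)
                continue
            rec.update(
                estimable=True,
                n=design.X.shape[0],
                rate_ratio=rr.point,
                lower=rr.lower,
                upper=rr.upper,
                p=rr.p,
            )
        rows.append(rec)
    return pd.DataFrame(rows)


def _fitted_means_grid(fit: glm.GlmFit, snp1: str, snp2: str) -> dict[tuple[int, int], float]:
    """Fitted rate for each carrier combination at age 0 (if adjusted).

    Under the log link an age term scales every combination by the same
    factor, so contrast signs do not depend on the age setting; penetrance
    profiles, which need absolute rates, pass an explicit age instead.
    """
    labels = list(fit.labels)
    inter = _interaction_label(snp1, snp2)
    out = {}
    for g1 in (0, 1):
        for g2 in (0, 1):
            x = np.zeros(len(labels))
            x[labels.index(INTERCEPT)] = 1.0
            if snp1 in labels:
                x[labels.index(snp1)] = g1
            if snp2 in labels:
                x[labels.index(snp2)] = g2
            if inter in labels:
                x[labels.index(inter)] = g1 * g2
            out[(g1, g2)] = float(fit.predict_mean(x)[0])
    return out


def classify_epistasis(report: EpistasisReport, alpha: float = 0.05) -> dict:
    """Label the interaction sign on each epistasis scale.

    * ``multiplicative``: sign of the interaction coefficient, gated by
      the additive-vs-multiplicative LRT at ``alpha`` ("none" when the
      gate fails or the coefficient is exactly zero).
    * ``additive``: sign of the risk-scale contrast
      lambda_11 - lambda_10 - lambda_01 + lambda_00 of the interaction
      fit's fitted means (positive when the joint mean exceeds the
      within-model independence prediction).
    * ``additive_vs_marginals``: sign of the joint risk increment minus
      the sum of the *single-locus models'* increments — the comparison
      under which two loci with positive log-scale interaction can still
      look (slightly) antagonistic on the risk scale.

    Age-adjusted fits evaluate all contrasts at age 0; the contrast signs
    are invariant to the (multiplicative) age factor under the log link.
    """
    snp1, snp2 = report.snps
    mult = report.fits["multiplicative"]
    if not mult.converged:
        raise glm.GlmError("multiplicative fit did not converge; cannot classify")
    inter = _interaction_label(snp1, snp2)
    b3 = float(mult.coefficients[inter])
    p_int = report.interaction_lrt().p

    if b3 == 0.0 or p_int >= alpha:
        mult_label = "none"
    else:
        mult_label = "positive" if b3 > 0 else "negative"

    lam = _fitted_means_grid(mult, snp1, snp2)
    within = lam[1, 1] - lam[1, 0] - lam[0, 1] + lam[0, 0]
    add_label = "none" if within == 0 else ("positive" if within > 0 else "negative")

    f1 = _fitted_means_grid(report.fits["snp1_only"], snp1, snp2)
    f2 = _fitted_means_grid(report.fits["snp2_only"], snp1, snp2)
    marg = (lam[1, 1] - lam[0, 0]) - ((f1[1, 0] - f1[0, 0]) + (f2[0, 1] - f2[0, 0]))
    marg_label = "none" if marg == 0 else ("positive" if marg > 0 else "negative")

    return {
        "multiplicative": mult_label,
        "interaction_coefficient": b3,
        "interaction_p": p_int,
        "alpha": alpha,
        "additive": add_label,
        "additive_contrast": within,
        "additive_vs_marginals": marg_label,
        "additive_marginal_contrast": marg,
        "fitted_means": lam,
    }
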