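"""End-to-end orchestration: cohort -> tables -> model ladder -> penetrance.

`run_pipeline` executes the whole analysis for a configured cohort (read
from TSV or simulated) and writes every result table as TSV plus a JSON
manifest recording the configuration, seed, package version, complete-case
sample sizes and convergence flags, so a run is reproducible and auditable
from its output directory alone.  Any stage failure leaves the partial
outputs in place together with a FAILED marker file.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__, aggregation, epistasis, penetrance, simulate
from .io import Cohort, SnpDef, read_cohort, write_cohort, write_table

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Exactly one of ``input_path`` / ``simulate_preset`` must be given, and
    risk alleles are mandatory for every SNP (``snps`` maps name ->
    risk allele).
    """

    snps: Mapping[str, str]
    input_path: str | None = None
    simulate_preset: str | None = None
    endpoints: Sequence[str] = ("all", "nonaggressive", "aggressive")
    alpha: float = 0.05
    k: int = 4
    adjust_age: Sequence[bool] = (False, True)
    out_dir: str = "famepi_out"
    seed: int = 0
    strict: bool = False

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.simulate_preset is None):
            raise ValueError("specify exactly one of input_path / simulate_preset")
        if not self.snps or any(not ra for ra in self.snps.values()):
            raise ValueError("risk alleles are mandatory for every SNP")
        if len(self.snps) != 2:
            raise ValueError("the pipeline analyses exactly two SNPs")


def _load(config: RunConfig, out: Path) -> Cohort:
    snps = [SnpDef(n, risk_allele=r) for n, r in config.snps.items()]
    if config.input_path is not None:
        return read_cohort(config.input_path, snps, strict=config.strict)
    if config.simulate_preset != "paper":
        raise ValueError(f"unknown simulation preset {config.simulate_preset!r}")
    cohort = simulate.simulate_cohort(simulate.paper_preset(), seed=config.seed)
    write_cohort(cohort, out / "cohort.tsv")
    return cohort


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest dict (also written)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed = out / "FAILED"
    if failed.exists():
        failed.unlink()
    try:
        manifest = _run(config, out)
    except Exception as exc:
        failed.write_text(f"{type(exc).__name__}: {exc}\n")
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _run(config: RunConfig, out: Path) -> dict:
    cohort = _load(config, out)
    snp1, snp2 = list(config.snps)
    logger.info(
        "cohort: %d subjects in %d families", cohort.n_subjects, cohort.n_families
    )

    fc = aggregation.family_case_counts(cohort)
    write_table(fc, out / "family_counts.tsv")

    tables = {}
    for snp in (snp1, snp2):
        for endpoint in ("all", "aggressive"):
            if endpoint == "aggressive" and not cohort.data["aggressive"].notna().any():
                continue
            tab = aggregation.carrier_count_table(cohort, snp, endpoint=endpoint)
            frame = tab.to_frame()
            try:
                chi2, df, p = aggregation.contingency_chisq(tab)
                tables[f"{snp}_{endpoint}"] = {"chi2": chi2, "df": df, "p": p}
            except ValueError as exc:
                tables[f"{snp}_{endpoint}"] = {"error": str(exc)}
            write_table(frame, out / f"table1_{snp}_{endpoint}.tsv", precision=1)

    reports = {}
    for endpoint in config.endpoints:
        if endpoint in ("aggressive", "nonaggressive") and not (
            cohort.data["aggressive"].notna().any()
        ):
            logger.info("skipping endpoint %s: no aggressive flags", endpoint)
            continue
        for adjust in config.adjust_age:
            if adjust and cohort.data["age"].isna().all():
                continue
            tag = f"{endpoint}{'_age' if adjust else ''}"
            rep = epistasis.run_ladder(
                cohort, snp1, snp2,
                endpoint=endpoint, adjust_age=adjust, alpha=config.alpha,
            )
            _write_report(rep, out, tag)
            reports[tag] = {
                "n_complete_case": int(rep.n_obs),
                "best_model_aic": rep.best_model,
                "interaction_p": float(rep.interaction_lrt().p),
                "classification": {
                    "multiplicative": rep.classification["multiplicative"],
                    "additive": rep.classification["additive"],
                    "additive_vs_marginals": rep.classification[
                        "additive_vs_marginals"
                    ],
                },
                "converged": {
                    name: bool(f.converged) for name, f in rep.fits.items()
                },
            }
            if endpoint == "all":
                fit = rep.fits["multiplicative"]
                age = (
                    float(np.nanmean(cohort.data["age"])) if adjust else None
                )
                prof = penetrance.penetrance_profile(
                    fit, snp1, snp2, k=config.k, age=age
                )
                write_table(prof, out / f"penetrance_{tag}.tsv")

    return {
        "package": "famepi",
        "version": __version__,
        "seed": config.seed,
        "config": {
            "snps": dict(config.snps),
            "input_path": config.input_path,
            "simulate_preset": config.simulate_preset,
            "endpoints": list(config.endpoints),
            "alpha": config.alpha,
            "k": config.k,
            "adjust_age": [bool(a) for a in config.adjust_age],
            "strict": config.strict,
        },
        "cohort": {
            "n_subjects": int(cohort.n_subjects),
            "n_families": int(cohort.n_families),
            "n_affected": int(cohort.data["affected"].sum()),
        },
        "contingency_tests": tables,
        "models": reports,
    }


def _write_report(rep: epistasis.EpistasisReport, out: Path, tag: str) -> None:
    coef_rows = []
    for name, fit in rep.fits.items():
        se = fit.se()
        pvals = fit.wald_p()
        for term in fit.labels:
            row = {
                "model": name,
                "term": term,
                "coefficient": fit.coefficients[term],
                "se": se[term],
                "wald_p": pvals[term],
            }
            if term not in (epistasis.INTERCEPT, epistasis.AGE):
                rr = pd.NA
                try:
                    from .glm import rate_ratio

                    r = rate_ratio(fit, term)
                    row.update(
                        rate_ratio=r.point, rr_lower=r.lower, rr_upper=r.upper
                    )
                except Exception:
                    row.update(rate_ratio=rr, rr_lower=rr, rr_upper=rr)
            coef_rows.append(row)
    write_table(pd.DataFrame(coef_rows), out / f"fits_{tag}.tsv")
    write_table(rep.lrts, out / f"lrt_{tag}.tsv")
    write_table(rep.aic_table, out / f"aic_{tag}.tsv")
    write_table(rep.stratified, out / f"stratified_{tag}.tsv")
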