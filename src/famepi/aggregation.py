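"""Family case counts, dominant genotype coding and carrier contingency tables.

The analysis outcome is the number of prostate-cancer cases among a
subject's family members (optionally restricted to aggressive or
non-aggressive disease), attributed to *every* genotyped member of the
family — including the cases themselves — so that contingency-table column
totals equal subject counts.  Genotypes are collapsed to dominant carrier
status (>=1 copy of the risk allele) before tabulation.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import Cohort, CohortValidationError, SnpDef

ENDPOINTS = ("all", "nonaggressive", "aggressive")

#: the study's outcome bins: per-family total case count for all PrCa,
#: per-family aggressive case count for the aggressive endpoint.
PAPER_BINS_ALL: tuple[object, ...] = (2, 3, 4, "5+")
PAPER_BINS_AGGRESSIVE: tuple[object, ...] = (0, 1, 2, 3)


def family_case_counts(cohort: Cohort) -> pd.DataFrame:
    """Per-family member/affected/aggressive counts.

    Returns one row per family (in first-appearance order) with columns
    ``family_id, n_members, n_affected, n_aggressive``.  Missing
    aggressiveness flags count as non-aggressive.
    """
    df = cohort.data
    aggr = df["aggressive"].fillna(False).astype(bool)
    out = (
        df.assign(_aggr=aggr)
        .groupby("family_id", sort=False)
        .agg(
            n_members=("subject_id", "size"),
            n_affected=("affected", "sum"),
            n_aggressive=("_aggr", "sum"),
        )
        .reset_index()
    )
    out["n_affected"] = out["n_affected"].astype(int)
    out["n_aggressive"] = out["n_aggressive"].astype(int)
    return out


def family_outcome(cohort: Cohort, endpoint: str = "all") -> pd.Series:
    """Map family_id -> the endpoint-specific case count used as outcome."""
    if endpoint not in ENDPOINTS:
        raise ValueError(f"endpoint must be one of {ENDPOINTS}, got {endpoint!r}")
    fc = family_case_counts(cohort).set_index("family_id")
    if endpoint == "all":
        return fc["n_affected"]
    if endpoint == "aggressive":
        if not cohort.data["aggressive"].notna().any():
            raise CohortValidationError(
                "endpoint='aggressive' but no aggressive flags are present"
            )
        return fc["n_aggressive"]
    return fc["n_affected"] - fc["n_aggressive"]


def dominant_code(genotype: str | None, risk_allele: str) -> int | None:
    """Dominant coding of one genotype: 1 iff the risk allele appears.

    ``None`` (missing) propagates.  The risk allele must be a single
    allele character; pass the SNP's declared risk allele.
    """
    if len(risk_allele) != 1:
        raise ValueError(f"risk allele must be one allele, got {risk_allele!r}")
    if genotype is None:
        return None
    return int(risk_allele in genotype)


def dominant_codes(cohort: Cohort, snp: str | SnpDef) -> np.ndarray:
    """Vectorised dominant codes for a cohort column (NaN where missing)."""
    sd = cohort.snp(snp) if isinstance(snp, str) else snp
    col = cohort.data[sd.name]
    return np.array(
        [np.nan if g is None else float(sd.risk_allele in g) for g in col]
    )


@dataclasses.dataclass
class ContingencyTable:
    """Carrier-vs-noncarrier subject counts binned by family case count.

    ``cells`` is a K x 2 integer array (columns: noncarriers, carriers);
    ``row_percentages`` the corresponding within-bin shares (summing to 100
    per bin).  Column sums equal the number of subjects genotyped at the
    SNP, because every genotyped member of a family is a row of the table.
    """

    snp: str
    endpoint: str
    bins: tuple[object, ...]
    cells: np.ndarray
    row_percentages: np.ndarray

    @property
    def totals(self) -> np.ndarray:
        return self.cells.sum(axis=0)

    def to_frame(self, decimals: int = 1) -> pd.DataFrame:
        pct = np.round(self.row_percentages, decimals)
        df = pd.DataFrame(
            {
                "cases_in_family": [str(b) for b in self.bins],
                "noncarriers": self.cells[:, 0],
                "noncarriers_pct": pct[:, 0],
                "carriers": self.cells[:, 1],
                "carriers_pct": pct[:, 1],
            }
        )
        total = pd.DataFrame(
            {
                "cases_in_family": ["total"],
                "noncarriers": [int(self.totals[0])],
                "noncarriers_pct": [np.nan],
                "carriers": [int(self.totals[1])],
                "carriers_pct": [np.nan],
            }
        )
        return pd.concat([df, total], ignore_index=True)


def _parse_bins(bins: Sequence[object]) -> list[tuple[object, int, float]]:
    """Each bin -> (label, low, high) inclusive; 'k+' means [k, inf)."""
    parsed = []
    for b in bins:
        if isinstance(b, str) and b.endswith("+"):
            parsed.append((b, int(b[:-1]), np.inf))
        else:
            parsed.append((b, int(b), float(int(b))))
    return parsed


def carrier_count_table(
    cohort: Cohort,
    snp: str,
    endpoint: str = "all",
    bins: Sequence[object] | None = None,
) -> ContingencyTable:
    """Tabulate carrier status against the per-family case-count outcome.

    Every subject genotyped at ``snp`` contributes one count to the bin of
    their family's case count; subjects with a missing genotype are
    excluded from the table (they are not genotyped rows).  Bins not
    observed in the data are reported with zero counts; an observed
    family count falling outside all bins is an error.
    """
    if bins is None:
        bins = PAPER_BINS_AGGRESSIVE if endpoint == "aggressive" else PAPER_BINS_ALL
    parsed = _parse_bins(bins)
    outcome = family_outcome(cohort, endpoint)
    codes = dominant_codes(cohort, snp)
    y = cohort.data["family_id"].map(outcome).to_numpy(dtype=float)

    cells = np.zeros((len(parsed), 2), dtype=int)
    mask = ~np.isnan(codes)
    for yi, ci in zip(y[mask], codes[mask].astype(int)):
        for k, (_, lo, hi) in enumerate(parsed):
            if lo <= yi <= hi:
                cells[k, ci] += 1
                break
        else:
            raise ValueError(
                f"family case count {int(yi)} falls outside bins {list(bins)}"
            )
    row_tot = cells.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * cells / row_tot
    return ContingencyTable(
        snp=snp,
        endpoint=endpoint,
        bins=tuple(bins),
        cells=cells,
        row_percentages=pct,
    )


def contingency_chisq(table: ContingencyTable) -> tuple[float, int, float]:
    """Pearson chi-square of independence on the K x 2 count table.

    Returns ``(statistic, df, p)`` with ``df = K - 1``.  Bins with zero
    subjects produce zero expected counts and are not testable; the error
    advises merging them.
    """
    cells = table.cells
    if cells.shape[0] < 2:
        raise ValueError("need at least 2 bins for a chi-square test")
    if (cells.sum(axis=1) == 0).any() or (cells.sum(axis=0) == 0).any():
        raise ValueError(
            "a bin (or carrier column) has zero subjects, so expected counts "
            "are zero; merge the empty bin with a neighbour before testing"
        )
    stat, p, df, _ = stats.chi2_contingency(cells, correction=False)
    return float(stat), int(df), float(p)


def trend_test(table: ContingencyTable) -> tuple[float, float]:
    """Cochran-Armitage-style trend test of carrier share across bins.

    Scores are the bins' numeric values ('k+' scores as k).  Returns the
    signed z statistic (positive = carrier share increases with case
    count) and the two-sided normal p-value.
    """
    scores = np.array([lo for _, lo, _ in _parse_bins(table.bins)], dtype=float)
    n = table.cells.sum(axis=1).astype(float)
    c = table.cells[:, 1].astype(float)
    N, C = n.sum(), c.sum()
    if N == 0 or C == 0 or C == N:
        raise ValueError("degenerate table: carrier share is constant")
    pbar = C / N
    t = float(np.sum(scores * (c - n * pbar)))
    var = pbar * (1 - pbar) * (np.sum(scores**2 * n) - np.sum(scores * n) ** 2 / N)
    z = t / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))
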