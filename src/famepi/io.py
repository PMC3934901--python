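"""Reading, validating and writing per-individual family-cohort tables.

The canonical input is a UTF-8 TSV with a header row and one row per
subject::

    family_id  subject_id  age  affected  aggressive  rs4242382  rs10486567
    F001       F001_01     65   1         0           GA         GG

Genotypes are unordered two-letter allele strings over the SNP's declared
alphabet (``GA`` and ``AG`` are the same genotype and are normalised to
sorted order on read); the missing token is ``NA``.  A whitespace-delimited
PED-style reader is provided for interoperability, but the TSV is canonical.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

MISSING_TOKEN = "NA"

#: canonical column names; a ``schema`` mapping may rename any of them.
CORE_COLUMNS = ("family_id", "subject_id", "age", "affected", "aggressive")

_TRUE_TOKENS = {"1", "true", "t", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "f", "no", "n"}


class CohortError(ValueError):
    """Base class for cohort file problems."""


class CohortParseError(CohortError):
    """A cell could not be parsed; the message names the offending row."""


class CohortValidationError(CohortError):
    """The parsed table violates a cohort invariant."""


@dataclasses.dataclass(frozen=True)
class SnpDef:
    """A SNP with its allele alphabet and (mandatory) risk allele.

    The risk allele is never defaulted: dominant coding is meaningless
    without it, and for loci such as rs10486567 the literature is not even
    internally consistent about which allele confers risk.
    """

    name: str
    risk_allele: str
    alleles: tuple[str, str] = ("A", "G")

    def __post_init__(self) -> None:
        if self.risk_allele not in self.alleles:
            raise CohortValidationError(
                f"risk allele {self.risk_allele!r} for {self.name} not in "
                f"alphabet {self.alleles}"
            )

    def normalize(self, token: str, row: object = "?") -> str | None:
        """Normalise a genotype token to sorted allele order; ``NA`` -> None."""
        token = token.strip()
        if token == MISSING_TOKEN or token == "":
            return None
        if len(token) != 2 or any(a not in self.alleles for a in token):
            raise CohortParseError(
                f"row {row}: genotype {token!r} at {self.name} is not a pair "
                f"of alleles from {'/'.join(self.alleles)}"
            )
        return "".join(sorted(token))


@dataclasses.dataclass(frozen=True)
class Individual:
    """One subject; ``genotypes`` maps SNP name to a normalised pair or None."""

    subject_id: str
    family_id: str
    age: float
    affected: bool
    aggressive: bool | None
    genotypes: Mapping[str, str | None]


@dataclasses.dataclass
class Cohort:
    """A validated family cohort.

    ``data`` has the core columns plus one object column per SNP holding
    normalised genotype strings (``None`` when missing).  Row order is the
    file order.  ``aggressive`` is a nullable boolean: missing is allowed
    and is treated as "not known aggressive" by downstream counts.
    """

    data: pd.DataFrame
    snps: tuple[SnpDef, ...]

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_families(self) -> int:
        return self.data["family_id"].nunique()

    def snp(self, name: str) -> SnpDef:
        for s in self.snps:
            if s.name == name:
                return s
        raise KeyError(f"SNP {name!r} not declared in cohort")

    def individuals(self) -> Iterator[Individual]:
        snp_names = [s.name for s in self.snps]
        for rec in self.data.itertuples(index=False):
            d = rec._asdict()
            aggr = d["aggressive"]
            yield Individual(
                subject_id=d["subject_id"],
                family_id=d["family_id"],
                age=d["age"],
                affected=bool(d["affected"]),
                aggressive=None if pd.isna(aggr) else bool(aggr),
                genotypes={n: d[n] for n in snp_names},
            )

    def validate(self, strict: bool = False) -> "Cohort":
        """Check cohort invariants; return self.

        ``strict`` additionally enforces the multiplex-family design: every
        family has at least two members and between 2 and 6 affected members
        (the study enrolled families through index cases with 2-6 cases).
        """
        _validate_frame(self.data, self.snps, strict=strict)
        return self


def _validate_frame(df: pd.DataFrame, snps: Sequence[SnpDef], strict: bool) -> None:
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if not dup.empty:
        raise CohortValidationError(
            f"duplicate subject_id {dup.iloc[0]!r} (row {dup.index[0] + 2})"
        )
    if (df["age"] < 0).any():
        bad = df.index[df["age"] < 0][0]
        raise CohortValidationError(f"row {bad + 2}: negative age")
    aggr = df["aggressive"]
    bad_aggr = aggr.notna() & aggr.astype("boolean").fillna(False) & ~df["affected"]
    if bad_aggr.any():
        row = df.index[bad_aggr][0]
        raise CohortValidationError(
            f"row {row + 2}: aggressive=true but affected=false "
            f"(subject {df.loc[row, 'subject_id']!r})"
        )
    if strict:
        grp = df.groupby("family_id", sort=False)
        sizes = grp.size()
        if (sizes < 2).any():
            fam = sizes.index[sizes < 2][0]
            raise CohortValidationError(
                f"strict mode: family {fam!r} has fewer than 2 members"
            )
        n_aff = grp["affected"].sum()
        bad = n_aff[(n_aff < 2) | (n_aff > 6)]
        if not bad.empty:
            raise CohortValidationError(
                f"strict mode: family {bad.index[0]!r} has {int(bad.iloc[0])} "
                "affected members (multiplex design requires 2-6)"
            )


def _parse_bool(token: str, row: int, col: str, allow_missing: bool) -> object:
    t = token.strip().lower()
    if t in _TRUE_TOKENS:
        return True
    if t in _FALSE_TOKENS:
        return False
    if allow_missing and (t == MISSING_TOKEN.lower() or t == ""):
        return pd.NA
    raise CohortParseError(f"row {row}: cannot parse {col}={token!r} as boolean")


def read_cohort(
    path: str | Path,
    snps: Sequence[SnpDef],
    schema: Mapping[str, str] | None = None,
    strict: bool = False,
) -> Cohort:
    """Read a cohort TSV into a validated :class:`Cohort`.

    Parameters
    ----------
    path:
        TSV file with a header.
    snps:
        SNP declarations; each ``SnpDef.name`` (via ``schema``) must be a
        column.
    schema:
        Optional mapping from canonical column names (``family_id`` ...,
        SNP names) to the file's column names.
    strict:
        Enforce the multiplex-family invariant (see :meth:`Cohort.validate`).
    """
    schema = dict(schema or {})
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    colmap = {name: schema.get(name, name) for name in CORE_COLUMNS}
    colmap.update({s.name: schema.get(s.name, s.name) for s in snps})
    missing_cols = [v for v in colmap.values() if v not in raw.columns]
    if missing_cols:
        raise CohortParseError(f"missing column(s) {missing_cols} in {path}")

    out: dict[str, object] = {}
    out["family_id"] = raw[colmap["family_id"]].str.strip()
    out["subject_id"] = raw[colmap["subject_id"]].str.strip()
    ages = []
    for i, tok in enumerate(raw[colmap["age"]]):
        tok = tok.strip()
        if tok in ("", MISSING_TOKEN):
            ages.append(math.nan)
            continue
        try:
            ages.append(float(tok))
        except ValueError:
            raise CohortParseError(f"row {i + 2}: cannot parse age={tok!r}") from None
    out["age"] = np.asarray(ages, dtype=float)
    out["affected"] = [
        _parse_bool(t, i + 2, "affected", allow_missing=False)
        for i, t in enumerate(raw[colmap["affected"]])
    ]
    out["aggressive"] = pd.array(
        [
            _parse_bool(t, i + 2, "aggressive", allow_missing=True)
            for i, t in enumerate(raw[colmap["aggressive"]])
        ],
        dtype="boolean",
    )
    for s in snps:
        out[s.name] = [
            s.normalize(tok, row=i + 2) for i, tok in enumerate(raw[colmap[s.name]])
        ]
    df = pd.DataFrame(out)
    df["affected"] = df["affected"].astype(bool)
    cohort = Cohort(data=df, snps=tuple(snps))
    return cohort.validate(strict=strict)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort back to the canonical TSV (round-trip exact)."""
    df = cohort.data.copy()
    df["affected"] = df["affected"].map({True: "1", False: "0"})
    df["aggressive"] = df["aggressive"].map(
        {True: "1", False: "0", pd.NA: MISSING_TOKEN}
    )
    df["age"] = [_fmt_number(a) for a in df["age"]]
    for s in cohort.snps:
        df[s.name] = df[s.name].map(lambda g: MISSING_TOKEN if g is None else g)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_ped(
    path: str | Path,
    snps: Sequence[SnpDef],
    strict: bool = False,
) -> Cohort:
    """Read a whitespace-delimited PED-style file (secondary entry point).

    Expected columns: family, individual, father, mother, sex, phenotype
    (1 = unaffected, 2 = affected), then two allele columns per declared SNP
    in order (``0`` = missing allele).  Ages and aggressiveness are not
    representable in PED and come back missing/NaN and NA respectively.
    """
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * len(snps):
                raise CohortParseError(
                    f"row {i + 1}: expected {6 + 2 * len(snps)} fields, "
                    f"got {len(fields)}"
                )
            rec: dict[str, object] = {
                "family_id": fields[0],
                "subject_id": fields[1],
                "age": math.nan,
                "affected": fields[5] == "2",
                "aggressive": pd.NA,
            }
            for j, s in enumerate(snps):
                a1, a2 = fields[6 + 2 * j], fields[7 + 2 * j]
                if a1 == "0" or a2 == "0":
                    rec[s.name] = None
                else:
                    rec[s.name] = s.normalize(a1 + a2, row=i + 1)
            rows.append(rec)
    df = pd.DataFrame(rows)
    df["aggressive"] = df["aggressive"].astype("boolean")
    return Cohort(data=df, snps=tuple(snps)).validate(strict=strict)


def _fmt_number(v: object, precision: int = 4) -> str:
    if isinstance(v, (bool, np.bool_)):
        return "1" if v else "0"
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return MISSING_TOKEN
    if isinstance(v, (int, np.integer)):
        return str(int(v))
    if isinstance(v, (float, np.floating)):
        if float(v).is_integer() and abs(v) < 1e15:
            return str(int(v))
        return f"{float(v):.{precision}f}"
    return str(v)


def write_table(
    rows: pd.DataFrame | Iterable[Mapping[str, object]],
    path: str | Path,
    format: str = "tsv",
    precision: int = 4,
) -> None:
    """Write homogeneous result records deterministically.

    Column order is the DataFrame's (or the first record's) order; floats
    are rendered at a fixed precision so two identical runs produce
    byte-identical files.  An empty record set yields a header-only file
    when the input is a DataFrame (which still carries columns).
    """
    if format not in ("tsv", "csv"):
        raise ValueError(f"unknown format {format!r}")
    sep = "\t" if format == "tsv" else ","
    if not isinstance(rows, pd.DataFrame):
        rows = pd.DataFrame(list(rows))
    cols = list(rows.columns)
    lines = [sep.join(map(str, cols))]
    for rec in rows.itertuples(index=False):
        lines.append(sep.join(_fmt_number(v, precision) for v in rec))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
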