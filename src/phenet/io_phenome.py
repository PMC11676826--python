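"""Tabular I/O, phenocode hierarchy utilities and export schemas.

Phenocodes are hierarchical strings such as ``"250"``, ``"250.1"`` or
``"250.11"``.  The *level* of a code is the number of digits after the
decimal point (0, 1 or 2), and a patient diagnosed with a level-1 or
level-2 code implicitly also carries every truncation ancestor of that
code.  Codes are handled as strings throughout: treating them as floats
would collapse distinct codes such as ``"250.10"`` and ``"250.1"``.

Edge lists are exchanged in four tab-separated schemas named after the
supplementary files they mirror:

========  =======================================================
schema    columns
========  =======================================================
``S3``    From, To, N, betaMerged, FromCode, ToCode, SNPs
``S4``    S3 columns plus C, MCC, fisherp
``S5``    Phenocode, Disease, Prev, Dprev, Category, Sink, Level
``S6``    First, Second, MedianTime, Time
========  =======================================================

``Time`` in the S6 schema is a categorical bin of the median inter-event
time in years: 1 for [0, 1), 2 for [1, 3), 3 for [3, 5), 4 for [5, 10)
and 5 for 10 years or more.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Grammar for a phenocode: 1-3 integer digits, optionally "." plus 1-2 digits.
PHENOCODE_RE = re.compile(r"^\d{1,3}(\.\d{1,2})?$")

#: Right edges (years, exclusive) of the S6 inter-event time bins 1..4;
#: everything at or above the last edge falls in bin 5.
TIME_BIN_EDGES = (1.0, 3.0, 5.0, 10.0)

SCHEMAS: dict[str, list[str]] = {
    "S3": ["From", "To", "N", "betaMerged", "FromCode", "ToCode", "SNPs"],
    "S4": ["From", "To", "N", "betaMerged", "FromCode", "ToCode", "SNPs",
           "C", "MCC", "fisherp"],
    "S5": ["Phenocode", "Disease", "Prev", "Dprev", "Category", "Sink", "Level"],
    "S6": ["First", "Second", "MedianTime", "Time"],
}

SUMMARY_STAT_COLUMNS = ["snp_id", "chrom", "pos", "phenocode", "beta", "pval", "maf"]


class PhenocodeFormatError(ValueError):
    """A string does not match the phenocode grammar."""


class SchemaError(ValueError):
    """A table is missing required columns or fields."""


class ParseError(ValueError):
    """A table cell could not be parsed as the expected type."""


@dataclass(frozen=True)
class Phenocode:
    """One phenotype code with its metadata-table attributes.

    The category is taken from the code's own metadata row; it is *not*
    inherited from (nor assumed to agree with) the code's ancestors.
    """

    code: str
    category: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if not PHENOCODE_RE.match(self.code):
            raise PhenocodeFormatError(f"malformed phenocode: {self.code!r}")

    @property
    def level(self) -> int:
        return phenocode_level(self.code)

    @property
    def ancestors(self) -> list[str]:
        return phenocode_ancestors(self.code)


def phenocode_level(code: str) -> int:
    """Number of digits after the decimal point (0 for integer codes)."""
    if not PHENOCODE_RE.match(code):
        raise PhenocodeFormatError(f"malformed phenocode: {code!r}")
    return len(code.partition(".")[2])


def phenocode_ancestors(code: str) -> list[str]:
    """Ancestor codes obtained by truncating one trailing digit at a time.

    Nearest ancestor first: ``"250.11" -> ["250.1", "250"]``.  Level-0
    codes have no ancestors.
    """
    if not PHENOCODE_RE.match(code):
        raise PhenocodeFormatError(f"malformed phenocode: {code!r}")
    out = []
    head, _, decimals = code.partition(".")
    while decimals:
        decimals = decimals[:-1]
        out.append(f"{head}.{decimals}" if decimals else head)
    return out


def is_ancestor(a: str, b: str) -> bool:
    """True when ``a`` is a truncation ancestor of ``b`` (strictly)."""
    return a in phenocode_ancestors(b)


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")


def _coerce_numeric(df: pd.DataFrame, columns: list[str], what: str) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            # +2: one for the header row, one for 1-based line numbers
            line = int(df.index[bad][0]) + 2
            raise ParseError(
                f"{what}: non-numeric value {df[col][bad].iloc[0]!r} "
                f"in column {col!r} at line {line}"
            )
        df[col] = coerced
    return df


def read_summary_stats(
    path,
    p_threshold: float = 1e-6,
    maf_cutoff: float = 0.001,
) -> pd.DataFrame:
    """Read a PheWAS top-hit table and apply the association filters.

    The TSV must carry the columns ``snp_id, chrom, pos, phenocode, beta,
    pval, maf``.  Rows with ``pval >= p_threshold`` or ``maf < maf_cutoff``
    are dropped (and counted in the log); duplicate ``(snp_id, phenocode)``
    rows raise a :class:`SchemaError`.
    """
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str,
                                            "phenocode": str})
    _check_columns(df, SUMMARY_STAT_COLUMNS, "summary statistics")
    df = _coerce_numeric(df, ["pos", "beta", "pval", "maf"], "summary statistics")
    dup = df.duplicated(subset=["snp_id", "phenocode"])
    if dup.any():
        pair = df.loc[dup, ["snp_id", "phenocode"]].iloc[0]
        raise SchemaError(
            f"duplicate association row for SNP {pair.snp_id!r} "
            f"and phenocode {pair.phenocode!r}"
        )
    keep = (df["pval"] < p_threshold) & (df["maf"] >= maf_cutoff)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("read_summary_stats: dropped %d of %d rows failing "
                    "p < %g or MAF >= %g", dropped, len(df), p_threshold, maf_cutoff)
    if len(df) == 0:
        logger.warning("read_summary_stats: %s contains no data rows", path)
    df = df.loc[keep].reset_index(drop=True)
    df["pos"] = df["pos"].astype(int)
    return df


def read_phenocode_metadata(path) -> pd.DataFrame:
    """Read the phenocode metadata table (phenocode, description, category)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _check_columns(df, ["phenocode", "description", "category"], "phenocode metadata")
    for code in df["phenocode"]:
        if not PHENOCODE_RE.match(code):
            raise PhenocodeFormatError(f"malformed phenocode: {code!r}")
    return df


def read_ld_table(path) -> pd.DataFrame:
    """Read a long-format pairwise LD table (snp1, snp2, r2)."""
    df = pd.read_csv(path, sep="\t", dtype={"snp1": str, "snp2": str})
    _check_columns(df, ["snp1", "snp2", "r2"], "LD table")
    df = _coerce_numeric(df, ["r2"], "LD table")
    return df


def read_events(path) -> pd.DataFrame:
    """Read patient diagnosis events (patient_id, phenocode, date)."""
    df = pd.read_csv(path, dtype={"patient_id": str, "phenocode": str})
    _check_columns(df, ["patient_id", "phenocode", "date"], "events")
    df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    return df


def read_patients(path) -> pd.DataFrame:
    """Read the patient table.

    Columns: ``patient_id, sex, birth_date, death_date, cod_phenocodes``
    where ``sex`` is a 0/1 code, ``death_date`` may be empty and
    ``cod_phenocodes`` is a ``;``-separated list of cause-of-death codes
    (empty for survivors).
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "cod_phenocodes": str})
    _check_columns(df, ["patient_id", "sex", "birth_date"], "patients")
    df["birth_date"] = pd.to_datetime(df["birth_date"], format="ISO8601")
    if "death_date" in df.columns:
        df["death_date"] = pd.to_datetime(df["death_date"], format="ISO8601")
    else:
        df["death_date"] = pd.NaT
    if "cod_phenocodes" not in df.columns:
        df["cod_phenocodes"] = ""
    df["cod_phenocodes"] = df["cod_phenocodes"].fillna("")
    return df


def read_icd_map(path) -> pd.DataFrame:
    """Read a two-column ICD-to-phenocode mapping table (icd, phenocode)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _check_columns(df, ["icd", "phenocode"], "ICD map")
    return df


def time_bin(median_years) -> int | np.ndarray:
    """Categorical bin of a median inter-event time in years.

    Bins are left-closed/right-open: [0,1) -> 1, [1,3) -> 2, [3,5) -> 3,
    [5,10) -> 4, [10,inf) -> 5.
    """
    bins = np.searchsorted(TIME_BIN_EDGES, median_years, side="right") + 1
    if np.isscalar(median_years):
        return int(bins)
    return bins


def write_edgelist(table: pd.DataFrame, schema: str, path) -> None:
    """Write a table in one of the S3/S4/S5/S6 schemas.

    For S6, the ``Time`` bin is derived from ``MedianTime`` when absent.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    table = table.copy()
    if schema == "S6" and "Time" not in table.columns:
        table["Time"] = time_bin(table["MedianTime"].to_numpy())
    missing = [c for c in SCHEMAS[schema] if c not in table.columns]
    if missing:
        raise SchemaError(f"schema {schema}: table is missing field(s) {missing}")
    table[SCHEMAS[schema]].to_csv(path, sep="\t", index=False)


def read_edgelist(path, schema: str) -> pd.DataFrame:
    """Read a table written by :func:`write_edgelist`."""
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema {schema!r}; expected one of {sorted(SCHEMAS)}")
    str_cols = {"From", "To", "FromCode", "ToCode", "SNPs", "Phenocode",
                "Disease", "Category", "First", "Second"}
    df = pd.read_csv(path, sep="\t", dtype={c: str for c in str_cols})
    _check_columns(df, SCHEMAS[schema], f"schema {schema}")
    return df


def write_graphml(graph: nx.Graph, path) -> None:
    """GraphML export; list-valued attributes are joined with ``;``."""
    g = graph.copy()
    for _, _, data in g.edges(data=True):
        for key, value in list(data.items()):
            if isinstance(value, (list, tuple, set, frozenset)):
                data[key] = ";".join(sorted(map(str, value)))
    for _, data in g.nodes(data=True):
        for key, value in list(data.items()):
            if isinstance(value, (list, tuple, set, frozenset)):
                data[key] = ";".join(sorted(map(str, value)))
    nx.write_graphml(g, path)
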