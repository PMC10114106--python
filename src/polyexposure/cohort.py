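"""Cohort data model: validated rectangular tables, group splits, complete cases.

A cohort is a rectangle with one row per individual: an ``ID`` column of
unique identifiers, a ``PHENO`` outcome (real-valued, or 0/1), an optional
``TIME`` column (follow-up time, required for survival analysis, in which
case ``PHENO`` is the 0/1 event indicator), and any number of exposure and
covariate columns, each continuous or categorical.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FAMILIES = ("lm", "logistic", "cox")

ID_COL = "ID"
PHENO_COL = "PHENO"
TIME_COL = "TIME"
RESERVED = {ID_COL, PHENO_COL, TIME_COL}

#: sentinel strings treated as missing on load
NA_VALUES = ("", "NA")


class CohortError(ValueError):
    """Raised for schema or validation failures on cohort tables."""


def check_family(family: str) -> str:
    if family not in FAMILIES:
        raise CohortError(f"unknown model family {family!r}; expected one of {FAMILIES}")
    return family


@dataclass
class CohortTable:
    """A validated cohort rectangle plus column metadata.

    Parameters
    ----------
    frame : DataFrame indexed by position, containing ID, PHENO, optional
        TIME, and every exposure/covariate column.
    family : one of ``lm`` / ``logistic`` / ``cox``.
    roles : mapping column -> ``"exposure"`` or ``"covariate"``.
    kinds : mapping column -> ``"continuous"`` or ``"categorical"``.
    levels : per categorical column, the ordered level set; the first level
        is the dummy-coding reference.
    """

    frame: pd.DataFrame
    family: str
    roles: dict[str, str]
    kinds: dict[str, str]
    levels: dict[str, list[str]] = field(default_factory=dict)

    # -- accessors -------------------------------------------------------
    @property
    def ids(self) -> pd.Series:
        return self.frame[ID_COL]

    @property
    def pheno(self) -> pd.Series:
        return self.frame[PHENO_COL]

    @property
    def time(self) -> pd.Series | None:
        return self.frame[TIME_COL] if TIME_COL in self.frame else None

    @property
    def event(self) -> pd.Series | None:
        """For survival cohorts the 0/1 event indicator (PHENO doubles as it)."""
        return self.frame[PHENO_COL] if self.family == "cox" else None

    @property
    def n(self) -> int:
        return len(self.frame)

    def columns_with_role(self, role: str) -> list[str]:
        return [c for c, r in self.roles.items() if r == role]

    @property
    def exposures(self) -> list[str]:
        return self.columns_with_role("exposure")

    @property
    def covariates(self) -> list[str]:
        return self.columns_with_role("covariate")

    def subset_ids(self, ids) -> "CohortTable":
        """Row-subset to the given identifiers, preserving order of the table."""
        keep = self.frame[ID_COL].isin(set(ids))
        return CohortTable(self.frame.loc[keep].reset_index(drop=True),
                           self.family, dict(self.roles), dict(self.kinds),
                           {k: list(v) for k, v in self.levels.items()})

    def validate(self) -> "CohortTable":
        f = self.frame
        for col in (ID_COL, PHENO_COL):
            if col not in f.columns:
                raise CohortError(f"required column {col!r} is missing")
        dup = f[ID_COL][f[ID_COL].duplicated()].unique()
        if len(dup):
            raise CohortError(f"duplicate IDs: {sorted(map(str, dup))}")
        if f[PHENO_COL].isna().any():
            raise CohortError("PHENO contains missing values")
        pheno = pd.to_numeric(f[PHENO_COL], errors="coerce")
        if pheno.isna().any():
            raise CohortError("PHENO must be numeric")
        check_family(self.family)
        if self.family in ("logistic", "cox"):
            vals = set(pheno.unique())
            if not vals <= {0, 1}:
                raise CohortError(
                    f"family={self.family} requires 0/1 PHENO; saw values {sorted(vals)[:5]}")
        if self.family == "cox":
            if TIME_COL not in f.columns:
                raise CohortError("family=cox requires a TIME column")
            t = pd.to_numeric(f[TIME_COL], errors="coerce")
            if t.isna().any():
                raise CohortError("TIME contains missing or non-numeric values")
            if (t <= 0).any():
                raise CohortError("TIME must be strictly positive")
        for col, role in self.roles.items():
            if role not in ("exposure", "covariate"):
                raise CohortError(f"column {col!r} has unknown role {role!r}")
            if col not in f.columns:
                raise CohortError(f"role declared for absent column {col!r}")
            if self.kinds.get(col) not in ("continuous", "categorical"):
                raise CohortError(f"column {col!r} must be tagged continuous or categorical")
        for col in self.roles:
            if self.kinds[col] == "categorical" and col not in self.levels:
                obs = f[col].dropna().astype(str)
                # first-seen order gives a deterministic reference level
                self.levels[col] = list(dict.fromkeys(obs))
        return self


def _sniff_delimiter(path: str) -> str:
    with open(path, newline="") as fh:
        header = fh.readline()
    try:
        return csv.Sniffer().sniff(header, delimiters=",\t").delimiter
    except csv.Error:
        return ","


def load_cohort(path: str, family: str, roles: dict[str, str],
                kinds: dict[str, str] | None = None,
                categorical_spec: dict[str, list[str]] | None = None,
                delimiter: str | None = None) -> CohortTable:
    """Load and validate a delimited cohort file.

    ``roles`` maps each analysis column to ``exposure``/``covariate``; file
    columns not named there (beyond ID/PHENO/TIME) are ignored with a
    warning. ``kinds`` tags columns continuous/categorical; unspecified
    columns are inferred (numeric dtype -> continuous). ``categorical_spec``
    optionally fixes the ordered level set per categorical column.
    """
    check_family(family)
    sep = delimiter or _sniff_delimiter(path)
    frame = pd.read_csv(path, sep=sep, dtype={ID_COL: str},
                        na_values=list(NA_VALUES), keep_default_na=False)
    ignored = [c for c in frame.columns if c not in roles and c not in RESERVED]
    if ignored:
        logger.warning("ignoring %d column(s) without a declared role: %s",
                       len(ignored), ignored)
        frame = frame.drop(columns=ignored)
    kinds = dict(kinds or {})
    for col in roles:
        if col not in frame.columns:
            raise CohortError(f"role declared for absent column {col!r}")
        if col not in kinds:
            kinds[col] = ("continuous"
                          if pd.api.types.is_numeric_dtype(frame[col]) else "categorical")
    levels = {c: list(v) for c, v in (categorical_spec or {}).items()}
    for col, lv in levels.items():
        if kinds.get(col) != "categorical":
            raise CohortError(f"level spec given for non-categorical column {col!r}")
        frame[col] = frame[col].where(frame[col].isna(), frame[col].astype(str))
    table = CohortTable(frame, family, dict(roles), kinds, levels)
    return table.validate()


def write_cohort(cohort: CohortTable, path: str, delimiter: str = ",") -> None:
    """Write the cohort rectangle; values round-trip through load_cohort."""
    cohort.frame.to_csv(path, sep=delimiter, index=False, na_rep="NA")


@dataclass(frozen=True)
class GroupSplit:
    """Three non-overlapping identifier sets: A for variable selection,
    B for calibration, C for held-out scoring/validation."""

    ids_a: frozenset
    ids_b: frozenset
    ids_c: frozenset

    def __post_init__(self):
        if (self.ids_a & self.ids_b) or (self.ids_a & self.ids_c) or (self.ids_b & self.ids_c):
            overlap = (self.ids_a & self.ids_b) | (self.ids_a & self.ids_c) | (self.ids_b & self.ids_c)
            raise CohortError(f"groups overlap: {sorted(map(str, overlap))[:10]}")


def split_groups(cohort: CohortTable,
                 ids_a=None, ids_b=None, ids_c=None,
                 fractions: tuple[float, float, float] | None = None,
                 seed: int | None = None) -> GroupSplit:
    """Partition the cohort into groups A/B/C.

    Either pass explicit id lists (validated disjoint and present), or
    ``fractions=(fa, fb, fc)`` with ``fa+fb+fc <= 1`` plus a ``seed`` for a
    reproducible uniform-permutation partition.
    """
    all_ids = set(cohort.ids)
    if fractions is not None:
        fa, fb, fc = fractions
        if min(fa, fb, fc) < 0 or fa + fb + fc > 1 + 1e-12:
            raise CohortError("fractions must be >= 0 and sum to at most 1")
        if seed is None:
            raise CohortError("fractional splitting requires a seed")
        rng = np.random.default_rng(seed)
        perm = rng.permutation(np.asarray(cohort.ids, dtype=object))
        n = len(perm)
        na, nb = int(round(fa * n)), int(round(fb * n))
        nc = min(int(round(fc * n)), n - na - nb)
        return GroupSplit(frozenset(perm[:na]), frozenset(perm[na:na + nb]),
                          frozenset(perm[na + nb:na + nb + nc]))
    sets = [frozenset(x or ()) for x in (ids_a, ids_b, ids_c)]
    for name, s in zip("ABC", sets):
        extra = s - all_ids
        if extra:
            raise CohortError(f"group {name} contains unknown ids: {sorted(map(str, extra))[:10]}")
    return GroupSplit(*sets)


def complete_cases(cohort: CohortTable, columns: list[str],
                   unwanted: dict[str, set] | None = None) -> CohortTable:
    """Row-subset with no missing value and no unwanted response code in
    any of the named columns. Ordering is preserved; drops are logged.

    ``unwanted`` maps categorical column -> set of response values (for
    example survey codes like "prefer_not_to_answer") treated as invalid in
    addition to missing.
    """
    unwanted = unwanted or {}
    for col in columns:
        if col not in cohort.frame.columns:
            raise CohortError(f"unknown column {col!r}")
    for col in unwanted:
        if col in cohort.kinds and cohort.kinds[col] != "categorical":
            raise CohortError(f"unwanted codes declared for non-categorical column {col!r}")
    keep = pd.Series(True, index=cohort.frame.index)
    for col in columns:
        ok = cohort.frame[col].notna()
        if col in unwanted:
            ok &= ~cohort.frame[col].astype(str).isin({str(u) for u in unwanted[col]})
        keep &= ok
    if not keep.any():
        raise CohortError(f"no rows remain after complete-case filtering on {list(columns)}")
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("complete_cases: dropped %d of %d rows on %s",
                    n_drop, len(keep), list(columns))
    out = CohortTable(cohort.frame.loc[keep].reset_index(drop=True),
                      cohort.family, dict(cohort.roles), dict(cohort.kinds),
                      {k: list(v) for k, v in cohort.levels.items()})
    return out
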