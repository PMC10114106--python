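"""Term expansion: dummy coding of categoricals and (optional) standardization.

Term naming convention: a continuous column contributes one term named
after itself; a categorical column with ordered levels ``[ref, l2, l3]``
contributes dummy terms ``col=l2``, ``col=l3`` (reference level dropped).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import CohortError, CohortTable


def term_names(column: str, kind: str, levels: list[str] | None) -> list[str]:
    if kind == "continuous":
        return [column]
    if not levels or len(levels) < 2:
        return []
    return [f"{column}={lv}" for lv in levels[1:]]


def expand_columns(cohort: CohortTable, columns: list[str]) -> pd.DataFrame:
    """Expand the named cohort columns into numeric term columns.

    Categorical values outside the declared level set become NaN in every
    dummy term of that column (so downstream scoring can flag them).
    """
    out = {}
    for col in columns:
        kind = cohort.kinds.get(col, "continuous")
        if kind == "continuous":
            out[col] = pd.to_numeric(cohort.frame[col], errors="coerce").to_numpy(float)
        else:
            levels = cohort.levels.get(col)
            if not levels:
                raise CohortError(f"categorical column {col!r} has no level set")
            vals = cohort.frame[col].astype("object")
            known = vals.isin(levels) & vals.notna()
            for lv in levels[1:]:
                t = (vals == lv).astype(float).to_numpy()
                t[~known.to_numpy()] = np.nan
                out[f"{col}={lv}"] = t
    return pd.DataFrame(out, index=cohort.frame.index)


@dataclass
class TermCoding:
    """Frozen coding of exposure terms: dummy layout plus the training
    centers and scales used for standardization, so that weights learned on
    the training scale can be applied to new individuals exactly."""

    exposures: list[str]
    kinds: dict[str, str]
    levels: dict[str, list[str]]
    terms: list[str] = field(default_factory=list)
    term_exposure: dict[str, str] = field(default_factory=dict)
    center: dict[str, float] = field(default_factory=dict)
    scale: dict[str, float] = field(default_factory=dict)

    def terms_of(self, exposure: str) -> list[str]:
        return [t for t in self.terms if self.term_exposure[t] == exposure]

    def restrict(self, exposures: list[str]) -> "TermCoding":
        """A copy covering only the named exposures (same constants)."""
        keep = [e for e in self.exposures if e in set(exposures)]
        terms = [t for t in self.terms if self.term_exposure[t] in set(keep)]
        return TermCoding(keep,
                          {e: self.kinds[e] for e in keep},
                          {e: self.levels[e] for e in keep if e in self.levels},
                          terms,
                          {t: self.term_exposure[t] for t in terms},
                          {t: self.center[t] for t in terms},
                          {t: self.scale[t] for t in terms})

    def transform(self, cohort: CohortTable) -> pd.DataFrame:
        """Standardized term matrix for (a subset of) a cohort, using the
        stored centers/scales. Unseen categorical levels yield NaN rows."""
        sub = expand_columns(cohort, self.exposures)
        out = pd.DataFrame(index=sub.index)
        for t in self.terms:
            out[t] = (sub[t] - self.center[t]) / self.scale[t]
        return out

    @classmethod
    def fit(cls, cohort: CohortTable, exposures: list[str],
            drop_constant: bool = True) -> tuple["TermCoding", pd.DataFrame]:
        """Learn coding + standardization constants from (complete-case)
        training rows; returns the coding and the standardized matrix.

        Constant terms carry no information for selection and are dropped
        (with their exposure if all its terms vanish)."""
        import logging
        coding = cls(list(exposures),
                     {c: cohort.kinds[c] for c in exposures},
                     {c: list(cohort.levels[c]) for c in exposures
                      if cohort.kinds[c] == "categorical"})
        raw = expand_columns(cohort, exposures)
        Z = pd.DataFrame(index=raw.index)
        for col in exposures:
            for t in term_names(col, cohort.kinds[col], cohort.levels.get(col)):
                v = raw[t].to_numpy(float)
                mu, sd = float(np.nanmean(v)), float(np.nanstd(v))
                if sd == 0 or not np.isfinite(sd):
                    if drop_constant:
                        logging.getLogger(__name__).warning(
                            "dropping constant term %s", t)
                        continue
                    sd = 1.0
                coding.terms.append(t)
                coding.term_exposure[t] = col
                coding.center[t], coding.scale[t] = mu, sd
                Z[t] = (v - mu) / sd
        if not coding.terms:
            raise CohortError("all exposure terms are constant after filtering")
        return coding, Z
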