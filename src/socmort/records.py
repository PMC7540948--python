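"""Individual registry records: parsing, validation and cohort tallies.

The registry is a delimited text table with one row per adult subject:
``id,sex,birth_min,birth_max,entry_date,last_date,fate,origin``.  Dates are
ISO-8601 calendar days; internally every date is converted to a decimal
year so that ages and exposures are plain floats.

``fate`` is one of ``death`` (observed dead), ``censored`` (alive at the
end of the observation period) and ``unknown`` (disappeared; may have died
or permanently left the study population).  ``origin`` distinguishes
``natal`` subjects (present in a study group at maturity) from
``immigrant`` subjects (entered the study population after maturity).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FATES = ("death", "censored", "unknown")
ORIGINS = ("natal", "immigrant")

#: default sexes for which the out-migration (dispersal) machinery is active;
#: in cercopithecine primates males disperse, females are philopatric.
OUTMIGRATION_SEXES = frozenset({"M"})

_EPOCH = pd.Timestamp("1970-01-01")
_DAYS_PER_YEAR = 365.25


def to_decimal_year(date) -> float:
    """ISO date (string or Timestamp) -> decimal calendar year."""
    ts = pd.Timestamp(date)
    return 1970.0 + (ts - _EPOCH).days / _DAYS_PER_YEAR


def from_decimal_year(year: float) -> str:
    """Decimal year -> ISO date string (nearest day)."""
    ts = _EPOCH + pd.Timedelta(days=round((year - 1970.0) * _DAYS_PER_YEAR))
    return ts.strftime("%Y-%m-%d")


def from_decimal_year_array(years) -> np.ndarray:
    """Vectorised decimal-year -> ISO date strings."""
    days = np.round((np.asarray(years, dtype=float) - 1970.0) * _DAYS_PER_YEAR)
    ts = _EPOCH + pd.to_timedelta(days, unit="D")
    return ts.strftime("%Y-%m-%d").to_numpy()


@dataclass(frozen=True)
class IndividualRecord:
    """One subject's demographic facts, all dates as decimal years.

    ``birth_min == birth_max`` when the birth date is known; otherwise the
    true birth lies somewhere inside the closed bracket.
    """

    id: str
    sex: str  # 'F' or 'M'
    birth_min: float
    birth_max: float
    entry: float
    last: float
    fate: str
    origin: str

    @property
    def birth_known(self) -> bool:
        return self.birth_min == self.birth_max

    @property
    def birth_mid(self) -> float:
        return 0.5 * (self.birth_min + self.birth_max)

    def validate(self, outmigration_sexes=OUTMIGRATION_SEXES) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError(f"{self.id}: sex must be 'F' or 'M', got {self.sex!r}")
        if self.fate not in FATES:
            raise ValueError(f"{self.id}: unknown fate {self.fate!r}")
        if self.origin not in ORIGINS:
            raise ValueError(f"{self.id}: unknown origin {self.origin!r}")
        if not self.birth_min <= self.birth_max <= self.entry <= self.last:
            raise ValueError(
                f"{self.id}: requires birth_min <= birth_max <= entry <= last "
                f"({self.birth_min}, {self.birth_max}, {self.entry}, {self.last})"
            )
        if self.fate == "unknown" and self.sex not in outmigration_sexes:
            raise ValueError(
                f"{self.id}: fate 'unknown' only permitted for sexes with "
                f"out-migration enabled ({sorted(outmigration_sexes)})"
            )


def load_individuals(path, outmigration_sexes=OUTMIGRATION_SEXES) -> list[IndividualRecord]:
    """Read and validate a registry CSV; logs a tally by sex and fate.

    Raises ``ValueError`` with a row-numbered message on the first invalid
    row; missing columns raise immediately.
    """
    df = pd.read_csv(path, dtype={"id": str})
    return records_from_frame(df, outmigration_sexes, source=str(path))


def records_from_frame(df: pd.DataFrame, outmigration_sexes=OUTMIGRATION_SEXES,
                       source: str = "registry") -> list[IndividualRecord]:
    """Validate a registry DataFrame (ISO dates) into IndividualRecords."""
    required = ["id", "sex", "birth_min", "birth_max", "entry_date", "last_date", "fate", "origin"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False)):
        try:
            rec = IndividualRecord(
                id=str(row.id),
                sex=str(row.sex),
                birth_min=to_decimal_year(row.birth_min),
                birth_max=to_decimal_year(row.birth_max),
                entry=to_decimal_year(row.entry_date),
                last=to_decimal_year(row.last_date),
                fate=str(row.fate),
                origin=str(row.origin),
            )
            rec.validate(outmigration_sexes)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{source} row {i + 2}: {exc}") from exc
        records.append(rec)
    tally = cohort_tally(records)
    logger.info("loaded %d individuals: %s", len(records), tally["counts"])
    return records


def cohort_tally(records) -> dict:
    """Cohort composition: counts and percentages by sex, fate and birth knowledge.

    Percentages are within-sex for fates and whole-cohort for known births,
    matching how such compositions are conventionally reported.
    """
    counts: dict[str, int] = {}
    known_birth = 0
    by_sex = {"F": 0, "M": 0}
    for rec in records:
        by_sex[rec.sex] += 1
        key = f"{rec.sex}_{rec.fate}"
        counts[key] = counts.get(key, 0) + 1
        if rec.birth_known:
            known_birth += 1
    n = len(records)
    pct = {}
    for sex in ("F", "M"):
        for fate in FATES:
            c = counts.get(f"{sex}_{fate}", 0)
            pct[f"{sex}_{fate}"] = 100.0 * c / by_sex[sex] if by_sex[sex] else np.nan
    pct["known_birth"] = 100.0 * known_birth / n if n else np.nan
    return {
        "n": n,
        "n_by_sex": by_sex,
        "counts": counts,
        "known_birth": known_birth,
        "percent": pct,
    }


def load_interactions(path, kind: str) -> pd.DataFrame:
    """Load grooming (``date,actor,recipient,group``) or agonism
    (``date,winner,loser,group,decided``) records.

    Returns a DataFrame with a ``year`` column (decimal). For agonism only
    decided interactions are retained (undecided never enter ranking).
    """
    if kind == "grooming":
        required = ["date", "actor", "recipient", "group"]
        a_col, b_col = "actor", "recipient"
    elif kind == "agonism":
        required = ["date", "winner", "loser", "group"]
        a_col, b_col = "winner", "loser"
    else:
        raise ValueError(f"kind must be 'grooming' or 'agonism', got {kind!r}")
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    same = df[a_col] == df[b_col]
    if same.any():
        raise ValueError(f"{path}: {int(same.sum())} self-directed records ({a_col} == {b_col})")
    if kind == "agonism":
        if "decided" in df.columns:
            keep = df["decided"].astype(str).str.lower().isin(("true", "1", "yes"))
            dropped = len(df) - int(keep.sum())
            if dropped:
                logger.info("%s: dropped %d undecided agonistic records", path, dropped)
            df = df[keep].reset_index(drop=True)
    df = df.copy()
    df["year"] = [to_decimal_year(d) for d in df["date"]]
    return df
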