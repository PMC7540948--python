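"""Social-bond and social-status covariates from raw interaction records.

Two covariate families are built here:

* **DSI** (dyadic sociality index): grooming-based bond strength between
  pairs of adults.  Per-dyad grooming counts within each life-year of the
  focal are corrected for observation effort, mean-normalised within dyad
  type (female-female vs female-male) and life-year, then z-scored within
  the same stratum.  An individual's bond-strength covariate for a
  life-year (DSI_F with female partners, DSI_M with male partners) is the
  mean standardized index over the top ``k`` partners (default 3).
  Male-male dyads are never scored: adult males do not regularly groom
  one another in this study system.

* **Dominance rank**: monthly win-loss matrices of decided agonistic
  interactions among same-sex adults of one group, ordered by minimising
  the total number of wins below the diagonal.  Ordinal ranks become
  proportional ranks (fraction of same-sex adults dominated, 1 = top,
  0 = bottom) and are averaged within each life-year.

Grooming direction is pooled: a dyad's bond is symmetric in who groomed
whom.  The DSI z-score uses the sample (n-1 denominator) standard
deviation within each stratum.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import to_decimal_year

logger = logging.getLogger(__name__)

DEFAULT_ALPHA = {"F": 5.0, "M": 7.0}
TOP_PARTNERS = 3


@dataclass
class RankMatrix:
    """Pairwise decided-win counts for one (month, group, sex)."""

    month: str
    group: str
    sex: str
    ids: list
    wins: np.ndarray  # wins[i, j] = decided wins of ids[i] over ids[j]

    def __post_init__(self):
        w = np.asarray(self.wins, dtype=float)
        if w.shape != (len(self.ids), len(self.ids)):
            raise ValueError("wins matrix shape does not match ids")
        if (w < 0).any() or np.diag(w).any():
            raise ValueError("wins must be non-negative with zero diagonal")
        self.wins = w


@dataclass
class RankAssignment:
    ordinal: dict = field(default_factory=dict)  # id -> 1..n (1 = top)
    proportional: dict = field(default_factory=dict)  # id -> [0, 1] or NaN


def life_year_of(year: float, birth: float, alpha: float):
    """Life-year index t = floor(age - alpha) of an event, None pre-maturity."""
    x = (year - birth) - alpha
    return int(math.floor(x)) if x >= 0 else None


# ---------------------------------------------------------------------------
# DSI
# ---------------------------------------------------------------------------

def _dyad_type(sex_a: str, sex_b: str):
    pair = frozenset((sex_a, sex_b))
    if pair == frozenset({"F"}):
        return "FF"
    if pair == frozenset({"F", "M"}):
        return "FM"
    return None  # male-male: not scored


def bin_grooming(grooming: pd.DataFrame, individuals, alpha=None) -> pd.DataFrame:
    """Pool grooming events into (focal, partner, life_year) counts.

    Each record contributes once per adult member of the dyad as focal,
    binned by the focal's age at the interaction date under the registry
    birth (bracket midpoint when uncertain).  Direction is ignored.
    """
    alpha = alpha or DEFAULT_ALPHA
    info = {r.id: r for r in individuals}
    counts: dict[tuple, int] = {}
    for row in grooming.itertuples(index=False):
        year = row.year if hasattr(row, "year") else to_decimal_year(row.date)
        a, b = str(row.actor), str(row.recipient)
        for focal, partner in ((a, b), (b, a)):
            rf, rp = info.get(focal), info.get(partner)
            if rf is None or rp is None:
                continue
            if _dyad_type(rf.sex, rp.sex) is None:
                continue
            # both members must be adult at the interaction
            if life_year_of(year, rp.birth_mid, alpha[rp.sex]) is None:
                continue
            t = life_year_of(year, rf.birth_mid, alpha[rf.sex])
            if t is None:
                continue
            key = (focal, partner, t)
            counts[key] = counts.get(key, 0) + 1
    return pd.DataFrame(
        [(f, p, t, c) for (f, p, t), c in sorted(counts.items())],
        columns=["focal", "partner", "life_year", "count"],
    )


def compute_dyadic_rates(counts: pd.DataFrame, effort: pd.DataFrame,
                         individuals) -> pd.DataFrame:
    """Effort-corrected, mean-normalised grooming rates per dyad-year.

    ``effort`` rows (``id_a,id_b,life_year,effort``) define the set of
    observed dyad-years (focal = id_a); zero-grooming dyad-years under
    observation enter with count 0.  The rate is count/effort divided by
    the mean rate of same-type dyads in the same life-year, so the
    population-mean dyad scores 1.  Grooming observed for a dyad-year with
    no (or non-positive) effort is rejected with a warning.
    """
    sex = {r.id: r.sex for r in individuals}
    eff = effort.copy()
    eff["id_a"] = eff["id_a"].astype(str)
    eff["id_b"] = eff["id_b"].astype(str)
    bad = eff["effort"] <= 0
    if bad.any():
        logger.warning("dropping %d effort rows with non-positive effort", int(bad.sum()))
        eff = eff[~bad]
    key_cols = ["focal", "partner", "life_year"]
    eff = eff.rename(columns={"id_a": "focal", "id_b": "partner"})
    merged = eff.merge(counts, on=key_cols, how="left")
    merged["count"] = merged["count"].fillna(0.0)
    if len(counts):
        orphan = counts.merge(eff[key_cols], on=key_cols, how="left", indicator=True)
        n_orphan = int((orphan["_merge"] == "left_only").sum())
        if n_orphan:
            logger.warning(
                "rejecting %d grooming dyad-years with zero/missing effort", n_orphan
            )
    if merged.empty:
        return pd.DataFrame(columns=key_cols + ["dyad_type", "raw_rate"])
    merged["dyad_type"] = [
        _dyad_type(sex.get(f, "?"), sex.get(p, "?"))
        for f, p in zip(merged["focal"], merged["partner"])
    ]
    merged = merged[merged["dyad_type"].notna()].copy()
    merged["raw_rate"] = merged["count"] / merged["effort"]
    stratum_mean = merged.groupby(["dyad_type", "life_year"])["raw_rate"].transform("mean")
    with np.errstate(invalid="ignore"):
        merged["raw_rate"] = np.where(stratum_mean > 0, merged["raw_rate"] / stratum_mean, 0.0)
    return merged[key_cols + ["dyad_type", "raw_rate"]].reset_index(drop=True)


def standardize_dsi(indices: pd.DataFrame) -> pd.DataFrame:
    """Z-score raw rates within each (dyad_type, life_year) stratum.

    Sample (n-1 denominator) standard deviation.  Strata of size 1 or
    with zero variance map to 0 with a warning.
    """
    out = indices.copy()
    if out.empty:
        out["dsi_z"] = pd.Series(dtype=float)
        return out
    grp = out.groupby(["dyad_type", "life_year"])["raw_rate"]
    mean = grp.transform("mean")
    sd = grp.transform(lambda v: v.std(ddof=1))
    degenerate = (sd == 0) | sd.isna()
    if degenerate.any():
        n_strata = out.loc[degenerate, ["dyad_type", "life_year"]].drop_duplicates()
        logger.warning("%d degenerate DSI strata mapped to z = 0", len(n_strata))
    out["dsi_z"] = np.where(degenerate, 0.0, (out["raw_rate"] - mean) / sd.replace(0, np.nan))
    return out


def focal_bond_strength(indices: pd.DataFrame, focal, partner_sex: str,
                        individuals=None, k: int = TOP_PARTNERS,
                        life_year=None) -> float:
    """Mean standardized DSI over the focal's top-k partners of one sex.

    With 1 <= m < k partners the mean of all m is returned; with none the
    covariate is missing (NaN).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    sub = indices[indices["focal"].astype(str) == str(focal)]
    if life_year is not None:
        sub = sub[sub["life_year"] == life_year]
    if individuals is not None:
        sex = {r.id: r.sex for r in individuals}
        sub = sub[[sex.get(str(p)) == partner_sex for p in sub["partner"]]]
    if sub.empty:
        return float("nan")
    z = np.sort(sub["dsi_z"].to_numpy())[::-1]
    return float(np.mean(z[:k]))


# ---------------------------------------------------------------------------
# Dominance rank
# ---------------------------------------------------------------------------

def wins_below_diagonal(wins: np.ndarray, order) -> float:
    """Objective: total wins of lower-ranked over higher-ranked individuals."""
    w = wins[np.ix_(order, order)]
    return float(np.tril(w, k=-1).sum())


def _displacement(order_ids, previous: RankAssignment | None) -> float:
    if previous is None or not previous.ordinal:
        return 0.0
    fallback = len(previous.ordinal) + 1
    return float(
        sum(abs((i + 1) - previous.ordinal.get(idv, fallback)) for i, idv in enumerate(order_ids))
    )


def ordinal_ranks(m: RankMatrix, previous: RankAssignment | None = None) -> RankAssignment:
    """Order individuals to minimise wins below the diagonal.

    Exhaustive search for n <= 8 (global optimum guaranteed); for larger
    matrices, best-improvement pairwise-swap descent started from the
    previous month's ordering (or wins-minus-losses order), which never
    returns a worse objective than its start.  Ties among minimising
    orderings prefer the smallest total rank displacement from
    ``previous``, then the lexicographically smallest id sequence.
    """
    n = len(m.ids)
    ids = list(m.ids)
    if n == 1:
        return RankAssignment(ordinal={ids[0]: 1}, proportional={ids[0]: float("nan")})
    if n <= 8:
        best = None
        for perm in itertools.permutations(range(n)):
            obj = wins_below_diagonal(m.wins, perm)
            order_ids = [ids[i] for i in perm]
            key = (obj, _displacement(order_ids, previous), order_ids)
            if best is None or key < best:
                best = key
        order_ids = best[2]
    else:
        if previous is not None and previous.ordinal:
            seed = sorted(ids, key=lambda i: previous.ordinal.get(i, len(ids) + 1))
        else:
            margin = m.wins.sum(axis=1) - m.wins.sum(axis=0)
            seed = [ids[i] for i in np.argsort(-margin, kind="stable")]
        pos = {idv: i for i, idv in enumerate(ids)}
        order = [pos[i] for i in seed]
        obj = wins_below_diagonal(m.wins, order)
        improved = True
        while improved:
            improved = False
            best_swap, best_obj = None, obj
            for i in range(n - 1):
                for j in range(i + 1, n):
                    order[i], order[j] = order[j], order[i]
                    o = wins_below_diagonal(m.wins, order)
                    if o < best_obj:
                        best_obj, best_swap = o, (i, j)
                    order[i], order[j] = order[j], order[i]
            if best_swap is not None:
                i, j = best_swap
                order[i], order[j] = order[j], order[i]
                obj = best_obj
                improved = True
        order_ids = [ids[i] for i in order]
    ordinal = {idv: r + 1 for r, idv in enumerate(order_ids)}
    proportional = {idv: proportional_rank(r, n) for idv, r in ordinal.items()}
    return RankAssignment(ordinal=ordinal, proportional=proportional)


def proportional_rank(r: int, n: int) -> float:
    """Fraction of same-sex adults in the group dominated by rank ``r`` of ``n``.

    1 = top, 0 = bottom; missing (NaN) for a singleton group, where the
    fraction is undefined.
    """
    if not 1 <= r <= n:
        raise ValueError(f"ordinal rank {r} outside 1..{n}: corrupted ordering")
    if n == 1:
        return float("nan")
    return (n - r) / (n - 1)


def annual_rank(monthly) -> float:
    """Mean of the available monthly proportional ranks in one life-year."""
    vals = [v for v in monthly if not (isinstance(v, float) and math.isnan(v))]
    return float(np.mean(vals)) if vals else float("nan")


def monthly_win_matrices(agonism: pd.DataFrame, individuals,
                         alpha=None) -> dict:
    """Compile decided same-sex interactions into per-(month, group, sex) matrices.

    Matrix membership is the set of same-sex adults of the group that
    interacted that month.  Mixed-sex or sub-adult records are dropped.
    """
    alpha = alpha or DEFAULT_ALPHA
    info = {r.id: r for r in individuals}
    buckets: dict[tuple, list] = {}
    for row in agonism.itertuples(index=False):
        year = row.year if hasattr(row, "year") else to_decimal_year(row.date)
        w, l = str(row.winner), str(row.loser)
        rw, rl = info.get(w), info.get(l)
        if rw is None or rl is None or rw.sex != rl.sex:
            continue
        if (life_year_of(year, rw.birth_mid, alpha[rw.sex]) is None
                or life_year_of(year, rl.birth_mid, alpha[rl.sex]) is None):
            continue
        month = str(row.date)[:7]
        buckets.setdefault((month, str(row.group), rw.sex), []).append((w, l))
    matrices = {}
    for key in sorted(buckets):
        pairs = buckets[key]
        ids = sorted({i for p in pairs for i in p})
        idx = {v: i for i, v in enumerate(ids)}
        wins = np.zeros((len(ids), len(ids)))
        for w, l in pairs:
            wins[idx[w], idx[l]] += 1
        month, group, sex = key
        matrices[key] = RankMatrix(month=month, group=group, sex=sex, ids=ids, wins=wins)
    return matrices


# ---------------------------------------------------------------------------
# Covariate-table assembly
# ---------------------------------------------------------------------------

def build_covariates(grooming: pd.DataFrame, agonism: pd.DataFrame,
                     individuals, effort: pd.DataFrame,
                     alpha=None, k: int = TOP_PARTNERS) -> pd.DataFrame:
    """Full metrics stage: interaction records -> covariate table.

    Output columns ``id,sex,life_year,dsi_f,dsi_m,prop_rank`` with NaN for
    missing cells (males never receive dsi_m).
    """
    alpha = alpha or DEFAULT_ALPHA
    sex = {r.id: r.sex for r in individuals}

    counts = bin_grooming(grooming, individuals, alpha)
    rates = compute_dyadic_rates(counts, effort, individuals)
    dsi = standardize_dsi(rates)

    cells: dict[tuple, dict] = {}

    def cell(idv, t):
        return cells.setdefault((idv, t), {"dsi_f": np.nan, "dsi_m": np.nan, "prop_rank": np.nan})

    if not dsi.empty:
        dsi = dsi.copy()
        dsi["partner_sex"] = [sex.get(str(p)) for p in dsi["partner"]]
        for (focal, t, psex), grp in dsi.groupby(["focal", "life_year", "partner_sex"]):
            if psex == "M" and sex.get(str(focal)) == "M":
                continue
            z = np.sort(grp["dsi_z"].to_numpy())[::-1]
            cell(str(focal), int(t))["dsi_f" if psex == "F" else "dsi_m"] = float(np.mean(z[:k]))

    matrices = monthly_win_matrices(agonism, individuals, alpha)
    info = {r.id: r for r in individuals}
    previous: dict[tuple, RankAssignment] = {}
    monthly_props: dict[tuple, list] = {}
    for (month, group, msex), mat in matrices.items():
        assign = ordinal_ranks(mat, previous.get((group, msex)))
        previous[(group, msex)] = assign
        mid = to_decimal_year(month + "-15")
        for idv, prop in assign.proportional.items():
            rec = info[idv]
            t = life_year_of(mid, rec.birth_mid, alpha[rec.sex])
            if t is not None:
                monthly_props.setdefault((idv, t), []).append(prop)
    for (idv, t), vals in monthly_props.items():
        cell(idv, t)["prop_rank"] = annual_rank(vals)

    rows = [
        {"id": idv, "sex": sex.get(idv, "?"), "life_year": t, **vals}
        for (idv, t), vals in sorted(cells.items())
    ]
    return pd.DataFrame(rows, columns=["id", "sex", "life_year", "dsi_f", "dsi_m", "prop_rank"])
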