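"""Synthetic reference registries for worked examples and checks.

``amboseli_cohort_registry`` builds a fully synthetic individual registry
whose composition matches the published 1984-2018 Amboseli adult baboon
cohort: 542 adults (265 females, 277 males); departures by death for 129
females and 41 males, by right-censoring for 136 females and 129 males,
and by disappearance with unknown fate for 0 females and 107 males;
birth dates known for 232 females and 108 males (162 immigrant males and
the remainder observation-onset or imprecise-birth cases carry
brackets).  Every date is generated by a deterministic formula — the
rows are a stand-in, not field data; only the composition is real.
"""

from __future__ import annotations

import pandas as pd

from .records import from_decimal_year

_STUDY_START, _STUDY_END = 1984.0, 2018.9


def _rows(sex, n, n_death, n_censored, n_unknown, n_uncertain, n_immigrant, alpha):
    rows = []
    for i in range(n):
        if i < n_death:
            fate = "death"
        elif i < n_death + n_censored:
            fate = "censored"
        else:
            fate = "unknown"
        # spread fate classes across the uncertainty/origin classes: walk the
        # list with a stride so each combination occurs
        k = (i * 7) % n
        immigrant = k < n_immigrant
        uncertain = k < n_uncertain
        birth = 1975.0 + (i * 1.37) % 32.0
        if immigrant:
            entry = birth + alpha + 1.0 + (i % 5) * 0.8
        else:
            entry = birth + alpha
        entry = min(entry, _STUDY_END - 1.0)
        last = min(entry + 1.0 + (i * 0.93) % 12.0, _STUDY_END)
        bmin = bmax = birth
        if uncertain:
            width = 1.5
            bmin = birth - width / 2
            bmax = min(birth + width / 2, entry - alpha)
        rows.append({
            "id": f"{sex}{i:03d}", "sex": sex,
            "birth_min": from_decimal_year(bmin),
            "birth_max": from_decimal_year(max(bmax, bmin)),
            "entry_date": from_decimal_year(max(entry, max(bmax, bmin))),
            "last_date": from_decimal_year(max(last, entry)),
            "fate": fate,
            "origin": "immigrant" if immigrant else "natal",
        })
    return rows


def amboseli_cohort_registry() -> pd.DataFrame:
    """Synthetic registry reproducing the published cohort composition."""
    rows = _rows("F", 265, n_death=129, n_censored=136, n_unknown=0,
                 n_uncertain=33, n_immigrant=0, alpha=5.0)
    rows += _rows("M", 277, n_death=41, n_censored=129, n_unknown=107,
                  n_uncertain=169, n_immigrant=162, alpha=7.0)
    return pd.DataFrame(rows)
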