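"""Two-tier OD+GRAD competence ranking and cohort outcome tabulations.

The ranking tool tests optical density first (tier 1) and the radial
gradient second (tier 2), both against their fertilisation optimal ranges:

    OD in, GRAD in  -> score 1 (highest competence)
    OD in, GRAD out -> score 2
    OD out, GRAD in -> score 3
    OD out, GRAD out-> score 4

OD occupies the first tier because it carries the largest odds ratio in
every outcome model; the mixed-case ordering is configurable.  For binary
performance metrics, scores {1, 2} predict success by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import OptimalRange
from .stats import ConfusionMetrics, confusion_metrics

DEFAULT_SCORE_MAP = {(True, True): 1, (True, False): 2,
                     (False, True): 3, (False, False): 4}


class CohortError(ValueError):
    """Raised for inconsistent cohort tables (hierarchy violations etc.)."""


def percent(count: int, denominator: int, mode: str = "round") -> float:
    """One-decimal percentage of ``count/denominator``.

    ``mode='round'`` rounds half away from zero (the reporting default);
    ``mode='truncate'`` drops digits beyond the first decimal, for
    concordance checks against truncated published figures.  A zero
    denominator yields 0.0 with the denominator preserved by the caller.
    """
    if denominator == 0:
        return 0.0
    x = 1000.0 * count / denominator
    if mode == "round":
        scaled = math.floor(x + 0.5) if x >= 0 else math.ceil(x - 0.5)
    elif mode == "truncate":
        scaled = math.trunc(x)
    else:
        raise ValueError(f"unknown rounding mode {mode!r}")
    return scaled / 10.0


@dataclass(frozen=True)
class RankScore:
    """Two-tier competence score for one oocyte."""

    oocyte_id: str
    od_in_range: bool
    grad_in_range: bool
    score: int


def score_oocyte(od: float, grad: float, od_range: OptimalRange,
                 grad_range: OptimalRange, oocyte_id: str = "",
                 score_map: dict | None = None) -> RankScore:
    """Score one oocyte from its OD and GRAD values and the fitted ranges.

    Raises
    ------
    CohortError
        If either feature value is missing (NaN).
    """
    if not (np.isfinite(od) and np.isfinite(grad)):
        raise CohortError(f"oocyte {oocyte_id!r}: missing OD or GRAD")
    mapping = DEFAULT_SCORE_MAP if score_map is None else score_map
    od_in = bool(od_range.contains(float(od)))
    grad_in = bool(grad_range.contains(float(grad)))
    return RankScore(oocyte_id=oocyte_id, od_in_range=od_in,
                     grad_in_range=grad_in, score=mapping[(od_in, grad_in)])


def score_cohort(features_df: pd.DataFrame, od_range: OptimalRange,
                 grad_range: OptimalRange, id_col: str = "oocyte_id",
                 od_col: str = "od", grad_col: str = "grad",
                 score_map: dict | None = None) -> pd.DataFrame:
    """Score every oocyte; returns a (id, od_in, grad_in, score) table."""
    rows = []
    for _, row in features_df.iterrows():
        rs = score_oocyte(row[od_col], row[grad_col], od_range, grad_range,
                          oocyte_id=str(row[id_col]) if id_col in row else "",
                          score_map=score_map)
        rows.append({"oocyte_id": rs.oocyte_id, "od_in": rs.od_in_range,
                     "grad_in": rs.grad_in_range, "score": rs.score})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortSummary:
    """Cohort counts and one-decimal rates, mirroring a results tabulation."""

    table: pd.DataFrame
    rounding: str

    def rate(self, category: str) -> float:
        row = self.table.loc[self.table["category"] == category]
        if row.empty:
            raise KeyError(category)
        return float(row["rate_pct"].iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


_HIERARCHY = (
    # child column, parent column, parent value required when child is defined
    ("blastulation", "fertilised", 1),
    ("implantation", "transferred", 1),
)


def validate_hierarchy(cohort: pd.DataFrame) -> None:
    """Check outcome nesting; lists every offending oocyte id on failure."""
    offenders: list[str] = []
    for child, parent, required in _HIERARCHY:
        if child not in cohort.columns or parent not in cohort.columns:
            continue
        defined = cohort[child].notna()
        bad = defined & (cohort[parent].fillna(0).astype(float) != required)
        if bad.any():
            ids = cohort.loc[bad, "oocyte_id"].astype(str).tolist() \
                if "oocyte_id" in cohort.columns else cohort.index[bad].astype(str).tolist()
            offenders.extend(f"{child}:{i}" for i in ids)
    if offenders:
        raise CohortError("outcome hierarchy violated for " + ", ".join(offenders))


def tabulate_cohort(cohort: pd.DataFrame, n_cocs: int | None = None,
                    rounding: str = "round") -> CohortSummary:
    """Counts, denominators and one-decimal rates for a scored cohort table.

    Expected columns (all optional except ``fertilised``): ``fertilised``
    (binary), ``failure_category`` (0PN/1PN/3PN/degenerated for unfertilised
    oocytes), ``blastulation`` (binary, NaN when not cultured),
    ``transferred`` (binary), ``implantation`` (binary, NaN unless
    transferred), ``score`` (1-4).  ``n_cocs`` adds the maturation rate
    (MII oocytes per retrieved cumulus-oocyte complex).
    """
    validate_hierarchy(cohort)
    n = len(cohort)
    rows = []

    def add(category: str, count: int, denom: int) -> None:
        rows.append({"category": category, "count": int(count),
                     "denominator": int(denom),
                     "rate_pct": percent(int(count), int(denom), rounding)})

    if n_cocs is not None:
        add("maturation", n, n_cocs)

    if "fertilised" in cohort.columns:
        fert = cohort["fertilised"].fillna(0).astype(float)
        n_fert = int((fert == 1).sum())
        add("fertilisation", n_fert, n)
        if "failure_category" in cohort.columns:
            failed = cohort.loc[fert != 1, "failure_category"]
            for cat in ("0PN", "1PN", "3PN", "degenerated"):
                add(cat, int((failed == cat).sum()), n)
        if "blastulation" in cohort.columns:
            blast = cohort["blastulation"]
            n_cultured = int(blast.notna().sum())
            n_blast = int((blast == 1).sum())
            add("blastulation_utilisation", n_blast, n_fert)
            add("blastulation_cultured", n_blast, n_cultured)

    if "implantation" in cohort.columns:
        impl = cohort["implantation"]
        add("implantation", int((impl == 1).sum()), int(impl.notna().sum()))

    if "score" in cohort.columns:
        for s in (1, 2, 3, 4):
            add(f"score_{s}", int((cohort["score"] == s).sum()), n)

    return CohortSummary(table=pd.DataFrame(rows), rounding=rounding)


def score_performance(scored: pd.DataFrame, outcomes: pd.DataFrame,
                      outcome_cols=("fertilised", "blastulation", "implantation"),
                      positive_scores=(1, 2)) -> dict[str, ConfusionMetrics]:
    """Confusion metrics of the score-based prediction for each outcome.

    Scores in ``positive_scores`` predict success.  For each outcome only
    rows where it is defined (non-NaN) enter the 2x2 table.
    """
    preds = scored["score"].isin(positive_scores).to_numpy()
    out = {}
    for col in outcome_cols:
        if col not in outcomes.columns:
            continue
        y = outcomes[col].to_numpy(dtype=float)
        defined = ~np.isnan(y)
        out[col] = confusion_metrics(preds[defined], y[defined] == 1)
    return out
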