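"""Complete-case sample construction and baseline descriptive tables.

The transition models require every subject to be observed in all rounds
with complete data, so the analytic sample is built by listwise deletion:
a subject missing any round, any required anthropometric state, or (when
in scope) any covariate is excluded entirely.  Every exclusion is logged
with its first failing reason.  Baseline tables compare covariate
distributions across baseline nutritional states with Pearson chi-squared
tests, and an included-vs-excluded comparison checks for selective
attrition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .states import STATES

COVARIATES = ("sex", "wealth_q", "residence", "hh_size", "mat_edu")

#: Exclusion reasons, in attribution priority order.
REASON_MISSING_ROUND = "missing round"
REASON_MISSING_ANTHRO = "missing anthropometry"
REASON_MISSING_COVARIATE = "missing covariate"


@dataclass
class ExclusionLog:
    """Per-subject exclusion reasons and their totals."""

    reasons: dict = field(default_factory=dict)  # subject_id -> reason

    @property
    def counts(self) -> dict:
        out: dict = {}
        for r in self.reasons.values():
            out[r] = out.get(r, 0) + 1
        return out

    @property
    def n_excluded(self) -> int:
        return len(self.reasons)


def complete_case_filter(
    panel: pd.DataFrame,
    n_rounds: int = 5,
    scope: str = "states_only",
    covariates: tuple = COVARIATES,
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Listwise deletion to the analytic complete-case sample.

    A subject is retained only if it has all ``n_rounds`` rounds, a
    non-missing state in every round and — with
    ``scope="states_and_covariates"`` — non-missing covariates in every
    round.  Each excluded subject is logged under its first failing
    reason, in the order missing round, missing anthropometry, missing
    covariate.

    Returns the retained panel and the :class:`ExclusionLog`; raises if
    nothing survives.
    """
    if panel.empty:
        raise ValueError("panel is empty")
    if scope not in ("states_only", "states_and_covariates"):
        raise ValueError(f"unknown scope {scope!r}")

    log = ExclusionLog()
    state_missing = panel["state"].isna()
    if "state_missing" in panel:
        state_missing = state_missing | panel["state_missing"].fillna(False).astype(bool)

    work = panel.assign(_state_missing=state_missing)
    by_subject = work.groupby("subject_id", sort=True)
    n_rounds_present = (
        work[work["round"].between(1, n_rounds)]
        .groupby("subject_id", sort=True)["round"]
        .nunique()
        .reindex(by_subject.size().index, fill_value=0)
    )
    has_all_rounds = n_rounds_present == n_rounds
    any_state_missing = by_subject["_state_missing"].any()
    cov_cols = [c for c in covariates if c in work.columns]
    if scope == "states_and_covariates" and cov_cols:
        any_cov_missing = work[cov_cols].isna().any(axis=1).groupby(work["subject_id"]).any()
    else:
        any_cov_missing = pd.Series(False, index=has_all_rounds.index)

    # first-failing-reason attribution, in priority order
    reason = np.select(
        [~has_all_rounds.to_numpy(), any_state_missing.to_numpy(), any_cov_missing.to_numpy()],
        [REASON_MISSING_ROUND, REASON_MISSING_ANTHRO, REASON_MISSING_COVARIATE],
        default="",
    )
    log.reasons = {
        sid: r for sid, r in zip(has_all_rounds.index, reason) if r
    }

    retained = panel[~panel["subject_id"].isin(log.reasons)].reset_index(drop=True)
    if retained.empty:
        raise ValueError(
            "no subject survives complete-case filtering; inspect the exclusion log"
        )
    return retained, log


def chi2_independence(table: np.ndarray) -> tuple[float, int, float, bool]:
    """Pearson chi-squared test of independence on an r x c count table.

    Returns (statistic, df, p, low_expected) where ``low_expected`` flags
    any expected cell count below 5.  No continuity correction.  Tables
    with a single non-empty row or column have no degrees of freedom; the
    p-value is then NaN.
    """
    table = np.asarray(table, dtype=float)
    table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
    if table.shape[0] < 2 or table.shape[1] < 2:
        return np.nan, 0, np.nan, False
    stat, p, df, expected = chi2_contingency(table, correction=False)
    return float(stat), int(df), float(p), bool((expected < 5).any())


def baseline_table(
    panel: pd.DataFrame,
    variables: tuple = COVARIATES,
    baseline_round: int = 1,
    by: str = "state",
) -> pd.DataFrame:
    """Baseline characteristics by nutritional state, with chi-squared tests.

    One row per variable level: counts and column percentages within each
    state at the baseline round, plus a per-variable Pearson chi-squared
    p-value for association across states.  Variables observed at a single
    level get an undefined (NaN) p-value.
    """
    base = panel[panel["round"] == baseline_round]
    if base.empty:
        raise ValueError(f"no rows at baseline round {baseline_round}")
    col_order = [s for s in STATES if s in set(base[by].dropna())]
    rows = []
    for var in variables:
        if var not in base.columns:
            continue
        ct = pd.crosstab(base[var], base[by]).reindex(columns=col_order, fill_value=0)
        stat, df, p, low_exp = chi2_independence(ct.to_numpy())
        col_tot = ct.sum(axis=0)
        for level in ct.index:
            row = {"variable": var, "level": level, "p_value": p, "chi2": stat,
                   "df": df, "low_expected": low_exp}
            for state in col_order:
                n = int(ct.loc[level, state])
                denom = col_tot[state]
                row[f"{state}_n"] = n
                row[f"{state}_pct"] = 100.0 * n / denom if denom > 0 else np.nan
            row["total_n"] = int(ct.loc[level].sum())
            rows.append(row)
    return pd.DataFrame(rows)


def attrition_comparison(
    included: pd.DataFrame,
    excluded: pd.DataFrame,
    variables: tuple = COVARIATES,
    baseline_round: int = 1,
) -> pd.DataFrame:
    """Baseline covariate distributions for included vs excluded subjects.

    Same layout as :func:`baseline_table` with the inclusion indicator as
    the column variable.  An empty excluded set yields the included-only
    table with undefined p-values.
    """
    inc = included[included["round"] == baseline_round].assign(_group="included")
    exc = excluded[excluded["round"] == baseline_round].assign(_group="excluded")
    both = pd.concat([inc, exc], ignore_index=True)
    rows = []
    groups = [g for g in ("included", "excluded") if (both["_group"] == g).any()]
    for var in variables:
        if var not in both.columns:
            continue
        ct = pd.crosstab(both[var], both["_group"]).reindex(columns=groups, fill_value=0)
        stat, df, p, low_exp = chi2_independence(ct.to_numpy())
        col_tot = ct.sum(axis=0)
        for level in ct.index:
            row = {"variable": var, "level": level, "p_value": p, "chi2": stat,
                   "df": df, "low_expected": low_exp}
            for g in groups:
                n = int(ct.loc[level, g])
                denom = col_tot[g]
                row[f"{g}_n"] = n
                row[f"{g}_pct"] = 100.0 * n / denom if denom > 0 else np.nan
            rows.append(row)
    return pd.DataFrame(rows)
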