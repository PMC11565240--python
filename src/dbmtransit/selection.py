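"""Covariate selection: univariate baseline screens, forward AIC stepwise.

The workflow mirrors common practice for transition models on cohort
data: candidate covariates are first screened by univariate logistic
regressions of baseline stunting and baseline overweight (a candidate
passes if any of its levels is associated at P < 0.05 with either
outcome), then added greedily to the two-state transition model in the
order that most lowers the combined AIC, stopping when no addition
improves it.  The full ladder is reported; by default the final model is
the fully adjusted one (all candidates), for consistency across targets
whose small samples would otherwise select different subsets — a config
switch returns the stepwise winner instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .logit import fit_logit
from .transitions import CATEGORY_LEVELS, TwoStateTransitionModel


def aic(loglik: float, k: int) -> float:
    """Akaike information criterion, 2k - 2*loglik."""
    if k < 0:
        raise ValueError("parameter count k must be non-negative")
    return 2.0 * k - 2.0 * loglik


def _baseline_design(df: pd.DataFrame, candidate: str) -> tuple[np.ndarray, list]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    if candidate in CATEGORY_LEVELS:
        levels = CATEGORY_LEVELS[candidate]
        for level in levels[1:]:
            cols.append((df[candidate] == level).astype(float).to_numpy())
            names.append(f"{candidate}[{level}]")
    else:
        cols.append(df[candidate].astype(float).to_numpy())
        names.append(candidate)
    return np.column_stack(cols), names


def univariate_screen(
    panel: pd.DataFrame,
    candidates: tuple,
    baseline_round: int = 1,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Univariate logistic screens of baseline stunting and overweight.

    One row per candidate x outcome x non-reference level with the Wald
    p-value; the ``passes`` column marks candidates whose minimum p-value
    across levels and outcomes is below ``alpha``.  Non-estimable fits
    (e.g. a constant covariate) are flagged, not silently excluded.
    """
    base = panel[panel["round"] == baseline_round]
    outcomes = {
        "baseline_stunting": base["state"].isin(("stunted", "cso")).to_numpy(dtype=float),
        "baseline_overweight": base["state"].isin(("overweight", "cso")).to_numpy(dtype=float),
    }
    rows = []
    for cand in candidates:
        for out_name, y in outcomes.items():
            X, names = _baseline_design(base, cand)
            fit = fit_logit(X, y)
            if not fit.estimable:
                rows.append(
                    {
                        "candidate": cand,
                        "outcome": out_name,
                        "term": "(all)",
                        "beta": np.nan,
                        "se": np.nan,
                        "p_value": np.nan,
                        "estimable": False,
                        "reason": fit.reason,
                    }
                )
                continue
            for i, term in enumerate(names):
                if term == "intercept":
                    continue
                z = fit.params[i] / fit.bse[i]
                p = 2.0 * norm.sf(abs(z))
                rows.append(
                    {
                        "candidate": cand,
                        "outcome": out_name,
                        "term": term,
                        "beta": fit.params[i],
                        "se": fit.bse[i],
                        "p_value": p,
                        "estimable": True,
                        "reason": "",
                    }
                )
    report = pd.DataFrame(rows)
    min_p = report[report["estimable"]].groupby("candidate")["p_value"].min()
    passes = report["candidate"].map(min_p < alpha).astype("boolean")
    report["passes"] = passes.fillna(False).astype(bool)
    return report


@dataclass
class SelectionReport:
    """Ladder of models explored by forward AIC selection."""

    target: str
    candidates: tuple
    ladder: list = field(default_factory=list)  # dicts: step, added, covariates, aic
    selected: tuple = ()
    final_covariates: tuple = ()
    screen: pd.DataFrame | None = None

    def ladder_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ladder)


def stepwise_aic(
    panel: pd.DataFrame,
    target: str,
    candidates: tuple,
    final: str = "full",
    tie_tol: float = 1e-9,
) -> SelectionReport:
    """Greedy forward covariate addition on the two-state transition model.

    At each step the candidate lowering the combined (entry + exit) AIC
    the most is added; AIC ties within ``tie_tol`` break lexicographically
    on the covariate name.  Stops when no addition lowers the AIC, or when
    every remaining fit is non-estimable.  ``final`` chooses what the
    report recommends: ``"full"`` (all candidates, the default for
    consistency across targets) or ``"stepwise"`` (the AIC winner).
    """
    if final not in ("full", "stepwise"):
        raise ValueError("final must be 'full' or 'stepwise'")
    report = SelectionReport(target=target, candidates=tuple(candidates))

    def model_aic(covs: tuple) -> float:
        res = TwoStateTransitionModel(panel, target, list(covs)).fit()
        if not (res.entry.estimable and res.exit.estimable):
            return np.nan
        return res.aic

    current: tuple = ()
    current_aic = model_aic(current)
    if np.isnan(current_aic):
        raise ValueError(f"intercept-only model for {target!r} is non-estimable")
    report.ladder.append(
        {"step": 0, "added": None, "covariates": current, "aic": current_aic}
    )
    remaining = sorted(candidates)
    step = 0
    while remaining:
        step += 1
        trials = []
        for cand in remaining:  # lexicographic order makes ties deterministic
            a = model_aic(current + (cand,))
            if not np.isnan(a):
                trials.append((cand, a))
        if not trials:
            report.ladder.append(
                {"step": step, "added": None, "covariates": current,
                 "aic": current_aic, "note": "all remaining fits non-estimable"}
            )
            break
        best_aic = min(a for _, a in trials)
        best_cand = next(c for c, a in trials if a <= best_aic + tie_tol)
        if best_aic >= current_aic:
            break
        current = current + (best_cand,)
        current_aic = best_aic
        remaining.remove(best_cand)
        report.ladder.append(
            {"step": step, "added": best_cand, "covariates": current, "aic": current_aic}
        )

    report.selected = current
    report.final_covariates = tuple(candidates) if final == "full" else current
    return report
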