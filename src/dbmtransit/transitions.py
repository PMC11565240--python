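"""Covariate-adjusted two-state transition models with logit parameterization.

Each malnourished condition is analysed with its own two-state collapse of
the four nutritional states — stunted/not ({stunted, cso} vs rest),
overweight/not ({overweight, cso} vs rest) and CSO/not — so every
condition keeps its marginal definition.  For each condition two binary
logit models are fitted, one per transition direction:

    entry: logit P(in target at t+1 | not in target at t, x_t) = a_e(t) + b_e' x_t
    exit : logit P(not in target at t+1 | in target at t, x_t) = a_x(t) + b_x' x_t

Intercepts are interval-specific (time-inhomogeneous baseline hazard of
transition) while covariate effects are shared across intervals, giving a
single odds ratio per covariate level: exp(b) is the multiplicative change
in the odds of transitioning, relative to remaining, per unit (or level vs
reference) of the covariate measured at the origin round.

Reference categories: male, urban residence, households of <=5 members,
poorest wealth quartile (Q1), maternal education <=6 years.

Directions with fewer than five observed transitions, or showing complete
separation, are reported as non-estimable rather than as extreme odds
ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .logit import LogitFit, _failed, fit_logit, wald_ci
from .simulate import TARGET_GROUPS

#: Declared level orders; the first level is the reference.
CATEGORY_LEVELS = {
    "sex": ("male", "female"),
    "wealth_q": ("Q1", "Q2", "Q3", "Q4"),
    "residence": ("urban", "rural"),
    "hh_size": ("<=5", ">5"),
    "mat_edu": ("<=6y", ">6y"),
}

MIN_EVENTS = 5  # per direction; below this the direction is non-estimable


def build_two_state_panel(
    panel: pd.DataFrame, target: str, covariates: list | None = None
) -> pd.DataFrame:
    """Collapse a complete-case four-state panel to subject x interval rows.

    Each row carries the binary origin indicator (in the target group at
    round t), the destination indicator (in the target group at round
    t+1), the interval index t and the covariates measured at the origin
    round (by default, every known sociodemographic column present).
    """
    if target not in TARGET_GROUPS:
        raise ValueError(f"unknown target {target!r}; choose from {sorted(TARGET_GROUPS)}")
    group = TARGET_GROUPS[target]
    wide = panel.sort_values(["subject_id", "round"])
    rounds = np.sort(wide["round"].unique())
    frames = []
    if covariates is None:
        covs = [c for c in CATEGORY_LEVELS if c in wide.columns]
    else:
        missing = [c for c in covariates if c not in wide.columns]
        if missing:
            raise ValueError(f"covariates not in panel: {missing}")
        covs = list(covariates)
    by_round = {r: g.set_index("subject_id") for r, g in wide.groupby("round")}
    for t in rounds[:-1]:
        origin = by_round[t]
        dest = by_round[t + 1]
        common = origin.index.intersection(dest.index)
        block = pd.DataFrame(
            {
                "subject_id": common,
                "interval": t,
                "origin": origin.loc[common, "state"].isin(group).astype(int).to_numpy(),
                "dest": dest.loc[common, "state"].isin(group).astype(int).to_numpy(),
            }
        )
        for c in covs:
            block[c] = origin.loc[common, c].to_numpy()
        frames.append(block)
    return pd.concat(frames, ignore_index=True)


def build_design(
    df: pd.DataFrame, covariates: list, intervals: np.ndarray | None = None
) -> tuple[np.ndarray, list]:
    """Design matrix: one dummy per interval (no global intercept) plus
    non-reference-level dummies for each categorical covariate; numeric
    covariates enter linearly.  Unknown category levels are an error."""
    cols = []
    names = []
    if intervals is None:
        intervals = np.sort(df["interval"].unique())
    for t in intervals:
        cols.append((df["interval"] == t).astype(float).to_numpy())
        names.append(f"interval[{t}]")
    for cov in covariates:
        if cov in CATEGORY_LEVELS:
            levels = CATEGORY_LEVELS[cov]
            seen = set(df[cov].dropna().unique())
            unknown = seen - set(levels)
            if unknown:
                raise ValueError(f"covariate {cov!r} has unknown levels {sorted(unknown)}")
            for level in levels[1:]:
                cols.append((df[cov] == level).astype(float).to_numpy())
                names.append(f"{cov}[{level}]")
        else:
            cols.append(df[cov].astype(float).to_numpy())
            names.append(cov)
    X = np.column_stack(cols) if cols else np.empty((len(df), 0))
    return X, names


@dataclass
class DirectionFit:
    """One fitted transition direction (entry into, or exit from, a state)."""

    direction: str
    fit: LogitFit
    term_names: list
    n_at_risk: int
    n_events: int

    @property
    def estimable(self) -> bool:
        return self.fit.estimable

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.fit.params, index=self.term_names)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self.fit.bse, index=self.term_names)


class TwoStateTransitionModel:
    """Adjusted two-state Markov transition model for one target condition.

    Parameters
    ----------
    panel : DataFrame
        Complete-case long-format panel with states and covariates.
    target : str
        ``"stunting"``, ``"overweight"`` or ``"cso"``.
    covariates : list of str
        Covariate names; categorical ones are expanded against their
        reference level.  An empty list gives the intercept-only
        (interval-specific rates) model.
    """

    def __init__(self, panel: pd.DataFrame, target: str, covariates: list = ()):  # noqa: D401
        self.target = target
        self.covariates = list(covariates)
        carry = sorted(
            set(c for c in CATEGORY_LEVELS if c in panel.columns) | set(self.covariates)
        )
        self.tsp = build_two_state_panel(panel, target, covariates=carry)
        self.intervals = np.sort(self.tsp["interval"].unique())

    def _fit_direction(self, direction: str) -> DirectionFit:
        if direction == "entry":
            sub = self.tsp[self.tsp["origin"] == 0]
            y = sub["dest"].to_numpy(dtype=float)
        else:
            sub = self.tsp[self.tsp["origin"] == 1]
            y = 1.0 - sub["dest"].to_numpy(dtype=float)
        X, names = build_design(sub, self.covariates, self.intervals)
        n_events = int(y.sum())
        if n_events < MIN_EVENTS or len(y) - n_events < MIN_EVENTS:
            fit = _failed(X.shape[1], len(y), n_events, f"fewer than {MIN_EVENTS} events or non-events")
            return DirectionFit(direction, fit, names, len(y), n_events)
        fit = fit_logit(X, y)
        return DirectionFit(direction, fit, names, len(y), n_events)

    def fit(self) -> "TwoStateTransitionResults":
        entry = self._fit_direction("entry")
        exit_ = self._fit_direction("exit")
        return TwoStateTransitionResults(self, entry, exit_)


class TwoStateTransitionResults:
    """Fitted entry/exit logit models for one target condition."""

    def __init__(self, model: TwoStateTransitionModel, entry: DirectionFit, exit_: DirectionFit):
        self.model = model
        self.target = model.target
        self.entry = entry
        self.exit = exit_

    @property
    def directions(self) -> dict:
        return {"into": self.entry, "out_of": self.exit}

    @property
    def llf(self) -> float:
        return sum(d.fit.llf for d in (self.entry, self.exit) if d.estimable)

    @property
    def df_model(self) -> int:
        return sum(d.fit.df_model for d in (self.entry, self.exit) if d.estimable)

    @property
    def aic(self) -> float:
        """Combined AIC over the two (independent) direction likelihoods."""
        return 2.0 * self.df_model - 2.0 * self.llf

    def odds_ratios(self, z: float = 1.96) -> pd.DataFrame:
        """OR = exp(beta) with Wald 95% CI per covariate term and direction.

        Interval intercepts are omitted (they are baseline transition
        rates, not covariate effects).  Non-estimable directions propagate
        as blank rows carrying the reason.
        """
        rows = []
        for dname, d in self.directions.items():
            terms = [t for t in d.term_names if not t.startswith("interval[")]
            if not d.estimable:
                for term in terms or ["(all)"]:
                    rows.append(
                        {
                            "target_state": self.target,
                            "direction": dname,
                            "term": term,
                            "OR": np.nan,
                            "ci_low": np.nan,
                            "ci_high": np.nan,
                            "beta": np.nan,
                            "se": np.nan,
                            "n_obs": d.n_at_risk,
                            "n_events": d.n_events,
                            "estimable": False,
                            "reason": d.fit.reason,
                            "loglik": np.nan,
                            "aic": np.nan,
                        }
                    )
                continue
            params, bse = d.params, d.bse
            for term in terms:
                lo, hi = wald_ci(params[term], bse[term], z)
                rows.append(
                    {
                        "target_state": self.target,
                        "direction": dname,
                        "term": term,
                        "OR": float(np.exp(params[term])),
                        "ci_low": float(np.exp(lo)),
                        "ci_high": float(np.exp(hi)),
                        "beta": float(params[term]),
                        "se": float(bse[term]),
                        "n_obs": d.n_at_risk,
                        "n_events": d.n_events,
                        "estimable": True,
                        "reason": "",
                        "loglik": d.fit.llf,
                        "aic": d.fit.aic,
                    }
                )
        return pd.DataFrame(rows)

    def fitted_rates(self, direction: str = "entry") -> pd.Series:
        """Model-implied per-interval transition probability at the
        reference covariate profile (inverse logit of the interval
        intercepts)."""
        d = self.entry if direction == "entry" else self.exit
        if not d.estimable:
            raise ValueError(f"{direction} direction non-estimable: {d.fit.reason}")
        alphas = d.params[[f"interval[{t}]" for t in self.model.intervals]]
        return pd.Series(1.0 / (1.0 + np.exp(-alphas.to_numpy())), index=self.model.intervals)

    def summary(self) -> str:
        lines = [f"Two-state transition model: {self.target}", ""]
        for dname, d in self.directions.items():
            lines.append(
                f"{dname} {self.target}: n_at_risk={d.n_at_risk}, transitions={d.n_events}"
            )
            if not d.estimable:
                lines.append(f"  non-estimable: {d.fit.reason}")
                continue
            lines.append(
                f"  loglik={d.fit.llf:.3f}  AIC={d.fit.aic:.3f}  converged={d.fit.converged}"
            )
            for term in d.term_names:
                b, s = d.params[term], d.bse[term]
                if term.startswith("interval["):
                    lines.append(f"    {term:>16}  beta={b:8.4f}  se={s:.4f}")
                else:
                    lo, hi = wald_ci(b, s)
                    lines.append(
                        f"    {term:>16}  OR={np.exp(b):6.3f}  95% CI ({np.exp(lo):.3f}, {np.exp(hi):.3f})"
                    )
            lines.append("")
        return "\n".join(lines)


def run_adjusted_models(
    panel: pd.DataFrame,
    targets: tuple = ("stunting", "overweight", "cso"),
    covariates: tuple = ("sex", "wealth_q", "residence", "hh_size"),
) -> dict:
    """Fit the adjusted two-state models for each malnourished condition.

    Returns a map target -> :class:`TwoStateTransitionResults`.  A
    sensitivity run adding maternal education is the same call with
    ``covariates + ("mat_edu",)``.
    """
    return {
        t: TwoStateTransitionModel(panel, t, list(covariates)).fit() for t in targets
    }


def odds_ratio_frame(results: dict) -> pd.DataFrame:
    """Stack the OR tables of several fitted targets into one report."""
    return pd.concat([r.odds_ratios() for r in results.values()], ignore_index=True)
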