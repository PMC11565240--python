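"""Time-inhomogeneous first-order four-state Markov chain on panel data.

With fully observed states the saturated time-inhomogeneous maximum-
likelihood estimate has closed form: the transition probability from
state i at round t to state j at round t+1 is the empirical frequency
n_ij(t) / n_i(t), with plug-in multinomial standard errors
sqrt(p(1-p)/n_i(t)).  No latent-state machinery is needed, and the
marginal state distribution propagated forward through the estimated
matrices coincides exactly with the raw round-wise frequencies on
complete-case data — an algebraic identity of the saturated model.

The model object follows the statsmodels convention: build
``FourStateMarkov(panel)`` from a complete-case long-format panel and call
``fit()`` for a results object carrying the per-interval matrices, their
standard errors, counts, marginal trajectory and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .states import STATES

_STATE_INDEX = {s: i for i, s in enumerate(STATES)}


@dataclass(frozen=True)
class TransitionCounts:
    """Sufficient statistics: per-interval 4x4 transition count matrices."""

    counts: np.ndarray  # (n_intervals, 4, 4) non-negative integers
    interval_labels: tuple

    @property
    def n_intervals(self) -> int:
        return self.counts.shape[0]

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=2)


def count_transitions(panel: pd.DataFrame, states: tuple = STATES) -> TransitionCounts:
    """Tally observed state-to-state moves between consecutive rounds.

    Requires a complete-case panel: every subject observed at every round
    from 1 to the panel maximum.  Subjects with gaps are a preparation
    problem and raise an error pointing at the complete-case filter.
    """
    rounds = np.sort(panel["round"].unique())
    n_rounds = len(rounds)
    if not np.array_equal(rounds, np.arange(1, n_rounds + 1)):
        raise ValueError("panel rounds must be 1..R; run the complete-case filter first")
    per_subject = panel.groupby("subject_id")["round"].nunique()
    if (per_subject != n_rounds).any():
        raise ValueError(
            "subjects with missing rounds present; run complete_case_filter first"
        )

    wide = panel.pivot(index="subject_id", columns="round", values="state")
    codes = np.empty(wide.shape, dtype=np.int64)
    for s, i in _STATE_INDEX.items():
        codes[(wide == s).to_numpy()] = i
    if wide.isna().any().any():
        raise ValueError("missing states present; run complete_case_filter first")

    n_int = n_rounds - 1
    counts = np.zeros((n_int, 4, 4), dtype=np.int64)
    for t in range(n_int):
        flat = codes[:, t] * 4 + codes[:, t + 1]
        counts[t] = np.bincount(flat, minlength=16).reshape(4, 4)

    if "age_years" in panel.columns:
        ages = (
            panel.drop_duplicates("round").set_index("round")["age_years"].sort_index()
        )
        labels = tuple(
            f"{ages.iloc[t]:g}-{ages.iloc[t + 1]:g} years" for t in range(n_int)
        )
    else:
        labels = tuple(f"round {t + 1}-{t + 2}" for t in range(n_int))
    return TransitionCounts(counts=counts, interval_labels=labels)


def mle_transitions(counts: TransitionCounts) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Closed-form saturated MLE of the per-interval transition matrices.

    Returns ``(P, SE, defined)``: probabilities n_ij/n_i, plug-in binomial
    standard errors sqrt(p(1-p)/n_i), and a per-row ``defined`` mask —
    rows with zero origin count are NaN and flagged undefined rather than
    imputed.
    """
    n = counts.counts.astype(float)
    row = n.sum(axis=2, keepdims=True)
    defined = row[..., 0] > 0
    with np.errstate(invalid="ignore", divide="ignore"):
        P = n / row
        SE = np.sqrt(P * (1.0 - P) / row)
    P[~defined] = np.nan
    SE[~defined] = np.nan
    return P, SE, defined


def marginal_trajectory(initial: np.ndarray, matrices: np.ndarray) -> np.ndarray:
    """Propagate an initial state distribution through per-interval matrices.

    pi(t+1) = pi(t) @ P(t).  Undefined matrix rows (NaN) reachable with
    positive probability make the product ill-defined and raise.
    """
    pi = np.asarray(initial, dtype=float)
    if abs(pi.sum() - 1.0) > 1e-9 or np.any(pi < 0):
        raise ValueError("initial distribution must be a probability vector")
    traj = [pi]
    for t, P in enumerate(matrices):
        undefined = np.isnan(P).any(axis=1)
        if np.any(undefined & (traj[-1] > 0)):
            raise ValueError(
                f"undefined transition row reachable with positive probability at interval {t}"
            )
        P_safe = np.nan_to_num(P)
        traj.append(traj[-1] @ P_safe)
    return np.vstack(traj)


class FourStateMarkov:
    """Unadjusted four-state Markov chain model for a complete-case panel.

    Parameters
    ----------
    panel : DataFrame
        Long-format complete-case panel with columns ``subject_id``,
        ``round`` (1..R) and ``state`` (normal/stunted/overweight/cso).
    initial : array-like, optional
        Baseline state distribution; defaults to the empirical round-1
        frequencies.
    """

    def __init__(self, panel: pd.DataFrame, initial=None):
        self.panel = panel
        self.counts = count_transitions(panel)
        base = panel[panel["round"] == 1]["state"]
        emp = np.array([(base == s).sum() for s in STATES], dtype=float)
        self.initial = np.asarray(initial, dtype=float) if initial is not None else emp / emp.sum()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "FourStateMarkov":
        return cls(df, **kwargs)

    def fit(self) -> "FourStateMarkovResults":
        P, SE, defined = mle_transitions(self.counts)
        marginals = marginal_trajectory(self.initial, P)
        return FourStateMarkovResults(
            model=self,
            transition_matrices=P,
            standard_errors=SE,
            row_defined=defined,
            marginals=marginals,
        )


class FourStateMarkovResults:
    """Fitted per-interval transition matrices and marginal trajectory."""

    def __init__(self, model, transition_matrices, standard_errors, row_defined, marginals):
        self.model = model
        self.counts = model.counts
        self.transition_matrices = transition_matrices
        self.standard_errors = standard_errors
        self.row_defined = row_defined
        self.marginals = marginals
        self.states = STATES
        self.interval_labels = model.counts.interval_labels

    def transitions_frame(self) -> pd.DataFrame:
        """Long-format table: interval, from_state, to_state, n_from, p, se."""
        rows = []
        row_tot = self.counts.row_totals()
        for t, label in enumerate(self.interval_labels):
            for i, si in enumerate(self.states):
                for j, sj in enumerate(self.states):
                    rows.append(
                        {
                            "interval": label,
                            "from_state": si,
                            "to_state": sj,
                            "n_from": int(row_tot[t, i]),
                            "n": int(self.counts.counts[t, i, j]),
                            "p": self.transition_matrices[t, i, j],
                            "se": self.standard_errors[t, i, j],
                            "defined": bool(self.row_defined[t, i]),
                        }
                    )
        return pd.DataFrame(rows)

    def marginals_frame(self) -> pd.DataFrame:
        """Long-format marginal state probabilities per round."""
        rows = []
        for r in range(self.marginals.shape[0]):
            for i, s in enumerate(self.states):
                rows.append({"round": r + 1, "state": s, "probability": self.marginals[r, i]})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = ["Four-state Markov chain (time-inhomogeneous, saturated MLE)", ""]
        lines.append("Marginal state probabilities by round:")
        header = "round " + " ".join(f"{s:>11}" for s in self.states)
        lines.append(header)
        for r in range(self.marginals.shape[0]):
            vals = " ".join(f"{v:11.4f}" for v in self.marginals[r])
            lines.append(f"{r + 1:>5} {vals}")
        for t, label in enumerate(self.interval_labels):
            lines.append("")
            lines.append(f"Transition probabilities, {label} (SE):")
            for i, si in enumerate(self.states):
                if not self.row_defined[t, i]:
                    lines.append(f"  {si:>10} -> undefined (no subjects in origin state)")
                    continue
                cells = "  ".join(
                    f"{sj}={self.transition_matrices[t, i, j]:.3f}({self.standard_errors[t, i, j]:.3f})"
                    for j, sj in enumerate(self.states)
                )
                lines.append(f"  {si:>10} -> {cells}")
        return "\n".join(lines)


def stratified_markov(panel: pd.DataFrame, stratifier: str) -> dict:
    """Independent four-state fits per stratum of a time-constant covariate
    (e.g. sex).  Strata with zero subjects raise via the model constructor."""
    per_subject = panel.groupby("subject_id")[stratifier].nunique()
    if (per_subject > 1).any():
        raise ValueError(f"stratifier {stratifier!r} varies within subject")
    out = {}
    for level, g in panel.groupby(stratifier, sort=True):
        out[level] = FourStateMarkov(g.reset_index(drop=True)).fit()
    return out
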