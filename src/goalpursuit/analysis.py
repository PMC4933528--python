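"""Decision coding, exclusions, and the goal-frame x decision-source analysis.

Every logged decision is compared with the normative model: the chosen
action is coded 1 if it prioritized the goal in the worse position (the
lower score) and 0 otherwise, and the corresponding optimal decision is
coded on the same scale from the solved value table. Decisions are
excluded when (a) at least one goal had already resolved, (b) the two
scores were equal (no worse position exists), or (c) the two actions'
expected values were exactly tied (no optimal decision exists).

Each kept decision then contributes two rows to the modelling table — the
participant's choice and the model's choice — and a logistic regression of
worse-position prioritization on goal frame (+1 approach / -1 avoidance),
decision source (+1 participant / -1 model) and their interaction is
fitted by iteratively reweighted least squares. The published analysis
used a logistic mixed-effects model with random effects of participant
and trial; here the nesting is handled by participant-clustered sandwich
standard errors instead, so coefficient magnitudes are comparable only
qualitatively while the inferential target (the sign and size of the
interaction) is preserved. A negative interaction means the
participant-minus-model gap in worse-position prioritization is lower
under approach than under avoidance framing — risk aversion for gains,
risk seeking for losses.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .mdp import (
    Action,
    GoalFrame,
    JointState,
    TaskSpec,
    ValuePolicyTable,
    backward_induction,
)

__all__ = [
    "code_decisions",
    "apply_exclusions",
    "stack_sources",
    "ClusterLogit",
    "ClusterLogitResults",
    "FrameSourceModel",
    "fit_interaction_model",
    "fit_per_frame_models",
    "summarize_proportions",
    "SeparationWarning",
]

EXCLUSION_NONE = "none"
EXCLUSION_RESOLVED = "goal_resolved"
EXCLUSION_EQUAL = "equal_scores"
EXCLUSION_TIE = "ev_tie"


class SeparationWarning(UserWarning):
    pass


@lru_cache(maxsize=1024)
def _table_for(spec: TaskSpec) -> ValuePolicyTable:
    return backward_induction(spec)


def _specs_from_logs(logs: pd.DataFrame) -> dict[tuple, TaskSpec]:
    cols = ["frame", "horizon", "d1_start", "d2_start"]
    out = {}
    for key in map(tuple, logs[cols].drop_duplicates().itertuples(index=False)):
        frame, horizon, d1s, d2s = key
        out[key] = TaskSpec(GoalFrame(frame), int(horizon), (int(d1s), int(d2s)))
    return out


def code_decisions(
    logs: pd.DataFrame,
    tables: Mapping[tuple, ValuePolicyTable] | None = None,
) -> pd.DataFrame:
    """Attach worse-position coding, the optimal decision, and exclusion flags.

    The worse-position goal is the one with the lower on-screen score.
    ``optimal_coded`` is "1"/"0" on the same scale, or "tie" when the two
    actions' expected values are equal. Rows that cannot be coded carry an
    ``exclusion_reason``; exclusion precedence is resolved-goal, then
    equal scores, then EV tie.
    """
    required = {"frame", "horizon", "d1_start", "d2_start", "d1", "d2", "remaining", "chosen"}
    missing = required - set(logs.columns)
    if missing:
        raise ValueError(f"decision log is missing columns: {sorted(missing)}")

    specs = _specs_from_logs(logs)
    if tables is None:
        tables = {key: _table_for(spec) for key, spec in specs.items()}

    out = logs.copy()
    worse_coded = np.full(len(logs), -1, dtype=int)
    optimal_coded = np.empty(len(logs), dtype=object)
    reasons = np.empty(len(logs), dtype=object)

    keys = list(zip(logs["frame"], logs["horizon"], logs["d1_start"], logs["d2_start"]))
    d1s = logs["d1"].to_numpy()
    d2s = logs["d2"].to_numpy()
    rems = logs["remaining"].to_numpy()
    chosen = logs["chosen"].to_numpy()
    for i, key in enumerate(keys):
        spec = specs[key]
        table = tables[key]
        state = JointState.make(spec.frame, int(d1s[i]), int(d2s[i]))
        if state not in table.states():
            raise KeyError(f"state {state} not in the value table for {spec}")
        optimal_coded[i] = ""
        if state.any_resolved:
            reasons[i] = EXCLUSION_RESOLVED
            continue
        if state.d1 == state.d2:
            reasons[i] = EXCLUSION_EQUAL
            continue
        farther = Action.GOAL1 if state.d1 > state.d2 else Action.GOAL2
        if spec.frame is GoalFrame.APPROACH:
            worse = farther
        else:
            worse = Action.GOAL2 if farther is Action.GOAL1 else Action.GOAL1
        opt = table.action(state, int(rems[i]))
        if opt is Action.TIE:
            reasons[i] = EXCLUSION_TIE
            continue
        reasons[i] = EXCLUSION_NONE
        worse_coded[i] = int(chosen[i] == worse.value)
        optimal_coded[i] = "1" if opt is worse else "0"
    out["worse_coded"] = worse_coded
    out["optimal_coded"] = optimal_coded
    out["exclusion_reason"] = reasons
    return out


def apply_exclusions(records: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop uncodeable decisions; tally counts per exclusion reason."""
    if "exclusion_reason" not in records.columns:
        raise ValueError("records must be coded first (missing exclusion_reason)")
    tally = records["exclusion_reason"].value_counts().to_dict()
    for reason in (EXCLUSION_NONE, EXCLUSION_RESOLVED, EXCLUSION_EQUAL, EXCLUSION_TIE):
        tally.setdefault(reason, 0)
    kept = records[records["exclusion_reason"] == EXCLUSION_NONE].copy()
    tally["kept"] = len(kept)
    tally["total"] = len(records)
    return kept, tally


def stack_sources(records: pd.DataFrame) -> pd.DataFrame:
    """Two modelling rows per kept decision: participant choice and model choice.

    Columns: participant, trial, frame_code (+1 approach / -1 avoidance),
    source (+1 participant / -1 optimal model), worse (0/1 outcome).
    """
    if len(records) == 0:
        return pd.DataFrame(columns=["participant", "trial", "frame_code", "source", "worse"])
    if (records["exclusion_reason"] != EXCLUSION_NONE).any():
        raise ValueError("stack_sources expects kept records only")
    frame_code = np.where(records["frame"] == GoalFrame.APPROACH.value, 1, -1)
    base = pd.DataFrame(
        {
            "participant": records["participant"].to_numpy(),
            "trial": records["trial"].to_numpy(),
            "frame_code": frame_code,
        }
    )
    part = base.copy()
    part["source"] = 1
    part["worse"] = records["worse_coded"].to_numpy()
    model = base.copy()
    model["source"] = -1
    model["worse"] = records["optimal_coded"].astype(int).to_numpy()
    return pd.concat([part, model], ignore_index=True)


# ---------------------------------------------------------------------------
# In-repo clustered logistic regression (IRLS + participant sandwich errors)
# ---------------------------------------------------------------------------


@dataclass
class ClusterLogitResults:
    """Fitted coefficients with cluster-robust inference.

    Attributes mirror the usual results-object surface: ``params``,
    ``bse``, ``zvalues`` and ``pvalues`` are Series indexed by predictor
    name; ``summary()`` renders a fixed-width coefficient table.
    """

    params: pd.Series
    bse: pd.Series
    nobs: int
    n_clusters: int
    deviance: float
    n_iter: int
    converged: bool
    separation: bool
    cov: pd.DataFrame

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(
            2 * stats.norm.sf(np.abs(self.zvalues.to_numpy())), index=self.params.index
        )

    def summary(self, title: str = "Clustered logistic regression") -> str:
        lines = [
            title,
            "=" * 64,
            f"N obs: {self.nobs}    clusters: {self.n_clusters}    "
            f"deviance: {self.deviance:.2f}    iter: {self.n_iter}",
            f"converged: {self.converged}    separation flagged: {self.separation}",
            "-" * 64,
            f"{'predictor':<28}{'beta':>9}{'SE':>9}{'z':>9}{'p':>9}",
            "-" * 64,
        ]
        for name in self.params.index:
            p = self.pvalues[name]
            lines.append(
                f"{name:<28}{self.params[name]:>9.3f}{self.bse[name]:>9.3f}"
                f"{self.zvalues[name]:>9.2f}{('<.001' if p < 0.001 else f'{p:.3f}'):>9}"
            )
        lines.append("=" * 64)
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "nobs": int(self.nobs),
            "n_clusters": int(self.n_clusters),
            "converged": bool(self.converged),
            "separation": bool(self.separation),
        }


class ClusterLogit:
    """Binary logistic regression fitted by IRLS with clustered sandwich SEs.

    The deviance-change stopping rule is 1e-8 with at most 100 iterations;
    separation is flagged when any coefficient exceeds 15 in magnitude.
    Standard errors use the CR1 small-sample correction
    ``G/(G-1) * (N-1)/(N-k)`` on the score-outer-product meat, clustered
    on ``groups`` (participants).
    """

    def __init__(
        self,
        endog: np.ndarray,
        exog: np.ndarray,
        groups: np.ndarray,
        exog_names: list[str] | None = None,
    ):
        self.endog = np.asarray(endog, dtype=float)
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or len(self.endog) != len(self.exog):
            raise ValueError("exog must be 2-D and conformable with endog")
        if len(self.endog) == 0:
            raise ValueError("empty estimation sample")
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise ValueError("endog must be binary 0/1")
        self.groups = np.asarray(groups)
        self.exog_names = exog_names or [f"x{i}" for i in range(self.exog.shape[1])]

    def fit(self, tol: float = 1e-8, maxiter: int = 100) -> ClusterLogitResults:
        X, y = self.exog, self.endog
        n, k = X.shape
        beta = np.zeros(k)
        dev_old = np.inf
        converged = False
        it = 0
        for it in range(1, maxiter + 1):
            eta = X @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            mu = np.clip(mu, 1e-10, 1 - 1e-10)
            w = mu * (1 - mu)
            z = eta + (y - mu) / w
            xtw = X.T * w
            beta = np.linalg.solve(xtw @ X, xtw @ z)
            with np.errstate(divide="ignore", invalid="ignore"):
                dev = -2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu))
            if abs(dev_old - dev) < tol:
                converged = True
                dev_old = dev
                break
            dev_old = dev
        separation = bool(np.any(np.abs(beta) > 15))

        eta = X @ beta
        mu = np.clip(1.0 / (1.0 + np.exp(-eta)), 1e-10, 1 - 1e-10)
        w = mu * (1 - mu)
        bread = np.linalg.inv((X.T * w) @ X)
        resid = y - mu
        score_df = pd.DataFrame(X * resid[:, None])
        score_df["__g"] = self.groups
        cluster_scores = score_df.groupby("__g").sum().to_numpy()
        g = cluster_scores.shape[0]
        meat = cluster_scores.T @ cluster_scores
        correction = (g / (g - 1)) * ((n - 1) / (n - k)) if g > 1 else 1.0
        cov = correction * bread @ meat @ bread
        names = self.exog_names
        return ClusterLogitResults(
            params=pd.Series(beta, index=names),
            bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
            nobs=n,
            n_clusters=g,
            deviance=float(dev_old),
            n_iter=it,
            converged=converged,
            separation=separation,
            cov=pd.DataFrame(cov, index=names, columns=names),
        )


class FrameSourceModel:
    """Worse-position prioritization as a function of frame and source.

    Statsmodels-style front end over :class:`ClusterLogit`: build from the
    stacked modelling table with :meth:`from_decisions`, call :meth:`fit`
    for the interaction model, and :meth:`fit_per_frame` for the follow-up
    single-predictor models within each frame.
    """

    PREDICTORS = ["intercept", "goal_frame", "decision_source", "frame_x_source"]

    def __init__(self, table: pd.DataFrame):
        required = {"participant", "frame_code", "source", "worse"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"modelling table is missing columns: {sorted(missing)}")
        if len(table) == 0:
            raise ValueError("empty modelling table")
        self.table = table.reset_index(drop=True)

    @classmethod
    def from_decisions(cls, records: pd.DataFrame) -> "FrameSourceModel":
        """Build directly from kept coded decision records (stacking included)."""
        return cls(stack_sources(records))

    def fit(self) -> ClusterLogitResults:
        t = self.table
        X = np.column_stack(
            [
                np.ones(len(t)),
                t["frame_code"].to_numpy(float),
                t["source"].to_numpy(float),
                (t["frame_code"] * t["source"]).to_numpy(float),
            ]
        )
        return ClusterLogit(
            t["worse"].to_numpy(float), X, t["participant"].to_numpy(), self.PREDICTORS
        ).fit()

    def fit_per_frame(self) -> dict[str, ClusterLogitResults]:
        """Separate source-only models for the approach and avoidance subsets."""
        out = {}
        for label, code in (("approach", 1), ("avoidance", -1)):
            sub = self.table[self.table["frame_code"] == code]
            if len(sub) == 0:
                raise ValueError(f"no observations in the {label} subset")
            X = np.column_stack([np.ones(len(sub)), sub["source"].to_numpy(float)])
            out[label] = ClusterLogit(
                sub["worse"].to_numpy(float),
                X,
                sub["participant"].to_numpy(),
                ["intercept", "decision_source"],
            ).fit()
        return out


def fit_interaction_model(table: pd.DataFrame) -> ClusterLogitResults:
    """Frame x source interaction logit on the stacked modelling table."""
    return FrameSourceModel(table).fit()


def fit_per_frame_models(table: pd.DataFrame) -> dict[str, ClusterLogitResults]:
    """Source-only logits within each goal frame."""
    return FrameSourceModel(table).fit_per_frame()


def summarize_proportions(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Worse-position prioritization rate per frame x source cell.

    Wilson score intervals at level ``1 - alpha``.
    """
    rows = []
    for (fc, src), sub in table.groupby(["frame_code", "source"]):
        n = len(sub)
        x = int(sub["worse"].sum())
        p = x / n
        z = stats.norm.ppf(1 - alpha / 2)
        denom = 1 + z**2 / n
        center = (p + z**2 / (2 * n)) / denom
        half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
        rows.append(
            {
                "frame": "approach" if fc == 1 else "avoidance",
                "source": "participant" if src == 1 else "model",
                "n": n,
                "prop_worse": p,
                "ci_low": max(0.0, center - half),
                "ci_high": min(1.0, center + half),
            }
        )
    return pd.DataFrame(rows).sort_values(["frame", "source"]).reset_index(drop=True)
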