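"""Spike-train selectivity statistics for maze-based decision tasks.

Given per-neuron spike times and the trajectory windows produced by the
query engine (turn traversals, central-arm runs, choice-turn intervals),
this module computes:

* firing rates over half-open windows [t0, t1);
* turn selectivity — a two-factor analysis of variance (direction x turn
  location) on per-traversal rates over the 8 maze turns x 2 directions,
  with a neuron called turn-selective when the direction main effect has
  p < 0.05; the preferred direction is the one with the higher grand mean;
* trajectory selectivity — a two-sample t-test on central-arm rates of
  trials originating at R1 vs R2;
* d-prime discriminability, d' = (mu_a - mu_b) / sigma, with sigma the
  standard deviation of the two mean-centred samples pooled together;
* prospective ramping profiles over the intervals a–j approaching the
  choice turn, split preferred/unpreferred x correct/error, with a
  two-factor ANOVA at the choice-turn interval h;
* correct-vs-error trial duration comparison (medians + Wilcoxon rank sum);
* the conjunctive-coding table of turn and trajectory d-primes for neurons
  passing either selectivity test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "firing_rate",
    "turn_rate_samples",
    "central_rate_samples",
    "TurnSelectivityResult",
    "turn_selectivity",
    "TrajectorySelectivityResult",
    "trajectory_selectivity",
    "DPrimeResult",
    "dprime",
    "RampingResult",
    "ramping_profile",
    "interval_rate_table",
    "duration_comparison",
    "classify_neurons",
    "conjunctive_scatter",
]

ALPHA = 0.05


def firing_rate(spike_times: np.ndarray, t0: float, t1: float) -> float:
    """Spike count in the half-open window [t0, t1) divided by its duration."""
    if not t1 > t0:
        raise ValueError("window must have t1 > t0")
    spike_times = np.asarray(spike_times)
    n = np.searchsorted(spike_times, t1, side="left") - np.searchsorted(
        spike_times, t0, side="left"
    )
    return float(n) / (t1 - t0)


def turn_rate_samples(spike_times: np.ndarray, turn_windows: pd.DataFrame) -> pd.DataFrame:
    """Per-traversal firing rates labelled by turn id and direction.

    ``turn_windows`` needs columns turn_id, direction and either
    (t_start, t_end) or (t_in, t_out).
    """
    c0 = "t_start" if "t_start" in turn_windows.columns else "t_in"
    c1 = "t_end" if "t_end" in turn_windows.columns else "t_out"
    df = turn_windows.copy()
    df["rate"] = [
        firing_rate(spike_times, a, b) for a, b in zip(df[c0], df[c1])
    ]
    df["duration"] = df[c1] - df[c0]
    return df


def central_rate_samples(spike_times: np.ndarray, trial_table: pd.DataFrame) -> pd.DataFrame:
    """Central-arm firing rates per choice trial (columns origin, central_t0/t1)."""
    df = trial_table.copy()
    df["rate"] = [
        firing_rate(spike_times, a, b) for a, b in zip(df["central_t0"], df["central_t1"])
    ]
    return df


# ---------------------------------------------------------------------------
# selectivity tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TurnSelectivityResult:
    p_direction: float
    preferred_direction: Optional[str]
    is_selective: bool
    mean_left: float
    mean_right: float
    degenerate: bool = False  # zero-variance (or saturated) design


def _anova_direction_p(df: pd.DataFrame, include_interaction: bool) -> float:
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    formula = "rate ~ C(direction) * C(turn_id)" if include_interaction else "rate ~ C(direction) + C(turn_id)"
    fit = smf.ols(formula, data=df).fit()
    if fit.df_resid <= 0 and include_interaction:
        # one observation per cell saturates the interaction model
        fit = smf.ols("rate ~ C(direction) + C(turn_id)", data=df).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = sm.stats.anova_lm(fit, typ=2)
    return float(table.loc["C(direction)", "PR(>F)"])


def turn_selectivity(
    samples: pd.DataFrame,
    alpha: float = ALPHA,
    include_interaction: bool = True,
) -> TurnSelectivityResult:
    """Two-factor ANOVA (direction x turn location) on per-traversal rates.

    The neuron is turn selective when the direction main effect is
    significant at ``alpha``; its preferred direction is the direction with
    the higher grand mean rate.  No minimum firing rate is demanded.  Cells
    may be unbalanced; Type II sums of squares are used.  A design with zero
    rate variance everywhere yields an undefined F and is reported as not
    selective with ``degenerate=True``.
    """
    df = samples[["direction", "turn_id", "rate"]].dropna()
    for d in ("left", "right"):
        if (df["direction"] == d).sum() < 1:
            raise ValueError(f"no traversals in direction {d!r}")
    if df.groupby("direction")["rate"].count().max() < 2:
        raise ValueError("need at least 2 traversals in one direction")
    mean_left = float(df.loc[df["direction"] == "left", "rate"].mean())
    mean_right = float(df.loc[df["direction"] == "right", "rate"].mean())
    if np.allclose(df["rate"].var(ddof=0), 0.0):
        return TurnSelectivityResult(float("nan"), None, False, mean_left, mean_right, True)
    p = _anova_direction_p(df, include_interaction)
    if not np.isfinite(p):
        return TurnSelectivityResult(float("nan"), None, False, mean_left, mean_right, True)
    preferred = "left" if mean_left >= mean_right else "right"
    return TurnSelectivityResult(p, preferred, bool(p < alpha), mean_left, mean_right)


@dataclass(frozen=True)
class TrajectorySelectivityResult:
    p: float
    is_selective: bool
    mean_r1: float
    mean_r2: float
    preferred_origin: Optional[str]
    degenerate: bool = False


def trajectory_selectivity(
    rates_r1: Sequence[float],
    rates_r2: Sequence[float],
    alpha: float = ALPHA,
) -> TrajectorySelectivityResult:
    """Two-sample t-test of central-arm rates on trials from R1 vs from R2."""
    a = np.asarray(rates_r1, dtype=float)
    b = np.asarray(rates_r2, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 trials per origin")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        if a.mean() == b.mean():
            return TrajectorySelectivityResult(float("nan"), False, a.mean(), b.mean(), None, True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(a, b)
    if not np.isfinite(p):
        return TrajectorySelectivityResult(float("nan"), False, a.mean(), b.mean(), None, True)
    preferred = "R1" if a.mean() >= b.mean() else "R2"
    return TrajectorySelectivityResult(float(p), bool(p < alpha), float(a.mean()), float(b.mean()), preferred)


# ---------------------------------------------------------------------------
# d-prime
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DPrimeResult:
    d_prime: float
    mu_a: float
    mu_b: float
    sigma: float


def dprime(rates_a: Sequence[float], rates_b: Sequence[float], ddof: int = 1) -> DPrimeResult:
    """Discriminability d' = (mu_a - mu_b) / sigma of two rate distributions.

    The common sigma is the standard deviation of the pooled mean-centred
    residuals: both samples are centred on their own mean and concatenated.
    ``ddof=1`` treats the pooled residuals as one sample (the convention
    used here); ``ddof=2`` removes one degree of freedom per centred group.
    A zero pooled sigma is signalled with a ValueError rather than
    returning an infinite d'.
    """
    a = np.asarray(rates_a, dtype=float)
    b = np.asarray(rates_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 observations per condition")
    mu_a, mu_b = float(a.mean()), float(b.mean())
    pooled = np.concatenate([a - mu_a, b - mu_b])
    sigma = float(np.sqrt((pooled**2).sum() / (pooled.size - ddof)))
    if sigma == 0.0:
        if mu_a == mu_b:
            return DPrimeResult(0.0, mu_a, mu_b, 0.0)
        raise ValueError("pooled sigma is zero; d-prime undefined")
    return DPrimeResult((mu_a - mu_b) / sigma, mu_a, mu_b, sigma)


# ---------------------------------------------------------------------------
# prospective ramping
# ---------------------------------------------------------------------------


@dataclass
class RampingResult:
    curves: pd.DataFrame  # index interval, columns (preference, outcome) mean rates
    n_neurons: int
    p_preference: float
    p_outcome: float
    p_interaction: float
    error_trials_present: bool


def interval_rate_table(
    spikes: Mapping[int, np.ndarray],
    trial_table: pd.DataFrame,
    preferred_direction: Mapping[int, str],
    intervals: Iterable[str] = tuple("abcdefghij"),
) -> pd.DataFrame:
    """Per-trial firing rates of turn-selective neurons in intervals a–j.

    ``trial_table`` is the choice-trial table (one row per trial with
    ``t_<interval>_0/1`` bounds, ``outcome`` and ``choice_dir``); each
    neuron's trials are labelled preferred/unpreferred by comparing the
    trial's choice-turn direction with the neuron's preferred direction.
    """
    rows = []
    for nid, pref in preferred_direction.items():
        st = spikes[nid]
        for _, tr in trial_table.iterrows():
            preference = "preferred" if tr["choice_dir"] == pref else "unpreferred"
            for nm in intervals:
                c0, c1 = f"t_{nm}_0", f"t_{nm}_1"
                if c0 not in tr or not np.isfinite(tr[c0]) or not tr[c1] > tr[c0]:
                    continue
                vcol = f"valid_{nm}"
                if vcol in tr and not tr[vcol]:
                    continue
                rows.append(
                    {
                        "neuron": nid,
                        "interval": nm,
                        "preference": preference,
                        "outcome": tr["outcome"],
                        "rate": firing_rate(st, tr[c0], tr[c1]),
                    }
                )
    return pd.DataFrame(rows)


def ramping_profile(
    rate_table: pd.DataFrame,
    choice_interval: str = "h",
    include_interaction: bool = True,
) -> RampingResult:
    """Average ramping curves and the choice-turn ANOVA.

    Curves are across-neuron means of within-neuron mean rates per interval
    for each (preference, outcome) condition.  At the choice-turn interval
    the within-neuron condition means enter a two-factor ANOVA
    (preference x outcome) whose main-effect and interaction p-values are
    returned.  Without error trials the error curves are omitted and the
    outcome factor is dropped.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if rate_table.empty:
        raise ValueError("empty rate table")
    per_neuron = (
        rate_table.groupby(["neuron", "interval", "preference", "outcome"])["rate"]
        .mean()
        .reset_index()
    )
    curves = (
        per_neuron.groupby(["interval", "preference", "outcome"])["rate"]
        .mean()
        .unstack(["preference", "outcome"])
    )
    has_error = "error" in rate_table["outcome"].unique()
    at_h = per_neuron[per_neuron["interval"] == choice_interval]
    p_pref = p_out = p_int = float("nan")
    if has_error:
        formula = (
            "rate ~ C(preference) * C(outcome)"
            if include_interaction
            else "rate ~ C(preference) + C(outcome)"
        )
        fit = smf.ols(formula, data=at_h).fit()
        if fit.df_resid <= 0:
            # one observation per cell saturates the interaction model
            include_interaction = False
            fit = smf.ols("rate ~ C(preference) + C(outcome)", data=at_h).fit()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table = sm.stats.anova_lm(fit, typ=2)
        p_pref = float(table.loc["C(preference)", "PR(>F)"])
        p_out = float(table.loc["C(outcome)", "PR(>F)"])
        if include_interaction:
            p_int = float(table.loc["C(preference):C(outcome)", "PR(>F)"])
    else:
        grp = [at_h.loc[at_h["preference"] == g, "rate"] for g in ("preferred", "unpreferred")]
        if all(len(g) > 1 for g in grp):
            _, p_pref = stats.ttest_ind(*grp)
    return RampingResult(
        curves=curves,
        n_neurons=rate_table["neuron"].nunique(),
        p_preference=p_pref,
        p_outcome=p_out,
        p_interaction=p_int,
        error_trials_present=has_error,
    )


# ---------------------------------------------------------------------------
# durations, classification, conjunctive coding
# ---------------------------------------------------------------------------


def duration_comparison(
    correct_durations: Sequence[float],
    error_durations: Sequence[float],
) -> tuple[float, float, float]:
    """Median correct / error durations and two-sided Wilcoxon rank-sum p."""
    a = np.asarray(correct_durations, dtype=float)
    b = np.asarray(error_durations, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both duration groups must be non-empty")
    stat, p = stats.ranksums(a, b)
    return float(np.median(a)), float(np.median(b)), float(p)


def classify_neurons(
    spikes: Mapping[int, np.ndarray],
    turn_windows: pd.DataFrame,
    trial_table: pd.DataFrame,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-neuron selectivity summary over a full session.

    Runs the turn-selectivity ANOVA on all turn traversals, the trajectory
    t-test on central-arm rates (R1- vs R2-origin choice trials, validity
    gated when a ``central_valid`` column is present), and both d-primes.
    Returns one row per neuron with p-values, preferred conditions, signed
    d-primes and the selectivity class (turn / trajectory / conjunctive /
    none).
    """
    trials = trial_table
    if "central_valid" in trials.columns:
        trials = trials[trials["central_valid"]]
    rows = []
    for nid, st in spikes.items():
        ts = turn_selectivity(turn_rate_samples(st, turn_windows))
        cen = central_rate_samples(st, trials)
        r1 = cen.loc[cen["origin"] == "R1", "rate"].to_numpy()
        r2 = cen.loc[cen["origin"] == "R2", "rate"].to_numpy()
        tj = trajectory_selectivity(r1, r2, alpha)
        samples = turn_rate_samples(st, turn_windows)
        left = samples.loc[samples["direction"] == "left", "rate"].to_numpy()
        right = samples.loc[samples["direction"] == "right", "rate"].to_numpy()
        try:
            turn_dp = dprime(left, right).d_prime
        except ValueError:
            turn_dp = float("nan")
        try:
            traj_dp = dprime(r1, r2).d_prime
        except ValueError:
            traj_dp = float("nan")
        if ts.is_selective and tj.is_selective:
            cls = "conjunctive"
        elif ts.is_selective:
            cls = "turn"
        elif tj.is_selective:
            cls = "trajectory"
        else:
            cls = "none"
        rows.append(
            {
                "neuron": nid,
                "p_turn": ts.p_direction,
                "preferred_turn": ts.preferred_direction,
                "turn_selective": ts.is_selective,
                "p_trajectory": tj.p,
                "preferred_origin": tj.preferred_origin,
                "trajectory_selective": tj.is_selective,
                "turn_dprime": turn_dp,
                "trajectory_dprime": traj_dp,
                "class": cls,
            }
        )
    return pd.DataFrame(rows)


def conjunctive_scatter(classification: pd.DataFrame) -> pd.DataFrame:
    """Turn vs trajectory d-prime table for neurons passing either test.

    Unselective neurons are excluded (the inclusion rule for the d-prime
    comparison); the class column distinguishes pure turn, pure trajectory
    and conjunctive neurons.  d-primes are stored signed; plot magnitudes.
    """
    sel = classification[classification["class"] != "none"]
    return sel[["neuron", "turn_dprime", "trajectory_dprime", "class"]].reset_index(drop=True)
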