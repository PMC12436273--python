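"""Kaplan-Meier estimation, K-group log-rank test and optimal-cutoff split.

The product-limit estimator and log-rank statistic are implemented from
their standard definitions (events precede censorings at tied times).
The optimal-cutoff scan — splitting a cohort at the score value whose
two-group log-rank test is most significant — is intentionally reported
without multiplicity correction; the returned p-value is flagged as
selection-biased.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist


@dataclass
class KmCurve:
    """Right-continuous product-limit survival curve."""

    times: np.ndarray  # distinct event times, ascending
    n_at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray  # S(t) just after each event time

    def survival_at(self, t: float) -> float:
        """S(t): probability of surviving beyond t."""
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])

    @property
    def median(self) -> float:
        below = np.flatnonzero(self.survival <= 0.5)
        return float(self.times[below[0]]) if below.size else float("nan")


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray
    groups: list


@dataclass
class CutoffResult:
    cutoff: float
    labels: pd.Series  # "high" / "low"
    p_min: float
    n_candidates: int
    selection_biased: bool = True  # p_min is a scan minimum, not corrected


def _check_records(time: np.ndarray, event: np.ndarray) -> None:
    if time.size == 0:
        raise ValueError("no survival records")
    if (time < 0).any():
        raise ValueError("negative survival times")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event flags must be 0 or 1")


def km_curve(time, event) -> KmCurve:
    """Product-limit estimator over distinct event times."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _check_records(time, event)

    order = np.argsort(time, kind="mergesort")
    t, e = time[order], event[order]
    n = t.size
    ev_times = np.unique(t[e == 1])
    n_at_risk = np.empty(ev_times.size, dtype=int)
    n_events = np.empty(ev_times.size, dtype=int)
    for i, ti in enumerate(ev_times):
        # events precede censorings at tied times: at risk = all with time >= ti
        n_at_risk[i] = int((t >= ti).sum())
        n_events[i] = int(((t == ti) & (e == 1)).sum())
    surv = np.cumprod(1.0 - n_events / np.maximum(n_at_risk, 1))
    return KmCurve(times=ev_times, n_at_risk=n_at_risk, n_events=n_events, survival=surv)


def logrank_test(time, event, group) -> LogrankResult:
    """K-group log-rank test (chi-square, K-1 degrees of freedom).

    At each distinct event time, the observed events per group are
    compared with their hypergeometric expectation given the at-risk
    sets; the quadratic form uses the hypergeometric covariance of the
    first K-1 groups.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    _check_records(time, event)
    if group.size != time.size:
        raise ValueError("group labels not aligned with records")

    levels = [g for g in pd.unique(group)]
    if len(levels) < 2:
        raise ValueError("log-rank needs at least 2 groups")
    for g in levels:
        if (group == g).sum() == 0:
            raise ValueError(f"group {g!r} has zero subjects")
    levels = sorted(levels, key=str)
    k = len(levels)
    gidx = np.array([levels.index(g) for g in group])

    ev_times = np.unique(time[event == 1])
    observed = np.zeros(k)
    expected = np.zeros(k)
    # covariance of O-E for the first k-1 groups
    cov = np.zeros((k - 1, k - 1))
    for ti in ev_times:
        at_risk = time >= ti
        n_i = int(at_risk.sum())
        d_i = int(((time == ti) & (event == 1)).sum())
        if n_i == 0:
            continue
        n_ij = np.bincount(gidx[at_risk], minlength=k).astype(float)
        d_ij = np.bincount(
            gidx[(time == ti) & (event == 1)], minlength=k
        ).astype(float)
        observed += d_ij
        e_ij = d_i * n_ij / n_i
        expected += e_ij
        if n_i > 1:
            frac = n_ij / n_i
            mult = d_i * (n_i - d_i) / (n_i - 1)
            for a in range(k - 1):
                for b in range(k - 1):
                    if a == b:
                        cov[a, b] += mult * frac[a] * (1 - frac[a])
                    else:
                        cov[a, b] -= mult * frac[a] * frac[b]

    diff = (observed - expected)[: k - 1]
    try:
        stat = float(diff @ np.linalg.solve(cov, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(cov) @ diff)
    stat = max(stat, 0.0)
    df = k - 1
    p = float(chi2_dist.sf(stat, df))
    return LogrankResult(
        statistic=stat, df=df, p_value=p, observed=observed, expected=expected,
        groups=levels,
    )


def _two_group_stats(time, event, membership) -> np.ndarray:
    """Vectorized two-group log-rank chi-square for many label vectors.

    ``membership`` is records x P (0/1 membership of group 1); returns P
    statistics. Used by the permutation reference.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    ev_times = np.unique(time[event == 1])
    at_risk = time[None, :] >= ev_times[:, None]  # T x n
    ev_here = (time[None, :] == ev_times[:, None]) & (event[None, :] == 1)
    n_i = at_risk.sum(axis=1).astype(float)  # T
    d_i = ev_here.sum(axis=1).astype(float)
    g = np.asarray(membership, dtype=float)  # n x P
    n1 = at_risk.astype(float) @ g  # T x P
    d1 = ev_here.astype(float) @ g
    frac = n1 / n_i[:, None]
    o_minus_e = (d1 - d_i[:, None] * frac).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        var_t = (
            (d_i * (n_i - d_i) / np.maximum(n_i - 1, 1.0))[:, None]
            * frac
            * (1.0 - frac)
        )
    var = var_t.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        stat = np.where(var > 0, o_minus_e**2 / var, 0.0)
    return stat


def logrank_permutation_p(
    time, event, group, n_perm: int = 20_000, seed: int = 0
) -> float:
    """Two-group permutation reference for the log-rank statistic."""
    group = np.asarray(group)
    levels = pd.unique(group)
    if len(levels) != 2:
        raise ValueError("permutation reference implemented for 2 groups")
    obs = logrank_test(time, event, group).statistic
    member = (group == levels[0]).astype(float)
    rng = np.random.default_rng(seed)
    perms = np.empty((member.size, n_perm))
    for j in range(n_perm):
        perms[:, j] = rng.permutation(member)
    stats = _two_group_stats(time, event, perms)
    hits = int((stats >= obs - 1e-12).sum())
    return (hits + 1) / (n_perm + 1)


def optimal_cutoff(
    scores,
    time,
    event,
    *,
    qrange: tuple[float, float] = (0.10, 0.90),
) -> CutoffResult:
    """Score cutoff giving the most significant two-group log-rank split.

    Candidate cutoffs are the observed score values whose high/low split
    leaves at least a ``qrange``-implied share of records on each side.
    The reported minimal p is selection-biased (no multiplicity
    correction) — by construction it overstates significance.
    """
    scores = pd.Series(scores)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    _check_records(time, event)
    if scores.size != time.size:
        raise ValueError("scores not aligned with records")
    if scores.size < 10:
        raise ValueError("need at least 10 records for a cutoff scan")
    arr = scores.to_numpy(dtype=float)
    if np.unique(arr).size < 2:
        raise ValueError("all scores identical; no cutoff exists")

    n = arr.size
    min_side = max(1, int(np.ceil(qrange[0] * n)))
    candidates = np.unique(arr)
    high_mat = arr[:, None] > candidates[None, :]  # n x C
    sides_ok = (high_mat.sum(axis=0) >= min_side) & (
        (~high_mat).sum(axis=0) >= min_side
    )
    if not sides_ok.any():
        raise ValueError("no candidate cutoff satisfies the group-size floor")
    candidates = candidates[sides_ok]
    stats = _two_group_stats(time, event, high_mat[:, sides_ok].astype(float))
    pvals = chi2_dist.sf(stats, 1)
    best = int(np.argmin(pvals))
    best_c = float(candidates[best])
    labels = pd.Series(
        np.where(arr > best_c, "high", "low"), index=scores.index, name="split"
    )
    return CutoffResult(
        cutoff=best_c,
        labels=labels,
        p_min=float(pvals[best]),
        n_candidates=int(sides_ok.sum()),
    )
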