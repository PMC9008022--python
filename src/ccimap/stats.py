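"""Association and survival statistics downstream of CCI scoring.

Correlation of scores with signature expression, two-group comparisons,
hypergeometric overlap of gene sets, Kaplan-Meier / log-rank stratification,
and a maximally selected log-rank cut-point for continuous scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from ccimap.io_qc import ExpressionMatrix, SignatureSet
from ccimap.cci import signature_score


@dataclass
class SurvivalRecord:
    """One subject's follow-up: time-to-event, event flag and score."""

    subject_id: str
    time: float
    event: bool
    score: float
    group: Literal["low", "high"] | None = None

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"time must be positive, got {self.time}")
        self.event = bool(self.event)


def records_to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in records],
            "time": [r.time for r in records],
            "event": [int(r.event) for r in records],
            "score": [r.score for r in records],
            "group": [r.group for r in records],
        }
    )


def read_survival(path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        SurvivalRecord(str(r.subject_id), float(r.time), bool(int(r.event)), float(r.score))
        for r in df.itertuples()
    ]


def score_signature_correlation(
    scores: np.ndarray,
    m: ExpressionMatrix,
    s: SignatureSet,
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[float, float]:
    """Correlate per-observation scores with mean signature expression.

    Returns (coefficient, two-sided p).
    """
    scores = np.asarray(scores, float)
    if len(scores) != m.n_obs:
        raise ValueError("scores length must equal the number of observations")
    if len(scores) < 10:
        raise ValueError("need >= 10 observations")
    sig = signature_score(m, s)
    if np.std(scores) == 0 or np.std(sig) == 0:
        raise ValueError("zero-variance input")
    if method == "pearson":
        res = stats.pearsonr(scores, sig)
    elif method == "spearman":
        res = stats.spearmanr(scores, sig)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def group_compare(
    values: np.ndarray,
    labels: np.ndarray,
    test: Literal["wilcoxon_ranksum", "t_test"] = "wilcoxon_ranksum",
) -> dict:
    """Two-sided two-group comparison.

    ``labels`` is a binary vector; returns statistic, p and per-group
    medians and means.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(levels)}")
    g0 = values[labels == levels[0]]
    g1 = values[labels == levels[1]]
    if len(g0) < 3 or len(g1) < 3:
        raise ValueError("each group needs >= 3 observations")
    if np.std(g0) == 0 and np.std(g1) == 0 and g0[0] == g1[0]:
        raise ValueError("both groups constant and equal: degenerate comparison")
    if test == "wilcoxon_ranksum":
        res = stats.mannwhitneyu(g0, g1, alternative="two-sided")
    elif test == "t_test":
        res = stats.ttest_ind(g0, g1)
    else:
        raise ValueError(f"unknown test {test!r}")
    return {
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "median": {str(levels[0]): float(np.median(g0)), str(levels[1]): float(np.median(g1))},
        "mean": {str(levels[0]): float(np.mean(g0)), str(levels[1]): float(np.mean(g1))},
    }


def hypergeom_overlap(universe_n: int, set_a: int, set_b: int, overlap: int) -> float:
    """Upper-tail hypergeometric probability of an overlap at least this large.

    P(X >= overlap) when drawing ``set_b`` items without replacement from a
    universe of ``universe_n`` with ``set_a`` marked.
    """
    if not (0 <= set_a <= universe_n and 0 <= set_b <= universe_n):
        raise ValueError("set sizes must lie within the universe")
    if overlap < 0 or overlap > min(set_a, set_b):
        raise ValueError("overlap must be within [0, min(set_a, set_b)]")
    return float(stats.hypergeom.sf(overlap - 1, universe_n, set_a, set_b))


def _logrank_scores(time: np.ndarray, event: np.ndarray) -> np.ndarray:
    """Per-subject log-rank (Savage) scores: event - Nelson-Aalen at own time."""
    order = np.argsort(time, kind="mergesort")
    t_sorted = time[order]
    e_sorted = event[order]
    n = len(time)
    uniq, first_idx = np.unique(t_sorted, return_index=True)
    at_risk = n - first_idx
    deaths = np.array([e_sorted[t_sorted == u].sum() for u in uniq], float)
    na_increments = deaths / at_risk
    na_cum = np.cumsum(na_increments)
    pos = np.searchsorted(uniq, time)
    return event.astype(float) - na_cum[pos]


def _standardized_linear_rank(scores_a: np.ndarray, in_group: np.ndarray) -> float:
    """Standardized linear rank statistic for the subjects flagged in_group."""
    n = len(scores_a)
    n1 = int(in_group.sum())
    if n1 == 0 or n1 == n:
        return 0.0
    s = scores_a[in_group].sum()
    mean_a = scores_a.mean()
    e = n1 * mean_a
    v = n1 * (n - n1) / (n * (n - 1)) * ((scores_a - mean_a) ** 2).sum()
    if v <= 0:
        return 0.0
    return float((s - e) / math.sqrt(v))


def maxstat_cutpoint(
    records: Sequence[SurvivalRecord],
    qmin: float = 0.1,
    qmax: float = 0.9,
) -> tuple[float, float]:
    """Maximally selected log-rank cut-point for a continuous score.

    Candidate cut-points are the distinct score values between the
    ``qmin``/``qmax`` quantiles; at each, subjects are split into
    score <= cut vs score > cut and the standardized log-rank statistic is
    computed from per-subject log-rank scores (permutation variance).
    Returns the cut-point with the largest |statistic| (ties broken toward
    the median score) and that statistic.

    The p-value at the selected cut-point is post-selection and
    anti-conservative; report it as descriptive only.
    """
    records = list(records)
    if len(records) < 20:
        raise ValueError("need >= 20 records")
    time = np.array([r.time for r in records])
    event = np.array([r.event for r in records], bool)
    score = np.array([r.score for r in records])
    if event.sum() < 5:
        raise ValueError("need >= 5 events")
    lo, hi = np.quantile(score, [qmin, qmax])
    candidates = np.unique(score)
    candidates = candidates[(candidates >= lo) & (candidates <= hi)]
    # a cut at the maximum score would leave the high group empty
    candidates = candidates[candidates < score.max()]
    if len(candidates) == 0:
        raise ValueError("no candidate cut-point inside the quantile window")
    a = _logrank_scores(time, event)
    stats_abs = np.empty(len(candidates))
    stat_signed = np.empty(len(candidates))
    for i, cut in enumerate(candidates):
        z = _standardized_linear_rank(a, score > cut)
        stat_signed[i] = z
        stats_abs[i] = abs(z)
    if np.all(stats_abs == 0):
        raise ValueError("every candidate split puts all events in one group")
    best = stats_abs.max()
    tied = np.where(stats_abs == best)[0]
    median = np.median(score)
    pick = tied[np.argmin(np.abs(candidates[tied] - median))]
    return float(candidates[pick]), float(stat_signed[pick])


def maxstat_permutation_null(
    records: Sequence[SurvivalRecord],
    n_permutations: int = 200,
    seed: int = 0,
    qmin: float = 0.1,
    qmax: float = 0.9,
) -> np.ndarray:
    """Null distribution of the selected |statistic| by permuting scores."""
    rng = np.random.default_rng(seed)
    records = list(records)
    scores = np.array([r.score for r in records])
    out = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(scores)
        shuffled = [
            SurvivalRecord(r.subject_id, r.time, r.event, s)
            for r, s in zip(records, perm)
        ]
        _, stat = maxstat_cutpoint(shuffled, qmin=qmin, qmax=qmax)
        out[i] = abs(stat)
    return out


def assign_groups(records: Sequence[SurvivalRecord], cutpoint: float) -> list[SurvivalRecord]:
    """Return copies with group = high when score > cutpoint, else low."""
    return [
        SurvivalRecord(r.subject_id, r.time, r.event, r.score, "high" if r.score > cutpoint else "low")
        for r in records
    ]


def km_logrank(records: Sequence[SurvivalRecord]) -> dict:
    """Kaplan-Meier medians per group plus the two-group log-rank test.

    Medians that are never reached are reported as ``inf``.  When no events
    occur at all, the log-rank test is degenerate and chi2/p are NaN.
    """
    records = list(records)
    groups = {r.group for r in records}
    if groups != {"low", "high"}:
        raise ValueError(f"records must be grouped into low/high, got {sorted(map(str, groups))}")
    out: dict = {}
    frames = {}
    for g in ("low", "high"):
        sub = [r for r in records if r.group == g]
        t = np.array([r.time for r in sub])
        e = np.array([int(r.event) for r in sub])
        kmf = KaplanMeierFitter()
        kmf.fit(t, e, label=g)
        out[f"median_{g}"] = float(kmf.median_survival_time_)
        frames[g] = (t, e)
    t_lo, e_lo = frames["low"]
    t_hi, e_hi = frames["high"]
    if e_lo.sum() + e_hi.sum() == 0:
        out["chi2"] = float("nan")
        out["p"] = float("nan")
        out["note"] = "no events observed; log-rank degenerate"
        return out
    res = logrank_test(t_lo, t_hi, event_observed_A=e_lo, event_observed_B=e_hi)
    out["chi2"] = float(res.test_statistic)
    out["p"] = float(res.p_value)
    return out


def km_table(records: Sequence[SurvivalRecord], group: str) -> pd.DataFrame:
    """Kaplan-Meier life table (time, at-risk, events, survival) for one group."""
    sub = [r for r in records if r.group == group]
    if not sub:
        raise ValueError(f"no records in group {group!r}")
    t = np.array([r.time for r in sub])
    e = np.array([int(r.event) for r in sub])
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    tbl = kmf.event_table.reset_index().rename(columns={"event_at": "time"})
    surv = kmf.survival_function_.reset_index(drop=True)
    tbl["survival"] = surv.iloc[:, 0].to_numpy()
    return tbl[["time", "at_risk", "observed", "survival"]].rename(columns={"observed": "events"})
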