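"""Within-subject comparison of dosing algorithms in a crossover design.

The unit of inference is the per-subject difference between the FPU and
the carbohydrate-counting arm of the same meal.  Continuous outcomes get
a paired t test and/or a Wilcoxon signed-rank test; the binary
"any hypoglycemic episode" outcome gets an exact discordant-pair
(McNemar) binomial test.

The signed-rank test uses the exact permutation null (dynamic
programming over the 2^n sign assignments, midranks for ties) up to
n = 15 non-zero differences and a normal approximation with continuity
and tie correction beyond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .metrics import GlycemicSummary, summarize
from .trace import GlucoseTrace

EXACT_WILCOXON_MAX_N = 15


@dataclass(frozen=True)
class PairedComparison:
    metric: str
    mean_a: float
    se_a: float
    mean_b: float
    se_b: float
    mean_diff: float  # b − a
    statistic: float
    p_value: float
    n_pairs: int
    n_excluded: int = 0


def paired_t_test(differences) -> tuple[float, float]:
    """One-sample t test of paired differences against zero.

    Returns (t, two-sided p) with n−1 degrees of freedom.  With zero
    variance the statistic is 0 (all differences zero, p = NaN) or ±inf
    (identical non-zero differences, p = 0).
    """
    d = np.asarray(differences, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least 2 paired differences")
    mean = d.mean()
    sd = d.std(ddof=1)
    if sd == 0:
        if mean == 0:
            return 0.0, float("nan")
        return math_inf_sign(mean), 0.0
    t = mean / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return float(t), float(p)


def math_inf_sign(x: float) -> float:
    return float("inf") if x > 0 else float("-inf")


def _signed_ranks(d: np.ndarray) -> np.ndarray:
    return stats.rankdata(np.abs(d))


def _exact_sign_distribution(ranks: np.ndarray) -> tuple[np.ndarray, int]:
    """Distribution of W+ over all 2^n sign assignments.

    Midranks are multiples of 0.5, so doubling makes them integers;
    returns (counts over doubled W+, scale=2).
    """
    doubled = np.rint(2 * ranks).astype(int)
    dist = np.zeros(doubled.sum() + 1, dtype=float)
    dist[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: dist.size - r]
        dist = dist + shifted
    return dist, 2


def wilcoxon_signed_rank(differences) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test of paired differences.

    Zero differences are dropped first.  Returns (W, p) where W is the
    smaller of the positive- and negative-rank sums.  All-zero input
    returns (0, NaN): the test is undefined.
    """
    d = np.asarray(differences, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 paired differences")
    d = d[d != 0]
    if d.size == 0:
        return 0.0, float("nan")
    ranks = _signed_ranks(d)
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w = min(w_plus, w_minus)
    n = d.size
    if n <= EXACT_WILCOXON_MAX_N:
        dist, scale = _exact_sign_distribution(ranks)
        total = dist.sum()
        w_scaled = int(np.rint(scale * w))
        p = 2.0 * dist[: w_scaled + 1].sum() / total
    else:
        mu = n * (n + 1) / 4.0
        _, counts = np.unique(ranks, return_counts=True)
        tie_term = ((counts**3 - counts).sum()) / 48.0
        sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
        z = (w - mu + 0.5) / sigma  # continuity correction toward the mean
        p = 2.0 * stats.norm.cdf(z)
    return w, float(min(p, 1.0))


def _pair_summaries(
    traces: list[GlucoseTrace], meal_type: str, iauc_policy: str
) -> tuple[list[GlycemicSummary], list[GlycemicSummary], int]:
    arm_a, arm_b = f"{meal_type}-CC", f"{meal_type}-FPU"
    by_subject: dict[str, dict[str, GlucoseTrace]] = {}
    for tr in traces:
        if tr.arm in (arm_a, arm_b):
            by_subject.setdefault(tr.subject_id, {})[tr.arm] = tr
    matched = sorted(s for s, arms in by_subject.items() if len(arms) == 2)
    excluded = len(by_subject) - len(matched)
    if not matched:
        raise ValueError(f"no subjects with both {arm_a} and {arm_b} traces")
    sa = [summarize(by_subject[s][arm_a], iauc_policy=iauc_policy) for s in matched]
    sb = [summarize(by_subject[s][arm_b], iauc_policy=iauc_policy) for s in matched]
    return sa, sb, excluded


def compare_arms(
    traces: list[GlucoseTrace],
    meal_type: str,
    test: str = "t",
    iauc_policy: str = "net",
) -> list[PairedComparison]:
    """CC-vs-FPU paired comparison of every scalar outcome for one meal.

    Subjects missing either arm are excluded and counted in
    ``n_excluded``.  ``test`` selects ``'t'`` (paired t) or
    ``'wilcoxon'`` (signed-rank).  Differences are FPU − CC.
    """
    if test not in ("t", "wilcoxon"):
        raise ValueError("test must be 't' or 'wilcoxon'")
    sa, sb, excluded = _pair_summaries(traces, meal_type, iauc_policy)
    n = len(sa)
    metrics = [m for m in sa[0].scalars() if m in sb[0].scalars()]
    results = []
    for metric in metrics:
        a = np.array([s.scalars()[metric] for s in sa])
        b = np.array([s.scalars()[metric] for s in sb])
        diff = b - a
        if n >= 2:
            stat, p = (
                paired_t_test(diff) if test == "t" else wilcoxon_signed_rank(diff)
            )
        else:
            stat, p = float("nan"), float("nan")
        results.append(
            PairedComparison(
                metric=metric,
                mean_a=float(a.mean()),
                se_a=float(a.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
                mean_b=float(b.mean()),
                se_b=float(b.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
                mean_diff=float(diff.mean()),
                statistic=stat,
                p_value=p,
                n_pairs=n,
                n_excluded=excluded,
            )
        )
    return results


@dataclass(frozen=True)
class HypoglycemiaRow:
    arm: str
    n: int
    n_with_episode: int
    pct_with_episode: float


@dataclass(frozen=True)
class HypoglycemiaTable:
    rows: list[HypoglycemiaRow]
    #: meal type -> exact discordant-pair (McNemar) two-sided p, CC vs FPU
    p_values: dict[str, float]


def hypoglycemia_table(
    traces: list[GlucoseTrace], threshold: float = 3.9
) -> HypoglycemiaTable:
    """Subjects with ≥1 hypoglycemic episode per arm, with exact paired test.

    Percentages always carry their denominator (``n``).  Within each meal
    type the CC and FPU arms are compared on the binary episode outcome
    with an exact binomial test on the discordant pairs; no discordant
    pairs gives p = 1.
    """
    by_arm: dict[str, dict[str, bool]] = {}
    for tr in traces:
        had = bool((tr.values < threshold).any())
        by_arm.setdefault(tr.arm, {})[tr.subject_id] = had
    rows = [
        HypoglycemiaRow(
            arm=arm,
            n=len(subs),
            n_with_episode=sum(subs.values()),
            pct_with_episode=100.0 * sum(subs.values()) / len(subs),
        )
        for arm, subs in sorted(by_arm.items())
    ]
    p_values: dict[str, float] = {}
    for meal_type in ("NPM", "HPFM"):
        a, b = by_arm.get(f"{meal_type}-CC"), by_arm.get(f"{meal_type}-FPU")
        if not a or not b:
            continue
        shared = sorted(set(a) & set(b))
        disc_b = sum(1 for s in shared if not a[s] and b[s])
        disc_a = sum(1 for s in shared if a[s] and not b[s])
        n_disc = disc_a + disc_b
        if n_disc == 0:
            p_values[meal_type] = 1.0
        else:
            p_values[meal_type] = float(
                stats.binomtest(min(disc_a, disc_b), n_disc, 0.5).pvalue
            )
    return HypoglycemiaTable(rows=rows, p_values=p_values)
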