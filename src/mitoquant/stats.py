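"""One-way ANOVA with Newman-Keuls post-hoc pairwise comparisons.

The Newman-Keuls (student-Newman-Keuls, SNK) procedure tests pairwise
differences of group means on the studentized range, stepping down from
the widest span of ordered means: a pair whose ordered ranks straddle
``p`` means is tested at the studentized-range quantile ``q(alpha; p,
df_within)``, and every sub-range of a non-significant range is declared
non-significant without testing. Using span-dependent critical values
makes SNK uniformly at least as rejecting as Tukey's HSD (which always
uses the full span) while still controlling the family-wise error rate
at the complete null.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats as sps


def _as_groups(data) -> dict:
    """Coerce mapping/sequence-of-arrays input into {label: float array}."""
    if isinstance(data, pd.DataFrame):
        data = {k: g["value"].to_numpy() for k, g in data.groupby("group")}
    if not isinstance(data, dict):
        data = {f"g{i + 1}": v for i, v in enumerate(data)}
    groups = {str(k): np.asarray(v, float).ravel() for k, v in data.items()}
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for k, v in groups.items():
        if v.size < 1:
            raise ValueError(f"group {k!r} is empty")
        if not np.all(np.isfinite(v)):
            raise ValueError(f"group {k!r} contains non-finite values")
    return groups


@dataclass
class AnovaTable:
    """Classical one-way ANOVA decomposition."""

    ss_between: float
    ss_within: float
    df_between: int
    df_within: int
    ms_between: float
    ms_within: float
    f: float
    p: float
    degenerate: bool = False  # zero within-variance with unequal means

    def as_dict(self) -> dict:
        return {
            "ss_between": self.ss_between, "ss_within": self.ss_within,
            "df_between": self.df_between, "df_within": self.df_within,
            "ms_between": self.ms_between, "ms_within": self.ms_within,
            "F": self.f, "p": self.p, "degenerate": self.degenerate,
        }


def one_way_anova(data) -> AnovaTable:
    """One-way fixed-effects ANOVA.

    ``data`` is a mapping group label -> replicate values, a sequence of
    arrays, or a long DataFrame with ``group``/``value`` columns.
    ``SS_between = sum n_g (mean_g - grand)^2``; ``SS_within`` pools the
    within-group squared deviations; ``F = MS_between / MS_within`` with
    the p-value from the F distribution. Zero within-group variance with
    unequal means yields F = inf, p = 0, flagged degenerate.
    """
    groups = _as_groups(data)
    values = np.concatenate(list(groups.values()))
    grand = values.mean()
    ns = np.array([v.size for v in groups.values()])
    means = np.array([v.mean() for v in groups.values()])
    ss_between = float(np.sum(ns * (means - grand) ** 2))
    ss_within = float(sum(np.sum((v - v.mean()) ** 2) for v in groups.values()))
    df_between = len(groups) - 1
    df_within = int(values.size - len(groups))
    if df_within < 1:
        raise ValueError("need at least one residual degree of freedom")
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        if ss_between > 0.0:
            return AnovaTable(ss_between, ss_within, df_between, df_within,
                              ms_between, ms_within, float("inf"), 0.0,
                              degenerate=True)
        return AnovaTable(ss_between, ss_within, df_between, df_within,
                          ms_between, ms_within, 0.0, 1.0)
    f = ms_between / ms_within
    p = float(sps.f.sf(f, df_between, df_within))
    return AnovaTable(ss_between, ss_within, df_between, df_within,
                      ms_between, ms_within, float(f), p)


@lru_cache(maxsize=4096)
def _q_crit(alpha: float, span: int, df: int) -> float:
    return float(sps.studentized_range.ppf(1.0 - alpha, span, df))


def newman_keuls(data, alpha: float = 0.05,
                 anova: AnovaTable | None = None) -> pd.DataFrame:
    """Newman-Keuls step-down pairwise comparisons.

    Group means are ordered (ties broken by group label); for the pair
    at ordered positions ``i < j`` the span is ``p = j - i + 1`` and

        q = |mean_i - mean_j| / sqrt(MS_within / n_h)

    with ``n_h`` the harmonic mean of the two group sizes (the standard
    unequal-n extension). q is compared with the studentized-range
    quantile ``q(alpha; p, df_within)``, testing from the widest span
    inward; all sub-ranges of a non-significant range are declared
    non-significant without testing (``tested`` False).

    Groups with fewer than 2 replicates are excluded with a warning
    column in mind: they cannot contribute a within-group variance.
    Returns one row per pair: group labels, mean difference, span,
    q statistic, critical q, tested flag, significant flag.
    """
    groups = _as_groups(data)
    small = [k for k, v in groups.items() if v.size < 2]
    if small:
        import warnings
        warnings.warn(f"groups excluded from post-hoc testing (n < 2): {small}")
        groups = {k: v for k, v in groups.items() if v.size >= 2}
        if len(groups) < 2:
            raise ValueError("fewer than 2 groups remain after n >= 2 filter")
    if anova is None:
        anova = one_way_anova(groups)
    labels = sorted(groups, key=lambda k: (groups[k].mean(), k))
    means = np.array([groups[k].mean() for k in labels])
    ns = np.array([groups[k].size for k in labels])
    k = len(labels)
    df_within = anova.df_within
    ms_within = anova.ms_within

    sig = {}       # (i, j) -> bool
    tested = {}    # (i, j) -> bool
    records = {}
    for span in range(k, 1, -1):
        for i in range(0, k - span + 1):
            j = i + span - 1
            pair = (i, j)
            inside_nonsig = any(
                tested.get((a, b)) is not None and not sig[(a, b)]
                for (a, b) in records
                if a <= i and j <= b and (a, b) != pair
            )
            n_h = 2.0 / (1.0 / ns[i] + 1.0 / ns[j])
            diff = means[j] - means[i]
            if ms_within > 0:
                q = abs(diff) / np.sqrt(ms_within / n_h)
            else:
                q = 0.0 if diff == 0 else float("inf")
            q_crit = _q_crit(alpha, span, df_within)
            if inside_nonsig:
                tested[pair] = None
                sig[pair] = False
            else:
                tested[pair] = True
                sig[pair] = bool(q > q_crit)
            records[pair] = {
                "group_low": labels[i], "group_high": labels[j],
                "mean_diff": float(diff), "span": span,
                "q": float(q), "q_crit": float(q_crit),
                "tested": tested[pair] is True,
                "significant": sig[pair],
            }
    out = pd.DataFrame([records[p] for p in sorted(records)])
    out.attrs["alpha"] = alpha
    out.attrs["anova"] = anova.as_dict()
    return out


def anova_with_posthoc(data, alpha: float = 0.05) -> dict:
    """Convenience wrapper: ANOVA table plus Newman-Keuls pairs as dicts."""
    anova = one_way_anova(data)
    pairs = newman_keuls(data, alpha=alpha, anova=anova)
    return {"anova": anova.as_dict(), "alpha": alpha,
            "pairs": pairs.drop(columns=[]).to_dict(orient="records")}
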