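"""Cytometry gating, event statistics, and normalized-ratio readouts.

Covers the non-imaging quantifications: percent-of-events gating against
a positive-control threshold (e.g. TMRM membrane-potential assays where
FCCP collapses the potential and defines the gate), location statistics
of event intensity distributions (DHE/MitoSOX superoxide readouts), and
signal/normalizer ratios for plate-reader tables (MitoSOX vs DAPI) and
immunoblot densitometry (target band vs loading control).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import NormalizationError


def percent_above_threshold(sample, control, q: float = 0.95) -> float:
    """Percent of sample events above a positive-control quantile gate.

    The threshold is the ``q``-quantile of the control intensities (the
    control collapses the signal, so events above its upper tail are
    scored positive); returns ``100 * fraction of sample events strictly
    above the threshold``. Invariant under any strictly increasing
    transform applied to both sample and control.
    """
    sample = np.asarray(sample, float)
    control = np.asarray(control, float)
    if sample.size == 0 or control.size == 0:
        raise ValueError("sample and control must be non-empty")
    if not 0.0 <= q <= 1.0:
        raise ValueError("q must lie in [0, 1]")
    if control.size < 100:
        warnings.warn(f"control has only {control.size} events; "
                      "threshold quantile will be noisy (>= 100 recommended)")
    threshold = float(np.quantile(control, q))
    return 100.0 * float(np.mean(sample > threshold))


def event_statistics(sample) -> dict:
    """Mean, median, and geometric mean of event intensities.

    The geometric mean is computed over strictly positive events only
    (no offset is added); the number of zero events is reported so the
    exclusion is auditable. An all-zero sample has undefined geometric
    mean, reported as NaN.
    """
    sample = np.asarray(sample, float)
    if sample.size < 1:
        raise ValueError("need at least one event")
    if np.any(sample < 0) or not np.all(np.isfinite(sample)):
        raise ValueError("intensities must be finite and >= 0")
    positive = sample[sample > 0]
    gmean = float(np.exp(np.mean(np.log(positive)))) if positive.size else float("nan")
    return {
        "mean": float(np.mean(sample)),
        "median": float(np.median(sample)),
        "geometric_mean": gmean,
        "n": int(sample.size),
        "n_zero": int(sample.size - positive.size),
    }


def ratio_to_normalizer(table: pd.DataFrame, signal_col: str = "signal",
                        normalizer_col: str = "normalizer",
                        group_col: str = "group",
                        reference_group: str | None = None):
    """Per-unit signal/normalizer ratios and their group summary.

    Works for plate-reader tables (well signal vs nuclei-stain intensity)
    and densitometry tables (target band vs loading-control band). With
    ``reference_group``, every ratio is rescaled so that group's mean
    ratio equals 1 (fold-change presentation). Returns
    ``(per_unit, summary)`` where summary carries group mean +/- SEM and n.

    Raises
    ------
    NormalizationError
        If any normalizer is nonpositive (names the offending unit row).
    """
    df = table.reset_index(drop=True).copy()
    bad = df.index[~(df[normalizer_col] > 0)]
    if len(bad):
        raise NormalizationError(
            f"nonpositive normalizer in rows {list(bad)} of the input table"
        )
    df["ratio"] = df[signal_col] / df[normalizer_col]
    if reference_group is not None:
        ref = df.loc[df[group_col] == reference_group, "ratio"]
        if ref.empty:
            raise ValueError(f"reference group {reference_group!r} not in table")
        df["ratio"] = df["ratio"] / ref.mean()
    rows = []
    for group, g in df.groupby(group_col, sort=True):
        n = len(g)
        rows.append({
            "group": group, "n": n,
            "ratio_mean": float(g["ratio"].mean()),
            "ratio_sem": float(g["ratio"].std(ddof=1) / np.sqrt(n)) if n > 1 else 0.0,
        })
    return df, pd.DataFrame(rows).set_index("group")
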