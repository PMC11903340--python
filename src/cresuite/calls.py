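"""Active-element calling against shuffled negative controls.

Activity of each foreground element (each tested orientation enters as its own
foreground entry) is converted to an empirical p-value against the pooled
shuffled-negative score distribution with +1 smoothing,

    p = (1 + #{negatives >= score}) / (1 + #negatives),

ties counting toward the negatives (conservative). Benjamini-Hochberg across
the foreground then yields q-values, and an element is called active when
q <= the FDR target (default 5%). Category-level shifts are tested with a
one-sided Wilcoxon rank-sum test with Bonferroni adjustment, and the
downsampling power curve re-runs quantification and calling at a series of
barcode proportions.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import quantify

__all__ = [
    "empirical_active_call",
    "call_both_orientations",
    "category_shift_test",
    "power_curve",
]


def empirical_active_call(
    scores: pd.Series, negatives: Sequence[float], fdr: float = 0.05
) -> pd.DataFrame:
    """Empirical-FDR active calls for a set of foreground scores.

    ``scores`` is indexed by foreground entry (element, or element/orientation
    when both orientations are tested). Returns a frame indexed like
    ``scores`` with empirical_p, q_value and active columns.
    """
    scores = scores.dropna()
    if len(scores) == 0:
        raise ValueError("empty foreground")
    neg = np.asarray(negatives, dtype=float)
    neg = neg[np.isfinite(neg)]
    if len(neg) < 5:
        raise ValueError(f"need >= 5 negative controls, got {len(neg)}")
    if len(neg) < 100:
        warnings.warn(
            f"only {len(neg)} negative controls; empirical p-values are coarse",
            stacklevel=2,
        )
    neg_sorted = np.sort(neg)
    # negatives >= score, ties inclusive
    n_ge = len(neg) - np.searchsorted(neg_sorted, scores.to_numpy(), side="left")
    p = (1.0 + n_ge) / (1.0 + len(neg))
    q = stats.false_discovery_control(p, method="bh")
    return pd.DataFrame(
        {"empirical_p": p, "q_value": q, "active": q <= fdr}, index=scores.index
    )


def call_both_orientations(
    forward: pd.Series,
    reverse: pd.Series,
    negatives: Sequence[float],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Call activity with forward and reverse scores as separate entries.

    Returns one row per element with per-orientation p/q/active columns and
    an overall ``active`` flag that is true if either orientation passes.
    Elements present in only one orientation are retained with the other side
    missing.
    """
    fg = pd.concat(
        [forward.dropna().add_suffix("|F"), reverse.dropna().add_suffix("|R")]
    )
    calls = empirical_active_call(fg, negatives, fdr)
    split = calls.index.str.rsplit("|", n=1)
    calls = calls.assign(
        element_id=[s[0] for s in split], orientation=[s[1] for s in split]
    )
    wide = calls.pivot(index="element_id", columns="orientation")
    out = pd.DataFrame(index=wide.index)
    for orient, tag in (("F", "forward"), ("R", "reverse")):
        for col in ("empirical_p", "q_value", "active"):
            if (col, orient) in wide.columns:
                out[f"{col}_{tag}"] = wide[(col, orient)]
    act_cols = [c for c in out.columns if c.startswith("active_")]
    out["active"] = out[act_cols].fillna(False).astype(bool).any(axis=1)
    return out


def category_shift_test(
    foreground: Sequence[float], background: Sequence[float], n_comparisons: int = 1
) -> tuple[float, float]:
    """One-sided Wilcoxon rank-sum test (foreground stochastically greater).

    Uses exact enumeration for small, tie-free samples (combined n <= 50) and
    the tie-corrected normal approximation otherwise. Returns the raw p and
    the Bonferroni-adjusted p = min(1, p * n_comparisons).
    """
    f = np.asarray(foreground, dtype=float)
    b = np.asarray(background, dtype=float)
    if len(f) < 3 or len(b) < 3:
        raise ValueError("both samples need >= 3 observations")
    combined = np.concatenate([f, b])
    has_ties = len(np.unique(combined)) < len(combined)
    method = "exact" if (len(combined) <= 50 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(f, b, alternative="greater", method=method)
    p = float(res.pvalue)
    return p, min(1.0, p * n_comparisons)


def power_curve(
    counts: pd.DataFrame,
    negative_ids: Sequence[str],
    proportions: Sequence[float],
    fdr: float = 0.05,
    seed: int = 0,
    min_barcodes: int = 10,
) -> pd.DataFrame:
    """Active fraction after downsampling barcodes to each proportion.

    For each proportion the counts are downsampled, re-quantified and
    re-called against the (re-quantified) negative controls; the reported
    active_fraction is the fraction of non-negative foreground elements
    called active. Proportion 1.0 reproduces the full-data call.
    """
    proportions = list(proportions)
    if any(not 0 < p <= 1 for p in proportions):
        raise ValueError("proportions must lie in (0, 1]")
    neg_ids = set(negative_ids)
    rows = []
    for prop in proportions:
        sub = quantify.downsample_barcodes(counts, prop, seed=seed)
        per_rep = quantify.element_activity(sub, min_barcodes=min_barcodes)
        combined = quantify.combine_replicates(per_rep)["mean_activity"]
        neg = combined[combined.index.isin(neg_ids)]
        fg = combined[~combined.index.isin(neg_ids)]
        calls = empirical_active_call(fg, neg.to_numpy(), fdr=fdr)
        rows.append(
            {
                "proportion": prop,
                "n_foreground": len(fg),
                "active_fraction": float(calls["active"].mean()),
            }
        )
    return pd.DataFrame(rows)
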