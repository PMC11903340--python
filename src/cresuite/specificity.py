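"""Orientation dependence and cell-type specificity of elements.

Orientation: elements cloned upstream of the reporter in both the forward and
reverse orientation give two activity measurements per element. Replicate
correlations are compared between same-orientation pairings (FvF, RvR) and
opposite pairings (FvR, RvF), and strand asymmetry |forward - reverse| is
compared between promoters and potential enhancers with a one-sided rank-sum
test.

Cell-type specificity: activities of a common element set measured in several
cell types are z-scored per cell type and each element's across-cell-type
mean is subtracted, giving element specificity scores (ESS) whose rows sum to
zero. A PCA of the element x cell-type matrix separates the dominant
"universal" activity component (component 1) from the cell-type-specific
structure on the remaining components; one-sided signed-rank tests ask
whether a category's median ESS in a given cell type exceeds zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats

from .calls import category_shift_test

__all__ = [
    "orientation_correlation_grid",
    "strand_asymmetry",
    "element_specificity_scores",
    "specificity_pca",
    "category_specificity_test",
    "PCAResult",
]

logger = logging.getLogger(__name__)


def _replicate_matrix(df: pd.DataFrame) -> pd.DataFrame:
    """Accept either a tidy per-replicate table or an element x replicate matrix."""
    if {"element_id", "replicate", "activity"}.issubset(df.columns):
        return df.pivot(index="element_id", columns="replicate", values="activity")
    return df


def orientation_correlation_grid(
    forward: pd.DataFrame, reverse: pd.DataFrame
) -> pd.DataFrame:
    """Pearson r for every replicate pairing within and across orientations.

    ``forward`` and ``reverse`` are per-replicate activity tables (tidy or
    element x replicate) for the same elements cloned in the two
    orientations. Same-orientation pairings (FvF, RvR) use distinct replicate
    pairs; opposite pairings (FvR, RvF) use all replicate combinations.
    """
    fwd = _replicate_matrix(forward)
    rev = _replicate_matrix(reverse)
    if fwd.shape[1] < 2 or rev.shape[1] < 2:
        raise ValueError("need >= 2 replicates per orientation")
    rows = []

    def corr(xs: pd.Series, ys: pd.Series, pairing: str, ra, rb) -> None:
        shared = pd.concat([xs, ys], axis=1, join="inner").dropna()
        if len(shared) < 3:
            raise ValueError(f"pairing {pairing} ({ra},{rb}) shares fewer than 3 elements")
        r = float(stats.pearsonr(shared.iloc[:, 0], shared.iloc[:, 1]).statistic)
        rows.append(
            {"pairing": pairing, "replicate_a": ra, "replicate_b": rb, "pearson": r}
        )

    for a, b in combinations(fwd.columns, 2):
        corr(fwd[a], fwd[b], "FvF", a, b)
    for a, b in combinations(rev.columns, 2):
        corr(rev[a], rev[b], "RvR", a, b)
    for a, b in product(fwd.columns, rev.columns):
        corr(fwd[a], rev[b], "FvR", a, b)
        corr(rev[b], fwd[a], "RvF", b, a)
    out = pd.DataFrame(rows)
    out["same_orientation"] = out["pairing"].isin(["FvF", "RvR"])
    return out


def strand_asymmetry(
    forward: pd.Series, reverse: pd.Series, categories: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Per-element strand asymmetry |fwd - rev| and the promoter-vs-enhancer test.

    Elements measured in only one orientation are excluded (count logged).
    Returns the orientation-pair table and the one-sided rank-sum p-value for
    promoters having larger asymmetry than enhancers.
    """
    paired = pd.concat(
        {"fwd_activity": forward, "rev_activity": reverse}, axis=1, join="inner"
    ).dropna()
    n_dropped = len(set(forward.dropna().index) ^ set(reverse.dropna().index))
    if n_dropped:
        logger.info("strand_asymmetry: %d elements measured in one orientation only", n_dropped)
    table = paired.assign(
        asymmetry=(paired["fwd_activity"] - paired["rev_activity"]).abs(),
        category=categories.reindex(paired.index),
    )
    prom = table.loc[table["category"] == "promoter", "asymmetry"]
    enh = table.loc[table["category"] == "enhancer", "asymmetry"]
    if len(prom) == 0 or len(enh) == 0:
        raise ValueError("both promoter and enhancer categories must be represented")
    p, _ = category_shift_test(prom.to_numpy(), enh.to_numpy())
    return table, p


def element_specificity_scores(activity_by_celltype: pd.DataFrame) -> pd.DataFrame:
    """ESS matrix: per-cell-type z-score, then subtract each element's mean.

    Elements missing any cell type are dropped (logged); z-scoring uses the
    sample (n-1) SD over retained elements. Every returned row sums to zero
    by construction.
    """
    if activity_by_celltype.shape[1] < 2:
        raise ValueError("need >= 2 cell types")
    mat = activity_by_celltype.dropna()
    dropped = len(activity_by_celltype) - len(mat)
    if dropped:
        logger.info("element_specificity_scores: dropped %d incomplete elements", dropped)
    sd = mat.std(axis=0, ddof=1)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"constant activity column(s): {bad}")
    z = (mat - mat.mean(axis=0)) / sd
    ess = z.sub(z.mean(axis=1), axis=0)
    return ess


@dataclass
class PCAResult:
    """PCA of the element x cell-type activity matrix.

    Component 1 carries the shared ("universal") activity signal and is
    reported but excluded from biplots; ``biplot_components`` lists the
    remaining component labels. Sign convention: each component's
    largest-magnitude loading is positive.
    """

    scores: pd.DataFrame  # element x component
    loadings: pd.DataFrame  # cell type x component
    variance_fractions: pd.Series

    @property
    def biplot_components(self) -> list[str]:
        return list(self.scores.columns[1:])


def specificity_pca(activity_by_celltype: pd.DataFrame) -> PCAResult:
    """Principal axes of the column-centered element x cell-type matrix."""
    if activity_by_celltype.shape[1] < 3:
        raise ValueError("need >= 3 cell types for a component-2/3 biplot")
    mat = activity_by_celltype.dropna()
    centered = mat - mat.mean(axis=0)
    u, s, vt = np.linalg.svd(centered.to_numpy(float), full_matrices=False)
    if s[0] == 0:
        raise ValueError("activity matrix has no variance after centering")
    # fix signs: largest-|loading| positive per component
    for k in range(len(s)):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1
            u[:, k] *= -1
    comps = [f"PC{k + 1}" for k in range(len(s))]
    total = float((s**2).sum())
    return PCAResult(
        scores=pd.DataFrame(u * s, index=mat.index, columns=comps),
        loadings=pd.DataFrame(vt.T, index=mat.columns, columns=comps),
        variance_fractions=pd.Series(s**2 / total, index=comps),
    )


def category_specificity_test(
    ess: pd.DataFrame,
    categories: pd.Series,
    category: str,
    cell_type: str,
    exact_max_n: int = 25,
) -> float:
    """One-sided signed-rank p for median ESS > 0 in one category/cell type.

    Exact signed-rank distribution for n <= ``exact_max_n``, normal
    approximation otherwise. All-zero ESS values give p = 1 with a warning.
    """
    values = ess.loc[categories.reindex(ess.index) == category, cell_type].dropna()
    if len(values) < 5:
        raise ValueError(f"category {category!r} has fewer than 5 elements")
    if (values == 0).all():
        warnings.warn("all ESS values are zero; returning p = 1", stacklevel=2)
        return 1.0
    method = "exact" if len(values) <= exact_max_n else "approx"
    res = stats.wilcoxon(values.to_numpy(), alternative="greater", method=method)
    return float(res.pvalue)
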