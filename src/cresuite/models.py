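"""Feature-based regression, in-silico mutagenesis, and ASV concordance.

The biochemical regression fits a lasso to z-scored element features with the
regularization strength chosen by 10-fold cross-validated mean-squared error
on a log-spaced grid whose largest value zeroes every coefficient; fold
membership is a seeded hash of the element id, so the same element always
lands in the same fold across runs and cell types. Ten per-fold models
(each trained on the other nine folds) provide held-out performance and an
ensemble for variant-effect uncertainty.

In-silico mutagenesis (ISM) scores every single-nucleotide substitution of a
sequence under any deterministic scorer. Variant effects are the mean delta
over a scorer ensemble with a one-sample t-test as the uncertainty p-value,
and concordance with observed allele-specific variants (ASVs) is summarized
by a 2x2 sign table, odds ratio and Fisher's exact test.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso

__all__ = [
    "LassoFit",
    "ConcordanceResult",
    "zscore_features",
    "assign_folds",
    "fit_lasso_cv",
    "ism",
    "predict_variant_effect",
    "asv_concordance",
]

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# lasso with hashed folds
# ---------------------------------------------------------------------------

def zscore_features(features: pd.DataFrame) -> pd.DataFrame:
    """Z-score each feature column (sample SD); constant columns become 0."""
    sd = features.std(axis=0, ddof=1).replace(0.0, 1.0)
    return (features - features.mean(axis=0)) / sd


def assign_folds(element_ids: Sequence[str], n_folds: int, seed: int) -> pd.Series:
    """Deterministic fold assignment by seeded hashing of element ids.

    The same (id, seed) pair always maps to the same fold, independent of
    the order or subset of elements presented.
    """
    folds = []
    for eid in element_ids:
        digest = hashlib.blake2b(
            f"{seed}:{eid}".encode(), digest_size=8
        ).digest()
        folds.append(int.from_bytes(digest, "big") % n_folds)
    return pd.Series(folds, index=pd.Index(element_ids, name="element_id"), name="fold")


@dataclass
class LassoFit:
    """A cross-validated lasso fit on z-scored features."""

    chosen_lambda: float
    coefficients: pd.Series  # on the z-scored feature scale
    intercept: float
    fold_assignment: pd.Series
    per_fold_r: pd.Series  # held-out Pearson r per fold (NaN if undefined)
    cv_mse: pd.Series  # mean CV MSE per grid lambda
    fold_models: list[Lasso] = field(default_factory=list, repr=False)

    def predict(self, features: pd.DataFrame) -> pd.Series:
        x = zscore_features(features)[self.coefficients.index]
        return pd.Series(
            x.to_numpy() @ self.coefficients.to_numpy() + self.intercept,
            index=features.index,
        )


def _lambda_grid(x: np.ndarray, y: np.ndarray, n_points: int = 100) -> np.ndarray:
    """Log-spaced grid whose largest lambda zeroes all lasso coefficients."""
    n = len(y)
    lam_max = float(np.abs(x.T @ (y - y.mean())).max()) / n
    lam_max = max(lam_max * 1.001, 1e-12)
    return np.geomspace(lam_max, lam_max * 1e-4, n_points)


def fit_lasso_cv(
    features: pd.DataFrame,
    activity: pd.Series,
    n_folds: int = 10,
    seed: int = 0,
) -> LassoFit:
    """Lasso regression with lambda chosen by n-fold cross-validated MSE.

    Features are z-scored internally. After choosing lambda, one model per
    fold is trained on the remaining folds and evaluated on the held-out
    fold (Pearson r); the reported coefficients come from a final fit on all
    data. A constant response is an error; per-fold r over a constant
    held-out prediction is reported as NaN with a warning.
    """
    shared = features.index.intersection(activity.dropna().index)
    if len(shared) < 10 * n_folds:
        raise ValueError(f"need >= {10 * n_folds} elements, got {len(shared)}")
    y = activity.loc[shared].to_numpy(float)
    if np.ptp(y) == 0:
        if not np.all(y == 0):
            raise ValueError("constant response")
        # identically-zero response: trivial zero model, held-out r undefined
        warnings.warn("response identically 0; per-fold r undefined", stacklevel=2)
        folds = assign_folds(list(shared), n_folds, seed)
        return LassoFit(
            chosen_lambda=np.inf,
            coefficients=pd.Series(0.0, index=features.columns),
            intercept=0.0,
            fold_assignment=folds,
            per_fold_r=pd.Series(np.nan, index=range(n_folds), name="pearson_r"),
            cv_mse=pd.Series(dtype=float, name="cv_mse"),
        )
    xz = zscore_features(features.loc[shared])
    x = xz.to_numpy(float)
    folds = assign_folds(list(shared), n_folds, seed)
    fold_arr = folds.to_numpy()

    grid = _lambda_grid(x, y)
    mse = np.zeros((len(grid), n_folds))
    for k in range(n_folds):
        tr, te = fold_arr != k, fold_arr == k
        for i, lam in enumerate(grid):
            model = Lasso(alpha=lam, max_iter=50_000)
            model.fit(x[tr], y[tr])
            mse[i, k] = float(np.mean((model.predict(x[te]) - y[te]) ** 2))
    cv_mse = mse.mean(axis=1)
    best = int(np.argmin(cv_mse))
    lam = float(grid[best])

    per_fold_r, fold_models = [], []
    for k in range(n_folds):
        tr, te = fold_arr != k, fold_arr == k
        model = Lasso(alpha=lam, max_iter=50_000)
        model.fit(x[tr], y[tr])
        fold_models.append(model)
        pred = model.predict(x[te])
        if np.ptp(pred) == 0 or np.ptp(y[te]) == 0:
            warnings.warn(
                f"fold {k}: held-out correlation undefined (constant values)",
                stacklevel=2,
            )
            per_fold_r.append(np.nan)
        else:
            per_fold_r.append(float(stats.pearsonr(pred, y[te]).statistic))

    final = Lasso(alpha=lam, max_iter=50_000)
    final.fit(x, y)
    return LassoFit(
        chosen_lambda=lam,
        coefficients=pd.Series(final.coef_, index=xz.columns),
        intercept=float(final.intercept_),
        fold_assignment=folds,
        per_fold_r=pd.Series(per_fold_r, index=range(n_folds), name="pearson_r"),
        cv_mse=pd.Series(cv_mse, index=grid, name="cv_mse"),
        fold_models=fold_models,
    )


# ---------------------------------------------------------------------------
# in-silico mutagenesis
# ---------------------------------------------------------------------------

def ism(scorer: Callable[[str], float], sequence: str) -> pd.DataFrame:
    """Score deltas for every single-nucleotide substitution of a sequence.

    Returns a (position x 3) frame of score(mutated) - score(reference) with
    one column per non-reference base; reference cells are omitted by
    construction. A 200-nt input yields exactly 600 deltas.
    """
    seq = sequence.upper()
    if set(seq) - set(_BASES):
        raise ValueError("sequence must be ACGT only")
    ref_score = scorer(seq)
    rows = []
    for pos, ref in enumerate(seq):
        deltas = {}
        for alt in _BASES:
            if alt == ref:
                continue
            mutated = seq[:pos] + alt + seq[pos + 1 :]
            deltas[alt] = scorer(mutated) - ref_score
        rows.append({"position": pos, "ref": ref, **deltas})
    frame = pd.DataFrame(rows).set_index("position")
    return frame


def predict_variant_effect(
    scorers: Sequence[Callable[[str], float]], ref_seq: str, alt_seq: str
) -> tuple[float, float, pd.Series]:
    """Ensemble variant effect: mean delta and a t-test uncertainty p-value.

    Each scorer contributes delta = score(alt) - score(ref); the uncertainty
    p is a two-sided one-sample t-test of the deltas against zero. Identical
    nonzero deltas (zero variance) give p = 0 with a degenerate-variance
    warning; all-zero deltas give p = 1.
    """
    if len(scorers) < 2:
        raise ValueError("need >= 2 scorers")
    deltas = np.array([s(alt_seq) - s(ref_seq) for s in scorers], dtype=float)
    mean = float(deltas.mean())
    if np.ptp(deltas) == 0:
        if mean == 0:
            p = 1.0
        else:
            warnings.warn(
                "degenerate variance: identical nonzero deltas, p set to 0",
                stacklevel=2,
            )
            p = 0.0
    else:
        p = float(stats.ttest_1samp(deltas, 0.0).pvalue)
    return mean, p, pd.Series(deltas, name="delta")


# ---------------------------------------------------------------------------
# ASV concordance
# ---------------------------------------------------------------------------

@dataclass
class ConcordanceResult:
    """Sign concordance between predicted and observed variant effects."""

    concordant: int
    discordant: int
    excluded: int
    table: np.ndarray  # 2x2: predicted sign (+/-) x observed sign (+/-)
    odds_ratio: float  # inf when a discordant cell is empty
    odds_ratio_haldane: float  # with 0.5 added to every cell if any is zero
    fisher_p: float
    degenerate: bool  # a zero cell made the plain OR unbounded or 0/0
    asv_fdr: float
    pred_p: float

    @property
    def total(self) -> int:
        return self.concordant + self.discordant + self.excluded


def asv_concordance(
    predicted: pd.DataFrame,
    observed: pd.DataFrame,
    asv_fdr: float = 0.05,
    pred_p: float = 0.05,
) -> ConcordanceResult:
    """Concordance of predicted variant effects with observed allelic imbalance.

    ``predicted`` needs columns variant, delta, uncertainty_p; ``observed``
    needs variant, observed_effect, fdr. Variants with ASV FDR > ``asv_fdr``
    or prediction uncertainty p > ``pred_p`` are excluded. The 2x2 table
    crosses predicted sign with observed sign; OR = (n_pp * n_mm) /
    (n_pm * n_mp), reported with a 0.5 Haldane correction (and flagged) when
    a cell is empty. Fisher's exact p comes from the hypergeometric tail.
    """
    merged = predicted.merge(observed, on="variant", how="inner", validate="1:1")
    if len(merged) == 0:
        raise ValueError("no shared variants between predicted and observed tables")
    keep = (merged["fdr"] <= asv_fdr) & (merged["uncertainty_p"] <= pred_p)
    excluded = int((~keep).sum())
    sub = merged[keep]
    if len(sub) == 0:
        raise ValueError("no variants left after exclusion")
    pred_pos = sub["delta"].to_numpy() >= 0
    obs_pos = sub["observed_effect"].to_numpy() >= 0
    n_pp = int((pred_pos & obs_pos).sum())
    n_pm = int((pred_pos & ~obs_pos).sum())
    n_mp = int((~pred_pos & obs_pos).sum())
    n_mm = int((~pred_pos & ~obs_pos).sum())
    table = np.array([[n_pp, n_pm], [n_mp, n_mm]])
    degenerate = (table == 0).any()
    if n_pm * n_mp == 0:
        odds = np.inf if n_pp * n_mm > 0 else np.nan
    else:
        odds = (n_pp * n_mm) / (n_pm * n_mp)
    th = table + 0.5 if degenerate else table
    odds_haldane = float((th[0, 0] * th[1, 1]) / (th[0, 1] * th[1, 0]))
    fisher_p = float(stats.fisher_exact(table, alternative="two-sided").pvalue)
    return ConcordanceResult(
        concordant=n_pp + n_mm,
        discordant=n_pm + n_mp,
        excluded=excluded,
        table=table,
        odds_ratio=float(odds) if np.isfinite(odds) else odds,
        odds_ratio_haldane=odds_haldane,
        fisher_p=fisher_p,
        degenerate=bool(degenerate),
        asv_fdr=asv_fdr,
        pred_p=pred_p,
    )
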