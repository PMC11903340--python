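"""Barcode-level counts to element activity scores.

An element's activity in one replicate is the log2 ratio of its summed
counts-per-million RNA over summed counts-per-million DNA, with a one-raw-
count pseudocount on the CPM scale in both numerator and denominator
(sum-then-ratio aggregation). Elements supported by fewer than
``min_barcodes`` DNA-positive barcodes in a replicate are censored in that
replicate. Replicates are combined by subtracting each replicate's median
activity over retained elements and averaging the available replicates.
Barcode downsampling and replicate-correlation utilities support the
sequencing-depth trade-off analyses.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "element_activity",
    "combine_replicates",
    "downsample_barcodes",
    "replicate_correlations",
]

logger = logging.getLogger(__name__)

_COUNT_COLUMNS = ["element_id", "barcode", "replicate", "dna_count", "rna_count"]


def _validate_counts(counts: pd.DataFrame) -> pd.DataFrame:
    missing = set(_COUNT_COLUMNS) - set(counts.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    if counts.empty:
        raise ValueError("count table is empty")
    if (counts[["dna_count", "rna_count"]] < 0).to_numpy().any():
        raise ValueError("counts must be nonnegative")
    if counts.duplicated(["element_id", "barcode", "replicate"]).any():
        raise ValueError("(element_id, barcode, replicate) rows must be unique")
    return counts


def element_activity(
    counts: pd.DataFrame, min_barcodes: int = 10, pseudocount: float = 1.0
) -> pd.DataFrame:
    """Per-replicate activity scores from a barcode-level count table.

    Counts are scaled to counts-per-million within each replicate and
    modality; per element,

        activity = log2((sum normRNA + pc*scaleRNA) / (sum normDNA + pc*scaleDNA))

    where the scale terms are the CPM equivalents of one raw count. A barcode
    counts toward ``n_barcodes`` only if its DNA count is positive; elements
    below ``min_barcodes`` in a replicate get NaN activity there.
    ``barcode_sd`` is the SD of per-barcode log2 CPM ratios (QC only).

    Returns a tidy frame: element_id, replicate, activity, n_barcodes,
    barcode_sd.
    """
    if min_barcodes < 1:
        raise ValueError("min_barcodes must be >= 1")
    counts = _validate_counts(counts)
    out = []
    for rep, grp in counts.groupby("replicate", sort=True):
        tot_dna = float(grp["dna_count"].sum())
        tot_rna = float(grp["rna_count"].sum())
        if tot_dna <= 0:
            raise ValueError(f"replicate {rep} has zero total DNA reads")
        if tot_rna <= 0:
            raise ValueError(f"replicate {rep} has zero total RNA reads")
        scale_dna = 1e6 / tot_dna
        scale_rna = 1e6 / tot_rna
        g = grp.assign(
            dna_cpm=grp["dna_count"] * scale_dna,
            rna_cpm=grp["rna_count"] * scale_rna,
            supported=grp["dna_count"] > 0,
        )
        per_bc_ratio = np.log2(
            (g["rna_cpm"] + pseudocount * scale_rna)
            / (g["dna_cpm"] + pseudocount * scale_dna)
        )
        g = g.assign(bc_ratio=per_bc_ratio.where(g["supported"]))
        agg = g.groupby("element_id", sort=True).agg(
            dna_sum=("dna_cpm", "sum"),
            rna_sum=("rna_cpm", "sum"),
            n_barcodes=("supported", "sum"),
            barcode_sd=("bc_ratio", lambda s: s.std(ddof=1)),
        )
        activity = np.log2(
            (agg["rna_sum"] + pseudocount * scale_rna)
            / (agg["dna_sum"] + pseudocount * scale_dna)
        )
        activity[agg["n_barcodes"] < min_barcodes] = np.nan
        out.append(
            pd.DataFrame(
                {
                    "element_id": agg.index,
                    "replicate": rep,
                    "activity": activity.to_numpy(),
                    "n_barcodes": agg["n_barcodes"].astype(int).to_numpy(),
                    "barcode_sd": agg["barcode_sd"].to_numpy(),
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def activity_matrix(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Pivot the tidy per-replicate table to an element x replicate matrix."""
    return per_replicate.pivot(index="element_id", columns="replicate", values="activity")


def combine_replicates(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Median-center each replicate over retained elements, then average.

    Elements missing (censored) in every replicate are dropped; the drop
    count is logged. Returns element_id-indexed frame with mean_activity and
    n_replicates_used.
    """
    mat = activity_matrix(per_replicate)
    centered = mat - mat.median(axis=0, skipna=True)
    n_used = centered.notna().sum(axis=1)
    dropped = int((n_used == 0).sum())
    if dropped:
        logger.info("combine_replicates: dropped %d elements missing in all replicates", dropped)
    keep = n_used > 0
    return pd.DataFrame(
        {
            "mean_activity": centered[keep].mean(axis=1, skipna=True),
            "n_replicates_used": n_used[keep].astype(int),
        }
    )


def downsample_barcodes(
    counts: pd.DataFrame, proportion: float, seed: int
) -> pd.DataFrame:
    """Keep ceil(proportion * B) barcodes per element per replicate.

    Sampling is without replacement and deterministic under ``seed``;
    proportion 1.0 returns the table unchanged.
    """
    if not 0 < proportion <= 1:
        raise ValueError("proportion must be in (0, 1]")
    counts = _validate_counts(counts)
    if proportion == 1.0:
        return counts.copy()
    rng = np.random.default_rng([seed, 3])
    keep_idx = []
    grouped = counts.groupby(["element_id", "replicate"], sort=True).indices
    for key in sorted(grouped):
        idx = grouped[key]
        k = int(np.ceil(proportion * len(idx)))
        keep_idx.append(rng.choice(idx, size=k, replace=False))
    kept = counts.loc[np.sort(np.concatenate(keep_idx))]
    return kept.reset_index(drop=True)


def replicate_correlations(per_replicate: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson and Spearman correlations between replicates.

    Correlations use elements retained (non-censored) in both replicates of
    each pair; fewer than 3 shared elements is an error.
    """
    mat = activity_matrix(per_replicate)
    reps = list(mat.columns)
    if len(reps) < 2:
        raise ValueError("need at least 2 replicates")
    rows = []
    for a, b in combinations(reps, 2):
        shared = mat[[a, b]].dropna()
        if len(shared) < 3:
            raise ValueError(f"replicates {a} and {b} share fewer than 3 elements")
        rows.append(
            {
                "replicate_a": a,
                "replicate_b": b,
                "n_shared": len(shared),
                "pearson": float(stats.pearsonr(shared[a], shared[b]).statistic),
                "spearman": float(stats.spearmanr(shared[a], shared[b]).statistic),
            }
        )
    return pd.DataFrame(rows)
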