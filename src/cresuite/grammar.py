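"""Transcription-factor binding-site grammar: PWM scanning and effect models.

This module scans position weight matrices (PWMs) over element sequences and
summarizes the hits into per-element count and log-likelihood matrices, then
models how reporter activity responds to binding-site dosage:

* homotypic dosage — median activity of elements carrying 0..5 sites of one
  factor, with expectation curves under a multiplicative (log-additive) and an
  additive model fitted by linear regression in log2 and linear space;
* heterotypic interactions — for a pair of factors, an interaction-term
  regression on activities adjusted for the log-likelihood contribution of all
  other factors; a positive interaction coefficient indicates a
  super-multiplicative (cooperative) effect, a negative one a sub-multiplicative
  (saturating) effect.

Scanning semantics follow FIMO's text mode: a log-odds score (log2 of PWM
probability over background) at every offset on both strands, with a hit
emitted when the score's exact null p-value falls at or below a threshold
(default 1e-3). The null distribution of scores under the background model is
computed exactly by dynamic-programming convolution over PWM positions on a
discretized score grid, so thresholds are reproducible without an external
scanner. Overlapping hits are all counted by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PWM",
    "MotifHitSummary",
    "DoseResponse",
    "InteractionFit",
    "scan_pwm",
    "summarize_hits",
    "homotypic_dose_response",
    "heterotypic_interaction",
]

#: probabilities are floored at this value before taking logs
PROB_FLOOR = 1e-4
#: width of the discretization bins of the exact null, in bits
SCORE_BIN = 1e-3

_BASES = "ACGT"
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
# index 4 is the "ambiguous" channel (N and other IUPAC degeneracy codes)
_IUPAC_AMBIGUOUS = set("RYSWKMBDHVN")
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_BASE_INDEX.update({b: 4 for b in _IUPAC_AMBIGUOUS})


def encode_sequence(sequence: str) -> np.ndarray:
    """Encode an upper/lower-case DNA string as indices (A,C,G,T=0..3, ambiguous=4)."""
    seq = sequence.upper()
    bad = set(seq) - set(_BASE_INDEX)
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)}")
    return np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))


def reverse_complement(sequence: str) -> str:
    return sequence.translate(str.maketrans("ACGTacgt", "TGCAtgca"))[::-1]


@dataclass(frozen=True)
class PWM:
    """A position weight matrix over ACGT with a 0-order background model.

    ``probs`` has shape (width, 4); each row must sum to 1 within 1e-6.
    """

    name: str
    probs: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        bg = np.asarray(self.background, dtype=float)
        if probs.ndim != 2 or probs.shape[1] != 4:
            raise ValueError(f"PWM {self.name}: matrix must be (width, 4)")
        if probs.shape[0] < 4:
            raise ValueError(f"PWM {self.name}: width must be >= 4")
        if not np.allclose(probs.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name}: rows must sum to 1 within 1e-6")
        if bg.shape != (4,) or not np.isclose(bg.sum(), 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.name}: background must be 4 probabilities")
        object.__setattr__(self, "probs", probs)
        object.__setattr__(self, "background", bg)

    @property
    def width(self) -> int:
        return self.probs.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.probs.argmax(axis=1))

    def log_odds(self) -> np.ndarray:
        """log2(p/bg) per (position, base), probabilities floored at PROB_FLOOR."""
        return np.log2(np.maximum(self.probs, PROB_FLOOR) / self.background)

    def log_probs(self) -> np.ndarray:
        """Natural log of the (floored) match probabilities per (position, base)."""
        return np.log(np.maximum(self.probs, PROB_FLOOR))

    def reverse_complement(self) -> "PWM":
        return PWM(self.name, self.probs[::-1, ::-1].copy(), self.background[::-1].copy())


# ---------------------------------------------------------------------------
# exact null distribution of log-odds scores
# ---------------------------------------------------------------------------

_null_cache: dict[bytes, tuple[int, np.ndarray]] = {}


def _binned_log_odds(pwm: PWM) -> np.ndarray:
    return np.rint(pwm.log_odds() / SCORE_BIN).astype(np.int64)


def score_null_survival(pwm: PWM) -> tuple[int, np.ndarray]:
    """Exact null survival function of the binned log-odds score.

    Returns ``(offset, sf)`` where ``sf[k]`` is P(score_bin >= k + offset)
    under the background model, computed by convolving the per-position score
    distributions (scores discretized to SCORE_BIN bits).
    """
    key = pwm.probs.tobytes() + pwm.background.tobytes()
    if key in _null_cache:
        return _null_cache[key]
    bins = _binned_log_odds(pwm)
    lo = int(bins.min(axis=1).sum())
    hi = int(bins.max(axis=1).sum())
    dist = np.zeros(hi - lo + 1)
    # running support starts at the empty-prefix point mass
    cur_lo = 0
    cur = np.array([1.0])
    for pos in range(pwm.width):
        nxt_lo = cur_lo + int(bins[pos].min())
        nxt = np.zeros(len(cur) + int(bins[pos].max() - bins[pos].min()))
        for b in range(4):
            shift = int(bins[pos, b]) + cur_lo - nxt_lo
            nxt[shift : shift + len(cur)] += pwm.background[b] * cur
        cur, cur_lo = nxt, nxt_lo
    dist[cur_lo - lo : cur_lo - lo + len(cur)] = cur
    sf = np.cumsum(dist[::-1])[::-1]
    out = (lo, sf)
    _null_cache[key] = out
    return out


def score_pvalue(pwm: PWM, score_bits: float) -> float:
    """Exact null p-value P(score >= observed) on the discretized grid."""
    offset, sf = score_null_survival(pwm)
    k = int(np.rint(score_bits / SCORE_BIN)) - offset
    if k < 0:
        return 1.0
    if k >= len(sf):
        return 0.0
    return float(min(sf[k], 1.0))


def hit_threshold_bin(pwm: PWM, p_threshold: float) -> int:
    """Smallest binned score whose exact null p-value is <= p_threshold.

    Returns one past the top of the support if no achievable score qualifies
    (e.g. an uninformative PWM), so that nothing is ever a hit.
    """
    offset, sf = score_null_survival(pwm)
    ok = np.nonzero(sf <= p_threshold)[0]
    if len(ok) == 0:
        return offset + len(sf)
    return offset + int(ok[0])


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _window_scores(encoded: np.ndarray, table: np.ndarray) -> np.ndarray:
    """Sum ``table[j, base_j]`` over each length-w window of an encoded sequence."""
    w = table.shape[0]
    windows = np.lib.stride_tricks.sliding_window_view(encoded, w)
    return table[np.arange(w)[None, :], windows].sum(axis=1)


def scan_pwm(sequence: str, pwm: PWM, p_threshold: float = 0.001) -> pd.DataFrame:
    """Scan one sequence with one PWM on both strands.

    Returns a DataFrame with columns ``position`` (0-based start of the hit
    window on the forward strand), ``strand`` (+/-), ``score`` (log-odds,
    bits) and ``log_prob`` (natural-log match probability of the hit, summed
    over positions). A window is a hit when the exact null p-value of its
    score is <= ``p_threshold``. Ambiguous bases contribute 0 to the log-odds
    score and log(1/4) to the log-probability.
    """
    if len(sequence) < pwm.width:
        raise ValueError(
            f"sequence length {len(sequence)} < PWM {pwm.name} width {pwm.width}"
        )
    encoded = encode_sequence(sequence)
    rows = []
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        lo_bins = np.column_stack([_binned_log_odds(mat), np.zeros(mat.width, np.int64)])
        lp = np.column_stack([mat.log_probs(), np.full(mat.width, np.log(0.25))])
        binned = _window_scores(encoded, lo_bins)
        thresh = hit_threshold_bin(mat, p_threshold)
        idx = np.nonzero(binned >= thresh)[0]
        if len(idx) == 0:
            continue
        logp = _window_scores(encoded, lp)
        rows.append(
            pd.DataFrame(
                {
                    "position": idx,
                    "strand": strand,
                    "score": binned[idx] * SCORE_BIN,
                    "log_prob": logp[idx],
                }
            )
        )
    if not rows:
        return pd.DataFrame(columns=["position", "strand", "score", "log_prob"])
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["position", "strand"], kind="stable").reset_index(drop=True)


@dataclass
class MotifHitSummary:
    """Element x TF matrices of hit counts and summed hit log-likelihoods.

    ``loglik`` sums the natural-log match probability over all hits on both
    strands; it is 0 exactly when ``site_count`` is 0 (summation convention
    for factors with no hits).
    """

    counts: pd.DataFrame
    loglik: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.loglik.index) or not self.counts.columns.equals(
            self.loglik.columns
        ):
            raise ValueError("counts and loglik must share index and columns")

    @property
    def tfs(self) -> list[str]:
        return list(self.counts.columns)


def summarize_hits(
    catalog: pd.DataFrame, pwms: Sequence[PWM], p_threshold: float = 0.001
) -> MotifHitSummary:
    """Scan every catalog sequence with every PWM and tabulate hits per element.

    ``catalog`` needs ``element_id`` and ``sequence`` columns. PWM names must
    be unique.
    """
    names = [p.name for p in pwms]
    if len(set(names)) != len(names):
        raise ValueError("PWM names must be unique")
    ids = catalog["element_id"].tolist()
    counts = np.zeros((len(ids), len(pwms)), dtype=int)
    logliks = np.zeros((len(ids), len(pwms)))
    for i, seq in enumerate(catalog["sequence"]):
        for j, pwm in enumerate(pwms):
            hits = scan_pwm(seq, pwm, p_threshold)
            counts[i, j] = len(hits)
            logliks[i, j] = hits["log_prob"].sum() if len(hits) else 0.0
    return MotifHitSummary(
        counts=pd.DataFrame(counts, index=pd.Index(ids, name="element_id"), columns=names),
        loglik=pd.DataFrame(logliks, index=pd.Index(ids, name="element_id"), columns=names),
    )


# ---------------------------------------------------------------------------
# homotypic dosage
# ---------------------------------------------------------------------------

@dataclass
class DoseResponse:
    """Observed medians and fitted expectation curves for one TF's dosage."""

    tf: str
    table: pd.DataFrame  # columns: dose, n, median_activity
    mult_slope: float  # log2 activity per site (multiplicative model)
    mult_intercept: float
    add_slope: float  # linear-space activity per site (additive model)
    add_intercept: float

    def expected_multiplicative(self, dose: np.ndarray) -> np.ndarray:
        return self.mult_intercept + self.mult_slope * np.asarray(dose, float)

    def expected_additive(self, dose: np.ndarray) -> np.ndarray:
        lin = self.add_intercept + self.add_slope * np.asarray(dose, float)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(lin > 0, np.log2(np.maximum(lin, np.finfo(float).tiny)), np.nan)


def homotypic_dose_response(
    activity: pd.Series,
    hits: MotifHitSummary,
    tf: str,
    top_tfs: Sequence[str],
    max_dose: int = 5,
    min_group: int = 10,
) -> DoseResponse:
    """Dosage analysis for one TF among elements clean of other top factors.

    Eligible elements carry 0 sites of every other TF in ``top_tfs`` and at
    most ``max_dose`` sites of ``tf``. Dose groups smaller than ``min_group``
    are dropped. Expectation lines are least-squares fits of activity on dose
    in log2 space (multiplicative) and of 2**activity on dose in linear space
    (additive), over element-level data of the retained dose groups.
    """
    if tf not in top_tfs:
        raise ValueError(f"{tf!r} is not in top_tfs")
    counts = hits.counts
    others = [t for t in top_tfs if t != tf]
    shared = counts.index.intersection(activity.dropna().index)
    sub = counts.loc[shared]
    eligible = sub.index[(sub[others].sum(axis=1) == 0) & (sub[tf] <= max_dose)]
    dose = sub.loc[eligible, tf]
    act = activity.loc[eligible].astype(float)
    sizes = dose.value_counts()
    keep_levels = sorted(sizes.index[sizes >= min_group])
    if len(keep_levels) < 2:
        raise ValueError(
            f"fewer than 2 dose levels with n >= {min_group} for {tf} "
            f"(levels kept: {keep_levels})"
        )
    mask = dose.isin(keep_levels)
    dose, act = dose[mask], act[mask]
    table = (
        pd.DataFrame({"dose": dose, "activity": act})
        .groupby("dose")["activity"]
        .agg(n="size", median_activity="median")
        .reset_index()
    )
    mult = np.polyfit(dose.to_numpy(float), act.to_numpy(), 1)
    add = np.polyfit(dose.to_numpy(float), np.exp2(act.to_numpy()), 1)
    return DoseResponse(
        tf=tf,
        table=table,
        mult_slope=float(mult[0]),
        mult_intercept=float(mult[1]),
        add_slope=float(add[0]),
        add_intercept=float(add[1]),
    )


# ---------------------------------------------------------------------------
# heterotypic interactions
# ---------------------------------------------------------------------------

@dataclass
class InteractionFit:
    """Interaction-term regression for a heterotypic TF pair.

    Coefficients are on the adjusted-log2 scale (activity residualized on the
    log-likelihoods of all factors outside the pair). ``b_int > 0`` indicates
    a super-multiplicative effect, ``b_int < 0`` a sub-multiplicative one.
    """

    tf1: str
    tf2: str
    n00: int
    n10: int
    n01: int
    n11: int
    b0: float
    b1: float
    b2: float
    b_int: float
    se: pd.Series  # standard errors indexed b0, b1, b2, b_int

    @property
    def classification(self) -> str:
        return "super-multiplicative" if self.b_int > 0 else "sub-multiplicative"


def _adjust_activity(
    activity: pd.Series, loglik: pd.DataFrame, exclude: Sequence[str]
) -> pd.Series:
    """Residualize activity on the log-likelihood columns of all other TFs."""
    covars = loglik.drop(columns=list(exclude))
    if covars.shape[1] == 0:
        return activity - activity.mean()
    X = sm.add_constant(covars.to_numpy())
    fit = sm.OLS(activity.to_numpy(float), X).fit()
    return pd.Series(fit.resid, index=activity.index)


def heterotypic_interaction(
    activity: pd.Series,
    hits: MotifHitSummary,
    tf1: str,
    tf2: str,
    top_tfs: Sequence[str],
    min_cell: int = 10,
) -> InteractionFit:
    """Fit the 2x2 interaction model for a pair of top activating TFs.

    Eligible elements carry 0 or 1 site of each of ``tf1``/``tf2`` and no
    sites of any other member of ``top_tfs``. Activity is first adjusted for
    the log-likelihoods of every scanned factor outside the pair (confounder
    removal), then regressed on presence indicators and their product.
    """
    if tf1 == tf2:
        raise ValueError("tf1 and tf2 must differ")
    for tf in (tf1, tf2):
        if tf not in top_tfs:
            raise ValueError(f"{tf!r} is not in top_tfs")
    counts = hits.counts
    others = [t for t in top_tfs if t not in (tf1, tf2)]
    shared = counts.index.intersection(activity.dropna().index)
    sub = counts.loc[shared]
    eligible = sub.index[
        sub[tf1].isin([0, 1])
        & sub[tf2].isin([0, 1])
        & (sub[others].sum(axis=1) == 0)
    ]
    i1 = sub.loc[eligible, tf1].to_numpy(float)
    i2 = sub.loc[eligible, tf2].to_numpy(float)
    ns = {}
    for a in (0, 1):
        for b in (0, 1):
            n = int(((i1 == a) & (i2 == b)).sum())
            ns[f"n{a}{b}"] = n
            if n < min_cell:
                raise ValueError(
                    f"group ({tf1}={a}, {tf2}={b}) has n={n} < {min_cell}"
                )
    adjusted = _adjust_activity(
        activity.loc[eligible].astype(float), hits.loglik.loc[eligible], [tf1, tf2]
    )
    X = sm.add_constant(np.column_stack([i1, i2, i1 * i2]))
    fit = sm.OLS(adjusted.to_numpy(), X).fit()
    names = ["b0", "b1", "b2", "b_int"]
    return InteractionFit(
        tf1=tf1,
        tf2=tf2,
        **ns,
        b0=float(fit.params[0]),
        b1=float(fit.params[1]),
        b2=float(fit.params[2]),
        b_int=float(fit.params[3]),
        se=pd.Series(fit.bse, index=names),
    )
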