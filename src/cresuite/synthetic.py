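"""Synthetic lentiMPRA libraries with fully known ground truth.

The generator emulates the statistical structure of a lentiviral massively
parallel reporter assay: an element catalog (200-bp promoters, potential
enhancers, dinucleotide-shuffled negatives and positive controls), sequences
with planted consensus binding sites obeying a multiplicative (log-additive)
grammar with optional pairwise interaction terms, barcode-level DNA/RNA count
tables with gamma-Poisson (negative binomial) noise and lognormal barcode
abundances, cell-type-specific activity deviations for enhancers, per-element
orientation offsets, biochemical feature matrices, and allele-specific-variant
tables. Everything is deterministic under a fixed seed.

True activity bookkeeping::

    activity[ct] = baseline(category)
                 + per_site_effect * total planted sites
                 + sum of gamma over planted co-occurring TF pairs
                 + cell-type deviation (enhancers only)

Background sequence is rejection-resampled until it contains no PWM hit at
the scan threshold before sites are planted, so the planted site counts are
the exact motif content of each emitted sequence and scans round-trip
cleanly.

A reporter readout is compositional: sequencing fixes the total read count,
so per-replicate normalization recovers activities only up to the constant
``log2(sum w * 2^act / sum w)`` determined by library composition. The count
simulator records this offset in ``counts.attrs["composition_offset"]`` so
calibration checks can compare estimated and true activities on one scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import grammar
from .grammar import PWM, encode_sequence

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_catalog",
    "simulate_counts",
    "simulate_features",
    "simulate_asv_table",
    "dinucleotide_shuffle",
    "truth_from_activities",
]

_BASES = "ACGT"
_DEFAULT_CELL_TYPES = ("HepG2", "K562", "WTC11")


@dataclass
class SimConfig:
    """Study conditions for one simulated library.

    Defaults mirror a desk-scale version of a large lentiMPRA library: a
    promoter:enhancer ratio of roughly 1:3.5, a few hundred shuffled
    negatives, three replicates, ~50 median barcodes per element from a
    clipped lognormal over 20-250, two million reads per replicate and
    modality, and mild overdispersion.
    """

    n_promoters: int = 400
    n_enhancers: int = 1400
    n_shuffled: int = 200
    n_positive: int = 50
    n_cell_types: int = 3
    barcodes_per_element: tuple[int, int, int] = (20, 50, 250)  # (min, median, max)
    depth_dna: float = 2e6
    depth_rna: float = 2e6
    dispersion: float = 0.1  # gamma-Poisson; 0 = Poisson limit
    n_replicates: int = 3
    element_length: int = 200
    per_site_effect: float = 0.4  # log2 units per planted site
    interaction_effects: list[tuple[str, str, float]] = field(default_factory=list)
    specificity_sd: float = 0.5  # SD of enhancer cell-type deviations (log2)
    specificity_shift: float = 1.0  # mean boost in an enhancer's origin cell type
    orientation_sd: float = 0.25  # enhancer orientation-offset SD; promoters get 2x
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_promoters", "n_enhancers", "n_shuffled", "n_positive"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_promoters + self.n_enhancers + self.n_shuffled + self.n_positive <= 0:
            raise ValueError("library must contain at least one element")
        for name in ("n_cell_types", "n_replicates", "element_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.element_length % 2:
            raise ValueError("element_length must be even")
        if self.depth_dna <= 0 or self.depth_rna <= 0:
            raise ValueError("depths must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        lo, med, hi = self.barcodes_per_element
        if not (1 <= lo <= med <= hi):
            raise ValueError("barcodes_per_element must satisfy 1 <= min <= median <= max")

    @property
    def cell_types(self) -> list[str]:
        if self.n_cell_types <= len(_DEFAULT_CELL_TYPES):
            return list(_DEFAULT_CELL_TYPES[: self.n_cell_types])
        extra = [f"cell{i + 1}" for i in range(len(_DEFAULT_CELL_TYPES), self.n_cell_types)]
        return list(_DEFAULT_CELL_TYPES) + extra


@dataclass
class GroundTruth:
    """Per-element truth: category, planted sites, offsets, true activities.

    ``elements`` is indexed by element_id with columns category, cell_type
    (origin cell type for enhancers, 'shared' otherwise), baseline and
    orientation_offset. ``site_counts`` is element x TF. ``activity`` is
    element x cell type in log2 units.
    """

    elements: pd.DataFrame
    site_counts: pd.DataFrame
    activity: pd.DataFrame
    interaction_effects: list[tuple[str, str, float]] = field(default_factory=list)

    @property
    def element_ids(self) -> pd.Index:
        return self.elements.index


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([seed, stream])


# ---------------------------------------------------------------------------
# dinucleotide shuffling (Altschul-Erickson Eulerian-path shuffle)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(sequence: str, seed: int) -> str:
    """Shuffle a DNA string preserving its exact dinucleotide composition.

    Implements the Eulerian-path shuffle: the sequence is viewed as a walk on
    the 4-vertex de Bruijn graph whose edges are its dinucleotides; a uniform
    random last-edge arborescence toward the final base plus uniform orderings
    of the remaining edges yields a uniform random sequence with identical
    dinucleotide counts, length, first and last nucleotide.
    """
    if len(sequence) < 2:
        raise ValueError("sequence must have length >= 2")
    seq = sequence.upper()
    if set(seq) - set(_BASES):
        raise ValueError(f"non-ACGT characters: {sorted(set(seq) - set(_BASES))}")
    rng = _rng(seed, 0)
    adj: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        adj.setdefault(a, []).append(b)
    adj.setdefault(seq[-1], [])
    last = seq[-1]
    verts = sorted(v for v in adj if v != last and adj[v])
    last_edge: dict[str, str] = {}
    if verts:
        while True:
            last_edge = {v: adj[v][rng.integers(len(adj[v]))] for v in verts}
            ok = True
            for v in verts:
                seen, u = set(), v
                while u != last and u not in seen:
                    seen.add(u)
                    u = last_edge[u]
                if u != last:
                    ok = False
                    break
            if ok:
                break
    ordered: dict[str, list[str]] = {}
    for v in sorted(adj):
        rest = adj[v].copy()
        if v in last_edge:
            rest.remove(last_edge[v])
        rng.shuffle(rest)
        if v in last_edge:
            rest.append(last_edge[v])
        ordered[v] = rest
    out = [seq[0]]
    ptr = {v: 0 for v in adj}
    u = seq[0]
    for _ in range(len(seq) - 1):
        nxt = ordered[u][ptr[u]]
        ptr[u] += 1
        out.append(nxt)
        u = nxt
    return "".join(out)


# ---------------------------------------------------------------------------
# catalog simulation
# ---------------------------------------------------------------------------

def _prepare_scanners(pwms: Sequence[PWM], p_threshold: float):
    """Per (PWM, strand): integer log-odds lookup (w,5) and hit threshold bin."""
    prepared = []
    for pwm in pwms:
        per_strand = []
        for mat in (pwm, pwm.reverse_complement()):
            bins = np.rint(mat.log_odds() / grammar.SCORE_BIN).astype(np.int64)
            table = np.column_stack([bins, np.zeros(mat.width, np.int64)])
            per_strand.append((table, grammar.hit_threshold_bin(mat, p_threshold)))
        prepared.append((pwm.name, pwm.width, per_strand))
    return prepared


def _hit_positions(encoded: np.ndarray, prepared_pwm) -> np.ndarray:
    """Forward-strand window starts that are hits on either strand."""
    _, width, per_strand = prepared_pwm
    if len(encoded) < width:
        return np.empty(0, dtype=int)
    pos = []
    for table, thresh in per_strand:
        scores = grammar._window_scores(encoded, table)
        pos.append(np.nonzero(scores >= thresh)[0])
    return np.unique(np.concatenate(pos))


def _clean_background(rng: np.random.Generator, length: int, prepared) -> np.ndarray:
    """Random encoded sequence guaranteed free of hits for every PWM."""
    encoded = rng.integers(0, 4, size=length).astype(np.int8)
    for _ in range(100):
        dirty = False
        for prep in prepared:
            hits = _hit_positions(encoded, prep)
            if len(hits):
                dirty = True
                width = prep[1]
                for p in hits:
                    encoded[p : p + width] = rng.integers(0, 4, size=width)
        if not dirty:
            return encoded
    raise RuntimeError("could not generate a motif-free background sequence")


def _plant_sites(
    rng: np.random.Generator,
    background: np.ndarray,
    pwms: Sequence[PWM],
    counts: dict[str, int],
    prepared,
    element_id: str,
) -> np.ndarray:
    """Plant consensus sites at non-overlapping positions; verify the scan."""
    length = len(background)
    widths = {p.name: p.width for p in pwms}
    order = [tf for tf, c in counts.items() for _ in range(c)]
    total_width = sum(widths[tf] for tf in order)
    if total_width > length:
        raise ValueError(f"planting overflow: sites cannot fit in element {element_id}")
    consensus = {p.name: encode_sequence(p.consensus) for p in pwms}
    k = len(order)
    for _attempt in range(20):
        encoded = background.copy()
        planted = np.zeros(length, dtype=bool)
        rng.shuffle(order)
        # distribute the free bases among the k+1 gaps: always fits
        gaps = (
            rng.multinomial(length - total_width, np.full(k + 1, 1.0 / (k + 1)))
            if k
            else np.zeros(1, dtype=int)
        )
        pos = 0
        starts: dict[str, list[int]] = {tf: [] for tf in counts}
        for i, tf in enumerate(order):
            pos += int(gaps[i])
            encoded[pos : pos + widths[tf]] = consensus[tf]
            planted[pos : pos + widths[tf]] = True
            starts[tf].append(pos)
            pos += widths[tf]
        # flanking windows that straddle a planted site can score as extra
        # hits; repair them by redrawing their background bases only
        for _repair in range(100):
            dirty, stuck = False, False
            for prep in prepared:
                name, width, _ = prep
                extra = set(map(int, _hit_positions(encoded, prep))) - set(
                    starts.get(name, [])
                )
                for p in extra:
                    free = np.nonzero(~planted[p : p + width])[0]
                    if len(free) == 0:
                        stuck = True  # adjacent sites collide; new layout
                        continue
                    dirty = True
                    encoded[p + free] = rng.integers(0, 4, size=len(free))
            if stuck:
                break
            if not dirty:
                if all(
                    len(_hit_positions(encoded, prep)) == counts.get(prep[0], 0)
                    for prep in prepared
                ):
                    return encoded
                break  # a planted site is not detected: PWM too weak
    raise RuntimeError(
        f"could not plant a scan-consistent layout for element {element_id}; "
        "check that each PWM's consensus is itself a hit at the scan threshold"
    )


def _decode(encoded: np.ndarray) -> str:
    return "".join(_BASES[i] for i in encoded)


_SITE_COUNT_PROBS = np.array([0.55, 0.20, 0.12, 0.07, 0.04, 0.02])


def simulate_catalog(
    config: SimConfig, pwms: Sequence[PWM]
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate an element catalog with planted motif grammar.

    Returns the catalog (element_id, category, cell_type, chrom, start, end,
    strand, sequence) and the GroundTruth. Promoters and enhancers carry 0-5
    planted consensus sites per TF at non-overlapping positions; shuffled
    negatives are dinucleotide shuffles of motif-free enhancer-like
    backgrounds; positive controls are strong motif-free sequences.
    """
    if not pwms:
        raise ValueError("at least one PWM is required")
    max_w = max(p.width for p in pwms)
    if config.element_length < max_w * 5:
        raise ValueError("element_length too short for up to 5 planted sites")
    rng = _rng(config.seed, 1)
    prepared = _prepare_scanners(pwms, p_threshold=0.001)
    tf_names = [p.name for p in pwms]
    cell_types = config.cell_types

    categories = (
        ["promoter"] * config.n_promoters
        + ["enhancer"] * config.n_enhancers
        + ["shuffled_negative"] * config.n_shuffled
        + ["positive_control"] * config.n_positive
    )
    n = len(categories)
    ids = [f"E{i:06d}" for i in range(n)]

    rows, site_rows, seqs = [], [], []
    for eid, cat in zip(ids, categories):
        counts = {tf: 0 for tf in tf_names}
        if cat in ("promoter", "enhancer"):
            for tf in tf_names:
                counts[tf] = int(rng.choice(6, p=_SITE_COUNT_PROBS))
            background = _clean_background(rng, config.element_length, prepared)
            encoded = _plant_sites(rng, background, pwms, counts, prepared, eid)
        elif cat == "shuffled_negative":
            for _try in range(50):
                src = _decode(_clean_background(rng, config.element_length, prepared))
                shuffled = dinucleotide_shuffle(src, seed=int(rng.integers(2**31)))
                encoded = encode_sequence(shuffled)
                if not any(len(_hit_positions(encoded, prep)) for prep in prepared):
                    break
            else:
                raise RuntimeError(f"could not derive a motif-free shuffle for {eid}")
        else:  # positive_control
            encoded = _clean_background(rng, config.element_length, prepared)

        if cat == "promoter":
            baseline = (
                rng.normal(0.0, 0.4) if rng.random() < 0.45 else rng.normal(3.0, 0.7)
            )
            orientation = rng.normal(0.0, 2.0 * config.orientation_sd)
            origin = "shared"
        elif cat == "enhancer":
            baseline = rng.gamma(2.0, 0.75)
            orientation = rng.normal(0.0, config.orientation_sd)
            origin = cell_types[int(rng.integers(len(cell_types)))]
        elif cat == "shuffled_negative":
            baseline, orientation, origin = 0.0, 0.0, "shared"
        else:
            baseline, orientation, origin = rng.normal(4.0, 0.3), 0.0, "shared"

        rows.append((eid, cat, origin, baseline, orientation))
        site_rows.append([counts[tf] for tf in tf_names])
        seqs.append(_decode(encoded))

    elements = pd.DataFrame(
        rows,
        columns=["element_id", "category", "cell_type", "baseline", "orientation_offset"],
    ).set_index("element_id")
    site_counts = pd.DataFrame(
        site_rows, index=elements.index, columns=tf_names, dtype=int
    )

    motif_term = config.per_site_effect * site_counts.sum(axis=1).to_numpy(float)
    for tf_i, tf_j, gamma in config.interaction_effects:
        co = ((site_counts[tf_i] >= 1) & (site_counts[tf_j] >= 1)).to_numpy()
        motif_term = motif_term + gamma * co
    base = elements["baseline"].to_numpy() + motif_term

    deviations = np.zeros((n, len(cell_types)))
    is_enh = (elements["category"] == "enhancer").to_numpy()
    for j, ct in enumerate(cell_types):
        dev = rng.normal(0.0, config.specificity_sd, size=n)
        dev += config.specificity_shift * (elements["cell_type"] == ct).to_numpy()
        deviations[:, j] = np.where(is_enh, dev, 0.0)
    activity = pd.DataFrame(
        base[:, None] + deviations, index=elements.index, columns=cell_types
    )

    catalog = pd.DataFrame(
        {
            "element_id": elements.index,
            "category": elements["category"].to_numpy(),
            "cell_type": elements["cell_type"].to_numpy(),
            "chrom": "chrS",
            "start": np.arange(n) * (config.element_length + 50),
            "end": np.arange(n) * (config.element_length + 50) + config.element_length,
            "strand": "+",
            "sequence": seqs,
        }
    )
    truth = GroundTruth(
        elements=elements,
        site_counts=site_counts,
        activity=activity,
        interaction_effects=list(config.interaction_effects),
    )
    return catalog, truth


def truth_from_activities(
    activity: pd.DataFrame | pd.Series,
    categories: pd.Series | None = None,
    orientation_offset: pd.Series | None = None,
) -> GroundTruth:
    """Build a GroundTruth directly from chosen true activities.

    Convenience for calibration studies where activities are prescribed
    (e.g. drawn uniformly) rather than derived from a motif grammar.
    """
    if isinstance(activity, pd.Series):
        activity = activity.to_frame(_DEFAULT_CELL_TYPES[0])
    idx = activity.index
    elements = pd.DataFrame(
        {
            "category": categories.reindex(idx) if categories is not None else "enhancer",
            "cell_type": "shared",
            "baseline": 0.0,
            "orientation_offset": (
                orientation_offset.reindex(idx).fillna(0.0)
                if orientation_offset is not None
                else 0.0
            ),
        },
        index=idx,
    )
    elements.index.name = "element_id"
    site_counts = pd.DataFrame(index=elements.index)
    return GroundTruth(elements=elements, site_counts=site_counts, activity=activity.copy())


# ---------------------------------------------------------------------------
# barcode-level counts
# ---------------------------------------------------------------------------

def _negative_binomial(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """Gamma-Poisson draws with Var = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.maximum(mean, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    return rng.poisson(rng.gamma(shape, mean / shape))


def simulate_counts(
    catalog: pd.DataFrame | None,
    truth: GroundTruth,
    config: SimConfig,
    cell_type: str | None = None,
    stream: int = 2,
) -> pd.DataFrame:
    """Simulate a barcode-level DNA/RNA count table for one cell type.

    Per element, B barcodes are drawn from a clipped lognormal matching the
    configured (min, median, max); per barcode, a lognormal abundance (sd 0.5
    on the log scale, emulating cloning-bottleneck heterogeneity) sets the
    DNA mean, and the RNA mean multiplies it by 2^(activity + orientation
    offset for reverse-cloned elements). Counts are gamma-Poisson around
    means scaled so each replicate's totals match the configured depths with
    +/-20% library-size jitter. ``stream`` selects an independent random
    substream of the config seed (use different streams for forward/reverse
    or per-cell-type tables).

    The library composition offset ``log2(sum w 2^g / sum w)`` — the constant
    by which relative (CPM-normalized) activity estimates are shifted from
    truth — is stored in ``.attrs["composition_offset"]``.
    """
    rng = _rng(config.seed, stream)
    if cell_type is None:
        cell_type = truth.activity.columns[0]
    if catalog is None:
        catalog = pd.DataFrame(
            {"element_id": truth.element_ids, "strand": "+"}
        )
    missing = set(catalog["element_id"]) - set(truth.element_ids)
    if missing:
        raise ValueError(f"catalog elements missing from truth: {sorted(missing)[:5]}")

    eids = catalog["element_id"].to_numpy()
    strands = (
        catalog["strand"].to_numpy() if "strand" in catalog else np.full(len(eids), "+")
    )
    act = truth.activity.loc[eids, cell_type].to_numpy(float)
    orient = truth.elements.loc[eids, "orientation_offset"].to_numpy(float)
    g = act + np.where(strands == "-", orient, 0.0)

    lo, med, hi = config.barcodes_per_element
    n_bc = np.clip(
        np.rint(rng.lognormal(math.log(med), 0.4, size=len(eids))), lo, hi
    ).astype(int)
    total_bc = int(n_bc.sum())
    abundance = rng.lognormal(0.0, 0.5, size=total_bc)

    elem_of_bc = np.repeat(np.arange(len(eids)), n_bc)
    g_bc = g[elem_of_bc]
    w_dna = abundance
    w_rna = abundance * np.exp2(g_bc)
    offset = float(np.log2(w_rna.sum() / w_dna.sum()))

    bc_labels = np.concatenate([np.arange(b) for b in n_bc])
    frames = []
    for rep in range(1, config.n_replicates + 1):
        jit_dna = 1.0 + rng.uniform(-0.2, 0.2)
        jit_rna = 1.0 + rng.uniform(-0.2, 0.2)
        mean_dna = config.depth_dna * jit_dna * w_dna / w_dna.sum()
        mean_rna = config.depth_rna * jit_rna * w_rna / w_rna.sum()
        frames.append(
            pd.DataFrame(
                {
                    "element_id": eids[elem_of_bc],
                    "barcode": [
                        f"{eids[e]}_bc{b:04d}" for e, b in zip(elem_of_bc, bc_labels)
                    ],
                    "replicate": rep,
                    "dna_count": _negative_binomial(rng, mean_dna, config.dispersion),
                    "rna_count": _negative_binomial(rng, mean_rna, config.dispersion),
                }
            )
        )
    counts = pd.concat(frames, ignore_index=True)
    counts.attrs["composition_offset"] = offset
    counts.attrs["cell_type"] = cell_type
    return counts


# ---------------------------------------------------------------------------
# feature matrices and ASV tables
# ---------------------------------------------------------------------------

def simulate_features(
    truth: GroundTruth,
    n_features: int,
    n_informative: int,
    noise_sd: float,
    seed: int,
    cell_type: str | None = None,
) -> pd.DataFrame:
    """Element x feature matrix emulating log-scale biochemical signal tracks.

    The first ``n_informative`` columns (named ``signal_*``) are positive
    linear transforms of true activity plus Gaussian noise; the remainder
    (``noise_*``) are independent noise. Columns are emitted directly on the
    log-signal scale (real signal tracks are right-skewed and log-transformed
    before modelling; the generator produces the post-transform scale).
    """
    if n_informative > n_features:
        raise ValueError("n_informative must be <= n_features")
    rng = _rng(seed, 5)
    if cell_type is None:
        cell_type = truth.activity.columns[0]
    act = truth.activity[cell_type].to_numpy(float)
    n = len(act)
    cols, names = [], []
    for j in range(n_informative):
        a = rng.uniform(0.5, 1.5)
        cols.append(a * act + rng.normal(0.0, noise_sd, size=n))
        names.append(f"signal_{j:03d}")
    for j in range(n_features - n_informative):
        cols.append(rng.normal(0.0, 1.0, size=n))
        names.append(f"noise_{j:03d}")
    return pd.DataFrame(
        np.column_stack(cols) if cols else np.empty((n, 0)),
        index=truth.element_ids,
        columns=names,
    )


def simulate_asv_table(
    predicted: pd.Series,
    error_rate: float,
    seed: int,
    nonsignificant_fraction: float = 0.0,
) -> pd.DataFrame:
    """Observed allelic-imbalance table linked to predicted variant effects.

    Each variant's observed imbalance sign matches the sign of its predicted
    effect with probability ``1 - error_rate``; magnitudes are |N(0.8, 0.3)|.
    A ``nonsignificant_fraction`` of variants receive FDR > 0.05, the rest
    FDR <= 0.05.
    """
    if not 0 <= error_rate < 1:
        raise ValueError("error_rate must be in [0, 1)")
    if not 0 <= nonsignificant_fraction <= 1:
        raise ValueError("nonsignificant_fraction must be in [0, 1]")
    rng = _rng(seed, 6)
    n = len(predicted)
    pred_sign = np.where(predicted.to_numpy(float) >= 0, 1.0, -1.0)
    flip = rng.random(n) < error_rate
    obs_sign = np.where(flip, -pred_sign, pred_sign)
    magnitude = np.abs(rng.normal(0.8, 0.3, size=n))
    n_nonsig = int(round(nonsignificant_fraction * n))
    nonsig = np.zeros(n, dtype=bool)
    if n_nonsig:
        nonsig[rng.choice(n, size=n_nonsig, replace=False)] = True
    fdr = np.where(
        nonsig, rng.uniform(0.051, 1.0, size=n), rng.uniform(1e-4, 0.05, size=n)
    )
    return pd.DataFrame(
        {
            "variant": predicted.index,
            "observed_effect": obs_sign * magnitude,
            "fdr": fdr,
        }
    )
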