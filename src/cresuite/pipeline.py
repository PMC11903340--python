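"""End-to-end demo pipeline: simulate -> quantify -> call -> specificity ->
grammar -> select.

Runs every stage on one synthetic library, writing TSV/BED/FASTA/MEME
outputs plus the resolved flat-key-value config and a filter ledger
(elements in/out per stage) into a run directory. Outputs are byte-identical
under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import calls, io, models, quantify, selection, specificity, synthetic
from .grammar import PWM, summarize_hits, homotypic_dose_response
from .synthetic import SimConfig

__all__ = ["RunConfig", "run_pipeline", "demo_pwms"]

logger = logging.getLogger(__name__)


def demo_pwms() -> list[PWM]:
    """Three demonstration PWMs with field-typical consensus patterns.

    Consensus bases carry probability 0.85 (0.05 elsewhere), informative
    enough that a scan at p <= 1e-3 admits at most one mismatch.
    """

    def make(name: str, consensus: str) -> PWM:
        idx = {b: i for i, b in enumerate("ACGT")}
        mat = np.full((len(consensus), 4), 0.05)
        for row, base in zip(mat, consensus):
            row[idx[base]] = 0.85
        return PWM(name, mat)

    return [
        make("KLF", "GGGGCGGGGC"),
        make("GATA", "AGATAAGA"),
        make("HNF4", "AGGTCAAAG"),
    ]


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run; unknown keys are rejected."""

    seed: int = 0
    outdir: str = "cresuite_run"
    # library
    n_promoters: int = 60
    n_enhancers: int = 150
    n_shuffled: int = 60
    n_positive: int = 20
    n_cell_types: int = 3
    n_replicates: int = 3
    barcodes_min: int = 10
    barcodes_median: int = 30
    barcodes_max: int = 80
    depth_dna: float = 5e5
    depth_rna: float = 5e5
    dispersion: float = 0.1
    element_length: int = 200
    per_site_effect: float = 0.4
    orientation_sd: float = 0.25
    specificity_sd: float = 0.5
    specificity_shift: float = 1.0
    # stage parameters
    min_barcodes: int = 10
    fdr: float = 0.05
    p_threshold: float = 0.001
    n_folds: int = 10
    k: int = 25
    n_features: int = 30
    n_informative: int = 5
    feature_noise_sd: float = 0.5
    motif_file: str = ""  # empty = built-in demo motifs

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = io.read_flat_config(path)
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(raw) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        for key, value in raw.items():
            typ = known[key].type
            if typ == "int":
                kwargs[key] = int(value)
            elif typ == "float":
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sim_config(self) -> SimConfig:
        return SimConfig(
            n_promoters=self.n_promoters,
            n_enhancers=self.n_enhancers,
            n_shuffled=self.n_shuffled,
            n_positive=self.n_positive,
            n_cell_types=self.n_cell_types,
            barcodes_per_element=(self.barcodes_min, self.barcodes_median, self.barcodes_max),
            depth_dna=self.depth_dna,
            depth_rna=self.depth_rna,
            dispersion=self.dispersion,
            n_replicates=self.n_replicates,
            element_length=self.element_length,
            per_site_effect=self.per_site_effect,
            specificity_sd=self.specificity_sd,
            specificity_shift=self.specificity_shift,
            orientation_sd=self.orientation_sd,
            seed=self.seed,
        )


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory. Deterministic per seed."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ledger: list[str] = []

    def note(stage: str, msg: str) -> None:
        logger.info("%s: %s", stage, msg)
        ledger.append(f"{stage}\t{msg}")

    io.write_flat_config(config.to_dict(), outdir / "resolved_config.txt")
    sim = config.sim_config()
    pwms = io.read_meme(config.motif_file) if config.motif_file else demo_pwms()

    # --- simulate ---------------------------------------------------------
    catalog, truth = synthetic.simulate_catalog(sim, pwms)
    io.write_catalog(catalog, outdir / "catalog.bed", outdir / "catalog.fa")
    io.write_ground_truth(truth, outdir / "ground_truth.tsv")
    io.write_meme(pwms, outdir / "motifs.meme")
    note("simulate", f"elements={len(catalog)} tfs={len(pwms)}")

    counts_fwd = synthetic.simulate_counts(catalog, truth, sim, stream=2)
    counts_rev = synthetic.simulate_counts(
        catalog.assign(strand="-"), truth, sim, stream=3
    )
    io.write_counts(counts_fwd, outdir / "counts_forward.tsv")
    io.write_counts(counts_rev, outdir / "counts_reverse.tsv")
    note("simulate", f"barcode_rows={len(counts_fwd)}")

    # --- quantify ---------------------------------------------------------
    per_rep_fwd = quantify.element_activity(counts_fwd, min_barcodes=config.min_barcodes)
    per_rep_rev = quantify.element_activity(counts_rev, min_barcodes=config.min_barcodes)
    comb_fwd = quantify.combine_replicates(per_rep_fwd)
    comb_rev = quantify.combine_replicates(per_rep_rev)
    per_rep_fwd.to_csv(outdir / "activity_forward.tsv", sep="\t", index=False)
    comb_fwd.to_csv(outdir / "activity_forward_combined.tsv", sep="\t")
    comb_rev.to_csv(outdir / "activity_reverse_combined.tsv", sep="\t")
    corr = quantify.replicate_correlations(per_rep_fwd)
    corr.to_csv(outdir / "replicate_correlations.tsv", sep="\t", index=False)
    note(
        "quantify",
        f"retained={comb_fwd.shape[0]}/{catalog.shape[0]} "
        f"min_pearson={corr['pearson'].min():.4f}",
    )

    # --- call active ------------------------------------------------------
    neg_ids = set(catalog.loc[catalog["category"] == "shuffled_negative", "element_id"])
    negatives = pd.concat(
        [
            comb_fwd.loc[comb_fwd.index.isin(neg_ids), "mean_activity"],
            comb_rev.loc[comb_rev.index.isin(neg_ids), "mean_activity"],
        ]
    )
    fwd_fg = comb_fwd.loc[~comb_fwd.index.isin(neg_ids), "mean_activity"]
    rev_fg = comb_rev.loc[~comb_rev.index.isin(neg_ids), "mean_activity"]
    active = calls.call_both_orientations(
        fwd_fg, rev_fg, negatives.to_numpy(), fdr=config.fdr
    )
    active.to_csv(outdir / "active_calls.tsv", sep="\t")
    note(
        "call",
        f"foreground={len(active)} active={int(active['active'].sum())} "
        f"fraction={active['active'].mean():.4f}",
    )

    # --- specificity ------------------------------------------------------
    by_ct = {}
    for j, ct in enumerate(sim.cell_types):
        cts = synthetic.simulate_counts(catalog, truth, sim, cell_type=ct, stream=10 + j)
        per = quantify.element_activity(cts, min_barcodes=config.min_barcodes)
        by_ct[ct] = quantify.combine_replicates(per)["mean_activity"]
    act_matrix = pd.DataFrame(by_ct)
    ess = specificity.element_specificity_scores(act_matrix)
    ess.to_csv(outdir / "element_specificity_scores.tsv", sep="\t")
    pca = specificity.specificity_pca(act_matrix)
    pca.loadings.to_csv(outdir / "specificity_pca_loadings.tsv", sep="\t")
    note("specificity", f"ess_elements={len(ess)} pc1_var={pca.variance_fractions.iloc[0]:.4f}")

    # --- grammar ----------------------------------------------------------
    hits = summarize_hits(catalog, pwms, p_threshold=config.p_threshold)
    hits.counts.to_csv(outdir / "motif_counts.tsv", sep="\t")
    hits.loglik.to_csv(outdir / "motif_logliks.tsv", sep="\t")
    top_tfs = [p.name for p in pwms]
    dose_rows = []
    for tf in top_tfs:
        try:
            dr = homotypic_dose_response(
                comb_fwd["mean_activity"], hits, tf, top_tfs
            )
        except ValueError as err:
            note("grammar", f"dose_response {tf}: skipped ({err})")
            continue
        dose_rows.append(
            {"tf": tf, "mult_slope": dr.mult_slope, "mult_intercept": dr.mult_intercept}
        )
    if dose_rows:
        pd.DataFrame(dose_rows).to_csv(outdir / "dose_response.tsv", sep="\t", index=False)
    note("grammar", f"scanned={hits.counts.shape[0]} dose_fits={len(dose_rows)}")

    # --- select -----------------------------------------------------------
    features = synthetic.simulate_features(
        truth,
        n_features=config.n_features,
        n_informative=config.n_informative,
        noise_sd=config.feature_noise_sd,
        seed=config.seed,
    )
    features.to_csv(outdir / "features.tsv", sep="\t")
    sim_matrix = selection.similarity_from_features(features)
    result = selection.greedy_select(sim_matrix, k=config.k)
    pd.DataFrame(
        {"element_id": result.selected, "marginal_gain": result.gains}
    ).to_csv(outdir / "selection.tsv", sep="\t", index=False)
    note("select", f"k={result.k} objective={result.objective:.6f}")

    (outdir / "filter_ledger.tsv").write_text("\n".join(ledger) + "\n")
    return outdir
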