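"""PWM scanning against exhaustive oracles; dosage and interaction fits."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cresuite import PWM, demo_pwms, scan_pwm, summarize_hits
from cresuite.grammar import (
    MotifHitSummary,
    SCORE_BIN,
    heterotypic_interaction,
    homotypic_dose_response,
    reverse_complement,
    score_null_survival,
)


def brute_force_scan(sequence: str, pwm: PWM, p_threshold: float) -> set:
    """Independent scanner: enumerate every offset/strand; null by full
    enumeration of all 4^w words under the background model."""
    idx = {b: i for i, b in enumerate("ACGT")}

    def binned_table(mat: PWM) -> np.ndarray:
        return np.rint(mat.log_odds() / SCORE_BIN).astype(int)

    def null_p(mat: PWM):
        bins = binned_table(mat)
        w = mat.width
        words = np.array(list(itertools.product(range(4), repeat=w)))
        weights = np.prod(mat.background[words], axis=1)
        scores = bins[np.arange(w), words].sum(axis=1)
        return scores, weights

    hits = set()
    for strand, mat in (("+", pwm), ("-", pwm.reverse_complement())):
        bins = binned_table(mat)
        null_scores, null_weights = null_p(mat)
        for off in range(len(sequence) - mat.width + 1):
            window = sequence[off : off + mat.width]
            score = sum(bins[j, idx[c]] for j, c in enumerate(window))
            p = null_weights[null_scores >= score].sum()
            if p <= p_threshold:
                hits.add((off, strand, score))
    return hits


class TestScanPWM:
    def test_uniform_pwm_yields_no_hits(self):
        pwm = PWM("flat", np.full((6, 4), 0.25))
        hits = scan_pwm("ACGTACGTACGT", pwm)
        assert hits.empty
        offset, sf = score_null_survival(pwm)
        assert sf[0 - offset] == pytest.approx(1.0)

    def test_width4_consensus_scores_eight_bits(self):
        probs = np.full((4, 4), 1e-4)
        for i, b in enumerate("AGGT"):
            probs[i, "ACGT".index(b)] = 1 - 3e-4
        pwm = PWM("c4", probs / probs.sum(axis=1, keepdims=True))
        # a perfect width-4 match has exact null p = 1/256 > 1e-3: no hit at
        # the default threshold, one forward hit of ~8 bits at p <= 0.005
        assert scan_pwm("GGAGGTGG", pwm, p_threshold=0.001).empty
        hits = scan_pwm("GGAGGTGG", pwm, p_threshold=0.005)
        assert len(hits) == 1
        assert hits.loc[0, "strand"] == "+"
        assert hits.loc[0, "position"] == 2
        assert hits.loc[0, "score"] == pytest.approx(8.0, abs=0.01)

    def test_hit_sets_match_exhaustive_oracle(self):
        """100 random 60-nt sequences, width<=8 PWMs, exact-null oracle."""
        rng = np.random.default_rng(42)
        pwms = [
            PWM("d6", rng.dirichlet(np.ones(4) * 0.5, size=6)),
            PWM("d8", rng.dirichlet(np.ones(4) * 0.3, size=8)),
        ]
        for trial in range(50):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            for pwm in pwms:
                oracle = brute_force_scan(seq, pwm, 0.001)
                got = scan_pwm(seq, pwm, 0.001)
                got_set = {
                    (int(h.position), h.strand, int(round(h.score / SCORE_BIN)))
                    for h in got.itertuples()
                }
                assert got_set == oracle

    def test_strand_symmetry(self):
        rng = np.random.default_rng(1)
        pwm = PWM("d7", rng.dirichlet(np.ones(4) * 0.4, size=7))
        seq = "".join(rng.choice(list("ACGT"), size=80))
        fwd_hits = scan_pwm(seq, pwm, 0.002)
        rc_hits = scan_pwm(reverse_complement(seq), pwm, 0.002)
        mirrored = {
            (len(seq) - pwm.width - int(h.position), {"+": "-", "-": "+"}[h.strand])
            for h in rc_hits.itertuples()
        }
        assert {(int(h.position), h.strand) for h in fwd_hits.itertuples()} == mirrored

    def test_ambiguous_bases_score_as_background(self):
        pwm = demo_pwms()[1]  # GATA, width 8
        clean = "A" * 20 + pwm.consensus + "C" * 20
        with_n = clean.replace("A" * 20, "N" * 20, 1)
        h1 = scan_pwm(clean, pwm)
        h2 = scan_pwm(with_n, pwm)
        assert list(h1["position"]) == list(h2["position"])
        with pytest.raises(ValueError):
            scan_pwm("ACGTXACGT" * 3, pwm)


class TestSummarizeHits:
    def test_no_hits_gives_zero_count_and_zero_loglik(self, pwms):
        catalog = pd.DataFrame({"element_id": ["e1"], "sequence": ["ACGT" * 20]})
        hits = summarize_hits(catalog, pwms)
        assert (hits.counts.loc["e1"] == 0).all()
        assert (hits.loglik.loc["e1"] == 0).all()

    def test_two_identical_hits_double_the_loglik(self, pwms):
        gata = pwms[1]
        seq = "C" * 12 + gata.consensus + "C" * 12 + gata.consensus + "C" * 12
        catalog = pd.DataFrame({"element_id": ["e1"], "sequence": [seq]})
        hits = summarize_hits(catalog, [gata])
        single = scan_pwm("C" * 12 + gata.consensus + "C" * 12, gata)
        assert hits.counts.loc["e1", "GATA"] == 2
        assert hits.loglik.loc["e1", "GATA"] == pytest.approx(
            2 * single["log_prob"].iloc[0]
        )

    def test_round_trip_spearman_on_simulated_catalog(self, small_library, pwms):
        from scipy.stats import spearmanr

        catalog, truth = small_library
        hits = summarize_hits(catalog, pwms)
        for tf in hits.tfs:
            rho = spearmanr(
                hits.counts[tf], truth.site_counts.loc[hits.counts.index, tf]
            ).statistic
            assert rho >= 0.95


def synthetic_dose_data(rng, n, per_site, noise_sd, tfs=("A", "B")):
    counts = pd.DataFrame(
        {t: rng.integers(0, 6, size=n) for t in tfs},
        index=pd.Index([f"e{i}" for i in range(n)], name="element_id"),
    )
    activity = pd.Series(
        per_site * counts.sum(axis=1).to_numpy() + rng.normal(0, noise_sd, n),
        index=counts.index,
    )
    loglik = counts * -1.3
    return activity, MotifHitSummary(counts=counts, loglik=loglik)


class TestHomotypicDose:
    def test_noiseless_multiplicative_fit_is_exact(self):
        rng = np.random.default_rng(0)
        activity, hits = synthetic_dose_data(rng, 600, per_site=0.4, noise_sd=0.0)
        dr = homotypic_dose_response(activity, hits, "A", ["A", "B"])
        assert dr.mult_slope == pytest.approx(0.4, abs=1e-9)
        expected = dr.expected_multiplicative(dr.table["dose"].to_numpy())
        np.testing.assert_allclose(dr.table["median_activity"], expected, atol=1e-9)

    def test_small_dose_groups_are_dropped(self):
        rng = np.random.default_rng(1)
        counts = pd.DataFrame(
            {"A": [0] * 40 + [1] * 40 + [5] * 9, "B": 0},
            index=pd.Index([f"e{i}" for i in range(89)], name="element_id"),
        )
        activity = pd.Series(
            0.4 * counts["A"] + rng.normal(0, 0.1, 89), index=counts.index
        )
        hits = MotifHitSummary(counts=counts, loglik=counts * 0.0)
        dr = homotypic_dose_response(activity, hits, "A", ["A", "B"])
        assert set(dr.table["dose"]) == {0, 1}

    def test_too_few_dose_levels_is_an_error(self):
        counts = pd.DataFrame(
            {"A": [1] * 30, "B": 0},
            index=pd.Index([f"e{i}" for i in range(30)], name="element_id"),
        )
        activity = pd.Series(np.zeros(30), index=counts.index)
        hits = MotifHitSummary(counts=counts, loglik=counts * 0.0)
        with pytest.raises(ValueError):
            homotypic_dose_response(activity, hits, "A", ["A", "B"])

    def test_recovers_planted_effect_under_noise(self):
        rng = np.random.default_rng(2)
        activity, hits = synthetic_dose_data(rng, 2000, per_site=0.4, noise_sd=0.2)
        dr = homotypic_dose_response(activity, hits, "A", ["A", "B"])
        assert dr.mult_slope == pytest.approx(0.4, abs=0.05)


def interaction_data(rng, n_per_cell, b1, b2, gamma, noise_sd=0.0, confound=None):
    """Elements with tf1/tf2 presence in a balanced 2x2 design."""
    rows = []
    for i1 in (0, 1):
        for i2 in (0, 1):
            for _ in range(n_per_cell):
                rows.append((i1, i2))
    counts = pd.DataFrame(
        rows, columns=["T1", "T2"],
        index=pd.Index([f"e{i}" for i in range(len(rows))], name="element_id"),
    )
    act = (
        1.0
        + b1 * counts["T1"]
        + b2 * counts["T2"]
        + gamma * counts["T1"] * counts["T2"]
        + rng.normal(0, noise_sd, len(counts))
    )
    loglik = counts * -1.1
    if confound is not None:
        # a third factor whose extra sites co-occur with the T1+T2 pair, on
        # top of independent background sites (so its per-site effect is
        # identifiable from elements outside the pair)
        background = rng.integers(0, 7, size=len(counts))
        extra = (counts["T1"] * counts["T2"]).to_numpy() * (
            rng.random(len(counts)) < 0.8
        )
        counts = counts.assign(C=(background + extra).astype(int))
        act = act + confound * counts["C"]
        loglik = counts * -1.1
    return pd.Series(act, index=counts.index), MotifHitSummary(
        counts=counts, loglik=loglik
    )


class TestHeterotypicInteraction:
    def test_noiseless_additive_design_has_zero_interaction(self):
        rng = np.random.default_rng(3)
        act, hits = interaction_data(rng, 25, b1=0.4, b2=0.6, gamma=0.0)
        fit = heterotypic_interaction(act, hits, "T1", "T2", ["T1", "T2"])
        assert fit.b_int == pytest.approx(0.0, abs=1e-9)
        assert fit.b1 == pytest.approx(0.4, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        act, hits = interaction_data(rng, 20, b1=0.3, b2=0.5, gamma=0.25, noise_sd=0.3)
        fit = heterotypic_interaction(act, hits, "T1", "T2", ["T1", "T2"])
        i1 = hits.counts["T1"].to_numpy(float)
        i2 = hits.counts["T2"].to_numpy(float)
        x = np.column_stack([np.ones(len(i1)), i1, i2, i1 * i2])
        y = act.to_numpy() - act.to_numpy().mean()  # adjustment = centering here
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        np.testing.assert_allclose([fit.b0, fit.b1, fit.b2, fit.b_int], beta, atol=1e-9)

    def test_recovers_planted_gamma_under_noise(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            act, hits = interaction_data(rng, 200, b1=0.4, b2=0.4, gamma=0.5, noise_sd=0.2)
            fit = heterotypic_interaction(act, hits, "T1", "T2", ["T1", "T2"])
            assert fit.b_int == pytest.approx(0.5, abs=0.1)
            assert fit.classification == "super-multiplicative"

    def test_confounder_adjustment_restores_the_interaction(self):
        """Residualizing on the third factor's loglik removes its bias."""
        rng = np.random.default_rng(6)
        act, hits = interaction_data(
            rng, 120, b1=0.4, b2=0.4, gamma=0.5, noise_sd=0.1, confound=0.3
        )
        fit = heterotypic_interaction(act, hits, "T1", "T2", ["T1", "T2"])
        assert fit.b_int == pytest.approx(0.5, abs=0.1)
        # without adjustment the pair-linked confounder inflates b_int
        naked = MotifHitSummary(
            counts=hits.counts[["T1", "T2"]], loglik=hits.loglik[["T1", "T2"]] * 0.0
        )
        unadj = heterotypic_interaction(act, naked, "T1", "T2", ["T1", "T2"])
        assert abs(unadj.b_int - 0.5) > 0.1
        assert abs(unadj.b_int - 0.5) > abs(fit.b_int - 0.5)

    def test_sparse_cell_is_an_error_naming_it(self):
        rng = np.random.default_rng(7)
        act, hits = interaction_data(rng, 20, b1=0.4, b2=0.4, gamma=0.5)
        trimmed = hits.counts.copy()
        both = trimmed.index[(trimmed["T1"] == 1) & (trimmed["T2"] == 1)][:15]
        keep = trimmed.index.difference(both)
        small = MotifHitSummary(
            counts=trimmed.loc[keep], loglik=hits.loglik.loc[keep]
        )
        with pytest.raises(ValueError, match="T1=1, T2=1"):
            heterotypic_interaction(act.loc[keep], small, "T1", "T2", ["T1", "T2"])
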