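"""P-site offsets, metagenes, codon occupancy, translation efficiency."""

import numpy as np
import pandas as pd
import pytest

import multiclip as mc
from multiclip.ribo import FootprintProfile, rolling_mean

from oracles import brute_start_metagene


def tx_uniform(tid="T1", len5=30, ncod=60, len3=30, seq=None):
    n = len5 + 3 * ncod + len3
    return mc.TranscriptModel(tid, f"G_{tid}", seq or ("A" * n), len5, 3 * ncod, len3)


def reads_df(rows):
    return pd.DataFrame(
        rows, columns=["transcript_id", "pos5p", "count", "condition", "replicate"]
    )


class TestPsiteOffset:
    def test_thirteen_nt_shift(self):
        tx = {"T1": tx_uniform()}
        profiles, dropped = mc.apply_psite_offset(
            reads_df([("T1", 100, 2, "WT", 1)]), tx
        )
        assert dropped == 0
        assert profiles[0].psite_counts[113] == 2

    def test_zero_offset_identity(self):
        tx = {"T1": tx_uniform()}
        profiles, _ = mc.apply_psite_offset(reads_df([("T1", 100, 2, "WT", 1)]), tx, offset=0)
        assert profiles[0].psite_counts[100] == 2

    def test_count_conservation(self, rng):
        tx = {"T1": tx_uniform()}
        n = tx["T1"].length
        rows = [
            ("T1", int(p), int(c), "WT", 1)
            for p, c in zip(rng.integers(0, n, 200), rng.integers(1, 9, 200))
        ]
        total = sum(r[2] for r in rows)
        profiles, dropped = mc.apply_psite_offset(reads_df(rows), tx)
        retained = sum(p.psite_counts.sum() for p in profiles)
        assert retained + dropped == total

    def test_negative_offset_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            mc.apply_psite_offset(reads_df([]), {}, offset=-1)


class TestStartStopMetagene:
    def make_profile(self, counts, tid="T1", len5=30, ncod=60, len3=30):
        return FootprintProfile(tid, "WT", 1, np.asarray(counts), len5, 3 * ncod)

    def test_uniform_coverage_scales_to_one(self):
        t = tx_uniform()
        prof = self.make_profile(np.full(t.length, 3), len5=t.len5utr, ncod=t.n_codons)
        start, stop = mc.metagene_start_stop([prof])
        assert np.allclose(start[~np.isnan(start)], 1.0)
        assert np.allclose(stop[~np.isnan(stop)], 1.0)

    def test_low_coverage_transcript_excluded(self):
        t = tx_uniform()
        counts = np.zeros(t.length)
        counts[t.cds_start + 30] = 4  # total codon coverage 4 < 5
        prof = self.make_profile(counts, len5=t.len5utr, ncod=t.n_codons)
        start, _ = mc.metagene_start_stop([prof])
        assert np.all(np.isnan(start))

    def test_short_cds_rejected(self):
        prof = FootprintProfile("T1", "WT", 1, np.zeros(42), 15, 12)
        with pytest.raises(ValueError, match="shorter"):
            mc.metagene_start_stop([prof], trim_codons=2)

    def test_matches_brute_force(self, rng):
        profiles = []
        by_tx = {}
        for i in range(12):
            len5, ncod, len3 = 30, int(rng.integers(40, 80)), 30
            n = len5 + 3 * ncod + len3
            counts = rng.poisson(2.0, n)
            tid = f"T{i}"
            profiles.append(FootprintProfile(tid, "WT", 1, counts, len5, 3 * ncod))
            by_tx[tid] = (counts, len5, 3 * ncod)
        span = (-30, 120)
        start, _ = mc.metagene_start_stop(profiles, roll=1, span_start=span)
        expected = brute_start_metagene(by_tx, span)
        assert np.allclose(start, expected, equal_nan=True)


class TestTargetingMetagene:
    def with_signal(self, tid="T1", ncod=120, sp_end=25):
        t = tx_uniform(tid=tid, ncod=ncod)
        t.signals = [mc.TargetingSignal(mc.SignalKind.SIGNAL_PEPTIDE, 1, sp_end)]
        return t

    def test_uniform_coverage_gives_unit_profile(self):
        t = self.with_signal()
        tx = {"T1": t}
        prof = FootprintProfile("T1", "WT", 1, np.full(t.length, 4), t.len5utr, t.lencds)
        table, medians = mc.metagene_targeting_signal([prof], tx, min_transcripts=1)
        vals = table.dropna(subset=["mean_scaled"])
        assert np.allclose(vals["mean_scaled"], 1.0)
        assert medians["SP"] == 25.0

    def test_norm_window_change_rescales_by_constant(self, rng):
        t = self.with_signal()
        tx = {"T1": t}
        counts = rng.poisson(5.0, t.length)
        prof = FootprintProfile("T1", "WT", 1, counts, t.len5utr, t.lencds)
        a, _ = mc.metagene_targeting_signal([prof], tx, norm_codons=(20, 40), min_transcripts=1)
        b, _ = mc.metagene_targeting_signal([prof], tx, norm_codons=(30, 50), min_transcripts=1)
        ra = a["mean_scaled"].to_numpy()
        rb = b["mean_scaled"].to_numpy()
        ok = np.isfinite(ra) & np.isfinite(rb) & (rb != 0)
        ratios = ra[ok] / rb[ok]
        assert np.allclose(ratios, ratios[0])

    def test_planted_pause_located_and_wt_above_ko(self, sim_bundle):
        tx, truth = sim_bundle["transcriptome"], sim_bundle["truth"]
        reads = mc.simulate_footprints(tx, truth, depth=80, seed=33)
        profiles, _ = mc.apply_psite_offset(reads, tx)
        by_cond = {}
        for p in profiles:
            by_cond.setdefault(p.condition, []).append(p)
        prof = {}
        for cond in ("WT", "KO"):
            table, _ = mc.metagene_targeting_signal(by_cond[cond], tx)
            prof[cond] = (
                table[table.group == "SP"].set_index("codon")["mean_scaled"]
            )
        onset = mc.locate_pause(prof["WT"].to_numpy())
        assert abs(onset - 25) <= 2
        peak = int(prof["WT"].iloc[20:40].idxmax())
        assert prof["WT"][peak] > prof["KO"][peak]


class TestCodonOccupancy:
    def test_identical_conditions_zero_delta(self, sim_bundle):
        tx, truth = sim_bundle["transcriptome"], sim_bundle["truth"]
        reads = mc.simulate_footprints(tx, truth, seed=44)
        profiles, _ = mc.apply_psite_offset(reads, tx)
        wt = [p for p in profiles if p.condition == "WT"]
        out = mc.codon_occupancy_shift(wt, wt, tx, site="P")
        assert np.allclose(out["delta"], 0.0)
        assert np.allclose(out["delta_sd"], 0.0)

    def test_delta_sums_to_zero_and_freqs_normalized(self, sim_bundle):
        tx, truth = sim_bundle["transcriptome"], sim_bundle["truth"]
        reads = mc.simulate_footprints(tx, truth, seed=45)
        profiles, _ = mc.apply_psite_offset(reads, tx)
        wt = [p for p in profiles if p.condition == "WT"]
        ko = [p for p in profiles if p.condition == "KO"]
        for site in ("P", "E"):
            out = mc.codon_occupancy_shift(wt, ko, tx, site=site)
            assert len(out) == 61
            assert np.isclose(out["freq_wt"].sum(), 1.0)
            assert np.isclose(out["freq_ko"].sum(), 1.0)
            assert abs(out["delta"].sum()) < 1e-12

    def test_planted_dwell_codons_rank_top(self, sim_bundle):
        tx, truth = sim_bundle["transcriptome"], sim_bundle["truth"]
        reads = mc.simulate_footprints(tx, truth, depth=80, seed=46)
        profiles, _ = mc.apply_psite_offset(reads, tx)
        wt = [p for p in profiles if p.condition == "WT"]
        ko = [p for p in profiles if p.condition == "KO"]
        out = mc.codon_occupancy_shift(wt, ko, tx, site="P")
        top5 = set(out.nlargest(5, "delta")["codon"])
        assert {"CUU", "CUC"} <= top5

    def test_mismatched_replicates_rejected(self, sim_bundle):
        tx, truth = sim_bundle["transcriptome"], sim_bundle["truth"]
        reads = mc.simulate_footprints(tx, truth, seed=47)
        profiles, _ = mc.apply_psite_offset(reads, tx)
        wt = [p for p in profiles if p.condition == "WT"]
        ko = [p for p in profiles if p.condition == "KO" and p.replicate == 1]
        with pytest.raises(ValueError, match="replicate sets"):
            mc.codon_occupancy_shift(wt, ko, tx)


class TestTranslationEfficiency:
    def matrices(self, rpf, rna):
        idx = [f"g{i}" for i in range(len(rpf))]
        cols = ["wt_1", "wt_2", "ko_1", "ko_2"]
        return (
            pd.DataFrame(rpf, index=idx, columns=cols),
            pd.DataFrame(rna, index=idx, columns=cols),
            {"wt_1": "WT", "wt_2": "WT", "ko_1": "KO", "ko_2": "KO"},
        )

    def test_equal_means_zero(self):
        rpf, rna, conds = self.matrices(
            np.full((5, 4), 100.0), np.full((5, 4), 100.0)
        )
        out = mc.translation_efficiency(rpf, rna, conds)
        assert np.allclose(out["log2_te_change"], 0.0)

    def test_halved_ko_rpf_gives_minus_one(self):
        # halve RPF_KO for a minority of genes so size factors stay at 1
        rpf = np.full((9, 4), 100.0)
        rpf[:2, 2:] = 50.0
        rna = np.full((9, 4), 100.0)
        rpf_df, rna_df, conds = self.matrices(rpf, rna)
        out = mc.translation_efficiency(rpf_df, rna_df, conds, pseudocount=0.0)
        assert np.allclose(out["log2_te_change"][:2], -1.0)
        assert np.allclose(out["log2_te_change"][2:], 0.0)

    def test_antisymmetric_under_condition_swap(self, rng):
        rpf = rng.integers(10, 500, (20, 4)).astype(float)
        rna = rng.integers(10, 500, (20, 4)).astype(float)
        rpf_df, rna_df, conds = self.matrices(rpf, rna)
        fwd = mc.translation_efficiency(rpf_df, rna_df, conds)
        rev = mc.translation_efficiency(rpf_df, rna_df, conds, ko="WT", wt="KO")
        assert np.allclose(
            fwd["log2_te_change"], -rev["log2_te_change"], atol=1e-12
        )

    def test_gene_mismatch_rejected(self):
        rpf_df, rna_df, conds = self.matrices(
            np.full((3, 4), 1.0), np.full((3, 4), 1.0)
        )
        with pytest.raises(ValueError, match="missing"):
            mc.translation_efficiency(rpf_df, rna_df.iloc[:2], conds)


def test_rolling_mean_truncates_at_edges():
    x = np.array([0.0, 0.0, 10.0, 0.0, 0.0])
    out = rolling_mean(x, 3)
    assert np.allclose(out, [0, 10 / 3, 10 / 3, 10 / 3, 0])
    assert rolling_mean(np.array([5.0]), 10)[0] == 5.0
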