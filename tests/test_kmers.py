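"""K-mer counting, class z-scores, multivalency and sliding windows."""

import numpy as np
import pandas as pd
import pytest

import multiclip as mc
from multiclip import kmers

from oracles import (
    brute_crosslinked_kmer_counts,
    brute_multivalency_score,
    brute_sliding_window_mean,
    brute_window_tc,
)


def tx_of(seq, len5=0, lencds=None, len3=0, tid="T1", gene="G1"):
    lencds = len(seq) - len5 - len3 if lencds is None else lencds
    return mc.TranscriptModel(tid, gene, seq, len5, lencds, len3)


def sites_of(pairs, tc=1.0):
    return pd.DataFrame(
        [{"transcript_id": t, "position": p, "tc": tc, "tcpm": tc} for t, p in pairs]
    )


class TestCountCrosslinkedKmers:
    def test_polyU_single_kmer(self):
        tx = {"T1": tx_of("T" * 30, lencds=30)}
        out = mc.count_crosslinked_kmers(sites_of([("T1", 10)]), tx, k=4)
        assert len(out) == 1
        assert out.iloc[0]["kmer"] == "UUUU"
        assert out.iloc[0]["frequency"] == 1.0
        assert out.iloc[0]["count"] == 4  # four overlapping windows

    def test_boundary_truncation_at_start(self):
        tx = {"T1": tx_of("ACGTACGTACGT", lencds=12)}
        out = mc.count_crosslinked_kmers(sites_of([("T1", 0)]), tx, k=4)
        assert out["count"].sum() == 1
        assert out.iloc[0]["kmer"] == "ACGU"

    def test_anchored_mode_single_register(self):
        tx = {"T1": tx_of("ACGTACGTACGT", lencds=12)}
        out = mc.count_crosslinked_kmers(sites_of([("T1", 4)]), tx, k=4, mode="anchored")
        assert out["count"].sum() == 1

    def test_k_out_of_range_rejected(self, sim_bundle):
        with pytest.raises(ValueError, match="k must be"):
            mc.count_crosslinked_kmers(
                sim_bundle["sites"], sim_bundle["transcriptome"], k=3
            )

    def test_matches_brute_force(self, sim_bundle):
        sites = sim_bundle["sites"].head(150)
        tx = sim_bundle["transcriptome"]
        out = mc.count_crosslinked_kmers(sites, tx, k=5)
        expected = brute_crosslinked_kmer_counts(
            sites, {t: m.sequence for t, m in tx.items()}, 5
        )
        got = {k.replace("U", "T"): c for k, c in zip(out["kmer"], out["count"])}
        assert got == expected
        assert np.isclose(out["frequency"].sum(), 1.0)


class TestKmerSignal:
    def test_normalization_arithmetic(self):
        # one site, TC 4, CDS length 100, TPM 2 -> 4/100/2 = 0.02
        tx = {"T1": tx_of("T" * 160, len5=30, lencds=99, len3=31)}
        sites = sites_of([("T1", 50)], tc=4.0)
        table, _ = mc.kmer_crosslink_signal(sites, tx, {"G1": 2.0})
        cds = table[table.region == "cds"]
        assert np.allclose(cds["signal"], 4 / 99 / 2.0)

    def test_doubling_tpm_halves_signal(self, sim_bundle):
        sites = sim_bundle["sites"].head(100)
        tx = sim_bundle["transcriptome"]
        tpm = sim_bundle["truth"].tpm()
        t1, _ = mc.kmer_crosslink_signal(sites, tx, tpm)
        t2, _ = mc.kmer_crosslink_signal(sites, tx, {g: 2 * v for g, v in tpm.items()})
        merged = t1.merge(t2, on=["gene_id", "region", "kmer"])
        assert np.allclose(merged["signal_x"], 2 * merged["signal_y"])

    def test_zero_tpm_gene_skipped(self):
        tx = {"T1": tx_of("T" * 60, lencds=60)}
        table, ranking = mc.kmer_crosslink_signal(sites_of([("T1", 10)]), tx, {"G1": 0.0})
        assert len(table) == 0 and len(ranking) == 0


class TestClassZscores:
    def test_identical_sets_all_zero(self):
        seqs = ["ACGTACGTTTTT", "CCCCGGGGTTTT"]
        df, _ = mc.kmer_class_zscores(seqs, list(seqs), k=4)
        assert np.allclose(df["delta_f"], 0.0)
        assert np.allclose(df["z"], 0.0)

    def test_enriched_kmer_has_max_z(self):
        base = "ACGGGCTTAACGGATC"
        enriched = base + "TCTT" * 4
        df, _ = mc.kmer_class_zscores([enriched] * 3, [base] * 3, k=4)
        assert df.loc[df["z"].idxmax(), "kmer"] == "UCUU"

    def test_zscores_standardized(self, sim_bundle):
        tx = sim_bundle["transcriptome"]
        mem = [m.region_sequence(mc.Region.CDS) for m in tx.values()
               if m.localization_class is mc.LocalizationClass.MEMBRANE]
        cyt = [m.region_sequence(mc.Region.CDS) for m in tx.values()
               if m.localization_class is mc.LocalizationClass.CYTOSOLIC]
        df, p = mc.kmer_class_zscores(mem, cyt, k=4, top_bound_set=["UCUU", "UUCU"])
        assert abs(df["z"].mean()) < 1e-9
        assert np.isclose(df["z"].std(ddof=0), 1.0)
        assert 0 <= p <= 1

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            mc.kmer_class_zscores([], ["ACGT"], k=4)


class TestMultivalency:
    GROUP = ["TTCT", "CTTC", "TCTT", "CTCT"]

    def test_no_nearby_occurrence_scores_zero(self):
        seq = "A" * 200
        tx = {"T1": tx_of(seq, lencds=0, len3=200)}
        rec, _ = mc.multivalency_scores(sites_of([("T1", 100)]), tx, self.GROUP)
        assert rec.iloc[0]["score"] == 0
        assert rec.iloc[0]["bin"] == 1

    def test_exclusion_zone_only_scores_zero(self):
        # occurrences only strictly inside (pos-4, pos+4) are excluded
        seq = "A" * 97 + "TTCT" + "A" * 99  # start 97, site at 100
        tx = {"T1": tx_of(seq, lencds=0, len3=200)}
        rec, _ = mc.multivalency_scores(sites_of([("T1", 100)]), tx, ["TTCT"])
        assert rec.iloc[0]["score"] == 0

    def test_occurrence_at_exact_boundary_counts(self):
        seq = "A" * 96 + "TTCT" + "A" * 100  # start 96 = pos - 4
        tx = {"T1": tx_of(seq, lencds=0, len3=200)}
        rec, _ = mc.multivalency_scores(sites_of([("T1", 100)]), tx, ["TTCT"])
        assert rec.iloc[0]["score"] == 1

    def test_matches_brute_force(self, sim_bundle):
        tx = sim_bundle["transcriptome"]
        sites = sim_bundle["sites"].head(300)
        rec, _ = mc.multivalency_scores(sites, tx, self.GROUP)
        group = set(self.GROUP)
        for row in rec.head(120).itertuples():
            seq = tx[row.transcript_id].sequence
            assert row.score == brute_multivalency_score(seq, row.position, group)
        for (tid,), grp in rec.groupby(["transcript_id"]):
            tx_sites = sites[sites.transcript_id == tid]
            for row in grp.head(5).itertuples():
                expected = brute_window_tc(
                    tx_sites["position"].to_numpy(),
                    tx_sites["tcpm"].to_numpy(),
                    row.position,
                )
                assert np.isclose(row.window_tc, expected)

    def test_bins_near_equal_and_profiles_sum_100(self, sim_bundle):
        rec, profiles = mc.multivalency_scores(
            sim_bundle["sites"], sim_bundle["transcriptome"], self.GROUP
        )
        sizes = rec["bin"].value_counts()
        assert sizes.max() - sizes.min() <= 1
        sums = profiles.sum(axis=1)
        assert np.allclose(sums, 100.0)

    def test_truncated_anchor_flagged(self):
        tx = {"T1": tx_of("A" * 100, lencds=0, len3=100)}
        rec, _ = mc.multivalency_scores(sites_of([("T1", 10), ("T1", 50)]), tx, ["TTCT"])
        assert rec.set_index("position")["truncated"].to_dict() == {10: True, 50: False}

    def test_empty_group_rejected(self, sim_bundle):
        with pytest.raises(ValueError, match="non-empty"):
            mc.multivalency_scores(
                sim_bundle["sites"], sim_bundle["transcriptome"], []
            )


class TestSlidingWindow:
    def test_window_below_min_count_discarded(self):
        # exactly 2 occurrences in the whole sequence -> all windows dropped
        seq = "TTCT" + "A" * 22 + "TTCT" + "A" * 30
        tx = {"T1": tx_of(seq, lencds=0, len3=len(seq))}
        out = mc.sliding_window_potential(tx, ["TTCT"], window=30, min_count=3,
                                          regions=(mc.Region.UTR3,))
        assert out.iloc[0]["mean_score"] == 0.0
        assert out.iloc[0]["n_kept"] == 0

    def test_tandem_repeats_match_brute_force(self):
        seq = "TTCT" * 20
        tx = {"T1": tx_of(seq, lencds=0, len3=len(seq))}
        out = mc.sliding_window_potential(tx, ["TTCT"], regions=(mc.Region.UTR3,))
        expected = brute_sliding_window_mean(seq, {"TTCT"})
        assert out.iloc[0]["mean_score"] == pytest.approx(expected)
        assert out.iloc[0]["n_kept"] == len(seq) - 30 + 1

    def test_absent_group_scores_zero(self):
        tx = {"T1": tx_of("A" * 90, lencds=90)}
        out = mc.sliding_window_potential(tx, ["TTCT"], regions=(mc.Region.CDS,))
        assert out.iloc[0]["mean_score"] == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_random_sequences_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), 300))
        lencds = 150
        tx = {"T1": tx_of(seq, len5=0, lencds=lencds, len3=150)}
        group = {"TTCT", "CTTC", "TCTT", "CTCT"}
        out = mc.sliding_window_potential(tx, sorted(group))
        for region, sub in (("cds", seq[:150]), ("utr3", seq[150:])):
            got = out[out.region == region].iloc[0]["mean_score"]
            assert got == pytest.approx(brute_sliding_window_mean(sub, group))


def test_occurrence_positions_counts_overlaps():
    # overlapping occurrences each count: TTTT contains TTCT? no; use TTTT x2
    assert kmers.occurrence_positions("TTTTT", ["TTTT"]).tolist() == [0, 1]
    with pytest.raises(ValueError, match="equal length"):
        kmers.occurrence_positions("ACGT", ["AC", "ACG"])
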