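"""Generator contracts: determinism, planted truth, conversion limits."""

import numpy as np
import pytest
from scipy import stats

from m5ckit import simulate
from m5ckit.simulate import (
    AssocEffect,
    SimConfig,
    Transcript,
    assign_truth,
    bisulfite_reads,
    clone_sequences,
    make_transcriptome,
    simulate_assoc_tables,
)


class TestTranscriptome:
    def test_counts_and_spikein_flags(self):
        txs = make_transcriptome(2, length=500, gc_fraction=0.5, n_spikeins=2, seed=7)
        assert len(txs) == 4
        assert sum(t.is_spikein for t in txs) == 2

    def test_seeded_determinism(self):
        a = make_transcriptome(3, 400, 0.5, 1, seed=7)
        b = make_transcriptome(3, 400, 0.5, 1, seed=7)
        assert [t.sequence for t in a] == [t.sequence for t in b]
        c = make_transcriptome(3, 400, 0.5, 1, seed=8)
        assert [t.sequence for t in a] != [t.sequence for t in c]

    def test_gc_boundary(self):
        txs = make_transcriptome(2, 300, gc_fraction=1.0, n_spikeins=0, seed=1)
        for t in txs:
            assert set(t.sequence) <= {"G", "C"}

    @pytest.mark.parametrize("kwargs", [
        {"n_transcripts": 0}, {"length": 0}, {"gc_fraction": 1.5},
    ])
    def test_invalid_arguments(self, kwargs):
        args = {"n_transcripts": 2, "length": 100, "gc_fraction": 0.5,
                "n_spikeins": 0, "seed": 0}
        args.update(kwargs)
        with pytest.raises(ValueError):
            make_transcriptome(**args)

    def test_transcript_alphabet_enforced(self):
        with pytest.raises(ValueError):
            Transcript("bad", "ACGU")
        with pytest.raises(ValueError):
            Transcript("empty", "")


class TestTruth:
    def test_storage_contract(self):
        tx = Transcript("tx1", "A" * 1323 + "C" + "A" * 200)
        truth = assign_truth([tx], sites=[("tx1", 1323, (0.0, 0.8))])
        assert truth.level("tx1", 1323, "EV") == 0.0
        assert truth.level("tx1", 1323, "NSUN7") == 0.8
        assert truth.level("tx1", 5, "NSUN7") == 0.0  # unplanted default

    def test_non_c_position_rejected(self):
        tx = Transcript("tx1", "ACGT")
        with pytest.raises(ValueError, match="tx1:0"):
            assign_truth([tx], sites=[("tx1", 0, (0.5, 0.5))])

    def test_spikein_rejected(self):
        spike = Transcript("sp1", "CCCC", is_spikein=True)
        with pytest.raises(ValueError, match="spike-in"):
            assign_truth([spike], sites=[("sp1", 0, (0.5, 0.5))])

    def test_random_placement_deterministic(self, transcriptome):
        kw = dict(n_random=10, random_levels={"EV": 0.1, "NSUN7": 0.9}, seed=3)
        t1 = assign_truth(transcriptome, **kw)
        t2 = assign_truth(transcriptome, **kw)
        assert t1.entries == t2.entries
        assert len(t1.entries) == 10

    def test_cluster_planting(self):
        tx = Transcript("tx1", "ATGCCCGTA")
        runs = simulate.find_c_runs(tx)
        assert runs == [3]
        truth = simulate.MethylTruth()
        pos = simulate.plant_cluster(truth, tx, 3, {"EV": 0.0, "NSUN7": 0.8})
        assert pos == [3, 4, 5]
        assert all(truth.level("tx1", p, "NSUN7") == 0.8 for p in pos)


def _site_counts(reads, tx_id, pos):
    c = t = 0
    for r in reads:
        origin = simulate.SimRead.parse_id(r.id)
        if origin["transcript_id"] != tx_id:
            continue
        off = pos - origin["start"]
        if 0 <= off < len(r.sequence):
            b = r.sequence[off]
            c += b == "C"
            t += b == "T"
    return c, t


class TestBisulfiteReads:
    def test_fully_converted_limit(self, transcriptome):
        cfg = SimConfig(conversion_efficiency=1.0, seq_error_rate=0.0, mean_depth=10)
        truth = assign_truth(transcriptome)
        reads = bisulfite_reads(transcriptome, truth, cfg, "EV", 0)
        by_id = {t.id: t for t in transcriptome}
        for r in reads[:200]:
            origin = simulate.SimRead.parse_id(r.id)
            ref = by_id[origin["transcript_id"]].sequence
            for i, b in enumerate(r.sequence):
                if ref[origin["start"] + i] == "C":
                    assert b == "T"

    def test_fully_methylated_limit(self):
        tx = Transcript("tx1", "ATGA" * 40 + "C" + "ATGA" * 40)
        truth = assign_truth([tx], sites=[("tx1", 160, (1.0, 1.0))])
        cfg = SimConfig(conversion_efficiency=1.0, seq_error_rate=0.0,
                        mean_depth=50, read_length=80)
        reads = bisulfite_reads([tx], truth, cfg, "EV", 0)
        c, t = _site_counts(reads, "tx1", 160)
        assert t == 0 and c > 0

    def test_incomplete_conversion_binomial_mean(self):
        # expected non-conversion = m + (1-m)(1-e) = 0.5 + 0.5*0.01 = 0.505
        tx = Transcript("tx1", "ATGA" * 40 + "C" + "ATGA" * 40)
        truth = assign_truth([tx], sites=[("tx1", 160, (0.5, 0.5))])
        cfg = SimConfig(conversion_efficiency=0.99, seq_error_rate=0.0,
                        mean_depth=1200, read_length=80)
        reads = bisulfite_reads([tx], truth, cfg, "EV", 0)
        c, t = _site_counts(reads, "tx1", 160)
        assert c + t >= 1000
        m_hat = c / (c + t)
        sigma = np.sqrt(0.505 * 0.495 / (c + t))
        assert abs(m_hat - 0.505) < max(4 * sigma, 1e-9)
        assert abs(m_hat - 0.505) < 0.05

    def test_conversion_algebra_with_overconversion(self):
        # expected observed level = m(1 - over) + (1-m)(1-e)
        tx = Transcript("tx1", "ATGA" * 40 + "C" + "ATGA" * 40)
        truth = assign_truth([tx], sites=[("tx1", 160, (0.6, 0.6))])
        cfg = SimConfig(conversion_efficiency=0.95, overconversion_rate=0.1,
                        seq_error_rate=0.0, mean_depth=2000, read_length=80)
        reads = bisulfite_reads([tx], truth, cfg, "EV", 0)
        c, t = _site_counts(reads, "tx1", 160)
        expect = 0.6 * 0.9 + 0.4 * 0.05
        sigma = np.sqrt(expect * (1 - expect) / (c + t))
        assert abs(c / (c + t) - expect) < 4 * sigma

    def test_spikein_purity(self, transcriptome):
        cfg = SimConfig(conversion_efficiency=1.0, seq_error_rate=0.0, mean_depth=20)
        truth = assign_truth(transcriptome)
        reads = bisulfite_reads(transcriptome, truth, cfg, "NSUN7", 1)
        spikes = {t.id: t for t in transcriptome if t.is_spikein}
        seen = 0
        for r in reads:
            origin = simulate.SimRead.parse_id(r.id)
            if origin["transcript_id"] not in spikes:
                continue
            seen += 1
            ref = spikes[origin["transcript_id"]].sequence
            for i, b in enumerate(r.sequence):
                if ref[origin["start"] + i] == "C":
                    assert b == "T"
        assert seen > 0

    def test_read_count_and_determinism(self, transcriptome, cluster_truth):
        txs, truth, _, _ = cluster_truth
        cfg = SimConfig(mean_depth=30, read_length=100, seed=11)
        a = bisulfite_reads(txs, truth, cfg, "EV", 0)
        b = bisulfite_reads(txs, truth, cfg, "EV", 0)
        assert [(r.id, r.sequence) for r in a] == [(r.id, r.sequence) for r in b]
        expected = sum(round(30 * len(t) / 100) for t in txs)
        assert len(a) == expected
        # replicate sub-streams differ
        other = bisulfite_reads(txs, truth, cfg, "EV", 1)
        assert [r.sequence for r in a] != [r.sequence for r in other]

    def test_short_transcript_skipped(self, caplog):
        tx = Transcript("short", "ACGT")
        cfg = SimConfig(read_length=100)
        reads = bisulfite_reads([tx], simulate.MethylTruth(), cfg, "EV", 0)
        assert reads == []

    def test_bad_replicate_index(self, transcriptome):
        cfg = SimConfig(n_replicates=2)
        with pytest.raises(ValueError):
            bisulfite_reads(transcriptome, simulate.MethylTruth(), cfg, "EV", 2)


class TestCloneSequences:
    REF = "AT" + "GCA" * 30 + "CCC" + "TAG" * 10

    def test_clean_conversion_limits(self):
        cs = clone_sequences(self.REF, "rna-anyc", None, 6, 0.0,
                             e_good=1.0, e_bad=0.5, seed=1)
        for clone in cs.clones:
            assert "C" not in clone
        meth = {i: 1.0 for i, b in enumerate(self.REF) if b == "C"}
        cs = clone_sequences(self.REF, "rna-anyc", meth, 6, 0.0,
                             e_good=1.0, e_bad=0.5, seed=1)
        assert all(clone == self.REF for clone in cs.clones)

    def test_incomplete_fraction_rounding(self):
        cs = clone_sequences(self.REF, "rna-anyc", None, 12, 0.25,
                             e_good=1.0, e_bad=0.7, seed=2)
        assert sum(cs.incomplete_flags) == 3

    def test_e_ordering_enforced(self):
        with pytest.raises(ValueError):
            clone_sequences(self.REF, "rna-anyc", None, 4, 0.5,
                            e_good=0.7, e_bad=0.9, seed=0)


class TestAssocTables:
    def test_determinism_and_shapes(self):
        a = simulate_assoc_tables(30, seed=4)
        b = simulate_assoc_tables(30, seed=4)
        assert a["samples"].equals(b["samples"])
        assert a["beta"].equals(b["beta"])
        assert len(a["samples"]) == 30

    def test_null_effect_groups_overlap(self):
        null = AssocEffect(beta_methylated=0.4, beta_unmethylated=0.4,
                           expr_methylated=0.0, expr_unmethylated=0.0)
        tab = simulate_assoc_tables(100, null, seed=5)["samples"]
        g = tab.groupby("group")["expression"].mean()
        assert abs(g["methylated"] - g["unmethylated"]) < 0.5

    def test_strong_effect_yields_negative_spearman(self):
        # beta 0.8 vs 0.1 (sd 0.05) at n=50: rho(beta, expression) < 0
        # in at least 95% of seeds
        eff = AssocEffect(beta_methylated=0.8, beta_unmethylated=0.1, beta_sd=0.05)
        hits = 0
        for seed in range(200):
            tab = simulate_assoc_tables(50, eff, seed=seed)["samples"]
            rho = stats.spearmanr(tab["mean_beta"], tab["expression"])[0]
            hits += rho < 0
        assert hits >= 190
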