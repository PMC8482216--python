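"""The generator must plant what it claims: class-conformant sequences,
threshold-respecting depths, controllable expression correlation."""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
import pytest

from snoscout.host_link import pearson
from snoscout.synthetic_data import (
    ConfigError,
    generate_genome,
    simulate_dataset,
    simulate_expression,
    simulate_reads,
)
from tests.conftest import small_sim_config

# independent motif oracles: plain regular expressions, not the scanner
C_BOX_RE = re.compile("[AG]TGATGA".replace("T", "U"))
D_BOX_RE = re.compile("CUGA")
H_BOX_RE = re.compile("A[ACGU]A[ACGU][ACGU]A")


class TestGenerateGenome:
    def test_deterministic_given_seed(self, tmp_path):
        a = simulate_dataset(small_sim_config(seed=5), tmp_path / "a")
        b = simulate_dataset(small_sim_config(seed=5), tmp_path / "b")
        for key in ("genome", "annotation", "truth_loci", "medium_alignments",
                    "candidate_counts"):
            assert a[key].read_bytes() == b[key].read_bytes(), key

    def test_planted_class_counts(self, small_dataset):
        classes = [l.sno_class for l in small_dataset.loci]
        assert classes.count("CD") == 3
        assert classes.count("HACA") == 3
        assert classes.count("SCA") == 3
        assert classes.count("decoy") == 3

    def test_cd_sequences_satisfy_box_architecture(self, small_dataset):
        for locus in small_dataset.loci:
            if locus.sno_class != "CD":
                continue
            m = C_BOX_RE.search(locus.sequence[:12])
            assert m is not None and 2 <= m.start() <= 10
            assert D_BOX_RE.search(locus.sequence[-10:]) is not None

    def test_haca_sequences_pass_regex_oracle(self, small_dataset):
        """Every planted H/ACA (and H/ACA-flavoured scaRNA) sequence carries
        an H box in its interior and ACA exactly 3 nt from the 3' end."""
        checked = 0
        for locus in small_dataset.loci:
            if locus.sno_class not in ("HACA", "SCA"):
                continue
            seq = locus.sequence
            if locus.sno_class == "SCA" and seq[-6:-3] != "ACA":
                continue  # C/D-flavoured scaRNA
            assert seq[-6:-3] == "ACA"
            assert H_BOX_RE.search(seq[len(seq) // 4 : -6]) is not None
            checked += 1
        assert checked >= 3

    def test_genome_carries_planted_sequences(self, small_dataset):
        from snoscout.io import reverse_complement

        contig = small_dataset.config.contig
        genome = small_dataset.genome[contig]
        for locus in small_dataset.loci:
            if not locus.sequence:
                continue
            sub = genome[locus.interval.start : locus.interval.end]
            if locus.interval.strand == "-":
                sub = reverse_complement(sub)
            assert sub.replace("T", "U") == locus.sequence

    def test_intronic_loci_inside_introns(self, small_dataset):
        introns = [f.interval for f in small_dataset.features if f.feature_class == "iR"]
        for locus in small_dataset.loci:
            if locus.context == "intronic" and locus.sno_class != "decoy":
                assert any(
                    i.start + 30 <= locus.interval.start and locus.interval.end <= i.end - 30
                    for i in introns
                )

    @pytest.mark.parametrize(
        "kw,msg",
        [
            ({"insert_size_range": (200, 50)}, "insert_size_range"),
            ({"n_intergenic": 99}, "n_intergenic"),
            ({"n_tu_hosted": 5, "n_intergenic": 2}, "n_tu_hosted"),
            ({"genome_length": 5_000}, "genome_length"),
            ({"n_genes": 1}, "intron slots"),
        ],
    )
    def test_invalid_configs_name_the_constraint(self, kw, msg):
        cfg = small_sim_config()
        for k, v in kw.items():
            setattr(cfg, k, v)
        with pytest.raises(ConfigError, match=msg):
            generate_genome(cfg)


class TestSimulateReads:
    def test_planted_above_and_decoys_below_threshold(self, small_dataset):
        reads, depths = simulate_reads(small_dataset)
        for locus in small_dataset.loci:
            if locus.sno_class == "decoy":
                assert depths[locus.locus_id] < 20
            else:
                assert depths[locus.locus_id] >= 20

    def test_every_read_inside_genome(self, small_dataset):
        reads, _ = simulate_reads(small_dataset)
        glen = len(small_dataset.genome[small_dataset.config.contig])
        for r in reads:
            assert 0 <= r.start and r.end <= glen

    def test_read_lengths_follow_clipped_jitter_model(self):
        """Mean read length over a deep pileup sits within +-2 nt of the locus
        length: the end jitter is symmetric and no planted locus is close
        enough to the insert-size bounds for clipping to bite."""
        cfg = small_sim_config(seed=3)
        cfg.reads_per_locus_mean = 400.0
        ds = generate_genome(cfg)
        reads, _ = simulate_reads(ds)
        by_locus = {l.locus_id: l for l in ds.loci if l.sno_class != "decoy"}
        for locus in by_locus.values():
            lens = [r.end - r.start for r in reads
                    if r.read_id.startswith(f"m_{locus.locus_id}_")]
            assert len(lens) >= 100
            assert abs(np.mean(lens) - len(locus.interval)) <= 2

    def test_zero_mean_depth_yields_no_locus_reads(self):
        cfg = small_sim_config(seed=6)
        cfg.reads_per_locus_mean = 0.0
        cfg.n_decoys = 0
        cfg.background_reads = 0
        cfg.known_sncrna_reads = 0
        reads, depths = simulate_reads(generate_genome(cfg))
        assert reads == []
        assert all(v == 0 for v in depths.values())

    def test_insert_size_window_enforced(self, small_dataset):
        reads, _ = simulate_reads(small_dataset)
        lo, hi = small_dataset.config.insert_size_range
        for r in reads:
            if r.read_id.startswith(("m_", "k_")):
                assert lo <= r.aligned_length <= hi


class TestSimulateExpression:
    def test_perfect_correlation_is_degenerate(self):
        c, h = simulate_expression([("c1", "g1")], 1.0, 10, seed=1)
        r = pearson(c.loc["c1"].to_numpy(), h.loc["g1"].to_numpy())
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_rejects_out_of_range_target(self):
        with pytest.raises(ValueError):
            simulate_expression([("c", "g")], 1.5, 10, seed=0)

    @pytest.mark.parametrize("r_target,tol", [(0.0, 0.02), (0.9, 0.05)])
    def test_mean_recovered_r(self, r_target, tol):
        root = np.random.default_rng(20_000)
        seeds = root.integers(0, 2**31 - 1, size=600)
        rs = []
        for s in seeds:
            c, h = simulate_expression([("c", "g")], r_target, 12, seed=int(s))
            rs.append(pearson(c.iloc[0].to_numpy(), h.iloc[0].to_numpy()))
        assert abs(float(np.mean(rs)) - r_target) <= tol

    def test_shared_host_pairs_each_hit_target(self):
        """Several snoRNAs in introns of one gene share the host vector but
        every pair still carries the target correlation."""
        pairs = [(f"c{i}", "g1") for i in range(3)]
        rs = {p[0]: [] for p in pairs}
        root = np.random.default_rng(77)
        for s in root.integers(0, 2**31 - 1, size=300):
            c, h = simulate_expression(pairs, 0.6, 12, seed=int(s))
            for cid, _ in pairs:
                rs[cid].append(pearson(c.loc[cid].to_numpy(), h.loc["g1"].to_numpy()))
        for cid, vals in rs.items():
            assert abs(float(np.mean(vals)) - 0.6) < 0.06


def test_truth_table_depths_match_alignment_file(small_paths):
    truth = pd.read_csv(small_paths["truth_loci"], sep="\t")
    aln = pd.read_csv(small_paths["medium_alignments"], sep="\t")
    for _, row in truth.iterrows():
        n = aln.read_id.str.startswith(f"m_{row.locus_id}_").sum()
        assert n == row.simulated_reads
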