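"""Generator contracts: toy tree shape, panel structure, library statistics."""

import math

import numpy as np
import pytest

from sedaprof.preprocess import reads_from_fastq
from sedaprof.simulate import (
    SimConfig,
    make_reference_panel,
    make_toy_taxonomy,
    parse_fasta,
    revcomp,
    simulate_library,
)


class TestToyTaxonomy:
    def test_required_clades_and_sizes(self, tree):
        vert = tree.find_name("Vertebrata")
        species_below = [
            t
            for t in tree
            if tree.rank(t) == "species" and vert in tree.path_to_root(t)
        ]
        assert len(species_below) >= 8
        families = [
            t
            for t in tree
            if tree.rank(t) == "family" and vert in tree.path_to_root(t)
        ]
        assert len(families) >= 4
        genera = [
            t
            for t in tree
            if tree.rank(t) == "genus" and vert in tree.path_to_root(t)
        ]
        assert len(genera) >= 6
        assert any(tree.rank(t) == "subspecies" for t in tree)
        for fam in ("Taeniidae", "Toxocaridae"):
            fam_id = tree.find_name(fam)
            n_sp = sum(
                1
                for t in tree
                if tree.rank(t) == "species" and fam_id in tree.path_to_root(t)
            )
            assert n_sp >= 2

    def test_lca_of_congenerics_forced_by_construction(self, tree, taxid_of):
        assert (
            tree.lca({taxid_of("Toxocara canis"), taxid_of("Toxocara cati")})
            == taxid_of("Toxocara")
        )


class TestReferencePanel:
    def test_one_record_per_leaf(self, tree, panel_bundle):
        fasta, acc_map, seqs = panel_bundle
        assert len(acc_map) == len(tree.leaves())
        assert set(acc_map.values()) == set(tree.leaves())
        assert all(len(s) == 1000 for s in seqs.values())

    def test_determinism(self, tree):
        a, _ = make_reference_panel(tree, seq_len=500, seed=3)
        b, _ = make_reference_panel(tree, seq_len=500, seed=3)
        assert a == b

    def test_pairwise_distinguishable(self, panel_bundle):
        _, _, seqs = panel_bundle
        accs = sorted(seqs)
        for i, a in enumerate(accs):
            for b in accs[i + 1 :]:
                d = sum(x != y for x, y in zip(seqs[a], seqs[b]))
                assert d >= 100  # 10% of 1000

    def test_congeneric_pair_shares_a_50mer(self, tree, panel_bundle):
        _, acc_map, seqs = panel_bundle
        taxid_to_acc = {t: a for a, t in acc_map.items()}
        s1 = seqs[taxid_to_acc[tree.find_name("Taenia hydatigena")]]
        s2 = seqs[taxid_to_acc[tree.find_name("Taenia multiceps")]]
        kmers = {s1[i : i + 50] for i in range(len(s1) - 49)}
        assert any(s2[i : i + 50] in kmers for i in range(len(s2) - 49))

    def test_seq_len_floor(self, tree):
        with pytest.raises(ValueError):
            make_reference_panel(tree, seq_len=100, seed=0)


class TestSimulateLibrary:
    def test_empty_library(self, panel_bundle):
        fasta, acc_map, _ = panel_bundle
        cfg = SimConfig(seed=0, n_reads=0, mixture={50: 1.0})
        fastq, truth = simulate_library(cfg, fasta, acc_map)
        assert fastq == "" and truth == []

    def test_noise_free_reads_are_reference_substrings(self, panel_bundle):
        fasta, acc_map, seqs = panel_bundle
        cfg = SimConfig(seed=5, n_reads=300, mixture={50: 0.5, 54: 0.5})
        fastq, truth = simulate_library(cfg, fasta, acc_map)
        reads = {r.read_id: r.sequence for r in reads_from_fastq(fastq)}
        for row in truth:
            ref = seqs[row.source_accession]
            seq = reads[row.read_id]
            frag = seq if row.strand == "+" else revcomp(seq)
            assert ref[row.ref_start : row.ref_start + len(seq)] == frag

    def test_determinism(self, panel_bundle):
        fasta, acc_map, _ = panel_bundle
        cfg = SimConfig(seed=9, n_reads=200, mixture={50: 1.0},
                        damage_d1=0.1, seq_error=0.01, dup_frac=0.1,
                        lowcomplex_frac=0.05)
        out1 = simulate_library(cfg, fasta, acc_map)
        out2 = simulate_library(cfg, fasta, acc_map)
        assert out1 == out2

    def test_damage_rate_matches_binomial_oracle(self, panel_bundle):
        fasta, acc_map, seqs = panel_bundle
        d1 = 0.1
        cfg = SimConfig(seed=13, n_reads=20_000, mixture={50: 1.0}, damage_d1=d1)
        fastq, truth = simulate_library(cfg, fasta, acc_map)
        reads = {r.read_id: r.sequence for r in reads_from_fastq(fastq)}
        n_c = n_t = 0
        for row in truth:
            ref = seqs[row.source_accession]
            L = len(reads[row.read_id])
            ref_base = (
                ref[row.ref_start]
                if row.strand == "+"
                else revcomp(ref[row.ref_start + L - 1])
            )
            if ref_base == "C":
                n_c += 1
                n_t += reads[row.read_id][0] == "T"
        se = math.sqrt(d1 * (1 - d1) / n_c)
        assert abs(n_t / n_c - d1) <= 3 * se

    def test_damage_monotone_in_position(self, panel_bundle):
        fasta, acc_map, _ = panel_bundle
        cfg = SimConfig(seed=21, n_reads=20_000, mixture={50: 1.0},
                        damage_d1=0.3, damage_decay=0.5)
        _, truth = simulate_library(cfg, fasta, acc_map)
        counts = np.zeros(4)
        for row in truth:
            for p in row.damaged_positions:
                if p <= 4:
                    counts[p - 1] += 1
        assert counts[0] > counts[1] > counts[2]

    def test_mixture_recovery(self, panel_bundle):
        fasta, acc_map, _ = panel_bundle
        mixture = {50: 0.6, 54: 0.3, 52: 0.1}
        n = 10_000
        cfg = SimConfig(seed=3, n_reads=n, mixture=mixture)
        _, truth = simulate_library(cfg, fasta, acc_map)
        freqs = {t: 0 for t in mixture}
        for row in truth:
            freqs[row.source_taxid] += 1
        for taxid, p in mixture.items():
            se = math.sqrt(p * (1 - p) / n)
            assert abs(freqs[taxid] / n - p) <= 3 * se

    def test_duplicate_and_contaminant_budget(self, panel_bundle):
        fasta, acc_map, _ = panel_bundle
        cfg = SimConfig(seed=1, n_reads=1000, mixture={50: 1.0},
                        dup_frac=0.2, lowcomplex_frac=0.1)
        fastq, truth = simulate_library(cfg, fasta, acc_map)
        reads = reads_from_fastq(fastq)
        assert len(reads) == 1000
        assert len(truth) == 900  # contaminants carry no truth rows
        assert sum(1 for r in reads if r.read_id.startswith("dup_")) == 200

    def test_mixture_taxid_absent_from_panel(self, panel_bundle):
        fasta, acc_map, _ = panel_bundle
        cfg = SimConfig(seed=0, n_reads=10, mixture={424242: 1.0})
        with pytest.raises(ValueError, match="424242"):
            simulate_library(cfg, fasta, acc_map)

    @pytest.mark.parametrize(
        "field,value",
        [("mixture", {50: 0.5, 54: 0.4}), ("damage_d1", 1.5),
         ("dup_frac", -0.1), ("n_reads", -1)],
    )
    def test_config_validation(self, field, value):
        kwargs = dict(seed=0, n_reads=10, mixture={50: 1.0})
        kwargs[field] = value
        with pytest.raises(ValueError):
            SimConfig(**kwargs)
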