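import math

import numpy as np
import pytest

from isopipe import io_formats as io
from isopipe.snps import pileup_matrix
from isopipe.syndata import (
    ConfigurationError,
    SimConfig,
    generate_assemblies,
    generate_assembly,
    generate_counts,
    generate_hit_table,
    generate_isotigs,
    generate_reference_panel,
)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_genes=0)
        with pytest.raises(ConfigurationError):
            SimConfig(novel_insert_len_range=(40, 100))
        with pytest.raises(ConfigurationError):
            SimConfig(library_weights=(0, 0, 0, 0))
        with pytest.raises(ConfigurationError):
            SimConfig(frac_novel_isotigs=1.5)


class TestReferencePanel:
    def test_zero_divergence_gives_identical_transcripts(self):
        cfg = SimConfig(seed=3, n_genes=1, substitution_divergence=0.0,
                        frac_species_dropout=0, frac_group_reassign=0,
                        frac_category1=0)
        panel = generate_reference_panel(cfg)
        seqs = {m.species: m.transcript_seq for m in panel.models}
        assert len(set(seqs.values())) == 1
        groups = {panel.orthology.group_of(m.species, m.gene_id) for m in panel.models}
        assert len(groups) == 1

    def test_same_seed_is_byte_identical(self, tmp_path):
        cfg = SimConfig(seed=9, n_genes=5)
        outs = []
        for run in range(2):
            panel = generate_reference_panel(cfg)
            fa = tmp_path / f"t{run}.fasta"
            gff = tmp_path / f"m{run}.gff3"
            io.write_fasta({m.transcript_id: m.transcript_seq for m in panel.models}, fa)
            io.write_gff3(panel.models, gff)
            outs.append(fa.read_bytes() + gff.read_bytes())
        assert outs[0] == outs[1]

    def test_pairwise_identity_matches_divergence(self):
        cfg = SimConfig(seed=5, n_genes=100, substitution_divergence=0.05,
                        frac_species_dropout=0, frac_group_reassign=0,
                        frac_category1=0)
        panel = generate_reference_panel(cfg)
        by_core = {}
        for m in panel.models:
            by_core.setdefault(m.gene_id.rsplit("_", 1)[0], []).append(m)
        idents = []
        for group in by_core.values():
            for i in range(len(group)):
                for j in range(i + 1, len(group)):
                    a, b = group[i].transcript_seq, group[j].transcript_seq
                    idents.append(sum(x == y for x, y in zip(a, b)) / len(a))
        assert abs(np.mean(idents) - 0.95) < 0.01

    def test_exons_tile_transcript_and_cds_inside(self, small_panel):
        for m in small_panel.models:
            assert sum(e - s for s, e in m.exons) == m.transcript_len
            s, e = m.cds_on_transcript
            assert 0 <= s < e <= m.transcript_len
            assert (e - s) % 3 == 0
            assert m.transcript_seq[s:s + 3] == "ATG"
            assert m.transcript_seq[e - 3:e] in ("TAA", "TAG", "TGA")

    def test_genome_exons_carry_transcript_sequence(self, small_panel):
        for m in small_panel.models:
            genome = small_panel.genomes[m.species][m.chrom]
            rebuilt = "".join(genome[s:e] for s, e in m.exons)
            assert rebuilt == m.transcript_seq


class TestIsotigs:
    def test_no_novel_fraction_plants_no_regions(self, small_panel):
        cfg = SimConfig(seed=1, n_genes=12, frac_novel_isotigs=0.0)
        _, truth = generate_isotigs(small_panel, cfg)
        assert truth.planted_novel_regions == []

    def test_planted_features_verify_against_sequences(self, small_panel, small_cfg):
        records, truth = generate_isotigs(small_panel, small_cfg)
        seqs = {r.isotig_id: r.seq for r in records}
        for s in truth.planted_snps:
            assert seqs[s.isotig_id][s.position] == s.ref_allele
            assert s.alt_allele != s.ref_allele
        models = {m.transcript_id: m for m in small_panel.models}
        for r in truth.planted_novel_regions:
            assert r.length >= 50
            insert = seqs[r.isotig_id][r.start:r.end]
            # inserts never appear in any reference transcript
            for m in models.values():
                assert insert not in m.transcript_seq

    def test_snp_count_tracks_poisson_expectation(self, small_panel):
        cfg = SimConfig(seed=77, n_genes=50, snp_rate=2.0,
                        frac_novel_isotigs=0, frac_splice_variants=0)
        panel = generate_reference_panel(cfg)
        records, truth = generate_isotigs(panel, cfg)
        expected = sum(len(r.seq) for r in records) * 2.0 / 1000.0
        n = len(truth.planted_snps)
        assert abs(n - expected) <= 3 * math.sqrt(expected)

    def test_splice_variants_share_gene(self, small_panel):
        cfg = SimConfig(seed=4, n_genes=12, frac_splice_variants=1.0)
        records, truth = generate_isotigs(small_panel, cfg)
        per_gene = {}
        for r in records:
            per_gene.setdefault(r.gene_core, []).append(r)
        multi = [g for g in per_gene.values() if len(g) >= 2]
        assert multi, "expected at least one gene with two isotigs"
        for group in multi:
            subsets = {tuple(seg[2:] for seg in r.segments) for r in group}
            assert len(subsets) == len(group)  # different exon subsets


class TestAssembly:
    def _one_snp_record(self, small_isotigs):
        records, truth = small_isotigs
        by_iso = {}
        for s in truth.planted_snps:
            by_iso.setdefault(s.isotig_id, []).append(s)
        iso = next(i for i in by_iso if by_iso[i])
        rec = next(r for r in records if r.isotig_id == iso)
        return rec, by_iso[iso]

    def test_alt_allele_count_is_rounded_fraction_of_coverage(self, small_panel):
        cfg = SimConfig(seed=2, n_genes=3, depth_range=(10, 10),
                        minor_allele_frac_range=(0.4, 0.4), read_len=100)
        records, truth = generate_isotigs(small_panel, cfg)
        assemblies = generate_assemblies(records, truth, cfg)
        mats = {a.isotig_id: (a, pileup_matrix(a)) for a in assemblies}
        checked = 0
        for s in truth.planted_snps:
            asm, mat = mats[s.isotig_id]
            alt_count = mat["ACGT".index(s.alt_allele), s.position]
            assert alt_count == int(math.floor(0.4 * s.true_depth + 0.5))
            assert s.true_depth == int(mat[:, s.position].sum())
            checked += 1
        assert checked > 0

    def test_zero_n_rate_means_no_ambiguous_bases(self, small_isotigs, small_cfg):
        records, truth = small_isotigs
        assemblies = generate_assemblies(records, truth, small_cfg)
        assert all("N" not in r.seq for a in assemblies for r in a.reads)

    def test_seeded_ace_output_is_identical(self, tmp_path, small_panel, small_cfg):
        outs = []
        for run in range(2):
            records, truth = generate_isotigs(small_panel, small_cfg)
            assemblies = generate_assemblies(records, truth, small_cfg)
            p = tmp_path / f"a{run}.ace"
            io.write_ace(assemblies, p)
            outs.append(p.read_bytes())
        assert outs[0] == outs[1]

    def test_reads_fit_consensus_and_carry_valid_tags(self, small_isotigs, small_cfg):
        records, truth = small_isotigs
        for asm in generate_assemblies(records, truth, small_cfg):
            asm.validate()


class TestHitTable:
    def test_single_exon_identical_isotig_gives_one_full_hsp(self):
        cfg = SimConfig(seed=8, n_genes=1, n_exons_range=(1, 1),
                        substitution_divergence=0.0, frac_novel_isotigs=0,
                        frac_splice_variants=0, frac_species_dropout=0,
                        frac_group_reassign=0, frac_category1=0, frac_decoy=0)
        panel = generate_reference_panel(cfg)
        records, truth = generate_isotigs(panel, cfg)
        hsps, chain_truth = generate_hit_table(records, panel, cfg)
        rec = records[0]
        mine = [h for h in hsps if h.target_id == rec.source_transcript]
        assert len(mine) == 1
        assert (mine[0].q_start, mine[0].q_end) == (0, len(rec.seq))
        assert mine[0].pct_identity == 100.0

    def test_novel_regions_produce_no_hsp(self, small_panel):
        cfg = SimConfig(seed=6, n_genes=12, frac_novel_isotigs=1.0, frac_decoy=0)
        records, truth = generate_isotigs(small_panel, cfg)
        hsps, _ = generate_hit_table(records, small_panel, cfg)
        for reg in truth.planted_novel_regions:
            for h in hsps:
                if h.query_id == reg.isotig_id:
                    assert h.q_end <= reg.start or h.q_start >= reg.end

    def test_decoy_coverage_and_bits_scale_with_ratio(self, small_panel):
        cfg = SimConfig(seed=6, n_genes=12, frac_decoy=1.0, decoy_ratio=0.4,
                        frac_novel_isotigs=0, frac_splice_variants=0)
        records, _ = generate_isotigs(small_panel, cfg)
        hsps, chain_truth = generate_hit_table(records, small_panel, cfg)
        sp0 = small_panel.species[0]
        for rec in records:
            entry = chain_truth[(rec.isotig_id, sp0)]
            if not entry["decoy"]:
                continue
            true_hits = [h for h in hsps if h.query_id == rec.isotig_id
                         and h.target_id == rec.source_transcript]
            decoys = [h for h in hsps if h.query_id == rec.isotig_id
                      and h.target_id != rec.source_transcript
                      and h.target_id.endswith(sp0)]
            assert len(decoys) == 1
            cov = sum(h.q_len for h in true_hits)
            bits = sum(h.bit_score for h in true_hits)
            assert decoys[0].q_len == int(math.floor(0.4 * cov))
            assert decoys[0].bit_score == pytest.approx(0.4 * bits)


class TestCounts:
    def test_equal_weights_give_quarter_proportions(self):
        cfg = SimConfig(seed=10, n_genes=1, mean_count=100000.0)
        table, _ = generate_counts(["g0"], cfg)
        props = table.counts.iloc[0].to_numpy() / table.counts.iloc[0].sum()
        assert np.allclose(props, 0.25, atol=0.01)

    def test_totals_equal_column_sums(self):
        cfg = SimConfig(seed=11, n_genes=200)
        table, _ = generate_counts([f"g{i}" for i in range(200)], cfg)
        assert tuple(table.counts.sum(axis=0)) == table.totals

    def test_seeded_runs_identical(self):
        cfg = SimConfig(seed=12, n_genes=50, n_de_genes=5)
        t1, p1 = generate_counts([f"g{i}" for i in range(50)], cfg)
        t2, p2 = generate_counts([f"g{i}" for i in range(50)], cfg)
        assert t1.counts.equals(t2.counts) and t1.totals == t2.totals
        assert [d.gene_id for d in p1] == [d.gene_id for d in p2]

    def test_planted_de_genes_shift_expected_proportion(self):
        cfg = SimConfig(seed=13, n_genes=1, n_de_genes=1, de_log2fc=2.0,
                        mean_count=100000.0)
        table, planted = generate_counts(["g0"], cfg)
        row = table.counts.iloc[0].to_numpy()
        assert planted[0].log2_fold == 2.0
        # weights (4,1,1,1)/7
        assert row[0] / row.sum() == pytest.approx(4 / 7, abs=0.01)
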