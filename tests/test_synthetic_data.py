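import numpy as np
import pytest

from berrymir._seq import dna, revcomp
from berrymir.config import ConfigurationError, SimulationConfig
from berrymir.hairpin_discovery import evaluate_duplex, fold
from berrymir.synthetic_data import (CapacityError, generate_genome,
                                     make_reference_set, plant_hairpins,
                                     simulate_annotation, simulate_dataset,
                                     simulate_srna_library, truth_table,
                                     verified_precursor, write_dataset)


class TestConfig:
    def test_defaults_valid(self):
        cfg = SimulationConfig()
        assert cfg.n_tissues == 46
        assert cfg.mature_length == 21

    @pytest.mark.parametrize("kwargs", [
        {"noise_fraction": 1.5},
        {"gc_fraction": -0.1},
        {"mature_length": 19},
        {"mature_length": 23},
        {"n_true_mirnas": -1},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)

    def test_yaml_roundtrip(self, tmp_path):
        cfg = SimulationConfig(seed=9, n_genes=12)
        cfg.to_yaml(tmp_path / "cfg.yaml")
        assert SimulationConfig.from_yaml(tmp_path / "cfg.yaml") == cfg


class TestGenerateGenome:
    def test_chromosome_count_and_length(self):
        cfg = SimulationConfig(seed=7, n_chromosomes=2, chrom_length=50_000)
        genome = generate_genome(cfg)
        assert len(genome) == 2
        assert all(len(s) == 50_000 for s in genome.values())
        assert all(set(s) <= set("ACGT") for s in genome.values())

    def test_gc_content_tracks_configuration(self):
        cfg = SimulationConfig(seed=1, n_chromosomes=1, chrom_length=100_000,
                               gc_fraction=0.5)
        (seq,) = generate_genome(cfg).values()
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert 0.47 <= gc <= 0.53

    def test_identical_config_identical_bytes(self):
        cfg = SimulationConfig(seed=3)
        assert generate_genome(cfg) == generate_genome(cfg)


class TestPlantHairpins:
    def test_truth_rows_and_nonoverlap(self, dataset):
        truth = dataset.truth
        assert len(truth) == dataset.cfg.n_true_mirnas
        by_chrom = {}
        for t in truth:
            by_chrom.setdefault(t.chrom, []).append(
                (t.precursor_start, t.precursor_end))
        for spans in by_chrom.values():
            spans.sort()
            assert all(a[1] < b[0] for a, b in zip(spans, spans[1:]))

    def test_genome_carries_the_mature_sequence(self, dataset):
        for t in dataset.truth[:6]:
            seg = dataset.genome[t.chrom][t.start - 1:t.end]
            expect = dna(t.mature_seq) if t.strand == "+" \
                else revcomp(dna(t.mature_seq))
            assert seg == expect

    @staticmethod
    def _screen(genome, t):
        from berrymir.genome_mapper import GenomicHit
        from berrymir.hairpin_discovery import screen_hit
        from berrymir.srna_preprocess import SmallRNATag

        mat = dna(t.mature_seq)
        return screen_hit(SmallRNATag(mat, 1),
                          GenomicHit(mat, t.chrom, t.start, t.end, t.strand),
                          genome)

    def test_planted_defects_measured_in_window(self, dataset):
        """Screening each truth locus reproduces the configured defects."""
        for t in dataset.truth:
            if t.mispairings > 4 or t.bulges > 1:
                continue
            cand = self._screen(dataset.genome, t)
            assert cand is not None and cand.accepted
            assert cand.duplex.mispairings == t.mispairings
            assert cand.duplex.bulges == t.bulges

    def test_perfect_stem_schedule_all_accepted(self):
        cfg = SimulationConfig(seed=21, n_true_mirnas=4)
        genome = generate_genome(cfg)
        genome, truth = plant_hairpins(genome, cfg)
        for t in truth:
            cand = self._screen(genome, t)
            assert cand is not None and cand.accepted

    def test_five_mispairing_schedule_all_rejected(self):
        cfg = SimulationConfig(seed=22, n_true_mirnas=4, star_mispairings=5)
        genome = generate_genome(cfg)
        genome, truth = plant_hairpins(genome, cfg)
        for t in truth:
            cand = self._screen(genome, t)
            assert cand is None or not cand.accepted

    def test_capacity_error_on_tiny_genome(self):
        cfg = SimulationConfig(seed=1, n_chromosomes=1, chrom_length=1000,
                               n_true_mirnas=5)
        with pytest.raises(CapacityError):
            plant_hairpins(generate_genome(cfg), cfg)

    def test_verified_precursor_measures_as_configured(self, rng):
        prec = verified_precursor("TTGACAGAAGATAGAGAGCAC",
                                  SimulationConfig(), 3, 1, rng)
        stats, _ = evaluate_duplex(fold(prec), 1, 21)
        assert (stats.mispairings, stats.bulges) == (3, 1)


class TestSimulateSrnaLibrary:
    def test_partition_is_exact(self, small_dataset):
        cfg = small_dataset.cfg
        reads = small_dataset.reads
        n_signal = sum(r.id.startswith("sig_") for r in reads)
        n_noise = sum(r.id.startswith("noise_") for r in reads)
        n_lowq = sum(r.id.startswith("lowq_") for r in reads)
        assert n_signal == round((1 - cfg.noise_fraction) * cfg.read_depth)
        assert n_signal + n_noise == cfg.read_depth
        assert n_lowq == round(cfg.low_quality_fraction * cfg.read_depth)

    def test_signal_reads_are_mature_plus_adapter(self, small_dataset):
        matures = {dna(t.mature_seq) for t in small_dataset.truth}
        adapter = small_dataset.cfg.adapter
        for r in small_dataset.reads:
            if r.id.startswith("sig_"):
                assert r.seq.endswith(adapter)
                assert r.seq[:-len(adapter)] in matures

    def test_noise_free_library_is_all_signal(self):
        cfg = SimulationConfig(seed=2, n_true_mirnas=3, read_depth=500,
                               noise_fraction=0.0, low_quality_fraction=0.0)
        genome, truth = plant_hairpins(generate_genome(cfg), cfg)
        reads = simulate_srna_library(truth, cfg)
        matures = {dna(t.mature_seq) for t in truth}
        assert len(reads) == 500
        for r in reads:
            assert r.seq[:-len(cfg.adapter)] in matures

    def test_abundance_follows_geometric_decay(self, small_dataset):
        counts = {}
        for r in small_dataset.reads:
            if r.id.startswith("sig_"):
                locus = r.id.split("_")[1]
                counts[locus] = counts.get(locus, 0) + 1
        ordered = [counts[t.locus_id] for t in small_dataset.truth]
        assert all(a >= b for a, b in zip(ordered, ordered[1:]))


class TestSimulateAnnotation:
    def test_gene_count(self, dataset):
        assert dataset.annotation.gff3.count("\tgene\t") == \
            dataset.cfg.n_genes

    def test_tpm_shape_and_scaling(self, dataset):
        tpm = dataset.annotation.tpm
        assert tpm.shape == (dataset.cfg.n_genes, dataset.cfg.n_tissues)
        assert np.allclose(tpm.sum(axis=0), 1e6)

    def test_expressed_truth_recovered_from_matrix(self, dataset):
        tpm = dataset.annotation.tpm
        expressed = sorted(tpm.index[tpm.max(axis=1) > 1.0])
        assert expressed == sorted(dataset.annotation.expressed_genes)

    def test_transcripts_contain_planted_sites(self, dataset):
        ann = dataset.annotation
        matures = {t.locus_id: dna(t.mature_seq) for t in dataset.truth}
        assert ann.target_truth, "no sites planted"
        for pt in ann.target_truth:
            tx = ann.transcripts[pt.transcript_id]
            site = tx[pt.site_start - 1:pt.site_end]
            assert site == revcomp(matures[pt.locus_id])

    def test_degradome_tags_start_at_cleavage_positions(self, dataset):
        ann = dataset.annotation
        planted = {d[0]: d for d in ann.degradome if d[0].startswith("deg_")}
        k = 0
        for pt in ann.target_truth:
            tx = ann.transcripts[pt.transcript_id]
            expected = tx[pt.cleavage_pos - 1:pt.cleavage_pos - 1 + 20]
            for _ in range(pt.n_tags):
                k += 1
                assert planted[f"deg_{k}"][1] == expected
        # cleavage position sits opposite miRNA position 10
        pt = ann.target_truth[0]
        m = len(dna(next(t.mature_seq for t in dataset.truth
                         if t.locus_id == pt.locus_id)))
        assert pt.cleavage_pos == pt.site_start + m - 10


class TestDeterminismAndOutput:
    def test_identical_seed_identical_files(self, tmp_path):
        cfg = SimulationConfig(seed=17, n_true_mirnas=4, read_depth=800,
                               n_genes=10)
        for sub in ("a", "b"):
            write_dataset(simulate_dataset(cfg), tmp_path / sub)
        for name in ("genome.fa", "reads.fastq", "annotation.gff3",
                     "transcripts.fa", "degradome.fa", "tpm.tsv",
                     "truth.tsv", "reference_mature.fa"):
            assert (tmp_path / "a" / name).read_bytes() == \
                (tmp_path / "b" / name).read_bytes(), name

    def test_truth_table_columns(self, small_dataset):
        df = truth_table(small_dataset.truth)
        assert len(df) == small_dataset.cfg.n_true_mirnas
        assert list(df.columns[:5]) == ["locus_id", "chrom", "start", "end",
                                        "strand"]

    def test_reference_set_is_mirbase_dialect(self, small_dataset):
        for name, seq in small_dataset.reference:
            assert name.startswith("ath-miR")
            assert set(seq) <= set("ACGU")
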