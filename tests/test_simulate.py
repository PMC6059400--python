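"""Simulator: reference, fragment models, amplification, droplets."""

import numpy as np
import pytest

import cfsieve as cf
from cfsieve.simulate import draw_umis, write_fastq, write_sam


class TestReference:
    def test_same_seed_gives_identical_fasta_bytes(self, small_config, tmp_path):
        r1 = cf.make_reference(small_config)
        r2 = cf.make_reference(small_config)
        p1, p2 = tmp_path / "a.fasta", tmp_path / "b.fasta"
        r1.write_fasta(p1)
        r2.write_fasta(p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_bed_intervals_cover_exactly_the_panel(self, tmp_path):
        cfg = cf.SimConfig(seed=0, panel_size_bp=128000)
        ref = cf.make_reference(cfg)
        assert ref.panel_length() == 128000
        ref.write_bed(tmp_path / "panel.bed")
        total = sum(int(l.split("\t")[2]) - int(l.split("\t")[1])
                    for l in (tmp_path / "panel.bed").read_text().splitlines())
        assert total == 128000

    def test_panel_too_small_for_reads_is_a_config_error(self):
        with pytest.raises(cf.ConfigError):
            cf.make_reference(cf.SimConfig(seed=0, panel_size_bp=100))
        with pytest.raises(cf.ConfigError):
            # 1 kb panel split over 16 targets cannot host 125 bp reads
            cf.make_reference(cf.SimConfig(seed=0, panel_size_bp=1000,
                                           n_targets=16))

    def test_config_validation_rejects_bad_fractions_and_rates(self):
        with pytest.raises(cf.ConfigError):
            cf.SimConfig(tumor_fraction=1.5)
        with pytest.raises(cf.ConfigError):
            cf.SimConfig(seq_error_rate=-1e-4)


class TestFragments:
    def test_zero_tumor_fraction_gives_no_variant_fragments(self, reference,
                                                            small_config):
        cfg = small_config.replace(tumor_fraction=0.0)
        frags = cf.simulate_fragments(cfg, reference, 500)
        assert all(f.allele_class == "WT" for f in frags)

    def test_wt_mononucleosome_mean_matches_configured_value(self, reference):
        cfg = cf.SimConfig(seed=7, panel_size_bp=8000, n_targets=2,
                           tumor_fraction=0.0, dinucleosome_weight=0.0)
        frags = cf.simulate_fragments(cfg, reference, 100000)
        mean = np.mean([f.insert_length_bp for f in frags])
        assert abs(mean - 166.9) < 0.1

    def test_variant_inserts_are_shorter_than_wild_type(self, reference,
                                                        small_config):
        frags = cf.simulate_fragments(small_config, reference, 20000)
        var = np.median([f.insert_length_bp for f in frags
                         if f.allele_class == "VARIANT"])
        wt = np.median([f.insert_length_bp for f in frags
                        if f.allele_class == "WT"])
        assert var < wt

    def test_exact_variant_count_and_length_floor(self, reference, small_config):
        frags = cf.simulate_fragments(small_config, reference, 1000)
        assert sum(f.allele_class == "VARIANT" for f in frags) == 50
        assert min(f.insert_length_bp for f in frags) >= 50

    def test_template_carries_alt_base_at_locus(self, reference, small_config):
        locus = reference.variant_locus
        for f in cf.simulate_fragments(small_config, reference, 200):
            base = f.template_sequence[locus.position - f.start]
            expected = locus.alt if f.allele_class == "VARIANT" else locus.ref
            assert base == expected

    def test_background_on_target_fraction(self, reference, small_config):
        frags = cf.simulate_background_fragments(small_config, reference, 1000)
        n_off = sum(f.allele_class == "OFF_TARGET" for f in frags)
        assert n_off == round(1000 * (1 - small_config.on_target_fraction))


class TestSpikeSeries:
    def test_vaf_halves_per_step_to_one_permille(self, reference, small_config):
        steps = cf.simulate_spike_series(small_config, reference,
                                         dilution_steps=8, start_vaf=0.128,
                                         dilution_factor=2.0, n_per_locus=500)
        assert steps[-1].target_vaf == pytest.approx(0.001)
        assert steps[0].target_vaf == pytest.approx(0.128)

    def test_unit_dilution_factor_keeps_vaf_constant(self, reference,
                                                     small_config):
        steps = cf.simulate_spike_series(small_config, reference,
                                         dilution_steps=4, start_vaf=0.01,
                                         dilution_factor=1.0, n_per_locus=200)
        assert len({s.target_vaf for s in steps}) == 1

    def test_spike_fragments_have_exactly_the_fixed_lengths(self, reference,
                                                            small_config):
        steps = cf.simulate_spike_series(small_config, reference,
                                         lengths=(130, 165), dilution_steps=1,
                                         start_vaf=0.1, n_per_locus=300)
        spikes = [f for f in steps[0].fragments if f.allele_class == "VARIANT"]
        assert {f.insert_length_bp for f in spikes} == {130, 165}

    def test_nonpositive_start_vaf_is_a_config_error(self, reference,
                                                     small_config):
        with pytest.raises(cf.ConfigError):
            cf.simulate_spike_series(small_config, reference, start_vaf=0.0)


class TestAmplifyAndSequence:
    def test_zero_noise_reads_equal_template_substrings(self, noise_free_library):
        frags = {f.fragment_id: f for f in noise_free_library["fragments"]}
        for r in noise_free_library["reads"][:2000]:
            f = frags[r.fragment_id]
            off = r.start - f.start
            assert r.seq == f.template_sequence[off:off + len(r.seq)]

    def test_every_read_maps_to_exactly_one_fragment_and_sizes_conserve(
            self, noise_free_library):
        reads = noise_free_library["reads"]
        ids = {f.fragment_id for f in noise_free_library["fragments"]}
        assert all(r.fragment_id in ids for r in reads)
        fams = noise_free_library["families"]
        assert sum(f.family_size for f in fams) == len(reads)

    def test_halved_complexity_roughly_doubles_family_size(self, reference):
        def mean_fs(n):
            cfg = cf.SimConfig(seed=9, panel_size_bp=8000, n_targets=2,
                               tumor_fraction=0.0, n_unique_molecules=n,
                               total_reads=20000)
            frags = cf.simulate_background_fragments(cfg, reference, n)
            fams, _ = cf.group_families(cf.amplify_and_sequence(frags, cfg))
            return sum(f.family_size for f in fams) / len(fams)

        ratio = mean_fs(1000) / mean_fs(2000)
        assert 1.8 <= ratio <= 2.2

    def test_sequencing_error_count_matches_binomial(self, reference):
        cfg = cf.SimConfig(seed=5, panel_size_bp=8000, n_targets=2,
                           pcr_cycles=0, tumor_fraction=0.0,
                           dinucleosome_weight=0.0, seq_error_rate=1e-3)
        frags = cf.simulate_background_fragments(cfg, reference, 4000)
        reads = cf.amplify_and_sequence(frags, cfg)
        by_id = {f.fragment_id: f for f in frags}
        mismatches = bases = 0
        for r in reads:
            f = by_id[r.fragment_id]
            off = r.start - f.start
            tpl = f.template_sequence[off:off + len(r.seq)]
            mismatches += sum(a != b for a, b in zip(r.seq, tpl))
            bases += len(r.seq)
        assert bases >= 10 ** 6
        expected = bases * 1e-3
        ci = 1.96 * np.sqrt(expected)
        assert abs(mismatches - expected) <= ci

    def test_amplification_free_mode_sequences_each_molecule_once(
            self, reference, small_config):
        cfg = small_config.replace(pcr_cycles=0)
        frags = cf.simulate_fragments(cfg, reference, 300)
        reads = cf.amplify_and_sequence(frags, cfg)
        assert len(reads) == 2 * 300

    def test_deterministic_for_seed(self, reference, small_config):
        frags = cf.simulate_fragments(small_config, reference, 100)
        r1 = cf.amplify_and_sequence(frags, small_config)
        r2 = cf.amplify_and_sequence(frags, small_config)
        assert [(a.name, a.seq, a.start) for a in r1] == \
               [(b.name, b.seq, b.start) for b in r2]

    def test_umis_are_collision_free_in_small_cohorts(self):
        rng = np.random.default_rng(0)
        umis = draw_umis(rng, 5000, 8)
        assert len(set(umis)) == 5000
        assert all(len(u) == 8 and set(u) <= set("ACGT") for u in umis)


class TestSamOutput:
    def test_sam_round_trip_preserves_reads(self, reference, small_config,
                                            tmp_path):
        import pysam

        frags = cf.simulate_fragments(small_config, reference, 50)
        reads = cf.amplify_and_sequence(frags, small_config)
        path = tmp_path / "reads.sam"
        write_sam(reads, reference, path)
        with pysam.AlignmentFile(str(path)) as fh:
            back = [cf.AlignedRead.from_pysam(a) for a in fh]
        assert len(back) == len(reads)
        key = lambda r: (r.start, r.name, r.strand)
        for orig, rt in zip(sorted(reads, key=key),
                            sorted(back, key=key)):
            assert rt.seq == orig.seq
            assert rt.umi == orig.umi
            assert abs(rt.tlen) == abs(orig.tlen)

    def test_fastq_emits_both_mates(self, reference, small_config, tmp_path):
        frags = cf.simulate_fragments(small_config, reference, 20)
        reads = cf.amplify_and_sequence(frags, small_config)
        write_fastq(reads, tmp_path / "r1.fastq", tmp_path / "r2.fastq")
        n1 = (tmp_path / "r1.fastq").read_text().count("@f")
        n2 = (tmp_path / "r2.fastq").read_text().count("@f")
        assert n1 == n2 == len(reads) // 2


class TestDroplets:
    def test_no_input_no_noise_gives_all_empty(self):
        exp = cf.DropletExperiment(1000, 0, 0, 0.0)
        dc = cf.simulate_droplets(exp, 1)
        assert dc.n_empty == 1000

    def test_occupancy_matches_poisson_limit(self):
        exp = cf.DropletExperiment(100000, 10000, 0, 0.0)
        dc = cf.simulate_droplets(exp, 2)
        p = 1 - np.exp(-0.1)
        frac = dc.positives("wt") / dc.n_total
        ci = 1.96 * np.sqrt(p * (1 - p) / dc.n_total)
        assert abs(frac - p) <= ci

    def test_false_positive_mean_matches_lambda(self):
        rng = np.random.default_rng(3)
        exp = cf.DropletExperiment(20000, 0, 0, 1.0)
        fp = [cf.simulate_droplets(exp, rng).positives("variant")
              for _ in range(1000)]
        assert abs(np.mean(fp) - 1.0) <= 1.96 / np.sqrt(1000)
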