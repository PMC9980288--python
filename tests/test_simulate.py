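import filecmp
import os

import numpy as np
import pytest

from sigscan import (
    GenomeSequence,
    SyntheticCohortConfig,
    classify_indel,
    classify_sbs,
    generate_cohort,
    generate_genome,
    generate_timing_track,
    quintilize,
    spawn_indels,
    spawn_sbs,
)
from sigscan.simulate import GenomeIndex, timing_site_weights
from sigscan.variants import apply_filters


class TestGenerateGenome:
    def test_deterministic(self):
        config = SyntheticCohortConfig(seed=42, n_contigs=2, contig_length=5000)
        assert generate_genome(config).contigs == generate_genome(config).contigs

    def test_composition_concentration(self):
        config = SyntheticCohortConfig(seed=1, n_contigs=1, contig_length=1_000_000)
        genome = generate_genome(config)
        seq = genome.contigs["c1"]
        for base in "ACGT":
            assert abs(seq.count(base) / len(seq) - 0.25) < 0.005

    def test_all_c_degenerate(self):
        config = SyntheticCohortConfig(
            seed=1, n_contigs=1, contig_length=2000, base_composition=(0, 1, 0, 0)
        )
        genome = generate_genome(config)
        assert set(genome.contigs["c1"]) == {"C"}
        assert len(GenomeIndex(genome).tcw_sites) == 0


class TestGenomeIndex:
    def test_tcw_sites_match_string_scan(self, sim_genome, sim_index):
        # independent oracle: regex-free direct substring scan
        expected = []
        offset = 0
        for name, seq in sim_genome.contigs.items():
            for i in range(1, len(seq) - 1):
                tri = seq[i - 1 : i + 2]
                if (tri[1] == "C" and tri[0] == "T" and tri[2] in "AT") or (
                    tri[1] == "G" and tri[2] == "A" and tri[0] in "TA"
                ):
                    expected.append(offset + i)
            offset += len(seq)
        assert sim_index.tcw_sites.tolist() == expected

    def test_global_site_mapping(self, sim_genome, sim_index):
        L1 = sim_genome.length("c1")
        assert sim_index.to_site(0) == ("c1", 1)
        assert sim_index.to_site(L1 - 1) == ("c1", L1)
        assert sim_index.to_site(L1) == ("c2", 1)


class TestSpawnSbs:
    def test_pure_apobec_all_tcw_ct(self, sim_genome, sim_index):
        records = spawn_sbs(sim_index, 300, 1.0, 1.0, seed=5)
        for rec in records:
            cls = classify_sbs(rec, sim_genome)
            assert cls.label in ("T[C>T]A", "T[C>T]T")

    def test_split_controls_ct_vs_cg(self, sim_genome, sim_index):
        records = spawn_sbs(sim_index, 400, 1.0, 0.5, seed=6)
        labels = [classify_sbs(r, sim_genome).label for r in records]
        ct = sum(1 for l in labels if ">T]" in l)
        assert all(l.startswith("T[C>") for l in labels)
        assert 140 < ct < 260  # binomial(400, 0.5) within ~5 sigma

    def test_records_pass_default_filters(self, sim_index):
        records = spawn_sbs(sim_index, 200, 0.5, 1.0, seed=7)
        assert len(apply_filters(records)) == 200

    def test_deterministic(self, sim_index):
        a = spawn_sbs(sim_index, 100, 0.3, 1.0, seed=8)
        b = spawn_sbs(sim_index, 100, 0.3, 1.0, seed=8)
        assert a == b

    def test_unique_positions(self, sim_index):
        records = spawn_sbs(sim_index, 500, 0.5, 1.0, seed=9)
        assert len({(r.contig, r.position) for r in records}) == 500

    def test_insufficient_sites_rejected(self):
        genome = GenomeSequence({"c1": "TCA" * 5})  # 5 TCW sites
        with pytest.raises(ValueError, match="eligible"):
            spawn_sbs(genome, 30, 1.0, 1.0, seed=1)

    def test_no_tcw_sites_rejected(self):
        genome = GenomeSequence({"c1": "ACGT" * 10})
        with pytest.raises(ValueError, match="TCW"):
            spawn_sbs(genome, 30, 1.0, 1.0, seed=1)


class TestSpawnIndels:
    def test_all_size_one(self, sim_genome, sim_index):
        records = spawn_indels(sim_index, 50, {"1": 1.0}, seed=2)
        for rec in records:
            assert classify_indel(rec, sim_genome).size_category == "1"

    def test_empty(self, sim_index):
        assert spawn_indels(sim_index, 0, {"1": 1.0}, seed=2) == []

    def test_category_round_trip(self, sim_genome, sim_index):
        records, truth = spawn_indels(
            sim_index,
            400,
            {"1": 0.3, "2": 0.2, "3": 0.2, "4": 0.1, "5plus": 0.2},
            seed=3,
            return_truth=True,
        )
        for rec, (kind, category) in zip(records, truth):
            cls = classify_indel(rec, sim_genome)
            assert (cls.kind, cls.size_category) == (kind, category)

    def test_ref_alleles_match_genome(self, sim_genome, sim_index):
        for rec in spawn_indels(sim_index, 100, {"2": 0.5, "5plus": 0.5}, seed=4):
            L = len(rec.ref_allele)
            assert sim_genome.slice(rec.contig, rec.position, rec.position + L - 1) == rec.ref_allele


class TestTimingTrackGeneration:
    def test_tiles_partition_genome(self, sim_genome):
        track = generate_timing_track(sim_genome, window=997, bias_ratio=0.5, seed=5)
        by_contig = {}
        for iv in track.intervals:
            by_contig.setdefault(iv.contig, []).append(iv)
        for contig, ivs in by_contig.items():
            ivs.sort(key=lambda iv: iv.start)
            assert ivs[0].start == 0
            assert ivs[-1].end == sim_genome.length(contig)
            for a, b in zip(ivs, ivs[1:]):
                assert a.end == b.start

    def test_quintilize_recovers_planted_labels(self, sim_genome):
        track = generate_timing_track(sim_genome, window=1000, bias_ratio=0.5, seed=6)
        labeled = quintilize(track)
        for raw, lab in zip(track.intervals, labeled.intervals):
            assert int(raw.value) + 1 == int(lab.value)

    def test_flat_bias_gives_unit_weights(self, sim_genome, sim_index):
        track = quintilize(generate_timing_track(sim_genome, 1000, 1.0, seed=7))
        weights = timing_site_weights(sim_index, track, 1.0)
        assert np.all(weights == 1.0)


@pytest.fixture(scope="module")
def small_config():
    return SyntheticCohortConfig(
        seed=13,
        n_contigs=2,
        contig_length=20_000,
        n_samples=4,
        sbs_per_sample=150,
        apobec_fraction=[0.0, 0.0, 0.6, 0.6],
        indels_per_sample=30,
        indel_rate_couples_to_apobec=True,
    )


class TestGenerateCohort:
    def test_truth_table(self, small_config):
        cohort = generate_cohort(small_config)
        assert len(cohort.truth) == 4
        assert list(cohort.truth["group"]) == ["background"] * 2 + ["apobec"] * 2
        # coupled mode: apobec samples get 30 * (1 + 2*0.6) = 66 indels
        assert list(cohort.truth["n_indels"]) == [30, 30, 66, 66]
        assert all(len(cohort.indels_by_sample[s]) == n
                   for s, n in zip(cohort.truth["sample"], cohort.truth["n_indels"]))

    def test_files_byte_identical_across_runs(self, small_config, tmp_path):
        dir_a, dir_b = str(tmp_path / "a"), str(tmp_path / "b")
        generate_cohort(small_config, out_dir=dir_a)
        generate_cohort(small_config, out_dir=dir_b)
        names = sorted(os.listdir(dir_a))
        assert names == sorted(os.listdir(dir_b))
        for name in names:
            if name.endswith(".tsv"):  # manifest embeds the directory path
                continue
            assert filecmp.cmp(
                os.path.join(dir_a, name), os.path.join(dir_b, name), shallow=False
            ), name

    def test_fraction_vector_length_checked(self):
        with pytest.raises(ValueError, match="length"):
            SyntheticCohortConfig(n_samples=3, apobec_fraction=[0.1, 0.2])
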