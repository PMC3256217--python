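"""Synthetic-data generator: panels, metagenomes, time course, qPCR truth."""

import math

import numpy as np
import pytest

from petromine.io import write_protein_fasta
from petromine.preprocess import remove_artificial_replicates
from petromine.search import local_align
from petromine.simulate import (
    DEFAULT_FAMILIES,
    DEFAULT_LOAD_PROFILE,
    FamilySpec,
    MetagenomeSpec,
    generate_metagenome,
    generate_qpcr_experiment,
    generate_reference_panel,
    generate_timecourse,
    global_identity,
    reverse_translate,
)
from petromine.qpcr import fit_standard_curve, quantify, spike_recovery


class TestReferencePanel:
    def test_default_panel_counts(self):
        panel, confirm = generate_reference_panel(DEFAULT_FAMILIES, seed=7)
        expected = sum(f.n_reference_proteins for f in DEFAULT_FAMILIES)
        assert len(panel) == expected == 17
        assert len(confirm) >= 20
        assert {p.accession for p in panel} <= {p.accession for p in confirm}

    def test_determinism_byte_identical(self, small_families, tmp_path):
        a1, c1 = generate_reference_panel(small_families, seed=11)
        a2, c2 = generate_reference_panel(small_families, seed=11)
        p1, p2 = tmp_path / "1.faa", tmp_path / "2.faa"
        write_protein_fasta(c1, p1)
        write_protein_fasta(c2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert [p.sequence for p in a1] == [p.sequence for p in a2]

    def test_duplicate_family_rejected(self, small_families):
        with pytest.raises(ValueError, match="duplicate family_id"):
            generate_reference_panel(list(small_families) + [small_families[0]], seed=0)

    def test_decoys_unrelated_to_all_families(self, small_panel):
        """Global-alignment identity of every decoy vs every family member < 0.25."""
        _, confirm = small_panel
        decoys = [p for p in confirm if p.family is None]
        members = [p for p in confirm if p.family is not None]
        assert len(decoys) >= 0.2 * len([p for p in confirm if p.family])
        for d in decoys:
            for m in members:
                assert global_identity(d.sequence, m.sequence) < 0.25

    def test_within_family_identity(self, small_panel):
        _, confirm = small_panel
        by_family = {}
        for p in confirm:
            if p.family:
                by_family.setdefault(p.family, []).append(p)
        for members in by_family.values():
            for i in range(len(members)):
                for j in range(i + 1, len(members)):
                    ident = global_identity(members[i].sequence, members[j].sequence)
                    assert ident >= 0.60

    def test_family_spec_validation(self):
        with pytest.raises(ValueError, match="protein_length"):
            FamilySpec("f", ("1.1.1.1",), ("A",), ("Actinobacteria",), protein_length=50)
        with pytest.raises(ValueError, match="unknown taxon group"):
            FamilySpec("f", ("1.1.1.1",), ("A",), ("Klingonbacteria",))


class TestMetagenomeSpec:
    def test_zero_reads_forbidden(self):
        with pytest.raises(ValueError, match="n_reads"):
            MetagenomeSpec("s", n_reads=0)

    def test_abundances_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum"):
            MetagenomeSpec("s", n_reads=10, taxon_abundances={"Actinobacteria": 0.5})

    def test_overloaded_plant_rejected(self):
        with pytest.raises(ValueError, match="load exceeds"):
            MetagenomeSpec(
                "s", n_reads=10,
                planted_gene_load={("alkane_1_monooxygenase", "Actinobacteria"): 50},
            )


class TestGenerateMetagenome:
    def test_truth_covers_every_read(self, small_panel):
        panel, _ = small_panel
        spec = MetagenomeSpec("s", n_reads=500, duplicate_rate=0.1, seed=3)
        ds, truth = generate_metagenome(spec, panel)
        assert ds.n_reads == 500
        assert len(truth) == 500
        assert set(truth["read_id"]) == set(ds.read_ids())

    def test_zero_duplicate_rate_no_replicates(self, small_panel):
        panel, _ = small_panel
        spec = MetagenomeSpec("s", n_reads=200, duplicate_rate=0.0, seed=1)
        _, truth = generate_metagenome(spec, panel)
        assert not truth["is_artificial_replicate"].any()

    def test_planted_count_poisson_consistent(self, small_panel):
        """Planted read count is a Poisson draw around the specified load."""
        panel, _ = small_panel
        load = 20
        spec = MetagenomeSpec(
            "s", n_reads=50000, seed=11,
            planted_gene_load={("alkane_1_monooxygenase", "Gammaproteobacteria"): load},
        )
        _, truth = generate_metagenome(spec, panel)
        planted = (truth["family"] == "alkane_1_monooxygenase").sum()
        assert abs(planted - load) <= 3 * math.sqrt(load)

    def test_unknown_family_rejected(self, small_panel):
        panel, _ = small_panel
        spec = MetagenomeSpec(
            "s", n_reads=100,
            planted_gene_load={("nitrogenase", "Actinobacteria"): 5},
        )
        with pytest.raises(ValueError, match="no panel references"):
            generate_metagenome(spec, panel)

    def test_planted_reads_recoverable_at_zero_mutation(self, small_panel, scheme):
        """Unmutated planted fragments >=150bp align >=95% identity to source."""
        panel, confirm = small_panel
        spec = MetagenomeSpec(
            "s", n_reads=40, read_length_mean=180, read_length_sd=10,
            mutation_rate=0.0, seed=5,
            planted_gene_load={("gentisate_1_2_dioxygenase", "Betaproteobacteria"): 15},
        )
        ds, truth = generate_metagenome(spec, panel, source_db=confirm)
        by_acc = {p.accession: p for p in confirm}
        planted = truth[truth["family"] != ""]
        assert len(planted) > 0
        reads = {r.read_id: r for r in ds}
        from petromine.search import six_frame_translate

        for _, row in planted.iterrows():
            read = reads[row["read_id"]]
            src = by_acc[row["source_accession"]]
            best = None
            for pep in six_frame_translate(read.sequence).values():
                aln = local_align(pep, src.sequence, scheme)
                if aln and (best is None or aln.raw_score > best.raw_score):
                    best = aln
            assert best is not None
            assert best.identity_fraction >= 0.95


class TestTimecourse:
    def test_scaled_read_counts(self, small_families):
        tc = generate_timecourse(
            families=small_families, scale=0.01, seed=0, duplicate_rate=0.0,
            load_profile={}, mutation_rate=0.0,
        )
        assert tc.samples["t1m"][0].n_reads == 1082
        assert tc.samples["uncont"][0].n_reads == 4578

    def test_duplicates_restore_nominal_size_after_derep(self, small_families):
        tc = generate_timecourse(
            families=small_families, scale=0.005, seed=2, duplicate_rate=0.2,
            load_profile={},
        )
        ds = tc.samples["t1m"][0]
        assert ds.n_reads == round(541 / 0.8)
        clean, _ = remove_artificial_replicates(ds)
        assert abs(clean.n_reads - 541) <= 2

    def test_uncont_alkb_load_about_tenth_of_t0(self):
        """Planted alkB per read: uncontaminated ~ one tenth of t=0."""
        tc = generate_timecourse(scale=0.001, seed=0)
        loads = {}
        for name in ("uncont", "t0"):
            spec = tc.specs[name]
            alkb = sum(
                v for (fam, _), v in spec.planted_gene_load.items()
                if fam == "alkane_1_monooxygenase"
            )
            loads[name] = alkb / spec.n_reads
        ratio = loads["uncont"] / loads["t0"]
        assert ratio == pytest.approx(11.2 / 113.5, rel=0.15)

    def test_t1y_actino_alpha_dominate_alkb(self):
        """The late-time-course planted design shifts alkB away from Gamma."""
        profile = DEFAULT_LOAD_PROFILE["alkane_1_monooxygenase"]
        t1y = {g: v[3] for g, v in profile.items()}
        assert t1y["Actinobacteria"] + t1y["Alphaproteobacteria"] > t1y["Gammaproteobacteria"]

    def test_same_seed_identical_datasets(self, small_families):
        profile = {
            fam: groups for fam, groups in DEFAULT_LOAD_PROFILE.items()
            if fam in {f.family_id for f in small_families}
        }
        a = generate_timecourse(families=small_families, scale=0.002, seed=9,
                                load_profile=profile)
        b = generate_timecourse(families=small_families, scale=0.002, seed=9,
                                load_profile=profile)
        for name in a.sample_names:
            assert [r.sequence for r in a.samples[name][0]] == [
                r.sequence for r in b.samples[name][0]
            ]

    def test_bad_scale_rejected(self):
        with pytest.raises(ValueError, match="scale"):
            generate_timecourse(scale=0.0)


class TestQpcrExperiment:
    def test_perfect_doubling_slope(self):
        table = generate_qpcr_experiment(
            {"s1": {"geneA": 1e4}}, efficiency=1.0, noise_sd=0.0, seed=0
        )
        std = table[(table["role"] == "standard") & (table["target"] == "geneA")]
        curve = fit_standard_curve(list(zip(std["known_copies"], std["ct"])))
        assert curve.slope == pytest.approx(-1 / math.log10(2), abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.efficiency == pytest.approx(1.0)

    def test_no_inhibition_spike_exact(self):
        table = generate_qpcr_experiment(
            {"s1": {"geneA": 1e4}}, efficiency=0.9, inhibition={"s1": 0.0},
            noise_sd=0.0, seed=0,
        )
        std = table[(table["role"] == "standard") & (table["target"] == "lambda")]
        curve = fit_standard_curve(list(zip(std["known_copies"], std["ct"])))
        spike_ct = table[table["role"] == "spike"]["ct"].iloc[0]
        assert quantify(spike_ct, curve) == pytest.approx(1e5, rel=1e-9)

    def test_worst_reported_rna_inhibition(self):
        """45.1% inhibition leaves a 54.9% spike recovery."""
        table = generate_qpcr_experiment(
            {"s1": {"geneA": 1e4}}, efficiency=0.9, inhibition={"s1": 0.451},
            noise_sd=0.0, seed=0,
        )
        std = table[(table["role"] == "standard") & (table["target"] == "lambda")]
        curve = fit_standard_curve(list(zip(std["known_copies"], std["ct"])))
        measured = quantify(table[table["role"] == "spike"]["ct"].iloc[0], curve)
        recovery, inhibition_pct = spike_recovery(measured)
        assert recovery == pytest.approx(0.549, abs=1e-6)
        assert inhibition_pct == pytest.approx(45.1, abs=1e-6)

    def test_validation(self):
        with pytest.raises(ValueError, match="efficiency"):
            generate_qpcr_experiment({"s": {"g": 1e3}}, efficiency=1.5)
        with pytest.raises(ValueError, match="inhibition"):
            generate_qpcr_experiment({"s": {"g": 1e3}}, inhibition={"s": 1.0})
        with pytest.raises(ValueError, match="positive"):
            generate_qpcr_experiment({"s": {"g": 0.0}})


def test_reverse_translate_faithful(rng):
    from petromine.search import six_frame_translate

    pep = "MAGICHEN"  # valid residues only
    dna = reverse_translate(rng, pep)
    assert six_frame_translate(dna)[1] == pep
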