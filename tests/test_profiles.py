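"""Normalization, totals convention, concordance, taxon profiles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as scipy_stats

from petromine.io import Dataset, Read
from petromine.profiles import (
    AbundanceTable,
    Genome,
    PipelineContext,
    concordance,
    normalize_by_subsampling,
    normalize_per_100_genomes,
    round_half_up,
    spearman,
    table_totals,
    taxon_profile,
)
from petromine.simulate import (
    MetagenomeSpec,
    generate_metagenome,
    reverse_translate,
)


class TestNormalization:
    def test_single_hit_unit_increments(self):
        """One hit in each dataset gives the minimal table increment."""
        assert normalize_per_100_genomes(1, 457781) == 1.6
        assert normalize_per_100_genomes(1, 364725) == 2.1
        assert normalize_per_100_genomes(1, 108203) == 6.9
        assert normalize_per_100_genomes(1, 287705) == 2.6

    def test_one_hit_per_unit_definition(self):
        assert normalize_per_100_genomes(1, 750000) == 1.0

    def test_zero_hits(self):
        assert normalize_per_100_genomes(0, 1000) == 0.0

    def test_linearity_before_rounding(self):
        for k, n in ((3, 108203), (7, 364725), (11, 457781)):
            assert (2 * k * 750000 / n) == pytest.approx(2 * (k * 750000 / n))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            normalize_per_100_genomes(1, 0)
        with pytest.raises(ValueError):
            normalize_per_100_genomes(-1, 10)

    def test_round_half_up_convention(self):
        assert round_half_up(2.05, 1) == 2.1
        assert round_half_up(2.04999, 1) == 2.0
        assert round_half_up(117.75, 1) == 117.8


class TestTableTotals:
    def _table(self, cells, n_reads):
        raw = pd.DataFrame(
            {"s": list(cells.values())},
            index=pd.MultiIndex.from_tuples(
                [("fam", g) for g in cells], names=["family", "group"]
            ),
        )
        return AbundanceTable(raw=raw, sample_n_reads={"s": n_reads})

    def test_sum_of_rounded_components(self):
        # five groups of the t=1m alkane-hydroxylase column
        t = self._table(
            {"Actinobacteria": 1, "Gammaproteobacteria": 9, "Eukaryotes": 1,
             "synthetic construct": 2, "uncultured/unclassified": 4},
            108203,
        )
        assert list(t.normalized["s"]) == [6.9, 62.4, 6.9, 13.9, 27.7]
        assert table_totals(t).loc["fam", "s"] == 117.8

    def test_single_group_total_is_that_value(self):
        t = self._table({"Actinobacteria": 3}, 108203)
        assert table_totals(t).loc["fam", "s"] == t.normalized.loc[("fam", "Actinobacteria"), "s"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            self._table({"Actinobacteria": -1}, 100)

    def test_missing_sample_size_rejected(self):
        raw = pd.DataFrame(
            {"s2": [1]},
            index=pd.MultiIndex.from_tuples([("f", "g")], names=["family", "group"]),
        )
        with pytest.raises(ValueError, match="no dataset size"):
            AbundanceTable(raw=raw, sample_n_reads={"s1": 10})


class TestSpearman:
    def test_identical_tables_rho_one(self):
        a = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]},
                         index=["f1", "f2", "f3"])
        rho, p, n = concordance(a, a)
        assert rho == pytest.approx(1.0)
        assert n == 6

    def test_reversed_ranks_rho_minus_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        rho, _ = spearman(x, x[::-1])
        assert rho == pytest.approx(-1.0)

    def test_matches_scipy_with_ties(self, rng):
        x = rng.integers(0, 10, size=40).astype(float)
        y = x + rng.normal(0, 3, size=40)
        rho, p = spearman(x, y)
        expected = scipy_stats.spearmanr(x, y)
        assert rho == pytest.approx(expected.statistic, abs=1e-12)
        assert p == pytest.approx(expected.pvalue, rel=1e-6)

    def test_exact_permutation_small_n(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        y = [1.0, 3.0, 2.0, 5.0, 4.0]
        rho, p = spearman(x, y)
        expected = scipy_stats.spearmanr(x, y)
        assert rho == pytest.approx(expected.statistic)
        assert 0.0 <= p <= 1.0

    def test_too_few_cells_rejected(self):
        a = pd.DataFrame({"s1": [1.0, 2.0]}, index=["f1", "f2"])
        with pytest.raises(ValueError, match="at least 5"):
            concordance(a, a)


@pytest.fixture(scope="module")
def context_and_dataset(small_panel, scheme):
    panel, confirm_db = small_panel
    spec = MetagenomeSpec(
        "t0", n_reads=600, read_length_mean=200, read_length_sd=20,
        mutation_rate=0.02, seed=23,
        planted_gene_load={
            ("alkane_1_monooxygenase", "Gammaproteobacteria"): 25,
            ("gentisate_1_2_dioxygenase", "Betaproteobacteria"): 15,
        },
    )
    dataset, _ = generate_metagenome(spec, panel, source_db=confirm_db)
    context = PipelineContext(
        panel=panel, confirmation_db=confirm_db, scheme=scheme, prefilter_k=6
    )
    return context, dataset


class TestSubsamplingNormalization:
    def test_full_size_equals_full_run(self, context_and_dataset):
        context, dataset = context_and_dataset
        full = normalize_by_subsampling(dataset, context, n=dataset.n_reads, seed=0)
        records = context.run(dataset)
        expected = pd.Series(
            [r.family_id for r in records if r.status == "confirmed"], dtype="object"
        ).value_counts().sort_index()
        assert full.astype(int).to_dict() == expected.to_dict()

    def test_oversize_warns_and_uses_full(self, context_and_dataset):
        context, dataset = context_and_dataset
        with pytest.warns(UserWarning, match="exceeds dataset size"):
            counts = normalize_by_subsampling(dataset, context, n=10**6, seed=0)
        assert counts.sum() > 0

    def test_expectation_scales_with_fraction(self, context_and_dataset):
        """Mean subsample count over 50 seeds tracks n/N x full count."""
        context, dataset = context_and_dataset
        records = context.run(dataset)
        full = sum(r.status == "confirmed" for r in records)
        n = dataset.n_reads // 5
        totals = [
            normalize_by_subsampling(dataset, context, n=n, seed=s).sum()
            for s in range(50)
        ]
        expected = full * n / dataset.n_reads
        sd_mean = np.sqrt(full * 0.2 * 0.8) / np.sqrt(50)
        assert abs(np.mean(totals) - expected) <= 3 * sd_mean

    def test_zero_confirmed_stays_zero(self, small_panel, scheme, rng):
        """A dataset with no confirmed hits yields zero in every subsample."""
        panel, confirm_db = small_panel
        reads = [
            Read(f"r{i}", "".join(rng.choice(list("ACGT"), size=80)))
            for i in range(60)
        ]
        probe = Dataset("probe", reads)
        context = PipelineContext(panel=panel, confirmation_db=confirm_db, scheme=scheme)
        hit_ids = {r.read_id for r in context.run(probe) if r.status == "confirmed"}
        clean = Dataset("clean", [r for r in reads if r.read_id not in hit_ids])
        for seed in (0, 1, 2):
            counts = normalize_by_subsampling(clean, context, n=20, seed=seed)
            assert counts.sum() == 0


def _genome(rng, organism, size, n_prot=2, plen=200):
    prots = [
        # uses the realistic-composition generator from the panel machinery
        None for _ in range(n_prot)
    ]
    from petromine.io import ProteinRef
    from petromine.simulate import _random_protein

    return Genome(
        organism=organism,
        genome_size=size,
        proteins=[
            ProteinRef(f"{organism}_{i}", _random_protein(rng, plen),
                       phylum="Actinobacteria", genus=organism)
            for i in range(n_prot)
        ],
    )


class TestTaxonProfile:
    def test_genome_size_correction_ratio(self, scheme):
        """Equal fragment counts, 3 vs 6 Mbp genomes -> 2:1 corrected ratio."""
        rng = np.random.default_rng(5)
        ga = _genome(rng, "orgA", 3_000_000)
        gb = _genome(rng, "orgB", 6_000_000)
        reads = []
        for i in range(15):
            for g, tag in ((ga, "a"), (gb, "b")):
                p = g.proteins[i % 2]
                reads.append(
                    Read(f"{tag}{i}", reverse_translate(rng, p.sequence[10:60]))
                )
        profile = taxon_profile(Dataset("s", reads), [ga, gb], scheme)
        assert profile.loc["orgA", "fragment_count"] == 15
        assert profile.loc["orgB", "fragment_count"] == 15
        ratio = (
            profile.loc["orgA", "corrected_abundance"]
            / profile.loc["orgB", "corrected_abundance"]
        )
        assert ratio == pytest.approx(2.0)
        assert profile["fraction"].sum() == pytest.approx(1.0)

    def test_short_alignment_not_counted(self, scheme):
        """A read shorter than the minimum span can never be counted."""
        rng = np.random.default_rng(6)
        g = _genome(rng, "orgA", 3_000_000)
        read = Read("short", reverse_translate(rng, g.proteins[0].sequence[:15]))
        assert read.length == 45
        profile = taxon_profile(Dataset("s", [read]), [g], scheme, min_aln_bp=50)
        assert profile.loc["orgA", "fragment_count"] == 0

    def test_planted_mix_recovered(self, scheme):
        """A 70/30 organism mix at equal genome size is recovered."""
        rng = np.random.default_rng(7)
        ga = _genome(rng, "orgA", 3_000_000)
        gb = _genome(rng, "orgB", 3_000_000)
        n_a, n_b = 70, 30
        reads = [
            Read(f"a{i}", reverse_translate(rng, ga.proteins[i % 2].sequence[20:70]))
            for i in range(n_a)
        ] + [
            Read(f"b{i}", reverse_translate(rng, gb.proteins[i % 2].sequence[20:70]))
            for i in range(n_b)
        ]
        profile = taxon_profile(Dataset("s", reads), [ga, gb], scheme)
        frac = profile.loc["orgA", "fraction"]
        sigma = np.sqrt(0.7 * 0.3 / 100)
        assert abs(frac - 0.7) <= 3 * sigma

    def test_sizeless_genome_excluded_with_warning(self, scheme):
        rng = np.random.default_rng(8)
        ga = _genome(rng, "orgA", 3_000_000)
        gb = _genome(rng, "orgB", None)
        read = Read("a0", reverse_translate(rng, ga.proteins[0].sequence[10:60]))
        with pytest.warns(UserWarning, match="no size"):
            profile = taxon_profile(Dataset("s", [read]), [ga, gb], scheme)
        assert "orgB" not in profile.index
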