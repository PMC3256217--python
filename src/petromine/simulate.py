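"""Synthetic data with known truth for every pipeline stage.

The generator emulates the study conditions of a 454-era biopile
time-course: four pooled pyrosequencing datasets (uncontaminated control,
t=0, t=1 month, t=1 year) carrying planted fragments of eight
hydrocarbon-degradation gene families whose per-taxon loads shift across
the time course, plus exact-copy artificial replicates and a qPCR
dilution-series/lambda-spike experiment.

Key modelling choices (see docs/methods.md):

* reference proteins are simulated ancestors per family with ~10%-mutated
  members, so within-family identity is ~80% (>= the 60% contract);
* planted reads are reverse-translated fragments with uniform synonymous
  codon choice, random strand and frame, and per-base substitutions;
* background reads are i.i.d. uniform nucleotides, which keeps chance
  recruitment rare at desk-scale database sizes;
* artificial replicates are exact copies of existing reads, optionally
  3'-truncated, matching the shared-start 454 artifact model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .io import Dataset, ProteinRef, Read
from .search import reverse_complement

__all__ = [
    "FamilySpec",
    "MetagenomeSpec",
    "Timecourse",
    "DEFAULT_FAMILIES",
    "DEFAULT_LOAD_PROFILE",
    "DEFAULT_READ_COUNTS",
    "DEFAULT_MEAN_LENGTHS",
    "GROUP_LINEAGES",
    "generate_reference_panel",
    "generate_metagenome",
    "generate_timecourse",
    "generate_qpcr_experiment",
    "reverse_translate",
    "global_identity",
]

# Robinson & Robinson-like background amino-acid frequencies (order ARNDCQEGHILKMFPSTWYV)
_AA = "ARNDCQEGHILKMFPSTWYV"
_AA_FREQ = np.array(
    [7.8, 5.1, 4.5, 5.4, 1.9, 4.3, 6.3, 7.4, 2.2, 5.1,
     9.1, 5.7, 2.2, 3.9, 5.2, 7.1, 5.8, 1.3, 3.2, 6.4]
)
_AA_FREQ = _AA_FREQ / _AA_FREQ.sum()

_CODONS_FOR_AA: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS_FOR_AA.setdefault(_aa, []).append(_codon)
for _aa in _CODONS_FOR_AA:
    _CODONS_FOR_AA[_aa].sort()

#: phylum/class group label -> (phylum, class-if-Proteobacteria, representative genus)
GROUP_LINEAGES: dict[str, tuple[str, str, str]] = {
    "Actinobacteria": ("Actinobacteria", "", "Rhodococcus"),
    "Alphaproteobacteria": ("Proteobacteria", "Alphaproteobacteria", "Sphingomonas"),
    "Betaproteobacteria": ("Proteobacteria", "Betaproteobacteria", "Burkholderia"),
    "Gammaproteobacteria": ("Proteobacteria", "Gammaproteobacteria", "Pseudomonas"),
    "Deltaproteobacteria": ("Proteobacteria", "Deltaproteobacteria", "Myxococcus"),
    "Firmicutes": ("Firmicutes", "", "Bacillus"),
    "Acidobacteria": ("Acidobacteria", "", "Solibacter"),
    "Chloroflexi": ("Chloroflexi", "", "Chloroflexus"),
    "Bacteroidetes": ("Bacteroidetes", "", "Flavobacterium"),
    "Deinococcus-Thermus": ("Deinococcus-Thermus", "", "Deinococcus"),
    "Planctomycetes": ("Planctomycetes", "", "Planctomyces"),
    "Gemmatimonadetes": ("Gemmatimonadetes", "", "Gemmatimonas"),
    "Eukaryotes": ("Eukaryotes", "", ""),
    "synthetic construct": ("synthetic construct", "", ""),
    "uncultured/unclassified": ("uncultured/unclassified", "", ""),
}


@dataclass
class FamilySpec:
    """One target gene family in a reference panel.

    ``ec_numbers`` lists the primary EC first, then accepted synonyms.
    ``synonym_families`` are closely related families whose members appear
    in the confirmation database only (best hits to them are kept by the
    synonym rule during confirmation).
    """

    family_id: str
    ec_numbers: tuple[str, ...]
    accessions: tuple[str, ...]
    member_taxa: tuple[str, ...]
    protein_length: int = 300
    synonym_families: tuple[tuple[str, str], ...] = ()  # (family_id, ec)

    def __post_init__(self) -> None:
        if self.protein_length < 100:
            raise ValueError(f"{self.family_id}: protein_length must be >= 100")
        if self.n_reference_proteins < 1:
            raise ValueError(f"{self.family_id}: need at least one reference protein")
        for g in self.member_taxa:
            if g not in GROUP_LINEAGES:
                raise ValueError(f"{self.family_id}: unknown taxon group {g!r}")

    @property
    def n_reference_proteins(self) -> int:
        return len(self.accessions)


# The eight families with the study's EC numbers and SwissProt reference
# accessions.  Gentisate 1,2-dioxygenase is EC 1.13.11.4.
DEFAULT_FAMILIES: tuple[FamilySpec, ...] = (
    FamilySpec(
        "alkane_1_monooxygenase", ("1.14.15.3",), ("O05895", "P12691"),
        ("Actinobacteria", "Alphaproteobacteria", "Betaproteobacteria",
         "Gammaproteobacteria", "Firmicutes", "Eukaryotes",
         "synthetic construct", "uncultured/unclassified"),
    ),
    FamilySpec(
        "cytochrome_p450_cyp153", ("1.14.-.-",), ("Q2MHE2", "A9CMS7"),
        ("Acidobacteria", "Actinobacteria", "Alphaproteobacteria",
         "Betaproteobacteria", "Gammaproteobacteria", "Deltaproteobacteria",
         "Chloroflexi", "Firmicutes", "Planctomycetes", "Eukaryotes",
         "uncultured/unclassified"),
    ),
    FamilySpec(
        "protocatechuate_3_4_dioxygenase", ("1.13.11.3",),
        ("P20371", "P20372", "Q8NN16", "Q8NN15"),
        ("Actinobacteria", "Alphaproteobacteria", "Betaproteobacteria",
         "Gammaproteobacteria", "Eukaryotes", "uncultured/unclassified"),
    ),
    FamilySpec(
        "catechol_1_2_dioxygenase", ("1.13.11.1",), ("P95607", "P07773"),
        ("Actinobacteria", "Alphaproteobacteria", "Betaproteobacteria",
         "Gammaproteobacteria", "Bacteroidetes", "uncultured/unclassified"),
    ),
    FamilySpec(
        "gentisate_1_2_dioxygenase", ("1.13.11.4",), ("Q13ZY3", "Q0SFK9"),
        ("Actinobacteria", "Alphaproteobacteria", "Betaproteobacteria",
         "Gammaproteobacteria"),
    ),
    FamilySpec(
        "homogentisate_1_2_dioxygenase", ("1.13.11.5",), ("B8H072", "Q828S5"),
        ("Acidobacteria", "Actinobacteria", "Alphaproteobacteria",
         "Betaproteobacteria", "Gammaproteobacteria", "Deltaproteobacteria",
         "Bacteroidetes", "Chloroflexi", "Firmicutes", "Gemmatimonadetes"),
    ),
    FamilySpec(
        "catechol_2_3_dioxygenase", ("1.13.11.2", "1.13.11.39", "1.13.11.-"),
        ("P06622", "Q53034"),
        ("Actinobacteria", "Alphaproteobacteria", "Betaproteobacteria",
         "Gammaproteobacteria", "Chloroflexi", "Deinococcus-Thermus",
         "Firmicutes", "uncultured/unclassified"),
        synonym_families=(
            ("biphenyl_2_3_diol_1_2_dioxygenase", "1.13.11.39"),
            ("dihydroxynaphthalene_dioxygenase", "1.13.11.-"),
        ),
    ),
    FamilySpec(
        "protocatechuate_4_5_dioxygenase", ("1.13.11.8",), ("P22635",),
        ("Actinobacteria", "Alphaproteobacteria", "Betaproteobacteria",
         "Gammaproteobacteria"),
    ),
)

#: which recruiting family a synonym subfamily belongs to
SYNONYM_PARENT: dict[str, str] = {
    "biphenyl_2_3_diol_1_2_dioxygenase": "catechol_2_3_dioxygenase",
    "dihydroxynaphthalene_dioxygenase": "catechol_2_3_dioxygenase",
}

#: post-dereplication read counts of the four pooled datasets
DEFAULT_READ_COUNTS = {"uncont": 457781, "t0": 364725, "t1m": 108203, "t1y": 287705}
DEFAULT_MEAN_LENGTHS = {"uncont": 441, "t0": 343, "t1m": 327, "t1y": 350}
SAMPLE_ORDER = ("uncont", "t0", "t1m", "t1y")

# Planted-load profile: per-100-genomes values per (family, group) across the
# four samples, mirroring the published time-course patterns (Gamma-dominant
# alkB at t=0/t=1m, Actino/Alpha-dominant at t=1y, ~10x lower load in the
# uncontaminated control).  Expected planted read counts are these values
# times N_sample/750000.
DEFAULT_LOAD_PROFILE: dict[str, dict[str, tuple[float, float, float, float]]] = {
    "alkane_1_monooxygenase": {
        "Actinobacteria": (3.2, 24.8, 6.9, 57.3),
        "Alphaproteobacteria": (4.8, 24.8, 0.0, 36.5),
        "Betaproteobacteria": (0.0, 2.1, 0.0, 0.0),
        "Gammaproteobacteria": (1.6, 45.3, 62.4, 18.2),
        "Firmicutes": (0.0, 0.0, 0.0, 2.6),
        "Eukaryotes": (0.0, 0.0, 6.9, 0.0),
        "synthetic construct": (0.0, 2.1, 13.9, 2.6),
        "uncultured/unclassified": (1.6, 14.4, 27.7, 10.4),
    },
    "cytochrome_p450_cyp153": {
        "Acidobacteria": (1.6, 0.0, 0.0, 0.0),
        "Actinobacteria": (55.6, 105.0, 103.9, 130.0),
        "Alphaproteobacteria": (42.4, 54.0, 13.8, 52.0),
        "Betaproteobacteria": (3.2, 8.3, 0.0, 2.6),
        "Gammaproteobacteria": (1.6, 10.0, 6.9, 10.4),
        "Deltaproteobacteria": (9.8, 4.1, 0.0, 0.0),
        "Chloroflexi": (9.9, 0.0, 6.9, 0.0),
        "Firmicutes": (3.3, 0.0, 0.0, 0.0),
        "Planctomycetes": (0.0, 0.0, 0.0, 2.6),
        "Eukaryotes": (0.0, 2.1, 0.0, 0.0),
        "uncultured/unclassified": (4.9, 12.0, 13.9, 36.5),
    },
    "catechol_2_3_dioxygenase": {
        "Actinobacteria": (3.3, 2.1, 6.9, 5.2),
        "Alphaproteobacteria": (1.6, 10.3, 0.0, 5.2),
        "Betaproteobacteria": (0.0, 2.1, 0.0, 13.0),
        "Gammaproteobacteria": (0.0, 4.1, 20.8, 0.0),
        "Chloroflexi": (1.6, 0.0, 0.0, 0.0),
        "Deinococcus-Thermus": (3.2, 0.0, 0.0, 0.0),
        "Firmicutes": (4.8, 0.0, 6.9, 2.6),
        "uncultured/unclassified": (4.9, 18.5, 13.9, 13.0),
    },
    "biphenyl_2_3_diol_1_2_dioxygenase": {
        "Actinobacteria": (1.6, 20.7, 6.9, 15.6),
        "Alphaproteobacteria": (4.9, 10.4, 0.0, 10.4),
        "Betaproteobacteria": (1.6, 2.1, 6.9, 2.6),
        "Gammaproteobacteria": (1.6, 4.1, 0.0, 5.2),
        "uncultured/unclassified": (0.0, 2.1, 6.9, 0.0),
    },
    "dihydroxynaphthalene_dioxygenase": {
        "Alphaproteobacteria": (0.0, 2.1, 0.0, 0.0),
        "Gammaproteobacteria": (0.0, 2.1, 0.0, 0.0),
    },
    "protocatechuate_4_5_dioxygenase": {
        "Actinobacteria": (1.6, 6.2, 0.0, 0.0),
        "Alphaproteobacteria": (0.0, 10.4, 6.9, 2.6),
        "Betaproteobacteria": (0.0, 10.4, 0.0, 2.6),
        "Gammaproteobacteria": (1.6, 4.2, 0.0, 0.0),
    },
    "catechol_1_2_dioxygenase": {
        "Actinobacteria": (3.3, 14.5, 6.9, 7.8),
        "Alphaproteobacteria": (1.6, 14.5, 6.9, 13.0),
        "Betaproteobacteria": (3.2, 12.6, 0.0, 18.2),
        "Gammaproteobacteria": (1.6, 24.8, 13.8, 13.0),
        "Bacteroidetes": (1.6, 0.0, 0.0, 0.0),
        "uncultured/unclassified": (0.0, 6.2, 0.0, 5.2),
    },
    "protocatechuate_3_4_dioxygenase": {
        "Actinobacteria": (9.6, 22.7, 34.5, 7.8),
        "Alphaproteobacteria": (8.0, 2.1, 6.9, 2.6),
        "Betaproteobacteria": (13.0, 4.2, 6.9, 2.6),
        "Gammaproteobacteria": (8.2, 30.8, 27.7, 5.2),
        "Eukaryotes": (0.0, 0.0, 0.0, 2.6),
        "uncultured/unclassified": (8.2, 0.0, 6.9, 0.0),
    },
    "gentisate_1_2_dioxygenase": {
        "Actinobacteria": (0.0, 6.2, 13.8, 5.2),
        "Alphaproteobacteria": (6.5, 6.2, 0.0, 5.2),
        "Betaproteobacteria": (14.5, 17.0, 13.8, 15.6),
        "Gammaproteobacteria": (4.9, 0.0, 0.0, 0.0),
    },
    "homogentisate_1_2_dioxygenase": {
        "Acidobacteria": (4.9, 0.0, 0.0, 2.6),
        "Actinobacteria": (3.2, 2.1, 0.0, 0.0),
        "Alphaproteobacteria": (13.0, 31.0, 0.0, 33.8),
        "Betaproteobacteria": (14.6, 8.3, 6.9, 18.2),
        "Gammaproteobacteria": (8.2, 60.0, 13.9, 46.9),
        "Deltaproteobacteria": (1.6, 0.0, 0.0, 7.8),
        "Bacteroidetes": (1.6, 4.2, 0.0, 0.0),
        "Chloroflexi": (4.9, 0.0, 0.0, 2.6),
        "Firmicutes": (3.2, 0.0, 0.0, 0.0),
        "Gemmatimonadetes": (1.6, 0.0, 0.0, 0.0),
    },
}

#: background community composition used only to label non-planted reads
DEFAULT_TAXON_ABUNDANCES = {
    "Actinobacteria": 0.25,
    "Alphaproteobacteria": 0.15,
    "Betaproteobacteria": 0.08,
    "Gammaproteobacteria": 0.22,
    "Acidobacteria": 0.10,
    "Bacteroidetes": 0.05,
    "Chloroflexi": 0.04,
    "Firmicutes": 0.05,
    "uncultured/unclassified": 0.06,
}


# --- protein generation ----------------------------------------------------
def _random_protein(rng: np.random.Generator, length: int, freq=None) -> str:
    p = _AA_FREQ if freq is None else freq
    return "".join(rng.choice(list(_AA), size=length, p=p))


def _mutate_protein(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            choices = [a for a in _AA if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


_global_aligner: PairwiseAligner | None = None


def global_identity(a: str, b: str) -> float:
    """Identity fraction over a global (Needleman-Wunsch) alignment."""
    global _global_aligner
    if _global_aligner is None:
        _global_aligner = PairwiseAligner(mode="global")
        _global_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        _global_aligner.open_gap_score = -12
        _global_aligner.extend_gap_score = -1
    aln = _global_aligner.align(a, b)[0]
    counts = aln.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / length if length else 0.0


def generate_reference_panel(
    specs: tuple[FamilySpec, ...] | list[FamilySpec] = DEFAULT_FAMILIES,
    seed: int = 0,
    member_mutation: float = 0.10,
    synonym_divergence: float = 0.25,
    decoy_fraction: float = 0.25,
    max_decoy_identity: float = 0.25,
) -> tuple[list[ProteinRef], list[ProteinRef]]:
    """Simulate a reference panel and its confirmation database.

    The panel carries ``n_reference_proteins`` per family.  The confirmation
    database is a superset: the panel, one lineage-labelled homolog per
    (family, member taxon), synonym-subfamily homologs, and >= ``decoy_fraction``
    unrelated decoy proteins whose global identity to every family member is
    below ``max_decoy_identity``.
    """
    ids = [s.family_id for s in specs]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate family_id in panel spec: {sorted(ids)}")
    rng = np.random.default_rng(seed)
    panel: list[ProteinRef] = []
    confirm: list[ProteinRef] = []
    family_members: list[str] = []

    for fi, spec in enumerate(specs):
        ancestor = _random_protein(rng, spec.protein_length)
        ec = spec.ec_numbers
        taxa = list(spec.member_taxa) or ["uncultured/unclassified"]
        for i, acc in enumerate(spec.accessions):
            seq = _mutate_protein(rng, ancestor, member_mutation)
            phylum, cls, genus = GROUP_LINEAGES[taxa[i % len(taxa)]]
            ref = ProteinRef(
                accession=acc, sequence=seq, family=spec.family_id,
                ec_numbers=ec, phylum=phylum, proteo_class=cls, genus=genus,
            )
            panel.append(ref)
            confirm.append(ref)
            family_members.append(seq)
        for group in spec.member_taxa:
            seq = _mutate_protein(rng, ancestor, member_mutation)
            phylum, cls, genus = GROUP_LINEAGES[group]
            confirm.append(
                ProteinRef(
                    accession=f"H{fi:02d}_{spec.family_id[:10].upper()}_{group[:4].upper().replace('/', '')}",
                    sequence=seq, family=spec.family_id, ec_numbers=ec,
                    phylum=phylum, proteo_class=cls, genus=genus,
                )
            )
            family_members.append(seq)
        for syn_id, syn_ec in spec.synonym_families:
            syn_ancestor = _mutate_protein(rng, ancestor, synonym_divergence)
            syn_profile = DEFAULT_LOAD_PROFILE.get(syn_id, {})
            syn_taxa = tuple(syn_profile) or spec.member_taxa
            for group in syn_taxa:
                seq = _mutate_protein(rng, syn_ancestor, member_mutation)
                phylum, cls, genus = GROUP_LINEAGES[group]
                confirm.append(
                    ProteinRef(
                        accession=f"S{fi:02d}_{syn_id[:10].upper()}_{group[:4].upper().replace('/', '')}",
                        sequence=seq, family=syn_id, ec_numbers=(syn_ec,),
                        phylum=phylum, proteo_class=cls, genus=genus,
                    )
                )
                family_members.append(seq)

    n_decoys = max(4, math.ceil(decoy_fraction * len(panel)))
    uniform = np.full(20, 1 / 20)
    decoy_groups = [g for g in GROUP_LINEAGES if g not in
                    ("Eukaryotes", "synthetic construct", "uncultured/unclassified")]
    mean_len = int(np.mean([s.protein_length for s in specs]))
    for d in range(n_decoys):
        for _attempt in range(50):
            seq = _random_protein(rng, mean_len, freq=uniform)
            if all(global_identity(seq, fam) < max_decoy_identity
                   for fam in family_members):
                break
        else:  # pragma: no cover - vanishingly unlikely
            raise RuntimeError("could not generate a sufficiently unrelated decoy")
        group = decoy_groups[int(rng.integers(len(decoy_groups)))]
        phylum, cls, genus = GROUP_LINEAGES[group]
        confirm.append(
            ProteinRef(
                accession=f"DECOY_{d:03d}", sequence=seq, family=None,
                ec_numbers=(), phylum=phylum, proteo_class=cls, genus=genus,
            )
        )
    return panel, confirm


# --- read generation -------------------------------------------------------
@dataclass
class MetagenomeSpec:
    """Parameters of one simulated 454-style dataset."""

    sample_id: str
    n_reads: int
    read_length_mean: float = 350.0
    read_length_sd: float = 50.0
    duplicate_rate: float = 0.0
    taxon_abundances: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TAXON_ABUNDANCES)
    )
    planted_gene_load: dict[tuple[str, str], float] = field(default_factory=dict)
    mutation_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        if not (0 <= self.duplicate_rate < 1):
            raise ValueError("duplicate_rate must be in [0, 1)")
        if not (0 <= self.mutation_rate < 1):
            raise ValueError("mutation_rate must be in [0, 1)")
        total = sum(self.taxon_abundances.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"taxon abundances sum to {total}, expected 1")
        if sum(self.planted_gene_load.values()) > self.n_reads:
            raise ValueError("planted gene load exceeds n_reads")


def reverse_translate(rng: np.random.Generator, peptide: str) -> str:
    """DNA encoding ``peptide`` with uniformly random synonymous codons."""
    codons = []
    for aa in peptide:
        options = _CODONS_FOR_AA[aa]
        codons.append(options[int(rng.integers(len(options)))])
    return "".join(codons)


_BASES = "ACGT"


def _mutate_dna(rng: np.random.Generator, dna: str, rate: float) -> str:
    if rate <= 0:
        return dna
    out = list(dna)
    hits = np.flatnonzero(rng.random(len(out)) < rate)
    for i in hits:
        choices = [b for b in _BASES if b != out[i]]
        out[i] = choices[int(rng.integers(3))]
    return "".join(out)


def _fragment_read(
    rng: np.random.Generator, protein: str, length: int, mutation_rate: float
) -> str:
    """A read of ~``length`` bp from a random protein fragment, random strand."""
    naa = min(length // 3 + 2, len(protein))
    start = int(rng.integers(0, len(protein) - naa + 1))
    dna = reverse_translate(rng, protein[start : start + naa])
    offset = int(rng.integers(0, 3))
    dna = dna[offset : offset + length]
    dna = _mutate_dna(rng, dna, mutation_rate)
    if rng.random() < 0.5:
        dna = reverse_complement(dna)
    return dna


def _random_dna(rng: np.random.Generator, length: int) -> str:
    codes = rng.integers(0, 4, size=length)
    return codes.astype(np.uint8).choose(
        np.frombuffer(b"ACGT", dtype=np.uint8)
    ).tobytes().decode()


def _draw_length(rng: np.random.Generator, spec: MetagenomeSpec) -> int:
    return max(60, int(round(rng.normal(spec.read_length_mean, spec.read_length_sd))))


def generate_metagenome(
    spec: MetagenomeSpec,
    panel: list[ProteinRef],
    source_db: list[ProteinRef] | None = None,
) -> tuple[Dataset, pd.DataFrame]:
    """Emit a dataset of exactly ``spec.n_reads`` reads plus its truth table.

    Planted counts per (family, taxon group) are Poisson draws around the
    specified loads; planted reads are fragments of lineage-matched proteins
    from ``source_db`` (the confirmation database in time-course runs;
    defaults to the panel).  Artificial replicates are exact copies of
    already-emitted reads, optionally 3'-truncated, appended until the
    duplicate fraction is reached.

    The truth table has one row per emitted read: taxon group, genus,
    planted family ('' for background), source protein accession, and an
    artificial-replicate flag.
    """
    rng = np.random.default_rng(spec.seed)
    sources = source_db if source_db is not None else panel
    panel_families = {p.family for p in panel if p.family}
    by_family: dict[str, list[ProteinRef]] = {}
    for p in sources:
        if p.family:
            by_family.setdefault(p.family, []).append(p)

    for (family, group), load in spec.planted_gene_load.items():
        recruiting = SYNONYM_PARENT.get(family, family)
        if recruiting not in panel_families:
            raise ValueError(f"planted family {family!r} has no panel references")
        if family not in by_family:
            raise ValueError(f"planted family {family!r} absent from source database")
        if group not in GROUP_LINEAGES:
            raise ValueError(f"unknown taxon group {group!r}")

    n_dup = int(round(spec.duplicate_rate * spec.n_reads))
    planted_counts = {
        key: int(rng.poisson(load)) for key, load in spec.planted_gene_load.items()
    }
    n_planted = sum(planted_counts.values())
    n_background = spec.n_reads - n_dup - n_planted
    if n_background < 0:
        raise ValueError("planted gene load exceeds n_reads after duplicates")

    bg_groups = list(spec.taxon_abundances)
    bg_probs = np.array([spec.taxon_abundances[g] for g in bg_groups])
    bg_probs = bg_probs / bg_probs.sum()

    # base reads (background + planted), then shuffled
    rows: list[tuple[str, str, str, str]] = []  # sequence, group, family, accession
    bg_choice = rng.choice(len(bg_groups), size=n_background, p=bg_probs)
    for gi in bg_choice:
        rows.append((_random_dna(rng, _draw_length(rng, spec)), bg_groups[gi], "", ""))
    for (family, group), count in planted_counts.items():
        candidates = [p for p in by_family[family] if p.group == group]
        if not candidates:
            candidates = by_family[family]
        for _ in range(count):
            src = candidates[int(rng.integers(len(candidates)))]
            seq = _fragment_read(
                rng, src.sequence, _draw_length(rng, spec), spec.mutation_rate
            )
            rows.append((seq, group, family, src.accession))
    order = rng.permutation(len(rows))
    rows = [rows[i] for i in order]

    reads: list[Read] = []
    truth_rows: list[dict] = []
    for i, (seq, group, family, acc) in enumerate(rows):
        rid = f"{spec.sample_id}_{i:07d}"
        reads.append(Read(rid, seq))
        truth_rows.append(
            {
                "read_id": rid,
                "group": group,
                "genus": GROUP_LINEAGES[group][2],
                "family": family,
                "source_accession": acc,
                "is_artificial_replicate": False,
                "replicate_of": "",
            }
        )

    n_base = len(reads)
    for j in range(n_dup):
        src_i = int(rng.integers(n_base))
        src = reads[src_i]
        seq = src.sequence
        if rng.random() < 0.5:  # 3' truncation, same 5' start
            keep = int(round(len(seq) * rng.uniform(0.7, 1.0)))
            seq = seq[: max(keep, 60)]
        rid = f"{spec.sample_id}_dup{j:06d}"
        reads.append(Read(rid, seq))
        t = dict(truth_rows[src_i])
        t.update(read_id=rid, is_artificial_replicate=True, replicate_of=src.read_id)
        truth_rows.append(t)

    truth = pd.DataFrame(truth_rows)
    return Dataset(sample_id=spec.sample_id, reads=reads), truth


@dataclass
class Timecourse:
    """A simulated four-sample time course plus its reference databases."""

    panel: list[ProteinRef]
    confirmation_db: list[ProteinRef]
    samples: dict[str, tuple[Dataset, pd.DataFrame]]
    specs: dict[str, MetagenomeSpec]

    @property
    def sample_names(self) -> tuple[str, ...]:
        return tuple(self.samples)


def generate_timecourse(
    families: tuple[FamilySpec, ...] = DEFAULT_FAMILIES,
    scale: float = 1.0,
    seed: int = 0,
    duplicate_rate: float = 0.10,
    mutation_rate: float = 0.02,
    load_profile: dict[str, dict[str, tuple[float, float, float, float]]] | None = None,
    read_counts: dict[str, int] | None = None,
    mean_lengths: dict[str, int] | None = None,
) -> Timecourse:
    """Simulate the four pooled datasets (uncont, t0, t1m, t1y).

    Read counts default to the four post-dereplication dataset sizes scaled
    by ``scale``; emission is inflated by ``1 / (1 - duplicate_rate)`` so
    that removing the artificial replicates brings each sample back to its
    nominal size.  Planted loads are the per-100-genomes load profile
    converted to expected read counts at each (scaled) dataset size, so the
    planted signal per 100 genome equivalents is scale-invariant.
    """
    if scale <= 0:
        raise ValueError("scale factor must be positive")
    profile = load_profile if load_profile is not None else DEFAULT_LOAD_PROFILE
    counts = read_counts if read_counts is not None else DEFAULT_READ_COUNTS
    lengths = mean_lengths if mean_lengths is not None else DEFAULT_MEAN_LENGTHS
    ss = np.random.SeedSequence(seed)
    panel_seed, *sample_seeds = [
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(1 + len(SAMPLE_ORDER))
    ]
    panel, confirm_db = generate_reference_panel(families, seed=panel_seed)
    samples: dict[str, tuple[Dataset, pd.DataFrame]] = {}
    specs: dict[str, MetagenomeSpec] = {}
    for si, name in enumerate(SAMPLE_ORDER):
        n_target = max(1, int(round(counts[name] * scale)))
        n_reads = max(1, int(round(n_target / (1.0 - duplicate_rate))))
        load = {
            (family, group): values[si] * n_target / 750000.0
            for family, groups in profile.items()
            for group, values in groups.items()
            if values[si] > 0
        }
        spec = MetagenomeSpec(
            sample_id=name,
            n_reads=n_reads,
            read_length_mean=float(lengths[name]),
            read_length_sd=0.15 * float(lengths[name]),
            duplicate_rate=duplicate_rate,
            planted_gene_load=load,
            mutation_rate=mutation_rate,
            seed=sample_seeds[si],
        )
        specs[name] = spec
        samples[name] = generate_metagenome(spec, panel, source_db=confirm_db)
    return Timecourse(panel=panel, confirmation_db=confirm_db, samples=samples, specs=specs)


# --- qPCR simulation -------------------------------------------------------
LAMBDA_SPIKE_COPIES = 1e5  # copies per microlitre of the lambda spike

DEFAULT_QPCR_TARGETS = (
    "Pseudomonas_alkB",
    "Pseudomonas_ndoB",
    "Rhodococcus_alkB1",
    "Rhodococcus_alkB2",
)


def generate_qpcr_experiment(
    true_copies: dict[str, dict[str, float]],
    efficiency: float = 0.95,
    inhibition: dict[str, float] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    intercept: float = 38.0,
    standard_copies: tuple[float, ...] = (1e2, 1e3, 1e4, 1e5, 1e6, 1e7),
) -> pd.DataFrame:
    """Simulate Ct tables: dilution-series standards, unknowns, lambda spikes.

    ``true_copies`` maps sample -> {target -> copies per ng}.  Measured Ct
    follows ``Ct = intercept - log10(copies_eff) / log10(1 + efficiency)``
    plus Gaussian noise, where ``copies_eff`` is the true quantity reduced by
    the sample's inhibition fraction.  The lambda spike enters every sample
    at 1e5 copies/ul.
    """
    if not (0 < efficiency <= 1):
        raise ValueError("efficiency must be in (0, 1]")
    inhibition = inhibition or {}
    for s, inh in inhibition.items():
        if not (0 <= inh < 1):
            raise ValueError(f"inhibition for {s!r} must be in [0, 1)")
    rng = np.random.default_rng(seed)
    slope = -1.0 / math.log10(1.0 + efficiency)

    def ct_of(copies: float) -> float:
        if copies <= 0:
            raise ValueError("copies must be positive")
        ct = intercept + slope * math.log10(copies)
        if noise_sd > 0:
            ct += rng.normal(0.0, noise_sd)
        return ct

    targets = sorted({t for per in true_copies.values() for t in per})
    rows = []
    for target in targets + ["lambda"]:
        for copies in standard_copies:
            rows.append(
                {"sample": "standard", "target": target, "role": "standard",
                 "known_copies": copies, "ct": ct_of(copies)}
            )
    for sample, per_target in true_copies.items():
        factor = 1.0 - inhibition.get(sample, 0.0)
        for target, copies in per_target.items():
            rows.append(
                {"sample": sample, "target": target, "role": "unknown",
                 "known_copies": float("nan"), "ct": ct_of(copies * factor)}
            )
        rows.append(
            {"sample": sample, "target": "lambda", "role": "spike",
             "known_copies": float("nan"),
             "ct": ct_of(LAMBDA_SPIKE_COPIES * factor)}
        )
    return pd.DataFrame(rows)
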