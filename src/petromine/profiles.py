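"""Abundance normalization and reporting.

Raw hit counts from datasets of different sizes are made comparable in two
ways:

* **per 100 genomes** -- counts are scaled to 100 genome equivalents,
  taking a genome as 3 Mbp and a read as 400 bp, so 100 genomes = 300 Mbp
  = 750,000 reads; the normalized value is
  ``count * 750000 / n_reads``, reported to one decimal
  (half-away-from-zero);
* **subsampling** -- the recruitment analysis is re-run on a fixed-size
  random subsample (default 100,000 reads) of each dataset and raw counts
  are compared directly.

Agreement between the two is summarized by a Spearman rank correlation
over matching (family, sample) cells.  Printed table totals are sums of
the rounded per-group values, which is how the published tables add up.

Taxonomic profiles from whole-metagenome annotation correct for genome
size: organisms with larger genomes yield more fragments at equal
abundance, so fragment counts are divided by genome size before
renormalization.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats as _scipy_stats

from .io import Dataset, ProteinRef
from .preprocess import subsample as _subsample
from .recruit import RecruitmentRecord, aggregate_counts, confirm, recruit
from .search import PanelIndex, ScoringScheme, search_dataset

__all__ = [
    "READS_PER_100_GENOMES",
    "round_half_up",
    "normalize_per_100_genomes",
    "AbundanceTable",
    "table_totals",
    "PipelineContext",
    "normalize_by_subsampling",
    "concordance",
    "spearman",
    "Genome",
    "taxon_profile",
]

#: 100 genomes x 3 Mbp / 400 bp reads
READS_PER_100_GENOMES = 750_000


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the convention of the printed tables)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def normalize_per_100_genomes(raw_count: int, n_reads: int) -> float:
    """Hits per 100 genome equivalents, one decimal.

    ``value = round(raw_count * 750000 / n_reads, 1)`` -- dividing by read
    count, not base count, which is what reproduces the published
    single-hit increments (e.g. 750000/364725 -> 2.1).
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    if raw_count < 0:
        raise ValueError("raw_count must be non-negative")
    return round_half_up(raw_count * READS_PER_100_GENOMES / n_reads, 1)


@dataclass
class AbundanceTable:
    """Gene family x taxon group x sample counts with their normalization.

    ``raw`` is indexed by (family, group) with one column per sample;
    ``sample_n_reads`` holds the dataset size backing each sample column.
    """

    raw: pd.DataFrame
    sample_n_reads: dict[str, int]

    def __post_init__(self) -> None:
        missing = [c for c in self.raw.columns if c not in self.sample_n_reads]
        if missing:
            raise ValueError(f"no dataset size for sample column(s) {missing}")
        if (self.raw.to_numpy() < 0).any():
            raise ValueError("raw counts must be non-negative")

    @property
    def normalized(self) -> pd.DataFrame:
        """Per-100-genomes values, one decimal per cell."""
        out = {}
        for col in self.raw.columns:
            n = self.sample_n_reads[col]
            out[col] = [
                normalize_per_100_genomes(int(v), n) for v in self.raw[col]
            ]
        return pd.DataFrame(out, index=self.raw.index)


def table_totals(table: AbundanceTable) -> pd.DataFrame:
    """Per-(family, sample) totals as sums of the rounded per-group values.

    This is the printed-table convention: totals add the one-decimal group
    values rather than normalizing the summed raw count.
    """
    norm = table.normalized
    totals = norm.groupby(level="family").sum()
    return totals.map(lambda v: round_half_up(v, 1))


@dataclass
class PipelineContext:
    """Everything needed to (re-)run recruitment on a dataset.

    Caches confirmed records per sample so that subsampling normalization
    can reuse the full run (the search is deterministic, so counting the
    full-run records that fall inside a subsample is identical to
    re-running the search on the subsample).
    """

    panel: list[ProteinRef]
    confirmation_db: list[ProteinRef]
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    e_max: float = 0.10
    prefilter_k: int | None = None
    synonym_map: dict[str, tuple[str, ...]] | None = None
    confirmed_records: dict[str, list[RecruitmentRecord]] = field(default_factory=dict)
    _panel_index: PanelIndex | None = None
    _confirm_index: PanelIndex | None = None

    def _indexes(self) -> tuple[PanelIndex | None, PanelIndex | None]:
        if self.prefilter_k is None:
            return None, None
        if self._panel_index is None:
            self._panel_index = PanelIndex(self.panel, self.prefilter_k)
            self._confirm_index = PanelIndex(self.confirmation_db, self.prefilter_k)
        return self._panel_index, self._confirm_index

    def run(self, dataset: Dataset) -> list[RecruitmentRecord]:
        """Recruit + confirm ``dataset``, caching the result by sample id."""
        if dataset.sample_id in self.confirmed_records:
            return self.confirmed_records[dataset.sample_id]
        pidx, cidx = self._indexes()
        records = recruit(
            dataset, self.panel, self.scheme, e_max=self.e_max,
            prefilter_k=self.prefilter_k, index=pidx,
        )
        records = confirm(
            records, self.confirmation_db, self.scheme,
            synonym_map=self.synonym_map, dataset=dataset,
            prefilter_k=self.prefilter_k, index=cidx,
        )
        self.confirmed_records[dataset.sample_id] = records
        return records


def normalize_by_subsampling(
    dataset: Dataset,
    context: PipelineContext,
    n: int = 100_000,
    seed: int = 0,
) -> pd.Series:
    """Raw per-family confirmed counts in an ``n``-read random subsample.

    If the full dataset has already been run through ``context`` the cached
    records are filtered to the subsample (equivalent to re-running, since
    the search is deterministic per read).  When ``n`` exceeds the dataset
    size the full dataset is used with a warning.
    """
    if n >= dataset.n_reads:
        if n > dataset.n_reads:
            warnings.warn(
                f"subsample size {n} exceeds dataset size {dataset.n_reads}; "
                "using the full dataset"
            )
        sub_ids = set(dataset.read_ids())
    else:
        sub_ids = set(_subsample(dataset, n, seed=seed).read_ids())
    records = context.run(dataset)
    kept = [
        r for r in records if r.status == "confirmed" and r.read_id in sub_ids
    ]
    counts = pd.Series(
        [r.family_id for r in kept], dtype="object"
    ).value_counts().sort_index()
    counts.name = dataset.sample_id
    counts.index.name = "family"
    return counts


# --- Spearman concordance --------------------------------------------------
def _average_ranks(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt((a @ a) * (b @ b))
    return float(a @ b / denom) if denom > 0 else float("nan")


def spearman(x, y, exact_below: int = 10) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The p-value uses the large-sample t approximation; below
    ``exact_below`` pairs it is an exact permutation test.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 2:
        raise ValueError("need two equal-length samples with >= 2 values")
    rx, ry = _average_ranks(x), _average_ranks(y)
    rho = _pearson(rx, ry)
    n = len(x)
    if math.isnan(rho):
        return rho, float("nan")
    if n < exact_below:
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = _pearson(rx, np.array(perm))
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        return rho, count / total
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * math.sqrt((n - 2) / (1 - rho * rho))
    p = 2.0 * float(_scipy_stats.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0)


def concordance(
    per100_table: pd.DataFrame, subsample_table: pd.DataFrame
) -> tuple[float, float, int]:
    """Spearman rho over matching (family, sample) cells of two tables.

    Both tables are indexed by family with one column per sample (the
    per-100-genomes family totals and the subsample raw counts).  Cells
    present in only one table count as zero in the other, since an absent
    family simply had no confirmed hits.
    """
    fams = sorted(set(per100_table.index) | set(subsample_table.index))
    cols = [c for c in per100_table.columns if c in subsample_table.columns]
    a = per100_table.reindex(index=fams, columns=cols).fillna(0.0)
    b = subsample_table.reindex(index=fams, columns=cols).fillna(0.0)
    x = a.to_numpy().ravel()
    y = b.to_numpy().ravel()
    if len(x) < 5:
        raise ValueError("need at least 5 paired cells for concordance")
    rho, p = spearman(x, y)
    return rho, p, len(x)


# --- genome-size-corrected taxonomic profiles ------------------------------
@dataclass
class Genome:
    """A reference genome: organism label, size in bp, and its proteins."""

    organism: str
    genome_size: int | None
    proteins: list[ProteinRef]


def taxon_profile(
    dataset: Dataset,
    genomes: list[Genome],
    scheme: ScoringScheme | None = None,
    e_max: float = 1e-5,
    min_aln_bp: int = 50,
    prefilter_k: int | None = None,
) -> pd.DataFrame:
    """Genome-size-corrected taxonomic profile of a dataset.

    Each read's best hit at E <= ``e_max`` spanning >= ``min_aln_bp`` bp on
    the read increments its organism's fragment count; corrected abundance
    divides by genome size (larger genomes attract more hits at equal cell
    abundance) and relative fractions are renormalized over classified
    organisms.  Genomes without a size are excluded with a warning.
    """
    scheme = scheme or ScoringScheme()
    usable = []
    for g in genomes:
        if not g.genome_size or g.genome_size <= 0:
            warnings.warn(f"genome {g.organism!r} has no size; excluded")
        else:
            usable.append(g)
    if not usable:
        raise ValueError("no genomes with sizes")
    organism_of: dict[str, str] = {}
    pooled: list[ProteinRef] = []
    for g in usable:
        for p in g.proteins:
            organism_of[p.accession] = g.organism
            pooled.append(p)
    hits_by_read = search_dataset(
        dataset, pooled, scheme, e_max=e_max, prefilter_k=prefilter_k
    )
    counts = {g.organism: 0 for g in usable}
    for hits in hits_by_read.values():
        good = [h for h in hits if h.alignment_span_bp >= min_aln_bp]
        if not good:
            continue
        best = max(good, key=lambda h: h.bit_score)
        counts[organism_of[best.subject_accession]] += 1
    rows = []
    for g in usable:
        corrected = counts[g.organism] / g.genome_size
        rows.append(
            {
                "organism": g.organism,
                "fragment_count": counts[g.organism],
                "genome_size": g.genome_size,
                "corrected_abundance": corrected,
            }
        )
    df = pd.DataFrame(rows).set_index("organism")
    total = df["corrected_abundance"].sum()
    df["fraction"] = df["corrected_abundance"] / total if total > 0 else 0.0
    return df
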