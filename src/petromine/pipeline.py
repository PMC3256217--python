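"""End-to-end orchestration: simulate -> dereplicate -> recruit -> profile.

`run_timecourse` is the analytic core: it simulates the four-sample time
course, removes artificial replicates, runs recruitment + confirmation,
builds both normalizations (per 100 genomes and fixed-size subsampling),
measures their Spearman concordance, and scores recovery against the
simulation truth.  `run_full` wraps it with file outputs and a manifest
(seed, config hash, versions) so any run can be reproduced exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .io import Dataset, write_fasta, write_protein_fasta
from .preprocess import dataset_stats, remove_artificial_replicates
from .profiles import (
    AbundanceTable,
    PipelineContext,
    concordance,
    normalize_by_subsampling,
    table_totals,
)
from .qpcr import analyze_qpcr
from .recruit import RecruitmentRecord, aggregate_counts, flag_weak_recruits
from .search import ScoringScheme
from .simulate import (
    SAMPLE_ORDER,
    SYNONYM_PARENT,
    Timecourse,
    generate_qpcr_experiment,
    generate_timecourse,
)

logger = logging.getLogger("petromine")

__all__ = ["PipelineConfig", "TimecourseResult", "run_timecourse", "run_full"]


@dataclass
class PipelineConfig:
    """All knobs of a pipeline run; round-trips losslessly through YAML."""

    seed: int = 0
    scale: float = 1.0
    duplicate_rate: float = 0.10
    mutation_rate: float = 0.02
    recruit_e: float = 0.10
    annotate_e: float = 1e-5
    min_aln_bp: int = 50
    weak_e: float = 1e-30
    subsample_n: int = 100_000
    prefilter_k: int | None = 6
    gap_open: float = 11.0
    gap_extend: float = 1.0
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041
    matrix: str = "BLOSUM62"
    output_dir: str = "petromine_out"
    qpcr_csv: str | None = None

    def __post_init__(self) -> None:
        for name in ("recruit_e", "annotate_e", "weak_e"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def scheme(self) -> ScoringScheme:
        return ScoringScheme(
            matrix_name=self.matrix,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
            lam=self.karlin_lambda,
            k=self.karlin_k,
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        """Hash of the analytic parameters (where outputs go is excluded)."""
        fields = {k: v for k, v in asdict(self).items() if k != "output_dir"}
        blob = yaml.safe_dump(fields, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class TimecourseResult:
    """Everything computed from one simulated time-course run."""

    timecourse: Timecourse
    derep: dict[str, Dataset]
    records: dict[str, list[RecruitmentRecord]]
    abundance: AbundanceTable
    per100_family: pd.DataFrame  # family x sample, per-100-genomes totals
    subsample_counts: pd.DataFrame  # family x sample, raw subsample counts
    rho: float
    rho_p: float
    n_cells: int
    weak_report: pd.DataFrame
    family_recall: float
    taxon_precision: float
    stats: dict[str, dict] = field(default_factory=dict)


def _truth_metrics(
    timecourse: Timecourse, records: dict[str, list[RecruitmentRecord]]
) -> tuple[float, float]:
    """Family recall over planted reads; taxon-group precision over
    confirmed planted reads."""
    n_planted = 0
    n_recalled = 0
    n_conf_planted = 0
    n_group_ok = 0
    for name, (_, truth) in timecourse.samples.items():
        planted = truth[(truth["family"] != "") & (~truth["is_artificial_replicate"])]
        truth_by_read = planted.set_index("read_id")
        confirmed = {
            r.read_id: r for r in records.get(name, []) if r.status == "confirmed"
        }
        n_planted += len(planted)
        for read_id, row in truth_by_read.iterrows():
            rec = confirmed.get(read_id)
            if rec is None:
                continue
            expected_family = SYNONYM_PARENT.get(row["family"], row["family"])
            if rec.family_id == expected_family:
                n_recalled += 1
            n_conf_planted += 1
            if rec.assigned_group == row["group"]:
                n_group_ok += 1
    recall = n_recalled / n_planted if n_planted else float("nan")
    precision = n_group_ok / n_conf_planted if n_conf_planted else float("nan")
    return recall, precision


def run_timecourse(
    config: PipelineConfig | None = None, progress: bool = False
) -> TimecourseResult:
    """Simulate and analyse the four-sample time course end to end."""
    config = config or PipelineConfig()
    t0 = time.time()

    def _log(msg: str) -> None:
        logger.info("%s (t=%.0fs)", msg, time.time() - t0)
        if progress:
            print(f"[petromine +{time.time() - t0:6.0f}s] {msg}", flush=True)

    tc = generate_timecourse(
        scale=config.scale,
        seed=config.seed,
        duplicate_rate=config.duplicate_rate,
        mutation_rate=config.mutation_rate,
    )
    _log("simulated time course")

    context = PipelineContext(
        panel=tc.panel,
        confirmation_db=tc.confirmation_db,
        scheme=config.scheme(),
        e_max=config.recruit_e,
        prefilter_k=config.prefilter_k,
    )
    derep: dict[str, Dataset] = {}
    records: dict[str, list[RecruitmentRecord]] = {}
    stats: dict[str, dict] = {}
    all_records: list[RecruitmentRecord] = []
    for name in tc.sample_names:
        dataset, _truth = tc.samples[name]
        clean, report = remove_artificial_replicates(dataset)
        derep[name] = clean
        st = dataset_stats(clean)
        stats[name] = {
            "n_input_reads": dataset.n_reads,
            "n_reads": st.n_reads,
            "n_removed_replicates": int((report["action"] == "removed").sum()),
            "mean_length": st.mean_length,
            "total_mbp": st.total_mbp,
        }
        _log(f"{name}: dereplicated {dataset.n_reads} -> {clean.n_reads} reads")
        recs = context.run(clean)
        records[name] = recs
        all_records.extend(recs)
        _log(
            f"{name}: {len(recs)} recruits, "
            f"{sum(r.status == 'confirmed' for r in recs)} confirmed"
        )

    raw = aggregate_counts(all_records, level="phylum_class")
    raw = raw.reindex(columns=list(SAMPLE_ORDER), fill_value=0)
    n_reads = {name: derep[name].n_reads for name in tc.sample_names}
    abundance = AbundanceTable(raw=raw.astype(int), sample_n_reads=n_reads)
    families = sorted({p.family for p in tc.panel if p.family})
    per100_family = table_totals(abundance).reindex(families, fill_value=0.0)

    sub_cols = {}
    for name in tc.sample_names:
        sub_cols[name] = normalize_by_subsampling(
            derep[name], context, n=config.subsample_n, seed=config.seed
        )
    subsample_counts = (
        pd.DataFrame(sub_cols).reindex(families).fillna(0).astype(int)
    )
    subsample_counts.index.name = "family"
    _log("built both normalizations")

    rho, p, n_cells = concordance(per100_family, subsample_counts)
    weak = flag_weak_recruits(all_records, e_threshold=config.weak_e)
    recall, precision = _truth_metrics(tc, records)
    _log(f"concordance rho={rho:.3f}; recall={recall:.3f}; precision={precision:.3f}")

    return TimecourseResult(
        timecourse=tc,
        derep=derep,
        records=records,
        abundance=abundance,
        per100_family=per100_family,
        subsample_counts=subsample_counts,
        rho=rho,
        rho_p=p,
        n_cells=n_cells,
        weak_report=weak,
        family_recall=recall,
        taxon_precision=precision,
        stats=stats,
    )


def _write_table(df: pd.DataFrame, path: Path, header: str) -> None:
    with open(path, "w") as fh:
        fh.write(header)
        df.to_csv(fh, sep="\t")


def records_to_frame(records: list[RecruitmentRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "read_id": r.read_id,
                "sample": r.sample_id,
                "family": r.family_id,
                "status": r.status,
                "group": r.assigned_group,
                "genus": r.assigned_genus,
                "recruit_E": r.recruit_hit.evalue,
                "confirm_E": r.confirm_hit.evalue if r.confirm_hit else float("nan"),
                "accession": r.confirm_hit.subject_accession if r.confirm_hit else "",
                "reason": r.reason,
            }
        )
    return pd.DataFrame(rows)


def run_full(config: PipelineConfig, progress: bool = False) -> TimecourseResult:
    """Run the time course and write all report tables under ``output_dir``."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = run_timecourse(config, progress=progress)
    header = f"# petromine {__version__} seed={config.seed} config={config.digest()}\n"

    write_protein_fasta(result.timecourse.panel, out / "reference_panel.faa")
    write_protein_fasta(result.timecourse.confirmation_db, out / "confirmation_db.faa")
    for name, dataset in result.derep.items():
        write_fasta(dataset, out / f"reads_{name}.derep.fasta")
    _write_table(
        result.abundance.normalized, out / "abundance_per100.tsv", header
    )
    _write_table(result.abundance.raw, out / "abundance_raw.tsv", header)
    _write_table(result.per100_family, out / "family_totals_per100.tsv", header)
    _write_table(result.subsample_counts, out / "family_counts_subsample.tsv", header)
    _write_table(result.weak_report.set_index("stratum"), out / "weak_recruits.tsv", header)
    all_records = [r for recs in result.records.values() for r in recs]
    _write_table(
        records_to_frame(all_records).set_index("read_id"),
        out / "recruitment_records.tsv",
        header,
    )

    qpcr_result = None
    if config.qpcr_csv:
        table = pd.read_csv(config.qpcr_csv)
        qpcr_result = analyze_qpcr(table)
        _write_table(qpcr_result.set_index("sample"), out / "qpcr_results.tsv", header)

    manifest = {
        "package": "petromine",
        "version": __version__,
        "seed": config.seed,
        "config_digest": config.digest(),
        "config": asdict(config),
        "samples": result.stats,
        "concordance_rho": result.rho,
        "concordance_p": result.rho_p,
        "family_recall": result.family_recall,
        "taxon_precision": result.taxon_precision,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    config.to_yaml(out / "config.yaml")
    return result


def simulate_qpcr_demo(seed: int = 0) -> pd.DataFrame:
    """A small deterministic qPCR experiment table for demos and the CLI."""
    true_copies = {
        "t0": {"Pseudomonas_alkB": 2.02e5, "Pseudomonas_ndoB": 9.5e4,
               "Rhodococcus_alkB1": 3.4e3, "Rhodococcus_alkB2": 2.4e3},
        "t1m": {"Pseudomonas_alkB": 3.02e5, "Pseudomonas_ndoB": 1.4e5,
                "Rhodococcus_alkB1": 4.8e3, "Rhodococcus_alkB2": 3.8e3},
        "t1y": {"Pseudomonas_alkB": 4.8e4, "Pseudomonas_ndoB": 9.0e3,
                "Rhodococcus_alkB1": 1.6e4, "Rhodococcus_alkB2": 1.25e4},
        "uncont": {"Pseudomonas_alkB": 1.7e2, "Pseudomonas_ndoB": 4.0e1,
                   "Rhodococcus_alkB1": 6.5e1, "Rhodococcus_alkB2": 6.0e1},
    }
    inhibition = {"t0": 0.20, "t1m": 0.062, "t1y": 0.451, "uncont": 0.0}
    return generate_qpcr_experiment(
        true_copies, efficiency=0.95, inhibition=inhibition,
        noise_sd=0.05, seed=seed,
    )
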