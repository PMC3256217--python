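"""Dataset statistics, 454 artificial-replicate removal, and subsampling.

Artificial replicates are a pyrosequencing artifact: multiple reads from
the same template that share a 5' start position.  Two reads are treated as
replicates when their first ``prefix_len`` bases are identical and their
end-free global identity over the shorter read's length reaches
``identity_threshold``; the longest read of each replicate cluster is kept
(ties broken by input order).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd

from .io import Dataset, Read

__all__ = [
    "DatasetStats",
    "dataset_stats",
    "remove_artificial_replicates",
    "subsample",
]


@dataclass(frozen=True)
class DatasetStats:
    n_reads: int
    mean_length: int
    total_bp: int
    total_mbp: int


def dataset_stats(d: Dataset) -> DatasetStats:
    """Read count, mean length (bp), total bp and total Mbp (rounded)."""
    if d.n_reads == 0:
        raise ValueError("dataset is empty")
    total = d.total_bp
    return DatasetStats(
        n_reads=d.n_reads,
        mean_length=round(total / d.n_reads),
        total_bp=total,
        total_mbp=round(total / 1_000_000),
    )


def _prefix_identity(shorter: str, longer: str) -> float:
    """Identity of ``shorter`` against ``longer`` over the shorter's length.

    End-free at the 3' end of the longer read (shared 5' start, 3'
    truncation allowed), computed as 1 - edit_distance / len(shorter).
    """
    res = edlib.align(shorter, longer, mode="SHW", task="distance")
    return 1.0 - res["editDistance"] / len(shorter)


def _is_replicate(a: Read, b: Read, prefix_len: int, threshold: float) -> bool:
    pa, pb = a.sequence[:prefix_len], b.sequence[:prefix_len]
    if pa != pb:
        return False
    if a.length <= b.length:
        return _prefix_identity(a.sequence, b.sequence) >= threshold
    return _prefix_identity(b.sequence, a.sequence) >= threshold


def remove_artificial_replicates(
    d: Dataset,
    prefix_len: int = 3,
    identity_threshold: float = 0.90,
    method: str = "auto",
    exact_max_reads: int = 5000,
    candidate_prefix: int = 16,
) -> tuple[Dataset, pd.DataFrame]:
    """Cluster replicate reads and keep the longest per cluster.

    Two clustering strategies share the same replicate definition:

    * ``exact`` - greedy all-pairs comparison against cluster
      representatives within each ``prefix_len`` bucket (quadratic; the
      reference behaviour);
    * ``prefix`` - candidate clusters first require ``candidate_prefix``
      identical leading bases, which is exact for replicates that are
      copies of their template over the first ~16 bp (the 454 artifact
      model) and scales linearly.

    ``auto`` picks ``exact`` up to ``exact_max_reads`` reads.  Returns the
    dereplicated dataset (input order preserved) and a report with one row
    per read: read_id, cluster_id, action (kept/removed).
    """
    if prefix_len < 1:
        raise ValueError("prefix_len must be >= 1")
    if not (0 < identity_threshold <= 1):
        raise ValueError("identity_threshold must be in (0, 1]")
    if method == "auto":
        method = "exact" if d.n_reads <= exact_max_reads else "prefix"
    if method not in {"exact", "prefix"}:
        raise ValueError(f"unknown method {method!r}")

    # order candidates longest-first (stable on input order) so the kept
    # representative of each cluster is the longest member
    order = sorted(range(d.n_reads), key=lambda i: -d.reads[i].length)
    cluster_of = np.full(d.n_reads, -1, dtype=np.int64)
    representatives: dict[str, list[int]] = {}  # bucket -> cluster rep indices
    n_clusters = 0

    def bucket_key(r: Read) -> str:
        if method == "exact":
            return r.sequence[:prefix_len]
        return r.sequence[: max(prefix_len, candidate_prefix)]

    for i in order:
        read = d.reads[i]
        key = bucket_key(read)
        reps = representatives.setdefault(key, [])
        for rep_i in reps:
            if _is_replicate(read, d.reads[rep_i], prefix_len, identity_threshold):
                cluster_of[i] = cluster_of[rep_i]
                break
        else:
            cluster_of[i] = n_clusters
            n_clusters += 1
            reps.append(i)

    # keep the longest read per cluster; ties -> first by input order
    keeper: dict[int, int] = {}
    for i, cid in enumerate(cluster_of):
        cid = int(cid)
        if cid not in keeper:
            keeper[cid] = i
        else:
            j = keeper[cid]
            if d.reads[i].length > d.reads[j].length:
                keeper[cid] = i
    kept = set(keeper.values())

    out_reads = [d.reads[i] for i in range(d.n_reads) if i in kept]
    report = pd.DataFrame(
        {
            "read_id": [r.read_id for r in d.reads],
            "cluster_id": cluster_of,
            "action": ["kept" if i in kept else "removed" for i in range(d.n_reads)],
        }
    )
    return Dataset(sample_id=d.sample_id, reads=out_reads), report


def subsample(d: Dataset, n: int, seed: int = 0) -> Dataset:
    """Uniform sample of ``n`` reads without replacement, order preserved."""
    if n <= 0:
        raise ValueError("n must be positive")
    if n > d.n_reads:
        raise ValueError(f"cannot sample {n} reads from {d.n_reads}")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(d.n_reads, size=n, replace=False))
    return Dataset(sample_id=d.sample_id, reads=[d.reads[i] for i in idx])
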