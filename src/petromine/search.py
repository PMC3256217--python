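"""Six-frame translated local alignment with BLAST-style statistics.

This is the computational engine standing in for blastx/tblastn in the
gene-recruitment pipeline: every read is translated in all six frames and
locally aligned (affine-gap Smith-Waterman, BLOSUM62) against a protein
panel; raw scores are converted to bit scores and E-values with fixed
Karlin-Altschul parameters.

Two search paths are provided.  :func:`search_read` is the exact reference
path (every frame against every panel member).  :func:`search_dataset` is a
seeded accelerator for dataset-scale runs: six-frame translations are
vectorized in bulk and only reads sharing an exact amino-acid k-mer with a
panel protein are aligned, against those candidate proteins only.  Planted
or genuinely homologous reads always carry exact k-mers, so the two paths
agree on real hits; the accelerator silently drops a small fraction of
borderline chance alignments (see the methods note).

Alignments never cross a stop codon: peptides are split at ``*`` and each
open segment is aligned separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

from .io import Dataset, ProteinRef, Read

__all__ = [
    "ScoringScheme",
    "AlignmentHit",
    "LocalAlignment",
    "six_frame_translate",
    "reverse_complement",
    "local_align",
    "search_read",
    "search_dataset",
    "PanelIndex",
    "hits_to_outfmt6",
]

FRAMES = (1, 2, 3, -1, -2, -3)

AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
_STOP_CODE = 20
_X_CODE = 21

# --- vectorized translation tables ---------------------------------------
_BASE_CODE = np.full(256, 4, dtype=np.uint8)  # A,C,G,T -> 0..3; anything else 4
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# codon index = 25*b0 + 5*b1 + b2 over base codes 0..4 (4 = N/other)
_CODON_AA = np.full(125, _X_CODE, dtype=np.uint8)
_AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
for _codon, _aa in standard_dna_table.forward_table.items():
    _idx = (
        _BASE_CODE[ord(_codon[0])] * 25
        + _BASE_CODE[ord(_codon[1])] * 5
        + _BASE_CODE[ord(_codon[2])]
    )
    _CODON_AA[_idx] = _AA_INDEX[_aa]
for _codon in standard_dna_table.stop_codons:
    _idx = (
        _BASE_CODE[ord(_codon[0])] * 25
        + _BASE_CODE[ord(_codon[1])] * 5
        + _BASE_CODE[ord(_codon[2])]
    )
    _CODON_AA[_idx] = _STOP_CODE

_AA_CHARS = np.frombuffer((AA_ORDER + "*X").encode(), dtype=np.uint8)


def reverse_complement(dna: str) -> str:
    return "".join(_COMP[b] for b in reversed(dna))


def _encode_dna(dna: str) -> np.ndarray:
    return _BASE_CODE[np.frombuffer(dna.encode(), dtype=np.uint8)]


def _translate_codes(codes: np.ndarray, offset: int) -> np.ndarray:
    """Translate base codes from ``offset`` into amino-acid codes (0..21)."""
    usable = (len(codes) - offset) // 3
    if usable <= 0:
        return np.empty(0, dtype=np.uint8)
    c = codes[offset : offset + usable * 3].reshape(-1, 3).astype(np.int32)
    return _CODON_AA[c[:, 0] * 25 + c[:, 1] * 5 + c[:, 2]]


def _aa_to_str(aa_codes: np.ndarray) -> str:
    return _AA_CHARS[aa_codes].tobytes().decode()


def six_frame_translate(dna: str) -> dict[int, str]:
    """Translate ``dna`` in all six frames under the standard genetic code.

    Codons containing ``N`` translate to ``X``; stop codons are rendered
    ``*``.  Frames -1..-3 are the forward frames of the reverse complement.
    An empty sequence yields six empty peptides.
    """
    dna = dna.upper()
    if set(dna) - set("ACGTN"):
        raise ValueError("sequence must be over {A,C,G,T,N}")
    codes = _encode_dna(dna)
    rc = np.where(codes < 4, 3 - codes, 4).astype(np.uint8)[::-1]
    out: dict[int, str] = {}
    for k in (1, 2, 3):
        out[k] = _aa_to_str(_translate_codes(codes, k - 1))
        out[-k] = _aa_to_str(_translate_codes(rc, k - 1))
    return out


# --- scoring --------------------------------------------------------------
@dataclass
class ScoringScheme:
    """Substitution matrix, affine gap costs and Karlin-Altschul constants.

    Gap costs follow the BLAST convention: a gap of length ``k`` costs
    ``gap_open + k * gap_extend``.  The defaults are the published gapped
    blastp constants for BLOSUM62 with gap open 11 / extend 1.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.267
    k: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if not (0 < self.k < 1):
            raise ValueError("K must be in (0, 1)")
        self._matrix = substitution_matrices.load(self.matrix_name)
        self._aligner = None

    @property
    def aligner(self) -> PairwiseAligner:
        if self._aligner is None:
            a = PairwiseAligner(mode="local")
            a.substitution_matrix = self._matrix
            a.open_gap_score = -(self.gap_open + self.gap_extend)
            a.extend_gap_score = -self.gap_extend
            self._aligner = a
        return self._aligner

    def pair_score(self, a: str, b: str) -> float:
        return float(self._matrix[a, b])

    def bit_score(self, raw_score: float) -> float:
        return (self.lam * raw_score - math.log(self.k)) / math.log(2)

    def evalue(self, raw_score: float, m: int, n: int) -> float:
        """Expected chance alignments at this score in an m x n search space."""
        return m * n * 2.0 ** (-self.bit_score(raw_score))


@dataclass
class LocalAlignment:
    """Best local alignment of one peptide against one protein."""

    raw_score: float
    query_start: int  # residues on the peptide, 0-based half-open
    query_end: int
    subject_start: int  # residues on the protein, 0-based half-open
    subject_end: int
    identity_fraction: float
    alignment_length: int  # columns, including gaps
    mismatches: int
    gap_opens: int


def _align_details(
    scheme: ScoringScheme, segment: str, protein: str
) -> LocalAlignment | None:
    alns = scheme.aligner.align(segment, protein)
    if len(alns) == 0:
        return None
    aln = alns[0]
    if aln.score <= 0:
        return None
    counts = aln.counts()
    qblocks, sblocks = aln.aligned
    if len(qblocks) == 0:
        return None
    gap_opens = 0
    for i in range(1, len(qblocks)):
        if qblocks[i][0] > qblocks[i - 1][1]:
            gap_opens += 1
        if sblocks[i][0] > sblocks[i - 1][1]:
            gap_opens += 1
    length = counts.gaps + counts.identities + counts.mismatches
    return LocalAlignment(
        raw_score=float(aln.score),
        query_start=int(qblocks[0][0]),
        query_end=int(qblocks[-1][1]),
        subject_start=int(sblocks[0][0]),
        subject_end=int(sblocks[-1][1]),
        identity_fraction=counts.identities / length if length else 0.0,
        alignment_length=length,
        mismatches=counts.mismatches,
        gap_opens=gap_opens,
    )


def _segments(peptide: str) -> list[tuple[int, str]]:
    """Open reading segments of a peptide: (offset, segment) split at stops."""
    out = []
    offset = 0
    for seg in peptide.split("*"):
        if seg:
            out.append((offset, seg))
        offset += len(seg) + 1
    return out


def local_align(
    peptide: str, protein: str, scheme: ScoringScheme | None = None
) -> LocalAlignment | None:
    """Affine-gap Smith-Waterman optimum of ``peptide`` vs ``protein``.

    The peptide is split at stop codons (``*``) and each segment aligned
    separately, so no alignment crosses a stop.  Returns ``None`` when no
    positive-scoring alignment exists.  Query coordinates are residues on
    the full peptide (segment offsets included).
    """
    scheme = scheme or ScoringScheme()
    if not peptide or not protein:
        return None
    best: LocalAlignment | None = None
    best_raw = 0.0
    best_offset = 0
    best_seg = ""
    for offset, seg in _segments(peptide):
        raw = float(scheme.aligner.score(seg, protein))
        if raw > best_raw:
            best_raw = raw
            best_offset, best_seg = offset, seg
    if best_raw <= 0:
        return None
    best = _align_details(scheme, best_seg, protein)
    if best is None:
        return None
    best.query_start += best_offset
    best.query_end += best_offset
    return best


# --- hits -----------------------------------------------------------------
@dataclass
class AlignmentHit:
    """A translated local alignment of a read against a panel protein.

    ``query_start``/``query_end`` are 0-based half-open bp on the read in
    forward-strand coordinates; ``frame`` records strand and phase.
    """

    query_id: str
    subject_accession: str
    family: str | None
    frame: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    raw_score: float
    bit_score: float
    evalue: float
    identity_fraction: float
    alignment_length: int
    mismatches: int
    gap_opens: int

    @property
    def alignment_span_bp(self) -> int:
        """bp spanned on the read (residue columns x 3)."""
        return self.alignment_length * 3


def _peptide_to_read_coords(
    frame: int, pep_start: int, pep_end: int, read_len: int
) -> tuple[int, int]:
    k = abs(frame) - 1
    start = k + 3 * pep_start
    end = k + 3 * pep_end
    if frame > 0:
        return start, end
    return read_len - end, read_len - start


def _make_hit(
    scheme: ScoringScheme,
    read: Read,
    protein: ProteinRef,
    frame: int,
    seg_offset: int,
    segment: str,
    m: int,
    n: int,
) -> AlignmentHit | None:
    det = _align_details(scheme, segment, protein.sequence)
    if det is None:
        return None
    ps = det.query_start + seg_offset
    pe = det.query_end + seg_offset
    qs, qe = _peptide_to_read_coords(frame, ps, pe, read.length)
    return AlignmentHit(
        query_id=read.read_id,
        subject_accession=protein.accession,
        family=protein.family,
        frame=frame,
        query_start=qs,
        query_end=qe,
        subject_start=det.subject_start,
        subject_end=det.subject_end,
        raw_score=det.raw_score,
        bit_score=scheme.bit_score(det.raw_score),
        evalue=scheme.evalue(det.raw_score, m, n),
        identity_fraction=det.identity_fraction,
        alignment_length=det.alignment_length,
        mismatches=det.mismatches,
        gap_opens=det.gap_opens,
    )


def _family_key(p: ProteinRef) -> str:
    return p.family if p.family is not None else f"__decoy__{p.accession}"


def search_read(
    read: Read,
    panel: Sequence[ProteinRef],
    scheme: ScoringScheme | None = None,
    e_max: float = 0.10,
    n_residues: int | None = None,
) -> list[AlignmentHit]:
    """Best hit per gene family for one read, exact (unseeded) search.

    The E-value search space is ``m x n`` with ``m`` the longest frame
    translation of the read (residues) and ``n`` the total panel residues
    (overridable via ``n_residues`` so a subset search can keep the full
    database statistics).  Hits with E > ``e_max`` are omitted.
    """
    scheme = scheme or ScoringScheme()
    if not panel:
        return []
    m = max(read.length // 3, 1)
    n = n_residues if n_residues is not None else sum(len(p.sequence) for p in panel)
    frames = six_frame_translate(read.sequence)
    # best (raw, frame, protein index, seg offset, segment) per family
    best: dict[str, tuple[float, int, int, int, str]] = {}
    for frame in FRAMES:
        pep = frames[frame]
        if not pep:
            continue
        segs = _segments(pep)
        for pi, prot in enumerate(panel):
            for offset, seg in segs:
                raw = float(scheme.aligner.score(seg, prot.sequence))
                if raw <= 0:
                    continue
                fam = _family_key(prot)
                cur = best.get(fam)
                if cur is None or raw > cur[0]:
                    best[fam] = (raw, frame, pi, offset, seg)
    hits = []
    for fam, (raw, frame, pi, offset, seg) in best.items():
        if scheme.evalue(raw, m, n) > e_max:
            continue
        hit = _make_hit(scheme, read, panel[pi], frame, offset, seg, m, n)
        if hit is not None:
            hits.append(hit)
    hits.sort(key=lambda h: (-h.bit_score, h.subject_accession))
    return hits


# --- seeded dataset-scale search ------------------------------------------
class PanelIndex:
    """Exact amino-acid k-mer index over a protein database.

    Backs the seeded search: a boolean membership table over all k-mers in
    base-22 encoding, plus a map from k-mer hash to the proteins containing
    it.
    """

    def __init__(self, panel: Sequence[ProteinRef], k: int = 6):
        if k < 3 or k > 7:
            raise ValueError("prefilter k must be in 3..7")
        self.panel = list(panel)
        self.k = k
        self.n_residues = sum(len(p.sequence) for p in self.panel)
        self._pow = (22 ** np.arange(k - 1, -1, -1)).astype(np.int64)
        self.table = np.zeros(22**k, dtype=bool)
        self.kmer_proteins: dict[int, tuple[int, ...]] = {}
        tmp: dict[int, list[int]] = {}
        for pi, prot in enumerate(self.panel):
            codes = np.array(
                [_AA_INDEX.get(a, _X_CODE) for a in prot.sequence], dtype=np.int64
            )
            if len(codes) < k:
                continue
            win = np.lib.stride_tricks.sliding_window_view(codes, k)
            valid = (win < _STOP_CODE).all(axis=1)
            hashes = win @ self._pow
            for h in np.unique(hashes[valid]):
                tmp.setdefault(int(h), []).append(pi)
        for h, pis in tmp.items():
            self.table[h] = True
            self.kmer_proteins[h] = tuple(dict.fromkeys(pis))

    def window_hash(self, aa_codes: np.ndarray, pos: int) -> int:
        return int(aa_codes[pos : pos + self.k] @ self._pow)


def _chunk_frames(
    codes: np.ndarray,
) -> list[np.ndarray]:
    """Six-frame amino-acid code matrices for a padded (R, L) base-code chunk."""
    rc = np.where(codes < 4, 3 - codes, 4).astype(np.uint8)[:, ::-1]
    out = []
    for src in (codes, rc):
        for off in range(3):
            ncod = (src.shape[1] - off) // 3
            if ncod <= 0:
                out.append(np.empty((codes.shape[0], 0), dtype=np.uint8))
                continue
            c = src[:, off : off + ncod * 3].reshape(codes.shape[0], ncod, 3)
            c = c.astype(np.int32)
            out.append(_CODON_AA[c[:, :, 0] * 25 + c[:, :, 1] * 5 + c[:, :, 2]])
    return out  # order: +1,+2,+3,-1,-2,-3


_FRAME_ORDER = (1, 2, 3, -1, -2, -3)


def search_dataset(
    dataset: Dataset,
    panel: Sequence[ProteinRef],
    scheme: ScoringScheme | None = None,
    e_max: float = 0.10,
    prefilter_k: int | None = 6,
    chunk_size: int = 4096,
    index: PanelIndex | None = None,
) -> dict[str, list[AlignmentHit]]:
    """Search every read of a dataset against a panel.

    With ``prefilter_k=None`` this is an exact per-read search.  Otherwise a
    bulk-vectorized exact k-mer seed prefilter selects candidate
    (read, frame segment, protein) triples and only those are aligned.
    Returns ``{read_id: [best hit per family]}`` for reads with hits.
    """
    scheme = scheme or ScoringScheme()
    if not panel:
        return {}
    if prefilter_k is None:
        out = {}
        for read in dataset:
            hits = search_read(read, panel, scheme, e_max)
            if hits:
                out[read.read_id] = hits
        return out

    idx = index if index is not None and index.k == prefilter_k else PanelIndex(
        panel, prefilter_k
    )
    n = idx.n_residues
    k = idx.k
    results: dict[str, list[AlignmentHit]] = {}
    reads = dataset.reads
    # batch reads of equal length so reverse-complement frames stay aligned
    by_length: dict[int, list[Read]] = {}
    for r in reads:
        by_length.setdefault(r.length, []).append(r)
    batches: list[list[Read]] = []
    for length in sorted(by_length):
        if length < 3 * k:
            continue
        group = by_length[length]
        for start in range(0, len(group), chunk_size):
            batches.append(group[start : start + chunk_size])
    for chunk in batches:
        mat = np.empty((len(chunk), chunk[0].length), dtype=np.uint8)
        for i, r in enumerate(chunk):
            mat[i] = _encode_dna(r.sequence)
        frames = _chunk_frames(mat)
        # per-read candidate tasks: (frame_idx, window_pos)
        cand: dict[int, list[tuple[int, int]]] = {}
        for fi, aa in enumerate(frames):
            if aa.shape[1] < k:
                continue
            win = np.lib.stride_tricks.sliding_window_view(aa, k, axis=1)
            valid = (win < _STOP_CODE).all(axis=2)
            h = win.astype(np.int64) @ idx._pow
            hit = idx.table[np.where(valid, h, 0)] & valid
            rows, poss = np.nonzero(hit)
            for r_i, p_i in zip(rows.tolist(), poss.tolist()):
                cand.setdefault(r_i, []).append((fi, p_i))
        for r_i, seeds in cand.items():
            read = chunk[r_i]
            m = max(read.length // 3, 1)
            # map seeds to (frame_idx, segment, protein) tasks
            tasks: set[tuple[int, int, int, int]] = set()  # fi, seg_start, seg_end, pi
            seg_cache: dict[int, list[tuple[int, int]]] = {}
            aa_by_frame: dict[int, np.ndarray] = {}
            for fi, pos in seeds:
                aa = frames[fi][r_i]
                aa_by_frame[fi] = aa
                if fi not in seg_cache:
                    stops = np.flatnonzero(aa >= _STOP_CODE)
                    bounds = [-1] + stops.tolist() + [len(aa)]
                    seg_cache[fi] = [
                        (bounds[j] + 1, bounds[j + 1])
                        for j in range(len(bounds) - 1)
                        if bounds[j + 1] - bounds[j] - 1 >= 1
                    ]
                h = idx.window_hash(aa.astype(np.int64), pos)
                prots = idx.kmer_proteins.get(h, ())
                for ss, se in seg_cache[fi]:
                    if ss <= pos and pos + k <= se:
                        for pi in prots:
                            tasks.add((fi, ss, se, pi))
                        break
            best: dict[str, tuple[float, int, int, int, str]] = {}
            for fi, ss, se, pi in sorted(tasks):
                seg = _aa_to_str(aa_by_frame[fi][ss:se])
                prot = idx.panel[pi]
                raw = float(scheme.aligner.score(seg, prot.sequence))
                if raw <= 0:
                    continue
                fam = _family_key(prot)
                cur = best.get(fam)
                if cur is None or raw > cur[0]:
                    best[fam] = (raw, fi, pi, ss, seg)
            hits = []
            for fam, (raw, fi, pi, ss, seg) in best.items():
                if scheme.evalue(raw, m, n) > e_max:
                    continue
                hit = _make_hit(
                    scheme, read, idx.panel[pi], _FRAME_ORDER[fi], ss, seg, m, n
                )
                if hit is not None:
                    hits.append(hit)
            if hits:
                hits.sort(key=lambda h: (-h.bit_score, h.subject_accession))
                results[read.read_id] = hits
    return results


def hits_to_outfmt6(hits: Iterable[AlignmentHit]) -> str:
    """Render hits as BLAST tabular (outfmt 6) text, 1-based inclusive coords.

    For minus-frame hits the query coordinates are printed descending, as
    blastx does.
    """
    lines = []
    for h in hits:
        if h.frame > 0:
            qs, qe = h.query_start + 1, h.query_end
        else:
            qs, qe = h.query_end, h.query_start + 1
        lines.append(
            "\t".join(
                [
                    h.query_id,
                    h.subject_accession,
                    f"{100 * h.identity_fraction:.2f}",
                    str(h.alignment_length),
                    str(h.mismatches),
                    str(h.gap_opens),
                    str(qs),
                    str(qe),
                    str(h.subject_start + 1),
                    str(h.subject_end),
                    f"{h.evalue:.2g}",
                    f"{h.bit_score:.1f}",
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
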