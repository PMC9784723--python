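"""Transposition-activity scoring across assemblies and accessions.

Two complementary copy-number assays:

* assembly-dependent: count genomic copies of an element under the 80/80
  rule (a hit is kept only when identity and query coverage both exceed
  80%), then normalize each element's counts by its minimum across
  assemblies;
* assembly-independent: normalized short-read coverage — mean per-base
  depth over the element divided by the accession's genome-wide mean
  depth, which approximates copy number without an assembly.

An element shows copy-number-variation evidence when any normalized count
(or the coverage fold change across accessions) reaches 2, the smallest
integer copy gain distinguishable from coverage noise at default depth.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import edlib
import numpy as np
import pandas as pd

from .seqcore import local_align, revcomp

CNV_FOLD = 2.0


# ---------------------------------------------------------------------------
# Assembly-dependent counting (80/80 rule)
# ---------------------------------------------------------------------------


def _candidate_windows(query: str, target: str, k: int = 15,
                       max_occ: int = 200, pad: float = 0.25) -> list[tuple[int, int]]:
    """Diagonal-clustered k-mer seed windows on the target."""
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(query) - k + 1):
        index[query[i : i + k]].append(i)
    hits: list[tuple[int, int]] = []  # (diag approx target start, target pos)
    for j in range(len(target) - k + 1):
        for i in index.get(target[j : j + k], ()):
            hits.append((j - i, j))
    if not hits:
        return []
    hits.sort()
    pad_bp = int(pad * len(query))
    clusters: list[list[tuple[int, int]]] = [[hits[0]]]
    for h in hits[1:]:
        if h[0] - clusters[-1][-1][0] <= len(query) // 2:
            clusters[-1].append(h)
        else:
            clusters.append([h])
    windows = []
    for cl in clusters:
        starts = [d for d, _ in cl]
        lo = max(0, min(starts) - pad_bp)
        hi = min(len(target), max(starts) + len(query) + pad_bp)
        windows.append((lo, hi))
    # merge overlaps
    windows.sort()
    merged = [windows[0]]
    for lo, hi in windows[1:]:
        if lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def count_copies_8080(element_seq: str, assembly: str,
                      min_identity: float = 0.80,
                      min_coverage: float = 0.80) -> int:
    """Number of non-overlapping 80/80 hits of the element in the assembly.

    Candidate loci come from k-mer seeding on both strands; each candidate
    window is locally aligned and kept when identity and query coverage are
    both strictly above the thresholds; hits are accepted greedily by score
    with overlap exclusion on the assembly.
    """
    if len(element_seq) < 500:
        raise ValueError("element shorter than 500 bp")
    element_seq = element_seq.upper()
    assembly = assembly.upper()
    hits: list[tuple[float, int, int]] = []  # (score, start, end) on assembly

    def harvest(strand_seq: str, lo: int, hi: int) -> None:
        # a merged window may hold several copies: split around each hit
        if hi - lo < min_coverage * len(strand_seq):
            return
        res = local_align(strand_seq, assembly[lo:hi])
        if res.score <= 0:
            return
        s, e = lo + res.target_span[0], lo + res.target_span[1]
        if res.identity > min_identity and res.query_coverage > min_coverage:
            hits.append((res.score, s, e))
            harvest(strand_seq, lo, s)
            harvest(strand_seq, e, hi)

    for strand_seq in (element_seq, revcomp(element_seq)):
        for lo, hi in _candidate_windows(strand_seq, assembly):
            harvest(strand_seq, lo, hi)
    hits.sort(key=lambda h: (-h[0], h[1]))
    accepted: list[tuple[int, int]] = []
    for _score, s, e in hits:
        ov = any(min(e, ae) - max(s, as_) > 0.1 * (e - s) for as_, ae in accepted)
        if not ov:
            accepted.append((s, e))
    return len(accepted)


@dataclass
class CopyNumberMatrix:
    counts: pd.DataFrame           # elements x assemblies, integer copies
    normalized: pd.DataFrame | None = None
    min_substituted: list[str] = field(default_factory=list)  # rows with min 0 -> 1


def count_copy_matrix(elements: dict[str, str],
                      assemblies: dict[str, str]) -> CopyNumberMatrix:
    counts = pd.DataFrame(
        {acc: {eid: count_copies_8080(seq, asm) for eid, seq in elements.items()}
         for acc, asm in assemblies.items()},
        dtype=int,
    )
    return CopyNumberMatrix(counts=counts.loc[list(elements)])


def normalize_copy_matrix(matrix: CopyNumberMatrix,
                          cnv_fold: float = CNV_FOLD) -> tuple[CopyNumberMatrix, pd.Series]:
    """Per-row division by the row minimum over assemblies (minimum 0 is
    substituted with 1 and logged). CNV evidence: any normalized cell >=
    ``cnv_fold``. Returns (matrix with .normalized set, evidence Series)."""
    counts = matrix.counts
    if counts.empty:
        raise ValueError("empty copy-number matrix")
    mins = counts.min(axis=1)
    substituted = mins[mins == 0].index.tolist()
    denom = mins.replace(0, 1)
    normalized = counts.div(denom, axis=0)
    evidence = (normalized >= cnv_fold).any(axis=1)
    out = CopyNumberMatrix(counts=counts, normalized=normalized,
                           min_substituted=substituted)
    return out, evidence


# ---------------------------------------------------------------------------
# Assembly-independent coverage CNV
# ---------------------------------------------------------------------------


@dataclass
class CnvCall:
    element_id: str
    assembly_dependent: bool
    coverage_based: bool
    max_fold_change: float


def normalized_coverage(
    element_seq: str,
    reads: list[tuple[str, str, str]] | list[tuple[str, str]],
    mean_depth: float,
    min_identity: float = 0.9,
    min_read_fraction: float = 0.9,
    k: int = 13,
) -> float:
    """Mean per-base element depth / genome-wide mean depth (~ copy number).

    Reads sharing an exact k-mer with the element (either strand) are
    aligned edit-distance-wise; alignments at >= ``min_identity`` over
    >= ``min_read_fraction`` of the read accumulate depth.
    """
    if mean_depth <= 0:
        raise ValueError("genome-wide mean depth must be > 0")
    element_seq = element_seq.upper()
    ekmers = {element_seq[i : i + k] for i in range(len(element_seq) - k + 1)}
    depth = np.zeros(len(element_seq))
    for read in reads:
        seq = read[1].upper()
        if len(seq) < k:
            continue
        for oriented in (seq, revcomp(seq)):
            if not any(oriented[i : i + k] in ekmers
                       for i in range(0, len(oriented) - k + 1, k)):
                continue
            res = edlib.align(oriented, element_seq, mode="HW", task="locations",
                              k=int(len(oriented) * (1 - min_identity)) + 1)
            if res["editDistance"] < 0:
                continue
            identity = 1.0 - res["editDistance"] / len(oriented)
            lo, hi = res["locations"][0]
            if identity >= min_identity and (hi + 1 - lo) / len(oriented) >= min_read_fraction:
                depth[lo : hi + 1] += 1
                break
    return float(depth.mean() / mean_depth)


def coverage_cnv(
    element_id: str,
    element_seq: str,
    reads_per_accession: dict[str, list],
    mean_depths: dict[str, float],
    cnv_fold: float = CNV_FOLD,
    assembly_dependent: bool | None = None,
) -> tuple[dict[str, float], CnvCall]:
    """Per-accession normalized coverage plus the CNV evidence call."""
    cov = {
        acc: normalized_coverage(element_seq, reads, mean_depths[acc])
        for acc, reads in reads_per_accession.items()
    }
    values = np.array(list(cov.values()))
    lo = values.min()
    denom = lo if lo > 1e-6 else 1.0
    fold = float(values.max() / denom)
    call = CnvCall(
        element_id=element_id,
        assembly_dependent=bool(assembly_dependent) if assembly_dependent is not None else False,
        coverage_based=fold >= cnv_fold,
        max_fold_change=fold,
    )
    return cov, call
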