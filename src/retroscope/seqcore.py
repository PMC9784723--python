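"""Foundational sequence algorithms.

Translation, ORF finding, local alignment and anchor chaining shared by the
structural annotator, the transcript mapper and the mobilome assays.

Coordinate convention: 0-based half-open everywhere in memory; conversion to
1-based closed intervals happens only in the GFF3 writers (:mod:`retroscope.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data.CodonTable import standard_dna_table

VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: codon -> amino acid, stops as '*'
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    CODON_TO_AA[_stop] = "*"

#: amino acid -> list of synonymous codons (used by the simulator)
AA_TO_CODONS: dict[str, list[str]] = {}
for _codon, _aa in sorted(standard_dna_table.forward_table.items()):
    AA_TO_CODONS.setdefault(_aa, []).append(_codon)

DEFAULT_MIN_ORF_AA = 80  # smaller than the GAG core domain, bounds ORF counts


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_alphabet(seq: str) -> None:
    bad = set(seq.upper()) - VALID_BASES
    if bad:
        raise ValueError(f"non-IUPAC characters in sequence: {sorted(bad)!r}")


def _translate(seq: str) -> str:
    aas = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        aas.append("X" if "N" in codon else CODON_TO_AA[codon])
    return "".join(aas)


def translate_frames(dna: str) -> dict[int, str]:
    """Translate all six frames; keys +1..+3 (given strand), -1..-3 (revcomp).

    Stops are rendered as ``'*'``; trailing incomplete codons are dropped;
    ``N``-containing codons translate to ``X``.
    """
    dna = dna.upper()
    _check_alphabet(dna)
    rc = revcomp(dna)
    out: dict[int, str] = {}
    for f in (1, 2, 3):
        out[f] = _translate(dna[f - 1 :])
        out[-f] = _translate(rc[f - 1 :])
    return out


@dataclass(frozen=True)
class Orf:
    """An ATG-initiated open reading frame in one of the six frames.

    ``nt_span`` is on the source (forward) sequence, 0-based half-open, and
    includes the stop codon when one terminates the ORF.
    """

    frame: int
    nt_span: tuple[int, int]
    peptide: str
    length_aa: int

    @property
    def has_stop(self) -> bool:
        return self.nt_span[1] - self.nt_span[0] == 3 * self.length_aa + 3


def find_orfs(dna: str, min_aa: int = DEFAULT_MIN_ORF_AA) -> list[Orf]:
    """All ATG-initiated ORFs of at least ``min_aa`` residues, six frames.

    Nested ORFs sharing a stop codon report only the longest (earliest ATG).
    Sorted by peptide length descending, ties by (frame, start).
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    dna = dna.upper()
    _check_alphabet(dna)
    n = len(dna)
    orfs: list[Orf] = []
    for frame, pep in translate_frames(dna).items():
        off = abs(frame) - 1
        start_aa: int | None = None
        for i, aa in enumerate(pep + "*"):  # sentinel closes a trailing ORF
            if aa == "M" and start_aa is None:
                start_aa = i
            elif aa == "*" and start_aa is not None:
                terminal = i < len(pep)  # real stop vs sentinel
                length = i - start_aa
                if length >= min_aa:
                    s = off + 3 * start_aa
                    e = off + 3 * i + (3 if terminal else 0)
                    if frame < 0:
                        s, e = n - e, n - s
                    orfs.append(Orf(frame, (s, e), pep[start_aa:i], length))
                start_aa = None
    orfs.sort(key=lambda o: (-o.length_aa, abs(o.frame), o.frame < 0, o.nt_span))
    return orfs


# ---------------------------------------------------------------------------
# Local alignment
# ---------------------------------------------------------------------------

@dataclass
class AlignmentResult:
    """Optimal local alignment with traceback-derived statistics.

    identity = matching columns / total alignment columns (gap columns count);
    query_coverage = aligned query length / query length.
    """

    score: float
    identity: float
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    op_list: list[tuple[str, int]] = field(default_factory=list)  # M/X/I/D runs
    query_coverage: float = 0.0


@lru_cache(maxsize=8)
def _aligner(mode: str, match: float, mismatch: float,
             gap_open: float, gap_extend: float) -> PairwiseAligner:
    al = PairwiseAligner()
    al.mode = "local"
    if mode == "protein":
        al.substitution_matrix = substitution_matrices.load("BLOSUM62")
        al.open_gap_score = -11.0
        al.extend_gap_score = -1.0
    else:
        al.match_score = match
        al.mismatch_score = mismatch
        al.open_gap_score = gap_open
        al.extend_gap_score = gap_extend
    return al


def local_align(
    query: str,
    target: str,
    mode: Literal["nucleotide", "protein"] = "nucleotide",
    match: float = 2.0,
    mismatch: float = -3.0,
    gap_open: float = -5.0,
    gap_extend: float = -2.0,
) -> AlignmentResult:
    """Smith-Waterman local alignment with affine gaps.

    Protein mode scores with BLOSUM62 (gap open -11 / extend -1); nucleotide
    mode uses the given match/mismatch/gap scores. A score of 0 with empty
    spans is returned when no positive-scoring alignment exists.
    """
    if not query or not target:
        raise ValueError("local_align requires nonempty sequences")
    al = _aligner(mode, match, mismatch, gap_open, gap_extend)
    score = al.score(query, target)
    if score <= 0:
        return AlignmentResult(0.0, 0.0, (0, 0), (0, 0), [], 0.0)
    aln = al.align(query, target)[0]
    qblocks, tblocks = aln.aligned
    ops: list[tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    matches = columns = 0
    prev_q = prev_t = None
    for (qs, qe), (ts, te) in zip(qblocks, tblocks):
        if prev_q is not None:
            push("I", qs - prev_q)   # unaligned query bases (insertion to query)
            push("D", ts - prev_t)   # unaligned target bases
            columns += (qs - prev_q) + (ts - prev_t)
        for qc, tc in zip(query[qs:qe], target[ts:te]):
            if qc == tc:
                push("M", 1)
                matches += 1
            else:
                push("X", 1)
            columns += 1
        prev_q, prev_t = qe, te
    q_span = (int(qblocks[0][0]), int(qblocks[-1][1]))
    t_span = (int(tblocks[0][0]), int(tblocks[-1][1]))
    identity = matches / columns if columns else 0.0
    coverage = (q_span[1] - q_span[0]) / len(query)
    return AlignmentResult(float(score), identity, q_span, t_span, ops, coverage)


# ---------------------------------------------------------------------------
# Anchor chaining (seed-chain step of the spliced mapper)
# ---------------------------------------------------------------------------

Anchor = tuple[int, int, int]  # (query_pos, target_pos, length)


def _gap_cost(gq: int, gt: int) -> float:
    # concave in the intron length: cheap to open a long target-side gap
    return 0.01 * min(gq, gt) + 0.5 * math.log2(1 + abs(gt - gq))


@dataclass
class Chain:
    score: float
    anchors: list[Anchor]


def chain_anchors(anchors: Sequence[Anchor], max_intron: int = 10_000) -> Chain:
    """Maximum-score collinear chain of exact-match anchors.

    Score = sum of anchor lengths minus a concave gap cost; target-side gaps
    up to ``max_intron`` are allowed (spliced alignment). Ties break toward
    the leftmost target position.
    """
    if not anchors:
        return Chain(0.0, [])
    order = sorted(range(len(anchors)), key=lambda i: (anchors[i][1], anchors[i][0]))
    a = [anchors[i] for i in order]
    n = len(a)
    score = [float(x[2]) for x in a]
    prev = [-1] * n
    for j in range(n):
        qj, tj, lj = a[j]
        for i in range(j):
            qi, ti, li = a[i]
            gq = qj - (qi + li)
            gt = tj - (ti + li)
            # anchors may slightly overlap (seeds crossing exon junctions):
            # trim the later anchor's start instead of rejecting the pair
            trim = -min(gq, gt, 0)
            if trim >= lj:
                continue
            gq += trim
            gt += trim
            if gq < 0 or gt < 0 or gt > max_intron:
                continue
            s = score[i] + (lj - trim) - _gap_cost(gq, gt)
            if s > score[j] + 1e-12:
                score[j] = s
                prev[j] = i
    best = max(range(n), key=lambda j: (score[j], -a[j][1]))
    chain: list[Anchor] = []
    j = best
    while j != -1:
        chain.append(a[j])
        j = prev[j]
    chain.reverse()
    return Chain(score[best], chain)
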