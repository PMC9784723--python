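"""Three-way origin classification of retroelement-related transcript loci.

The central decision procedure of the pipeline: each retained transcript
model is assigned to one of three categories by intersecting its genomic
locus with the structural element annotation —

1. LTR_RTE: the locus lies (>= 80% by default) within one annotated LTR
   retrotransposon; completeness follows the element call. If that element
   is a two-LTR structure whose single protein-coding ORF carries a proper
   subset of the five retroelement domains, the locus is instead a
   non-autonomous TR_RTE and is named after the domains it encodes
   (TR-GAG, TR-RT, TR-RT-RH, TR-RH, TR-INT-RT, ...).
2. LTR_RTE truncated (remnant): no containing element, but a detected LTR
   lies within a flanking window (1 kb by default) of the locus.
3. nonLTR_RTE: no LTR signature at all — a gene-like locus encoding a
   retroelement-related protein.

nonLTR loci with a fragmentary GAG fused to a host domain in the same ORF
and a multi-exon gene structure are flagged as domestication candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .annotate import DomainHit, ElementCall, LtrElement
from .simkit import RTE_DOMAINS
from .transcript import TranscriptModel

DEFAULT_OVERLAP = 0.80
DEFAULT_FLANK = 1000


@dataclass
class OriginCall:
    cluster_id: str
    category: str  # "LTR_RTE" | "TR_RTE" | "nonLTR_RTE"
    completeness: str  # "full_length" | "truncated" | "not_applicable"
    subtype: str = ""  # TR-RTEs only
    matched_element_id: str | None = None
    encoded_domains: list[str] = field(default_factory=list)
    exon_count: int = 0
    overlap_fraction: float = 0.0


def tr_subtype_name(domains: list[str]) -> str:
    """Subtype name of a non-autonomous TR element: "TR-" + encoded domains
    joined in genomic order (e.g. [INT, RT] -> "TR-INT-RT")."""
    if not domains:
        raise ValueError("TR subtype requires at least one encoded domain")
    bad = [d for d in domains if d not in RTE_DOMAINS]
    if bad:
        raise ValueError(f"not retroelement domains: {bad}")
    if set(domains) == set(RTE_DOMAINS):
        raise ValueError("full domain set encodes an autonomous element, not a TR")
    return "TR-" + "-".join(domains)


class ElementIndex:
    """Interval-indexed element annotation for locus intersection queries."""

    def __init__(self, elements: list[tuple[LtrElement, ElementCall]]):
        self.elements = elements
        self.span_tree = IntervalTree()
        self.ltr_tree = IntervalTree()
        for el, call in elements:
            self.span_tree[el.span[0] : el.span[1]] = (el, call)
            self.ltr_tree[el.ltr5_span[0] : el.ltr5_span[1]] = el
            self.ltr_tree[el.ltr3_span[0] : el.ltr3_span[1]] = el


def _is_tr_structure(call: ElementCall) -> list[str] | None:
    """Encoded domain list when the element is a two-LTR single-ORF
    non-autonomous structure; None otherwise.

    "Single ORF" counts protein-coding (domain-bearing) ORFs: random
    sequence yields spurious long ORFs often enough that the literal ORF
    count would be unstable.
    """
    if len(call.orf_domains) != 1:
        return None
    names = [h.domain for h in call.orf_domains[0] if h.domain_class == "rte"]
    if any(h.domain_class != "rte" for h in call.orf_domains[0]):
        return None
    if not names or set(names) == set(RTE_DOMAINS):
        return None
    return names


def classify_origin(
    model: TranscriptModel,
    elements: ElementIndex | list[tuple[LtrElement, ElementCall]],
    overlap_threshold: float = DEFAULT_OVERLAP,
    flank: int = DEFAULT_FLANK,
) -> OriginCall:
    """Assign one transcript model to LTR_RTE / TR_RTE / nonLTR_RTE."""
    if model.mq <= 0:
        raise ValueError("unmapped or ambiguous model must be filtered upstream")
    index = elements if isinstance(elements, ElementIndex) else ElementIndex(elements)
    locus = model.locus
    length = locus[1] - locus[0]
    encoded = [h.domain for h in model.domains]
    best: tuple[float, LtrElement, ElementCall] | None = None
    for iv in index.span_tree[locus[0] : locus[1]]:
        el, call = iv.data
        ov = (min(locus[1], el.span[1]) - max(locus[0], el.span[0])) / length
        if best is None or ov > best[0]:
            best = (ov, el, call)
    if best is not None and best[0] >= overlap_threshold:
        ov, el, call = best
        tr_domains = _is_tr_structure(call)
        if tr_domains is not None:
            return OriginCall(
                cluster_id=model.cluster_id,
                category="TR_RTE",
                completeness="not_applicable",
                subtype=tr_subtype_name(tr_domains),
                matched_element_id=el.element_id,
                encoded_domains=encoded,
                exon_count=model.exon_count,
                overlap_fraction=ov,
            )
        return OriginCall(
            cluster_id=model.cluster_id,
            category="LTR_RTE",
            completeness=call.completeness,
            matched_element_id=el.element_id,
            encoded_domains=encoded,
            exon_count=model.exon_count,
            overlap_fraction=ov,
        )
    # LTR remnant: any detected LTR within the flanking window
    window = index.ltr_tree[max(0, locus[0] - flank) : locus[1] + flank]
    if window:
        nearest = min(
            window,
            key=lambda iv: min(abs(iv.begin - locus[1]), abs(locus[0] - iv.end)),
        )
        ov = best[0] if best else 0.0
        return OriginCall(
            cluster_id=model.cluster_id,
            category="LTR_RTE",
            completeness="truncated",
            matched_element_id=nearest.data.element_id,
            encoded_domains=encoded,
            exon_count=model.exon_count,
            overlap_fraction=ov,
        )
    return OriginCall(
        cluster_id=model.cluster_id,
        category="nonLTR_RTE",
        completeness="not_applicable",
        matched_element_id=None,
        encoded_domains=encoded,
        exon_count=model.exon_count,
        overlap_fraction=0.0,
    )


# ---------------------------------------------------------------------------
# Domestication screen
# ---------------------------------------------------------------------------


@dataclass
class DomesticationCandidate:
    cluster_id: str
    exon_count: int
    gag_consensus_coverage: float
    host_domains: list[str]
    same_orf_fusion: bool = True


def find_domestication_candidates(
    calls: list[OriginCall],
    models: dict[str, TranscriptModel],
    min_exons: int = 4,
    max_gag_coverage: float = 0.8,
) -> list[DomesticationCandidate]:
    """Screen nonLTR loci for host-fusion (domesticated) GAG genes.

    A candidate must simultaneously show a gene-like multi-exon structure
    (>= ``min_exons``), a fragmentary GAG (consensus coverage below
    ``max_gag_coverage``) and a host-class domain encoded by the same ORF
    as the GAG fragment.
    """
    out: list[DomesticationCandidate] = []
    for call in calls:
        if call.category != "nonLTR_RTE":
            continue
        model = models[call.cluster_id]
        if model.exon_count < min_exons:
            continue
        for orf_hits in model.orf_domains:
            gag = [h for h in orf_hits if h.domain == "GAG"]
            hosts = [h for h in orf_hits if h.domain_class == "host"]
            if not gag or not hosts:
                continue
            cov = max(h.consensus_coverage for h in gag)
            if cov < max_gag_coverage:
                out.append(DomesticationCandidate(
                    cluster_id=call.cluster_id,
                    exon_count=model.exon_count,
                    gag_consensus_coverage=cov,
                    host_domains=[h.domain for h in hosts],
                ))
                break
    return out
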