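"""Synthetic genomes, long cDNA reads, accession genomes and short reads.

Every downstream stage of the pipeline is exercised against genomes built
here, with full ground truth: planted LTR retrotransposons (autonomous full
and truncated), non-autonomous TR elements (two LTRs around a single ORF),
gene-like multi-exon loci encoding retroelement proteins (including host
fusions emulating domesticated GAG genes), accession genomes differing in
copy number, and short genomic reads for coverage assays.

The generator is a pure function of (config, seed): identical seeds give
byte-identical output. Background sequence is i.i.d. at the configured GC
content — the simplest null that cannot spuriously contain LTR-length direct
repeats at the configured identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio import SeqIO

from .seqcore import AA_TO_CODONS, revcomp

CATEGORIES = (
    "autonomous_full",
    "autonomous_truncated",
    "tr_gag",
    "tr_rt",
    "tr_rt_rh",
    "tr_rh",
    "tr_int_rt",
    "nonltr_gene",
)

TR_DOMAINS = {
    "tr_gag": ["GAG"],
    "tr_rt": ["RT"],
    "tr_rt_rh": ["RT", "RH"],
    "tr_rh": ["RH"],
    "tr_int_rt": ["INT", "RT"],
}

RTE_DOMAINS = ("GAG", "AP", "INT", "RT", "RH")
HOST_DOMAINS = ("host_UBP", "host_KELP", "host_NTF2")

#: default per-category census, mirroring the study's 56-locus composition
#: (22 full + 2 truncated autonomous; TR subtypes 6/1/1/1/1; 22 gene-like)
#: at roughly half scale so ten replicate genomes stay desk-sized.
DEFAULT_CENSUS = {
    "autonomous_full": 8,
    "autonomous_truncated": 2,
    "tr_gag": 6,
    "tr_rt": 1,
    "tr_rt_rh": 1,
    "tr_rh": 1,
    "tr_int_rt": 1,
    "nonltr_gene": 10,
}

DEFAULT_SAMPLES = ("control", "AZ_0.5_12HS", "AZ_24HS", "ActyDZ_24HS")

MIN_SPACING = 1000  # bp of background guaranteed between planted elements


def load_domain_peptides() -> dict[str, str]:
    """The bundled synthetic consensus peptide set (retroelement + host)."""
    ref = resources.files("retroscope.data") / "domain_consensus.synthetic.faa"
    with ref.open() as fh:
        return {r.id: str(r.seq) for r in SeqIO.parse(fh, "fasta")}


@dataclass
class SimConfig:
    """Study conditions for one synthetic scenario."""

    seed: int = 1
    genome_length: int = 1_000_000
    n_per_category: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_CENSUS))
    n_fusion_genes: int = 3  # of the nonltr_gene loci: host-fusion (partial GAG)
    ltr_length: tuple[int, int] = (250, 600)
    ltr_identity: float = 0.95
    tsd_length: tuple[int, int] = (4, 6)
    gc_content: float = 0.41
    error_rates: tuple[float, float, float] = (0.03, 0.02, 0.02)  # sub, ins, del
    samples: tuple[str, ...] = DEFAULT_SAMPLES
    abundance: dict[tuple[str, str], float] | None = None  # (element_id, sample) -> E[reads]
    truncation_rate: float = 0.10  # fraction of reads 5'-truncated

    def validate(self) -> None:
        for name, v in [("ltr_identity", self.ltr_identity), ("gc_content", self.gc_content)]:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if any(not 0.0 <= r <= 1.0 for r in self.error_rates):
            raise ValueError("error rates must be in [0,1]")
        for cat in self.n_per_category:
            if cat not in CATEGORIES:
                raise ValueError(f"unknown category {cat!r}")
        if any(n < 0 for n in self.n_per_category.values()):
            raise ValueError("element counts must be >= 0")


@dataclass
class TruthElement:
    """One planted locus with its full structural ground truth."""

    element_id: str
    category: str
    span: tuple[int, int]
    ltr5_span: tuple[int, int] | None
    ltr3_span: tuple[int, int] | None
    tsd: str
    domain_layout: list[str]
    exon_spans: list[tuple[int, int]]
    strand: str


def truth_transcript(genome: str, te: TruthElement) -> str:
    """Spliced transcript sequence of a planted locus (exons concatenated)."""
    spliced = "".join(genome[s:e] for s, e in te.exon_spans)
    return revcomp(spliced) if te.strand == "-" else spliced


# ---------------------------------------------------------------------------
# Sequence building blocks
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


def _encode_peptide(rng: np.random.Generator, peptide: str) -> str:
    """Random synonymous codons: silent variation around the consensus."""
    return "".join(AA_TO_CODONS[aa][rng.integers(len(AA_TO_CODONS[aa]))] for aa in peptide)


def _mutate_substitutions(rng: np.random.Generator, seq: str, identity: float,
                          protect: int = 2) -> str:
    """Substitute bases to reach the target identity; ends are protected."""
    n_sub = int(round((1 - identity) * len(seq)))
    if n_sub == 0:
        return seq
    positions = rng.choice(np.arange(protect, len(seq) - protect), size=n_sub, replace=False)
    s = list(seq)
    for p in positions:
        choices = [b for b in "ACGT" if b != s[p]]
        s[p] = choices[rng.integers(3)]
    return "".join(s)


def _make_orf(rng: np.random.Generator, domains: list[str],
              peptides: dict[str, str], linker_aa: int = 10) -> str:
    parts = []
    aas = list(AA_TO_CODONS)
    aas.remove("M")  # linkers free of ATG starts, keeps one unambiguous ORF start
    for i, d in enumerate(domains):
        if i:
            parts.append("".join(rng.choice(aas) for _ in range(linker_aa)))
        parts.append(peptides[d])
    return "ATG" + _encode_peptide(rng, "".join(parts)) + "TAA"


@dataclass
class _Cassette:
    """An element in local (pre-insertion) coordinates."""

    seq: str
    category: str
    ltr5: tuple[int, int] | None
    ltr3: tuple[int, int] | None
    domain_layout: list[str]
    exons: list[tuple[int, int]]
    strand: str
    tsd: str


def _build_ltr_cassette(rng: np.random.Generator, cfg: SimConfig, category: str,
                        peptides: dict[str, str]) -> _Cassette:
    ltr_len = int(rng.integers(cfg.ltr_length[0], cfg.ltr_length[1] + 1))
    ltr5 = "TG" + random_seq(rng, ltr_len - 4, cfg.gc_content) + "CA"
    ltr3 = _mutate_substitutions(rng, ltr5, cfg.ltr_identity)
    utr5 = random_seq(rng, int(rng.integers(60, 150)), cfg.gc_content)
    utr3 = random_seq(rng, int(rng.integers(80, 200)), cfg.gc_content)
    if category == "autonomous_full":
        layout = list(RTE_DOMAINS) if rng.random() < 0.5 else ["GAG", "AP", "RT", "RH", "INT"]
        coding = _make_orf(rng, layout, peptides)
    elif category == "autonomous_truncated":
        # two domain-bearing ORFs, incomplete domain set: detected as an
        # element but neither full-length nor a single-ORF TR structure
        layout = ["GAG", "AP", "INT"]
        coding = (_make_orf(rng, ["GAG", "AP"], peptides)
                  + random_seq(rng, int(rng.integers(100, 200)), cfg.gc_content)
                  + _make_orf(rng, ["INT"], peptides))
    else:
        layout = list(TR_DOMAINS[category])
        coding = _make_orf(rng, layout, peptides)
    seq = ltr5 + utr5 + coding + utr3 + ltr3
    l5 = (0, len(ltr5))
    l3 = (len(seq) - len(ltr3), len(seq))
    # transcript: mid 5' LTR (promoter/R region) to mid 3' LTR, single exon
    exons = [(l5[1] // 2, len(seq) - len(ltr3) // 2)]
    strand = "+" if rng.random() < 0.5 else "-"
    tsd_len = int(rng.integers(cfg.tsd_length[0], cfg.tsd_length[1] + 1))
    tsd = random_seq(rng, tsd_len, cfg.gc_content)
    if strand == "-":
        L = len(seq)
        seq = revcomp(seq)
        flip = lambda sp: (L - sp[1], L - sp[0])
        l5, l3 = flip(l5), flip(l3)
        exons = [flip(e) for e in reversed(exons)]
    return _Cassette(seq, category, l5, l3, layout, exons, strand, tsd)


def _build_gene_cassette(rng: np.random.Generator, cfg: SimConfig, fusion: bool,
                         peptides: dict[str, str]) -> _Cassette:
    gag = peptides["GAG"]
    if fusion:
        frac = rng.uniform(0.45, 0.60)  # clearly partial GAG core
        start = int(rng.integers(0, int(len(gag) * (1 - frac))))
        gag_part = gag[start : start + int(len(gag) * frac)]
        host = HOST_DOMAINS[rng.integers(len(HOST_DOMAINS))]
        layout = ["GAG", host]
        pep_parts = [gag_part, peptides[host]]
    else:
        layout = ["GAG"]
        pep_parts = [gag]
    aas = [a for a in AA_TO_CODONS if a != "M"]
    linker = "".join(rng.choice(aas) for _ in range(10))
    cds = "ATG" + _encode_peptide(rng, (linker.join(pep_parts)) if fusion else pep_parts[0]) + "TAA"
    utr5 = random_seq(rng, int(rng.integers(40, 80)), cfg.gc_content)
    utr3 = random_seq(rng, int(rng.integers(60, 150)), cfg.gc_content)
    mrna = utr5 + cds + utr3
    n_exons = int(rng.integers(4, 11))  # gene-like 4-10 exon structure
    # cut points keeping every exon >= 30 bp
    while True:
        cuts = np.sort(rng.choice(np.arange(30, len(mrna) - 30), size=n_exons - 1, replace=False))
        bounds = [0, *cuts.tolist(), len(mrna)]
        if all(bounds[i + 1] - bounds[i] >= 30 for i in range(n_exons)):
            break
    pieces: list[str] = []
    exons: list[tuple[int, int]] = []
    pos = 0
    for i in range(n_exons):
        exon = mrna[bounds[i] : bounds[i + 1]]
        pieces.append(exon)
        exons.append((pos, pos + len(exon)))
        pos += len(exon)
        if i < n_exons - 1:
            intron = "GT" + random_seq(rng, int(rng.integers(76, 396)), cfg.gc_content) + "AG"
            pieces.append(intron)
            pos += len(intron)
    seq = "".join(pieces)
    strand = "+" if rng.random() < 0.5 else "-"
    if strand == "-":
        L = len(seq)
        seq = revcomp(seq)
        exons = [(L - e, L - s) for s, e in reversed(exons)]
    return _Cassette(seq, "nonltr_gene", None, None, layout, exons, strand, "")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def simulate_genome(config: SimConfig) -> tuple[str, list[TruthElement]]:
    """Plant the configured elements into an i.i.d. background genome.

    Returns the genome string and the truth records sorted by coordinate.
    Raises ``ValueError`` when the element budget exceeds ``genome_length``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0xC0FFEE])
    peptides = load_domain_peptides()
    cassettes: list[_Cassette] = []
    for cat in CATEGORIES:
        n = config.n_per_category.get(cat, 0)
        for i in range(n):
            if cat == "nonltr_gene":
                fusion = i < min(config.n_fusion_genes, n)
                cassettes.append(_build_gene_cassette(rng, config, fusion, peptides))
            else:
                cassettes.append(_build_ltr_cassette(rng, config, cat, peptides))
    order = rng.permutation(len(cassettes))
    cassettes = [cassettes[i] for i in order]
    footprint = sum(len(c.seq) + 2 * len(c.tsd) for c in cassettes)
    min_needed = footprint + MIN_SPACING * (len(cassettes) + 1)
    if min_needed > config.genome_length:
        raise ValueError(
            f"element budget ({min_needed} bp incl. spacing) exceeds genome_length "
            f"({config.genome_length} bp)"
        )
    slack = config.genome_length - min_needed
    extras = rng.multinomial(slack, np.ones(len(cassettes) + 1) / (len(cassettes) + 1)) if cassettes else [slack]
    parts: list[str] = []
    truth: list[TruthElement] = []
    pos = 0
    for idx, cas in enumerate(cassettes):
        gap = MIN_SPACING + int(extras[idx])
        parts.append(random_seq(rng, gap, config.gc_content))
        pos += gap
        if cas.tsd:
            parts.append(cas.tsd)
            pos += len(cas.tsd)
        start = pos
        parts.append(cas.seq)
        pos += len(cas.seq)
        if cas.tsd:
            parts.append(cas.tsd)
            pos += len(cas.tsd)
        shift = lambda sp: (start + sp[0], start + sp[1])
        truth.append(TruthElement(
            element_id="",  # assigned after coordinate sort
            category=cas.category,
            span=(start, start + len(cas.seq)),
            ltr5_span=shift(cas.ltr5) if cas.ltr5 else None,
            ltr3_span=shift(cas.ltr3) if cas.ltr3 else None,
            tsd=cas.tsd,
            domain_layout=list(cas.domain_layout),
            exon_spans=[shift(e) for e in cas.exons],
            strand=cas.strand,
        ))
    tail = config.genome_length - pos
    parts.append(random_seq(rng, tail, config.gc_content))
    genome = "".join(parts)
    truth.sort(key=lambda t: t.span)
    for i, te in enumerate(truth):
        te.element_id = f"elem_{i:03d}_{te.category}"
    return genome, truth


def default_abundance(truth: list[TruthElement],
                      samples: tuple[str, ...] = DEFAULT_SAMPLES,
                      seed: int = 1,
                      base_reads: float = 20.0) -> dict[tuple[str, str], float]:
    """Expected per-(locus, sample) read counts emulating the study design:

    control plus provocative treatments, with ~30% of loci silent in the
    control and detectable only under treatment.
    """
    rng = np.random.default_rng([seed, 0xAB])
    ab: dict[tuple[str, str], float] = {}
    control = samples[0]
    for te in truth:
        treatment_only = rng.random() < 0.3
        level = base_reads * float(rng.uniform(0.5, 3.0))
        for s in samples:
            if s == control and treatment_only:
                ab[(te.element_id, s)] = 0.0
            else:
                scale = 1.0 if s == control else float(rng.uniform(0.8, 2.5))
                ab[(te.element_id, s)] = level * scale
    return ab


_BASE_TO_IDX = np.full(256, 0, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_TO_IDX[_b] = _i
_IDX_TO_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _corrupt(rng: np.random.Generator, seq: str,
             rates: tuple[float, float, float]) -> str:
    """Per-base substitution/insertion/deletion noise (substitutions always
    change the base; insertions add one random base after a position)."""
    sub, ins, dele = rates
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(arr)
    idx = _BASE_TO_IDX[arr].copy()
    if sub:
        m = rng.random(n) < sub
        idx[m] = (idx[m] + rng.integers(1, 4, size=int(m.sum()), dtype=np.uint8)) % 4
    out = _IDX_TO_BASE[idx]
    del_mask = rng.random(n) < dele if dele else np.zeros(n, dtype=bool)
    ins_mask = rng.random(n) < ins if ins else np.zeros(n, dtype=bool)
    if not del_mask.any() and not ins_mask.any():
        return out.tobytes().decode()
    events = np.flatnonzero(del_mask | ins_mask)
    parts: list[bytes] = []
    prev = 0
    raw = out.tobytes()
    for p in events:
        parts.append(raw[prev:p])
        if not del_mask[p]:
            parts.append(raw[p : p + 1])
        if ins_mask[p]:
            parts.append(bytes([b"ACGT"[rng.integers(4)]]))
        prev = p + 1
    parts.append(raw[prev:])
    return b"".join(parts).decode()


def simulate_reads(
    genome: str,
    truth: list[TruthElement],
    config: SimConfig,
) -> dict[str, list[tuple[str, str, str]]]:
    """Per-sample error-bearing cDNA reads: ``{sample: [(id, seq, qual)]}``.

    Read counts are Poisson around the configured expectation; read names
    encode the truth locus (``<element_id>|<sample>|<n>``) for test oracles.
    A configurable fraction of reads is 5'-truncated (uniform up to 50%),
    mimicking long-read cDNA length bias.
    """
    abundance = config.abundance
    if abundance is None:
        abundance = default_abundance(truth, config.samples, config.seed)
    known = {te.element_id for te in truth}
    for (eid, sample) in abundance:
        if eid not in known:
            raise ValueError(f"abundance references unknown locus {eid!r}")
        if sample not in config.samples:
            raise ValueError(f"abundance references unknown sample {sample!r}")
    transcripts = {te.element_id: truth_transcript(genome, te) for te in truth}
    reads: dict[str, list[tuple[str, str, str]]] = {s: [] for s in config.samples}
    for s_idx, sample in enumerate(config.samples):
        rng = np.random.default_rng([config.seed, 7, s_idx])
        for te in truth:
            lam = abundance.get((te.element_id, sample), 0.0)
            n = int(rng.poisson(lam)) if lam > 0 else 0
            tx = transcripts[te.element_id]
            for i in range(n):
                seq = tx
                if rng.random() < config.truncation_rate:
                    cut = int(rng.uniform(0, 0.5) * len(seq))
                    seq = seq[cut:]
                seq = _corrupt(rng, seq, config.error_rates)
                if not seq:
                    continue
                qual = "?" * len(seq)  # fixed Q30 per base
                reads[sample].append((f"{te.element_id}|{sample}|{i}", seq, qual))
    return reads


def simulate_accessions(
    genome: str,
    truth: list[TruthElement],
    cnv_spec: dict[tuple[str, str], int],
    seed: int = 1,
) -> tuple[dict[str, str], "object"]:
    """Accession genomes with specified element copy numbers + truth table.

    ``cnv_spec`` maps (element_id, accession) -> copy count; unspecified
    pairs keep the single planted copy. Count 0 deletes the planted copy;
    counts > 1 insert extra copies (0-5% random substitutions) at random
    intergenic positions. Returns ``({accession: genome}, DataFrame)``.
    """
    import pandas as pd

    by_id = {te.element_id: te for te in truth}
    accessions = sorted({acc for (_, acc) in cnv_spec})
    for (eid, _), n in cnv_spec.items():
        if eid not in by_id:
            raise ValueError(f"cnv_spec references unknown element {eid!r}")
        if n < 0:
            raise ValueError(f"negative copy count for {eid!r}")
    if not accessions:
        return {}, pd.DataFrame()
    # intergenic gaps of the base genome (candidate insertion sites)
    spans = sorted(te.span for te in truth)
    gaps: list[tuple[int, int]] = []
    prev = 0
    for s, e in spans:
        if s - prev >= 2 * MIN_SPACING:
            gaps.append((prev + MIN_SPACING // 2, s - MIN_SPACING // 2))
        prev = e
    if len(genome) - prev >= 2 * MIN_SPACING:
        gaps.append((prev + MIN_SPACING // 2, len(genome) - MIN_SPACING // 2))
    table = pd.DataFrame(1, index=[te.element_id for te in truth], columns=accessions)
    out: dict[str, str] = {}
    for a_idx, acc in enumerate(accessions):
        rng = np.random.default_rng([seed, 11, a_idx])
        edits: list[tuple[int, int, str]] = []  # (pos, del_len, insert_seq)
        for te in truth:
            n = cnv_spec.get((te.element_id, acc), 1)
            table.loc[te.element_id, acc] = n
            if n == 0:
                edits.append((te.span[0], te.span[1] - te.span[0], ""))
            elif n > 1:
                src = genome[te.span[0] : te.span[1]]
                for _ in range(n - 1):
                    gs, ge = gaps[rng.integers(len(gaps))]
                    pos = int(rng.integers(gs, ge))
                    copy = _mutate_substitutions(rng, src, 1.0 - float(rng.uniform(0.0, 0.05)),
                                                 protect=0)
                    edits.append((pos, 0, copy))
        g = genome
        for pos, dlen, ins in sorted(edits, key=lambda e: -e[0]):
            g = g[:pos] + ins + g[pos + dlen :]
        out[acc] = g
    return out, table


def simulate_short_reads(
    genome: str,
    depth: float,
    read_length: int,
    seed: int = 1,
) -> list[tuple[str, str, str]]:
    """Uniform error-free short reads at the given expected coverage.

    Read count is the closed form ``round(depth * len(genome) / read_length)``;
    start positions are uniform, strands random.
    """
    if depth <= 0:
        raise ValueError("depth must be > 0")
    if read_length >= len(genome):
        raise ValueError("read_length must be smaller than the genome")
    rng = np.random.default_rng([seed, 13])
    n = int(round(depth * len(genome) / read_length))
    starts = rng.integers(0, len(genome) - read_length + 1, size=n)
    strands = rng.random(n) < 0.5
    reads = []
    qual = "I" * read_length
    for i, (st, minus) in enumerate(zip(starts, strands)):
        seq = genome[st : st + read_length]
        if minus:
            seq = revcomp(seq)
        reads.append((f"sr_{i}|{st}|{'-' if minus else '+'}", seq, qual))
    return reads
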