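"""Enrichment statistics, expression clustering and condition overlaps.

The clade enrichment test is the Yates-continuity-corrected chi-square on a
2x2 table built directly from the four published-style numbers (clade count
in the expressed set, expressed-set total, clade count in the genome,
genome total); this cell construction reproduces printed retrotransposon
clade statistics exactly, whereas a totals-minus-counts table does not.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import chi2 as chi2_dist
from statsmodels.stats.multitest import multipletests


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 cell counts, row-major: [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("empty table")


@dataclass(frozen=True)
class TestResult:
    chi2: float
    df: int
    p: float


def yates_chisq(t: ContingencyTable) -> TestResult:
    """Pearson chi-square with Yates' continuity correction, df = 1.

    chi2 = N * max(0, |ad - bc| - N/2)^2 / ((a+b)(c+d)(a+c)(b+d)).
    """
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    n = a + b + c + d
    margins = {"row1": a + b, "row2": c + d, "col1": a + c, "col2": b + d}
    zero = [name for name, m in margins.items() if m == 0]
    if zero:
        raise ValueError(f"degenerate margin(s) {zero}: chi-square undefined")
    num = max(0.0, abs(a * d - b * c) - n / 2.0) ** 2
    chi2 = n * num / (margins["row1"] * margins["row2"] * margins["col1"] * margins["col2"])
    p = float(chi2_dist.sf(chi2, 1)) if chi2 > 0 else 1.0
    return TestResult(chi2=chi2, df=1, p=p)


def clade_enrichment(
    expressed_counts: dict[str, int],
    genome_counts: dict[str, int],
    expressed_total: int | None = None,
    genome_total: int | None = None,
) -> pd.DataFrame:
    """Per-clade enrichment of the expressed element set vs the genome.

    For each clade the 2x2 table is (clade expressed, expressed total,
    clade genomic, genome total); direction compares the two proportions.
    Benjamini-Hochberg adjusted p-values are reported alongside raw ones.
    Clades absent from the genome counts are skipped (recorded in the
    ``skipped`` attribute of the returned frame).
    """
    if expressed_total is None:
        expressed_total = sum(expressed_counts.values())
    if genome_total is None:
        genome_total = sum(genome_counts.values())
    rows = []
    skipped = []
    for clade in expressed_counts:
        if clade not in genome_counts:
            skipped.append(clade)
            continue
        a, b = expressed_counts[clade], expressed_total
        c, d = genome_counts[clade], genome_total
        res = yates_chisq(ContingencyTable(a, b, c, d))
        direction = "enriched" if a / b > c / d else ("depleted" if a / b < c / d else "equal")
        rows.append({"clade": clade, "a": a, "b": b, "c": c, "d": d,
                     "chi2": res.chi2, "p": res.p, "direction": direction})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    out.attrs["skipped"] = skipped
    return out


# ---------------------------------------------------------------------------
# Expression clustering
# ---------------------------------------------------------------------------


def pearson_hclust(matrix: pd.DataFrame, k: int,
                   log_transform: bool = True) -> tuple[pd.Series, np.ndarray]:
    """Average-linkage hierarchical clustering on 1 - Pearson correlation.

    Rows are expression profiles (RPM); by default the distance is computed
    on log2(RPM + 1). Zero-variance rows get distance 1 to every other row.
    Returns (cluster labels relabeled in row order, scipy linkage matrix).
    """
    if len(matrix) < 2:
        raise ValueError("need at least two rows to cluster")
    if k > len(matrix):
        raise ValueError(f"k={k} exceeds number of rows ({len(matrix)})")
    x = np.log2(matrix.to_numpy(dtype=float) + 1.0) if log_transform else matrix.to_numpy(dtype=float)
    n = len(x)
    sd = x.std(axis=1)
    dist = np.ones((n, n))
    np.fill_diagonal(dist, 0.0)
    ok = sd > 0
    if ok.sum() >= 2:
        sub = x[ok]
        corr = np.corrcoef(sub)
        d = 1.0 - corr
        idx = np.flatnonzero(ok)
        dist[np.ix_(idx, idx)] = d
        np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, None)
    z = linkage(squareform(dist, checks=False), method="average")
    raw = fcluster(z, t=k, criterion="maxclust")
    # deterministic relabeling: cluster 1 is the first row's cluster, etc.
    relabel: dict[int, int] = {}
    labels = []
    for lab in raw:
        if lab not in relabel:
            relabel[lab] = len(relabel) + 1
        labels.append(relabel[lab])
    return pd.Series(labels, index=matrix.index, name="cluster"), z


# ---------------------------------------------------------------------------
# Condition overlap (upset-style counts)
# ---------------------------------------------------------------------------


def condition_overlap(detected: pd.DataFrame,
                      control: str | None = None) -> pd.DataFrame:
    """Counts of transcripts detected in exactly each condition subset.

    ``detected`` is boolean, transcripts x conditions. All-false rows are
    excluded, so subset counts sum to the number of transcripts detected
    anywhere. The frame's ``treatment_only`` attribute counts transcripts
    detected in at least one non-control condition but not in the control
    (when ``control`` is given).
    """
    conditions = list(detected.columns)
    counts: dict[tuple[str, ...], int] = {}
    for _, row in detected.iterrows():
        subset = tuple(c for c in conditions if bool(row[c]))
        if subset:
            counts[subset] = counts.get(subset, 0) + 1
    rows = [{"subset": s, "size": len(s), "count": n} for s, n in counts.items()]
    out = pd.DataFrame(rows, columns=["subset", "size", "count"])
    if len(out):
        out = out.sort_values(["size", "subset"]).reset_index(drop=True)
    if control is not None and control in conditions:
        treatments = [c for c in conditions if c != control]
        mask = detected[treatments].any(axis=1) & ~detected[control].astype(bool)
        out.attrs["treatment_only"] = int(mask.sum())
    return out


def all_subset_counts(detected: pd.DataFrame) -> dict[tuple[str, ...], int]:
    """Exhaustive-enumeration companion of :func:`condition_overlap`
    (every possible subset, zeros included) — mainly for verification."""
    conditions = list(detected.columns)
    counts = {}
    for r in range(1, len(conditions) + 1):
        for subset in combinations(conditions, r):
            counts[subset] = 0
    for _, row in detected.iterrows():
        subset = tuple(c for c in conditions if bool(row[c]))
        if subset:
            counts[subset] += 1
    return counts
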