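"""Clade enrichment of expressed elements vs the whole genome.

The published sunflower counts are the canonical example: among 34
expressed autonomous/TR elements, the Ale clade holds 20 (vs 1816 of
23,727 genome-wide) and Tekay only 4 (vs 8855). A Yates-corrected
chi-square per clade tests the proportion difference.
"""

import numpy as np
import pandas as pd

from retroscope import clade_enrichment, condition_overlap, pearson_hclust

table = clade_enrichment(
    expressed_counts={"Ale": 20, "Tekay": 4},
    genome_counts={"Ale": 1816, "Tekay": 8855},
    expressed_total=34, genome_total=23727,
)
print(table[["clade", "chi2", "p", "direction", "p_bh"]].to_string(index=False))
# Ale: p < 2.2e-16 (enriched); Tekay: p = 0.03367 (depleted) -- matching
# the printed values digit for digit.

rng = np.random.default_rng(5)
profiles = np.array([[1, 5, 12, 30], [30, 12, 5, 1], [1, 25, 25, 1]])
rpm = pd.DataFrame([p * rng.lognormal(0, 0.15, 4) for p in profiles for _ in range(5)],
                   columns=["control", "AZ_0.5_12HS", "AZ_24HS", "ActyDZ_24HS"])
labels, _ = pearson_hclust(rpm, k=3)
print("\nexpression clusters (correlation distance):", labels.tolist())

overlap = condition_overlap(rpm > 2, control="control")
print("\ncondition subsets (upset counts):")
print(overlap.assign(subset=overlap.subset.map("|".join)).to_string(index=False))
print("treatment-only transcripts:", overlap.attrs["treatment_only"])
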