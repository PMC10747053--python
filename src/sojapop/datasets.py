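"""Bundled example data: the 64-accession wild-soybean phenotype survey.

Eleven categorical traits scored on 64 *G. soja* accessions from the three
Chinese eco-regional groups (NER northeastern, CR central/Huang-Huai, SR
southern; 32/16/16 accessions).  The survey is stored as per-group category
counts and expanded deterministically to one row per accession, so the
expansion is an exact reconstruction of the group-level survey table, not
individual-level records.
"""

from __future__ import annotations

import pandas as pd

GROUPS = ("NER", "CR", "SR")
GROUP_SIZES = {"NER": 32, "CR": 16, "SR": 16}

# trait -> category -> (NER, CR, SR) counts
PHENOTYPE_COUNTS = {
    "flower_color": {"Purple": (32, 16, 16)},
    "pubescence_color": {"Brown": (32, 16, 16)},
    "seed_coat_color": {"Black": (32, 16, 16)},
    "leaf_shape": {"Lanceolate": (6, 2, 2), "Ovoid": (15, 2, 3), "Ellipse": (11, 12, 11)},
    "pubescence_type": {"Erect": (0, 0, 5), "Oblique": (15, 14, 8), "Flat": (17, 2, 3)},
    "seed_shape": {"Round": (1, 0, 0), "Oblate": (6, 0, 1), "Ellipse": (1, 0, 0),
                   "Flat ellipse": (24, 16, 13), "Long ellipse": (0, 0, 2)},
    "hilum_color": {"Yellow": (1, 1, 2), "Light black": (1, 3, 4), "Black": (30, 12, 10)},
    "seed_coat_bloom": {"No": (0, 0, 3), "Yes": (32, 16, 13)},
    "seed_luster": {"No": (28, 11, 9), "Weak": (4, 5, 7)},
    "pod_shape": {"Straight": (10, 3, 2), "Bent": (22, 13, 14)},
    "pod_color": {"Brown": (5, 6, 7), "Dark brown": (15, 7, 8), "Black": (12, 3, 1)},
}


def phenotype_survey() -> pd.DataFrame:
    """One row per accession with ``accession``, ``group`` and the 11 traits.

    Within each group, trait categories are assigned to accessions in fixed
    declaration order, which reproduces the group-level counts exactly.
    """
    accessions, groups = [], []
    for g in GROUPS:
        for i in range(GROUP_SIZES[g]):
            accessions.append(f"{g}{i + 1:02d}")
            groups.append(g)
    out = pd.DataFrame({"accession": accessions, "group": groups})
    for trait, cats in PHENOTYPE_COUNTS.items():
        col = []
        for gi, g in enumerate(GROUPS):
            for cat, counts in cats.items():
                col.extend([cat] * counts[gi])
        if len(col) != len(out):
            raise AssertionError(f"trait {trait} counts do not partition the panel")
        out[trait] = col
    return out
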