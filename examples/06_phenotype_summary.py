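"""Tabulate the bundled 64-accession phenotype survey by eco-regional group.

Prints the per-group counts and whole-population percentages for a few
informative traits of the NER/CR/SR wild-soybean panel.
"""

from sojapop.datasets import phenotype_survey
from sojapop.pheno import category_percent, category_total, summarize

survey = phenotype_survey()
summary = summarize(survey, allowed_groups=("NER", "CR", "SR"))

print(f"{len(survey)} accessions, "
      f"{survey.shape[1] - 2} categorical traits\n")
for trait, cat in [("pubescence_type", "Oblique"), ("pod_color", "Dark brown"),
                   ("seed_coat_bloom", "Yes"), ("hilum_color", "Black"),
                   ("seed_shape", "Flat ellipse")]:
    total = category_total(summary, trait, cat)
    pct = category_percent(summary, trait, cat)
    by_group = (summary.query("trait == @trait and category == @cat")
                .set_index("group")["count"].to_dict())
    print(f"{trait:16s} {cat:13s} total {total:2d} ({pct:.0f}%) "
          f"by group: {by_group}")
# e.g. 37 accessions with oblique pubescence (15 NER + 14 CR + 8 SR) and
# 30 with dark-brown pods; 95% show a bloomed seed coat.
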