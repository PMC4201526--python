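"""Reclassify the packaged 63-miRNA enrichment fixture from its TPM values.

Applies the detection cutoff (TPM > 5 in at least one library) and the
two-fold enrichment rule (log2 EV/CL >= 1) to the packaged TPM table and
prints the resulting Venn partition and the first rows of each category.
"""

from evmir.pipeline import enrich_fixture, fixture_check

records, summary = enrich_fixture()

print("enriched miRNAs:", summary["n_enriched"])
for cat in ("A33_only", "EpCAM_only", "sMV_only", "all_EVs",
            "A33_EpCAM", "A33_sMV", "EpCAM_sMV"):
    print(f"  {cat}: {summary[cat]}")
print("per-EV totals:", summary["total_A33"], summary["total_EpCAM"], summary["total_sMV"])
print("enriched in both exosome captures:", summary["both_exosomes"])

print("\ntop of each category:")
for cat, block in records.groupby("category", sort=False):
    row = block.iloc[0]
    print(f"  {cat}: {row['arm_id']} (log2 A33/CL = {row['log2fc_a33_cl']:.2f})")

report = fixture_check()
print("\nfixture check all_pass:", report["all_pass"]["pass"])
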