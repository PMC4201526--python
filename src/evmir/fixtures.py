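"""Packaged study fixtures: the published per-library read-count summary and
the 63-row enriched-miRNA TPM matrix with its printed log2 columns.

These are the printed tables of the original study, shipped so the
classification arithmetic can be recomputed and checked without the raw
sequencing archive.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

LIBRARIES = ("A33-Exos", "EpCAM-Exos", "sMVs", "CL")

TPM_COLUMNS = {"A33-Exos": "tpm_a33", "EpCAM-Exos": "tpm_epcam", "sMVs": "tpm_smv", "CL": "tpm_cl"}

# printed log2 column -> (numerator TPM column, denominator TPM column)
PRINTED_LOG2_COLUMNS = {
    "log2_a33_cl": ("tpm_a33", "tpm_cl"),
    "log2_epcam_cl": ("tpm_epcam", "tpm_cl"),
    "log2_smv_cl": ("tpm_smv", "tpm_cl"),
    "log2_a33_epcam": ("tpm_a33", "tpm_epcam"),
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("evmir.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def enriched_mirna_table() -> pd.DataFrame:
    """63-row enriched-miRNA fixture: group, TPMs and printed log2 ratios."""
    return _read("table2_enriched_mirnas.tsv")


def enriched_mirna_tpm() -> pd.DataFrame:
    """Arms x libraries TPM matrix from the enriched-miRNA fixture."""
    table = enriched_mirna_table().set_index("mir_id")
    tpm = table[[TPM_COLUMNS[lib] for lib in LIBRARIES]].copy()
    tpm.columns = list(LIBRARIES)
    return tpm


def read_count_summary() -> pd.DataFrame:
    """Per-library raw/clean/annotated read counts with printed percentages."""
    return _read("table1_read_counts.tsv").set_index("library")
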