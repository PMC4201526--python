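"""EV-enrichment analysis: fold changes, Audic-Claverie test, Venn categories.

An arm is called enriched in an EV library when its log2 TPM ratio against the
parental cell library (CL) is at least ``threshold_log2`` (default 1.0, i.e.
a two-fold change). The combination of the three EV-vs-CL calls places each
arm in one of seven Venn categories (or ``not_enriched``).

Differential significance between two count libraries uses the Audic-Claverie
posterior-predictive test: given ``x`` counts in a library of size ``n1``, the
count ``y'`` in a library of size ``n2`` follows

    p(y' | x) = (n2/n1)^y' * (x+y')! / (x! * y'! * (1 + n2/n1)^(x+y'+1)),

a negative binomial with ``x+1`` successes and success probability
``n1/(n1+n2)``; tails are evaluated through the regularised incomplete beta
function and are stable for counts up to 1e7. P-values are reported alongside
the fold-change classification but do not enter it by default (a minimum
significance can be required via ``require_p``).
"""

from __future__ import annotations

from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PSEUDOCOUNT = 0.01


class VennCategory(str, Enum):
    A33_ONLY = "A33_only"
    EPCAM_ONLY = "EpCAM_only"
    SMV_ONLY = "sMV_only"
    ALL_EVS = "all_EVs"
    A33_EPCAM = "A33_EpCAM"
    A33_SMV = "A33_sMV"
    EPCAM_SMV = "EpCAM_sMV"
    NOT_ENRICHED = "not_enriched"


# membership flag triple (A33, EpCAM, sMV) -> category
_FLAGS_TO_CATEGORY = {
    (True, False, False): VennCategory.A33_ONLY,
    (False, True, False): VennCategory.EPCAM_ONLY,
    (False, False, True): VennCategory.SMV_ONLY,
    (True, True, True): VennCategory.ALL_EVS,
    (True, True, False): VennCategory.A33_EPCAM,
    (True, False, True): VennCategory.A33_SMV,
    (False, True, True): VennCategory.EPCAM_SMV,
    (False, False, False): VennCategory.NOT_ENRICHED,
}

CATEGORY_MEMBERS = {
    VennCategory.A33_ONLY: ("A33",),
    VennCategory.EPCAM_ONLY: ("EpCAM",),
    VennCategory.SMV_ONLY: ("sMV",),
    VennCategory.ALL_EVS: ("A33", "EpCAM", "sMV"),
    VennCategory.A33_EPCAM: ("A33", "EpCAM"),
    VennCategory.A33_SMV: ("A33", "sMV"),
    VennCategory.EPCAM_SMV: ("EpCAM", "sMV"),
    VennCategory.NOT_ENRICHED: (),
}


def log2_fold_change(
    tpm_sample: float, tpm_control: float, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> float:
    """log2(sample/control) on TPM values; pseudocount engages only on zeros."""
    if tpm_sample < 0 or tpm_control < 0:
        raise ValueError("TPM values must be non-negative")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if tpm_sample == 0 and tpm_control == 0:
        return 0.0
    a = pseudocount if min(tpm_sample, tpm_control) == 0 else 0.0
    return float(np.log2((tpm_sample + a) / (tpm_control + a)))


def audic_claverie_pvalue(
    x: int, y: int, n1: float, n2: float, side: str = "two_sided"
) -> float:
    """Audic-Claverie p-value for observing ``y`` in library 2 given ``x`` in library 1.

    ``side``: ``upper`` is P(Y' >= y | x), ``lower`` is P(Y' <= y | x),
    ``two_sided`` is min(1, 2 * min(lower, upper)).
    """
    for v, name in ((x, "x"), (y, "y")):
        if not float(v).is_integer() or v < 0:
            raise ValueError(f"count {name} must be a non-negative integer, got {v!r}")
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library sizes must be positive")
    x, y = int(x), int(y)
    # Y' | x ~ NegBinom(successes = x+1, success prob = n1/(n1+n2))
    dist = stats.nbinom(x + 1, n1 / (n1 + n2))
    if side == "upper":
        return float(dist.sf(y - 1))
    if side == "lower":
        return float(dist.cdf(y))
    if side == "two_sided":
        return float(min(1.0, 2.0 * min(dist.cdf(y), dist.sf(y - 1))))
    raise ValueError(f"unknown side {side!r}")


def classify_venn(
    log2fc_a33: float, log2fc_epcam: float, log2fc_smv: float, threshold_log2: float = 1.0
) -> VennCategory:
    """Venn category from the three EV-vs-CL log2 fold changes (>= is inclusive)."""
    flags = (
        log2fc_a33 >= threshold_log2,
        log2fc_epcam >= threshold_log2,
        log2fc_smv >= threshold_log2,
    )
    return _FLAGS_TO_CATEGORY[flags]


_CATEGORY_ORDER = [
    VennCategory.A33_ONLY,
    VennCategory.EPCAM_ONLY,
    VennCategory.SMV_ONLY,
    VennCategory.ALL_EVS,
    VennCategory.A33_EPCAM,
    VennCategory.A33_SMV,
    VennCategory.EPCAM_SMV,
]


def _sort_key_fc(row: pd.Series) -> float:
    """Within-category ordering: descending fold change of the leading member EV."""
    members = CATEGORY_MEMBERS[VennCategory(row["category"])]
    if "A33" in members:
        return row["log2fc_a33_cl"]
    if "EpCAM" in members:
        return row["log2fc_epcam_cl"]
    if "sMV" in members:
        return row["log2fc_smv_cl"]
    return row["log2fc_a33_cl"]


def enrichment_table(
    matrix: pd.DataFrame,
    a33: str = "A33-Exos",
    epcam: str = "EpCAM-Exos",
    smv: str = "sMVs",
    cl: str = "CL",
    counts: pd.DataFrame | None = None,
    library_sizes: dict[str, float] | None = None,
    threshold_log2: float = 1.0,
    tpm_cutoff: float = 5.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    require_p: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Build the per-arm enrichment table and the Venn summary.

    ``matrix`` is the arms x libraries TPM table; ``counts`` (optional, same
    shape) supplies integer counts for the Audic-Claverie p-values and the
    count-pooled exosome column; ``library_sizes`` gives the per-library
    miRNA-read totals used with ``counts``. With ``require_p`` set, membership
    additionally requires a two-sided p-value below that level.

    Returns (records, summary). ``summary`` holds the seven category counts,
    per-EV totals under union semantics, and the exosome-intersection count.
    """
    for lib in (a33, epcam, smv, cl):
        if lib not in matrix.columns:
            raise KeyError(f"library {lib!r} missing from the expression matrix")

    from .quantify import expression_cutoff

    kept = expression_cutoff(matrix[[a33, epcam, smv, cl]], tpm_cutoff)

    rows = []
    for arm_id, tpm in kept.iterrows():
        fc = {
            "log2fc_a33_cl": log2_fold_change(tpm[a33], tpm[cl], pseudocount),
            "log2fc_epcam_cl": log2_fold_change(tpm[epcam], tpm[cl], pseudocount),
            "log2fc_smv_cl": log2_fold_change(tpm[smv], tpm[cl], pseudocount),
            "log2fc_a33_epcam": log2_fold_change(tpm[a33], tpm[epcam], pseudocount),
        }
        pvals = dict.fromkeys(("pvalue_a33_cl", "pvalue_epcam_cl", "pvalue_smv_cl"), np.nan)
        if counts is not None and library_sizes is not None and arm_id in counts.index:
            c = counts.loc[arm_id]
            for key, lib in (("pvalue_a33_cl", a33), ("pvalue_epcam_cl", epcam), ("pvalue_smv_cl", smv)):
                pvals[key] = audic_claverie_pvalue(
                    int(round(c[cl])), int(round(c[lib])), library_sizes[cl], library_sizes[lib]
                )
        # pooled exosome column: count-pooled TPM when counts are available,
        # otherwise the mean of the two exosome TPMs (approximate either way)
        if counts is not None and library_sizes is not None and arm_id in counts.index:
            c = counts.loc[arm_id]
            pooled = (c[a33] + c[epcam]) / (library_sizes[a33] + library_sizes[epcam]) * 1e6
        else:
            pooled = (tpm[a33] + tpm[epcam]) / 2.0
        fc["log2fc_exos_smv"] = log2_fold_change(pooled, tpm[smv], pseudocount)

        category = classify_venn(
            fc["log2fc_a33_cl"], fc["log2fc_epcam_cl"], fc["log2fc_smv_cl"], threshold_log2
        )
        if require_p is not None and category is not VennCategory.NOT_ENRICHED:
            flags = [
                fc["log2fc_a33_cl"] >= threshold_log2 and pvals["pvalue_a33_cl"] < require_p,
                fc["log2fc_epcam_cl"] >= threshold_log2 and pvals["pvalue_epcam_cl"] < require_p,
                fc["log2fc_smv_cl"] >= threshold_log2 and pvals["pvalue_smv_cl"] < require_p,
            ]
            category = _FLAGS_TO_CATEGORY[tuple(bool(f) for f in flags)]
        rows.append(
            {
                "arm_id": arm_id,
                "tpm_a33": tpm[a33],
                "tpm_epcam": tpm[epcam],
                "tpm_smv": tpm[smv],
                "tpm_cl": tpm[cl],
                **fc,
                **pvals,
                "category": category.value,
            }
        )

    records = pd.DataFrame(rows)
    if not records.empty:
        records = records[records["category"] != VennCategory.NOT_ENRICHED.value].copy()
    if not records.empty:
        cat_rank = {c.value: i for i, c in enumerate(_CATEGORY_ORDER)}
        records["_rank"] = records["category"].map(cat_rank)
        records["_fc"] = records.apply(_sort_key_fc, axis=1)
        records = (
            records.sort_values(["_rank", "_fc"], ascending=[True, False])
            .drop(columns=["_rank", "_fc"])
            .reset_index(drop=True)
        )

    summary = {c.value: 0 for c in _CATEGORY_ORDER}
    if not records.empty:
        for cat, n in records["category"].value_counts().items():
            summary[cat] = int(n)
    totals = {"A33": 0, "EpCAM": 0, "sMV": 0}
    for cat in _CATEGORY_ORDER:
        for member in CATEGORY_MEMBERS[cat]:
            totals[member] += summary[cat.value]
    summary["total_A33"] = totals["A33"]
    summary["total_EpCAM"] = totals["EpCAM"]
    summary["total_sMV"] = totals["sMV"]
    summary["both_exosomes"] = (
        summary[VennCategory.ALL_EVS.value] + summary[VennCategory.A33_EPCAM.value]
    )
    summary["n_enriched"] = int(len(records))
    return records, summary
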