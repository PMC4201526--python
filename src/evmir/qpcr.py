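"""qRT-PCR relative quantification (delta-delta-Ct) and sequencing concordance.

Relative expression of a target between an EV sample and the parental cells is

    ddCt = (Ct_target,EV - Ct_ref,EV) - (Ct_target,CL - Ct_ref,CL)

where the reference Ct of a sample is the mean over the named normaliser
assays (default) or, in ``global_mean`` mode, the mean over all measured
targets in that sample. ``-ddCt`` approximates the sequencing log2 fold
change, so concordance is fraction of targets whose ``-ddCt`` sign matches
the sequencing fold-change sign. Assays with any required Ct above the
detection cutoff (default 35 cycles) are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_CT_CUTOFF = 35.0
DEFAULT_CONTROLS = ("U6-snRNA", "MaMMU6")


@dataclass
class QpcrAssay:
    target_id: str
    included: bool
    delta_delta_ct: dict[str, float]  # per EV-vs-CL comparison

    @property
    def neg_ddct(self) -> dict[str, float]:
        return {k: -v for k, v in self.delta_delta_ct.items()}


def delta_delta_ct(
    ct_target_ev: float, ct_ref_ev: float, ct_target_cl: float, ct_ref_cl: float
) -> float:
    """ddCt for one target/comparison; caller enforces the Ct cutoff."""
    return (ct_target_ev - ct_ref_ev) - (ct_target_cl - ct_ref_cl)


def read_ct_table(path: str | Path) -> pd.DataFrame:
    """Ct TSV (target_id, sample, ct) -> targets x samples table."""
    df = pd.read_csv(path, sep="\t")
    return df.pivot(index="target_id", columns="sample", values="ct")


def ddct_table(
    ct: pd.DataFrame,
    ev_samples: tuple[str, ...],
    cl_sample: str,
    controls: tuple[str, ...] = DEFAULT_CONTROLS,
    ct_cutoff: float = DEFAULT_CT_CUTOFF,
    mode: str = "controls",
) -> list[QpcrAssay]:
    """Compute per-target ddCt for each EV-vs-CL comparison.

    ``mode="controls"`` normalises against the mean Ct of the named control
    assays per sample; ``mode="global_mean"`` against the per-sample mean Ct
    over all non-control targets. A target is excluded when any of its Ct
    values in the compared samples exceeds ``ct_cutoff``.
    """
    if mode not in ("controls", "global_mean"):
        raise ValueError(f"unknown normalisation mode {mode!r}")
    samples = (*ev_samples, cl_sample)
    targets = [t for t in ct.index if t not in controls]
    if mode == "controls":
        missing = [c for c in controls if c not in ct.index]
        if missing:
            raise KeyError(f"control assays missing from Ct table: {missing}")
        ref = ct.loc[list(controls), list(samples)].mean(axis=0)
    else:
        ref = ct.loc[targets, list(samples)].mean(axis=0)

    assays = []
    for target in targets:
        row = ct.loc[target, list(samples)]
        included = bool(row.notna().all() and (row <= ct_cutoff).all())
        ddct = {}
        if included:
            for ev in ev_samples:
                ddct[f"{ev}_vs_{cl_sample}"] = delta_delta_ct(
                    row[ev], ref[ev], row[cl_sample], ref[cl_sample]
                )
        assays.append(QpcrAssay(target_id=target, included=included, delta_delta_ct=ddct))
    return assays


def concordance(
    seq_log2fc: pd.Series, neg_ddct: pd.Series
) -> tuple[int, int, float]:
    """Direction agreement between sequencing fold changes and -ddCt.

    Targets are matched by id; a pair agrees when the signs match (zero agrees
    only with zero). Returns (n_compared, n_same_direction, fraction).
    """
    shared = seq_log2fc.index.intersection(neg_ddct.index)
    shared = [t for t in shared if pd.notna(seq_log2fc[t]) and pd.notna(neg_ddct[t])]
    if len(shared) == 0:
        raise ValueError("no targets shared between sequencing and qPCR results")
    same = sum(1 for t in shared if np.sign(seq_log2fc[t]) == np.sign(neg_ddct[t]))
    return len(shared), same, same / len(shared)
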