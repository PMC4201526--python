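"""Passenger-strand (miRNA*) dominance analysis.

Each precursor yields a duplex whose two arms are annotated as the mature
strand and the star (passenger) strand; star identity is a fixed reference
annotation, while which strand dominates expression can differ between
libraries. A dominance *switch* for an EV library is a precursor whose star
arm out-expresses the mature arm in that EV while the mature arm dominates in
the parental cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .enrichment import DEFAULT_PSEUDOCOUNT
from .reference import ReferenceBundle


@dataclass
class StrandPairRecord:
    precursor_id: str
    mature_arm_id: str
    star_arm_id: str
    tpm_mature: dict[str, float]
    tpm_star: dict[str, float]
    log2_star_over_mature: dict[str, float] = field(default_factory=dict)
    star_dominant: dict[str, bool] = field(default_factory=dict)

    def star_dominant_all(self) -> bool:
        return all(self.star_dominant.values())


def pair_strands(
    bundle: ReferenceBundle,
    matrix: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[list[StrandPairRecord], int]:
    """Pair mature and star arms per two-arm precursor present in the matrix.

    Returns the pair records and the number of precursors skipped because they
    have a single arm or an arm absent from the expression matrix. Ratio
    columns use the pseudocount only when a TPM is zero; dominance compares
    raw TPM (ties dominate neither way).
    """
    records: list[StrandPairRecord] = []
    skipped = 0
    for pre_id in sorted(bundle.precursors):
        arms = bundle.arms_of(pre_id)
        if len(arms) != 2:
            skipped += 1
            continue
        stars = [a for a in arms if a.star]
        if len(stars) == 2:
            raise ValueError(f"precursor {pre_id} has two arms flagged star")
        if len(stars) == 0:
            raise ValueError(f"precursor {pre_id} has two arms but no star flag")
        star, mature = stars[0], next(a for a in arms if not a.star)
        if star.id not in matrix.index or mature.id not in matrix.index:
            skipped += 1
            continue
        tpm_star = matrix.loc[star.id].to_dict()
        tpm_mature = matrix.loc[mature.id].to_dict()
        rec = StrandPairRecord(
            precursor_id=pre_id,
            mature_arm_id=mature.id,
            star_arm_id=star.id,
            tpm_mature=tpm_mature,
            tpm_star=tpm_star,
        )
        for lib in matrix.columns:
            s, m = tpm_star[lib], tpm_mature[lib]
            if s == 0 and m == 0:
                ratio = 0.0
            else:
                a = pseudocount if min(s, m) == 0 else 0.0
                ratio = float(np.log2((s + a) / (m + a)))
            rec.log2_star_over_mature[lib] = ratio
            rec.star_dominant[lib] = s > m
        records.append(rec)
    return records, skipped


def detect_dominance_switch(
    record: StrandPairRecord, ev_library: str, cl_library: str
) -> bool:
    """True iff the star arm dominates in the EV and the mature arm in CL."""
    for lib in (ev_library, cl_library):
        if lib not in record.tpm_star:
            raise KeyError(f"library {lib!r} absent from strand-pair record")
    return (
        record.tpm_star[ev_library] > record.tpm_mature[ev_library]
        and record.tpm_star[cl_library] < record.tpm_mature[cl_library]
    )


def star_enrichment_report(
    records: list[StrandPairRecord],
    enrichment_records: pd.DataFrame,
    bundle: ReferenceBundle,
    ev_libraries: tuple[str, ...],
    cl_library: str,
) -> dict:
    """Summary of star-arm representation and dominance switches.

    Counts star-flagged arms present in the strand pairs, how many of those
    fall in the EV-enriched set, and lists switch precursors per EV library.
    """
    star_arms = {r.star_arm_id for r in records}
    enriched_ids = (
        set(enrichment_records["arm_id"]) if not enrichment_records.empty else set()
    )
    switches = {
        ev: sorted(
            r.precursor_id for r in records if detect_dominance_switch(r, ev, cl_library)
        )
        for ev in ev_libraries
    }
    return {
        "n_star_arms_detected": len(star_arms),
        "n_star_arms_enriched": len(star_arms & enriched_ids),
        "n_star_dominant_all_libraries": sum(1 for r in records if r.star_dominant_all()),
        "switches": switches,
    }


def strand_pair_table(records: list[StrandPairRecord], libraries: list[str]) -> pd.DataFrame:
    rows = []
    for r in records:
        for lib in libraries:
            rows.append(
                {
                    "precursor_id": r.precursor_id,
                    "library": lib,
                    "mature_arm": r.mature_arm_id,
                    "star_arm": r.star_arm_id,
                    "tpm_mature": r.tpm_mature[lib],
                    "tpm_star": r.tpm_star[lib],
                    "log2_star_over_mature": r.log2_star_over_mature[lib],
                    "star_dominant": r.star_dominant[lib],
                }
            )
    return pd.DataFrame(rows)
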