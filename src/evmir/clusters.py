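"""Genomic context: polycistronic miRNA clusters and family representation.

Precursors lying within a genomic window (default 10 kbp, measured as
intervening bases between precursor intervals) are chained into clusters,
mirroring the convention that such groups sit on one polycistronic transcript.
Cluster enrichment of a detected precursor set is scored with a one-sided
Fisher exact test and Benjamini-Hochberg q-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .reference import Precursor, ReferenceBundle


@dataclass
class ClusterCall:
    cluster_id: str
    chromosome: str
    members: list[str]  # precursor ids ordered by start
    span: tuple[int, int]
    n_members_total: int = 0
    n_members_detected: int = 0

    def __post_init__(self) -> None:
        if not self.n_members_total:
            self.n_members_total = len(self.members)


def detect_clusters(
    precursors: list[Precursor] | dict[str, Precursor],
    max_gap: int = 10_000,
    gap_mode: str = "interval",
) -> list[ClusterCall]:
    """Chain precursors within ``max_gap`` of each other; emit chains of >= 2.

    ``gap_mode="interval"`` counts intervening bases between intervals
    (``next.start - current.end - 1``); ``"start"`` measures start-to-start
    distance. Chaining is per chromosome and strand-agnostic; against nested
    or overlapping intervals the running chain end is the maximum end seen.
    """
    if isinstance(precursors, dict):
        precursors = list(precursors.values())
    seen = set()
    for p in precursors:
        if p.id in seen:
            raise ValueError(f"duplicate precursor id {p.id!r}")
        seen.add(p.id)
    if gap_mode not in ("interval", "start"):
        raise ValueError(f"unknown gap_mode {gap_mode!r}")

    by_chrom: dict[str, list[Precursor]] = {}
    for p in precursors:
        by_chrom.setdefault(p.chrom, []).append(p)

    calls: list[ClusterCall] = []
    for chrom in sorted(by_chrom):
        loci = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end, p.id))
        chain: list[Precursor] = []
        chain_end = None
        prev_start = None

        def flush() -> None:
            if len(chain) >= 2:
                calls.append(
                    ClusterCall(
                        cluster_id=f"cluster_{len(calls) + 1}",
                        chromosome=chrom,
                        members=[p.id for p in chain],
                        span=(min(p.start for p in chain), max(p.end for p in chain)),
                    )
                )

        for p in loci:
            if chain:
                if gap_mode == "interval":
                    gap = p.start - chain_end - 1
                else:
                    gap = p.start - prev_start
                if gap <= max_gap:
                    chain.append(p)
                    chain_end = max(chain_end, p.end)
                    prev_start = p.start
                    continue
                flush()
            chain = [p]
            chain_end = p.end
            prev_start = p.start
        flush()
    return calls


def annotate_detection(clusters: list[ClusterCall], detected_precursors: set[str]) -> None:
    """Fill ``n_members_detected`` on each cluster in place."""
    for c in clusters:
        c.n_members_detected = sum(1 for m in c.members if m in detected_precursors)


def cluster_enrichment(
    clusters: list[ClusterCall],
    detected_precursors: set[str],
    universe_size: int,
) -> pd.DataFrame:
    """Per-cluster Fisher exact enrichment of the detected set, with BH q-values.

    For each cluster the 2x2 table is (in-cluster vs outside) x (detected vs
    not), tested one-sided for over-representation of detected precursors.
    """
    n_detected = len(detected_precursors)
    if universe_size < n_detected:
        raise ValueError("universe smaller than the detected set")
    annotate_detection(clusters, detected_precursors)
    rows = []
    for c in clusters:
        a = c.n_members_detected
        b = c.n_members_total - a
        outside_detected = n_detected - a
        outside_missed = universe_size - c.n_members_total - outside_detected
        _, p = fisher_exact([[a, b], [outside_detected, outside_missed]], alternative="greater")
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "chromosome": c.chromosome,
                "n_detected": a,
                "n_total": c.n_members_total,
                "p_value": p,
            }
        )
    df = pd.DataFrame(rows)
    if not df.empty:
        df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df = df.sort_values("p_value", kind="stable").reset_index(drop=True)
    return df


def family_summary(bundle: ReferenceBundle, detected_arms: set[str]) -> pd.DataFrame:
    """Per-family (n_detected, n_total, fraction) over the reference families."""
    unknown = sorted(
        m for members in bundle.families.values() for m in members if m not in bundle.arms
    )
    if unknown:
        raise ValueError(f"family table lists arms absent from the reference: {unknown}")
    rows = []
    for fam in sorted(bundle.families):
        members = bundle.families[fam]
        n_det = sum(1 for m in members if m in detected_arms)
        rows.append(
            {
                "family": fam,
                "n_detected": n_det,
                "n_total": len(members),
                "fraction": n_det / len(members) if members else 0.0,
            }
        )
    return pd.DataFrame(rows)


def chromosome_distribution(clusters: list[ClusterCall]) -> pd.Series:
    """Cluster counts per chromosome, descending."""
    counts: dict[str, int] = {}
    for c in clusters:
        counts[c.chromosome] = counts.get(c.chromosome, 0) + 1
    return pd.Series(counts, dtype=int).sort_values(ascending=False)
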