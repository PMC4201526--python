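"""Assign clean reads to miRNA arms, count libraries and normalise to TPM.

Read assignment is prefix-anchored: the 5' end of a small-RNA read defines the
seed, so a read matches an arm when it equals the arm sequence exactly, equals
the arm with its last 1-2 bases removed (3' isomiR trimming), or extends the
arm by 1-2 bases at the 3' end. Reads matching several arms are split
fractionally (1/k each) so that column sums are conserved. Reads matching no
arm are checked against the contaminant references (exact substring, in the
fixed order rRNA, tRNA, snRNA, snoRNA, srpRNA) and otherwise left unannotated.

TPM uses the library's miRNA-assigned reads as denominator:
``TPM(arm) = count(arm) / miRNA_reads * 1e6`` (configurable to all clean
reads), so each library column sums to one million over arms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .qc import ReadRecord
from .reference import CONTAMINANT_ORDER, ReferenceBundle

CATEGORIES = ("miRNA",) + tuple(f"{c}-like" for c in CONTAMINANT_ORDER) + ("unannotated",)


class ArmIndex:
    """Hash index over arm sequences supporting the 3' +/-2 nt match policy."""

    def __init__(self, bundle: ReferenceBundle):
        self.bundle = bundle
        self.exact: dict[str, list[str]] = {}
        self.trimmed: dict[str, list[str]] = {}  # arm seq minus 1 or 2 nt -> arm ids
        for arm in bundle.arms.values():
            self.exact.setdefault(arm.sequence, []).append(arm.id)
            for k in (1, 2):
                self.trimmed.setdefault(arm.sequence[:-k], []).append(arm.id)
        self._contaminants = [
            (cat, [seq for _, seq in bundle.contaminants.get(cat, [])])
            for cat in CONTAMINANT_ORDER
        ]

    def assign(self, sequence: str) -> tuple[str, list[str] | None]:
        """Classify one read sequence.

        Returns ``("miRNA", [arm ids])``, ``("<cat>-like", None)`` or
        ``("unannotated", None)``.
        """
        if not (18 <= len(sequence) <= 30):
            raise ValueError(
                f"read length {len(sequence)} violates the 18-30 nt clean-read contract"
            )
        hits: list[str] = []
        hits += self.exact.get(sequence, [])
        hits += self.trimmed.get(sequence, [])  # read is a 3'-trimmed arm
        for k in (1, 2):  # read extends an arm by k nt
            hits += self.exact.get(sequence[:-k], [])
        if hits:
            return "miRNA", sorted(set(hits))
        for cat, refs in self._contaminants:
            for ref in refs:
                if sequence in ref:
                    return f"{cat}-like", None
        return "unannotated", None


def assign_read(sequence: str, bundle: ReferenceBundle) -> tuple[str, list[str] | None]:
    """One-shot read assignment (builds a throwaway index; prefer ArmIndex)."""
    return ArmIndex(bundle).assign(sequence)


@dataclass
class CountProfile:
    """Per-library arm counts (fractional) and small-RNA category tallies."""

    library: str
    arm_counts: dict[str, float] = field(default_factory=dict)
    category_counts: dict[str, float] = field(default_factory=lambda: dict.fromkeys(CATEGORIES, 0.0))
    total_clean: int = 0

    def check(self) -> None:
        if abs(sum(self.category_counts.values()) - self.total_clean) > 1e-6:
            raise AssertionError("category counts do not partition the clean reads")
        if abs(sum(self.arm_counts.values()) - self.category_counts["miRNA"]) > 1e-6:
            raise AssertionError("arm counts do not sum to the miRNA category count")


def count_library(
    reads: Iterable[ReadRecord],
    bundle: ReferenceBundle,
    library: str = "",
    index: ArmIndex | None = None,
) -> CountProfile:
    """Count clean reads of one library against the reference bundle."""
    index = index or ArmIndex(bundle)
    profile = CountProfile(library=library)
    counts = profile.arm_counts
    cats = profile.category_counts
    for read in reads:
        profile.total_clean += 1
        category, arms = index.assign(read.sequence)
        cats[category] += 1
        if arms:
            w = 1.0 / len(arms)
            for arm_id in arms:
                counts[arm_id] = counts.get(arm_id, 0.0) + w
    profile.check()
    return profile


def tpm_normalize(profile: CountProfile, denominator: str = "miRNA") -> pd.Series:
    """TPM column for one library.

    ``denominator`` is ``"miRNA"`` (miRNA-assigned reads; default) or
    ``"clean"`` (all clean reads).
    """
    if denominator == "miRNA":
        total = profile.category_counts["miRNA"]
    elif denominator == "clean":
        total = float(profile.total_clean)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if total <= 0:
        raise ValueError(f"library {profile.library!r} has no miRNA-mapped reads")
    col = pd.Series(profile.arm_counts, dtype=float) / total * 1e6
    col.name = profile.library
    return col


def expression_matrix(profiles: Iterable[CountProfile], denominator: str = "miRNA") -> pd.DataFrame:
    """Arms x libraries TPM table (absent arms filled with 0)."""
    cols = [tpm_normalize(p, denominator) for p in profiles]
    return pd.concat(cols, axis=1).fillna(0.0).sort_index()


def expression_cutoff(matrix: pd.DataFrame, threshold: float = 5.0) -> pd.DataFrame:
    """Retain arms with TPM strictly above ``threshold`` in at least one library.

    Library denominators are NOT recomputed; dropped arms keep their share of
    the per-million scale.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    return matrix.loc[(matrix > threshold).any(axis=1)]


def category_summary(profiles: Iterable[CountProfile]) -> pd.DataFrame:
    """Libraries x categories table with counts and percentages of clean reads."""
    rows = {}
    for p in profiles:
        row = {"clean_reads": p.total_clean}
        for cat in CATEGORIES:
            row[cat] = p.category_counts[cat]
            row[f"{cat}_pct"] = (
                100.0 * p.category_counts[cat] / p.total_clean if p.total_clean else 0.0
            )
        rows[p.library] = row
    return pd.DataFrame(rows).T


def write_counts(profiles: Iterable[CountProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("arm_id\tlibrary\tcount\n")
        for p in profiles:
            for arm_id in sorted(p.arm_counts):
                fh.write(f"{arm_id}\t{p.library}\t{p.arm_counts[arm_id]:.6g}\n")
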