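"""Synthetic study generator: reference bundle, FASTQ libraries, qPCR tables.

Emulates the study design end to end so every pipeline stage is testable
without external data: four small-RNA libraries (two exosome populations, shed
microvesicles and the parental cell line), 18-30 nt inserts followed by the
TruSeq 3' adapter on a fixed-length read, per-base sequencing errors,
contaminant (rRNA/tRNA-like) reads, deliberately defective reads to exercise
QC, per-arm abundance profiles with designated enrichment categories, and Ct
tables linked to expression by ``Ct = baseline - log2(TPM) + noise``.

All randomness derives from one seed; identical configurations produce
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .enrichment import CATEGORY_MEMBERS, VennCategory
from .qc import DEFAULT_ADAPTER3, ReadRecord, trim_adapter
from .reference import CONTAMINANT_ORDER, Arm, Precursor, ReferenceBundle

_BASES = np.frombuffer(b"ACGT", dtype="S1").astype("U1")

# EV role of each library slot in ``library_names``; the last slot is CL
_ROLES = ("A33", "EpCAM", "sMV")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_precursors: int = 60
    n_chromosomes: int = 4
    chromosome_length: int = 2**24
    # (chromosome, n_members, intervening-bp gap) groups laid out first
    cluster_spec: list[tuple[str, int, int]] = field(
        default_factory=lambda: [("chr1", 6, 800)]
    )
    family_spec: list[tuple[str, int]] = field(default_factory=list)
    isolation_gap: int = 50_000  # spacing between non-clustered precursors
    n_reads_per_library: int = 50_000
    read_length: int = 50
    adapter3: str = DEFAULT_ADAPTER3
    sequencing_error_rate: float = 0.005
    contaminant_fraction: float = 0.05
    n_base_read_fraction: float = 0.005
    low_quality_read_fraction: float = 0.01
    truncation_probs: tuple[float, float, float] = (0.8, 0.15, 0.05)  # 3' -0/-1/-2 nt
    abundance_dispersion: float = 1.5  # log-normal sigma of baseline abundance
    effect_log2: float = 2.0
    n_enriched_per_category: int = 3
    library_names: tuple[str, str, str, str] = ("A33-Exos", "EpCAM-Exos", "sMVs", "CL")

    def __post_init__(self) -> None:
        if self.n_reads_per_library <= 0:
            raise ValueError("n_reads_per_library must be positive")
        for name, v in (
            ("sequencing_error_rate", self.sequencing_error_rate),
            ("contaminant_fraction", self.contaminant_fraction),
            ("n_base_read_fraction", self.n_base_read_fraction),
            ("low_quality_read_fraction", self.low_quality_read_fraction),
        ):
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_precursors < 1:
            raise ValueError("n_precursors must be >= 1")
        if sum(n for _, n, _ in self.cluster_spec) > self.n_precursors:
            raise ValueError("cluster_spec member counts exceed n_precursors")
        if len(self.library_names) != 4:
            raise ValueError("exactly four library names required")

    @property
    def cl_library(self) -> str:
        return self.library_names[3]

    def role_libraries(self) -> dict[str, str]:
        """EV role -> library name mapping (slot order A33, EpCAM, sMV)."""
        return dict(zip(_ROLES, self.library_names[:3]))


@dataclass
class TruthTable:
    """Ground truth behind a simulated study."""

    abundances: pd.DataFrame  # arms x libraries, per-library proportions sum to 1
    venn: dict[str, str]  # arm id -> Venn category value

    def check(self) -> None:
        sums = self.abundances.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise AssertionError(f"truth proportions do not sum to 1: {sums.to_dict()}")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, length)])


def _insert_is_trim_safe(insert: str, adapter3: str) -> bool:
    """True when the trimmer recovers the insert exactly from insert+adapter."""
    read = ReadRecord("t", insert + adapter3, "I" * (len(insert) + len(adapter3)))
    trimmed, flagged = trim_adapter(read, adapter3)
    return flagged and trimmed.sequence == insert


def generate_reference(config: SimulationConfig) -> ReferenceBundle:
    """Build a reference bundle honouring the configured cluster layout.

    Every precursor gets a 5p and a 3p arm (20-23 nt, mutually prefix-free so
    that the 3' +/-2 nt read-assignment policy is unambiguous), exactly one of
    which is flagged star. Cluster groups are placed first with the requested
    intervening gaps; remaining precursors are spread across chromosomes at
    ``isolation_gap`` spacing.
    """
    rng = np.random.default_rng([config.seed, 0])
    bundle = ReferenceBundle()

    arm_seqs: set[str] = set()
    prefixes: set[str] = set()

    def new_arm_seq() -> str:
        for _ in range(1000):
            length = int(rng.integers(20, 24))
            s = _random_seq(rng, length)
            if s in arm_seqs or s in prefixes:
                continue
            if any(s[:L] in arm_seqs for L in range(18, len(s))):
                continue
            if not all(
                _insert_is_trim_safe(s[: len(s) - k], config.adapter3) for k in (0, 1, 2)
            ):
                continue
            arm_seqs.add(s)
            for L in range(18, len(s) + 1):
                prefixes.add(s[:L])
            return s
        raise RuntimeError("could not generate a fresh arm sequence")

    # sequences first (deterministic order), then layout with actual lengths
    hairpins = []
    for _ in range(config.n_precursors):
        arm5 = new_arm_seq()
        arm3 = new_arm_seq()
        hairpins.append((arm5, arm3, arm5 + _random_seq(rng, 15) + arm3))

    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursor = dict.fromkeys(chroms, 10_000)
    placements: list[tuple[str, int, int]] = []  # (chrom, start, end) in id order
    idx = 0

    def place(chrom: str, gap_after: int) -> None:
        nonlocal idx
        start = cursor[chrom]
        end = start + len(hairpins[idx][2]) - 1
        if end > config.chromosome_length:
            raise ValueError(
                "cluster/precursor layout exceeds the chromosome length model "
                f"({config.chromosome_length} bp); reduce counts or gaps"
            )
        placements.append((chrom, start, end))
        cursor[chrom] = end + gap_after + 1  # next.start - end - 1 == gap_after
        idx += 1

    for chrom, n_members, gap in config.cluster_spec:
        if chrom not in cursor:
            raise ValueError(f"cluster_spec names unknown chromosome {chrom!r}")
        for j in range(n_members):
            place(chrom, gap if j < n_members - 1 else config.isolation_gap)
    for i in range(config.n_precursors - idx):
        place(chroms[i % len(chroms)], config.isolation_gap)

    for i, (chrom, start, end) in enumerate(placements):
        pid = f"pre-{i + 1:04d}"
        arm5, arm3, hairpin = hairpins[i]
        strand = "+" if rng.random() < 0.5 else "-"
        star_is_3p = bool(rng.random() < 0.5)
        bundle.precursors[pid] = Precursor(
            id=pid, chrom=chrom, start=start, end=end, strand=strand, sequence=hairpin
        )
        bundle.arms[f"{pid}-5p"] = Arm(
            id=f"{pid}-5p", precursor_id=pid, arm="5p", sequence=arm5, star=not star_is_3p
        )
        bundle.arms[f"{pid}-3p"] = Arm(
            id=f"{pid}-3p", precursor_id=pid, arm="3p", sequence=arm3, star=star_is_3p
        )

    # families: configured families consume mature arms of successive precursors,
    # the rest become singleton families named after their precursor
    pre_ids = sorted(bundle.precursors)
    mature_of = {
        pid: next(a.id for a in bundle.arms_of(pid) if not a.star) for pid in pre_ids
    }
    pool = iter(pre_ids)
    for fam_name, n_members in config.family_spec:
        members = []
        for _ in range(n_members):
            try:
                members.append(mature_of[next(pool)])
            except StopIteration:
                raise ValueError("family_spec requires more precursors than available")
        bundle.families[fam_name] = members
    for pid in pool:
        bundle.families[f"fam-{pid}"] = [mature_of[pid]]

    for cat in CONTAMINANT_ORDER:
        bundle.contaminants[cat] = [
            (f"{cat}_{j + 1}", _random_seq(rng, int(rng.integers(150, 301))))
            for j in range(3)
        ]

    bundle.validate()
    return bundle


def default_base_profile(bundle: ReferenceBundle, config: SimulationConfig) -> pd.Series:
    """Log-normal baseline abundance over arms (proportions summing to 1)."""
    rng = np.random.default_rng([config.seed, 1])
    arms = sorted(bundle.arms)
    weights = rng.lognormal(mean=0.0, sigma=config.abundance_dispersion, size=len(arms))
    return pd.Series(weights / weights.sum(), index=arms)


def make_enrichment_scenario(
    bundle: ReferenceBundle,
    base_profile: pd.Series,
    venn_assignment: dict[str, str],
    effect_log2: float,
    library_names: tuple[str, str, str, str] = ("A33-Exos", "EpCAM-Exos", "sMVs", "CL"),
) -> tuple[pd.DataFrame, TruthTable]:
    """Derive four per-library abundance profiles from a baseline.

    Arms assigned an enrichment category get their abundance multiplied by
    ``2**effect_log2`` in the member EV libraries; every column is then
    renormalised to sum to 1. The CL column is the untouched baseline.
    """
    if effect_log2 < 1:
        raise ValueError("effect_log2 must be >= 1 so categories stay recoverable")
    valid = {c.value for c in VennCategory}
    for arm, cat in venn_assignment.items():
        if cat not in valid:
            raise ValueError(f"unknown Venn category {cat!r} for arm {arm}")
        if arm not in base_profile.index:
            raise ValueError(f"assigned arm {arm!r} absent from base profile")

    role_lib = dict(zip(_ROLES, library_names[:3]))
    cl = library_names[3]
    profiles = pd.DataFrame({lib: base_profile.copy() for lib in library_names})
    factor = 2.0**effect_log2
    for arm, cat in venn_assignment.items():
        for role in CATEGORY_MEMBERS[VennCategory(cat)]:
            profiles.loc[arm, role_lib[role]] *= factor
    profiles = profiles / profiles.sum(axis=0)

    venn = {arm: VennCategory.NOT_ENRICHED.value for arm in base_profile.index}
    venn.update(venn_assignment)
    truth = TruthTable(abundances=profiles, venn=venn)
    truth.check()
    return profiles, truth


def default_venn_assignment(
    bundle: ReferenceBundle, config: SimulationConfig
) -> dict[str, str]:
    """Assign ``n_enriched_per_category`` arms to each of the 7 EV categories."""
    rng = np.random.default_rng([config.seed, 2])
    arms = sorted(bundle.arms)
    categories = [c for c in VennCategory if c is not VennCategory.NOT_ENRICHED]
    n_needed = config.n_enriched_per_category * len(categories)
    if n_needed > len(arms):
        raise ValueError("not enough arms for the requested enrichment assignment")
    chosen = rng.choice(len(arms), size=n_needed, replace=False)
    assignment = {}
    for i, idx in enumerate(chosen):
        assignment[arms[idx]] = categories[i % len(categories)].value
    return assignment


_SUBSTITUTIONS = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}

_QUAL_HIGH = chr(40 + 33)
_QUAL_LOW = chr(12 + 33)


def generate_library_reads(
    bundle: ReferenceBundle,
    truth: TruthTable,
    library: str,
    config: SimulationConfig,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Simulate one library's raw reads with per-read truth labels.

    Each miRNA read is an arm sequence (3'-shortened by 0-2 nt) followed by the
    3' adapter, padded with random bases to the configured read length;
    contaminant reads are random 18-30 nt substrings of the contaminant
    references. Per-base substitution errors are injected at the configured
    rate; a small fraction of reads is made deliberately defective (an "N"
    base, or seven bases at quality 12) to exercise QC.
    """
    if library not in config.library_names:
        raise KeyError(f"unknown library {library!r}")
    lib_index = config.library_names.index(library)
    rng = np.random.default_rng([config.seed, 3, lib_index])

    arms = list(truth.abundances.index)
    if truth.abundances[library].isna().any():
        raise ValueError("abundance proportions missing for some arms")
    arm_seqs = [bundle.arms[a].sequence for a in arms]
    arm_probs = truth.abundances[library].to_numpy()

    contaminant_pool = [
        (cat, seq)
        for cat in CONTAMINANT_ORDER
        for _, seq in bundle.contaminants.get(cat, [])
    ]
    c = config.contaminant_fraction if contaminant_pool else 0.0
    probs = np.concatenate(
        [arm_probs * (1.0 - c), np.full(len(contaminant_pool), c / max(len(contaminant_pool), 1))]
    )
    probs = probs / probs.sum()

    n = config.n_reads_per_library
    L = config.read_length
    src = rng.choice(len(probs), size=n, p=probs)
    trunc = rng.choice(3, size=n, p=config.truncation_probs)
    defect = rng.choice(
        3,
        size=n,
        p=[
            1.0 - config.n_base_read_fraction - config.low_quality_read_fraction,
            config.n_base_read_fraction,
            config.low_quality_read_fraction,
        ],
    )
    n_errors = (
        rng.binomial(L, config.sequencing_error_rate, size=n)
        if config.sequencing_error_rate > 0
        else np.zeros(n, dtype=int)
    )
    # pools of pre-drawn randomness to avoid per-read generator calls
    pad_pool = _random_seq(rng, 1 << 16)
    pad_off = rng.integers(0, (1 << 16) - L, size=n)
    u_sub = rng.random(size=n)  # substring start for contaminant reads
    sub_len = rng.integers(18, 31, size=n)
    u_npos = rng.random(size=n)

    adapter = config.adapter3
    defect_names = ("none", "n_base", "low_quality")
    reads: list[ReadRecord] = []
    labels = []
    for i in range(n):
        s = src[i]
        if s < len(arms):
            insert = arm_seqs[s]
            if trunc[i]:
                insert = insert[: len(insert) - trunc[i]]
            source, label = "arm", arms[s]
        else:
            cat, ref = contaminant_pool[s - len(arms)]
            k = int(sub_len[i])
            start = int(u_sub[i] * (len(ref) - k))
            insert = ref[start : start + k]
            source, label = "contaminant", cat
        insert_len = len(insert)
        seq = (insert + adapter)[:L]
        if len(seq) < L:
            off = int(pad_off[i])
            seq += pad_pool[off : off + (L - len(seq))]
        if n_errors[i]:
            chars = list(seq)
            for pos in rng.choice(L, size=n_errors[i], replace=False):
                alternatives = _SUBSTITUTIONS.get(chars[pos], "ACGT")
                chars[pos] = alternatives[rng.integers(0, len(alternatives))]
            seq = "".join(chars)
        qual = _QUAL_HIGH * L
        if defect[i] == 1:
            pos = int(u_npos[i] * insert_len)
            seq = seq[:pos] + "N" + seq[pos + 1 :]
        elif defect[i] == 2:
            # low-quality positions land inside the insert so the defect
            # survives adapter trimming and trips the quality filter
            chars = list(qual)
            for pos in rng.choice(insert_len, size=7, replace=False):
                chars[pos] = _QUAL_LOW
            qual = "".join(chars)
        read_id = f"{library}:read{i:07d}"
        reads.append(ReadRecord(read_id, seq, qual))
        labels.append((read_id, source, label, defect_names[defect[i]], insert_len))

    label_df = pd.DataFrame(
        labels, columns=["read_id", "source", "label", "defect", "insert_len"]
    )
    return reads, label_df


def generate_qpcr_table(
    tpm: pd.DataFrame,
    noise_sd_ct: float,
    seed: int,
    baseline: float = 36.0,
    controls: tuple[str, ...] = ("U6-snRNA", "MaMMU6"),
    control_ct: float = 20.0,
    max_ct: float = 40.0,
) -> pd.DataFrame:
    """Tidy Ct table (target_id, sample, ct) linked to TPM by a log2 law.

    ``Ct = baseline - log2(TPM) + N(0, noise_sd)``, clipped at ``max_ct``;
    reference-control assays get a constant Ct in every sample. Arms with zero
    TPM in a sample are omitted (no amplification).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for target in tpm.index:
        for sample in tpm.columns:
            v = tpm.loc[target, sample]
            if v <= 0:
                continue
            ct = baseline - float(np.log2(v))
            if noise_sd_ct > 0:
                ct += rng.normal(0.0, noise_sd_ct)
            rows.append((target, sample, min(ct, max_ct)))
    for ctrl in controls:
        for sample in tpm.columns:
            rows.append((ctrl, sample, control_ct))
    return pd.DataFrame(rows, columns=["target_id", "sample", "ct"])


def simulate_study(
    config: SimulationConfig,
) -> tuple[ReferenceBundle, TruthTable, dict[str, tuple[list[ReadRecord], pd.DataFrame]]]:
    """Full scenario: reference, enriched truth profiles, four read libraries."""
    bundle = generate_reference(config)
    base = default_base_profile(bundle, config)
    assignment = default_venn_assignment(bundle, config)
    _, truth = make_enrichment_scenario(
        bundle, base, assignment, config.effect_log2, config.library_names
    )
    libraries = {
        lib: generate_library_reads(bundle, truth, lib, config)
        for lib in config.library_names
    }
    return bundle, truth, libraries


def write_truth(truth: TruthTable, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "abundances": outdir / "truth_abundances.tsv",
        "venn": outdir / "truth_venn.tsv",
    }
    truth.abundances.to_csv(paths["abundances"], sep="\t", index_label="arm_id")
    with open(paths["venn"], "w") as fh:
        fh.write("arm_id\tcategory\n")
        for arm in sorted(truth.venn):
            fh.write(f"{arm}\t{truth.venn[arm]}\n")
    return paths
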