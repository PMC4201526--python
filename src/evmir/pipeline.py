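"""End-to-end orchestration: simulate/QC/quantify/enrich/cluster/strand/qPCR.

``run_pipeline`` executes every stage from a single configuration and writes
each stage's tables plus a manifest (parameters and content hashes of every
emitted file), so a rerun with the same configuration is byte-identical.
``fixture_check`` recomputes the packaged printed-table arithmetic and reports
pass/fail per quantity.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import clusters as gc
from . import enrichment as en
from . import fixtures, qpcr, quantify, simulate, strands
from .qc import parse_fastq, run_qc, write_fastq
from .reference import ReferenceBundle

logger = logging.getLogger("evmir")


@dataclass
class PipelineConfig:
    outdir: str
    simulate: simulate.SimulationConfig | None = None
    fastq: dict[str, str] | None = None  # library name -> FASTQ path
    reference_dir: str | None = None
    library_names: tuple[str, str, str, str] = ("A33-Exos", "EpCAM-Exos", "sMVs", "CL")
    tpm_cutoff: float = 5.0
    fc_log2: float = 1.0
    cluster_gap: int = 10_000
    ct_cutoff: float = 35.0
    qpcr_noise_sd: float = 0.0
    run_qpcr: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.simulate is None and (self.fastq is None or self.reference_dir is None):
            raise ValueError("either a simulate block or fastq+reference_dir is required")
        if len(self.library_names) != 4:
            raise ValueError("exactly four library roles required (A33, EpCAM, sMV, CL)")

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        raw = json.loads(Path(path).read_text())
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            if "cluster_spec" in sim:
                sim["cluster_spec"] = [tuple(c) for c in sim["cluster_spec"]]
            if "family_spec" in sim:
                sim["family_spec"] = [tuple(f) for f in sim["family_spec"]]
            if "library_names" in sim:
                sim["library_names"] = tuple(sim["library_names"])
            raw["simulate"] = simulate.SimulationConfig(**sim)
        if "library_names" in raw:
            raw["library_names"] = tuple(raw["library_names"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to the output dir)."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "parameters": _jsonable(config)}
    a33, epcam, smv, cl = config.library_names
    stage = "setup"

    def record(stage_name: str, paths: dict[str, Path]) -> None:
        manifest["stages"][stage_name] = {
            name: {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
            for name, p in paths.items()
        }

    try:
        # ---------------------------------------------------------- stage 1
        stage = "simulate"
        truth = None
        if config.simulate is not None:
            bundle, truth, libraries = simulate.simulate_study(config.simulate)
            ref_paths = bundle.save(outdir / "reference")
            truth_paths = simulate.write_truth(truth, outdir / "truth")
            raw_paths = {}
            for lib, (reads, labels) in libraries.items():
                p = outdir / "raw" / f"{lib}.fastq"
                p.parent.mkdir(parents=True, exist_ok=True)
                write_fastq(reads, p)
                lp = outdir / "raw" / f"{lib}.labels.tsv"
                labels.to_csv(lp, sep="\t", index=False)
                raw_paths[f"{lib}.fastq"] = p
                raw_paths[f"{lib}.labels"] = lp
            record("simulate", {**ref_paths, **truth_paths, **raw_paths})
            fastq_paths = {lib: outdir / "raw" / f"{lib}.fastq" for lib in libraries}
            library_names = config.simulate.library_names
        else:
            bundle = ReferenceBundle.load(config.reference_dir)
            fastq_paths = {lib: Path(p) for lib, p in config.fastq.items()}
            library_names = config.library_names
        a33, epcam, smv, cl = library_names

        # ---------------------------------------------------------- stage 2
        stage = "qc"
        clean_by_lib, qc_paths = {}, {}
        for lib in library_names:
            clean, stats = run_qc(parse_fastq(fastq_paths[lib]), library=lib)
            logger.info("%s: %d raw -> %d clean reads", lib, stats.raw_reads, stats.clean_reads)
            clean_by_lib[lib] = clean
            p = outdir / "clean" / f"{lib}.clean.fastq"
            p.parent.mkdir(parents=True, exist_ok=True)
            write_fastq(clean, p)
            sp = outdir / "clean" / f"{lib}.qc_stats.json"
            stats.to_json(sp)
            stats.to_tsv(outdir / "clean" / f"{lib}.qc_stats.tsv")
            qc_paths[f"{lib}.clean"] = p
            qc_paths[f"{lib}.stats"] = sp
        record("qc", qc_paths)

        # ---------------------------------------------------------- stage 3
        stage = "quantify"
        index = quantify.ArmIndex(bundle)
        profiles = [
            quantify.count_library(clean_by_lib[lib], bundle, library=lib, index=index)
            for lib in library_names
        ]
        matrix = quantify.expression_matrix(profiles)
        qpaths = {
            "counts": outdir / "counts.tsv",
            "tpm": outdir / "tpm_matrix.tsv",
            "categories": outdir / "category_summary.tsv",
        }
        quantify.write_counts(profiles, qpaths["counts"])
        matrix.to_csv(qpaths["tpm"], sep="\t", index_label="arm_id")
        quantify.category_summary(profiles).to_csv(qpaths["categories"], sep="\t")
        record("quantify", qpaths)

        # ---------------------------------------------------------- stage 4
        stage = "enrich"
        counts_df = pd.DataFrame(
            {p.library: pd.Series(p.arm_counts, dtype=float) for p in profiles}
        ).fillna(0.0)
        sizes = {p.library: p.category_counts["miRNA"] for p in profiles}
        records, summary = en.enrichment_table(
            matrix, a33=a33, epcam=epcam, smv=smv, cl=cl,
            counts=counts_df, library_sizes=sizes,
            threshold_log2=config.fc_log2, tpm_cutoff=config.tpm_cutoff,
        )
        epaths = {
            "enrichment": outdir / "enrichment_table.tsv",
            "venn": outdir / "venn_summary.json",
        }
        records.to_csv(epaths["enrichment"], sep="\t", index=False)
        epaths["venn"].write_text(json.dumps(summary, indent=2) + "\n")
        record("enrich", epaths)

        # ---------------------------------------------------------- stage 5
        stage = "cluster"
        detected_matrix = quantify.expression_cutoff(matrix, config.tpm_cutoff)
        detected_arms = set(detected_matrix.index)
        detected_pre = {bundle.arms[a].precursor_id for a in detected_arms if a in bundle.arms}
        calls = gc.detect_clusters(bundle.precursors, max_gap=config.cluster_gap)
        stats = gc.cluster_enrichment(calls, detected_pre, universe_size=len(bundle.precursors))
        cpaths = {
            "clusters": outdir / "clusters.tsv",
            "cluster_enrichment": outdir / "cluster_enrichment.tsv",
            "chromosomes": outdir / "cluster_chromosomes.tsv",
        }
        pd.DataFrame(
            [
                {
                    "cluster_id": c.cluster_id,
                    "chromosome": c.chromosome,
                    "members": ",".join(c.members),
                    "start": c.span[0],
                    "end": c.span[1],
                    "n_detected": c.n_members_detected,
                    "n_total": c.n_members_total,
                }
                for c in calls
            ]
        ).to_csv(cpaths["clusters"], sep="\t", index=False)
        stats.to_csv(cpaths["cluster_enrichment"], sep="\t", index=False)
        gc.chromosome_distribution(calls).to_csv(
            cpaths["chromosomes"], sep="\t", header=["n_clusters"], index_label="chromosome"
        )
        record("cluster", cpaths)

        # ---------------------------------------------------------- stage 6
        stage = "families"
        fam = gc.family_summary(bundle, detected_arms)
        fpaths = {"families": outdir / "family_summary.tsv"}
        fam.to_csv(fpaths["families"], sep="\t", index=False)
        record("families", fpaths)

        # ---------------------------------------------------------- stage 7
        stage = "strand"
        pairs, skipped = strands.pair_strands(bundle, matrix)
        report = strands.star_enrichment_report(
            pairs, records, bundle, ev_libraries=(a33, epcam, smv), cl_library=cl
        )
        report["n_single_arm_or_absent_skipped"] = skipped
        spaths = {
            "strand_pairs": outdir / "strand_pairs.tsv",
            "star_report": outdir / "star_report.json",
        }
        strands.strand_pair_table(pairs, list(library_names)).to_csv(
            spaths["strand_pairs"], sep="\t", index=False
        )
        spaths["star_report"].write_text(json.dumps(report, indent=2) + "\n")
        record("strand", spaths)

        # ---------------------------------------------------------- stage 8
        stage = "qpcr"
        if config.run_qpcr:
            ct = simulate.generate_qpcr_table(
                detected_matrix, noise_sd_ct=config.qpcr_noise_sd, seed=config.seed
            )
            ct_path = outdir / "qpcr_ct.tsv"
            ct.to_csv(ct_path, sep="\t", index=False)
            ct_wide = qpcr.read_ct_table(ct_path)
            assays = qpcr.ddct_table(
                ct_wide, ev_samples=(a33, epcam, smv), cl_sample=cl,
                ct_cutoff=config.ct_cutoff,
            )
            rows, conc = [], {}
            for ev in (a33, epcam, smv):
                key = f"{ev}_vs_{cl}"
                neg = pd.Series(
                    {x.target_id: -x.delta_delta_ct[key] for x in assays if x.included}
                )
                seq_fc = pd.Series(
                    {
                        arm: en.log2_fold_change(
                            detected_matrix.loc[arm, ev], detected_matrix.loc[arm, cl]
                        )
                        for arm in detected_matrix.index
                    }
                )
                n, same, frac = qpcr.concordance(seq_fc, neg)
                conc[key] = {"n_compared": n, "n_same_direction": same, "fraction": frac}
                for t, v in neg.items():
                    rows.append({"target_id": t, "comparison": key, "neg_ddct": v})
            qpaths2 = {
                "ct": ct_path,
                "ddct": outdir / "qpcr_ddct.tsv",
                "concordance": outdir / "qpcr_concordance.json",
            }
            pd.DataFrame(rows).to_csv(qpaths2["ddct"], sep="\t", index=False)
            qpaths2["concordance"].write_text(json.dumps(conc, indent=2) + "\n")
            record("qpcr", qpaths2)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


# --------------------------------------------------------------------------
# fixture checks: recompute the printed-table arithmetic from packaged data


def enrich_fixture(tpm_cutoff: float = 5.0, fc_log2: float = 1.0):
    """Run the enrichment classification on the packaged TPM fixture."""
    matrix = fixtures.enriched_mirna_tpm()
    return en.enrichment_table(
        matrix,
        a33="A33-Exos", epcam="EpCAM-Exos", smv="sMVs", cl="CL",
        threshold_log2=fc_log2, tpm_cutoff=tpm_cutoff,
    )


def fixture_check() -> dict:
    """Recompute every packaged printed quantity; report observed vs expected.

    The expected values come from the packaged tables themselves (group
    labels, printed log2 ratios and printed percentages), so a perturbed
    fixture fails exactly the corresponding entries.
    """
    report: dict[str, dict] = {}
    table = fixtures.enriched_mirna_table()
    records, summary = enrich_fixture()

    expected_groups = table["group"].value_counts().to_dict()
    for cat in sorted(expected_groups):
        report[f"venn_{cat}"] = _entry(summary.get(cat, 0), expected_groups[cat])
    by_arm = records.set_index("arm_id")["category"]
    mismatches = sum(
        1
        for _, row in table.iterrows()
        if by_arm.get(row["mir_id"]) != row["group"]
    )
    report["misclassified_rows"] = _entry(mismatches, 0)

    # per-EV totals under union semantics, expected from the group labels
    member_of = {
        "A33": {"A33_only", "all_EVs", "A33_EpCAM", "A33_sMV"},
        "EpCAM": {"EpCAM_only", "all_EVs", "A33_EpCAM", "EpCAM_sMV"},
        "sMV": {"sMV_only", "all_EVs", "A33_sMV", "EpCAM_sMV"},
    }
    for ev, groups in member_of.items():
        expected = int(table["group"].isin(groups).sum())
        report[f"total_{ev}"] = _entry(summary[f"total_{ev}"], expected)

    # printed log2 ratios recomputed from printed TPMs; the tolerance per cell
    # is 0.02 (0.01 when both TPMs >= 50) or, if wider, the exact propagation
    # of the +/-0.005 rounding of the printed 2-decimal TPM inputs
    worst = 0.0
    ok = True
    for col, (num, den) in fixtures.PRINTED_LOG2_COLUMNS.items():
        for _, row in table.iterrows():
            recomputed = en.log2_fold_change(row[num], row[den])
            err = abs(recomputed - row[col])
            tol = printed_log2_tolerance(row[num], row[den])
            worst = max(worst, err)
            ok = ok and err <= tol
    report["log2_recomputation_max_abs_error"] = {
        "observed": worst,
        "expected": "within printed-precision tolerance per cell",
        "pass": bool(ok),
    }

    # read-count summary percentages
    t1 = fixtures.read_count_summary()
    clean_pct = 100.0 * t1["clean_reads"] / t1["raw_reads"]
    mirbase_pct = 100.0 * t1["mirbase_reads"] / t1["clean_reads"]
    report["clean_pct_max_abs_error"] = _entry(
        float((clean_pct - t1["clean_pct"]).abs().max()), 0.0, tol=0.01
    )
    report["mirbase_pct_max_abs_error"] = _entry(
        float((mirbase_pct - t1["mirbase_pct"]).abs().max()), 0.0, tol=0.01
    )

    report["all_pass"] = {"pass": all(v.get("pass", True) for v in report.values())}
    return report


def printed_log2_tolerance(num: float, den: float) -> float:
    """Tolerance for recomputing a printed log2 ratio from printed TPM cells.

    0.02 in general, 0.01 when both TPMs are at least 50, but never tighter
    than the exact worst-case propagation of the +/-0.005 rounding the printed
    2-decimal TPM values carry: |d log2(n/d)| <= (0.005/n + 0.005/d) / ln 2.
    """
    base = 0.01 if min(num, den) >= 50 else 0.02
    rounding = (0.005 / num + 0.005 / den) / math.log(2)
    return max(base, rounding)


def _entry(observed, expected, tol: float = 0.0) -> dict:
    if tol:
        passed = abs(observed - expected) <= tol
    else:
        passed = observed == expected
    return {"observed": observed, "expected": expected, "pass": bool(passed)}
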