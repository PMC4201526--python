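"""Synthetic study generator: layout, truth, reads, qPCR link, determinism."""

import numpy as np
import pandas as pd
import pytest

from evmir import simulate
from evmir.quantify import ArmIndex
from evmir.qc import ReadRecord, trim_adapter


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            simulate.SimulationConfig(n_reads_per_library=0)
        with pytest.raises(ValueError):
            simulate.SimulationConfig(sequencing_error_rate=1.5)
        with pytest.raises(ValueError):
            simulate.SimulationConfig(n_precursors=2, cluster_spec=[("chr1", 3, 100)])
        with pytest.raises(ValueError):
            simulate.SimulationConfig(library_names=("a", "b", "c"))

    def test_role_mapping(self, small_config):
        roles = small_config.role_libraries()
        assert roles == {"A33": "A33-Exos", "EpCAM": "EpCAM-Exos", "sMV": "sMVs"}
        assert small_config.cl_library == "CL"


class TestGenerateReference:
    def test_counts_and_arms(self, small_bundle, small_config):
        assert len(small_bundle.precursors) == small_config.n_precursors
        assert len(small_bundle.arms) == 2 * small_config.n_precursors
        for pid in small_bundle.precursors:
            arms = small_bundle.arms_of(pid)
            assert sorted(a.arm for a in arms) == ["3p", "5p"]
            assert sum(a.star for a in arms) == 1

    def test_cluster_layout_gaps_exact(self, small_bundle, small_config):
        pre = [small_bundle.precursors[f"pre-{i:04d}"] for i in range(1, 8)]
        # first group: 4 members on chr1 with 800 bp intervening gaps
        for p in pre[:4]:
            assert p.chrom == "chr1"
        for a, b in zip(pre[:3], pre[1:4]):
            assert b.start - a.end - 1 == 800
        # second group: 3 members on chr2 with 2000 bp gaps
        for p in pre[4:7]:
            assert p.chrom == "chr2"
        for a, b in zip(pre[4:6], pre[5:7]):
            assert b.start - a.end - 1 == 2_000

    def test_hairpin_composition(self, small_bundle):
        for pid, p in small_bundle.precursors.items():
            arm5 = next(a for a in small_bundle.arms_of(pid) if a.arm == "5p")
            arm3 = next(a for a in small_bundle.arms_of(pid) if a.arm == "3p")
            assert p.sequence.startswith(arm5.sequence)
            assert p.sequence.endswith(arm3.sequence)
            assert len(p.sequence) == p.end - p.start + 1

    def test_arms_unambiguous_under_isomir_policy(self, small_bundle):
        # every arm, 3'-trimmed by 0-2 nt, assigns back to exactly itself
        index = ArmIndex(small_bundle)
        for arm in small_bundle.arms.values():
            for k in (0, 1, 2):
                cat, hits = index.assign(arm.sequence[: len(arm.sequence) - k])
                assert cat == "miRNA" and hits == [arm.id], (arm.id, k)

    def test_arms_trim_safe(self, small_bundle, small_config):
        for arm in small_bundle.arms.values():
            read = ReadRecord(
                "r",
                arm.sequence + small_config.adapter3,
                "I" * (len(arm.sequence) + len(small_config.adapter3)),
            )
            trimmed, flagged = trim_adapter(read, small_config.adapter3)
            assert flagged and trimmed.sequence == arm.sequence

    def test_layout_overflow_raises(self):
        config = simulate.SimulationConfig(
            n_precursors=4, chromosome_length=500, cluster_spec=[]
        )
        with pytest.raises(ValueError, match="chromosome length"):
            simulate.generate_reference(config)

    def test_deterministic(self, small_config, small_bundle):
        again = simulate.generate_reference(small_config)
        assert again.arms == small_bundle.arms
        assert again.precursors == small_bundle.precursors


class TestScenario:
    def test_truth_columns_sum_to_one(self, small_truth):
        small_truth.check()

    def test_effect_applied_then_renormalised(self, small_bundle, small_config):
        base = simulate.default_base_profile(small_bundle, small_config)
        arms = sorted(small_bundle.arms)
        assignment = {arms[0]: "A33_only", arms[1]: "all_EVs"}
        profiles, truth = simulate.make_enrichment_scenario(
            small_bundle, base, assignment, effect_log2=2.0
        )
        # ratio of an enriched arm to an untouched arm, member lib vs CL: 2^2
        ratio = (profiles.loc[arms[0], "A33-Exos"] / profiles.loc[arms[2], "A33-Exos"]) / (
            profiles.loc[arms[0], "CL"] / profiles.loc[arms[2], "CL"]
        )
        assert ratio == pytest.approx(4.0)
        # A33_only arm untouched in the other EVs
        ratio_ep = (profiles.loc[arms[0], "EpCAM-Exos"] / profiles.loc[arms[2], "EpCAM-Exos"]) / (
            profiles.loc[arms[0], "CL"] / profiles.loc[arms[2], "CL"]
        )
        assert ratio_ep == pytest.approx(1.0)
        assert truth.venn[arms[0]] == "A33_only"
        assert truth.venn[arms[2]] == "not_enriched"

    def test_scenario_input_validation(self, small_bundle, small_config):
        base = simulate.default_base_profile(small_bundle, small_config)
        arm = sorted(small_bundle.arms)[0]
        with pytest.raises(ValueError, match="effect_log2"):
            simulate.make_enrichment_scenario(small_bundle, base, {}, effect_log2=0.5)
        with pytest.raises(ValueError, match="unknown Venn category"):
            simulate.make_enrichment_scenario(small_bundle, base, {arm: "bogus"}, 2.0)
        with pytest.raises(ValueError, match="absent"):
            simulate.make_enrichment_scenario(small_bundle, base, {"ghost": "all_EVs"}, 2.0)

    def test_default_assignment_covers_all_categories(self, small_bundle, small_config):
        assignment = simulate.default_venn_assignment(small_bundle, small_config)
        counts = pd.Series(assignment).value_counts()
        assert len(counts) == 7
        assert set(counts) == {small_config.n_enriched_per_category}


class TestLibraryReads:
    def test_read_shape_and_labels(self, small_study, small_config):
        _, _, libraries = small_study
        reads, labels = libraries["CL"]
        assert len(reads) == small_config.n_reads_per_library
        assert len(labels) == len(reads)
        assert all(len(r.sequence) == small_config.read_length for r in reads)
        assert all(len(r.quality) == small_config.read_length for r in reads)
        assert list(labels["read_id"]) == [r.id for r in reads]

    def test_defect_reads_match_labels(self, small_study):
        _, _, libraries = small_study
        reads, labels = libraries["CL"]
        by_id = {r.id: r for r in reads}
        q_low = chr(12 + 33)
        n_defects = 0
        for _, row in labels.iterrows():
            r = by_id[row["read_id"]]
            if row["defect"] == "n_base":
                assert "N" in r.sequence
                n_defects += 1
            elif row["defect"] == "low_quality":
                assert sum(1 for c in r.quality if c == q_low) == 7
                n_defects += 1
        assert n_defects > 0

    def test_truncation_and_source_fractions(self, small_study, small_config):
        _, _, libraries = small_study
        _, labels = libraries["sMVs"]
        arm_rows = labels[labels["source"] == "arm"]
        frac_contaminant = (labels["source"] == "contaminant").mean()
        assert frac_contaminant == pytest.approx(
            small_config.contaminant_fraction, abs=0.02
        )
        # full-length inserts ~ truncation_probs[0]
        bundle = small_study[0]
        full = [
            row["insert_len"] == len(bundle.arms[row["label"]].sequence)
            for _, row in arm_rows.iterrows()
        ]
        assert np.mean(full) == pytest.approx(small_config.truncation_probs[0], abs=0.03)

    def test_arm_reads_start_with_truncated_arm(self, small_study):
        bundle, _, libraries = small_study
        reads, labels = libraries["A33-Exos"]
        by_id = {r.id: r for r in reads}
        arm_rows = labels[(labels["source"] == "arm") & (labels["defect"] == "none")]
        exact = 0
        for _, row in arm_rows.head(500).iterrows():
            seq = by_id[row["read_id"]].sequence
            want = bundle.arms[row["label"]].sequence[: row["insert_len"]]
            exact += seq.startswith(want)
        # most reads are error-free over the insert
        assert exact / min(len(arm_rows), 500) > 0.8

    def test_deterministic(self, small_study, small_bundle, small_truth, small_config):
        _, truth, libraries = small_study
        reads2, labels2 = simulate.generate_library_reads(
            small_bundle, truth, "CL", small_config
        )
        assert reads2 == libraries["CL"][0]
        assert labels2.equals(libraries["CL"][1])

    def test_unknown_library_rejected(self, small_bundle, small_truth, small_config):
        with pytest.raises(KeyError):
            simulate.generate_library_reads(small_bundle, small_truth, "nope", small_config)


class TestQpcrTable:
    def test_noiseless_link(self):
        tpm = pd.DataFrame({"EV": [64.0, 0.0], "CL": [16.0, 8.0]}, index=["a", "b"])
        ct = simulate.generate_qpcr_table(tpm, noise_sd_ct=0.0, seed=1)
        wide = ct.pivot(index="target_id", columns="sample", values="ct")
        assert wide.loc["a", "EV"] == pytest.approx(36 - 6)
        assert wide.loc["a", "CL"] == pytest.approx(36 - 4)
        # zero TPM omitted; controls constant
        assert np.isnan(wide.loc["b", "EV"])
        assert wide.loc["U6-snRNA", "EV"] == 20.0
        assert wide.loc["MaMMU6", "CL"] == 20.0

    def test_ct_clipped_at_max(self):
        tpm = pd.DataFrame({"EV": [2.0 ** -10]}, index=["a"])
        ct = simulate.generate_qpcr_table(tpm, noise_sd_ct=0.0, seed=1)
        assert ct["ct"].max() == 40.0


def test_write_truth(tmp_path, small_truth):
    paths = simulate.write_truth(small_truth, tmp_path)
    back = pd.read_csv(paths["abundances"], sep="\t", index_col=0)
    assert np.allclose(back.sum(axis=0), 1.0)
    venn = pd.read_csv(paths["venn"], sep="\t")
    assert set(venn.columns) == {"arm_id", "category"}
    assert len(venn) == len(small_truth.venn)
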