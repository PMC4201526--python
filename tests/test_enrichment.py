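"""Fold changes, Audic-Claverie test (vs direct summation) and Venn classes."""

import numpy as np
import pandas as pd
import pytest

from evmir.enrichment import (
    VennCategory,
    audic_claverie_pvalue,
    classify_venn,
    enrichment_table,
    log2_fold_change,
)

from _oracles import ac_lower_sum, ac_upper_sum


class TestLog2FoldChange:
    def test_plain_ratio(self):
        assert log2_fold_change(8.0, 2.0) == pytest.approx(2.0)

    def test_pseudocount_only_on_zero(self):
        assert log2_fold_change(1.0, 0.0) == pytest.approx(np.log2(1.01 / 0.01))
        assert log2_fold_change(0.0, 1.0) == pytest.approx(np.log2(0.01 / 1.01))
        # non-zero operands are unshifted even when tiny
        assert log2_fold_change(0.02, 0.04) == pytest.approx(-1.0)

    def test_both_zero_is_zero(self):
        assert log2_fold_change(0.0, 0.0) == 0.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            log2_fold_change(-1.0, 1.0)
        with pytest.raises(ValueError):
            log2_fold_change(1.0, 1.0, pseudocount=0.0)


class TestAudicClaverie:
    def test_equal_libraries_x0_y0(self):
        # p(y'|x=0) = (1/2)^(y'+1) for n1 == n2
        assert audic_claverie_pvalue(0, 0, 1e6, 1e6, "lower") == pytest.approx(0.5)
        assert audic_claverie_pvalue(0, 0, 1e6, 1e6, "upper") == pytest.approx(1.0)
        assert audic_claverie_pvalue(0, 1, 1e6, 1e6, "upper") == pytest.approx(0.5)

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            x = int(rng.integers(0, 51))
            y = int(rng.integers(0, 51))
            n1 = float(rng.uniform(1e5, 1e7))
            n2 = n1 * float(rng.uniform(0.1, 10.0))
            lo = audic_claverie_pvalue(x, y, n1, n2, "lower")
            up = audic_claverie_pvalue(x, y, n1, n2, "upper")
            assert lo == pytest.approx(ac_lower_sum(x, y, n1, n2), rel=1e-10)
            assert up == pytest.approx(ac_upper_sum(x, y, n1, n2), rel=1e-10)

    def test_two_sided_definition(self):
        lo = audic_claverie_pvalue(3, 9, 1e6, 1e6, "lower")
        up = audic_claverie_pvalue(3, 9, 1e6, 1e6, "upper")
        two = audic_claverie_pvalue(3, 9, 1e6, 1e6, "two_sided")
        assert two == pytest.approx(min(1.0, 2 * min(lo, up)))

    def test_tail_identity_property(self):
        # exact negative-binomial tail identity:
        # P(Y' >= y | x; n1, n2) == P(X' <= x | y - 1; n2, n1)
        rng = np.random.default_rng(12)
        for _ in range(300):
            x = int(rng.integers(0, 200))
            y = int(rng.integers(1, 200))
            n1 = float(rng.uniform(1e4, 1e7))
            n2 = n1 * float(rng.uniform(0.1, 10.0))
            up = audic_claverie_pvalue(x, y, n1, n2, "upper")
            lo = audic_claverie_pvalue(y - 1, x, n2, n1, "lower")
            assert up == pytest.approx(lo, rel=1e-9)

    def test_large_counts_stable(self):
        p = audic_claverie_pvalue(10_000_000, 9_990_000, 2e7, 2e7, "two_sided")
        assert 0.0 < p <= 1.0 and np.isfinite(p)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            audic_claverie_pvalue(-1, 0, 1e6, 1e6)
        with pytest.raises(ValueError):
            audic_claverie_pvalue(1.5, 0, 1e6, 1e6)
        with pytest.raises(ValueError):
            audic_claverie_pvalue(1, 0, 0, 1e6)
        with pytest.raises(ValueError):
            audic_claverie_pvalue(1, 0, 1e6, 1e6, side="middle")


class TestClassifyVenn:
    def test_threshold_inclusive(self):
        assert classify_venn(1.0, 0.0, 0.0) is VennCategory.A33_ONLY
        assert classify_venn(0.999, 0.0, 0.0) is VennCategory.NOT_ENRICHED

    def test_all_eight_combinations(self):
        hi, lo = 2.0, 0.0
        cases = {
            (hi, lo, lo): VennCategory.A33_ONLY,
            (lo, hi, lo): VennCategory.EPCAM_ONLY,
            (lo, lo, hi): VennCategory.SMV_ONLY,
            (hi, hi, hi): VennCategory.ALL_EVS,
            (hi, hi, lo): VennCategory.A33_EPCAM,
            (hi, lo, hi): VennCategory.A33_SMV,
            (lo, hi, hi): VennCategory.EPCAM_SMV,
            (lo, lo, lo): VennCategory.NOT_ENRICHED,
        }
        for args, expected in cases.items():
            assert classify_venn(*args) is expected


class TestEnrichmentTable:
    def matrix(self):
        return pd.DataFrame(
            {
                "A33-Exos": [40.0, 4.0, 40.0, 10.0, 1.0],
                "EpCAM-Exos": [40.0, 4.0, 10.0, 10.0, 1.0],
                "sMVs": [40.0, 44.0, 10.0, 10.0, 1.0],
                "CL": [10.0, 4.0, 10.0, 10.0, 1.0],
            },
            index=["all3", "smv_only", "a33_only", "flat", "below_cutoff"],
        )

    def test_summary_counts_and_totals(self):
        records, summary = enrichment_table(self.matrix())
        assert summary["all_EVs"] == 1
        assert summary["sMV_only"] == 1
        assert summary["A33_only"] == 1
        assert summary["n_enriched"] == 3
        assert summary["total_A33"] == 2
        assert summary["total_EpCAM"] == 1
        assert summary["total_sMV"] == 2
        assert summary["both_exosomes"] == 1
        # flat and below-cutoff arms never appear in the records
        assert set(records["arm_id"]) == {"all3", "smv_only", "a33_only"}

    def test_category_block_order(self):
        records, _ = enrichment_table(self.matrix())
        assert list(records["category"]) == ["A33_only", "sMV_only", "all_EVs"]

    def test_pvalues_and_pooled_exosomes_from_counts(self):
        m = self.matrix()
        counts = m * 10  # pretend integer-ish counts
        sizes = {c: 1e5 for c in m.columns}
        records, _ = enrichment_table(m, counts=counts, library_sizes=sizes)
        row = records.set_index("arm_id").loc["all3"]
        expected = audic_claverie_pvalue(100, 400, 1e5, 1e5)
        assert row["pvalue_a33_cl"] == pytest.approx(expected)
        # count-pooled exosome TPM: (400+400)/(2e5) * 1e6 = 4000
        assert row["log2fc_exos_smv"] == pytest.approx(np.log2(4000 / 40.0))

    def test_require_p_demotes_insignificant_calls(self):
        m = self.matrix()
        counts = pd.DataFrame(
            {c: [4, 1, 4, 1, 1] for c in m.columns}, index=m.index
        ).astype(float)
        counts.loc["all3", "CL"] = 1
        sizes = {c: 1e5 for c in m.columns}
        _, summary = enrichment_table(
            m, counts=counts, library_sizes=sizes, require_p=1e-6
        )
        assert summary["n_enriched"] == 0

    def test_missing_library_raises(self):
        with pytest.raises(KeyError):
            enrichment_table(self.matrix().drop(columns=["CL"]))
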