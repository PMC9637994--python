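"""Allelic ratios, gene filters, normalization and tertiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import xsilence as xs
from xsilence.expression import FilterConfig, sample_ratios, tertile_assign


def make_sheet(samples, wt=True, condition="nodox", day=0.0, state="mESC"):
    return pd.DataFrame(
        {
            "sample_id": samples,
            "line": "WT",
            "condition": condition,
            "day": day,
            "replicate": range(1, len(samples) + 1),
            "cell_state": state,
            "wt_flag": wt,
        }
    )


class TestAllelicRatio:
    @pytest.mark.parametrize("xi,xa,expected", [(5, 5, 0.5), (0, 10, 0.0), (7, 0, 1.0)])
    def test_examples(self, xi, xa, expected):
        assert xs.allelic_ratio(xi, xa) == expected

    def test_zero_coverage_is_missing(self):
        assert np.isnan(xs.allelic_ratio(0, 0))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            xs.allelic_ratio(-1, 5)

    @given(st.integers(0, 1000), st.integers(0, 1000))
    @settings(derandomize=True, max_examples=50)
    def test_complement_symmetry(self, xi, xa):
        if xi + xa == 0:
            return
        assert xs.allelic_ratio(xi, xa) + xs.allelic_ratio(xa, xi) == pytest.approx(1.0)


class TestIO:
    def test_roundtrip(self, toy_matrix, tmp_path):
        path = tmp_path / "counts.tsv"
        xs.write_counts(toy_matrix, path)
        back = xs.read_counts(path)
        pd.testing.assert_frame_equal(back.total, toy_matrix.total)
        pd.testing.assert_frame_equal(back.xi, toy_matrix.xi)

    def test_sheet_sample_missing_from_matrix(self, toy_matrix, tmp_path):
        xs.write_counts(toy_matrix, tmp_path / "c.tsv")
        sheet = make_sheet(["s1", "s2", "ghost"])
        sheet.to_csv(tmp_path / "s.csv", index=False)
        with pytest.raises(ValueError, match="ghost"):
            xs.read_counts(tmp_path / "c.tsv", tmp_path / "s.csv")

    def test_allelic_exceeding_total_rejected(self, toy_matrix):
        bad_xi = toy_matrix.xi.copy()
        bad_xi.loc["gA", "s1"] = 999
        with pytest.raises(ValueError, match="gA"):
            xs.AllelicCountMatrix(toy_matrix.total, bad_xi, toy_matrix.xa)

    def test_negative_counts_rejected(self, toy_matrix):
        bad = toy_matrix.total.copy()
        bad.loc["gA", "s1"] = -1
        with pytest.raises(ValueError, match="negative"):
            xs.AllelicCountMatrix(bad, toy_matrix.xi, toy_matrix.xa)


def brute_force_filter(m, wt, baseline, cfg):
    """Independent re-statement of the admission rules, gene by gene."""
    kept = []
    for g in m.genes:
        covered = sum(
            (m.xi.at[g, s] + m.xa.at[g, s]) >= cfg.min_allelic_frags for s in wt
        )
        if not covered > cfg.min_wt_sample_frac * len(wt):
            continue
        vals = []
        for s in baseline:
            n = m.xi.at[g, s] + m.xa.at[g, s]
            if n > 0:
                vals.append(m.xi.at[g, s] / n)
        if not vals:
            continue
        mean = sum(vals) / len(vals)
        if cfg.baseline_low < mean < cfg.baseline_high:
            kept.append(g)
    return kept


def random_matrix(rng, n_genes=50, n_samples=5):
    genes = pd.Index([f"g{i}" for i in range(n_genes)], name="gene_id")
    cols = [f"s{j}" for j in range(n_samples)]
    xi = pd.DataFrame(rng.integers(0, 15, (n_genes, n_samples)), index=genes, columns=cols)
    xa = pd.DataFrame(rng.integers(0, 15, (n_genes, n_samples)), index=genes, columns=cols)
    total = xi + xa + rng.integers(0, 30, (n_genes, n_samples))
    return xs.AllelicCountMatrix(total, xi, xa)


class TestFilter:
    def setup_method(self):
        self.cfg = FilterConfig()

    def _matrix(self, allelic_per_sample, ratio=0.5):
        cols = [f"s{i}" for i in range(len(allelic_per_sample))]
        genes = pd.Index(["g"], name="gene_id")
        xi = pd.DataFrame(
            [[round(a * ratio) for a in allelic_per_sample]], index=genes, columns=cols
        )
        xa = pd.DataFrame(
            [[a - round(a * ratio) for a in allelic_per_sample]], index=genes, columns=cols
        )
        return xs.AllelicCountMatrix(xi + xa, xi, xa)

    def test_covered_biallelic_gene_retained(self):
        m = self._matrix([12, 11, 15, 10, 10])
        retained, reasons = xs.filter_informative_genes(m, make_sheet(list(m.samples)))
        assert list(retained) == ["g"] and reasons["g"] == "ok"

    def test_exact_80_percent_coverage_rejected(self):
        """4/5 covered samples is not strictly more than 80%."""
        m = self._matrix([12, 11, 15, 9, 10])
        retained, reasons = xs.filter_informative_genes(m, make_sheet(list(m.samples)))
        assert len(retained) == 0 and reasons["g"] == "coverage"

    def test_baseline_boundary_is_strict(self):
        m = self._matrix([20, 20, 20, 20, 20], ratio=0.1)
        retained, reasons = xs.filter_informative_genes(m, make_sheet(list(m.samples)))
        assert len(retained) == 0 and reasons["g"] == "baseline"

    def test_no_wt_samples_is_an_error(self, toy_matrix):
        sheet = make_sheet(["s1", "s2"], wt=False)
        with pytest.raises(ValueError, match="wild-type"):
            xs.filter_informative_genes(toy_matrix, sheet)

    def test_matches_brute_force_and_is_idempotent(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            m = random_matrix(rng)
            sheet = make_sheet(list(m.samples))
            retained, _ = xs.filter_informative_genes(m, sheet, self.cfg)
            expected = brute_force_filter(
                m, list(m.samples), list(m.samples), self.cfg
            )
            assert list(retained) == expected
            again, _ = xs.filter_informative_genes(m.subset_genes(retained), sheet, self.cfg)
            assert list(again) == list(retained)


class TestRatioTable:
    def test_replicate_averaging_and_missing_handling(self):
        genes = pd.Index(["g1", "g2"], name="gene_id")
        cols = ["r1", "r2"]
        xi = pd.DataFrame([[4, 6], [4, 0]], index=genes, columns=cols)
        xa = pd.DataFrame([[6, 4], [6, 0]], index=genes, columns=cols)
        m = xs.AllelicCountMatrix(xi + xa, xi, xa)
        sheet = make_sheet(cols, condition="dox", day=2.0)
        table = xs.ratio_table(m, sheet, average=True)
        col = ("WT", "dox", 2.0)
        assert table.at["g1", col] == pytest.approx(0.5)  # mean of 0.4, 0.6
        assert table.at["g2", col] == pytest.approx(0.4)  # missing replicate omitted

    def test_averaging_equals_mean_of_per_replicate_tables(self, counts300):
        m, sheet = counts300
        averaged = xs.ratio_table(m, sheet, average=True)
        per_sample = xs.ratio_table(m, sheet, average=False)
        meta = sheet.set_index("sample_id")
        key = ("WT", "dox", 7.0)
        reps = [s for s in per_sample.columns
                if (meta.at[s, "line"], meta.at[s, "condition"], meta.at[s, "day"]) == key]
        manual = per_sample[reps].mean(axis=1)
        pd.testing.assert_series_equal(averaged[key], manual, check_names=False)

    def test_delta_silencing(self):
        assert xs.delta_silencing(0.2, 0.5) == pytest.approx(-0.3)
        assert xs.delta_silencing(0.5, 0.2) == pytest.approx(0.3)
        assert np.isnan(xs.delta_silencing(np.nan, 0.5))


class TestNormalization:
    def test_rpm_arithmetic(self):
        genes = pd.Index(["g1", "g2"], name="gene_id")
        total = pd.DataFrame({"s": [200, 2_000_000 - 200]}, index=genes)
        zero = total * 0
        m = xs.AllelicCountMatrix(total, zero, zero)
        rpm = xs.normalize_expression(m, mode="rpm")
        assert rpm.at["g1", "s"] == pytest.approx(100.0)

    def test_tpm_closed_form(self):
        genes = pd.Index(["g1", "g2"], name="gene_id")
        total = pd.DataFrame({"s": [100, 100]}, index=genes)
        zero = total * 0
        m = xs.AllelicCountMatrix(total, zero, zero)
        ann = pd.DataFrame({"exonic_length": [1000, 2000]}, index=genes)
        tpm = xs.normalize_expression(m, ann, mode="tpm")
        assert tpm.at["g1", "s"] == pytest.approx(666_666.6667)
        assert tpm.at["g2", "s"] == pytest.approx(333_333.3333)
        assert tpm["s"].sum() == pytest.approx(1e6)

    def test_scale_invariance_per_sample(self, toy_matrix):
        rpm = xs.normalize_expression(toy_matrix, mode="rpm")
        scaled = xs.AllelicCountMatrix(
            toy_matrix.total * 7, toy_matrix.xi * 7, toy_matrix.xa * 7
        )
        pd.testing.assert_frame_equal(rpm, xs.normalize_expression(scaled, mode="rpm"))

    def test_zero_depth_sample_rejected(self):
        genes = pd.Index(["g1"], name="gene_id")
        total = pd.DataFrame({"s": [0]}, index=genes)
        m = xs.AllelicCountMatrix(total, total * 0, total * 0)
        with pytest.raises(ValueError, match="zero-depth"):
            xs.normalize_expression(m, mode="rpm")


class TestTertiles:
    def test_nine_distinct_values(self):
        vals = pd.Series(range(9, 0, -1), index=[f"g{i}" for i in range(9)])
        labels = xs.expression_tertiles(vals.astype(float))
        assert labels.value_counts().to_dict() == {"low": 3, "medium": 3, "high": 3}
        assert set(labels[vals <= 3].unique()) == {"low"}

    def test_ten_values_remainder_to_lowest(self):
        vals = pd.Series(np.arange(10.0), index=[f"g{i}" for i in range(10)])
        counts = xs.expression_tertiles(vals).value_counts()
        assert counts["low"] == 4 and counts["medium"] == 3 and counts["high"] == 3

    def test_all_equal_uses_stable_order(self):
        vals = pd.Series(1.0, index=[f"g{i}" for i in range(9)])
        labels = xs.expression_tertiles(vals)
        assert list(labels) == ["low"] * 3 + ["medium"] * 3 + ["high"] * 3

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            xs.expression_tertiles(pd.Series([1.0, 2.0]))


class TestXist:
    def test_rpm_of_xist_row(self):
        genes = pd.Index(["Xist", "g"], name="gene_id")
        total = pd.DataFrame({"s": [1000, 999_000]}, index=genes)
        m = xs.AllelicCountMatrix(total, total * 0, total * 0)
        assert xs.xist_abundance(m)["s"] == pytest.approx(1000.0)

    def test_missing_xist_rejected(self, toy_matrix):
        with pytest.raises(KeyError):
            xs.xist_abundance(toy_matrix)

    def test_scale_invariance(self, counts300):
        m, _ = counts300
        doubled = xs.AllelicCountMatrix(m.total * 2, m.xi * 2, m.xa * 2)
        pd.testing.assert_series_equal(xs.xist_abundance(m), xs.xist_abundance(doubled))
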