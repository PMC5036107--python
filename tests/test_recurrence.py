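"""SNV ingestion, recurrence spectra, Poisson expectations and the excess test."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from recurrency.genome_context import GenomePartition
from recurrency.recurrence import (
    ExpectedSpectrum,
    RecurrenceSpectrum,
    aggregate_expected,
    aggregate_spectrum,
    build_spectrum,
    excess_summary,
    excess_test,
    expected_spectrum,
    read_snvs,
)


def snv_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "sample", "cancer_type", "lab"])


class TestReadSnvs:
    def test_empty_table(self, tmp_path):
        p = tmp_path / "s.tsv"
        p.write_text("chrom\tpos\tref\talt\tsample\tcancer_type\n")
        df, report = read_snvs(p)
        assert len(df) == 0 and report.n_rows == 0

    def test_row_level_rejection(self):
        df, report = read_snvs(
            snv_frame(
                [
                    ("c", 5, "A", "G", "s1", "LIVER", "L1"),
                    ("c", 6, "C", "T", "s1", "LIVER", "L1"),
                    ("c", 7, "G", "T", "s2", "LIVER", "L1"),
                    ("c", 8, "A", "A", "s1", "LIVER", "L1"),  # ref == alt
                    ("c", 9, "AT", "A", "s1", "LIVER", "L1"),  # indel
                ]
            )
        )
        assert len(df) == 3
        assert report.n_rejected == 2
        assert report.reject_reasons == {"ref equals alt": 1, "non-single-base allele": 1}

    def test_same_site_two_samples_kept_duplicates_collapsed(self):
        df, report = read_snvs(
            snv_frame(
                [
                    ("c", 5, "A", "G", "s1", "LIVER", "L1"),
                    ("c", 5, "A", "G", "s2", "LIVER", "L1"),
                    ("c", 5, "A", "T", "s2", "LIVER", "L1"),  # dup (chrom,pos,sample)
                ]
            )
        )
        assert len(df) == 2
        assert report.n_duplicates == 1

    def test_ref_mismatch_rejected_when_fasta_given(self):
        df, report = read_snvs(
            snv_frame([("c", 2, "C", "T", "s1", "LIVER", "L1"), ("c", 3, "C", "T", "s1", "LIVER", "L1")]),
            fasta={"c": "ACGT"},
        )
        assert len(df) == 1
        assert report.reject_reasons.get("ref mismatch") == 1


class TestBuildSpectrum:
    def test_no_snvs_everything_in_zero_class(self):
        part = GenomePartition.from_files({"c": "ACGT" * 50})
        spectra, dropped = build_spectrum(snv_frame([]), part)
        agg = aggregate_spectrum(spectra["NTE"], "NTE")
        assert agg.m == 0
        assert agg.l == part.census("NTE").total()

    def test_distinct_sites_land_in_one_hit_class(self):
        part = GenomePartition.from_files({"c": "ACGT" * 50})
        rows = [("c", p, "ACGT"[(p - 1) % 4], "T" if (p - 1) % 4 != 3 else "A", f"s{p}", "X", "L1") for p in (2, 6, 10, 14, 18)]
        spectra, dropped = build_spectrum(snv_frame(rows), part)
        agg = aggregate_spectrum(spectra["NTE"], "NTE")
        assert agg.counts[1] == 5
        assert agg.m == 5
        assert agg.l == part.census("NTE").total()

    def test_conservation_identities(self, rng):
        # sum n_x = l and sum x*n_x = m for spectra built from random SNVs
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 2000)])
        part = GenomePartition.from_files({"c": seq}, te_mask={"c": [(500, 1500)]})
        rows = []
        for i in range(300):
            p = int(rng.integers(2, 1999))
            ref = seq[p - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            rows.append(("c", p, ref, alt, f"s{rng.integers(0, 40)}", "X", "L1"))
        snvs, _ = read_snvs(snv_frame(rows))
        spectra, dropped = build_spectrum(snvs, part)
        n_placed = 0
        for frac in ("TE", "NTE", "EX"):
            census = part.census(frac)
            for ctx, spec in spectra[frac].items():
                assert spec.l == census.counts[ctx]
            n_placed += sum(s.m for s in spectra[frac].values())
        assert n_placed + sum(dropped.values()) == len(snvs)

    def test_impossible_hit_count_raises(self):
        part = GenomePartition.from_files({"c": "ACGT" * 10})
        rows = [("c", 6, "C", "T", f"s{i}", "X", "L1") for i in range(4)]
        with pytest.raises(ValueError, match="samples"):
            build_spectrum(snv_frame(rows), part, n_samples=2)


class TestExpectedSpectrum:
    def test_zero_snvs(self):
        e = expected_spectrum(1000, 0, 5)
        assert e.counts[0] == 1000
        assert np.all(e.counts[1:] == 0)

    def test_single_site_closed_form(self):
        e = expected_spectrum(1, 1, 3)
        assert e.counts[0] == pytest.approx(np.exp(-1))

    def test_l_zero_with_snvs_is_an_error(self):
        with pytest.raises(ValueError):
            expected_spectrum(0, 5, 3)

    def test_normalisation_to_l_within_tolerance(self):
        l, m = 10**7, 10**5  # mu = 0.01
        e = expected_spectrum(l, m, 20)
        assert e.counts.sum() + e.tail_mass == pytest.approx(l, rel=1e-12)
        assert e.counts.sum() == pytest.approx(l, abs=1e-6 * l)

    def test_monotone_decreasing_below_mu_one(self):
        e = expected_spectrum(1000, 800, 10)  # mu = 0.8 < 1
        assert np.all(np.diff(e.counts) < 0)

    def test_aggregate_identity_and_doubling(self):
        one = expected_spectrum(100, 5, 7)
        agg1 = aggregate_expected([one])
        assert np.allclose(agg1.counts, one.counts)
        agg2 = aggregate_expected([one, expected_spectrum(100, 5, 7)])
        assert np.allclose(agg2.counts, 2 * one.counts)

    def test_poisson_additivity_under_equal_rate(self, rng):
        # splitting a census into two contexts with the same mu leaves the sum unchanged
        l, m = 9000, 90
        l1 = int(rng.integers(10, 80)) * 100  # keeps mu = m/l exactly equal in both parts
        m1 = l1 // 100
        whole = expected_spectrum(l, m, 8)
        split = aggregate_expected(
            [expected_spectrum(l1, m1, 8), expected_spectrum(l - l1, m - m1, 8)]
        )
        assert np.allclose(split.counts, whole.counts, rtol=1e-6)


class TestExcessTest:
    def test_exact_agreement_gives_zero_statistic(self):
        obs = np.array([90.0, 9.0, 6.0])
        res = excess_test(obs, obs.copy(), pool_min=5)
        assert res.statistic == 0 and res.p_value == 1

    def test_hand_computed_three_cells(self):
        obs = np.array([80.0, 15.0, 10.0])
        exp = np.array([85.0, 12.0, 8.0])
        res = excess_test(obs, exp, pool_min=5)
        hand = (80 - 85) ** 2 / 85 + (15 - 12) ** 2 / 12 + (10 - 8) ** 2 / 8
        assert res.statistic == pytest.approx(hand)
        assert res.df == 2
        assert res.p_value == pytest.approx(stats.chi2.sf(hand, 2))

    def test_pooling_merges_subthreshold_tail_into_one_cell(self):
        obs = np.array([100.0, 20.0, 3.0, 1.0, 0.0])
        exp = np.array([101.0, 19.0, 2.0, 1.5, 0.5])
        res = excess_test(obs, exp, pool_min=5)
        # cells x >= 2 (each expected < 5) pool into one tail: [0, 1, 2+]
        assert res.n_cells == 3
        assert res.df == 2
        hand = (100 - 101) ** 2 / 101 + (20 - 19) ** 2 / 19 + (4 - 4) ** 2 / 4
        assert res.statistic == pytest.approx(hand)

    def test_single_extreme_site_is_highly_significant(self):
        # one 7-hit site against a vanishing expectation
        obs = np.array([1_000_000.0, 100.0, 0, 0, 0, 0, 0, 1])
        exp = expected_spectrum(1_000_100, 102, 7).counts
        res = excess_test(obs, exp, pool_min=5)
        assert res.p_value < 1e-4

    def test_undefined_when_everything_pools_to_one_cell(self):
        with pytest.raises(ValueError):
            excess_test(np.array([1.0, 1.0, 0.0]), np.array([0.9, 1.0, 0.1]), pool_min=5)


class TestExcessSummary:
    def test_all_zero_spectra_report_na_ratios(self):
        spectra = {
            f: RecurrenceSpectrum(f, None, np.array([100, 0, 0, 0])) for f in ("TE", "NTE", "EX")
        }
        df = excess_summary(spectra, {"TE": 100, "NTE": 100, "EX": 100})
        assert (df.loc[["TE", "NTE", "EX"], "excess_sites"] == 0).all()
        assert df["fold_vs_TE"].isna().all()

    def test_fold_ratio_arithmetic(self):
        spectra = {
            "TE": RecurrenceSpectrum("TE", None, np.array([0, 0, 0, 39])),
            "NTE": RecurrenceSpectrum("NTE", None, np.array([0, 0, 0, 10])),
        }
        df = excess_summary(spectra, {"TE": 1000, "NTE": 1000})
        assert df.loc["NTE", "fold_vs_TE"] == pytest.approx(3.9)
        assert df.loc["Total", "excess_sites"] == 49
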