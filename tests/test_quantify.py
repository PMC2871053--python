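"""RPM normalization, N/C statistics, isomiR grouping and motif analyses."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from srnanc.preprocess import UniqueSeqRecord
from srnanc.published import MIRNA_EXAMPLES
from srnanc.quantify import (
    CYTOPLASMIC_ONLY,
    NUCLEAR_ONLY,
    MotifRecord,
    NCRecord,
    group_isomirs,
    hexamer_extract,
    histogram_mode,
    length_distribution,
    mirna_correlation,
    motif_nc_association,
    nc_ratio,
    nc_summary,
    rpm_normalize,
)


class TestRpm:
    def test_identity(self):
        assert rpm_normalize(5_321_867, 5_321_867) == 1e6

    def test_published_trailer_rpm_arithmetic(self):
        # 6,295 trailer reads over the 5,321,867-read nuclear library
        assert rpm_normalize(6_295, 5_321_867) == pytest.approx(1182.9, abs=0.05)

    def test_zero(self):
        assert rpm_normalize(0, 1000) == 0.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            rpm_normalize(1, 0)

    def test_rpm_sums_to_one_million(self, sim_result):
        for lib, total in sim_result.mapped_totals.items():
            s = sum(
                r.rpm[lib]
                for r in sim_result.annotation.records
            )
            assert s == pytest.approx(1e6, rel=1e-9)


class TestNcRatio:
    @pytest.mark.parametrize(
        "nuclear,cytoplasmic,expected",
        [(355.3, 78.2, 4.54), (15.6, 2.5, 6.24), (41.9, 8.6, 4.87)],
    )
    def test_published_values(self, nuclear, cytoplasmic, expected):
        nc, flag = nc_ratio(nuclear, cytoplasmic)
        assert flag is None
        assert round(nc, 2) == expected

    def test_exclusivity_flags(self):
        assert nc_ratio(12.0, 0.0) == (None, NUCLEAR_ONLY)
        assert nc_ratio(0.0, 3.0) == (None, CYTOPLASMIC_ONLY)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            nc_ratio(0.0, 0.0)

    @settings(max_examples=100, deadline=None)
    @given(
        st.floats(0.1, 1e5),
        st.floats(0.1, 1e5),
        st.floats(0.01, 100.0),
    )
    def test_scale_invariance(self, nuc, cyt, scale):
        """Multiplying both libraries' abundances by a constant leaves
        every N/C unchanged."""
        base, _ = nc_ratio(nuc, cyt)
        scaled, _ = nc_ratio(nuc * scale, cyt * scale)
        assert scaled == pytest.approx(base, rel=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(1.0, 1e4), st.floats(1.0, 1e4), st.floats(0.1, 1e3))
    def test_monotone_in_nuclear_rpm(self, nuc, delta, cyt):
        low, _ = nc_ratio(nuc, cyt)
        high, _ = nc_ratio(nuc + delta, cyt)
        assert high > low


class TestNcSummary:
    def _rec(self, nc=None, flag=None, eligible=True):
        return NCRecord("ACGT" * 5, 1.0, 1.0, nc, flag, eligible)

    def test_fractions(self):
        records = [
            self._rec(nc=0.5),
            self._rec(nc=1.0),
            self._rec(nc=10.0),
            self._rec(flag=NUCLEAR_ONLY),
        ]
        summary = nc_summary(records)
        assert summary.fraction_in_range == 0.5
        assert summary.fraction_nuclear_only == 0.25
        assert summary.fraction_cytoplasmic_only == 0.0

    def test_all_nuclear_only(self):
        records = [self._rec(flag=NUCLEAR_ONLY) for _ in range(3)]
        summary = nc_summary(records)
        assert summary.fraction_in_range == 0.0
        assert summary.fraction_nuclear_only == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            nc_summary([self._rec(nc=1.0, eligible=False)])

    def test_eligibility_uses_raw_counts_not_rpm(self, clean_result):
        for nc_rec in clean_result.nc:
            rec = next(
                r
                for r in clean_result.annotation.records
                if r.sequence == nc_rec.sequence
            )
            assert nc_rec.eligible == (max(rec.counts.values()) > 10)


def _member(seq, nuclear, cytoplasmic, ref="mir-1"):
    rec = UniqueSeqRecord(seq, {"nuclear": nuclear, "cytoplasmic": cytoplasmic})
    rec.status = "mapped"
    rec.matched_ref = ref
    rec.rpm = {"nuclear": float(nuclear), "cytoplasmic": float(cytoplasmic)}
    return rec


class TestIsomirGrouping:
    def test_representative_is_argmax(self):
        groups = group_isomirs([_member("AAAA", 50, 50), _member("CCCC", 3, 3)])
        group = groups[0]
        assert group.representatives["nuclear"].sequence == "AAAA"
        assert not group.discordant

    def test_discordant_flagged_and_excluded(self):
        from srnanc.quantify import concordant_groups

        groups = group_isomirs([_member("AAAA", 50, 3), _member("CCCC", 3, 50)])
        assert groups[0].discordant
        assert concordant_groups(groups) == []

    def test_tie_breaks_lexicographically(self):
        groups = group_isomirs([_member("TTTT", 5, 5), _member("AAAA", 5, 5)])
        assert groups[0].representatives["nuclear"].sequence == "AAAA"

    def test_grouping_by_mature_arm(self, clean_dataset, clean_result):
        """With zero end jitter every simulated mature arm forms its own
        concordant group keyed by the mature miRNA id."""
        mature_ids = {
            mat for arms in clean_dataset.hairpin_arms.values() for mat, _, _ in arms
        }
        group_ids = {g.mirna_id for g in clean_result.isomir_groups}
        assert mature_ids <= group_ids


class TestCorrelation:
    def test_proportional_pairs_r2_one(self):
        groups = group_isomirs(
            [_member(f"AAA{b}", 3 * x, x, ref=f"m{x}") for x, b in zip((1, 2, 4), "ACG")]
        )
        assert mirna_correlation(groups) == pytest.approx(1.0)

    def test_two_points_degenerate(self):
        groups = group_isomirs(
            [_member("AAAA", 1, 2, ref="m1"), _member("CCCC", 2, 1, ref="m2")]
        )
        with pytest.warns(UserWarning, match="two points"):
            assert mirna_correlation(groups) == pytest.approx(1.0)

    def test_fewer_than_two_rejected(self):
        groups = group_isomirs([_member("AAAA", 1, 2)])
        with pytest.raises(ValueError):
            mirna_correlation(groups)

    def test_monte_carlo_recovery_of_planted_correlation(self):
        """R^2 of planted bivariate-normal abundances lands within 3 SE of
        rho^2 (n = 300, seeded)."""
        rng = np.random.default_rng(17)
        rho, n = 0.9, 300
        cov = [[1.0, rho], [rho, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=n)
        members = [
            _member(f"SEQ{i}", max(x + 5, 0.01), max(y + 5, 0.01), ref=f"m{i}")
            for i, (x, y) in enumerate(xy)
        ]
        groups = group_isomirs(members)
        r2 = mirna_correlation(groups)
        se = (1 - rho**2) * 2 * abs(rho) / math.sqrt(n)  # delta-method SE of r^2
        assert abs(r2 - rho**2) < 3 * se + 0.02


class TestHexamerAndMotifs:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("UAGCACCAUUUGAAAUCAGUGUU", "AGUGUU"),
            ("UCAGUGCACUACAGAACUUUGU", "CUUUGU"),
        ],
    )
    def test_published_hexamers(self, seq, expected):
        assert hexamer_extract(seq) == expected

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            hexamer_extract("ACGUU")

    def test_published_representatives_hexamers_consistent(self):
        for _, seq, _, _ in MIRNA_EXAMPLES:
            assert hexamer_extract(seq) == seq[-6:]

    def test_motif_enrichment_arithmetic(self):
        records = [
            MotifRecord("AAAAAGTGTT", "AAGTGTT"[-6:], 4.5),
            MotifRecord("CCCCAGTGTT", "AGTGTT", 4.4),
            MotifRecord("AAAACCCGGG", "CCCGGG", 1.0),
            MotifRecord("TTTTCCCGGG", "CCCGGG", 0.9),
        ]
        assoc = motif_nc_association(records, "AGUGUU")
        assert (assoc.n_with, assoc.n_without) == (2, 2)
        assert assoc.median_nc_with / assoc.median_nc_without > 4.5

    def test_single_nonenriched_carrier_reported(self):
        records = [
            MotifRecord("CCCCAGTGTT", "AGTGTT", 0.84),
            MotifRecord("AAAACCCGGG", "CCCGGG", 1.0),
        ]
        assoc = motif_nc_association(records, "AGUGUU")
        assert assoc.n_with == 1
        assert assoc.median_nc_with == pytest.approx(0.84)
        assert assoc.p_value is None  # too few carriers for a rank test

    def test_absent_motif_reported_not_fatal(self):
        records = [MotifRecord("AAAACCCGGG", "CCCGGG", 1.0)]
        assoc = motif_nc_association(records, "AGUGUU")
        assert assoc.n_with == 0 and assoc.median_nc_with is None

    def test_planted_motif_effect_recovered(self):
        """Carriers planted with a 5x mixing ratio surface in the median."""
        rng = np.random.default_rng(23)
        records = []
        for i in range(60):
            carrier = i < 20
            suffix = "AGTGTT" if carrier else "CCCGGG"
            base = float(np.exp(rng.normal(0.0, 0.3)))
            nc = base * (5.0 if carrier else 1.0)
            records.append(MotifRecord(f"SEQ{i:02d}" + suffix, suffix, nc))
        assoc = motif_nc_association(records, "AGTGTT")
        assert assoc.median_nc_with / assoc.median_nc_without > 3.0
        assert assoc.p_value < 0.001


class TestLengthDistribution:
    def test_single_length(self):
        recs = [_member("A" * 22, 5, 5)]
        hist = length_distribution(recs, "nuclear")
        assert hist[22] == 5 and sum(hist.values()) == 5
        assert histogram_mode(hist) == 22

    def test_simulated_mirna_mode_22(self, clean_result):
        from srnanc.classes import ClassLabel

        hist = length_distribution(
            clean_result.annotation.records, "nuclear", ClassLabel.MIRNA
        )
        assert histogram_mode(hist) == 22

    def test_empty_class_warns(self):
        with pytest.warns(UserWarning, match="no records"):
            hist = length_distribution([], "nuclear")
        assert histogram_mode(hist) is None
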