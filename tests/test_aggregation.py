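import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from otuspace.aggregation import (asand, lai, lai_for_members, lai_scan,
                                  member_sands, otu_summary, sand,
                                  write_lai_report)
from otuspace.otu_io import SampleMetadata, to_relative_abundance

from .conftest import make_table

LINE = np.array([[0.0], [1.0], [3.0]])  # members on a line at 0, 1, 3


class TestOtuSummary:
    def test_values_over_nonzero_samples_only(self):
        rel = to_relative_abundance(make_table([[2, 98], [4, 96], [0, 100]]))
        df = otu_summary(rel)
        assert df.loc["o0", "prevalence"] == 2
        assert df.loc["o0", "average_abundance"] == pytest.approx(0.03)

    def test_singleton(self):
        rel = to_relative_abundance(make_table([[1, 99]]))
        df = otu_summary(rel)
        assert df.loc["o0", "prevalence"] == 1
        assert df.loc["o0", "average_abundance"] == pytest.approx(0.01)

    def test_prevalence_matches_nonzero_cells(self, fixture_pipeline):
        rel = fixture_pipeline["rel"]
        df = otu_summary(rel)
        np.testing.assert_array_equal(
            df["prevalence"].to_numpy(),
            np.asarray((rel.rel > 0).sum(axis=0)).ravel(),
        )


class TestSand:
    def test_two_members_forced(self):
        X = np.array([[0.0], [5.0]])
        assert sand(X, 0, np.array([0, 1])) == 5.0
        assert sand(X, 1, np.array([0, 1])) == 5.0

    def test_coincident_members_zero(self):
        X = np.array([[2.0, 2.0], [2.0, 2.0], [9.0, 9.0]])
        assert sand(X, 0, np.array([0, 1, 2])) == 0.0

    def test_line_oracle(self):
        sands = member_sands(LINE, np.array([0, 1, 2]))
        assert sorted(sands.tolist()) == [1.0, 1.0, 2.0]

    def test_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            sand(LINE, 0, np.array([0]))
        with pytest.raises(ValueError, match="belong"):
            sand(LINE, 2, np.array([0, 1]))


class TestAsand:
    def test_top_ten_percent_of_twenty_is_two(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 3))
        members = np.arange(20)
        sands = np.sort(member_sands(X, members))
        assert asand(X, members) == pytest.approx(sands[:2].mean())

    def test_coincident_zero(self):
        X = np.zeros((5, 2))
        assert asand(X, np.arange(5)) == 0.0

    def test_full_fraction_line_oracle(self):
        assert asand(LINE, np.array([0, 1, 2]), top_frac=1.0) == pytest.approx(4 / 3)

    @given(factor=st.floats(0.1, 10))
    def test_scaling_homogeneity(self, factor):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(15, 4))
        members = np.arange(10)
        base = asand(X, members)
        assert asand(X * factor, members) == pytest.approx(factor * base, rel=1e-9)


class TestLai:
    def test_coincident_members_maximally_aggregated(self):
        # 3 coincident members among 40: a permutation reaches ASAND=0 only
        # by landing two labels on the coincident samples (P ~ 0.011)
        rng = np.random.default_rng(1)
        X = np.vstack([np.zeros((3, 2)), rng.normal(size=(37, 2))])
        res = lai_for_members(X, np.arange(3), n_perm=1000, rng=2)
        assert res.asand_real == 0.0
        assert res.lai < 0.05

    def test_single_permutation_support(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(20, 2))
        res = lai_for_members(X, np.arange(5), n_perm=1, rng=4)
        assert res.lai in (0.0, 1.0)

    def test_seed_reproducibility(self):
        X = np.random.default_rng(5).normal(size=(30, 3))
        a = lai_for_members(X, np.arange(8), n_perm=200, rng=9)
        b = lai_for_members(X, np.arange(8), n_perm=200, rng=9)
        assert a.count_leq == b.count_leq

    def test_isometry_invariance(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(25, 4))
        members = np.arange(6)
        q, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        Y = X @ q + 13.0
        a = lai_for_members(X, members, n_perm=300, rng=11)
        b = lai_for_members(Y, members, n_perm=300, rng=11)
        assert a.count_leq == b.count_leq

    def test_continuity_correction_mode(self):
        X = np.random.default_rng(7).normal(size=(20, 2))
        res = lai_for_members(X, np.arange(5), n_perm=99, rng=1, continuity=True)
        assert res.lai == pytest.approx((1 + res.count_leq) / 100)

    def test_group_size_guard(self):
        X = np.zeros((20, 2))
        labels = ["a"] * 3 + ["b"] * 17
        with pytest.raises(ValueError, match="min_group"):
            lai(X, labels, "a", n_perm=10, rng=0)

    def test_exact_enumeration_oracle(self):
        """Sampled LAI converges to the exhaustive label-placement value."""
        rng = np.random.default_rng(8)
        X = rng.normal(size=(10, 2))
        members = np.array([0, 1, 2, 3])
        real = asand(X, members)
        hits = total = 0
        for combo in itertools.combinations(range(10), 4):
            hits += asand(X, np.array(combo)) <= real
            total += 1
        exact = hits / total
        n_perm = 2000
        sampled = lai_for_members(X, members, n_perm=n_perm, rng=12).lai
        se = np.sqrt(exact * (1 - exact) / n_perm)
        assert abs(sampled - exact) <= 3 * se + 1e-12


class TestLaiScan:
    def test_planted_attribute_detected(self, fixture_pipeline):
        X = fixture_pipeline["sample_space"]
        meta = fixture_pipeline["meta"]
        df = lai_scan(X, meta, ["PLANTED_GUILD"], n_perm=1000, rng=7)
        planted = df[(df.attribute == "PLANTED_GUILD") & (df.sub_attribute == "Yes")]
        assert len(planted) == 1
        assert planted["lai"].iloc[0] < 0.05

    def test_na_excluded_and_sorted(self, fixture_pipeline):
        X = fixture_pipeline["sample_space"]
        meta = fixture_pipeline["meta"]
        df = lai_scan(X, meta, n_perm=50, rng=1)
        assert not (df.sub_attribute == "NA").any()
        assert df["lai"].is_monotonic_increasing

    def test_all_na_attribute_excluded(self):
        X = np.random.default_rng(0).normal(size=(20, 2))
        ids = [f"s{i}" for i in range(20)]
        meta = SampleMetadata(ids, {"EMPTY": {s: "NA" for s in ids}})
        with pytest.warns(UserWarning, match="no qualifying"):
            df = lai_scan(X, meta, n_perm=10, rng=0)
        assert df.empty


def test_lai_report_writer(tmp_path, fixture_pipeline):
    X = fixture_pipeline["sample_space"]
    meta = fixture_pipeline["meta"]
    df = lai_scan(X, meta, ["NULL_BINARY"], n_perm=20, rng=3)
    path = tmp_path / "lai.tsv"
    write_lai_report(df, path)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("attribute\tsub_attribute")
    assert lines[-1].startswith("#")
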