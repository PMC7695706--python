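"""fa_data: containers, CSV I/O, consumer simulation, CCs and tracer filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famix import (
    CCSet,
    ConsumerDataset,
    FAClassTable,
    FAProfile,
    SourceSummary,
    apply_ccs,
    average_ccs,
    compute_ccs,
    read_cc_csv,
    read_consumer_csv,
    read_source_csv,
    select_fas,
    simulate_consumers_from_summary,
    write_cc_csv,
    write_consumer_csv,
    write_source_csv,
)

FA4 = ["14:0", "16:1n-7", "20:5n-3", "22:6n-3"]


def _dataset(values, fa=FA4, factors=None):
    factors = factors or {}
    profs = [
        FAProfile(fa, row, subject_id=f"c{i}", factor_labels=factors)
        for i, row in enumerate(np.atleast_2d(values))
    ]
    return ConsumerDataset(profs, list(factors))


class TestContainers:
    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            FAProfile(FA4, [10.0, -1.0, 50.0, 41.0])

    def test_row_sum_check(self):
        p = FAProfile(FA4, [60.0, 60.0, 60.0, 70.0])  # sums to 250
        with pytest.raises(ValueError, match="sums to"):
            p.check_sum()

    def test_mismatched_fa_orderings_rejected(self):
        a = FAProfile(FA4, [25, 25, 25, 25])
        b = FAProfile(list(reversed(FA4)), [25, 25, 25, 25])
        with pytest.raises(ValueError, match="ordering"):
            ConsumerDataset([a, b])

    def test_predator_space_only_via_apply_ccs(self):
        with pytest.raises(ValueError):
            SourceSummary("x", FA4, [1, 2, 3, 4], [0, 0, 0, 0], space="made_up")
        src = SourceSummary("x", FA4, [10, 20, 30, 40], [1, 1, 1, 1])
        pred = apply_ccs([src], CCSet(FA4, [1, 1, 1, 1]))[0]
        assert pred.space == "predator"
        with pytest.raises(ValueError, match="predator space"):
            apply_ccs([pred], CCSet(FA4, [1, 1, 1, 1]))

    def test_cc_must_be_positive(self):
        with pytest.raises(ValueError):
            CCSet(FA4, [1.0, 0.0, 1.0, 1.0])


class TestCsvIO:
    def test_consumer_roundtrip_identity(self, tmp_path):
        ds = _dataset(
            [[20, 30, 25, 25], [22, 28, 26, 24]], factors={"day": "21"}
        )
        path = tmp_path / "consumers.csv"
        write_consumer_csv(ds, path)
        back = read_consumer_csv(path, factors=("day",))
        assert back.fa_names == ds.fa_names
        assert back.factor_names == ["day"]
        assert back.factor_values("day") == ["21", "21"]
        np.testing.assert_allclose(back.to_matrix(), ds.to_matrix())

    def test_shape_and_factor_declaration(self, tmp_path):
        rng = np.random.default_rng(0)
        vals = rng.dirichlet(np.ones(20), size=8) * 100
        fa = [f"FA{j}" for j in range(20)]
        profs = [
            FAProfile(fa, v, subject_id=f"e{i}", factor_labels={"day": "0"})
            for i, v in enumerate(vals)
        ]
        path = tmp_path / "wide.csv"
        write_consumer_csv(ConsumerDataset(profs, ["day"]), path)
        ds = read_consumer_csv(path, factors=("day",))
        assert ds.n == 8 and len(ds.fa_names) == 20
        assert ds.factor_names == ["day"]

    def test_bad_row_sum_rejected_on_read(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,FA1,FA2\nc1,150,100\n")
        with pytest.raises(ValueError, match="sums to"):
            read_consumer_csv(path)

    def test_non_numeric_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "nan.csv"
        path.write_text("id,FA1,FA2\nc1,50,oops\n")
        with pytest.raises(ValueError, match=r"row 1.*FA2"):
            read_consumer_csv(path)

    def test_duplicate_fa_name_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("id,FA1,FA1.0\nc1,50,50\n")
        with pytest.raises(ValueError):
            # pandas mangles exact duplicates, so construct directly too
            FAProfile(["FA1", "FA1"], [50, 50])

    def test_source_csv_roundtrip_both_layouts(self, tmp_path):
        sources = [
            SourceSummary("krill", FA4, [40, 30, 20, 10], [4, 3, 2, 1]),
            SourceSummary("herring", FA4, [10, 20, 30, 40], [1, 2, 3, 4]),
        ]
        long_path = tmp_path / "long.csv"
        write_source_csv(sources, long_path)
        back = read_source_csv(long_path)
        assert [s.source_name for s in back] == ["krill", "herring"]
        np.testing.assert_allclose(back[0].means, sources[0].means)
        wide = tmp_path / "wide.csv"
        header = "source," + ",".join(
            [f"mean_{f}" for f in FA4] + [f"sd_{f}" for f in FA4]
        )
        wide.write_text(header + "\nkrill,40,30,20,10,4,3,2,1\n")
        w = read_source_csv(wide)[0]
        np.testing.assert_allclose(w.means, [40, 30, 20, 10])
        np.testing.assert_allclose(w.sds, [4, 3, 2, 1])

    def test_cc_csv_roundtrip(self, tmp_path):
        cc = CCSet(FA4, [0.8, 1.2, 1.0, 1.5])
        path = tmp_path / "cc.csv"
        write_cc_csv(cc, path)
        back = read_cc_csv(path)
        assert back.fa_names == FA4
        np.testing.assert_allclose(back.cc, cc.cc)


class TestSimulateConsumers:
    def test_zero_sd_reproduces_means(self):
        ds = simulate_consumers_from_summary([40.0, 60.0], [0.0, 0.0], n=5, seed=0)
        np.testing.assert_allclose(ds.to_matrix(), np.tile([40.0, 60.0], (5, 1)))

    def test_sample_moments_match_inputs(self):
        # CLT bound: sample means within 3*sd/sqrt(n) of the inputs
        means, sds, n = np.array([50.0, 50.0]), np.array([5.0, 5.0]), 1000
        ds = simulate_consumers_from_summary(means, sds, n=n, seed=42)
        got = ds.to_matrix().mean(axis=0)
        np.testing.assert_array_less(np.abs(got - means), 3 * sds / np.sqrt(n))
        got_sd = ds.to_matrix().std(axis=0, ddof=1)
        assert np.all(np.abs(got_sd - sds) < 0.5)

    def test_seeded_determinism(self):
        a = simulate_consumers_from_summary([10.0, 20.0], [2.0, 3.0], n=7, seed=9)
        b = simulate_consumers_from_summary([10.0, 20.0], [2.0, 3.0], n=7, seed=9)
        np.testing.assert_array_equal(a.to_matrix(), b.to_matrix())

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            simulate_consumers_from_summary([10.0], [-1.0], n=2, seed=0)

    def test_redraw_keeps_values_non_negative(self):
        # mean near zero with a large SD forces many redraws
        ds = simulate_consumers_from_summary([0.5], [2.0], n=200, seed=3)
        assert np.all(ds.to_matrix() >= 0)


class TestCalibrationCoefficients:
    def test_identity_diet_gives_unit_ccs(self, prey_sources):
        src = prey_sources[0]
        cons = simulate_consumers_from_summary(
            src.means, np.zeros_like(src.sds), n=4, seed=0, fa_names=src.fa_names
        )
        cc = compute_ccs(cons, [(src, 1.0)])
        np.testing.assert_allclose(cc.cc, 1.0)

    def test_single_prey_division(self):
        fa = ["a"]
        prey = SourceSummary("p", fa, [8.0], [1.0])
        cons = simulate_consumers_from_summary([12.0], [0.0], n=3, seed=0, fa_names=fa)
        assert compute_ccs(cons, [(prey, 1.0)]).cc[0] == pytest.approx(1.5)

    def test_mixed_diet_weighted_denominator(self):
        # consumer mean 8 against 0.6*10 + 0.4*5 = 8 -> cc exactly 1
        fa = ["a"]
        p1 = SourceSummary("p1", fa, [10.0], [1.0])
        p2 = SourceSummary("p2", fa, [5.0], [1.0])
        cons = simulate_consumers_from_summary([8.0], [0.0], n=3, seed=0, fa_names=fa)
        cc = compute_ccs(cons, [(p1, 0.6), (p2, 0.4)])
        assert cc.cc[0] == pytest.approx(1.0)

    def test_zero_diet_mean_is_an_error(self):
        fa = ["a"]
        prey = SourceSummary("p", fa, [0.0], [0.0])
        cons = simulate_consumers_from_summary([5.0], [0.0], n=2, seed=0, fa_names=fa)
        with pytest.raises(ZeroDivisionError):
            compute_ccs(cons, [(prey, 1.0)])

    def test_apply_ccs_scales_mean_and_sd(self):
        src = SourceSummary("p", ["a"], [10.0], [2.0])
        out = apply_ccs([src], CCSet(["a"], [1.5]))[0]
        assert out.means[0] == pytest.approx(15.0)
        assert out.sds[0] == pytest.approx(3.0)
        assert out.space == "predator"

    def test_identity_cc_preserves_sources(self, prey_sources, unit_cc):
        out = apply_ccs(prey_sources, unit_cc)
        for before, after in zip(prey_sources, out):
            np.testing.assert_allclose(after.means, before.means)
            np.testing.assert_allclose(after.sds, before.sds)

    def test_missing_cc_entry_is_an_error(self, prey_sources):
        cc = CCSet(["16:1n-7"], [1.0])
        with pytest.raises(KeyError, match="no calibration coefficient"):
            apply_ccs(prey_sources, cc)

    def test_compute_apply_roundtrip_reproduces_consumer_means(self, prey_sources):
        """CCs computed from consumers, applied back to the single prey they
        ate, give predator-space means exactly equal to the consumer means —
        the mechanism that makes identity fits recover the true diet."""
        src = prey_sources[0]
        cons = simulate_consumers_from_summary(
            src.means * 1.3, src.sds, n=6, seed=11, fa_names=src.fa_names
        )
        cc = compute_ccs(cons, [(src, 1.0)])
        pred = apply_ccs([src], cc)[0]
        np.testing.assert_allclose(pred.means, cons.mean_profile(), rtol=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        means=st.lists(st.floats(0.5, 50.0), min_size=2, max_size=6),
        ccs=st.lists(st.floats(0.2, 2.0), min_size=2, max_size=6),
    )
    def test_cc_roundtrip_property(self, means, ccs):
        # consumers built as the exact CC-multiplied image of a prey recover
        # those CCs to machine precision
        j = min(len(means), len(ccs))
        fa = [f"FA{i}" for i in range(j)]
        prey = SourceSummary("p", fa, means[:j], np.zeros(j))
        cons = simulate_consumers_from_summary(
            np.array(means[:j]) * np.array(ccs[:j]),
            np.zeros(j),
            n=3,
            seed=0,
            fa_names=fa,
        )
        got = compute_ccs(cons, [(prey, 1.0)])
        np.testing.assert_allclose(got.cc, ccs[:j], rtol=1e-10)

    def test_average_ccs(self):
        a = CCSet(["x"], [1.0])
        b = CCSet(["x"], [2.0])
        assert average_ccs([a, b]).cc[0] == pytest.approx(1.5)


class TestSelectFas:
    @pytest.fixture
    def filter_inputs(self):
        fa = ["18:2n-6", "18:3n-3", "20:5n-3", "16:0", "22:6n-3"]
        # grand means: 0.4 (too scarce), 3.0, 1.0, 5.0 (endogenous), 2.0
        vals = np.tile([0.4, 3.0, 1.0, 5.0, 2.0], (4, 1))
        cons = ConsumerDataset(
            [FAProfile(fa, v, subject_id=str(i)) for i, v in enumerate(vals)]
        )
        cc = CCSet(fa, [1.0, 2.3, 1.2, 1.0, 1.0])
        return cons, cc

    def test_filters(self, filter_inputs):
        cons, cc = filter_inputs
        kept = select_fas(cons, cc, FAClassTable.default())
        # 18:2n-6 scarce (0.4 < 0.5), 18:3n-3 has CC 2.3 > 2, 16:0 endogenous
        assert kept == ["20:5n-3", "22:6n-3"]

    def test_threshold_monotonicity(self, filter_inputs):
        cons, cc = filter_inputs
        classes = FAClassTable.default()
        previous = None
        for thr in (0.1, 0.5, 1.5):
            try:
                kept = set(select_fas(cons, cc, classes, abundance_threshold=thr))
            except ValueError:
                kept = set()
            if previous is not None:
                assert kept <= previous
            previous = kept

    def test_empty_selection_is_an_error(self, filter_inputs):
        cons, cc = filter_inputs
        with pytest.raises(ValueError, match="no FAs survive"):
            select_fas(cons, cc, FAClassTable.default(), abundance_threshold=99.0)

    def test_unclassified_fa_is_an_error(self, filter_inputs):
        cons, cc = filter_inputs
        with pytest.raises(KeyError, match="no classification"):
            select_fas(cons, cc, FAClassTable({"18:2n-6": "dietary"}))


def test_default_class_table_covers_common_marine_fas():
    table = FAClassTable.default()
    assert table.class_of("20:5n-3") == "extended_dietary"
    assert table.class_of("18:2n-6") == "dietary"
    assert table.class_of("16:0") == "endogenous"
    assert len(table) >= 25
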