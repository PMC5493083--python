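"""Container invariants, descriptor-table I/O and activity-unit conversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hsp90qsar import (
    CompoundRecord,
    QSARDataset,
    ic50_to_pic50,
    load_descriptor_catalog,
    load_fixture_table5,
    pic50_to_ic50,
    read_descriptor_table,
    write_descriptor_table,
)


class TestCompoundRecord:
    def test_accepts_alphanumeric_ids(self):
        rec = CompoundRecord("75a", 4.9, group="B")
        assert rec.compound_id == "75a"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"compound_id": "", "activity": 1.0},
            {"compound_id": "x", "activity": float("nan")},
            {"compound_id": "x", "activity": 1.0, "group": "D"},
        ],
    )
    def test_rejects_invalid_fields(self, kwargs):
        with pytest.raises(ValueError):
            CompoundRecord(**kwargs)


class TestQSARDataset:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="81d"):
            QSARDataset(["81d", "81d"], ["a"], [[1.0], [2.0]], [0.0, 0.0])

    def test_nonfinite_value_names_cell(self):
        with pytest.raises(ValueError, match=r"c2.*X5A"):
            QSARDataset(["c1", "c2"], ["X5A"], [[1.0], [np.nan]], [0.0, 0.0])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            QSARDataset(["c1"], ["a", "b"], [[1.0]], [0.0])


class TestDescriptorTableIO:
    def test_write_read_round_trip(self, tmp_path, rng):
        X = rng.standard_normal((3, 2))
        ds = QSARDataset(["c1", "c2", "81d"], ["X5A", "TIE"], X, rng.standard_normal(3))
        path = tmp_path / "table.csv"
        write_descriptor_table(ds, path)
        back = read_descriptor_table(path)
        assert back.compound_ids == ds.compound_ids
        assert back.descriptor_names == ds.descriptor_names
        np.testing.assert_array_equal(back.values, ds.values)
        np.testing.assert_array_equal(back.activities, ds.activities)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(2, 8), st.integers(1, 6), st.integers(0, 2**31 - 1))
    def test_round_trip_identity_property(self, tmp_path_factory, n, p, seed):
        rng = np.random.default_rng(seed)
        ds = QSARDataset(
            [f"c{i}" for i in range(n)],
            [f"d{j}" for j in range(p)],
            rng.standard_normal((n, p)) * 10.0 ** int(rng.integers(-6, 6)),
            rng.standard_normal(n),
        )
        path = tmp_path_factory.mktemp("io") / "t.csv"
        write_descriptor_table(ds, path)
        back = read_descriptor_table(path)
        np.testing.assert_array_equal(back.values, ds.values)
        np.testing.assert_array_equal(back.activities, ds.activities)

    def test_missing_cell_names_row_and_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("compound_id,pIC50,X5A,TIE\nc1,4.2,0.1,3\nc2,4.5,,7\n")
        with pytest.raises(ValueError, match=r"c2.*X5A"):
            read_descriptor_table(path)

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("compound_id,pIC50,X5A\n81d,4.2,0.1\n81d,4.5,0.2\n")
        with pytest.raises(ValueError, match="81d"):
            read_descriptor_table(path)

    def test_non_numeric_cell_rejected(self, tmp_path):
        path = tmp_path / "nonnum.csv"
        path.write_text("compound_id,pIC50,X5A\nc1,4.2,abc\n")
        with pytest.raises(ValueError, match=r"abc.*c1.*X5A"):
            read_descriptor_table(path)

    def test_tsv_accepted_by_sniffing(self, tmp_path):
        path = tmp_path / "t.tsv"
        path.write_text("compound_id\tpIC50\tX5A\nc1\t4.2\t0.1\n")
        ds = read_descriptor_table(path)
        assert ds.descriptor_names == ["X5A"]
        assert ds.values[0, 0] == 0.1


class TestActivityConversion:
    @pytest.mark.parametrize(
        "ic50_um, expected_2dp",
        [(0.153, 3.82), (0.020, 4.70), (1000.0, 0.0)],
    )
    def test_mm_scale_convention(self, ic50_um, expected_2dp):
        assert round(ic50_to_pic50(ic50_um), 2) == expected_2dp

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            ic50_to_pic50(0.0)
        with pytest.raises(ValueError):
            ic50_to_pic50(-1.0)

    def test_unit_parameter(self):
        # 1 μM on the molar scale is pIC50 = 6
        assert ic50_to_pic50(1.0, unit="M") == pytest.approx(6.0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.floats(1e-6, 1e6), st.sampled_from(["M", "mM", "uM", "nM"]))
    def test_round_trip_inverse(self, ic50, unit):
        back = pic50_to_ic50(ic50_to_pic50(ic50, unit=unit), unit=unit)
        assert back == pytest.approx(ic50, rel=1e-12)


class TestPackagedFixtures:
    def test_activity_table_has_50_records(self):
        fx = load_fixture_table5()
        assert len(fx.activity) == 50

    @pytest.mark.parametrize(
        "compound, column, value",
        [
            ("69", "experimental_pic50", 4.70),
            ("15", "mlr_pic50", 3.64),
            ("15", "experimental_pic50", 3.82),
            ("26", "gapls_pic50", 5.39),
            ("81d", "experimental_pic50", 2.80),
        ],
    )
    def test_printed_values(self, compound, column, value):
        fx = load_fixture_table5()
        assert fx.activity.loc[compound, column] == pytest.approx(value)

    def test_ic50_table_positive(self):
        fx = load_fixture_table5()
        assert (fx.ic50_um["ic50_um"] > 0).all()

    def test_ic50_consistent_with_experimental_pic50(self):
        """Every compound printed with both an IC50 and a pIC50 obeys the
        millimolar conversion to within print rounding."""
        fx = load_fixture_table5()
        shared = fx.ic50_um.index.intersection(fx.activity.index)
        assert len(shared) == 25
        for c in shared:
            ic50 = fx.ic50_um.loc[c, "ic50_um"]
            derived = ic50_to_pic50(ic50)
            # half a printed digit on the pIC50 plus the propagated half-digit
            # uncertainty of the 3-dp printed IC50
            tol = 0.005 + 0.0005 / ic50 / np.log(10)
            assert abs(derived - fx.activity.loc[c, "experimental_pic50"]) <= tol

    def test_catalog_resolves_every_published_descriptor(self):
        from hsp90qsar import GAPLS, MLR_GENERAL

        catalog = load_descriptor_catalog()
        for eq in (MLR_GENERAL, GAPLS):
            for name in eq.coefficients:
                assert name in catalog

    def test_catalog_lookup_is_whitespace_insensitive(self):
        catalog = load_descriptor_catalog()
        assert catalog.family("dipole_z") == "quantum chemical"
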