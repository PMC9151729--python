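"""Domain types, conversions, CSV I/O, bundled fixture and synthetic data."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sco2sol as sc
from sco2sol.data import DataValidationError


class TestConversions:
    def test_s_from_y2_printed_row(self, solute, solvent):
        # 328 K / 27 MPa row: y2 = 22.60e-6 at rho = 829 corresponds to the
        # printed equilibrium concentration 0.1920 g/L
        s = sc.s_from_y2(22.60e-6, 829.0, solute.M, solvent.M)
        assert s == pytest.approx(0.1920, rel=5e-3)

    @pytest.mark.parametrize(
        "y2, rho, expected",
        [
            (0.0, 829.0, 0.0),
            # direct substitution: 500*(450.9/44.01)*1e-5/(1-1e-5)
            (1e-5, 500.0, 500.0 * (450.9 / 44.01) * 1e-5 / (1 - 1e-5)),
        ],
    )
    def test_s_from_y2_values(self, y2, rho, expected, solute, solvent):
        assert sc.s_from_y2(y2, rho, solute.M, solvent.M) == pytest.approx(
            expected, abs=1e-15)
        assert sc.s_from_y2(1e-5, 500.0, 450.9, 44.01) == pytest.approx(
            0.05123, rel=1e-3)

    def test_s_from_y2_domain(self, solute, solvent):
        with pytest.raises(DataValidationError):
            sc.s_from_y2(1.0, 829.0, solute.M, solvent.M)

    @settings(derandomize=True, max_examples=200)
    @given(y2=st.floats(1e-9, 0.5), rho=st.floats(100.0, 1000.0))
    def test_round_trip_identity(self, y2, rho):
        s = sc.s_from_y2(y2, rho, 450.9, 44.01)
        back = sc.y2_from_s(s, rho, 450.9, 44.01)
        assert back == pytest.approx(y2, rel=1e-12)

    def test_round_trip_on_fixture(self, dataset, solute, solvent):
        for rec in dataset:
            s = sc.s_from_y2(rec.y2, rec.rho1, solute.M, solvent.M)
            assert sc.y2_from_s(s, rec.rho1, solute.M, solvent.M) == \
                pytest.approx(rec.y2, rel=1e-12)

    def test_y2_from_counts(self, solute, solvent):
        # zero solute and equimolar symmetry
        assert sc.y2_from_counts(0.0, 5e-3, 600e-6, 829.0, solute.M,
                                 solvent.M) == 0.0
        # n_drug = n_CO2 -> exactly one half
        n_co2 = 600e-6 * 829.0 / solvent.M
        cs = n_co2 * solute.M / 5e-3
        assert sc.y2_from_counts(cs, 5e-3, 600e-6, 829.0, solute.M,
                                 solvent.M) == pytest.approx(0.5)
        with pytest.raises(DataValidationError):
            sc.y2_from_counts(0.1, 5e-3, 600e-6, -1.0, solute.M, solvent.M)

    def test_y2_from_counts_matches_concentration_relation(self, solute,
                                                           solvent):
        # the loop-referred solubility S = Cs*Vs/V1 = 0.1920 g/L must give
        # the same mole fraction as inverting the concentration relation
        S, rho = 0.1920, 829.0
        cs_vial = S * 600e-6 / 5e-3
        y_counts = sc.y2_from_counts(cs_vial, 5e-3, 600e-6, rho, solute.M,
                                     solvent.M)
        y_inv = sc.y2_from_s(S, rho, solute.M, solvent.M)
        assert y_counts == pytest.approx(y_inv, rel=1e-12)
        assert y_counts == pytest.approx(22.6e-6, rel=1e-3)

    @pytest.mark.parametrize(
        "T, rho, expected",
        [
            (304.18, 467.6, (1.0, 1.0)),
            (308.0, 769.0, (308.0 / 304.18, 769.0 / 467.6)),
            (338.0, 388.0, (338.0 / 304.18, 388.0 / 467.6)),
        ],
    )
    def test_reduced_state(self, T, rho, expected, solvent):
        tr, rr = sc.reduced_state(T, rho, solvent)
        assert tr == pytest.approx(expected[0], rel=1e-12)
        assert rr == pytest.approx(expected[1], rel=1e-12)


class TestFixture:
    def test_shape(self, dataset):
        assert len(dataset) == 24
        assert len(dataset.temperatures()) == 4
        assert len(np.unique(dataset.P)) == 6

    def test_extrema(self, dataset):
        assert dataset.y2.min() == pytest.approx(5.14e-6)
        # the published table's maximum is the 338 K / 24 MPa point; the
        # abstract's quoted upper end (25.9e-6) is the 27 MPa endpoint
        assert dataset.y2.max() == pytest.approx(26.37e-6)
        end_point = next(r for r in dataset if r.T == 338.0 and r.P == 27.0)
        assert end_point.y2 == pytest.approx(25.9e-6)

    def test_first_row(self, dataset):
        rec = dataset.records[0]
        assert (rec.T, rec.P, rec.rho1) == (308.0, 12.0, 769.0)
        assert rec.y2 == pytest.approx(8.14e-6)

    def test_density_monotonicity(self, dataset):
        for T in dataset.temperatures():
            iso = dataset.isotherm(T)
            order = np.argsort(iso.P)
            assert np.all(np.diff(iso.rho1[order]) > 0)
        for P in np.unique(dataset.P):
            rhos = [r.rho1 for r in sorted(
                (r for r in dataset if r.P == P), key=lambda r: r.T)]
            assert np.all(np.diff(rhos) < 0)

    def test_s_consistency(self, dataset, solute, solvent):
        # one printed S value (318 K / 24 MPa) is internally inconsistent
        # with its own printed y2 by 1.84%; every other row closes to 0.35%
        rels = {}
        for rec in dataset:
            s = sc.s_from_y2(rec.y2, rec.rho1, solute.M, solvent.M)
            rels[(rec.T, rec.P)] = abs(s - rec.S) / rec.S
        outlier = rels.pop((318.0, 24.0))
        assert outlier < 0.02
        assert max(rels.values()) < 0.0035

    def test_properties(self, solute, solvent):
        assert solute.M == 450.9 and solute.Tm == 426.1
        assert solute.dHm == pytest.approx(60238.0)
        assert solute.Pc == pytest.approx(18.7565e5)  # printed in bar
        assert solvent.rho_c == pytest.approx(467.6)

    def test_sublimation_pressure_interpolation(self, solute):
        assert solute.sublimation_pressure(318.0) == pytest.approx(0.0089)
        # between nodes: ln P linear in 1/T
        t = 313.0
        inv = 1.0 / t
        lo, hi = 1.0 / 308.0, 1.0 / 318.0
        w = (inv - lo) / (hi - lo)
        expected = math.exp((1 - w) * math.log(0.0034) + w * math.log(0.0089))
        assert solute.sublimation_pressure(t) == pytest.approx(expected,
                                                               rel=1e-12)
        with pytest.raises(ValueError):
            solute.sublimation_pressure(350.0)


class TestIo:
    def test_save_load_round_trip(self, dataset, solute, solvent, tmp_path):
        path = tmp_path / "ds.csv"
        sc.save_dataset(dataset, path)
        back = sc.load_dataset(path, solute=solute, solvent=solvent)
        assert len(back) == len(dataset)
        for a, b in zip(dataset, back):
            assert a.T == b.T and a.P == b.P and a.rho1 == b.rho1
            assert a.y2 == pytest.approx(b.y2, rel=1e-15)
            assert a.S == pytest.approx(b.S, rel=1e-15)

    def test_extra_columns_preserved(self, tmp_path, solute, solvent):
        path = tmp_path / "ds.csv"
        path.write_text("T_K,P_MPa,rho_kg_m3,y2,note\n308,12,769,8.14e-6,a\n"
                        "308,15,817,1.27e-5,b\n")
        ds = sc.load_dataset(path)
        assert list(ds.extra["note"]) == ["a", "b"]
        out = tmp_path / "out.csv"
        sc.save_dataset(ds, out)
        assert "note" in out.read_text().splitlines()[0]

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        with pytest.raises(DataValidationError, match="no records"):
            sc.load_dataset(path)

    def test_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("T_K,P_MPa,y2\n308,12,8e-6\n")
        with pytest.raises(DataValidationError, match="rho_kg_m3"):
            sc.load_dataset(path)

    def test_non_numeric_cell_reports_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("T_K,P_MPa,rho_kg_m3,y2\n308,12,769,8.14e-6\n"
                        "308,15,oops,1.2e-5\n")
        with pytest.raises(DataValidationError, match="line 3"):
            sc.load_dataset(path)

    def test_duplicate_tp(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("T_K,P_MPa,rho_kg_m3,y2\n308,12,769,8.14e-6\n"
                        "308,12,769,8.15e-6\n")
        with pytest.raises(DataValidationError, match="duplicate"):
            sc.load_dataset(path)

    def test_s_only_requires_properties(self, tmp_path, solute, solvent):
        path = tmp_path / "s_only.csv"
        path.write_text("T_K,P_MPa,rho_kg_m3,S_g_L\n328,27,829,0.1920\n")
        with pytest.raises(DataValidationError):
            sc.load_dataset(path)
        ds = sc.load_dataset(path, solute=solute, solvent=solvent)
        assert ds.records[0].y2 == pytest.approx(22.6e-6, rel=1e-3)


class TestSynthetic:
    CONDS = [(308.0, 12.0, 769.0), (308.0, 27.0, 914.0),
             (338.0, 12.0, 388.0), (338.0, 27.0, 783.0)]

    def test_zero_noise_equals_model(self, solute, solvent):
        from conftest import TABLE4_PARAMS

        spec = sc.SyntheticSpec("chrastil", TABLE4_PARAMS["chrastil"],
                                self.CONDS, noise_cv=0.0, seed=1)
        ds = sc.generate_synthetic(spec)
        model = sc.get_model("chrastil")
        for rec in ds:
            expected = float(model.evaluate(
                np.array(TABLE4_PARAMS["chrastil"]), np.array([rec.T]),
                np.array([rec.P]), np.array([rec.rho1]), solute, solvent)[0])
            assert rec.y2 == expected

    def test_determinism(self):
        from conftest import TABLE4_PARAMS

        spec = sc.SyntheticSpec("chrastil", TABLE4_PARAMS["chrastil"],
                                self.CONDS, noise_cv=0.1, seed=42)
        a = sc.generate_synthetic(spec)
        b = sc.generate_synthetic(spec)
        assert all(x.y2 == y.y2 for x, y in zip(a, b))

    def test_noise_changes_values(self):
        from conftest import TABLE4_PARAMS

        noisy = sc.SyntheticSpec("chrastil", TABLE4_PARAMS["chrastil"],
                                 self.CONDS, noise_cv=0.1, seed=42)
        clean = sc.SyntheticSpec("chrastil", TABLE4_PARAMS["chrastil"],
                                 self.CONDS, noise_cv=0.0, seed=42)
        a, b = sc.generate_synthetic(noisy), sc.generate_synthetic(clean)
        assert any(x.y2 != y.y2 for x, y in zip(a, b))

    def test_validation(self):
        with pytest.raises(DataValidationError):
            sc.SyntheticSpec("chrastil", (1.0, 2.0, 3.0), self.CONDS,
                             noise_cv=-0.1, seed=1)
        with pytest.raises(KeyError):
            sc.generate_synthetic(sc.SyntheticSpec(
                "no_such_model", (1.0,), self.CONDS, 0.0, 1))

    def test_record_invariants(self):
        with pytest.raises(DataValidationError):
            sc.SolubilityRecord(T=-1.0, P=12.0, rho1=769.0, y2=8e-6)
        with pytest.raises(DataValidationError):
            sc.SolubilityRecord(T=308.0, P=12.0, rho1=769.0, y2=1.5)
        with pytest.raises(DataValidationError):
            sc.SolubilityDataset([])
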