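"""Per-area correction of instrument logs: flux conservation and parsing."""

import io

import numpy as np
import pytest

from leafgasket import (
    GasExchangeRecord,
    correct_log,
    correct_record,
    generate_log,
    iwue,
    parse_log,
    width_based_area,
)
from leafgasket.errors import (
    InvalidAreaError,
    JoinError,
    OversizedAreaError,
    SchemaError,
    UndefinedIWUEError,
)


def record(pn=10.0, gs=0.2, s=2.0, **kw):
    return GasExchangeRecord(assumed_area_S=s, photo_PN=pn, cond_gs=gs, **kw)


class TestCorrectRecord:
    def test_full_coverage_is_identity(self):
        corr = correct_record(record(), 2.0)
        assert corr.correction_factor == 1.0
        assert corr.photo_PN == 10.0
        assert corr.cond_gs == 0.2

    def test_partial_coverage_rescales_rates(self):
        al = 1.4840967955403666  # enclosed area for a 1 cm leaf in the 2 cm^2 gasket
        corr = correct_record(record(trans_E=3.0, Ci=280.0, PhiPSII=0.7), al)
        factor = 2.0 / al
        assert corr.photo_PN == pytest.approx(10.0 * factor, rel=1e-12)
        assert corr.cond_gs == pytest.approx(0.2 * factor, rel=1e-12)
        assert corr.trans_E == pytest.approx(3.0 * factor, rel=1e-12)
        # iWUE is invariant; mole fractions and fluorescence pass through
        assert corr.iWUE == pytest.approx(50.0, rel=1e-12)
        assert corr.Ci == 280.0 and corr.ci_uncorrected
        assert corr.PhiPSII == 0.7

    def test_flux_conservation(self):
        for al in (0.3, 0.9, 1.7, 2.0):
            corr = correct_record(record(), al)
            assert corr.photo_PN * al == pytest.approx(10.0 * 2.0, rel=1e-9)
            assert corr.cond_gs * al == pytest.approx(0.2 * 2.0, rel=1e-9)

    def test_correction_factor_monotone_in_area(self):
        factors = [correct_record(record(), a).correction_factor
                   for a in np.linspace(0.2, 2.0, 30)]
        assert all(a > b for a, b in zip(factors, factors[1:]))

    def test_inverse_factor_recovers_original(self):
        # rescaling back by A_L/S restores the rates to within an ulp
        corr = correct_record(record(), 1.3)
        assert corr.photo_PN * (1.3 / 2.0) == pytest.approx(10.0, rel=1e-15)
        assert corr.cond_gs * (1.3 / 2.0) == pytest.approx(0.2, rel=1e-15)

    def test_invalid_and_oversized_area(self):
        with pytest.raises(InvalidAreaError):
            correct_record(record(), 0.0)
        with pytest.raises(OversizedAreaError):
            correct_record(record(), 2.5)


class TestIWUE:
    def test_ratio(self):
        assert iwue(10.0, 0.2) == 50.0
        assert iwue(0.0, 0.2) == 0.0

    def test_zero_conductance_undefined(self):
        with pytest.raises(UndefinedIWUEError):
            iwue(10.0, 0.0)

    def test_invariance_under_correction(self):
        r = record(pn=13.7, gs=0.31)
        for al in (0.4, 1.1, 1.9):
            corr = correct_record(r, al)
            assert corr.iWUE == pytest.approx(iwue(r.photo_PN, r.cond_gs), rel=1e-12)


class TestParseLog:
    def test_round_trip_synthetic_log(self, gasket):
        bundle = generate_log(10, gasket, seed=3)
        records = parse_log(io.StringIO(bundle.log_text))
        assert len(records) == 10
        # spot-check against the raw text
        first_data = bundle.log_text.splitlines()[3].split("\t")
        assert records[0].photo_PN == float(first_data[3])
        assert records[0].cond_gs == float(first_data[4])
        assert records[0].label == first_data[8]

    def test_banner_lines_tolerated(self):
        text = "junk line\nanother banner\nArea\tPhoto\tCond\n2.0\t10\t0.2\n"
        (rec,) = parse_log(io.StringIO(text))
        assert rec.photo_PN == 10.0
        assert rec.trans_E is None and rec.PhiPSII is None

    def test_comma_dialect(self):
        text = "Area,Photo,Cond\n2.0,10,0.2\n"
        (rec,) = parse_log(io.StringIO(text))
        assert rec.cond_gs == 0.2

    def test_missing_mandatory_column_raises(self):
        text = "Area\tPhoto\n2.0\t10\n"
        with pytest.raises(SchemaError):
            parse_log(io.StringIO(text))

    def test_custom_column_map(self):
        text = "S\tA\tgsw\n2.0\t10\t0.2\n"
        (rec,) = parse_log(
            io.StringIO(text), column_map={"area": "S", "photo": "A", "cond": "gsw"}
        )
        assert rec.photo_PN == 10.0


class TestCorrectLog:
    def test_identity_when_leaf_fills_gasket(self, gasket, tmp_path):
        bundle = generate_log(4, gasket, seed=2)
        log = tmp_path / "log.tsv"
        log.write_text(bundle.log_text)
        table, report = correct_log(log, gasket.area_AG, gasket=gasket)
        assert (table["corr_factor"] == 1.0).all()
        assert np.allclose(table["Photo_corr"], table["Photo"])
        assert report["uncorrected_error_percent"]["max"] == pytest.approx(0.0)

    def test_half_area_doubles_rates(self, gasket, tmp_path):
        bundle = generate_log(4, gasket, seed=2)
        log = tmp_path / "log.tsv"
        log.write_text(bundle.log_text)
        table, _ = correct_log(log, gasket.area_AG / 2, gasket=gasket)
        assert np.allclose(table["Photo_corr"], 2.0 * table["Photo"])
        assert np.allclose(table["Cond_corr"], 2.0 * table["Cond"])
        assert np.allclose(table["Trmmol_corr"], 2.0 * table["Trmmol"])

    def test_annotation_join_by_label(self, gasket, tmp_path):
        al = [1.0, 1.2, 1.5]
        bundle = generate_log(3, gasket, seed=4, al_values=al)
        log = tmp_path / "log.tsv"
        ann = tmp_path / "areas.csv"
        log.write_text(bundle.log_text)
        ann.write_text(bundle.annotation_text)
        table, _ = correct_log(log, ann, gasket=gasket)
        assert np.allclose(table["AL_cm2"], al)
        assert np.allclose(table["corr_factor"], gasket.area_AG / np.array(al))

    def test_width_annotation_converted_through_geometry(self, gasket, tmp_path):
        bundle = generate_log(2, gasket, seed=4)
        log = tmp_path / "log.tsv"
        ann = tmp_path / "widths.csv"
        log.write_text(bundle.log_text)
        ann.write_text("label,width_cm\nleaf001,1.0\nleaf002,0.5\n")
        table, _ = correct_log(log, ann, gasket=gasket)
        expected = [width_based_area(w, gasket).enclosed_area_wAL for w in (1.0, 0.5)]
        assert np.allclose(table["AL_cm2"], expected)

    def test_unmatched_label_raises_join_error(self, gasket, tmp_path):
        bundle = generate_log(2, gasket, seed=4)
        log = tmp_path / "log.tsv"
        ann = tmp_path / "areas.csv"
        log.write_text(bundle.log_text)
        ann.write_text("label,AL_cm2\nleaf001,1.0\nnosuch,1.0\n")
        with pytest.raises(JoinError) as err:
            correct_log(log, ann, gasket=gasket)
        assert "nosuch" in str(err.value)

    def test_flux_conserved_on_every_row(self, gasket, tmp_path):
        rng = np.random.default_rng(13)
        al = rng.uniform(0.5, 2.0, 8)
        bundle = generate_log(8, gasket, seed=13, al_values=al)
        log = tmp_path / "log.tsv"
        ann = tmp_path / "areas.csv"
        log.write_text(bundle.log_text)
        ann.write_text(bundle.annotation_text)
        table, _ = correct_log(log, ann, gasket=gasket)
        for col in ("Photo", "Cond", "Trmmol"):
            assert np.allclose(
                table[f"{col}_corr"] * table["AL_cm2"],
                table[col] * table["Area"],
                rtol=1e-9,
            )

    def test_output_written_and_source_preserved(self, gasket, tmp_path):
        bundle = generate_log(3, gasket, seed=1)
        log = tmp_path / "log.tsv"
        log.write_text(bundle.log_text)
        out = tmp_path / "corrected.tsv"
        correct_log(log, 1.0, gasket=gasket, out_path=out)
        assert out.exists()
        assert log.read_text() == bundle.log_text
        with pytest.raises(InvalidAreaError):
            correct_log(log, 1.0, gasket=gasket, out_path=log)
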