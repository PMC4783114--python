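"""Surrogate-standard quantification and class profiles."""

import numpy as np
import pandas as pd
import pytest

from gastrodia_ms.quant import (
    QUANT_CLASSES,
    SurrogateMap,
    class_profile,
    quantify,
    quantify_table,
)
from gastrodia_ms.validation import CalibrationModel

PARISHIN_MODEL = CalibrationModel(
    "parishin", slope=315580, intercept=-7052.4, r2=0.9999,
    range_low=40.66, range_high=203.30,
)
GASTRODIN_MODEL = CalibrationModel(
    "gastrodin", slope=79899, intercept=-1108.1, r2=0.9999,
    range_low=8.89, range_high=44.48,
)
MODELS = {
    "parishin": PARISHIN_MODEL,
    "gastrodin": GASTRODIN_MODEL,
    "parishin E": PARISHIN_MODEL,
    "parishin B": PARISHIN_MODEL,
}


class TestQuantify:
    def test_inverts_printed_regression(self):
        area = 315580 * 50 - 7052.4
        conc, extrapolated = quantify(area, PARISHIN_MODEL)
        assert conc == pytest.approx(50.0)
        assert not extrapolated

    def test_area_equal_intercept_gives_zero(self):
        conc, _ = quantify(PARISHIN_MODEL.intercept, PARISHIN_MODEL)
        assert conc == pytest.approx(0.0)

    def test_outside_linear_range_flagged(self):
        area = PARISHIN_MODEL.response(300.0)
        conc, extrapolated = quantify(area, PARISHIN_MODEL)
        assert conc == pytest.approx(300.0) and extrapolated

    def test_round_trip_identity(self):
        for x in np.geomspace(0.01, 500, 20):
            conc, _ = quantify(PARISHIN_MODEL.response(x), PARISHIN_MODEL)
            assert conc == pytest.approx(x, rel=1e-9)

    def test_zero_slope_rejected(self):
        flat = CalibrationModel("flat", slope=0.0, intercept=1.0, r2=0.5)
        with pytest.raises(ValueError):
            quantify(100.0, flat)


class TestSurrogateMap:
    def test_resolution_rules(self):
        smap = SurrogateMap(MODELS)
        assert smap.standard_for("parishin", "parishin derivative") == "parishin"
        assert smap.standard_for("di-substituted parishin", "parishin derivative") == "parishin B"
        assert smap.standard_for("methoxy parishin", "parishin derivative") == "parishin"
        assert smap.standard_for("uridine", "nucleoside") == "gastrodin"
        assert smap.standard_for("tyrosine", "amino acid") == "gastrodin"

    def test_missing_standard_raises(self):
        smap = SurrogateMap({"gastrodin": GASTRODIN_MODEL})
        with pytest.raises(KeyError):
            smap.standard_for("parishin", "parishin derivative")


class TestClassProfile:
    def test_single_compound_single_class(self):
        q = pd.DataFrame(
            [{"sample": "s1", "compound": "parishin", "compound_class": "parishin derivative",
              "concentration": 10.0}]
        )
        prof = class_profile(q)
        assert prof.loc["s1", "parishin derivative"] == 10.0
        assert prof.loc["s1"].drop("parishin derivative").sum() == 0.0
        assert list(prof.columns) == list(QUANT_CLASSES)

    def test_absent_compound_contributes_zero(self):
        # mirrors a cultivar in which gastrodin is not detected
        q = pd.DataFrame(
            [
                {"sample": "shanxi-red", "compound": "parishin",
                 "compound_class": "parishin derivative", "concentration": 5.0},
                {"sample": "other", "compound": "gastrodin",
                 "compound_class": "gastrodin", "concentration": 2.0},
            ]
        )
        prof = class_profile(q)
        assert prof.loc["shanxi-red", "gastrodin"] == 0.0
        assert prof.loc["other", "gastrodin"] == 2.0

    def test_permutation_invariance(self):
        rows = [
            {"sample": "s", "compound": f"c{i}", "compound_class": "amino acid",
             "concentration": float(i)}
            for i in range(5)
        ]
        a = class_profile(pd.DataFrame(rows))
        b = class_profile(pd.DataFrame(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_unknown_class_rejected(self):
        q = pd.DataFrame(
            [{"sample": "s", "compound": "x", "compound_class": "mystery",
              "concentration": 1.0}]
        )
        with pytest.raises(ValueError):
            class_profile(q)


class TestQuantifyTable:
    def test_bookkeeping_recovers_known_sums(self):
        rng = np.random.default_rng(2)
        class_of = {"parishin": "parishin derivative",
                    "methoxy parishin": "parishin derivative",
                    "gastrodin": "gastrodin"}
        rows, truth = [], {}
        for sample in ("s1", "s2"):
            total = 0.0
            for compound in class_of:
                conc = float(rng.uniform(45, 150))
                model = SurrogateMap(MODELS).model_for(compound, class_of[compound])
                rows.append({"sample": sample, "compound": compound,
                             "area": model.response(conc)})
                if class_of[compound] == "parishin derivative":
                    total += conc
            truth[sample] = total
        quantified = quantify_table(pd.DataFrame(rows), SurrogateMap(MODELS), class_of)
        prof = class_profile(quantified)
        for sample, expected in truth.items():
            assert prof.loc[sample, "parishin derivative"] == pytest.approx(expected)

    def test_semi_quantitative_flag_and_standard_column(self):
        class_of = {"methoxy parishin": "parishin derivative", "gastrodin": "gastrodin"}
        rows = pd.DataFrame(
            [{"sample": "s", "compound": "methoxy parishin", "area": 1e6},
             {"sample": "s", "compound": "gastrodin", "area": 1e6}]
        )
        q = quantify_table(rows, SurrogateMap(MODELS), class_of)
        by_compound = q.set_index("compound")
        assert by_compound.loc["methoxy parishin", "semi_quantitative"]
        assert by_compound.loc["methoxy parishin", "standard"] == "parishin"
        assert not by_compound.loc["gastrodin", "semi_quantitative"]

    def test_unregistered_compound_raises(self):
        rows = pd.DataFrame([{"sample": "s", "compound": "novel", "area": 1.0}])
        with pytest.raises(KeyError):
            quantify_table(rows, SurrogateMap(MODELS), {})
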