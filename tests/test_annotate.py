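"""Precursor matching, loss-path search and dataset annotation."""

import itertools

import pytest

from gastrodia_ms.annotate import (
    H2_MASS,
    NEUTRAL_LOSSES,
    AnnotateConfig,
    annotate_dataset,
    explain_fragments,
    match_precursor,
)
from gastrodia_ms.chemcore import get_adduct, ion_mz
from gastrodia_ms.spectra_io import FragmentPeak, Spectrum


def _spectrum(mz, polarity=-1, frags=(), rt=None):
    return Spectrum(
        "s", mz, polarity, rt_min=rt, fragments=tuple(FragmentPeak(f, 100.0) for f in frags)
    )


class TestMatchPrecursor:
    def test_parishin_printed_precursor(self, candidates):
        hits = match_precursor(_spectrum(995.3034), candidates)
        assert hits and hits[0].candidate.name == "parishin"
        assert hits[0].adduct.name == "[M-H]-"
        assert hits[0].ppm == pytest.approx(-0.4, abs=0.1)

    def test_formate_adduct_hit(self, candidates):
        hits = match_precursor(_spectrum(787.2303), candidates)
        assert hits[0].candidate.name == "methyl di-substituted parishin"
        assert hits[0].adduct.name == "[M+HCOO]-"

    def test_tight_gate_empty(self, candidates):
        assert match_precursor(_spectrum(995.3034), candidates, gate_ppm=0.1) == []

    def test_gate_monotonicity(self, candidates):
        """Hits at a small gate are a subset of hits at any larger gate."""
        spectrum = _spectrum(727.2083)
        for small, large in [(1, 2), (2, 5), (5, 20)]:
            inner = {
                (h.candidate.name, h.adduct.name)
                for h in match_precursor(spectrum, candidates, gate_ppm=small)
            }
            outer = {
                (h.candidate.name, h.adduct.name)
                for h in match_precursor(spectrum, candidates, gate_ppm=large)
            }
            assert inner <= outer

    def test_polarity_filters_adducts(self, candidates):
        for hit in match_precursor(_spectrum(414.1331, polarity=+1), candidates):
            assert hit.adduct.polarity == +1

    def test_no_candidates_is_empty_not_error(self):
        assert match_precursor(_spectrum(500.0), []) == []


def brute_force_paths(candidate, adduct, fragment_mz, max_depth, tol):
    """Independent oracle: exhaustively enumerate loss multisets."""
    adduct = get_adduct(adduct)
    pool = []
    for loss in NEUTRAL_LOSSES.values():
        cap = loss.applicability(candidate)
        if loss.name == "HCOOH" and adduct.name == "[M+HCOO]-":
            cap = max(cap, 1)
        pool.extend([loss.name] * min(cap, max_depth))
    precursor = ion_mz(candidate.mass, adduct)
    found = []
    for depth in range(0, max_depth + 1):
        for combo in set(itertools.combinations(sorted(pool), depth)):
            total = sum(NEUTRAL_LOSSES[n].mass for n in combo)
            for h2 in ((False, True) if adduct.polarity < 0 else (False,)):
                predicted = precursor - total - (H2_MASS if h2 else 0.0)
                if abs(fragment_mz - predicted) <= tol:
                    found.append((tuple(sorted(combo)), h2, predicted))
    return found


class TestExplainFragments:
    def test_parishin_b_gastrodinyl_loss(self, by_name):
        cand = by_name["di-substituted parishin"]
        spec = _spectrum(727.2091, frags=[459.1144])
        (ann,) = explain_fragments(spec, cand, "[M-H]-")
        assert ann.losses == ("gastrodinyl",)
        assert abs(ann.residual) <= 0.01
        assert ann.path_string(get_adduct("[M-H]-")) == "[M-H-268]-"

    def test_parishin_deep_path(self, by_name):
        cand = by_name["parishin"]
        frag = 995.30380 - 2 * 268.09469 - 18.01056 - 43.98983
        spec = _spectrum(995.3038, frags=[frag])
        (ann,) = explain_fragments(spec, cand, "[M-H]-")
        assert sorted(ann.losses) == ["CO2", "H2O", "gastrodinyl", "gastrodinyl"]

    def test_precursor_itself_gets_empty_path(self, by_name):
        cand = by_name["parishin"]
        spec = _spectrum(995.3038, frags=[995.3038])
        (ann,) = explain_fragments(spec, cand, "[M-H]-")
        assert ann.explained and ann.losses == ()

    def test_unexplained_fragment_returned_with_empty_path(self, by_name):
        spec = _spectrum(995.3038, frags=[500.0])
        (ann,) = explain_fragments(spec, by_name["parishin"], "[M-H]-")
        assert not ann.explained and ann.losses == ()

    def test_unlicensed_losses_never_used(self, by_name):
        # citric acid licenses only water/CO2; a 106 Da loss must stay unexplained
        cand = by_name["citric acid"]
        spec = _spectrum(191.0197, frags=[191.0197 - 106.04186])
        (ann,) = explain_fragments(spec, cand, "[M-H]-")
        assert not ann.explained

    @pytest.mark.parametrize("depth", [1, 2, 3])
    def test_matches_brute_force_oracle(self, by_name, depth):
        """Search equals exhaustive enumeration on small instances."""
        cases = [
            ("di-substituted parishin", "[M-H]-", [459.114, 441.104, 397.115, 369.119]),
            ("mono-substituted parishin glucoside", "[M-H]-", [459.114, 441.104, 397.114]),
            ("methyl di-substituted parishin", "[M+HCOO]-", [741.225, 473.130]),
        ]
        for name, adduct, frags in cases:
            cand = by_name[name]
            spec = _spectrum(ion_mz(cand.mass, adduct), frags=frags)
            anns = explain_fragments(spec, cand, adduct, max_depth=depth)
            for ann in anns:
                oracle = brute_force_paths(cand, adduct, ann.mz, depth, 0.01)
                if not oracle:
                    assert not ann.explained
                else:
                    best = min(oracle, key=lambda o: (len(o[0]), o[1], abs(ann.mz - o[2]), o[0]))
                    assert (ann.losses, ann.h2_deficit) == (best[0], best[1])

    def test_score_monotone_in_tolerance(self, by_name, table5_spectra):
        cand = by_name["parishin"]
        spec = next(s for s in table5_spectra if s.identifier.startswith("peak25"))
        explained = []
        for tol in (0.001, 0.01, 0.05, 0.2):
            anns = explain_fragments(spec, cand, "[M-H]-", frag_tol_da=tol)
            explained.append(sum(a.explained for a in anns))
        assert explained == sorted(explained)

    def test_bad_parameters(self, by_name):
        spec = _spectrum(995.3038)
        with pytest.raises(ValueError):
            explain_fragments(spec, by_name["parishin"], "[M-H]-", max_depth=0)
        with pytest.raises(ValueError):
            explain_fragments(spec, by_name["parishin"], "[M-H]-", frag_tol_da=0)


class TestAnnotateDataset:
    def test_full_printed_table_is_annotated(self, table5_spectra, candidates):
        results, summary = annotate_dataset(table5_spectra, candidates)
        assert summary["n_spectra"] == summary["n_annotated"] == 31
        assert summary["per_class"]["parishin derivative"] == 21

    def test_top_hits_match_reference_identities(
        self, table5_spectra, candidates, table5_reference
    ):
        results, _ = annotate_dataset(table5_spectra, candidates)
        expected = {f"peak{int(r['peak']):02d}": r["candidate"] for r in table5_reference}
        for res in results:
            peak = res.spectrum_id.split()[0]
            assert res.candidate.name == expected[peak], peak

    def test_nominal_fallback_flags_low_trust_rows(self, table5_spectra, candidates):
        results, summary = annotate_dataset(table5_spectra, candidates)
        nominal = {r.spectrum_id.split()[0] for r in results if r.confidence == "nominal"}
        assert nominal == {"peak02", "peak03", "peak05", "peak07", "peak08"}
        assert summary["n_nominal"] == 5

    def test_no_fallback_means_strict_gate_only(self, table5_spectra, candidates):
        _, summary = annotate_dataset(
            table5_spectra, candidates, AnnotateConfig(nominal_fallback=False)
        )
        assert summary["n_annotated"] == 26

    def test_isomer_labels_follow_rt_order(self, table5_spectra, candidates):
        results, _ = annotate_dataset(table5_spectra, candidates)
        labels = {r.spectrum_id.split()[0]: r.label for r in results}
        assert labels["peak10"] == "mono-substituted parishin"
        assert labels["peak11"] == "mono-substituted parishin isomer-2"
        assert labels["peak16"] == "di-substituted parishin"
        assert labels["peak17"] == "di-substituted parishin isomer-2"
        assert labels["peak20"] == "di-substituted parishin isomer-3"

    def test_empty_dataset(self, candidates):
        results, summary = annotate_dataset([], candidates)
        assert results == [] and summary["n_annotated"] == 0

    def test_deterministic(self, table5_spectra, candidates):
        r1, _ = annotate_dataset(table5_spectra, candidates)
        r2, _ = annotate_dataset(table5_spectra, candidates)
        assert [(a.spectrum_id, a.candidate.name, a.label) for a in r1] == [
            (a.spectrum_id, a.candidate.name, a.label) for a in r2
        ]


class TestAssignmentRegression:
    def test_every_usable_printed_assignment_is_recovered(
        self, table5_assignments, by_name
    ):
        """Printed bracket assignments come back as the winning loss path."""
        checked = 0
        for row in table5_assignments:
            if row["include"] != "1":
                continue
            cand = by_name[row["candidate"]]
            adduct = get_adduct(row["adduct"])
            losses = tuple(sorted(row["losses"].split(";"))) if row["losses"] else ()
            h2 = row["h2"] == "1"
            expected_mz = (
                ion_mz(cand.mass, adduct)
                - sum(NEUTRAL_LOSSES[n].mass for n in losses)
                - (H2_MASS if h2 else 0.0)
            )
            spec = Spectrum(
                "frag", ion_mz(cand.mass, adduct), adduct.polarity,
                fragments=(FragmentPeak(expected_mz, 100.0),),
            )
            (ann,) = explain_fragments(spec, cand, adduct)
            assert ann.explained, row["printed_assignment"]
            assert ann.losses == losses, row["printed_assignment"]
            assert ann.h2_deficit == h2
            assert abs(ann.residual) <= 0.01
            checked += 1
        assert checked >= 60
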