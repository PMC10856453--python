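"""Suspect matching, CF2 series detection, spectral/class scoring, isomer
reasoning, and the confidence-level decision list."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfascreen.chem import CF2_EXACT_MASS, adduct_mz, monoisotopic_mass, parse_formula
from pfascreen.io import Feature, Ms2Spectrum, SuspectEntry
from pfascreen.annotate import (
    Evidence,
    assign_confidence,
    class_fragment_score,
    detect_series,
    flag_branched_isomer,
    match_suspects,
    spectral_similarity,
)


def _feat(fid, mz, rt=1.0):
    return Feature(fid, mz, rt, {})


class TestMatchSuspects:
    PFOS = SuspectEntry("Perfluoro-n-octanesulfonate", "C8HF17O3S", "PFSA")

    def test_printed_mass_error_recovered(self):
        hits = match_suspects(498.9321, [self.PFOS], tol_ppm=5)
        assert len(hits) == 1
        assert hits[0][1] == pytest.approx(3.77, abs=0.01)

    def test_exact_mass_gives_zero_delta(self):
        theo = adduct_mz(self.PFOS.neutral_mass)
        hits = match_suspects(theo, [self.PFOS])
        assert hits[0][1] == 0.0

    def test_outside_tolerance_no_hit(self):
        theo = adduct_mz(self.PFOS.neutral_mass)
        assert match_suspects(theo * (1 + 10e-6), [self.PFOS], tol_ppm=5) == []

    def test_empty_library_warns(self):
        with pytest.warns(UserWarning):
            assert match_suspects(400.0, []) == []

    def test_ties_broken_by_name(self):
        a = SuspectEntry("B-isomer", "C8HF17O3S")
        b = SuspectEntry("A-isomer", "C8HF17O3S")
        hits = match_suspects(adduct_mz(a.neutral_mass), [a, b])
        assert [h[0].name for h in hits] == ["A-isomer", "B-isomer"]


def brute_force_longest_chain(feats, spacing, tol_ppm, max_step=3, rt_increase=True):
    """O(n^2) DP longest-chain finder, independent of the greedy extractor."""
    feats = sorted(feats, key=lambda f: (f.mz, f.feature_id))
    n = len(feats)
    best = [1] * n
    prev = [-1] * n
    for j in range(n):
        for i in range(j):
            gap = feats[j].mz - feats[i].mz
            k = round(gap / spacing) if gap > 0 else 0
            ok = (
                1 <= k <= max_step
                and abs(gap - k * spacing) <= tol_ppm * 1e-6 * feats[j].mz
                and (not rt_increase or feats[j].rt > feats[i].rt)
            )
            if ok and best[i] + 1 > best[j]:
                best[j] = best[i] + 1
                prev[j] = i
    end = int(np.argmax(best))
    chain = []
    while end != -1:
        chain.append(feats[end].feature_id)
        end = prev[end]
    return chain[::-1]


class TestDetectSeries:
    def _pfca_chain(self):
        # C5-C7 perfluorocarboxylates: one CF2 apart, RT increasing with chain length
        masses = [
            adduct_mz(monoisotopic_mass(parse_formula(f)))
            for f in ["C5HF9O2", "C6HF11O2", "C7HF13O2"]
        ]
        assert masses[0] == pytest.approx(262.9760, abs=1e-4)
        return [
            _feat(f"F{i}", m, rt=5.0 + 2 * i) for i, m in enumerate(masses)
        ]

    def test_three_member_pfca_series(self):
        series = detect_series(self._pfca_chain())
        assert len(series) == 1
        assert series[0].member_feature_ids == ["F0", "F1", "F2"]
        assert series[0].n_cf2_steps == [1, 1]
        assert series[0].rt_monotone

    def test_rt_gate_blocks_shuffled_chain(self):
        feats = self._pfca_chain()
        feats[1].rt = 20.0  # middle member elutes last
        assert detect_series(feats, require_rt_increase=True) == []

    def test_non_homologous_masses_no_series(self):
        rng = np.random.default_rng(5)
        feats = [_feat(f"F{i}", float(rng.uniform(200, 900)), float(rng.uniform(0, 15)))
                 for i in range(30)]
        series = detect_series(feats)
        for s in series:  # verify against the definition directly
            mzs = {f.feature_id: f.mz for f in feats}
            for a, b, k in zip(s.member_feature_ids, s.member_feature_ids[1:], s.n_cf2_steps):
                gap = mzs[b] - mzs[a]
                assert abs(gap - k * CF2_EXACT_MASS) <= 5e-6 * mzs[b]

    @pytest.mark.parametrize("k", [3, 5, 8])
    def test_arithmetic_chain_recovered_whole(self, k):
        feats = [
            _feat(f"F{i}", 250.0 + i * CF2_EXACT_MASS, rt=3.0 + i) for i in range(k)
        ]
        series = detect_series(feats)
        assert len(series) == 1
        assert series[0].member_feature_ids == [f"F{i}" for i in range(k)]

    def test_longest_chain_matches_brute_force(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(2, 60))
            feats = []
            base = float(rng.uniform(200, 400))
            for i in range(n):
                if rng.uniform() < 0.5:  # homologue-ish
                    mz = base + int(rng.integers(0, 8)) * CF2_EXACT_MASS
                    mz *= 1 + float(rng.normal(0, 1e-6))
                else:
                    mz = float(rng.uniform(200, 900))
                feats.append(_feat(f"F{i}", mz, float(rng.uniform(0, 15))))
            series = detect_series(feats, min_members=2)
            expected = brute_force_longest_chain(feats, CF2_EXACT_MASS, 5.0)
            got = series[0].member_feature_ids if series else []
            assert len(got) == len(expected)


class TestSpectralSimilarity:
    def test_identical_spectra_score_100(self):
        s = Ms2Spectrum("a", 400.0, [(100.0, 1.0), (200.0, 5.0), (300.0, 2.0)])
        assert spectral_similarity(s, s) == pytest.approx(100.0)

    def test_disjoint_spectra_score_0(self):
        a = Ms2Spectrum("a", 400.0, [(100.0, 1.0), (150.0, 2.0)])
        b = Ms2Spectrum("b", 400.0, [(200.0, 1.0), (250.0, 2.0)])
        assert spectral_similarity(a, b) == 0.0

    def test_hand_cosine_on_perturbed_peak(self):
        # one of three peaks doubled: cosine computed by hand on the vectors
        a = Ms2Spectrum("a", 400.0, [(100.0, 1.0), (200.0, 2.0), (300.0, 3.0)])
        b = Ms2Spectrum("b", 400.0, [(100.0, 1.0), (200.0, 4.0), (300.0, 3.0)])
        va, vb = np.array([1.0, 2.0, 3.0]), np.array([1.0, 4.0, 3.0])
        expected = 100 * float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))
        assert spectral_similarity(a, b) == pytest.approx(expected, abs=1e-9)

    def test_symmetry(self):
        a = Ms2Spectrum("a", 400.0, [(100.0, 1.0), (200.0, 2.0)])
        b = Ms2Spectrum("b", 400.0, [(100.003, 3.0), (250.0, 1.0)])
        assert spectral_similarity(a, b) == pytest.approx(spectral_similarity(b, a))

    def test_agrees_with_matchms_greedy_cosine(self):
        """Independent oracle: matchms CosineGreedy at a matching Da tolerance."""
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import CosineGreedy

        rng = np.random.default_rng(3)
        for _ in range(10):
            na, nb = int(rng.integers(2, 10)), int(rng.integers(2, 10))
            pa = sorted((float(rng.uniform(50, 500)), float(rng.uniform(1, 100)))
                        for _ in range(na))
            pb = sorted((float(rng.uniform(50, 500)), float(rng.uniform(1, 100)))
                        for _ in range(nb))
            a = Ms2Spectrum("a", 600.0, pa)
            b = Ms2Spectrum("b", 600.0, pb)
            ours = spectral_similarity(a, b, frag_tol_ppm=0.0)  # floor 0.01 Th applies
            sa = matchms.Spectrum(mz=np.array([p[0] for p in a.peaks]),
                                  intensities=np.array([p[1] for p in a.peaks]),
                                  metadata={"precursor_mz": 600.0})
            sb = matchms.Spectrum(mz=np.array([p[0] for p in b.peaks]),
                                  intensities=np.array([p[1] for p in b.peaks]),
                                  metadata={"precursor_mz": 600.0})
            theirs = 100 * float(CosineGreedy(tolerance=0.01).pair(sa, sb)["score"])
            assert ours == pytest.approx(theirs, abs=1e-6)

    def test_empty_spectrum_rejected(self):
        a = Ms2Spectrum("a", 400.0, [(100.0, 1.0)])
        b = Ms2Spectrum("b", 400.0, [(100.0, 1.0)])
        b.peaks = []
        with pytest.raises(ValueError):
            spectral_similarity(a, b)


class TestClassFragmentScore:
    PFOS_IONS = [118.232, 168.145, 218.784]

    def test_two_of_three_at_printed_precision(self):
        ms2 = Ms2Spectrum("q", 498.93, [(118.23, 10.0), (168.15, 5.0)])
        frac, n = class_fragment_score(ms2, self.PFOS_IONS)
        assert (frac, n) == (pytest.approx(2 / 3), 2)

    def test_empty_intersection(self):
        ms2 = Ms2Spectrum("q", 498.93, [(50.0, 1.0)])
        assert class_fragment_score(ms2, self.PFOS_IONS) == (0.0, 0)

    def test_all_present(self):
        ms2 = Ms2Spectrum("q", 498.93, [(m, 1.0) for m in self.PFOS_IONS])
        frac, n = class_fragment_score(ms2, self.PFOS_IONS)
        assert (frac, n) == (pytest.approx(1.0), 3)

    def test_diagnostic_ion_counts_once(self):
        ms2 = Ms2Spectrum("q", 498.93, [(118.232, 1.0), (118.233, 1.0)])
        _, n = class_fragment_score(ms2, [118.232])
        assert n == 1


class TestBranchedIsomer:
    def test_branched_vs_linear_sulfonate(self):
        branched = _feat("F49", 498.9319, rt=17.91)
        linear = _feat("F51", 498.9321, rt=18.26)
        tags = flag_branched_isomer([branched, linear], standard_rt=18.26)
        assert tags == {"F49": "branched-candidate", "F51": "linear/confirmed"}

    def test_single_feature_untagged(self):
        assert flag_branched_isomer([_feat("F1", 400.0)], standard_rt=10.0) == {}

    def test_all_earlier_isomers_tagged(self):
        feats = [_feat(f"F{i}", 400.0, rt=rt) for i, rt in enumerate([5.0, 6.0, 8.0])]
        tags = flag_branched_isomer(feats, standard_rt=8.0)
        assert tags["F0"] == tags["F1"] == "branched-candidate"
        assert tags["F2"] == "linear/confirmed"


class TestAssignConfidence:
    def test_standard_plus_fragments_is_cl1(self):
        ev = Evidence(has_ms2=True, standard_match=True, n_diagnostic_matched=2,
                      masslist_hit=True, unambiguous_formula=True)
        level, rationale = assign_confidence(ev)
        assert level == 1 and rationale

    def test_score_above_60_is_cl2(self):
        ev = Evidence(has_ms2=True, spectral_score=60.01)
        assert assign_confidence(ev)[0] == 2

    def test_score_exactly_60_falls_through(self):
        # "higher than 60" is strict: 60.0 fails the CL2 gate
        ev = Evidence(has_ms2=True, spectral_score=60.0, masslist_hit=True,
                      n_diagnostic_matched=1, unambiguous_formula=True)
        assert assign_confidence(ev)[0] == 3
        ev2 = Evidence(has_ms2=True, spectral_score=60.0, unambiguous_formula=True)
        assert assign_confidence(ev2)[0] == 4

    def test_masslist_plus_series_is_cl3(self):
        ev = Evidence(masslist_hit=True, series_member=True)
        assert assign_confidence(ev)[0] == 3

    def test_no_evidence_is_cl5(self):
        assert assign_confidence(Evidence())[0] == 5

    def test_score_without_ms2_is_inconsistent(self):
        with pytest.raises(ValueError, match="inconsistent"):
            assign_confidence(Evidence(has_ms2=False, spectral_score=80.0))

    @settings(deadline=None, max_examples=200)
    @given(
        has_ms2=st.booleans(),
        score=st.one_of(st.none(), st.floats(0, 100)),
        masslist=st.booleans(),
        n_diag=st.integers(0, 5),
        series=st.booleans(),
        formula=st.booleans(),
    )
    def test_adding_a_standard_never_worsens_the_level(
        self, has_ms2, score, masslist, n_diag, series, formula
    ):
        if score is not None and not has_ms2:
            has_ms2 = True
        base = Evidence(has_ms2=has_ms2, standard_match=False, spectral_score=score,
                        masslist_hit=masslist, n_diagnostic_matched=n_diag,
                        series_member=series, unambiguous_formula=formula)
        with_std = Evidence(has_ms2=has_ms2, standard_match=True, spectral_score=score,
                            masslist_hit=masslist, n_diagnostic_matched=n_diag,
                            series_member=series, unambiguous_formula=formula)
        assert assign_confidence(with_std)[0] <= assign_confidence(base)[0]

    @settings(deadline=None, max_examples=200)
    @given(
        score=st.floats(0, 99),
        bump=st.floats(0.01, 40),
        masslist=st.booleans(),
        n_diag=st.integers(0, 5),
    )
    def test_raising_spectral_score_never_worsens_the_level(
        self, score, bump, masslist, n_diag
    ):
        lo = Evidence(has_ms2=True, spectral_score=score, masslist_hit=masslist,
                      n_diagnostic_matched=n_diag, unambiguous_formula=True)
        hi = Evidence(has_ms2=True, spectral_score=min(100.0, score + bump),
                      masslist_hit=masslist, n_diagnostic_matched=n_diag,
                      unambiguous_formula=True)
        assert assign_confidence(hi)[0] <= assign_confidence(lo)[0]
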