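"""The feature-reduction cascade: stage rules, funnel bookkeeping, oracle
equivalence against a brute-force reapplication of the rule definitions."""

import numpy as np
import pytest

from pfascreen.chem import CF2_EXACT_MASS, CF2_NOMINAL_MASS, kendrick
from pfascreen.io import Feature, SampleRecord
from pfascreen.prioritize import (
    FilterConfig,
    blank_ratio_filter,
    build_exclusion_list,
    collapse_replicates,
    exclusion_list_filter,
    intensity_filter,
    kmd_filter,
    run_cascade,
)

SAMPLES = [
    SampleRecord("liver_A01", "liver", "A01", 1),
    SampleRecord("muscle_A01", "muscle", "A01", 1),
    SampleRecord("blank_B1", "blank", None, 1),
]
REAL = ["liver_A01", "muscle_A01"]
BLANK = ["blank_B1"]


def feat(fid, mz=300.0, rt=5.0, liver=0.0, muscle=0.0, blank=0.0, ms2=None):
    return Feature(fid, mz, rt,
                   {"liver_A01": liver, "muscle_A01": muscle, "blank_B1": blank},
                   ms2_id=ms2)


class TestBlankRatio:
    def test_ratio_below_threshold_removed(self):
        f = feat("F1", liver=9e5, blank=1e5)  # ratio 9 < 10
        kept, removed = blank_ratio_filter([f], BLANK, REAL)
        assert removed == [f] and kept == []

    def test_absent_from_blanks_always_kept(self):
        f = feat("F1", liver=5.0, blank=0.0)
        kept, removed = blank_ratio_filter([f], BLANK, REAL)
        assert kept == [f]

    def test_ratio_at_threshold_kept(self):
        f = feat("F1", liver=1e6, blank=1e5)  # ratio exactly 10, not below
        kept, _ = blank_ratio_filter([f], BLANK, REAL)
        assert kept == [f]

    def test_no_blanks_instructs_to_skip(self):
        with pytest.raises(ValueError, match="skip"):
            blank_ratio_filter([feat("F1")], [], REAL)


class TestIntensity:
    def test_strict_boundary(self):
        above = feat("F1", liver=1_000_001.0)
        at = feat("F2", liver=1_000_000.0)
        kept, removed = intensity_filter([above, at], REAL)
        assert kept == [above] and removed == [at]

    def test_blank_area_does_not_count(self):
        f = feat("F1", liver=10.0, blank=5e6)
        _, removed = intensity_filter([f], REAL)
        assert removed == [f]


class TestKmdWindow:
    def test_pfos_like_kept(self):
        f = feat("F1", mz=498.9321)  # kmd ~ -0.036
        kept, _ = kmd_filter([f])
        assert kept == [f]

    def test_boundary_inclusive(self):
        mz_low = (300 - 0.25) * CF2_EXACT_MASS / CF2_NOMINAL_MASS
        f = feat("F1", mz=mz_low)
        assert kendrick(f.mz).kmd == pytest.approx(-0.25, abs=1e-9)
        kept, _ = kmd_filter([f])
        assert kept == [f]

    def test_hydrogen_rich_removed_in_hard_mode(self):
        mz = (300 + 0.30) * CF2_EXACT_MASS / CF2_NOMINAL_MASS
        f = feat("F1", mz=mz)
        _, removed = kmd_filter([f], mode="hard")
        assert removed == [f]

    def test_suspect_hit_rescues_out_of_window(self):
        mz = (300 + 0.30) * CF2_EXACT_MASS / CF2_NOMINAL_MASS
        f = feat("F1", mz=mz)
        kept, _ = kmd_filter([f], mode="or_with_suspect", suspect_hit_ids={"F1"})
        assert kept == [f]
        assert "kmd_rescued_by_suspect" in f.provenance


class TestExclusionList:
    def test_merge_within_tolerance(self):
        f1 = feat("B1", mz=300.0, rt=5.00)
        f2 = feat("B2", mz=300.0 * (1 + 4e-6), rt=5.05)
        entries = build_exclusion_list([f1, f2], mz_tol_ppm=5, rt_tol_min=0.2)
        assert len(entries) == 1

    def test_disjoint_not_merged(self):
        f1 = feat("B1", mz=300.0)
        f2 = feat("B2", mz=300.0 * (1 + 20e-6))
        assert len(build_exclusion_list([f1, f2])) == 2

    def test_empty_blank_set_warns(self):
        with pytest.warns(UserWarning):
            assert build_exclusion_list([]) == []

    def test_filter_removes_matches(self):
        f = feat("F1", mz=300.0, rt=5.0)
        kept, removed = exclusion_list_filter([f], [(300.0, 5.0)])
        assert removed == [f] and kept == []


class TestReplicateCollapse:
    def test_mean_of_duplicate_injections(self):
        samples = [
            SampleRecord("liver_A01_r1", "liver", "A01", 1),
            SampleRecord("liver_A01_r2", "liver", "A01", 2),
        ]
        f = Feature("F1", 300.0, 5.0, {"liver_A01_r1": 10.0, "liver_A01_r2": 20.0})
        collapsed, csamples = collapse_replicates([f], samples)
        assert [s.sample_id for s in csamples] == ["liver_A01"]
        assert collapsed[0].areas == {"liver_A01": 15.0}

    def test_max_mode(self):
        samples = [
            SampleRecord("liver_A01_r1", "liver", "A01", 1),
            SampleRecord("liver_A01_r2", "liver", "A01", 2),
        ]
        f = Feature("F1", 300.0, 5.0, {"liver_A01_r1": 10.0, "liver_A01_r2": 20.0})
        collapsed, _ = collapse_replicates([f], samples, "max")
        assert collapsed[0].areas == {"liver_A01": 20.0}


def brute_force_cascade(features, config, suspect_hits):
    """Independent re-application of the rule definitions, feature by feature."""
    survivors = []
    counts = {"exclusion_list": 0, "blank_ratio": 0, "intensity": 0,
              "kmd_window": 0, "ms2_available": 0}
    for f in features:
        blank_max = f.areas.get("blank_B1", 0.0)
        real_max = max(f.areas.get("liver_A01", 0.0), f.areas.get("muscle_A01", 0.0))
        if blank_max > 0 and real_max < config.blank_ratio_threshold * blank_max:
            counts["blank_ratio"] += 1
            continue
        if not real_max > config.min_area:
            counts["intensity"] += 1
            continue
        kmd = kendrick(f.mz).kmd
        in_window = config.kmd_window[0] <= kmd <= config.kmd_window[1]
        rescued = config.kmd_mode == "or_with_suspect" and f.feature_id in suspect_hits
        if not (in_window or rescued):
            counts["kmd_window"] += 1
            continue
        if config.require_ms2 and f.ms2_id is None:
            counts["ms2_available"] += 1
            continue
        survivors.append(f.feature_id)
    return survivors, counts


def random_instance(rng, n):
    feats = []
    for i in range(n):
        mz = float(rng.uniform(200, 900))
        feats.append(
            feat(
                f"F{i}",
                mz=mz,
                rt=float(rng.uniform(0, 15)),
                liver=float(rng.choice([0, 1e5, 9e5, 2e6, 5e7])),
                muscle=float(rng.choice([0, 1e5, 2e6])),
                blank=float(rng.choice([0, 0, 1e5, 1e6])),
                ms2=("m" + str(i)) if rng.uniform() < 0.5 else None,
            )
        )
    hits = {f.feature_id for f in feats if rng.uniform() < 0.3}
    return feats, hits


class TestCascade:
    def test_empty_input(self):
        candidates, report = run_cascade([], SAMPLES)
        assert candidates == []
        assert all(s.n_in == 0 and s.n_out == 0 for s in report.stages)

    def test_relaxing_ms2_gate_is_monotone(self):
        rng = np.random.default_rng(7)
        feats, hits = random_instance(rng, 100)
        strict, _ = run_cascade([_copy(f) for f in feats], SAMPLES,
                                FilterConfig(), hits)
        loose, _ = run_cascade([_copy(f) for f in feats], SAMPLES,
                               FilterConfig(require_ms2=False), hits)
        assert {f.feature_id for f in strict} <= {f.feature_id for f in loose}

    def test_relaxing_thresholds_is_monotone(self):
        rng = np.random.default_rng(11)
        feats, hits = random_instance(rng, 150)
        base, _ = run_cascade([_copy(f) for f in feats], SAMPLES, FilterConfig(), hits)
        relaxed_cfg = FilterConfig(
            blank_ratio_threshold=5, min_area=1e5, kmd_window=(-0.4, 0.4)
        )
        relaxed, _ = run_cascade([_copy(f) for f in feats], SAMPLES, relaxed_cfg, hits)
        assert {f.feature_id for f in base} <= {f.feature_id for f in relaxed}

    def test_oracle_equivalence_on_random_instances(self):
        """Cascade output equals brute-force rule reapplication; funnel telescopes."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(1, 201))
            feats, hits = random_instance(rng, n)
            config = FilterConfig()
            candidates, report = run_cascade(
                [_copy(f) for f in feats], SAMPLES, config, hits
            )
            expected, counts = brute_force_cascade(feats, config, hits)
            assert [f.feature_id for f in candidates] == expected
            report.validate()
            for st in report.stages:
                assert st.n_in == st.n_out + len(st.removed_ids)
                assert st.n_in - st.n_out == counts.get(st.name, 0)
            removed_all = {fid for st in report.stages for fid in st.removed_ids}
            assert removed_all | {f.feature_id for f in candidates} == {
                f.feature_id for f in feats
            }


def _copy(f):
    return Feature(f.feature_id, f.mz, f.rt, dict(f.areas), f.ms2_id, [])
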