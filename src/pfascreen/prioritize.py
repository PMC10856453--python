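"""Feature-reduction cascade for non-targeted PFAS screening.

Raw aligned feature lists from a non-targeted run contain thousands of
background and matrix signals for every genuine fluorochemical.  The
cascade prunes them in auditable stages:

1. exclusion list  — drop features matching a blank-run exclusion list
   (optional; skipped when no list is supplied),
2. blank ratio     — drop features whose best sample area is less than
   ``blank_ratio_threshold`` times their best procedural-blank area,
3. intensity       — keep features whose best non-blank area is strictly
   above ``min_area``,
4. Kendrick window — keep features whose CF2-based Kendrick mass defect
   lies inside ``kmd_window`` (fluorine-rich ions sit slightly negative);
   in ``or_with_suspect`` mode a suspect-list hit rescues an out-of-window
   feature,
5. MS2 gate        — keep only features with an MS2 spectrum, so every
   surviving candidate can be fragment-annotated.

Every stage records what it removed; the funnel report telescopes (out of
stage k equals in of stage k+1) and each surviving feature carries
provenance tags naming the stages it passed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .chem import kendrick
from .io import Feature, SampleRecord


@dataclass
class FilterConfig:
    """Thresholds of the prioritization cascade."""

    blank_ratio_threshold: float = 10.0
    min_area: float = 1_000_000.0
    kmd_window: tuple[float, float] = (-0.25, +0.15)
    require_ms2: bool = True
    mz_tol_ppm: float = 5.0
    rt_tol_min: float = 0.2
    kmd_mode: str = "or_with_suspect"  # or "hard"
    replicate_collapse: str = "mean"  # or "max"

    def __post_init__(self) -> None:
        lo, hi = self.kmd_window
        if not lo < hi:
            raise ValueError(f"kmd_window low must be < high, got {self.kmd_window}")
        if self.blank_ratio_threshold <= 0 or self.min_area <= 0:
            raise ValueError("thresholds must be positive")
        if self.kmd_mode not in ("hard", "or_with_suspect"):
            raise ValueError(f"unknown kmd_mode {self.kmd_mode!r}")
        if self.replicate_collapse not in ("mean", "max"):
            raise ValueError(f"unknown replicate_collapse {self.replicate_collapse!r}")


@dataclass
class StageResult:
    name: str
    n_in: int
    n_out: int
    removed_ids: list[str]


@dataclass
class FunnelReport:
    """Per-stage bookkeeping of the cascade."""

    stages: list[StageResult] = field(default_factory=list)

    def add(self, name: str, kept: Sequence[Feature], removed: Sequence[Feature]) -> None:
        self.stages.append(
            StageResult(
                name=name,
                n_in=len(kept) + len(removed),
                n_out=len(kept),
                removed_ids=[f.feature_id for f in removed],
            )
        )

    def validate(self) -> None:
        for prev, nxt in zip(self.stages, self.stages[1:]):
            if prev.n_out != nxt.n_in:
                raise ValueError(
                    f"funnel does not telescope: {prev.name} out {prev.n_out} "
                    f"!= {nxt.name} in {nxt.n_in}"
                )
        seen: set[str] = set()
        for st in self.stages:
            overlap = seen & set(st.removed_ids)
            if overlap:
                raise ValueError(f"feature(s) removed twice: {sorted(overlap)[:5]}")
            seen |= set(st.removed_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "stage": [s.name for s in self.stages],
                "n_in": [s.n_in for s in self.stages],
                "n_out": [s.n_out for s in self.stages],
                "n_removed": [s.n_in - s.n_out for s in self.stages],
            }
        )

    def log_lines(self) -> list[str]:
        return [
            f"[funnel] {s.name}: {s.n_in} -> {s.n_out} (removed {s.n_in - s.n_out})"
            for s in self.stages
        ]


def split_sample_ids(samples: Sequence[SampleRecord]) -> tuple[list[str], list[str]]:
    """(real tissue sample ids, blank sample ids); QCs count as neither."""
    real = [s.sample_id for s in samples if s.group in ("liver", "muscle")]
    blank = [s.sample_id for s in samples if s.group == "blank"]
    return real, blank


def collapse_replicates(
    features: Sequence[Feature], samples: Sequence[SampleRecord], method: str = "mean"
) -> tuple[list[Feature], list[SampleRecord]]:
    """Collapse duplicate injections into one column per biological sample.

    Injection replicates of the same (animal, tissue) — or of the same blank
    or QC pool — are averaged (or maxed).  Returned sample records carry
    ``injection_replicate = 1`` and a sample id without the replicate suffix.
    """
    if method not in ("mean", "max"):
        raise ValueError(f"unknown replicate collapse method {method!r}")
    groups: dict[tuple, list[SampleRecord]] = {}
    for s in samples:
        key = (s.group, s.animal_id, s.sample_id.rsplit("_r", 1)[0])
        groups.setdefault(key, []).append(s)

    collapsed_samples = []
    member_ids: dict[str, list[str]] = {}
    for (grp, animal, base), members in groups.items():
        collapsed_samples.append(
            SampleRecord(sample_id=base, group=grp, animal_id=animal, injection_replicate=1)
        )
        member_ids[base] = [m.sample_id for m in members]

    out = []
    for f in features:
        areas = {}
        for base, ids in member_ids.items():
            vals = [f.areas.get(i, 0.0) for i in ids]
            areas[base] = max(vals) if method == "max" else sum(vals) / len(vals)
        out.append(
            Feature(
                feature_id=f.feature_id,
                mz=f.mz,
                rt=f.rt,
                areas=areas,
                ms2_id=f.ms2_id,
                provenance=list(f.provenance),
            )
        )
    return out, collapsed_samples


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def build_exclusion_list(
    blank_features: Sequence[Feature],
    mz_tol_ppm: float = 5.0,
    rt_tol_min: float = 0.2,
) -> list[tuple[float, float]]:
    """Merge features seen in blank-only runs into a deduplicated (m/z, RT) list.

    Entries within both tolerances of each other are merged to their mean
    m/z and RT; the result is sorted by m/z.
    """
    if not blank_features:
        warnings.warn("no blank features supplied; exclusion list is empty")
        return []
    entries: list[list[float]] = []  # [sum_mz, sum_rt, n]
    for f in sorted(blank_features, key=lambda x: (x.mz, x.rt)):
        merged = False
        for e in entries:
            mean_mz = e[0] / e[2]
            mean_rt = e[1] / e[2]
            if abs(f.mz - mean_mz) <= mz_tol_ppm * 1e-6 * mean_mz and abs(f.rt - mean_rt) <= rt_tol_min:
                e[0] += f.mz
                e[1] += f.rt
                e[2] += 1
                merged = True
                break
        if not merged:
            entries.append([f.mz, f.rt, 1])
    out = [(e[0] / e[2], e[1] / e[2]) for e in entries]
    return sorted(out)


def exclusion_list_filter(
    features: Sequence[Feature],
    exclusion: Sequence[tuple[float, float]],
    mz_tol_ppm: float = 5.0,
    rt_tol_min: float = 0.2,
) -> tuple[list[Feature], list[Feature]]:
    """Remove features matching an exclusion entry within both tolerances."""
    kept, removed = [], []
    for f in features:
        hit = any(
            abs(f.mz - mz) <= mz_tol_ppm * 1e-6 * mz and abs(f.rt - rt) <= rt_tol_min
            for mz, rt in exclusion
        )
        (removed if hit else kept).append(f)
    return kept, removed


def blank_ratio_filter(
    features: Sequence[Feature],
    blank_sample_ids: Sequence[str],
    real_sample_ids: Sequence[str],
    threshold: float = 10.0,
) -> tuple[list[Feature], list[Feature]]:
    """Remove features whose sample/blank max-area ratio is below threshold.

    A feature absent from every blank (blank max area 0) is always kept.
    """
    if not blank_sample_ids:
        raise ValueError(
            "no blank samples in the design; skip the blank-ratio stage explicitly "
            "instead of running it without blanks"
        )
    kept, removed = [], []
    for f in features:
        blank_max = f.max_area(blank_sample_ids)
        if blank_max == 0:
            kept.append(f)
        elif f.max_area(real_sample_ids) < threshold * blank_max:
            removed.append(f)
        else:
            kept.append(f)
    return kept, removed


def intensity_filter(
    features: Sequence[Feature],
    real_sample_ids: Sequence[str],
    min_area: float = 1_000_000.0,
) -> tuple[list[Feature], list[Feature]]:
    """Keep features whose best non-blank area is strictly greater than min_area."""
    kept, removed = [], []
    for f in features:
        (kept if f.max_area(real_sample_ids) > min_area else removed).append(f)
    return kept, removed


def kmd_filter(
    features: Sequence[Feature],
    window: tuple[float, float] = (-0.25, +0.15),
    mode: str = "hard",
    suspect_hit_ids: Iterable[str] = (),
) -> tuple[list[Feature], list[Feature]]:
    """Keep features with Kendrick mass defect inside the window (inclusive).

    In ``or_with_suspect`` mode, out-of-window features with a suspect-list
    hit are retained and tagged ``kmd_rescued_by_suspect``.
    """
    lo, hi = window
    hits = set(suspect_hit_ids)
    kept, removed = [], []
    eps = 1e-12  # inclusive bounds, robust to rescaling round-off
    for f in features:
        kmd = kendrick(f.mz).kmd
        if lo - eps <= kmd <= hi + eps:
            kept.append(f)
        elif mode == "or_with_suspect" and f.feature_id in hits:
            f.provenance.append("kmd_rescued_by_suspect")
            kept.append(f)
        else:
            removed.append(f)
    return kept, removed


def ms2_filter(features: Sequence[Feature]) -> tuple[list[Feature], list[Feature]]:
    """Keep features that carry an MS2 spectrum."""
    kept, removed = [], []
    for f in features:
        (kept if f.ms2_id is not None else removed).append(f)
    return kept, removed


# ---------------------------------------------------------------------------
# cascade
# ---------------------------------------------------------------------------

def run_cascade(
    features: Sequence[Feature],
    samples: Sequence[SampleRecord],
    config: FilterConfig | None = None,
    suspect_hit_ids: Iterable[str] = (),
    exclusion: Sequence[tuple[float, float]] | None = None,
    skip_blank_ratio: bool = False,
) -> tuple[list[Feature], FunnelReport]:
    """Run the full prioritization cascade and return (candidates, funnel).

    Stage order: exclusion list (pass-through when ``exclusion`` is None),
    blank ratio, intensity, Kendrick window, MS2 gate.  Surviving features
    carry one provenance tag per stage passed.
    """
    config = config or FilterConfig()
    real_ids, blank_ids = split_sample_ids(samples)
    report = FunnelReport()
    current = list(features)

    def record(name: str, kept: list[Feature], removed: list[Feature]) -> list[Feature]:
        for f in kept:
            f.provenance.append(f"passed:{name}")
        report.add(name, kept, removed)
        return kept

    if exclusion is not None:
        kept, removed = exclusion_list_filter(
            current, exclusion, config.mz_tol_ppm, config.rt_tol_min
        )
    else:
        kept, removed = list(current), []
    current = record("exclusion_list", kept, removed)

    if skip_blank_ratio:
        kept, removed = list(current), []
    else:
        kept, removed = blank_ratio_filter(
            current, blank_ids, real_ids, config.blank_ratio_threshold
        )
    current = record("blank_ratio", kept, removed)

    kept, removed = intensity_filter(current, real_ids, config.min_area)
    current = record("intensity", kept, removed)

    kept, removed = kmd_filter(current, config.kmd_window, config.kmd_mode, suspect_hit_ids)
    current = record("kmd_window", kept, removed)

    if config.require_ms2:
        kept, removed = ms2_filter(current)
    else:
        kept, removed = list(current), []
    current = record("ms2_available", kept, removed)

    report.validate()
    return current, report
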