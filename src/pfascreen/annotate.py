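"""Candidate identification for prioritized PFAS features.

A prioritized feature becomes an annotation through accumulating evidence:
an accurate-mass suspect-list hit, membership in a CF2 homologous series
with retention times increasing along the chain, diagnostic class
fragments in its MS2 spectrum, spectral similarity to a library spectrum,
and — the gold standard — retention-time agreement with an authentic
analytical standard.  The evidence is folded into a Schymanski-style
confidence level:

    CL1  confirmed by standard (RT match) plus fragment or spectral support
    CL2  probable structure: library spectral match (> 60 on a 0-100 scale)
    CL3  tentative candidate: mass-list hit supported by a diagnostic
         fragment or homologous-series membership
    CL4  unambiguous molecular formula only
    CL5  exact mass only

The decision list is deliberately explicit and ordered; the rationale of
every assignment records which clauses fired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .chem import CF2_EXACT_MASS, adduct_mz, ppm_error
from .io import Feature, Ms2Spectrum, SuspectEntry

DEFAULT_FRAG_TOL_PPM = 10.0
#: Diagnostic ions are typically printed at 2-3 decimals; a ppm tolerance
#: alone would be tighter than that precision for small fragments.
FRAG_TOL_FLOOR_TH = 0.01


@dataclass
class SeriesAssignment:
    """A detected CF2 homologous series (members ordered by m/z)."""

    series_id: str
    member_feature_ids: list[str]
    n_cf2_steps: list[int]
    rt_monotone: bool


@dataclass
class Evidence:
    """Per-feature identification evidence, input to the confidence decision."""

    has_ms2: bool = False
    standard_match: bool = False
    spectral_score: float | None = None
    masslist_hit: bool = False
    n_diagnostic_matched: int = 0
    series_member: bool = False
    unambiguous_formula: bool = False


@dataclass
class Annotation:
    """A feature <-> suspect match with its evidence and confidence level."""

    feature_id: str
    suspect_name: str | None = None
    source_list: str | None = None
    delta_ppm: float | None = None
    spectral_score: float | None = None
    class_score: float | None = None
    n_diagnostic_matched: int = 0
    series_id: str | None = None
    standard_match: bool = False
    isomer_tag: str | None = None
    confidence_level: int = 5
    rationale: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# suspect matching
# ---------------------------------------------------------------------------

def match_suspects(
    mz: float,
    suspects: Sequence[SuspectEntry],
    tol_ppm: float = 5.0,
) -> list[tuple[SuspectEntry, float]]:
    """Rank suspect candidates for an observed [M-H]- m/z.

    Returns (suspect, signed delta ppm) pairs with |delta| <= tol_ppm,
    sorted by |delta| ascending, ties broken by suspect name.
    """
    if not suspects:
        warnings.warn("empty suspect library; no matches possible")
        return []
    out = []
    for s in suspects:
        theo = adduct_mz(s.neutral_mass)
        d = ppm_error(mz, theo)
        if abs(d) <= tol_ppm:
            out.append((s, d))
    out.sort(key=lambda t: (abs(t[1]), t[0].name))
    return out


# ---------------------------------------------------------------------------
# homologous-series detection
# ---------------------------------------------------------------------------

def detect_series(
    features: Sequence[Feature],
    spacing: float = CF2_EXACT_MASS,
    tol_ppm: float = 5.0,
    min_members: int = 3,
    require_rt_increase: bool = True,
    max_step: int = 3,
) -> list[SeriesAssignment]:
    """Find CF2 homologous series among features.

    Consecutive members must differ by n x spacing (1 <= n <= max_step)
    within ``tol_ppm`` of the heavier m/z and, if required, elute at
    strictly increasing retention times.  Chains are extracted greedily,
    longest first (ties to the lower-m/z start); each feature belongs to
    at most one series.
    """
    order = sorted(range(len(features)), key=lambda i: (features[i].mz, features[i].feature_id))
    feats = [features[i] for i in order]
    n = len(feats)
    # DAG edges i -> j (mz_i < mz_j) where the gap is an integer CF2 multiple.
    succ: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            gap = feats[j].mz - feats[i].mz
            if gap <= 0:
                continue
            k = round(gap / spacing)
            if k < 1 or k > max_step:
                continue
            if abs(gap - k * spacing) > tol_ppm * 1e-6 * feats[j].mz:
                continue
            if require_rt_increase and not feats[j].rt > feats[i].rt:
                continue
            succ[i].append(j)

    assigned = [False] * n
    series: list[SeriesAssignment] = []

    def longest_chain() -> list[int]:
        # DP over the m/z-ordered DAG restricted to unassigned nodes.
        best_len = [0] * n
        best_next = [-1] * n
        for i in range(n - 1, -1, -1):
            if assigned[i]:
                continue
            best_len[i] = 1
            for j in succ[i]:
                if assigned[j]:
                    continue
                if 1 + best_len[j] > best_len[i]:
                    best_len[i] = 1 + best_len[j]
                    best_next[i] = j
        start, length = -1, 0
        for i in range(n):  # ties resolve to the lower-m/z start
            if not assigned[i] and best_len[i] > length:
                start, length = i, best_len[i]
        chain = []
        cur = start
        while cur != -1:
            chain.append(cur)
            cur = best_next[cur]
        return chain

    sid = 0
    while True:
        chain = longest_chain()
        if len(chain) < min_members:
            break
        sid += 1
        steps = [
            round((feats[b].mz - feats[a].mz) / spacing)
            for a, b in zip(chain, chain[1:])
        ]
        rts = [feats[i].rt for i in chain]
        series.append(
            SeriesAssignment(
                series_id=f"S{sid:03d}",
                member_feature_ids=[feats[i].feature_id for i in chain],
                n_cf2_steps=steps,
                rt_monotone=all(b > a for a, b in zip(rts, rts[1:])),
            )
        )
        for i in chain:
            assigned[i] = True
    return series


# ---------------------------------------------------------------------------
# spectral scoring
# ---------------------------------------------------------------------------

def _frag_tol(mz: float, tol_ppm: float) -> float:
    return max(tol_ppm * 1e-6 * mz, FRAG_TOL_FLOOR_TH)


def _greedy_pairs(
    a: list[tuple[float, float]], b: list[tuple[float, float]], tol_ppm: float
) -> list[tuple[int, int]]:
    """Greedy one-to-one peak pairing by closest m/z within tolerance."""
    cands = []
    for i, (ma, _) in enumerate(a):
        for j, (mb, _) in enumerate(b):
            d = abs(ma - mb)
            if d <= _frag_tol(max(ma, mb), tol_ppm):
                cands.append((d, i, j))
    cands.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in cands:
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    return pairs


def spectral_similarity(
    query: Ms2Spectrum, library: Ms2Spectrum, frag_tol_ppm: float = DEFAULT_FRAG_TOL_PPM
) -> float:
    """Cosine similarity (0-100) between two spectra after greedy peak pairing.

    Intensity vectors are L2-normalized over all peaks of each spectrum, so
    unmatched peaks penalize the score; the measure is symmetric.
    """
    if not query.peaks or not library.peaks:
        raise ValueError("cannot score an empty spectrum")
    na = sum(i * i for _, i in query.peaks) ** 0.5
    nb = sum(i * i for _, i in library.peaks) ** 0.5
    if na == 0 or nb == 0:
        raise ValueError("cannot score a spectrum with all-zero intensities")
    pairs = _greedy_pairs(query.peaks, library.peaks, frag_tol_ppm)
    dot = sum(query.peaks[i][1] * library.peaks[j][1] for i, j in pairs)
    return 100.0 * dot / (na * nb)


def class_fragment_score(
    ms2: Ms2Spectrum,
    class_fragments: Sequence[float],
    frag_tol_ppm: float = DEFAULT_FRAG_TOL_PPM,
) -> tuple[float, int]:
    """Fraction and count of diagnostic class fragments found in a spectrum.

    Each diagnostic ion counts at most once however many spectrum peaks
    fall within tolerance.
    """
    if not class_fragments:
        return 0.0, 0
    matched = 0
    for frag in class_fragments:
        tol = _frag_tol(frag, frag_tol_ppm)
        if any(abs(mz - frag) <= tol for mz, _ in ms2.peaks):
            matched += 1
    return matched / len(class_fragments), matched


# ---------------------------------------------------------------------------
# isomer reasoning
# ---------------------------------------------------------------------------

def flag_branched_isomer(
    features: Sequence[Feature],
    standard_rt: float | None,
    rt_tol_min: float = 0.2,
) -> dict[str, str]:
    """Tag same-formula isomers by elution order against an authentic standard.

    Branched perfluoroalkyl isomers elute before the linear chain.  The
    feature whose RT matches the standard is tagged ``linear/confirmed``;
    earlier-eluting same-formula features are ``branched-candidate``.
    Without a standard RT, or with a single feature, nothing is tagged.
    """
    if len(features) < 2 or standard_rt is None:
        return {}
    tags = {}
    for f in features:
        if abs(f.rt - standard_rt) <= rt_tol_min:
            tags[f.feature_id] = "linear/confirmed"
        elif f.rt < standard_rt:
            tags[f.feature_id] = "branched-candidate"
    return tags


# ---------------------------------------------------------------------------
# confidence levels
# ---------------------------------------------------------------------------

def assign_confidence(ev: Evidence) -> tuple[int, list[str]]:
    """Fold an evidence record into a confidence level 1-5 plus rationale.

    Ordered decision list; the first clause that fires sets the level.
    The library-match gate at CL2 is strict (> 60), honoring a "higher
    than 60" criterion; at CL1 the standard is the primary evidence and
    spectral support of exactly 60 suffices.
    """
    if ev.spectral_score is not None and not ev.has_ms2:
        raise ValueError("inconsistent evidence: spectral score without an MS2 spectrum")
    rationale: list[str] = []
    if ev.standard_match and (
        (ev.spectral_score is not None and ev.spectral_score >= 60)
        or ev.n_diagnostic_matched >= 1
    ):
        rationale.append("standard RT match with fragment/spectral support")
        return 1, rationale
    if ev.spectral_score is not None and ev.spectral_score > 60:
        rationale.append(f"library spectral match {ev.spectral_score:.1f} > 60")
        return 2, rationale
    if ev.masslist_hit and (ev.n_diagnostic_matched >= 1 or ev.series_member):
        why = "diagnostic fragment" if ev.n_diagnostic_matched >= 1 else "homologous series"
        rationale.append(f"mass-list hit supported by {why}")
        return 3, rationale
    if ev.unambiguous_formula or ev.masslist_hit:
        rationale.append("unambiguous formula only")
        return 4, rationale
    rationale.append("exact mass only")
    return 5, rationale


# ---------------------------------------------------------------------------
# end-to-end annotation of a candidate list
# ---------------------------------------------------------------------------

def annotate_features(
    features: Sequence[Feature],
    suspects: Sequence[SuspectEntry],
    spectra: dict[str, Ms2Spectrum],
    library: dict[str, Ms2Spectrum] | None = None,
    tol_ppm: float = 5.0,
    frag_tol_ppm: float = DEFAULT_FRAG_TOL_PPM,
    rt_tol_min: float = 0.2,
) -> list[Annotation]:
    """Annotate prioritized features against a suspect library.

    ``spectra`` maps ms2_id -> spectrum for the query features; ``library``
    maps suspect name -> reference spectrum.  Series detection runs over
    the full feature list so chain context is not lost to earlier filters.
    """
    library = library or {}
    series = detect_series(features, tol_ppm=tol_ppm)
    series_of = {
        fid: s.series_id for s in series for fid in s.member_feature_ids
    }

    # Score every in-tolerance suspect; fragment and spectral evidence
    # disambiguates isobaric/isomeric candidates sharing a formula.
    @dataclass
    class _Hit:
        suspect: SuspectEntry
        delta: float
        spectral: float | None
        class_frac: float | None
        n_diag: int
        standard: bool

    def score_hits(f: Feature) -> list[_Hit]:
        ms2 = spectra.get(f.ms2_id) if f.ms2_id else None
        out = []
        for suspect, delta in match_suspects(f.mz, suspects, tol_ppm) if suspects else []:
            spec = frac = None
            n_diag = 0
            if ms2 is not None and suspect.diagnostic_fragments:
                frac, n_diag = class_fragment_score(
                    ms2, suspect.diagnostic_fragments, frag_tol_ppm
                )
            if ms2 is not None and suspect.name in library:
                spec = spectral_similarity(ms2, library[suspect.name], frag_tol_ppm)
            standard = (
                suspect.standard_rt is not None
                and abs(f.rt - suspect.standard_rt) <= rt_tol_min
                and n_diag >= 1
            )
            out.append(_Hit(suspect, delta, spec, frac, n_diag, standard))
        out.sort(
            key=lambda h: (
                not h.standard,
                -(h.spectral if h.spectral is not None else -1.0),
                -h.n_diag,
                abs(h.delta),
                h.suspect.name,
            )
        )
        return out

    best_hit: dict[str, "_Hit | None"] = {}
    for f in features:
        hits = score_hits(f)
        best_hit[f.feature_id] = hits[0] if hits else None

    # isomer tags: group features by chosen suspect formula
    by_formula: dict[str, list[Feature]] = {}
    for f in features:
        hit = best_hit[f.feature_id]
        if hit is not None:
            by_formula.setdefault(hit.suspect.formula, []).append(f)
    isomer_tags: dict[str, str] = {}
    for formula, members in by_formula.items():
        std_rts = [
            s.standard_rt
            for s in suspects
            if s.formula == formula and s.standard_rt is not None
        ]
        if std_rts:
            isomer_tags.update(flag_branched_isomer(members, std_rts[0], rt_tol_min))

    annotations = []
    for f in features:
        hit = best_hit[f.feature_id]
        ms2 = spectra.get(f.ms2_id) if f.ms2_id else None
        ann = Annotation(feature_id=f.feature_id)
        ann.series_id = series_of.get(f.feature_id)
        if hit is not None:
            ann.suspect_name = hit.suspect.name
            ann.source_list = hit.suspect.source_list
            ann.delta_ppm = hit.delta
            ann.spectral_score = hit.spectral
            ann.class_score = hit.class_frac
            ann.n_diagnostic_matched = hit.n_diag
            ann.standard_match = hit.standard
        ann.isomer_tag = isomer_tags.get(f.feature_id)
        ev = Evidence(
            has_ms2=ms2 is not None,
            standard_match=ann.standard_match,
            spectral_score=ann.spectral_score,
            masslist_hit=hit is not None,
            n_diagnostic_matched=ann.n_diagnostic_matched,
            series_member=ann.series_id is not None,
            unambiguous_formula=hit is not None,
        )
        ann.confidence_level, ann.rationale = assign_confidence(ev)
        annotations.append(ann)
    return annotations
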