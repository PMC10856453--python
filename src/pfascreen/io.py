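"""Data model and file I/O for aligned LC-HRMS feature data.

The pipeline starts from an aligned feature table (one row per feature,
one area column per injection), a sample/design table, MS2 spectra in MGF,
and suspect lists as TSV.  A curated 60-compound PFAS identification table
(negative-mode roe deer liver/muscle study) ships with the package and
doubles as validation oracle and default suspect library.

All tabular formats are tab-separated with "." decimals; writers prepend a
``# pfascreen <version>`` comment line and readers skip ``#`` comments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from pyteomics import mgf as _mgf

from . import __version__
from .chem import (
    ElementComposition,
    deprotonated_mz,
    kendrick,
    monoisotopic_mass,
    parse_formula,
    ppm_error,
)

SAMPLE_GROUPS = ("liver", "muscle", "blank", "qc")

_FIXTURE_NAME = "curated_pfas_table.tsv"


@dataclass(frozen=True)
class SampleRecord:
    """One injection in the study design."""

    sample_id: str
    group: str  # liver | muscle | blank | qc
    animal_id: str | None = None
    injection_replicate: int = 1

    def __post_init__(self) -> None:
        if self.group not in SAMPLE_GROUPS:
            raise ValueError(f"unknown sample group {self.group!r} for {self.sample_id}")
        if self.group in ("blank", "qc") and self.animal_id is not None:
            raise ValueError(f"{self.group} sample {self.sample_id} must have animal_id null")
        if self.injection_replicate < 1:
            raise ValueError("injection_replicate must be >= 1")


@dataclass
class Feature:
    """One aligned LC-HRMS feature: observed [M-H]- m/z, RT, per-sample areas."""

    feature_id: str
    mz: float
    rt: float
    areas: dict[str, float]
    ms2_id: str | None = None
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"feature {self.feature_id}: m/z must be positive")
        if self.rt < 0:
            raise ValueError(f"feature {self.feature_id}: negative RT")
        for sid, a in self.areas.items():
            if a < 0:
                raise ValueError(f"feature {self.feature_id}: negative area for {sid}")

    def max_area(self, sample_ids: Iterable[str]) -> float:
        return max((self.areas.get(s, 0.0) for s in sample_ids), default=0.0)


@dataclass
class Ms2Spectrum:
    """A centroided MS2 spectrum; peaks sorted by fragment m/z."""

    ms2_id: str
    precursor_mz: float
    peaks: list[tuple[float, float]]
    collision_energy: str = ""

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ValueError(f"spectrum {self.ms2_id} has no peaks")
        if any(i < 0 for _, i in self.peaks):
            raise ValueError(f"spectrum {self.ms2_id} has negative intensities")
        self.peaks = sorted(self.peaks)


@dataclass
class SuspectEntry:
    """One suspect-library candidate (neutral formula plus diagnostic fragments)."""

    name: str
    formula: str
    compound_class: str = "PFAS"
    diagnostic_fragments: list[float] = field(default_factory=list)
    standard_rt: float | None = None
    source_list: str = ""
    neutral_mass: float | None = None

    def __post_init__(self) -> None:
        comp = parse_formula(self.formula)
        mass = monoisotopic_mass(comp)
        if self.neutral_mass is None:
            self.neutral_mass = mass
        elif abs(self.neutral_mass - mass) > 1e-6:
            raise ValueError(
                f"suspect {self.name}: neutral_mass {self.neutral_mass} inconsistent "
                f"with formula {self.formula} ({mass:.7f})"
            )

    @property
    def composition(self) -> ElementComposition:
        return parse_formula(self.formula)


@dataclass(frozen=True)
class CuratedRow:
    """One row of the packaged 60-compound identification table."""

    code: int
    iupac_name: str
    formula: str
    printed_mz: float
    printed_ppm: float
    diagnostic_ions: tuple[float, ...]
    rt: float
    max_area: float
    confidence_level: int


def _version_header() -> str:
    return f"# pfascreen {__version__}\n"


# ---------------------------------------------------------------------------
# sample table
# ---------------------------------------------------------------------------

def read_sample_table(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"animal_id": "string"})
    required = {"sample_id", "group", "animal_id", "injection_replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"sample table {path}: missing columns {sorted(missing)}")
    if df.sample_id.duplicated().any():
        dup = df.sample_id[df.sample_id.duplicated()].iloc[0]
        raise ValueError(f"sample table {path}: duplicate sample_id {dup!r}")
    out = []
    for row in df.itertuples():
        animal = None if pd.isna(row.animal_id) else str(row.animal_id)
        out.append(
            SampleRecord(
                sample_id=str(row.sample_id),
                group=str(row.group),
                animal_id=animal,
                injection_replicate=int(row.injection_replicate),
            )
        )
    return out


def write_sample_table(samples: Sequence[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "group": [s.group for s in samples],
            "animal_id": [s.animal_id if s.animal_id is not None else "" for s in samples],
            "injection_replicate": [s.injection_replicate for s in samples],
        }
    )
    with open(path, "w") as fh:
        fh.write(_version_header())
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# feature table (wide: one area column per sample_id)
# ---------------------------------------------------------------------------

def read_feature_table(path: str | Path, samples: Sequence[SampleRecord]) -> list[Feature]:
    """Read a wide feature table; area columns must match the sample table."""
    df = pd.read_csv(path, sep="\t", comment="#")
    base_cols = {"feature_id", "mz", "rt"}
    missing = base_cols - set(df.columns)
    if missing:
        raise ValueError(f"feature table {path}: missing columns {sorted(missing)}")
    sample_ids = [s.sample_id for s in samples]
    known = set(sample_ids) | base_cols | {"ms2_id"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValueError(
            f"feature table {path}: area columns {unknown} not in the sample table"
        )
    if df.feature_id.duplicated().any():
        dup = df.feature_id[df.feature_id.duplicated()].iloc[0]
        raise ValueError(f"feature table {path}: duplicate feature_id {dup!r}")

    present = [sid for sid in sample_ids if sid in df.columns]
    area_block = df[present].astype(float)
    n_missing = int(area_block.isna().sum().sum()) + len(df) * (len(sample_ids) - len(present))
    area_block = area_block.fillna(0.0)
    ms2_col = df["ms2_id"].astype("string") if "ms2_id" in df.columns else None

    features = []
    for i in range(len(df)):
        areas = {sid: 0.0 for sid in sample_ids}
        areas.update(area_block.iloc[i].to_dict())
        ms2 = None
        if ms2_col is not None:
            raw = ms2_col.iloc[i]
            if not (pd.isna(raw) or str(raw) == ""):
                ms2 = str(raw)
        features.append(
            Feature(
                feature_id=str(df["feature_id"].iloc[i]),
                mz=float(df["mz"].iloc[i]),
                rt=float(df["rt"].iloc[i]),
                areas=areas,
                ms2_id=ms2,
            )
        )
    if n_missing:
        import warnings

        warnings.warn(f"feature table {path}: {n_missing} missing areas set to 0")
    return features


def write_feature_table(
    features: Sequence[Feature], samples: Sequence[SampleRecord], path: str | Path
) -> None:
    sample_ids = [s.sample_id for s in samples]
    rows = []
    for f in features:
        row = {"feature_id": f.feature_id, "mz": round(f.mz, 6), "rt": round(f.rt, 4),
               "ms2_id": f.ms2_id or ""}
        for sid in sample_ids:
            row[sid] = round(f.areas.get(sid, 0.0), 1)
        rows.append(row)
    df = pd.DataFrame(rows, columns=["feature_id", "mz", "rt", "ms2_id", *sample_ids])
    with open(path, "w") as fh:
        fh.write(_version_header())
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# MS2 spectra (MGF)
# ---------------------------------------------------------------------------

def read_mgf(path: str | Path) -> list[Ms2Spectrum]:
    """Read MS2 spectra from an MGF file; TITLE carries the ms2_id."""
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for spec in reader:
            params = spec["params"]
            title = str(params.get("title", "")).strip()
            if "pepmass" not in params:
                raise ValueError(f"MGF {path}: block {title!r} missing PEPMASS")
            pep = params["pepmass"]
            precursor = float(pep[0] if isinstance(pep, (tuple, list)) else pep)
            peaks = list(zip((float(x) for x in spec["m/z array"]),
                             (float(x) for x in spec["intensity array"])))
            spectra.append(
                Ms2Spectrum(
                    ms2_id=title,
                    precursor_mz=precursor,
                    peaks=peaks,
                    collision_energy=str(params.get("collision_energy", "")),
                )
            )
    return spectra


def write_mgf(spectra: Sequence[Ms2Spectrum], path: str | Path) -> None:
    entries = []
    for s in spectra:
        params = {"title": s.ms2_id, "pepmass": s.precursor_mz, "charge": "1-"}
        if s.collision_energy:
            params["collision_energy"] = s.collision_energy
        entries.append(
            {
                "params": params,
                "m/z array": [p[0] for p in s.peaks],
                "intensity array": [p[1] for p in s.peaks],
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


def link_ms2_by_precursor(
    features: Sequence[Feature],
    spectra: Sequence[Ms2Spectrum],
    tol_ppm: float = 10.0,
    rt_tol_min: float = 0.2,
    feature_rts: dict[str, float] | None = None,
) -> int:
    """Attach spectra to features by precursor m/z (+- tol_ppm).

    For externally produced data without explicit ms2_id links.  RT matching
    is applied only when per-spectrum RTs are supplied via ``feature_rts``
    (ms2_id -> RT).  Returns the number of features linked.
    """
    linked = 0
    for f in features:
        if f.ms2_id is not None:
            continue
        for s in spectra:
            if abs(ppm_error(s.precursor_mz, f.mz)) <= tol_ppm:
                if feature_rts is not None:
                    rt = feature_rts.get(s.ms2_id)
                    if rt is not None and abs(rt - f.rt) > rt_tol_min:
                        continue
                f.ms2_id = s.ms2_id
                linked += 1
                break
    return linked


# ---------------------------------------------------------------------------
# suspect lists
# ---------------------------------------------------------------------------

def read_suspect_list(path: str | Path) -> list[SuspectEntry]:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "formula"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"suspect list {path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples():
        frags = []
        raw = getattr(row, "diagnostic_fragments", "")
        if isinstance(raw, str) and raw.strip():
            frags = [float(x) for x in raw.replace(",", ";").split(";") if x.strip()]
        std_rt = getattr(row, "standard_rt", None)
        std_rt = None if std_rt is None or pd.isna(std_rt) else float(std_rt)
        out.append(
            SuspectEntry(
                name=str(row.name),
                formula=str(row.formula),
                compound_class=str(getattr(row, "compound_class", "PFAS")),
                diagnostic_fragments=frags,
                standard_rt=std_rt,
                source_list=str(getattr(row, "source_list", "")),
            )
        )
    return out


def write_suspect_list(suspects: Sequence[SuspectEntry], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "name": [s.name for s in suspects],
            "formula": [s.formula for s in suspects],
            "compound_class": [s.compound_class for s in suspects],
            "diagnostic_fragments": [
                ";".join(f"{x:g}" for x in s.diagnostic_fragments) for s in suspects
            ],
            "standard_rt": [s.standard_rt if s.standard_rt is not None else "" for s in suspects],
            "source_list": [s.source_list for s in suspects],
        }
    )
    with open(path, "w") as fh:
        fh.write(_version_header())
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# packaged curated table
# ---------------------------------------------------------------------------

def load_curated_table() -> list[CuratedRow]:
    """Load the packaged 60-compound curated PFAS identification table."""
    ref = resources.files("pfascreen").joinpath("data", _FIXTURE_NAME)
    with resources.as_file(ref) as p:
        df = pd.read_csv(p, sep="\t", comment="#")
    problems = []
    rows = []
    for r in df.itertuples():
        try:
            ions = tuple(float(x) for x in str(r.diagnostic_ions).split(";") if x.strip())
            row = CuratedRow(
                code=int(r.code),
                iupac_name=str(r.iupac_name),
                formula=str(r.formula),
                printed_mz=float(r.printed_mz),
                printed_ppm=float(r.printed_ppm),
                diagnostic_ions=ions,
                rt=float(r.rt),
                max_area=float(r.max_area),
                confidence_level=int(r.confidence_level),
            )
            parse_formula(row.formula)
            if row.confidence_level not in (1, 2, 3, 4, 5):
                raise ValueError(f"confidence level {row.confidence_level}")
            rows.append(row)
        except (ValueError, TypeError) as exc:
            problems.append(f"row code {getattr(r, 'code', '?')}: {exc}")
    if problems:
        raise ValueError("curated table failed validation:\n" + "\n".join(problems))
    codes = sorted(r.code for r in rows)
    if len(rows) != 60 or codes != list(range(1, 61)):
        raise ValueError(f"curated table must hold codes 1..60 once each, got {len(rows)} rows")
    return rows


def validate_curated_table(
    rows: Sequence[CuratedRow] | None = None,
    tight_ppm: float = 0.25,
    loose_ppm: float = 0.5,
) -> pd.DataFrame:
    """Recompute theoretical [M-H]- m/z, ppm error and KMD for every row.

    Discrepancies against the printed mass errors are reported, never
    raised: the printed observed m/z is rounded to 4 decimals, which alone
    bounds agreement at roughly +-0.15 ppm, and a handful of rows carry
    apparent transcription errors.  The returned frame has one row per
    compound plus ``attrs["summary"]`` with the agreement counts.
    """
    import warnings as _warnings

    if rows is None:
        rows = load_curated_table()
    recs = []
    for r in rows:
        comp = parse_formula(r.formula)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")  # H-free formulas are expected here
            theo = deprotonated_mz(comp)
        recalc = ppm_error(r.printed_mz, theo)
        delta = abs(recalc - r.printed_ppm)
        recs.append(
            {
                "code": r.code,
                "formula": r.formula,
                "printed_mz": r.printed_mz,
                "theoretical_mz": theo,
                "printed_ppm": r.printed_ppm,
                "recomputed_ppm": recalc,
                "abs_delta_ppm": delta,
                "kmd": kendrick(r.printed_mz).kmd,
                "agrees": delta <= loose_ppm,
                "confidence_level": r.confidence_level,
            }
        )
    df = pd.DataFrame(recs)
    df.attrs["summary"] = {
        "n_rows": len(df),
        "n_within_tight": int((df.abs_delta_ppm <= tight_ppm).sum()),
        "n_within_loose": int((df.abs_delta_ppm <= loose_ppm).sum()),
        "discrepant_codes": df.loc[~df.agrees, "code"].tolist(),
    }
    return df


def curated_suspect_list(source_list: str = "curated-roedeer") -> list[SuspectEntry]:
    """Build a suspect library from the packaged curated table.

    Rows identified against an authentic standard (confidence level 1)
    carry their retention time as ``standard_rt``.
    """
    suspects = []
    for r in load_curated_table():
        name = r.iupac_name.lower()
        if "sulfonate" in name or "sulfon" in name:
            cls = "PFSA"
        elif "acid" in name or "oic" in name:
            cls = "PFCA"
        else:
            cls = "PFAS"
        suspects.append(
            SuspectEntry(
                name=r.iupac_name,
                formula=r.formula,
                compound_class=cls,
                diagnostic_fragments=list(r.diagnostic_ions),
                standard_rt=r.rt if r.confidence_level == 1 else None,
                source_list=source_list,
            )
        )
    return suspects
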