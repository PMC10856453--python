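"""Synthetic LC-HRMS scenario generator for end-to-end pipeline validation.

Raw data for real tissue studies of this kind are rarely deposited, so the
package validates itself on synthetic scenarios that emulate the study
design the curated table came from: two tissues (liver, muscle) from 18
animals, duplicate injections per sample, a procedural blank run twice,
pooled QC injections, and three feature populations —

* true PFAS: the 60 curated compounds placed at their theoretical [M-H]-
  m/z plus ppm-scale mass error, with MS2 spectra containing their
  diagnostic ions, arranged in their natural CF2 homologous series with
  retention time increasing along the chain;
* blank contaminants: present in procedural blanks with sample/blank
  max-area ratios drawn strictly below 10, so the blank-ratio rule can
  remove them all;
* hydrogen-rich background: Kendrick mass defects drawn from +0.15..+0.45
  (outside the PFAS window) and mostly without MS2.

Planted tissue effects (defaults: 20 compounds up in liver and 12 up in
muscle at 2-8x fold, plus 4 muscle-only and 3 liver-only exclusives, the
exclusives being the compounds the source study reported as
tissue-exclusive) make the differential stage testable.  Every feature is
covered exactly once by the ground-truth manifest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import detect_series
from .chem import CF2_EXACT_MASS, CF2_NOMINAL_MASS, deprotonated_mz, parse_formula
from .io import (
    CuratedRow,
    Feature,
    Ms2Spectrum,
    SampleRecord,
    SuspectEntry,
    curated_suspect_list,
    load_curated_table,
    read_feature_table,
    read_mgf,
    read_sample_table,
    read_suspect_list,
    write_feature_table,
    write_mgf,
    write_sample_table,
    write_suspect_list,
)

#: Compound codes the source table reports as detected in one tissue only.
DEFAULT_MUSCLE_EXCLUSIVE = (2, 9, 11, 38)
DEFAULT_LIVER_EXCLUSIVE = (46, 52, 56)


@dataclass
class ScenarioConfig:
    """Knobs of the synthetic study; defaults emulate the real design."""

    n_per_group: int = 18
    n_injections: int = 2
    n_true_pfas: int = 60
    n_blank_contaminants: int = 50
    n_background_features: int = 2000
    mass_error_sd_ppm: float = 1.5
    rt_jitter_sd_min: float = 0.05
    biological_cv: float = 0.30
    technical_cv: float = 0.10
    loading_sd: float = 0.20
    n_up_liver: int = 20
    n_up_muscle: int = 12
    fold_range: tuple[float, float] = (2.0, 8.0)
    muscle_exclusive_codes: tuple[int, ...] = DEFAULT_MUSCLE_EXCLUSIVE
    liver_exclusive_codes: tuple[int, ...] = DEFAULT_LIVER_EXCLUSIVE
    background_kmd_range: tuple[float, float] = (0.15, 0.45)
    background_ms2_fraction: float = 0.05
    run_length_min: float = 15.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory for reproducibility")
        for name in ("n_per_group", "n_injections", "n_true_pfas",
                     "n_blank_contaminants", "n_background_features"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.fold_range[0] <= 1:
            raise ValueError("planted folds must exceed 1")
        n_excl = len(self.muscle_exclusive_codes) + len(self.liver_exclusive_codes)
        if self.n_up_liver + self.n_up_muscle + n_excl > self.n_true_pfas:
            raise ValueError(
                "more differential + exclusive compounds than true PFAS compounds"
            )


@dataclass
class Scenario:
    """An in-memory synthetic dataset plus its ground truth."""

    config: ScenarioConfig
    samples: list[SampleRecord]
    features: list[Feature]
    spectra: list[Ms2Spectrum]
    suspects: list[SuspectEntry]
    library: dict[str, Ms2Spectrum]
    manifest: pd.DataFrame
    planted_series: list = field(default_factory=list)


def _sigma_from_cv(cv: float) -> float:
    return math.sqrt(math.log(1.0 + cv * cv))


def _build_samples(cfg: ScenarioConfig) -> list[SampleRecord]:
    samples = []
    for tissue in ("liver", "muscle"):
        for a in range(1, cfg.n_per_group + 1):
            animal = f"A{a:02d}"
            for r in range(1, cfg.n_injections + 1):
                samples.append(
                    SampleRecord(
                        sample_id=f"{tissue}_{animal}_r{r}",
                        group=tissue,
                        animal_id=animal,
                        injection_replicate=r,
                    )
                )
    for r in range(1, cfg.n_injections + 1):
        samples.append(SampleRecord(f"blank_B1_r{r}", "blank", None, r))
    for r in range(1, cfg.n_injections + 1):
        samples.append(SampleRecord(f"qc_Q1_r{r}", "qc", None, r))
    return samples


def _planted_series_truth(
    rows: list[CuratedRow], rts: dict[int, float], mz: dict[int, float]
) -> list:
    """Homologous-series ground truth on noise-free masses and generated RTs."""
    feats = [
        Feature(feature_id=f"F{r.code:04d}", mz=mz[r.code], rt=rts[r.code], areas={})
        for r in rows
    ]
    return detect_series(feats, tol_ppm=0.1, min_members=3)


def generate_scenario(config: ScenarioConfig | None = None) -> Scenario:
    """Generate a fully deterministic synthetic scenario for the given config."""
    cfg = config or ScenarioConfig()
    rng = np.random.default_rng(cfg.seed)
    rows = load_curated_table()[: cfg.n_true_pfas]
    samples = _build_samples(cfg)
    real = [s for s in samples if s.group in ("liver", "muscle")]
    blanks = [s for s in samples if s.group == "blank"]
    qcs = [s for s in samples if s.group == "qc"]

    sigma_bio = _sigma_from_cv(cfg.biological_cv)
    sigma_tech = _sigma_from_cv(cfg.technical_cv)

    # per-injection loading factors (extraction/injection efficiency)
    loading = {s.sample_id: float(rng.lognormal(0.0, cfg.loading_sd)) for s in samples}

    # --- planted design over the curated compounds --------------------------
    excl_muscle = [c for c in cfg.muscle_exclusive_codes if c <= cfg.n_true_pfas]
    excl_liver = [c for c in cfg.liver_exclusive_codes if c <= cfg.n_true_pfas]
    exclusives = set(excl_muscle) | set(excl_liver)
    eligible = [r.code for r in rows if r.code not in exclusives]
    picked = rng.choice(len(eligible), size=cfg.n_up_liver + cfg.n_up_muscle, replace=False)
    up_liver = {eligible[i] for i in picked[: cfg.n_up_liver]}
    up_muscle = {eligible[i] for i in picked[cfg.n_up_liver:]}
    folds = {
        code: float(rng.uniform(*cfg.fold_range))
        for code in sorted(up_liver | up_muscle)
    }

    features: list[Feature] = []
    spectra: list[Ms2Spectrum] = []
    manifest_rows: list[dict] = []
    library: dict[str, Ms2Spectrum] = {}

    # --- true PFAS ----------------------------------------------------------
    theo_mz: dict[int, float] = {}
    gen_rt: dict[int, float] = {}
    import warnings as _warnings

    for r in rows:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            theo_mz[r.code] = deprotonated_mz(parse_formula(r.formula))
        gen_rt[r.code] = max(0.1, r.rt + float(rng.normal(0.0, cfg.rt_jitter_sd_min)))

    for r in rows:
        fid = f"F{r.code:04d}"
        obs_mz = theo_mz[r.code] * (1.0 + float(rng.normal(0.0, cfg.mass_error_sd_ppm)) * 1e-6)
        base = r.max_area / 3.0
        tissue_mult = {"liver": 1.0, "muscle": 1.0}
        if r.code in up_liver:
            tissue_mult["liver"] = folds[r.code]
        elif r.code in up_muscle:
            tissue_mult["muscle"] = folds[r.code]
        present_in = {"liver", "muscle"}
        if r.code in excl_muscle:
            present_in = {"muscle"}
        elif r.code in excl_liver:
            present_in = {"liver"}

        areas: dict[str, float] = {}
        bio_value: dict[tuple[str, str], float] = {}
        for tissue in ("liver", "muscle"):
            for a in range(1, cfg.n_per_group + 1):
                animal = f"A{a:02d}"
                if tissue in present_in:
                    v = base * tissue_mult[tissue] * float(rng.lognormal(0.0, sigma_bio))
                else:
                    v = 0.0
                bio_value[(tissue, animal)] = v
        for s in real:
            v = bio_value[(s.group, s.animal_id)]
            areas[s.sample_id] = (
                v * loading[s.sample_id] * float(rng.lognormal(0.0, sigma_tech))
                if v > 0
                else 0.0
            )
        pooled = float(np.mean([v for v in bio_value.values()]))
        for s in qcs:
            areas[s.sample_id] = pooled * loading[s.sample_id] * float(
                rng.lognormal(0.0, sigma_tech)
            )
        for s in blanks:
            areas[s.sample_id] = 0.0

        # query MS2: diagnostic ions with perturbed intensities + a few noise peaks
        lib_peaks = [
            (frag, float(rng.uniform(20.0, 100.0))) for frag in r.diagnostic_ions
        ]
        if r.iupac_name not in library:
            library[r.iupac_name] = Ms2Spectrum(
                ms2_id=f"lib_{r.code:04d}",
                precursor_mz=theo_mz[r.code],
                peaks=list(lib_peaks),
                collision_energy="10,70",
            )
        query_peaks = [
            (mzf, inten * float(rng.lognormal(0.0, 0.2))) for mzf, inten in lib_peaks
        ]
        n_noise = int(rng.poisson(3.0))
        for _ in range(n_noise):
            query_peaks.append(
                (float(rng.uniform(50.0, max(60.0, obs_mz - 5))), float(rng.uniform(1.0, 8.0)))
            )
        ms2_id = f"ms2_{fid}"
        spectra.append(
            Ms2Spectrum(ms2_id=ms2_id, precursor_mz=obs_mz, peaks=query_peaks,
                        collision_energy="10,70")
        )
        features.append(
            Feature(feature_id=fid, mz=obs_mz, rt=gen_rt[r.code], areas=areas, ms2_id=ms2_id)
        )
        effect_tissue = (
            "liver" if r.code in up_liver else "muscle" if r.code in up_muscle else ""
        )
        manifest_rows.append(
            {
                "feature_id": fid,
                "origin": "true_pfas",
                "formula": r.formula,
                "code": r.code,
                "series_id": "",
                "effect_tissue": effect_tissue,
                "effect_fold": folds.get(r.code, 1.0),
                "exclusive_to": (
                    "muscle" if r.code in excl_muscle
                    else "liver" if r.code in excl_liver
                    else ""
                ),
                "standard_evidence": r.confidence_level == 1,
            }
        )

    # series ground truth from noise-free masses and the generated RTs
    planted_series = _planted_series_truth(rows, gen_rt, theo_mz)
    series_of = {fid: s.series_id for s in planted_series for fid in s.member_feature_ids}
    for m in manifest_rows:
        m["series_id"] = series_of.get(m["feature_id"], "")

    # --- blank contaminants -------------------------------------------------
    for i in range(cfg.n_blank_contaminants):
        fid = f"C{i + 1:04d}"
        mz = float(rng.uniform(200.0, 900.0))
        rt = float(rng.uniform(0.5, cfg.run_length_min - 0.5))
        blank_level = 10.0 ** float(rng.uniform(5.5, 7.0))
        ratio = float(rng.uniform(0.5, 8.0))  # strictly below the removal threshold
        raw = rng.lognormal(0.0, sigma_bio, size=len(real))
        raw = raw / raw.max() * (ratio * blank_level)  # max real area = ratio x blank
        areas = {s.sample_id: float(v) for s, v in zip(real, raw)}
        for s in blanks:
            areas[s.sample_id] = blank_level * float(rng.lognormal(0.0, sigma_tech))
        # blank max can only shrink below blank_level by tech noise; pin it
        bmax = max(areas[s.sample_id] for s in blanks)
        for s in blanks:
            areas[s.sample_id] *= blank_level / bmax if bmax > 0 else 1.0
        for s in qcs:
            areas[s.sample_id] = ratio * blank_level * 0.5 * float(
                rng.lognormal(0.0, sigma_tech)
            )
        features.append(Feature(feature_id=fid, mz=mz, rt=rt, areas=areas, ms2_id=None))
        manifest_rows.append(
            {
                "feature_id": fid,
                "origin": "blank_contaminant",
                "formula": "",
                "code": 0,
                "series_id": "",
                "effect_tissue": "",
                "effect_fold": 1.0,
                "exclusive_to": "",
                "standard_evidence": False,
            }
        )

    # --- hydrogen-rich background -------------------------------------------
    for i in range(cfg.n_background_features):
        fid = f"B{i + 1:04d}"
        nominal = int(rng.integers(200, 900))
        kmd = float(rng.uniform(*cfg.background_kmd_range))
        mz = (nominal + kmd) * CF2_EXACT_MASS / CF2_NOMINAL_MASS
        rt = float(rng.uniform(0.5, cfg.run_length_min - 0.5))
        level = 10.0 ** float(rng.uniform(4.5, 6.8))
        raw = level * rng.lognormal(0.0, sigma_bio, size=len(real))
        areas = {s.sample_id: float(v) for s, v in zip(real, raw)}
        for s in blanks:
            areas[s.sample_id] = 0.0
        for s in qcs:
            areas[s.sample_id] = level * float(rng.lognormal(0.0, sigma_tech))
        ms2_id = None
        if float(rng.uniform()) < cfg.background_ms2_fraction:
            ms2_id = f"ms2_{fid}"
            n_pk = 2 + int(rng.poisson(4.0))
            pks = [
                (float(rng.uniform(50.0, mz)), float(rng.uniform(1.0, 100.0)))
                for _ in range(n_pk)
            ]
            spectra.append(
                Ms2Spectrum(ms2_id=ms2_id, precursor_mz=mz, peaks=pks,
                            collision_energy="10,70")
            )
        features.append(Feature(feature_id=fid, mz=mz, rt=rt, areas=areas, ms2_id=ms2_id))
        manifest_rows.append(
            {
                "feature_id": fid,
                "origin": "background",
                "formula": "",
                "code": 0,
                "series_id": "",
                "effect_tissue": "",
                "effect_fold": 1.0,
                "exclusive_to": "",
                "standard_evidence": False,
            }
        )

    suspects = curated_suspect_list()[: cfg.n_true_pfas]
    manifest = pd.DataFrame(manifest_rows)
    return Scenario(
        config=cfg,
        samples=samples,
        features=features,
        spectra=spectra,
        suspects=suspects,
        library=library,
        manifest=manifest,
        planted_series=planted_series,
    )


# ---------------------------------------------------------------------------
# disk round trip
# ---------------------------------------------------------------------------

SCENARIO_FILES = (
    "samples.tsv",
    "features.tsv",
    "spectra.mgf",
    "suspects.tsv",
    "library.mgf",
    "manifest.tsv",
)


def export_scenario(scenario: Scenario, outdir: str | Path) -> list[Path]:
    """Write the scenario to six plain-text files; returns the paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_sample_table(scenario.samples, out / "samples.tsv")
    write_feature_table(scenario.features, scenario.samples, out / "features.tsv")
    write_mgf(scenario.spectra, out / "spectra.mgf")
    write_suspect_list(scenario.suspects, out / "suspects.tsv")
    lib = [scenario.library[name] for name in sorted(scenario.library)]
    write_mgf(lib, out / "library.mgf")
    with open(out / "manifest.tsv", "w") as fh:
        scenario.manifest.to_csv(fh, sep="\t", index=False)
    return [out / name for name in SCENARIO_FILES]


def read_scenario(indir: str | Path) -> Scenario:
    """Read an exported scenario back from disk (manifest included)."""
    ind = Path(indir)
    samples = read_sample_table(ind / "samples.tsv")
    features = read_feature_table(ind / "features.tsv", samples)
    spectra = read_mgf(ind / "spectra.mgf")
    suspects = read_suspect_list(ind / "suspects.tsv")
    lib_list = read_mgf(ind / "library.mgf")
    manifest = pd.read_csv(ind / "manifest.tsv", sep="\t", keep_default_na=False)
    # library spectra are keyed by suspect name via their lib_<code> id order
    code_to_name = {f"lib_{i + 1:04d}": s.name for i, s in enumerate(suspects)}
    library = {code_to_name.get(s.ms2_id, s.ms2_id): s for s in lib_list}
    return Scenario(
        config=ScenarioConfig(),
        samples=samples,
        features=features,
        spectra=spectra,
        suspects=suspects,
        library=library,
        manifest=manifest,
    )
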