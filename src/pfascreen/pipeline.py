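"""High-level orchestration: prioritize -> annotate -> differential -> report.

The CLI is a thin wrapper over these functions; they are equally usable
from a notebook.  All stage outputs are plain tab-separated tables plus a
JSON run report whose counts are regenerable from the tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from . import __version__
from .annotate import Annotation, annotate_features, match_suspects
from .diffstats import (
    DiffResult,
    diff_table,
    hclust_heatmap,
    linkage_to_newick,
    log2_transform,
    normalize,
    pca,
    volcano,
)
from .io import Feature, Ms2Spectrum, SampleRecord, SuspectEntry
from .prioritize import FilterConfig, FunnelReport, collapse_replicates, run_cascade

#: The default profile mirrors the published parameter set: blank ratio 10,
#: intensity cutoff 1e6, Kendrick window [-0.25, +0.15], MS2 required,
#: volcano at p 0.05 and |log2FC| 1.
PAPER_PROFILE = "paper2024"


@dataclass
class PipelineConfig:
    """Single config governing every stage; YAML keys mirror the fields."""

    filters: FilterConfig = field(default_factory=FilterConfig)
    suspect_tol_ppm: float = 5.0
    frag_tol_ppm: float = 10.0
    rt_tol_min: float = 0.2
    p_threshold: float = 0.05
    lfc_threshold: float = 1.0
    fdr: bool = False
    skip_diff: bool = False
    profile: str = PAPER_PROFILE

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        filt = raw.pop("filters", {})
        if "kmd_window" in filt:
            filt["kmd_window"] = tuple(filt["kmd_window"])
        cfg = cls(**{k: v for k, v in raw.items() if k != "filters"})
        cfg.filters = FilterConfig(**filt)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["filters"]["kmd_window"] = list(d["filters"]["kmd_window"])
        return d


@dataclass
class RunResult:
    candidates: list[Feature]
    funnel: FunnelReport
    annotations: list[Annotation]
    diff_results: list[DiffResult] | None
    abundance: pd.DataFrame | None
    report: dict


def annotation_table(annotations: Sequence[Annotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [a.feature_id for a in annotations],
            "suspect_name": [a.suspect_name or "" for a in annotations],
            "source_list": [a.source_list or "" for a in annotations],
            "delta_ppm": [a.delta_ppm for a in annotations],
            "spectral_score": [a.spectral_score for a in annotations],
            "class_score": [a.class_score for a in annotations],
            "n_diagnostic_matched": [a.n_diagnostic_matched for a in annotations],
            "series_id": [a.series_id or "" for a in annotations],
            "standard_match": [a.standard_match for a in annotations],
            "isomer_tag": [a.isomer_tag or "" for a in annotations],
            "confidence_level": [a.confidence_level for a in annotations],
            "rationale": ["; ".join(a.rationale) for a in annotations],
        }
    )


def abundance_matrix(
    features: Sequence[Feature],
    samples: Sequence[SampleRecord],
    labels: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Compounds x tissue-samples matrix of areas plus the group labels.

    ``labels`` optionally maps feature_id -> display label (suspect name);
    unlabeled features keep their id.  Blank and QC columns are excluded.
    """
    labels = labels or {}
    tissue = [s for s in samples if s.group in ("liver", "muscle")]
    cols = [s.sample_id for s in tissue]
    data = {}
    for f in features:
        label = labels.get(f.feature_id, f.feature_id)
        if label in data:  # isomers can share a suspect name candidate
            label = f"{label} [{f.feature_id}]"
        data[label] = [f.areas.get(c, 0.0) for c in cols]
    matrix = pd.DataFrame.from_dict(data, orient="index", columns=cols)
    groups = pd.Series({s.sample_id: s.group for s in tissue})
    return matrix, groups


def run_pipeline(
    features: Sequence[Feature],
    samples: Sequence[SampleRecord],
    suspects: Sequence[SuspectEntry],
    spectra: Sequence[Ms2Spectrum],
    library: dict[str, Ms2Spectrum] | None = None,
    config: PipelineConfig | None = None,
    exclusion: Sequence[tuple[float, float]] | None = None,
) -> RunResult:
    """Run prioritization, annotation and (optionally) differential analysis."""
    cfg = config or PipelineConfig()
    collapsed, csamples = collapse_replicates(
        features, samples, cfg.filters.replicate_collapse
    )
    spectra_by_id = {s.ms2_id: s for s in spectra}

    suspect_hits = {
        f.feature_id
        for f in collapsed
        if match_suspects(f.mz, suspects, cfg.suspect_tol_ppm)
    } if suspects else set()

    candidates, funnel = run_cascade(
        collapsed, csamples, cfg.filters, suspect_hits, exclusion
    )
    annotations = annotate_features(
        candidates,
        suspects,
        spectra_by_id,
        library,
        tol_ppm=cfg.suspect_tol_ppm,
        frag_tol_ppm=cfg.frag_tol_ppm,
        rt_tol_min=cfg.rt_tol_min,
    )

    diff_results = None
    matrix = None
    if not cfg.skip_diff:
        labels = {
            a.feature_id: a.suspect_name
            for a in annotations
            if a.suspect_name is not None
        }
        matrix, groups = abundance_matrix(candidates, csamples, labels)
        if matrix.shape[0] > 0:
            diff_results = volcano(
                matrix, groups, cfg.p_threshold, cfg.lfc_threshold, fdr=cfg.fdr
            )

    cl_counts: dict[int, int] = {}
    for a in annotations:
        cl_counts[a.confidence_level] = cl_counts.get(a.confidence_level, 0) + 1
    report = {
        "version": __version__,
        "profile": cfg.profile,
        "config": cfg.to_dict(),
        "funnel": funnel.to_frame().to_dict(orient="records"),
        "n_candidates": len(candidates),
        "confidence_levels": {str(k): v for k, v in sorted(cl_counts.items())},
        "differential": None,
    }
    if diff_results is not None:
        report["differential"] = {
            "up_liver": sum(r.volcano_class == "up_liver" for r in diff_results),
            "up_muscle": sum(r.volcano_class == "up_muscle" for r in diff_results),
            "ns": sum(r.volcano_class == "ns" for r in diff_results),
            "exclusive_liver": sum(r.exclusive_to == "liver" for r in diff_results),
            "exclusive_muscle": sum(r.exclusive_to == "muscle" for r in diff_results),
        }
    elif cfg.skip_diff:
        report["differential"] = "skipped"
    return RunResult(candidates, funnel, annotations, diff_results, matrix, report)


def write_run_outputs(result: RunResult, outdir: str | Path) -> None:
    """Write every stage table, the trees, and the machine-readable report."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    result.funnel.to_frame().to_csv(out / "funnel.tsv", sep="\t", index=False)
    cand = pd.DataFrame(
        {
            "feature_id": [f.feature_id for f in result.candidates],
            "mz": [f.mz for f in result.candidates],
            "rt": [f.rt for f in result.candidates],
            "provenance": ["|".join(f.provenance) for f in result.candidates],
        }
    )
    cand.to_csv(out / "candidates.tsv", sep="\t", index=False)
    annotation_table(result.annotations).to_csv(
        out / "annotations.tsv", sep="\t", index=False
    )
    if result.diff_results is not None:
        diff_table(result.diff_results).to_csv(out / "diff.tsv", sep="\t", index=False)
        sig = [
            r.compound
            for r in result.diff_results
            if r.volcano_class in ("up_liver", "up_muscle")
        ]
        matrix = result.abundance
        if matrix is not None and len(sig) >= 2:
            logm = log2_transform(normalize(matrix))
            scores, loadings, evr = pca(logm)
            scores.to_csv(out / "pca_scores.tsv", sep="\t")
            loadings.to_csv(out / "pca_loadings.tsv", sep="\t")
            row_link, col_link, ordered = hclust_heatmap(logm.loc[sig])
            ordered.to_csv(out / "heatmap_matrix.tsv", sep="\t")
            (out / "compound_tree.nwk").write_text(
                linkage_to_newick(row_link, list(logm.loc[sig].index)) + "\n"
            )
            (out / "sample_tree.nwk").write_text(
                linkage_to_newick(col_link, list(logm.columns)) + "\n"
            )
    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2)
    (out / "report.txt").write_text(
        "\n".join(
            [
                f"pfascreen {__version__} run report",
                *result.funnel.log_lines(),
                f"candidates: {result.report['n_candidates']}",
                f"confidence levels: {result.report['confidence_levels']}",
                f"differential: {result.report['differential']}",
                "",
            ]
        )
    )
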