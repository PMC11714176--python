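"""Pipeline orchestration: profile tumors, build scores, analyse a cohort.

``score_cohort`` turns per-tumor cell maps plus tumor-level measurements
(CLR count, margin length, PD-L1 histoscore) into the score table;
``analyze_cohort`` merges scores with clinical records, applies the 30-day
post-operative exclusion and produces the association report, the survival
model battery and Kaplan–Meier step files; ``run_pipeline`` wires the stages
together and writes a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .scoring import (
    CLR_CUTOFF_PER_MM,
    DENSITY_BREAKS,
    clr_categorize,
    clr_density,
    pdl1_tumor_categorize,
    percentile_score,
    roc_optimal_cutoff,
    tertile_classify,
)
from .spatial import CorePattern, region_density, tumor_gcross_profile
from .survival import (
    exclude_postoperative,
    km_estimate,
    reverse_km_median_followup,
    run_model_battery,
)
from .tables import table1_report

log = logging.getLogger("tmescore")

TABLE1_VARIABLES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("age_group", ("<60", "60-80", ">80")),
    ("sex", ("male", "female")),
    ("cci_group", ("1-2", "3-4", ">=5")),
    ("location", ("right", "left")),
    ("t_stage", ("1", "2", "3", "4")),
    ("n_stage", ("0", "1", "2")),
    ("m_stage", ("0", "1")),
    ("tnm_stage", ("I", "II", "III", "IV")),
    ("lvi", ("no", "yes")),
    ("budding_group", ("0-4", "5-9", ">=10")),
    ("grade", ("low", "high")),
    ("braf", ("no", "yes")),
    ("necrosis_group", ("<10%", "10-<40%", ">=40%")),
    ("stroma_group", ("<50%", ">=50%")),
    ("density_score", ("low", "intermediate", "high")),
    ("proximity_score", ("low", "intermediate", "high")),
    ("clr_category", ("low", "high")),
    ("pdl1_tumor_category", ("negative", "1-<5", ">=5")),
    ("lynch", ("no", "yes")),
    ("adjuvant", ("no", "yes")),
)

KM_FEATURES = ("proximity_score", "clr_category", "necrosis_group", "stroma_group",
               "pdl1_mac_ct_tertile", "pdl1_mac_im_tertile")


@dataclass
class PipelineConfig:
    """Run configuration; mirrors the CLI flags."""

    cells_path: str | None = None
    geometry_path: str | None = None
    patients_path: str | None = None
    scores_path: str | None = None
    out_dir: str = "out"
    gcross_radius_um: float = 20.0
    percentile_breaks: tuple[float, float] = DENSITY_BREAKS
    clr_cutoff_per_mm: float | str = CLR_CUTOFF_PER_MM  # number or "auto"
    seed: int = 0
    verbosity: int = 1

    def validate(self) -> None:
        if not self.gcross_radius_um > 0:
            raise ValueError("gcross_radius_um must be positive")
        lo, hi = self.percentile_breaks
        if not (0 < lo < hi < 100):
            raise ValueError("percentile_breaks must be strictly increasing in (0,100)")
        for p in (self.cells_path, self.geometry_path, self.patients_path,
                  self.scores_path):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)


def profile_tumor(
    patterns: Sequence[CorePattern], gcross_radius_um: float = 20.0
) -> dict:
    """Per-tumor derived quantities: region densities and pooled G-cross."""
    prof: dict = {}
    for marker, phen in (("CD3", "T_CD3"), ("CD8", "T_CD8")):
        for region in ("CT", "IM"):
            prof[f"density_{marker.lower()}_{region.lower()}"] = region_density(
                patterns, phen, region, marker_panel=marker
            )
    gx = tumor_gcross_profile(patterns, r=gcross_radius_um)
    for (marker, region), val in gx.items():
        key = f"gcross_{marker.lower()}_{region.lower()}"
        prof[key] = np.nan if val.missing else val.value
    for region in ("CT", "IM"):
        prof[f"density_pdl1_mac_{region.lower()}"] = region_density(
            patterns, "macrophage", region, marker_panel="multiplex", pdl1=True
        )
        prof[f"density_pd1_t_{region.lower()}"] = region_density(
            patterns, "T_CD3", region, marker_panel="multiplex", pd1=True
        )
    return prof


def score_cohort(
    patterns_by_tumor: Mapping[str, Sequence[CorePattern]],
    tumor_data: pd.DataFrame | None = None,
    gcross_radius_um: float = 20.0,
    percentile_breaks: tuple[float, float] = DENSITY_BREAKS,
    clr_cutoff_per_mm: float | str = CLR_CUTOFF_PER_MM,
) -> pd.DataFrame:
    """Build the per-tumor score table from cell maps + tumor-level inputs.

    ``tumor_data`` (indexed or keyed by ``patient_id``) supplies
    ``clr_count``, ``margin_length_mm``, ``pdl1_tumor_histoscore`` and —
    when the CLR cutoff is "auto" — ``dss_event`` for the ROC scan.
    """
    rows = []
    for tumor_id, pats in patterns_by_tumor.items():
        prof = profile_tumor(pats, gcross_radius_um)
        prof["patient_id"] = tumor_id
        rows.append(prof)
    scores = pd.DataFrame(rows).set_index("patient_id")

    dens = percentile_score(
        scores[["density_cd3_ct", "density_cd3_im",
                "density_cd8_ct", "density_cd8_im"]],
        percentile_breaks,
    )
    scores["density_score"] = dens["score"].to_numpy()
    scores["density_mean_percentile"] = dens["mean_percentile"].to_numpy()
    prox = percentile_score(
        scores[["gcross_cd3_ct", "gcross_cd3_im",
                "gcross_cd8_ct", "gcross_cd8_im"]],
        percentile_breaks,
    )
    scores["proximity_score"] = prox["score"].to_numpy()
    scores["proximity_mean_percentile"] = prox["mean_percentile"].to_numpy()

    for col in ("density_cd3_ct", "density_cd3_im", "density_cd8_ct",
                "density_cd8_im", "density_pdl1_mac_ct", "density_pdl1_mac_im",
                "density_pd1_t_ct", "density_pd1_t_im"):
        vals = scores[col].to_numpy(dtype=float)
        if np.isfinite(vals).sum() >= 2:
            tert = tertile_classify(vals)
        else:
            tert = np.full(vals.shape, None, dtype=object)
        scores[col.replace("density_", "") + "_tertile"] = tert

    if tumor_data is not None:
        td = tumor_data.set_index("patient_id") if "patient_id" in tumor_data else tumor_data
        td = td.reindex(scores.index)
        if {"clr_count", "margin_length_mm"} <= set(td.columns):
            dens_clr = clr_density(td["clr_count"], td["margin_length_mm"])
            scores["clr_density_per_mm"] = dens_clr
            cutoff = clr_cutoff_per_mm
            if cutoff == "auto":
                if "dss_event" not in td.columns:
                    raise ValueError("clr cutoff 'auto' needs dss_event in tumor_data")
                ok = ~np.isnan(np.asarray(dens_clr, dtype=float))
                cutoff = roc_optimal_cutoff(
                    np.asarray(dens_clr)[ok],
                    td["dss_event"].to_numpy()[ok].astype(bool),
                ).cutoff
            scores["clr_category"] = clr_categorize(dens_clr, float(cutoff))
            scores.attrs["clr_cutoff_per_mm"] = float(cutoff)
        if "pdl1_tumor_histoscore" in td.columns:
            scores["pdl1_tumor_category"] = pdl1_tumor_categorize(
                td["pdl1_tumor_histoscore"]
            )
    return scores.reset_index()


# columns the score stage contributes to the analysis cohort
_SCORE_COLUMNS = ("density_score", "proximity_score", "clr_density_per_mm",
                  "clr_category", "pdl1_tumor_category",
                  "pdl1_mac_ct_tertile", "pdl1_mac_im_tertile")


def analyze_cohort(
    patients: pd.DataFrame,
    scores: pd.DataFrame | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Association tables + survival battery on a (score-merged) cohort.

    Post-operative deaths are excluded before any survival model.  Returns a
    dict with the merged cohort, exclusion count, Table-1 report, fitted
    models, follow-up estimate and KM step frames; writes the declared output
    files when ``out_dir`` is given.
    """
    cohort = patients.copy()
    if scores is not None:
        overlap = [c for c in _SCORE_COLUMNS if c in scores.columns]
        cohort = cohort.drop(columns=[c for c in overlap if c in cohort.columns])
        cohort = cohort.merge(
            scores[["patient_id", *overlap]], on="patient_id", how="left"
        )

    filtered, n_excluded = exclude_postoperative(cohort)
    log.info("post-operative exclusion: %d removed, %d retained",
             n_excluded, len(filtered))

    variables = [v for v in TABLE1_VARIABLES if v[0] in cohort.columns]
    report = table1_report(cohort, variables, col_var="metastatic",
                           col_order=("no", "yes"))

    followup = reverse_km_median_followup(
        filtered["os_time"].to_numpy(), filtered["os_event"].to_numpy()
    )
    fits = run_model_battery(filtered)

    km_steps: dict[str, pd.DataFrame] = {}
    for feat in KM_FEATURES:
        if feat not in filtered.columns:
            continue
        frames = []
        for level, grp in filtered.dropna(subset=[feat]).groupby(feat):
            if len(grp) == 0:
                continue
            est = km_estimate(grp["dss_time"].to_numpy(),
                              grp["dss_event"].to_numpy(), label=str(level))
            f = est.steps()
            f.insert(0, "level", str(level))
            frames.append(f)
        if frames:
            km_steps[feat] = pd.concat(frames, ignore_index=True)

    result = dict(cohort=cohort, filtered=filtered, n_excluded=n_excluded,
                  table1=report, followup=followup, fits=fits, km_steps=km_steps)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_frame().to_csv(out / "table1.tsv", sep="\t", index=False)
        (out / "table1.txt").write_text(report.render())
        model_rows = []
        for key, fit in fits.items():
            t = fit.table.copy()
            t.insert(0, "model", key)
            t.insert(1, "outcome", fit.outcome)
            model_rows.append(t)
        if model_rows:
            pd.concat(model_rows, ignore_index=True).to_csv(
                out / "cox_models.tsv", sep="\t", index=False
            )
        for feat, steps in km_steps.items():
            steps.to_csv(out / f"km_{feat}.tsv", sep="\t", index=False)
    return result


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(asdict(config), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(config: PipelineConfig, out_dir: Path, extra: dict | None = None) -> None:
    manifest = {
        "config": asdict(config),
        "config_hash": config_hash(config),
        "seed": config.seed,
        "versions": {
            "tmescore": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    if extra:
        manifest.update(extra)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def run_pipeline(config: PipelineConfig) -> dict:
    """score → associations → survival models, with manifest; see the CLI."""
    from .io import read_cell_table, read_patient_table

    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    patients = read_patient_table(config.patients_path)
    if config.scores_path is not None:
        scores = pd.read_csv(config.scores_path, sep="\t", dtype={"patient_id": str})
    elif config.cells_path is not None:
        patterns = read_cell_table(config.cells_path, config.geometry_path)
        log.info("scoring %d tumors", len(patterns))
        scores = score_cohort(
            patterns, tumor_data=patients,
            gcross_radius_um=config.gcross_radius_um,
            percentile_breaks=config.percentile_breaks,
            clr_cutoff_per_mm=config.clr_cutoff_per_mm,
        )
        scores.to_csv(out / "scores.tsv", sep="\t", index=False)
    else:
        scores = None

    result = analyze_cohort(patients, scores, out_dir=out)
    write_manifest(config, out, extra={
        "n_patients": len(patients),
        "n_postoperative_excluded": result["n_excluded"],
        "median_followup_years": result["followup"].median_years,
    })
    return result
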