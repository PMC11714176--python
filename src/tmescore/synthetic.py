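"""Synthetic TMA-core point patterns and patient cohorts with known truth.

Patient-level data behind this kind of study are not shareable, so every
pipeline stage is exercised on simulated data whose generating parameters
are known exactly:

* **Core patterns** — tumor cells follow a Thomas cluster process (Poisson
  parents, Gaussian offspring) thinned to the 1-mm-diameter disc; immune
  cells are a mixture of a completely spatially random (CSR) component and an
  "attracted" component placed as Gaussian offspring of randomly chosen tumor
  cells.  The attraction fraction ρ is the ground-truth co-localization dial
  that the G-cross statistic must recover monotonically.
* **Cohorts** — categorical covariates drawn to target marginals; survival
  via a Weibull proportional-hazards model with chosen log-hazard effects.
  Two latent cause-specific times are drawn (cancer, driven by the DSS
  log-HRs; other causes, driven by the OS/other log-HRs); overall survival is
  their minimum and the disease-specific event fires when the cancer cause
  wins.  Cause-specific Cox regression therefore recovers the DSS effects
  exactly in expectation.

One global seed drives a named stream per sub-generator, so adding a
variable never perturbs earlier draws.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spatial import CellRecord, CorePattern

# ---------------------------------------------------------------------------
# seeding

def stream(seed: int, name: str) -> np.random.Generator:
    """Named, platform-stable child RNG of a single global seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])
    )


# ---------------------------------------------------------------------------
# core point patterns

@dataclass
class PatternParams:
    """Parameters of one synthetic TMA core.

    Intensities are in cells/mm²; lengths in μm.  ``attraction`` is the
    fraction ρ of each immune phenotype placed as Gaussian offspring (sd
    ``attraction_sd``) of random tumor cells; the rest are CSR.
    """

    radius: float = 500.0
    tumor_parent_intensity: float = 50.0     # Thomas parents per mm²
    tumor_offspring_mean: float = 16.0       # mean cells per parent
    tumor_offspring_sd: float = 25.0         # Gaussian cluster spread, μm
    immune_intensity: Mapping[str, float] = field(
        default_factory=lambda: {"T_CD3": 300.0, "other": 400.0}
    )
    attraction: float = 0.3
    attraction_sd: float = 15.0              # μm
    p_pd1_tcell: float = 0.3
    p_pdl1_macrophage: float = 0.4
    p_pdl1_tumor: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.attraction <= 1.0:
            raise ValueError("attraction must lie in [0, 1]")
        if self.attraction_sd <= 0 or self.tumor_offspring_sd <= 0:
            raise ValueError("Gaussian spreads must be positive")
        if any(v < 0 for v in self.immune_intensity.values()):
            raise ValueError("intensities must be non-negative")


def _disc_area_mm2(radius_um: float) -> float:
    return math.pi * (radius_um / 1000.0) ** 2


def _uniform_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0.0, 2.0 * math.pi, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _thomas_disc(
    rng: np.random.Generator,
    radius: float,
    parent_intensity_mm2: float,
    offspring_mean: float,
    offspring_sd: float,
) -> np.ndarray:
    """Thomas cluster process restricted to the disc centered at the origin.

    Parents are simulated on a square extended by 3 sd so clusters whose
    parent falls just outside still contribute; offspring outside the disc
    are discarded (thinning).
    """
    half = radius + 3.0 * offspring_sd
    area_mm2 = (2.0 * half / 1000.0) ** 2
    n_parents = rng.poisson(parent_intensity_mm2 * area_mm2)
    pts = []
    for _ in range(n_parents):
        parent = rng.uniform(-half, half, size=2)
        n_off = rng.poisson(offspring_mean)
        if n_off == 0:
            continue
        off = parent + rng.normal(0.0, offspring_sd, size=(n_off, 2))
        keep = np.hypot(off[:, 0], off[:, 1]) <= radius
        pts.append(off[keep])
    if not pts:
        return np.empty((0, 2))
    return np.concatenate(pts)


def _attracted_points(
    rng: np.random.Generator,
    n: int,
    anchors: np.ndarray,
    sd: float,
    radius: float,
    max_tries: int = 200,
) -> np.ndarray:
    """Gaussian offspring of random anchor points, resampled into the disc."""
    out = np.empty((n, 2))
    for i in range(n):
        for _ in range(max_tries):
            a = anchors[rng.integers(anchors.shape[0])]
            p = a + rng.normal(0.0, sd, size=2)
            if math.hypot(p[0], p[1]) <= radius:
                out[i] = p
                break
        else:  # anchor wedged at the boundary: fall back to CSR
            out[i] = _uniform_disc(rng, 1, radius)[0]
    return out


def simulate_core_pattern(
    params: PatternParams,
    core_id: str = "core",
    region: str = "CT",
    marker_panel: str | None = None,
    center: tuple[float, float] = (0.0, 0.0),
) -> CorePattern:
    """Draw one synthetic core; fully deterministic under ``params.seed``."""
    R = params.radius
    rng_t = stream(params.seed, f"{core_id}:tumor")
    tumor = _thomas_disc(
        rng_t, R, params.tumor_parent_intensity,
        params.tumor_offspring_mean, params.tumor_offspring_sd,
    )
    cells: list[CellRecord] = []
    rng_flag = stream(params.seed, f"{core_id}:flags")
    for x, y in tumor:
        cells.append(
            CellRecord(
                x + center[0], y + center[1], "tumor",
                pdl1_positive=bool(rng_flag.random() < params.p_pdl1_tumor),
                region=region,
            )
        )
    for phen, lam in params.immune_intensity.items():
        rng_p = stream(params.seed, f"{core_id}:{phen}")
        n = rng_p.poisson(lam * _disc_area_mm2(R))
        if n == 0:
            continue
        rho = params.attraction if tumor.shape[0] > 0 and phen != "other" else 0.0
        n_attr = rng_p.binomial(n, rho)
        pts = []
        if n_attr:
            pts.append(_attracted_points(rng_p, n_attr, tumor, params.attraction_sd, R))
        if n - n_attr:
            pts.append(_uniform_disc(rng_p, n - n_attr, R))
        for x, y in np.concatenate(pts):
            pd1 = phen in ("T_CD3", "T_CD8") and rng_p.random() < params.p_pd1_tcell
            pdl1 = phen == "macrophage" and rng_p.random() < params.p_pdl1_macrophage
            cells.append(
                CellRecord(
                    x + center[0], y + center[1], phen,
                    pd1_positive=bool(pd1), pdl1_positive=bool(pdl1), region=region,
                )
            )
    return CorePattern(
        core_id=core_id, center=center, radius=R, cells=tuple(cells),
        region=region, marker_panel=marker_panel,
    )


# ---------------------------------------------------------------------------
# cohorts

#: Categorical marginals of the emulated 171-patient cohort (counts).
REFERENCE_MARGINALS: dict[str, dict[str, int]] = {
    "age_group": {"<60": 21, "60-80": 95, ">80": 55},
    "sex": {"male": 55, "female": 116},
    "cci_group": {"1-2": 39, "3-4": 76, ">=5": 55},          # + 1 missing
    "location": {"right": 146, "left": 25},
    "t_stage": {"1": 10, "2": 20, "3": 112, "4": 29},
    "n_stage": {"0": 115, "1": 29, "2": 27},
    "m_stage": {"0": 160, "1": 11},
    "tnm_stage": {"I": 26, "II": 85, "III": 49, "IV": 11},
    "lvi": {"no": 149, "yes": 22},
    "budding_group": {"0-4": 130, "5-9": 22, ">=10": 19},
    "grade": {"low": 87, "high": 84},
    "braf": {"no": 54, "yes": 117},
    "necrosis_group": {"<10%": 91, "10-<40%": 58, ">=40%": 22},
    "stroma_group": {"<50%": 95, ">=50%": 76},
    "density_score": {"low": 13, "intermediate": 81, "high": 65},     # + 12 missing
    "proximity_score": {"low": 10, "intermediate": 64, "high": 84},   # + 13 missing
    "clr_category": {"low": 55, "high": 116},
    "pdl1_tumor_category": {"negative": 84, "1-<5": 32, ">=5": 41},   # + 14 missing
    "lynch": {"no": 164, "yes": 7},
    "adjuvant": {"no": 113, "yes": 58},
    "metastatic": {"no": 136, "yes": 35},
}

REFERENCE_N = 171
REFERENCE_MISSING = {"cci_group": 1, "density_score": 12, "proximity_score": 13,
                 "pdl1_tumor_category": 14}
#: CLR × metastasis cross-tab (rows low/high, cols non-metastatic/metastatic)
REFERENCE_CLR_CROSSTAB = {"no": {"low": 34, "high": 102}, "yes": {"low": 21, "high": 14}}
REFERENCE_POSTOP = {"no": 7, "yes": 2}


def _marginal_probs(counts: Mapping[str, int]) -> dict[str, float]:
    tot = sum(counts.values())
    return {k: v / tot for k, v in counts.items()}


def _default_cohort_covariates() -> dict[str, dict[str, float]]:
    cov = {
        name: _marginal_probs(REFERENCE_MARGINALS[name])
        for name in ("cci_group", "necrosis_group", "stroma_group",
                     "clr_category", "proximity_score")
    }
    cov["tnm_group"] = {"I-II": 111 / 171, "III": 49 / 171, "IV": 11 / 171}
    cov["pdl1_mac_ct_tertile"] = {"low": 1 / 3, "moderate": 1 / 3, "high": 1 / 3}
    cov["pdl1_mac_im_tertile"] = {"low": 1 / 3, "moderate": 1 / 3, "high": 1 / 3}
    return cov


def _default_log_hr_dss() -> dict[str, dict[str, float]]:
    # Effect directions follow the study's findings.  Only one immune factor
    # (CLR) is causal by default, mirroring the one-immune-factor-per-model
    # structure of the adjusted analyses; the other immune covariates are
    # drawn but carry null effects unless the caller sets them.
    return {
        "tnm_group": {"III": math.log(6.0), "IV": math.log(20.0)},
        "necrosis_group": {"10-<40%": math.log(2.5), ">=40%": math.log(4.5)},
        "stroma_group": {">=50%": math.log(2.2)},
        "clr_category": {"low": math.log(2.7)},
    }


def _default_log_hr_other() -> dict[str, dict[str, float]]:
    # Other-cause mortality driven mainly by comorbidity burden.
    return {"cci_group": {"3-4": math.log(2.3), ">=5": math.log(3.8)}}


@dataclass
class CohortParams:
    """Generating parameters of a synthetic patient cohort."""

    n_patients: int = REFERENCE_N
    covariates: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_cohort_covariates
    )
    log_hr_dss: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_log_hr_dss
    )
    log_hr_os: Mapping[str, Mapping[str, float]] = field(
        default_factory=_default_log_hr_other
    )
    baseline_shape: float = 1.1
    baseline_scale_cancer: float = 220.0  # years; cancer deaths are the rarer cause
    baseline_scale_other: float = 32.0    # years
    censor_range: tuple[float, float] = (5.0, 16.0)  # staggered study entry
    metastasis_intercept: float = -1.75
    metastasis_coef: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {"clr_category": {"low": 1.5}}
    )
    postop_death_prob: float = 9 / 171
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        if self.censor_range[1] <= 0:
            raise ValueError("censoring time must be positive")


def _linear_predictor(
    df: pd.DataFrame, coefs: Mapping[str, Mapping[str, float]]
) -> np.ndarray:
    xb = np.zeros(len(df))
    for var, levels in coefs.items():
        if var not in df.columns:
            raise KeyError(f"log-HR refers to unknown covariate {var!r}")
        for level, beta in levels.items():
            xb += beta * (df[var].astype(str) == level).to_numpy(dtype=float)
    return xb


def _weibull_ph_times(
    rng: np.random.Generator, xb: np.ndarray, shape: float, scale: float
) -> np.ndarray:
    """Inverse-transform sampling from S(t) = exp(-(t/scale)^shape * e^xb)."""
    e = rng.exponential(size=xb.size)
    return scale * (e / np.exp(xb)) ** (1.0 / shape)


def simulate_cohort(params: CohortParams) -> tuple[pd.DataFrame, dict]:
    """Draw a cohort; returns (records, ground-truth record).

    Covariates are sampled independently to the marginal targets.  Latent
    cancer and other-cause death times follow Weibull proportional-hazards
    models with ``log_hr_dss`` and ``log_hr_os`` respectively; administrative
    censoring is uniform over ``censor_range``.
    """
    n = params.n_patients
    df = pd.DataFrame({"patient_id": [f"P{i:04d}" for i in range(n)]})
    for var, probs in params.covariates.items():
        rng = stream(params.seed, f"cov:{var}")
        levels = list(probs)
        p = np.asarray([probs[l] for l in levels], dtype=float)
        p = p / p.sum()
        df[var] = rng.choice(levels, size=n, p=p)

    xb_c = _linear_predictor(df, params.log_hr_dss)
    xb_o = _linear_predictor(df, params.log_hr_os)
    rng_t = stream(params.seed, "survival")
    t_cancer = _weibull_ph_times(
        rng_t, xb_c, params.baseline_shape, params.baseline_scale_cancer
    )
    t_other = _weibull_ph_times(
        rng_t, xb_o, params.baseline_shape, params.baseline_scale_other
    )
    censor = rng_t.uniform(*params.censor_range, size=n)
    t_death = np.minimum(t_cancer, t_other)
    os_event = t_death <= censor
    os_time = np.minimum(t_death, censor)
    dss_event = os_event & (t_cancer <= t_other)

    df["os_time"] = os_time
    df["os_event"] = os_event.astype(int)
    df["dss_time"] = os_time
    df["dss_event"] = dss_event.astype(int)

    rng_p = stream(params.seed, "postop")
    postop = rng_p.random(n) < params.postop_death_prob
    df["postoperative_death"] = postop
    if postop.any():
        t_po = rng_p.uniform(1.0 / 365.25, 30.0 / 365.25, size=int(postop.sum()))
        df.loc[postop, "os_time"] = t_po
        df.loc[postop, "dss_time"] = t_po
        df.loc[postop, "os_event"] = 1
        df.loc[postop, "dss_event"] = 0

    if "metastatic" not in df.columns:
        rng_m = stream(params.seed, "metastasis")
        coef = {k: v for k, v in params.metastasis_coef.items() if k in df.columns}
        eta = params.metastasis_intercept + _linear_predictor(df, coef)
        df["metastatic"] = np.where(
            rng_m.random(n) < 1.0 / (1.0 + np.exp(-eta)), "yes", "no"
        )

    truth = {
        "seed": params.seed,
        "n_patients": n,
        "log_hr_dss": {k: dict(v) for k, v in params.log_hr_dss.items()},
        "log_hr_os": {k: dict(v) for k, v in params.log_hr_os.items()},
        "baseline_shape": params.baseline_shape,
        "baseline_scale_cancer": params.baseline_scale_cancer,
        "baseline_scale_other": params.baseline_scale_other,
        "censor_range": list(params.censor_range),
        "n_postoperative": int(postop.sum()),
    }
    return df, truth


def _permuted_multiset(
    rng: np.random.Generator, counts: Mapping[str, int], n: int, n_missing: int = 0
) -> np.ndarray:
    labels: list = []
    for level, c in counts.items():
        labels.extend([level] * c)
    labels.extend([None] * n_missing)
    if len(labels) != n:
        raise ValueError(f"multiset sums to {len(labels)}, expected {n}")
    arr = np.asarray(labels, dtype=object)
    rng.shuffle(arr)
    return arr


def emulate_reference_cohort(seed: int = 0) -> pd.DataFrame:
    """A fixed-seed 171-patient cohort whose categorical marginals match the
    published cohort's counts exactly.

    Each variable is a permuted fixed multiset, drawn independently of the
    others, so only the marginals (plus the pinned CLR × metastasis cross-tab
    and the postoperative-death split) are faithful — the joint distribution
    is synthetic.  Intended for pipeline smoke tests and report-shape checks,
    not for reproducing hazard ratios.
    """
    n = REFERENCE_N
    df = pd.DataFrame({"patient_id": [f"P{i:04d}" for i in range(n)]})

    rng = stream(seed, "emulate:metastatic")
    df["metastatic"] = _permuted_multiset(rng, REFERENCE_MARGINALS["metastatic"], n)

    # Pinned within-group structure: CLR category and postoperative deaths.
    for var, table in (("clr_category", REFERENCE_CLR_CROSSTAB),):
        col = np.empty(n, dtype=object)
        for grp, counts in table.items():
            idx = np.flatnonzero((df["metastatic"] == grp).to_numpy())
            col[idx] = _permuted_multiset(
                stream(seed, f"emulate:{var}:{grp}"), counts, idx.size
            )
        df[var] = col
    postop = np.zeros(n, dtype=bool)
    for grp, k in REFERENCE_POSTOP.items():
        idx = np.flatnonzero((df["metastatic"] == grp).to_numpy())
        pick = stream(seed, f"emulate:postop:{grp}").choice(idx, size=k, replace=False)
        postop[pick] = True
    df["postoperative_death"] = postop

    skip = {"metastatic", "clr_category"}
    for var, counts in REFERENCE_MARGINALS.items():
        if var in skip:
            continue
        rng = stream(seed, f"emulate:{var}")
        df[var] = _permuted_multiset(rng, counts, n, REFERENCE_MISSING.get(var, 0))

    # CLR density / margin length consistent with the pinned categories.
    rng = stream(seed, "emulate:clr_density")
    margin = np.clip(rng.normal(55.0, 12.0, size=n), 25.0, 95.0)
    dens = np.where(
        df["clr_category"].to_numpy() == "high",
        rng.uniform(0.42, 1.5, size=n),
        rng.uniform(0.0, 0.42, size=n),
    )
    count = np.round(dens * margin).astype(int)
    high = df["clr_category"].to_numpy() == "high"
    count[high] = np.maximum(count[high], np.ceil(0.42 * margin[high]).astype(int))
    count[~high] = np.minimum(count[~high], np.ceil(0.42 * margin[~high]).astype(int) - 1)
    df["margin_length_mm"] = margin
    df["clr_count"] = count

    rng = stream(seed, "emulate:histoscore")
    histo = np.full(n, np.nan)
    cat = df["pdl1_tumor_category"].to_numpy(dtype=object)
    histo[cat == "negative"] = rng.uniform(0.0, 1.0, size=int((cat == "negative").sum()))
    histo[cat == "1-<5"] = rng.uniform(1.0, 5.0, size=int((cat == "1-<5").sum()))
    histo[cat == ">=5"] = rng.uniform(5.0, 100.0, size=int((cat == ">=5").sum()))
    df["pdl1_tumor_histoscore"] = histo

    # Survival with moderate stage/comorbidity effects; same clock for DSS/OS.
    xb_c = _linear_predictor(
        df.assign(tnm_group=df["tnm_stage"].map(
            lambda s: "I-II" if s in ("I", "II") else s)),
        {"tnm_group": {"III": math.log(6.0), "IV": math.log(20.0)},
         "clr_category": {"low": math.log(2.7)}},
    )
    xb_o = _linear_predictor(
        df, {"cci_group": {"3-4": math.log(2.3), ">=5": math.log(3.8)}}
    )
    rng_t = stream(seed, "emulate:survival")
    t_cancer = _weibull_ph_times(rng_t, xb_c, 1.1, 130.0)
    t_other = _weibull_ph_times(rng_t, xb_o, 1.1, 30.0)
    censor = rng_t.uniform(5.0, 16.0, size=n)
    t_death = np.minimum(t_cancer, t_other)
    os_event = t_death <= censor
    df["os_time"] = np.minimum(t_death, censor)
    df["os_event"] = os_event.astype(int)
    df["dss_time"] = df["os_time"]
    df["dss_event"] = (os_event & (t_cancer <= t_other)).astype(int)
    t_po = rng_t.uniform(1.0 / 365.25, 30.0 / 365.25, size=int(postop.sum()))
    df.loc[postop, "os_time"] = t_po
    df.loc[postop, "dss_time"] = t_po
    df.loc[postop, "os_event"] = 1
    df.loc[postop, "dss_event"] = 0
    return df


# ---------------------------------------------------------------------------
# end-to-end study generator (cell maps + linked patient table)

@dataclass
class StudyParams:
    """Parameters of a full synthetic study: per-tumor cell maps whose immune
    content is driven by a latent immune-quality variable that also lowers
    the cancer-specific hazard (better-infiltrated tumors do better)."""

    n_tumors: int = 12
    cores_per_region: int = 2
    panels: tuple[str, ...] = ("CD3", "CD8", "multiplex")
    radius: float = 500.0
    tumor_parent_intensity: float = 30.0
    tumor_offspring_mean: float = 14.0
    tcell_intensity: float = 250.0           # scaled by immune quality
    macrophage_intensity: float = 120.0
    other_intensity: float = 200.0
    attraction_range: tuple[float, float] = (0.05, 0.7)
    protective_log_hr: float = -1.5          # per unit immune quality, cancer cause
    seed: int = 0


def _panel_intensities(p: StudyParams, panel: str, q: float) -> dict[str, float]:
    t = p.tcell_intensity * (0.4 + 1.6 * q)
    if panel == "CD3":
        return {"T_CD3": t, "other": p.other_intensity}
    if panel == "CD8":
        return {"T_CD8": 0.6 * t, "other": p.other_intensity}
    return {"T_CD3": t, "macrophage": p.macrophage_intensity,
            "other": p.other_intensity}


def simulate_study(params: StudyParams) -> tuple[dict[str, list[CorePattern]], pd.DataFrame, dict]:
    """Generate linked cell maps and a patient table for ``n_tumors`` tumors.

    Returns (patterns per tumor, patient table, ground truth).  Each tumor
    draws a latent immune quality q ~ U(0,1) controlling T-cell intensity,
    attraction ρ, CLR density and (protectively) the cancer-specific hazard.
    """
    rng_q = stream(params.seed, "study:quality")
    q = rng_q.uniform(size=params.n_tumors)
    lo, hi = params.attraction_range
    rho = lo + (hi - lo) * q

    patterns: dict[str, list[CorePattern]] = {}
    for i in range(params.n_tumors):
        tumor_id = f"T{i:03d}"
        pats: list[CorePattern] = []
        for region in ("CT", "IM"):
            for panel in params.panels:
                for k in range(params.cores_per_region):
                    core_id = f"{tumor_id}_{region}{k + 1}_{panel}"
                    pp = PatternParams(
                        radius=params.radius,
                        tumor_parent_intensity=params.tumor_parent_intensity,
                        tumor_offspring_mean=params.tumor_offspring_mean,
                        immune_intensity=_panel_intensities(params, panel, q[i]),
                        attraction=float(rho[i]),
                        seed=params.seed,
                    )
                    pat = simulate_core_pattern(
                        pp, core_id=core_id, region=region, marker_panel=panel
                    )
                    pat.tumor_id = tumor_id
                    pats.append(pat)
        patterns[tumor_id] = pats

    n = params.n_tumors
    df = pd.DataFrame({"patient_id": list(patterns)})
    for var in ("age_group", "sex", "cci_group", "location", "t_stage", "n_stage",
                "m_stage", "tnm_stage", "lvi", "budding_group", "grade", "braf",
                "necrosis_group", "stroma_group", "lynch", "adjuvant"):
        rng = stream(params.seed, f"study:cov:{var}")
        probs = _marginal_probs(REFERENCE_MARGINALS[var])
        levels = list(probs)
        df[var] = rng.choice(levels, size=n, p=np.asarray(list(probs.values())))

    rng_c = stream(params.seed, "study:clr")
    margin = np.clip(rng_c.normal(55.0, 12.0, size=n), 25.0, 95.0)
    clr_rate = 0.1 + 0.9 * q
    df["margin_length_mm"] = margin
    df["clr_count"] = rng_c.poisson(clr_rate * margin)
    rng_h = stream(params.seed, "study:histoscore")
    df["pdl1_tumor_histoscore"] = np.round(rng_h.exponential(3.0, size=n), 2)

    xb_c = params.protective_log_hr * q + _linear_predictor(
        df.assign(tnm_group=df["tnm_stage"].map(
            lambda s: "I-II" if s in ("I", "II") else s)),
        {"tnm_group": {"III": math.log(6.0), "IV": math.log(20.0)}},
    )
    xb_o = _linear_predictor(
        df, {"cci_group": {"3-4": math.log(2.3), ">=5": math.log(3.8)}}
    )
    rng_t = stream(params.seed, "study:survival")
    t_cancer = _weibull_ph_times(rng_t, xb_c, 1.1, 130.0)
    t_other = _weibull_ph_times(rng_t, xb_o, 1.1, 30.0)
    censor = rng_t.uniform(5.0, 16.0, size=n)
    t_death = np.minimum(t_cancer, t_other)
    os_event = t_death <= censor
    df["os_time"] = np.minimum(t_death, censor)
    df["os_event"] = os_event.astype(int)
    df["dss_time"] = df["os_time"]
    df["dss_event"] = (os_event & (t_cancer <= t_other)).astype(int)
    rng_p = stream(params.seed, "study:postop")
    postop = rng_p.random(n) < 9 / 171
    df["postoperative_death"] = postop
    if postop.any():
        t_po = rng_p.uniform(1.0 / 365.25, 30.0 / 365.25, size=int(postop.sum()))
        df.loc[postop, "os_time"] = t_po
        df.loc[postop, "dss_time"] = t_po
        df.loc[postop, "os_event"] = 1
        df.loc[postop, "dss_event"] = 0
    rng_m = stream(params.seed, "study:metastasis")
    eta = -1.0 - 2.0 * q
    df["metastatic"] = np.where(
        rng_m.random(n) < 1.0 / (1.0 + np.exp(-eta)), "yes", "no"
    )

    truth = {
        "seed": params.seed,
        "immune_quality": q.tolist(),
        "attraction": rho.tolist(),
        "protective_log_hr": params.protective_log_hr,
        "n_postoperative": int(postop.sum()),
    }
    return patterns, df, truth
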