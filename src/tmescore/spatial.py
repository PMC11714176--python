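"""Cross-type nearest-neighbour statistics on TMA-core cell point patterns.

A tissue-microarray (TMA) core is a 1-mm-diameter disc of tissue; image
analysis exports one row per detected cell with planar coordinates in μm and
an exclusive phenotype label.  The central statistic here is the empirical
G-cross function evaluated at a single radius: the fraction of reference-type
cells (tumor cells) that have at least one target-type cell (e.g. a CD3+
T cell) within ``r`` μm.  Edge effects are handled by minus-sampling: with
edge correction on, only reference cells at least ``r`` from the disc
boundary are eligible, which makes the estimator unbiased for a completely
spatially random (homogeneous Poisson) target process, where the expected
value is ``1 - exp(-lambda * pi * r**2)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

PHENOTYPES = ("tumor", "T_CD3", "T_CD8", "macrophage", "other")
T_CELL_PHENOTYPES = ("T_CD3", "T_CD8")
REGIONS = ("CT", "IM")
MARKERS = ("CD3", "CD8")

#: disc-containment tolerance in μm
_DISC_TOL = 1e-6


class PatternError(ValueError):
    """Invalid cell pattern input (unknown phenotype, cell outside disc, ...)."""


@dataclass(frozen=True)
class CellRecord:
    """A single detected cell.

    ``pd1_positive`` is only meaningful for T cells and ``pdl1_positive``
    only for macrophages and tumor cells; the flags must be False elsewhere.
    """

    x: float
    y: float
    phenotype: str
    pd1_positive: bool = False
    pdl1_positive: bool = False
    region: str = "CT"

    def __post_init__(self) -> None:
        if self.phenotype not in PHENOTYPES:
            raise PatternError(
                f"unknown phenotype {self.phenotype!r}; expected one of {PHENOTYPES}"
            )
        if self.region not in REGIONS:
            raise PatternError(f"unknown region {self.region!r}; expected CT or IM")
        if self.pd1_positive and self.phenotype not in T_CELL_PHENOTYPES:
            raise PatternError("pd1_positive is only valid on T cells")
        if self.pdl1_positive and self.phenotype not in ("macrophage", "tumor"):
            raise PatternError("pdl1_positive is only valid on macrophages and tumor cells")


@dataclass
class CorePattern:
    """One TMA core's cell map: disc geometry plus the cells inside it."""

    core_id: str
    center: tuple[float, float]
    radius: float
    cells: Sequence[CellRecord] = field(default_factory=tuple)
    region: str | None = None
    marker_panel: str | None = None
    tumor_id: str | None = None

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise PatternError(f"core {self.core_id}: radius must be positive")
        cx, cy = self.center
        for i, c in enumerate(self.cells):
            d = math.hypot(c.x - cx, c.y - cy)
            if d > self.radius + _DISC_TOL:
                raise PatternError(
                    f"core {self.core_id}: cell {i} at ({c.x:.3f}, {c.y:.3f}) lies "
                    f"{d - self.radius:.3g} μm outside the disc"
                )

    def __len__(self) -> int:
        return len(self.cells)

    def coords(self, phenotype: str | None = None) -> np.ndarray:
        """(n, 2) coordinate array, optionally restricted to one phenotype."""
        if phenotype is not None and phenotype not in PHENOTYPES:
            raise PatternError(f"unknown phenotype {phenotype!r}")
        pts = [
            (c.x, c.y)
            for c in self.cells
            if phenotype is None or c.phenotype == phenotype
        ]
        return np.asarray(pts, dtype=float).reshape(-1, 2)

    def boundary_distances(self, phenotype: str | None = None) -> np.ndarray:
        """Distance from each (phenotype-filtered) cell to the disc boundary."""
        pts = self.coords(phenotype)
        if pts.size == 0:
            return np.empty(0)
        d_center = np.hypot(pts[:, 0] - self.center[0], pts[:, 1] - self.center[1])
        return self.radius - d_center


@dataclass(frozen=True)
class GCrossValue:
    """Empirical G-cross value at one radius.

    ``value`` is None when no eligible reference cell exists (missing, never
    coerced to 0); a pattern with reference cells but no target cells yields
    0.0 — biologically a minimal-co-localization tumor, not a missing one.
    """

    from_type: str
    to_type: str
    radius: float
    value: float | None
    n_reference: int

    @property
    def missing(self) -> bool:
        return self.value is None


def nearest_cross_distances(
    pattern: CorePattern, from_type: str, to_type: str
) -> np.ndarray:
    """Distance from every from-type cell to its nearest to-type cell.

    Returns one distance per from-type cell (order of appearance in the
    pattern); ``inf`` where the pattern contains no to-type cell.
    """
    if from_type == to_type:
        raise PatternError("from_type and to_type must differ")
    ref = pattern.coords(from_type)
    tgt = pattern.coords(to_type)
    if ref.shape[0] == 0:
        return np.empty(0)
    if tgt.shape[0] == 0:
        return np.full(ref.shape[0], np.inf)
    dist, _ = cKDTree(tgt).query(ref, k=1)
    return np.asarray(dist, dtype=float)


def gcross_at_radius(
    pattern: CorePattern,
    from_type: str = "tumor",
    to_type: str = "T_CD3",
    r: float = 20.0,
    edge_correction: bool = True,
) -> GCrossValue:
    """Fraction of eligible from-type cells with a to-type cell within ``r`` μm.

    With ``edge_correction`` (minus-sampling, the default) only reference
    cells whose distance to the disc boundary is at least ``r`` are eligible.
    """
    if not r > 0:
        raise PatternError("radius r must be positive")
    dists = nearest_cross_distances(pattern, from_type, to_type)
    if dists.size == 0:
        return GCrossValue(from_type, to_type, r, None, 0)
    if edge_correction:
        eligible = pattern.boundary_distances(from_type) >= r
    else:
        eligible = np.ones(dists.size, dtype=bool)
    n_ref = int(eligible.sum())
    if n_ref == 0:
        return GCrossValue(from_type, to_type, r, None, 0)
    value = float(np.mean(dists[eligible] <= r))
    return GCrossValue(from_type, to_type, r, value, n_ref)


def pool_gcross(values: Iterable[GCrossValue]) -> GCrossValue:
    """Reference-cell-count-weighted mean of per-core G-cross values.

    Missing cores (no eligible reference cells) carry zero weight; when every
    core is missing the pooled value is missing too.
    """
    vals = [v for v in values if not v.missing]
    template = vals[0] if vals else None
    if template is None:
        return GCrossValue("tumor", "none", 0.0, None, 0)
    w = np.array([v.n_reference for v in vals], dtype=float)
    x = np.array([v.value for v in vals], dtype=float)
    pooled = float(np.sum(w * x) / np.sum(w))
    return GCrossValue(
        template.from_type, template.to_type, template.radius, pooled, int(w.sum())
    )


def tumor_gcross_profile(
    patterns: Iterable[CorePattern], r: float = 20.0
) -> dict[tuple[str, str], GCrossValue]:
    """Pooled tumor→T-cell G-cross per (marker, region) for one tumor.

    CD3 and CD8 are stained on separate sections, so each marker's value is
    computed only from cores of that panel; distances are never taken across
    cores.  Cores are pooled within a region by reference-cell-count weights.
    """
    per_cell: dict[tuple[str, str], list[GCrossValue]] = {
        (m, reg): [] for m in MARKERS for reg in REGIONS
    }
    for p in patterns:
        if p.marker_panel not in MARKERS or p.region not in REGIONS:
            continue
        to_type = f"T_{p.marker_panel}"
        per_cell[(p.marker_panel, p.region)].append(
            gcross_at_radius(p, "tumor", to_type, r=r)
        )
    return {key: pool_gcross(vals) for key, vals in per_cell.items()}


def region_density(
    patterns: Iterable[CorePattern],
    phenotype: str,
    region: str,
    marker_panel: str | None = None,
    pd1: bool | None = None,
    pdl1: bool | None = None,
) -> float:
    """Cell density (cells per mm²) of a phenotype pooled over a region's cores.

    Counts cells matching the phenotype (and optional marker-flag filters)
    across all cores of the region (and panel, if given) and divides by the
    summed disc area.  Returns NaN when the region has no matching core.
    """
    count = 0
    area_mm2 = 0.0
    for p in patterns:
        if p.region != region:
            continue
        if marker_panel is not None and p.marker_panel != marker_panel:
            continue
        area_mm2 += math.pi * (p.radius / 1000.0) ** 2
        for c in p.cells:
            if c.phenotype != phenotype:
                continue
            if pd1 is not None and c.pd1_positive != pd1:
                continue
            if pdl1 is not None and c.pdl1_positive != pdl1:
                continue
            count += 1
    if area_mm2 == 0.0:
        return float("nan")
    return count / area_mm2
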