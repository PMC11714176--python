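"""Cross-tabulations with Pearson chi-square tests, in the style of a
clinicopathological "Table 1" comparing patient groups.

Pearson's chi-square is used without continuity correction and without a
Fisher fallback; tables with small expected counts (< 5) raise a warning but
the method never switches.  Column percentages are rounded half away from
zero to integers, matching how such tables are printed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency


class SmallExpectedCountWarning(UserWarning):
    pass


def _round_half_away(x: np.ndarray) -> np.ndarray:
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


@dataclass
class ContingencyResult:
    row_var: str
    col_var: str
    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray          # (rows, cols) observed counts
    col_percent: np.ndarray     # integer column percentages
    chi2: float
    df: int
    p_value: float
    n: int
    n_missing: int
    degenerate: bool = False    # fewer than 2 observed levels in a margin

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, rl in enumerate(self.row_labels):
            row = {"variable": self.row_var, "level": rl}
            for j, cl in enumerate(self.col_labels):
                row[f"{cl}_n"] = int(self.counts[i, j])
                row[f"{cl}_pct"] = int(self.col_percent[i, j])
            row["p"] = self.p_value
            rows.append(row)
        return pd.DataFrame(rows)


def crosstab(
    cohort: pd.DataFrame,
    row_var: str,
    col_var: str,
    row_order: Sequence[str] | None = None,
    col_order: Sequence[str] | None = None,
) -> ContingencyResult:
    """Observed counts, column percentages and Pearson chi-square.

    Rows with a missing value in either variable are excluded pairwise and
    counted in ``n_missing``.  A margin with a single observed level makes
    the chi-square undefined; the result is returned flagged ``degenerate``
    with NaN statistic rather than raising.
    """
    pair = cohort[[row_var, col_var]]
    missing = pair.isna().any(axis=1)
    used = pair.loc[~missing].astype(str)
    tab = pd.crosstab(used[row_var], used[col_var])
    if row_order is not None:
        tab = tab.reindex(index=[r for r in row_order if r in tab.index])
    if col_order is not None:
        tab = tab.reindex(columns=[c for c in col_order if c in tab.columns])
    counts = tab.to_numpy(dtype=float)
    n = int(counts.sum())
    col_tot = counts.sum(axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = _round_half_away(100.0 * counts / col_tot)
    pct = np.nan_to_num(pct)

    degenerate = counts.shape[0] < 2 or counts.shape[1] < 2
    if degenerate:
        chi2, p, dof = np.nan, np.nan, 0
    else:
        expected = col_tot * counts.sum(axis=1, keepdims=True) / n
        if (expected < 5).any():
            warnings.warn(
                f"{row_var} x {col_var}: expected counts below 5; "
                "Pearson chi-square may be unreliable",
                SmallExpectedCountWarning,
                stacklevel=2,
            )
        chi2, p, dof, _ = chi2_contingency(counts, correction=False)
    return ContingencyResult(
        row_var=row_var,
        col_var=col_var,
        row_labels=list(tab.index),
        col_labels=list(tab.columns),
        counts=counts.astype(int),
        col_percent=pct.astype(int),
        chi2=float(chi2),
        df=int(dof),
        p_value=float(p),
        n=n,
        n_missing=int(missing.sum()),
        degenerate=degenerate,
    )


@dataclass
class Table1Report:
    col_var: str
    results: list[ContingencyResult]
    alpha: float = 0.05

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for res in self.results:
            f = res.to_frame()
            f["significant"] = res.p_value < self.alpha
            f["n_missing"] = res.n_missing
            frames.append(f)
        return pd.concat(frames, ignore_index=True)

    def render(self) -> str:
        """Aligned human-readable rendering."""
        lines = []
        for res in self.results:
            star = " *" if (not res.degenerate and res.p_value < self.alpha) else ""
            p_txt = "NA" if res.degenerate else f"p={res.p_value:.3g}"
            lines.append(f"{res.row_var}  ({p_txt}{star}, missing={res.n_missing})")
            header = "".join(f"{c:>18}" for c in res.col_labels)
            lines.append(f"  {'':<16}{header}")
            for i, rl in enumerate(res.row_labels):
                cells = "".join(
                    f"{int(res.counts[i, j]):>10} ({int(res.col_percent[i, j]):>3}%)"
                    for j in range(len(res.col_labels))
                )
                lines.append(f"  {rl:<16}{cells}")
            lines.append("")
        return "\n".join(lines)


def table1_report(
    cohort: pd.DataFrame,
    variables: Sequence[str | tuple[str, Sequence[str]]],
    col_var: str = "metastatic",
    col_order: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> Table1Report:
    """Stacked cross-tabulations of each variable against ``col_var``.

    ``variables`` entries are column names or (name, level-order) pairs; the
    report preserves the given order.
    """
    results = []
    for var in variables:
        if isinstance(var, tuple):
            name, order = var
        else:
            name, order = var, None
        results.append(
            crosstab(cohort, name, col_var, row_order=order, col_order=col_order)
        )
    return Table1Report(col_var=col_var, results=results, alpha=alpha)
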