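"""Small table procedures: differential-expression filtering and transcription
factor ranking, section-coordinate normalization, and the normality-gated
statistical-test selector.

The differential-expression filter consumes a finished DESeq2-style results
table (gene, log2 fold change, adjusted p-value); the model fitting itself is
out of scope.  Genes pass at padj <= 0.05 and |log2FC| >= 0.59 (both bounds
inclusive); genes with a missing adjusted p-value count as not expressed.

Section coordinates are normalized to the central canal as origin, scaling
each side of the canal independently by its own maximal extent, so every
cell lands in [-1, 1]^2 with the canal at (0, 0).

The test selector reproduces a fixed decision tree: Shapiro-Wilk gates each
group at alpha = 0.05; when all groups pass, the parametric branch is used
(Welch's t / paired t / Welch ANOVA / repeated-measures ANOVA with
Geisser-Greenhouse correction), otherwise the rank-based branch
(Mann-Whitney U / Wilcoxon signed-rank, and Kruskal-Wallis / Friedman for
three or more groups).  The chosen test's name is always reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple, Union

import numpy as np
import pandas as pd
from scipy import stats

REQUIRED_DE_COLUMNS = ("gene", "log2fc", "padj")


def _check_de_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_DE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")
    padj = table["padj"]
    bad = padj.dropna()
    if ((bad < 0) | (bad > 1)).any():
        raise ValueError("padj values must be in [0, 1] or missing")
    return table


def filter_de_table(table: pd.DataFrame, lfc_min: float = 0.59,
                    padj_max: float = 0.05) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Split a DE table into (upregulated, downregulated) at inclusive
    thresholds; rows with missing padj are excluded as not expressed."""
    if lfc_min <= 0 or padj_max <= 0:
        raise ValueError("thresholds must be positive")
    table = _check_de_table(table)
    expressed = table[table["padj"].notna()]
    sig = expressed[expressed["padj"] <= padj_max]
    up = sig[sig["log2fc"] >= lfc_min]
    down = sig[sig["log2fc"] <= -lfc_min]
    return up.reset_index(drop=True), down.reset_index(drop=True)


def rank_top_tf(filtered: pd.DataFrame, tf_membership: Union[Set[str], Sequence[str]],
                k: int = 20) -> pd.DataFrame:
    """Transcription-factor rows ordered by descending |log2FC| (ties by
    ascending padj, then gene id); the first ``k`` are returned."""
    filtered = _check_de_table(filtered)
    members = set(tf_membership)
    tfs = filtered[filtered["gene"].isin(members)].copy()
    tfs["_abs_lfc"] = tfs["log2fc"].abs()
    tfs = tfs.sort_values(["_abs_lfc", "padj", "gene"],
                          ascending=[False, True, True]).drop(columns="_abs_lfc")
    return tfs.head(k).reset_index(drop=True)


@dataclass
class SectionCoordinates:
    """Cell positions in a transverse section with landmarks.

    ``positions`` is (n, 2) of (x, y) pixels; ``canal`` the central canal;
    ``bbox`` the (left, right, dorsal, ventral) bounding-box extremes, with
    x growing rightward and y growing ventralward.
    """

    positions: np.ndarray
    canal: Tuple[float, float]
    bbox: Tuple[float, float, float, float]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 2)
        if not self.normalized:
            left, right, dorsal, ventral = self.bbox
            cx, cy = self.canal
            if not (left < cx < right and dorsal < cy < ventral):
                raise ValueError("central canal must lie strictly inside the bounding box")


def normalize_section_coords(coords: SectionCoordinates) -> SectionCoordinates:
    """Map positions to [-1, 1]^2 with the canal at (0, 0), each side scaled
    by its own extent (right edge -> x = +1, left edge -> x = -1, ventral
    edge -> y = +1, dorsal edge -> y = -1)."""
    if coords.normalized:
        return coords
    left, right, dorsal, ventral = coords.bbox
    cx, cy = coords.canal
    for name, extent in (("left", cx - left), ("right", right - cx),
                         ("dorsal", cy - dorsal), ("ventral", ventral - cy)):
        if extent <= 0:
            raise ValueError(f"zero {name} extent: cannot normalize")
    x, y = coords.positions[:, 0], coords.positions[:, 1]
    nx = np.where(x >= cx, (x - cx) / (right - cx), (x - cx) / (cx - left))
    ny = np.where(y >= cy, (y - cy) / (ventral - cy), (y - cy) / (cy - dorsal))
    return SectionCoordinates(positions=np.column_stack([nx, ny]),
                              canal=(0.0, 0.0), bbox=(-1.0, 1.0, -1.0, 1.0),
                              normalized=True)


def denormalize_section_coords(coords: SectionCoordinates,
                               canal: Tuple[float, float],
                               bbox: Tuple[float, float, float, float],
                               ) -> SectionCoordinates:
    """Inverse of :func:`normalize_section_coords` given the original landmarks."""
    if not coords.normalized:
        raise ValueError("coordinates are not normalized")
    left, right, dorsal, ventral = bbox
    cx, cy = canal
    nx, ny = coords.positions[:, 0], coords.positions[:, 1]
    x = np.where(nx >= 0, cx + nx * (right - cx), cx + nx * (cx - left))
    y = np.where(ny >= 0, cy + ny * (ventral - cy), cy + ny * (cy - dorsal))
    return SectionCoordinates(positions=np.column_stack([x, y]), canal=canal,
                              bbox=bbox, normalized=False)


@dataclass
class GroupComparison:
    """Outcome of the normality-gated comparison: which test fired and why."""

    test: str
    statistic: float
    p: float
    df: Optional[object] = None
    normality_p: Optional[List[float]] = None
    parametric: bool = True


def compare_groups(groups: Sequence[Sequence[float]], design: str = "unpaired",
                   alpha_normality: float = 0.05) -> GroupComparison:
    """Select and run the comparison the decision tree prescribes.

    All groups Gaussian by Shapiro-Wilk (each at ``alpha_normality``) selects
    the parametric branch; any non-Gaussian group selects the rank branch.
    ``design`` is "paired" or "unpaired"; paired designs require equal group
    sizes.
    """
    if design not in ("paired", "unpaired"):
        raise ValueError(f"design must be 'paired' or 'unpaired', got '{design}'")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    if k < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(arrs):
        if g.size < 3:
            raise ValueError(f"group {i} has n = {g.size} < 3")
    if design == "paired" and len({g.size for g in arrs}) != 1:
        raise ValueError("paired design requires equal group sizes")

    shapiro_p = [float(stats.shapiro(g).pvalue) for g in arrs]
    normal = all(p > alpha_normality for p in shapiro_p)

    if k == 2:
        a, b = arrs
        if design == "unpaired":
            if normal:
                res = stats.ttest_ind(a, b, equal_var=False)
                return GroupComparison("Welch t", float(res.statistic),
                                       float(res.pvalue), df=float(res.df),
                                       normality_p=shapiro_p)
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            return GroupComparison("Mann-Whitney U", float(res.statistic),
                                   float(res.pvalue), normality_p=shapiro_p,
                                   parametric=False)
        # paired
        diffs = a - b
        if np.all(diffs == 0):
            name = "paired t" if normal else "Wilcoxon signed-rank"
            return GroupComparison(name, 0.0, 1.0, normality_p=shapiro_p,
                                   parametric=normal)
        if normal:
            res = stats.ttest_rel(a, b)
            return GroupComparison("paired t", float(res.statistic),
                                   float(res.pvalue), df=float(res.df),
                                   normality_p=shapiro_p)
        res = stats.wilcoxon(a, b)
        return GroupComparison("Wilcoxon signed-rank", float(res.statistic),
                               float(res.pvalue), normality_p=shapiro_p,
                               parametric=False)

    # k >= 3
    if design == "unpaired":
        if normal:
            import pingouin as pg
            df_long = pd.DataFrame({
                "value": np.concatenate(arrs),
                "group": np.concatenate([[f"g{i}"] * g.size for i, g in enumerate(arrs)]),
            })
            aov = pg.welch_anova(data=df_long, dv="value", between="group")
            p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
            return GroupComparison("Brown-Forsythe/Welch ANOVA",
                                   float(aov["F"].iloc[0]), float(aov[p_col].iloc[0]),
                                   df=(float(aov["ddof1"].iloc[0]),
                                       float(aov["ddof2"].iloc[0])),
                                   normality_p=shapiro_p)
        res = stats.kruskal(*arrs)
        return GroupComparison("Kruskal-Wallis", float(res.statistic),
                               float(res.pvalue), normality_p=shapiro_p,
                               parametric=False)
    # paired, k >= 3
    if normal:
        import pingouin as pg
        n = arrs[0].size
        df_long = pd.DataFrame({
            "value": np.concatenate(arrs),
            "cond": np.concatenate([[f"g{i}"] * n for i in range(k)]),
            "subject": np.tile(np.arange(n), k),
        })
        aov = pg.rm_anova(data=df_long, dv="value", within="cond", subject="subject",
                          correction=True)
        row = aov.iloc[0]
        gg_col = next((c for c in ("p_GG_corr", "p-GG-corr") if c in aov.columns), None)
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        p = (float(row[gg_col]) if gg_col is not None and np.isfinite(row[gg_col])
             else float(row[p_col]))
        return GroupComparison("repeated-measures ANOVA (Geisser-Greenhouse)",
                               float(row["F"]), p,
                               df=(float(row["ddof1"]), float(row["ddof2"])),
                               normality_p=shapiro_p)
    res = stats.friedmanchisquare(*arrs)
    return GroupComparison("Friedman", float(res.statistic), float(res.pvalue),
                           normality_p=shapiro_p, parametric=False)
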