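"""Per-sample vascular morphometry and between-group statistics.

Morphometry summarises a vascular graph into the quantities compared
across experimental groups: branch count, node count, branch-length
statistics, a branch-diameter frequency distribution over the fixed bins
<10, 10–20, 20–50 and >50 μm, the vascular volume fraction and the
ischemic-cavity volume.  Group comparison is classical one-way
fixed-effects ANOVA followed by Tukey's HSD post-hoc test (α = 0.05).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from matplotlib import colormaps
from scipy import stats
from statsmodels.stats.multicomp import MultiComparison

from angiotomo.graph import VascularGraph
from angiotomo.segmentation import CavityMask, VesselMask

__all__ = [
    "DIAMETER_BIN_EDGES_UM",
    "Morphometry",
    "GroupComparison",
    "summarize",
    "compare_groups",
    "diameter_colormap",
    "trend_report",
    "TrendReport",
]

#: histogram bin edges in μm → bins [0,10), [10,20), [20,50), [50,∞)
DIAMETER_BIN_EDGES_UM = (0.0, 10.0, 20.0, 50.0, math.inf)
DIAMETER_BIN_LABELS = ("<10", "10-20", "20-50", ">50")

#: morphometry fields that participate in group comparison
METRIC_FIELDS = (
    "n_branches",
    "n_nodes",
    "mean_length_um",
    "total_length_um",
    "vascular_volume_fraction",
    "cavity_volume_um3",
    "hist_<10",
    "hist_10-20",
    "hist_20-50",
    "hist_>50",
)


@dataclass
class Morphometry:
    sample_id: str
    condition: str
    n_branches: int
    n_nodes: int
    mean_length_um: float
    total_length_um: float
    diameter_histogram: tuple[int, int, int, int]
    vascular_volume_fraction: float
    cavity_volume_um3: float
    warning: str | None = None

    def metric(self, name: str) -> float:
        if name.startswith("hist_"):
            return float(self.diameter_histogram[DIAMETER_BIN_LABELS.index(name[5:])])
        return float(getattr(self, name))

    def as_dict(self) -> dict:
        d = {
            "sample_id": self.sample_id,
            "condition": self.condition,
            "n_branches": self.n_branches,
            "n_nodes": self.n_nodes,
            "mean_length_um": self.mean_length_um,
            "total_length_um": self.total_length_um,
            "vascular_volume_fraction": self.vascular_volume_fraction,
            "cavity_volume_um3": self.cavity_volume_um3,
        }
        for label, count in zip(DIAMETER_BIN_LABELS, self.diameter_histogram):
            d[f"hist_{label}"] = count
        return d


def summarize(
    graph: VascularGraph,
    vessel_mask: VesselMask | None = None,
    cavity: CavityMask | None = None,
    brain_mask: np.ndarray | None = None,
    sample_id: str = "",
    condition: str = "",
) -> Morphometry:
    """Per-sample morphometry from a vascular graph and its masks.

    The diameter histogram uses the fixed 10/20/50 μm edges; counts always
    sum to the number of branches.  The vascular volume fraction is vessel
    voxels over brain voxels (over all voxels when no brain mask is
    given).
    """
    n_branches = graph.n_branches
    n_nodes = graph.n_nodes
    warning = None
    if n_branches == 0:
        hist = (0, 0, 0, 0)
        mean_len = 0.0
        total_len = 0.0
        warning = "empty graph"
    else:
        lengths = graph.lengths_um()
        total_len = float(lengths.sum())
        mean_len = total_len / n_branches
        d = graph.diameters_um()
        edges = np.array(DIAMETER_BIN_EDGES_UM[1:-1])
        hist_counts = np.bincount(np.searchsorted(edges, d, side="right"), minlength=4)
        hist = tuple(int(c) for c in hist_counts[:4])

    frac = 0.0
    if vessel_mask is not None:
        denom = (
            int(np.asarray(brain_mask, dtype=bool).sum())
            if brain_mask is not None
            else vessel_mask.mask.size
        )
        frac = float(vessel_mask.mask.sum()) / denom if denom else 0.0
    cavity_volume = float(cavity.volume_um3) if cavity is not None else 0.0
    return Morphometry(
        sample_id=sample_id,
        condition=condition,
        n_branches=n_branches,
        n_nodes=n_nodes,
        mean_length_um=mean_len,
        total_length_um=total_len,
        diameter_histogram=hist,
        vascular_volume_fraction=frac,
        cavity_volume_um3=cavity_volume,
        warning=warning,
    )


@dataclass
class GroupComparison:
    metric: str
    group_means: dict[str, float]
    group_sds: dict[str, float]
    F_statistic: float
    p_value: float
    tukey_pairs: list[tuple[str, str, float, float]]
    df_between: int = 0
    df_within: int = 0
    flag: str | None = None


def _anova_oneway(groups: dict[str, np.ndarray]) -> tuple[float, float, int, int, str | None]:
    """Fixed-effects one-way ANOVA from sums of squares."""
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    if ss_between <= 0:
        return 0.0, 1.0, df_b, df_w, None
    if ss_within <= 0:
        return math.inf, 0.0, df_b, df_w, "zero within-group variance"
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(F, df_b, df_w))
    return float(F), p, df_b, df_w, None


def compare_groups(
    samples: list[Morphometry], metric: str, alpha: float = 0.05
) -> GroupComparison:
    """One-way ANOVA over condition groups followed by Tukey HSD.

    Every group needs at least two samples.  With a single group the
    comparison degenerates to group means (no test; flagged).
    """
    if metric not in METRIC_FIELDS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRIC_FIELDS}")
    groups: dict[str, list[float]] = {}
    for s in samples:
        groups.setdefault(s.condition, []).append(s.metric(metric))
    for name, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 samples")
    arr = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    means = {k: float(v.mean()) for k, v in arr.items()}
    sds = {k: float(v.std(ddof=1)) for k, v in arr.items()}

    if len(arr) < 2:
        return GroupComparison(metric, means, sds, math.nan, math.nan, [],
                               flag="single group: means only, no test")

    F, p, df_b, df_w, flag = _anova_oneway(arr)

    tukey_pairs: list[tuple[str, str, float, float]] = []
    values = np.concatenate(list(arr.values()))
    labels = np.concatenate([[k] * len(v) for k, v in arr.items()])
    if flag == "zero within-group variance":
        names = list(arr)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                diff = means[names[j]] - means[names[i]]
                tukey_pairs.append((names[i], names[j], diff, 0.0 if diff else 1.0))
    elif np.ptp(values) > 0:
        mc = MultiComparison(values, labels)
        res = mc.tukeyhsd(alpha=alpha)
        for i, j, diff, padj in zip(*mc.pairindices, res.meandiffs, res.pvalues):
            tukey_pairs.append(
                (str(mc.groupsunique[i]), str(mc.groupsunique[j]), float(diff), float(padj))
            )
    else:
        # all observations identical: every pairwise difference is 0, p = 1
        names = list(arr)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                tukey_pairs.append((names[i], names[j], 0.0, 1.0))
    return GroupComparison(metric, means, sds, F, p, tukey_pairs, df_b, df_w, flag)


def diameter_colormap(
    graph: VascularGraph, range_um: tuple[float, float] = (10.0, 50.0)
) -> tuple[pd.DataFrame, dict]:
    """Linear blue→red pseudocolor per branch diameter, clamped at the
    range ends (defaults 10–50 μm).  Returns a per-branch color table and
    a legend record."""
    lo, hi = range_um
    if not lo < hi:
        raise ValueError("range_um must be increasing")
    cmap = colormaps["jet"]
    rows = []
    for b in graph.branches:
        t = min(max((b.diameter_um - lo) / (hi - lo), 0.0), 1.0)
        r, g, bl, _ = cmap(t)
        rows.append({
            "branch_id": b.id, "diameter_um": b.diameter_um, "t": t,
            "r": r, "g": g, "b": bl,
        })
    table = pd.DataFrame(rows, columns=["branch_id", "diameter_um", "t", "r", "g", "b"])
    legend = {
        "range_um": (lo, hi),
        "colormap": "jet",
        "min_color": tuple(cmap(0.0)[:3]),
        "max_color": tuple(cmap(1.0)[:3]),
    }
    return table, legend


@dataclass
class TrendReport:
    table: pd.DataFrame
    text: str
    orderings: dict[str, list[str]] = field(default_factory=dict)


_GROUP_ORDER = ("sham", "4h", "6h", "3d", "18d")


def trend_report(comparisons: list[GroupComparison], alpha: float = 0.05,
                 control: str = "sham") -> TrendReport:
    """Per-metric group means with significance markers against the control
    group, plus the rank ordering of the group means."""
    rows = []
    orderings: dict[str, list[str]] = {}
    for comp in comparisons:
        sig_vs_control = {}
        for a, b, diff, padj in comp.tukey_pairs:
            if control in (a, b):
                other = b if a == control else a
                sig_vs_control[other] = padj < alpha
        groups = sorted(comp.group_means, key=lambda g: _GROUP_ORDER.index(g)
                        if g in _GROUP_ORDER else len(_GROUP_ORDER))
        row: dict = {"metric": comp.metric, "F": comp.F_statistic, "p": comp.p_value}
        for g in groups:
            marker = "*" if sig_vs_control.get(g, False) else ""
            row[g] = comp.group_means[g]
            row[f"{g}_sd"] = comp.group_sds[g]
            row[f"{g}_sig"] = marker
        rows.append(row)
        orderings[comp.metric] = sorted(comp.group_means, key=comp.group_means.get)
    table = pd.DataFrame(rows)

    lines = ["# Group trend report", ""]
    for comp in comparisons:
        lines.append(f"## {comp.metric}")
        if not math.isnan(comp.F_statistic):
            lines.append(
                f"ANOVA F({comp.df_between},{comp.df_within}) = {comp.F_statistic:.3g}, "
                f"p = {comp.p_value:.3g}"
            )
        else:
            lines.append("single group: means only, no test")
        order = orderings[comp.metric]
        lines.append("ascending group means: " + " < ".join(order))
        for g in sorted(comp.group_means, key=lambda g: _GROUP_ORDER.index(g)
                        if g in _GROUP_ORDER else len(_GROUP_ORDER)):
            mean = comp.group_means[g]
            sd = comp.group_sds[g]
            mark = ""
            for a, b, diff, padj in comp.tukey_pairs:
                if control in (a, b) and g in (a, b) and g != control and padj < alpha:
                    mark = " *"
            lines.append(f"- {g}: {mean:.4g} ± {sd:.3g}{mark}")
        lines.append("")
    return TrendReport(table, "\n".join(lines), orderings)
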