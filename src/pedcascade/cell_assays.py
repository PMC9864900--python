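"""Quantification of the three fibroblast assays with nonparametric stats.

* G/F actin ratio from fractionation band intensities, with a GAPDH
  separation QC (GAPDH must appear only in the supernatant).
* Puncta counting over the cytochalasin-D recovery time course
  (threshold -> connected components -> size gate), compared per timepoint
  with Kruskal-Wallis and Dunn's multiple-comparison post-test.
* Wound-healing metrics: contact time of the two advancing fronts and
  nine-square coverage at 5-hour intervals.

Significance marks follow the study legend (* p <= 0.005, ** p <= 0.001,
*** p <= 0.0005; overall criterion p < 0.05); a flag switches to the
conventional 0.05/0.01/0.001 marks.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from skimage.filters import threshold_otsu
from skimage.measure import label

#: Study-legend significance-mark thresholds, strictest first.
STUDY_MARKS = (("***", 0.0005), ("**", 0.001), ("*", 0.005))
CONVENTIONAL_MARKS = (("***", 0.001), ("**", 0.01), ("*", 0.05))
SIGNIFICANCE_ALPHA = 0.05


class AssayInvalidError(ValueError):
    pass


class InputError(ValueError):
    pass


def significance_mark(p: float, conventional: bool = False) -> str:
    marks = CONVENTIONAL_MARKS if conventional else STUDY_MARKS
    for mark, cutoff in marks:
        if p <= cutoff:
            return mark
    return "ns" if p >= SIGNIFICANCE_ALPHA else ""


# ---------------------------------------------------------------------------
# G/F actin ratio
# ---------------------------------------------------------------------------

@dataclass
class GFRatioResult:
    per_replicate: pd.DataFrame         # group, replicate, ratio, qc_pass
    group_means: dict[str, float]
    group_sds: dict[str, float]
    excluded: list[tuple[str, int, str]]  # (group, replicate, reason)
    p_value: float | None
    test: str

    @property
    def ratio_quotient(self) -> float:
        """Patient mean ratio over control mean ratio."""
        return self.group_means["PATIENT"] / self.group_means["CONTROL"]


def gf_ratio(table: pd.DataFrame, qc_tolerance: float = 0.1,
             test: str = "mannwhitney", alternative: str = "two-sided",
             ) -> GFRatioResult:
    """Per-replicate G/F ratios with separation QC and a group comparison.

    A replicate passes QC when its pellet GAPDH is at most ``qc_tolerance``
    times its supernatant GAPDH (fractionation succeeded). Ratios are
    G / F; the group comparison is a Mann-Whitney U test by default
    (``test="ttest"`` switches to Welch's t).
    """
    required = {"group", "replicate", "G", "F", "GAPDH_supernatant", "GAPDH_pellet"}
    missing = required - set(table.columns)
    if missing:
        raise InputError(f"band table lacks columns {sorted(missing)}")

    rows, excluded = [], []
    for _, row in table.iterrows():
        group, rep = row["group"], int(row["replicate"])
        if row["GAPDH_pellet"] > qc_tolerance * row["GAPDH_supernatant"]:
            excluded.append((group, rep, "gapdh_in_pellet"))
            continue
        if row["F"] == 0:
            excluded.append((group, rep, "zero_F"))
            continue
        rows.append({"group": group, "replicate": rep,
                     "ratio": row["G"] / row["F"]})
    if not rows:
        raise AssayInvalidError("all replicates failed QC; separation invalid")
    per_rep = pd.DataFrame(rows)

    means = per_rep.groupby("group")["ratio"].mean().to_dict()
    sds = per_rep.groupby("group")["ratio"].std(ddof=1).to_dict()

    p_value: float | None = None
    groups = sorted(per_rep["group"].unique())
    if len(groups) == 2:
        a = per_rep.loc[per_rep["group"] == groups[0], "ratio"]
        b = per_rep.loc[per_rep["group"] == groups[1], "ratio"]
        if len(a) >= 2 and len(b) >= 2:
            if test == "mannwhitney":
                p_value = float(stats.mannwhitneyu(
                    a, b, alternative=alternative).pvalue)
            elif test == "ttest":
                p_value = float(stats.ttest_ind(
                    a, b, equal_var=False, alternative=alternative).pvalue)
            else:
                raise InputError(f"unknown test {test!r}")
    return GFRatioResult(per_replicate=per_rep, group_means=means,
                         group_sds=sds, excluded=excluded,
                         p_value=p_value, test=test)


# ---------------------------------------------------------------------------
# Puncta counting
# ---------------------------------------------------------------------------

def count_puncta(image: np.ndarray, threshold_policy: str = "otsu",
                 size_range: tuple[float, float] = (4.0, 400.0)) -> int:
    """Count bright puncta: threshold, 8-connected components, size gate.

    A blank (constant) image yields a count of 0. Components outside
    ``size_range`` (pixels, inclusive) are discarded.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InputError(f"expected a single-channel 2D image, got shape {img.shape}")
    if np.ptp(img) == 0:
        return 0
    if threshold_policy == "otsu":
        thr = threshold_otsu(img)
    else:
        try:
            thr = float(threshold_policy)
        except (TypeError, ValueError):
            raise InputError(f"unknown threshold policy {threshold_policy!r}")
    binary = img > thr
    labels = label(binary, connectivity=2)
    if labels.max() == 0:
        return 0
    sizes = np.bincount(labels.ravel())[1:]
    lo, hi = size_range
    return int(np.sum((sizes >= lo) & (sizes <= hi)))


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn's post-test
# ---------------------------------------------------------------------------

def dunn_posthoc(groups: dict[str, np.ndarray], adjust: str = "bonferroni",
                 ) -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons after a Kruskal-Wallis test.

    For groups i, j with mean ranks Ri, Rj over the pooled sample of size N:

        z = (Ri - Rj) / sqrt([N(N+1)/12 - T] * (1/ni + 1/nj))

    where T = sum(t^3 - t) / (12 (N - 1)) corrects for ties. Raw p-values
    are two-sided normal tails; Bonferroni adjustment multiplies by the
    k(k-1)/2 comparisons (``adjust="none"`` disables it).
    """
    names = list(groups)
    values = [np.asarray(groups[n], dtype=float) for n in names]
    pooled = np.concatenate(values)
    n_total = len(pooled)
    ranks = stats.rankdata(pooled)
    mean_ranks, sizes = {}, {}
    offset = 0
    for name, vals in zip(names, values):
        mean_ranks[name] = float(np.mean(ranks[offset:offset + len(vals)]))
        sizes[name] = len(vals)
        offset += len(vals)

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    variance_base = n_total * (n_total + 1) / 12.0 - tie_term

    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in itertools.combinations(names, 2):
        se = np.sqrt(variance_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        p_raw = 2.0 * stats.norm.sf(abs(z))
        if adjust == "bonferroni":
            p_adj = min(1.0, p_raw * n_pairs)
        elif adjust == "none":
            p_adj = p_raw
        else:
            raise InputError(f"unknown adjustment {adjust!r}")
        rows.append({"group_a": a, "group_b": b, "z": float(z),
                     "p_raw": float(p_raw), "p_adjusted": float(p_adj)})
    return pd.DataFrame(rows)


@dataclass
class TimepointComparison:
    timepoint_min: int
    H: float | None
    p: float | None
    significant: bool
    mark: str
    dunn: pd.DataFrame | None
    all_tied: bool = False


@dataclass
class RecoveryAnalysis:
    per_timepoint: list[TimepointComparison] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "timepoint_min": c.timepoint_min, "H": c.H, "p": c.p,
            "significant": c.significant, "mark": c.mark,
            "all_tied": c.all_tied} for c in self.per_timepoint])


def recovery_analysis(counts: dict[int, dict[str, list[int]]],
                      adjust: str = "bonferroni",
                      conventional_marks: bool = False) -> RecoveryAnalysis:
    """Group comparison of puncta counts at each recovery timepoint.

    Kruskal-Wallis H and p per timepoint, Dunn pairwise z with raw and
    adjusted p, and the study's significance marks. Requires >= 2 groups
    of >= 3 observations each; a timepoint where every value is tied has
    no defined H and is flagged instead.
    """
    result = RecoveryAnalysis()
    for t in sorted(counts):
        groups = {g: np.asarray(v, dtype=float) for g, v in counts[t].items()}
        if len(groups) < 2:
            raise InputError(f"timepoint {t}: need >= 2 groups")
        if any(len(v) < 3 for v in groups.values()):
            raise InputError(f"timepoint {t}: need >= 3 observations per group")
        pooled = np.concatenate(list(groups.values()))
        if np.ptp(pooled) == 0:
            result.per_timepoint.append(TimepointComparison(
                timepoint_min=t, H=None, p=None, significant=False,
                mark="", dunn=None, all_tied=True))
            continue
        H, p = stats.kruskal(*groups.values())
        result.per_timepoint.append(TimepointComparison(
            timepoint_min=t, H=float(H), p=float(p),
            significant=p < SIGNIFICANCE_ALPHA,
            mark=significance_mark(float(p), conventional_marks),
            dunn=dunn_posthoc(groups, adjust=adjust)))
    return result


# ---------------------------------------------------------------------------
# Wound healing
# ---------------------------------------------------------------------------

@dataclass
class WoundSeries:
    """Ordered binary masks of a scratch-wound time lapse."""

    masks: np.ndarray               # (n_frames, H, W) boolean
    frame_interval_min: float = 20.0
    gap_width_um: float = 500.0
    total_duration_h: float | None = None

    def __post_init__(self) -> None:
        self.masks = np.asarray(self.masks, dtype=bool)
        if self.masks.ndim != 3 or self.masks.shape[0] < 1:
            raise InputError("masks must be a non-empty (frames, H, W) stack")
        if self.frame_interval_min <= 0:
            raise InputError("frame interval must be > 0")

    @property
    def n_frames(self) -> int:
        return self.masks.shape[0]

    def time_h(self, frame: int) -> float:
        return frame * self.frame_interval_min / 60.0


def contact_time(series: WoundSeries) -> float | None:
    """Hours from insert removal until the two fronts first touch.

    Frame 0 must contain exactly two disjoint cell regions separated by the
    gap. Every pixel is assigned to its nearest initial region (Euclidean);
    contact is the first frame in which one 8-connected component contains
    pixels assigned to both. Returns hours, or None if they never touch.
    """
    first = series.masks[0]
    initial_labels = label(first, connectivity=2)
    if initial_labels.max() != 2:
        raise InputError(
            f"frame 0 must contain exactly 2 disjoint regions, found {initial_labels.max()}")
    d1 = ndimage.distance_transform_edt(initial_labels != 1)
    d2 = ndimage.distance_transform_edt(initial_labels != 2)
    nearest = np.where(d1 <= d2, 1, 2)

    for t in range(series.n_frames):
        labels = label(series.masks[t], connectivity=2)
        for comp in range(1, labels.max() + 1):
            sides = np.unique(nearest[labels == comp])
            if len(sides) == 2:
                return series.time_h(t)
    return None


def coverage_timecourse(series: WoundSeries, grid: tuple[int, int] = (3, 3),
                        report_interval_h: float = 5.0) -> pd.DataFrame:
    """Nine-square coverage at fixed reporting intervals.

    Each frame is split into a ``grid`` of squares (remainder pixels join
    the last row/column, keeping the split area-conserving); the covered
    fraction is reported per square together with their mean. Rows are the
    frames closest to each multiple of ``report_interval_h``, always
    including frame 0 and the final frame.
    """
    if series.n_frames == 0:
        raise InputError("empty series")
    n_frames, h, w = series.masks.shape
    gr, gc = grid
    row_edges = [int(i * h / gr) for i in range(gr)] + [h]
    col_edges = [int(j * w / gc) for j in range(gc)] + [w]

    frames_per_interval = report_interval_h * 60.0 / series.frame_interval_min
    report_frames = sorted({min(n_frames - 1, int(round(k * frames_per_interval)))
                            for k in range(int(np.ceil((n_frames - 1)
                                                       / frames_per_interval)) + 1)}
                           | {0, n_frames - 1})

    rows = []
    for t in report_frames:
        mask = series.masks[t]
        fractions = []
        for i in range(gr):
            for j in range(gc):
                square = mask[row_edges[i]:row_edges[i + 1],
                              col_edges[j]:col_edges[j + 1]]
                fractions.append(float(square.mean()))
        record = {"frame": t, "time_h": series.time_h(t),
                  "mean_coverage": float(np.average(
                      fractions,
                      weights=[(row_edges[i + 1] - row_edges[i])
                               * (col_edges[j + 1] - col_edges[j])
                               for i in range(gr) for j in range(gc)]))}
        for idx, f in enumerate(fractions, start=1):
            record[f"square_{idx}"] = f
        rows.append(record)
    return pd.DataFrame(rows)
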