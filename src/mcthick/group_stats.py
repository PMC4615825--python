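"""ROI summaries, atlas averaging, group comparison and power analysis.

Group analysis mirrors a standard clinical thickness workflow: per-subject
ROI means of the thickness metrics feed a one-way ANOVA with Tukey HSD
pairwise comparisons, gated (warn, don't abort) by an Anderson–Darling
normality check per group and a Levene variance-homogeneity check. With
two groups the ANOVA F-test is equivalent to the two-sample t-test; the
equivalent t statistic is exposed in the output. The minimal detectable
effect is the smallest percent difference in group means a two-sided
two-sample t-test would detect at the stated alpha and power, solved
from the noncentral-t power function using the control-group variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dfield

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.diagnostic import normal_ad
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.power import TTestIndPower

from .thickness import ThicknessMaps
from .volume_io import MaskVolume, Volume3D, require_grid_compatible

__all__ = ["ROISummary", "GroupComparison", "roi_extract", "average_atlas",
           "group_compare", "detectable_effect", "simulate_summary_cohort"]

logger = logging.getLogger(__name__)

METRICS = ("T", "G", "M", "P")


@dataclass
class ROISummary:
    """Per-subject ROI means/sds of the thickness metrics."""

    subject: str
    group: str
    roi: str
    means: dict
    sds: dict
    voxel_count: int
    undefined_count: int = 0

    def as_row(self) -> dict:
        row = {"subject": self.subject, "group": self.group, "roi": self.roi,
               "voxel_count": self.voxel_count, "undefined_count": self.undefined_count}
        for m in METRICS:
            row[f"mean_{m}"] = self.means.get(m, np.nan)
            row[f"sd_{m}"] = self.sds.get(m, np.nan)
        return row


@dataclass
class GroupComparison:
    """One metric's group comparison: assumption checks, ANOVA, Tukey."""

    metric: str
    groups: list
    group_means: dict
    group_sds: dict
    normality_p: dict
    levene_p: float
    equal_variances: bool
    anova_f: float
    anova_p: float
    t_statistic: float | None       # exposed when there are exactly 2 groups
    tukey: pd.DataFrame = dfield(repr=False, default=None)
    percent_difference: float | None = None
    alpha: float = 0.05

    def significant(self) -> bool:
        return bool(self.anova_p < self.alpha)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "tukey"}
        d["tukey"] = self.tukey.to_dict(orient="records") if self.tukey is not None else None
        return d


def _grid_proxy(maps: ThicknessMaps) -> Volume3D:
    # grid-compatibility checks only need shape/affine, not the NaN payload
    return Volume3D(np.zeros(maps.T.shape, dtype=np.uint8), affine=maps.affine)


def roi_extract(maps: ThicknessMaps, roi: MaskVolume, subject: str = "",
                group: str = "", roi_name: str = "roi") -> ROISummary:
    """Means and sds of T, G, M, P over ROI voxels with defined metrics.

    Undefined voxels inside the ROI are excluded and counted.
    """
    require_grid_compatible(_grid_proxy(maps), roi)
    sel = roi.bool_data & maps.defined
    n = int(sel.sum())
    if n == 0:
        raise ValueError("ROI does not intersect the defined-metric region")
    means, sds = {}, {}
    for m in METRICS:
        v = getattr(maps, m)[sel]
        means[m] = float(np.mean(v))
        sds[m] = float(np.std(v, ddof=1)) if n > 1 else 0.0
    return ROISummary(subject=subject, group=group, roi=roi_name, means=means,
                      sds=sds, voxel_count=n,
                      undefined_count=int((roi.bool_data & ~maps.defined).sum()))


def average_atlas(maps_list: list[ThicknessMaps],
                  min_coverage: float = 0.5) -> ThicknessMaps:
    """Voxelwise mean of co-registered metric maps over subjects.

    A voxel enters the atlas only if the metric is defined there in at
    least ``min_coverage`` of subjects; the resulting coverage mask is the
    atlas's ``defined`` field.
    """
    if len(maps_list) < 2:
        raise ValueError("atlas averaging needs at least 2 subjects")
    ref = maps_list[0]
    for m in maps_list[1:]:
        require_grid_compatible(_grid_proxy(ref), _grid_proxy(m))
    counts = np.sum([m.defined for m in maps_list], axis=0)
    coverage = counts >= min_coverage * len(maps_list)
    out = {}
    for key in METRICS:
        stack = np.stack([np.where(m.defined, getattr(m, key), np.nan)
                          for m in maps_list])
        valid = ~np.isnan(stack)
        mean = np.nansum(np.where(valid, stack, 0.0), axis=0) \
            / np.maximum(valid.sum(axis=0), 1)
        mean[~coverage] = np.nan
        out[key] = mean
    pial = np.logical_or.reduce([m.pial for m in maps_list]) & coverage
    return ThicknessMaps(T=out["T"], G=out["G"], M=out["M"], P=out["P"],
                         defined=coverage, pial=pial, affine=ref.affine)


def group_compare(summaries: list[ROISummary], metric: str = "M",
                  alpha: float = 0.05) -> GroupComparison:
    """One-way ANOVA with Tukey HSD over subject-level ROI means.

    Normality (Anderson–Darling, per group) and variance homogeneity
    (Levene) are reported as gates: violations are logged as warnings and
    the parametric analysis proceeds. Percent difference is reported for
    the two-group case as 100·(case − control)/control, taking the first
    group encountered as the control reference.
    """
    df = pd.DataFrame([s.as_row() for s in summaries])
    if df.empty:
        raise ValueError("no summaries supplied")
    col = f"mean_{metric}"
    groups = list(dict.fromkeys(df["group"]))   # preserve encounter order
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    samples = [df.loc[df["group"] == g, col].to_numpy(dtype=float) for g in groups]
    for g, s in zip(groups, samples):
        if len(s) < 3:
            raise ValueError(f"group {g!r} has fewer than 3 subjects")
        if np.std(s, ddof=1) == 0:
            raise ValueError(f"group {g!r} has zero variance in {metric}")

    normality_p = {}
    for g, s in zip(groups, samples):
        _, p = normal_ad(s)
        normality_p[g] = float(p)
        if p < alpha:
            logger.warning("group %s fails Anderson–Darling normality (p=%.3g) "
                           "for %s; proceeding", g, p, metric)
    _, levene_p = stats.levene(*samples)
    equal_var = bool(levene_p >= alpha)
    if not equal_var:
        logger.warning("Levene test rejects equal variances (p=%.3g) for %s; "
                       "proceeding", levene_p, metric)

    f_stat, anova_p = stats.f_oneway(*samples)
    if not np.isfinite(f_stat):           # identical groups: zero between-group SS
        f_stat, anova_p = 0.0, 1.0
    tk = pairwise_tukeyhsd(df[col].to_numpy(dtype=float),
                           df["group"].to_numpy(), alpha=alpha)
    tukey_df = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])

    means = {g: float(np.mean(s)) for g, s in zip(groups, samples)}
    sds = {g: float(np.std(s, ddof=1)) for g, s in zip(groups, samples)}
    t_stat = None
    pct = None
    if len(groups) == 2:
        t_stat = float(stats.ttest_ind(samples[1], samples[0]).statistic)
        pct = 100.0 * (means[groups[1]] - means[groups[0]]) / means[groups[0]]
    return GroupComparison(metric=metric, groups=groups, group_means=means,
                           group_sds=sds, normality_p=normality_p,
                           levene_p=float(levene_p), equal_variances=equal_var,
                           anova_f=float(f_stat), anova_p=float(anova_p),
                           t_statistic=t_stat, tukey=tukey_df,
                           percent_difference=pct, alpha=alpha)


def detectable_effect(control_summaries: list[ROISummary] | None = None,
                      metric: str = "M", alpha: float = 0.05,
                      power: float = 0.8, n_per_group: int = 10,
                      control_mean: float | None = None,
                      control_sd: float | None = None) -> float:
    """Minimal detectable percent difference in group means.

    Solves the two-sided two-sample t-test power equation (noncentral t)
    for the effect size at the requested alpha and power, scales by the
    control standard deviation, and expresses the mean difference as a
    percentage of the control mean. Either control summaries or explicit
    (control_mean, control_sd) must be given.
    """
    if control_summaries is not None:
        vals = np.array([s.means[metric] for s in control_summaries], dtype=float)
        control_mean = float(np.mean(vals))
        control_sd = float(np.std(vals, ddof=1))
    if control_mean is None or control_sd is None:
        raise ValueError("supply control summaries or control_mean and control_sd")
    if control_sd <= 0:
        raise ValueError("control standard deviation must be positive")
    if n_per_group < 2:
        raise ValueError("need n >= 2 per group")
    d = TTestIndPower().solve_power(effect_size=None, nobs1=n_per_group,
                                    alpha=alpha, power=power, ratio=1.0,
                                    alternative="two-sided")
    delta = float(d) * control_sd
    return 100.0 * delta / control_mean


def simulate_summary_cohort(n_per_group: int = 10, control_mean: float = 3.0,
                            control_sd: float = 0.2, effect: float = 0.0,
                            metric: str = "M", seed: int = 0) -> list[ROISummary]:
    """Draw subject-level ROI means directly from Gaussian group models.

    A fast summary-level stand-in for a full imaging cohort: controls are
    N(mean, sd²), cases are N(mean·(1 − effect), sd²). Used for
    calibration studies (type-I error, power) where generating and
    processing thousands of image volumes would add nothing.
    """
    rng = np.random.default_rng(seed)
    out = []
    for group, mu in (("control", control_mean),
                      ("case", control_mean * (1 - effect))):
        draws = mu + control_sd * rng.standard_normal(n_per_group)
        for i, v in enumerate(draws):
            means = {m: (v if m == metric else np.nan) for m in METRICS}
            out.append(ROISummary(subject=f"{group}{i:02d}", group=group,
                                  roi="sim", means=means,
                                  sds={m: 0.0 for m in METRICS}, voxel_count=1))
    return out
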