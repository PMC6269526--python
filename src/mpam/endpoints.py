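"""Study endpoints: wound closure, noncompartmental PK, group statistics.

Wound closure is the open-wound area as a percent of the day-0 area
(values above 100% early after wounding are reported as-is). PK summaries
are noncompartmental: Cmax/Tmax from the observed maximum and the AUC by the
linear trapezoidal rule over the sampled window, with no extrapolation.
Group/time comparisons use a two-factor (group x time) analysis of variance
with Tukey-adjusted pairwise group comparisons at each timepoint, reported
with the conventional significance stars.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic import PKProfile

STAR_TIERS = ((0.0001, "****"), (0.001, "***"), (0.01, "**"), (0.05, "*"))


# ---------------------------------------------------------------------------
# Wound closure
# ---------------------------------------------------------------------------

def mask_area_mm2(mask: np.ndarray, pixel_size_mm: float) -> float:
    """Area of a binary mask in mm^2."""
    return float(np.count_nonzero(mask)) * pixel_size_mm**2


def closure_fraction(mask_t: np.ndarray, mask_0: np.ndarray, pixel_size_mm: float = 1.0) -> float:
    """Open-wound size at time t as percent of the original (day-0) area."""
    mask_t = np.asarray(mask_t, dtype=bool)
    mask_0 = np.asarray(mask_0, dtype=bool)
    if mask_t.shape != mask_0.shape:
        raise ValueError("masks must share one shape")
    area0 = np.count_nonzero(mask_0)
    if area0 == 0:
        raise ValueError("day-0 wound mask is empty")
    del pixel_size_mm  # the ratio is scale-free; kept for interface symmetry
    return 100.0 * np.count_nonzero(mask_t) / area0


def wound_series_table(
    masks: dict[int, np.ndarray], pixel_size_mm: float, group: str, animal_id
) -> pd.DataFrame:
    """Per-day area and closure fraction for one animal's mask series."""
    if 0 not in masks:
        raise ValueError("wound series requires a day-0 mask")
    rows = []
    for day in sorted(masks):
        rows.append(
            {
                "group": group,
                "animal_id": animal_id,
                "day": day,
                "area_mm2": mask_area_mm2(masks[day], pixel_size_mm),
                "pct_original_area": closure_fraction(masks[day], masks[0]),
            }
        )
    return pd.DataFrame(rows)


def segment_wound(photo: np.ndarray, threshold: float | None = None) -> np.ndarray:
    """Optional automatic wound segmenter for bright-field photographs.

    Thresholds the redness (red minus mean of green/blue for RGB input, or
    intensity for grayscale) and keeps the largest connected component.
    Drawn masks remain the primary input; this is a convenience only.
    """
    img = np.asarray(photo, dtype=float)
    if img.ndim == 3:
        score = img[..., 0] - img[..., 1:].mean(axis=-1)
    else:
        score = img
    if threshold is None:
        threshold = 0.5 * (score.min() + score.max())
    mask = score > threshold
    labels, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


# ---------------------------------------------------------------------------
# Pharmacokinetics
# ---------------------------------------------------------------------------

def cmax_tmax(profile: PKProfile) -> tuple[float, float]:
    """Maximum observed concentration and its time (ties -> earliest time)."""
    if len(profile.conc) < 1:
        raise ValueError("profile is empty")
    idx = int(np.argmax(profile.conc))  # argmax returns the first maximum
    return float(profile.conc[idx]), float(profile.time_h[idx])


def auc_trapezoid(profile: PKProfile) -> float:
    """Linear trapezoidal AUC over the observed window (no extrapolation)."""
    if len(profile.conc) < 2:
        raise ValueError("AUC needs at least two samples")
    return float(np.trapezoid(profile.conc, profile.time_h))


def pk_summary(profile: PKProfile) -> dict:
    """Cmax, Tmax and observed-window AUC for one profile."""
    cmax, tmax = cmax_tmax(profile)
    return {
        "cmax": cmax,
        "tmax_h": tmax,
        "auc": auc_trapezoid(profile),
        "window_h": (float(profile.time_h[0]), float(profile.time_h[-1])),
    }


def median_profile(profiles: list[PKProfile]) -> PKProfile:
    """Pointwise median profile across animals sampled at identical times."""
    times = profiles[0].time_h
    for p in profiles[1:]:
        if not np.array_equal(p.time_h, times):
            raise ValueError("median profile requires identical sampling times")
    conc = np.median(np.stack([p.conc for p in profiles]), axis=0)
    return PKProfile(time_h=times, conc=conc)


# ---------------------------------------------------------------------------
# Group statistics
# ---------------------------------------------------------------------------

def significance_stars(p: float) -> str:
    """Conventional star notation: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    for cutoff, stars in STAR_TIERS:
        if p < cutoff:
            return stars
    return "ns"


def group_compare(table: pd.DataFrame) -> dict:
    """Two-way (group x time) ANOVA with Tukey-adjusted comparisons per timepoint.

    ``table`` holds one row per animal x timepoint with columns ``value``,
    ``group`` and ``timepoint``. Requires >= 2 groups, >= 2 timepoints and
    >= 2 replicates in every group x timepoint cell. Returns the ANOVA table
    and, for each timepoint, all pairwise group comparisons with
    Tukey-adjusted p-values and significance stars.
    """
    from statsmodels.formula.api import ols
    from statsmodels.stats.anova import anova_lm
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = pd.DataFrame(table).copy()
    for col in ("value", "group", "timepoint"):
        if col not in df.columns:
            raise ValueError(f"metric table needs a {col!r} column")
    groups = sorted(df["group"].unique())
    times = sorted(df["timepoint"].unique())
    if len(groups) < 2 or len(times) < 2:
        raise ValueError("need at least two groups and two timepoints")
    counts = df.groupby(["group", "timepoint"]).size()
    if len(counts) < len(groups) * len(times):
        raise ValueError("empty group x timepoint cells")
    if (counts < 2).any():
        raise ValueError("need at least two replicates per group x timepoint cell")

    model = ols("value ~ C(group) * C(timepoint)", data=df).fit()
    anova = anova_lm(model, typ=2)

    comparisons = []
    for t in times:
        sub = df[df["timepoint"] == t]
        tukey = pairwise_tukeyhsd(sub["value"].to_numpy(), sub["group"].to_numpy())
        res = tukey.summary().data[1:]
        for row, p_adj in zip(res, np.atleast_1d(tukey.pvalues)):
            comparisons.append(
                {
                    "timepoint": t.item() if hasattr(t, "item") else t,
                    "group_a": row[0],
                    "group_b": row[1],
                    "mean_diff": float(row[2]),
                    "p_adj": float(p_adj),
                    "stars": significance_stars(float(p_adj)),
                    "significant_0.05": bool(p_adj < 0.05),
                }
            )
    return {
        "anova": {
            str(idx): {
                "F": float(row["F"]) if np.isfinite(row["F"]) else None,
                "p": float(row["PR(>F)"]) if np.isfinite(row["PR(>F)"]) else None,
            }
            for idx, row in anova.iterrows()
        },
        "comparisons": comparisons,
    }


def comparisons_text_table(result: dict) -> str:
    """Human-readable star table for the pairwise comparisons."""
    lines = [f"{'timepoint':>10} {'groups':>24} {'p(adj)':>10}  sig"]
    for c in result["comparisons"]:
        pair = f"{c['group_a']} vs {c['group_b']}"
        lines.append(f"{str(c['timepoint']):>10} {pair:>24} {c['p_adj']:>10.4g}  {c['stars']}")
    return "\n".join(lines)


def permutation_pvalue(a: np.ndarray, b: np.ndarray, n_perm: int = 100_000, seed: int = 0) -> float:
    """Two-sided permutation test on the difference of group means.

    Independent of the parametric machinery; used as an oracle for tier
    agreement on strongly separated groups.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    observed = abs(a.mean() - b.mean())
    n_a = len(a)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        count += abs(perm[:n_a].mean() - perm[n_a:].mean()) >= observed
    return (count + 1) / (n_perm + 1)
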