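"""Per-feature agreement of a machine annotator with the human average,
benchmarked against single-rater and group-of-raters reliability.

Three indices, all Pearson correlations across stimuli:

* **agreement** — machine mean rating vs the human pool mean, per feature;
* **intersubject consistency** — mean, over raters, of each rater's
  correlation with the mean of all other raters (leave-one-out); the
  single-human reliability benchmark;
* **group consistency** — mean correlation between the mean ratings of
  two disjoint rater subgroups over every possible split; the
  group-of-raters benchmark.

Index sets are compared across features with Welch two-sample t-tests on
Fisher-z transformed correlations.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .rating_model import MIN_COMPLETE_PAIRS, MeanRatingMatrix, RatingPanel

__all__ = [
    "AgreementReport",
    "pearson_r",
    "feature_agreement",
    "intersubject_consistency",
    "group_consistency",
    "n_group_splits",
    "fisher_z",
    "compare_agreement_sets",
    "exceedance_fraction",
    "agreement_report",
]


def pearson_r(x, y, min_pairs: int = MIN_COMPLETE_PAIRS) -> float:
    """Product-moment correlation on pairwise-complete observations.

    Returns NaN (the undefined-with-flag convention used throughout)
    when fewer than ``min_pairs`` complete pairs exist or either vector
    is constant on the complete pairs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < min_pairs:
        return float("nan")
    xs, ys = x[ok], y[ok]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return float("nan")
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    return float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))


def _columnwise_r(a: np.ndarray, b: np.ndarray,
                  min_pairs: int = MIN_COMPLETE_PAIRS) -> np.ndarray:
    """Pearson r between matching columns of two item x feature arrays."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.isfinite(a).all() and np.isfinite(b).all():
        # complete data: one vectorised pass over all columns
        if a.shape[0] < min_pairs:
            return np.full(a.shape[1], np.nan)
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        na = np.sqrt((ac * ac).sum(axis=0))
        nb = np.sqrt((bc * bc).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (ac * bc).sum(axis=0) / (na * nb)
        r[(na == 0) | (nb == 0)] = np.nan
        return r
    out = np.full(a.shape[1], np.nan)
    for j in range(a.shape[1]):
        out[j] = pearson_r(a[:, j], b[:, j], min_pairs)
    return out


def feature_agreement(machine_mean: MeanRatingMatrix,
                      human_mean: MeanRatingMatrix) -> np.ndarray:
    """Per-feature correlation between machine and human mean ratings.

    The two matrices are aligned on their shared items (machine items
    failed in all rounds have already been dropped from ``machine_mean``)
    and must present the same features in the same order.
    """
    if list(machine_mean.features) != list(human_mean.features):
        raise ValueError("feature axes differ between machine and human means")
    shared = [it for it in human_mean.items if it in set(machine_mean.items)]
    if len(shared) < MIN_COMPLETE_PAIRS:
        raise ValueError("fewer than 3 shared items after dropping failures")
    hm = human_mean.restrict_items(shared)
    mm = machine_mean.restrict_items(shared)
    return _columnwise_r(mm.values, hm.values)


def intersubject_consistency(panel: RatingPanel, return_counts: bool = False):
    """Leave-one-out single-rater reliability, per feature.

    For each rater, their ratings are correlated with the mean of all
    other raters over the items both sides cover; the per-feature value
    is the mean of those correlations.  Raters whose correlation is
    undefined (constant ratings, too few items) are dropped from the
    mean and counted.
    """
    cube = panel.ratings  # items x features x raters
    n_items, n_feat, n_raters = cube.shape
    if n_raters < 2:
        raise ValueError("need at least 2 raters")
    finite = np.isfinite(cube)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        total = np.nansum(cube, axis=2)
    count = finite.sum(axis=2)

    rs = np.full((n_feat, n_raters), np.nan)
    for r in range(n_raters):
        others_sum = total - np.where(finite[:, :, r], cube[:, :, r], 0.0)
        others_n = count - finite[:, :, r].astype(int)
        with np.errstate(invalid="ignore", divide="ignore"):
            others_mean = np.where(others_n > 0, others_sum / others_n, np.nan)
        rs[:, r] = _columnwise_r(cube[:, :, r], others_mean)
    defined = np.isfinite(rs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        per_feature = np.nanmean(rs, axis=1)
    per_feature[defined.sum(axis=1) == 0] = np.nan
    if return_counts:
        return per_feature, (defined.shape[1] - defined.sum(axis=1))
    return per_feature


def n_group_splits(n_raters: int, group_size: int) -> int:
    """Number of unordered disjoint pairs of size-``group_size`` subsets.

    Every unordered pair {A, B} is counted twice by the ordered product
    C(R, g) * C(R - g, g), so the count is C(R, g) * C(R - g, g) / 2;
    for R = 2g this reduces to C(R, g) / 2 (e.g. 126 splits for ten
    raters in groups of five).
    """
    return comb(n_raters, group_size) * comb(n_raters - group_size, group_size) // 2


def group_consistency(panel: RatingPanel, group_size: int = 5) -> np.ndarray:
    """Split-group reliability: mean correlation of two group means.

    Enumerates every unordered pair of disjoint rater subsets of size
    ``group_size``, correlates the two subset means per feature, and
    averages over splits.
    """
    cube = panel.ratings
    n_raters = cube.shape[2]
    g = group_size
    if n_raters < 2 * g:
        raise ValueError(f"need at least {2 * g} raters for group size {g}")
    finite = np.isfinite(cube)
    filled = np.where(finite, cube, 0.0)

    def group_mean(idx):
        s = filled[:, :, idx].sum(axis=2)
        n = finite[:, :, idx].sum(axis=2)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, s / n, np.nan)

    n_feat = cube.shape[1]
    acc = np.zeros(n_feat)
    n_def = np.zeros(n_feat, dtype=int)
    n_splits = 0
    all_raters = range(n_raters)
    for a in combinations(all_raters, g):
        rest = [r for r in all_raters if r not in a]
        for b in combinations(rest, g):
            if b < a:  # each unordered pair once
                continue
            n_splits += 1
            r = _columnwise_r(group_mean(list(a)), group_mean(list(b)))
            ok = np.isfinite(r)
            acc[ok] += r[ok]
            n_def += ok
    assert n_splits == n_group_splits(n_raters, g)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(n_def > 0, acc / np.maximum(n_def, 1), np.nan)
    return out


def fisher_z(r):
    """Variance-stabilising artanh transform; |r| >= 1 is clipped."""
    r = np.asarray(r, dtype=float)
    clipped = np.abs(r) >= 1
    if np.any(clipped & np.isfinite(r)):
        warnings.warn("correlation(s) at +/-1 clipped before Fisher transform")
    safe = np.clip(r, -1 + 1e-7, 1 - 1e-7)
    out = np.arctanh(safe)
    out = np.where(np.isfinite(r), out, np.nan)
    return float(out) if out.ndim == 0 else out


def compare_agreement_sets(z_a, z_b):
    """Welch two-sample t-test between two sets of Fisher-z values.

    Returns ``(t, p, direction)`` with a two-sided p and direction the
    sign of ``mean(z_a) - mean(z_b)``.  NaN entries are dropped.
    """
    z_a = np.asarray(z_a, dtype=float)
    z_b = np.asarray(z_b, dtype=float)
    z_a = z_a[np.isfinite(z_a)]
    z_b = z_b[np.isfinite(z_b)]
    if z_a.size < 2 or z_b.size < 2:
        raise ValueError("need at least 2 defined values per set")
    if np.ptp(z_a) == 0 and np.ptp(z_b) == 0:
        if z_a.mean() == z_b.mean():
            return 0.0, 1.0, 0
        return float("nan"), float("nan"), int(np.sign(z_a.mean() - z_b.mean()))
    t, p = stats.ttest_ind(z_a, z_b, equal_var=False)
    return float(t), float(p), int(np.sign(z_a.mean() - z_b.mean()))


def exceedance_fraction(agreement, benchmark, return_n: bool = False):
    """Fraction of features where agreement strictly exceeds a benchmark."""
    agreement = np.asarray(agreement, dtype=float)
    benchmark = np.asarray(benchmark, dtype=float)
    if agreement.shape != benchmark.shape:
        raise ValueError("feature axes differ")
    ok = np.isfinite(agreement) & np.isfinite(benchmark)
    n = int(ok.sum())
    frac = float((agreement[ok] > benchmark[ok]).sum() / n) if n else float("nan")
    if return_n:
        return frac, n
    return frac


@dataclass
class AgreementReport:
    """Per-feature indices plus global summaries and comparison tests."""

    features: list
    agreement_r: np.ndarray
    intersubject: np.ndarray
    group: np.ndarray
    n_items_used: int
    group_size: int
    mean_agreement: float
    mean_intersubject: float
    mean_group: float
    frac_above_intersubject: float
    frac_above_group: float
    t_vs_intersubject: tuple  # (t, p, direction)
    t_vs_group: tuple

    def per_feature_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature": self.features,
                "agreement_r": self.agreement_r,
                "intersubject_consistency": self.intersubject,
                "group_consistency": self.group,
            }
        )

    def summary(self) -> dict:
        t1, p1, d1 = self.t_vs_intersubject
        t2, p2, d2 = self.t_vs_group
        return {
            "n_items_used": self.n_items_used,
            "group_size": self.group_size,
            "mean_agreement": self.mean_agreement,
            "mean_intersubject_consistency": self.mean_intersubject,
            "mean_group_consistency": self.mean_group,
            "frac_agreement_above_intersubject": self.frac_above_intersubject,
            "frac_agreement_above_group": self.frac_above_group,
            "welch_t_vs_intersubject": {"t": t1, "p": p1, "direction": d1},
            "welch_t_vs_group": {"t": t2, "p": p2, "direction": d2},
        }


def agreement_report(human: RatingPanel, machine_mean: MeanRatingMatrix,
                     group_size: int = 5) -> AgreementReport:
    """Run the full stage-1 analysis and bundle the results."""
    from .rating_model import mean_over_raters

    human_mean = mean_over_raters(human)
    agr = feature_agreement(machine_mean, human_mean)
    isc = intersubject_consistency(human)
    grp = group_consistency(human, group_size)
    shared = [it for it in human.items if it in set(machine_mean.items)]

    z_agr, z_isc, z_grp = fisher_z(agr), fisher_z(isc), fisher_z(grp)
    return AgreementReport(
        features=list(human.features),
        agreement_r=agr,
        intersubject=isc,
        group=grp,
        n_items_used=len(shared),
        group_size=group_size,
        mean_agreement=float(np.nanmean(agr)),
        mean_intersubject=float(np.nanmean(isc)),
        mean_group=float(np.nanmean(grp)),
        frac_above_intersubject=exceedance_fraction(agr, isc),
        frac_above_group=exceedance_fraction(agr, grp),
        t_vs_intersubject=compare_agreement_sets(z_agr, z_isc),
        t_vs_group=compare_agreement_sets(z_agr, z_grp),
    )
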