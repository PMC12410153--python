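"""Massive-univariate fMRI encoding with feature regressors, group-level
thresholding, and comparison of the maps produced by two stimulus models.

Each feature's stimulus time course (a boxcar at the clip's rated
intensity over its duration) is convolved with the canonical
double-gamma hemodynamic response function, sampled at volume
acquisition times, and fitted voxel-by-voxel to each subject's BOLD data
as a *simple* regression (one feature at a time, intercept plus
regressor).  Subject beta maps enter a one-sample t-test; group maps are
thresholded uncorrected or with Bonferroni voxel-level FWE.  Two
stimulus models (e.g. machine-derived vs human-derived ratings) are then
compared by spatial correlation of unthresholded betas, PPV/NPV of the
thresholded maps, and the correlation of cumulative tuning-breadth maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StimulusSchedule",
    "FeatureRegressor",
    "StatMapSet",
    "EncodingComparison",
    "canonical_hrf",
    "build_feature_regressor",
    "first_level_betas",
    "group_one_sample_t",
    "threshold_map",
    "ppv_npv",
    "cumulative_map",
    "spatial_correlation",
    "run_encoding",
    "compare_encodings",
]


@dataclass
class StimulusSchedule:
    """Clip onsets/durations for one scanning run.

    ``clips`` is an ordered list of ``(item_id, onset_s, duration_s)``;
    onsets must ascend without overlap and the last offset must fit
    within ``tr * n_volumes``.
    """

    clips: list
    tr: float
    n_volumes: int

    def __post_init__(self):
        last_off = 0.0
        for item, onset, dur in self.clips:
            if onset < last_off - 1e-9:
                raise ValueError(f"clip {item!r} overlaps the previous clip")
            if dur <= 0:
                raise ValueError(f"clip {item!r} has non-positive duration")
            last_off = onset + dur
        if last_off > self.tr * self.n_volumes + 1e-9:
            raise ValueError(
                f"schedule runs to {last_off:.1f}s, past the last volume at "
                f"{self.tr * self.n_volumes:.1f}s"
            )

    @property
    def item_ids(self):
        return [c[0] for c in self.clips]

    @classmethod
    def from_csv(cls, path, tr: float, n_volumes: int) -> "StimulusSchedule":
        df = pd.read_csv(path)
        need = {"item_id", "onset_s", "duration_s"}
        if not need.issubset(df.columns):
            raise ValueError(f"schedule CSV needs columns {sorted(need)}")
        clips = list(df[["item_id", "onset_s", "duration_s"]].itertuples(
            index=False, name=None))
        return cls(clips, tr, n_volumes)

    def to_csv(self, path):
        pd.DataFrame(self.clips,
                     columns=["item_id", "onset_s", "duration_s"]
                     ).to_csv(path, index=False)


@dataclass
class FeatureRegressor:
    """Convolved, mean-centred predicted BOLD time course of one feature."""

    feature: str
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("regressor contains non-finite values")


def canonical_hrf(dt: float, duration: float = 32.0,
                  peak_delay: float = 6.0, undershoot_delay: float = 16.0,
                  peak_disp: float = 1.0, undershoot_disp: float = 1.0,
                  ratio: float = 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response kernel.

    Difference of two gamma densities — a response peaking near 5 s and
    an undershoot near 15 s at one sixth the amplitude — sampled every
    ``dt`` seconds over ``duration`` (default 32 s) and normalised to
    unit peak.
    """
    if not 0 < dt <= 1:
        raise ValueError("dt must be in (0, 1] seconds")
    t = np.arange(0, duration + dt / 2, dt)
    peak = stats.gamma.pdf(t, peak_delay / peak_disp, scale=peak_disp)
    under = stats.gamma.pdf(t, undershoot_delay / undershoot_disp,
                            scale=undershoot_disp)
    h = peak - under / ratio
    return h / h.max()


def build_feature_regressor(schedule: StimulusSchedule, feature_values: dict,
                            feature: str = "", microtime: int = 16) -> FeatureRegressor:
    """Build one feature's convolved regressor from per-clip intensities.

    A boxcar at ``microtime`` bins per TR carries each clip's rated
    intensity over its duration; it is convolved with
    :func:`canonical_hrf`, sampled at volume acquisition times, and
    mean-centred.

    ``feature_values`` maps every scheduled item_id to its intensity.
    """
    missing = [it for it in schedule.item_ids if it not in feature_values]
    if missing:
        raise ValueError(f"no feature value for scheduled clip(s) {missing[:5]}")
    dt = schedule.tr / microtime
    n_fine = schedule.n_volumes * microtime
    boxcar = np.zeros(n_fine + int(np.ceil(32.0 / dt)) + 1)
    for item, onset, dur in schedule.clips:
        a = int(round(onset / dt))
        b = int(round((onset + dur) / dt))
        boxcar[a:b] = feature_values[item]
    h = canonical_hrf(dt)
    conv = np.convolve(boxcar, h)[:n_fine]
    # sample at acquisition times t = n * TR
    samples = conv[np.arange(schedule.n_volumes) * microtime]
    return FeatureRegressor(feature, samples - samples.mean())


def first_level_betas(bold: np.ndarray, regressor: FeatureRegressor) -> np.ndarray:
    """Per-voxel OLS slope of the BOLD signal on one feature regressor.

    Simple regression with an intercept, fitted independently at every
    voxel; returns the regressor coefficient per voxel.
    """
    x = regressor.values
    if np.ptp(x) == 0:
        raise ValueError("constant regressor")
    bold = np.asarray(bold, dtype=float)
    if bold.shape[1] != x.size:
        raise ValueError("time axes differ between BOLD and regressor")
    xc = x - x.mean()
    yc = bold - bold.mean(axis=1, keepdims=True)
    return yc @ xc / (xc @ xc)


def group_one_sample_t(betas: np.ndarray):
    """One-sample t-test across subjects at every voxel.

    ``betas`` is subject x voxel; returns ``(t, p)`` with a one-sided p
    for a positive group mean (df = n_subjects - 1).  Zero-variance
    voxels get NaN.
    """
    betas = np.asarray(betas, dtype=float)
    n = betas.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    mean = betas.mean(axis=0)
    sd = betas.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[sd == 0] = np.nan
    p = stats.t.sf(t, df=n - 1)
    return t, p


def threshold_map(p: np.ndarray, alpha: float,
                  correction: str = "none",
                  mask: np.ndarray | None = None) -> np.ndarray:
    """Binary map of voxels passing a significance threshold.

    ``correction="none"`` thresholds at ``p < alpha``;
    ``"bonferroni_fwe"`` at ``p < alpha / V`` over the V in-mask voxels
    (a conservative voxel-level family-wise error control).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    p = np.asarray(p, dtype=float)
    if mask is None:
        mask = np.ones(p.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    v = int(mask.sum())
    if v == 0:
        raise ValueError("empty mask")
    if correction == "none":
        cut = alpha
    elif correction == "bonferroni_fwe":
        cut = alpha / v
    else:
        raise ValueError(f"unknown correction {correction!r}")
    with np.errstate(invalid="ignore"):
        out = (p < cut) & mask & np.isfinite(p)
    return out


def ppv_npv(test_map: np.ndarray, reference_map: np.ndarray,
            mask: np.ndarray | None = None):
    """Positive and negative predictive value of a test map.

    The reference map is treated as ground truth: PPV = TP/(TP+FP) over
    voxels the test declares positive, NPV = TN/(TN+FN) over voxels it
    declares negative.  An empty positive (or negative) set leaves PPV
    (or NPV) NaN.
    """
    test_map = np.asarray(test_map, dtype=bool)
    reference_map = np.asarray(reference_map, dtype=bool)
    if test_map.shape != reference_map.shape:
        raise ValueError("map shapes differ")
    if mask is None:
        mask = np.ones(test_map.shape, dtype=bool)
    t = test_map[mask]
    r = reference_map[mask]
    tp = int((t & r).sum())
    fp = int((t & ~r).sum())
    tn = int((~t & ~r).sum())
    fn = int((~t & r).sum())
    ppv = tp / (tp + fp) if (tp + fp) else float("nan")
    npv = tn / (tn + fn) if (tn + fn) else float("nan")
    return ppv, npv


def cumulative_map(binary_maps: np.ndarray) -> np.ndarray:
    """Per-voxel count of features passing threshold (tuning breadth)."""
    binary_maps = np.asarray(binary_maps)
    return binary_maps.astype(int).sum(axis=0)


def spatial_correlation(map_a: np.ndarray, map_b: np.ndarray,
                        mask: np.ndarray | None = None) -> float:
    """Pearson correlation of two real-valued maps over in-mask voxels."""
    map_a = np.asarray(map_a, dtype=float)
    map_b = np.asarray(map_b, dtype=float)
    if map_a.shape != map_b.shape:
        raise ValueError("map shapes differ")
    if mask is None:
        mask = np.ones(map_a.shape, dtype=bool)
    a = map_a[mask]
    b = map_b[mask]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    ac = a - a.mean()
    bc = b - b.mean()
    return float(ac @ bc / np.sqrt((ac @ ac) * (bc @ bc)))


# ---------------------------------------------------------------------------
# Orchestration over features and subjects
# ---------------------------------------------------------------------------

@dataclass
class StatMapSet:
    """Group-level encoding results for one stimulus model."""

    features: list
    subject_betas: np.ndarray        # feature x subject x voxel
    group_beta: np.ndarray           # feature x voxel
    t: np.ndarray                    # feature x voxel
    p: np.ndarray                    # feature x voxel (one-sided positive)
    binary: dict = field(default_factory=dict)   # threshold label -> feature x voxel bool
    cumulative: dict = field(default_factory=dict)  # threshold label -> voxel counts
    mask: np.ndarray | None = None


@dataclass
class EncodingComparison:
    """Feature-wise similarity of two encoding results."""

    features: list
    spatial_r: np.ndarray
    ppv: dict       # threshold label -> per-feature PPV
    npv: dict       # threshold label -> per-feature NPV
    cumulative_r: dict  # threshold label -> scalar r

    def per_feature_frame(self) -> pd.DataFrame:
        data = {"feature": self.features, "spatial_r": self.spatial_r}
        for label in self.ppv:
            data[f"ppv_{label}"] = self.ppv[label]
            data[f"npv_{label}"] = self.npv[label]
        return pd.DataFrame(data)


DEFAULT_THRESHOLDS = {
    "lenient": (0.001, "none"),
    "conservative": (0.05, "bonferroni_fwe"),
}


def run_encoding(bold_per_subject, schedule: StimulusSchedule,
                 feature_table: pd.DataFrame,
                 thresholds: dict = None,
                 mask: np.ndarray | None = None) -> StatMapSet:
    """First- and group-level analysis for every feature of one model.

    Parameters
    ----------
    bold_per_subject
        Sequence of voxel x time arrays, one per subject.
    schedule
        The stimulus schedule shared by all subjects.
    feature_table
        Item x feature DataFrame of the stimulus model's ratings
        (index = item_id); every scheduled item must be present.
    thresholds
        Mapping label -> (alpha, correction); defaults to the lenient
        p < 0.001 uncorrected and conservative FWE p < 0.05 pair.
    """
    thresholds = DEFAULT_THRESHOLDS if thresholds is None else thresholds
    features = list(feature_table.columns)
    n_sub = len(bold_per_subject)
    n_vox = bold_per_subject[0].shape[0]
    if mask is None:
        mask = np.ones(n_vox, dtype=bool)

    sub_betas = np.empty((len(features), n_sub, n_vox))
    tmap = np.empty((len(features), n_vox))
    pmap = np.empty((len(features), n_vox))
    for fi, feat in enumerate(features):
        reg = build_feature_regressor(
            schedule, feature_table[feat].to_dict(), feature=feat)
        for si, bold in enumerate(bold_per_subject):
            sub_betas[fi, si] = first_level_betas(bold, reg)
        tmap[fi], pmap[fi] = group_one_sample_t(sub_betas[fi])

    binary = {}
    cum = {}
    for label, (alpha, corr) in thresholds.items():
        binary[label] = np.stack([
            threshold_map(pmap[fi], alpha, corr, mask)
            for fi in range(len(features))
        ])
        cum[label] = cumulative_map(binary[label])
    return StatMapSet(
        features=features,
        subject_betas=sub_betas,
        group_beta=sub_betas.mean(axis=1),
        t=tmap,
        p=pmap,
        binary=binary,
        cumulative=cum,
        mask=mask,
    )


def compare_encodings(test: StatMapSet, reference: StatMapSet) -> EncodingComparison:
    """Compare a test model's maps against a reference model's maps.

    Spatial correlation of unthresholded group betas per feature,
    PPV/NPV of the thresholded test maps with the reference as ground
    truth, and the correlation of cumulative maps per threshold.
    """
    if test.features != reference.features:
        raise ValueError("feature sets differ")
    mask = test.mask
    spat = np.array([
        spatial_correlation(test.group_beta[fi], reference.group_beta[fi], mask)
        for fi in range(len(test.features))
    ])
    ppv, npv, cum_r = {}, {}, {}
    for label in test.binary:
        pv = np.empty(len(test.features))
        nv = np.empty(len(test.features))
        for fi in range(len(test.features)):
            pv[fi], nv[fi] = ppv_npv(test.binary[label][fi],
                                     reference.binary[label][fi], mask)
        ppv[label], npv[label] = pv, nv
        cum_r[label] = spatial_correlation(
            test.cumulative[label].astype(float),
            reference.cumulative[label].astype(float), mask)
    return EncodingComparison(
        features=list(test.features),
        spatial_r=spat, ppv=ppv, npv=npv, cumulative_r=cum_r,
    )
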