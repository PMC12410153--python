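"""Synthetic rater pools, machine annotators and event-related BOLD with
known ground truth.

The generators emulate the statistical structure of a social-annotation
study — a pool of raters scoring features of naturalistic clips on a
0-10 scale, an item-level latent low-dimensional correlation structure
among features, a machine annotator averaged over repeated collection
rounds with a compressive bias below the scale midpoint and occasional
item refusals, and event-related BOLD with sparse voxel tuning to the
features — so that every downstream stage can be exercised against a
planted truth without any external data.

Human rating noise is Gaussian with clipping to the scale; the rater
noise scale is calibrated per feature so the expected single-rater
(leave-one-out) consistency matches a requested reliability profile.
All generators take explicit seeds; there is no hidden global state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encoding import StimulusSchedule, build_feature_regressor
from .rating_model import MachineRatingSet, RatingPanel

__all__ = [
    "RatingGroundTruth",
    "BoldGroundTruth",
    "noise_sd_for_consistency",
    "generate_rating_panel",
    "sample_panel_from_truth",
    "generate_machine_ratings",
    "make_schedule",
    "bold_noise_sd_for_effect_size",
    "generate_bold",
    "write_bold_nifti",
]

SCALE = (0.0, 10.0)


@dataclass
class RatingGroundTruth:
    """Planted structure behind a synthetic rating panel."""

    latent_loadings: np.ndarray     # feature x K
    item_scores: np.ndarray         # item x K
    true_intensity: np.ndarray      # item x feature, within the scale
    rater_noise_sd: np.ndarray      # per feature
    consistency_profile: np.ndarray  # per-feature target single-rater reliability
    items: list = None
    features: list = None

    def __post_init__(self):
        lo, hi = SCALE
        if self.true_intensity.min() < lo or self.true_intensity.max() > hi:
            raise ValueError("true intensity outside the rating scale")
        if np.any(self.rater_noise_sd < 0):
            raise ValueError("noise sd must be non-negative")


@dataclass
class BoldGroundTruth:
    """Planted voxel tuning behind synthetic BOLD data."""

    true_beta: np.ndarray           # voxel x feature
    tuned_mask: np.ndarray          # voxel x feature bool, beta > 0
    noise_sd: float
    subject_beta_jitter_sd: float

    def __post_init__(self):
        if self.noise_sd < 0 or self.subject_beta_jitter_sd < 0:
            raise ValueError("sd must be non-negative")
        if not np.array_equal(self.tuned_mask, self.true_beta > 0):
            raise ValueError("tuned_mask inconsistent with true_beta sign")


def noise_sd_for_consistency(rho, signal_sd, n_raters: int):
    """Rater noise sd giving expected leave-one-out consistency ``rho``.

    With signal variance s2 and noise variance v*s2, the population
    correlation between one rater and the mean of the other m = R - 1 is

        rho = 1 / sqrt((1 + v) (1 + v / m)),

    solved for v:  v = (-(m+1) + sqrt((m+1)^2 - 4 m (1 - 1/rho^2))) / 2.
    """
    rho = np.asarray(rho, dtype=float)
    if np.any(rho <= 0) or np.any(rho >= 1):
        raise ValueError("consistency targets must lie in (0, 1)")
    m = n_raters - 1
    if m < 1:
        raise ValueError("need at least 2 raters")
    disc = (m + 1) ** 2 - 4 * m * (1 - 1 / rho**2)
    v = (-(m + 1) + np.sqrt(disc)) / 2
    return np.sqrt(v) * np.asarray(signal_sd, dtype=float)


def generate_rating_panel(n_items: int, n_features: int, n_raters: int = 10,
                          k_latent: int = 8, consistency_profile=0.6,
                          seed: int = 0, intensity_mean: float = 5.0,
                          intensity_sd: float = 1.5, modality: str = "video"):
    """Generate a human rater pool with a planted latent structure.

    True per-item feature intensities are a clipped affine image of
    ``item_scores @ latent_loadings.T`` on [0, 10], centred at
    ``intensity_mean`` with across-item sd ``intensity_sd``; latent
    component strengths decay across the K dimensions so the planted
    ordination has a stable component order.  Each rater adds
    independent Gaussian noise whose per-feature sd is calibrated so the
    expected single-rater consistency matches ``consistency_profile``
    (scalar or per-feature array in (0, 1)); ratings are clipped to the
    scale.

    Returns ``(RatingPanel, RatingGroundTruth)``.
    """
    if min(n_items, n_features, n_raters, k_latent) < 1:
        raise ValueError("all counts must be >= 1")
    profile = np.broadcast_to(
        np.asarray(consistency_profile, dtype=float), (n_features,)).copy()
    if np.any(profile <= 0) or np.any(profile >= 1):
        raise ValueError("consistency_profile values must lie in (0, 1)")
    rng = np.random.default_rng(seed)

    # decaying component strengths keep the eigenvalue order identifiable
    strengths = np.linspace(1.6, 0.6, k_latent)
    loadings = rng.standard_normal((n_features, k_latent)) * strengths
    scores = rng.standard_normal((n_items, k_latent))
    raw = scores @ loadings.T
    raw_sd = raw.std(axis=0)
    raw_sd[raw_sd == 0] = 1.0
    true = np.clip(intensity_mean + raw / raw_sd * intensity_sd, *SCALE)

    signal_sd = true.std(axis=0)
    signal_sd[signal_sd == 0] = intensity_sd
    noise_sd = noise_sd_for_consistency(profile, signal_sd, n_raters)

    items = [f"item{i:04d}" for i in range(n_items)]
    features = [f"feat{j:03d}" for j in range(n_features)]
    truth = RatingGroundTruth(
        latent_loadings=loadings, item_scores=scores, true_intensity=true,
        rater_noise_sd=noise_sd, consistency_profile=profile,
        items=items, features=features,
    )
    panel = sample_panel_from_truth(truth, n_raters,
                                    seed=int(rng.integers(2**31)),
                                    modality=modality)
    return panel, truth


def sample_panel_from_truth(truth: RatingGroundTruth, n_raters: int = 10,
                            seed: int = 0, modality: str = "video") -> RatingPanel:
    """Draw an independent rater pool from an existing ground truth.

    Repeated draws with different seeds yield replicate panels sharing
    the same planted intensities and noise calibration — e.g. to test
    whether a recovered latent structure replicates.
    """
    rng = np.random.default_rng(seed)
    true = truth.true_intensity
    n_items, n_features = true.shape
    noise = rng.standard_normal((n_items, n_features, n_raters)) \
        * truth.rater_noise_sd[None, :, None]
    ratings = np.clip(true[:, :, None] + noise, *SCALE)
    raters = [f"rater{r:02d}" for r in range(n_raters)]
    return RatingPanel(truth.items, truth.features, raters, ratings, SCALE,
                       modality)


def generate_machine_ratings(truth: RatingGroundTruth, n_rounds: int = 5,
                             round_noise_sd: float = 1.0,
                             floor_bias: float = 0.2,
                             fail_rate: float = 0.03,
                             seed: int = 0) -> MachineRatingSet:
    """Simulate a machine annotator queried over repeated rounds.

    Each round applies a compressive low-end bias to the true intensity
    — values below the scale midpoint 5 are multiplied by
    ``1 - floor_bias`` while values at or above 5 pass unchanged,
    reproducing the tendency of the machine to under-rate weak feature
    presence — then adds round noise and clips to the scale.  A
    ``fail_rate`` fraction of items is refused in every round (missing
    throughout) and will be flagged failed.
    """
    if n_rounds < 1:
        raise ValueError("need at least 1 round")
    if not 0 <= fail_rate < 1:
        raise ValueError("fail_rate must be in [0, 1)")
    if not 0 <= floor_bias < 1:
        raise ValueError("floor_bias must be in [0, 1)")
    rng = np.random.default_rng(seed)
    true = truth.true_intensity
    n_items, n_features = true.shape
    biased = np.where(true < 5.0, true * (1.0 - floor_bias), true)
    noise = rng.standard_normal((n_items, n_features, n_rounds)) * round_noise_sd
    ratings = np.clip(biased[:, :, None] + noise, *SCALE)
    failed = rng.random(n_items) < fail_rate
    ratings[failed] = np.nan
    items = truth.items or [f"item{i:04d}" for i in range(n_items)]
    features = truth.features or [f"feat{j:03d}" for j in range(n_features)]
    rounds = [f"round{k}" for k in range(1, n_rounds + 1)]
    return MachineRatingSet(items, features, rounds, ratings, SCALE)


# ---------------------------------------------------------------------------
# Event-related BOLD
# ---------------------------------------------------------------------------

def make_schedule(item_ids, tr: float = 2.6, n_volumes: int = 467,
                  clip_duration: float = 8.0, gap: float = 4.0,
                  start: float = 10.0) -> StimulusSchedule:
    """Pack as many clips as fit into one run, in the given item order.

    Clips of ``clip_duration`` seconds follow each other separated by
    ``gap`` seconds of rest, starting at ``start`` seconds.  Items that
    do not fit before the last volume are omitted.
    """
    total = tr * n_volumes
    clips = []
    t = start
    for item in item_ids:
        if t + clip_duration > total:
            break
        clips.append((item, t, clip_duration))
        t += clip_duration + gap
    if not clips:
        raise ValueError("no clip fits in the run")
    return StimulusSchedule(clips, tr, n_volumes)


def bold_noise_sd_for_effect_size(effect_size_d: float, beta: float,
                                  jitter_sd: float,
                                  regressors: np.ndarray) -> float:
    """Scanner noise sd giving a tuned-voxel group effect size ``d``.

    The across-subject sd of an estimated beta combines the planted
    between-subject jitter with the OLS estimation error
    ``noise_sd / sqrt(sum of squared centred regressor)``; solving
    ``beta / d = sqrt(jitter^2 + est^2)`` for the noise sd, using the
    mean regressor energy over features.
    """
    target_var = (beta / effect_size_d) ** 2 - jitter_sd**2
    if target_var <= 0:
        raise ValueError("jitter alone exceeds the requested total variability")
    regressors = np.atleast_2d(np.asarray(regressors, dtype=float))
    xc = regressors - regressors.mean(axis=1, keepdims=True)
    energy = (xc * xc).sum(axis=1).mean()
    return float(np.sqrt(target_var * energy))


def generate_bold(schedule: StimulusSchedule, feature_values: pd.DataFrame,
                  n_subjects: int = 20, n_voxels: int = 2000,
                  beta: float = 1.0, tuned_fraction: float = 0.05,
                  effect_size_d: float = 1.1, jitter_frac: float = 0.4,
                  noise_sd: float | None = None,
                  jitter_sd: float | None = None,
                  seed: int = 0):
    """Simulate per-subject BOLD driven by feature regressors.

    A sparse ``tuned_fraction`` of voxel x feature cells carries a
    positive true beta; each subject's beta adds Gaussian jitter and the
    signal is the sum of subject betas times the convolved feature
    regressors plus white scanner noise.  By default the noise and
    jitter scales are calibrated so the group-level effect size at tuned
    voxels is ``effect_size_d`` with a ``jitter_frac`` share of the
    between-subject sd coming from genuine subject variability;
    pass explicit ``noise_sd`` / ``jitter_sd`` to override.

    ``feature_values`` is an item x feature DataFrame (index item_id)
    covering every scheduled clip.

    Returns ``(bold_per_subject, BoldGroundTruth, regressors)`` where
    ``bold_per_subject`` is a list of voxel x time arrays and
    ``regressors`` the feature x time design used.
    """
    if n_subjects < 1 or n_voxels < 1:
        raise ValueError("n_subjects and n_voxels must be >= 1")
    features = list(feature_values.columns)
    regs = np.stack([
        build_feature_regressor(schedule, feature_values[f].to_dict(), f).values
        for f in features
    ])
    rng = np.random.default_rng(seed)
    n_feat = len(features)

    tuned = rng.random((n_voxels, n_feat)) < tuned_fraction
    true_beta = np.where(tuned, beta, 0.0)

    if jitter_sd is None:
        jitter_sd = jitter_frac * beta / effect_size_d
    if noise_sd is None:
        noise_sd = bold_noise_sd_for_effect_size(
            effect_size_d, beta, jitter_sd, regs)

    truth = BoldGroundTruth(true_beta=true_beta, tuned_mask=true_beta > 0,
                            noise_sd=float(noise_sd),
                            subject_beta_jitter_sd=float(jitter_sd))
    n_t = schedule.n_volumes
    bold = []
    for _ in range(n_subjects):
        subj_beta = true_beta + rng.standard_normal((n_voxels, n_feat)) * jitter_sd
        signal = subj_beta @ regs
        signal += rng.standard_normal((n_voxels, n_t)) * noise_sd
        bold.append(signal)
    return bold, truth, regs


def write_bold_nifti(bold_per_subject, out_dir, truth: BoldGroundTruth = None,
                     prefix: str = "sub"):
    """Write each subject's voxel x time array as a 4-D NIfTI-1 file.

    Voxels are laid out along the first axis (V x 1 x 1 x T); a JSON
    ground-truth sidecar records the planted betas when given.
    """
    import os

    import nibabel as nib

    os.makedirs(out_dir, exist_ok=True)
    paths = []
    for i, arr in enumerate(bold_per_subject):
        v, t = arr.shape
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32).reshape(v, 1, 1, t),
                              affine=np.eye(4))
        path = os.path.join(out_dir, f"{prefix}-{i + 1:02d}_bold.nii")
        nib.save(img, path)
        paths.append(path)
    if truth is not None:
        side = {
            "true_beta": truth.true_beta.tolist(),
            "noise_sd": truth.noise_sd,
            "subject_beta_jitter_sd": truth.subject_beta_jitter_sd,
        }
        with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
            json.dump(side, fh)
    return paths
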