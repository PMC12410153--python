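"""Multi-rater annotation data model and I/O.

Ratings of perceptual features (e.g. social features of naturalistic
images or video clips) are collected from a pool of human raters, or
from a machine annotator queried over repeated collection rounds.  This
module holds the shared containers — an item x feature x rater panel, an
item x feature x round machine set, and their missing-aware means — plus
the scaling, averaging and feature-exclusion rules every downstream
stage relies on.

Missing ratings are represented as NaN throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "RatingPanel",
    "MachineRatingSet",
    "MeanRatingMatrix",
    "SchemaError",
    "IntegrityError",
    "load_rating_table",
    "write_rating_table",
    "scale_ratings",
    "mean_over_raters",
    "mean_over_rounds",
    "exclude_unperceived_features",
]

#: Minimum pairwise-complete observations for any correlation downstream.
MIN_COMPLETE_PAIRS = 3


class SchemaError(ValueError):
    """A rating table lacks a mandatory column or has an unusable layout."""


class IntegrityError(ValueError):
    """Duplicate cells or values violating the declared bounds."""


def _check_unique(labels, axis_name):
    labels = list(labels)
    if len(set(labels)) != len(labels):
        raise IntegrityError(f"duplicate {axis_name} identifiers")
    return labels


@dataclass
class RatingPanel:
    """Item x feature x rater array of bounded ratings with missingness.

    Parameters
    ----------
    items, features, raters
        Ordered, unique identifiers along each axis.
    ratings
        Array of shape ``(n_items, n_features, n_raters)``; NaN marks a
        missing rating, every finite value must lie in ``scale``.
    scale
        Inclusive rating bounds ``(lo, hi)``.
    modality
        Free label such as ``"image"`` or ``"video"``.
    """

    items: list
    features: list
    raters: list
    ratings: np.ndarray
    scale: tuple = (0.0, 10.0)
    modality: str = "other"

    def __post_init__(self):
        self.items = _check_unique(self.items, "item")
        self.features = _check_unique(self.features, "feature")
        self.raters = _check_unique(self.raters, "rater")
        self.ratings = np.asarray(self.ratings, dtype=float)
        expected = (len(self.items), len(self.features), len(self.raters))
        if self.ratings.shape != expected:
            raise ValueError(
                f"ratings shape {self.ratings.shape} != {expected}"
            )
        lo, hi = self.scale
        if hi <= lo:
            raise ValueError("degenerate scale")
        finite = self.ratings[np.isfinite(self.ratings)]
        if finite.size and (finite.min() < lo - 1e-9 or finite.max() > hi + 1e-9):
            raise IntegrityError("rating outside declared scale")

    @property
    def shape(self):
        return self.ratings.shape

    def raters_with_data(self, feature_index: int) -> int:
        """Number of raters contributing at least one rating to a feature."""
        return int(
            np.isfinite(self.ratings[:, feature_index, :]).any(axis=0).sum()
        )


@dataclass
class MachineRatingSet:
    """Item x feature x round machine ratings; refusals appear as NaN.

    An item missing in *every* round is "failed" and excluded from
    downstream pairing with the human data.
    """

    items: list
    features: list
    rounds: list
    ratings: np.ndarray
    scale: tuple = (0.0, 10.0)
    modality: str = "other"

    def __post_init__(self):
        self.items = _check_unique(self.items, "item")
        self.features = _check_unique(self.features, "feature")
        self.rounds = _check_unique(self.rounds, "round")
        self.ratings = np.asarray(self.ratings, dtype=float)
        expected = (len(self.items), len(self.features), len(self.rounds))
        if self.ratings.shape != expected:
            raise ValueError(
                f"ratings shape {self.ratings.shape} != {expected}"
            )
        lo, hi = self.scale
        if hi <= lo:
            raise ValueError("degenerate scale")
        finite = self.ratings[np.isfinite(self.ratings)]
        if finite.size and (finite.min() < lo - 1e-9 or finite.max() > hi + 1e-9):
            raise IntegrityError("rating outside declared scale")

    @property
    def failed_items(self) -> list:
        """Items with no rating in any round (annotator refused them)."""
        all_missing = ~np.isfinite(self.ratings).any(axis=(1, 2))
        return [it for it, bad in zip(self.items, all_missing) if bad]


@dataclass
class MeanRatingMatrix:
    """Item x feature means over raters or rounds, missing-aware.

    ``n_contributing`` counts the raters/rounds behind each cell; a cell
    is NaN iff nothing contributed.
    """

    items: list
    features: list
    values: np.ndarray
    n_contributing: np.ndarray
    scale: tuple = (0.0, 10.0)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.n_contributing = np.asarray(self.n_contributing, dtype=int)
        if self.values.shape != (len(self.items), len(self.features)):
            raise ValueError("values shape mismatch")
        if self.n_contributing.shape != self.values.shape:
            raise ValueError("n_contributing shape mismatch")
        bad = np.isfinite(self.values) & (self.n_contributing < 1)
        if bad.any():
            raise IntegrityError("non-missing mean with zero contributors")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.items, columns=self.features)

    def restrict_items(self, items) -> "MeanRatingMatrix":
        """Subset (and reorder) the item axis."""
        idx = [self.items.index(it) for it in items]
        return MeanRatingMatrix(
            items=list(items),
            features=list(self.features),
            values=self.values[idx],
            n_contributing=self.n_contributing[idx],
            scale=self.scale,
        )


# ---------------------------------------------------------------------------
# I/O: long CSV is the canonical interchange format
# ---------------------------------------------------------------------------

DEFAULT_SCHEMA = {
    "item": "item_id",
    "feature": "feature",
    "rater": "rater_id",
    "rating": "rating",
}


def load_rating_table(path, schema=None, scale=(0.0, 10.0), kind="human",
                      modality="other"):
    """Read a long-format rating CSV into a panel.

    Parameters
    ----------
    path : str or file-like
        CSV with one row per (item, feature, rater-or-round, rating).
    schema : dict, optional
        Maps the logical names ``item``, ``feature``, ``rater`` (or
        ``round`` for machine tables) and ``rating`` to column names.
    scale : tuple
        Declared rating bounds.
    kind : {"human", "machine"}
        ``"human"`` returns a :class:`RatingPanel` (third axis = raters),
        ``"machine"`` a :class:`MachineRatingSet` (third axis = rounds).

    Returns
    -------
    (panel, n_dropped)
        The panel and the count of rows dropped for unparseable ratings.
    """
    eff = dict(DEFAULT_SCHEMA)
    if kind == "machine":
        eff["rater"] = "round"
    if schema:
        eff.update(schema)

    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in (eff["item"], eff["feature"], eff["rater"], eff["rating"])
               if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {missing}")

    ratings = pd.to_numeric(df[eff["rating"]], errors="coerce")
    explicit_na = df[eff["rating"]].isna()
    unparseable = ratings.isna() & ~explicit_na
    n_dropped = int(unparseable.sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} row(s) with unparseable ratings")
    df = df.loc[~unparseable].copy()
    df["_rating"] = ratings.loc[~unparseable]

    key_cols = [eff["item"], eff["feature"], eff["rater"]]
    if df.duplicated(subset=key_cols).any():
        dup = df.loc[df.duplicated(subset=key_cols), key_cols].iloc[0].tolist()
        raise IntegrityError(f"duplicate rating cell for {tuple(dup)}")

    items = list(pd.unique(df[eff["item"]]))
    features = list(pd.unique(df[eff["feature"]]))
    thirds = list(pd.unique(df[eff["rater"]]))

    cube = np.full((len(items), len(features), len(thirds)), np.nan)
    ii = pd.Categorical(df[eff["item"]], categories=items).codes
    ff = pd.Categorical(df[eff["feature"]], categories=features).codes
    rr = pd.Categorical(df[eff["rater"]], categories=thirds).codes
    cube[ii, ff, rr] = df["_rating"].to_numpy()

    if kind == "machine":
        panel = MachineRatingSet(items, features, thirds, cube, scale, modality)
    else:
        panel = RatingPanel(items, features, thirds, cube, scale, modality)
    return panel, n_dropped


def write_rating_table(panel, path):
    """Write a panel back to the long CSV schema ``load_rating_table`` reads."""
    is_machine = isinstance(panel, MachineRatingSet)
    third_name = "round" if is_machine else "rater_id"
    thirds = panel.rounds if is_machine else panel.raters
    idx = np.argwhere(np.isfinite(panel.ratings))
    rows = {
        "item_id": [panel.items[i] for i, _, _ in idx],
        "feature": [panel.features[f] for _, f, _ in idx],
        third_name: [thirds[r] for _, _, r in idx],
        "rating": panel.ratings[idx[:, 0], idx[:, 1], idx[:, 2]],
        "modality": panel.modality,
    }
    # 17 significant digits: round-trips float64 exactly
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Scaling and averaging
# ---------------------------------------------------------------------------

def scale_ratings(panel, target_scale):
    """Affinely map all ratings onto ``target_scale``.

    The human reference data are collected on a 0-100 slider and scaled
    to the 0-10 analysis scale; this is that map.  Missing values are
    preserved and the operation is the identity when scales coincide.
    """
    lo, hi = panel.scale
    tlo, thi = target_scale
    if hi <= lo:
        raise ValueError("degenerate source scale")
    if thi <= tlo:
        raise ValueError("degenerate target scale")
    new = (panel.ratings - lo) * ((thi - tlo) / (hi - lo)) + tlo
    return replace(panel, ratings=new, scale=(float(tlo), float(thi)))


def _mean_over_last_axis(items, features, cube, scale):
    n = np.isfinite(cube).sum(axis=2)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN cells
        vals = np.nanmean(cube, axis=2)
    vals[n == 0] = np.nan
    return MeanRatingMatrix(list(items), list(features), vals, n, scale)


def mean_over_raters(panel: RatingPanel) -> MeanRatingMatrix:
    """Per-(item, feature) mean over the raters that responded.

    This is the population-average ("human average") reference used as
    the target of the machine-agreement index.
    """
    return _mean_over_last_axis(panel.items, panel.features, panel.ratings,
                                panel.scale)


def mean_over_rounds(machine: MachineRatingSet) -> MeanRatingMatrix:
    """Mean over collection rounds, dropping items failed in all rounds.

    Averaging repeated machine annotation rounds plays the same
    stabilising role as averaging human raters; items the annotator
    refused in every round are excluded entirely.
    """
    keep = [it for it in machine.items if it not in set(machine.failed_items)]
    kidx = [machine.items.index(it) for it in keep]
    return _mean_over_last_axis(keep, machine.features,
                                machine.ratings[kidx], machine.scale)


def exclude_unperceived_features(human: RatingPanel):
    """Drop features nobody perceived or with zero across-item variance.

    A feature whose human mean sits at the scale minimum for every item
    was not present in the stimulus at all; a feature whose mean is
    constant across items has no variance and every correlation with it
    is undefined.  Both are removed before any correlation stage.

    Returns
    -------
    (reduced_panel, dropped)
        The panel restricted to retained features and the list of
        dropped feature names.
    """
    mean = mean_over_raters(human)
    lo = human.scale[0]
    dropped = []
    for j, feat in enumerate(human.features):
        col = mean.values[:, j]
        obs = col[np.isfinite(col)]
        if obs.size == 0:
            dropped.append(feat)
        elif np.all(np.abs(obs - lo) < 1e-12):
            dropped.append(feat)
        elif np.ptp(obs) < 1e-12:
            dropped.append(feat)
    keep_idx = [j for j, f in enumerate(human.features) if f not in dropped]
    reduced = RatingPanel(
        items=human.items,
        features=[human.features[j] for j in keep_idx],
        raters=human.raters,
        ratings=human.ratings[:, keep_idx, :],
        scale=human.scale,
        modality=human.modality,
    )
    return reduced, dropped
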