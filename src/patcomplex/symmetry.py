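"""Weighted four-axis mirror-symmetry measure for binary raster images.

A pattern's symmetry about a predefined axis is quantified by comparing
pixels on opposite sides of the axis of reflection.  Matching reflected
pairs are counted with weights that grow linearly from 1 at the image
border to 2 next to the axis, so that pixels close to the axis have more
influence.  For the vertical axis of an ``m x w`` image with ``n = w/2``
pair columns (``(w-1)/2`` when ``w`` is odd; the centre column is ignored)
the per-axis score is

    s = 2/(3*m*n) * sum_i sum_j X_ij * (1 + (j-1)/(n-1)),

where ``X_ij`` is 1 iff the two pixels of reflected pair ``j`` in row ``i``
are equal, and ``j`` runs from the border (weight 1) toward the axis
(weight 2).  The normaliser equals the total weight, so a perfectly
mirror-symmetric image scores exactly 1.  The horizontal axis applies the
same rule to rows.  For the two diagonal axes of a square image, reflected
pairs are ``(i, j) <-> (j, i)`` (main diagonal) and
``(i, j) <-> (w-1-j, w-1-i)`` (secondary diagonal), indexed by their
distance class ``d = 1 .. w-1`` from the axis with the same border-to-axis
weighting and normalised by the total weight.

The aggregate mirror symmetry is ``MS = 100*(s_h + s_v + s_d1 + s_d2)/4``
on a 0-100 scale.  Per-axis scores can further be sharpened by non-linear
transforms (power, exponential, threshold-stretch) that give small
deviations from perfect symmetry more influence, e.g.
``MSA20 = 100*mean(s_axis**20)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

AXES = ("horizontal", "vertical", "main-diagonal", "secondary-diagonal")

#: Column names used for the four per-axis scores in predictor tables,
#: in the fixed order horizontal, vertical, main diagonal, secondary diagonal.
AXIS_COLUMNS = ("MSA", "MSB", "MSC", "MSD")

TRANSFORM_FAMILIES = ("power", "exponential", "threshold-stretch")


class SymmetryError(ValueError):
    """Invalid input for the symmetry measure."""


@dataclass(frozen=True)
class SymmetryProfile:
    """Per-axis mirror-symmetry scores of one image.

    Attributes
    ----------
    s_h, s_v, s_d1, s_d2 : float
        Unit-interval scores for the horizontal, vertical, main-diagonal
        and secondary-diagonal axes.
    image_shape : tuple of int
        ``(rows, cols)`` of the scored image.
    """

    s_h: float
    s_v: float
    s_d1: float
    s_d2: float
    image_shape: tuple[int, int]

    @property
    def axis_scores(self) -> np.ndarray:
        return np.array([self.s_h, self.s_v, self.s_d1, self.s_d2])

    @property
    def ms(self) -> float:
        """Aggregate mirror symmetry on the 0-100 scale."""
        return 100.0 * float(self.axis_scores.sum()) / 4.0


@dataclass(frozen=True)
class TransformSpec:
    """Non-linear per-axis transform of the symmetry scores.

    ``family`` is one of ``power`` (s**a), ``exponential``
    (normalised ``exp(-a*(1-s))``), or ``threshold-stretch``
    (``max(0, (s-t)/(1-t))``).  ``parameter`` is the exponent ``a >= 1``
    for the first two families and the threshold ``t in [0, 1)`` for the
    stretch.
    """

    family: str = "power"
    parameter: float = 1.0

    def __post_init__(self) -> None:
        if self.family not in TRANSFORM_FAMILIES:
            raise SymmetryError(
                f"unknown transform family {self.family!r}; "
                f"expected one of {TRANSFORM_FAMILIES}"
            )
        if self.family in ("power", "exponential") and self.parameter < 1:
            raise SymmetryError("exponent must be >= 1")
        if self.family == "threshold-stretch" and not 0 <= self.parameter < 1:
            raise SymmetryError("threshold must lie in [0, 1)")

    @property
    def name(self) -> str:
        if self.family == "power":
            return f"MSA{self.parameter:g}"
        if self.family == "exponential":
            return f"MSE{self.parameter:g}"
        return f"MST{self.parameter:g}"


def _as_binary(img: np.ndarray) -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise SymmetryError(f"expected a 2-D image, got shape {arr.shape}")
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise SymmetryError("image must be binary with values in {0, 1}")
    return arr

def _pair_weights(n: int) -> np.ndarray:
    # weight 1 at the border (j=1) rising linearly to 2 next to the axis (j=n)
    if n < 1:
        raise SymmetryError("image too small: no reflected pairs")
    if n == 1:
        return np.ones(1)
    j = np.arange(1, n + 1, dtype=float)
    return 1.0 + (j - 1.0) / (n - 1.0)

def _vertical(img: np.ndarray) -> float:
    m, w = img.shape
    n = w // 2
    weights = _pair_weights(n)
    # pair j (from the border) compares column j-1 with column w-j
    match = img[:, :n] == img[:, ::-1][:, :n]
    return float((match * weights).sum() / (m * weights.sum()))

def _diagonal(img: np.ndarray, secondary: bool) -> float:
    w = img.shape[0]
    if img.shape[0] != img.shape[1]:
        raise SymmetryError("diagonal axes require a square image")
    reflected = img[::-1, ::-1].T if secondary else img.T
    i, j = np.indices(img.shape)
    d = np.abs((i + j) - (w - 1)) if secondary else np.abs(i - j)
    upper = ((i + j) < (w - 1)) if secondary else (j > i)  # one pixel per pair
    n = w - 1  # distance classes, d = 1 (at axis) .. w-1 (corner)
    if n < 1:
        raise SymmetryError("image too small: no reflected pairs")
    if n == 1:
        weight_of_d = np.array([np.nan, 1.0])
    else:
        dd = np.arange(1, n + 1, dtype=float)
        # index from the border: d = n -> weight 1, d = 1 -> weight 2
        weight_of_d = np.concatenate(([np.nan], 1.0 + (n - dd) / (n - 1.0)))
    wmap = weight_of_d[d[upper]]
    match = (img == reflected)[upper]
    return float((match * wmap).sum() / wmap.sum())


def axis_symmetry(img: np.ndarray, axis: str) -> float:
    """Mirror-symmetry score of a binary image about one predefined axis.

    Parameters
    ----------
    img : ndarray
        2-D binary image (values 0/1).  Must be square for the diagonal
        axes.
    axis : str
        One of ``horizontal``, ``vertical``, ``main-diagonal``,
        ``secondary-diagonal``.

    Returns
    -------
    float
        Score in ``[0, 1]``; exactly 1 iff the image is mirror-symmetric
        about the axis.
    """
    arr = _as_binary(img)
    if axis == "vertical":
        return _vertical(arr)
    if axis == "horizontal":
        return _vertical(arr.T)
    if axis == "main-diagonal":
        return _diagonal(arr, secondary=False)
    if axis == "secondary-diagonal":
        return _diagonal(arr, secondary=True)
    raise SymmetryError(f"unknown axis {axis!r}; expected one of {AXES}")


def mirror_symmetry(img: np.ndarray) -> SymmetryProfile:
    """Score a square binary image on all four axes.

    Returns a :class:`SymmetryProfile`; its ``ms`` property is the 0-100
    aggregate ``100*(s_h + s_v + s_d1 + s_d2)/4``.
    """
    arr = _as_binary(img)
    if arr.shape[0] != arr.shape[1]:
        raise SymmetryError("mirror_symmetry requires a square image")
    return SymmetryProfile(
        s_h=axis_symmetry(arr, "horizontal"),
        s_v=axis_symmetry(arr, "vertical"),
        s_d1=axis_symmetry(arr, "main-diagonal"),
        s_d2=axis_symmetry(arr, "secondary-diagonal"),
        image_shape=tuple(arr.shape),
    )


def transform_scores(scores: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Apply the non-linear transform to unit-interval per-axis scores."""
    s = np.asarray(scores, dtype=float)
    if spec.family == "power":
        return s ** spec.parameter
    if spec.family == "exponential":
        a = spec.parameter
        return (np.exp(-a * (1.0 - s)) - np.exp(-a)) / (1.0 - np.exp(-a))
    t = spec.parameter
    return np.clip((s - t) / (1.0 - t), 0.0, None)


def transform_profile(profile: SymmetryProfile, spec: TransformSpec) -> float:
    """Transformed aggregate symmetry, ``100*mean(f(s_axis))``.

    At ``power`` exponent 1 this is exactly ``profile.ms``; it is
    non-increasing in the exponent and emphasises small deviations from
    perfect symmetry for large exponents (e.g. MSA20).
    """
    return 100.0 * float(np.mean(transform_scores(profile.axis_scores, spec)))


@dataclass(frozen=True)
class TransformSearchResult:
    spec: TransformSpec
    r_squared: float
    column_name: str


def transform_search(
    table: pd.DataFrame,
    ratings: pd.Series,
    companion_predictor: str,
    grid: Sequence[TransformSpec],
) -> list[TransformSearchResult]:
    """Rank candidate symmetry transforms by two-predictor model fit.

    For each candidate the four per-axis columns (``MSA`` .. ``MSD``) are
    transformed and aggregated to a 0-100 predictor, z-standardised
    together with the companion predictor, and an OLS model of the mean
    ratings on the pair is fitted.  Results are sorted by R² descending
    (stable for ties).
    """
    from . import modeling

    if len(grid) == 0:
        raise SymmetryError("transform grid must not be empty")
    missing = [c for c in (*AXIS_COLUMNS, companion_predictor) if c not in table]
    if missing:
        raise SymmetryError(f"table lacks required columns: {missing}")
    common = table.index.intersection(ratings.index)
    if len(common) == 0:
        raise SymmetryError("table and ratings share no stimulus ids")
    axes = table.loc[common, list(AXIS_COLUMNS)].to_numpy(dtype=float)
    companion = table.loc[common, companion_predictor]
    y = ratings.loc[common]
    results = []
    for spec in grid:
        transformed = 100.0 * transform_scores(axes, spec).mean(axis=1)
        X = pd.DataFrame(
            {spec.name: transformed, companion_predictor: companion}, index=common
        )
        Xz, _ = modeling.zstandardize(X)
        fit = modeling.fit_ols(Xz, y)
        results.append(TransformSearchResult(spec, fit.r_squared, spec.name))
    return sorted(results, key=lambda r: -r.r_squared)
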