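"""Sequence-to-image (S2I) transforms for unequal-length 1-D signals.

A raw current trace of arbitrary length ``n`` becomes a fixed ``l x l`` image
in four steps:

1. **PAA** — piecewise aggregate approximation reduces (or stretches) the
   series to length ``l`` by averaging over ``l`` equal-width windows, with
   fractional-overlap weighting when ``n`` is not a multiple of ``l``.
2. **Min–max scaling** to ``[0, 1]`` (default) or ``[-1, 1]``.
3. **Polar encoding** — angle ``phi_i = arccos(x_i)``, radius ``(i+1)/l``.
   The radii carry the time axis for visualization; the Gramian matrices
   depend on the angles alone.
4. **Gramian angular field** — GASF ``cos(phi_i + phi_j)`` or GADF
   ``sin(phi_i - phi_j)``.

Markov transition fields (quantile-bin transition probabilities) and
recurrence plots (thresholded pairwise distance) are provided as alternative
strategies operating on the scaled series.

The GASF diagonal is ``2 x_i^2 - 1``, so with unit scaling the scaled series
is recoverable as ``sqrt((diag + 1) / 2)``; with symmetric scaling the sign
of ``x_i`` is lost and inversion is refused.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signal_io import ImageDataset, RawRecord, SignalDataset

__all__ = [
    "NormalizedSeries",
    "PolarSeries",
    "GAFImage",
    "paa_reduce",
    "minmax_normalize",
    "to_polar",
    "gasf",
    "gadf",
    "invert_gasf_diagonal",
    "mtf",
    "recurrence_plot",
    "transform_record",
    "transform_dataset",
    "DEFAULT_IMAGE_SIZE",
]

DEFAULT_IMAGE_SIZE = 64
_CLIP_TOL = 1e-12  # arccos endpoint guard against float drift

_RANGES = {"unit": (0.0, 1.0), "sym": (-1.0, 1.0)}


@dataclass(frozen=True)
class NormalizedSeries:
    """Min–max scaled series tagged with its target range (``unit`` or ``sym``)."""

    values: np.ndarray
    range: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if self.range not in _RANGES:
            raise ValueError(f"range must be 'unit' or 'sym', got {self.range!r}")
        if v.size < 2:
            raise ValueError("normalized series must have length >= 2")
        lo, hi = _RANGES[self.range]
        if v.min() < lo - _CLIP_TOL or v.max() > hi + _CLIP_TOL:
            raise ValueError(f"values outside declared range [{lo}, {hi}]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class PolarSeries:
    """Polar encoding: angles in [0, pi] radians, radii (i+1)/l on (0, 1]."""

    angles: np.ndarray
    radii: np.ndarray


@dataclass(frozen=True)
class GAFImage:
    """An ``l x l`` image produced by one strategy (GASF/GADF/MTF/RP)."""

    matrix: np.ndarray
    strategy: str

    @property
    def size(self) -> int:
        return self.matrix.shape[0]


def paa_reduce(signal: np.ndarray, l: int) -> np.ndarray:
    """Piecewise aggregate approximation of ``signal`` to length ``l``.

    Treats the series as a step function on [0, n) and returns the mean over
    each window ``[k*n/l, (k+1)*n/l)``; fractional sample overlap is weighted
    exactly, so non-divisible lengths and l > n (sample repetition) are
    handled uniformly. ``l == n`` returns the input unchanged.
    """
    sig = np.asarray(signal, dtype=float)
    if sig.ndim != 1 or sig.size < 1:
        raise ValueError("signal must be a nonempty 1-D array")
    if l < 1:
        raise ValueError(f"target length must be >= 1, got {l}")
    n = sig.size
    if l == n:
        return sig.copy()
    # prefix integral of the step function: F[i] = integral of sig over [0, i)
    prefix = np.concatenate(([0.0], np.cumsum(sig)))

    def integral(t: float) -> float:
        i = int(np.floor(t))
        if i >= n:
            return prefix[n]
        return prefix[i] + sig[i] * (t - i)

    edges = np.arange(l + 1) * (n / l)
    out = np.empty(l)
    w = n / l
    for k in range(l):
        out[k] = (integral(edges[k + 1]) - integral(edges[k])) / w
    return out


def minmax_normalize(signal: np.ndarray, range: str = "unit") -> NormalizedSeries:
    """Min–max scale to [0,1] (``unit``) or [-1,1] (``sym``).

    Raises on a constant signal: with ``max == min`` the scale factor is
    undefined (degenerate signal).
    """
    sig = np.asarray(signal, dtype=float)
    lo, hi = sig.min(), sig.max()
    if hi == lo:
        raise ValueError("degenerate signal: max == min, cannot min-max scale")
    if range == "unit":
        vals = (sig - lo) / (hi - lo)
    elif range == "sym":
        vals = (2.0 * sig - hi - lo) / (hi - lo)
    else:
        raise ValueError(f"range must be 'unit' or 'sym', got {range!r}")
    return NormalizedSeries(vals, range)


def to_polar(ns: NormalizedSeries) -> PolarSeries:
    """Encode a scaled series in polar coordinates.

    ``arccos`` is applied to the scaled values directly (unit scaling yields
    angles in [0, pi/2], symmetric scaling the full [0, pi]); the time index
    becomes the radius ``(i+1)/l``. Values beyond [-1, 1] by more than 1e-12
    raise; drift within tolerance is clipped.
    """
    v = np.asarray(ns.values, dtype=float)
    if v.min() < -1.0 - _CLIP_TOL or v.max() > 1.0 + _CLIP_TOL:
        raise ValueError("values outside [-1, 1] beyond tolerance; cannot take arccos")
    angles = np.arccos(np.clip(v, -1.0, 1.0))
    l = v.size
    radii = (np.arange(l) + 1.0) / l
    return PolarSeries(angles, radii)


def gasf(ps: PolarSeries) -> GAFImage:
    """Gramian angular summation field: ``M[i, j] = cos(phi_i + phi_j)``.

    Equivalent to the vectorized form ``x x^T - sqrt(1-x^2) sqrt(1-x^2)^T``
    with elementwise squares; symmetric with entries in [-1, 1].
    """
    phi = np.asarray(ps.angles, dtype=float)
    return GAFImage(np.cos(phi[:, None] + phi[None, :]), "GASF")


def gadf(ps: PolarSeries) -> GAFImage:
    """Gramian angular difference field: ``M[i, j] = sin(phi_i - phi_j)``.

    Antisymmetric with zero diagonal and entries in [-1, 1].
    """
    phi = np.asarray(ps.angles, dtype=float)
    return GAFImage(np.sin(phi[:, None] - phi[None, :]), "GADF")


def invert_gasf_diagonal(img: GAFImage, range: str = "unit") -> np.ndarray:
    """Recover the unit-scaled series from a GASF diagonal.

    The diagonal is ``2 x_i^2 - 1``; ``sqrt((diag + 1) / 2)`` returns ``|x_i|``,
    which equals ``x_i`` only when the series was scaled to [0, 1] — symmetric
    scaling is refused as sign-ambiguous.
    """
    if img.strategy != "GASF":
        raise ValueError(f"diagonal inversion requires a GASF image, got {img.strategy}")
    if range != "unit":
        raise ValueError("sign-ambiguous inversion: only unit-range GASF is invertible")
    diag = np.diagonal(img.matrix).astype(float)
    if diag.min() < -1.0 - _CLIP_TOL:
        raise ValueError("GASF diagonal entry below -1 beyond tolerance")
    return np.sqrt(np.clip((diag + 1.0) / 2.0, 0.0, None))


def mtf(signal: np.ndarray, n_bins: int = 8) -> GAFImage:
    """Markov transition field from first-order quantile-bin dynamics.

    Samples are ranked into ``n_bins`` equal-count quantile bins (ties broken
    by sample order via a stable sort); ``W[a, b]`` is the empirical
    probability of a one-step transition from bin ``a`` to bin ``b`` (rows
    with no outflow stay all-zero), and the image is
    ``M[i, j] = W[bin(i), bin(j)]``.
    """
    sig = np.asarray(signal, dtype=float)
    l = sig.size
    if l < 2:
        raise ValueError("MTF requires length >= 2")
    if not 2 <= n_bins <= l:
        raise ValueError(f"n_bins must be in [2, {l}], got {n_bins}")
    if sig.max() == sig.min():
        raise ValueError("degenerate signal: constant series has no quantile bins")
    ranks = np.empty(l, dtype=int)
    ranks[np.argsort(sig, kind="stable")] = np.arange(l)
    bins = (ranks * n_bins) // l
    counts = np.zeros((n_bins, n_bins))
    np.add.at(counts, (bins[:-1], bins[1:]), 1.0)
    outflow = counts.sum(axis=1, keepdims=True)
    W = np.divide(counts, outflow, out=np.zeros_like(counts), where=outflow > 0)
    return GAFImage(W[np.ix_(bins, bins)], "MTF")


def recurrence_plot(signal: np.ndarray, epsilon: float = 0.1) -> GAFImage:
    """Binary recurrence plot: 1 where ``|s_i - s_j| <= epsilon``.

    Scalar absolute-difference recurrence without time-delay embedding;
    symmetric with unit diagonal.
    """
    sig = np.asarray(signal, dtype=float)
    if sig.size < 2:
        raise ValueError("recurrence plot requires length >= 2")
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    dist = np.abs(sig[:, None] - sig[None, :])
    return GAFImage((dist <= epsilon).astype(float), "RP")


def transform_record(
    rec: RawRecord,
    strategy: str = "GADF",
    l: int = DEFAULT_IMAGE_SIZE,
    range: str = "unit",
    *,
    mtf_bins: int = 8,
    rp_epsilon: float = 0.1,
) -> GAFImage:
    """Full S2I chain for one record: PAA to length ``l``, min–max scale,
    then the chosen strategy (polar + Gramian for GASF/GADF; MTF/RP act on
    the scaled series directly)."""
    strategy = strategy.upper()
    reduced = paa_reduce(rec.signal, l)
    ns = minmax_normalize(reduced, range)
    if strategy == "GASF":
        return gasf(to_polar(ns))
    if strategy == "GADF":
        return gadf(to_polar(ns))
    if strategy == "MTF":
        return mtf(ns.values, n_bins=min(mtf_bins, l))
    if strategy == "RP":
        return recurrence_plot(ns.values, epsilon=rp_epsilon)
    raise ValueError(f"unknown strategy {strategy!r}")


def transform_dataset(
    ds: SignalDataset,
    strategy: str = "GADF",
    l: int = DEFAULT_IMAGE_SIZE,
    range: str = "unit",
    **params,
) -> ImageDataset:
    """Transform every record of a dataset into an :class:`ImageDataset`."""
    images = np.empty((len(ds), l, l))
    for i, rec in enumerate(ds):
        images[i] = transform_record(rec, strategy, l, range, **params).matrix
    return ImageDataset(
        images=images,
        labels=ds.label_indices(),
        strategy=strategy.upper(),
        image_size=l,
        class_names=list(ds.classes),
    )
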