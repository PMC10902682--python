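"""Synthetic nanopore-like signal generators.

Two study conditions are emulated so the whole transform-and-classify chain
can be exercised without instrument data:

* **analyte** — classes that mimic distinct molecules translocating a pore:
  each class has a baseline blockade level and a square-pulse dwell of
  class-specific depth and duration, with widely varying record lengths.
* **barcode** — peak-train molecular labels: a start peak, three identity
  bit slots (peak present iff the bit is 1), and an end peak on a flat
  baseline, giving the eight codes "000".."111". Short records can be
  right-padded with Gaussian noise (mean 0, sigma 0.072 by default) to a
  fixed vector length such as 700.

Peaks are raised half-cosines — smooth and bandwidth-limited like real
blockade events. Everything is deterministic given the spec's seed.

The stylized analyte templates are synthetic stand-ins: real analyte traces
differ in kinetics and noise spectrum, and no template here is fit to data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .signal_io import RawRecord, SignalDataset

__all__ = [
    "SyntheticSpec",
    "gen_analyte",
    "gen_barcode",
    "gen_worked_example",
    "classify_barcode_peaks",
    "BARCODE_CODES",
    "PAD_SIGMA",
]

PAD_SIGMA = 0.072  # average noise level used for right-padding
BARCODE_CODES = tuple(format(k, "03b") for k in range(8))

# relative positions of start / bit1 / bit2 / bit3 / end peak centers
_SLOT_FRACS = (0.08, 0.26, 0.44, 0.62, 0.80)
_PEAK_HALFWIDTH_FRAC = 0.035  # half-width of the raised half-cosine peak
_MAX_ANALYTE_CLASSES = 16


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic generation run.

    ``length_range`` bounds the raw (pre-padding) record length; ``pad_to``
    right-pads barcode records with N(0, 0.072) noise to a fixed length.
    """

    task: str  # "analyte" | "barcode"
    n_classes: int = 8
    per_class: int = 100
    length_range: tuple[int, int] = (200, 2000)
    noise_sigma: float = 0.05
    pad_to: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.task not in ("analyte", "barcode"):
            raise ValueError(f"task must be 'analyte' or 'barcode', got {self.task!r}")
        lo, hi = self.length_range
        if lo < 16 or hi < lo:
            raise ValueError(f"length_range must satisfy 16 <= min <= max, got {self.length_range}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.task == "barcode" and self.n_classes != 8:
            raise ValueError('barcode task has exactly 8 classes ("000".."111")')
        if self.per_class < 1:
            raise ValueError("per_class must be >= 1")


def _half_cosine_peak(n: int, center: float, halfwidth: float, depth: float) -> np.ndarray:
    """Raised half-cosine bump of given depth centered at ``center`` samples."""
    t = np.arange(n)
    u = (t - center) / halfwidth
    bump = np.where(np.abs(u) <= 1.0, 0.5 * depth * (1.0 + np.cos(np.pi * u)), 0.0)
    return bump


def gen_analyte(spec: SyntheticSpec) -> SignalDataset:
    """Generate amplitude/morphology-distinct analyte classes.

    Class ``k`` (0-based) sits at baseline ``b_k = 0.15 + 0.7 k/(K-1)`` with a
    square-pulse dwell of relative depth ``d_k = 0.25 + 0.5 k/(K-1)`` times
    the baseline over a class-specific fraction of the record; dwell position
    is jittered per record. Baselines are strictly increasing in ``k`` and
    spaced so classes are essentially separable at noise sigma <= 0.05.
    """
    if spec.task != "analyte":
        raise ValueError("spec.task must be 'analyte'")
    K = spec.n_classes
    if K < 2:
        raise ValueError("analyte task needs n_classes >= 2")
    if K > _MAX_ANALYTE_CLASSES:
        raise ValueError(f"at most {_MAX_ANALYTE_CLASSES} analyte template slots, got {K}")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    records = []
    for k in range(K):
        frac = k / (K - 1)
        b_k = 0.15 + 0.7 * frac
        d_k = (0.25 + 0.5 * frac) * b_k
        dwell_frac = 0.2 + 0.4 * ((k % 4) / 4.0)  # morphology varies within amplitude ladder
        for r in range(spec.per_class):
            n = int(rng.integers(lo, hi + 1))
            start = 0.5 * (1 - dwell_frac) * n * (1 + 0.2 * rng.uniform(-1, 1))
            width = dwell_frac * n
            sig = np.full(n, b_k)
            a, b = int(round(start)), int(round(start + width))
            sig[max(a, 0) : min(b, n)] -= d_k
            sig += rng.normal(0.0, spec.noise_sigma, size=n)
            records.append(RawRecord(f"analyte{k}_{r}", sig, f"class{k}"))
    return SignalDataset(records)


def analyte_template(spec: SyntheticSpec, k: int, n: int) -> tuple[float, float]:
    """Noise-free (baseline, dwell depth) of analyte class ``k`` — the
    analytic means the generator realizes; used as an oracle in tests."""
    K = spec.n_classes
    frac = k / (K - 1)
    b_k = 0.15 + 0.7 * frac
    d_k = (0.25 + 0.5 * frac) * b_k
    return b_k, d_k


def gen_barcode(spec: SyntheticSpec) -> SignalDataset:
    """Generate 3-bit peak-train barcodes, 8 codes x ``per_class`` records.

    Peak layout per record of raw length n: start peak at 8% of n, bit slots
    at 26/44/62%, end peak at 80%, each center jittered by +-5% of n; peak
    amplitude 1 over baseline 0. If ``pad_to`` is set, records are
    right-padded to that length with N(0, 0.072) samples.
    """
    if spec.task != "barcode":
        raise ValueError("spec.task must be 'barcode'")
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.length_range
    if spec.pad_to is not None and spec.pad_to < hi:
        raise ValueError(f"pad_to={spec.pad_to} is less than max generated length {hi}")
    records = []
    for code in BARCODE_CODES:
        bits = [int(c) for c in code]
        present = [True, *(b == 1 for b in bits), True]  # start, b1..b3, end
        for r in range(spec.per_class):
            n = int(rng.integers(lo, hi + 1))
            sig = np.zeros(n)
            halfwidth = _PEAK_HALFWIDTH_FRAC * n
            for slot_frac, on in zip(_SLOT_FRACS, present):
                if not on:
                    continue
                center = (slot_frac + 0.05 * rng.uniform(-1, 1)) * n
                sig += _half_cosine_peak(n, center, halfwidth, depth=1.0)
            sig += rng.normal(0.0, spec.noise_sigma, size=n)
            if spec.pad_to is not None and n < spec.pad_to:
                pad = rng.normal(0.0, PAD_SIGMA, size=spec.pad_to - n)
                sig = np.concatenate([sig, pad])
            records.append(RawRecord(f"bc{code}_{r}", sig, code))
    return SignalDataset(records)


def gen_worked_example() -> RawRecord:
    """Fixed length-10 sequence used in the docs to walk the full S2I chain
    (PAA -> scale -> polar -> GADF/GASF)."""
    values = np.array([1.2, 2.1, 3.4, 4.0, 3.1, 2.2, 1.5, 2.4, 3.6, 1.0])
    return RawRecord("worked-example", values, "demo")


def classify_barcode_peaks(signal: np.ndarray, noise_sigma: float) -> str:
    """Threshold peak-reading oracle for synthetic barcodes.

    Samples above ``baseline + max(3 sigma, 0.3)`` mark peak excursions; the
    first and last excursion centers anchor the start and end peaks, the
    three bit slots lie at quarters of that span, and a bit is 1 iff an
    interior excursion center falls within half a slot of its expected
    position. Independent of any learned model — used to certify that the
    synthetic task is solvable before a classifier is blamed.
    """
    sig = np.asarray(signal, dtype=float)
    thresh = max(3.0 * noise_sigma, 0.3)
    above = sig > thresh
    # excursion segments -> centers
    starts = list(np.flatnonzero(np.diff(np.concatenate(([0], above.astype(int)))) == 1))
    ends = list(np.flatnonzero(np.diff(np.concatenate((above.astype(int), [0]))) == -1))
    centers = [0.5 * (a + b) for a, b in zip(starts, ends)]
    if len(centers) < 2:
        return "000"  # unreadable: no anchors
    first, last = centers[0], centers[-1]
    span = last - first
    interior = centers[1:-1]
    bits = []
    for k in range(3):
        expected = first + span * (k + 1) / 4.0
        hit = any(abs(c - expected) <= span / 8.0 for c in interior)
        bits.append("1" if hit else "0")
    return "".join(bits)
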