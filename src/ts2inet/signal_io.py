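"""Containers and I/O for ragged labeled signal collections and image datasets.

Nanopore blockade-current events are variable-length 1-D float series; no
rectangular text format holds them comfortably, so the delimited dialect is
one record per line::

    id<TAB>label<TAB>v1,v2,...,vn

HDF5 stores signals losslessly as one dataset per record (ragged lengths) and
image datasets as a single ``(n, l, l)`` array with a strategy tag.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import h5py
import numpy as np

__all__ = [
    "RawRecord",
    "SignalDataset",
    "ImageDataset",
    "read_signals",
    "write_signals",
    "read_images",
    "write_images",
    "export_png",
    "split_dataset",
]


@dataclass(frozen=True)
class RawRecord:
    """One variable-length labeled current signal.

    ``signal`` holds normalized blockade current (dimensionless); at least two
    samples are required (a single sample cannot be min–max scaled) and every
    sample must be finite.
    """

    id: str
    signal: np.ndarray
    label: str

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 1 or sig.size < 2:
            raise ValueError(
                f"record {self.id!r}: signal must be 1-D with >= 2 samples, got shape {sig.shape}"
            )
        if not np.all(np.isfinite(sig)):
            raise ValueError(f"record {self.id!r}: signal contains non-finite samples")
        object.__setattr__(self, "signal", sig)


class SignalDataset:
    """Ordered collection of :class:`RawRecord` with a first-appearance class list."""

    def __init__(self, records: Iterable[RawRecord] = ()) -> None:
        self.records: list[RawRecord] = list(records)
        classes: list[str] = []
        for rec in self.records:
            if rec.label not in classes:
                classes.append(rec.label)
        self.classes: list[str] = classes

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[RawRecord]:
        return iter(self.records)

    def __getitem__(self, i: int) -> RawRecord:
        return self.records[i]

    def label_indices(self) -> np.ndarray:
        """Integer class index per record, classes numbered by first appearance."""
        lut = {c: k for k, c in enumerate(self.classes)}
        return np.array([lut[r.label] for r in self.records], dtype=int)

    def subset(self, indices: Sequence[int]) -> "SignalDataset":
        ds = SignalDataset(self.records[i] for i in indices)
        # keep the parent's class ordering so label indices stay comparable
        ds.classes = list(self.classes)
        return ds


STRATEGIES = ("GASF", "GADF", "MTF", "RP")


@dataclass
class ImageDataset:
    """Fixed-size image stack produced by one sequence-to-image strategy."""

    images: np.ndarray  # (n, l, l) float
    labels: np.ndarray  # (n,) int class indices
    strategy: str
    image_size: int
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.images = np.asarray(self.images, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; expected one of {STRATEGIES}")
        n = len(self.labels)
        if self.images.shape != (n, self.image_size, self.image_size):
            raise ValueError(
                f"images shape {self.images.shape} inconsistent with "
                f"{n} labels and image_size {self.image_size}"
            )
        if n and (self.labels.min() < 0 or (self.class_names and self.labels.max() >= len(self.class_names))):
            raise ValueError("labels out of range for class_names")

    def __len__(self) -> int:
        return len(self.labels)


def read_signals(path: str | os.PathLike, format: str = "delimited") -> SignalDataset:
    """Read a labeled signal collection from ``delimited`` text or ``hdf5``."""
    if format == "delimited":
        return _read_delimited(path)
    if format == "hdf5":
        return _read_signals_h5(path)
    raise ValueError(f"unknown format {format!r}")


def write_signals(ds: SignalDataset, path: str | os.PathLike, format: str = "delimited") -> None:
    if format == "delimited":
        with open(path, "w") as fh:
            for rec in ds:
                fh.write(f"{rec.id}\t{rec.label}\t{','.join(repr(float(v)) for v in rec.signal)}\n")
    elif format == "hdf5":
        with h5py.File(path, "w") as h5:
            grp = h5.create_group("signals")
            h5.attrs["record_order"] = [rec.id for rec in ds]
            h5.attrs["class_order"] = ds.classes
            for rec in ds:
                d = grp.create_dataset(rec.id, data=rec.signal)
                d.attrs["label"] = rec.label
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_delimited(path: str | os.PathLike) -> SignalDataset:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 TAB-separated fields, got {len(parts)}"
                )
            rec_id, label, payload = parts
            try:
                sig = np.array([float(tok) for tok in payload.split(",")], dtype=float)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-numeric sample ({exc})") from None
            try:
                records.append(RawRecord(rec_id, sig, label))
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
    return SignalDataset(records)


def _read_signals_h5(path: str | os.PathLike) -> SignalDataset:
    with h5py.File(path, "r") as h5:
        order = [str(x) for x in h5.attrs["record_order"]]
        grp = h5["signals"]
        records = [RawRecord(rid, grp[rid][...], str(grp[rid].attrs["label"])) for rid in order]
    return SignalDataset(records)


def write_images(ds: ImageDataset, path: str | os.PathLike) -> None:
    """Write an image dataset to HDF5; round-trips bit-exactly via :func:`read_images`."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("images", data=ds.images.reshape(len(ds), ds.image_size, ds.image_size))
        h5.create_dataset("labels", data=ds.labels)
        h5.attrs["strategy"] = ds.strategy
        h5.attrs["image_size"] = ds.image_size
        h5.attrs["class_names"] = ds.class_names


def read_images(path: str | os.PathLike) -> ImageDataset:
    with h5py.File(path, "r") as h5:
        return ImageDataset(
            images=h5["images"][...],
            labels=h5["labels"][...],
            strategy=str(h5.attrs["strategy"]),
            image_size=int(h5.attrs["image_size"]),
            class_names=[str(c) for c in h5.attrs["class_names"]],
        )


def export_png(image: np.ndarray, path: str | os.PathLike) -> None:
    """Export one matrix as 8-bit grayscale PNG (min–max mapped; inspection only, lossy)."""
    from PIL import Image

    img = np.asarray(image, dtype=float)
    lo, hi = img.min(), img.max()
    scaled = np.zeros_like(img) if hi == lo else (img - lo) / (hi - lo)
    Image.fromarray((scaled * 255).round().astype(np.uint8), mode="L").save(path)


def split_dataset(
    ds: SignalDataset,
    fractions: tuple[float, float, float],
    seed: int,
) -> tuple[SignalDataset, SignalDataset, SignalDataset]:
    """Stratified deterministic train/val/test split.

    Fractions must be positive and sum to 1. Per-class counts are allocated by
    largest remainder so the parts partition the input exactly; a class with
    fewer records than split parts raises.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must all be positive")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    n_parts = len(fractions)
    rng = np.random.default_rng(seed)
    parts: list[list[int]] = [[], [], []]
    labels = [rec.label for rec in ds.records]
    for cls in ds.classes:
        idx = [i for i, lab in enumerate(labels) if lab == cls]
        if len(idx) < n_parts:
            raise ValueError(
                f"class {cls!r} has {len(idx)} record(s), fewer than the {n_parts} split parts"
            )
        idx = list(rng.permutation(idx))
        counts = _largest_remainder(len(idx), fractions)
        # guarantee every part gets at least one record of this class
        for p in range(n_parts):
            if counts[p] == 0:
                donor = int(np.argmax(counts))
                counts[donor] -= 1
                counts[p] += 1
        start = 0
        for p, c in enumerate(counts):
            parts[p].extend(idx[start : start + c])
            start += c
    out = []
    for p in parts:
        sub = ds.subset(sorted(p))
        out.append(sub)
    return tuple(out)


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    exact = [n * f for f in fractions]
    base = [int(np.floor(e)) for e in exact]
    short = n - sum(base)
    order = np.argsort([-(e - b) for e, b in zip(exact, base)], kind="stable")
    for j in order[:short]:
        base[j] += 1
    return base
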