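"""Synthetic binary input generators and the binarized-MNIST reader.

Four artificial families drive the simulations:

* ``random_sparse_inputs`` — 32x32 images whose active fraction is drawn
  uniformly from 2-20%, with active positions uniform without replacement;
* ``random_bar_pairs`` — 10x10 images with one horizontal and one vertical
  five-pixel bar at independent random positions (overlap OR-ed);
* ``random_crosses`` — 10x10 images with a single cross (horizontal and
  vertical five-pixel bars sharing their centre pixel), placed fully inside
  the image;
* ``random_bar_sets`` — 32x32 images that OR together six bars of length 7,
  each independently horizontal or vertical, placed fully inside the image.

Every generator is a pure function of its arguments and seed.  MNIST images
(IDX format) can be read and thresholded for receptive-field visualisation.
"""

from __future__ import annotations

import math
import struct
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PatternSet", "DatasetSpec",
    "random_sparse_inputs", "random_bar_pairs", "random_crosses",
    "random_bar_sets", "load_mnist_binarized",
    "save_patterns_csv", "load_patterns_csv",
    "save_patterns_packed", "load_patterns_packed",
]


@dataclass
class PatternSet:
    """A stack of binary patterns with a common topology.

    ``X`` has shape (n_patterns, n_bits) with entries in {0, 1}; ``dims`` is
    the topology each row flattens (C order).
    """

    X: np.ndarray
    dims: tuple
    name: str = ""

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.uint8)
        self.dims = tuple(int(d) for d in self.dims)
        if self.X.ndim != 2 or self.X.shape[1] != math.prod(self.dims):
            raise ValueError("pattern length must equal prod(dims)")
        if not np.isin(self.X, (0, 1)).all():
            raise ValueError("patterns must be binary")

    def __len__(self) -> int:
        return self.X.shape[0]

    def __getitem__(self, i) -> np.ndarray:
        return self.X[i]

    def images(self) -> np.ndarray:
        return self.X.reshape((-1,) + self.dims)

    def popcounts(self) -> np.ndarray:
        return self.X.sum(axis=1)


def random_sparse_inputs(n: int = 100, dims=(32, 32),
                         sparsity_range=(0.02, 0.20), seed=None) -> PatternSet:
    """Random binary images with per-image active fraction uniform in a range."""
    lo, hi = sparsity_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError(f"sparsity range must lie in (0, 1), got {sparsity_range}")
    rng = np.random.default_rng(seed)
    n_bits = math.prod(dims)
    X = np.zeros((n, n_bits), dtype=np.uint8)
    for i in range(n):
        frac = rng.uniform(lo, hi)
        n_active = int(np.floor(frac * n_bits + 0.5))
        X[i, rng.choice(n_bits, size=n_active, replace=False)] = 1
    return PatternSet(X, dims, name="random_sparse")


def _place_bar(img: np.ndarray, horizontal: bool, row: int, col: int,
               length: int) -> None:
    if horizontal:
        img[row, col:col + length] = 1
    else:
        img[row:row + length, col] = 1


def random_bar_pairs(n: int = 100, dims=(10, 10), bar_len: int = 5,
                     seed=None) -> PatternSet:
    """One horizontal and one vertical bar at independent random positions."""
    h, w = dims
    if bar_len > min(h, w):
        raise ValueError("bar length exceeds image size")
    rng = np.random.default_rng(seed)
    X = np.zeros((n, h, w), dtype=np.uint8)
    for i in range(n):
        _place_bar(X[i], True, rng.integers(h), rng.integers(w - bar_len + 1), bar_len)
        _place_bar(X[i], False, rng.integers(h - bar_len + 1), rng.integers(w), bar_len)
    return PatternSet(X.reshape(n, -1), dims, name="bar_pairs")


def random_crosses(n: int = 100, dims=(10, 10), bar_len: int = 5,
                   seed=None) -> PatternSet:
    """A single cross (two bars sharing their centre pixel) per image."""
    h, w = dims
    if bar_len % 2 == 0:
        raise ValueError("bar_len must be odd so the bars share a centre pixel")
    half = bar_len // 2
    if h < bar_len or w < bar_len:
        raise ValueError("cross does not fit inside the image")
    rng = np.random.default_rng(seed)
    X = np.zeros((n, h, w), dtype=np.uint8)
    for i in range(n):
        r = int(rng.integers(half, h - half))
        c = int(rng.integers(half, w - half))
        X[i, r, c - half:c + half + 1] = 1
        X[i, r - half:r + half + 1, c] = 1
    return PatternSet(X.reshape(n, -1), dims, name="crosses")


def random_bar_sets(n: int = 100, dims=(32, 32), n_bars: int = 6,
                    bar_len: int = 7, seed=None) -> PatternSet:
    """OR of several bars, each independently horizontal or vertical."""
    h, w = dims
    if bar_len > min(h, w):
        raise ValueError("bar length exceeds image size")
    rng = np.random.default_rng(seed)
    X = np.zeros((n, h, w), dtype=np.uint8)
    for i in range(n):
        for _ in range(n_bars):
            if rng.random() < 0.5:
                _place_bar(X[i], True, int(rng.integers(h)),
                           int(rng.integers(w - bar_len + 1)), bar_len)
            else:
                _place_bar(X[i], False, int(rng.integers(h - bar_len + 1)),
                           int(rng.integers(w)), bar_len)
    return PatternSet(X.reshape(n, -1), dims, name="bar_sets")


_FAMILIES = {
    "random_sparse": random_sparse_inputs,
    "bar_pairs": random_bar_pairs,
    "crosses": random_crosses,
    "bar_sets": random_bar_sets,
}


@dataclass
class DatasetSpec:
    """Declarative description of a synthetic dataset family."""

    family: str
    n_patterns: int = 100
    dims: tuple = (32, 32)
    params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.family not in _FAMILIES and self.family != "mnist":
            raise ValueError(f"unknown dataset family {self.family!r}")
        self.dims = tuple(int(d) for d in self.dims)

    def generate(self, seed=None) -> PatternSet:
        if self.family == "mnist":
            return load_mnist_binarized(self.params["path"],
                                        threshold=self.params.get("threshold", 0))
        fn = _FAMILIES[self.family]
        return fn(n=self.n_patterns, dims=self.dims,
                  seed=self.seed if seed is None else seed, **self.params)

    def to_dict(self) -> dict:
        return {"family": self.family, "n_patterns": self.n_patterns,
                "dims": list(self.dims), "params": dict(self.params),
                "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetSpec":
        known = {"family", "n_patterns", "dims", "params", "seed"}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown dataset keys: {sorted(unknown)}")
        return cls(**d)


# ----------------------------------------------------------------- MNIST IDX

def load_mnist_binarized(idx_images_path, threshold: int = 0) -> PatternSet:
    """Read an IDX image file (MNIST format) and binarize at ``pixel > threshold``."""
    path = Path(idx_images_path)
    raw = path.read_bytes()
    if len(raw) < 4:
        raise ValueError(f"{path}: truncated IDX header")
    zero, dtype_code, ndim = raw[0] << 8 | raw[1], raw[2], raw[3]
    if zero != 0 or dtype_code != 0x08 or ndim < 2:
        raise ValueError(f"{path}: not an unsigned-byte IDX image file")
    header_len = 4 + 4 * ndim
    if len(raw) < header_len:
        raise ValueError(f"{path}: truncated IDX header")
    dims = struct.unpack(f">{ndim}I", raw[4:header_len])
    n, img_dims = dims[0], dims[1:]
    n_bits = math.prod(img_dims)
    body = np.frombuffer(raw, dtype=np.uint8, offset=header_len)
    if body.size != n * n_bits:
        raise ValueError(f"{path}: IDX payload size mismatch")
    X = (body.reshape(n, n_bits) > threshold).astype(np.uint8)
    return PatternSet(X, img_dims, name="mnist")


# ------------------------------------------------------------- serialization

def save_patterns_csv(patterns: PatternSet, path) -> None:
    header = ",".join(str(d) for d in patterns.dims)
    np.savetxt(path, patterns.X, fmt="%d", delimiter=",",
               header=f"dims={header}", comments="# ")


def load_patterns_csv(path) -> PatternSet:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("# dims="):
        raise ValueError(f"{path}: missing dims header")
    dims = tuple(int(v) for v in first.removeprefix("# dims=").split(","))
    X = np.loadtxt(path, delimiter=",", dtype=np.uint8, ndmin=2)
    return PatternSet(X, dims)


def save_patterns_packed(patterns: PatternSet, path) -> None:
    """Compact bit-packed binary container (one byte per 8 bits)."""
    np.savez_compressed(
        path, packed=np.packbits(patterns.X, axis=1),
        n_bits=np.int64(patterns.X.shape[1]),
        dims=np.asarray(patterns.dims, dtype=np.int64))


def load_patterns_packed(path) -> PatternSet:
    with np.load(path) as z:
        n_bits = int(z["n_bits"])
        X = np.unpackbits(z["packed"], axis=1)[:, :n_bits]
        dims = tuple(int(d) for d in z["dims"])
    return PatternSet(X, dims)
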