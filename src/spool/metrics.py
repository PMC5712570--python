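"""SDR quality metrics.

Four statistics quantify the health of a spatial pooler code directly from its
inputs and outputs, with no reference to a downstream task:

* **sparseness** — fraction of mini-columns active at one step;
* **entropy** — sum of per-column binary entropies of the activation
  frequencies over a dataset (bits; also reported per mini-column).  High
  entropy means all columns are used at similar rates;
* **noise robustness** — area under the curve of the fraction of clean-output
  active columns retained as a growing share of the input's active bits is
  randomly relocated (sparsity-preserving corruption);
* **stability** — fraction of a pattern's active columns retained between two
  consecutive frozen test points during continual learning.

All evaluation here is side-effect free: the pooler is only ever run with
learning disabled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "sparseness", "binary_entropy", "entropy", "corrupt",
    "noise_robustness", "stability", "synapse_turnover",
    "EntropyReport", "NoiseRobustnessReport",
]


def sparseness(active, alive_mask=None) -> float:
    """Population sparseness: fraction of (living) columns active."""
    a = np.asarray(active).ravel().astype(bool)
    if a.size == 0:
        raise ValueError("empty activation vector")
    if alive_mask is None:
        return float(a.sum() / a.size)
    alive = np.asarray(alive_mask, dtype=bool).ravel()
    n = int(alive.sum())
    if n == 0:
        raise ValueError("no living columns")
    return float((a & alive).sum() / n)


def binary_entropy(p) -> np.ndarray:
    """Binary entropy H(p) in bits, defined as 0 at p in {0, 1}."""
    p = np.asarray(p, dtype=np.float64)
    out = np.zeros_like(p)
    interior = (p > 0) & (p < 1)
    pi = p[interior]
    out[interior] = -pi * np.log2(pi) - (1 - pi) * np.log2(1 - pi)
    return out


@dataclass
class EntropyReport:
    per_column: np.ndarray      # bits, one entry per (living) column
    frequencies: np.ndarray     # activation frequency per (living) column

    @property
    def total(self) -> float:
        return float(self.per_column.sum())

    @property
    def per_minicolumn(self) -> float:
        """Total entropy divided by the number of (living) columns."""
        return float(self.per_column.mean())

    @property
    def max_per_minicolumn(self) -> float:
        """Upper bound: entropy if every column shared the mean frequency."""
        return float(binary_entropy(self.frequencies.mean()))

    @property
    def zero_frequency_fraction(self) -> float:
        """Fraction of columns never active over the dataset."""
        return float((self.frequencies == 0).mean())


def entropy(activations, alive_mask=None) -> EntropyReport:
    """Entropy of the pooler code over a dataset.

    Parameters
    ----------
    activations : sequence of boolean vectors, or (M, N) array
        The active-column vectors for M presented inputs.
    alive_mask : optional boolean vector
        Restrict the statistic to living columns (after a lesion).
    """
    A = np.asarray([np.asarray(a).ravel() for a in activations], dtype=bool)
    if A.ndim != 2 or A.shape[0] < 1:
        raise ValueError("need at least one activation vector")
    freq = A.mean(axis=0)
    if alive_mask is not None:
        freq = freq[np.asarray(alive_mask, dtype=bool).ravel()]
    return EntropyReport(per_column=binary_entropy(freq), frequencies=freq)


def corrupt(z, noise, rng) -> np.ndarray:
    """Sparsity-preserving corruption of a binary pattern.

    Turns off ``round(noise * n_active)`` randomly chosen active bits and
    turns on the same number of randomly chosen inactive bits, so the
    popcount is exactly preserved.  ``noise`` is a fraction in [0, 1].
    """
    z = np.asarray(z).ravel()
    zb = z != 0
    if not (0.0 <= noise <= 1.0):
        raise ValueError(f"noise must be in [0, 1], got {noise}")
    on = np.flatnonzero(zb)
    off = np.flatnonzero(~zb)
    if on.size == 0:
        raise ValueError("pattern has no active bits")
    n_flip = int(np.floor(noise * on.size + 0.5))   # round half up
    if n_flip > off.size:
        raise ValueError(
            f"cannot flip {n_flip} bits on: only {off.size} inactive bits")
    out = zb.copy()
    if n_flip:
        out[rng.choice(on, size=n_flip, replace=False)] = False
        out[rng.choice(off, size=n_flip, replace=False)] = True
    return out.astype(np.uint8)


DEFAULT_NOISE_LEVELS = np.round(np.arange(0.0, 1.0001, 0.05), 2)


@dataclass
class NoiseRobustnessReport:
    levels: np.ndarray          # noise fractions swept
    curve: np.ndarray           # mean retained-output fraction per level
    curve_sd: np.ndarray        # sd over patterns per level
    index: float                # trapezoid area under the curve over [0, 1]

    def max_unchanged_level(self) -> float:
        """Largest tested noise level whose mean retained fraction is 1.0."""
        exact = self.levels[self.curve >= 1.0]
        return float(exact.max()) if exact.size else 0.0


def noise_robustness(sp, patterns, levels=None, rng=None) -> NoiseRobustnessReport:
    """Noise robustness index of a pooler on a set of patterns.

    For each pattern and noise level the pattern is corrupted (fresh draw per
    level) and the fraction of the clean output's active columns that are
    retained is recorded; the index is the trapezoidal integral of the mean
    curve over noise in [0, 1].  Learning stays disabled throughout; patterns
    whose clean output has no active column are excluded with a warning.
    """
    if levels is None:
        levels = DEFAULT_NOISE_LEVELS
    levels = np.asarray(levels, dtype=np.float64)
    if rng is None:
        rng = np.random.default_rng()
    X = np.asarray([np.asarray(p).ravel() for p in patterns])
    fracs = []
    for z in X:
        clean = sp.compute(z, learn=False).active
        n_clean = int(clean.sum())
        if n_clean == 0:
            warnings.warn("pattern with no active output columns excluded "
                          "from noise robustness", stacklevel=2)
            continue
        row = np.empty(levels.size)
        for li, k in enumerate(levels):
            zc = corrupt(z, float(k), rng)
            noisy = sp.compute(zc, learn=False).active
            row[li] = (clean & noisy).sum() / n_clean
        fracs.append(row)
    if not fracs:
        raise ValueError("no pattern produced active output columns")
    F = np.asarray(fracs)
    curve = F.mean(axis=0)
    index = float(np.trapezoid(curve, levels))
    return NoiseRobustnessReport(levels=levels, curve=curve,
                                 curve_sd=F.std(axis=0), index=index)


def stability(outputs_prev, outputs_curr) -> float:
    """Stability index between two frozen test points.

    Mean over patterns of the fraction of previously active columns still
    active now.  Patterns with no active columns at the earlier test point
    are excluded with a warning.
    """
    vals = []
    for prev, curr in zip(outputs_prev, outputs_curr, strict=True):
        p = np.asarray(prev).ravel().astype(bool)
        c = np.asarray(curr).ravel().astype(bool)
        n_prev = int(p.sum())
        if n_prev == 0:
            warnings.warn("pattern with no previously active columns excluded "
                          "from stability", stacklevel=2)
            continue
        vals.append((p & c).sum() / n_prev)
    if not vals:
        raise ValueError("no pattern had active columns at the previous test point")
    return float(np.mean(vals))


def synapse_turnover(W_prev, W_curr) -> tuple[int, int]:
    """Counts of connected synapses formed (0->1) and removed (1->0)."""
    Wp = np.asarray(W_prev, dtype=bool)
    Wc = np.asarray(W_curr, dtype=bool)
    if Wp.shape != Wc.shape:
        raise ValueError("connected matrices must have the same shape")
    formed = int((~Wp & Wc).sum())
    removed = int((Wp & ~Wc).sum())
    return formed, removed
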