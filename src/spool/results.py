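"""Result containers for pooler training runs."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SPFitResults"]


@dataclass
class SPFitResults:
    """Metric traces recorded while training a spatial pooler online.

    Test points are epoch boundaries (0 = untrained) at which learning was
    frozen and the SDR metrics were evaluated on the current dataset.
    """

    model: object                      # the trained SpatialPooler
    test_epochs: list                  # epoch index of each test point
    entropy_per_minicolumn: np.ndarray  # bits/mini-column at each test point
    entropy_total: np.ndarray
    max_entropy_per_minicolumn: np.ndarray
    zero_frequency_fraction: np.ndarray
    eval_sparseness: np.ndarray        # mean frozen sparseness at each test point
    stability: np.ndarray              # nan at test point 0
    noise_robustness: dict = field(default_factory=dict)   # epoch -> report
    sparseness_trace: np.ndarray = None  # per training step
    synapses_formed: np.ndarray = None   # per epoch
    synapses_removed: np.ndarray = None
    phase_of_epoch: np.ndarray = None    # which training phase each epoch used

    @property
    def n_epochs(self) -> int:
        return int(max(self.test_epochs))

    def metrics_frame(self) -> pd.DataFrame:
        """One row per test point."""
        df = pd.DataFrame({
            "epoch": self.test_epochs,
            "entropy_bits_per_minicolumn": self.entropy_per_minicolumn,
            "entropy_total_bits": self.entropy_total,
            "max_entropy_bits_per_minicolumn": self.max_entropy_per_minicolumn,
            "zero_frequency_fraction": self.zero_frequency_fraction,
            "eval_sparseness": self.eval_sparseness,
            "stability": self.stability,
        })
        nr = {e: r.index for e, r in self.noise_robustness.items()}
        df["noise_robustness"] = [nr.get(e, np.nan) for e in self.test_epochs]
        return df

    def summary(self) -> str:
        df = self.metrics_frame()
        first, last = df.iloc[0], df.iloc[-1]
        lines = [
            "Spatial pooler fit results",
            "==========================",
            f"epochs trained:            {self.n_epochs}",
            f"training steps:            {self.model.step_count}",
            f"mean step sparseness:      {np.mean(self.sparseness_trace):.4f}"
            if self.sparseness_trace is not None and len(self.sparseness_trace)
            else "mean step sparseness:      n/a",
            f"entropy (bits/mini-column): {first.entropy_bits_per_minicolumn:.4f} "
            f"untrained -> {last.entropy_bits_per_minicolumn:.4f} trained "
            f"(max {last.max_entropy_bits_per_minicolumn:.4f})",
            f"zero-frequency columns:     {first.zero_frequency_fraction:.1%} "
            f"untrained -> {last.zero_frequency_fraction:.1%} trained",
        ]
        if self.noise_robustness:
            es = sorted(self.noise_robustness)
            lines.append(
                "noise robustness:           "
                + " -> ".join(f"{self.noise_robustness[e].index:.3f} (epoch {e})"
                              for e in es))
        if len(df) > 1 and np.isfinite(df.stability.iloc[-1]):
            lines.append(f"final stability:            {df.stability.iloc[-1]:.4f}")
        return "\n".join(lines)

    def to_csv(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics_frame().to_csv(out / "metrics.csv", index=False)
        if self.sparseness_trace is not None:
            pd.DataFrame({"step": np.arange(len(self.sparseness_trace)),
                          "sparseness": self.sparseness_trace}
                         ).to_csv(out / "sparseness.csv", index=False)
        if self.synapses_formed is not None:
            pd.DataFrame({"epoch": np.arange(1, len(self.synapses_formed) + 1),
                          "synapses_formed": self.synapses_formed,
                          "synapses_removed": self.synapses_removed}
                         ).to_csv(out / "synapse_turnover.csv", index=False)
        for e, rep in self.noise_robustness.items():
            pd.DataFrame({"noise_level": rep.levels, "mean_overlap": rep.curve,
                          "sd": rep.curve_sd}
                         ).to_csv(out / f"noise_curve_epoch{e}.csv", index=False)

    def plot_metrics(self, axes=None):
        """Metric trajectories (entropy, stability, turnover) on one figure."""
        import matplotlib.pyplot as plt
        if axes is None:
            _, axes = plt.subplots(3, 1, sharex=True, figsize=(6, 8))
        ep = self.test_epochs
        axes[0].plot(ep, self.entropy_per_minicolumn, marker="o")
        axes[0].axhline(self.max_entropy_per_minicolumn[-1], ls="--", c="k", lw=0.8)
        axes[0].set_ylabel("entropy (bits/col)")
        axes[1].plot(ep, self.stability, marker="o")
        axes[1].set_ylabel("stability")
        if self.synapses_formed is not None:
            e2 = np.arange(1, len(self.synapses_formed) + 1)
            axes[2].plot(e2, self.synapses_formed, label="formed")
            axes[2].plot(e2, self.synapses_removed, label="removed")
            axes[2].legend()
        axes[2].set_ylabel("synapses / epoch")
        axes[2].set_xlabel("epoch")
        return axes
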