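"""Scripted experiments: baseline learning, dataset switch, lesions, RF probes.

The training loop is online throughout: one pattern at a time, one pass over
the dataset per epoch in a fresh random order, metrics evaluated at epoch
boundaries with learning frozen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import SPConfig
from .pooler import SpatialPooler
from .datasets import PatternSet, random_bar_sets
from .results import SPFitResults
from . import metrics as M

__all__ = [
    "train_with_metrics", "run_baseline", "run_dataset_switch",
    "run_stroke", "run_input_lesion", "receptive_field_analysis",
    "mixed_input_probe", "coverage_map", "region_connection_count",
    "center_block_indices", "plateau_epoch",
    "BaselineResult", "LesionResult", "RFAnalysis",
]


def _eval_rng(sp: SpatialPooler, tag: int, epoch: int) -> np.random.Generator:
    # evaluation draws must not consume the pooler's own stream
    return np.random.default_rng(
        np.random.SeedSequence((sp.config.seed & 0x7FFFFFFF, tag, epoch)))


def _frozen_outputs(sp: SpatialPooler, X) -> list:
    return [sp.compute(z, learn=False).active for z in X]


def train_with_metrics(sp: SpatialPooler, patterns, n_epochs: int = 40, *,
                       phases=None, noise_eval_epochs=(), noise_levels=None,
                       stability_subset: int = 50, track_turnover: bool = True,
                       record_sparseness: bool = True,
                       progress: bool = False) -> SPFitResults:
    """Train a pooler online with frozen metric evaluation between epochs.

    Parameters
    ----------
    patterns : PatternSet or array
        Training data (ignored if ``phases`` is given).
    n_epochs : int
        Number of passes over the data (each in a fresh random order drawn
        from the pooler's own RNG, so checkpoint/resume is exact).
    phases : list of (patterns, n_epochs), optional
        Curriculum of datasets; metrics at each test point are evaluated on
        the dataset of the epoch just trained (dataset-switch experiments).
    noise_eval_epochs : iterable of int
        Test points at which the (expensive) noise-robustness sweep runs.
    stability_subset : int
        Size of the fixed random subset of each phase used for the stability
        index.
    """
    if phases is None:
        phases = [(patterns, n_epochs)]
    phase_X = [np.asarray(p.X if isinstance(p, PatternSet) else p) for p, _ in phases]
    phase_epochs = [int(e) for _, e in phases]
    total_epochs = sum(phase_epochs)
    phase_of_epoch = np.repeat(np.arange(len(phases)), phase_epochs)
    noise_eval_epochs = set(int(e) for e in noise_eval_epochs)

    # fixed stability subsets, one per phase
    sub_rng = _eval_rng(sp, 101, 0)
    subsets = []
    for X in phase_X:
        k = min(stability_subset, X.shape[0])
        subsets.append(X[sub_rng.choice(X.shape[0], size=k, replace=False)])

    test_epochs, ent_pc, ent_tot, ent_max, zero_frac, ev_sp, stab = \
        [], [], [], [], [], [], []
    nr_reports = {}
    prev_stab_outputs = [None] * len(phases)
    sparse_trace = [] if record_sparseness else None
    formed = np.zeros(total_epochs, dtype=np.int64)
    removed = np.zeros(total_epochs, dtype=np.int64)

    def evaluate(epoch: int, phase: int) -> None:
        X = phase_X[phase]
        outs = _frozen_outputs(sp, X)
        rep = M.entropy(outs, alive_mask=sp.alive_mask)
        test_epochs.append(epoch)
        ent_pc.append(rep.per_minicolumn)
        ent_tot.append(rep.total)
        ent_max.append(rep.max_per_minicolumn)
        zero_frac.append(rep.zero_frequency_fraction)
        ev_sp.append(np.mean([M.sparseness(a, sp.alive_mask) for a in outs]))
        for ph in range(len(phases)):
            cur = _frozen_outputs(sp, subsets[ph])
            if ph == phase and prev_stab_outputs[ph] is not None and epoch > 0:
                stab.append(M.stability(prev_stab_outputs[ph], cur))
            prev_stab_outputs[ph] = cur
        if len(stab) < len(test_epochs):
            stab.append(np.nan)
        if epoch in noise_eval_epochs:
            nr_reports[epoch] = M.noise_robustness(
                sp, X, levels=noise_levels, rng=_eval_rng(sp, 202, epoch))

    evaluate(0, 0)
    epoch = 0
    for phase, (X, n_ep) in enumerate(zip(phase_X, phase_epochs)):
        for _ in range(n_ep):
            epoch += 1
            W_before = sp.connected.copy() if track_turnover else None
            order = sp.rng.permutation(X.shape[0])
            for t in order:
                act = sp.compute(X[t], learn=True)
                if record_sparseness:
                    sparse_trace.append(M.sparseness(act.active, sp.alive_mask))
            if track_turnover:
                f, r = M.synapse_turnover(W_before, sp.connected)
                formed[epoch - 1], removed[epoch - 1] = f, r
            evaluate(epoch, phase)
            if progress:
                print(f"epoch {epoch}/{total_epochs}  "
                      f"entropy={ent_pc[-1]:.4f}  stability={stab[-1]:.3f}")

    return SPFitResults(
        model=sp,
        test_epochs=test_epochs,
        entropy_per_minicolumn=np.asarray(ent_pc),
        entropy_total=np.asarray(ent_tot),
        max_entropy_per_minicolumn=np.asarray(ent_max),
        zero_frequency_fraction=np.asarray(zero_frac),
        eval_sparseness=np.asarray(ev_sp),
        stability=np.asarray(stab),
        noise_robustness=nr_reports,
        sparseness_trace=(np.asarray(sparse_trace) if record_sparseness else None),
        synapses_formed=formed if track_turnover else None,
        synapses_removed=removed if track_turnover else None,
        phase_of_epoch=phase_of_epoch,
    )


# ------------------------------------------------------------------ baseline

@dataclass
class BaselineResult:
    """Per-seed fit results plus cross-seed aggregates of the endpoint metrics."""

    runs: list

    def _stat(self, fn):
        vals = np.asarray([fn(r) for r in self.runs])
        return float(vals.mean()), float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    @property
    def entropy_untrained(self):
        return self._stat(lambda r: r.entropy_per_minicolumn[0])

    @property
    def entropy_trained(self):
        return self._stat(lambda r: r.entropy_per_minicolumn[-1])

    @property
    def zero_frequency_untrained(self):
        return self._stat(lambda r: r.zero_frequency_fraction[0])

    @property
    def noise_robustness_untrained(self):
        return self._stat(lambda r: r.noise_robustness[0].index)

    @property
    def noise_robustness_trained(self):
        return self._stat(lambda r: r.noise_robustness[max(r.noise_robustness)].index)

    @property
    def mean_sparseness(self):
        return self._stat(lambda r: float(np.mean(r.sparseness_trace)))

    def summary(self) -> str:
        rows = [
            ("mean step sparseness", self.mean_sparseness),
            ("entropy untrained (bits/col)", self.entropy_untrained),
            ("entropy trained (bits/col)", self.entropy_trained),
            ("zero-frequency fraction untrained", self.zero_frequency_untrained),
        ]
        if self.runs[0].noise_robustness:
            rows += [("noise robustness untrained", self.noise_robustness_untrained),
                     ("noise robustness trained", self.noise_robustness_trained)]
        w = max(len(k) for k, _ in rows)
        lines = [f"Baseline experiment ({len(self.runs)} seeds)", "=" * 40]
        lines += [f"{k:<{w}}  {m:.4f} +/- {s:.4f}" for k, (m, s) in rows]
        return "\n".join(lines)


def run_baseline(dataset, n_epochs: int = 40, seeds=range(10), *,
                 config: SPConfig = None, noise_eval: bool = True,
                 progress: bool = False) -> BaselineResult:
    """Train fresh poolers on one dataset across seeds and collect metrics.

    ``dataset`` may be a PatternSet (same data for every seed) or a callable
    ``seed -> PatternSet`` (fresh inputs per repeat, as when each repeated
    experiment uses a different random input set).
    """
    runs = []
    for seed in seeds:
        cfg = (config or SPConfig.topological())
        cfg = SPConfig.from_dict({**cfg.to_dict(), "seed": int(seed)})
        sp = SpatialPooler(cfg)
        pats = dataset(seed) if callable(dataset) else dataset
        res = train_with_metrics(
            sp, pats, n_epochs=n_epochs,
            noise_eval_epochs=(0, n_epochs) if noise_eval else (),
            progress=progress)
        runs.append(res)
    return BaselineResult(runs=runs)


def run_dataset_switch(dataset_a, dataset_b, switch_epoch: int = 50,
                       n_epochs: int = 120, *, config: SPConfig = None,
                       noise_eval_epochs=None, seed: int = 0,
                       progress: bool = False) -> SPFitResults:
    """Train on dataset A, switch to dataset B, and track adaptation."""
    if not (0 < switch_epoch < n_epochs):
        raise ValueError("switch_epoch must lie strictly inside the run")
    cfg = config or SPConfig.topological()
    cfg = SPConfig.from_dict({**cfg.to_dict(), "seed": int(seed)})
    sp = SpatialPooler(cfg)
    if noise_eval_epochs is None:
        # pre-switch, right after the first epoch on the new data, and the end
        noise_eval_epochs = (switch_epoch, switch_epoch + 1, n_epochs)
    return train_with_metrics(
        sp, None, phases=[(dataset_a, switch_epoch),
                          (dataset_b, n_epochs - switch_epoch)],
        noise_eval_epochs=noise_eval_epochs, progress=progress)


# ----------------------------------------------------------- lesion studies

def center_block_indices(dims, block=(11, 11), offset=None) -> np.ndarray:
    """Flat indices of a rectangular block of a grid (centred by default)."""
    dims = tuple(dims)
    block = tuple(block)
    if offset is None:
        offset = tuple((d - b) // 2 for d, b in zip(dims, block))
    slices = tuple(slice(o, o + b) for o, b in zip(offset, block))
    idx = np.arange(math.prod(dims)).reshape(dims)
    return idx[slices].ravel()


def coverage_map(sp: SpatialPooler) -> np.ndarray:
    """Number of living mini-columns connected to each input bit."""
    return sp.connected[sp.alive_mask].sum(axis=0).astype(np.int64)


def region_connection_count(sp: SpatialPooler, region) -> int:
    """Number of living mini-columns with >= 1 connected synapse in a region."""
    region = np.asarray(region, dtype=np.int64)
    return int(sp.connected[np.ix_(sp.alive_mask, region)].any(axis=1).sum())


def plateau_epoch(trace, tol: float = 0.05) -> int:
    """First index from which the trace stays within ``tol`` of its final value."""
    trace = np.asarray(trace, dtype=np.float64)
    final = trace[-1]
    band = max(abs(final) * tol, 1e-12)
    off = np.abs(trace - final) > band
    if not off.any():
        return 0
    return int(np.flatnonzero(off).max() + 1)


@dataclass
class LesionResult:
    kind: str                       # "stroke" or "input_lesion"
    lesion_epoch: int
    epochs: np.ndarray              # epoch index of each tracked point
    center_counts: np.ndarray       # columns connected to the centre input region
    neighbor_counts: np.ndarray     # same for the adjacent comparison region
    formed: np.ndarray              # synapses formed per epoch
    removed: np.ndarray
    center_formed: np.ndarray       # turnover restricted to centre-region inputs
    center_removed: np.ndarray
    coverage: dict = field(default_factory=dict)     # "pre"/"post"/"end" maps
    rf_centers: dict = field(default_factory=dict)
    region_synapses: np.ndarray = None   # connected synapses into centre region

    @property
    def idx_post_lesion(self) -> int:
        """Index of the immediately-post-lesion record (same epoch value as pre)."""
        return int(np.searchsorted(self.epochs, self.lesion_epoch, side="right") - 1)

    @property
    def idx_pre_lesion(self) -> int:
        return self.idx_post_lesion - 1

    def recovery_plateau_epochs(self, tol: float = 0.05) -> int:
        """Epochs after the lesion until the centre-coverage trace plateaus."""
        post = self.center_counts[self.idx_post_lesion:]
        return plateau_epoch(post, tol)

    def summary(self) -> str:
        i, j = self.idx_pre_lesion, self.idx_post_lesion
        return "\n".join([
            f"{self.kind} experiment",
            "=" * 30,
            f"lesion at epoch:             {self.lesion_epoch}",
            f"centre coverage pre-lesion:  {self.center_counts[i]}",
            f"centre coverage post-lesion: {self.center_counts[j]}",
            f"centre coverage final:       {self.center_counts[-1]}",
            f"neighbour coverage pre/post: {self.neighbor_counts[i]} / "
            f"{self.neighbor_counts[j]}",
            f"plateau after lesion:        {self.recovery_plateau_epochs()} epochs",
        ])


def _run_lesion(kind: str, config: SPConfig = None, *, n_pre_inputs: int = 18000,
                n_post_inputs: int = 42000, epoch_size: int = 100,
                lesion_block=(11, 11), bar_params=None, seed: int = 0,
                progress: bool = False) -> LesionResult:
    cfg = config or SPConfig.topological()
    cfg = SPConfig.from_dict({**cfg.to_dict(), "seed": int(seed)})
    sp = SpatialPooler(cfg)
    bar_params = dict(n_bars=6, bar_len=7) if bar_params is None else bar_params
    dims = cfg.input_dims

    n_pre = n_pre_inputs // epoch_size
    n_post = n_post_inputs // epoch_size
    total = n_pre + n_post

    center_in = center_block_indices(dims, lesion_block)
    # comparison region: an equally sized block immediately right of the centre
    cdim0 = (dims[0] - lesion_block[0]) // 2
    cdim1 = (dims[1] - lesion_block[1]) // 2 + lesion_block[1]
    neighbor_in = center_block_indices(dims, lesion_block, offset=(cdim0, cdim1))

    epochs, c_counts, n_counts = [], [], []
    formed = np.zeros(total, dtype=np.int64)
    removed = np.zeros(total, dtype=np.int64)
    c_formed = np.zeros(total, dtype=np.int64)
    c_removed = np.zeros(total, dtype=np.int64)
    region_syn = []
    coverage, rf_cent = {}, {}

    def record(epoch):
        epochs.append(epoch)
        c_counts.append(region_connection_count(sp, center_in))
        n_counts.append(region_connection_count(sp, neighbor_in))
        region_syn.append(int(sp.connected[np.ix_(sp.alive_mask, center_in)].sum()))

    record(0)
    data_ss = np.random.SeedSequence((cfg.seed & 0x7FFFFFFF, 303))
    epoch_seeds = data_ss.generate_state(total, dtype=np.uint32) % (2 ** 31)
    for epoch in range(1, total + 1):
        if epoch - 1 == n_pre:
            # apply the trauma between epochs
            coverage["pre"] = coverage_map(sp)
            rf_cent["pre"] = receptive_field_analysis(sp).centers
            if kind == "stroke":
                cols = center_block_indices(cfg.column_dims, lesion_block)
                sp.lesion_columns(cols)
            else:
                sp.lesion_inputs(center_in)
            coverage["post"] = coverage_map(sp)
            rf_cent["post"] = receptive_field_analysis(sp).centers
            record(epoch - 1)   # immediately-post point shares the epoch index
        pats = random_bar_sets(n=epoch_size, dims=dims, seed=int(epoch_seeds[epoch - 1]),
                               **bar_params)
        W_before = sp.connected.copy()
        for t in sp.rng.permutation(len(pats)):
            sp.compute(pats[t], learn=True)
        diff_new = ~W_before & sp.connected
        diff_gone = W_before & ~sp.connected
        formed[epoch - 1] = int(diff_new.sum())
        removed[epoch - 1] = int(diff_gone.sum())
        c_formed[epoch - 1] = int(diff_new[:, center_in].sum())
        c_removed[epoch - 1] = int(diff_gone[:, center_in].sum())
        record(epoch)
        if progress and epoch % 10 == 0:
            print(f"{kind} epoch {epoch}/{total} centre={c_counts[-1]}")
    coverage["end"] = coverage_map(sp)
    rf_cent["end"] = receptive_field_analysis(sp).centers

    return LesionResult(
        kind=kind, lesion_epoch=n_pre,
        epochs=np.asarray(epochs), center_counts=np.asarray(c_counts),
        neighbor_counts=np.asarray(n_counts),
        formed=formed, removed=removed,
        center_formed=c_formed, center_removed=c_removed,
        coverage=coverage, rf_centers=rf_cent,
        region_synapses=np.asarray(region_syn))


def run_stroke(config: SPConfig = None, **kwargs) -> LesionResult:
    """Kill the central block of mini-columns mid-training and track recovery."""
    return _run_lesion("stroke", config, **kwargs)


def run_input_lesion(config: SPConfig = None, **kwargs) -> LesionResult:
    """Silence the central block of input bits mid-training and track rewiring."""
    return _run_lesion("input_lesion", config, **kwargs)


# --------------------------------------------------------------- RF analysis

@dataclass
class RFAnalysis:
    connected: np.ndarray     # bool (n_columns, n_inputs)
    centers: np.ndarray       # (n_columns, ndim), nan rows for empty RFs
    coverage: np.ndarray      # per input bit, over living columns
    input_dims: tuple
    alive: np.ndarray

    def rf_image(self, column: int) -> np.ndarray:
        return self.connected[column].reshape(self.input_dims)

    @property
    def empty_rf_columns(self) -> np.ndarray:
        return np.flatnonzero(~self.connected.any(axis=1))


def receptive_field_analysis(sp: SpatialPooler) -> RFAnalysis:
    """Connected maps, RF centroids, and the input coverage map of a pooler."""
    W = sp.connected
    counts = W.sum(axis=1).astype(np.float64)
    with np.errstate(invalid="ignore"):
        centers = (W.astype(np.float64) @ sp.input_coords) / counts[:, None]
    centers[counts == 0] = np.nan
    return RFAnalysis(connected=W.copy(), centers=centers,
                      coverage=coverage_map(sp),
                      input_dims=sp.config.input_dims,
                      alive=sp.alive_mask.copy())


def mixed_input_probe(sp: SpatialPooler, patterns, n_pairs: int = 100,
                      rng=None) -> dict:
    """Output overlap for random pattern pairs vs merged (OR-ed) inputs.

    Returns mean active-column overlaps: between the outputs of two random
    patterns, and between the output of their union and each constituent.
    """
    if rng is None:
        rng = np.random.default_rng()
    X = np.asarray(patterns.X if isinstance(patterns, PatternSet) else patterns)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least two patterns")
    pair_ov, merged_ov = [], []
    for _ in range(n_pairs):
        i, j = rng.choice(n, size=2, replace=False)
        ai = sp.compute(X[i], learn=False).active
        aj = sp.compute(X[j], learn=False).active
        am = sp.compute(X[i] | X[j], learn=False).active
        pair_ov.append(int((ai & aj).sum()))
        merged_ov.append(((am & ai).sum() + (am & aj).sum()) / 2.0)
    return {
        "mean_pair_overlap": float(np.mean(pair_ov)),
        "mean_merged_overlap": float(np.mean(merged_ov)),
        "n_pairs": int(n_pairs),
    }
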