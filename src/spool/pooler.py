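"""The HTM spatial pooler.

The pooler maps binary input patterns onto a fixed-sparsity binary code over a
sheet of mini-columns.  Each mini-column owns a fixed *potential pool* of input
bits (a hypercube of edge length ``gamma`` around its projection into input
space, thinned by the potential fraction ``p``).  Every potential synapse
carries a scalar *permanence* in [0, 1]; the synapse is connected when the
permanence reaches the connection threshold ``theta_c``.  On each step the
feedforward *overlap* of a column is its boosted count of connected synapses
onto active input bits; a k-winners-take-all competition within each column's
inhibition neighborhood selects the active columns; Hebbian updates then
reinforce active inputs of winners (``p+``) and punish their inactive inputs
(``p-``).  A slow homeostatic loop tracks per-column activation duty cycles and
multiplies each column's excitability by ``exp(-beta (duty - neighborhood
mean))`` so that all columns end up used at similar rates.

Lesion hooks support two fault-tolerance manipulations: killing a set of
mini-columns ("stroke": the columns can never activate or learn again) and
permanently silencing a set of input bits ("input lesion": the bits read as
zero forever, while existing synapses decay only through learning).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import SPConfig, ConfigError

__all__ = ["SpatialPooler", "Activation", "InitializationError"]


class InitializationError(RuntimeError):
    """A column ended up with an empty potential pool (after one resample)."""


@dataclass
class Activation:
    """One compute step: boolean active vector and boosted overlap vector."""

    active: np.ndarray   # bool, shape (n_columns,)
    overlaps: np.ndarray  # float, shape (n_columns,)

    @property
    def active_indices(self) -> np.ndarray:
        return np.flatnonzero(self.active)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())


def _grid_coords(dims) -> np.ndarray:
    """Integer lattice coordinates for a grid, shape (prod(dims), ndim)."""
    return np.stack(
        [g.ravel() for g in np.meshgrid(*[np.arange(d) for d in dims], indexing="ij")],
        axis=1,
    ).astype(np.float64)


class SpatialPooler:
    """Online spatial pooler model.

    Parameters
    ----------
    config : SPConfig
        Full parameter set; see :class:`spool.config.SPConfig`.

    Notes
    -----
    Construction performs the one-off random initialization (potential pools
    and uniform permanences) from ``config.seed``; the same seed always yields
    a bit-identical pooler.  All subsequent computation with learning disabled
    is a pure function of the state and the input.
    """

    STATE_ARRAYS = (
        "permanences", "potential", "boosts", "duty_cycles",
        "alive_mask", "input_mask",
    )

    def __init__(self, config: SPConfig):
        self.config = config
        self.n_columns = config.n_columns
        self.n_inputs = config.n_inputs

        ss = np.random.SeedSequence(config.seed)
        pool_ss, perm_ss, run_ss = ss.spawn(3)
        self.rng = np.random.Generator(np.random.PCG64(run_ss))

        self.column_coords = _grid_coords(config.column_dims)
        self.input_coords = _grid_coords(config.input_dims)
        self.column_centers = self._compute_centers()

        self.potential = self._init_potential_pool(np.random.Generator(np.random.PCG64(pool_ss)))
        self.permanences = self._init_permanences(np.random.Generator(np.random.PCG64(perm_ss)))
        self.connected = (self.permanences >= config.connection_threshold) & self.potential
        self._Wf = self.connected.astype(np.float64)

        self.boosts = np.ones(self.n_columns)
        self.duty_cycles = np.zeros(self.n_columns)
        self.alive_mask = np.ones(self.n_columns, dtype=bool)
        self.input_mask = np.ones(self.n_inputs, dtype=bool)
        self.step_count = 0

        if config.global_inhibition:
            self.inhibition_radius = math.inf
            self._dist2 = None
        else:
            self._dist2 = self._pairwise_dist2(self.column_coords)
            self.inhibition_radius = max(1.0, self._connected_span_radius())
        self._rebuild_neighborhoods()

    # ------------------------------------------------------------------ init

    def _compute_centers(self) -> np.ndarray:
        """Project each column's grid coordinate linearly into input space."""
        if len(self.config.column_dims) != len(self.config.input_dims):
            return np.zeros_like(self.column_coords)
        cd = np.asarray(self.config.column_dims, dtype=float)
        idim = np.asarray(self.config.input_dims, dtype=float)
        # map cell centres of the column grid onto cell centres of the input grid
        centers = (self.column_coords + 0.5) * idim / cd - 0.5
        return np.rint(centers)

    def _init_potential_pool(self, rng: np.random.Generator) -> np.ndarray:
        cfg = self.config
        if math.isinf(cfg.potential_radius):
            inside = np.ones((self.n_columns, self.n_inputs), dtype=bool)
        else:
            # gamma is a *radius*: the hypercube spans 2*gamma + 1 lattice
            # sites per dimension around the column's centre (clipped at the
            # borders, no wraparound)
            inside = np.ones((self.n_columns, self.n_inputs), dtype=bool)
            for d in range(self.input_coords.shape[1]):
                delta = np.abs(self.input_coords[None, :, d]
                               - self.column_centers[:, None, d])
                inside &= delta <= cfg.potential_radius
        if cfg.potential_fraction >= 1.0:
            pool = inside
        else:
            pool = inside & (rng.random((self.n_columns, self.n_inputs))
                             < cfg.potential_fraction)
            empty = ~pool.any(axis=1)
            if empty.any():
                # one resample for unlucky columns, then fail loudly
                redraw = inside[empty] & (
                    rng.random((int(empty.sum()), self.n_inputs))
                    < cfg.potential_fraction)
                pool[empty] = redraw
                if (~pool.any(axis=1)).any():
                    raise InitializationError(
                        "some columns have an empty potential pool even after "
                        "resampling; increase potential_fraction or potential_radius")
        if (~pool.any(axis=1)).any():
            raise InitializationError("some columns have an empty potential pool")
        return pool

    def _init_permanences(self, rng: np.random.Generator) -> np.ndarray:
        perms = rng.random((self.n_columns, self.n_inputs))
        perms[~self.potential] = 0.0
        return perms

    @staticmethod
    def _pairwise_dist2(coords: np.ndarray) -> np.ndarray:
        diff = coords[:, None, :] - coords[None, :, :]
        return np.einsum("ijk,ijk->ij", diff, diff).astype(np.float64)

    # --------------------------------------------------------- neighborhoods

    def _rebuild_neighborhoods(self) -> None:
        """Cache neighbor index lists and winner quotas for the current radius,
        excluding dead columns everywhere."""
        n = self.n_columns
        s = self.config.target_density
        alive = self.alive_mask
        if self.config.global_inhibition or math.isinf(self.inhibition_radius):
            self._nbr_idx = None
            self._nbr_counts = None
            n_alive = int(alive.sum())
            m = max(n_alive - 1, 0)
            self._global_quota = max(1, int(math.floor(0.5 + s * (m + 1))))
            return
        adj = (self._dist2 < self.inhibition_radius ** 2)
        np.fill_diagonal(adj, False)
        adj &= alive[None, :]
        adj[~alive, :] = False
        counts = adj.sum(axis=1).astype(np.int64)
        kmax = max(int(counts.max()), 1)
        order = np.argsort(~adj, axis=1, kind="stable")[:, :kmax]
        valid = np.arange(kmax)[None, :] < counts[:, None]
        self._nbr_idx = np.where(valid, order, n).astype(np.int64)
        self._nbr_counts = counts
        # winner quota per column under the counting rule
        self._quota = np.maximum(1, np.floor(0.5 + s * (counts + 1)).astype(np.int64))
        # nearest-rank index (0-based, into ascending neighbor overlaps)
        q = 100.0 * (1.0 - s)
        self._rank_idx = np.maximum(np.ceil(q / 100.0 * counts).astype(np.int64) - 1, 0)

    def neighborhood(self, column: int) -> np.ndarray:
        """Indices of the columns inhibiting column ``column`` (Euclidean ball
        of the current inhibition radius, self excluded; all other living
        columns under global inhibition)."""
        if self.config.global_inhibition or math.isinf(self.inhibition_radius):
            others = np.flatnonzero(self.alive_mask)
            return others[others != column]
        idx = self._nbr_idx[column]
        return idx[idx < self.n_columns]

    # ---------------------------------------------------------- compute path

    def _check_input(self, z) -> np.ndarray:
        z = np.asarray(z).ravel()
        if z.size != self.n_inputs:
            raise ValueError(
                f"input has {z.size} bits, expected {self.n_inputs}")
        return (z != 0)

    def compute_overlap(self, z, boosted: bool = True) -> np.ndarray:
        """Overlap of every column with the input pattern ``z``.

        With ``boosted=True`` (the learning path) each column's connected-
        synapse count onto active bits is multiplied by its homeostatic boost
        factor; inference applies no boost."""
        zb = self._check_input(z) & self.input_mask
        o = self._Wf @ zb.astype(np.float64)
        if boosted:
            o *= self.boosts
        o[~self.alive_mask] = 0.0
        return o

    def inhibit(self, overlaps: np.ndarray) -> np.ndarray:
        """k-winners-take-all activation from an overlap vector."""
        o = np.asarray(overlaps, dtype=np.float64)
        meets = (o >= self.config.stimulus_threshold) & self.alive_mask
        if not meets.any():
            return np.zeros(self.n_columns, dtype=bool)
        if self.config.global_inhibition or math.isinf(self.inhibition_radius):
            a = self._inhibit_global(o)
        else:
            a = self._inhibit_local(o)
        return a & meets

    def _inhibit_global(self, o: np.ndarray) -> np.ndarray:
        alive = self.alive_mask
        oa = o[alive]
        n_alive = oa.size
        if n_alive <= 1:
            return alive.copy()
        S = np.sort(oa)
        if self.config.winner_rule == "count":
            bigger = n_alive - np.searchsorted(S, o, side="right")
            win = bigger < self._global_quota
        elif self.config.winner_rule == "topk":
            # exactly k winners; ties at the cut broken by column index
            k = min(self._global_quota, n_alive)
            alive_idx = np.flatnonzero(alive)
            order = alive_idx[np.argsort(-oa, kind="stable")]
            win = np.zeros(self.n_columns, dtype=bool)
            win[order[:k]] = True
        else:
            # nearest-rank percentile over all *other* living columns
            q = 1.0 - self.config.target_density
            r = max(int(math.ceil(q * (n_alive - 1))), 1)
            idx = r - 1
            thr_lo = S[idx]
            thr_hi = S[min(idx + 1, n_alive - 1)]
            thr = np.where(o > thr_lo, thr_lo, thr_hi)
            win = o >= thr
        return win

    def _inhibit_local(self, o: np.ndarray) -> np.ndarray:
        o_ext_low = np.append(o, -np.inf)
        nbr = o_ext_low[self._nbr_idx]          # (n, kmax), pads are -inf
        if self.config.winner_rule in ("count", "topk"):
            bigger = (nbr > o[:, None]).sum(axis=1)
            return bigger < self._quota
        o_ext_high = np.append(o, np.inf)
        nbr_hi = o_ext_high[self._nbr_idx]      # pads are +inf -> sort to the end
        nbr_sorted = np.sort(nbr_hi, axis=1)
        thr = np.take_along_axis(nbr_sorted, self._rank_idx[:, None], axis=1)[:, 0]
        win = o >= thr
        win |= self._nbr_counts == 0            # empty neighborhood: self-win
        return win

    def learn(self, z, active: np.ndarray) -> None:
        """Hebbian permanence update for the winning columns."""
        idx = np.flatnonzero(active & self.alive_mask)
        if idx.size == 0:
            return
        cfg = self.config
        zb = self._check_input(z) & self.input_mask
        delta = np.where(zb, cfg.perm_increment, -cfg.perm_decrement)
        sub = self.permanences[idx] + self.potential[idx] * delta
        np.clip(sub, 0.0, 1.0, out=sub)
        sub[~self.potential[idx]] = 0.0
        self.permanences[idx] = sub
        wsub = (sub >= cfg.connection_threshold) & self.potential[idx]
        self.connected[idx] = wsub
        self._Wf[idx] = wsub

    def update_duty_cycles(self, active: np.ndarray) -> None:
        T = self.config.duty_cycle_period
        alive = self.alive_mask
        self.duty_cycles[alive] = (
            (T - 1) * self.duty_cycles[alive] + active[alive]) / T

    def update_boosts(self) -> None:
        beta = self.config.boost_strength
        if beta == 0:
            self.boosts[:] = 1.0
            return
        alive = self.alive_mask
        d = self.duty_cycles
        if self.config.global_inhibition or math.isinf(self.inhibition_radius):
            n_alive = int(alive.sum())
            if n_alive <= 1:
                mean_nbr = d.copy()
            else:
                total = d[alive].sum()
                mean_nbr = np.where(alive, (total - d) / (n_alive - 1), d)
        else:
            d_ext = np.append(d, 0.0)
            sums = d_ext[self._nbr_idx].sum(axis=1)
            counts = self._nbr_counts
            mean_nbr = np.where(counts > 0, sums / np.maximum(counts, 1), d)
        self.boosts = np.exp(-beta * (d - mean_nbr))
        self.boosts[~alive] = 1.0

    def _connected_span_radius(self) -> float:
        """Dynamic inhibition radius from the average connected receptive field.

        The span of a column is the per-dimension extent (max - min + 1) of
        its connected inputs' coordinates, averaged over dimensions; columns
        with no connected synapses are skipped.  The radius is half of (mean
        span x columns-per-input - 1), so that a pooler whose connected
        fields initially fill their potential hypercubes (span 2*gamma + 1,
        one column per input) starts with an inhibition radius equal to the
        potential radius gamma."""
        W = self.connected & self.alive_mask[:, None]
        has = W.any(axis=1)
        if not has.any():
            return self.inhibition_radius if math.isfinite(self.inhibition_radius) else 1.0
        spans = np.zeros((int(has.sum()), self.input_coords.shape[1]))
        Wh = W[has]
        for d in range(self.input_coords.shape[1]):
            coord = self.input_coords[:, d]
            hi = np.where(Wh, coord[None, :], -np.inf).max(axis=1)
            lo = np.where(Wh, coord[None, :], np.inf).min(axis=1)
            spans[:, d] = hi - lo + 1.0
        mean_span = spans.mean()
        columns_per_input = self.n_columns / self.n_inputs
        return float((mean_span * columns_per_input - 1.0) / 2.0)

    def update_inhibition_radius(self) -> None:
        """Recompute the dynamic inhibition radius from the connected matrix."""
        if self.config.global_inhibition:
            return
        new = max(1.0, self._connected_span_radius())
        if new != self.inhibition_radius:
            self.inhibition_radius = new
            self._rebuild_neighborhoods()

    def compute(self, z, learn: bool = True) -> Activation:
        """One pooling step: overlap, inhibition and (optionally) learning.

        Boost factors modulate the competition only while learning: frozen
        evaluation (``learn=False``) ranks columns by their raw connected
        overlaps, and the state is bit-identical before and after the call,
        so evaluation is side-effect free.
        """
        o = self.compute_overlap(z, boosted=learn)
        a = self.inhibit(o)
        if learn:
            self.learn(z, a)
            self.update_duty_cycles(a)
            self.update_boosts()
            self.step_count += 1
            if (not self.config.global_inhibition
                    and self.step_count % self.config.radius_update_period == 0):
                self.update_inhibition_radius()
        return Activation(active=a, overlaps=o)

    # --------------------------------------------------------------- lesions

    def lesion_columns(self, columns) -> None:
        """Permanently kill a set of mini-columns (simulated stroke)."""
        columns = np.asarray(columns, dtype=np.int64).ravel()
        if columns.size and (columns.min() < 0 or columns.max() >= self.n_columns):
            raise IndexError("column index out of range")
        mask = self.alive_mask.copy()
        mask[columns] = False
        if not mask.any():
            raise ValueError("cannot lesion every column")
        if mask.sum() == self.alive_mask.sum():
            return
        self.alive_mask = mask
        self._rebuild_neighborhoods()

    def lesion_inputs(self, inputs) -> None:
        """Permanently silence a set of input bits (simulated input lesion).

        Synapses onto the silenced bits are retained; they only decay through
        subsequent learning (the bits always read as inactive)."""
        inputs = np.asarray(inputs, dtype=np.int64).ravel()
        if inputs.size and (inputs.min() < 0 or inputs.max() >= self.n_inputs):
            raise IndexError("input index out of range")
        self.input_mask[inputs] = False

    # --------------------------------------------------------------- fitting

    def fit(self, patterns, n_epochs: int = 40, **kwargs):
        """Train online on a pattern set, tracking SDR quality metrics.

        Thin wrapper around :func:`spool.experiments.train_with_metrics`;
        returns an :class:`spool.results.SPFitResults`.
        """
        from .experiments import train_with_metrics
        return train_with_metrics(self, patterns, n_epochs=n_epochs, **kwargs)

    # ----------------------------------------------------------------- state

    def save(self, path) -> None:
        from .serialize import save_state
        save_state(self, path)

    @classmethod
    def load(cls, path) -> "SpatialPooler":
        from .serialize import load_state
        return load_state(path)

    def state_equal(self, other: "SpatialPooler") -> bool:
        """Bit-exact comparison of the full mutable state."""
        if self.config != other.config:
            return False
        same = all(
            np.array_equal(getattr(self, n), getattr(other, n))
            for n in self.STATE_ARRAYS)
        return (same
                and self.step_count == other.step_count
                and self.inhibition_radius == other.inhibition_radius
                and self.rng.bit_generator.state == other.rng.bit_generator.state)
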