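"""Spatial pooler configuration.

All algorithm parameters live in :class:`SPConfig`.  Defaults reproduce the
standard parameter set used throughout the experiments: 2% target activation
density, connection threshold 0.5, permanence increment/decrement 0.1/0.02,
boost strength 100, duty-cycle period 1000, stimulus threshold 1, full
potential fraction.  Two standard layouts exist: a two-dimensional 32x32
mini-column sheet with local inhibition and potential radius 5, and a
dimensionless 1024-column pooler with global inhibition and an unbounded
potential radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, asdict
from typing import Tuple


class ConfigError(ValueError):
    """Raised when a configuration value is outside its legal range."""


def _as_dims(value) -> Tuple[int, ...]:
    if isinstance(value, int):
        value = (value,)
    dims = tuple(int(v) for v in value)
    if len(dims) == 0 or any(d <= 0 for d in dims):
        raise ConfigError(f"dimensions must be positive integers, got {value!r}")
    return dims


@dataclass(frozen=True)
class SPConfig:
    """Parameters of the HTM spatial pooler.

    Parameters
    ----------
    column_dims, input_dims
        Topology of the mini-column sheet and of the input space.  For local
        inhibition both must have the same number of dimensions.
    target_density
        Fraction ``s`` of mini-columns that should be active at any time
        (the k-winners-take-all target, default 2%).
    connection_threshold
        Permanence value above which a potential synapse counts as
        connected (``theta_c``).
    perm_increment, perm_decrement
        Hebbian permanence updates ``p+`` / ``p-`` applied to active /
        inactive inputs of a winning column.
    boost_strength
        Homeostatic gain parameter ``beta``; 0 disables boosting.
    duty_cycle_period
        Time constant ``T`` (in input presentations) of the exponential
        moving average used for activation duty cycles.
    stimulus_threshold
        Minimum (boosted) overlap ``theta_stim`` required for activation.
    potential_fraction
        Probability ``p`` that an input inside a column's potential
        hypercube joins the potential pool.
    potential_radius
        Radius ``gamma`` of the potential hypercube centred on the column's
        projection into input space (the hypercube spans ``2*gamma + 1``
        lattice sites per dimension, clipped at the borders);  ``math.inf``
        gives every column the whole input space.
    global_inhibition
        If true the inhibition neighborhood of every column is all other
        columns (infinite inhibition radius).
    winner_rule
        Tie policy of the k-WTA step.  ``"topk"`` (default) activates, under
        global inhibition, exactly ``round(s * N)`` columns, breaking overlap
        ties by column index; under local inhibition it behaves like
        ``"count"``, which activates a column when fewer than
        ``round(s * (|N_i| + 1))`` neighbors have strictly greater overlap
        (ties keep all tied columns active).  ``"percentile"`` applies the
        nearest-rank percentile test ``o_i >= Z(V_i, 100 - s)`` literally.
    seed
        Master seed for potential-pool and permanence initialization and
        for the pooler's own stream (epoch shuffles during ``fit``).
    """

    column_dims: Tuple[int, ...]
    input_dims: Tuple[int, ...]
    target_density: float = 0.02
    connection_threshold: float = 0.5
    perm_increment: float = 0.1
    perm_decrement: float = 0.02
    boost_strength: float = 100.0
    duty_cycle_period: int = 1000
    stimulus_threshold: float = 1.0
    potential_fraction: float = 1.0
    potential_radius: float = math.inf
    global_inhibition: bool = True
    winner_rule: str = "topk"
    radius_update_period: int = 50
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "column_dims", _as_dims(self.column_dims))
        object.__setattr__(self, "input_dims", _as_dims(self.input_dims))
        if not (0.0 < self.target_density <= 1.0):
            raise ConfigError(f"target_density must be in (0, 1], got {self.target_density}")
        if not (0.0 < self.connection_threshold < 1.0):
            raise ConfigError(
                f"connection_threshold must be in (0, 1), got {self.connection_threshold}")
        if self.perm_increment < 0:
            raise ConfigError(f"perm_increment must be >= 0, got {self.perm_increment}")
        if self.perm_decrement < 0:
            raise ConfigError(f"perm_decrement must be >= 0, got {self.perm_decrement}")
        if self.boost_strength < 0:
            raise ConfigError(f"boost_strength must be >= 0, got {self.boost_strength}")
        if int(self.duty_cycle_period) < 1:
            raise ConfigError(
                f"duty_cycle_period must be a positive integer, got {self.duty_cycle_period}")
        object.__setattr__(self, "duty_cycle_period", int(self.duty_cycle_period))
        if self.stimulus_threshold < 0:
            raise ConfigError(
                f"stimulus_threshold must be >= 0, got {self.stimulus_threshold}")
        if not (0.0 < self.potential_fraction <= 1.0):
            raise ConfigError(
                f"potential_fraction must be in (0, 1], got {self.potential_fraction}")
        if not (self.potential_radius > 0):
            raise ConfigError(
                f"potential_radius must be positive, got {self.potential_radius}")
        if self.winner_rule not in ("count", "percentile", "topk"):
            raise ConfigError(
                f"winner_rule must be 'count', 'percentile' or 'topk', "
                f"got {self.winner_rule!r}")
        if int(self.radius_update_period) < 1:
            raise ConfigError(
                f"radius_update_period must be >= 1, got {self.radius_update_period}")
        object.__setattr__(self, "radius_update_period", int(self.radius_update_period))
        object.__setattr__(self, "seed", int(self.seed))
        if not self.global_inhibition:
            if len(self.column_dims) != len(self.input_dims):
                raise ConfigError(
                    "local inhibition requires column_dims and input_dims of equal rank")
        if math.isfinite(self.potential_radius):
            if len(self.column_dims) != len(self.input_dims):
                raise ConfigError(
                    "a finite potential_radius requires column_dims and input_dims "
                    "of equal rank")

    # -- convenience constructors -------------------------------------------------

    @classmethod
    def topological(cls, input_dims=(32, 32), column_dims=(32, 32),
                    potential_radius: float = 5, **kwargs) -> "SPConfig":
        """Two-dimensional pooler with local inhibition (the with-topology setup)."""
        kwargs.setdefault("global_inhibition", False)
        return cls(column_dims=column_dims, input_dims=input_dims,
                   potential_radius=potential_radius, **kwargs)

    @classmethod
    def dimensionless(cls, n_columns: int = 1024, input_dims=(32, 32),
                      **kwargs) -> "SPConfig":
        """Flat pooler with global inhibition and unbounded potential radius."""
        kwargs.setdefault("global_inhibition", True)
        kwargs.setdefault("potential_radius", math.inf)
        return cls(column_dims=(n_columns,), input_dims=input_dims, **kwargs)

    # -- derived quantities -------------------------------------------------------

    @property
    def n_columns(self) -> int:
        return int(math.prod(self.column_dims))

    @property
    def n_inputs(self) -> int:
        return int(math.prod(self.input_dims))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["column_dims"] = list(self.column_dims)
        d["input_dims"] = list(self.input_dims)
        d["potential_radius"] = (
            "inf" if math.isinf(self.potential_radius) else self.potential_radius)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SPConfig":
        d = dict(d)
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        if "column_dims" not in d or "input_dims" not in d:
            raise ConfigError("column_dims and input_dims are required")
        pr = d.get("potential_radius")
        if isinstance(pr, str):
            if pr.lower() in ("inf", "infinity", "infinite"):
                d["potential_radius"] = math.inf
            else:
                try:
                    d["potential_radius"] = float(pr)
                except ValueError:
                    raise ConfigError(f"potential_radius: cannot parse {pr!r}") from None
        return cls(**d)
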