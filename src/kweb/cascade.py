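"""Thresholded secondary-extinction cascades.

Removing a species deletes all its edges.  Every surviving species i is
then judged by the fraction of its original energy intake it still
receives,

    P(i) = (imports_i + sum over alive prey j of w_ji) / baseline_inflow_i,

and goes extinct secondarily when P(i) <= t for extinction threshold
t in [0, 1].  Extinctions propagate in synchronous rounds until a fixed
point; because losing a species can only lower other species' inflow, the
cascade is monotone and the fixed point is unique, so synchronous and
asynchronous orders agree.

The disintegration of a removal strategy X_ind is F = f(G0) - f(G), where
f counts the species whose survival fraction stays above t — primary
removals included with indicator 0, hence F >= n always.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .webio import AugmentedWeb

__all__ = ["RemovalVector", "CascadeResult", "simulate_cascade", "disintegration_F"]


@dataclass(frozen=True)
class RemovalVector:
    """Binary removal strategy: ``states[i] = 0`` removes species i, 1 keeps it.

    The virtual environment node has no entry — it is never removable.
    """

    states: np.ndarray

    def __post_init__(self) -> None:
        states = np.asarray(self.states)
        if states.ndim != 1 or not np.isin(states, (0, 1)).all():
            raise ValueError("states must be a flat 0/1 vector")
        object.__setattr__(self, "states", states.astype(np.int8))

    @classmethod
    def from_indices(cls, n_species: int, removed: Iterable[int]) -> "RemovalVector":
        states = np.ones(n_species, dtype=np.int8)
        idx = list(removed)
        if idx and (min(idx) < 0 or max(idx) >= n_species):
            raise ValueError(f"removal index out of range for N={n_species}")
        states[idx] = 0
        return cls(states)

    @property
    def n(self) -> int:
        """Number of primarily removed species."""
        return int(len(self.states) - self.states.sum())

    @property
    def removed_indices(self) -> np.ndarray:
        return np.flatnonzero(self.states == 0)


@dataclass(frozen=True)
class CascadeResult:
    threshold: float
    alive: np.ndarray          # post-fixed-point survival mask
    fractions: np.ndarray      # P(i) at the fixed point (0 for dead species)
    f: int                     # surviving species count f(G)
    F: int                     # disintegration f(G0) - f(G)
    secondary_count: int       # F minus the primary removals
    rounds: int                # synchronous propagation rounds run


def simulate_cascade(
    aug: AugmentedWeb,
    removal: RemovalVector | Sequence[int],
    t: float,
    *,
    strict_less: bool = False,
) -> CascadeResult:
    """Propagate secondary extinctions to the fixed point.

    Parameters
    ----------
    aug
        Augmented web (baseline inflows cached on the intact web).
    removal
        A :class:`RemovalVector`, or a sequence of species indices to
        remove primarily.
    t
        Extinction threshold in [0, 1]: species die when P(i) <= t
        (or strictly < t with ``strict_less=True``, kept as a
        sensitivity switch).

    Species with zero baseline inflow have P(i) defined as 0 and die in
    the first round.  Import edges come from the environment node and are
    never removed.
    """
    if not isinstance(removal, RemovalVector):
        removal = RemovalVector.from_indices(aug.n_species, removal)
    n_sp = aug.n_species
    if len(removal.states) != n_sp:
        raise ValueError(
            f"removal vector length {len(removal.states)} != N={n_sp}"
        )
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold t={t} outside [0, 1]")

    flows = aug.base.flows
    imports = aug.env_out
    baseline = aug.baseline_inflow
    safe_baseline = np.where(baseline > 0, baseline, 1.0)

    alive = removal.states.astype(bool)
    rounds = 0
    while True:
        inflow = imports + alive @ flows  # dead prey contribute nothing
        fractions = np.where(baseline > 0, inflow / safe_baseline, 0.0)
        doomed = alive & (
            (fractions < t) if strict_less else (fractions <= t)
        )
        if not doomed.any():
            break
        alive = alive & ~doomed
        rounds += 1

    fractions = np.where(alive, fractions, 0.0)
    f = int(alive.sum())
    return CascadeResult(
        threshold=t,
        alive=alive,
        fractions=fractions,
        f=f,
        F=n_sp - f,
        secondary_count=n_sp - f - removal.n,
        rounds=rounds,
    )


def disintegration_F(
    aug: AugmentedWeb,
    removal: RemovalVector | Sequence[int],
    t: float,
    *,
    strict_less: bool = False,
) -> int:
    """Disintegration F(X_ind) = f(G0) - f(G) of a removal strategy."""
    return simulate_cascade(aug, removal, t, strict_less=strict_less).F
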