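"""Robustness metrics of secondary-extinction curves.

A removal protocol on an N-species web yields the series N_p — total
extinct species after p primary removals.  Two scalars summarise it:

* SEA, the secondary extinction area: SEA = (sum_p N_p) / N^2 - 0.5,
  the area between the cumulative-extinction curve and the 1:1 line.
  It is 0.5 when the first removal collapses the whole web.  For the
  no-secondary-extinction curve N_p = p the literal formula gives
  1/(2N) (the discrete sum of the diagonal), which tends to 0 as N
  grows — the idealised "no secondary extinction -> 0" reading.
* R50, robustness: the minimum fraction p/N of primary removals that
  drives total extinctions to at least half the species (ties at
  exactly N/2 count).

The threshold sweep evaluates a strategy's R50 and SEA across a grid of
extinction thresholds, by default 0.05 to 0.95 in steps of 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .strategies import BASELINE_STRATEGIES, RemovalSequenceResult, sequential_removal
from .tabu import TabuConfig, tabu_removal_curve
from .webio import AugmentedWeb

__all__ = ["ExtinctionCurve", "sea", "r50", "default_threshold_grid", "threshold_sweep"]


def default_threshold_grid() -> np.ndarray:
    """The 19-point grid 0.05, 0.10, ..., 0.95."""
    return np.round(np.arange(1, 20) * 0.05, 2)


@dataclass(frozen=True)
class ExtinctionCurve:
    """N_p series of one removal protocol at one threshold."""

    N: int
    counts: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.shape != (self.N,):
            raise ValueError(
                f"counts series has length {counts.size}, expected N={self.N} "
                "(padding the collapsed tail is the producer's job)"
            )
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_sequence(cls, result: RemovalSequenceResult) -> "ExtinctionCurve":
        return cls(
            N=result.n_species, counts=result.counts, threshold=result.threshold
        )

    @property
    def sea(self) -> float:
        return sea(self)

    @property
    def r50(self) -> float:
        return r50(self)


def sea(curve: ExtinctionCurve) -> float:
    """Secondary extinction area: (sum_p N_p)/N^2 - 0.5."""
    return float(curve.counts.sum()) / curve.N**2 - 0.5


def r50(curve: ExtinctionCurve) -> float:
    """Minimum fraction of primary removals killing >= half the species."""
    half = curve.N / 2
    hit = np.flatnonzero(curve.counts >= half)
    if hit.size == 0:
        raise ValueError("counts never reaches N/2 — series not padded to collapse?")
    return float(hit[0] + 1) / curve.N


def threshold_sweep(
    aug: AugmentedWeb,
    strategy: str,
    *,
    cfg: TabuConfig | None = None,
    grid: Sequence[float] | None = None,
    reps: int = 1,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Evaluate SEA and R50 of one strategy across a threshold grid.

    Returns a tidy frame with columns (t, rep, SEA, R50).  Deterministic
    strategies ignore ``reps`` beyond duplicating rows; TS replicates get
    seeds ``base_seed + rep`` (budgets then derive their own seeds).
    """
    grid = default_threshold_grid() if grid is None else np.asarray(grid, dtype=float)
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("threshold grid must lie inside (0, 1)")
    cfg = cfg or TabuConfig()
    rows = []
    for t in grid:
        for rep in range(reps):
            if strategy == "TS":
                rep_cfg = TabuConfig(
                    T_max=cfg.T_max,
                    n_can=cfg.n_can,
                    L=cfg.L,
                    seed=(base_seed + rep) & 0x7FFFFFFF,
                    retry_cap=cfg.retry_cap,
                )
                result = tabu_removal_curve(aug, float(t), rep_cfg)
            else:
                result = sequential_removal(aug, strategy, float(t))
            curve = ExtinctionCurve.from_sequence(result)
            rows.append(
                {"t": float(t), "rep": rep, "SEA": curve.sea, "R50": curve.r50}
            )
    return pd.DataFrame(rows)
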