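"""Centrality-based sequential removal strategies.

Five baselines remove one species per step and let the cascade settle in
between: decreasing weighted out-degree (OD), weighted in-degree (ID),
their sum (SD), their product (PD), and weighted eigenvector centrality
(EIG).  Degrees are flux-weighted and, by default, include the
environment edges (imports on the in-side, exports + respiration on the
out-side), since those edges are part of the augmented graph.

In the default *dynamic* mode scores are recomputed on the current
surviving web at every step; *static* mode ranks once on the intact web.
The tabu-search strategy (TS) lives in :mod:`kweb.tabu`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .cascade import RemovalVector, simulate_cascade
from .webio import AugmentedWeb

__all__ = [
    "BASELINE_STRATEGIES",
    "STRATEGY_NAMES",
    "RemovalSequenceResult",
    "weighted_degrees",
    "eigenvector_scores",
    "sequential_removal",
]

BASELINE_STRATEGIES = ("OD", "ID", "SD", "PD", "EIG")
STRATEGY_NAMES = BASELINE_STRATEGIES + ("TS",)

_EIG_TOL = 1e-10
_EIG_MAX_ITER = 10_000


@dataclass(frozen=True)
class RemovalSequenceResult:
    """Outcome of a one-species-per-step removal protocol.

    ``counts[p-1]`` is N_p, the cumulative number of extinct species
    (primary + secondary) after p primary removals; once the web has
    collapsed the series is padded with N so it always has length N.
    """

    strategy: str
    threshold: float
    order: tuple[str, ...]
    counts: np.ndarray

    @property
    def n_species(self) -> int:
        return len(self.counts)


def weighted_degrees(
    aug: AugmentedWeb,
    alive: np.ndarray | None = None,
    *,
    include_env: bool = True,
) -> dict[str, np.ndarray]:
    """Flux-weighted in/out degrees and their sum and product.

    Computed on the subweb induced by ``alive`` (all species by default);
    dead species score 0.  ``include_env=False`` drops the environment
    edges from both sides.
    """
    n = aug.n_species
    alive = np.ones(n, dtype=bool) if alive is None else np.asarray(alive, dtype=bool)
    flows = aug.base.flows
    in_deg = alive @ flows
    out_deg = flows @ alive
    if include_env:
        in_deg = in_deg + aug.env_out
        out_deg = out_deg + aug.env_in
    in_deg = np.where(alive, in_deg, 0.0)
    out_deg = np.where(alive, out_deg, 0.0)
    return {
        "in": in_deg,
        "out": out_deg,
        "sum": in_deg + out_deg,
        "product": in_deg * out_deg,
    }


def eigenvector_scores(aug: AugmentedWeb, alive: np.ndarray | None = None) -> np.ndarray:
    """Weighted eigenvector centrality of the surviving subweb.

    Power iteration on the transpose of the alive inter-species flow
    matrix, so a species scores highly when it receives much energy from
    high-scoring species.  Scores are non-negative and L1-normalised over
    the alive set.  On acyclic webs the iteration eventually annihilates
    the vector (dominant eigenvalue 0); the last non-zero iterate is
    returned, which concentrates mass on terminal consumers.  An all-zero
    subweb yields uniform scores over the alive species.
    """
    n = aug.n_species
    alive = np.ones(n, dtype=bool) if alive is None else np.asarray(alive, dtype=bool)
    k = int(alive.sum())
    if k == 0:
        raise ValueError("eigenvector_scores: no alive species")
    sub = aug.base.flows[np.ix_(alive, alive)].T
    x = np.full(k, 1.0 / k)
    if np.any(sub > 0):
        for _ in range(_EIG_MAX_ITER):
            y = sub @ x
            norm = y.sum()
            if norm == 0.0:  # nilpotent direction exhausted; keep last iterate
                break
            y /= norm
            if np.abs(y - x).sum() < _EIG_TOL:
                x = y
                break
            x = y
    scores = np.zeros(n)
    scores[alive] = x
    return scores


def _score(
    aug: AugmentedWeb,
    strategy: str,
    alive: np.ndarray,
    *,
    include_env: bool,
) -> np.ndarray:
    if strategy == "EIG":
        return eigenvector_scores(aug, alive)
    deg = weighted_degrees(aug, alive, include_env=include_env)
    key = {"OD": "out", "ID": "in", "SD": "sum", "PD": "product"}[strategy]
    return deg[key]


def sequential_removal(
    aug: AugmentedWeb,
    strategy: str,
    t: float,
    *,
    mode: Literal["dynamic", "static"] = "dynamic",
    include_env: bool = True,
    tie_rng: np.random.Generator | None = None,
) -> RemovalSequenceResult:
    """Run a centrality strategy as a one-per-step removal protocol.

    At each step the top-ranked *alive* species is removed primarily (ties
    broken by lowest index, or uniformly by ``tie_rng`` when given), the
    cascade is run at threshold ``t`` over the cumulative removal set, and
    the cumulative extinct count N_p is recorded.  Species already extinct
    secondarily are never chosen.  The series is padded with N once the
    web has collapsed.
    """
    if strategy not in BASELINE_STRATEGIES:
        raise ValueError(
            f"unknown strategy {strategy!r}; expected one of {BASELINE_STRATEGIES} "
            "(TS runs through kweb.tabu)"
        )
    n = aug.n_species
    static_scores = (
        _score(aug, strategy, np.ones(n, dtype=bool), include_env=include_env)
        if mode == "static"
        else None
    )
    removed: list[int] = []
    alive = np.ones(n, dtype=bool)
    counts: list[int] = []
    while alive.any():
        scores = (
            static_scores
            if static_scores is not None
            else _score(aug, strategy, alive, include_env=include_env)
        )
        masked = np.where(alive, scores, -np.inf)
        best = masked.max()
        candidates = np.flatnonzero(masked == best)
        pick = (
            int(candidates[0])
            if tie_rng is None
            else int(tie_rng.choice(candidates))
        )
        removed.append(pick)
        result = simulate_cascade(aug, removed, t)
        alive = result.alive
        counts.append(int(result.F))
    counts += [n] * (n - len(counts))
    return RemovalSequenceResult(
        strategy=strategy,
        threshold=t,
        order=tuple(aug.species[i] for i in removed),
        counts=np.asarray(counts, dtype=int),
    )
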