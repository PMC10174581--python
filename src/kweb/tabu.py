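"""Tabu search for the optimal food-web disintegration strategy.

The optimisation problem: among all sets of n species, find the one whose
primary removal maximises the disintegration F (primary + secondary
extinctions) at a given threshold t.  Exhaustive search costs C(N, n)
cascade evaluations and is infeasible on real webs, so a tabu search
walks the swap neighbourhood instead:

* a solution is a binary vector with exactly n species removed;
* a move swaps one removed species with one kept species;
* recently used swaps live in a bounded FIFO tabu list and may not be
  redrawn, which forces the walk out of local optima;
* aspiration: whenever the current solution beats the best seen so far,
  the best is updated and the tabu list is cleared;
* the search stops after a fixed number of iterations.

The removal *curve* protocol re-optimises independently for each budget
p = 1..N and reports the resulting disintegration series N_p.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cascade import RemovalVector, disintegration_F
from .strategies import RemovalSequenceResult
from .webio import AugmentedWeb

__all__ = [
    "TabuConfig",
    "SwapMove",
    "random_initial_solution",
    "generate_candidates",
    "tabu_search_optimize",
    "tabu_removal_curve",
]

#: Seeds are XOR-folded per removal budget; keep them under 2**31.
_SEED_MASK = 0x7FFFFFFF


@dataclass(frozen=True)
class TabuConfig:
    """Search hyper-parameters.

    T_max
        Iterations to run (each evaluates up to ``n_can`` candidates).
    n_can
        Candidate solutions drawn per iteration.
    L
        Tabu-list capacity: a swap stays forbidden for L insertions.
    seed
        Base RNG seed; every stochastic path derives from it.
    retry_cap
        Failed draws tolerated before the oldest tabu entry is evicted to
        break a deadlock.
    """

    T_max: int = 100
    n_can: int = 20
    L: int = 7
    seed: int = 0
    retry_cap: int = 200

    def __post_init__(self) -> None:
        if self.T_max < 1 or self.n_can < 1 or self.L < 0:
            raise ValueError("need T_max >= 1, n_can >= 1, L >= 0")
        if self.retry_cap < self.n_can:
            raise ValueError("retry_cap must be >= n_can")


@dataclass(frozen=True)
class SwapMove:
    """Unordered pair {restored, removed}: one species flips 0->1, one 1->0."""

    restored: int
    removed: int

    def __post_init__(self) -> None:
        if self.restored == self.removed:
            raise ValueError("swap must involve two distinct species")

    @property
    def key(self) -> frozenset[int]:
        return frozenset((self.restored, self.removed))


@dataclass
class _TabuState:
    x_cur: np.ndarray
    x_opt: np.ndarray
    f_opt: int
    t_list: deque = field(default_factory=deque)


def random_initial_solution(
    n_species: int, n: int, rng: np.random.Generator | int
) -> RemovalVector:
    """Uniformly random solution removing exactly ``n`` of ``n_species``."""
    if not 1 <= n <= n_species:
        raise ValueError(f"removal budget n={n} outside 1..{n_species}")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    removed = rng.choice(n_species, size=n, replace=False)
    return RemovalVector.from_indices(n_species, removed)


def generate_candidates(
    state: _TabuState, cfg: TabuConfig, rng: np.random.Generator
) -> list[tuple[np.ndarray, SwapMove]]:
    """Draw up to ``n_can`` one-swap neighbours of the current solution.

    A draw picks a removed species to restore and a kept species to remove;
    draws whose swap already sits in this iteration's swap list or in the
    tabu list are rejected and retried.  After ``retry_cap`` consecutive
    failures the oldest tabu entry is evicted (deadlock breaker); when
    every distinct swap has been used the candidates found so far are
    returned.  At least one candidate is always produced.
    """
    removed = np.flatnonzero(state.x_cur == 0)
    kept = np.flatnonzero(state.x_cur == 1)
    if removed.size == 0 or kept.size == 0:
        raise ValueError("current solution must have >=1 removed and >=1 kept species")
    max_swaps = removed.size * kept.size
    s_list: set[frozenset[int]] = set()
    candidates: list[tuple[np.ndarray, SwapMove]] = []
    failures = 0
    while len(candidates) < cfg.n_can and len(s_list) < max_swaps:
        move = SwapMove(
            restored=int(rng.choice(removed)), removed=int(rng.choice(kept))
        )
        tabu_keys = {m.key for m in state.t_list}
        if move.key in s_list or move.key in tabu_keys:
            failures += 1
            if failures >= cfg.retry_cap:
                if candidates:  # settle for what we have
                    break
                if state.t_list:  # deadlock: relax the oldest prohibition
                    state.t_list.popleft()
                failures = 0
            continue
        failures = 0
        s_list.add(move.key)
        x = state.x_cur.copy()
        x[move.restored] = 1
        x[move.removed] = 0
        candidates.append((x, move))
    if not candidates:  # every swap tabu and s_list empty cannot co-occur
        raise RuntimeError("candidate generation produced no solution")
    return candidates


def tabu_search_optimize(
    aug: AugmentedWeb,
    n: int,
    t: float,
    cfg: TabuConfig | None = None,
    *,
    on_iteration=None,
) -> tuple[RemovalVector, int, list[int]]:
    """Maximise disintegration F over n-species removal sets.

    Returns the best solution found, its F, and the per-iteration
    best-so-far trace (length ``T_max``; non-decreasing by construction).
    Identical inputs (web, n, t, config incl. seed) give identical output.
    ``on_iteration(iteration, improved, tabu_len, accepted_move)`` is an
    optional observer hook (diagnostics and invariant checks).
    """
    cfg = cfg or TabuConfig()
    n_sp = aug.n_species
    if not 1 <= n <= n_sp:
        raise ValueError(f"removal budget n={n} outside 1..{n_sp}")
    rng = np.random.default_rng(cfg.seed)
    x0 = random_initial_solution(n_sp, n, rng)
    if n == n_sp:  # nothing to swap: every species removed
        return x0, n_sp, [n_sp] * cfg.T_max

    state = _TabuState(
        x_cur=x0.states.copy(),
        x_opt=x0.states.copy(),
        f_opt=disintegration_F(aug, x0, t),
    )
    trace: list[int] = []
    for it in range(cfg.T_max):
        candidates = generate_candidates(state, cfg, rng)
        values = [disintegration_F(aug, RemovalVector(x), t) for x, _ in candidates]
        k = int(np.argmax(values))  # ties: first encountered wins
        x_k, s_k = candidates[k]
        state.x_cur = x_k
        improved = values[k] > state.f_opt
        if improved:
            state.x_opt = x_k.copy()
            state.f_opt = values[k]
            state.t_list.clear()  # aspiration: improvement resets the memory
        else:
            state.t_list.append(s_k)
            while len(state.t_list) > cfg.L:
                state.t_list.popleft()
        trace.append(state.f_opt)
        if on_iteration is not None:
            on_iteration(it, improved, len(state.t_list), s_k)
    return RemovalVector(state.x_opt), state.f_opt, trace


def tabu_removal_curve(
    aug: AugmentedWeb,
    t: float,
    cfg: TabuConfig | None = None,
) -> RemovalSequenceResult:
    """TS removal curve: independent optimisation per budget p = 1..N.

    ``counts[p-1]`` is the best disintegration found with p primary
    removals (seed derived as ``cfg.seed XOR p``); once a budget achieves
    total collapse the remaining entries are padded with N.  The reported
    ``order`` is the optimal set at the first collapsing budget.

    Each budget's search runs independently, but the previous budget's
    best set plus one extra species is also evaluated as a fallback
    incumbent: since removing more species never lowers F, this keeps the
    reported curve non-decreasing even when a single search run is
    unlucky.
    """
    cfg = cfg or TabuConfig()
    n_sp = aug.n_species
    counts: list[int] = []
    order: tuple[str, ...] = ()
    prev_best: RemovalVector | None = None
    for p in range(1, n_sp + 1):
        sub_cfg = TabuConfig(
            T_max=cfg.T_max,
            n_can=cfg.n_can,
            L=cfg.L,
            seed=(cfg.seed ^ p) & _SEED_MASK,
            retry_cap=cfg.retry_cap,
        )
        best, f_best, _ = tabu_search_optimize(aug, p, t, sub_cfg)
        if prev_best is not None:
            extra = int(np.flatnonzero(prev_best.states == 1)[0])
            grown = prev_best.states.copy()
            grown[extra] = 0
            grown_vec = RemovalVector(grown)
            f_grown = disintegration_F(aug, grown_vec, t)
            if f_grown > f_best:
                best, f_best = grown_vec, f_grown
        counts.append(f_best)
        prev_best = best
        order = tuple(aug.species[i] for i in best.removed_indices)
        if f_best == n_sp:
            counts += [n_sp] * (n_sp - p)
            break
    return RemovalSequenceResult(
        strategy="TS",
        threshold=t,
        order=order,
        counts=np.asarray(counts, dtype=int),
    )
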