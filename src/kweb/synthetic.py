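"""Synthetic quantitative food webs, hand-checked fixtures, and the
exhaustive removal oracle.

The generator builds a niche-model topology (species ordered on a niche
axis; each consumer eats everything inside a contiguous niche interval)
at a target binary connectance, then draws positive skewed flux weights.
Real webs in the size range this emulates have S ~ 20-130 species and
binary connectance ~ 0.08-0.37, so defaults sit inside that envelope.
Basal species receive imports from the environment; every species gets a
positive export and respiration so boundary vectors are well-formed.

The brute-force oracle enumerates all C(N, n) removal sets — exactly the
traversal that is infeasible at scale and motivates tabu search — and is
used to certify the optimizer on small webs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from .cascade import RemovalVector, disintegration_F
from .webio import AugmentedWeb, FoodWeb

__all__ = [
    "SynthesisParams",
    "generate_niche_web",
    "fixture_web",
    "FIXTURE_NAMES",
    "brute_force_optimal_removal",
]

FIXTURE_NAMES = ("chain3", "two_prey", "isolated", "rank_swap")


@dataclass(frozen=True)
class SynthesisParams:
    """Knobs of the generator.

    S
        Species count (>= 2).
    target_C
        Binary directed connectance to aim for; the topology is
        resampled until the realised C_n/S^2 is within ``tolerance``.
    sigma
        Log-scale spread of the lognormal(0, sigma) flux weights.
    import_fraction
        Share of non-basal species that also receive an import edge
        (basal species always do).
    seed
        RNG seed; identical params give identical webs.
    """

    S: int = 30
    target_C: float = 0.15
    sigma: float = 1.0
    import_fraction: float = 0.1
    tolerance: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ValueError("need S >= 2")
        if not 0 < self.target_C < 1:
            raise ValueError("target_C must lie in (0, 1)")
        if self.target_C * self.S**2 < self.S - 1:
            raise ValueError(
                f"target_C={self.target_C} too sparse for S={self.S}: "
                "cannot even connect the web"
            )


def _niche_topology(s: int, c: float, rng: np.random.Generator) -> np.ndarray:
    """One niche-model draw: adjacency[prey, consumer] boolean."""
    niche = np.sort(rng.uniform(size=s))
    beta = 1.0 / (2.0 * c) - 1.0
    ranges = niche * rng.beta(1.0, beta, size=s)
    ranges[0] = 0.0  # the lowest-niche species is basal
    centres = rng.uniform(ranges / 2.0, np.minimum(niche, 1.0 - ranges / 2.0))
    lo = centres - ranges / 2.0
    hi = centres + ranges / 2.0
    adj = (niche[:, None] >= lo[None, :]) & (niche[:, None] <= hi[None, :])
    return adj


def generate_niche_web(params: SynthesisParams) -> FoodWeb:
    """Generate a quantitative web with niche-model topology.

    The topology is redrawn (up to 500 attempts) until the realised
    binary connectance lands within ``params.tolerance`` of the target;
    cycles and cannibalism are allowed, as in real webs.  Flux weights
    are lognormal(0, sigma).  Basal species (no prey) import from the
    environment, and a ``import_fraction`` share of consumers do too.
    """
    rng = np.random.default_rng(params.seed)
    s, c = params.S, params.target_C
    adj = None
    for _ in range(500):
        cand = _niche_topology(s, c, rng)
        realized = cand.sum() / s**2
        if abs(realized - c) <= params.tolerance:
            adj = cand
            break
    if adj is None:
        raise RuntimeError(
            f"could not hit connectance {c} +/- {params.tolerance} for S={s}"
        )
    flows = np.where(adj, rng.lognormal(0.0, params.sigma, size=(s, s)), 0.0)
    basal = adj.sum(axis=0) == 0  # no prey -> fed by the environment
    extra = (~basal) & (rng.uniform(size=s) < params.import_fraction)
    imports = np.where(basal | extra, rng.lognormal(0.0, params.sigma, size=s), 0.0)
    exports = rng.lognormal(-2.0, 0.5, size=s)
    respiration = rng.lognormal(-2.0, 0.5, size=s)
    return FoodWeb(
        name=f"niche_S{s}_C{c}_seed{params.seed}",
        species=tuple(f"sp{i:03d}" for i in range(s)),
        flows=flows,
        imports=imports,
        exports=exports,
        respiration=respiration,
    )


def fixture_web(name: str) -> FoodWeb:
    """Hand-computable fixtures used throughout the test-suite.

    chain3
        A -> B -> C food chain; imports (10, 0, 0), flows A->B = 5,
        B->C = 2.  Baseline inflows (10, 5, 2); removing A at t = 0.5
        collapses the whole chain.
    two_prey
        Consumer D eats A (flux 3) and B (flux 1); removing B leaves
        P(D) = 3/4, so D survives any threshold below 0.75.
    isolated
        Five species fed only by imports — no secondary extinction can
        ever happen below t = 1.
    rank_swap
        Removing the top in-degree species (C1) drains consumer C2, so
        dynamic and static in-degree rankings pick different second
        removals.
    """
    if name == "chain3":
        return FoodWeb(
            name="chain3",
            species=("A", "B", "C"),
            flows=[[0, 5, 0], [0, 0, 2], [0, 0, 0]],
            imports=[10, 0, 0],
            exports=[5, 3, 2],
            respiration=[0, 0, 0],
        )
    if name == "two_prey":
        return FoodWeb(
            name="two_prey",
            species=("A", "B", "D"),
            flows=[[0, 0, 3], [0, 0, 1], [0, 0, 0]],
            imports=[4, 2, 0],
            exports=[1, 1, 4],
            respiration=[0, 0, 0],
        )
    if name == "isolated":
        return FoodWeb(
            name="isolated",
            species=("s1", "s2", "s3", "s4", "s5"),
            flows=np.zeros((5, 5)),
            imports=[2, 2, 2, 2, 2],
            exports=[1, 1, 1, 1, 1],
            respiration=[1, 1, 1, 1, 1],
        )
    if name == "rank_swap":
        # In-degrees on the intact web: C1=8 > C2=7 > A=6 > B=5.
        # Removing C1 drops C2's inflow to 3, so the dynamic second pick
        # is A while the static ranking would choose C2.
        return FoodWeb(
            name="rank_swap",
            species=("A", "B", "C1", "C2"),
            flows=[
                [0, 0, 8, 3],
                [0, 0, 0, 0],
                [0, 0, 0, 4],
                [0, 0, 0, 0],
            ],
            imports=[6, 5, 0, 0],
            exports=[1, 1, 1, 1],
            respiration=[0.5, 0.5, 0.5, 0.5],
        )
    raise KeyError(f"unknown fixture {name!r}; choose from {FIXTURE_NAMES}")


def brute_force_optimal_removal(
    aug: AugmentedWeb,
    n: int,
    t: float,
    *,
    cap: int = 10**6,
) -> tuple[tuple[int, ...], int]:
    """Exhaustive maximum of F over all n-subsets of species.

    Ties resolve to the lexicographically smallest index set.  Refuses to
    enumerate more than ``cap`` subsets — that regime is what the tabu
    search exists for.
    """
    n_sp = aug.n_species
    if not 1 <= n <= n_sp:
        raise ValueError(f"budget n={n} outside 1..{n_sp}")
    n_subsets = math.comb(n_sp, n)
    if n_subsets > cap:
        raise ValueError(
            f"C({n_sp}, {n}) = {n_subsets} subsets exceeds cap={cap}; "
            "use tabu_search_optimize instead"
        )
    best_set: tuple[int, ...] | None = None
    best_f = -1
    for subset in itertools.combinations(range(n_sp), n):
        f_val = disintegration_F(aug, subset, t)
        if f_val > best_f:  # first strict max => lexicographic tie-break
            best_f = f_val
            best_set = subset
    assert best_set is not None
    return best_set, best_f
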