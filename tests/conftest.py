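import numpy as np
import pytest

from kweb import (
    SynthesisParams,
    augment_with_environment,
    fixture_web,
    generate_niche_web,
)


@pytest.fixture
def chain3():
    return fixture_web("chain3")


@pytest.fixture
def chain3_aug(chain3):
    return augment_with_environment(chain3)


@pytest.fixture
def two_prey_aug():
    return augment_with_environment(fixture_web("two_prey"))


@pytest.fixture
def isolated_aug():
    return augment_with_environment(fixture_web("isolated"))


@pytest.fixture
def rank_swap_aug():
    return augment_with_environment(fixture_web("rank_swap"))


def small_web(seed: int, s: int = 10, c: float = 0.2):
    """Seeded small synthetic web, augmented, for property tests."""
    return augment_with_environment(
        generate_niche_web(SynthesisParams(S=s, target_C=c, seed=seed))
    )


def async_cascade_oracle(aug, removed, t, order_seed=0):
    """Independent one-at-a-time cascade used to cross-check the
    synchronous simulator: repeatedly kill a single random species whose
    surviving inflow fraction is <= t, until none qualifies."""
    n = aug.n_species
    rng = np.random.default_rng(order_seed)
    alive = np.ones(n, dtype=bool)
    alive[list(removed)] = False
    while True:
        inflow = aug.env_out + alive @ aug.base.flows
        frac = np.where(
            aug.baseline_inflow > 0,
            inflow / np.where(aug.baseline_inflow > 0, aug.baseline_inflow, 1.0),
            0.0,
        )
        doomed = np.flatnonzero(alive & (frac <= t))
        if doomed.size == 0:
            return alive
        alive[rng.choice(doomed)] = False
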