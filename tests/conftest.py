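import numpy as np
import pytest

import smoltjms as sj
from smoltjms.simulate import DEFAULT_DEPOSITION


@pytest.fixture
def worked_design():
    """Two reaches, one recapture site, one colony foraging both reaches."""
    return sj.StudyDesign(n_reaches=2, colony_ids=("c1",),
                          forage_map={"c1": (1, 2)})


@pytest.fixture
def worked_state(worked_design):
    """The fully worked 2-reach state: reach 1 (consumed .2, other .1,
    survive .7), reach 2 (other .2, survive .8), p1 = .5, gamma = .5."""
    phi = np.array([[0.2, 0.1], [0.0, 0.2]])
    return sj.ParameterState.from_conditional(phi, p=[0.5, 0.0], gamma=[0.5],
                                              design=worked_design)


def random_state(rng: np.random.Generator, J: int, C: int,
                 design=None) -> sj.ParameterState:
    """A random valid parameter state (interior of the simplex)."""
    mass = rng.dirichlet(np.ones(J * (C + 1) + 1))
    Theta = mass[:-1].reshape(J, C + 1)
    p = np.concatenate([rng.uniform(0.05, 0.95, size=J - 1), [0.0]])
    gamma = rng.uniform(0.05, 0.95, size=C)
    return sj.ParameterState(Theta, p, gamma, design=design)


@pytest.fixture(scope="session")
def small2():
    """Simulated small_2reach dataset with its truth and matched priors."""
    sc = sj.get_scenario("small_2reach")
    truth = sj.draw_true_parameters(sc.design, sc, seed=1)
    counts = sj.simulate_histories(truth, seed=2)
    priors = sj.PriorSpec.from_truth(truth, DEFAULT_DEPOSITION, sc.colonies)
    return {"scenario": sc, "truth": truth, "counts": counts, "priors": priors}


@pytest.fixture(scope="session")
def small2_results(small2):
    """One shared posterior fit of the small_2reach dataset."""
    m = sj.JMSModel(small2["counts"], small2["scenario"].design,
                    small2["priors"], colonies=small2["scenario"].colonies)
    return m.fit(chains=2, warmup=250, draws=250, thin=2, seed=5)
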