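import numpy as np
import pandas as pd
import pytest

from gwgtraj import preprocess as pp
from gwgtraj import synthetic as syn
from gwgtraj.engine import default_bct_spec, fit_gamlss


def simulate_clean(n_women: int, seed: int, truth=None):
    """Observations drawn exactly from the BCT truth law (no measurement
    noise, no week-0 pseudo rows): the correctly-specified setting used
    by recovery and coverage tests."""
    truth = truth or syn.TruthModel()
    cfg = syn.CohortConfig(n_women=n_women, seed=seed)
    rngs = cfg.spawn_rngs()
    cohort = syn.generate_cohort(cfg, rngs["cohort"])
    visits = syn.generate_visits(cohort, cfg, rngs["visits"])
    visits, cohort = syn.generate_weights(
        visits, cohort, truth, cfg, rngs["weights"], measurement_error=False
    )
    return pp.compute_gwg(visits, cohort), cohort, truth


def simulate_noisy(n_women: int, seed: int, truth=None):
    """The full observational pipeline: measurement + self-report noise,
    week-0 pseudo-observations, 4 SD exclusion."""
    truth = truth or syn.TruthModel()
    cfg = syn.CohortConfig(n_women=n_women, seed=seed)
    cohort, visits = syn.simulate_dataset(cfg, truth)
    obs = pp.compute_gwg(visits, cohort)
    w0 = pp.draw_week0(cohort, seed=seed)
    obs = pd.concat([obs, w0], ignore_index=True)
    obs, _, _ = pp.exclude_4sd(obs)
    return obs, cohort, visits, truth


REFERENCE_PROFILE = {
    "age": 28.4,
    "bmi": 24.0,
    "parity_class": "0",
    "ethnicity_region": "Australian/European",
}


@pytest.fixture(scope="session")
def clean_sim():
    obs, cohort, truth = simulate_clean(5000, seed=42)
    return {"obs": obs, "cohort": cohort, "truth": truth}


@pytest.fixture(scope="session")
def clean_fit(clean_sim):
    """BCT-pspline fit of correctly specified data (n=5000 women)."""
    return fit_gamlss(clean_sim["obs"], default_bct_spec("pspline"))


@pytest.fixture(scope="session")
def heldout_clean():
    obs, _, truth = simulate_clean(5000, seed=314)
    return obs


@pytest.fixture(scope="session")
def noisy_sim():
    obs, cohort, visits, truth = simulate_noisy(2000, seed=11)
    return {"obs": obs, "cohort": cohort, "visits": visits, "truth": truth}
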