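import pytest

from phenowarm import synthetic_data as synth
from phenowarm import prep, censored_mle
from phenowarm.hierarchical import ModelSpec


def recovery_truth(beta: float = -2.4) -> synth.TruthParameters:
    """Single-phenophase truth with group SDs in the 1-3 day range."""
    return synth.TruthParameters(
        intercepts={"flowering": 175.0},
        treatment_effects={"flowering": beta},
        groups={
            "species": synth.GroupEffectTruth(3.0, 1.5),
            "site": synth.GroupEffectTruth(3.0, 1.5),
            "site_year": synth.GroupEffectTruth(2.0, 1.0),
            "site_subsite": synth.GroupEffectTruth(1.0, 1.0),
        },
        residual_sd=3.0,
    )


def simulate_replicates(
    truth,
    n_sites=4,
    n_subsites=2,
    n_species=8,
    n_years=4,
    n_plots=5,
    seed=1,
    phenophases=("flowering",),
):
    """Design -> events -> censoring -> prep -> stage-1 estimates."""
    design = synth.generate_design(
        n_sites, n_subsites, n_species, n_years, n_plots, seed,
        phenophases=phenophases,
    )
    events = synth.simulate_events(design, truth, seed + 1)
    obs, visits = synth.censor_by_census(events, synth.CensusConfig(), seed + 2)
    std, scalings, _ = prep.prepare(obs, visits)
    est = censored_mle.estimate_replicates(std)
    return est, scalings, std


@pytest.fixture(scope="session")
def recovery_fit_inputs():
    """Stage-1 estimates for the standard recovery scenario (true beta -2.4)."""
    truth = recovery_truth()
    est, scalings, std = simulate_replicates(truth, seed=11)
    return est, scalings["flowering"], truth


@pytest.fixture(scope="session")
def small_fit_inputs():
    """A small, quick-to-fit dataset for sampler behaviour tests."""
    truth = recovery_truth(beta=-3.0)
    est, scalings, _ = simulate_replicates(
        truth, n_sites=3, n_subsites=2, n_species=5, n_years=2, n_plots=3, seed=5
    )
    return est, scalings["flowering"], truth


def quick_spec(**kwargs) -> ModelSpec:
    defaults = dict(
        phenophase="flowering", chains=2, iterations=1500, warmup=750, seed=3
    )
    defaults.update(kwargs)
    return ModelSpec(**defaults)
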