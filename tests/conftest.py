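import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True,
                          deadline=None)
settings.load_profile("deterministic")

from htr3mix import synthetic_data as sd
from htr3mix.estimation import ModelSpec
from htr3mix.population_model import (
    OmegaMatrix,
    RandomEffectsSpec,
    RuvParameters,
)
from htr3mix.structural_model import (
    DrugParams,
    ObservationRecord,
    PopulationParameters,
)


@pytest.fixture(scope="session")
def reference():
    """Generative truth of the oocyte study (fixed effects, etas, RUV)."""
    pop, respec, omega, ruv = sd.reference_parameters()
    return {"pop": pop, "respec": respec, "omega": omega, "ruv": ruv}


def small_citral_population():
    """A two-eta, one-drug truth used by the scaled-down simulations."""
    pop = PopulationParameters(
        max0=4.94, pec50_0=5.65, nh_a=2.94, nt=0.0,
        drugs={"citral": DrugParams(pic50=3.92, nh=1.34, ng=0.0)},
    )
    respec = RandomEffectsSpec(
        entries=(("pec50_0", "additive"), ("max0", "exponential"))
    )
    omega = OmegaMatrix.from_sd_corr(
        np.array([0.18, 0.95]), corr={(0, 1): 0.87}
    )
    ruv = RuvParameters(alpha=0.30, gamma=1.30)
    return pop, respec, omega, ruv


def small_citral_design(n_oocytes=15):
    """Agonist curve + fixed-agonist citral inhibition, 8 points/oocyte."""
    protocols = []
    for i in range(n_oocytes):
        entries = [(a, "none", 0.0) for a in (0.3, 1.7, 10.0, 100.0)]
        entries += [(10.0, "citral", c)
                    for c in (100.0, 200.0, 300.0, 600.0)]
        protocols.append(tuple(
            ObservationRecord(
                oocyte_id=f"c{i:02d}", time_h=round(j * 0.07, 6),
                agonist_conc=a * 1e-6, drug_id=d, drug_conc=c * 1e-6,
            )
            for j, (a, d, c) in enumerate(entries)
        ))
    return sd.DesignSpec(protocols=tuple(protocols))


def small_citral_model(pop, respec, omega, ruv) -> ModelSpec:
    return ModelSpec(
        pop=pop,
        free=("max0", "pec50_0", "nh_a", "pic50_citral", "nh_citral"),
        random_effects=respec, omega=omega, ruv=ruv,
        free_corr=((0, 1),), free_ruv=("alpha",),
    )


@pytest.fixture()
def small_citral():
    pop, respec, omega, ruv = small_citral_population()
    design = small_citral_design()
    data = sd.simulate_dataset(design, pop, respec, omega, ruv, seed=7)
    model = small_citral_model(pop, respec, omega, ruv)
    return {"pop": pop, "respec": respec, "omega": omega, "ruv": ruv,
            "design": design, "data": data, "model": model}
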