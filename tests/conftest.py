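import pytest
from hypothesis import settings as hypothesis_settings

hypothesis_settings.register_profile("deterministic", derandomize=True)
hypothesis_settings.load_profile("deterministic")

from barduplex.adapter import AdapterSpec
from barduplex.quantify import TargetSite
from barduplex.simulate import (SimulationConfig, default_targets,
                                make_reference, simulate_run)


@pytest.fixture(scope="session")
def reference():
    return make_reference()


@pytest.fixture(scope="session")
def adapter_v2():
    return AdapterSpec.v2_default()


@pytest.fixture(scope="session")
def adapter_v1():
    return AdapterSpec.v1_default()


def clean_config(reference, vaf=0.2, n_molecules=40, family_size=4, seed=7,
                 **overrides):
    """Error-free simulation with deterministic family sizes."""
    kwargs = dict(
        reference=reference,
        target_sites=default_targets(reference, vaf),
        n_molecules=n_molecules,
        family_size_model="fixed",
        family_size_params={"size": family_size},
        polymerase_error_rate=0.0,
        damage_rate_c_to_a=0.0,
        seq_error_rate=0.0,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def as_pairs(result):
    return [(r.name, r.comment, r.r1_seq, r.r1_qual, r.r2_seq, r.r2_qual)
            for r in result.reads]


def sites_of(config):
    return [TargetSite(t.locus, t.position, t.ref, t.alt)
            for t in config.target_sites]


@pytest.fixture(scope="session")
def clean_run(reference):
    """One shared error-free simulation and its pipeline result."""
    from barduplex.pipeline import run_call

    config = clean_config(reference)
    result = simulate_run(config)
    call = run_call(as_pairs(result), reference, sites_of(config))
    return config, result, call
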