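from dataclasses import replace

import pytest
from hypothesis import settings

from nitropath.simulator import KineticParams

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def registry():
    from nitropath.species import builtin_species

    return builtin_species()


@pytest.fixture(scope="session")
def reactions():
    from nitropath.stoichiometry import builtin_reactions

    return builtin_reactions()


@pytest.fixture(scope="session")
def cases():
    from nitropath.stoichiometry import builtin_cases

    return builtin_cases()


def guild_subset(*active: str) -> KineticParams:
    """Kinetics with only the named guilds carrying biomass."""
    kp = KineticParams()
    guilds = {
        g: replace(gk, fraction=gk.fraction if g in active else 0.0)
        for g, gk in kp.guilds.items()
    }
    return replace(kp, guilds=guilds)


@pytest.fixture(scope="session")
def anammox_only_kinetics():
    return guild_subset("anammox")


@pytest.fixture(scope="session")
def no_nitrifier_kinetics():
    return guild_subset("anammox", "denitratation", "denitritation", "aerobic")
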