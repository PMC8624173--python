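import pytest

from polarlipid import simulate
from polarlipid.chem import AcylChain, default_library, make_species
from polarlipid.io import PipelineConfig
from polarlipid.workflow import run_pipeline


def species_from_name(name: str):
    """Build a LipidSpecies from a rendered name like 'PG(16:0_20:5)'."""
    code, body = name[:-1].split("(", 1)
    if code == "PI-Cer":
        c, d = body.lstrip("d").split(":")
        return make_species("PI-Cer",
                            chains=[AcylChain(int(c) - 18, int(d) - 1)])
    sep = "/" if "/" in body else "_"
    chains = [AcylChain.parse(t) for t in body.split(sep)]
    return make_species(code, chains=chains, sn_resolved=sep == "/")


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def rt_windows():
    return simulate.default_rt_windows()


@pytest.fixture(scope="session")
def default_run():
    """Full pipeline on the default-seed synthetic dataset (shared)."""
    return run_pipeline(config=PipelineConfig())
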