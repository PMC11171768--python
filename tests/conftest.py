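import pytest
from hypothesis import settings

from ecotoxscreen.germination import GerminationReplicate

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")

#: brine-shrimp dilution series: dose (µg/mL) -> observed mean mortality %
#: at 24 h and 48 h, 10 organisms per vessel
DOSES = (250.0, 500.0, 1000.0, 2000.0)
MORTALITY_24H = (0.0, 0.0, 37.0, 100.0)
MORTALITY_48H = (17.0, 57.0, 100.0, 100.0)
N_PER_GROUP = 10


@pytest.fixture
def wheat_like_replicates():
    """Five control dishes and five treated dishes with known quantities."""

    def dish(condition, conc, rid, n_final, root, shoot, n_energy=None):
        return GerminationReplicate(
            condition=condition,
            concentration=conc,
            replicate_id=rid,
            n_seeds=10,
            n_germ_energy=n_energy if n_energy is not None else max(n_final - 2, 0),
            n_germ_final=n_final,
            root_lengths=tuple([root] * n_final),
            shoot_lengths=tuple([shoot] * n_final),
        )

    control = [dish("control", None, f"C{i}", 7, 6.0, 8.0) for i in range(1, 6)]
    treated = [dish("1000 ug/mL", 1000.0, f"T{i}", 5, 3.0, 7.0) for i in range(1, 6)]
    return control, treated
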