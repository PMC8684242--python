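import numpy as np
import pytest

import dsnchip as dc


@pytest.fixture(scope="session")
def panel() -> dc.BreedPanel:
    return dc.BreedPanel("DSN", ("Holstein",))


@pytest.fixture(scope="session")
def small_cohort() -> dc.SimulatedCohort:
    """1 Mb, 2 breeds x 50 animals — shared by read-only tests."""
    spec = dc.CohortSpec(
        chromosomes=(("1", 1_000_000),),
        breeds=(("DSN", 50), ("Holstein", 50)),
        seed=11,
    )
    return dc.simulate_cohort(spec)


def make_genotype_matrix(codes, breeds=None, prefix="a", variant_ids=None):
    """Small helper: wrap a raw code array into a GenotypeMatrix."""
    codes = np.asarray(codes, dtype=np.int8)
    nvar, nanim = codes.shape
    animals = [f"{prefix}{i}" for i in range(nanim)]
    if breeds is None:
        breed_of = {a: "DSN" for a in animals}
    else:
        breed_of = dict(zip(animals, breeds))
    if variant_ids is None:
        variant_ids = [f"v{i}" for i in range(nvar)]
    return dc.GenotypeMatrix(variant_ids, animals, codes, breed_of)
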