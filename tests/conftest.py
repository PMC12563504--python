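import itertools

import pytest

from serotonin_presynapse import (
    ActivityCoefficients,
    KineticParameters,
    default_variant_specs,
    simulate,
)
from serotonin_presynapse.cohort import CohortCell, CohortDesign, DEFAULT_ALLELE_FREQS
from serotonin_presynapse.variants import variant_coefficient


@pytest.fixture(scope="session")
def specs():
    return default_variant_specs()


@pytest.fixture(scope="session")
def specs_by_id(specs):
    return {s.variant_id: s for s in specs}


@pytest.fixture(scope="session")
def default_params():
    return KineticParameters()


@pytest.fixture(scope="session")
def reference_trajectory(default_params):
    """Pulse-input run with the all-reference genotype."""
    return simulate(ActivityCoefficients(1.0, 1.0, 1.0), default_params)


@pytest.fixture(scope="session")
def coefficient_grid(specs_by_id):
    """All diploid coefficient values reachable per gene.

    27 TPH2 products x 3 HTTLPR values x 3 MAOA values (female genotype
    means of the {1, 5.5} multipliers plus male hemizygotes collapse to
    {1, 3.25, 5.5}).
    """

    def diploid(vid):
        s = specs_by_id[vid]
        return sorted(
            {
                variant_coefficient((a, b), s)
                for a, b in itertools.combinations_with_replacement(s.alleles, 2)
            }
        )

    tph2 = sorted(
        {
            a * b * c
            for a in diploid("rs111798998")
            for b in diploid("rs4290270")
            for c in diploid("rs7305115")
        }
    )
    return {"tph2": tph2, "sert": diploid("HTTLPR"), "maoa": [1.0, 3.25, 5.5]}


@pytest.fixture(scope="session")
def small_cells():
    """Study layout scaled to ~200 individuals (cell shares preserved)."""
    return (
        CohortCell("BD", "SA", 17, 13),
        CohortCell("BD", "NONSA", 21, 16),
        CohortCell("MDD", "SA", 29, 21),
        CohortCell("MDD", "NONSA", 27, 17),
        CohortCell("SCH", "SA", 20, 11),
        CohortCell("SCH", "NONSA", 34, 20),
        CohortCell("UNAFFECTED", "NA", 52, 18),
    )


@pytest.fixture()
def small_design(small_cells):
    import copy

    return CohortDesign(
        cells=small_cells,
        allele_freqs=copy.deepcopy(DEFAULT_ALLELE_FREQS),
        seed=11,
    )
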