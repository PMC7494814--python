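import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("default", derandomize=True)
settings.load_profile("default")

from guideforge import Genome, GenomeInterval, Placement, PlantSpec, make_genome

#: the worked-example spacer for parallel targeting of TF binding sites
TSSF_SPACER = "GTGAGAAGGTCGCCTTTATT"


@pytest.fixture(scope="session")
def small_genome() -> Genome:
    """10 kb random two-chromosome genome, fixed seed."""
    rng = np.random.default_rng(42)
    return Genome({
        "chr1": "".join(rng.choice(list("ACGT"), size=6000)),
        "chr2": "".join(rng.choice(list("ACGT"), size=4000)),
    }, assembly_name="toy")


@pytest.fixture(scope="session")
def planted_two_loci():
    """Genome with the TSSF worked-example spacer planted at two loci
    (one per strand), clean within 2 mismatches elsewhere."""
    plan = PlantSpec(
        TSSF_SPACER + "AGG",
        [Placement("chr1", 500), Placement("chr2", 1200, "-")],
        {"chr1": 5000, "chr2": 5000},
        max_mm=2,
    )
    genome = make_genome(plan, seed=11)
    loci = [
        GenomeInterval("chr1", 500, 519, "+", "siteA"),
        GenomeInterval("chr2", 1203, 1222, "-", "siteB"),
    ]
    return genome, loci
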