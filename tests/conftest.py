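"""Shared fixtures: a default synthetic scenario and one full pipeline run.

Both are session-scoped — the end-to-end run is the most expensive single
computation in the suite and several test modules inspect different facets
of the same result.
"""

import numpy as np
import pytest

from transrna import pipeline, synthetic_data


@pytest.fixture(scope="session")
def scenario():
    return synthetic_data.make_scenario(seed=11)


@pytest.fixture(scope="session")
def pipeline_result(scenario):
    return pipeline.run_pipeline(
        scenario.srna_records,
        scenario.libraries,
        scenario.host_mirnas,
        scenario.transcripts,
        scenario.annotations,
        scenario.degradome,
        scenario.locus_summaries,
        [f.homologs for f in scenario.families],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))
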