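import numpy as np
import pandas as pd
import pytest

from b1cycle import synth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def prototroph_scenario():
    """Four complete prototroph genomes over three timepoints, no noise."""
    specs = [synth.prototroph_spec(f"g{i}") for i in range(4)]
    return synth.random_scenario(specs, n_timepoints=3, seed=7)


@pytest.fixture
def feature_frame():
    """Helper to build small curated-feature tables."""

    def build(rows):
        return pd.DataFrame(
            rows, columns=["mag_id", "contig_id", "gene_label", "start", "end",
                           "strand", "fp_override"]
        )

    return build
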