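import numpy as np
import pandas as pd
import pytest

from nephromark.atlas import AtlasMatrix, GenomicBlock, SampleInfo


@pytest.fixture
def tiny_atlas() -> AtlasMatrix:
    """3 blocks x 4 samples (2 groups x 2 replicates), one missing cell."""
    blocks = [
        GenomicBlock("chr1", 100, 600, "b1"),
        GenomicBlock("chr1", 1000, 1500, "b2"),
        GenomicBlock("chr2", 50, 400, "b3"),
    ]
    samples = [
        SampleInfo("kid_1", "kidney", 1),
        SampleInfo("kid_2", "kidney", 2),
        SampleInfo("liv_1", "liver", 1),
        SampleInfo("liv_2", "liver", 2),
    ]
    beta = pd.DataFrame(
        [
            [0.9, 0.95, 0.05, 0.1],
            [0.2, 0.4, 0.3, np.nan],
            [0.5, 0.5, 0.5, 0.5],
        ],
        index=pd.Index(["b1", "b2", "b3"], name="block_id"),
        columns=["kid_1", "kid_2", "liv_1", "liv_2"],
    )
    return AtlasMatrix(blocks=blocks, samples=samples, beta=beta)
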