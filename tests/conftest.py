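import numpy as np
import pandas as pd
import pytest

from apexmir.io import APEX_DOMAINS, ExpressionAtlas, PareLibrary


@pytest.fixture
def small_atlas() -> ExpressionAtlas:
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.uniform(0, 50, size=(6, len(APEX_DOMAINS))),
        index=[f"g{i}" for i in range(6)],
        columns=list(APEX_DOMAINS),
    )
    return ExpressionAtlas(data)


def make_library(
    lengths: dict[str, int],
    tags: dict[tuple[str, str], dict[int, int]],
    replicates: list[str] | None = None,
) -> PareLibrary:
    """Build a PareLibrary from {(transcript, replicate): {pos: count}}."""
    if replicates is None:
        replicates = sorted({rep for _, rep in tags})
    counts = {}
    for (tid, rep), positions in tags.items():
        vec = np.zeros(lengths[tid], dtype=np.int64)
        for pos, ct in positions.items():
            vec[pos - 1] = ct
        counts[(tid, rep)] = vec
    return PareLibrary(transcript_lengths=dict(lengths), replicates=replicates, counts=counts)
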