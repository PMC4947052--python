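import numpy as np
import pytest

from measelect import (
    ArrayGeometry,
    ProtocolSpec,
    SpikeTrainSet,
    StimulationLog,
    WindowSpec,
    extract_patterns,
    generate_recording,
    make_response_model,
)


@pytest.fixture
def geometry_4x4():
    return ArrayGeometry(n_rows=4, n_cols=4)


@pytest.fixture
def geometry_8x8():
    return ArrayGeometry()


@pytest.fixture
def protocol():
    return ProtocolSpec()


@pytest.fixture
def window():
    return WindowSpec()


def quick_recording(
    n_electrodes=16,
    seed=0,
    spontaneous=False,
    **model_kwargs,
):
    """Small deterministic recording for tests (grid chosen to fit n_electrodes)."""
    rows = {4: (2, 2), 8: (2, 4), 12: (3, 4), 16: (4, 4), 64: (8, 8)}[n_electrodes]
    geom = ArrayGeometry(n_rows=rows[0], n_cols=rows[1])
    model = make_response_model(
        n_electrodes=n_electrodes, spontaneous=spontaneous, **model_kwargs
    )
    return generate_recording(geom, ProtocolSpec(), model, seed=seed)


def patterns_from_counts(counts_per_stim, sites, n_bins=15):
    """Build ResponsePattern objects from explicit per-stimulus count matrices."""
    from measelect import ResponsePattern

    out = []
    for i, (counts, site) in enumerate(zip(counts_per_stim, sites)):
        counts = np.asarray(counts, dtype=int)
        activation = np.where(counts.sum(axis=1) > 0, 20.0, np.nan)
        out.append(ResponsePattern(i, site, counts, activation))
    return out
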