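import warnings

import numpy as np
import pytest

from colspike.core import StimulusSchedule
from colspike.synthetic import (
    ClassArchetype,
    CohortConfig,
    CouplingEdge,
    TuningSpec,
    make_cohort,
    synth_spikes,
    synth_template,
)


@pytest.fixture(autouse=True)
def _quiet_numba_umap():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", module="umap")
        warnings.filterwarnings("ignore", message=".*n_jobs.*")
        yield


@pytest.fixture(scope="session")
def small_schedule():
    return StimulusSchedule(repeats=2, spatial_frequencies_cpd=(1.0,))


@pytest.fixture(scope="session")
def tuned_cohort():
    """Three well-driven units with strong planted tuning, 10 repeats."""
    arch = ClassArchetype(
        "X",
        ttp_width_ms=0.3,
        repolarization_ms=0.2,
        tuning=TuningSpec(
            pref_direction_deg=90.0,
            target_DI=0.8,
            target_OI=0.6,
            baseline_rate_hz=2.0,
            evoked_rate_hz=30.0,
            latency_ms=40.0,
        ),
    )
    cfg = CohortConfig(
        counts={"X": 3},
        archetypes=(arch,),
        schedule=StimulusSchedule(repeats=10, spatial_frequencies_cpd=(1.0,)),
    )
    cohort = make_cohort(cfg, 7)
    tables, counts = synth_spikes(cohort, 11)
    return cohort, tables, counts


def waveform_family(ttp_ms, n, seed, noise=0.01, name="F"):
    """Aligned, normalised soma waveforms of one planted family."""
    from colspike.waveform import align_normalize

    arch = ClassArchetype(
        name, ttp_width_ms=ttp_ms, repolarization_ms=max(0.6 * ttp_ms, 0.12)
    )
    return np.stack(
        [
            align_normalize(
                synth_template(arch, seed=seed * 1000 + i, noise=noise).soma_waveform,
                "negative",
            )
            for i in range(n)
        ]
    )
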