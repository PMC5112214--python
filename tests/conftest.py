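import numpy as np
import pytest

from mocgain import (
    CochlearIOParams,
    MaskingContext,
    load_reference_cohort,
)
from mocgain import synthetic_data as sd
from mocgain import tmc_fit


@pytest.fixture(scope="session")
def demo_params() -> CochlearIOParams:
    """IO-model parameter set used for worked forward predictions."""
    return CochlearIOParams(g_max=30.0, c=0.2, bp1=28.125, p=20.0)


@pytest.fixture(scope="session")
def demo_ctx() -> MaskingContext:
    return MaskingContext(l_s=20.0, k=1.5, mu=0.5)


@pytest.fixture(scope="session")
def cohort():
    return load_reference_cohort()


def make_subject(
    params: CochlearIOParams,
    ctx: MaskingContext,
    delta_g: float,
    noise_sd: float = 0.0,
    subject_id: str = "SYN",
) -> sd.SubjectRecord:
    return sd.SubjectRecord(
        subject_id=subject_id,
        params=params,
        ctx=ctx,
        delta_g=delta_g,
        noise_sd=noise_sd,
    )


@pytest.fixture(scope="session")
def noisy_recovery_study():
    """Fit a 100-subject simulated cohort at 2-dB observer noise.

    Shared across tests because the adaptive-track simulation plus the
    multistart fits are the most expensive step in the suite.  Returns a
    list of (true SubjectRecord, FitResult) pairs.
    """
    rng = np.random.default_rng(2026)
    spec = sd.PopulationSpec(noise_sd=2.0)
    pairs = []
    for i in range(100):
        subject = sd.sample_subject(spec, rng, f"SYN{i + 1}")
        table = sd.generate_tmc_dataset(
            subject, sd.identifiable_design(subject), rng=rng
        )
        pairs.append((subject, tmc_fit.fit_subject(table)))
    return pairs
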