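import numpy as np
import pytest

from ecgqc.covariance import EigenSpectrum, extract_features
from ecgqc.synthetic import SyntheticConfig, generate_cohort, mix_and_contaminate


def spectrum_from_log10(values) -> EigenSpectrum:
    """Build a spectrum from log10 eigenvalues (must be descending)."""
    return EigenSpectrum(lambdas=10.0 ** np.asarray(values, dtype=float))


def random_spectra(n: int, seed: int) -> list[EigenSpectrum]:
    """Random descending spectra with log10 eigenvalues spread over [-3, 9]."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        logs = np.sort(rng.uniform(-3.0, 9.0, size=8))[::-1]
        out.append(EigenSpectrum(lambdas=10.0**logs))
    return out


@pytest.fixture(scope="session")
def clean_record():
    """A noise-free 3-source synthetic record at default settings."""
    record, _ = mix_and_contaminate(SyntheticConfig(seed=42))
    return record


@pytest.fixture(scope="session")
def cohort():
    """A 200-record labeled synthetic cohort (50% acceptable), seed 1."""
    return generate_cohort(200, ac_fraction=0.5, seed=1)


@pytest.fixture(scope="session")
def cohort_spectra(cohort):
    return [extract_features(item.record) for item in cohort]
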