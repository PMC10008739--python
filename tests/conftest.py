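import numpy as np
import pytest

from fluormr.artifact import ArtifactPrior
from fluormr.simulate import SpectroAcqParams, coil_artifact_stats
from fluormr.spectra import Spectrum


@pytest.fixture
def acq():
    """Single-channel spectroscopy acquisition, 200 kHz bandwidth at 9.4 T."""
    return SpectroAcqParams(n_points=512, n_channels=1)


@pytest.fixture
def builtin_prior():
    """Artifact prior assembled from the characterised coil statistics."""
    stats = {ch: coil_artifact_stats(ch) for ch in (1, 2)}
    return ArtifactPrior(
        means={ch - 1: {k: v[0] for k, v in s.items()} for ch, s in stats.items()},
        sds={ch - 1: {k: v[1] for k, v in s.items()} for ch, s in stats.items()},
    )


def single_channel(spec: Spectrum) -> Spectrum:
    vals = np.atleast_2d(spec.values)
    return Spectrum(vals[0], spec.ppm_axis, spec.reference_frequency, spec.noise_sd)
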