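import numpy as np
import pytest

from eegfuse.types import MultichannelRecord


@pytest.fixture
def zeros_record():
    """Silent 3-channel record long enough for the AU-4 worked construction."""
    return MultichannelRecord(
        data=np.zeros((3, 7875)),
        sampling_rate=250.0,
        channel_names=["Fp1", "Fpz", "Fp2"],
        subject_id="zeros",
        label=0,
    )


def make_record(n_samples: int, n_channels: int = 1, subject_id: str = "rec",
                label: int = 0, seed: int = 0) -> MultichannelRecord:
    rng = np.random.default_rng(seed)
    return MultichannelRecord(
        data=rng.standard_normal((n_channels, n_samples)),
        sampling_rate=250.0,
        channel_names=[f"C{i}" for i in range(n_channels)],
        subject_id=subject_id,
        label=label,
    )
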