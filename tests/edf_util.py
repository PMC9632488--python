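"""Minimal EDF writer used only to build synthetic test fixtures.

Writes a valid single-record EDF file (ASCII header, 16-bit little-endian
samples) so the package's EDF *reader* can be exercised without shipping any
binary file in the repository.  Values are quantized to the 16-bit digital
range, so a written-then-read signal agrees with the original only up to
``(phys_max - phys_min) / 65535`` — the inherent EDF quantization step.
"""

from __future__ import annotations

import numpy as np


def write_edf(path, data: np.ndarray, sampling_rate: float,
              channel_names: list[str]) -> float:
    """Write one EDF data record containing all samples; returns the
    quantization step (physical units per digital unit)."""
    n_channels, n_samples = data.shape
    assert len(channel_names) == n_channels
    phys_min = float(np.floor(data.min())) - 1.0
    phys_max = float(np.ceil(data.max())) + 1.0
    dig_min, dig_max = -32768, 32767
    duration = n_samples / sampling_rate

    def pad(value, width):
        s = str(value)[:width]
        return s.ljust(width).encode("ascii")

    header = b"".join([
        pad("0", 8),                       # version
        pad("synthetic fixture", 80),      # patient id
        pad("eegfuse test", 80),           # recording id
        pad("01.01.20", 8),                # start date
        pad("00.00.00", 8),                # start time
        pad(256 + 256 * n_channels, 8),    # header bytes
        pad("", 44),                       # reserved
        pad(1, 8),                         # number of data records
        pad(f"{duration:.6f}"[:8], 8),     # record duration, seconds
        pad(n_channels, 4),
    ])
    header += b"".join(pad(name, 16) for name in channel_names)
    header += b"".join(pad("AgAgCl electrode", 80) for _ in range(n_channels))
    header += b"".join(pad("uV", 8) for _ in range(n_channels))
    header += b"".join(pad(f"{phys_min:.3f}"[:8], 8) for _ in range(n_channels))
    header += b"".join(pad(f"{phys_max:.3f}"[:8], 8) for _ in range(n_channels))
    header += b"".join(pad(dig_min, 8) for _ in range(n_channels))
    header += b"".join(pad(dig_max, 8) for _ in range(n_channels))
    header += b"".join(pad("", 80) for _ in range(n_channels))      # prefilter
    header += b"".join(pad(n_samples, 8) for _ in range(n_channels))
    header += b"".join(pad("", 32) for _ in range(n_channels))      # reserved

    gain = (phys_max - phys_min) / (dig_max - dig_min)
    digital = np.round((data - phys_min) / gain + dig_min).astype("<i2")
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(digital.tobytes())  # channel-sequential within the record
    return gain
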