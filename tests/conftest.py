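import struct

import numpy as np
import pytest


def write_minimal_edf(path, signals, labels, sfreq):
    """Write a minimal single-record EDF file for reader tests.

    ``signals`` is (n_channels, n_samples) in microvolt-scale units; the file
    uses one data record of n_samples / sfreq seconds.  Synthetic fixture
    writer — supports just enough of the format for round-trip tests.
    """
    signals = np.asarray(signals, dtype=float)
    n_ch, n_samp = signals.shape
    record_seconds = n_samp / sfreq
    phys_min, phys_max = -1000.0, 1000.0
    dig_min, dig_max = -32768, 32767

    def pad(text, width):
        return text.ljust(width)[:width].encode("ascii")

    header = b"".join(
        [
            pad("0", 8),
            pad("synthetic patient", 80),
            pad("synthetic recording", 80),
            pad("01.01.20", 8),
            pad("00.00.00", 8),
            pad(str(256 + 256 * n_ch), 8),
            pad("", 44),
            pad("1", 8),  # number of data records
            pad(f"{record_seconds:g}", 8),
            pad(str(n_ch), 4),
        ]
    )
    header += b"".join(pad(l, 16) for l in labels)
    header += b"".join(pad("", 80) for _ in range(n_ch))       # transducer
    header += b"".join(pad("uV", 8) for _ in range(n_ch))       # unit
    header += b"".join(pad(f"{phys_min:g}", 8) for _ in range(n_ch))
    header += b"".join(pad(f"{phys_max:g}", 8) for _ in range(n_ch))
    header += b"".join(pad(str(dig_min), 8) for _ in range(n_ch))
    header += b"".join(pad(str(dig_max), 8) for _ in range(n_ch))
    header += b"".join(pad("", 80) for _ in range(n_ch))        # prefiltering
    header += b"".join(pad(str(n_samp), 8) for _ in range(n_ch))
    header += b"".join(pad("", 32) for _ in range(n_ch))        # reserved

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.clip((signals - phys_min) * scale + dig_min, dig_min, dig_max)
    body = digital.astype("<i2").tobytes()
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(body)


@pytest.fixture
def edf_writer():
    return write_minimal_edf
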