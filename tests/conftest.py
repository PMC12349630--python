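import numpy as np
import pytest

from pulsebp.preprocess import PulseSegment


def make_segment(
    amplitude: float = 1.0,
    period_s: float = 0.8,
    fs_hz: float = 125.0,
    onset_idx: int = 100,
    peak_frac: float = 0.25,
) -> PulseSegment:
    """Triangular pulse segment with exact amplitude and period."""
    n = int(round(period_s * fs_hz))
    peak = max(1, int(round(peak_frac * n)))
    up = np.linspace(0.0, amplitude, peak + 1)
    down = np.linspace(amplitude, 0.0, n - peak + 1)[1:]
    samples = np.concatenate([up, down])
    return PulseSegment(
        onset_idx=onset_idx,
        peak_idx=onset_idx + peak,
        end_idx=onset_idx + n,
        samples=samples,
        fs_hz=fs_hz,
    )


@pytest.fixture
def triangle_segment() -> PulseSegment:
    """The 125 Hz triangle with on-grid vertices: onset (0 s, 0 au),
    peak (0.2 s, 1 au), end (0.6 s, 0 au)."""
    up = np.linspace(0.0, 1.0, 26)
    down = np.linspace(1.0, 0.0, 51)[1:]
    return PulseSegment(
        onset_idx=0,
        peak_idx=25,
        end_idx=75,
        samples=np.concatenate([up, down]),
        fs_hz=125.0,
    )
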