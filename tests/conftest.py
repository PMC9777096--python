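import numpy as np
import pytest

from pcgkit.io_dataset import CLASSES, PCGRecording, write_wav
from pcgkit.synthetic import SynthConfig, generate_recording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tone_2k():
    """A 100 Hz unit tone at the 2 kHz analysis rate, 2312 samples."""
    t = np.arange(2312) / 2000.0
    return PCGRecording("tone100", np.sin(2 * np.pi * 100.0 * t), 2000)


@pytest.fixture
def synth_rec():
    return generate_recording("AS", SynthConfig(), rng=np.random.default_rng(3))


@pytest.fixture
def dataset_tree(tmp_path):
    """A tiny on-disk five-class dataset: 3 WAVs per class folder."""
    rng = np.random.default_rng(0)
    for label in CLASSES:
        d = tmp_path / label
        d.mkdir()
        for i in range(3):
            rec = generate_recording(label, SynthConfig(), rng=rng)
            rec.id = f"{label.lower()}_{i}"
            write_wav(rec, d / f"{label.lower()}_{i}.wav")
    return tmp_path
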