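import numpy as np
import pytest

from methylvote.sequence_io import DnaWindow, LabeledDataset


def random_window(rng: np.random.Generator, length: int = 41,
                  alphabet: str = "ACGTN", central_a: bool = False) -> str:
    seq = "".join(rng.choice(list(alphabet), size=length))
    if central_a:
        mid = length // 2
        seq = seq[:mid] + "A" + seq[mid + 1:]
    return seq


def make_dataset(sequences, labels, name="test"):
    windows = [DnaWindow(s, f"w{i}") for i, s in enumerate(sequences)]
    return LabeledDataset(windows, list(labels), name=name)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def fasta_writer(tmp_path):
    """Write raw FASTA text and return the path."""
    def _write(text, name="input.fasta"):
        path = tmp_path / name
        path.write_text(text)
        return path
    return _write
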