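import pytest

from litlang import get_tagger, load_default_banks
from litlang.transcript_io import CleanTranscript, Utterance


@pytest.fixture(scope="session")
def banks():
    return load_default_banks()


@pytest.fixture(scope="session")
def tagger():
    return get_tagger()


@pytest.fixture
def make_ct():
    """Build a CleanTranscript from whitespace-tokenized utterance strings."""

    def _make(*lines: str, transcript_id: str = "t") -> CleanTranscript:
        utts = tuple(
            Utterance(index=i, tokens=tuple(line.split()))
            for i, line in enumerate(lines)
        )
        return CleanTranscript(transcript_id=transcript_id, utterances=utts)

    return _make
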