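import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from speechgraph import Group, build_graph, parse_transcript

#: the dream-report walkthrough: 8 elements, the last two a waking deviation
MINI_TEXT = "I / walked / I / found / I / hugged / [ I / woke ]"


@pytest.fixture
def mini_transcript():
    return parse_transcript(MINI_TEXT, subject_id="demo", group=Group.CONTROL)


@pytest.fixture
def mini_graph(mini_transcript):
    return build_graph(mini_transcript)


def random_transcript(rng: np.random.Generator, max_elements: int = 30):
    """Small random transcript over a tiny alphabet, with deviation spans."""
    n = int(rng.integers(1, max_elements + 1))
    alphabet = [f"w{i}" for i in range(int(rng.integers(1, 7)))]
    parts = []
    in_dev = False
    for _ in range(n):
        if not in_dev and rng.random() < 0.15:
            parts.append("[")
            in_dev = True
        elif in_dev and rng.random() < 0.4:
            parts.append("]")
            in_dev = False
        parts.append(str(rng.choice(alphabet)))
    if in_dev:
        parts.append("]")
    return parse_transcript(" ".join(parts))


@pytest.fixture
def corpus_on_disk(tmp_path):
    """Three tiny transcripts plus a metadata CSV."""
    texts = {
        "s01": "a / b / [ c ]",
        "s02": "x / x / y",
        "s03": "p / q / r / p",
    }
    for sid, text in texts.items():
        (tmp_path / f"{sid}.txt").write_text(text, encoding="utf-8")
    meta = tmp_path / "metadata.csv"
    meta.write_text(
        "subject_id,group,word_count,bprs,panss\n"
        "s01,schizophrenic,10,42,80\n"
        "s02,manic,12,,\n"
        "s03,control,,30,55\n",
        encoding="utf-8",
    )
    return tmp_path, meta
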