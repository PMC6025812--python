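import random

import pytest


@pytest.fixture
def rng():
    return random.Random(42)


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def mutate(rng: random.Random, seq: str, positions: int) -> str:
    """Substitute exactly `positions` distinct sites (never to the same base)."""
    out = list(seq)
    for i in rng.sample(range(len(seq)), positions):
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def write_fastq(path, records, offset=33):
    """records: iterable of (title, seq, quals:list[int])."""
    with open(path, "w") as fh:
        for title, seq, quals in records:
            qual = "".join(chr(offset + q) for q in quals)
            fh.write(f"@{title}\n{seq}\n+\n{qual}\n")
    return path
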