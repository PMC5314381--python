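import numpy as np
import pytest

import hlabind as hb


@pytest.fixture(scope="session")
def scales():
    return hb.default_scales()


@pytest.fixture()
def tiny_dataset():
    """Three alleles, six labelled records, deterministic."""
    alleles = {
        f"A*{i:02d}": hb.ProteinSequence(f"A*{i:02d}", seq)
        for i, seq in enumerate(
            ["ACDEFGHIKLMNPQRSTVWY" * 3, "ACDEFGHIKLMNPQRSTVWY" * 2 + "AAAAA" * 4,
             "MKTAYIAKQRQISFVKSHFS" * 3]
        )
    }
    rows = [
        ("A*00", "LLFGYPVYV", 30.0),
        ("A*01", "LFGYPVYVK", 51.0),
        ("A*02", "ACDEFGHIK", 12.0),
        ("A*00", "KLMNPQRST", 500.0),
        ("A*01", "VVVVVVVV", 50.0),
        ("A*02", "YYYYYYYYYY", 2000.0),
    ]
    records = [
        hb.InteractionRecord(a, p, c, hb.label_affinity(c)) for a, p, c in rows
    ]
    return hb.Dataset(alleles=alleles, records=records)


def random_peptides(rng: np.random.Generator, n: int, lengths=(5, 30)) -> list[str]:
    letters = np.array(list(hb.ALPHABET))
    out = []
    for _ in range(n):
        L = rng.integers(lengths[0], lengths[1] + 1)
        out.append("".join(letters[rng.integers(0, 20, size=L)]))
    return out
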