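import pytest

from irscan import build_database, standard_fixture, summary_demo_fixture


@pytest.fixture(scope="session")
def std_fixture():
    """One 20 kb study fixture: genome, transcripts, expected records, plants."""
    return standard_fixture(1)


@pytest.fixture(scope="session")
def std_db(std_fixture):
    genome, transcripts, _, _ = std_fixture
    return build_database(genome, transcripts, kmin=7, kmax=12)


@pytest.fixture(scope="session")
def demo():
    """The deterministic 50 kb demo gene and its built database."""
    genome, transcripts = summary_demo_fixture()
    db = build_database(genome, transcripts, kmin=7, kmax=20)
    return genome, transcripts, db


def naive_pairs(seq, k, max_spacer, allow_mismatch):
    """Minimal pure-python enumeration of repeat pairs, for tiny inputs only.

    Independent of both the production pairing and the vectorized oracle.
    """
    limit = 1 if allow_mismatch else 0
    n = len(seq)
    out = []
    for s1 in range(n - k + 1):
        w1 = seq[s1 : s1 + k]
        if "N" in w1:
            continue
        for s2 in range(s1 + k, min(n - k, s1 + k + max_spacer) + 1):
            w2 = seq[s2 : s2 + k]
            if "N" in w2:
                continue
            mism = sum(a != b for a, b in zip(w1, w2))
            if mism <= limit:
                out.append((s1, s2, mism))
    return out
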