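import numpy as np
import pytest

BASES = "ACGT"


def random_seq(rng, n):
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def nonrepetitive_seq(rng, n, avoid_motifs=(), min_span=6):
    """Random sequence screened to contain no short pure-repeat run and not to
    start/end with any motif we are about to place next to it."""
    from trtruth.catalog import scan_pure_repeats

    for _ in range(300):
        s = random_seq(rng, n)
        if scan_pure_repeats(s, min_motif=1, max_motif=8, min_span_bp=min_span):
            continue
        if any(m and (s.startswith(m) or s.endswith(m)) for m in avoid_motifs):
            continue
        return s
    raise RuntimeError("could not build a non-repetitive flank")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def make_tract_contig(rng, motif, ref_copies, left=40, right=40):
    """Contig = screened flank + motif*ref_copies + screened flank.

    Returns (sequence, tract_start0). The screening guarantees the planted
    tract is the only motif run adjacent to its boundaries.
    """
    lf = nonrepetitive_seq(rng, left, avoid_motifs=[motif])
    rf = nonrepetitive_seq(rng, right, avoid_motifs=[motif])
    return lf + motif * ref_copies + rf, len(lf)
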