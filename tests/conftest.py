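from __future__ import annotations

import numpy as np
import pytest

from vcmap import ReferenceSet, build_index


def random_refs(rng: np.random.Generator, lengths: list[int]) -> ReferenceSet:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    seqs = [bases[rng.integers(0, 4, L)].tobytes().decode() for L in lengths]
    return ReferenceSet([f"chr{i}" for i in range(len(lengths))], seqs)


@pytest.fixture(scope="session")
def small_refs() -> ReferenceSet:
    """5 kb two-reference genome with a duplicated segment and an N gap."""
    rng = np.random.default_rng(42)
    refs = random_refs(rng, [3000, 2000])
    s0 = list(refs.seqs[0])
    s1 = list(refs.seqs[1])
    s1[500:700] = s0[1000:1200]          # cross-reference duplication
    s0[2500:2520] = ["N"] * 20           # N gap splits chr0 into contigs
    return ReferenceSet(refs.names, ["".join(s0), "".join(s1)])


@pytest.fixture(scope="session")
def small_index(small_refs) -> "object":
    return build_index(small_refs, 15, verify=True)
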