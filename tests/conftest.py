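"""Shared fixtures: a small synthetic community and trained profiles."""

import numpy as np
import pytest

from ssutag import profiles as profiles_mod
from ssutag import synthetic
from ssutag.profiles import AlignedReference, RecognitionProfile


@pytest.fixture(scope="session")
def small_spec():
    return synthetic.CommunitySpec(n_taxa=12, seed=7, n_reads=3000)


@pytest.fixture(scope="session")
def small_ref(small_spec):
    return synthetic.make_reference(small_spec,
                                    np.random.default_rng(small_spec.seed))


@pytest.fixture(scope="session")
def v4_profile(small_ref):
    return profiles_mod.build_profile(small_ref, "V4")


def uniform_alignment(seqs, region_map=None, lineages=None):
    """AlignedReference from raw sequences with placeholder lineages."""
    n = len(seqs)
    if lineages is None:
        lineages = [("Bacteria", f"P{i % 2}", "", "", "", "", "")
                    for i in range(n)]
    records = [(f"s{i}", s, tuple(lin))
               for i, (s, lin) in enumerate(zip(seqs, lineages))]
    return AlignedReference(records=records, region_map=region_map or {})


def toy_profile(rs: str, tag_length: int = 33, long_length: int = 60,
                threshold: float = 30.0, side: str = "upstream",
                region: str = "V4", pid: str = "toy") -> RecognitionProfile:
    """Hand-built profile: +2 bits for each consensus base, -5 else."""
    assert len(rs) == 23
    pssm = np.full((23, 4), -5.0)
    for i, b in enumerate(rs):
        pssm[i, "ACGT".index(b)] = 2.0
    return RecognitionProfile(
        profile_id=pid, target_region=region, target_domain="bacteria",
        side=side, pssm=pssm, probe_pattern=rs[:8], probe_offset=0,
        score_threshold=threshold, tag_length=tag_length,
        long_length=long_length)


RS23 = "GATTACAGGCTTCAAGCGTTCAG"
TAG33 = "CCTGAGTTATAACGGAGCTTAAGCATTCCGTAT"
assert len(RS23) == 23 and len(TAG33) == 33
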