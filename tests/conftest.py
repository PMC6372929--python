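"""Shared fixtures: small synthetic databases and one shared mapped run.

Everything is generated programmatically with fixed seeds; the heavier
simulate-and-map fixtures are session-scoped so several test modules can
share one mapping.
"""

from types import SimpleNamespace

import pytest

import rrnmap as rm
from rrnmap import simulate as S


@pytest.fixture(scope="session")
def rrn_db8():
    """8 rrn-operon species; species00/species01 are the ~97% close pair."""
    return S.synthesize_reference_set(8, "rrn", seed=101)


@pytest.fixture(scope="session")
def rrn_db_decoys(rrn_db8):
    """The 8 species plus one ~97% decoy relative for each."""
    return S.add_close_relatives(rrn_db8, rrn_db8.species, 0.97, seed=202)


@pytest.fixture(scope="session")
def s16_db6():
    """6 full-length-16S species with the designated close pair."""
    return S.synthesize_reference_set(6, "16S", seed=303)


@pytest.fixture(scope="session")
def even_rrn_run(rrn_db8, rrn_db_decoys):
    """Even 8-species rrn community (n=400, 5% chimeras, 5% short fragments)
    simulated and pushed through the full pipeline against the decoy-salted DB."""
    design = S.even_design(rrn_db8.species, 400, "rrn")
    reads, truth = S.simulate_reads(
        rrn_db8, design, chimera_rate=0.05, short_fragment_rate=0.05, seed=7
    )
    res = rm.run_reads(reads, rrn_db_decoys)
    return SimpleNamespace(
        reads=reads, truth=truth, res=res, design=design, db=rrn_db_decoys
    )
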