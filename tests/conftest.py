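"""Shared fixtures: one simulated scenario reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from retroscope.annotate import call_element, default_library, find_ltr_elements
from retroscope.origin import ElementIndex
from retroscope.simkit import (SimConfig, simulate_genome, simulate_reads,
                               truth_transcript)
from retroscope.transcript import SplicedMapper, model_from_sequence


@pytest.fixture(scope="session")
def library():
    return default_library()


@pytest.fixture(scope="session")
def scenario(library):
    """A 300 kb genome with the default element census, fully annotated."""
    cfg = SimConfig(seed=1, genome_length=300_000)
    genome, truth = simulate_genome(cfg)
    elements = find_ltr_elements(genome)
    calls = {e.element_id: call_element(e, genome, library) for e in elements}
    index = ElementIndex([(e, calls[e.element_id]) for e in elements])
    mapper = SplicedMapper(genome)
    return {
        "config": cfg,
        "genome": genome,
        "truth": truth,
        "elements": elements,
        "calls": calls,
        "index": index,
        "mapper": mapper,
    }


@pytest.fixture(scope="session")
def truth_models(scenario, library):
    """Transcript models built from the noiseless truth transcripts
    (exercises the spliced mapper and the domain scanner, not the read
    clustering)."""
    models = {}
    for te in scenario["truth"]:
        tx = truth_transcript(scenario["genome"], te)
        m = model_from_sequence(te.element_id, tx, scenario["mapper"], library)
        assert m is not None
        models[te.element_id] = m
    return models


@pytest.fixture(scope="session")
def read_scenario(scenario):
    """Per-sample simulated long reads for the session scenario."""
    reads = simulate_reads(scenario["genome"], scenario["truth"], scenario["config"])
    per_sample = {s: [(rid, seq) for rid, seq, _q in rs] for s, rs in reads.items()}
    allreads = [r for rs in per_sample.values() for r in rs]
    return {"per_sample": per_sample, "all": allreads, "sequences": dict(allreads)}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
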