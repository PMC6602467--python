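"""Shared fixtures: the default synthetic plastome is generated once per
session (it is deterministic for a given seed) and reused everywhere."""

from __future__ import annotations

import random

import pytest

from plastann.fixtures import generate_plastome
from plastann.genome_model import Plastome
from plastann.reference_db import load_reference


@pytest.fixture(scope="session")
def truth7():
    return generate_plastome(7)


@pytest.fixture(scope="session")
def fixture_paths(truth7, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("fixture7")
    paths = truth7.write(str(outdir))
    pa, pb = truth7.write_trna_predictions(str(outdir))
    paths["trna_a"] = pa
    paths["trna_b"] = pb
    return paths


@pytest.fixture(scope="session")
def db7(fixture_paths):
    return load_reference([fixture_paths["reference"]])


@pytest.fixture(scope="session")
def annotation7(truth7, db7):
    from plastann.annotate_core import annotate_genome

    return annotate_genome(truth7.genome, db7)


def random_genome(seed: int, length: int, genome_id: str = "rand") -> Plastome:
    rng = random.Random(seed)
    return Plastome(
        id=genome_id,
        sequence="".join(rng.choice("ACGT") for _ in range(length)),
    )
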