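"""Shared fixtures: small ideal-geometry peptides and their contexts."""

from __future__ import annotations

import numpy as np
import pytest

from fcrfrag.bench import FixtureSpec, build_polypeptide
from fcrfrag.pipeline import FragmentationContext, prepare


@pytest.fixture(scope="session")
def dipeptide_ala():
    return build_polypeptide(FixtureSpec("AA", "extended", seed=1))


@pytest.fixture(scope="session")
def dipeptide_gly():
    return build_polypeptide(FixtureSpec("GG", "extended", seed=1))


@pytest.fixture(scope="session")
def tripeptide_ala():
    return build_polypeptide(FixtureSpec("AAA", "extended", seed=1))


@pytest.fixture(scope="session")
def pentapeptide():
    return build_polypeptide(FixtureSpec("GAKAG", "coil", seed=2))


@pytest.fixture(scope="session")
def cys_bridge():
    return build_polypeptide(FixtureSpec("CC", "extended", ((0, 1),), seed=3))


@pytest.fixture(scope="session")
def proline_peptide():
    return build_polypeptide(FixtureSpec("APA", "extended", seed=1))


@pytest.fixture(scope="session")
def single_gly():
    return build_polypeptide(FixtureSpec("G", "extended", seed=1))


def _ctx_cache():
    cache: dict[int, FragmentationContext] = {}

    def get(structure) -> FragmentationContext:
        key = id(structure)
        if key not in cache:
            cache[key] = prepare(structure)
        return cache[key]

    return get


@pytest.fixture(scope="session")
def ctx_of():
    """Callable mapping a structure to its (cached) fragmentation context."""
    return _ctx_cache()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
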