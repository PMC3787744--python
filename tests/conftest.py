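"""Shared fixtures: small deterministic domains and superfamilies."""

from __future__ import annotations

import numpy as np
import pytest

from siteplast import DomainStructure, ResidueRef, make_template


def make_domain(domain_id: str, coords, sequence: str | None = None,
                chain: str = "A", superfamily_id: str = "SF") -> DomainStructure:
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    seq = sequence or "A" * n
    refs = [ResidueRef(chain, i + 1, "") for i in range(n)]
    return DomainStructure(domain_id, refs, seq, coords,
                           superfamily_id=superfamily_id)


@pytest.fixture(scope="session")
def template120() -> DomainStructure:
    return make_template(120, seed_or_rng=2024)


@pytest.fixture(scope="session")
def template60() -> DomainStructure:
    return make_template(60, seed_or_rng=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
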