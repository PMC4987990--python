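"""Shared fixtures: every test input is generated programmatically."""

from __future__ import annotations

import pytest

from alnkit.fixtures import FixtureSpec, write_fixture


@pytest.fixture
def small_fixture(tmp_path):
    """A default-sized on-disk fixture: ref.fa + reads.sam + reads.bam."""
    return write_fixture(tmp_path / "fx", FixtureSpec(seed=11, n_reads=300))


@pytest.fixture
def fixture_factory(tmp_path):
    """Callable producing an on-disk fixture for an arbitrary spec."""
    counter = {"n": 0}

    def make(spec: FixtureSpec):
        counter["n"] += 1
        return write_fixture(tmp_path / f"fx{counter['n']}", spec)

    return make
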