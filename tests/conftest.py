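"""Shared fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from bacsim.oracle import forced_import_arg as build_forced_import_arg  # noqa: F401


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
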