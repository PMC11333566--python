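from __future__ import annotations

import numpy as np
import pytest

from phaseprep.panel_io import HaplotypePanel, SiteMeta, TargetGenotypes


def make_panel(rows: np.ndarray) -> HaplotypePanel:
    rows = np.asarray(rows, dtype=np.uint8)
    sites = [SiteMeta("1", 100 * (m + 1), "A", "G") for m in range(rows.shape[0])]
    return HaplotypePanel(rows=rows, sites=sites)


def make_target(classes: str) -> TargetGenotypes:
    """Build a target from a per-site class string: 0=hom-ref, 2=hom-alt, h=het, .=missing."""
    is0 = np.array([c == "0" for c in classes], dtype=np.uint8)
    is2 = np.array([c == "2" for c in classes], dtype=np.uint8)
    missing = np.array([c == "." for c in classes], dtype=np.uint8)
    het = np.array([c == "h" for c in classes], dtype=np.uint8)
    return TargetGenotypes(is0=is0, is2=is2, missing=missing, call=het)


def random_target(m: int, rng: np.random.Generator) -> TargetGenotypes:
    """Random partition of m sites into hom-ref / hom-alt / het / missing."""
    cls = rng.choice(np.array(list("02h.")), size=m, p=[0.35, 0.35, 0.2, 0.1])
    return make_target("".join(cls))


@pytest.fixture
def rng():
    return np.random.default_rng(20240730)
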