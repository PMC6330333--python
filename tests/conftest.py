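"""Shared fixtures.

Heavy end-to-end pipeline runs are session-scoped so the density sweep and
the distribution fixture are generated and analyzed once for the whole suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from mctrace.pipeline import run_synthetic, true_counts_by_section
from mctrace.synthetic import preset


def three_population_image(shape=(256, 256), tissue=(50.0, 5.0),
                           soma=(200.0, 10.0), n_cells=30, seed=1):
    """Background 0, elliptical tissue at ``tissue`` mean/sd, flat-core somata
    at ``soma`` mean/sd.  Returns (uint8 image, tissue mask, soma centers)."""
    rng = np.random.default_rng(seed)
    img = np.zeros(shape)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    cy, cx = shape[0] / 2, shape[1] / 2
    mask = ((yy - cy) ** 2 / (0.39 * shape[0]) ** 2
            + (xx - cx) ** 2 / (0.31 * shape[1]) ** 2) <= 1
    img[mask] = rng.normal(tissue[0], tissue[1], mask.sum())
    centers = []
    while len(centers) < n_cells:
        r, c = rng.integers(10, shape[0] - 10), rng.integers(10, shape[1] - 10)
        if not mask[r, c]:
            continue
        if any((r - r0) ** 2 + (c - c0) ** 2 < 64 for r0, c0 in centers):
            continue  # keep somata separated: recovery fixtures are overlap-free
        d = np.sqrt((yy - r) ** 2.0 + (xx - c) ** 2.0)
        prof = np.where(d <= 1.6, 1.0, np.exp(-0.5 * ((d - 1.6) / 0.6) ** 2))
        img = np.maximum(img, rng.normal(soma[0], soma[1]) * prof)
        centers.append((r, c))
    return np.clip(np.rint(img), 0, 255).astype(np.uint8), mask, centers


@pytest.fixture(scope="session")
def fig3_run():
    """Full pipeline over the density sweep; reused by several tests."""
    spec = preset("fig3_density_sweep")
    result = run_synthetic(spec, align=False)
    true_counts = true_counts_by_section(result.truth, spec.n_sections)
    return result, true_counts


@pytest.fixture(scope="session")
def fig5_run():
    spec = preset("fig5_distribution")
    return run_synthetic(spec, align=False)
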