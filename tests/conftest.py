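"""Shared fixtures: synthetic scenes used across the test modules."""

from __future__ import annotations

import numpy as np
import pytest

from chemoreflex import synthgen


def make_separated_cells(
    rng: np.random.Generator,
    n: int,
    height: int,
    width: int,
    freq_range: tuple[float, float] = (0.15, 0.35),
    min_dist: float = 12.0,
    amplitude: float = 0.4,
    jitter_sd: float = 0.05,
) -> tuple[synthgen.CellSpec, ...]:
    """Cells at mutually distant centers with evenly spread frequencies."""
    centers: list[tuple[float, float]] = []
    while len(centers) < n:
        r = 8 + (height - 16) * rng.random()
        c = 8 + (width - 16) * rng.random()
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_dist**2 for r0, c0 in centers):
            centers.append((r, c))
    freqs = np.linspace(*freq_range, n)
    return tuple(
        synthgen.CellSpec(
            center=ct,
            radius=2.0,
            burst_frequency=float(f),
            burst_amplitude=amplitude,
            burst_decay_tau=1.0,
            jitter_sd=jitter_sd,
            phase=float(5 * rng.random()),
        )
        for ct, f in zip(centers, freqs)
    )


@pytest.fixture(scope="session")
def twenty_cell_movie():
    """The standard end-to-end recovery scene: 20 in-band cells, fixed seed."""
    rng = np.random.default_rng(7)
    cells = make_separated_cells(rng, 20, 128, 128)
    spec = synthgen.MovieSpec(
        height=128, width=128, n_frames=1800, cells=cells, noise_sd=1.0, seed=2
    )
    stack, gt = synthgen.generate_calcium_movie(spec)
    return spec, stack, gt
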