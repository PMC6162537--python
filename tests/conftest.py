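"""Shared helpers: cached synthetic cells so expensive renders are reused."""

from __future__ import annotations

from dataclasses import replace
from functools import lru_cache

from laminatlas.nucseg import decompose_lamin, segment_nucleus
from laminatlas.synthgen import CellSpec, render_cell, spec_for_pattern

ALL_PATTERNS = ("H0", "HA", "HB", "HC", "HD", "RS2", "RS3", "RS4", "RSmulti")


@lru_cache(maxsize=64)
def rendered(pattern: str, seed: int = 0, noiseless: bool = False, **overrides):
    """Render one canonical cell (cached across tests)."""
    spec = spec_for_pattern(pattern, CellSpec(), **overrides)
    if noiseless:
        spec = replace(spec, noise_poisson_scale=0.0, noise_gaussian_sd=0.0)
    return render_cell(spec, seed=seed)


@lru_cache(maxsize=64)
def analyzed(pattern: str, seed: int = 0, noiseless: bool = False):
    """Render + segment + decompose one canonical cell (cached)."""
    stack, truth = rendered(pattern, seed, noiseless)
    seg = segment_nucleus(stack["DAPI"], stack["LAMIN"])
    dec = decompose_lamin(stack["LAMIN"], seg)
    return stack, truth, seg, dec
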