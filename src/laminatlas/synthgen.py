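"""Synthetic 3D nuclei with known ground truth.

The generator renders multi-channel z-stacks emulating the imaging study
conditions: mononuclear Hodgkin (H) nuclei whose lamin A/C shell is
subdivided by 0-3 internal septa, and bi- to multi-lobed Reed-Sternberg
(RS) nuclei in which every lobe carries its own complete lamin shell.
Each cell also carries a DAPI texture with DNA-free cavities of a
controllable size distribution and telomere spots with a controllable
lamin-overlap fraction.  Every stochastic choice is driven by a single
seed, and the pre-blur geometry is emitted as ground truth.

Geometry model
--------------
* A lobe is an ellipsoid with physical semi-axes ``(az, ay, ax)`` µm; its
  shell is the region between the ellipsoid and a copy shrunk by
  ``shell_thickness``.
* Internal septa are slabs of thickness ``septum_thickness`` perpendicular
  to one randomly oriented unit normal, evenly offset so that ``k`` septa
  cut a lobe interior into exactly ``k + 1`` connected compartments.
* Partial septa (the "short internal structures" of pattern A) are the
  same slabs restricted to one side of the lobe, so they add internal
  lamin without dividing the interior.
* Accumulation points are bright lamin blobs placed just beneath the
  shell; they count as internal structure.
* Multi-lobed nuclei are rows of lobes whose outer surfaces barely
  overlap, keeping the nucleus one connected body while the lobe interiors
  stay separate.

The rendered lamin channel is shell + septa + accumulation blobs, blurred
by a separable anisotropic Gaussian PSF, with Poisson photon noise and
additive Gaussian read noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from laminatlas.imgio import DEFAULT_VOXEL_SIZE, CellStack, VoxelGrid

__all__ = [
    "CellSpec",
    "SynthTruth",
    "render_cell",
    "sample_population",
    "spec_for_pattern",
    "calibrate_internal_brightness",
]

#: H-family pattern -> number of interior compartments of the single lobe.
H_COMPARTMENTS = {"H0": 1, "HA": 1, "HB": 2, "HC": 3, "HD": 4}
#: RS-family pattern -> lobe count.
RS_LOBES = {"RS2": 2, "RS3": 3, "RS4": 4, "RSmulti": 5}


@dataclass
class CellSpec:
    """Full parameterisation of one synthetic cell.

    Lengths are µm, intensities arbitrary units (the study's acquisitions
    carry no intensity calibration).  ``septum_brightness`` and
    ``accumulation_brightness`` are relative to ``shell_brightness``.
    """

    pattern: str = "H0"
    n_lobes: int = 1
    n_compartments: int = 1
    n_partial_septa: int = 0
    semi_axes: tuple[float, float, float] = (2.0, 2.6, 2.6)
    shell_thickness: float = 0.30
    septum_thickness: float = 0.30
    septum_brightness: float = 1.0
    #: lamin density of inter-lobe walls relative to the single envelope
    wall_brightness: float = 1.0
    shell_brightness: float = 200.0
    n_accumulation_points: int = 2
    accumulation_brightness: float = 2.0
    accumulation_radius: float = 0.25
    n_telomeres: int = 0
    telomere_intensity: float = 500.0
    telomere_sigma: tuple[float, float, float] = (0.18, 0.11, 0.11)
    #: minimum pairwise spot separation (µm); keep above the two-point
    #: resolution limit (~2 apparent axial sigma) so planted spots remain
    #: individually detectable; best-effort when the geometry is crowded
    telomere_min_separation: float = 0.8
    coloc_fraction: float = 0.0
    aggregate_fraction: float = 0.0
    free_space_means: tuple[float, float] = (0.30, 0.55)
    free_space_sds: tuple[float, float] = (0.05, 0.08)
    free_space_weights: tuple[float, float] = (0.5, 0.5)
    n_cavities: int = 25
    dna_brightness: float = 150.0
    psf_sigma: tuple[float, float, float] = (0.25, 0.12, 0.12)
    noise_poisson_scale: float = 1.0
    noise_gaussian_sd: float = 2.0
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE

    def __post_init__(self) -> None:
        if self.n_lobes < 1 or self.n_compartments < 1:
            raise ValueError("n_lobes and n_compartments must be >= 1")
        if any(a <= 0 for a in self.semi_axes):
            raise ValueError("semi_axes must be positive")
        for name in ("coloc_fraction", "aggregate_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_compartments % self.n_lobes != 0:
            raise ValueError(
                "n_compartments must be n_lobes * (compartments per lobe); "
                f"got {self.n_compartments} for {self.n_lobes} lobes"
            )
        if self.pattern in H_COMPARTMENTS:
            if self.n_lobes != 1:
                raise ValueError(f"H pattern {self.pattern} requires a single lobe")
            if self.n_compartments != H_COMPARTMENTS[self.pattern]:
                raise ValueError(
                    f"pattern {self.pattern} implies {H_COMPARTMENTS[self.pattern]} "
                    f"compartments, got {self.n_compartments}"
                )
        elif self.pattern in RS_LOBES:
            want = RS_LOBES[self.pattern]
            ok = self.n_lobes >= 5 if self.pattern == "RSmulti" else self.n_lobes == want
            if not ok:
                raise ValueError(f"pattern {self.pattern} implies {want}+ lobes")

    @property
    def septa_per_lobe(self) -> int:
        return self.n_compartments // self.n_lobes - 1


@dataclass
class SynthTruth:
    """Ground truth emitted with each rendered cell (pre-blur geometry)."""

    nucleus_mask: VoxelGrid
    lobe_labels: VoxelGrid
    shell_mask: VoxelGrid
    internal_mask: VoxelGrid
    compartment_labels: VoxelGrid
    dna_mask: VoxelGrid
    free_space_mask: VoxelGrid
    telomere_centres: np.ndarray          # (n, 3) physical (z, y, x) µm
    telomere_coloc: np.ndarray            # (n,) bool, spot placed on internal lamin
    telomere_aggregate: np.ndarray        # (n,) bool, spot in a sub-resolution cluster
    true_Ie: float
    true_Ii: float
    spec: CellSpec
    seed: int

    @property
    def realized_coloc_fraction(self) -> float:
        """Realized (not target) fraction of spots on internal lamin."""
        if self.telomere_coloc.size == 0:
            return float("nan")
        return float(self.telomere_coloc.mean())

    @property
    def n_compartments(self) -> int:
        labels = np.unique(self.compartment_labels.data)
        return int((labels > 0).sum())


def spec_for_pattern(pattern: str, base: CellSpec | None = None, **overrides) -> CellSpec:
    """Canonical :class:`CellSpec` for one taxonomy label.

    H0 carries only accumulation points, HA one partial septum, HB/HC/HD
    1/2/3 full septa; RS cells get 2/3/4/5 lobes each with a partial
    septum (internal lamin features are present in RS lobes too).
    """
    base = base or CellSpec()
    if pattern in H_COMPARTMENTS:
        kw = dict(
            pattern=pattern,
            n_lobes=1,
            n_compartments=H_COMPARTMENTS[pattern],
            n_partial_septa=1 if pattern == "HA" else 0,
        )
    elif pattern in RS_LOBES:
        n = RS_LOBES[pattern]
        kw = dict(pattern=pattern, n_lobes=n, n_compartments=n, n_partial_septa=1)
    else:
        raise ValueError(f"unknown pattern label {pattern!r}")
    kw.update(overrides)
    return replace(base, **kw)


# ---------------------------------------------------------------------------
# geometry helpers

def _grid(spec: CellSpec):
    """Physical coordinate vectors and lobe centres for the cell's bounding grid."""
    az, ay, ax = spec.semi_axes
    dz, dy, dx = spec.voxel_size
    pad = 0.5 + 2.0 * max(spec.psf_sigma)
    spacing = 2.0 * ay * 0.97            # lobes along y, barely overlapping
    ylen = spacing * (spec.n_lobes - 1) + 2 * ay + 2 * pad
    zlen, xlen = 2 * az + 2 * pad, 2 * ax + 2 * pad
    shape = (int(math.ceil(zlen / dz)) + 1,
             int(math.ceil(ylen / dy)) + 1,
             int(math.ceil(xlen / dx)) + 1)
    zc = np.arange(shape[0]) * dz - zlen / 2
    yc = np.arange(shape[1]) * dy - ylen / 2
    xc = np.arange(shape[2]) * dx - xlen / 2
    centres = [(0.0, yc[0] + pad + ay + i * spacing, 0.0) for i in range(spec.n_lobes)]
    return (zc, yc, xc), shape, centres


def _ellipsoid_q(coords, centre, semi_axes) -> np.ndarray:
    """Quadratic form ((p-c)/s)^2 summed; <= 1 inside the ellipsoid."""
    zc, yc, xc = coords
    az, ay, ax = semi_axes
    q = (((zc - centre[0]) / az) ** 2)[:, None, None] \
        + (((yc - centre[1]) / ay) ** 2)[None, :, None] \
        + (((xc - centre[2]) / ax) ** 2)[None, None, :]
    return q


def _support_radius(normal: np.ndarray, semi_axes: Sequence[float]) -> float:
    """Half-extent of the ellipsoid along a unit direction."""
    return float(np.sqrt(np.sum((np.asarray(semi_axes) * normal) ** 2)))


def _random_unit_vector(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    n = np.linalg.norm(v)
    while n < 1e-9:            # pragma: no cover - measure-zero
        v = rng.normal(size=3)
        n = np.linalg.norm(v)
    return v / n


def _random_lateral_normal(rng: np.random.Generator) -> np.ndarray:
    """Random unit normal in the lateral (y, x) plane.

    Septa are modelled perpendicular to the focal plane: the axial PSF is
    about twice as wide as the lateral one, and only laterally oriented
    slabs stay resolvable between close neighbours.
    """
    phi = rng.uniform(0.0, 2.0 * np.pi)
    return np.array([0.0, np.cos(phi), np.sin(phi)])


def _projection(coords, centre, normal) -> np.ndarray:
    zc, yc, xc = coords
    return ((zc - centre[0]) * normal[0])[:, None, None] \
        + ((yc - centre[1]) * normal[1])[None, :, None] \
        + ((xc - centre[2]) * normal[2])[None, None, :]


def _ball_mask(coords, centre, radius) -> np.ndarray:
    return _ellipsoid_q(coords, centre, (radius, radius, radius)) <= 1.0


# ---------------------------------------------------------------------------
# rendering

def render_cell(spec: CellSpec, seed: int) -> tuple[CellStack, SynthTruth]:
    """Render one cell; identical ``(spec, seed)`` give bit-identical output.

    Returns the noisy, PSF-blurred :class:`CellStack` (channels DAPI,
    LAMIN, and TELO when ``n_telomeres > 0``) together with the
    pre-blur :class:`SynthTruth`.
    """
    rng = np.random.default_rng(seed)
    coords, shape, centres = _grid(spec)
    vs = spec.voxel_size
    az, ay, ax = spec.semi_axes
    t = spec.shell_thickness
    if min(spec.semi_axes) <= t + 2 * max(vs):
        raise ValueError("semi_axes too small for the requested shell thickness")
    inner_axes = (az - t, ay - t, ax - t)

    nucleus = np.zeros(shape, bool)
    shell = np.zeros(shape, bool)
    inner = np.zeros(shape, bool)
    q_all = np.full(shape, np.inf)
    lobe_labels = np.zeros(shape, np.int32)
    septa = np.zeros(shape, bool)
    k_full = spec.septa_per_lobe

    for i, c in enumerate(centres):
        q = _ellipsoid_q(coords, c, spec.semi_axes)
        out_i = q <= 1.0
        in_i = _ellipsoid_q(coords, c, inner_axes) <= 1.0
        nucleus |= out_i
        inner |= in_i
        shell |= out_i & ~in_i
        closer = out_i & (q < q_all)
        q_all[closer] = q[closer]
        lobe_labels[closer] = i + 1

        normal = _random_lateral_normal(rng)
        r_n = _support_radius(normal, inner_axes)
        min_gap = 2.0 * max(vs)
        if k_full and k_full * spec.septum_thickness + (k_full + 1) * min_gap > 2 * r_n:
            raise ValueError(
                f"{k_full} septa of thickness {spec.septum_thickness} µm cannot "
                f"realize {spec.n_compartments} compartments inside semi-axes "
                f"{spec.semi_axes}"
            )
        proj = _projection(coords, c, normal) if (k_full or spec.n_partial_septa) else None
        for j in range(k_full):
            off = r_n * (2.0 * (j + 1) / (k_full + 1) - 1.0)
            septa |= in_i & (np.abs(proj - off) <= spec.septum_thickness / 2)
        if spec.n_partial_septa:
            # partial slab hugging one side: adds internal lamin volume
            # without disconnecting the interior
            side = _random_unit_vector(rng)
            side -= normal * (side @ normal)
            nrm = np.linalg.norm(side)
            side = side / nrm if nrm > 1e-6 else np.array([0.0, 0.0, 1.0])
            lateral = _projection(coords, c, side)
            r_s = _support_radius(side, inner_axes)
            for _ in range(spec.n_partial_septa):
                septa |= (in_i & (np.abs(proj) <= spec.septum_thickness / 2)
                          & (lateral >= 0.35 * r_s))

    shell &= ~septa  # septa take precedence where shrunk lobes overlap

    # accumulation blobs beneath the shell, clear of the shell layer
    acc = np.zeros(shape, bool)
    depth_in = spec.accumulation_radius + t + 0.45
    for i, c in enumerate(centres):
        for _ in range(spec.n_accumulation_points):
            u = _random_unit_vector(rng)
            r_u = _support_radius(u, spec.semi_axes)
            pos = np.asarray(c) + u * max(r_u - depth_in, 0.0)
            acc |= _ball_mask(coords, pos, spec.accumulation_radius)
    acc &= inner & ~shell

    internal = septa | acc

    # compartments: interiors minus septa (accumulation blobs never divide)
    comp_open = inner & ~septa
    compartments, _ = ndimage.label(comp_open, structure=np.ones((3, 3, 3), bool))
    n_comp = compartments.max()
    if n_comp != spec.n_compartments:
        raise ValueError(
            f"septum geometry realized {n_comp} compartments, "
            f"spec demands {spec.n_compartments}"
        )

    # ---- DNA and DNA-free cavities -------------------------------------
    free = np.zeros(shape, bool)
    inner_idx = np.argwhere(inner)
    if spec.n_cavities and inner_idx.size:
        picks = inner_idx[rng.integers(0, len(inner_idx), spec.n_cavities)]
        comp_choice = rng.random(spec.n_cavities) < spec.free_space_weights[0]
        means = np.where(comp_choice, spec.free_space_means[0], spec.free_space_means[1])
        sds = np.where(comp_choice, spec.free_space_sds[0], spec.free_space_sds[1])
        radii = np.clip(rng.normal(means, sds), 0.08, None)
        for (iz, iy, ix), r in zip(picks, radii):
            pos = (coords[0][iz], coords[1][iy], coords[2][ix])
            free |= _ball_mask(coords, pos, r)
    free &= inner
    dna = inner & ~free

    # ---- telomere spots -------------------------------------------------
    n_telo = spec.n_telomeres
    telo_centres = np.zeros((n_telo, 3))
    telo_coloc = np.zeros(n_telo, bool)
    telo_agg = np.zeros(n_telo, bool)
    telo_img = np.zeros(shape, np.float64)
    if n_telo:
        telo_coloc[:] = rng.random(n_telo) < spec.coloc_fraction
        if not internal.any():
            telo_coloc[:] = False
        on_idx = np.argwhere(internal) if internal.any() else inner_idx
        # a spot is only genuinely non-colocalized if it clears the
        # structure's apparent (post-PSF) footprint: half-width after
        # blurring (~0.5 µm) plus the spot's own apparent radius
        # (~0.35 µm), one voxel of gate dilation and a noise margin
        off_candidates = inner & ~internal
        if internal.any():
            # EDT threshold == dilation by the closed 1.25 um ball, but
            # much cheaper than an explicit structuring element this size
            d_int = ndimage.distance_transform_edt(~internal, sampling=vs)
            off_candidates &= d_int > 1.25 + 1e-9
        off_idx = np.argwhere(off_candidates)
        if off_idx.size == 0:
            off_idx = inner_idx
        min_sep = spec.telomere_min_separation
        placed = np.zeros((0, 3))
        for s in range(n_telo):
            pool = on_idx if telo_coloc[s] else off_idx
            for _attempt in range(200):
                iz, iy, ix = pool[rng.integers(0, len(pool))]
                pos = np.array([coords[0][iz], coords[1][iy], coords[2][ix]])
                pos += (rng.random(3) - 0.5) * np.asarray(vs) * 0.5
                if not placed.size or \
                        np.linalg.norm(placed - pos, axis=1).min() >= min_sep:
                    break
            placed = np.vstack([placed, pos])
            telo_centres[s] = pos
        # sub-resolution clusters: convert pairs of non-coloc spots into
        # aggregates by snapping the second member next to the first
        n_pairs = int(round(spec.aggregate_fraction * n_telo / 2.0))
        for p in range(n_pairs):
            a, b = 2 * p, 2 * p + 1
            if b >= n_telo:
                break
            offset = _random_unit_vector(rng) * 0.15
            telo_centres[b] = telo_centres[a] + offset
            telo_coloc[b] = telo_coloc[a]
            telo_agg[a] = telo_agg[b] = True
        for s in range(n_telo):
            _add_gaussian_spot(telo_img, coords, telo_centres[s],
                               spec.telomere_sigma, spec.telomere_intensity)

    # ---- intensity images ----------------------------------------------
    sb = spec.shell_brightness
    lamin_clean = np.zeros(shape, np.float64)
    lamin_clean[shell] = sb
    lamin_clean[septa] = spec.septum_brightness * sb
    lamin_clean[acc] = np.maximum(lamin_clean[acc], spec.accumulation_brightness * sb)

    # inter-lobe walls: lamin deep below the whole-nucleus surface is internal
    # structure even where it belongs to a lobe's own complete shell
    if spec.n_lobes > 1:
        depth_true = ndimage.distance_transform_edt(nucleus, sampling=vs)
        wall = shell & (depth_true > t + 0.2)
        internal = internal | wall
        shell = shell & ~wall
        lamin_clean[wall] = spec.wall_brightness * sb

    true_Ie = float(lamin_clean[shell].sum())
    true_Ii = float(lamin_clean[internal].sum())

    dapi_clean = np.where(dna, spec.dna_brightness, 0.0)

    sigma_vox = tuple(s / v for s, v in zip(spec.psf_sigma, vs))
    lamin_img = _blur_and_noise(lamin_clean, sigma_vox, spec, rng)
    dapi_img = _blur_and_noise(dapi_clean, sigma_vox, spec, rng)

    channels = {
        "DAPI": VoxelGrid(dapi_img, vs, "DAPI"),
        "LAMIN": VoxelGrid(lamin_img, vs, "LAMIN"),
    }
    if n_telo:
        telo_img = _noise_only(telo_img, spec, rng)
        channels["TELO"] = VoxelGrid(telo_img, vs, "TELO")

    stack = CellStack(channels, cell_id=f"{spec.pattern}-{seed}")
    mk = lambda a, dt=np.uint8: VoxelGrid(a.astype(dt), vs, "MASK")
    truth = SynthTruth(
        nucleus_mask=mk(nucleus),
        lobe_labels=mk(lobe_labels, np.int32),
        shell_mask=mk(shell),
        internal_mask=mk(internal),
        compartment_labels=mk(compartments, np.int32),
        dna_mask=mk(dna),
        free_space_mask=mk(free),
        # shift from the generator's centred frame to the array-origin
        # physical frame (voxel index times voxel size) used by detection
        telomere_centres=telo_centres
        - np.array([coords[0][0], coords[1][0], coords[2][0]]),
        telomere_coloc=telo_coloc,
        telomere_aggregate=telo_agg,
        true_Ie=true_Ie,
        true_Ii=true_Ii,
        spec=spec,
        seed=seed,
    )
    return stack, truth


def _add_gaussian_spot(img, coords, centre, sigma, total_intensity) -> None:
    """Accumulate an anisotropic Gaussian of given integral at a subvoxel position."""
    zc, yc, xc = coords
    sl = []
    axes_vals = []
    for ax_coords, c, s in zip((zc, yc, xc), centre, sigma):
        lo = np.searchsorted(ax_coords, c - 4 * s)
        hi = np.searchsorted(ax_coords, c + 4 * s)
        lo, hi = max(lo - 1, 0), min(hi + 1, len(ax_coords))
        sl.append(slice(lo, hi))
        axes_vals.append(np.exp(-0.5 * ((ax_coords[lo:hi] - c) / s) ** 2))
    kernel = axes_vals[0][:, None, None] * axes_vals[1][None, :, None] \
        * axes_vals[2][None, None, :]
    ssum = kernel.sum()
    if ssum > 0:
        img[tuple(sl)] += total_intensity * kernel / ssum


def _blur_and_noise(img, sigma_vox, spec: CellSpec, rng) -> np.ndarray:
    if any(s > 0 for s in sigma_vox):
        img = ndimage.gaussian_filter(img, sigma_vox)
    return _noise_only(img, spec, rng)


def _noise_only(img, spec: CellSpec, rng) -> np.ndarray:
    if spec.noise_poisson_scale > 0:
        img = rng.poisson(np.clip(img, 0, None) * spec.noise_poisson_scale) \
            / spec.noise_poisson_scale
    if spec.noise_gaussian_sd > 0:
        img = img + rng.normal(0.0, spec.noise_gaussian_sd, img.shape)
    return np.clip(img, 0.0, None)


def calibrate_internal_brightness(spec: CellSpec, target_ratio: float,
                                  seed: int = 0) -> CellSpec:
    """Set the internal-structure brightness so the true I_e/I_i hits a target.

    A noiseless render establishes the shell and internal-structure voxel
    counts for this geometry; the septum/accumulation brightness is then the
    unique multiplier making ``true_Ie / true_Ii == target_ratio``.
    """
    if target_ratio <= 0:
        raise ValueError("target_ratio must be positive")
    probe = replace(spec, noise_poisson_scale=0.0, noise_gaussian_sd=0.0,
                    n_telomeres=0)
    _, truth = render_cell(probe, seed)
    v_shell = int(truth.shell_mask.data.sum())
    internal = truth.internal_mask.data.astype(bool)
    septa_like = internal  # brightness applied uniformly to internal voxels
    v_int = int(septa_like.sum())
    if v_int == 0:
        raise ValueError("geometry has no internal lamin to calibrate")
    b = v_shell / (target_ratio * v_int)
    return replace(spec, septum_brightness=b, accumulation_brightness=b,
                   wall_brightness=b)


def sample_population(
    pattern_freqs: Mapping[str, float],
    n_cells: int,
    base_spec: CellSpec | None = None,
    seed: int = 0,
    spec_overrides: Mapping[str, Mapping] | None = None,
) -> list[tuple[CellStack, SynthTruth]]:
    """Draw ``n_cells`` cells with pattern labels i.i.d. from ``pattern_freqs``.

    Per-cell seeds derive deterministically from ``(seed, index)``, so the
    same call reproduces the same population bit-for-bit.
    ``spec_overrides`` maps pattern label -> extra :class:`CellSpec` fields
    (e.g. per-label internal brightness).
    """
    if not pattern_freqs:
        raise ValueError("empty frequency map")
    labels = list(pattern_freqs)
    probs = np.array([pattern_freqs[l] for l in labels], float)
    if (probs < 0).any():
        raise ValueError("negative probability")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {probs.sum()}, expected 1")
    base_spec = base_spec or CellSpec()
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xA11]))
    draws = rng.choice(len(labels), size=n_cells, p=probs)
    out = []
    for i, li in enumerate(draws):
        label = labels[li]
        overrides = dict((spec_overrides or {}).get(label, {}))
        spec = spec_for_pattern(label, base_spec, **overrides)
        cell_seed = int(
            np.random.SeedSequence([seed, i + 1]).generate_state(1)[0] % (2 ** 31)
        )
        out.append(render_cell(spec, cell_seed))
    return out
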