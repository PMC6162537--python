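# Methods

Algorithms and conventions used by `laminatlas`. All physical quantities
are in micrometres (µm); all arrays are z-stacks indexed `(z, y, x)`.

## Coordinate conventions (`imgio`)

- A `VoxelGrid` couples a 3D array with `voxel_size = (dz, dy, dx)` in µm
  (default acquisition geometry `(0.2, 0.1, 0.1)` — 200 nm z-step,
  ~100 nm lateral sampling).
- Physical position of voxel `(i, j, k)` is `(i·dz, j·dy, k·dx)`:
  voxel-centre convention with the origin at the centre of the corner
  voxel. All centroids, spot positions and ground-truth coordinates use
  this frame.
- OME-TIFF round-trips carry `PhysicalSizeZ/Y/X` and channel names; plain
  TIFFs require an explicit `voxel_size_override` and `channel_map`.
  Channel roles: `DAPI`, `LAMIN`, `TELO`, plus `MASK` for label/binary
  grids.

## Synthetic generator (`synthgen`)

Each cell is rendered from a `CellSpec` and returns `(CellStack,
SynthTruth)` with voxel-exact truth masks.

- **Nuclear geometry**: 1–4+ ellipsoidal lobes (default semi-axes
  `(2.0, 2.6, 2.6)` µm), overlapping for multilobed RS nuclei. The lamin
  shell is a 0.30 µm rind inside the nuclear surface.
- **Internal lamin**: `k` parallel septa normal to a lateral axis divide
  the interior into `k + 1` compartments; septa may be partial (lateral
  extent ≥ 0.35 of the local radius). Parallel geometry was chosen so
  that the compartment count is exactly `k + 1` by construction,
  giving an unambiguous ground truth for the pattern taxonomy.
  Accumulation-point patterns add two bright blobs ~1.0 µm below the
  surface.
- **DNA texture**: DNA-free cavities are spheres with radii drawn from a
  two-component mixture (`free_space_means`, `free_space_sds`); shrinking
  the means emulates "finer structure".
- **Telomeres**: `n_telomeres` point sources placed inside the nucleus; a
  target `coloc_fraction` selects how many are placed on internal lamin
  structures. Non-colocalized spots keep a 1.25 µm clearance from
  internal lamin so the truth label is unambiguous after blurring, and
  spots keep a minimum mutual separation (`telomere_min_separation`,
  default 0.8 µm) so they remain resolvable; the realized fraction is
  reported in the truth. Aggregates are emulated as close pairs.
- **Rendering**: separable anisotropic Gaussian PSF (σ
  `(0.25, 0.12, 0.12)` µm), then Poisson noise and additive Gaussian
  read noise. Everything is driven by `numpy` `SeedSequence`, so renders
  are bit-reproducible per `(spec, seed)`.
- `calibrate_internal_brightness(spec, target)` solves for the
  internal-structure brightness that makes the generator's true
  I_e/I_i equal a requested target.

## Segmentation and lamin decomposition (`nucseg`)

- **Nucleus**: Otsu threshold on the smoothed DAPI + lamin evidence,
  closed-ball morphological cleanup, largest connected component. Lobes
  are counted by a watershed on the Euclidean distance transform (EDT)
  seeded at distance maxima separated by a physical minimum distance.
  Note the segmented boundary sits roughly one PSF sigma outside the
  true surface (thresholding a blurred edge), a known, documented bias.
- **Morphology in physical units**: all openings/closings/dilations use
  voxelized closed balls of a physical radius; they are implemented with
  two EDTs and match explicit structuring-element morphology exactly.
  Structuring-element extents use `floor(radius/voxel + 1e-9)` to avoid
  floating-point truncation (e.g. `0.3/0.1 = 2.999…`).
- **Shell vs internal**: thresholds are *shell-referenced* and therefore
  scale-invariant: the reference level is the median smoothed lamin in a
  depth band (0.1–0.5 µm below the surface); the working masks are
  `> 0.25·level` (lo) and `> 0.5·level` (hi). The internal zone is the
  region deeper than a per-lobe closing (0.65 µm ball) of the shell,
  union the region deeper than 0.8 µm. A Hessian sheet-orientation
  rescue reclaims septum voxels in the boundary band whose sheet normal
  disagrees with the surface normal; rescued voxels must be 26-connected
  to, and within 0.65 µm of, a hi-mask deep-zone seed, which suppresses
  orientation noise on the faint inner fringe of the blurred shell.
- **Compartments**: connected components (26-connectivity) of the
  lamin-free interior, keeping components ≥ 0.5 % of the nuclear volume.
- **Internal burden**: fraction of nuclear voxels carrying internal
  lamin (hi mask ∩ internal zone); used to separate H0 (no internal
  structure) from HA.

## Pattern taxonomy and I_e/I_i (`patterns`)

- Classification uses `(n_lobes, n_compartments, internal_burden)`:
  mononuclear → H0 (no internal lamin), HA (internal lamin, one
  compartment), HB/HC/HD (2/3/≥4 compartments); multilobed → RS2/RS3/RS4
  /RSmulti by compartment count.
- **I_e/I_i**: each mask (shell, internal) is extended by a 0.4 µm
  capture dilation; contested voxels are attributed to the nearest
  structure by EDT; mean intensities are background-subtracted. The
  ratio is undefined (flagged) when no internal structure exists.
  Note the published ratios were measured on 2D confocal sections; this
  implementation integrates over the full 3D masks, so absolute values
  are comparable only through the generator's matching 3D truth.

## Telomere spots (`telospots`)

- **Detection**: band-pass (difference of Gaussians: spot scale 0.12 µm
  vs background 0.5 µm), relative threshold at 10 % of the maximum
  in-nucleus response, local maxima separated by ≥ 0.25 µm, watershed
  regions. Intensity-scale invariant by construction.
- **Aggregates**: a spot is flagged when another spot lies within the
  merge distance (0.3 µm) or when its region volume exceeds 1.4× the
  median spot volume. An unresolved pair never doubles the
  above-threshold footprint of a single spot, but exceeds it by well
  over the ~20 % scatter of singles, hence the 1.4 multiple.
- **a/c ratio**: principal axes of the spot-centroid covariance
  (longest/shortest singular value); undefined for < 4 spots or
  degenerate (coplanar) clouds.
- **Colocalization**: object-based — a spot colocalizes if its detected
  region, dilated by one voxel (26-connectivity tolerance), intersects
  the internal lamin mask; the fraction is over all detected spots.

## Granulometry (`granulo`)

- DNA vs free-space masks: Otsu threshold of smoothed DAPI inside the
  nucleus; the two masks partition the nucleus.
- `granulometry(mask, radii)` sieves the mask with anisotropy-aware
  physical balls: `retained(r)` is the volume covered by some inscribed
  ball of radius ≥ r — the union of the ball openings at all sieve radii
  ≥ r. This equals the plain opening at each radius whenever the
  digitized openings are nested and, unlike the plain opening, is
  monotone even in the rare anisotropic-grid cases where they are not
  (digital balls on a 2:1 anisotropic grid are not always open with
  respect to smaller ones). `cumulative_fraction = 1 − retained/volume`
  is non-decreasing by construction. The EDT implementation matches
  explicit structuring-element morphology exactly.
- `compare_populations` pools volume-weighted per-cell structure-size
  samples (equal weight per cell) and applies the two-sample KS test;
  the direction output reports which population is stochastically
  smaller ("finer structure").

## Statistics (`stats`)

Self-written (the point of the module is oracle-checkable primitives):

- `chi_square`: Pearson statistic on an r×c table, optional Yates
  correction, chi-square survival function for the p-value.
- `ks_two_sample`: exact D from right-continuous ECDFs evaluated on the
  pooled sample grid; asymptotic Kolmogorov distribution for the
  p-value (requires n, m ≥ 2).

## Pipeline and determinism (`pipeline`, `cli`)

`run(RunConfig)` orchestrates simulate → segment → classify → telomeres →
granulometry → statistics, writing `calls.csv`, `pattern_table.csv`,
`ratio_summary.csv`, `granulometry_curves.csv` and `report.json`. The
report's `content_hash()` is a SHA-256 over the canonical CSV/JSON
serializations; identical configs reproduce it bit-for-bit because every
stochastic stage derives its seed from the master seed via
`SeedSequence`.
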