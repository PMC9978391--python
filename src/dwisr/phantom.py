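"""Multi-tensor diffusion phantoms with Rician noise.

The study data this package targets are multi-shell brain DWI (b = 0, 1000,
1500, 2000 s/mm^2) that are not publicly distributable, so validation runs on
synthetic phantoms with known ground truth: straight anisotropic fiber
bundles (a 90-degree crossing at the in-plane center), an isotropic CSF-like
ellipsoid, and magnitude (Rician) noise.

Each voxel's signal follows the standard multi-tensor forward model

    S(b, g) = S0 * sum_k f_k * exp(-b * g^T D_k g)

with axially symmetric tensors D_k (axial/radial diffusivities in mm^2/s) and
volume fractions f_k summing to 1.  Default diffusivities are adult-brain
literature values: fiber axial 1.7e-3, radial 0.3e-3; CSF isotropic 3.0e-3
mm^2/s.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Sequence

import numpy as np

from .io import DWIVolume

__all__ = [
    "TensorCompartment",
    "PhantomSpec",
    "simulate_voxel_signal",
    "add_rician_noise",
    "generate_phantom",
    "default_gradient_table",
    "icosahedral_directions",
    "default_phantom_spec",
    "region_masks",
]

AXIAL_DIFFUSIVITY = 1.7e-3  # mm^2/s, fiber bundle, along the axon
RADIAL_DIFFUSIVITY = 0.3e-3  # mm^2/s, fiber bundle, across the axon
CSF_DIFFUSIVITY = 3.0e-3  # mm^2/s, isotropic free water


@dataclasses.dataclass(frozen=True)
class TensorCompartment:
    """One axially symmetric diffusion tensor with a volume fraction."""

    principal_direction: tuple
    axial_diffusivity: float = AXIAL_DIFFUSIVITY
    radial_diffusivity: float = RADIAL_DIFFUSIVITY
    volume_fraction: float = 1.0

    def __post_init__(self):
        d = np.asarray(self.principal_direction, dtype=np.float64)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("principal_direction must be non-zero")
        object.__setattr__(self, "principal_direction", tuple(d / n))
        if not (self.axial_diffusivity >= self.radial_diffusivity > 0):
            raise ValueError(
                "need axial_diffusivity >= radial_diffusivity > 0, got "
                f"{self.axial_diffusivity} / {self.radial_diffusivity}"
            )
        if not 0.0 <= self.volume_fraction <= 1.0:
            raise ValueError(f"volume_fraction {self.volume_fraction} outside [0, 1]")

    def tensor(self) -> np.ndarray:
        """The 3x3 diffusion tensor in mm^2/s."""
        d = np.asarray(self.principal_direction)
        return self.radial_diffusivity * np.eye(3) + (
            self.axial_diffusivity - self.radial_diffusivity
        ) * np.outer(d, d)


def icosahedral_directions() -> np.ndarray:
    """Six unit directions along the icosahedron's vertex axes.

    The classic minimal multi-shell DWI scheme: one representative per
    antipodal vertex pair of the regular icosahedron.
    """
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    raw = np.array(
        [
            [1, phi, 0],
            [1, -phi, 0],
            [0, 1, phi],
            [0, 1, -phi],
            [phi, 0, 1],
            [-phi, 0, 1],
        ],
        dtype=np.float64,
    )
    return raw / np.linalg.norm(raw, axis=1, keepdims=True)


def default_gradient_table(directions: np.ndarray = None,
                           shells: Sequence[float] = (1000.0, 1500.0, 2000.0)):
    """One b=0 entry plus the given directions at each shell.

    Defaults to the 6 icosahedral axes per shell: 19 entries over
    b = 0/1000/1500/2000 s/mm^2, a desk-scale version of the study's
    four-shell, 193-direction acquisition.
    """
    if directions is None:
        directions = icosahedral_directions()
    directions = np.asarray(directions, dtype=np.float64)
    bvals = [0.0]
    bvecs = [np.zeros(3)]
    for b in shells:
        for d in directions:
            bvals.append(float(b))
            bvecs.append(d)
    return np.array(bvals), np.array(bvecs)


@dataclasses.dataclass
class PhantomSpec:
    """Geometry, gradient table and noise level of one synthetic subject.

    ``bundle_definitions`` is a list of ``(mask_predicate, compartments)``
    where the predicate maps integer index grids (i, j, k) to a boolean mask.
    Overlap is resolved by priority: CSF region first, then bundles in listed
    order, then zero background.
    """

    grid_shape: tuple = (24, 24, 12)
    voxel_size: tuple = (3.4, 3.4, 4.0)
    bvals: np.ndarray = None
    bvecs: np.ndarray = None
    s0: float = 100.0
    bundle_definitions: list = None
    csf_region: Callable = None
    csf_diffusivity: float = CSF_DIFFUSIVITY
    # CSF is hyperintense on the unweighted (b=0) image because of its long
    # T2; this factor scales the CSF baseline relative to tissue s0 and is
    # what makes ventricles bright in ISO maps.
    csf_s0_factor: float = 3.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if any(int(s) % 3 != 0 or s < 1 for s in self.grid_shape):
            raise ValueError(
                f"grid_shape {self.grid_shape} must be positive and divisible "
                "by 3 so the factor-3 degrade/restore cycle is exact"
            )
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.bvals is None or self.bvecs is None:
            self.bvals, self.bvecs = default_gradient_table()
        self.bvals = np.asarray(self.bvals, dtype=np.float64)
        self.bvecs = np.asarray(self.bvecs, dtype=np.float64)
        if self.bundle_definitions is None or self.csf_region is None:
            geom = _default_geometry(self.grid_shape)
            if self.bundle_definitions is None:
                self.bundle_definitions = geom["bundles"]
            if self.csf_region is None:
                self.csf_region = geom["csf"]


def _default_geometry(grid_shape):
    """Two orthogonal bundles crossing at the in-plane center; CSF ellipsoid
    centered in-plane but shifted into the slab above the bundles so it does
    not erase the crossing (region priority gives CSF the right of way)."""
    nx, ny, nz = grid_shape
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    half_y = max(1, ny // 8)
    half_x = max(1, nx // 8)
    z_lo, z_hi = 0, max(1, nz // 3)  # bundles live in the lower z slab

    def bundle_x(i, j, k):
        return (np.abs(j - cy) <= half_y) & (k >= z_lo) & (k < z_hi)

    def bundle_y(i, j, k):
        return (np.abs(i - cx) <= half_x) & (k >= z_lo) & (k < z_hi)

    csf_c = (cx, cy, cz + nz / 4.0)
    csf_r = (max(2.0, nx / 5.0), max(2.0, ny / 5.0), max(1.5, nz / 5.0))

    def csf(i, j, k):
        return (
            ((i - csf_c[0]) / csf_r[0]) ** 2
            + ((j - csf_c[1]) / csf_r[1]) ** 2
            + ((k - csf_c[2]) / csf_r[2]) ** 2
        ) <= 1.0

    bundles = [
        (bundle_x, [TensorCompartment((1.0, 0.0, 0.0))]),
        (bundle_y, [TensorCompartment((0.0, 1.0, 0.0))]),
    ]
    return {"bundles": bundles, "csf": csf}


def simulate_voxel_signal(compartments, s0, bval, bvec) -> float:
    """Noiseless multi-tensor signal for a single voxel and gradient.

    Fractions are renormalized only in the trivial sense that they must sum
    to 1 (within 1e-9); b = 0 returns ``s0`` exactly.
    """
    if bval < 0:
        raise ValueError(f"negative b-value {bval}")
    fractions = sum(c.volume_fraction for c in compartments)
    if abs(fractions - 1.0) > 1e-9:
        raise ValueError(f"volume fractions sum to {fractions}, expected 1")
    g = np.asarray(bvec, dtype=np.float64)
    signal = 0.0
    for c in compartments:
        signal += c.volume_fraction * np.exp(-bval * g @ c.tensor() @ g)
    return float(s0 * signal)


def add_rician_noise(signal, sigma, seed):
    """Magnitude-MRI noise: sqrt((s + n1)^2 + n2^2), n1, n2 ~ N(0, sigma^2).

    Deterministic given ``seed``; sigma = 0 returns the input unchanged.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    signal = np.asarray(signal, dtype=np.float64)
    if sigma == 0:
        return signal.copy()
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def region_masks(spec: PhantomSpec):
    """Boolean masks (csf, [bundle...], crossing) after priority resolution.

    ``crossing`` marks voxels claimed by two or more bundle predicates before
    priority resolution (those voxels get the mixed compartment model).
    """
    idx = np.indices(spec.grid_shape)
    i, j, k = idx[0], idx[1], idx[2]
    csf = np.asarray(spec.csf_region(i, j, k), dtype=bool)
    raw = [np.asarray(pred(i, j, k), dtype=bool) for pred, _ in spec.bundle_definitions]
    overlap = np.sum(raw, axis=0) >= 2
    crossing = overlap & ~csf
    claimed = csf.copy()
    bundles = []
    for m in raw:
        bundles.append(m & ~claimed & ~crossing)
        claimed |= m
    return csf, bundles, crossing


def generate_phantom(spec: PhantomSpec) -> DWIVolume:
    """Render the full 4-D phantom volume; bit-identical for equal seeds.

    Voxels claimed by two or more bundle regions receive an equal-fraction
    mixture of the bundles' compartments (the crossing-fiber model);
    otherwise CSF has priority over bundles over zero background.
    """
    csf, bundles, crossing = region_masks(spec)
    n_grad = len(spec.bvals)
    data = np.zeros(spec.grid_shape + (n_grad,), dtype=np.float64)

    csf_comp = [
        TensorCompartment(
            (1.0, 0.0, 0.0),
            axial_diffusivity=spec.csf_diffusivity,
            radial_diffusivity=spec.csf_diffusivity,
        )
    ]
    cross_comps = []
    for _, comps in spec.bundle_definitions:
        share = 1.0 / len(spec.bundle_definitions)
        for c in comps:
            cross_comps.append(dataclasses.replace(c, volume_fraction=c.volume_fraction * share))

    regions = [(csf, csf_comp), (crossing, cross_comps)]
    regions += [(m, comps) for m, (_, comps) in zip(bundles, spec.bundle_definitions)]

    s0_by_region = [spec.s0 * spec.csf_s0_factor, spec.s0, spec.s0]
    s0_by_region += [spec.s0] * max(0, len(regions) - 3)
    for g in range(n_grad):
        for (mask, comps), s0 in zip(regions, s0_by_region):
            if not mask.any() or not comps:
                continue
            data[mask, g] = simulate_voxel_signal(
                comps, s0, spec.bvals[g], spec.bvecs[g]
            )
    if spec.noise_sigma > 0:
        data = add_rician_noise(data, spec.noise_sigma, spec.seed)
    return DWIVolume(
        data=data,
        voxel_size=spec.voxel_size,
        bvals=spec.bvals.copy(),
        bvecs=spec.bvecs.copy(),
    )


def default_phantom_spec(seed: int = 0, noise_sigma: float = None, **kwargs) -> PhantomSpec:
    """A ready-to-use spec; noise defaults to 2% of the baseline intensity."""
    spec = PhantomSpec(seed=seed, **kwargs)
    spec.noise_sigma = 0.02 * spec.s0 if noise_sigma is None else noise_sigma
    return spec
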