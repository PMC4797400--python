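"""Parameterized voxel mouse phantom ("MOBY-lite").

Organs are modelled as non-overlapping geometric primitives (ellipsoids,
spheres, cylinders) at literature-informed anatomical positions inside an
ellipsoidal body contour, each scaled so its voxelized mass matches a
target mass at a configurable tissue density.  Two features follow the
dosimetry model this phantom feeds:

* the subcutaneous tumor is a solid ellipsoid attached at the right flank
  *outside* the body contour, with axis ratio 1:2:2 (short axis
  perpendicular to the skin);
* the submandibular gland is a solid sphere with radius
  r = (3 m / 4 pi rho)^(1/3).

Coordinate convention: 0-based voxel indices; z runs along the body axis
(nose at high z), x is the left-right axis with the right flank at +x,
y is dorsoventral.  Default grid 160 x 160 x 440 voxels.  All tissue is
water-equivalent (1.0 g/cm^3) by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "PhantomSpec",
    "VoxelPhantom",
    "build_phantom",
    "region_centroids_and_distances",
    "ResolutionError",
    "DEFAULT_ORGAN_MASSES",
]

BODY = "body"
TUMOR = "tumor"

#: Typical organ masses (g) for a ~25 g tumor-bearing nude mouse; the body
#: entry is the remainder soft tissue and is computed, not listed here.
DEFAULT_ORGAN_MASSES: dict[str, float] = {
    "brain": 0.40,
    "heart": 0.15,
    "lung": 0.15,
    "liver": 1.30,
    "spleen": 0.10,
    "kidney": 0.40,
    "gi_tract": 2.50,
    "testes": 0.20,
    "bone": 1.60,
    "marrow": 0.25,
    "submandibular": 0.10,
}


class ResolutionError(ValueError):
    """An organ is too small to occupy a single voxel at this resolution."""


@dataclass(frozen=True)
class PhantomSpec:
    """Target geometry for the voxel phantom."""

    body_weight_g: float = 25.0
    organ_masses_g: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ORGAN_MASSES)
    )
    tumor_mass_g: float = 0.5
    grid: tuple[int, int, int] = (160, 160, 440)
    voxel_size_mm: float = 0.25
    tissue_density_g_cm3: float = 1.0

    def __post_init__(self) -> None:
        if min(self.grid) <= 0 or self.voxel_size_mm <= 0:
            raise ValueError("grid dimensions and voxel size must be positive")
        if self.body_weight_g <= 0 or self.tumor_mass_g < 0:
            raise ValueError("body weight must be positive, tumor mass non-negative")
        if self.tissue_density_g_cm3 <= 0:
            raise ValueError("tissue density must be positive")
        organs = sum(self.organ_masses_g.values())
        if organs >= self.body_weight_g:
            raise ValueError(
                f"organ masses ({organs:.2f} g) exceed body weight "
                f"({self.body_weight_g:.2f} g); no remainder tissue left"
            )

    @property
    def voxel_volume_mm3(self) -> float:
        return self.voxel_size_mm**3

    @property
    def voxel_mass_g(self) -> float:
        # 1 mm^3 = 1e-3 cm^3
        return self.voxel_volume_mm3 * 1e-3 * self.tissue_density_g_cm3


@dataclass(frozen=True)
class VoxelPhantom:
    """Labeled voxel grid with achieved region masses.

    ``labels`` holds small integer region ids (0 = outside the animal);
    ``region_ids`` maps region name -> id.
    """

    labels: np.ndarray
    region_ids: dict[str, int]
    spec: PhantomSpec

    @property
    def region_names(self) -> list[str]:
        return list(self.region_ids)

    def region_mask(self, region: str) -> np.ndarray:
        return self.labels == self.region_ids[region]

    def region_voxel_counts(self) -> dict[str, int]:
        counts = np.bincount(self.labels.ravel(), minlength=max(self.region_ids.values()) + 1)
        return {name: int(counts[rid]) for name, rid in self.region_ids.items()}

    def region_masses(self) -> dict[str, float]:
        """Achieved masses: voxel count x voxel volume x density."""
        vm = self.spec.voxel_mass_g
        return {name: n * vm for name, n in self.region_voxel_counts().items()}

    # -- I/O ---------------------------------------------------------------

    def save(self, stem: str | Path) -> None:
        """Write <stem>.npy (labels) + <stem>.json sidecar."""
        stem = Path(stem)
        np.save(stem.with_suffix(".npy"), self.labels)
        sidecar = {
            "grid": list(self.spec.grid),
            "voxel_size_mm": self.spec.voxel_size_mm,
            "tissue_density_g_cm3": self.spec.tissue_density_g_cm3,
            "body_weight_g": self.spec.body_weight_g,
            "tumor_mass_g": self.spec.tumor_mass_g,
            "organ_masses_g": self.spec.organ_masses_g,
            "region_ids": self.region_ids,
            "axes": "x: left->right (+x = right flank), y: dorsoventral, z: body axis",
        }
        stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, stem: str | Path) -> "VoxelPhantom":
        stem = Path(stem)
        meta = json.loads(stem.with_suffix(".json").read_text())
        labels = np.load(stem.with_suffix(".npy"))
        spec = PhantomSpec(
            body_weight_g=meta["body_weight_g"],
            organ_masses_g=meta["organ_masses_g"],
            tumor_mass_g=meta["tumor_mass_g"],
            grid=tuple(meta["grid"]),
            voxel_size_mm=meta["voxel_size_mm"],
            tissue_density_g_cm3=meta["tissue_density_g_cm3"],
        )
        return cls(labels=labels, region_ids={k: int(v) for k, v in meta["region_ids"].items()}, spec=spec)

    def to_nifti(self, path: str | Path) -> None:
        """Optional NIfTI export for viewers."""
        import nibabel as nib

        aff = np.diag([self.spec.voxel_size_mm] * 3 + [1.0])
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), aff), str(path))


# ---------------------------------------------------------------------------
# geometry helpers


def _ellipsoid_mask(shape, center, semi, voxel):
    """Boolean mask of an axis-aligned ellipsoid; coordinates in mm."""
    nx, ny, nz = shape
    x = (np.arange(nx) + 0.5) * voxel
    y = (np.arange(ny) + 0.5) * voxel
    z = (np.arange(nz) + 0.5) * voxel
    dx = ((x - center[0]) / semi[0]) ** 2
    dy = ((y - center[1]) / semi[1]) ** 2
    dz = ((z - center[2]) / semi[2]) ** 2
    return (dx[:, None, None] + dy[None, :, None] + dz[None, None, :]) <= 1.0


def sphere_radius_mm(mass_g: float, density_g_cm3: float = 1.0) -> float:
    """Radius of a sphere of given mass: r = (3 m / 4 pi rho)^(1/3), in mm."""
    vol_mm3 = mass_g / density_g_cm3 * 1e3
    return (3.0 * vol_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)


def tumor_semi_axes_mm(mass_g: float, density_g_cm3: float = 1.0) -> tuple[float, float, float]:
    """Semi-axes (a, 2a, 2a) of the flank-tumor ellipsoid from its mass.

    Volume (4/3) pi a (2a)(2a) = m/rho  =>  a = (3V / 16 pi)^(1/3).
    """
    vol_mm3 = mass_g / density_g_cm3 * 1e3
    a = (3.0 * vol_mm3 / (16.0 * np.pi)) ** (1.0 / 3.0)
    return (a, 2.0 * a, 2.0 * a)


# fractional organ positions (x, y of the transverse semi-axis; z of the
# longitudinal semi-axis); z grows towards the head, +y is ventral.
# Values chosen for anatomical plausibility and non-overlap at default masses.
_ORGAN_LAYOUT: dict[str, tuple[float, float, float]] = {
    "brain": (0.0, 0.0, 0.84),
    "submandibular": (0.0, 0.42, 0.70),
    "lung": (0.0, 0.20, 0.56),
    "heart": (0.0, 0.45, 0.42),
    "liver": (-0.10, 0.30, 0.22),
    "spleen": (-0.60, 0.10, -0.02),
    "kidney": (0.55, 0.05, 0.02),
    "gi_tract": (0.05, 0.25, -0.26),
    "testes": (0.0, 0.25, -0.72),
}

# xy/z semi-axis aspect for the two large oblate organs (others are spheres)
_ORGAN_ASPECT: dict[str, tuple[float, float, float]] = {
    "liver": (1.4, 1.4, 1.0),
    "gi_tract": (1.45, 1.0, 1.45),
}


def build_phantom(spec: PhantomSpec) -> VoxelPhantom:
    """Deterministically voxelize the phantom described by ``spec``.

    Raises :class:`ResolutionError` (with a suggested voxel size) if any
    organ is lighter than one voxel.
    """
    rho = spec.tissue_density_g_cm3
    voxel = spec.voxel_size_mm
    vm = spec.voxel_mass_g
    for name, m in {**spec.organ_masses_g, TUMOR: spec.tumor_mass_g}.items():
        if 0 < m < vm:
            suggest = (m / rho) ** (1 / 3.0) * 10.0  # cm -> mm
            raise ResolutionError(
                f"organ '{name}' ({m} g) lighter than one voxel ({vm:.4g} g); "
                f"use voxel_size <= {suggest:.3g} mm"
            )

    nx, ny, nz = spec.grid
    extent = np.array([nx, ny, nz]) * voxel  # mm
    center = extent / 2.0

    # body contour: prolate ellipsoid along z, ax = ay, az = 3.75 ax,
    # sized to the whole-animal soft-tissue volume (body weight minus tumor)
    body_vol_mm3 = (spec.body_weight_g - spec.tumor_mass_g) / rho * 1e3
    elong = 3.75
    ax = (3.0 * body_vol_mm3 / (4.0 * np.pi * elong)) ** (1.0 / 3.0)
    body_semi = (ax, ax, elong * ax)
    if 2 * body_semi[2] > extent[2] or 2 * ax > min(extent[0], extent[1]):
        raise ValueError(
            f"body contour ({2*ax:.1f} x {2*ax:.1f} x {2*body_semi[2]:.1f} mm) "
            f"does not fit the grid extent {extent} mm; enlarge grid or voxel size"
        )

    labels = np.zeros(spec.grid, dtype=np.uint8)
    region_ids: dict[str, int] = {}
    next_id = 1

    body_mask = _ellipsoid_mask(spec.grid, center, body_semi, voxel)
    labels[body_mask] = next_id
    region_ids[BODY] = next_id
    next_id += 1

    def carve(name: str, mask: np.ndarray) -> None:
        nonlocal next_id
        sel = mask & (labels == region_ids[BODY])
        if not sel.any():
            raise ResolutionError(f"organ '{name}' occupies no voxel inside the body")
        labels[sel] = next_id
        region_ids[name] = next_id
        next_id += 1

    # skeleton: spine cylinder (dorsal, along z) carrying bone + inner marrow
    bone_m = spec.organ_masses_g.get("bone", 0.0)
    marrow_m = spec.organ_masses_g.get("marrow", 0.0)
    if bone_m > 0 or marrow_m > 0:
        spine_len = 1.2 * body_semi[2]
        tot_vol = (bone_m + marrow_m) / rho * 1e3
        r_spine = np.sqrt(tot_vol / (np.pi * spine_len))
        r_marrow = r_spine * np.sqrt(marrow_m / (bone_m + marrow_m)) if marrow_m else 0.0
        cy = center[1] - 0.45 * ax  # dorsal shift
        x = (np.arange(nx) + 0.5) * voxel - center[0]
        y = (np.arange(ny) + 0.5) * voxel - cy
        z = (np.arange(nz) + 0.5) * voxel - center[2]
        r2 = x[:, None, None] ** 2 + y[None, :, None] ** 2
        inz = (np.abs(z) <= spine_len / 2.0)[None, None, :]
        if bone_m > 0:
            carve("bone", (r2 <= r_spine**2) & inz)
        if marrow_m > 0:
            marrow_mask = (r2 <= r_marrow**2) & inz
            sel = marrow_mask & (labels == region_ids["bone"])
            labels[sel] = next_id
            region_ids["marrow"] = next_id
            next_id += 1

    # soft organs: spheres (oblate ellipsoids for liver / GI tract)
    for name, frac in _ORGAN_LAYOUT.items():
        m = spec.organ_masses_g.get(name, 0.0)
        if m <= 0:
            continue
        pos = center + np.array(
            [frac[0] * ax, frac[1] * ax, frac[2] * body_semi[2]]
        )
        if name in _ORGAN_ASPECT:
            fx, fy, fz = _ORGAN_ASPECT[name]
            s = (3.0 * m / rho * 1e3 / (4.0 * np.pi * fx * fy * fz)) ** (1.0 / 3.0)
            semi = (fx * s, fy * s, fz * s)
        else:
            r = sphere_radius_mm(m, rho)
            semi = (r, r, r)
        carve(name, _ellipsoid_mask(spec.grid, pos, semi, voxel))

    # tumor: 1:2:2 ellipsoid on the right flank, outside the body contour,
    # short axis (a) along +x (perpendicular to the skin), touching the skin
    if spec.tumor_mass_g > 0:
        a, b, c = tumor_semi_axes_mm(spec.tumor_mass_g, rho)
        z_frac = -0.15
        x_skin = ax * np.sqrt(1.0 - z_frac**2)  # local body radius at tumor z
        t_center = center + np.array([x_skin + a, 0.0, z_frac * body_semi[2]])
        t_mask = _ellipsoid_mask(spec.grid, t_center, (a, b, c), voxel)
        t_mask &= ~body_mask  # strictly outside the body contour
        if not t_mask.any():
            raise ResolutionError("tumor occupies no voxel; grid too small or coarse")
        labels[t_mask] = next_id
        region_ids[TUMOR] = next_id
        next_id += 1

    phantom = VoxelPhantom(labels=labels, region_ids=region_ids, spec=spec)
    _check_masses(phantom)
    return phantom


def _check_masses(phantom: VoxelPhantom, tol: float = 0.05) -> None:
    """Warn-level check that achieved masses are within 5 % of targets."""
    spec = phantom.spec
    achieved = phantom.region_masses()
    targets = {**spec.organ_masses_g, TUMOR: spec.tumor_mass_g}
    for name, target in targets.items():
        if target <= 0 or name not in achieved:
            continue
        got = achieved[name]
        if abs(got - target) > tol * target:
            import warnings

            warnings.warn(
                f"phantom region '{name}': achieved {got:.3g} g vs target "
                f"{target:.3g} g (>{tol:.0%} off); consider a finer voxel size",
                stacklevel=2,
            )


def region_centroids_and_distances(
    phantom: VoxelPhantom,
) -> tuple[dict[str, np.ndarray], dict[tuple[str, str], float]]:
    """Region centroids (mm) and pairwise Euclidean centroid distances (mm)."""
    voxel = phantom.spec.voxel_size_mm
    centroids = {}
    for name in phantom.region_names:
        idx = np.argwhere(phantom.region_mask(name))
        if idx.size == 0:
            continue
        centroids[name] = (idx.mean(axis=0) + 0.5) * voxel
    dists = {}
    for a, ca in centroids.items():
        for b, cb in centroids.items():
            dists[(a, b)] = float(np.linalg.norm(ca - cb))
    return centroids, dists
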