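"""Monte Carlo S-factor estimation on the voxel phantom.

Estimates S(rT <- rS), the mean absorbed dose to target region rT per
disintegration in source region rS, for a beta/gamma emitter such as
Lu-177, with deliberately simplified (but documented) physics:

* decay sites are sampled uniformly within each source region, with the
  history quota stratified so every source region receives exactly its
  share;
* **electrons** travel in a straight line and deposit energy linearly
  along a track of CSDA range in water (constant stopping power E/R).
  Lu-177 beta ranges are below ~2 mm, comparable to one or two voxels,
  so angular detail is second order for organ-mean doses;
* **photons** undergo photoelectric absorption and incoherent (Compton)
  scattering in water; the photoelectric coefficient comes from an
  embedded table (log-log interpolated) and the incoherent one from the
  Klein-Nishina cross section.  Coherent scattering and bremsstrahlung
  are neglected.  Photons below the energy cutoff (default 10 keV)
  deposit locally.  Voxels outside the animal are vacuum: no
  interaction, no energy loss.

Transport is analog (no variance reduction); uncertainties come from 10
equal-size batches.  Everything is driven by a single integer seed, so a
run is exactly reproducible.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .decay import NuclideData, _read_csv
from .phantom import VoxelPhantom

__all__ = [
    "SFactorMatrix",
    "simulate_s_factors",
    "split_self_vs_cross",
    "read_s_matrix",
]

KEV_TO_J = 1.602176634e-16
ELECTRON_REST_KEV = 510.998950
#: electrons per gram of water (N_A * Z/A)
WATER_ELECTRONS_PER_G = 3.3428e23
#: classical electron radius squared, in cm^2 (r_e^2)
RE2_CM2 = 7.940787e-26

_N_BATCHES = 10


# ---------------------------------------------------------------------------
# water physics tables


class _WaterPhysics:
    """Interpolators for photon attenuation and electron CSDA range in water."""

    def __init__(self) -> None:
        pe = _read_csv("water_photoelectric.csv", 2)
        self._pe_loge = np.log(pe[:, 0])
        self._pe_logmu = np.log(pe[:, 1])
        rng = _read_csv("electron_csda_water.csv", 2)
        self._r_loge = np.log(rng[:, 0])
        self._r_logr = np.log(rng[:, 1])

    def mu_photoelectric(self, e_kev: float) -> float:
        """Photoelectric attenuation coefficient in water, per mm (rho = 1)."""
        logmu = np.interp(math.log(e_kev), self._pe_loge, self._pe_logmu)
        return math.exp(logmu) / 10.0  # cm^2/g * 1 g/cm^3 -> cm^-1 -> mm^-1

    def mu_incoherent(self, e_kev: float) -> float:
        """Klein-Nishina incoherent coefficient in water, per mm (rho = 1)."""
        a = e_kev / ELECTRON_REST_KEV
        # total KN cross section per electron, cm^2
        t1 = (1 + a) / a**2 * (2 * (1 + a) / (1 + 2 * a) - math.log(1 + 2 * a) / a)
        t2 = math.log(1 + 2 * a) / (2 * a)
        t3 = -(1 + 3 * a) / (1 + 2 * a) ** 2
        sigma = 2 * math.pi * RE2_CM2 * (t1 + t2 + t3)
        return sigma * WATER_ELECTRONS_PER_G / 10.0  # per mm at rho 1 g/cm^3

    def csda_range_mm(self, e_kev: np.ndarray) -> np.ndarray:
        """CSDA range in water (mm at rho = 1), log-log interpolated."""
        e = np.maximum(np.asarray(e_kev, float), 1e-3)
        logr = np.interp(np.log(e), self._r_loge, self._r_logr)
        return np.exp(logr) * 10.0  # g/cm^2 at 1 g/cm^3 -> cm -> mm


_PHYSICS: _WaterPhysics | None = None


def _physics() -> _WaterPhysics:
    global _PHYSICS
    if _PHYSICS is None:
        _PHYSICS = _WaterPhysics()
    return _PHYSICS


# ---------------------------------------------------------------------------
# result container


@dataclass(frozen=True)
class SFactorMatrix:
    """S-factors in Gy per disintegration, with Monte Carlo uncertainties.

    ``s[(target, source)]`` maps region-name pairs to Gy/decay;
    ``rel_uncertainty`` holds the fractional standard error of each entry
    (NaN where the estimate is zero).
    """

    s: dict[tuple[str, str], float]
    rel_uncertainty: dict[tuple[str, str], float]
    n_histories: int
    physics_config: dict = field(default_factory=dict)

    def targets(self) -> list[str]:
        return sorted({t for t, _ in self.s})

    def sources(self) -> list[str]:
        return sorted({s for _, s in self.s})

    def self_factor(self, region: str) -> float:
        return self.s.get((region, region), 0.0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "target": t,
                "source": src,
                "gy_per_decay": v,
                "rel_unc": self.rel_uncertainty.get((t, src), float("nan")),
            }
            for (t, src), v in sorted(self.s.items())
        ]
        return pd.DataFrame(rows)

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)
        meta = {"n_histories": self.n_histories, "physics_config": self.physics_config}
        Path(path).with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_s_matrix(path: str | Path) -> SFactorMatrix:
    """Import an externally supplied S-matrix CSV (target,source,gy_per_decay[,rel_unc]).

    This is the bypass path for published S-values: the MIRD stage accepts
    such a matrix in place of a simulation result.
    """
    df = pd.read_csv(path)
    need = {"target", "source", "gy_per_decay"}
    if not need.issubset(df.columns):
        raise ValueError(f"S-matrix file {path} must have columns {sorted(need)}")
    s = {}
    unc = {}
    for _, row in df.iterrows():
        key = (str(row["target"]), str(row["source"]))
        s[key] = float(row["gy_per_decay"])
        unc[key] = float(row["rel_unc"]) if "rel_unc" in df.columns else float("nan")
    meta_path = Path(path).with_suffix(".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    return SFactorMatrix(
        s=s,
        rel_uncertainty=unc,
        n_histories=int(meta.get("n_histories", 0)),
        physics_config=meta.get("physics_config", {"imported_from": str(path)}),
    )


# ---------------------------------------------------------------------------
# particle tracking (straight-line DDA through the label grid)


def _isotropic_directions(rng: np.random.Generator, n: int) -> np.ndarray:
    cos_t = rng.uniform(-1.0, 1.0, n)
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    sin_t = np.sqrt(1.0 - cos_t**2)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), cos_t])


def _track_electron(labels, shape, voxel, pos, direction, energy, rng_range, edep):
    """Deposit ``energy`` linearly along a straight water track of range
    ``rng_range`` mm starting at ``pos`` (mm).  Vacuum voxels (label 0) cost
    no range.  ``edep`` is a per-label accumulator (keV)."""
    nx, ny, nz = shape
    ix = int(pos[0] / voxel)
    iy = int(pos[1] / voxel)
    iz = int(pos[2] / voxel)
    if not (0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz):
        return
    dx, dy, dz = direction
    # per-axis step direction and distance to the next voxel plane
    big = 1e30
    sx = 1 if dx > 0 else -1
    sy = 1 if dy > 0 else -1
    sz = 1 if dz > 0 else -1
    tdx = voxel / abs(dx) if dx != 0 else big
    tdy = voxel / abs(dy) if dy != 0 else big
    tdz = voxel / abs(dz) if dz != 0 else big
    tx = ((ix + (sx > 0)) * voxel - pos[0]) / dx if dx != 0 else big
    ty = ((iy + (sy > 0)) * voxel - pos[1]) / dy if dy != 0 else big
    tz = ((iz + (sz > 0)) * voxel - pos[2]) / dz if dz != 0 else big
    t_prev = 0.0
    remaining = rng_range
    lab_flat = labels
    while True:
        t_next = tx if tx < ty else ty
        if tz < t_next:
            t_next = tz
        seg = t_next - t_prev
        lab = lab_flat[ix, iy, iz]
        if lab != 0:
            if seg >= remaining:
                edep[lab] += energy * remaining / rng_range
                return
            edep[lab] += energy * seg / rng_range
            remaining -= seg
        # advance to next voxel
        if tx <= ty and tx <= tz:
            ix += sx
            tx += tdx
            if not (0 <= ix < nx):
                return
        elif ty <= tz:
            iy += sy
            ty += tdy
            if not (0 <= iy < ny):
                return
        else:
            iz += sz
            tz += tdz
            if not (0 <= iz < nz):
                return
        t_prev = t_next


def _march_photon(labels, shape, voxel, pos, direction, water_path):
    """Advance a photon by ``water_path`` mm of water-equivalent depth.

    Returns (label, new_pos) at the interaction site, or (0, None) if the
    photon leaves the grid first.  Vacuum voxels add no depth."""
    nx, ny, nz = shape
    ix = int(pos[0] / voxel)
    iy = int(pos[1] / voxel)
    iz = int(pos[2] / voxel)
    if not (0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz):
        return 0, None
    dx, dy, dz = direction
    big = 1e30
    sx = 1 if dx > 0 else -1
    sy = 1 if dy > 0 else -1
    sz = 1 if dz > 0 else -1
    tdx = voxel / abs(dx) if dx != 0 else big
    tdy = voxel / abs(dy) if dy != 0 else big
    tdz = voxel / abs(dz) if dz != 0 else big
    tx = ((ix + (sx > 0)) * voxel - pos[0]) / dx if dx != 0 else big
    ty = ((iy + (sy > 0)) * voxel - pos[1]) / dy if dy != 0 else big
    tz = ((iz + (sz > 0)) * voxel - pos[2]) / dz if dz != 0 else big
    t_prev = 0.0
    remaining = water_path
    while True:
        t_next = tx if tx < ty else ty
        if tz < t_next:
            t_next = tz
        seg = t_next - t_prev
        lab = labels[ix, iy, iz]
        if lab != 0 and seg >= remaining:
            t_hit = t_prev + remaining
            return lab, (pos[0] + dx * t_hit, pos[1] + dy * t_hit, pos[2] + dz * t_hit)
        if lab != 0:
            remaining -= seg
        if tx <= ty and tx <= tz:
            ix += sx
            tx += tdx
            if not (0 <= ix < nx):
                return 0, None
        elif ty <= tz:
            iy += sy
            ty += tdy
            if not (0 <= iy < ny):
                return 0, None
        else:
            iz += sz
            tz += tdz
            if not (0 <= iz < nz):
                return 0, None
        t_prev = t_next


def _sample_compton(alpha: float, rng: np.random.Generator) -> float:
    """Kahn's rejection sampling of the Klein-Nishina scattered-photon
    energy ratio x = E'/E for incident alpha = E/m_e c^2."""
    while True:
        r1, r2, r3 = rng.random(3)
        if r1 <= (1 + 2 * alpha) / (9 + 2 * alpha):
            x = 1 + 2 * alpha * r2
            if r3 <= 4 * (1 / x - 1 / x**2):
                return 1.0 / x
        else:
            x = (1 + 2 * alpha) / (1 + 2 * alpha * r2)
            cos_t = 1 - (x - 1) / alpha
            if r3 <= 0.5 * (cos_t**2 + 1 / x):
                return 1.0 / x


def _rotate(direction, cos_t, phi):
    """New unit vector at polar angle acos(cos_t), azimuth phi, about ``direction``."""
    ux, uy, uz = direction
    sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
    cphi, sphi = math.cos(phi), math.sin(phi)
    if abs(uz) > 0.99999:
        sign = 1.0 if uz > 0 else -1.0
        return (sin_t * cphi, sign * sin_t * sphi, sign * cos_t)
    s = math.sqrt(1.0 - uz * uz)
    vx = sin_t * (cphi * uz * ux - sphi * uy) / s + cos_t * ux
    vy = sin_t * (cphi * uz * uy + sphi * ux) / s + cos_t * uy
    vz = -sin_t * cphi * s + cos_t * uz
    return (vx, vy, vz)


# ---------------------------------------------------------------------------
# main driver


def simulate_s_factors(
    phantom: VoxelPhantom,
    nuclide: NuclideData,
    n_histories: int,
    seed: int,
    *,
    include_electrons: bool = True,
    include_photons: bool = True,
    cutoff_kev: float = 10.0,
    source_regions: list[str] | None = None,
) -> SFactorMatrix:
    """Estimate the S-factor matrix by analog Monte Carlo.

    ``n_histories`` decays are simulated **per source region** (stratified
    sampling: every region gets exactly its quota).  Results are split into
    10 equal batches; ``rel_uncertainty`` is the fractional standard error
    of the batch means.

    Raises ``ValueError`` for empty source regions or an unphysical photon
    cutoff (outside 1-100 keV).
    """
    if n_histories < 1000:
        raise ValueError("n_histories must be >= 1000 for meaningful batch statistics")
    if not (1.0 <= cutoff_kev <= 100.0):
        raise ValueError(f"photon cutoff {cutoff_kev} keV outside the physical 1-100 keV window")
    phys = _physics()
    rng = np.random.default_rng(seed)
    labels = phantom.labels
    voxel = phantom.spec.voxel_size_mm
    shape = labels.shape
    names = phantom.region_names
    id_of = phantom.region_ids
    name_of = {v: k for k, v in id_of.items()}
    max_id = max(id_of.values())
    masses = phantom.region_masses()

    sources = source_regions if source_regions is not None else names
    for s_name in sources:
        if s_name not in id_of:
            raise ValueError(f"unknown source region '{s_name}'")

    lines = nuclide.photon_lines
    beta_yield = min(nuclide.beta_yield, 1.0)

    per_batch = n_histories // _N_BATCHES
    n_used = per_batch * _N_BATCHES

    s_est: dict[tuple[str, str], float] = {}
    s_unc: dict[tuple[str, str], float] = {}

    for s_name in sources:
        src_voxels = np.argwhere(labels == id_of[s_name])
        if src_voxels.size == 0:
            raise ValueError(f"source region '{s_name}' is empty")
        batch_edep = np.zeros((_N_BATCHES, max_id + 1))
        for b in range(_N_BATCHES):
            # decay sites: uniform over source voxels, uniform within voxel
            pick = rng.integers(0, src_voxels.shape[0], per_batch)
            pos = (src_voxels[pick] + rng.random((per_batch, 3))) * voxel
            edep = batch_edep[b]
            if include_electrons:
                emit = rng.random(per_batch) < beta_yield
                energies = nuclide.sample_beta_energy(rng, per_batch)
                ranges = phys.csda_range_mm(energies)
                dirs = _isotropic_directions(rng, per_batch)
                for i in range(per_batch):
                    if not emit[i]:
                        continue
                    e = energies[i]
                    if e < 1.0:  # sub-keV electrons: deposit at the decay site
                        lab = labels[
                            int(pos[i, 0] / voxel), int(pos[i, 1] / voxel), int(pos[i, 2] / voxel)
                        ]
                        edep[lab] += e
                        continue
                    _track_electron(labels, shape, voxel, pos[i], dirs[i], e, ranges[i], edep)
            if include_photons:
                for e_line, intensity in lines:
                    fire = rng.random(per_batch) < intensity
                    idx = np.nonzero(fire)[0]
                    dirs = _isotropic_directions(rng, idx.size)
                    for j, i in enumerate(idx):
                        _track_photon(
                            labels, shape, voxel,
                            (pos[i, 0], pos[i, 1], pos[i, 2]),
                            tuple(dirs[j]), e_line, cutoff_kev, phys, rng, edep,
                        )
        # convert keV -> Gy per decay for every nonempty target region
        for t_name in names:
            m_kg = masses[t_name] * 1e-3
            if m_kg <= 0:
                continue
            tid = id_of[t_name]
            vals = batch_edep[:, tid] * KEV_TO_J / m_kg / per_batch
            mean = float(vals.mean())
            s_est[(t_name, s_name)] = mean
            if mean > 0:
                sem = float(vals.std(ddof=1) / math.sqrt(_N_BATCHES))
                s_unc[(t_name, s_name)] = sem / mean
            else:
                s_unc[(t_name, s_name)] = float("nan")

    config = {
        "seed": seed,
        "n_histories_per_source": n_used,
        "include_electrons": include_electrons,
        "include_photons": include_photons,
        "cutoff_kev": cutoff_kev,
        "voxel_size_mm": voxel,
        "grid": list(shape),
    }
    return SFactorMatrix(s=s_est, rel_uncertainty=s_unc, n_histories=n_used, physics_config=config)


def _track_photon(labels, shape, voxel, pos, direction, energy, cutoff, phys, rng, edep):
    """Transport one photon until absorption, cutoff, or escape."""
    e = energy
    p = pos
    d = direction
    for _ in range(1000):  # hard cap on scatter chain length
        mu_pe = phys.mu_photoelectric(e)
        mu_inc = phys.mu_incoherent(e)
        mu_tot = mu_pe + mu_inc
        path = -math.log(1.0 - rng.random()) / mu_tot
        lab, hit = _march_photon(labels, shape, voxel, p, d, path)
        if hit is None:
            return  # escaped
        if rng.random() < mu_pe / mu_tot:
            edep[lab] += e  # photoelectric absorption
            return
        alpha = e / ELECTRON_REST_KEV
        ratio = _sample_compton(alpha, rng)
        e_sc = e * ratio
        edep[lab] += e - e_sc  # Compton electron deposited locally
        if e_sc < cutoff:
            edep[lab] += e_sc
            return
        cos_t = 1.0 - (1.0 / ratio - 1.0) / alpha
        d = _rotate(d, cos_t, 2.0 * math.pi * rng.random())
        p = hit
        e = e_sc


# ---------------------------------------------------------------------------
# self vs cross dose split


def split_self_vs_cross(
    s: SFactorMatrix, cumulated: dict[str, float]
) -> dict[str, tuple[float, float]]:
    """Per-target (self-dose, total dose) in Gy from cumulated decays.

    ``cumulated`` maps source region -> disintegrations.  The self-dose of a
    target uses only the diagonal S entry; the total sums all sources.
    Raises ``ValueError`` if an active source has no S-matrix entries.
    """
    matrix_sources = set(s.sources())
    missing = [r for r, a in cumulated.items() if a != 0 and r not in matrix_sources]
    if missing:
        raise ValueError(f"sources with cumulated activity but no S entries: {missing}")
    out: dict[str, tuple[float, float]] = {}
    for t in s.targets():
        self_dose = cumulated.get(t, 0.0) * s.s.get((t, t), 0.0)
        total = sum(a * s.s.get((t, src), 0.0) for src, a in cumulated.items())
        out[t] = (self_dose, total)
    return out
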