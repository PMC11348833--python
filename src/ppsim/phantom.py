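"""Voxelized tissue phantoms.

A phantom is a 3D integer label grid plus a tissue-class table.  Voxel
indices are 0-based; physical coordinates are voxel-center, in micrometres,
right-handed, with z the insertion/depth axis (z = 0 is the outer surface
through which a probe enters).

Two builders are provided: a layered slab (the canonical Monte Carlo test
geometry) and a parametric rat-head phantom — skull shell, CSF gap, grey
matter bulk, white-matter ellipsoid, a nerve-tract cylinder, blood-vessel
cylinders, and a hippocampus stand-in target ellipsoid recorded as a voxel
mask.  The parametric phantom deliberately replaces MRI-derived anatomy:
it reproduces the optical layering that controls light delivery without
pretending to anatomical fidelity.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .optics import OpticalProperties, TissueClass, load_tissue_table


@dataclass
class TissuePhantom:
    """Voxel label grid + tissue classes + run metadata."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float]
    classes: list[TissueClass]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.ascontiguousarray(self.labels, dtype=np.int16)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D grid")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be three strictly positive values [um]")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        labels_used = set(np.unique(self.labels).tolist())
        known = {c.label for c in self.classes}
        if len(known) != len(self.classes):
            raise ValueError("duplicate labels in class table")
        missing = labels_used - known
        if missing:
            raise ValueError(f"label(s) {sorted(missing)} in grid have no TissueClass")
        self.metadata.setdefault("origin_um", (0.0, 0.0, 0.0))
        self.metadata.setdefault("axes", "RAS-like, z = insertion/depth axis")

    # ------------------------------------------------------------------ info
    @property
    def dims(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_cm3(self) -> float:
        dx, dy, dz = self.voxel_size
        return (dx * dy * dz) * 1e-12  # um^3 -> cm^3

    @property
    def class_map(self) -> dict[int, TissueClass]:
        return {c.label: c for c in self.classes}

    def class_by_name(self, name: str) -> TissueClass:
        for c in self.classes:
            if c.name == name:
                return c
        raise KeyError(f"no tissue class named '{name}'")

    def class_counts(self) -> dict[str, int]:
        """Voxel count per class name; counts sum to nx*ny*nz."""
        labels, counts = np.unique(self.labels, return_counts=True)
        cmap = self.class_map
        return {cmap[int(l)].name: int(c) for l, c in zip(labels, counts)}

    def target_mask(self) -> np.ndarray | None:
        return self.metadata.get("target_mask")

    def property_arrays(
        self, wavelength: float, interpolate: bool = False
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Per-label lookup arrays (mu_a, mu_s, g, n) at one wavelength.

        Arrays are indexed by label id; labels without a class (unused ids)
        get vacuum-like placeholders.
        """
        nmax = max(int(self.labels.max()), max(c.label for c in self.classes)) + 1
        mua = np.zeros(nmax)
        mus = np.zeros(nmax)
        g = np.zeros(nmax)
        n = np.ones(nmax)
        for c in self.classes:
            if c.label >= nmax:
                continue
            p = c.at(wavelength, interpolate=interpolate)
            mua[c.label] = p.mu_a
            mus[c.label] = p.mu_s
            g[c.label] = p.g
            n[c.label] = p.n
        return mua, mus, g, n

    def voxel_centers(self, axis: int) -> np.ndarray:
        """Physical voxel-center coordinates [um] along one axis."""
        return (np.arange(self.dims[axis]) + 0.5) * self.voxel_size[axis]


# ---------------------------------------------------------------- builders
def build_layered_slab(
    layers: Sequence[tuple[TissueClass, float]],
    dims: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
) -> TissuePhantom:
    """Stack tissue layers along z.

    Each (class, thickness_um) layer is rounded to whole voxels; a layer
    thinner than one voxel is an error.  Any depth beyond the last layer is
    filled with ambient.
    """
    if not layers:
        raise ValueError("at least one layer required")
    nx, ny, nz = dims
    dz = voxel_size[2]
    total = sum(t for _, t in layers)
    if total > nz * dz + 1e-9:
        raise ValueError(
            f"layer thicknesses sum to {total} um > domain depth {nz * dz} um"
        )
    classes: dict[int, TissueClass] = {}
    labels = np.zeros(dims, dtype=np.int16)
    z0 = 0
    for cls, thickness in layers:
        if thickness < dz:
            raise ValueError(
                f"layer '{cls.name}' ({thickness} um) is thinner than one voxel ({dz} um)"
            )
        nvox = int(round(thickness / dz))
        labels[:, :, z0 : z0 + nvox] = cls.label
        if cls.label in classes and classes[cls.label].name != cls.name:
            raise ValueError(f"conflicting classes for label {cls.label}")
        classes[cls.label] = cls
        z0 += nvox
    if z0 < nz:
        ambient = _default_class("ambient")
        if ambient.label in classes and classes[ambient.label].name != "ambient":
            raise ValueError("label 0 already used by a non-ambient layer")
        classes.setdefault(ambient.label, ambient)
        labels[:, :, z0:] = ambient.label
    return TissuePhantom(labels=labels, voxel_size=voxel_size, classes=list(classes.values()))


_RAT_HEAD_DEFAULTS = {
    "ambient_thickness_um": 200.0,
    "skull_thickness_um": 600.0,
    "csf_thickness_um": 200.0,
    # hippocampus stand-in, centred laterally at ~3.5 mm depth
    "target_center_um": None,  # None -> lateral centre, depth 3500
    "target_depth_um": 3500.0,
    "target_semiaxes_um": (800.0, 800.0, 600.0),
    "white_depth_um": 5200.0,
    "white_semiaxes_um": (1200.0, 1200.0, 2200.0),
    "nerve_depth_um": 6800.0,
    "nerve_radius_um": 200.0,
    "n_vessels": 3,
    "vessel_radius_um": 60.0,
}


def build_rat_head_phantom(
    dims: tuple[int, int, int] = (100, 100, 200),
    voxel_size: tuple[float, float, float] = (40.0, 40.0, 40.0),
    config: dict | None = None,
    classes: list[TissueClass] | None = None,
) -> TissuePhantom:
    """Parametric six-tissue rat-head section phantom.

    Along z: ambient gap, skull shell, CSF gap, then brain (grey-matter bulk
    with a white-matter ellipsoid and a nerve-tract cylinder).  Blood vessels
    are thin cylinders.  The target region (hippocampus stand-in) is an
    ellipsoid recorded in ``metadata['target_mask']``; it must lie fully
    inside grey/white matter.
    """
    cfg = dict(_RAT_HEAD_DEFAULTS)
    if config:
        unknown = set(config) - set(cfg)
        if unknown:
            raise ValueError(f"unknown rat-head config keys: {sorted(unknown)}")
        cfg.update(config)
    table = {c.name: c for c in (classes or load_tissue_table())}
    for name in (
        "ambient",
        "grey_matter",
        "white_matter",
        "csf",
        "bone",
        "blood_vessel",
        "nerve_tissue",
    ):
        if name not in table:
            raise ValueError(f"class table lacks '{name}'")

    nx, ny, nz = dims
    dx, dy, dz = voxel_size
    depth_total = nz * dz
    z_brain_top = (
        cfg["ambient_thickness_um"]
        + cfg["skull_thickness_um"]
        + cfg["csf_thickness_um"]
    )
    if z_brain_top + 1000.0 > depth_total:
        raise ValueError(
            "domain too shallow for skull + CSF + brain; increase nz or dz"
        )

    x = (np.arange(nx) + 0.5) * dx
    y = (np.arange(ny) + 0.5) * dy
    z = (np.arange(nz) + 0.5) * dz
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    cx, cy = nx * dx / 2.0, ny * dy / 2.0

    lab = np.full(dims, table["grey_matter"].label, dtype=np.int16)
    lab[Z < z_brain_top] = table["csf"].label
    lab[Z < cfg["ambient_thickness_um"] + cfg["skull_thickness_um"]] = table["bone"].label
    lab[Z < cfg["ambient_thickness_um"]] = table["ambient"].label

    def _ellipsoid(center, semi):
        return (
            ((X - center[0]) / semi[0]) ** 2
            + ((Y - center[1]) / semi[1]) ** 2
            + ((Z - center[2]) / semi[2]) ** 2
        ) <= 1.0

    white = _ellipsoid((cx, cy, cfg["white_depth_um"]), cfg["white_semiaxes_um"])
    white &= Z >= z_brain_top
    lab[white] = table["white_matter"].label

    # nerve tract: cylinder along y at fixed depth
    nerve = (
        (X - cx) ** 2 + (Z - cfg["nerve_depth_um"]) ** 2
    ) <= cfg["nerve_radius_um"] ** 2
    nerve &= Z >= z_brain_top
    lab[nerve] = table["nerve_tissue"].label

    # blood vessels: up to two penetrating (along z) + one transverse (along x)
    rv = cfg["vessel_radius_um"]
    vessel_axes = [
        ("z", (cx - 1200.0, cy - 800.0)),
        ("z", (cx + 1200.0, cy + 800.0)),
        ("x", (cy + 1000.0, 2000.0 + z_brain_top)),
    ][: int(cfg["n_vessels"])]
    for axis, c in vessel_axes:
        if axis == "z":
            m = ((X - c[0]) ** 2 + (Y - c[1]) ** 2) <= rv**2
            m &= Z >= z_brain_top
        else:
            m = ((Y - c[0]) ** 2 + (Z - c[1]) ** 2) <= rv**2
            m &= Z >= z_brain_top
        lab[m] = table["blood_vessel"].label

    tc = cfg["target_center_um"] or (cx, cy, cfg["target_depth_um"])
    target = _ellipsoid(tc, cfg["target_semiaxes_um"])
    if not target.any():
        raise ValueError("target ellipsoid contains no voxels")
    brain_labels = {table["grey_matter"].label, table["white_matter"].label}
    inside = np.isin(lab[target], list(brain_labels))
    if not inside.all():
        raise ValueError(
            "target region extends outside grey/white brain tissue "
            f"({(~inside).sum()} of {inside.size} voxels)"
        )

    phantom = TissuePhantom(
        labels=lab,
        voxel_size=voxel_size,
        classes=[copy.deepcopy(c) for c in table.values()],
        metadata={"preset": "rat_head", "target_mask": target, "config": cfg},
    )
    return phantom


# ------------------------------------------------------------------- probe
@dataclass
class ProbeSpec:
    """Implanted light-delivery probe, modelled optically only.

    The shaft is a rectangular cuboid inserted along z from the z=0 face; a
    transparent core is wrapped laterally by a thin lower-index cladding
    (the emission face at the tip is open).  Core index > cladding index is
    the total-internal-reflection guiding condition.
    """

    width_um: float = 200.0
    height_um: float = 200.0
    depth_um: float = 4000.0
    cladding_um: float = 4.0
    core_n: float = 1.56
    cladding_n: float = 1.40
    center_um: tuple[float, float] | None = None

    @property
    def guiding(self) -> bool:
        return self.core_n > self.cladding_n

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0:
            raise ValueError("probe cross-section must be positive")
        if self.depth_um < 0:
            raise ValueError("insertion depth must be >= 0")
        if self.cladding_um < 0 or 2 * self.cladding_um >= min(
            self.width_um, self.height_um
        ):
            raise ValueError("cladding thickness incompatible with shaft cross-section")


def insert_probe(phantom: TissuePhantom, probe: ProbeSpec) -> TissuePhantom:
    """Return a new phantom with the probe shaft stamped into the label grid.

    Only voxels whose centres lie geometrically inside the shaft are
    reassigned (to probe_core / probe_cladding); all other labels are
    preserved.  The emission-face position and the guiding flag are recorded
    in metadata.  Raises if the shaft extends outside the grid.
    """
    nx, ny, nz = phantom.dims
    dx, dy, dz = phantom.voxel_size
    cx, cy = probe.center_um or (nx * dx / 2.0, ny * dy / 2.0)
    hw, hh = probe.width_um / 2.0, probe.height_um / 2.0
    if cx - hw < 0 or cx + hw > nx * dx or cy - hh < 0 or cy + hh > ny * dy:
        raise ValueError("probe shaft extends laterally outside the grid")
    if probe.depth_um > nz * dz:
        raise ValueError("probe insertion depth exceeds grid depth")

    new = TissuePhantom(
        labels=phantom.labels.copy(),
        voxel_size=phantom.voxel_size,
        classes=[copy.deepcopy(c) for c in phantom.classes],
        metadata=dict(phantom.metadata),
    )
    core_cls = _ensure_probe_class(new, "probe_core", probe.core_n)
    clad_cls = _ensure_probe_class(new, "probe_cladding", probe.cladding_n)

    if probe.depth_um > 0:
        x = (np.arange(nx) + 0.5) * dx
        y = (np.arange(ny) + 0.5) * dy
        z = (np.arange(nz) + 0.5) * dz
        in_x = np.abs(x - cx) < hw
        in_y = np.abs(y - cy) < hh
        in_z = z < probe.depth_um
        shaft = in_x[:, None, None] & in_y[None, :, None] & in_z[None, None, :]
        core_x = np.abs(x - cx) < hw - probe.cladding_um
        core_y = np.abs(y - cy) < hh - probe.cladding_um
        core = core_x[:, None, None] & core_y[None, :, None] & in_z[None, None, :]
        new.labels[shaft] = clad_cls.label
        new.labels[core] = core_cls.label

    new.metadata["probe"] = {
        "emission_face_um": (float(cx), float(cy), float(probe.depth_um)),
        "cross_section_um": (probe.width_um, probe.height_um),
        "cladding_um": probe.cladding_um,
        "core_n": probe.core_n,
        "cladding_n": probe.cladding_n,
        "guiding": probe.guiding,
    }
    return new


def _default_class(name: str) -> TissueClass:
    for c in load_tissue_table():
        if c.name == name:
            return c
    raise KeyError(name)


def _ensure_probe_class(phantom: TissuePhantom, name: str, n: float) -> TissueClass:
    """Find or add the probe class, overriding its refractive index."""
    try:
        cls = phantom.class_by_name(name)
    except KeyError:
        cls = copy.deepcopy(_default_class(name))
        used = {c.label for c in phantom.classes}
        if cls.label in used:
            cls.label = max(used) + 1
        phantom.classes.append(cls)
    cls.properties = {
        wl: replace(p, n=n) for wl, p in cls.properties.items()
    }
    return cls
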