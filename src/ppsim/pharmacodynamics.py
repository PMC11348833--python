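"""IC50-based pharmacodynamic mapping.

The active-isomer concentration field is converted voxelwise to a
fractional inhibition via the Hill equation

    f = C^h / (C^h + IC50^h)

and to a binary inhibited/unaffected classification at a configurable
threshold (half-maximal by default, boundary inclusive: a voxel exactly at
C = IC50 with threshold 0.5 counts as inhibited).  Inhibition is modelled
as direct occupancy; there is no receptor-density or competition model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .photokinetics import ConcentrationField


@dataclass
class PharmacodynamicSpec:
    """IC50 [mol L⁻¹], Hill coefficient, active isomer and binary threshold."""

    ic50: float = 3.1e-6
    hill: float = 1.0
    active_isomer: str = "Z"
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.ic50 <= 0:
            raise ValueError("IC50 must be > 0")
        if self.hill <= 0:
            raise ValueError("Hill coefficient must be > 0")
        if self.active_isomer not in ("E", "Z"):
            raise ValueError("active isomer must be 'E' or 'Z'")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")


def inhibition_fraction(c_active, pd_spec: PharmacodynamicSpec):
    """Hill occupancy f = C^h/(C^h + IC50^h); monotone in C, f(0) = 0."""
    c = np.asarray(c_active, dtype=float)
    if (c < 0).any():
        raise ValueError("concentrations must be >= 0")
    if pd_spec.hill == 1.0:  # avoids pow: exact, and the common case
        out = c / (c + pd_spec.ic50)
    else:
        ch = c**pd_spec.hill
        out = ch / (ch + pd_spec.ic50**pd_spec.hill)
    return out if out.ndim else float(out)


@dataclass
class InhibitionMap:
    fraction: np.ndarray
    inhibited: np.ndarray
    voxel_size_um: tuple[float, float, float]
    inhibited_count: int
    inhibited_volume_mm3: float
    target_fraction_inhibited: float | None = None

    def summary(self) -> dict:
        d = {
            "inhibited_voxels": self.inhibited_count,
            "inhibited_volume_mm3": self.inhibited_volume_mm3,
        }
        if self.target_fraction_inhibited is not None:
            d["target_fraction_inhibited"] = self.target_fraction_inhibited
        return d


def classify_map(
    field: ConcentrationField,
    pd_spec: PharmacodynamicSpec,
    voxel_size_um: tuple[float, float, float],
    target_mask: np.ndarray | None = None,
) -> InhibitionMap:
    """Voxelwise inhibition map + inhibited/unaffected classification.

    Summaries cover the whole grid and, when a target mask is given, the
    fraction of target voxels classified inhibited.  Volume is exactly
    count × voxel volume.
    """
    c_active = field.c_z if pd_spec.active_isomer == "Z" else field.c_e
    fraction = inhibition_fraction(c_active, pd_spec)
    inhibited = fraction >= pd_spec.threshold
    count = int(inhibited.sum())
    voxel_mm3 = float(np.prod(voxel_size_um)) * 1e-9
    target_frac = None
    if target_mask is not None:
        target_mask = np.asarray(target_mask, dtype=bool)
        if target_mask.shape != fraction.shape:
            raise ValueError("target mask grid does not match the field")
        n_target = int(target_mask.sum())
        target_frac = float(inhibited[target_mask].sum() / n_target) if n_target else 0.0
    return InhibitionMap(
        fraction=fraction,
        inhibited=inhibited,
        voxel_size_um=tuple(voxel_size_um),
        inhibited_count=count,
        inhibited_volume_mm3=count * voxel_mm3,
        target_fraction_inhibited=target_frac,
    )


def dose_response_report(
    powers_w,
    solve,
    pd_spec: PharmacodynamicSpec,
    voxel_size_um: tuple[float, float, float],
    target_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Inhibited fraction versus source power.

    ``solve(power)`` must return a ConcentrationField for the given source
    power [W] (typically a closure over ``coupled_solve``); one row is
    produced per requested power.  This answers the design question of how
    the light power modulates the treated volume.
    """
    rows = []
    for p in powers_w:
        field = solve(float(p))
        imap = classify_map(field, pd_spec, voxel_size_um, target_mask)
        row = {"power_w": float(p), **imap.summary()}
        rows.append(row)
    return pd.DataFrame(rows)
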