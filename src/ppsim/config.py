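"""Pipeline configuration: loading, validation, construction of run objects.

A single YAML file drives the whole pipeline.  ``validate_config`` performs
schema and cross-reference checks (every wavelength referenced by a source
must have an entry in the tissue optical table and lie inside the
photoswitch spectra) before any compute is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .phantom import ProbeSpec, TissuePhantom, build_layered_slab, build_rat_head_phantom, insert_probe
from .photokinetics import PhotoswitchSpec
from .pharmacodynamics import PharmacodynamicSpec
from .sources import SourceSpec
from .transport import RunConfig

def demo_config_path() -> Path:
    """Path to the packaged rat-head demo pipeline configuration."""
    from importlib import resources

    return Path(str(resources.files("ppsim").joinpath("data/demo_pipeline.yaml")))


_DEFAULTS = {
    "seed": 1,
    "output_dir": "ppsim_out",
    "c0_mol_per_l": 1.0e-5,
}


@dataclass
class PipelineConfig:
    """Validated, materialized pipeline configuration."""

    phantom: TissuePhantom
    sources: list[SourceSpec]
    run: RunConfig
    photoswitch: PhotoswitchSpec
    c0_mol_per_l: float
    pharmacodynamics: PharmacodynamicSpec
    coupling: dict
    output_dir: Path
    seed: int
    raw: dict = field(default_factory=dict)


def load_config(path: str | Path) -> PipelineConfig:
    """Load + validate a pipeline YAML; raises ValueError listing problems."""
    raw = yaml.safe_load(Path(path).read_text())
    errors = _check(raw, base_dir=Path(path).parent)
    if errors:
        raise ValueError("invalid config:\n- " + "\n- ".join(errors))
    return _materialize(raw, base_dir=Path(path).parent)


def validate_config(path: str | Path) -> list[str]:
    """Return the list of validation errors (empty when the config is valid)."""
    try:
        raw = yaml.safe_load(Path(path).read_text())
    except Exception as exc:  # malformed YAML is a validation failure
        return [f"cannot parse YAML: {exc}"]
    if not isinstance(raw, dict):
        return ["config must be a mapping"]
    return _check(raw, base_dir=Path(path).parent)


def _build_phantom(raw: dict, base_dir: Path) -> TissuePhantom:
    from .io import read_phantom
    from .optics import load_tissue_table

    ph = raw.get("phantom", {})
    if "path" in ph:
        phantom = read_phantom(base_dir / ph["path"])
    else:
        preset = ph.get("preset", "rat_head")
        dims = tuple(ph.get("dims", (100, 100, 200)))
        vox = tuple(ph.get("voxel_um", (40.0, 40.0, 40.0)))
        if preset in ("rat_head", "rat-head"):
            phantom = build_rat_head_phantom(dims, vox, config=ph.get("config"))
        elif preset == "slab":
            table = {c.name: c for c in load_tissue_table()}
            layers = [
                (table[name], float(thickness))
                for name, thickness in ph.get(
                    "layers", [["grey_matter", dims[2] * vox[2]]]
                )
            ]
            phantom = build_layered_slab(layers, dims, vox)
        else:
            raise ValueError(f"unknown phantom preset '{preset}'")
    if ph.get("probe"):
        phantom = insert_probe(phantom, ProbeSpec(**ph["probe"]))
    return phantom


def _photoswitch(raw: dict, base_dir: Path) -> PhotoswitchSpec:
    ps = raw.get("photoswitch", "synthetic")
    if ps == "synthetic":
        return PhotoswitchSpec.synthetic_azobenzene_inhibitor()
    return PhotoswitchSpec.from_files(base_dir / ps)


def _sources(raw: dict) -> list[SourceSpec]:
    out = []
    for s in raw.get("sources", []):
        out.append(
            SourceSpec(
                kind=s["kind"],
                position_um=tuple(s["position_um"]),
                direction=tuple(s.get("direction", (0, 0, 1))),
                radius_um=float(s.get("radius_um", 0.0)),
                half_angle_deg=float(s.get("half_angle_deg", 20.0)),
                power_w={float(k): float(v) for k, v in s.get("power_w", {}).items()},
            )
        )
    return out


def _check(raw: dict, base_dir: Path) -> list[str]:
    errors: list[str] = []
    run = raw.get("run", {})
    n_photons = run.get("n_photons", 100_000)
    if not isinstance(n_photons, (int, float)) or n_photons < 1:
        errors.append(f"run.n_photons must be a positive count, got {n_photons!r}")
    wavelengths = [float(w) for w in run.get("wavelengths", [460.0])]
    if not raw.get("sources"):
        errors.append("at least one source is required")

    # phantom + optical-table cross-checks
    try:
        phantom = _build_phantom(raw, base_dir)
    except Exception as exc:
        errors.append(f"phantom: {exc}")
        phantom = None
    if phantom is not None:
        for wl in wavelengths:
            for cls in phantom.classes:
                try:
                    p = cls.at(wl)
                except KeyError:
                    errors.append(
                        f"tissue class '{cls.name}' has no optical properties "
                        f"at {wl} nm"
                    )
                    continue
                if not (-1.0 < p.g < 1.0):
                    errors.append(f"class '{cls.name}': anisotropy g={p.g} invalid")

    try:
        spec = _photoswitch(raw, base_dir)
    except Exception as exc:
        errors.append(f"photoswitch: {exc}")
        spec = None
    if spec is not None:
        lo, hi = spec.wavelengths_nm[0], spec.wavelengths_nm[-1]
        for wl in wavelengths:
            if not (lo <= wl <= hi):
                errors.append(
                    f"wavelength {wl} nm outside photoswitch spectra range "
                    f"[{lo}, {hi}] nm"
                )

    for i, s in enumerate(raw.get("sources", [])):
        try:
            src = SourceSpec(
                kind=s.get("kind", "pencil"),
                position_um=tuple(s.get("position_um", (0, 0, 0))),
                direction=tuple(s.get("direction", (0, 0, 1))),
                radius_um=float(s.get("radius_um", 0.0)),
                half_angle_deg=float(s.get("half_angle_deg", 20.0)),
                power_w={float(k): float(v) for k, v in s.get("power_w", {}).items()},
            )
        except Exception as exc:
            errors.append(f"sources[{i}]: {exc}")
            continue
        for wl in src.power_w:
            if wl not in wavelengths:
                errors.append(
                    f"sources[{i}] provides power at {wl} nm which is not in "
                    f"run.wavelengths {wavelengths}"
                )

    pdc = raw.get("pharmacodynamics", {})
    try:
        PharmacodynamicSpec(
            ic50=float(pdc.get("ic50", 3.1e-6)),
            hill=float(pdc.get("hill", 1.0)),
            active_isomer=pdc.get("active_isomer", "Z"),
            threshold=float(pdc.get("threshold", 0.5)),
        )
    except Exception as exc:
        errors.append(f"pharmacodynamics: {exc}")

    c0 = raw.get("c0_mol_per_l", _DEFAULTS["c0_mol_per_l"])
    if not (float(c0) >= 0):
        errors.append(f"c0_mol_per_l must be >= 0, got {c0}")
    coupling = raw.get("coupling", {})
    if coupling.get("mode", "pss") not in ("pss", "time", "uncoupled"):
        errors.append("coupling.mode must be pss, time or uncoupled")
    return errors


def _materialize(raw: dict, base_dir: Path) -> PipelineConfig:
    run_raw = raw.get("run", {})
    seed = int(raw.get("seed", _DEFAULTS["seed"]))
    run = RunConfig(
        n_photons=int(run_raw.get("n_photons", 100_000)),
        rng_seed=seed,
        wavelengths=tuple(float(w) for w in run_raw.get("wavelengths", [460.0])),
        roulette_threshold=float(run_raw.get("roulette_threshold", 1e-4)),
        roulette_survival=float(run_raw.get("roulette_survival", 0.1)),
        max_path_cm=float(run_raw.get("max_path_cm", 100.0)),
    )
    pdc = raw.get("pharmacodynamics", {})
    return PipelineConfig(
        phantom=_build_phantom(raw, base_dir),
        sources=_sources(raw),
        run=run,
        photoswitch=_photoswitch(raw, base_dir),
        c0_mol_per_l=float(raw.get("c0_mol_per_l", _DEFAULTS["c0_mol_per_l"])),
        pharmacodynamics=PharmacodynamicSpec(
            ic50=float(pdc.get("ic50", 3.1e-6)),
            hill=float(pdc.get("hill", 1.0)),
            active_isomer=pdc.get("active_isomer", "Z"),
            threshold=float(pdc.get("threshold", 0.5)),
        ),
        coupling=dict(raw.get("coupling", {"mode": "pss", "tolerance": 1e-2, "max_iter": 5})),
        output_dir=Path(raw.get("output_dir", _DEFAULTS["output_dir"])),
        seed=seed,
        raw=raw,
    )
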