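"""Serialization glue: subject metadata, fit results, cohort specs, manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path

import yaml

from .data_model import Dosing, PlasmaParams, SubjectDataset, TissueParams, read_tac_csv, write_tac_csv
from .fitting import FitResult

__all__ = [
    "save_subject",
    "load_subject",
    "save_fit",
    "load_fit",
    "save_json",
    "load_json",
    "file_sha256",
    "write_manifest",
]


def save_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def load_json(path):
    return json.loads(Path(path).read_text())


def save_fit(path, fit: FitResult) -> None:
    save_json(path, fit.to_dict())


def load_fit(path) -> FitResult:
    return FitResult.from_dict(load_json(path))


def save_subject(out_dir, subject: SubjectDataset) -> tuple[Path, Path]:
    """Write one subject as a TAC CSV plus a YAML metadata sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tac_path = out_dir / f"{subject.subject_id}_tacs.csv"
    meta_path = out_dir / f"{subject.subject_id}_meta.yaml"
    tacs = {"blood": subject.blood_tac, **subject.region_tacs}
    write_tac_csv(tac_path, tacs)
    meta = {
        "subject_id": subject.subject_id,
        "fus_applied": bool(subject.fus_applied),
        "fus_to_injection_delay_min": float(subject.fus_to_injection_delay),
        "dosing": {
            "injected_activity_MBq": subject.dosing.injected_activity,
            "specific_activity_MBq_per_nmol": subject.dosing.specific_activity,
            "molar_mass_ug_per_nmol": subject.dosing.molar_mass,
        },
    }
    true_params = subject.true_params
    if true_params:
        meta["true_params"] = {
            "plasma": asdict(true_params["plasma"]),
            "tissue": {r: asdict(tp) for r, tp in true_params["tissue"].items()},
            "flooring_rate": float(true_params.get("flooring_rate", 0.0)),
        }
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=False))
    return tac_path, meta_path


def load_subject(tac_path, meta_path) -> SubjectDataset:
    meta = yaml.safe_load(Path(meta_path).read_text())
    tacs = read_tac_csv(tac_path)
    if "blood" not in tacs:
        raise ValueError(f"{tac_path}: no 'blood' region found")
    blood = tacs.pop("blood")
    d = meta["dosing"]
    true_params = {}
    if "true_params" in meta:
        tp = meta["true_params"]
        true_params = {
            "plasma": PlasmaParams(**tp["plasma"]),
            "tissue": {r: TissueParams(**v) for r, v in tp["tissue"].items()},
            "flooring_rate": tp.get("flooring_rate", 0.0),
        }
    return SubjectDataset(
        subject_id=meta["subject_id"],
        dosing=Dosing(
            injected_activity=d["injected_activity_MBq"],
            specific_activity=d["specific_activity_MBq_per_nmol"],
            molar_mass=d.get("molar_mass_ug_per_nmol", 150.0),
        ),
        fus_applied=meta["fus_applied"],
        fus_to_injection_delay=meta.get("fus_to_injection_delay_min", 1.7),
        blood_tac=blood,
        region_tacs=tacs,
        true_params=true_params,
    )


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, inputs: dict, seed: int, outputs: list) -> None:
    """Reproducibility manifest: seed, inputs, and output file hashes."""
    import fuspet

    manifest = {
        "package_version": fuspet.__version__,
        "seed": seed,
        "inputs": inputs,
        "outputs": {str(p): file_sha256(p) for p in outputs},
    }
    save_json(path, manifest)
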