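"""File formats: TCSPC stacks as multi-page TIFF, manifests and configs as YAML,
curves as CSV, case reports as JSON.

A TCSPC image is stored as a multi-page TIFF whose pages are the K time bins, with
a small YAML sidecar (``<stem>.meta.yaml``) carrying the acquisition metadata needed
to interpret it (repetition rate, bin count/width, harmonic). Fraction maps and
ground-truth fields are single-page floating-point TIFFs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .config import TIMEPOINTS, AcquisitionConfig
from .errors import FormatError, ManifestError
from .fractions import FractionalDistribution
from .phasor import TCSPCImage


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".meta.yaml")


def save_tcspc(image: TCSPCImage, path: str | Path) -> Path:
    """Write a TCSPC image as a multi-page TIFF (pages = time bins) plus sidecar."""
    path = Path(path)
    stack = np.moveaxis(image.counts, 2, 0).astype(np.uint32)
    tifffile.imwrite(path, stack)
    meta = {
        "repetition_rate_mhz": image.acquisition.repetition_rate_mhz,
        "n_time_bins": image.acquisition.n_time_bins,
        "bin_width_ns": image.acquisition.bin_width_ns,
        "harmonic": image.acquisition.harmonic,
    }
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    return path


def load_tcspc(path: str | Path, acquisition: AcquisitionConfig) -> TCSPCImage:
    """Load a multi-page TIFF stack and validate it against the run configuration."""
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"TCSPC file not found: {path}")
    stack = tifffile.imread(path)
    if stack.ndim == 2:
        stack = stack[None, ...]
    if stack.ndim != 3:
        raise FormatError(f"{path}: expected a 3-D page stack, got shape {stack.shape}")
    if stack.shape[0] != acquisition.n_time_bins:
        raise FormatError(
            f"{path}: stack has {stack.shape[0]} pages but the configuration "
            f"declares {acquisition.n_time_bins} time bins"
        )
    counts = np.moveaxis(stack, 0, 2)
    if counts.size and counts.min() < 0:
        raise FormatError(f"{path}: negative photon counts")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
        rate = meta.get("repetition_rate_mhz")
        if rate is not None and not np.isclose(rate, acquisition.repetition_rate_mhz):
            raise FormatError(
                f"{path}: sidecar repetition rate {rate} MHz does not match "
                f"configured {acquisition.repetition_rate_mhz} MHz"
            )
    return TCSPCImage(counts=counts.astype(np.int64), acquisition=acquisition)


def save_float_image(array: np.ndarray, path: str | Path) -> Path:
    """Write a single-page floating-point TIFF (fraction maps, ground truth)."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(array, dtype=np.float32))
    return path


@dataclass(frozen=True)
class CaseManifest:
    """One case: per timepoint, the control and treated replicate image paths."""

    case_id: str
    timepoints: dict[str, tuple[list[Path], list[Path]]]
    calibration_path: Path | None = None
    calibration_tau_ns: float | None = None


def save_manifest(manifest: CaseManifest, path: str | Path) -> Path:
    path = Path(path)
    doc: dict = {"case_id": manifest.case_id, "timepoints": {}}
    for tp, (ctrl, trt) in manifest.timepoints.items():
        doc["timepoints"][tp] = {
            "control": [str(p) for p in ctrl],
            "treated": [str(p) for p in trt],
        }
    if manifest.calibration_path is not None:
        doc["calibration"] = {
            "path": str(manifest.calibration_path),
            "tau_ns": manifest.calibration_tau_ns,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)
    return path


def load_manifest(path: str | Path) -> CaseManifest:
    """Parse and validate a case manifest; all referenced files must exist."""
    path = Path(path)
    if not path.exists():
        raise ManifestError(f"manifest not found: {path}")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "timepoints" not in doc:
        raise ManifestError(f"{path}: manifest must be a mapping with a 'timepoints' key")
    base = path.parent
    timepoints: dict[str, tuple[list[Path], list[Path]]] = {}
    for tp, arms in doc["timepoints"].items():
        if tp not in TIMEPOINTS:
            raise ManifestError(f"{path}: unknown timepoint label {tp!r}")
        resolved: dict[str, list[Path]] = {}
        for arm in ("control", "treated"):
            paths = [base / p for p in arms.get(arm, [])]
            if len(paths) < 2:
                raise ManifestError(
                    f"{path}: timepoint {tp} arm {arm} lists {len(paths)} images; "
                    "at least 2 replicates are required"
                )
            for p in paths:
                if not p.exists():
                    raise ManifestError(f"{path}: referenced file missing: {p}")
            resolved[arm] = paths
        timepoints[tp] = (resolved["control"], resolved["treated"])
    if not timepoints:
        raise ManifestError(f"{path}: no timepoints listed")
    cal = doc.get("calibration")
    cal_path = cal_tau = None
    if cal is not None:
        cal_path = base / cal["path"]
        cal_tau = float(cal["tau_ns"])
        if not cal_path.exists():
            raise ManifestError(f"{path}: calibration file missing: {cal_path}")
    return CaseManifest(
        case_id=str(doc.get("case_id", path.stem)),
        timepoints=timepoints,
        calibration_path=cal_path,
        calibration_tau_ns=cal_tau,
    )


def score_table(
    bin_edges: np.ndarray,
    control_mean: np.ndarray,
    treated_mean: np.ndarray,
    p_values: np.ndarray,
    significant: np.ndarray,
) -> pd.DataFrame:
    """Per-segment comparison table written alongside each timepoint score."""
    return pd.DataFrame(
        {
            "bin_low": bin_edges[:-1],
            "bin_high": bin_edges[1:],
            "control_mean": control_mean,
            "treated_mean": treated_mean,
            "p_value": p_values,
            "significant": significant.astype(bool),
        }
    )


def distribution_to_csv(dist: FractionalDistribution, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {"bin_low": dist.bin_edges[:-1], "bin_high": dist.bin_edges[1:], "height": dist.heights}
    ).to_csv(path, index=False)
    return path


def write_report(report: dict, path: str | Path) -> Path:
    """Write a case report as JSON with stable key order (diff-able artifacts)."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
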