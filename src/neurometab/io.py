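"""File formats, run configuration and provenance.

Cohort tables are CSV with missing values as empty fields (never sentinel
numbers).  Voxel stacks are 4D NIfTI (subject along the 4th axis) with a
3D NIfTI mask and a sidecar CSV recording subject order; missing imaging
sessions are represented by absent subjects in the sidecar, not by NaN
volumes.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from neurometab.voxel import VoxelStack

COHORT_COLUMNS = [
    "subject_id", "group", "hoc", "sex", "age", "collision", "session",
    "dacu", "drtp", "naa_cr", "ins_cr", "naa_cho", "ins_cho", "observed",
]


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Malformed or inconsistent input data (CLI exit code 3)."""


@dataclass
class RunConfig:
    """All tunable analysis knobs with their standard defaults."""

    seed: int = 0
    B: int = 1000
    M: int = 10
    fdr_q: float = 0.05
    voxel_p: float = 0.005
    cluster_alpha: float = 0.05
    winsor_tail: float = 0.05
    imputation_mode: str = "conditional"
    connectivity: int = 6
    cluster_n_sims: int = 1000
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.B < 1 or self.M < 1:
            raise ConfigError("B and M must be >= 1")
        for name in ("fdr_q", "voxel_p", "cluster_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ConfigError(f"{name} must lie in (0, 1)")
        if self.imputation_mode not in ("conditional", "marginal"):
            raise ConfigError("imputation_mode must be conditional or marginal")
        if self.connectivity not in (6, 18, 26):
            raise ConfigError("connectivity must be 6, 18 or 26")


def load_config(path) -> RunConfig:
    """Read a YAML/JSON run configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    try:
        return RunConfig(**raw)
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def provenance(config: RunConfig) -> dict:
    """Reproducibility block: config hash, seed, package versions."""
    import neurometab

    cfg = asdict(config)
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    return {
        "config": cfg,
        "config_sha256": digest,
        "seed": config.seed,
        "versions": {
            "neurometab": neurometab.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write the cohort table; missing values become empty fields."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, na_rep="")


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table, restoring dtypes and the observed flag."""
    try:
        df = pd.read_csv(path)
    except (pd.errors.ParserError, FileNotFoundError, UnicodeDecodeError) as exc:
        raise DataError(f"cannot read cohort CSV {path}: {exc}") from exc
    missing = {"subject_id", "group", "session", "observed"} - set(df.columns)
    if missing:
        raise DataError(f"cohort CSV {path} lacks columns {sorted(missing)}")
    df["observed"] = df["observed"].astype(bool)
    return df


def _affine(voxel_size, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(np.broadcast_to(np.asarray(voxel_size, float), (3,)))
    aff[:3, 3] = origin
    return aff


def write_voxel_stack(stack: VoxelStack, prefix) -> None:
    """Write ``<prefix>.nii.gz`` (4D), ``<prefix>_mask.nii.gz`` and
    ``<prefix>_subjects.csv`` (subject order sidecar)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    aff = _affine(stack.voxel_size, stack.origin)
    vol4 = np.zeros(stack.grid_shape + (stack.n_subjects,), dtype=np.float32)
    for i in range(stack.n_subjects):
        vol4[..., i][stack.mask] = stack.data[i]
    nib.save(nib.Nifti1Image(vol4, aff), str(prefix) + ".nii.gz")
    nib.save(
        nib.Nifti1Image(stack.mask.astype(np.uint8), aff),
        str(prefix) + "_mask.nii.gz",
    )
    pd.DataFrame({"index": np.arange(stack.n_subjects)}).to_csv(
        str(prefix) + "_subjects.csv", index=False
    )


def read_voxel_stack(stack_path, mask_path) -> VoxelStack:
    """Read a 4D stack + 3D mask back into a :class:`VoxelStack`."""
    img = nib.load(str(stack_path))
    mask_img = nib.load(str(mask_path))
    mask = np.asarray(mask_img.dataobj).astype(bool)
    vol4 = np.asarray(img.dataobj, dtype=float)
    if vol4.ndim == 3:
        vol4 = vol4[..., None]
    if vol4.shape[:3] != mask.shape:
        raise DataError("stack grid does not match mask grid")
    data = vol4[mask].T  # (n_subjects, n_voxels)
    voxel_size = tuple(float(v) for v in img.header.get_zooms()[:3])
    origin = tuple(float(v) for v in img.affine[:3, 3])
    return VoxelStack(data=data, mask=mask, voxel_size=voxel_size, origin=origin)


def write_map(stack: VoxelStack, values, path) -> None:
    """Scatter a masked statistic vector onto the grid and save as NIfTI."""
    vol = stack.unflatten(np.asarray(values, dtype=float)).astype(np.float32)
    nib.save(nib.Nifti1Image(vol, _affine(stack.voxel_size, stack.origin)), str(path))


def cluster_table(reports) -> pd.DataFrame:
    """Cluster reports as a table: center of mass, size (mm^3), peak rho."""
    rows = [
        {
            "cluster": r.cluster_id,
            "com_x_mm": r.center_of_mass_mm[0],
            "com_y_mm": r.center_of_mass_mm[1],
            "com_z_mm": r.center_of_mass_mm[2],
            "size_mm3": r.size_mm3,
            "n_voxels": r.n_voxels,
            "peak_rho": r.peak_rho,
        }
        for r in reports
    ]
    return pd.DataFrame(
        rows,
        columns=["cluster", "com_x_mm", "com_y_mm", "com_z_mm",
                 "size_mm3", "n_voxels", "peak_rho"],
    )


def summaries_table(summaries) -> pd.DataFrame:
    """Boot summaries as a report table (term, b, CI, BSR, p, FDR flag)."""
    return pd.DataFrame(
        [
            {
                "term": s.term,
                "b": s.point,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
                "bsr": s.bsr,
                "p": s.p,
                "fdr_significant": s.fdr_significant,
            }
            for s in summaries
        ]
    )
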