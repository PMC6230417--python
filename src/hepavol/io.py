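"""Volumes, masks and the cohort table: containers and file I/O.

All image computation in the package runs on :class:`CTVolume` (a 3-D grid of
Hounsfield units with voxel spacing in mm) and :class:`BinaryMask` (a boolean
grid on the same lattice).  The internal axis convention is fixed:

    axis 0 = axial slice index, axis 1 = row (y), axis 2 = column (x)

with ``spacing = (dz, dy, dx)`` in mm.  Longest "axial" diameters are measured
in the (row, column) plane of axis 0.

On disk the canonical format is NIfTI-1 (via nibabel); MetaImage (.mha/.mhd,
via SimpleITK) is accepted on read.  Masks are stored as unsigned 8-bit.

The cohort table is a per-patient CSV of percent changes in total tumor
volume (dV), mean volumetric tumor density (dD), RECIST diameter sum (dS),
the combined statistic d(V+D) = dV + dD, the RECIST 1.1 category and
progression-free survival in months.  A 25-patient table of a treated
GEP-NET diffuse-liver-metastasis cohort ships with the package as
``hepavol.io.load_reference_cohort()``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import ContractError, ValidationError

__all__ = [
    "CTVolume",
    "BinaryMask",
    "CohortTable",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_cohort",
    "load_reference_cohort",
    "load_reference_metadata",
]

_PHASES = ("portal", "arterial", "unenhanced")

COHORT_COLUMNS = (
    "case",
    "density_pct",
    "volume_pct",
    "size_pct",
    "combined_pct",
    "recist",
    "pfs_months",
)

#: strings interpreted as missing PFS in the cohort CSV
_MISSING_TOKENS = {"", "—", "-", "–", "NA", "NaN", "nan", "None"}


@dataclass
class CTVolume:
    """A 3-D CT image in Hounsfield units.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        HU values, finite everywhere.
    spacing : tuple of float
        Voxel spacing ``(dz, dy, dx)`` in mm, all strictly positive.
    phase : str
        Contrast phase label; all measurements assume the portal venous phase.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    phase: str = "portal"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ContractError(f"volume must be 3-D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ContractError("volume contains non-finite HU values")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ContractError(f"spacing must be 3 positive values, got {self.spacing}")
        if self.phase not in _PHASES:
            raise ContractError(f"phase must be one of {_PHASES}, got {self.phase!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm^3 (mm^3 / 1000)."""
        dz, dy, dx = self.spacing
        return dz * dy * dx / 1000.0


@dataclass
class BinaryMask:
    """A boolean grid aligned to a :class:`CTVolume`."""

    data: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self):
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ContractError(f"mask must be 3-D, got shape {arr.shape}")
        if arr.dtype != bool:
            uniq = np.unique(arr)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ContractError("mask values must be in {0, 1}")
        self.data = arr.astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ContractError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def check_aligned(self, other: "CTVolume | BinaryMask") -> None:
        if self.shape != other.shape or not np.allclose(self.spacing, other.spacing):
            raise ContractError(
                f"grids misaligned: {self.shape}@{self.spacing} vs "
                f"{other.shape}@{other.spacing}"
            )


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    # data written to disk as (x, y, z); diagonal affine carries the zooms
    dz, dy, dx = spacing
    return np.diag([dx, dy, dz, 1.0])


def write_volume(volume: CTVolume, path: str | Path) -> Path:
    """Write a volume as NIfTI-1; spacing goes into the header zooms."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(volume.data.T, dtype=np.float32), _affine(volume.spacing))
    nib.save(img, str(path))
    return path


def write_mask(mask: BinaryMask, path: str | Path) -> Path:
    """Write a mask as unsigned 8-bit NIfTI-1."""
    path = Path(path)
    img = nib.Nifti1Image(mask.data.T.astype(np.uint8), _affine(mask.spacing))
    nib.save(img, str(path))
    return path


def _read_any(path: Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    suffixes = "".join(path.suffixes).lower()
    if suffixes.endswith((".mha", ".mhd")):
        import SimpleITK as sitk

        img = sitk.ReadImage(str(path))
        arr = sitk.GetArrayFromImage(img)  # already (z, y, x)
        sx, sy, sz = img.GetSpacing()
        spacing = (sz, sy, sx)
    else:
        img = nib.load(str(path))
        arr = np.asanyarray(img.dataobj)
        if arr.ndim != 3:
            raise ContractError(f"expected a 3-D image, got {arr.ndim}-D in {path}")
        zooms = img.header.get_zooms()[:3]
        arr = arr.T  # (x, y, z) on disk -> (z, y, x)
        spacing = (float(zooms[2]), float(zooms[1]), float(zooms[0]))
    if arr.ndim != 3:
        raise ContractError(f"expected a 3-D image, got {arr.ndim}-D in {path}")
    if any(s <= 0 for s in spacing):
        raise ValidationError(f"non-positive voxel spacing {spacing} in header of {path}")
    return np.asarray(arr), spacing


def read_volume(path: str | Path, phase: str = "portal") -> CTVolume:
    """Read a CT volume (NIfTI-1 or MetaImage) into the (axial, row, col) convention."""
    arr, spacing = _read_any(Path(path))
    return CTVolume(arr.astype(np.float64), spacing, phase=phase)


def read_mask(path: str | Path) -> BinaryMask:
    """Read a binary mask; any nonzero voxel is foreground."""
    arr, spacing = _read_any(Path(path))
    return BinaryMask(arr > 0, spacing)


@dataclass
class CohortTable:
    """Per-patient response table.

    ``rows`` is a DataFrame with the :data:`COHORT_COLUMNS` schema, one row per
    case.  Missing PFS is NaN and is excluded (never imputed) from any
    statistic that needs PFS.
    """

    rows: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        missing = set(COHORT_COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValidationError(f"cohort table missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def n_with_pfs(self) -> int:
        return int(self.rows["pfs_months"].notna().sum())

    def complete_cases(self) -> pd.DataFrame:
        """Rows with recorded PFS (complete-case subset for correlations)."""
        return self.rows[self.rows["pfs_months"].notna()].copy()

    def recist_counts(self) -> dict[str, int]:
        return self.rows["recist"].value_counts().to_dict()


def read_cohort(path: str | Path, combined_tol: float = 0.01) -> CohortTable:
    """Read a cohort CSV.

    The CSV header must be ``case,density_pct,volume_pct,size_pct,
    combined_pct,recist,pfs_months``; an em-dash or empty field denotes
    missing PFS.  Rows where ``combined_pct`` differs from
    ``density_pct + volume_pct`` by more than ``combined_tol`` trigger a
    warning naming the offending cases; duplicate case numbers are an error.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    if df.empty:
        raise ValidationError(f"cohort table {path} has no data rows")
    missing = set(COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"cohort table {path} missing columns: {sorted(missing)}")

    def _num(col):
        return pd.to_numeric(df[col].str.strip(), errors="raise")

    out = pd.DataFrame(
        {
            "case": _num("case").astype(int),
            "density_pct": _num("density_pct").astype(float),
            "volume_pct": _num("volume_pct").astype(float),
            "size_pct": _num("size_pct").astype(float),
            "combined_pct": _num("combined_pct").astype(float),
            "recist": df["recist"].str.strip(),
        }
    )
    pfs_raw = df["pfs_months"].fillna("").str.strip()
    out["pfs_months"] = pd.to_numeric(
        pfs_raw.where(~pfs_raw.isin(_MISSING_TOKENS), other=pd.NA), errors="raise"
    ).astype(float)

    dup = out["case"][out["case"].duplicated()].tolist()
    if dup:
        raise ValidationError(f"duplicate case numbers in {path}: {dup}")
    bad = out["recist"][~out["recist"].isin(("CR", "PR", "SD", "PD"))].tolist()
    if bad:
        raise ValidationError(f"unknown RECIST categories in {path}: {bad}")
    resid = (out["combined_pct"] - (out["density_pct"] + out["volume_pct"])).abs()
    off = out.loc[resid > combined_tol, "case"].tolist()
    if off:
        warnings.warn(
            f"combined_pct != density_pct + volume_pct beyond ±{combined_tol} "
            f"for cases {off}",
            stacklevel=2,
        )
    return CohortTable(out.reset_index(drop=True))


def load_reference_cohort() -> CohortTable:
    """The packaged 25-patient GEP-NET cohort response table."""
    with resources.as_file(resources.files("hepavol.data") / "table2.csv") as p:
        return read_cohort(p)


def load_reference_metadata() -> pd.DataFrame:
    """Per-patient tumor grade / therapy metadata for the packaged cohort."""
    with resources.as_file(resources.files("hepavol.data") / "table1.csv") as p:
        return pd.read_csv(p)
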