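"""Measurement-table data model, CSV I/O, and synthetic normative-cohort generators.

FA (fractional anisotropy) is a dimensionless scalar in [0, 1] derived from
the diffusion tensor. A normative measurement table holds one FA value per
(subject, ROI-group, ROI-label, gradient-scheme) combination; repeated ROIs
within a subject are the repeated observations that motivate the
random-intercept model in :mod:`falut.normative_model`.

The synthetic generator draws from exactly that model: per-group population
mean plus a between-subject random intercept and a within-subject residual,
with the total variance recovered from the published 95% prediction-interval
width. It emulates the normative cohort (76 subjects, 16 ROIs per subject)
when called with the default group specifications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "ROI_GROUPS",
    "FAMeasurement",
    "MeasurementTable",
    "GroupSpec",
    "DEFAULT_SCHEME_12MPG",
    "DEFAULT_SCHEME_30MPG",
    "PYRAMIDAL_COMBINED_SPEC",
    "MCP_COMBINED_SPEC",
    "read_measurement_table",
    "write_measurement_table",
    "generate_measurements",
    "generate_phantom",
    "save_phantom",
]

#: Canonical ROI groups. ``custom`` covers site-specific additions.
ROI_GROUPS = ("BG", "GM", "CC_FREEHAND", "CC_CROI", "PYRAMIDAL", "MCP", "custom")

ROI_KINDS = ("freehand", "circular")

MPG_SCHEMES = (12, 30)

#: z quantile used throughout to convert a 95% PI half-width into a total SD.
Z_975 = 1.959964

_COLUMNS = ["subject_id", "roi_group", "roi_label", "roi_kind", "mpg_scheme", "fa"]


class SchemaError(ValueError):
    """A measurement file is missing a required column."""


class RowValidationError(ValueError):
    """A measurement row violates a field constraint (reported with its line)."""


@dataclass(frozen=True)
class FAMeasurement:
    """One FA observation for one ROI of one subject."""

    subject_id: str
    roi_group: str
    roi_label: str
    roi_kind: str
    mpg_scheme: int
    fa: float

    def __post_init__(self) -> None:
        if self.roi_group not in ROI_GROUPS:
            raise ValueError(f"unknown roi_group {self.roi_group!r}; expected one of {ROI_GROUPS}")
        if self.roi_kind not in ROI_KINDS:
            raise ValueError(f"unknown roi_kind {self.roi_kind!r}; expected one of {ROI_KINDS}")
        if int(self.mpg_scheme) not in MPG_SCHEMES:
            raise ValueError(f"mpg_scheme must be 12 or 30, got {self.mpg_scheme}")
        if not math.isfinite(self.fa) or not (0.0 <= self.fa <= 1.0):
            raise ValueError(f"fa must be finite and in [0, 1], got {self.fa}")


@dataclass
class MeasurementTable:
    """Ordered collection of FA measurements plus free-text provenance."""

    records: list[FAMeasurement] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        if len(self.records) != len(other.records):
            return False
        for a, b in zip(self.records, other.records):
            if (a.subject_id, a.roi_group, a.roi_label, a.roi_kind, a.mpg_scheme) != (
                b.subject_id,
                b.roi_group,
                b.roi_label,
                b.roi_kind,
                b.mpg_scheme,
            ):
                return False
            if not math.isclose(a.fa, b.fa, rel_tol=0.0, abs_tol=1e-12):
                return False
        return True

    def to_frame(self) -> pd.DataFrame:
        """Return the records as a pandas DataFrame in file column order."""
        return pd.DataFrame(
            [
                (r.subject_id, r.roi_group, r.roi_label, r.roi_kind, r.mpg_scheme, r.fa)
                for r in self.records
            ],
            columns=_COLUMNS,
        )

    def subset(self, roi_group: str | None = None, mpg_scheme: int | None = None) -> "MeasurementTable":
        recs = [
            r
            for r in self.records
            if (roi_group is None or r.roi_group == roi_group)
            and (mpg_scheme is None or r.mpg_scheme == int(mpg_scheme))
        ]
        return MeasurementTable(records=recs, provenance=self.provenance)


@dataclass(frozen=True)
class GroupSpec:
    """Generating parameters for one ROI group of the synthetic cohort.

    ``mean`` and ``(pi_low, pi_high)`` are on the FA scale; the 95% PI width
    fixes the total variance tau^2 + sigma^2 = ((pi_high - pi_low) / (2 z))^2,
    and ``icc_fraction`` says what share of it is between-subject (tau^2).
    """

    roi_group: str
    mean: float
    pi_low: float
    pi_high: float
    n_subjects: int = 76
    rois_per_subject: int = 4
    icc_fraction: float = 0.5
    roi_kind: str = "circular"
    roi_labels: tuple[str, ...] | None = None
    mpg_scheme: int = 12

    def __post_init__(self) -> None:
        if not (self.pi_low < self.mean < self.pi_high):
            raise ValueError(
                f"{self.roi_group}: require pi_low < mean < pi_high, "
                f"got ({self.pi_low}, {self.mean}, {self.pi_high})"
            )
        if not (0.0 < self.icc_fraction < 1.0):
            raise ValueError(f"icc_fraction must be in (0, 1), got {self.icc_fraction}")
        if self.n_subjects <= 0 or self.rois_per_subject <= 0:
            raise ValueError("n_subjects and rois_per_subject must be positive")
        if self.roi_labels is not None and len(self.roi_labels) != self.rois_per_subject:
            raise ValueError("roi_labels length must equal rois_per_subject")

    @property
    def total_sd(self) -> float:
        return (self.pi_high - self.pi_low) / (2.0 * Z_975)

    @property
    def tau2(self) -> float:
        return self.icc_fraction * self.total_sd**2

    @property
    def sigma2(self) -> float:
        return (1.0 - self.icc_fraction) * self.total_sd**2


def _default_scheme(mpg: int, table1: Mapping[str, tuple[float, float, float]]) -> tuple[GroupSpec, ...]:
    # 16 ROIs/subject: BG 6 (putamen/pallidum/caudate bilateral), GM 4
    # (precentral + thalamus bilateral), CC freehand 2, CC circular 4.
    return (
        GroupSpec(
            "BG", *table1["BG"], n_subjects=76, rois_per_subject=6,
            roi_labels=("putamen_L", "putamen_R", "pallidum_L", "pallidum_R", "caudate_L", "caudate_R"),
            mpg_scheme=mpg,
        ),
        GroupSpec(
            "GM", *table1["GM"], n_subjects=76, rois_per_subject=4,
            roi_labels=("precentral_L", "precentral_R", "thalamus_L", "thalamus_R"),
            mpg_scheme=mpg,
        ),
        GroupSpec(
            "CC_FREEHAND", *table1["CC_FREEHAND"], n_subjects=76, rois_per_subject=2,
            roi_kind="freehand", roi_labels=("rostrum_genu", "splenium"), mpg_scheme=mpg,
        ),
        GroupSpec(
            "CC_CROI", *table1["CC_CROI"], n_subjects=76, rois_per_subject=4,
            roi_labels=("genu_1", "genu_2", "splenium_1", "splenium_2"), mpg_scheme=mpg,
        ),
    )


# Published normative estimates (mean, PI low, PI high) per gradient scheme.
TABLE1_12MPG: dict[str, tuple[float, float, float]] = {
    "BG": (0.218, 0.077, 0.359),
    "GM": (0.323, 0.181, 0.464),
    "CC_FREEHAND": (0.709, 0.627, 0.792),
    "CC_CROI": (0.858, 0.731, 0.986),
}

TABLE1_30MPG: dict[str, tuple[float, float, float]] = {
    "BG": (0.173, 0.073, 0.273),
    "GM": (0.328, 0.175, 0.481),
    "CC_FREEHAND": (0.703, 0.608, 0.797),
    "CC_CROI": (0.855, 0.717, 0.992),
}

DEFAULT_SCHEME_12MPG = _default_scheme(12, TABLE1_12MPG)
DEFAULT_SCHEME_30MPG = _default_scheme(30, TABLE1_30MPG)

#: Pooled pyramidal-tract normative estimate (circular + freehand records).
PYRAMIDAL_COMBINED_SPEC = GroupSpec(
    "PYRAMIDAL", 0.75, 0.67, 0.82, n_subjects=76, rois_per_subject=2,
    roi_labels=("pyramidal_croi", "pyramidal_freehand"),
)

#: Pooled middle-cerebellar-peduncle normative estimate.
MCP_COMBINED_SPEC = GroupSpec(
    "MCP", 0.73, 0.54, 0.93, n_subjects=76, rois_per_subject=2,
    roi_labels=("mcp_croi", "mcp_freehand"),
)


def read_measurement_table(path: str | Path, delimiter: str = ",") -> MeasurementTable:
    """Read a measurement table from delimited text.

    The header must name all six fields. Raises :class:`SchemaError` on a
    missing column and :class:`RowValidationError` (with the 1-based file
    line) on an invalid value.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=delimiter, dtype={"subject_id": str, "roi_label": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")
    records: list[FAMeasurement] = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        try:
            fa = float(row.fa)
        except (TypeError, ValueError) as exc:
            raise RowValidationError(f"{path}, line {line}: fa is not numeric: {row.fa!r}") from exc
        try:
            records.append(
                FAMeasurement(
                    subject_id=str(row.subject_id),
                    roi_group=str(row.roi_group),
                    roi_label=str(row.roi_label),
                    roi_kind=str(row.roi_kind),
                    mpg_scheme=int(row.mpg_scheme),
                    fa=fa,
                )
            )
        except ValueError as exc:
            raise RowValidationError(f"{path}, line {line}: {exc}") from exc
    return MeasurementTable(records=records)


def write_measurement_table(table: MeasurementTable, path: str | Path, delimiter: str = ",") -> None:
    """Write ``table`` as delimited text (header always included)."""
    df = table.to_frame()
    # repr-round-trip float formatting keeps write->read an identity
    df.to_csv(Path(path), sep=delimiter, index=False, float_format="%.17g")


def generate_measurements(
    specs: Sequence[GroupSpec],
    seed: int,
    provenance: str | None = None,
) -> MeasurementTable:
    """Draw a synthetic measurement table from random-intercept models.

    For each group spec, subject effects b_i ~ N(0, tau^2) and residuals
    e_ij ~ N(0, sigma^2) are drawn with tau^2 + sigma^2 equal to the squared
    PI half-width over z_{0.975}^2, and y_ij = mean + b_i + e_ij clipped to
    [0, 1]. The same seed always yields the same table.
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    rng = np.random.default_rng(seed)
    records: list[FAMeasurement] = []
    for spec in specs:
        labels = spec.roi_labels or tuple(
            f"{spec.roi_group.lower()}_{j + 1}" for j in range(spec.rois_per_subject)
        )
        tau = math.sqrt(spec.tau2)
        sigma = math.sqrt(spec.sigma2)
        b = rng.normal(0.0, tau, size=spec.n_subjects)
        eps = rng.normal(0.0, sigma, size=(spec.n_subjects, spec.rois_per_subject))
        y = np.clip(spec.mean + b[:, None] + eps, 0.0, 1.0)
        for i in range(spec.n_subjects):
            sid = f"S{i + 1:03d}"
            for j, lab in enumerate(labels):
                records.append(
                    FAMeasurement(
                        subject_id=sid,
                        roi_group=spec.roi_group,
                        roi_label=lab,
                        roi_kind=spec.roi_kind,
                        mpg_scheme=spec.mpg_scheme,
                        fa=float(y[i, j]),
                    )
                )
    if provenance is None:
        provenance = f"synthetic; seed={seed}; groups={[s.roi_group for s in specs]}"
    return MeasurementTable(records=records, provenance=provenance)


# --- geometric FA phantom -------------------------------------------------

#: Integer codes of the phantom's labelled regions.
PHANTOM_LABELS = {"background": 0, "gm_shell": 1, "wm_core": 2, "peduncle_L": 3, "peduncle_R": 4}

#: Default region FA values: cortical shell at the GM normative mean, deep
#: white matter at the CC-freehand mean, peduncles at the MCP circular mean.
DEFAULT_REGION_FA = {"gm_shell": 0.323, "wm_core": 0.709, "peduncle_L": 0.82, "peduncle_R": 0.82}

PEDUNCLE_REGIONS = ("peduncle_L", "peduncle_R")


def _phantom_labels(shape: tuple[int, int, int]) -> np.ndarray:
    nx, ny, nz = shape
    labels = np.zeros(shape, dtype=np.int16)
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz), indexing="ij")
    # outer ellipsoid = "head"; inner ellipsoid = deep white-matter core;
    # the space between them is the gray-matter shell
    outer = ((x - cx) / (0.45 * nx)) ** 2 + ((y - cy) / (0.45 * ny)) ** 2 + ((z - cz) / (0.45 * nz)) ** 2 <= 1.0
    inner = ((x - cx) / (0.22 * nx)) ** 2 + ((y - cy) / (0.22 * ny)) ** 2 + ((z - cz) / (0.22 * nz)) ** 2 <= 1.0
    labels[outer] = PHANTOM_LABELS["gm_shell"]
    labels[inner] = PHANTOM_LABELS["wm_core"]
    # paired peduncle blobs: small spheres lateral and inferior to the core
    r = max(2.0, 0.07 * min(shape))
    for name, sx in (("peduncle_L", -1.0), ("peduncle_R", 1.0)):
        px, py, pz = cx + sx * 0.3 * nx, cy, cz - 0.25 * nz
        blob = (x - px) ** 2 + (y - py) ** 2 + (z - pz) ** 2 <= r**2
        labels[blob] = PHANTOM_LABELS[name]
    return labels


def generate_phantom(
    shape: tuple[int, int, int] = (64, 64, 64),
    region_fa: Mapping[str, float] | None = None,
    noise_sd: float = 0.02,
    msa_delta: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Build a geometric FA phantom and its aligned integer label volume.

    The phantom nests a gray-matter shell and a deep white-matter core inside
    a background of FA 0, with two paired "peduncle" blobs. ``msa_delta`` is
    subtracted from the peduncle FA before noise, mimicking the peduncular FA
    decrease seen in multiple system atrophy. Gaussian noise of SD
    ``noise_sd`` is added voxelwise and the result is clipped to [0, 1].
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    fa_by_region = dict(DEFAULT_REGION_FA)
    if region_fa:
        fa_by_region.update(region_fa)
    for name, v in fa_by_region.items():
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"region {name!r}: FA {v} outside [0, 1]")
        if name in PEDUNCLE_REGIONS and v - msa_delta < 0:
            raise ValueError(f"msa_delta {msa_delta} drives region {name!r} FA below 0")
    labels = _phantom_labels(tuple(int(s) for s in shape))
    fa = np.zeros(labels.shape, dtype=np.float64)
    for name, code in PHANTOM_LABELS.items():
        if name == "background":
            continue
        value = fa_by_region[name]
        if name in PEDUNCLE_REGIONS:
            value = value - msa_delta
        fa[labels == code] = value
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        fa = fa + rng.normal(0.0, noise_sd, size=fa.shape)
    fa = np.clip(fa, 0.0, 1.0)
    return fa, labels


def phantom_affine(voxel_size_mm: float = 2.2) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_size_mm
    return aff


def save_phantom(fa: np.ndarray, path: str | Path, voxel_size_mm: float = 2.2) -> None:
    """Write a phantom FA volume as NIfTI-1 with an isotropic-voxel affine."""
    img = nib.Nifti1Image(fa.astype(np.float32), phantom_affine(voxel_size_mm))
    img.header.set_zooms((voxel_size_mm,) * 3)
    nib.save(img, str(path))
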