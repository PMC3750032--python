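"""Nonlinear color look-up tables anchored at normative FA statistics.

A LUT is an ordered set of (FA, RGB) inflection points with linear
per-channel ramps between consecutive points. Anchors are placed at
normative statistics of four ROI groups — half the basal-ganglia PI lower
bound, the BG PI lower bound and mean, the gray-matter mean and PI upper
bound, the corpus-callosum freehand PI bounds, and the CC circular-ROI mean
— so that color, unlike a linear gray ramp, resolves the FA strata that
matter clinically (deep gray, cortical gray, white-matter periphery, packed
white-matter core).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from math import floor
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .normative_model import RandomInterceptFit

__all__ = [
    "ANCHOR_LABELS",
    "InflectionPoint",
    "ColorLUT",
    "load_palette",
    "default_palette",
    "build_inflection_points",
    "builtin_lut",
    "interpolate_color",
    "sample_lut",
    "export_imagej_lut",
    "import_imagej_lut",
    "export_csv_colormap",
    "import_csv_colormap",
]

#: Anchor labels in ascending-FA order, domain endpoints included.
ANCHOR_LABELS = (
    "DOMAIN_MIN",
    "BG_HALF_PILOW",
    "BG_PILOW",
    "BG_MEAN",
    "GM_MEAN",
    "GM_PIUP",
    "CCF_PILOW",
    "CCF_PIUP",
    "CCROI_MEAN",
    "DOMAIN_MAX",
)

RGB = tuple[int, int, int]


class OrderingError(ValueError):
    """Anchor FA values are not strictly increasing (pathological cohort)."""


class PaletteError(ValueError):
    """Palette is incomplete or holds an invalid color."""


@dataclass(frozen=True)
class InflectionPoint:
    """One (FA, color) anchor of the LUT."""

    label: str
    fa: float
    rgb: RGB

    def __post_init__(self) -> None:
        if len(self.rgb) != 3 or any(not (0 <= c <= 255) for c in self.rgb):
            raise ValueError(f"{self.label}: rgb components must be in [0, 255], got {self.rgb}")


@dataclass(frozen=True)
class ColorLUT:
    """Piecewise-linear color map over the FA domain [0, 1]."""

    points: tuple[InflectionPoint, ...]
    name: str = "custom"
    source: str = "fitted"

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise ValueError("a LUT needs at least two inflection points")
        fas = [p.fa for p in self.points]
        for a, b in zip(self.points, self.points[1:]):
            if not a.fa < b.fa:
                raise OrderingError(
                    f"anchor FA values must be strictly increasing: "
                    f"{a.label} (fa={a.fa:.4g}) >= {b.label} (fa={b.fa:.4g})"
                )
        if fas[0] != 0.0 or fas[-1] != 1.0:
            raise ValueError("LUT must span the FA domain: first anchor at 0, last at 1")

    @property
    def anchor_fa(self) -> tuple[float, ...]:
        return tuple(p.fa for p in self.points)


def _validate_palette(palette: Mapping[str, Sequence[int]]) -> dict[str, RGB]:
    missing = [lab for lab in ANCHOR_LABELS if lab not in palette]
    if missing:
        raise PaletteError(f"palette missing label(s): {', '.join(missing)}")
    out: dict[str, RGB] = {}
    for lab, rgb in palette.items():
        rgb = tuple(int(c) for c in rgb)
        if len(rgb) != 3 or any(not (0 <= c <= 255) for c in rgb):
            raise PaletteError(f"palette[{lab}]: invalid rgb {rgb}")
        out[lab] = rgb
    return out


def load_palette(path: str | Path) -> dict[str, RGB]:
    """Load a YAML palette mapping anchor labels to ``[r, g, b]`` triples."""
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict):
        raise PaletteError(f"{path}: expected a mapping of label -> [r, g, b]")
    return _validate_palette(data)


def default_palette() -> dict[str, RGB]:
    """The packaged default palette (editable YAML shipped with the package).

    Chosen so rising FA in dense white matter renders red through yellow;
    the published anchor colors are not recoverable from print, so this is a
    stand-in with the same qualitative reading, not a reproduction.
    """
    text = resources.files("falut").joinpath("data/palette_default.yaml").read_text()
    return _validate_palette(yaml.safe_load(text))


def build_inflection_points(
    fits: Mapping[str, RandomInterceptFit],
    palette: Mapping[str, RGB] | None = None,
    name: str = "fitted",
    source: str = "fitted",
) -> ColorLUT:
    """Derive the LUT anchors from the four group fits.

    Anchors: BG.pi_low/2, BG.pi_low, BG.mu, GM.mu, GM.pi_high, CCF.pi_low,
    CCF.pi_high, CCROI.mu, flanked by DOMAIN_MIN at FA 0 and DOMAIN_MAX at
    FA 1. Anchor FA values are clipped into [0, 1] before the strict
    monotonicity check; a non-increasing sequence raises
    :class:`OrderingError` naming the offending pair.
    """
    pal = _validate_palette(palette) if palette is not None else default_palette()
    required = ("BG", "GM", "CC_FREEHAND", "CC_CROI")
    missing = [g for g in required if g not in fits]
    if missing:
        raise KeyError(f"fits missing group(s): {', '.join(missing)}")
    bg, gm = fits["BG"], fits["GM"]
    ccf, ccroi = fits["CC_FREEHAND"], fits["CC_CROI"]
    anchors = [
        ("DOMAIN_MIN", 0.0),
        ("BG_HALF_PILOW", bg.pi_low / 2.0),
        ("BG_PILOW", bg.pi_low),
        ("BG_MEAN", bg.mu_hat),
        ("GM_MEAN", gm.mu_hat),
        ("GM_PIUP", gm.pi_high),
        ("CCF_PILOW", ccf.pi_low),
        ("CCF_PIUP", ccf.pi_high),
        ("CCROI_MEAN", ccroi.mu_hat),
        ("DOMAIN_MAX", 1.0),
    ]
    points = tuple(
        InflectionPoint(lab, float(np.clip(fa, 0.0, 1.0)), pal[lab]) for lab, fa in anchors
    )
    return ColorLUT(points=points, name=name, source=source)


def builtin_lut(scheme: int | str = 12, palette: Mapping[str, RGB] | None = None) -> ColorLUT:
    """LUT built from the published normative estimates (12 or 30 MPG)."""
    from .roi_data import TABLE1_12MPG, TABLE1_30MPG

    key = str(scheme).lower().replace("mpg", "").strip()
    if key == "12":
        table, src = TABLE1_12MPG, "builtin-12MPG"
    elif key == "30":
        table, src = TABLE1_30MPG, "builtin-30MPG"
    else:
        raise ValueError(f"unknown builtin scheme {scheme!r}; use 12 or 30")
    fits = {
        g: RandomInterceptFit(
            roi_group=g, mu_hat=mean, tau2_hat=0.0, sigma2_hat=0.0,
            pi_low=lo, pi_high=hi, n_subjects=0, n_obs=0, method="published",
        )
        for g, (mean, lo, hi) in table.items()
    }
    return build_inflection_points(fits, palette, name=src, source=src)


def _round_half_up(x: np.ndarray | float) -> np.ndarray:
    return np.floor(np.asarray(x, dtype=float) + 0.5)


def interpolate_color(lut: ColorLUT, fa: float) -> RGB:
    """Color at ``fa``: per-channel linear interpolation between anchors.

    ``fa`` is clamped to [0, 1]; channels are interpolated in continuous
    space and rounded half-up to integers. FA exactly at an anchor returns
    that anchor's color exactly.
    """
    if not np.isfinite(fa):
        raise ValueError(f"fa must be finite, got {fa}")
    fa = min(1.0, max(0.0, float(fa)))
    xs = np.array([p.fa for p in lut.points])
    idx = int(np.searchsorted(xs, fa))
    if idx < len(xs) and xs[idx] == fa:
        return lut.points[idx].rgb
    lo, hi = lut.points[idx - 1], lut.points[idx]
    t = (fa - lo.fa) / (hi.fa - lo.fa)
    return tuple(
        int(floor(lo.rgb[c] + t * (hi.rgb[c] - lo.rgb[c]) + 0.5)) for c in range(3)
    )


def sample_lut(lut: ColorLUT, n_entries: int = 256) -> np.ndarray:
    """Discretize the LUT on the closed uniform grid fa_k = k/(n-1).

    Returns an (n_entries, 3) uint8 array; entry 0 carries the DOMAIN_MIN
    color and the last entry the DOMAIN_MAX color.
    """
    if n_entries < 2:
        raise ValueError(f"n_entries must be >= 2, got {n_entries}")
    grid = np.arange(n_entries) / (n_entries - 1)
    xs = np.array([p.fa for p in lut.points])
    out = np.empty((n_entries, 3), dtype=np.uint8)
    for c in range(3):
        ys = np.array([p.rgb[c] for p in lut.points], dtype=float)
        out[:, c] = _round_half_up(np.interp(grid, xs, ys)).astype(np.uint8)
    return out


def export_imagej_lut(lut: ColorLUT, path: str | Path) -> None:
    """Write the raw ImageJ ``.lut`` layout: 256 R, 256 G, 256 B bytes."""
    table = sample_lut(lut, 256)
    Path(path).write_bytes(table.T.tobytes())  # channel-major: R block, G block, B block


def import_imagej_lut(path: str | Path) -> np.ndarray:
    """Read a raw ImageJ ``.lut`` file back into a (256, 3) uint8 table."""
    raw = Path(path).read_bytes()
    if len(raw) != 768:
        raise ValueError(f"{path}: expected exactly 768 bytes, got {len(raw)}")
    return np.frombuffer(raw, dtype=np.uint8).reshape(3, 256).T.copy()


def export_csv_colormap(lut: ColorLUT, path: str | Path, n_entries: int = 256) -> None:
    """Write the sampled LUT as CSV with columns ``index,fa,r,g,b``."""
    table = sample_lut(lut, n_entries)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "fa", "r", "g", "b"])
        for k, (r, g, b) in enumerate(table):
            writer.writerow([k, repr(k / (n_entries - 1)), int(r), int(g), int(b)])


def import_csv_colormap(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    """Read a CSV colormap; returns (fa grid, (n, 3) uint8 color table)."""
    fas: list[float] = []
    rgbs: list[tuple[int, int, int]] = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["index", "fa", "r", "g", "b"]:
            raise ValueError(f"{path}, line 1: expected header index,fa,r,g,b, got {header}")
        for lineno, row in enumerate(reader, start=2):
            try:
                fas.append(float(row[1]))
                rgbs.append((int(row[2]), int(row[3]), int(row[4])))
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}, line {lineno}: malformed row {row!r}") from exc
    return np.array(fas), np.array(rgbs, dtype=np.uint8)
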