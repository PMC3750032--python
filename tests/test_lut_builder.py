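"""LUT anchors, piecewise-linear color ramps, and file exports."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import falut
from falut.lut_builder import (
    ANCHOR_LABELS,
    ColorLUT,
    InflectionPoint,
    OrderingError,
    PaletteError,
    builtin_lut,
    build_inflection_points,
    default_palette,
    export_csv_colormap,
    export_imagej_lut,
    import_csv_colormap,
    import_imagej_lut,
    interpolate_color,
    sample_lut,
)
from falut.normative_model import RandomInterceptFit


def make_fit(group, mu, lo, hi):
    return RandomInterceptFit(group, mu, 0.0, 0.0, lo, hi, 0, 0, "published")


def gray_lut():
    return ColorLUT(
        points=(
            InflectionPoint("DOMAIN_MIN", 0.0, (0, 0, 0)),
            InflectionPoint("DOMAIN_MAX", 1.0, (255, 255, 255)),
        ),
        name="gray",
    )


# Anchor FA sequences implied by the published normative estimates:
# (BG pi_low/2, BG pi_low, BG mean, GM mean, GM pi_high,
#  CCF pi_low, CCF pi_high, CC-cROI mean)
ANCHORS_12 = (0.0385, 0.077, 0.218, 0.323, 0.464, 0.627, 0.792, 0.858)
ANCHORS_30 = (0.0365, 0.073, 0.173, 0.328, 0.481, 0.608, 0.797, 0.855)


class TestInflectionPoints:
    def test_builtin_12mpg_anchor_sequence(self, lut12):
        assert lut12.anchor_fa == pytest.approx((0.0,) + ANCHORS_12 + (1.0,), abs=1e-12)
        assert tuple(p.label for p in lut12.points) == ANCHOR_LABELS

    def test_builtin_30mpg_anchor_sequence(self, lut30):
        assert lut30.anchor_fa == pytest.approx((0.0,) + ANCHORS_30 + (1.0,), abs=1e-12)
        assert all(a < b for a, b in zip(lut30.anchor_fa, lut30.anchor_fa[1:]))

    def test_builtins_mean_anchors_stable_except_bg(self, lut12, lut30):
        # between acquisition schemes, the group-mean anchors agree to about
        # 0.01 FA except in the basal ganglia, which are noise-sensitive
        diffs = {p12.label: abs(p12.fa - p30.fa)
                 for p12, p30 in zip(lut12.points, lut30.points)}
        for label in ("GM_MEAN", "CCROI_MEAN"):
            assert diffs[label] <= 0.01, f"{label} moved {diffs[label]:.3f}"
        assert diffs["BG_MEAN"] > 0.01

    def test_built_from_fitted_cohort(self, fits_12):
        lut = build_inflection_points(fits_12)
        fas = lut.anchor_fa
        assert fas[0] == 0.0 and fas[-1] == 1.0
        assert all(a < b for a, b in zip(fas, fas[1:]))
        assert lut.points[1].fa == pytest.approx(fits_12["BG"].pi_low / 2)

    def test_disordered_fits_raise_naming_pair(self):
        fits = {
            "BG": make_fit("BG", 0.218, 0.077, 0.359),
            "GM": make_fit("GM", 0.323, 0.181, 0.70),  # GM PI top above CCF PI low
            "CC_FREEHAND": make_fit("CC_FREEHAND", 0.709, 0.627, 0.792),
            "CC_CROI": make_fit("CC_CROI", 0.858, 0.731, 0.986),
        }
        with pytest.raises(OrderingError, match="GM_PIUP.*CCF_PILOW"):
            build_inflection_points(fits)

    def test_missing_fit_group_rejected(self):
        with pytest.raises(KeyError, match="CC_CROI"):
            build_inflection_points({"BG": make_fit("BG", 0.2, 0.1, 0.3),
                                     "GM": make_fit("GM", 0.3, 0.2, 0.4),
                                     "CC_FREEHAND": make_fit("CC_FREEHAND", 0.7, 0.6, 0.8)})

    def test_incomplete_palette_rejected(self):
        with pytest.raises(PaletteError, match="missing"):
            builtin_lut(12, palette={"DOMAIN_MIN": (0, 0, 0)})


class TestInterpolateColor:
    def test_anchors_reproduce_palette_exactly(self, lut12):
        pal = default_palette()
        for p in lut12.points:
            assert interpolate_color(lut12, p.fa) == pal[p.label]

    def test_midpoint_half_up_rounding(self):
        lut = gray_lut()
        assert interpolate_color(lut, 0.5) == (128, 128, 128)  # 127.5 rounds up

    def test_out_of_range_clamps_to_endpoints(self, lut12):
        assert interpolate_color(lut12, -0.5) == lut12.points[0].rgb
        assert interpolate_color(lut12, 1.5) == lut12.points[-1].rgb

    def test_non_finite_fa_rejected(self, lut12):
        with pytest.raises(ValueError, match="finite"):
            interpolate_color(lut12, float("nan"))

    def test_sweep_matches_bruteforce_oracle(self, lut12):
        """1000-point sweep against an independent per-channel linear
        interpolation written from the two bracketing anchors."""
        pts = lut12.points
        for fa in np.linspace(0.0, 1.0, 1000):
            k = max(1, np.searchsorted([p.fa for p in pts], fa, side="left"))
            k = min(k, len(pts) - 1)
            lo, hi = pts[k - 1], pts[k]
            t = (fa - lo.fa) / (hi.fa - lo.fa)
            expected = tuple(
                int(np.floor(lo.rgb[c] + t * (hi.rgb[c] - lo.rgb[c]) + 0.5)) for c in range(3)
            )
            assert interpolate_color(lut12, float(fa)) == expected

    @given(st.floats(min_value=0.0, max_value=1.0 - 1e-6))
    def test_continuity_under_rounding(self, fa):
        lut = falut.builtin_lut(12)
        a = np.array(interpolate_color(lut, fa))
        b = np.array(interpolate_color(lut, fa + 1e-6))
        assert np.max(np.abs(a.astype(int) - b.astype(int))) <= 1

    def test_default_palette_injective_at_256_samples(self, lut12):
        table = sample_lut(lut12, 256)
        assert len({tuple(row) for row in table}) == 256


class TestSampleLut:
    def test_two_entries_are_endpoints(self, lut12):
        table = sample_lut(lut12, 2)
        assert tuple(table[0]) == lut12.points[0].rgb
        assert tuple(table[1]) == lut12.points[-1].rgb

    def test_monotone_gray_levels(self):
        table = sample_lut(gray_lut(), 256)
        assert np.all(np.diff(table[:, 0].astype(int)) >= 0)
        assert np.all(table[:, 0] == table[:, 1])

    def test_upsampling_consistent_at_shared_grid(self, lut12):
        t256 = sample_lut(lut12, 256)
        t1021 = sample_lut(lut12, 1021)  # 1021 - 1 = 4 * (256 - 1)
        assert np.array_equal(t256, t1021[::4])

    def test_too_few_entries_rejected(self, lut12):
        with pytest.raises(ValueError, match="n_entries"):
            sample_lut(lut12, 1)


class TestExports:
    def test_imagej_export_is_768_bytes(self, lut12, tmp_path):
        p = tmp_path / "scale.lut"
        export_imagej_lut(lut12, p)
        assert p.stat().st_size == 768

    def test_imagej_round_trip(self, lut12, tmp_path):
        p = tmp_path / "scale.lut"
        export_imagej_lut(lut12, p)
        assert np.array_equal(import_imagej_lut(p), sample_lut(lut12, 256))

    def test_all_black_palette_exports_zero_bytes(self, tmp_path):
        pal = {lab: (0, 0, 0) for lab in ANCHOR_LABELS}
        p = tmp_path / "black.lut"
        export_imagej_lut(builtin_lut(12, palette=pal), p)
        assert p.read_bytes() == b"\x00" * 768

    def test_exports_are_deterministic(self, lut12, tmp_path):
        a, b = tmp_path / "a.lut", tmp_path / "b.lut"
        export_imagej_lut(lut12, a)
        export_imagej_lut(lut12, b)
        assert a.read_bytes() == b.read_bytes()

    def test_csv_has_header_plus_entries(self, lut12, tmp_path):
        p = tmp_path / "map.csv"
        export_csv_colormap(lut12, p, n_entries=256)
        assert len(p.read_text().splitlines()) == 257

    def test_csv_round_trip_and_fa_grid(self, lut12, tmp_path):
        p = tmp_path / "map.csv"
        export_csv_colormap(lut12, p, n_entries=256)
        fas, rgbs = import_csv_colormap(p)
        assert np.array_equal(rgbs, sample_lut(lut12, 256))
        assert np.array_equal(fas, np.arange(256) / 255)

    def test_malformed_csv_cites_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("index,fa,r,g,b\n0,0.0,0,0,0\n1,oops,0,0\n")
        with pytest.raises(ValueError, match="line 3"):
            import_csv_colormap(p)


class TestLutValidation:
    def test_tied_anchors_rejected(self):
        with pytest.raises(OrderingError):
            ColorLUT(points=(
                InflectionPoint("DOMAIN_MIN", 0.0, (0, 0, 0)),
                InflectionPoint("A", 0.5, (1, 1, 1)),
                InflectionPoint("B", 0.5, (2, 2, 2)),
                InflectionPoint("DOMAIN_MAX", 1.0, (255, 255, 255)),
            ))

    def test_domain_must_span_unit_interval(self):
        with pytest.raises(ValueError, match="span"):
            ColorLUT(points=(
                InflectionPoint("A", 0.1, (0, 0, 0)),
                InflectionPoint("B", 1.0, (255, 255, 255)),
            ))

    def test_rgb_bounds_enforced(self):
        with pytest.raises(ValueError, match="rgb"):
            InflectionPoint("A", 0.0, (256, 0, 0))
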