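"""Scoring pipeline: montage, cell detection, colonies, six parameters."""

import math
from dataclasses import replace

import numpy as np
import pytest

from nichescreen import (
    FieldImage,
    FieldSpec,
    ScoringParams,
    WellPhenotype,
    compute_phenotype,
    detect_cells,
    expected_phenotype,
    generate_field,
    generate_well,
    identify_colonies,
    montage_fields,
    score_well,
)
from nichescreen.imaging import CellRecord, ColonyRecord, colony_filter
from nichescreen.synth import CANCER_POS


def _blank_field(shape=(64, 64), px=1.0, index=0, level=0.0):
    z = np.full(shape, level, dtype=float)
    return FieldImage(z.copy(), z.copy(), z.copy(), pixel_size_um=px, field_index=index)


class TestMontage:
    def test_single_field_identity(self):
        f = _blank_field()
        m = montage_fields([f])
        assert m.shape == f.shape
        assert np.array_equal(m.nuclear, f.nuclear)
        assert m.field_origins == {0: (0, 0)}

    def test_four_fields_double_geometry(self):
        fields = [_blank_field(shape=(512, 512), index=i) for i in range(4)]
        m = montage_fields(fields)
        assert m.shape == (1024, 1024)

    def test_bottom_right_field_offset(self):
        # a cell at (10, 10) in field index 3 lands at (522, 522)
        fields = [_blank_field(shape=(512, 512), index=i) for i in range(4)]
        fields[3].nuclear[10, 10] = 1.0
        m = montage_fields(fields)
        y0, x0 = m.field_origins[3]
        assert (y0 + 10, x0 + 10) == (522, 522)
        assert m.nuclear[522, 522] == 1.0

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            montage_fields([_blank_field((64, 64)), _blank_field((32, 32), index=1)])

    def test_mismatched_pixel_sizes_rejected(self):
        with pytest.raises(ValueError, match="pixel"):
            montage_fields([_blank_field(px=1.0), _blank_field(px=2.0, index=1)])


class TestDetectCells:
    def test_blank_montage_yields_no_cells(self):
        m = montage_fields([_blank_field(level=500.0)])
        assert detect_cells(m) == []

    def test_nonfinite_pixels_rejected(self):
        f = _blank_field()
        f.nuclear[3, 3] = np.nan
        with pytest.raises(ValueError, match="finite"):
            detect_cells(montage_fields([f]))

    def test_synthetic_field_classes_match_ground_truth(self, small_spec):
        img, truth = generate_field(small_spec)
        m = montage_fields([img])
        cells = detect_cells(m)
        assert len(cells) == len(truth.cells)
        # match each detection to the nearest true cell and compare class
        tx = truth.cells["x"].to_numpy()
        ty = truth.cells["y"].to_numpy()
        cls = truth.cells["cls"].to_numpy()
        for c in cells:
            i = int(np.argmin((tx - c.centroid_x) ** 2 + (ty - c.centroid_y) ** 2))
            assert c.cd90_pos == (cls[i] == "caf")
            assert c.nanog_pos == (cls[i] == CANCER_POS)

    def test_oversized_nucleus_excluded(self):
        f = _blank_field(shape=(256, 256), level=600.0)
        # one normal nucleus and one blob far wider than the max width
        yy, xx = np.mgrid[:256, :256]
        f.nuclear[((yy - 40) ** 2 + (xx - 40) ** 2) <= 25] = 30000.0
        f.nuclear[120:200, 120:200] = 30000.0
        cells = detect_cells(montage_fields([f]))
        assert len(cells) == 1
        assert cells[0].centroid_x == pytest.approx(40, abs=0.5)


class TestColonies:
    def test_colonies_recovered_with_full_membership(self, small_spec):
        img, truth = generate_field(small_spec)
        _, cells, colonies = score_well(montage_fields([img]))
        assert len(colonies) == small_spec.n_colonies
        assert sum(c.member_count for c in colonies) == small_spec.n_cancer

    def test_isolated_cells_fail_area_filter(self):
        spec = FieldSpec(width_px=400, height_px=400, n_caf=0, n_cancer=5,
                         n_colonies=0, noise_sd=(0, 0, 0), seed=9)
        img, _ = generate_field(spec)
        ph, cells, colonies = score_well(montage_fields([img]))
        assert len(cells) == 5
        assert colonies == []
        assert ph.no_colonies

    def test_elongated_chain_fails_form_factor(self):
        # straight chain of nuclei: merged component with length/breadth ~ 3.6
        f = _blank_field(shape=(600, 200), px=10.0)
        for k in range(12):
            y, x = 80 + 36 * k, 100
            yy, xx = np.mgrid[y - 5 : y + 6, x - 5 : x + 6]
            f.nuclear[y - 5 : y + 6, x - 5 : x + 6][
                (yy - y) ** 2 + (xx - x) ** 2 <= 25
            ] = 30000.0
        f.stemness[:] = f.nuclear  # all Nanog+ so the SD filter is not limiting
        m = montage_fields([f])
        params = ScoringParams(grow_px=14, min_stemness_sd=0.0)
        cells = detect_cells(m, params)
        assert len(cells) == 12
        colonies = identify_colonies(cells, m, params)
        assert colonies == []  # area is ample (px=10 um) but shape fails

    @pytest.mark.parametrize(
        "area,ff,sd,min_sd,keep",
        [
            (10_100.0, 1.0, 5.0, 0.0, True),
            (9_900.0, 1.0, 5.0, 0.0, False),   # area must exceed 10,000 um^2
            (10_000.0, 1.0, 5.0, 0.0, False),  # threshold is strict
            (20_000.0, 2.4, 5.0, 0.0, True),
            (20_000.0, 2.5, 5.0, 0.0, True),   # form factor <= 2.5 inclusive
            (20_000.0, 2.6, 5.0, 0.0, False),
            (20_000.0, 1.0, 0.5, 1.0, False),  # below the minimum Nanog SD
        ],
    )
    def test_filter_thresholds_exact(self, area, ff, sd, min_sd, keep):
        assert colony_filter(area, ff, sd, ScoringParams(), min_sd=min_sd) is keep


class TestPhenotype:
    def test_six_parameters_from_definitions(self):
        cells = [
            CellRecord(i, 0, 0, i + 1, 50, 8.0, 1, 1, 1, nanog_pos=i < 3, cd90_pos=i >= 8)
            for i in range(10)
        ]
        colony = ColonyRecord(0, list(range(8)), 5000, 12_500.0, 1.2, 3, 5, 9.0, 0, 0)
        ph = compute_phenotype(cells, [colony])
        assert ph.total_cells == 10
        assert ph.total_cafs == 2
        assert ph.total_cscs == 3
        assert ph.colony_count == 1
        assert ph.total_colony_cells == 8
        # one colony, 8 cells, area 12,500 um^2
        assert ph.colony_density == pytest.approx(8 / 12_500.0)

    def test_no_colonies_zeroes_colony_parameters(self):
        cells = [CellRecord(0, 0, 0, 1, 50, 8.0, 1, 1, 1, nanog_pos=True, cd90_pos=False)]
        ph = compute_phenotype(cells, [])
        assert ph.total_cells == 1
        assert ph.total_cscs == 0 and ph.total_colony_cells == 0
        assert ph.colony_density == 0.0 and ph.no_colonies

    def test_density_area_product_identity(self, small_spec):
        img, _ = generate_field(small_spec)
        ph, _, colonies = score_well(montage_fields([img]))
        total_area = sum(c.area_um2 for c in colonies)
        assert ph.colony_density * total_area == pytest.approx(
            ph.total_colony_cells, abs=1e-9
        )

    def test_count_ordering_invariant(self, small_spec):
        img, _ = generate_field(small_spec)
        ph, _, _ = score_well(montage_fields([img]))
        assert ph.total_cscs <= ph.total_colony_cells <= ph.total_cells


class TestEndToEnd:
    def test_noise_free_well_recovers_ground_truth_exactly(self, small_spec):
        fields, truth = generate_well(small_spec)
        ph, _, _ = score_well(montage_fields(fields))
        assert ph == expected_phenotype(truth)

    def test_noisy_well_counts_within_two_percent(self, small_spec):
        spec = replace(small_spec, noise_sd=(1500.0, 1500.0, 1500.0), seed=21)
        fields, truth = generate_well(spec)
        ph = score_well(montage_fields(fields))[0]
        exp = expected_phenotype(truth)
        for p in ("total_cells", "total_cafs", "total_cscs",
                  "colony_count", "total_colony_cells"):
            got, want = getattr(ph, p), getattr(exp, p)
            assert abs(got - want) <= max(0.02 * want, 0)

    def test_area_scales_with_pixel_size_squared(self, small_spec):
        img, _ = generate_field(small_spec)
        m1 = montage_fields([img])
        double = FieldImage(img.nuclear, img.stemness, img.fibroblast,
                            pixel_size_um=2 * small_spec.pixel_size_um)
        m2 = montage_fields([double])
        c1 = score_well(m1)[2]
        params = ScoringParams(colony_min_area_um2=40_000.0)  # same pixel cut
        c2 = score_well(m2, params)[2]
        a1 = sorted(c.area_um2 for c in c1)
        a2 = sorted(c.area_um2 for c in c2)
        assert np.allclose(np.asarray(a2), 4 * np.asarray(a1))
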