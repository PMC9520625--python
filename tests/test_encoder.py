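import numpy as np
import pytest

from sonocrack import (
    EchoModelParams,
    EncoderConfig,
    ModeMatrix,
    VMDConfig,
    build_background,
    build_mode_matrix,
    encode_dataset,
    generate_dataset,
    map_coordinates,
    render,
)
from sonocrack.encoder import MASTER_PALETTE, downsample_transform


@pytest.fixture(scope="module")
def mode_matrix(default_vmd):
    return build_mode_matrix(default_vmd)


# conftest fixtures are function-scoped by default; re-request at module level
@pytest.fixture(scope="module")
def default_vmd():
    from sonocrack import generate_signal, vmd_decompose
    record = generate_signal(1, EchoModelParams(), seed=1)
    return vmd_decompose(record.amplitudes, VMDConfig())


def test_mode_matrix_extrema_match_full_scan(default_vmd):
    matrix = build_mode_matrix(default_vmd)
    assert matrix.S.shape == (3, 450)
    assert matrix.s_max == max(float(v) for row in matrix.S for v in row)
    assert matrix.s_min == min(float(v) for row in matrix.S for v in row)


def test_zero_modes_matrix():
    from sonocrack.vmd import VMDResult
    result = VMDResult(modes=np.zeros((2, 10)), omegas=np.array([0.1, 0.2]),
                       iterations=1, converged=True)
    matrix = build_mode_matrix(result)
    assert matrix.s_max == matrix.s_min == 0.0


class TestCoordinateMapping:
    def test_x_positions_default_geometry(self, mode_matrix, encoder_config):
        points = map_coordinates(mode_matrix, encoder_config)
        xs = sorted({p[0] for column in points for p in column})
        assert xs == [288, 900, 1512]

    def test_extreme_values_map_to_band_edges(self, encoder_config):
        S = np.array([[0.0, 1.0], [0.5, 0.25]])
        matrix = ModeMatrix(S=S, s_max=1.0, s_min=0.0)
        points = map_coordinates(matrix, encoder_config)
        # column 0 row 0 holds s_min -> band top; column 1 row 0 holds s_max
        assert points[0][0][1] == encoder_config.draw_top == 190
        assert points[1][0][1] == encoder_config.origin_y == 1010

    def test_y_monotone_in_value(self, encoder_config):
        values = np.linspace(-2, 2, 9)
        S = np.vstack([values, values])
        matrix = ModeMatrix(S=S, s_max=2.0, s_min=-2.0)
        points = map_coordinates(matrix, encoder_config)
        ys = [points[l][0][1] for l in range(9)]
        # larger value -> closer to the origin row (larger y, image-down axis)
        assert all(b >= a for a, b in zip(ys, ys[1:]))

    def test_constant_matrix_maps_to_origin_row(self, encoder_config):
        matrix = ModeMatrix(S=np.ones((3, 5)), s_max=1.0, s_min=1.0)
        points = map_coordinates(matrix, encoder_config)
        assert all(p[1] == encoder_config.origin_y for col in points for p in col)

    def test_single_mode_rejected(self, encoder_config):
        matrix = ModeMatrix(S=np.ones((1, 5)), s_max=1.0, s_min=0.0)
        with pytest.raises(ValueError, match="2 modes"):
            map_coordinates(matrix, encoder_config)

    def test_vertices_inside_drawing_band(self, mode_matrix, encoder_config):
        points = map_coordinates(mode_matrix, encoder_config)
        for column in points:
            for x, y in column:
                assert encoder_config.origin_x <= x <= (
                    encoder_config.origin_x + encoder_config.draw_width
                )
                assert encoder_config.draw_top <= y <= encoder_config.origin_y


class TestRender:
    def test_canvas_dimensions(self, mode_matrix, encoder_config):
        image = render(mode_matrix, encoder_config)
        assert image.width == 1800
        assert image.height == 1200

    def test_deterministic(self, mode_matrix, encoder_config):
        a = render(mode_matrix, encoder_config)
        b = render(mode_matrix, encoder_config)
        assert np.array_equal(a.pixels, b.pixels)

    def test_color_cycle_period(self, encoder_config):
        """Columns l and l+B are drawn in the identical palette color."""
        B = encoder_config.n_colors
        assert encoder_config.palette[0] == encoder_config.palette[(B) % B]
        # render two tiny matrices differing only in columns >= B; the
        # cycling means column B reuses color 1
        L = B + 1
        S = np.vstack([np.linspace(0, 1, L), np.linspace(1, 0, L)])
        matrix = ModeMatrix(S=S, s_max=1.0, s_min=0.0)
        points = map_coordinates(matrix, encoder_config)
        img = render(matrix, encoder_config)
        # the pixels of the last polyline (over-painted last) carry color 1
        x, y = points[B][0]
        assert tuple(img.pixels[y, x]) == encoder_config.palette[0]

    def test_scale_invariance_of_encoding(self, mode_matrix, encoder_config):
        scaled = ModeMatrix(S=3.5 * mode_matrix.S, s_max=3.5 * mode_matrix.s_max,
                            s_min=3.5 * mode_matrix.s_min)
        assert np.array_equal(render(mode_matrix, encoder_config).pixels,
                              render(scaled, encoder_config).pixels)


@pytest.fixture(scope="module")
def records():
    return generate_dataset(8, 8, EchoModelParams(), seed=5)


class TestDatasetEncoding:
    def test_single_record_background_equals_standalone(self, records):
        from sonocrack import vmd_decompose
        bg = build_background(records[:1], VMDConfig(), EncoderConfig())
        standalone = render(
            build_mode_matrix(vmd_decompose(records[0].amplitudes, VMDConfig())),
            EncoderConfig(),
        )
        assert np.array_equal(bg.pixels, standalone.pixels)

    def test_reservation_counts(self, records):
        background, images = encode_dataset(
            records, VMDConfig(), EncoderConfig(),
            n_background_per_class=2, seed=9,
        )
        labels = [im.label for im in images]
        assert labels.count(1) == 6 and labels.count(0) == 6
        assert background is not None

    def test_no_background_reservation(self, records):
        background, images = encode_dataset(
            records, VMDConfig(), EncoderConfig(),
            n_background_per_class=0, seed=9,
        )
        assert background is None
        assert len(images) == len(records)

    def test_seeded_reservation_reproducible(self, records):
        a = encode_dataset(records, VMDConfig(), EncoderConfig(), 2, seed=13)
        b = encode_dataset(records, VMDConfig(), EncoderConfig(), 2, seed=13)
        assert np.array_equal(a[0].pixels, b[0].pixels)
        for ia, ib in zip(a[1], b[1]):
            assert ia.sample_id == ib.sample_id
            assert np.array_equal(ia.pixels, ib.pixels)

    def test_class_too_small_rejected(self, records):
        with pytest.raises(ValueError, match="need more"):
            encode_dataset(records, VMDConfig(), EncoderConfig(),
                           n_background_per_class=8, seed=1)

    def test_transform_applied(self, records):
        _, images = encode_dataset(
            records, VMDConfig(), EncoderConfig(), 0, seed=1,
            transform=downsample_transform(32),
        )
        assert all(im.width == im.height == 32 for im in images)
        assert all(im.label in (0, 1) for im in images)


def test_color_count_changes_colors_not_geometry(mode_matrix):
    """Different B values ink the identical pixel set, colors aside."""
    img_b2 = render(mode_matrix, EncoderConfig(n_colors=2,
                                               palette=MASTER_PALETTE))
    img_b10 = render(mode_matrix, EncoderConfig(n_colors=10,
                                                palette=MASTER_PALETTE))
    inked2 = (img_b2.pixels != 255).any(axis=2)
    inked10 = (img_b10.pixels != 255).any(axis=2)
    assert np.array_equal(inked2, inked10)


def test_palette_invariants():
    assert len(MASTER_PALETTE) == 12
    assert len(set(MASTER_PALETTE)) == 12
    config = EncoderConfig(n_colors=7, palette=list(MASTER_PALETTE))
    assert len(config.palette) == 7
    with pytest.raises(ValueError, match="palette"):
        EncoderConfig(n_colors=13, palette=list(MASTER_PALETTE))
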