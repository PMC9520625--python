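"""Color-polyline encoding of VMD mode matrices into RGB images.

The M modes of one signal are stacked into an M x L matrix S; each
column s_l (the M mode values at time index l) becomes one polyline of
M vertices drawn on the canvas, with polyline colors cycling through a
B-color palette (columns l and l+B share a color).  Vertex x positions
spread the M mode indices evenly across the drawing band; y positions
map the matrix values linearly between the band's top and the origin
row using the matrix's own global extrema, so every signal fills the
band regardless of its absolute amplitude.

Optionally, a shared background — the overlaid encodings of a reserved
set of signals — is built first, and every sample is then drawn on a
copy of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

from .signal_io import UltrasoundRecord
from .vmd import VMDConfig, VMDResult, vmd_decompose

__all__ = [
    "MASTER_PALETTE",
    "DEFAULT_PALETTE",
    "ModeMatrix",
    "EncoderConfig",
    "EncodedImage",
    "build_mode_matrix",
    "downsample_transform",
    "map_coordinates",
    "render",
    "build_background",
    "encode_dataset",
]

# 12 maximally distinct colors; the default 10-color cycle is its prefix
# and the full list serves color-count sweeps up to B = 12.
MASTER_PALETTE: list[tuple[int, int, int]] = [
    (230, 25, 75),    # red
    (60, 180, 75),    # green
    (255, 225, 25),   # yellow
    (0, 130, 200),    # blue
    (245, 130, 48),   # orange
    (145, 30, 180),   # purple
    (70, 240, 240),   # cyan
    (240, 50, 230),   # magenta
    (210, 245, 60),   # lime
    (0, 128, 128),    # teal
    (170, 110, 40),   # brown
    (0, 0, 128),      # navy
]
DEFAULT_PALETTE = MASTER_PALETTE[:10]


@dataclass
class ModeMatrix:
    """Stacked IMF matrix S (rows = modes, columns = time) with its extrema."""

    S: np.ndarray
    s_max: float
    s_min: float

    @property
    def n_modes(self) -> int:
        return int(self.S.shape[0])

    @property
    def length(self) -> int:
        return int(self.S.shape[1])


@dataclass
class EncoderConfig:
    """Canvas geometry and palette of the polyline encoding.

    The 1800 x 1200 canvas with drawing origin (288, 1010) leaves
    symmetric side margins, giving a drawing band 1224 px wide whose top
    row is 190 px from the canvas top.
    """

    n_colors: int = 10
    palette: list[tuple[int, int, int]] = field(
        default_factory=lambda: list(DEFAULT_PALETTE)
    )
    image_width: int = 1800
    image_height: int = 1200
    origin_x: int = 288
    origin_y: int = 1010
    draw_width: int = 1224      # W_S
    draw_top: int = 190         # H_S: y of the band's top row
    line_width: int = 2
    background: "EncodedImage | None" = None

    def band_crop_fractions(self) -> tuple[float, float, float, float]:
        """The drawing band as (x0, y0, x1, y1) fractions of the canvas."""
        return (
            self.origin_x / self.image_width,
            self.draw_top / self.image_height,
            (self.origin_x + self.draw_width) / self.image_width,
            self.origin_y / self.image_height,
        )

    def __post_init__(self) -> None:
        if len(self.palette) < self.n_colors:
            raise ValueError(
                f"palette has {len(self.palette)} colors, need n_colors={self.n_colors}"
            )
        self.palette = [tuple(c) for c in self.palette[: self.n_colors]]
        if len(set(self.palette)) != self.n_colors:
            raise ValueError("palette colors must be pairwise distinct")
        if self.origin_x + self.draw_width > self.image_width:
            raise ValueError("drawing band exceeds the canvas width")
        if not (self.draw_top < self.origin_y <= self.image_height):
            raise ValueError("need draw_top < origin_y <= image_height")


@dataclass
class EncodedImage:
    """8-bit RGB raster with an optional class label."""

    pixels: np.ndarray                  # (H, W, 3) uint8
    label: int | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        self.pixels = np.ascontiguousarray(self.pixels, dtype=np.uint8)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) array")

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    def to_pil(self) -> Image.Image:
        return Image.fromarray(self.pixels, mode="RGB")

    def save(self, path: str | Path) -> None:
        self.to_pil().save(Path(path))

    def copy(self) -> "EncodedImage":
        return EncodedImage(self.pixels.copy(), self.label, self.sample_id)


def downsample_transform(size: int, crop_box=None):
    """A transform for :func:`encode_dataset`: optional fractional crop,
    then bilinear resize to a ``size`` x ``size`` square.

    ``crop_box`` is (x0, y0, x1, y1) as fractions of the raster — e.g.
    :meth:`EncoderConfig.band_crop_fractions` to zoom onto the drawing
    band before downsampling.
    """
    def _resize(image: EncodedImage) -> EncodedImage:
        pil = image.to_pil()
        if crop_box is not None:
            w, h = pil.size
            x0, y0, x1, y1 = crop_box
            pil = pil.crop((round(x0 * w), round(y0 * h),
                            round(x1 * w), round(y1 * h)))
        pil = pil.resize((size, size), Image.BILINEAR)
        return EncodedImage(np.asarray(pil, dtype=np.uint8),
                            label=image.label, sample_id=image.sample_id)
    return _resize


def build_mode_matrix(result: VMDResult) -> ModeMatrix:
    """Stack the modes of a decomposition and record the global extrema."""
    if result.n_modes < 1:
        raise ValueError("decomposition has no modes")
    S = np.asarray(result.modes, dtype=float)
    return ModeMatrix(S=S, s_max=float(S.max()), s_min=float(S.min()))


def map_coordinates(matrix: ModeMatrix, config: EncoderConfig | None = None) -> list[list[tuple[int, int]]]:
    """Pixel vertices of every polyline: L lists of M (x, y) points.

    x spreads the M mode indices evenly across the band:
    x_m = x_O + (m-1) * W_S / (M-1).  y maps values linearly with the
    matrix extrema, the maximum landing on the origin row and the
    minimum on the band's top row (image y grows downward).  When the
    matrix is constant every vertex sits on the origin row.
    """
    config = config or EncoderConfig()
    M, L = matrix.n_modes, matrix.length
    if M < 2:
        raise ValueError("coordinate mapping needs at least 2 modes")
    xs = [int(round(config.origin_x + (m - 1) * config.draw_width / (M - 1)))
          for m in range(1, M + 1)]
    span = matrix.s_max - matrix.s_min
    if span == 0.0:
        ys = np.full((M, L), config.origin_y, dtype=int)
    else:
        frac = (matrix.s_max - matrix.S) / span            # 0 at max, 1 at min
        ys = np.rint(config.origin_y + (config.draw_top - config.origin_y) * frac
                     ).astype(int)
    return [[(xs[m], int(ys[m, l])) for m in range(M)] for l in range(L)]


def render(matrix: ModeMatrix, config: EncoderConfig | None = None) -> EncodedImage:
    """Draw the L color-cycled polylines; later columns over-paint earlier ones."""
    config = config or EncoderConfig()
    if config.background is not None:
        if (config.background.width, config.background.height) != (
            config.image_width, config.image_height
        ):
            raise ValueError("background dimensions do not match the canvas")
        canvas = config.background.to_pil().copy()
    else:
        canvas = Image.new(
            "RGB", (config.image_width, config.image_height), (255, 255, 255)
        )
    draw = ImageDraw.Draw(canvas)
    polylines = map_coordinates(matrix, config)
    B = config.n_colors
    for l, points in enumerate(polylines):
        color = config.palette[l % B]
        draw.line(points, fill=color, width=config.line_width)
    return EncodedImage(np.asarray(canvas, dtype=np.uint8))


def _encode_record(
    record: UltrasoundRecord,
    vmd_config: VMDConfig,
    config: EncoderConfig,
) -> EncodedImage:
    result = vmd_decompose(record.amplitudes, vmd_config)
    image = render(build_mode_matrix(result), config)
    image.label = record.label
    image.sample_id = record.sample_id
    return image


def build_background(
    records: list[UltrasoundRecord],
    vmd_config: VMDConfig | None = None,
    config: EncoderConfig | None = None,
) -> EncodedImage:
    """Overlay the encodings of the reserved records on one shared canvas.

    Each record is decomposed and normalised on its own; its polylines
    are drawn onto the accumulating canvas in record order.
    """
    if not records:
        raise ValueError("background needs at least one record")
    vmd_config = vmd_config or VMDConfig()
    config = config or EncoderConfig()
    if config.background is not None:
        raise ValueError("background construction starts from a blank canvas")
    canvas: EncodedImage | None = None
    for record in records:
        cfg_kwargs = {k: v for k, v in vars(config).items() if k != "background"}
        cfg = EncoderConfig(background=canvas, **cfg_kwargs)
        result = vmd_decompose(record.amplitudes, vmd_config)
        canvas = render(build_mode_matrix(result), cfg)
    canvas.label = None
    canvas.sample_id = "background"
    return canvas


def encode_dataset(
    records: list[UltrasoundRecord],
    vmd_config: VMDConfig | None = None,
    encoder_config: EncoderConfig | None = None,
    n_background_per_class: int = 30,
    seed: int = 0,
    transform=None,
) -> tuple[EncodedImage | None, list[EncodedImage]]:
    """Reserve a seeded random subset per class for the background, encode the rest.

    Returns the shared background (``None`` when no records are
    reserved) and the encoded images of all remaining records, each
    carrying its source label and sample id.  ``transform``, when
    given, is applied to each sample image as it is produced and its
    result stored instead — e.g. an early downsampling step so a large
    dataset never holds hundreds of full-resolution rasters at once.
    """
    vmd_config = vmd_config or VMDConfig()
    encoder_config = encoder_config or EncoderConfig()
    rng = np.random.default_rng(seed)

    reserved_idx: list[int] = []
    if n_background_per_class > 0:
        for cls in (1, 0):
            members = [i for i, r in enumerate(records) if r.label == cls]
            if len(members) <= n_background_per_class:
                raise ValueError(
                    f"class {cls} has {len(members)} records; need more than "
                    f"{n_background_per_class} to reserve a background subset"
                )
            chosen = rng.choice(len(members), size=n_background_per_class, replace=False)
            reserved_idx.extend(members[i] for i in sorted(chosen))
    reserved = sorted(reserved_idx)
    reserved_set = set(reserved)

    background: EncodedImage | None = None
    if reserved:
        background = build_background(
            [records[i] for i in reserved], vmd_config, encoder_config
        )

    cfg_kwargs = {k: v for k, v in vars(encoder_config).items() if k != "background"}
    sample_cfg = EncoderConfig(background=background, **cfg_kwargs)
    images = []
    for i in range(len(records)):
        if i in reserved_set:
            continue
        img = _encode_record(records[i], vmd_config, sample_cfg)
        images.append(transform(img) if transform is not None else img)
    return background, images
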