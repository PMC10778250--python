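"""The pixel-counting protocol for pseudocolour thermograms.

A thermogram is rendered (or supplied) as an 8-bit RGB raster in which the
background is exact ``#000000`` and every body-surface pixel carries a
pseudocolour encoding its temperature on a 28.0-38.0 degC scale. The protocol
counts the distinct surface colours, converts each to CIELAB, assigns it by
CIE76 distance to the nearest of five reference colours — one per 2 degC
temperature bin — and reports per-bin pixel counts as percentages of the
total body-surface pixel count.

Bin edges follow the half-open convention [28,30), [30,32), [32,34),
[34,36) with a closed top bin [36,38]; temperatures below 28 are
background, temperatures above 38 clamp into the top bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from skimage import color as _skcolor

T_MIN = 28.0
T_MAX = 38.0
#: Bin edges in degC; five 2-degree bins.
BIN_EDGES = (28.0, 30.0, 32.0, 34.0, 36.0, 38.0)
N_BINS = 5
#: Sentinel bin index for background (below-threshold) temperatures.
BACKGROUND = 0

BIN_LABELS = (
    "T in [28;30)",
    "T in [30;32)",
    "T in [32;34)",
    "T in [34;36)",
    "T in [36;38]",
)


def bin_of_temperature(t: float) -> int:
    """Temperature bin index 1-5, or 0 (background) for t < 28 degC.

    Bins are half-open below the top: [28,30), [30,32), [32,34), [34,36),
    and the final bin is closed, [36,38]. Temperatures above 38 clamp to
    bin 5 (the rendering scale saturates there).
    """
    if not np.isfinite(t):
        raise ValueError(f"temperature must be finite, got {t}")
    if t < T_MIN:
        return BACKGROUND
    if t >= BIN_EDGES[-2]:
        return N_BINS
    return int((t - T_MIN) // 2.0) + 1


def bins_of_temperatures(t: np.ndarray) -> np.ndarray:
    """Vectorised :func:`bin_of_temperature`; NaN maps to background."""
    t = np.asarray(t, dtype=float)
    out = np.zeros(t.shape, dtype=np.int64)
    surface = ~np.isnan(t) & (t >= T_MIN)
    clipped = np.clip(t, T_MIN, T_MAX - 1e-12)
    out[surface] = ((clipped[surface] - T_MIN) // 2.0).astype(np.int64) + 1
    np.clip(out, 0, N_BINS, out=out)
    return out


@dataclass
class ThermalScene:
    """A per-pixel temperature field (degC) with a body-surface mask."""

    temperatures: np.ndarray  # (h, w) float; NaN allowed on background
    mask: np.ndarray          # (h, w) bool, True = body surface

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.temperatures.shape != self.mask.shape:
            raise ValueError("temperature grid and mask must be congruent")
        if not np.all(np.isfinite(self.temperatures[self.mask])):
            raise ValueError("surface temperatures must be finite")

    @property
    def width(self) -> int:
        return self.temperatures.shape[1]

    @property
    def height(self) -> int:
        return self.temperatures.shape[0]

    @classmethod
    def from_grid(cls, grid: np.ndarray) -> "ThermalScene":
        """Build a scene from a raw numeric grid: NaN or sub-threshold values
        become background."""
        grid = np.asarray(grid, dtype=float)
        mask = np.isfinite(grid) & (grid >= T_MIN)
        return cls(grid, mask)

    def bin_tally(self) -> np.ndarray:
        """Direct per-pixel temperature-bin counts over the surface."""
        bins = bins_of_temperatures(np.where(self.mask, self.temperatures, np.nan))
        return np.bincount(bins[self.mask], minlength=N_BINS + 1)[1:]


@dataclass
class Palette:
    """Pseudocolour palette: ordered (temperature, RGB) stops on [28, 38].

    Rendering interpolates the stops piecewise-linearly in RGB and
    quantises to 8 bits (round-half-up). The bundled default palette jumps
    to a new hue family at every 2 degC bin edge (purple/navy, blue, green,
    yellow/orange, red) so that nearest-reference CIE76 classification of
    any rendered colour recovers exactly the bin of the temperature that
    produced it.
    """

    stops: tuple[tuple[float, tuple[int, int, int]], ...]
    background: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        temps = [t for t, _ in self.stops]
        if any(b <= a for a, b in zip(temps, temps[1:])):
            raise ValueError("palette stops must be strictly increasing in temperature")
        if temps[0] != T_MIN or temps[-1] != T_MAX:
            raise ValueError(f"palette must span [{T_MIN}, {T_MAX}] degC")

    def color_at(self, t: float) -> tuple[int, int, int]:
        """8-bit RGB colour for a surface temperature (clamped to [28, 38])."""
        return tuple(int(v) for v in self.colors_at(np.array(t)).reshape(3))

    def colors_at(self, t: np.ndarray) -> np.ndarray:
        """Vectorised colour lookup -> (..., 3) uint8.

        Each temperature is first clamped into the ramp of its own bin so
        that palettes with colour jumps at bin edges never blend across an
        edge: a temperature arbitrarily close below an edge still renders
        within the lower bin's hue family.
        """
        temps = np.array([s[0] for s in self.stops])
        rgbs = np.array([s[1] for s in self.stops], dtype=float)
        tc = np.clip(np.asarray(t, dtype=float), T_MIN, T_MAX)
        bins = np.clip(((tc - T_MIN) // 2.0).astype(int), 0, N_BINS - 1)
        lows = np.asarray(BIN_EDGES)[bins]
        highs = np.asarray(BIN_EDGES)[bins + 1]
        # ramp of bin i ends just below the next edge (at/before the last
        # stop of the bin's hue family)
        ramp_high = np.where(bins == N_BINS - 1, T_MAX, highs - _RAMP_MARGIN)
        tc = np.minimum(np.maximum(tc, lows), ramp_high)
        out = np.stack([np.interp(tc, temps, rgbs[:, c]) for c in range(3)], axis=-1)
        return np.floor(out + 0.5).astype(np.uint8)

    def bin_reference(self, bin_index: int) -> tuple[int, int, int]:
        """Reference colour of a bin: the palette sampled at its midpoint."""
        if not 1 <= bin_index <= N_BINS:
            raise ValueError(f"bin index must be 1..{N_BINS}")
        mid = BIN_EDGES[bin_index - 1] + 1.0
        return self.color_at(mid)

    def bin_references_lab(self) -> np.ndarray:
        """(5, 3) Lab coordinates of the bin reference colours."""
        refs = np.array([self.bin_reference(b) for b in range(1, N_BINS + 1)], dtype=np.uint8)
        return srgb_to_lab(refs)

    @classmethod
    def from_config(cls, path: str | Path) -> "Palette":
        """Load a palette from a YAML config of {stops: [[t, '#rrggbb'], ...]}."""
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        stops = tuple(
            (float(t), _hex_to_rgb(colour)) for t, colour in data["stops"]
        )
        return cls(stops=stops)


def _hex_to_rgb(code: str) -> tuple[int, int, int]:
    code = code.lstrip("#")
    return tuple(int(code[i : i + 2], 16) for i in (0, 2, 4))


# Each 2 degC bin interpolates within one hue family; the colour jumps at
# every bin edge keep nearest-reference classification exact for all
# temperatures, including those arbitrarily close to an edge.
_EPS = 0.005
#: temperatures within this margin below a bin edge render at the margin,
#: so interpolation never blends across an edge jump
_RAMP_MARGIN = 0.01
DEFAULT_STOPS: tuple[tuple[float, tuple[int, int, int]], ...] = (
    (28.0, (88, 8, 116)),            # dark purple
    (30.0 - _EPS, (24, 8, 132)),     # navy
    (30.0, (8, 72, 208)),            # deep blue
    (32.0 - _EPS, (40, 160, 248)),   # light blue
    (32.0, (8, 132, 24)),            # green
    (34.0 - _EPS, (120, 216, 48)),   # yellow-green
    (34.0, (248, 224, 24)),          # yellow
    (36.0 - _EPS, (248, 144, 16)),   # orange
    (36.0, (240, 56, 16)),           # red
    (38.0, (152, 8, 24)),            # dark red
)


def default_palette() -> Palette:
    """The bundled pseudocolour palette (purple/navy, blue, green,
    yellow/orange, red over the five 2 degC bins)."""
    return Palette(stops=DEFAULT_STOPS)


def render_thermogram(scene: ThermalScene, palette: Palette | None = None) -> np.ndarray:
    """Render a scene to an (h, w, 3) uint8 pseudocolour raster.

    Masked pixels and any pixel below the 28 degC threshold are exact
    ``#000000``; surface pixels are coloured by piecewise-linear
    interpolation of the palette stops (clamping above 38 degC).
    """
    palette = palette or default_palette()
    t = scene.temperatures
    img = np.zeros((*t.shape, 3), dtype=np.uint8)
    with np.errstate(invalid="ignore"):
        surface = scene.mask & np.isfinite(t) & (t >= T_MIN)
    if surface.any():
        img[surface] = palette.colors_at(t[surface])
    return img


def mask_background(image: np.ndarray) -> np.ndarray:
    """Boolean surface mask: all and only pixels not exactly ``#000000``."""
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty raster")
    surface = np.any(image != 0, axis=-1)
    if not surface.any():
        raise ValueError("no non-background pixels: empty body surface")
    return surface


def srgb_to_lab(rgb: np.ndarray | Sequence[int]) -> np.ndarray:
    """Convert 8-bit sRGB (D65) to CIELAB. Accepts a triple or an array."""
    arr = np.asarray(rgb, dtype=float)
    single = arr.ndim == 1
    lab = _skcolor.rgb2lab((arr[None] if single else arr) / 255.0)
    return lab[0] if single else lab


def delta_e76(c1: Sequence[float], c2: Sequence[float]) -> float:
    """CIE76 colour difference: Euclidean distance in CIELAB space."""
    d = np.asarray(c1, dtype=float) - np.asarray(c2, dtype=float)
    return float(np.sqrt(np.sum(d**2)))


def extract_color_histogram(
    image: np.ndarray, surface: np.ndarray | None = None
) -> list[tuple[tuple[int, int, int], int]]:
    """Exact counts of distinct surface colours, most frequent first."""
    image = np.asarray(image)
    if surface is None:
        surface = mask_background(image)
    pixels = image[surface].reshape(-1, 3)
    if len(pixels) == 0:
        raise ValueError("empty surface")
    colors, counts = np.unique(pixels, axis=0, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    return [
        (tuple(int(v) for v in colors[i]), int(counts[i])) for i in order
    ]


def classify_color(rgb: Sequence[int], palette: Palette | None = None) -> int:
    """Assign one RGB colour to the temperature bin whose reference colour
    is nearest by CIE76; ties break toward the lower bin."""
    palette = palette or default_palette()
    lab = srgb_to_lab(np.asarray(rgb, dtype=np.uint8))
    refs = palette.bin_references_lab()
    d = np.sqrt(np.sum((refs - lab) ** 2, axis=1))
    return int(np.argmin(d)) + 1  # argmin takes the first (lower) bin on ties


def classify_colors(rgbs: np.ndarray, palette: Palette | None = None) -> np.ndarray:
    """Vectorised :func:`classify_color` for an (n, 3) colour array."""
    palette = palette or default_palette()
    labs = srgb_to_lab(np.asarray(rgbs, dtype=np.uint8))
    refs = palette.bin_references_lab()
    d = np.sqrt(np.sum((labs[:, None, :] - refs[None]) ** 2, axis=2))
    return np.argmin(d, axis=1) + 1


@dataclass
class SurfaceProfile:
    """Per-bin pixel counts and percentages of the body surface."""

    counts: np.ndarray                # (5,) int
    total_surface_pixels: int
    percentages: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (N_BINS,) or np.any(self.counts < 0):
            raise ValueError("counts must be five non-negative integers")
        if int(self.counts.sum()) != self.total_surface_pixels:
            raise ValueError("counts must sum to the surface pixel total")
        if self.total_surface_pixels <= 0:
            raise ValueError("surface must contain at least one pixel")
        self.percentages = self.counts / self.total_surface_pixels * 100.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin": np.arange(1, N_BINS + 1),
                "t_low": BIN_EDGES[:-1],
                "t_high": BIN_EDGES[1:],
                "count": self.counts,
                "percent": self.percentages,
            }
        )


def surface_profile(image: np.ndarray, palette: Palette | None = None) -> SurfaceProfile:
    """Run the pixel-counting protocol on a pseudocolour raster.

    Background (exact ``#000000``) pixels are excluded; the distinct surface
    colours are tallied, classified by nearest CIE76 reference, and
    aggregated into per-bin counts and percentages of the surface total.
    """
    palette = palette or default_palette()
    surface = mask_background(image)
    hist = extract_color_histogram(image, surface)
    colors = np.array([c for c, _ in hist], dtype=np.uint8)
    counts = np.array([n for _, n in hist], dtype=np.int64)
    bins = classify_colors(colors, palette)
    per_bin = np.zeros(N_BINS, dtype=np.int64)
    np.add.at(per_bin, bins - 1, counts)
    return SurfaceProfile(counts=per_bin, total_surface_pixels=int(counts.sum()))


def profile_to_pie(
    profile: SurfaceProfile,
    path: str | Path | None = None,
    palette: Palette | None = None,
    title: str | None = None,
):
    """Five-sector pie chart of a surface profile.

    Sector angles are proportional to bin percentages; sector colours are
    the bin reference colours. Saving to SVG is deterministic (fixed hash
    salt, no embedded date), so regenerating from the same profile yields
    byte-identical output.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    palette = palette or default_palette()
    colors = [np.array(palette.bin_reference(b)) / 255.0 for b in range(1, N_BINS + 1)]
    with plt.rc_context({"svg.hashsalt": "equilunge"}):
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.pie(
            profile.percentages,
            labels=[f"{lab}\n{pct:.1f}%" for lab, pct in zip(BIN_LABELS, profile.percentages)],
            colors=colors,
            normalize=False if abs(profile.percentages.sum() - 100) > 1e-6 else True,
            startangle=90,
            counterclock=False,
        )
        if title:
            ax.set_title(title)
        if path is not None:
            fig.savefig(path, metadata={"Date": None} if str(path).endswith(".svg") else None)
            plt.close(fig)
            return Path(path)
    return fig


# --- raster I/O ------------------------------------------------------------

def load_raster(path: str | Path) -> np.ndarray:
    """Read a BMP/PNG raster as (h, w, 3) uint8; warns for lossy formats."""
    import warnings

    from PIL import Image

    path = Path(path)
    if path.suffix.lower() in {".jpg", ".jpeg"}:
        warnings.warn(
            "lossy JPEG input: quantisation may move colours across bin boundaries",
            stacklevel=2,
        )
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_raster(image: np.ndarray, path: str | Path) -> Path:
    """Write an (h, w, 3) uint8 raster losslessly (PNG/BMP)."""
    from PIL import Image

    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)
    return Path(path)
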