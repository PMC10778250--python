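"""Landmark I/O and dorsal-profile curve construction.

The unit of analysis is a 30-point semilandmark curve tracing the horse's
dorsal profile from the base of the tail to the end of the facial crest.
Eight anatomical anchors are digitised, and 22 intermediate semilandmarks
are interpolated between them in fixed runs of 3, 2, 6 and 11 points.
Configurations travel in the TPS text format (``LM=``/``ID=`` records, one
``x y`` pair per line, dot decimal separators), with the study's classifier
labels — lunging aid, time relative to lunging, and individual — encoded in
the ID code.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum, IntEnum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

N_LANDMARKS = 30

#: 1-based landmark index -> body region.
HINDQUARTER_RANGE = range(1, 9)
BACK_RANGE = range(9, 20)
HEAD_NECK_RANGE = range(20, 31)


class LungingAid(str, Enum):
    """Lunging condition; values are the one-letter codes used in ID codes."""

    FMH = "A"  # freely moving head
    CH = "B"   # chambon
    RB = "C"   # rubber band
    TRS = "D"  # triangle side reins


class Time(IntEnum):
    """Imaging occasion relative to the lunging session."""

    BEFORE = 0
    AFTER = 1


def region_of(index: int) -> str:
    """Body region of a 1-based landmark index.

    Indices 1-8 lie in the hindquarter region, 9-19 in the back region and
    20-30 in the head-and-neck region.
    """
    if index in HINDQUARTER_RANGE:
        return "hindquarter"
    if index in BACK_RANGE:
        return "back"
    if index in HEAD_NECK_RANGE:
        return "head_neck"
    raise ValueError(f"landmark index must be 1..{N_LANDMARKS}, got {index}")


_ID_RE = re.compile(r"^([A-D])([01])(\d{2})$")


def parse_id_code(code: str) -> tuple[LungingAid, Time, int]:
    """Decode an ID code such as ``"A001"`` into (lunging aid, time, individual).

    The code is one letter A-D (lunging aid), one digit 0/1 (before/after
    lunging) and a two-digit individual number 01-52.
    """
    m = _ID_RE.match(code.strip())
    if m is None:
        raise ValueError(
            f"ID code {code!r} does not match letter A-D, digit 0/1, two-digit individual"
        )
    aid = LungingAid(m.group(1))
    time = Time(int(m.group(2)))
    individual = int(m.group(3))
    if not 1 <= individual <= 52:
        raise ValueError(f"individual code must be 01..52, got {individual:02d}")
    return aid, time, individual


def format_id_code(aid: LungingAid, time: Time, individual: int) -> str:
    """Inverse of :func:`parse_id_code`."""
    if not 1 <= individual <= 52:
        raise ValueError(f"individual code must be 01..52, got {individual}")
    return f"{LungingAid(aid).value}{int(time)}{individual:02d}"


@dataclass
class LandmarkConfiguration:
    """One specimen's 30 ordered dorsal-profile landmarks plus classifiers.

    Coordinates are in image-pixel units with y increasing upward in
    analysis space. ``extra_keys`` preserves unrecognised TPS record keys
    (other than LM/ID/IMAGE/SCALE) for lossless round-trips.
    """

    specimen_id: str
    lunging_aid: LungingAid
    time: Time
    individual: int
    points: np.ndarray  # (30, 2) float
    image: str | None = None
    scale: float | None = None
    extra_keys: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"expected {N_LANDMARKS} (x, y) landmarks, got array of shape {self.points.shape}"
            )
        if not np.all(np.isfinite(self.points)):
            raise ValueError("landmark coordinates must be finite")

    @classmethod
    def from_points(cls, points: np.ndarray, id_code: str, **kw) -> "LandmarkConfiguration":
        aid, time, individual = parse_id_code(id_code)
        return cls(
            specimen_id=id_code,
            lunging_aid=aid,
            time=time,
            individual=individual,
            points=points,
            **kw,
        )

    @property
    def id_code(self) -> str:
        return format_id_code(self.lunging_aid, self.time, self.individual)

    def region(self, index: int) -> str:
        """Region of the 1-based landmark ``index``."""
        return region_of(index)


# --- TPS dialect -----------------------------------------------------------

class TpsParseError(ValueError):
    """Malformed TPS record; message names the record index and file line."""


def read_tps(path: str | Path) -> list[LandmarkConfiguration]:
    """Read a TPS file into a list of configurations.

    Each record must declare ``LM=30``, provide 30 ``x y`` coordinate lines
    with dot decimal separators, and carry an ``ID=`` key whose value is a
    well-formed study ID code. ``IMAGE=`` and ``SCALE=`` are kept; any other
    key is preserved verbatim in ``extra_keys``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i = 0
    record_idx = 0
    while i < len(lines):
        line = lines[i].strip()
        if not line:
            i += 1
            continue
        if not line.upper().startswith("LM="):
            raise TpsParseError(
                f"record {record_idx}: expected LM= at line {i + 1}, got {line!r}"
            )
        try:
            n_lm = int(line.split("=", 1)[1])
        except ValueError:
            raise TpsParseError(f"record {record_idx}: bad LM count at line {i + 1}") from None
        if n_lm != N_LANDMARKS:
            raise TpsParseError(
                f"record {record_idx}: LM={n_lm} at line {i + 1}, expected LM={N_LANDMARKS}"
            )
        i += 1
        pts = np.empty((n_lm, 2), dtype=float)
        for j in range(n_lm):
            if i >= len(lines):
                raise TpsParseError(f"record {record_idx}: truncated coordinate block")
            raw = lines[i].strip()
            parts = raw.split()
            if len(parts) != 2 or any("," in p for p in parts):
                raise TpsParseError(
                    f"record {record_idx}: bad coordinate line {i + 1}: {raw!r}"
                    " (expected two dot-decimal numbers)"
                )
            try:
                pts[j] = [float(parts[0]), float(parts[1])]
            except ValueError:
                raise TpsParseError(
                    f"record {record_idx}: non-numeric coordinate at line {i + 1}: {raw!r}"
                ) from None
            i += 1
        id_code: str | None = None
        image: str | None = None
        scale: float | None = None
        extra: dict[str, str] = {}
        while i < len(lines) and lines[i].strip() and "=" in lines[i] and not lines[i].strip().upper().startswith("LM="):
            key, value = lines[i].strip().split("=", 1)
            key_u = key.strip().upper()
            if key_u == "ID":
                id_code = value.strip()
            elif key_u == "IMAGE":
                image = value.strip()
            elif key_u == "SCALE":
                scale = float(value.strip())
            else:
                extra[key.strip()] = value.strip()
            i += 1
        if id_code is None:
            raise TpsParseError(f"record {record_idx}: missing ID= key")
        try:
            config = LandmarkConfiguration.from_points(
                pts, id_code, image=image, scale=scale, extra_keys=extra
            )
        except ValueError as e:
            raise TpsParseError(f"record {record_idx}: {e}") from None
        configs.append(config)
        record_idx += 1
    return configs


def write_tps(dataset: Iterable[LandmarkConfiguration], path: str | Path) -> None:
    """Write configurations to a TPS file (dot decimals, y-up convention)."""
    out: list[str] = []
    for config in dataset:
        if config.points.shape != (N_LANDMARKS, 2):
            raise ValueError(
                f"{config.specimen_id}: refusing to write configuration with "
                f"{config.points.shape[0]} points"
            )
        out.append(f"LM={N_LANDMARKS}")
        for x, y in config.points:
            out.append(f"{x:.6f} {y:.6f}")
        if config.image:
            out.append(f"IMAGE={config.image}")
        out.append(f"ID={config.id_code}")
        if config.scale is not None:
            out.append(f"SCALE={config.scale}")
        for key, value in config.extra_keys.items():
            out.append(f"{key}={value}")
    Path(path).write_text("\n".join(out) + ("\n" if out else ""))


def dataset_to_frame(dataset: Sequence[LandmarkConfiguration]) -> pd.DataFrame:
    """Long-format export: one row per landmark with classifiers and region."""
    rows = []
    for config in dataset:
        for idx, (x, y) in enumerate(config.points, start=1):
            rows.append(
                {
                    "specimen_id": config.specimen_id,
                    "la": config.lunging_aid.name,
                    "time": int(config.time),
                    "individual": config.individual,
                    "lm_index": idx,
                    "x": x,
                    "y": y,
                    "region": region_of(idx),
                }
            )
    return pd.DataFrame(rows)


# --- curve construction ----------------------------------------------------

ANCHOR_NAMES = (
    "tail_base",
    "lumbosacral",
    "L1",
    "T10",
    "atlantooccipital",
    "temporomandibular",
    "eye_canthus",
    "facial_crest_end",
)

#: Intermediate semilandmark counts inserted after anchors 1, 2, 3 and 4.
INSERT_COUNTS = (3, 2, 6, 11)

#: 1-based curve indices at which each anchor is pinned. The 22 intermediates
#: fill the runs 2-4, 6-7, 9-14 and 16-26; anchors 5-8 are consecutive along
#: the head and neck.
ANCHOR_CURVE_INDICES = (1, 5, 8, 15, 27, 28, 29, 30)


@dataclass
class AnchorSet:
    """Eight named anatomical anchors, in tail-to-face curve order."""

    anchors: np.ndarray  # (8, 2)
    insert_counts: tuple[int, ...] = INSERT_COUNTS

    def __post_init__(self) -> None:
        self.anchors = np.asarray(self.anchors, dtype=float)
        if self.anchors.shape != (8, 2):
            raise ValueError(f"expected 8 (x, y) anchors, got shape {self.anchors.shape}")
        if not np.all(np.isfinite(self.anchors)):
            raise ValueError("anchors must be finite")
        if 8 + sum(self.insert_counts) != N_LANDMARKS:
            raise ValueError("insert counts must total 22 intermediates")

    def named(self) -> dict[str, np.ndarray]:
        return dict(zip(ANCHOR_NAMES, self.anchors))


def build_curve_landmarks(anchor_set: AnchorSet, id_code: str = "A001") -> LandmarkConfiguration:
    """Interpolate the 30-point dorsal-profile curve through the 8 anchors.

    A chord-length-parameterised natural cubic spline is fitted through the
    anchor polyline; each run of intermediates is placed at equal arc-length
    fractions along the spline segment between its flanking anchors. Anchors
    are pinned bit-exactly at their canonical curve indices. The spline
    depends on the anchors only through inter-anchor chord lengths and
    positions, so the construction is equivariant under rigid motions.
    """
    anchors = anchor_set.anchors
    chords = np.linalg.norm(np.diff(anchors, axis=0), axis=1)
    if np.any(chords == 0.0):
        bad = int(np.argmin(chords)) + 1
        raise ValueError(f"coincident consecutive anchors at positions {bad}, {bad + 1}")
    u = np.concatenate([[0.0], np.cumsum(chords)])
    spline_x = CubicSpline(u, anchors[:, 0], bc_type="natural")
    spline_y = CubicSpline(u, anchors[:, 1], bc_type="natural")

    points = np.empty((N_LANDMARKS, 2), dtype=float)
    for idx, anchor in zip(ANCHOR_CURVE_INDICES, anchors):
        points[idx - 1] = anchor

    for seg, n_mid in enumerate(anchor_set.insert_counts):
        u0, u1 = u[seg], u[seg + 1]
        # equal-arc-length placement via dense sampling of the segment
        dense = np.linspace(u0, u1, 4001)
        xy = np.column_stack([spline_x(dense), spline_y(dense)])
        arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(xy, axis=0), axis=1))])
        total = arc[-1]
        fractions = np.arange(1, n_mid + 1) / (n_mid + 1)
        u_mid = np.interp(fractions * total, arc, dense)
        start_idx = ANCHOR_CURVE_INDICES[seg]  # 1-based index of left anchor
        for k, um in enumerate(u_mid):
            points[start_idx + k] = [spline_x(um), spline_y(um)]

    return LandmarkConfiguration.from_points(points, id_code)


# --- angles ----------------------------------------------------------------

#: Target windows (degrees) for the head/neck angle: "open" during free
#: movement and chambon work, "closed" under rubber band or side reins.
HNA_WINDOWS = {"open": (110.0, 115.0), "closed": (85.0, 90.0)}


@dataclass
class HeadNeckAngle:
    """A goniometric head/neck angle with its posture class."""

    posture: str  # "open" or "closed"
    degrees: float

    def in_window(self) -> bool:
        lo, hi = HNA_WINDOWS[self.posture]
        return lo <= self.degrees <= hi


def compute_angle(p_a: Sequence[float], vertex: Sequence[float], p_b: Sequence[float]) -> float:
    """Interior angle at ``vertex`` between rays to ``p_a`` and ``p_b``, in degrees."""
    a = np.asarray(p_a, dtype=float) - np.asarray(vertex, dtype=float)
    b = np.asarray(p_b, dtype=float) - np.asarray(vertex, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("angle undefined: zero-length arm at vertex")
    cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    return float(np.degrees(np.arccos(cosang)))
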