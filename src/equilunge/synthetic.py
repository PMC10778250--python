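"""Synthetic study data: landmark datasets, thermal scenes and the cohort.

The study's images are not public, so this module generates data with the
statistical structure the analyses assume: (a) 104 dorsal-profile landmark
configurations — 13 horses x 4 lunging conditions x 2 time points — built
from a versioned template profile, per-horse shape/size perturbations,
condition-specific after-lunging displacement fields and isotropic landmark
noise; (b) horse-silhouette temperature fields whose per-bin pixel
fractions follow the before/after patterns observed thermographically
(before: mass in the two coolest bins; after: condition-dependent shifts
toward warmer bins, strongest under triangle side reins). The 13-horse
demographics table ships as an in-memory fixture.

All randomness flows from explicit integer seeds; there is no hidden
global state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from io import StringIO

import numpy as np
import pandas as pd

from equilunge.landmarks import (
    AnchorSet,
    LandmarkConfiguration,
    LungingAid,
    N_LANDMARKS,
    Time,
    build_curve_landmarks,
    format_id_code,
)
from equilunge.thermal import BIN_EDGES, N_BINS, ThermalScene


@dataclass
class StudyDesign:
    """The imaging design: horses x conditions x time points."""

    n_horses: int = 13
    conditions: tuple[LungingAid, ...] = (
        LungingAid.FMH,
        LungingAid.CH,
        LungingAid.RB,
        LungingAid.TRS,
    )
    time_points: tuple[Time, ...] = (Time.BEFORE, Time.AFTER)
    frames_per_occasion_visible: int = 5
    frames_per_occasion_infrared: int = 2
    selected_per_occasion: int = 1

    @property
    def occasions(self) -> int:
        return self.n_horses * len(self.conditions) * len(self.time_points)


@dataclass
class ImagingCounts:
    visible_captured: int
    visible_selected: int
    infrared_captured: int
    infrared_selected: int


def imaging_bookkeeping(design: StudyDesign | None = None) -> ImagingCounts:
    """Frame bookkeeping: captured = occasions x frames, selected = occasions x 1.

    The default design gives 520 visible frames captured / 104 selected and
    208 infrared frames captured / 104 selected.
    """
    design = design or StudyDesign()
    occ = design.occasions
    return ImagingCounts(
        visible_captured=occ * design.frames_per_occasion_visible,
        visible_selected=occ * design.selected_per_occasion,
        infrared_captured=occ * design.frames_per_occasion_infrared,
        infrared_selected=occ * design.selected_per_occasion,
    )


_COHORT_CSV = """\
no,sex,breed,age_years,bcs,height_cm,lameness,training_background,current_training
1,G,PHB,15,3,166,0,leisure work for 10 years,1-2 h/day 5 days/week
2,G,PHB,17,4,155,0,leisure work for 13 years,1-2 h/day 5 days/week
3,M,MLP,18,3,167,0,leisure work for 14 years,1-2 h/day 5 days/week
4,M,PHB,10,3,168,0,leisure work for 5 years,1-2 h/day 5 days/week
5,G,MLP,8,4,164,0,leisure work for 4 years,1-2 h/day 5 days/week
6,G,MLP,12,3,166,0,leisure work for 8 years,1-2 h/day 5 days/week
7,M,MLP,16,3,154,0,leisure work for 11 years,1-2 h/day 5 days/week
8,G,PHB,14,4,160,0,leisure work for 9 years,1-2 h/day 5 days/week
9,M,MLP,10,3,161,0,leisure work for 8 years,1-2 h/day 5 days/week
10,G,PHB,18,3,159,0,leisure work for 14 years,1-2 h/day 5 days/week
11,G,PHB,6,4,152,0,leisure work for 2 years,1-2 h/day 5 days/week
12,M,PHB,12,3,160,0,leisure work for 8 years,1-2 h/day 5 days/week
13,G,PHB,8,3,156,0,leisure work for 2 years,1-2 h/day 5 days/week
"""


def cohort_fixture() -> pd.DataFrame:
    """The 13-horse demographics table (sex, breed, age, BCS, height,
    lameness score, training background and current training)."""
    return pd.read_csv(StringIO(_COHORT_CSV))


# --- landmark generator ----------------------------------------------------

#: Versioned template dorsal profile: 8 anchors in tail-to-face order,
#: image-pixel units, y up. Back rises gently from the tail base to the
#: withers, the neck climbs to the poll (atlantooccipital), and the face
#: drops over jaw, eye and facial crest.
TEMPLATE_ANCHORS = np.array(
    [
        [60.0, 330.0],   # tail_base
        [190.0, 370.0],  # lumbosacral
        [330.0, 385.0],  # L1
        [470.0, 395.0],  # T10
        [700.0, 560.0],  # atlantooccipital
        [740.0, 505.0],  # temporomandibular
        [775.0, 535.0],  # eye_canthus
        [820.0, 470.0],  # facial_crest_end
    ]
)


def template_anchor_set() -> AnchorSet:
    return AnchorSet(TEMPLATE_ANCHORS.copy())


def _bump(center: int, peak: float, sigma: float = 1.5) -> np.ndarray:
    """Smooth displacement bump over 1-based landmark indices."""
    idx = np.arange(1, N_LANDMARKS + 1, dtype=float)
    return peak * np.exp(-((idx - center) ** 2) / (2.0 * sigma**2))


@dataclass
class PostureEffectSpec:
    """Condition-specific after-lunging vertical displacement fields.

    Displacements are expressed in units of the isotropic landmark-noise SD
    (the study reports which regions moved, not by how much; 2 SD at the
    peak landmark is the documented default calibration). Freely-moving-head
    work raises the poll and the tail base and lowers the mid-back; the
    chambon leaves posture unchanged; the rubber band raises the mid-back;
    side reins lower poll and tail base and raise the mid-back.
    """

    noise_sd: float = 4.0          # pixels, isotropic per coordinate
    peak: float = 2.0              # noise-SD units at the peak landmark
    bump_sigma: float = 1.5        # landmark-index width of each bump
    horse_shape_sd: float = 8.0    # pixels, per-anchor per-horse jitter
    horse_size_log_sd: float = 0.05

    def displacement_field(self, condition: LungingAid) -> np.ndarray:
        """(30,) vertical offsets in noise-SD units for one condition."""
        p, s = self.peak, self.bump_sigma
        tail, midback, poll = 1, 14, 27
        condition = LungingAid(condition)
        if condition is LungingAid.CH:
            return np.zeros(N_LANDMARKS)
        if condition is LungingAid.FMH:
            return _bump(poll, p, s) - _bump(midback, p, s) + _bump(tail, p, s)
        if condition is LungingAid.RB:
            return _bump(midback, p, s)
        # triangle side reins
        return -_bump(poll, p, s) + _bump(midback, p, s) - _bump(tail, p, s)


def generate_landmark_dataset(
    design: StudyDesign | None = None,
    effect_spec: PostureEffectSpec | None = None,
    seed: int = 0,
) -> list[LandmarkConfiguration]:
    """Generate the full synthetic landmark dataset (104 configurations).

    Each horse x condition occasion gets its own individual code (1-52);
    a per-horse base profile (template anchors + shape jitter, random size
    factor) yields a 30-point curve; the before configuration adds
    isotropic noise, the after configuration additionally applies the
    condition's vertical displacement field scaled by the noise SD.
    """
    design = design or StudyDesign()
    spec = effect_spec or PostureEffectSpec()
    if spec.noise_sd < 0 or spec.horse_shape_sd < 0:
        raise ValueError("noise magnitudes must be non-negative")
    rng = np.random.default_rng(seed)
    identical_horses = spec.horse_shape_sd == 0.0 and spec.horse_size_log_sd == 0.0
    template_curve = build_curve_landmarks(AnchorSet(TEMPLATE_ANCHORS.copy())).points
    configs: list[LandmarkConfiguration] = []
    for ci, condition in enumerate(design.conditions):
        field_y = spec.displacement_field(condition) * spec.noise_sd
        for horse in range(design.n_horses):
            individual = ci * design.n_horses + horse + 1
            if identical_horses:
                base = template_curve
            else:
                anchors = TEMPLATE_ANCHORS + rng.normal(0.0, spec.horse_shape_sd, (8, 2))
                scale = np.exp(rng.normal(0.0, spec.horse_size_log_sd))
                anchors = anchors.mean(axis=0) + (anchors - anchors.mean(axis=0)) * scale
                base = build_curve_landmarks(AnchorSet(anchors)).points
            for time in design.time_points:
                pts = base + rng.normal(0.0, spec.noise_sd, (N_LANDMARKS, 2))
                if time is Time.AFTER:
                    pts[:, 1] += field_y
                configs.append(
                    LandmarkConfiguration.from_points(
                        pts, format_id_code(condition, time, individual)
                    )
                )
    return configs


# --- thermal generator -----------------------------------------------------

#: Target per-bin pixel-fraction vectors (bins [28;30) ... [36;38]).
#: Before lunging the two coolest bins dominate and the hottest bin is
#: empty; after lunging the mass shifts by condition, furthest toward the
#: hottest bins under triangle side reins.
DEFAULT_BIN_TARGETS: dict[tuple[str, int], tuple[float, ...]] = {
    ("before", 0): (0.38, 0.36, 0.18, 0.08, 0.00),
    ("A", 1): (0.12, 0.12, 0.32, 0.34, 0.10),
    ("B", 1): (0.05, 0.14, 0.33, 0.35, 0.13),
    ("C", 1): (0.08, 0.08, 0.28, 0.28, 0.28),
    ("D", 1): (0.04, 0.12, 0.14, 0.34, 0.36),
}


@dataclass
class ThermalProfileSpec:
    """Targets and noise for the thermal-scene generator.

    ``targets`` maps (condition letter | "before", time) to a five-bin
    fraction vector; per-scene Dirichlet jitter with concentration
    ``noise_concentration`` perturbs the target (larger = less noise).
    ``shape`` is the raster (height, width); the study raster is 709 x 968
    and smaller rasters are supported for fast runs.
    """

    targets: dict = field(default_factory=lambda: dict(DEFAULT_BIN_TARGETS))
    noise_concentration: float = 300.0
    shape: tuple[int, int] = (709, 968)

    def target_for(self, condition: LungingAid, time: Time) -> np.ndarray:
        key = ("before", 0) if int(time) == 0 else (LungingAid(condition).value, 1)
        v = np.asarray(self.targets[key], dtype=float)
        if v.shape != (N_BINS,) or np.any(v < 0):
            raise ValueError(f"target vector for {key} must be 5 non-negative fractions")
        if not np.isclose(v.sum(), 1.0):
            raise ValueError(f"target vector for {key} must sum to 1")
        return v


def horse_silhouette(shape: tuple[int, int]) -> np.ndarray:
    """Boolean body mask: trunk ellipse + neck + head + four legs.

    Tail end on the left, head on the right, in image coordinates
    (row 0 at the top).
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    u, v = xx / w, yy / h  # 0..1, v down
    body = ((u - 0.42) / 0.27) ** 2 + ((v - 0.52) / 0.17) ** 2 <= 1.0
    neck = (
        (np.abs((v - (1.05 - u) * 1.05) * 1.0) <= 0.085)
        & (u >= 0.60)
        & (u <= 0.82)
        & (v >= 0.18)
        & (v <= 0.55)
    )
    head = ((u - 0.84) / 0.055) ** 2 + ((v - 0.26) / 0.085) ** 2 <= 1.0
    legs = np.zeros_like(body)
    for cx in (0.24, 0.33, 0.52, 0.61):
        legs |= (np.abs(u - cx) <= 0.022) & (v >= 0.52) & (v <= 0.92)
    return body | neck | head | legs


def generate_thermal_scene(
    profile_spec: ThermalProfileSpec | None = None,
    condition: LungingAid = LungingAid.FMH,
    time: Time = Time.BEFORE,
    seed: int = 0,
) -> tuple[ThermalScene, np.ndarray]:
    """Generate one horse-silhouette temperature field and its ground truth.

    The target bin-fraction vector for (condition, time) is jittered with
    Dirichlet noise, quantised to whole pixels by largest remainder, and
    laid out region-wise: surface pixels are ranked by a warmth score that
    increases from the hindquarter toward the cranial back and the ventral
    neck/head (plus smooth spatial noise), and bins are assigned coolest to
    warmest along that ranking. Per-pixel temperatures are drawn uniformly
    from the interior of their bin. Returns the scene and the exact
    realised bin fractions.
    """
    spec = profile_spec or ThermalProfileSpec()
    rng = np.random.default_rng(seed)
    target = spec.target_for(condition, time)
    if spec.noise_concentration > 0:
        # Dirichlet needs strictly positive concentration parameters
        alpha = np.maximum(target, 1e-3) * spec.noise_concentration
        target = rng.dirichlet(alpha)
    mask = horse_silhouette(spec.shape)
    n_surface = int(mask.sum())
    if n_surface == 0:
        raise ValueError("degenerate raster: empty silhouette")

    # largest-remainder quantisation of fractions to pixel counts
    raw = target * n_surface
    counts = np.floor(raw).astype(int)
    remainder = n_surface - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:remainder]] += 1

    h, w = spec.shape
    yy, xx = np.nonzero(mask)
    u, v = xx / w, yy / h
    warmth = u + 0.45 * v * (u > 0.55) - 0.25 * v * (u <= 0.55)
    warmth = warmth + rng.normal(0.0, 0.12, n_surface)
    rank = np.argsort(warmth, kind="stable")

    temps = np.full(spec.shape, np.nan)
    lo = 0
    edges = np.asarray(BIN_EDGES)
    for b in range(N_BINS):
        sel = rank[lo : lo + counts[b]]
        lo += counts[b]
        t = rng.uniform(edges[b] + 0.02, edges[b + 1] - 0.02, counts[b])
        temps[yy[sel], xx[sel]] = t
    scene = ThermalScene(temperatures=temps, mask=mask)
    return scene, counts / n_surface
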