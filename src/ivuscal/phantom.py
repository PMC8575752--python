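"""Polar-domain IVUS pullback phantom with exact calcium ground truth.

The phantom renders each A-line as envelope-detected ultrasound speckle
(Rayleigh-distributed, the standard incoherent-scattering model): a
low-intensity lumen, a brighter vessel-wall band (speckle times
``wall_echo_gain``), and plain speckle beyond the wall.  A calcium
deposit covers a contiguous block of frames and a circumferential arc
of A-lines (wrapping modulo the A-line count); on every covered A-line
the intensity ramps to ``calcium_peak_intensity`` within
``interface_rise_samples`` at the deposit's leading-edge depth — the
sharp white border — and everything distal to the interface is
multiplied by ``shadow_attenuation``, producing the dark acoustic
shadow that defines calcium on IVUS.  The returned mask is true exactly
on deposit-covered (frame, A-line) cells, so rendered pullbacks come
with pixel-perfect per-A-line labels.

Rendering and deposit sampling are fully deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Sequence, Tuple

import numpy as np

from .io import AcquisitionMeta, AnnotationMask, Pullback, QualityFlags
from .score import compute_ics


@dataclass(frozen=True)
class CalciumDeposit:
    """One calcified plate: a frame range x A-line arc at a given depth.

    ``frame_start``/``frame_end`` are inclusive; the arc starts at
    ``aline_start`` and spans ``arc_width`` A-lines, wrapping modulo the
    frame's A-line count; ``depth_sample`` is the radial sample index of
    the calcium leading edge (must lie within the wall band).
    """

    frame_start: int
    frame_end: int
    aline_start: int
    arc_width: int
    depth_sample: int


# Distribution specs are ("fixed", v) | ("uniform", lo, hi) |
# ("lognormal", median, sigma_log).
DistSpec = Tuple


def _draw(spec: DistSpec, rng: np.random.Generator) -> float:
    kind = spec[0]
    if kind == "fixed":
        return float(spec[1])
    if kind == "uniform":
        return float(rng.uniform(spec[1], spec[2]))
    if kind == "lognormal":
        return float(spec[1] * np.exp(rng.normal(0.0, spec[2])))
    raise ValueError(f"unknown distribution spec {spec!r}")


@dataclass(frozen=True)
class BurdenModel:
    """Cohort-level calcium burden: how many deposits, how large.

    Deposit count is Poisson(``expected_n_deposits``); arc widths
    (A-lines) and axial lengths (frames) are drawn from the stated
    distributions and clipped to the grid.  Defaults give a typical
    pullback a low-double-digit percentage of calcium-positive A-lines,
    on the scale seen in clinical pullbacks.
    """

    expected_n_deposits: float = 6.0
    arc_width_distribution: DistSpec = ("lognormal", 32.0, 0.5)
    axial_length_distribution: DistSpec = ("lognormal", 12.0, 0.6)

    def __post_init__(self) -> None:
        if self.expected_n_deposits < 0:
            raise ValueError("expected_n_deposits must be >= 0")


@dataclass
class PhantomConfig:
    """Geometry and rendering parameters of the pullback phantom."""

    n_frames: int = 100
    n_alines: int = 256
    n_samples: int = 512
    lumen_radius_samples: int = 160
    wall_thickness_samples: int = 96
    speckle_scale: float = 25.0
    wall_echo_gain: float = 3.0
    calcium_peak_intensity: float = 250.0
    interface_rise_samples: int = 2
    shadow_attenuation: float = 0.15
    deposits: List[CalciumDeposit] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lumen_radius_samples + self.wall_thickness_samples >= self.n_samples:
            raise ValueError("lumen + wall must fit inside the A-line")
        if not 0 < self.shadow_attenuation < 1:
            raise ValueError("shadow_attenuation must lie in (0, 1)")
        if self.speckle_scale < 0:
            raise ValueError("speckle_scale must be >= 0")

    @property
    def wall_end(self) -> int:
        return self.lumen_radius_samples + self.wall_thickness_samples

    def depth_range(self) -> Tuple[int, int]:
        """[lo, hi) range of admissible deposit leading-edge depths."""
        lo = self.lumen_radius_samples
        hi = min(self.wall_end, self.n_samples - self.interface_rise_samples)
        return lo, hi

    def meta(self) -> AcquisitionMeta:
        return AcquisitionMeta(n_alines=self.n_alines, n_samples=self.n_samples)


def _validate_deposit(d: CalciumDeposit, config: PhantomConfig) -> None:
    lo, hi = config.depth_range()
    if not (0 <= d.frame_start <= d.frame_end < config.n_frames):
        raise ValueError(f"deposit frames [{d.frame_start}, {d.frame_end}] outside grid")
    if not (0 <= d.aline_start < config.n_alines):
        raise ValueError("deposit aline_start outside grid")
    if not (1 <= d.arc_width <= config.n_alines):
        raise ValueError("deposit arc_width must be in [1, n_alines]")
    if not (lo <= d.depth_sample < hi):
        raise ValueError(f"deposit depth {d.depth_sample} outside wall band [{lo}, {hi})")


def _depth_map(deposits: Sequence[CalciumDeposit], config: PhantomConfig) -> np.ndarray:
    """Per-(frame, A-line) leading-edge depth; -1 where no deposit.

    Overlapping deposits merge: the shallowest leading edge wins.
    """
    depth = np.full((config.n_frames, config.n_alines), -1, dtype=int)
    for d in deposits:
        _validate_deposit(d, config)
        alines = (d.aline_start + np.arange(d.arc_width)) % config.n_alines
        block = depth[d.frame_start:d.frame_end + 1, alines]
        block = np.where(block < 0, d.depth_sample, np.minimum(block, d.depth_sample))
        depth[d.frame_start:d.frame_end + 1, alines] = block
    return depth


def union_mask(deposits: Sequence[CalciumDeposit], config: PhantomConfig) -> AnnotationMask:
    """Ground-truth mask covered by the union of deposits."""
    return AnnotationMask(mask=_depth_map(deposits, config) >= 0, source="ground_truth")


def render_pullback(config: PhantomConfig) -> Tuple[Pullback, AnnotationMask]:
    """Render a pullback and its exact ground-truth mask.

    Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    shape = (config.n_frames, config.n_alines, config.n_samples)
    if config.speckle_scale > 0:
        img = rng.rayleigh(config.speckle_scale, size=shape)
    else:
        img = np.zeros(shape)
    lr, we = config.lumen_radius_samples, config.wall_end
    img[:, :, lr:we] *= config.wall_echo_gain

    depth = _depth_map(config.deposits, config)
    rise = config.interface_rise_samples
    for d in np.unique(depth[depth >= 0]):
        cells = depth == d  # (frame, aline) cells whose interface sits at depth d
        ramp = config.calcium_peak_intensity * (np.arange(1, rise + 1) / rise)
        img[cells, d:d + rise] = ramp
        img[cells, d + rise:] *= config.shadow_attenuation

    frames = np.clip(img, 0, 255).astype(np.uint8)
    pb = Pullback(frames=frames, meta=config.meta(), flags=QualityFlags(),
                  vessel_label="synthetic")
    return pb, AnnotationMask(mask=depth >= 0, source="ground_truth")


def sample_deposits(burden: BurdenModel, geometry: PhantomConfig,
                    seed: int) -> List[CalciumDeposit]:
    """Draw a random deposit population, clipped to the grid."""
    rng = np.random.default_rng(seed)
    lo, hi = geometry.depth_range()
    n = int(rng.poisson(burden.expected_n_deposits))
    deposits = []
    for _ in range(n):
        f0 = int(rng.integers(0, geometry.n_frames))
        length = max(1, int(round(_draw(burden.axial_length_distribution, rng))))
        f1 = min(geometry.n_frames - 1, f0 + length - 1)
        a0 = int(rng.integers(0, geometry.n_alines))
        width = int(np.clip(round(_draw(burden.arc_width_distribution, rng)),
                            1, geometry.n_alines))
        d = int(rng.integers(lo, hi))
        deposits.append(CalciumDeposit(f0, f1, a0, width, d))
    return deposits


def ground_truth_ics(deposits: Sequence[CalciumDeposit],
                     geometry: PhantomConfig) -> float:
    """ICS implied by a deposit list (union semantics: overlaps count once)."""
    if not deposits:
        return 0.0
    return compute_ics(union_mask(deposits, geometry)).ics


def simulate_pullback(geometry: PhantomConfig, burden: BurdenModel,
                      seed: int) -> Tuple[Pullback, AnnotationMask, List[CalciumDeposit]]:
    """Sample a deposit population and render it in one step.

    Deposit sampling and speckle rendering use independent substreams of
    ``seed``, so the same seed always yields the same pullback.
    """
    dep_seed, render_seed = np.random.SeedSequence(seed).spawn(2)
    deposits = sample_deposits(burden, geometry, dep_seed)
    config = PhantomConfig(**{**geometry.__dict__, "deposits": deposits,
                              "seed": render_seed})
    pb, mask = render_pullback(config)
    return pb, mask, deposits
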