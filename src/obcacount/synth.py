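"""Seeded generator of ground-truthed multiplex fluorescence scenes.

The generator emulates the two situations both counting methods face in
immunostained tissue: round, well-separated "easy" cells (lymphocyte-like
Gaussian blobs) and irregular "hard" cells whose marker signal fragments
into several blobs along a jittered skeleton (macrophage-like), which is
what provokes maxima overcounting.  Each scene carries its ground truth
(object centers and which nuclei are colocalized), standing in for the
error-free analog of manual "gold standard" counts.

Conventions (8-bit intensity scale before any 16-bit conversion):
background 10, nuclei peak ~200, markers peak ~180, so that additive
Gaussian noise of SD 25 is a meaningful challenge.  The reference field of
the imaging protocol is 5000 x 5000 px (25,000,000 px^2 at 0.325 um/px);
the default working field is 512 x 512 for desk-scale runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .containers import ChannelImage, DEFAULT_PIXEL_SIZE_UM
from .exceptions import ParameterError, PlacementError

__all__ = [
    "SceneSpec",
    "SyntheticScene",
    "NoisePanelEntry",
    "generate_scene",
    "add_gaussian_noise",
    "make_noise_panel",
]

#: Density-class conventions per 512x512 field: (n_nuclei, coloc_fraction,
#: n_decoys override).  "none" fields contain tissue nuclei but no marker
#: objects at all.
DENSITY_CLASSES = {
    "none": (30, 0.0, 0),
    "medium": (50, 0.5, None),
    "high": (200, 0.5, None),
}


@dataclass
class SceneSpec:
    """Everything needed to generate one scene, reproducibly.

    shape : field dimensions in pixels (default 512 x 512; the imaging
        protocol's reference field is 5000 x 5000).
    n_nuclei : nuclei to place.
    coloc_fraction : fraction of nuclei carrying a colocalized marker;
        the ground-truth colocalized count is round(fraction * n_nuclei).
    morphology : ``"easy"`` (round single blobs) or ``"hard"``
        (fragmented multi-blob markers).
    density_class : optional label (none/medium/high); when given it
        overrides n_nuclei/coloc_fraction/n_decoys with the package's
        density conventions.
    noise_sd : additive Gaussian noise SD applied at generation time
        (0 = clean; the degraded-image experiments use 25).
    illumination : optional 6 coefficients (a, b, c, d, e, f) of a
        multiplicative quadratic gradient over normalized coordinates.
    n_channels : 2 (nuclear + marker) or 3 (+ second marker).
    seed : RNG seed; scenes are bit-reproducible from it.

    Geometry knobs (pixels): nucleus_sigma / marker_sigma are Gaussian
    profile widths; min_separation keeps nuclei apart; decoy markers are
    kept strictly farther than decoy_clearance from every nucleus (the
    default 15 clears the automated capture distance 2*expand + 5);
    colocalized markers sit within coexpr_displacement of their nucleus
    (nuclear vs. cytoplasmic markers co-express without overlapping in
    space); border_margin keeps every truth point away from the edge.
    """

    shape: Tuple[int, int] = (512, 512)
    n_nuclei: int = 50
    coloc_fraction: float = 0.5
    morphology: str = "easy"
    density_class: Optional[str] = None
    noise_sd: float = 0.0
    illumination: Optional[Tuple[float, ...]] = None
    n_channels: int = 2
    seed: int = 0
    # geometry / intensity conventions
    background: float = 10.0
    nucleus_amp: float = 190.0
    marker_amp: float = 170.0
    nucleus_sigma: float = 5.0
    marker_sigma: float = 4.0
    min_separation: float = 24.0
    coexpr_displacement: float = 3.0
    decoy_clearance: float = 15.0
    border_margin: float = 20.0
    n_decoys: Optional[int] = None
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.morphology not in ("easy", "hard"):
            raise ParameterError(f"morphology must be easy/hard, got {self.morphology!r}")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ParameterError("coloc_fraction must be in [0, 1]")
        if self.n_channels not in (2, 3):
            raise ParameterError("n_channels must be 2 or 3")
        if self.density_class is not None:
            if self.density_class not in DENSITY_CLASSES:
                raise ParameterError(f"unknown density class {self.density_class!r}")
            n, f, nd = DENSITY_CLASSES[self.density_class]
            self.n_nuclei, self.coloc_fraction, self.n_decoys = n, f, nd

    @property
    def n_coloc_truth(self) -> int:
        return int(round(self.coloc_fraction * self.n_nuclei))

    @property
    def n_decoys_effective(self) -> int:
        if self.n_decoys is not None:
            return self.n_decoys
        return int(round((1.0 - self.coloc_fraction) * self.n_nuclei))


@dataclass
class SyntheticScene:
    """Generated channels plus ground truth.

    truth_centers : per-channel (n, 2) center arrays, ordered
        [nuclei, markers, (markers2)]; marker arrays list colocalized
        markers first (aligned with ``truth_coloc``), then decoys.
    truth_coloc : indices into the nuclei array of the colocalized nuclei
        (for 3-channel scenes these nuclei carry both markers, i.e. the
        ground-truth triples).
    """

    channels: List[ChannelImage]
    truth_centers: List[np.ndarray]
    truth_coloc: np.ndarray
    spec: SceneSpec

    @property
    def n_coloc_truth(self) -> int:
        return int(len(self.truth_coloc))

    def with_noise(self, sd: float, seed: int) -> "SyntheticScene":
        """Noisy copy sharing this scene's ground truth."""
        noisy = [
            add_gaussian_noise(ch, sd, seed=(seed + 7919 * i) % (2**31 - 1))
            for i, ch in enumerate(self.channels)
        ]
        return SyntheticScene(
            channels=noisy,
            truth_centers=self.truth_centers,
            truth_coloc=self.truth_coloc,
            spec=replace(self.spec, noise_sd=sd),
        )


def _place_points(
    rng: np.random.Generator,
    n: int,
    shape: Tuple[int, int],
    margin: float,
    min_sep: float,
    avoid: Sequence[Tuple[np.ndarray, float]] = (),
    max_tries_per_point: int = 2000,
) -> np.ndarray:
    """Rejection-sample n points with mutual min_sep, margin from the
    border, and strict clearance from each (points, clearance) in avoid."""
    h, w = shape
    if h - 2 * margin <= 0 or w - 2 * margin <= 0:
        raise PlacementError(f"margin {margin} leaves no room in field {shape}")
    placed: List[np.ndarray] = []
    tries = 0
    budget = max_tries_per_point * max(n, 1)
    while len(placed) < n:
        if tries >= budget:
            raise PlacementError(
                f"could not place {n} points with min separation {min_sep} "
                f"and margin {margin} in field {shape} after {budget} tries"
            )
        tries += 1
        p = np.array(
            [rng.uniform(margin, h - 1 - margin), rng.uniform(margin, w - 1 - margin)]
        )
        ok = all(np.hypot(*(p - q)) >= min_sep for q in placed)
        if ok:
            for pts, clearance in avoid:
                if len(pts) and np.hypot(pts[:, 0] - p[0], pts[:, 1] - p[1]).min() <= clearance:
                    ok = False
                    break
        if ok:
            placed.append(p)
    return np.asarray(placed).reshape(n, 2)


def _stamp_blob(img: np.ndarray, center, amp: float, sigma: float) -> None:
    h, w = img.shape
    reach = int(np.ceil(4 * sigma))
    r0 = max(int(np.floor(center[0])) - reach, 0)
    r1 = min(int(np.ceil(center[0])) + reach, h - 1)
    c0 = max(int(np.floor(center[1])) - reach, 0)
    c1 = min(int(np.ceil(center[1])) + reach, w - 1)
    if r1 < r0 or c1 < c0:
        return
    rr = np.arange(r0, r1 + 1)[:, None] - center[0]
    cc = np.arange(c0, c1 + 1)[None, :] - center[1]
    img[r0 : r1 + 1, c0 : c1 + 1] += amp * np.exp(-(rr * rr + cc * cc) / (2 * sigma * sigma))


def _render_marker(
    img: np.ndarray, center: np.ndarray, spec: SceneSpec, rng: np.random.Generator
) -> None:
    if spec.morphology == "easy":
        _stamp_blob(img, center, spec.marker_amp, spec.marker_sigma)
        return
    # hard: 3-7 fragments along a jittered random-walk skeleton
    n_frag = int(rng.integers(3, 8))
    pos = center.astype(np.float64).copy()
    angle = rng.uniform(0, 2 * np.pi)
    for k in range(n_frag):
        sigma = rng.uniform(1.5, 2.5)
        amp = spec.marker_amp * rng.uniform(0.6, 1.0)
        _stamp_blob(img, pos, amp, sigma)
        step = rng.uniform(3.0, 6.0)
        angle += rng.normal(0.0, 0.7)
        pos = pos + step * np.array([np.sin(angle), np.cos(angle)])
        h, w = img.shape
        pos[0] = np.clip(pos[0], 2, h - 3)
        pos[1] = np.clip(pos[1], 2, w - 3)


def _illumination_surface(shape, coeffs) -> np.ndarray:
    h, w = shape
    y = np.linspace(0.0, 1.0, h)[:, None]
    x = np.linspace(0.0, 1.0, w)[None, :]
    a, b, c, d, e, f = coeffs
    return a + b * x + c * y + d * x * x + e * y * y + f * x * y


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Generate one scene, fully reproducible from ``spec.seed``.

    Nuclei are Gaussian-profile disks in the nuclear channel; each
    colocalized nucleus gets a marker object displaced by at most
    ``coexpr_displacement``; decoy markers (the (1 - fraction) share,
    unless overridden) are placed strictly farther than
    ``decoy_clearance`` from every nucleus.  Channels are 8-bit.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    nuclei = _place_points(
        rng, spec.n_nuclei, spec.shape, spec.border_margin, spec.min_separation
    )
    n_coloc = spec.n_coloc_truth
    if n_coloc:
        coloc_idx = np.sort(rng.choice(spec.n_nuclei, size=n_coloc, replace=False))
    else:
        coloc_idx = np.empty(0, dtype=int)

    def coexpressed_positions() -> np.ndarray:
        if not n_coloc:
            return np.empty((0, 2))
        theta = rng.uniform(0, 2 * np.pi, n_coloc)
        rad = spec.coexpr_displacement * np.sqrt(rng.uniform(0, 1, n_coloc))
        offs = np.column_stack([rad * np.sin(theta), rad * np.cos(theta)])
        return nuclei[coloc_idx] + offs

    marker_centers = [coexpressed_positions() for _ in range(spec.n_channels - 1)]
    n_decoys = spec.n_decoys_effective
    for m in range(spec.n_channels - 1):
        if n_decoys:
            decoys = _place_points(
                rng,
                n_decoys,
                spec.shape,
                spec.border_margin,
                min_sep=20.0,
                avoid=[(nuclei, spec.decoy_clearance)],
            )
            marker_centers[m] = np.vstack([marker_centers[m], decoys])

    # render channels
    nuc = np.full(spec.shape, spec.background, dtype=np.float64)
    for p in nuclei:
        _stamp_blob(nuc, p, spec.nucleus_amp, spec.nucleus_sigma)
    planes = [nuc]
    for m in range(spec.n_channels - 1):
        plane = np.full(spec.shape, spec.background, dtype=np.float64)
        for p in marker_centers[m]:
            _render_marker(plane, p, spec, rng)
        planes.append(plane)

    if spec.illumination is not None:
        surf = _illumination_surface(spec.shape, spec.illumination)
        if surf.min() <= 0:
            raise ParameterError("illumination surface must be strictly positive")
        planes = [pl * surf for pl in planes]

    roles = ["DAPI", "marker", "marker2"][: spec.n_channels]
    channels = []
    for plane, role in zip(planes, roles):
        arr = np.clip(np.rint(plane), 0, 255).astype(np.uint8)
        channels.append(
            ChannelImage(arr, bit_depth=8, pixel_size_um=spec.pixel_size_um, role=role)
        )
    scene = SyntheticScene(
        channels=channels,
        truth_centers=[nuclei] + marker_centers,
        truth_coloc=coloc_idx,
        spec=spec,
    )
    if spec.noise_sd > 0:
        scene = scene.with_noise(spec.noise_sd, seed=(spec.seed + 104729) % (2**31 - 1))
    return scene


def add_gaussian_noise(
    img: ChannelImage, sd: float, seed: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
) -> ChannelImage:
    """Add i.i.d. zero-mean Gaussian noise, clipped to the bit range.

    Clipping at 0 shifts the mean of dark backgrounds upward — inherent to
    bounded intensities, as in any noisy acquisition.  sd = 0 returns the
    image unchanged.
    """
    if sd < 0:
        raise ParameterError("noise sd must be >= 0")
    if sd == 0:
        return img
    gen = rng if rng is not None else np.random.default_rng(seed)
    noisy = img.astype_float() + gen.normal(0.0, sd, img.shape)
    noisy = np.clip(noisy, 0, img.max_value)
    if np.issubdtype(img.pixels.dtype, np.integer):
        noisy = np.rint(noisy).astype(img.pixels.dtype)
    return img.with_pixels(noisy)


@dataclass
class NoisePanelEntry:
    """One clean/noisy scene pair of the degraded-image experiment."""

    marker: str
    density: str
    morphology: str
    clean: SyntheticScene
    noisy: SyntheticScene


#: Cell types of the degraded-image experiment: (marker, morphology, channels).
PANEL_CELL_TYPES = [
    ("CD4", "easy", 2),
    ("CD8", "easy", 2),
    ("CD20", "easy", 2),
    ("CD68", "hard", 2),
    ("IBA1", "hard", 2),
    ("CD68/IBA1", "hard", 3),
]


def make_noise_panel(
    base_specs: Optional[Sequence[SceneSpec]] = None,
    sd: float = 25.0,
    seed: int = 0,
    shape: Tuple[int, int] = (512, 512),
) -> List[NoisePanelEntry]:
    """Build the degraded-image panel: paired clean/noisy scenes sharing
    ground truth.

    The default panel reproduces the experiment's structure — 3 density
    classes x 6 cell types = 18 scenes — each paired with a Gaussian-noise
    (default SD 25) variant.  Passing ``base_specs`` builds pairs for
    those scenes instead (an empty list yields an empty panel).
    """
    named: List[Tuple[str, SceneSpec]] = []
    if base_specs is None:
        for di, density in enumerate(("none", "medium", "high")):
            for ci, (marker_name, morph, n_ch) in enumerate(PANEL_CELL_TYPES):
                named.append(
                    (
                        marker_name,
                        SceneSpec(
                            shape=shape,
                            morphology=morph,
                            density_class=density,
                            n_channels=n_ch,
                            seed=(seed * 10007 + di * 101 + ci) % (2**31 - 1),
                        ),
                    )
                )
    else:
        named = [(f"scene_{i}", sp) for i, sp in enumerate(base_specs)]
    entries: List[NoisePanelEntry] = []
    for i, (marker_name, sp) in enumerate(named):
        clean = generate_scene(sp)
        noisy = clean.with_noise(sd, seed=(seed * 31337 + i) % (2**31 - 1))
        entries.append(
            NoisePanelEntry(
                marker=marker_name,
                density=sp.density_class or "custom",
                morphology=sp.morphology,
                clean=clean,
                noisy=noisy,
            )
        )
    return entries
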