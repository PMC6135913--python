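"""Synthesis of translucent two-surface figure-ground stimuli.

Two natural-looking binary shape masks are layered with alpha blending so
that a translucent *front* surface partially occludes a *back* surface on a
white ground.  The composite is then translated horizontally so that a
contour of either the front or the back surface passes through the stimulus
centre.  When the centre contour belongs to the front surface, the local
direction of figure (DOF) at the centre agrees with the global figure-ground
(FG) assignment (a *consistent* display); when it belongs to the occluded
back surface, DOF points toward a surface that is not the figure
(*contradictory*).

Blending follows the standard over-operator per region, evaluated in
floating point and quantized to 8 bit only on image export::

    I'_back       = a_b * I_back  + (1 - a_b) * W        (back over ground)
    S_superimpose = a_f * I_front + (1 - a_f) * I'_back  (front over back)
    S_front       = a_f * I_front + (1 - a_f) * W
    S_back        = a_b * I_back  + (1 - a_b) * W

Coordinates are degrees of visual angle, origin at the stimulus centre,
x rightward, y upward.  Pixel centres sit at half-integer offsets; the
"centre contour" is a mask boundary between the two columns flanking x = 0
on the centre row.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from itertools import product
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

# region labels
GROUND = 0
FRONT_ONLY = 1
BACK_ONLY = 2
OVERLAP = 3
REGION_NAMES = {
    GROUND: "ground",
    FRONT_ONLY: "front_only",
    BACK_ONLY: "back_only",
    OVERLAP: "overlap",
}

RED = (255.0, 0.0, 0.0)
GREEN = (0.0, 255.0, 0.0)
WHITE = (255.0, 255.0, 255.0)

DEPTH_ORDERS = ("red-front", "green-front")


class StimulusError(Exception):
    """Base class for stimulus-construction failures."""


class GenerationError(StimulusError):
    """Procedural shape generation exhausted its retry budget."""


class GeometryError(StimulusError):
    """Operands do not share raster geometry."""


class ConstructionError(StimulusError):
    """No solvable centre-contour translation exists."""


@dataclass(frozen=True)
class BlendParams:
    """Alpha-blending parameters: permeation rates and per-channel colors.

    ``alpha_front``/``alpha_back`` are the permeation rates of the front and
    back surfaces (1 = opaque).  Colors are RGB triples in [0, 255].
    """

    alpha_front: float = 0.5
    alpha_back: float = 0.5
    color_front: tuple = GREEN
    color_back: tuple = RED
    color_ground: tuple = WHITE

    def __post_init__(self) -> None:
        for name in ("alpha_front", "alpha_back"):
            a = getattr(self, name)
            if not 0.0 <= a <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {a!r}")
        for name in ("color_front", "color_back", "color_ground"):
            c = np.asarray(getattr(self, name), dtype=float)
            if c.shape != (3,) or np.any(c < 0) or np.any(c > 255):
                raise ValueError(f"{name} must be an RGB triple in [0, 255]")


@dataclass
class ShapePatch:
    """A binary figure mask on a square raster (True = figure region)."""

    mask: np.ndarray
    base_id: int
    extent_deg: float
    px_per_deg: float

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2 or self.mask.shape[0] != self.mask.shape[1]:
            raise ValueError("mask must be a square 2-D raster")

    @property
    def n(self) -> int:
        return self.mask.shape[0]

    def validate(self) -> None:
        """Raise if any ShapePatch invariant is violated."""
        if not self.mask.any():
            raise GenerationError("mask is empty")
        if self.mask.all():
            raise GenerationError("mask fills the raster")
        _, n_comp = ndimage.label(self.mask)
        if n_comp != 1:
            raise GenerationError(f"figure region has {n_comp} components")
        if not _has_midline_contour(self.mask):
            raise GenerationError("no contour point on the horizontal midline")

    def mirrored(self) -> "ShapePatch":
        """Mirror image about the vertical midline."""
        return ShapePatch(np.fliplr(self.mask), self.base_id,
                          self.extent_deg, self.px_per_deg)


@dataclass
class StimulusMeta:
    """Condition and ground-truth labels of one generated stimulus."""

    stimulus_id: str = ""
    base_id: int = -1
    mirror: bool = False
    depth_order: str = ""          # "red-front" | "green-front"
    translation_variant: str = ""  # "center-on-red" | "center-on-green"
    condition: str = ""            # "consistent" | "contradictory"
    dof_truth: str = ""            # "left" | "right"
    figure_color_truth: str = ""   # "red" | "green"


@dataclass
class TranslucentStimulus:
    """Rasterized stimulus with region labels and ground-truth metadata."""

    image: np.ndarray       # (n, n, 3) float, un-quantized intensities
    region_map: np.ndarray  # (n, n) uint8, labels GROUND..OVERLAP
    front_mask: np.ndarray
    back_mask: np.ndarray
    blend: BlendParams
    extent_deg: float
    px_per_deg: float
    meta: Optional[StimulusMeta] = None

    @property
    def n(self) -> int:
        return self.region_map.shape[0]

    def region_label_at(self, x_deg: float, y_deg: float) -> Optional[int]:
        """Region label under a point, or None when off the stimulus field."""
        col = int(np.floor((x_deg + self.extent_deg / 2) * self.px_per_deg))
        row = int(np.floor((self.extent_deg / 2 - y_deg) * self.px_per_deg))
        if not (0 <= col < self.n and 0 <= row < self.n):
            return None
        return int(self.region_map[row, col])

    def quantized_image(self) -> np.ndarray:
        """8-bit image for export; analysis always uses the float raster."""
        return np.clip(np.rint(self.image), 0, 255).astype(np.uint8)


def _has_midline_contour(mask: np.ndarray) -> bool:
    row = mask[mask.shape[0] // 2]
    return bool(row.any() and not row.all())


def _blob(rng: np.random.Generator, n: int, extent_deg: float,
          px_per_deg: float, center: tuple, radius_deg: float,
          noise_amp: float, smooth_deg: float) -> Optional[np.ndarray]:
    """One smoothed-noise blob: a disk of ``radius_deg`` perturbed by
    low-pass Gaussian noise, reduced to its largest connected component."""
    xs = (np.arange(n) + 0.5) / px_per_deg - extent_deg / 2
    ys = extent_deg / 2 - (np.arange(n) + 0.5) / px_per_deg
    X, Y = np.meshgrid(xs, ys)
    noise = ndimage.gaussian_filter(rng.standard_normal((n, n)),
                                    smooth_deg * px_per_deg)
    sd = noise.std()
    if sd > 0:
        noise = noise / sd
    d = np.hypot(X - center[0], Y - center[1])
    mask = (1.0 - d / radius_deg + noise_amp * noise) > 0
    labels, n_comp = ndimage.label(mask)
    if n_comp == 0:
        return None
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n_comp + 1))
    mask = labels == (int(np.argmax(sizes)) + 1)
    return ndimage.binary_fill_holes(mask)


def generate_shape_pair(seed: int, extent_deg: float = 9.0,
                        px_per_deg: float = 50.0, *,
                        base_id: Optional[int] = None,
                        blob_radius_deg: float = 2.4,
                        blob_offset_deg: float = 1.2,
                        noise_amp: float = 0.45,
                        smooth_deg: float = 0.8,
                        max_retries: int = 32) -> tuple:
    """Generate a (front, back) pair of natural-looking shape masks.

    Deterministic for a fixed seed.  Degenerate draws (empty mask, multiple
    components, no midline contour, zero overlap) are retried with a derived
    sub-seed; exhausting ``max_retries`` raises :class:`GenerationError`.
    """
    if extent_deg <= 0 or px_per_deg <= 0:
        raise ValueError("extent_deg and px_per_deg must be positive")
    n = int(round(extent_deg * px_per_deg))
    bid = int(seed) if base_id is None else int(base_id)
    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), attempt]))
        fm = _blob(rng, n, extent_deg, px_per_deg, (-blob_offset_deg, 0.0),
                   blob_radius_deg, noise_amp, smooth_deg)
        bm = _blob(rng, n, extent_deg, px_per_deg, (+blob_offset_deg, 0.0),
                   blob_radius_deg, noise_amp, smooth_deg)
        if fm is None or bm is None:
            continue
        front = ShapePatch(fm, bid, extent_deg, px_per_deg)
        back = ShapePatch(bm, bid, extent_deg, px_per_deg)
        try:
            front.validate()
            back.validate()
        except GenerationError:
            continue
        if not (fm & bm).any():
            continue
        return front, back
    raise GenerationError(
        f"no valid shape pair after {max_retries} attempts (seed={seed})")


def alpha_blend(front: ShapePatch, back: ShapePatch,
                params: BlendParams) -> TranslucentStimulus:
    """Compose two filled patches by alpha blending into a four-region
    stimulus (front-only, back-only, overlap, ground)."""
    if (front.mask.shape != back.mask.shape
            or front.extent_deg != back.extent_deg
            or front.px_per_deg != back.px_per_deg):
        raise GeometryError("patches do not share raster geometry")
    fm, bm = front.mask, back.mask
    region_map = np.full(fm.shape, GROUND, dtype=np.uint8)
    region_map[bm & ~fm] = BACK_ONLY
    region_map[fm & ~bm] = FRONT_ONLY
    region_map[fm & bm] = OVERLAP

    w = np.asarray(params.color_ground, dtype=float)
    i_f = np.asarray(params.color_front, dtype=float)
    i_b = np.asarray(params.color_back, dtype=float)
    a_f, a_b = params.alpha_front, params.alpha_back
    s_back = a_b * i_b + (1 - a_b) * w          # back surface over ground
    s_front = a_f * i_f + (1 - a_f) * w
    s_sup = a_f * i_f + (1 - a_f) * s_back      # front over blended back

    image = np.empty(fm.shape + (3,), dtype=float)
    image[region_map == GROUND] = w
    image[region_map == BACK_ONLY] = s_back
    image[region_map == FRONT_ONLY] = s_front
    image[region_map == OVERLAP] = s_sup
    return TranslucentStimulus(image=image, region_map=region_map,
                               front_mask=fm, back_mask=bm, blend=params,
                               extent_deg=front.extent_deg,
                               px_per_deg=front.px_per_deg)


def _hshift(mask: np.ndarray, s: int) -> np.ndarray:
    out = np.zeros_like(mask)
    if s > 0:
        out[:, s:] = mask[:, :-s]
    elif s < 0:
        out[:, :s] = mask[:, -s:]
    else:
        out[:] = mask
    return out


def _run_length(row: np.ndarray, start: int, step: int, cap: int) -> int:
    count = 0
    j = start
    while 0 <= j < row.size and row[j] and count < cap:
        count += 1
        j += step
    return count


def center_contour_translate(stim: TranslucentStimulus,
                             target: str = "front") -> TranslucentStimulus:
    """Translate the whole composite horizontally so that a contour of the
    target surface falls on the stimulus centre.

    Sets ``meta.condition`` (consistent when the front surface's own contour
    is centred, contradictory for the back surface) and ``meta.dof_truth``
    (the side on which the target surface's interior lies at the centre,
    i.e. the side toward the surface owning the centre contour).
    """
    if target not in ("front", "back"):
        raise ValueError("target must be 'front' or 'back'")
    n = stim.n
    mask = stim.front_mask if target == "front" else stim.back_mask
    mid = n // 2
    row = mask[mid]
    crossings = np.flatnonzero(row[:-1] != row[1:])  # boundary between j, j+1
    if crossings.size == 0:
        raise ConstructionError(
            f"{target} surface has no contour on the midline row")
    center_left = mid - 1
    shifts = center_left - crossings
    shift = int(shifts[np.argmin(np.abs(shifts))])

    fm = _hshift(stim.front_mask, shift)
    bm = _hshift(stim.back_mask, shift)
    out = alpha_blend(
        ShapePatch(fm, -1, stim.extent_deg, stim.px_per_deg),
        ShapePatch(bm, -1, stim.extent_deg, stim.px_per_deg),
        stim.blend)

    # interior side of the centred contour within a 0.5 deg window;
    # ties broken by the longer interior run
    trow = (fm if target == "front" else bm)[mid]
    cap = max(1, int(round(0.5 * stim.px_per_deg)))
    left_run = _run_length(trow, center_left, -1, cap)
    right_run = _run_length(trow, center_left + 1, +1, cap)
    if left_run == 0 and right_run == 0:
        raise ConstructionError("centre contour lost after translation")
    dof = "left" if left_run > right_run else "right"

    meta = replace(stim.meta) if stim.meta is not None else StimulusMeta()
    meta.condition = "consistent" if target == "front" else "contradictory"
    meta.dof_truth = dof
    out.meta = meta
    return out


def make_variant_set(base: Sequence[ShapePatch],
                     params: Optional[BlendParams] = None) -> list:
    """The 8 factorial variants of one base pair:
    2 mirror x 2 depth order (color swap) x 2 translation targets."""
    front_p, back_p = base
    params = params if params is not None else BlendParams()
    out = []
    for mirror, depth, target in product((False, True), DEPTH_ORDERS,
                                         ("front", "back")):
        fp = front_p.mirrored() if mirror else front_p
        bp = back_p.mirrored() if mirror else back_p
        cf, cb = (RED, GREEN) if depth == "red-front" else (GREEN, RED)
        blend = replace(params, color_front=cf, color_back=cb)
        stim = alpha_blend(fp, bp, blend)
        stim.meta = StimulusMeta(base_id=front_p.base_id, mirror=mirror,
                                 depth_order=depth)
        stim = center_contour_translate(stim, target)
        m = stim.meta
        target_color = ("red" if (target == "front") == (depth == "red-front")
                        else "green")
        m.translation_variant = f"center-on-{target_color}"
        m.figure_color_truth = "red" if depth == "red-front" else "green"
        m.stimulus_id = (f"b{front_p.base_id:03d}_m{int(mirror)}"
                         f"_{'rf' if depth == 'red-front' else 'gf'}"
                         f"_{'cr' if target_color == 'red' else 'cg'}")
        out.append(stim)
    return out


def stimulus_manifest(stimuli: Sequence[TranslucentStimulus]) -> pd.DataFrame:
    """Tabulate condition and ground-truth metadata for a stimulus list."""
    rows = []
    for s in stimuli:
        m = s.meta
        rows.append({
            "stimulus_id": m.stimulus_id,
            "base_id": m.base_id,
            "mirror": int(m.mirror),
            "depth_order": m.depth_order,
            "translation_variant": m.translation_variant,
            "condition": m.condition,
            "dof_truth": m.dof_truth,
            "figure_color_truth": m.figure_color_truth,
            "alpha_front": s.blend.alpha_front,
            "alpha_back": s.blend.alpha_back,
        })
    return pd.DataFrame(rows)


def build_stimulus_set(n_bases: int = 38, extent_deg: float = 9.0,
                       px_per_deg: float = 50.0,
                       alphas: Sequence[float] = (0.5, 0.5),
                       seed: int = 0) -> tuple:
    """Generate the full factorial stimulus set (``8 * n_bases`` stimuli).

    Returns ``(stimuli, manifest)``; deterministic for a fixed seed.
    """
    root = np.random.SeedSequence(int(seed))
    base_seeds = root.generate_state(n_bases)
    params = BlendParams(alpha_front=float(alphas[0]),
                         alpha_back=float(alphas[1]))
    stimuli = []
    for i, s in enumerate(base_seeds):
        pair = generate_shape_pair(int(s), extent_deg, px_per_deg, base_id=i)
        stimuli.extend(make_variant_set(pair, params))
    return stimuli, stimulus_manifest(stimuli)


def save_stimulus_set(stimuli: Sequence[TranslucentStimulus], out_dir,
                      write_images: bool = True) -> pd.DataFrame:
    """Write stimulus PNGs, indexed label PNGs and the manifest CSV.

    Returns the manifest (with file-path columns) as written.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "labels").mkdir(parents=True, exist_ok=True)
    manifest = stimulus_manifest(stimuli)
    img_paths, lab_paths = [], []
    for s in stimuli:
        sid = s.meta.stimulus_id
        img_rel = f"images/{sid}.png"
        lab_rel = f"labels/{sid}.png"
        if write_images:
            Image.fromarray(s.quantized_image()).save(out_dir / img_rel)
        Image.fromarray(s.region_map, mode="L").save(out_dir / lab_rel)
        img_paths.append(img_rel if write_images else "")
        lab_paths.append(lab_rel)
    manifest["image_path"] = img_paths
    manifest["label_path"] = lab_paths
    manifest["extent_deg"] = stimuli[0].extent_deg if stimuli else np.nan
    manifest["px_per_deg"] = stimuli[0].px_per_deg if stimuli else np.nan
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def load_stimulus_set(manifest_path) -> tuple:
    """Reload stimuli from a manifest CSV and its label rasters.

    The float image raster is recomputed exactly from the masks and blend
    parameters, so reloaded stimuli are equivalent to freshly built ones.
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path)
    base = manifest_path.parent
    stimuli = []
    for _, r in manifest.iterrows():
        region_map = np.asarray(Image.open(base / r["label_path"]),
                                dtype=np.uint8)
        fm = (region_map == FRONT_ONLY) | (region_map == OVERLAP)
        bm = (region_map == BACK_ONLY) | (region_map == OVERLAP)
        cf, cb = ((RED, GREEN) if r["depth_order"] == "red-front"
                  else (GREEN, RED))
        blend = BlendParams(alpha_front=float(r["alpha_front"]),
                            alpha_back=float(r["alpha_back"]),
                            color_front=cf, color_back=cb)
        extent = float(r["extent_deg"])
        ppd = float(r["px_per_deg"])
        stim = alpha_blend(ShapePatch(fm, int(r["base_id"]), extent, ppd),
                           ShapePatch(bm, int(r["base_id"]), extent, ppd),
                           blend)
        stim.meta = StimulusMeta(
            stimulus_id=r["stimulus_id"], base_id=int(r["base_id"]),
            mirror=bool(r["mirror"]), depth_order=r["depth_order"],
            translation_variant=r["translation_variant"],
            condition=r["condition"], dof_truth=r["dof_truth"],
            figure_color_truth=r["figure_color_truth"])
        stimuli.append(stim)
    return stimuli, manifest
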