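"""End-to-end per-slice segmentation: preprocessing, contour initialization,
wall-finding evolution, FCM clustering of each side, stripping, labelling.

The flow per slice is: normalize → background removal → anisotropic
diffusion → edge enhancement → adaptive threshold (body mask) → boundary
chain → shrink-and-place initial contour → hybrid evolution to the muscle
wall. The converged contour splits the body into a subcutaneous side
(outside the curve) and a visceral side (inside); each side is clustered —
by default pooled across slices — and fat-like clusters merged; skin and
wall voxels are stripped from the subcutaneous mask. The edge-enhanced
image drives the contour; the diffused (intensity-faithful) image feeds the
clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import contour as ct
from .fcm import fcm as _fcm, harden as _harden, merge_regions as _merge, strip_skin_wall as _strip
from . import preprocess as pp
from . import snake as sn
from .config import PipelineConfig
from .errors import AdipoQuantError, ValidationError
from .io import DepotLabelVolume, ImageVolume, LABEL_CODES


@dataclass
class SliceResult:
    """Per-slice intermediate products kept for labelling and diagnostics."""

    index: int
    body_mask: np.ndarray | None = None
    phi: ct.LevelSetField | None = None
    trace: sn.EvolutionTrace | None = None
    diffused: np.ndarray | None = None
    error: str | None = None


@dataclass
class SegmentationResult:
    labels: DepotLabelVolume
    slices: list[SliceResult] = field(default_factory=list)

    @property
    def failed_slices(self) -> list[int]:
        return [s.index for s in self.slices if s.error is not None]


def preprocess_slice(pixels: np.ndarray, config: PipelineConfig) -> dict:
    """Run the preprocessing chain on one slice; returns every stage output."""
    c = config.preprocess
    norm = pp.normalize_intensity(pixels, c.low_percentile, c.high_percentile)
    nobg = pp.remove_background(norm, c.bg_threshold)
    diffused = pp.anisotropic_diffuse(
        nobg,
        pp.DiffusionParams(
            n_iterations=c.diffusion_iterations,
            kappa=c.diffusion_kappa,
            step_size=c.diffusion_step,
            conductance_form=c.conductance_form,
        ),
    )
    enhanced = pp.enhance_edges(diffused, c.edge_gain, c.edge_gain_sigma)
    return {"normalized": norm, "diffused": diffused, "enhanced": enhanced}


def find_wall_contour(
    enhanced: np.ndarray,
    body_mask: np.ndarray,
    config: PipelineConfig,
    bright_mask: np.ndarray | None = None,
) -> tuple[ct.LevelSetField, sn.EvolutionTrace]:
    """Initial contour from the body mask, evolved to the muscle wall.

    With ``init.adaptive_scale`` the shrink factor is derived per slice
    from the size of the binary mask (thicker subcutaneous shells shrink
    harder); otherwise the configured ``shrink_scale`` is used.
    """
    chain = ct.edge_map(body_mask)
    scale = config.init.shrink_scale
    if config.init.adaptive_scale and bright_mask is not None:
        scale = ct.auto_shrink_scale(
            body_mask, bright_mask, wall_clearance=config.init.wall_clearance
        )
    phi0 = ct.shrink_and_place(
        chain,
        ct.InitParams(shrink_scale=scale, center_mode=config.init.center_mode),
        body_mask.shape,
        band_width=config.init.band_width,
    )
    params = sn.SnakeParams(**config.snake.model_dump())
    return sn.evolve(enhanced, phi0, params)


def _cluster_side(
    intensities_volume: np.ndarray,
    side_mask: np.ndarray,
    n_classes: int,
    config: PipelineConfig,
) -> np.ndarray:
    """FCM + harden + merge on one side; returns the binary fat mask."""
    vals = intensities_volume[side_mask]
    seed = None
    if config.fcm.perturb_init:
        seed = int(
            np.random.SeedSequence([config.seed, 7]).generate_state(1)[0] % (2**31)
        )
    mm = _fcm(
        vals,
        n_classes=n_classes,
        fuzzifier_m=config.fcm.fuzzifier_m,
        tol=config.fcm.tol,
        max_iter=config.fcm.max_iter,
        seed=seed,
    )
    part = _harden(mm, side_mask, intensities_volume)
    return _merge(part, config.fcm.intensity_gap)


def segment_volume(
    volume: ImageVolume,
    config: PipelineConfig | None = None,
    on_error: str = "raise",
) -> SegmentationResult:
    """Segment a full volume into SAT/VAT/skin-wall/organ labels.

    ``on_error='collect'`` records per-slice failures (e.g. a collapsed
    contour) in the result instead of raising, leaving failed slices as
    background.
    """
    if config is None:
        config = PipelineConfig()
    if on_error not in ("raise", "collect"):
        raise ValidationError("on_error must be 'raise' or 'collect'")

    lo = config.slice_start or 0
    hi = config.slice_stop if config.slice_stop is not None else volume.n_slices
    indices = range(lo, min(hi, volume.n_slices))
    if len(indices) == 0:
        raise ValidationError("empty slice selection")

    shape = volume.slice_shape
    n_sel = len(indices)
    diffused = np.zeros(shape + (n_sel,))
    body = np.zeros(shape + (n_sel,), dtype=bool)
    sat_side = np.zeros_like(body)
    vat_side = np.zeros_like(body)
    slices: list[SliceResult] = []

    for k, idx in enumerate(indices):
        res = SliceResult(index=idx)
        slices.append(res)
        try:
            stages = preprocess_slice(volume.get_slice(idx), config)
            res.diffused = stages["diffused"]
            bright = pp.bright_foreground(stages["enhanced"])
            res.body_mask = ndimage.binary_fill_holes(bright)
            res.phi, res.trace = find_wall_contour(
                stages["enhanced"], res.body_mask, config, bright_mask=bright
            )
        except AdipoQuantError as exc:
            res.error = f"slice {idx}: {exc}"
            if on_error == "raise":
                raise type(exc)(res.error) from exc
            continue
        diffused[:, :, k] = res.diffused
        body[:, :, k] = res.body_mask
        inside = res.phi.phi < 0
        sat_side[:, :, k] = res.body_mask & ~inside
        vat_side[:, :, k] = res.body_mask & inside

    labels = np.zeros(shape + (n_sel,), dtype=np.uint8)
    ok = [s for s in slices if s.error is None]
    if ok:
        sat_fat = _segment_fat(diffused, sat_side, config.fcm.sat_classes, config)
        vat_fat = _segment_fat(diffused, vat_side, config.fcm.vat_classes, config)

        for k, res in enumerate(slices):
            if res.error is not None:
                continue
            bm = res.body_mask
            sl_sat = _strip(
                sat_fat[:, :, k],
                bm,
                res.phi,
                skin_depth=config.strip.skin_depth,
                wall_depth=config.strip.wall_depth,
            )
            sl_vat = vat_fat[:, :, k]
            lab = np.zeros(shape, dtype=np.uint8)
            lab[bm] = LABEL_CODES["organ"]
            skin_band = bm & (
                ndimage.distance_transform_edt(bm) - 0.5 <= config.strip.skin_depth
            )
            wall_band = bm & (np.abs(res.phi.phi) < config.strip.wall_depth)
            lab[skin_band | wall_band] = LABEL_CODES["skin_wall"]
            lab[sl_vat] = LABEL_CODES["vat"]
            lab[sl_sat] = LABEL_CODES["sat"]
            labels[:, :, k] = lab

    sel_labels = [
        volume.slice_labels[i] for i in indices
    ] if volume.slice_labels is not None else None
    return SegmentationResult(
        labels=DepotLabelVolume(
            labels=labels,
            in_plane_spacing=volume.in_plane_spacing,
            slice_thickness=volume.slice_thickness,
            slice_labels=sel_labels,
        ),
        slices=slices,
    )


def _segment_fat(
    diffused: np.ndarray,
    side_mask: np.ndarray,
    n_classes: int,
    config: PipelineConfig,
) -> np.ndarray:
    """Cluster one side of the wall into a fat mask, pooled or per-slice."""
    fat = np.zeros_like(side_mask)
    if not side_mask.any():
        return fat
    if config.fcm.pooled:
        try:
            fat = _cluster_side(diffused, side_mask, n_classes, config)
        except ValidationError:
            # fewer distinct values than classes: degenerate side, keep empty
            pass
        return fat
    for k in range(side_mask.shape[2]):
        sm = side_mask[:, :, k]
        if not sm.any():
            continue
        try:
            fat[:, :, k] = _cluster_side(diffused[:, :, k], sm, n_classes, config)
        except ValidationError:
            continue
    return fat
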