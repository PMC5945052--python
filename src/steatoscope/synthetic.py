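"""Synthetic H&E-like murine liver slides with ground truth.

Renders the visual vocabulary the detection and classification stages rely
on: eosin-pink cytoplasm with multiplicative texture and dark nuclei on a
white slide background; large circular white macrosteatosis droplets with a
faint compressed-cytoplasm rim and an optional displaced crescent nucleus;
foamy microsteatosis foci made of 1-3 px white vesicles; and white-lumen
confusers that are *not* fat — central veins (irregular lumen, dark
endothelial rim), and portal triads (portal vein + thick-walled artery +
bile-duct ring, co-located) — so the classifier faces genuine look-alikes.

Droplets are placed with a 3 px separation gap while feasible; for high
target fractions the placer relaxes to clustered/tangent placement (centers
never inside existing fat), mirroring how vacuoles abut in severe steatosis.
Placement stops once the rendered fat fraction is within +/-1 percentage
point of the target.

Every slide regenerates bit-identically from (params, seed).
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage

from .annotations import Annotation, write_annotations
from .image_io import SlideImage, save_image
from .quantify import grade_from_percent

# Palette (float RGB in [0,1]); the green channel is the working contrast:
# background ~0.97, cytoplasm ~0.63, lumina ~0.98, droplet rim ~0.84 (faint),
# vessel rims/walls ~0.3-0.4 (dark) — the cue separating fat from vessels.
BACKGROUND = (0.972, 0.968, 0.972)
CYTOPLASM = (0.902, 0.627, 0.667)
NUCLEUS = (0.353, 0.235, 0.510)
LUMEN = (0.980, 0.980, 0.980)
DROPLET_RIM = (0.859, 0.780, 0.812)
VEIN_RIM = (0.549, 0.329, 0.502)
ARTERY_WALL = (0.620, 0.310, 0.478)
DUCT_WALL = (0.639, 0.400, 0.620)


class PlacementError(RuntimeError):
    """Target fat fraction unreachable for the given dimensions."""


@dataclass
class GeneratorParams:
    dims: tuple[int, int] = (512, 512)
    target_percent: float = 20.0
    n_macro_droplets: int | None = None   # optional cap on droplet count
    micro_focus_count: int = 3
    n_portal_triads: int = 2
    n_central_veins: int = 2
    noise_sd: float = 0.02                # additive pixel noise, [0,1] scale
    droplet_radius_range: tuple[float, float] = (8.0, 30.0)
    n_sinusoid_patches: int = 5
    texture_amp: float = 0.03             # multiplicative cytoplasm texture

    def __post_init__(self) -> None:
        h, w = self.dims
        if h < 256 or w < 256:
            raise ValueError("dims must be at least 256 x 256")
        if not (0.0 <= self.target_percent <= 70.0):
            raise ValueError("target_percent must lie in [0, 70]")


@dataclass
class SyntheticSlide:
    image: SlideImage
    truth_annotations: list[Annotation]
    truth_fat_mask: np.ndarray
    truth_tissue_mask: np.ndarray
    true_percent_steatosis: float
    seed: int
    params: GeneratorParams
    droplet_radii: list[float] = field(default_factory=list)
    grade: int = 0
    slide_id: str = ""


def _disk(shape, center, radius):
    """(slices, local bool mask) of a rasterized disk clipped to the image."""
    h, w = shape
    r0 = max(0, int(np.floor(center[0] - radius)))
    r1 = min(h, int(np.ceil(center[0] + radius)) + 1)
    c0 = max(0, int(np.floor(center[1] - radius)))
    c1 = min(w, int(np.ceil(center[1] + radius)) + 1)
    yy, xx = np.mgrid[r0:r1, c0:c1]
    mask = (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius ** 2
    return (slice(r0, r1), slice(c0, c1)), mask


def _irregular_blob(shape, center, radius, rng, amp=0.16):
    """Rasterized star-convex blob: radius modulated by random harmonics."""
    coeffs = rng.uniform(-1.0, 1.0, size=4)
    phases = rng.uniform(0.0, 2 * np.pi, size=4)
    pad = radius * (1 + amp * 4) + 2
    sl, _ = _disk(shape, center, pad)
    yy, xx = np.mgrid[sl[0], sl[1]]
    dy, dx = yy - center[0], xx - center[1]
    phi = np.arctan2(dy, dx)
    rho = np.hypot(dy, dx)
    mod = np.ones_like(phi)
    for k, (a, p) in enumerate(zip(coeffs, phases), start=2):
        mod += amp * a * np.cos(k * phi + p) / 2.0
    return sl, rho <= radius * mod


def _ring(mask: np.ndarray, width: float) -> np.ndarray:
    """Pixels within ``width`` (Euclidean) outside the mask."""
    dist = ndimage.distance_transform_edt(~mask)
    return (dist > 0) & (dist <= width)


def _paint(img, sl, mask, color):
    for ch in range(3):
        img[sl[0], sl[1], ch][mask] = color[ch]


def _tissue_blob(params: GeneratorParams, rng) -> np.ndarray:
    """A wavy-edged elliptical tissue section with a clear background margin."""
    h, w = params.dims
    coeffs = rng.uniform(-1.0, 1.0, size=3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - h / 2.0, xx - w / 2.0
    phi = np.arctan2(dy, dx)
    rho = np.hypot(dy / (0.42 * h), dx / (0.44 * w))
    mod = np.ones_like(phi)
    for k, (a, p) in enumerate(zip(coeffs, phases), start=2):
        mod += 0.05 * a * np.cos(k * phi + p)
    return rho <= mod


def _sample_center(rng, dist_in, need, occupied, radius, tries=200):
    """Random tissue point with clearance ``need`` from the boundary and no
    overlap of disk(radius) with ``occupied``; None if none found."""
    h, w = dist_in.shape
    for _ in range(tries):
        r = rng.uniform(0, h)
        c = rng.uniform(0, w)
        ri, ci = int(r), int(c)
        if dist_in[ri, ci] <= need:
            continue
        sl, m = _disk(dist_in.shape, (r, c), radius)
        if not (occupied[sl] & m).any():
            return (r, c)
    return None


def _circle_polygon(center, radius, n=24):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return [(center[0] + radius * np.sin(a), center[1] + radius * np.cos(a))
            for a in ang]


def generate_slide(params: GeneratorParams | dict | None = None,
                   seed: int = 0, slide_id: str = "",
                   **overrides) -> SyntheticSlide:
    """Render one slide with ground-truth masks and annotations."""
    if params is None:
        params = GeneratorParams(**overrides)
    elif isinstance(params, dict):
        params = GeneratorParams(**{**params, **overrides})
    rng = np.random.default_rng(seed)
    h, w = params.dims
    shape = (h, w)

    tissue = _tissue_blob(params, rng)
    dist_in = ndimage.distance_transform_edt(tissue)
    tissue_area = int(tissue.sum())
    occupied = np.zeros(shape, dtype=bool)
    anns: list[Annotation] = []
    structures = []  # deferred paint ops: (slices, mask, color)

    # --- central veins: irregular lumen, dark endothelial rim, isolated ---
    for _ in range(params.n_central_veins):
        radius = rng.uniform(16, 26)
        ctr = _sample_center(rng, dist_in, radius * 1.3 + 8, occupied,
                             radius * 1.3 + 6)
        if ctr is None:
            continue
        sl, lumen = _irregular_blob(shape, ctr, radius, rng)
        rim = _ring(lumen, 2.5)
        structures.append((sl, rim, VEIN_RIM))
        structures.append((sl, lumen, LUMEN))
        occupied[sl] |= ndimage.binary_dilation(lumen, iterations=4)
        anns.append(Annotation("central_vein", (ctr[0], ctr[1]),
                               slide_id=slide_id))

    # --- portal triads: portal vein + thick-walled artery + bile duct ---
    for _ in range(params.n_portal_triads):
        rv = rng.uniform(10, 16)
        ctr = _sample_center(rng, dist_in, rv + 34, occupied, rv + 30)
        if ctr is None:
            continue
        sl, lumen = _irregular_blob(shape, ctr, rv, rng)
        rim = _ring(lumen, 2.0)
        structures.append((sl, rim, VEIN_RIM))
        structures.append((sl, lumen, LUMEN))
        anns.append(Annotation("portal_vein", (ctr[0], ctr[1]),
                               slide_id=slide_id))
        occupied[sl] |= ndimage.binary_dilation(lumen, iterations=4)
        ang_a = rng.uniform(0, 2 * np.pi)
        for which, ang in (("portal_artery", ang_a),
                           ("bile_duct", ang_a + rng.uniform(1.6, 2.8))):
            off = rv + rng.uniform(14, 20)
            cc = (ctr[0] + off * np.sin(ang), ctr[1] + off * np.cos(ang))
            r_lum = rng.uniform(6.0, 7.5)
            wall = 3.0 if which == "portal_artery" else 2.5
            ssl, lum = _disk(shape, cc, r_lum)
            wall_mask = _ring(lum, wall)
            color = ARTERY_WALL if which == "portal_artery" else DUCT_WALL
            structures.append((ssl, wall_mask, color))
            structures.append((ssl, lum, LUMEN))
            anns.append(Annotation(which, (cc[0], cc[1]), slide_id=slide_id))
            gsl, gm = _disk(shape, cc, r_lum + wall + 4)
            occupied[gsl] |= gm

    # --- microsteatosis foci (foamy vesicle clusters) ---
    vesicles = np.zeros(shape, dtype=bool)
    foci_guard = np.zeros(shape, dtype=bool)
    for _ in range(params.micro_focus_count):
        radius = rng.uniform(14, 22)
        ctr = _sample_center(rng, dist_in, radius + 6, occupied, radius + 4)
        if ctr is None:
            continue
        n_ves = int(0.09 * np.pi * radius ** 2)
        for _ in range(n_ves):
            rho = radius * np.sqrt(rng.uniform())
            ang = rng.uniform(0, 2 * np.pi)
            vc = (ctr[0] + rho * np.sin(ang), ctr[1] + rho * np.cos(ang))
            vsl, vm = _disk(shape, vc, rng.uniform(0.5, 1.5))
            vesicles[vsl] |= vm
        anns.append(Annotation("micro_fat", _circle_polygon(ctr, radius),
                               slide_id=slide_id))
        gsl, gm = _disk(shape, ctr, radius + 4)
        occupied[gsl] |= gm
        foci_guard[gsl] |= gm

    # --- non-foamy parenchyma survey polygons (the "others" pixel pool for
    # micro training).  Deliberately large and allowed to contain droplets,
    # nuclei, vessels and plain cytoplasm — every feature except foamy foci —
    # so the negative pool dwarfs the micro pool as it does on annotated
    # biopsies, where "other" spans the whole histological vocabulary and
    # its pixel pool is on par with the annotated foamy area times the
    # subsampling-rate ratio.
    for _ in range(params.n_sinusoid_patches):
        radius = rng.uniform(0.12, 0.17) * min(h, w)
        ctr = _sample_center(rng, dist_in, radius + 4, foci_guard, radius)
        if ctr is None:
            continue
        anns.append(Annotation("sinusoid", _circle_polygon(ctr, radius),
                               slide_id=slide_id))

    # --- macrosteatosis droplets ---
    fat = np.zeros(shape, dtype=bool)
    radii: list[float] = []
    droplet_centers: list[tuple[float, float]] = []
    target_px = params.target_percent / 100.0 * tissue_area
    lo_stop = target_px - 0.005 * tissue_area
    hi_cap = target_px + 0.009 * tissue_area
    placed = 0
    attempts = 0
    consec_fail = 0
    clustered = False
    max_attempts = 20000
    # droplet disks must clear structure guard zones entirely, else a merged
    # fat+vessel component would inherit the vessel's label
    dist_occ = ndimage.distance_transform_edt(~occupied)
    while placed < lo_stop:
        if (params.n_macro_droplets is not None
                and len(radii) >= params.n_macro_droplets):
            break
        attempts += 1
        if attempts > max_attempts:
            if placed >= target_px - 0.01 * tissue_area:
                break
            raise PlacementError(
                f"could not reach {params.target_percent}% fat in "
                f"{params.dims} after {max_attempts} attempts "
                f"(reached {100.0 * placed / tissue_area:.2f}%)")
        # fall back to clustered placement once disjoint placement jams;
        # when even clustered placement crawls, in-fill with small vacuoles
        # (the interstitial pattern of severe steatosis)
        if not clustered and consec_fail > 100:
            clustered = True
            consec_fail = 0
        infill = clustered and consec_fail > 200
        r_lo, r_hi = params.droplet_radius_range
        r = rng.uniform(r_lo, min(r_lo + 4.0, r_hi) if infill else r_hi)
        # valid centers: inside tissue with boundary clearance, outside
        # structure guards; outside fat once clustered, else with a 3 px gap
        free = tissue & (dist_in > r + 3) & (dist_occ > r + 2)
        if infill:
            # centers may sit on existing fat, but must reach uncovered
            # tissue so each in-fill vacuole contributes area
            gap = ndimage.distance_transform_edt(fat | ~tissue)
            free &= gap <= r - 2
        elif clustered:
            free &= ~fat
        else:
            gap = ndimage.distance_transform_edt(~fat) if fat.any() else None
            if gap is not None:
                free &= gap > r + 3
        candidates = np.flatnonzero(free)
        if candidates.size == 0:
            consec_fail += 1
            continue
        pick = int(candidates[rng.integers(candidates.size)])
        ctr = (float(pick // w), float(pick % w))
        sl, m = _disk(shape, ctr, r)
        new_px = int((m & tissue[sl] & ~fat[sl]).sum())
        if placed + new_px > hi_cap or (infill and new_px < 0.1 * m.sum()):
            consec_fail += 1
            continue
        consec_fail = 0
        fat[sl] |= m
        placed += new_px
        radii.append(float(r))
        droplet_centers.append(ctr)
        anns.append(Annotation("macro_fat", (ctr[0], ctr[1]),
                               slide_id=slide_id))

    # --- render -----------------------------------------------------------
    img = np.empty((h, w, 3), dtype=np.float64)
    for ch in range(3):
        img[:, :, ch] = BACKGROUND[ch]
    texture = 1.0 + params.texture_amp * ndimage.gaussian_filter(
        rng.standard_normal(shape), sigma=1.5) * 3.0
    for ch in range(3):
        img[:, :, ch][tissue] = CYTOPLASM[ch] * texture[tissue]

    # nuclei: dark ellipses scattered through the parenchyma
    n_nuclei = tissue_area // 450
    for _ in range(n_nuclei):
        rr = rng.uniform(0, h)
        cc = rng.uniform(0, w)
        if not tissue[int(rr), int(cc)]:
            continue
        a, b = rng.uniform(2.0, 3.6), rng.uniform(1.4, 2.4)
        ang = rng.uniform(0, np.pi)
        sl, m = _disk(shape, (rr, cc), a + 1)
        yy, xx = np.mgrid[sl[0], sl[1]]
        dy, dx = yy - rr, xx - cc
        u = dy * np.cos(ang) + dx * np.sin(ang)
        v = -dy * np.sin(ang) + dx * np.cos(ang)
        em = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        _paint(img, sl, em & tissue[sl], NUCLEUS)

    _paint(img, (slice(None), slice(None)), vesicles & tissue, LUMEN)

    for sl, m, color in structures:
        _paint(img, sl, m, color)

    # droplet rims then lumina; displaced crescent nuclei on ~half of them
    rim_all = _ring(fat, 2.0) & tissue
    _paint(img, (slice(None), slice(None)), rim_all, DROPLET_RIM)
    _paint(img, (slice(None), slice(None)), fat, LUMEN)
    for (cr, cc), r in zip(droplet_centers, radii):
        if rng.uniform() < 0.5:
            ang = rng.uniform(0, 2 * np.pi)
            nc = (cr + (r + 3.5) * np.sin(ang), cc + (r + 3.5) * np.cos(ang))
            nsl, nm = _disk(shape, nc, 2.2)
            _paint(img, nsl, nm & tissue[nsl] & ~fat[nsl] & ~rim_all[nsl],
                   NUCLEUS)

    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    np.clip(img, 0.0, 1.0, out=img)
    pixels = np.floor(img * 255.0 + 0.5).astype(np.uint8)

    fat &= tissue
    true_pct = 100.0 * fat.sum() / tissue_area
    return SyntheticSlide(
        image=SlideImage(pixels=pixels, scale_factor=1.0,
                         source_path=f"synthetic:{slide_id or seed}"),
        truth_annotations=anns, truth_fat_mask=fat,
        truth_tissue_mask=tissue,
        true_percent_steatosis=float(true_pct), seed=seed, params=params,
        droplet_radii=radii, grade=grade_from_percent(true_pct),
        slide_id=slide_id or f"slide-{seed}")


#: NASH-CRN grade bins as (low, high) percent, capped at the generator limit.
GRADE_BINS = {0: (0.0, 5.0), 1: (5.0, 33.0), 2: (33.0, 66.0), 3: (66.0, 70.0)}


def generate_dataset(n_slides: int | None = None,
                     grade_mix: tuple[int, int, int, int] = (9, 10, 4, 4),
                     seed: int = 0, bin_margin: float = 1.5,
                     **param_overrides) -> list[SyntheticSlide]:
    """A cohort of slides with per-grade target fractions.

    Targets are sampled uniformly inside each grade bin shrunk by
    ``bin_margin`` percentage points at interior edges, so the +/-1 pp
    placement tolerance cannot push a slide's truth across a bin boundary.
    Per-slide seeds derive from the master seed.
    """
    if n_slides is not None and n_slides != sum(grade_mix):
        raise ValueError("n_slides must equal sum(grade_mix)")
    rng = np.random.default_rng(seed)
    slides = []
    idx = 0
    for grade, count in enumerate(grade_mix):
        lo, hi = GRADE_BINS[grade]
        lo_m = lo + bin_margin if grade > 0 else lo
        hi_m = hi - bin_margin if grade < 3 else hi
        for _ in range(count):
            target = float(rng.uniform(lo_m, hi_m))
            sub_seed = int(rng.integers(0, 2 ** 31 - 1))
            slide = generate_slide(
                params=GeneratorParams(target_percent=target,
                                       **param_overrides),
                seed=sub_seed, slide_id=f"slide-{idx:03d}-g{grade}")
            slides.append(slide)
            idx += 1
    return slides


def write_slide(slide: SyntheticSlide, outdir: str | os.PathLike) -> None:
    """PNG image + GeoJSON truth + truth-mask PNG + metadata JSON."""
    from PIL import Image

    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    stem = os.path.join(outdir, slide.slide_id)
    save_image(slide.image, stem + ".png")
    write_annotations(slide.truth_annotations, stem + ".geojson")
    Image.fromarray(slide.truth_fat_mask.astype(np.uint8) * 255).save(
        stem + "_fatmask.png")
    meta = {"slide_id": slide.slide_id, "seed": slide.seed,
            "true_percent_steatosis": slide.true_percent_steatosis,
            "grade": slide.grade, "n_droplets": len(slide.droplet_radii),
            "params": asdict(slide.params)}
    with open(stem + ".json", "w") as fh:
        json.dump(meta, fh, indent=1)
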