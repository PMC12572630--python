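"""Procedural generation of standardized butterfly-specimen images.

The generator emulates spread, dorsal-side specimen photographs on a white
background, with the morphological axes that matter for the *Papilio
bootes* / *Byasa* mimicry system: the number (0-4) and size of hindwing
white discal spots, red submarginal marks, tails with an optional red tail
spot, and overall ground colour.  Specimens are bilaterally symmetric; the
``hindwing_mask`` annotates the right hindwing, and the white-spot counter
operates on that single wing, mirroring how the trait is scored per wing
on real specimens.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from PIL import Image
from skimage import measure

__all__ = [
    "TaxonTemplate",
    "SpecimenImage",
    "generate_specimen",
    "generate_dataset",
    "count_hindwing_white_spots",
    "spot_count_distribution",
    "load_templates",
    "save_templates",
]

#: white-background tolerance (per channel) used when rendering and counting
WHITE_LO = 245
#: threshold above which a pixel inside the wing counts as "white spot"
SPOT_THRESHOLD = 200
#: minimum component area, as a fraction of the hindwing area
MIN_SPOT_AREA_FRAC = 0.001

DEFAULT_SHAPE = {
    "fore_rx": 0.20,
    "fore_ry": 0.13,
    "fore_angle_deg": 25.0,
    "hind_rx": 0.13,
    "hind_ry": 0.16,
}


@dataclass
class TaxonTemplate:
    """Generative parameters for one taxon.

    ``spot_size`` is the spot diameter as a fraction of the hindwing width;
    ``variability`` maps parameter names (``n_white_spots``, ``spot_size``,
    ``red_intensity``, ``ground_color``, ``shape``) to jitter standard
    deviations applied per specimen.
    """

    taxon_id: str
    group: str  # "mimic" | "model"
    regions: frozenset[str]
    n_white_spots: int
    spot_size: float = 0.15
    spot_size_sd: float = 0.0
    red_submarginal_count: int = 4
    red_intensity: float = 0.8
    has_tail: bool = True
    tail_red_spot: bool = False
    ground_color: tuple[int, int, int] = (25, 22, 28)
    shape_params: dict = field(default_factory=lambda: dict(DEFAULT_SHAPE))
    variability: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.regions = frozenset(self.regions)
        if self.group not in ("mimic", "model"):
            raise ValueError(f"group must be 'mimic' or 'model', got {self.group!r}")
        if not (0 <= int(self.n_white_spots) <= 4):
            raise ValueError(f"n_white_spots must be in 0..4, got {self.n_white_spots}")
        if self.spot_size <= 0:
            raise ValueError("spot_size mean must be > 0")
        if not (0 <= self.red_submarginal_count <= 7):
            raise ValueError("red_submarginal_count must be in 0..7")
        if not self.regions:
            raise ValueError(f"taxon {self.taxon_id}: regions must be nonempty")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["regions"] = sorted(self.regions)
        d["ground_color"] = list(self.ground_color)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaxonTemplate":
        d = dict(d)
        d["regions"] = frozenset(d["regions"])
        d["ground_color"] = tuple(d["ground_color"])
        return cls(**d)


@dataclass
class SpecimenImage:
    """One rendered specimen: pixel grid plus taxon/side metadata."""

    pixels: np.ndarray  # H x W x 3 uint8
    specimen_id: str
    taxon_id: str
    side: str  # "dorsal" | "ventral"
    hindwing_mask: np.ndarray  # H x W bool, right hindwing
    realized_params: dict

    def to_png(self, path: str | Path) -> None:
        Image.fromarray(self.pixels).save(str(path), format="PNG")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def _ellipse_mask(h, w, cy, cx, ry, rx, angle_deg=0.0):
    """Boolean mask of a rotated, axis-centered ellipse (vectorized)."""
    yy, xx = np.ogrid[:h, :w]
    th = np.deg2rad(angle_deg)
    dy, dx = yy - cy, xx - cx
    u = dx * np.cos(th) + dy * np.sin(th)
    v = -dx * np.sin(th) + dy * np.cos(th)
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _jitter(rng: np.random.Generator, value: float, sd: float) -> float:
    return float(value + rng.normal(0.0, sd)) if sd > 0 else float(value)


def generate_specimen(
    template: TaxonTemplate,
    side: str = "dorsal",
    seed: int = 0,
    size: int = 256,
    specimen_id: str | None = None,
) -> SpecimenImage:
    """Render one specimen image deterministically from (template, side, seed).

    White spots are placed on a fixed arc in the hindwing discal region with
    rejection sampling to keep them pairwise non-overlapping; realized
    (jittered) parameter values are recorded in ``realized_params``.
    """
    if side not in ("dorsal", "ventral"):
        raise ValueError(f"side must be dorsal|ventral, got {side!r}")
    if seed < 0:
        raise ValueError("seed must be >= 0")
    rng = np.random.default_rng(seed)
    var = template.variability
    H = W = int(size)

    # --- realized parameters -------------------------------------------------
    n_spots = int(np.clip(round(_jitter(rng, template.n_white_spots,
                                        var.get("n_white_spots", 0.0))), 0, 4))
    spot_frac = max(0.02, _jitter(rng, template.spot_size,
                                  template.spot_size_sd + var.get("spot_size", 0.0)))
    red_int = float(np.clip(_jitter(rng, template.red_intensity,
                                    var.get("red_intensity", 0.0)), 0.0, 1.0))
    gc_sd = var.get("ground_color", 0.0)
    ground = np.clip(np.asarray(template.ground_color, float)
                     + rng.normal(0.0, gc_sd, 3), 0, 110).astype(np.uint8)
    sh_sd = var.get("shape", 0.0)
    sp = {k: (_jitter(rng, v, sh_sd * abs(v)) if isinstance(v, (int, float)) else v)
          for k, v in template.shape_params.items()}

    img = np.full((H, W, 3), 255, np.uint8)
    cx = W / 2.0

    # --- wings and body (mirrored about the vertical axis) -------------------
    fore_cy, hind_cy = 0.36 * H, 0.60 * H
    fore_off, hind_off = 0.215 * W, 0.145 * W
    wings = np.zeros((H, W), bool)
    for sgn in (-1, +1):
        wings |= _ellipse_mask(H, W, fore_cy, cx + sgn * fore_off,
                               sp["fore_ry"] * H, sp["fore_rx"] * W,
                               sgn * sp["fore_angle_deg"])
    hind_masks = {}
    for sgn, name in ((-1, "left"), (+1, "right")):
        m = _ellipse_mask(H, W, hind_cy, cx + sgn * hind_off,
                          sp["hind_ry"] * H, sp["hind_rx"] * W)
        hind_masks[name] = m
        wings |= m
    if template.has_tail:
        tail_cy = hind_cy + sp["hind_ry"] * H * 0.95
        for sgn in (-1, +1):
            tail_cx = cx + sgn * hind_off * 1.15
            wings |= _ellipse_mask(H, W, tail_cy + 0.04 * H, tail_cx,
                                   0.065 * H, 0.018 * W)
    body = _ellipse_mask(H, W, 0.48 * H, cx, 0.26 * H, 0.022 * W)
    img[wings | body] = ground

    # --- hindwing white discal spots (mirrored, non-overlapping) -------------
    hind_rx_px, hind_ry_px = sp["hind_rx"] * W, sp["hind_ry"] * H
    spot_r = 0.5 * spot_frac * (2.0 * hind_rx_px)
    centers: list[tuple[float, float]] = []  # right-wing centers (y, x)
    if n_spots > 0:
        # evenly spaced slots on an arc through the discal region
        arc_angles = np.linspace(-55.0, 55.0, n_spots) if n_spots > 1 else np.array([0.0])
        arc_rad = 0.52
        for a in arc_angles:
            placed = False
            for _attempt in range(200):
                aj = a + rng.normal(0.0, 4.0)
                rj = arc_rad * (1.0 + rng.normal(0.0, 0.05))
                th = np.deg2rad(aj)
                y = hind_cy + rj * hind_ry_px * np.sin(th) * 1.1
                x = cx + hind_off + rj * hind_rx_px * np.cos(th) * 0.9 - 0.25 * hind_rx_px
                # inside the (shrunk) hindwing ellipse and clear of other spots
                inside = (((x - (cx + hind_off)) / (hind_rx_px - spot_r - 1)) ** 2
                          + ((y - hind_cy) / (hind_ry_px - spot_r - 1)) ** 2) <= 1.0
                clear = all(np.hypot(y - y0, x - x0) >= 2 * spot_r + 2.0
                            for y0, x0 in centers)
                if inside and clear:
                    centers.append((y, x))
                    placed = True
                    break
            if not placed:  # fall back to the unjittered slot position
                th = np.deg2rad(a)
                centers.append((hind_cy + arc_rad * hind_ry_px * np.sin(th) * 1.1,
                                cx + hind_off + arc_rad * hind_rx_px * np.cos(th) * 0.9
                                - 0.25 * hind_rx_px))
        for y, x in centers:
            for mx in (x, 2 * cx - x):  # mirror onto the left wing
                # creamy white: above the spot threshold but below the
                # paper-white background tolerance, as on real specimens
                img[_ellipse_mask(H, W, y, mx, spot_r, spot_r)] = (235, 235, 230)

    # --- red submarginal marks ------------------------------------------------
    red = np.clip(np.array([200.0 * red_int + 40, 30, 45]), 0, 255).astype(np.uint8)
    if template.red_submarginal_count > 0 and red_int > 0:
        mark_angles = np.linspace(-60, 60, template.red_submarginal_count)
        mr = 0.045 * hind_rx_px * 2
        for a in mark_angles:
            th = np.deg2rad(a)
            y = hind_cy + 0.85 * hind_ry_px * np.sin(th)
            x0 = cx + hind_off + 0.85 * hind_rx_px * np.cos(th)
            for mx in (x0, 2 * cx - x0):
                img[_ellipse_mask(H, W, y, mx, mr * 1.3, mr)] = red
    if template.has_tail and template.tail_red_spot:
        tip_y = hind_cy + sp["hind_ry"] * H * 0.95 + 0.085 * H
        for sgn in (-1, +1):
            img[_ellipse_mask(H, W, tip_y, cx + sgn * hind_off * 1.15,
                              0.014 * H, 0.014 * W)] = red

    realized = {
        "n_white_spots": n_spots,
        "spot_size": spot_frac,
        "spot_radius_px": spot_r,
        "red_submarginal_count": template.red_submarginal_count,
        "red_intensity": red_int,
        "ground_color": [int(v) for v in ground],
        "has_tail": template.has_tail,
        "tail_red_spot": template.tail_red_spot,
        "spot_centers": [(float(y), float(x)) for y, x in centers],
        "seed": int(seed),
    }
    return SpecimenImage(
        pixels=img,
        specimen_id=specimen_id or f"{template.taxon_id}_s{seed}",
        taxon_id=template.taxon_id,
        side=side,
        hindwing_mask=hind_masks["right"],
        realized_params=realized,
    )


def count_hindwing_white_spots(
    image: SpecimenImage,
    threshold: int = SPOT_THRESHOLD,
    min_area_frac: float = MIN_SPOT_AREA_FRAC,
) -> int:
    """Count connected white components inside the hindwing mask.

    Uses 8-connectivity; components smaller than ``min_area_frac`` of the
    hindwing area are ignored.  Overlapping spots merged into one blob count
    as a single component.
    """
    if image.hindwing_mask is None:
        raise ValueError("hindwing_mask is required for spot counting")
    mask = image.hindwing_mask
    white = np.all(image.pixels >= threshold, axis=-1) & mask
    labels = measure.label(white, connectivity=2)
    min_area = max(1, int(min_area_frac * mask.sum()))
    counts = np.bincount(labels.ravel())
    return int(np.sum(counts[1:] >= min_area))


def _specimen_seeds(master_seed: int, n: int) -> np.ndarray:
    """Reproducible per-specimen seeds derived from one master seed."""
    ss = np.random.SeedSequence(master_seed)
    return np.array([int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)])


def generate_dataset(
    templates: Sequence[TaxonTemplate],
    n_per_taxon: int,
    seed: int = 0,
    sides: Iterable[str] = ("dorsal",),
    out_dir: str | Path | None = None,
    size: int = 256,
) -> tuple[list[SpecimenImage], pd.DataFrame]:
    """Generate ``n_per_taxon`` specimens per template and a manifest table.

    The manifest has one row per image with columns (specimen_id, taxon_id,
    group, side, path, n_white_spots, seed).  ``path`` is empty unless
    ``out_dir`` is given, in which case PNGs are written there.
    """
    if n_per_taxon < 1:
        raise ValueError("n_per_taxon must be >= 1")
    ids = [t.taxon_id for t in templates]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate taxon_ids in templates")
    sides = list(sides)
    seeds = _specimen_seeds(seed, len(templates) * n_per_taxon)
    images, rows = [], []
    si = 0
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    for t in templates:
        for j in range(n_per_taxon):
            sp_seed = int(seeds[si]); si += 1
            for side in sides:
                spec_id = f"{t.taxon_id}_{side[0]}{j:03d}"
                img = generate_specimen(t, side=side, seed=sp_seed,
                                        size=size, specimen_id=spec_id)
                path = ""
                if out_dir is not None:
                    path = str(out_dir / f"{spec_id}.png")
                    img.to_png(path)
                images.append(img)
                rows.append({
                    "specimen_id": spec_id, "taxon_id": t.taxon_id,
                    "group": t.group, "side": side, "path": path,
                    "n_white_spots": img.realized_params["n_white_spots"],
                    "seed": sp_seed,
                })
    manifest = pd.DataFrame(rows)
    if manifest["specimen_id"].duplicated().any():
        raise ValueError("specimen_ids not unique")
    return images, manifest


def spot_count_distribution(manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-taxon percentages of specimens in each spot-count class 0-4.

    Returns a DataFrame indexed by taxon_id with columns 0..4 summing to 100.
    """
    if manifest.empty:
        raise ValueError("manifest is empty")
    tab = (manifest.groupby("taxon_id")["n_white_spots"]
           .value_counts(normalize=True).unstack(fill_value=0.0) * 100.0)
    for c in range(5):
        if c not in tab.columns:
            tab[c] = 0.0
    return tab[[0, 1, 2, 3, 4]].sort_index()


def save_templates(templates: Sequence[TaxonTemplate], path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"taxa": [t.to_dict() for t in templates]}, fh,
                       sort_keys=False)


def load_templates(path: str | Path) -> list[TaxonTemplate]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return [TaxonTemplate.from_dict(d) for d in doc["taxa"]]
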