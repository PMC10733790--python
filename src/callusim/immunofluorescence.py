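"""In silico immunofluorescence: rendering, cell records, ROI quantification.

Simulation states are rendered with the experimental stain code — DAPI
nuclei in blue, the pan-macrophage marker CD68 in green, the M1 co-marker
CD80 in red (CD68+CD80 composites to yellow) and the M2 co-marker CD206
shown magenta in single-image composites.  The quantification side consumes
a segmented label mask plus marker-positivity channels (from any external
whole-cell segmentation, or from the synthetic fixture generator here),
applies the 80–200 µm² cell-size filter, classifies marker combinations and
reports per-phenotype concentrations inside a region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from skimage.draw import disk as draw_disk
from skimage.draw import ellipse as draw_ellipse
from skimage.measure import regionprops

MARKERS = ("DAPI", "CD68", "CD80", "CD206")

#: cell-size filter bounds, µm² (inclusive)
AREA_MIN, AREA_MAX = 80.0, 200.0

DEFAULT_PALETTE = {
    "nucleus": (0, 0, 255),        # DAPI
    "MPhi": (0, 255, 0),           # CD68
    "M1": (255, 255, 0),           # CD68 + CD80 -> green + red
    "M2": (255, 0, 255),           # CD68 + CD206, magenta in composites
}


@dataclass
class CellRecord:
    """One segmented cell: geometry plus marker positivity and the call."""

    id: int
    centroid: tuple[float, float]  # µm
    area: float                    # µm²
    markers: dict[str, bool] = field(default_factory=dict)
    phenotype_call: str = "other"


@dataclass
class ROIQuantification:
    """Counts and concentrations of each phenotype inside one ROI."""

    roi_area: float                # mm²
    counts: dict[str, int]
    concentrations: dict[str, float]  # mm^-2


def classify_markers(markers: dict[str, bool]) -> str:
    """Marker combination → phenotype call.

    CD68+CD80 → M1, CD68+CD206 → M2, CD68 alone → MΦ (non-polarized or
    unresolved macrophage), anything else → other.  A doubly co-marked cell
    (CD80 and CD206) is called M1; the stains are on separate slides in
    practice, so the case only arises in synthetic data.
    """
    if not markers.get("CD68", False):
        return "other"
    if markers.get("CD80", False):
        return "M1"
    if markers.get("CD206", False):
        return "M2"
    return "MPhi"


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render(state, palette: dict | None = None, pixel_size: float = 2.0,
           cell_radius: float = 6.5, nucleus_radius: float = 2.5,
           scalebar_um: float = 200.0) -> np.ndarray:
    """Render a simulation state as an RGB pseudo-immunofluorescence image.

    All macrophages get a CD68-green cytoplasm disk; M1 additionally CD80
    red (yellow composite), M2 CD206 shown magenta; PMNs show only the DAPI
    nucleus.  A white scalebar is drawn bottom-right.  Pure function of the
    state: identical states render identical images.
    """
    palette = palette or DEFAULT_PALETTE
    masks = state.domain
    spec = masks.spec
    extent_x = masks.shape[1] * masks.resolution
    extent_y = masks.shape[0] * masks.resolution
    W = int(round(extent_x / pixel_size))
    H = int(round(extent_y / pixel_size))
    img = np.zeros((H, W, 3), dtype=np.uint8)

    pop = state.pop
    r_cyt = cell_radius / pixel_size
    r_nuc = nucleus_radius / pixel_size

    def paint(cx: float, cy: float, radius: float, rgb: tuple) -> None:
        rr, cc = draw_disk((cy, cx), radius, shape=(H, W))
        img[rr, cc] = np.maximum(img[rr, cc], np.array(rgb, dtype=np.uint8))

    cyto_color = {0: palette["MPhi"], 1: palette["M1"], 2: palette["M2"]}
    for i in range(len(pop)):
        px = (pop.x[i] - masks.origin[0]) / pixel_size
        py = (pop.y[i] - masks.origin[1]) / pixel_size
        ph = int(pop.phen[i])
        if ph in cyto_color:
            paint(px, py, r_cyt, cyto_color[ph])
        paint(px, py, r_nuc, palette["nucleus"])

    bar_px = int(round(scalebar_um / pixel_size))
    if 0 < bar_px < W:
        img[H - 12:H - 8, W - 10 - bar_px:W - 10] = 255
    return img


# ---------------------------------------------------------------------------
# records from segmented images
# ---------------------------------------------------------------------------

def records_from_labels(label_mask: np.ndarray,
                        channels: dict[str, np.ndarray],
                        pixel_size: float = 1.0,
                        positivity_threshold: float = 0.5) -> list[CellRecord]:
    """Measure a label mask into cell records.

    ``channels`` maps marker names to rasters on the same grid; a cell is
    marker-positive when the marker's mean intensity over the cell's pixels
    exceeds ``positivity_threshold``.  Centroids and areas are converted to
    µm via ``pixel_size``.  No size filtering here — see
    :func:`filter_by_area`.
    """
    records = []
    for prop in regionprops(label_mask.astype(np.int64)):
        pix = tuple(np.transpose(prop.coords))
        markers = {}
        for name in MARKERS:
            ch = channels.get(name)
            markers[name] = bool(ch is not None and float(np.mean(ch[pix])) > positivity_threshold)
        cy, cx = prop.centroid
        records.append(CellRecord(
            id=int(prop.label),
            centroid=(cx * pixel_size, cy * pixel_size),
            area=float(prop.area) * pixel_size**2,
            markers=markers,
            phenotype_call=classify_markers(markers),
        ))
    return records


def filter_by_area(records: list[CellRecord],
                   lo: float = AREA_MIN, hi: float = AREA_MAX) -> list[CellRecord]:
    """Keep records with ``lo <= area <= hi`` µm² (bounds inclusive)."""
    return [r for r in records if lo <= r.area <= hi]


def quantify(records: list[CellRecord], roi) -> ROIQuantification:
    """Count cells whose centroid lies in the ROI and convert to mm⁻².

    ``roi`` is a shapely polygon or an (N, 2) vertex array in µm; centroids
    on the boundary count as inside.
    """
    poly = roi if isinstance(roi, Polygon) else Polygon(np.asarray(roi, dtype=float))
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("degenerate ROI polygon")
    area_mm2 = poly.area * 1e-6
    counts = {"MPhi": 0, "M1": 0, "M2": 0, "other": 0}
    for rec in records:
        if poly.covers(Point(*rec.centroid)):
            counts[rec.phenotype_call] = counts.get(rec.phenotype_call, 0) + 1
    conc = {k: v / area_mm2 for k, v in counts.items()}
    conc["MPhi_total"] = (counts["MPhi"] + counts["M1"] + counts["M2"]) / area_mm2
    return ROIQuantification(roi_area=area_mm2, counts=counts, concentrations=conc)


def records_to_dataframe(records: list[CellRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {"id": r.id, "x": r.centroid[0], "y": r.centroid[1], "area": r.area,
               "phenotype_call": r.phenotype_call}
        row.update({m: r.markers.get(m, False) for m in MARKERS})
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# synthetic fixtures (stand-in for externally segmented images)
# ---------------------------------------------------------------------------

_FIXTURE_MARKERS = {
    "MPhi": ("DAPI", "CD68"),
    "M1": ("DAPI", "CD68", "CD80"),
    "M2": ("DAPI", "CD68", "CD206"),
    "other": ("DAPI",),
}


def synthesize_fixture(n_per_phenotype: dict[str, int],
                       shape: tuple[int, int] = (512, 512),
                       pixel_size: float = 1.0,
                       area_range: tuple[float, float] = (100.0, 180.0),
                       n_undersized: int = 0,
                       n_oversized: int = 0,
                       seed: int = 0):
    """Generate a synthetic segmented image with known ground truth.

    Non-overlapping elliptical cells are placed uniformly at random; each
    phenotype key of ``n_per_phenotype`` ("MPhi", "M1", "M2", "other")
    yields cells with the matching marker channels.  ``n_undersized`` /
    ``n_oversized`` add extra CD68+ objects outside the 80–200 µm² band to
    exercise the size filter.  Returns ``(label_mask, channels,
    ground_truth)`` where ground truth is a dataframe of intended cells.

    Synthetic stand-in for an externally segmented immunofluorescence
    image; it emulates marker positivity exactly, with no staining noise.
    """
    rng = np.random.default_rng(seed)
    H, W = shape
    label_mask = np.zeros(shape, dtype=np.int32)
    channels = {m: np.zeros(shape, dtype=float) for m in MARKERS}
    truth_rows = []
    label = 0

    jobs: list[tuple[str, float]] = []
    for phen, n in n_per_phenotype.items():
        if phen not in _FIXTURE_MARKERS:
            raise ValueError(f"unknown phenotype key: {phen!r}")
        for _ in range(int(n)):
            jobs.append((phen, float(rng.uniform(*area_range))))
    for _ in range(int(n_undersized)):
        jobs.append(("MPhi", float(rng.uniform(20.0, AREA_MIN - 5.0))))
    for _ in range(int(n_oversized)):
        jobs.append(("MPhi", float(rng.uniform(AREA_MAX + 20.0, AREA_MAX + 150.0))))

    for phen, target_area in jobs:
        aspect = float(rng.uniform(1.0, 1.4))
        # ellipse area = pi a b, b = a / aspect (semi-axes in pixels)
        a = np.sqrt(target_area * aspect / np.pi) / pixel_size
        b = a / aspect
        theta = float(rng.uniform(0, np.pi))
        placed = False
        for _attempt in range(500):
            cy = float(rng.uniform(a + 2, H - a - 2))
            cx = float(rng.uniform(a + 2, W - a - 2))
            rr, cc = draw_ellipse(cy, cx, a, b, shape=shape, rotation=theta)
            if len(rr) == 0 or label_mask[rr, cc].any():
                continue
            label += 1
            label_mask[rr, cc] = label
            for m in _FIXTURE_MARKERS[phen]:
                channels[m][rr, cc] = 1.0
            truth_rows.append({
                "id": label, "phenotype": phen,
                "x": cx * pixel_size, "y": cy * pixel_size,
                "area": len(rr) * pixel_size**2,
            })
            placed = True
            break
        if not placed:
            raise ValueError("infeasible packing: cannot place all requested cells")

    return label_mask, channels, pd.DataFrame(
        truth_rows, columns=["id", "phenotype", "x", "y", "area"])


def read_roi_csv(path) -> Polygon:
    """Read an ROI polygon from a two-column (x, y) µm vertex CSV."""
    verts = pd.read_csv(path).to_numpy(dtype=float)
    if verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValueError("ROI file must list at least three x,y vertices")
    return Polygon(verts)
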