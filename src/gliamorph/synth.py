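"""Synthetic two-channel fluorescence scenes with per-cell ground truth.

The generator emulates the acquisition the analysis chain assumes: a
210 x 210 x 12 um two-channel volume (channel 0 = Tmem119, channel 1 =
Iba1) at 0.2 um/px lateral sampling and ~1.13 um z-steps, 12-bit gray
levels.  Cells of three morphologies are synthesized so that their
ground-truth footprints straddle the area/circularity gates used for
classification:

* ramified     — small soma (5-8 um diameter) with 4-8 thin (<= 1 um)
  processes 10-25 um long; area in [60, 240] um^2, circularity <= 0.16;
* hypertrophic — large soma (12-18 um) with 3-6 thick (2-3 um) processes;
  area > 250 um^2;
* ameboid      — perturbed disk/ellipse; area in [60, 240] um^2,
  circularity > 0.16 (a configurable fraction nearly round, > 0.5).

Iba1 is painted uniformly over each footprint; Tmem119 with
class-dependent soma/process means (processes brighter than somata for
ramified/hypertrophic cells, ameboid cells near background).  Cells are
extruded over a few z-slices, blurred by a Gaussian PSF, and corrupted by
a planar background gradient plus Poisson-Gaussian noise.  Every shape is
validated against the morphometry gates at construction (resampling on
the rare misses), so ground truth lands in the intended gate by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage import draw, morphology

from .morphometry import classify, shape_descriptors
from .stack import CalibratedStack, write_stack

__all__ = [
    "ChannelIntensity",
    "SceneSpec",
    "CellTruth",
    "SceneTruth",
    "make_cell_shape",
    "render_scene",
    "write_scene",
    "load_truth",
]

CHANNELS = ("tmem119", "iba1")

TRUTH_CSV_COLUMNS = [
    "cell_id", "class", "centroid_x_px", "centroid_y_px", "area_um2",
    "circularity", "mean_iba1", "mean_tmem_total", "mean_tmem_soma",
    "mean_tmem_process",
]


@dataclass(frozen=True)
class ChannelIntensity:
    """Painted Tmem119/Iba1 gray levels for one morphology class."""

    tmem_soma_mean: float
    tmem_process_mean: float
    iba1_mean: float


# Default contrast structure: marker signal concentrated on processes of
# ramified/hypertrophic cells, ameboid cells close to background; Iba1
# identical across classes (no class difference is assumed for the
# segmentation channel).
DEFAULT_INTENSITY: dict[str, ChannelIntensity] = {
    "ramified": ChannelIntensity(tmem_soma_mean=150, tmem_process_mean=400, iba1_mean=600),
    "hypertrophic": ChannelIntensity(tmem_soma_mean=130, tmem_process_mean=320, iba1_mean=600),
    "ameboid": ChannelIntensity(tmem_soma_mean=60, tmem_process_mean=60, iba1_mean=600),
}


@dataclass
class SceneSpec:
    """Full parameterization of one synthetic scene.

    Geometry defaults match the emulated acquisition (210 x 210 x 12 um
    at 0.2 um/px, 1.13 um z-step, 12-bit).  Noise defaults are a planar
    background of ~40 gray levels with a +-10 gradient, shot noise at one
    photon per gray level, and 10 gray levels of read noise.
    """

    width_um: float = 210.0
    height_um: float = 210.0
    depth_um: float = 12.0
    pixel_size_um: float = 0.2
    z_step_um: float = 1.13
    bit_max: int = 4096
    n_cells_per_class: dict[str, int] = field(
        default_factory=lambda: {"ramified": 6, "hypertrophic": 6, "ameboid": 6}
    )
    intensity: dict[str, ChannelIntensity] = field(
        default_factory=lambda: dict(DEFAULT_INTENSITY)
    )
    background_level: float = 40.0
    background_gradient_amplitude: float = 20.0
    gaussian_noise_sd: float = 10.0
    poisson_scaling: float = 1.0
    psf_sigma_um: float = 0.3
    ameboid_high_circ_fraction: float = 0.5
    border_margin_um: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if any(n < 0 for n in self.n_cells_per_class.values()):
            raise ValueError("cell counts must be >= 0")
        unknown = set(self.n_cells_per_class) - set(DEFAULT_INTENSITY)
        if unknown:
            raise ValueError(f"unknown class labels in n_cells_per_class: {sorted(unknown)}")
        for label, ci in self.intensity.items():
            for v in (ci.tmem_soma_mean, ci.tmem_process_mean, ci.iba1_mean):
                if not (0 <= v <= self.bit_max):
                    raise ValueError(
                        f"{label} intensity {v} outside [0, {self.bit_max}]"
                    )

    @property
    def shape_yx(self) -> tuple[int, int]:
        return (
            int(round(self.height_um / self.pixel_size_um)),
            int(round(self.width_um / self.pixel_size_um)),
        )

    @property
    def n_z(self) -> int:
        return max(1, int(round(self.depth_um / self.z_step_um)))


@dataclass
class CellTruth:
    """Ground truth for one synthesized cell.

    Masks are stored as local boolean patches with a bounding-box origin;
    ``soma | process == footprint`` and ``soma & process == 0`` by
    construction.  True means are measured on the clean painted image
    before blur, background and noise.
    """

    cell_id: int
    class_label: str
    origin_yx: tuple[int, int]
    footprint: np.ndarray
    soma: np.ndarray
    process: np.ndarray
    centroid_yx_px: tuple[float, float]
    area_um2: float
    circularity: float
    mean_iba1: float = np.nan
    mean_tmem_total: float = np.nan
    mean_tmem_soma: float = np.nan
    mean_tmem_process: float = np.nan

    def full_mask(self, shape: tuple[int, int], which: str = "footprint") -> np.ndarray:
        local = getattr(self, which)
        out = np.zeros(shape, bool)
        y0, x0 = self.origin_yx
        out[y0 : y0 + local.shape[0], x0 : x0 + local.shape[1]] = local
        return out


@dataclass
class SceneTruth:
    cells: list[CellTruth]
    label_image: np.ndarray  # 0 background, k = cell_id k
    pixel_size_um: float

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cell_id": c.cell_id,
                "class": c.class_label,
                "centroid_x_px": c.centroid_yx_px[1],
                "centroid_y_px": c.centroid_yx_px[0],
                "area_um2": c.area_um2,
                "circularity": c.circularity,
                "mean_iba1": c.mean_iba1,
                "mean_tmem_total": c.mean_tmem_total,
                "mean_tmem_soma": c.mean_tmem_soma,
                "mean_tmem_process": c.mean_tmem_process,
            }
            for c in self.cells
        ]
        return pd.DataFrame(rows, columns=TRUTH_CSV_COLUMNS)


def _disk_mask(radius_px: float, shape: tuple[int, int], center: tuple[float, float]) -> np.ndarray:
    out = np.zeros(shape, bool)
    rr, cc = draw.disk(center, radius_px, shape=shape)
    out[rr, cc] = True
    return out


def _draw_process(
    patch: np.ndarray,
    center: tuple[float, float],
    angle: float,
    length_px: float,
    half_width_px: int,
    rng: np.random.Generator,
) -> None:
    """Paint one process stroke: a two-segment polyline dilated to width."""
    cy, cx = center
    bend = rng.uniform(-0.35, 0.35)
    mid_len = 0.55 * length_px
    my = cy + mid_len * np.sin(angle)
    mx = cx + mid_len * np.cos(angle)
    ey = cy + length_px * np.sin(angle + bend)
    ex = cx + length_px * np.cos(angle + bend)
    stroke = np.zeros_like(patch)
    for (y0, x0), (y1, x1) in (((cy, cx), (my, mx)), ((my, mx), (ey, ex))):
        rr, cc = draw.line(int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1)))
        keep = (rr >= 0) & (rr < patch.shape[0]) & (cc >= 0) & (cc < patch.shape[1])
        stroke[rr[keep], cc[keep]] = True
    if half_width_px >= 1:
        stroke = morphology.dilation(stroke, morphology.disk(half_width_px))
    patch |= stroke


def _blob_mask(
    semi_a_px: float,
    semi_b_px: float,
    wobble: float,
    shape: tuple[int, int],
    center: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """Perturbed-ellipse polygon: radius modulated by low-order harmonics."""
    theta = np.linspace(0, 2 * np.pi, 48, endpoint=False)
    r0 = semi_a_px * semi_b_px / np.sqrt(
        (semi_b_px * np.cos(theta)) ** 2 + (semi_a_px * np.sin(theta)) ** 2
    )
    mod = np.ones_like(theta)
    for k in (2, 3, 5):
        mod += wobble * rng.uniform(-1, 1) * np.sin(k * theta + rng.uniform(0, 2 * np.pi))
    r = np.clip(r0 * mod, 2.0, None)
    rot = rng.uniform(0, 2 * np.pi)
    ys = center[0] + r * np.sin(theta + rot)
    xs = center[1] + r * np.cos(theta + rot)
    out = np.zeros(shape, bool)
    rr, cc = draw.polygon(ys, xs, shape=shape)
    out[rr, cc] = True
    return out


def _largest_component(mask: np.ndarray) -> np.ndarray:
    labels, n = ndi.label(mask)
    if n <= 1:
        return mask
    sizes = ndi.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def make_cell_shape(
    class_label: str,
    pixel_size_um: float,
    rng: np.random.Generator,
    ameboid_high_circ: bool | None = None,
    max_tries: int = 60,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample one cell footprint with its soma/process decomposition.

    Returns local boolean patches ``(footprint, soma, process)`` with
    ``soma | process == footprint`` and ``soma & process`` empty.  Shapes
    are resampled until their measured descriptors fall in the class gate
    (ramified: area in [60, 240] um^2 and circularity <= 0.16;
    hypertrophic: area > 250; ameboid: area in [60, 240] and circularity
    > 0.16, with ``ameboid_high_circ`` selecting the nearly-round
    sub-population above 0.5).
    """
    if class_label not in DEFAULT_INTENSITY:
        raise ValueError(
            f"unknown class label {class_label!r}; expected one of "
            f"{sorted(DEFAULT_INTENSITY)}"
        )
    um = 1.0 / pixel_size_um  # px per um
    for _ in range(max_tries):
        if class_label == "ramified":
            size = int(np.ceil(2 * (25 + 5) * um)) + 4
            patch_shape = (size, size)
            center = (size / 2, size / 2)
            soma_r = rng.uniform(2.5, 4.0) * um
            soma = _disk_mask(soma_r, patch_shape, center)
            foot = soma.copy()
            n_proc = rng.integers(4, 9)
            base = rng.uniform(0, 2 * np.pi)
            for k in range(n_proc):
                angle = base + 2 * np.pi * k / n_proc + rng.uniform(-0.3, 0.3)
                length = rng.uniform(10, 25) * um
                half_w = max(1, int(round(rng.uniform(0.6, 1.0) * um / 2)))
                _draw_process(foot, center, angle, length, half_w, rng)
            lo, hi, circ_ok = 60.0, 240.0, lambda c: c <= 0.16
        elif class_label == "hypertrophic":
            size = int(np.ceil(2 * (15 + 10) * um)) + 4
            patch_shape = (size, size)
            center = (size / 2, size / 2)
            soma_r = rng.uniform(6.0, 9.0) * um
            soma = _blob_mask(soma_r, soma_r * rng.uniform(0.85, 1.0), 0.04,
                              patch_shape, center, rng)
            foot = soma.copy()
            n_proc = rng.integers(3, 7)
            base = rng.uniform(0, 2 * np.pi)
            for k in range(n_proc):
                angle = base + 2 * np.pi * k / n_proc + rng.uniform(-0.25, 0.25)
                length = rng.uniform(8, 15) * um
                half_w = max(1, int(round(rng.uniform(2.0, 3.0) * um / 2)))
                _draw_process(foot, center, angle, length, half_w, rng)
            lo, hi, circ_ok = 250.0 + 1e-9, np.inf, lambda c: True
        else:  # ameboid
            high = ameboid_high_circ if ameboid_high_circ is not None else bool(rng.random() < 0.5)
            if high:
                a = rng.uniform(4.5, 8.0) * um
                size = int(np.ceil(2 * a)) + 8
                patch_shape = (size, size)
                center = (size / 2, size / 2)
                b = a * rng.uniform(0.85, 1.0)
                soma = _blob_mask(a, b, 0.03, patch_shape, center, rng)
            else:
                # elongated, lobed blob: aspect and wobble push circularity
                # below 0.5 while the convex hull keeps it above 0.16
                target_area = rng.uniform(70, 200)  # um^2
                q = rng.uniform(0.12, 0.28)
                a = np.sqrt(target_area / (np.pi * q)) * um
                size = int(np.ceil(2 * (a + 6 * um))) + 8
                patch_shape = (size, size)
                center = (size / 2, size / 2)
                soma = _blob_mask(a, a * q, 0.15, patch_shape, center, rng)
                for _ in range(int(rng.integers(2, 5))):
                    _draw_process(
                        soma, center, rng.uniform(0, 2 * np.pi),
                        rng.uniform(3, 6) * um,
                        max(1, int(round(rng.uniform(1.2, 2.0) * um / 2))), rng,
                    )
            foot = soma.copy()
            lo, hi = 60.0, 240.0
            if high:
                circ_ok = lambda c: c > 0.5
            else:
                circ_ok = lambda c: 0.16 < c <= 0.5

        foot = _largest_component(foot)
        soma = soma & foot
        if class_label == "ameboid":
            soma = foot.copy()
        d = shape_descriptors(foot, pixel_size_um)
        if lo < d.area_um2 < hi and circ_ok(d.circularity):
            # sanity: assigned gate must agree with the classifier
            if classify(d).label == class_label:
                process = foot & ~soma
                return foot, soma, process
    raise RuntimeError(
        f"could not synthesize a {class_label} cell inside its gate "
        f"after {max_tries} tries"
    )


def _crop_to_content(mask: np.ndarray, pad: int = 2) -> tuple[np.ndarray, tuple[int, int]]:
    ys, xs = np.nonzero(mask)
    y0, y1 = max(0, ys.min() - pad), min(mask.shape[0], ys.max() + pad + 1)
    x0, x1 = max(0, xs.min() - pad), min(mask.shape[1], xs.max() + pad + 1)
    return mask[y0:y1, x0:x1], (y0, x0)


def render_scene(spec: SceneSpec) -> tuple[CalibratedStack, SceneTruth]:
    """Render one scene and its ground truth, deterministically from the seed."""
    rng = np.random.default_rng(spec.seed)
    H, W = spec.shape_yx
    n_z = spec.n_z
    margin = int(round(spec.border_margin_um / spec.pixel_size_um))

    label_image = np.zeros((H, W), np.int32)
    occupied = np.zeros((H, W), bool)
    tmem_clean = np.zeros((H, W), np.float32)
    iba1_clean = np.zeros((H, W), np.float32)
    cells: list[CellTruth] = []
    cell_id = 0

    # place the largest morphologies first: rejection sampling packs far
    # better when sprawling shapes go in before compact ones
    order: list[str] = []
    for label in ("hypertrophic", "ramified", "ameboid"):
        order.extend([label] * spec.n_cells_per_class.get(label, 0))

    n_high_left = int(round(spec.ameboid_high_circ_fraction
                            * spec.n_cells_per_class.get("ameboid", 0)))
    for label in order:
        high: bool | None = None
        if label == "ameboid":
            high = n_high_left > 0
            n_high_left -= 1 if high else 0
        # placement failures resample the shape: a sprawling draw that does
        # not fit between already-placed cells is replaced, not fatal
        placed = False
        for _shape_try in range(6):
            foot, soma, proc = make_cell_shape(label, spec.pixel_size_um, rng,
                                               ameboid_high_circ=high)
            foot, (oy, ox) = _crop_to_content(foot)
            soma = soma[oy : oy + foot.shape[0], ox : ox + foot.shape[1]]
            proc = proc[oy : oy + foot.shape[0], ox : ox + foot.shape[1]]
            h, w = foot.shape
            if h > H - 2 * margin or w > W - 2 * margin:
                raise RuntimeError(f"{label} cell larger than the placeable field")
            # keep-out zones: footprints must stay >= 5 px apart so that PSF
            # blur cannot bridge neighbours above threshold
            check_zone = morphology.dilation(foot, morphology.disk(2))
            store_zone = morphology.dilation(check_zone, morphology.disk(1))
            for _ in range(600):
                y0 = int(rng.integers(margin, H - margin - h + 1))
                x0 = int(rng.integers(margin, W - margin - w + 1))
                window = occupied[y0 : y0 + h, x0 : x0 + w]
                if not (window & check_zone).any():
                    placed = True
                    break
            if placed:
                break
        if not placed:
            raise RuntimeError(
                f"failed to place a {label} cell (requested "
                f"{spec.n_cells_per_class.get(label)}); "
                "reduce counts or enlarge the field"
            )
        cell_id += 1
        occupied[y0 : y0 + h, x0 : x0 + w] |= store_zone
        label_image[y0 : y0 + h, x0 : x0 + w][foot] = cell_id
        ci = spec.intensity[label]
        tmem_patch = tmem_clean[y0 : y0 + h, x0 : x0 + w]
        tmem_patch[soma] = ci.tmem_soma_mean
        tmem_patch[proc] = ci.tmem_process_mean
        iba1_clean[y0 : y0 + h, x0 : x0 + w][foot] = ci.iba1_mean

        ys, xs = np.nonzero(foot)
        d = shape_descriptors(foot, spec.pixel_size_um)
        n_s, n_p, n_f = soma.sum(), proc.sum(), foot.sum()
        mean_total = (n_s * ci.tmem_soma_mean + n_p * ci.tmem_process_mean) / n_f
        cells.append(
            CellTruth(
                cell_id=cell_id,
                class_label=label,
                origin_yx=(y0, x0),
                footprint=foot,
                soma=soma,
                process=proc,
                centroid_yx_px=(float(ys.mean()) + y0, float(xs.mean()) + x0),
                area_um2=d.area_um2,
                circularity=d.circularity,
                mean_iba1=float(ci.iba1_mean),
                mean_tmem_total=float(mean_total),
                mean_tmem_soma=float(ci.tmem_soma_mean),
                mean_tmem_process=(
                    float(ci.tmem_process_mean) if n_p else float("nan")
                ),
            )
        )

    # extrude into z: each cell occupies a random contiguous run of slices
    vol = np.zeros((2, n_z, H, W), np.float32)
    for c in cells:
        span = int(rng.integers(3, min(6, n_z) + 1)) if n_z >= 3 else n_z
        z0 = int(rng.integers(0, n_z - span + 1))
        y0, x0 = c.origin_yx
        h, w = c.footprint.shape
        ci = spec.intensity[c.class_label]
        for z in range(z0, z0 + span):
            tp = vol[0, z, y0 : y0 + h, x0 : x0 + w]
            tp[c.soma] = ci.tmem_soma_mean
            tp[c.process] = ci.tmem_process_mean
            vol[1, z, y0 : y0 + h, x0 : x0 + w][c.footprint] = ci.iba1_mean

    sigma_px = spec.psf_sigma_um / spec.pixel_size_um
    if sigma_px > 0:
        for ch in range(2):
            for z in range(n_z):
                if vol[ch, z].any():
                    vol[ch, z] = ndi.gaussian_filter(vol[ch, z], sigma_px)

    if spec.background_level or spec.background_gradient_amplitude:
        yy, xx = np.mgrid[0:H, 0:W]
        angle = rng.uniform(0, 2 * np.pi)
        ramp = (np.cos(angle) * xx + np.sin(angle) * yy).astype(np.float32)
        ramp -= ramp.min()
        if ramp.max() > 0:
            ramp /= ramp.max()
        background = spec.background_level + spec.background_gradient_amplitude * (ramp - 0.5)
        vol += np.clip(background, 0, None)[None, None]

    out = np.empty_like(vol)
    for ch in range(2):
        for z in range(n_z):
            plane = vol[ch, z]
            if spec.poisson_scaling > 0:
                plane = rng.poisson(
                    np.clip(plane, 0, None) * spec.poisson_scaling
                ).astype(np.float32) / spec.poisson_scaling
            if spec.gaussian_noise_sd > 0:
                plane = plane + rng.normal(0, spec.gaussian_noise_sd, plane.shape)
            out[ch, z] = plane

    data = np.clip(np.rint(out), 0, spec.bit_max).astype(np.uint16)
    stack = CalibratedStack(
        data=data,
        pixel_size_um=spec.pixel_size_um,
        z_step_um=spec.z_step_um,
        bit_max=spec.bit_max,
        channel_names=CHANNELS,
    )
    truth = SceneTruth(cells=cells, label_image=label_image,
                       pixel_size_um=spec.pixel_size_um)
    return stack, truth


def write_scene(
    stack: CalibratedStack, truth: SceneTruth, out_dir: str | Path
) -> dict[str, Path]:
    """Write stack (TIFF + sidecar), truth label TIFF and truth CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stack_path = out_dir / "scene.tif"
    write_stack(stack, stack_path)
    labels_path = out_dir / "truth_labels.tif"
    if truth.label_image.max() > np.iinfo(np.uint16).max:
        raise ValueError("more than 65535 cells cannot be stored as 16-bit labels")
    tifffile.imwrite(labels_path, truth.label_image.astype(np.uint16), photometric="minisblack")
    csv_path = out_dir / "truth.csv"
    truth.to_frame().to_csv(csv_path, index=False, float_format="%.6g")
    return {"stack": stack_path, "labels": labels_path, "truth_csv": csv_path}


def load_truth(out_dir: str | Path, pixel_size_um: float) -> tuple[np.ndarray, pd.DataFrame]:
    """Read back the truth label image and table written by write_scene."""
    out_dir = Path(out_dir)
    labels = tifffile.imread(out_dir / "truth_labels.tif").astype(np.int32)
    table = pd.read_csv(out_dir / "truth.csv")
    return labels, table
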