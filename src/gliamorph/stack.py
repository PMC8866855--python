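"""Calibrated multi-channel image stacks and their on-disk representation.

A stack is stored as a channel-major multi-page TIFF (page order
``c0z0, c0z1, ..., c1z0, ...``) next to a sidecar JSON carrying the
acquisition calibration: pixel size, z step, bit depth, and channel names.
The sidecar is authoritative for the page layout; reading fails loudly if
it disagrees with the TIFF.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["CalibratedStack", "read_stack", "write_stack"]

SIDECAR_SUFFIX = ".json"


@dataclass
class CalibratedStack:
    """Multi-channel 3D fluorescence volume with pixel calibration.

    Parameters
    ----------
    data:
        Integer gray levels, shape ``(channels, z, y, x)``.
    pixel_size_um:
        Lateral pixel size in micrometres per pixel.
    z_step_um:
        Axial step between z-slices in micrometres.
    bit_max:
        Maximum representable gray level (4096 for 12-bit acquisition).
    channel_names:
        One name per channel, e.g. ``("tmem119", "iba1")``.
    """

    data: np.ndarray
    pixel_size_um: float
    z_step_um: float
    bit_max: int = 4096
    channel_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(
                f"stack data must be (channels, z, y, x); got shape {self.data.shape}"
            )
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.data.min() < 0 or self.data.max() > self.bit_max:
            raise ValueError(f"gray levels must lie in [0, {self.bit_max}]")
        if not self.channel_names:
            self.channel_names = tuple(f"ch{i}" for i in range(self.n_channels))
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must match channel count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_z(self) -> int:
        return self.data.shape[1]

    @property
    def shape_yx(self) -> tuple[int, int]:
        return self.data.shape[2], self.data.shape[3]

    def channel(self, name_or_index: str | int) -> np.ndarray:
        """Return the (z, y, x) sub-volume of one channel."""
        if isinstance(name_or_index, str):
            try:
                idx = self.channel_names.index(name_or_index)
            except ValueError:
                raise KeyError(
                    f"unknown channel {name_or_index!r}; have {self.channel_names}"
                ) from None
        else:
            idx = name_or_index
        return self.data[idx]


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(tiff_path.suffix + SIDECAR_SUFFIX)


def write_stack(stack: CalibratedStack, path: str | Path) -> Path:
    """Write a stack as channel-major multi-page TIFF plus sidecar JSON.

    Returns the sidecar path.  Pages are written in ``(c, z)`` order so that
    page ``c * n_z + z`` holds channel ``c``, slice ``z``.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    c, z, y, x = stack.data.shape
    pages = stack.data.reshape(c * z, y, x).astype(np.uint16)
    tifffile.imwrite(path, pages, photometric="minisblack")
    meta = {
        "pixel_size_um": stack.pixel_size_um,
        "z_step_um": stack.z_step_um,
        "bit_max": int(stack.bit_max),
        "channel_names": list(stack.channel_names),
        "n_channels": c,
        "n_z": z,
        "page_order": "channel_major",
    }
    sidecar = _sidecar_path(path)
    sidecar.write_text(json.dumps(meta, indent=2))
    return sidecar


def read_stack(path: str | Path, sidecar: str | Path | None = None) -> CalibratedStack:
    """Read a TIFF stack with its calibration sidecar.

    Raises if the sidecar is missing, lacks calibration, or disagrees with
    the TIFF page count.
    """
    path = Path(path)
    sidecar = Path(sidecar) if sidecar is not None else _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"calibration sidecar not found: {sidecar}")
    meta = json.loads(sidecar.read_text())
    for key in ("pixel_size_um", "z_step_um", "bit_max", "n_channels", "n_z"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar} missing calibration field {key!r}")
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    n_pages = pages.shape[0]
    c, z = int(meta["n_channels"]), int(meta["n_z"])
    if n_pages != c * z:
        raise ValueError(
            f"TIFF has {n_pages} pages but sidecar declares "
            f"{c} channels x {z} slices = {c * z}"
        )
    data = pages.reshape(c, z, pages.shape[1], pages.shape[2])
    return CalibratedStack(
        data=data,
        pixel_size_um=float(meta["pixel_size_um"]),
        z_step_um=float(meta["z_step_um"]),
        bit_max=int(meta["bit_max"]),
        channel_names=tuple(meta.get("channel_names", ())),
    )
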