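"""Cone-catch image container and on-disk formats.

A cone-catch image stores, per pixel, the quantum catch of each of the
observer's photoreceptor channels (here sw, mw, lw single cones and the
dbl double cone used for luminance). Images are written as 32-bit float
multi-page TIFFs (one page per channel) with a JSON sidecar holding the
physical scale; masks are single-page 8-bit TIFFs (0/255).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

CHANNELS = ("sw", "mw", "lw", "dbl")


@dataclass
class ConeCatchImage:
    """H x W x 4 photoreceptor quantum-catch raster with physical scale.

    Parameters
    ----------
    data : ndarray, shape (H, W, 4)
        Strictly positive linear quantum catches, channel order
        (sw, mw, lw, dbl).
    px_per_mm : float
        Pixels per millimetre in the scene plane.
    image_id : str
        Identifier used in output tables.
    """

    data: np.ndarray
    px_per_mm: float
    image_id: str = ""
    channels: tuple[str, ...] = field(default=CHANNELS)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or self.data.shape[2] != len(self.channels):
            raise ValueError(
                f"expected (H, W, {len(self.channels)}) array, got {self.data.shape}"
            )
        if self.px_per_mm <= 0:
            raise ValueError("px_per_mm must be positive")
        if not np.all(np.isfinite(self.data)) or np.any(self.data <= 0):
            raise ValueError("cone catches must be strictly positive and finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def chromatic(self) -> np.ndarray:
        """Catches of the three single-cone channels, shape (H, W, 3)."""
        return self.data[..., :3]

    @property
    def luminance(self) -> np.ndarray:
        """Double-cone catch, shape (H, W)."""
        return self.data[..., 3]

    def with_data(self, data: np.ndarray) -> "ConeCatchImage":
        return ConeCatchImage(data, self.px_per_mm, self.image_id, self.channels)

    # ---- I/O ----------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Write a multi-page float32 TIFF plus a JSON scale sidecar."""
        path = Path(path)
        pages = np.moveaxis(self.data.astype(np.float32), -1, 0)
        tifffile.imwrite(path, pages)
        sidecar = {
            "px_per_mm": self.px_per_mm,
            "image_id": self.image_id,
            "channels": list(self.channels),
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "ConeCatchImage":
        path = Path(path)
        pages = tifffile.imread(path)
        if pages.ndim == 2:
            pages = pages[None]
        data = np.moveaxis(pages, 0, -1).astype(np.float64)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            data,
            px_per_mm=float(meta["px_per_mm"]),
            image_id=str(meta.get("image_id", path.stem)),
            channels=tuple(meta.get("channels", CHANNELS)),
        )


def save_mask(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), np.where(mask, 255, 0).astype(np.uint8))


def load_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)) > 0
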