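"""Reading and writing images, masks, tables and run manifests.

Images travel as OME-TIFF with channel names and the physical pixel size in
the metadata; masks as PNG or TIFF (nonzero = true); tables as CSV; run
manifests as JSON carrying the full configuration, the seed and the package
version so a run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Optional, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

from .types import DataError, ImageStack


def write_image_stack(stack: ImageStack, path) -> None:
    """Write an OME-TIFF with channel names and pixel size in metadata."""
    path = Path(path)
    names = list(stack.channels)
    data = np.stack([stack.channels[n] for n in names])
    axes = "CZYX" if stack.is_3d else "CYX"
    metadata = {
        "axes": axes,
        "Channel": {"Name": names},
        "PhysicalSizeX": stack.pixel_size_um,
        "PhysicalSizeXUnit": "µm",
        "PhysicalSizeY": stack.pixel_size_um,
        "PhysicalSizeYUnit": "µm",
    }
    if stack.z_step_um is not None:
        metadata["PhysicalSizeZ"] = stack.z_step_um
        metadata["PhysicalSizeZUnit"] = "µm"
    tifffile.imwrite(path, data, ome=True, metadata=metadata)


def _ome_channel_names(ome_xml: str) -> list:
    ns = {"ome": ET.fromstring(ome_xml).tag.split("}")[0].strip("{")}
    root = ET.fromstring(ome_xml)
    return [
        ch.get("Name") or f"C{i}"
        for i, ch in enumerate(root.iter(f"{{{ns['ome']}}}Channel"))
    ]


def _ome_pixel_sizes(ome_xml: str) -> tuple:
    root = ET.fromstring(ome_xml)
    ns = root.tag.split("}")[0].strip("{")
    px = next(root.iter(f"{{{ns}}}Pixels"), None)
    if px is None:
        return None, None
    sx = px.get("PhysicalSizeX")
    sz = px.get("PhysicalSizeZ")
    return (float(sx) if sx else None, float(sz) if sz else None)


def read_image_stack(
    path,
    channel_names: Optional[Sequence[str]] = None,
    pixel_size_um: Optional[float] = None,
    z_step_um: Optional[float] = None,
) -> ImageStack:
    """Read a (OME-)TIFF into an ImageStack.

    Channel names and pixel size come from OME metadata when present;
    explicit arguments override them. Plain multi-page TIFFs need both
    ``channel_names`` and ``pixel_size_um``. The leading axis is taken as
    the channel axis (2D images become a single channel named C0).
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        ome = tf.ome_metadata
    names, meta_px, meta_z = None, None, None
    if ome:
        try:
            names = _ome_channel_names(ome)
            meta_px, meta_z = _ome_pixel_sizes(ome)
        except ET.ParseError:
            pass
    if channel_names is not None:
        names = list(channel_names)
    if pixel_size_um is None:
        pixel_size_um = meta_px
    if z_step_um is None:
        z_step_um = meta_z
    if pixel_size_um is None:
        raise DataError(f"{path}: pixel size not in metadata; pass pixel_size_um")
    if data.ndim == 2:
        data = data[None]
        names = names or ["C0"]
    if names is None or len(names) != data.shape[0]:
        raise DataError(
            f"{path}: need {data.shape[0]} channel names, got "
            f"{names if names is None else len(names)}"
        )
    return ImageStack(
        channels={n: data[i] for i, n in enumerate(names)},
        pixel_size_um=float(pixel_size_um),
        z_step_um=z_step_um,
    )


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as 8-bit PNG/TIFF (255 = true)."""
    path = Path(path)
    img = (np.asarray(mask, dtype=bool) * np.uint8(255))
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img)


def read_mask(path) -> np.ndarray:
    """Read a binary mask image (any nonzero pixel is true)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = iio.imread(path)
    if img.ndim == 3:  # drop a color/alpha axis
        img = img[..., 0]
    return np.asarray(img) > 0


def write_manifest(path, config: dict, seed: int) -> None:
    """JSON run manifest: configuration + seed + software version."""
    from . import __version__

    payload = {"config": config, "seed": seed, "epiquant_version": __version__}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
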