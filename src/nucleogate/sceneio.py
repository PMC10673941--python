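"""Scene and table I/O: multi-channel OME-TIFF, label TIFF, CSV, YAML."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
import yaml

from .synthetic import CHANNELS, Scene


def write_scene(scene: Scene, path) -> None:
    """Write a scene as one multi-channel OME-TIFF with channel names."""
    path = Path(path)
    stack = np.stack([scene.channels[name] for name in CHANNELS])
    tifffile.imwrite(
        path, stack.astype(np.float32), ome=True,
        metadata={
            "axes": "CYX",
            "Channel": {"Name": list(CHANNELS)},
            "PhysicalSizeX": scene.pixel_size_um,
            "PhysicalSizeY": scene.pixel_size_um,
            "PhysicalSizeXUnit": "µm",
            "PhysicalSizeYUnit": "µm",
        })


def read_scene(path, pixel_size_um: float | None = None,
               condition: str = "", channel_names=None) -> Scene:
    """Read a multi-channel TIFF back into a :class:`Scene`.

    Channel names are taken from OME metadata when present, from
    ``channel_names`` otherwise.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        names = channel_names
        if names is None and tf.ome_metadata:
            import re
            names = re.findall(r'Channel[^>]*Name="([^"]+)"', tf.ome_metadata)
        if pixel_size_um is None and tf.ome_metadata:
            import re
            m = re.search(r'PhysicalSizeX="([0-9.eE+-]+)"', tf.ome_metadata)
            pixel_size_um = float(m.group(1)) if m else 1.0
    if stack.ndim == 2:
        stack = stack[None]
    if names is None or len(names) != stack.shape[0]:
        names = list(CHANNELS)[:stack.shape[0]]
    channels = {name: stack[i].astype(np.float32)
                for i, name in enumerate(names)}
    return Scene(channels=channels, pixel_size_um=pixel_size_um or 1.0,
                 condition=condition)


def write_labels(label_image: np.ndarray, path) -> None:
    """Write a label image as 16-bit TIFF (labels above 65535 rejected)."""
    if label_image.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit label image")
    tifffile.imwrite(Path(path), label_image.astype(np.uint16))


def read_labels(path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(np.int32)


def write_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
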