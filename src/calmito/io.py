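"""Shared readers and writers: OME-TIFF images, ROI masks/polygons,
stimulus protocols (YAML) and tabular outputs (CSV/JSON).

Axis order is normalized on read to (T, Y, X) for movies and
(T,) Z, Y, X for stacks; physical pixel/voxel sizes come from OME metadata
when present, else must be supplied explicitly.
"""

from __future__ import annotations

import json
from pathlib import Path
from xml.etree import ElementTree

import numpy as np
import tifffile
import yaml
from skimage.draw import polygon as draw_polygon

from calmito.calcium.movie import NeuronROI, StimulusWindow, rois_from_label_mask


def write_image(
    path: str | Path,
    data: np.ndarray,
    axes: str,
    pixel_size_um: tuple[float, ...] | float | None = None,
    frame_interval_s: float | None = None,
) -> None:
    """Write an array as OME-TIFF with physical-size metadata.

    axes is e.g. 'TYX', 'ZYX' or 'TZYX'. pixel_size_um is a scalar for 2-D
    pixels or (z, y, x) for voxels; stored as PhysicalSizeX/Y/Z (um).
    """
    metadata: dict = {"axes": axes}
    if pixel_size_um is not None:
        if np.isscalar(pixel_size_um):
            sizes = {"X": float(pixel_size_um), "Y": float(pixel_size_um)}
        else:
            z, y, x = pixel_size_um  # type: ignore[misc]
            sizes = {"X": float(x), "Y": float(y), "Z": float(z)}
        for ax, v in sizes.items():
            metadata[f"PhysicalSize{ax}"] = v
            metadata[f"PhysicalSize{ax}Unit"] = "µm"
    if frame_interval_s is not None:
        metadata["TimeIncrement"] = float(frame_interval_s)
        metadata["TimeIncrementUnit"] = "s"
    # single-channel data: never let tiny trailing dims be inferred as RGB(A)
    tifffile.imwrite(
        str(path), np.asarray(data), ome=True, photometric="minisblack",
        metadata=metadata,
    )


def _parse_ome_metadata(ome_xml: str) -> dict:
    """Pull physical sizes and time increment out of OME-XML."""
    meta: dict = {}
    root = ElementTree.fromstring(ome_xml)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    pixels = root.find(".//ome:Pixels", ns)
    if pixels is None:
        return meta
    for ax in "XYZ":
        v = pixels.get(f"PhysicalSize{ax}")
        if v is not None:
            meta[f"pixel_size_{ax.lower()}_um"] = float(v)
    t = pixels.get("TimeIncrement")
    if t is not None:
        meta["frame_interval_s"] = float(t)
    return meta


def read_image(path: str | Path, expected_ndim: int) -> tuple[np.ndarray, dict]:
    """Read a TIFF/OME-TIFF and normalize axes.

    expected_ndim: 2 (Y,X), 3 ((T|Z),Y,X) or 4 (T,Z,Y,X). Singleton
    channel/sample axes are squeezed. Returns (array, metadata) where
    metadata holds 'axes' plus any physical sizes parsed from OME-XML.
    Callers must supply sizes explicitly when the metadata lacks them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tf:
        series = tf.series[0]
        data = series.asarray()
        axes = series.axes
        meta: dict = {}
        if tf.ome_metadata:
            meta.update(_parse_ome_metadata(tf.ome_metadata))
    # drop singleton non-spatial axes (channel, sample, ...)
    keep = [i for i, ax in enumerate(axes) if ax in "TZYX" or data.shape[i] > 1]
    squeeze = tuple(i for i in range(data.ndim) if i not in keep)
    if squeeze:
        data = data.squeeze(axis=squeeze)
        axes = "".join(ax for i, ax in enumerate(axes) if i in keep)
    if data.ndim != expected_ndim:
        raise ValueError(
            f"{path.name}: expected a {expected_ndim}-D image, got "
            f"{data.ndim}-D with axes {axes!r}"
        )
    meta["axes"] = axes
    return data, meta


def read_rois(path: str | Path, image_shape_yx: tuple[int, int]) -> list[NeuronROI]:
    """Read neuron ROIs from a label-mask TIFF (0 = background) or a
    polygon JSON file [{"id": 1, "polygon": [[y, x], ...]}, ...]."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        mask, _ = read_image(path, expected_ndim=2)
        return rois_from_label_mask(mask)
    if path.suffix.lower() == ".json":
        entries = json.loads(path.read_text())
        rois = []
        for e in entries:
            poly = np.asarray(e["polygon"], dtype=np.float64)
            rr, cc = draw_polygon(poly[:, 0], poly[:, 1], shape=image_shape_yx)
            rois.append(NeuronROI(int(e["id"]), np.stack([rr, cc], axis=1)))
        return rois
    raise ValueError(f"unsupported ROI format: {path.suffix}")


def read_protocol(path: str | Path) -> list[StimulusWindow]:
    """Read a stimulus protocol YAML: a list of {label, start_s, end_s}."""
    entries = yaml.safe_load(Path(path).read_text())
    if not isinstance(entries, list) or not entries:
        raise ValueError("protocol must be a non-empty list of stimulus windows")
    return [
        StimulusWindow(e["label"], float(e["start_s"]), float(e["end_s"]))
        for e in entries
    ]


def write_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
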