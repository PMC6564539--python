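"""BrainNet-Viewer-compatible exports and the bundled Destrieux resources."""

from __future__ import annotations

from importlib import resources as _resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "destrieux_roi_names",
    "destrieux_lobe_map",
    "placeholder_coordinates",
    "export_brainnet_node",
    "export_brainnet_edge",
    "read_brainnet_node",
]


def destrieux_roi_names() -> list[str]:
    """The 148 Destrieux-atlas ROI names (74 per hemisphere), lh_ then rh_."""
    text = _resources.files("covnet.resources").joinpath("destrieux_rois.txt").read_text()
    return [line for line in text.splitlines() if line.strip()]


def destrieux_lobe_map() -> dict[str, str]:
    """ROI name -> lobe (frontal/parietal/temporal/occipital/limbic/insula)."""
    text = _resources.files("covnet.resources").joinpath("destrieux_lobes.tsv").read_text()
    out = {}
    for line in text.splitlines()[1:]:
        if line.strip():
            roi, lobe = line.split("\t")
            out[roi] = lobe
    return out


def placeholder_coordinates(roi_names: list[str]) -> pd.DataFrame:
    """Deterministic spherical layout (Fibonacci lattice) for visualization.

    Stands in when true atlas centroids (which require surface
    reconstructions) are not supplied; radius 70 mm, roughly head-sized.
    """
    n = len(roi_names)
    i = np.arange(n)
    golden = (1 + 5**0.5) / 2
    theta = 2 * np.pi * i / golden
    z = 1 - 2 * (i + 0.5) / n
    r = np.sqrt(1 - z**2)
    coords = 70.0 * np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return pd.DataFrame(coords, index=roi_names, columns=["x", "y", "z"])


def export_brainnet_node(
    path,
    roi_names: list[str],
    module_labels: np.ndarray,
    degree: np.ndarray,
    coordinates: pd.DataFrame | None = None,
) -> None:
    """Write a BrainNet ``.node`` file: x y z color(=module) size(=degree) label.

    Module colors are written 1-based.  Missing coordinates for any ROI are
    rejected by name.
    """
    if coordinates is None:
        coordinates = placeholder_coordinates(roi_names)
    missing = [r for r in roi_names if r not in coordinates.index]
    if missing:
        raise ValueError(f"no coordinates for ROI(s): {missing[:5]}")
    module_labels = np.asarray(module_labels)
    degree = np.asarray(degree)
    if not (len(roi_names) == len(module_labels) == len(degree)):
        raise ValueError("roi_names, module_labels and degree must align")
    lines = []
    for i, roi in enumerate(roi_names):
        x, y, z = coordinates.loc[roi, ["x", "y", "z"]]
        lines.append(
            f"{x:.4f}\t{y:.4f}\t{z:.4f}\t{int(module_labels[i]) + 1}\t{degree[i]:g}\t{roi}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def export_brainnet_edge(path, adjacency: np.ndarray) -> None:
    """Write a BrainNet ``.edge`` file: whitespace-delimited square matrix."""
    np.savetxt(path, np.asarray(adjacency), fmt="%g", delimiter="\t")


def read_brainnet_node(path) -> pd.DataFrame:
    """Parse a ``.node`` file back into a DataFrame (module is 0-based again)."""
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        x, y, z, color, size, label = line.split("\t")
        rows.append({"roi": label, "x": float(x), "y": float(y), "z": float(z),
                     "module": int(color) - 1, "degree": float(size)})
    return pd.DataFrame(rows).set_index("roi")
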