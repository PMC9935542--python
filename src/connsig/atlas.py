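"""Parcellation support: the 106-region label table and atlas volumes.

The default label table emulates the Conn/Harvard-Oxford parcellation used
for ROI-to-ROI connectivity: 48 cortical structures per hemisphere plus five
paired subcortical structures (106 regions in total).  Region labels are the
short names conventional in the field (``pSTG l`` = left posterior superior
temporal gyrus, ``TOFusC r`` = right temporal-occipital fusiform cortex, ...).

A synthetic labelled NIfTI volume is provided for tests and simulations: each
region occupies one rectangular block of voxels in a regular grid, which is
enough structure to exercise sample-to-parcellation mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "AtlasVolume",
    "default_labels",
    "region_sets",
    "synthetic_atlas",
    "load_atlas",
    "save_atlas",
]

# 48 cortical structures (Harvard-Oxford naming, Conn-style abbreviations).
_CORTICAL = [
    "FP", "IC", "SFG", "MidFG", "IFG tri", "IFG oper", "PreCG", "TP",
    "aSTG", "pSTG", "aMTG", "pMTG", "toMTG", "aITG", "pITG", "toITG",
    "PostCG", "SPL", "aSMG", "pSMG", "AG", "sLOC", "iLOC", "ICC",
    "MedFC", "SMA", "SubCalC", "PaCiG", "AC", "PC", "Precuneous",
    "Cuneal", "FOrb", "aPaHC", "pPaHC", "LG", "aTFusC", "pTFusC",
    "TOFusC", "OFusG", "FO", "CO", "PO", "PP", "HG", "PT", "SCC", "OP",
]
_SUBCORTICAL = ["Thalamus", "Caudate", "Putamen", "Pallidum", "Hippocampus"]


def default_labels() -> pd.DataFrame:
    """The default 106-region label table (columns: ``label``, ``name``).

    Integer labels run 1..106; 0 is background.  Left/right homologues are
    adjacent (``... l`` before ``... r``).
    """
    names: list[str] = []
    for base in _CORTICAL + _SUBCORTICAL:
        names.append(f"{base} l")
        names.append(f"{base} r")
    return pd.DataFrame({"label": np.arange(1, len(names) + 1), "name": names})


def _bilateral(*bases: str) -> list[str]:
    return [f"{b} {h}" for b in bases for h in ("l", "r")]


def region_sets() -> dict[str, list[str]]:
    """A-priori region sets used in the network-level analyses.

    ``SPT``: striato-pallido-thalamic set (caudate, putamen, pallidum and
    thalamus, bilaterally).  ``ASM``: auditory-sensory-motor cortex
    (Heschl's gyrus, planum temporale, posterior superior temporal gyrus,
    pre-/postcentral gyri, insula).  ``STG`` and ``TO`` are the auditory
    (superior temporal) and visual (temporo-occipital) clusters examined in
    the data-driven network analysis.
    """
    return {
        "SPT": _bilateral("Caudate", "Putamen", "Pallidum", "Thalamus"),
        "ASM": _bilateral("HG", "PT", "pSTG", "PreCG", "PostCG", "IC"),
        "STG": _bilateral("aSTG", "pSTG"),
        "TO": _bilateral("iLOC", "OFusG", "TOFusC"),
    }


@dataclass
class AtlasVolume:
    """A labelled parcellation volume.

    Attributes
    ----------
    label_grid
        3-D integer array; 0 is background.
    affine
        4x4 voxel-to-mm transform.
    label_names
        Integer label -> region name; every label occurs in the grid.
    """

    label_grid: np.ndarray
    affine: np.ndarray
    label_names: dict[int, str]

    def __post_init__(self) -> None:
        present = set(np.unique(self.label_grid)) - {0}
        missing = set(self.label_names) - present
        if missing:
            raise ValueError(f"labels absent from the grid: {sorted(missing)}")

    @property
    def region_names(self) -> list[str]:
        return [self.label_names[k] for k in sorted(self.label_names)]


def synthetic_atlas(
    labels: pd.DataFrame | None = None,
    block: tuple[int, int, int] = (2, 2, 4),
    voxel_size: float = 2.0,
) -> AtlasVolume:
    """Build a synthetic block-structured atlas volume for the label table.

    Regions tile a rectangular grid as ``block``-sized cuboids, separated by
    background; the affine scales voxels to ``voxel_size`` mm and centres the
    grid near the origin, mimicking MNI-space coordinates.
    """
    if labels is None:
        labels = default_labels()
    n = len(labels)
    nx = int(np.ceil(np.sqrt(n)))
    ny = int(np.ceil(n / nx))
    bx, by, bz = block
    # one-voxel background gutters between blocks
    grid = np.zeros((nx * (bx + 1) + 1, ny * (by + 1) + 1, bz + 2), dtype=np.int32)
    for idx, lab in enumerate(labels["label"].to_numpy()):
        i, j = divmod(idx, ny)
        x0 = 1 + i * (bx + 1)
        y0 = 1 + j * (by + 1)
        grid[x0 : x0 + bx, y0 : y0 + by, 1 : 1 + bz] = lab
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    affine[:3, 3] = -voxel_size * (np.asarray(grid.shape) - 1) / 2.0
    names = dict(zip(labels["label"].astype(int), labels["name"]))
    return AtlasVolume(label_grid=grid, affine=affine, label_names=names)


def save_atlas(atlas: AtlasVolume, nifti_path, labels_path) -> None:
    """Write the atlas as NIfTI plus a tab-separated label table."""
    img = nib.Nifti1Image(atlas.label_grid.astype(np.int32), atlas.affine)
    nib.save(img, str(nifti_path))
    pd.DataFrame(
        {"label": sorted(atlas.label_names), "name": [atlas.label_names[k] for k in sorted(atlas.label_names)]}
    ).to_csv(labels_path, sep="\t", index=False)


def load_atlas(nifti_path, labels_path) -> AtlasVolume:
    """Read an atlas from a NIfTI volume and its TSV label table."""
    img = nib.load(str(nifti_path))
    table = pd.read_csv(labels_path, sep="\t")
    names = dict(zip(table["label"].astype(int), table["name"]))
    return AtlasVolume(
        label_grid=np.asarray(img.dataobj).astype(np.int32),
        affine=np.asarray(img.affine),
        label_names=names,
    )
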