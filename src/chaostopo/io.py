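"""File I/O: PDB C-alpha traces, coordinate / signal CSVs, trajectories."""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import PointCloud, SignalSet
from .dynamics import TrajectoryEnsemble

__all__ = [
    "read_pdb_calpha",
    "read_point_cloud_csv",
    "write_point_cloud_csv",
    "read_signals_csv",
    "write_trajectory_csv",
]


def read_pdb_calpha(path: str | Path) -> tuple[PointCloud, np.ndarray]:
    """C-alpha coordinates and experimental B-factors from a PDB file.

    One entry per residue's CA ATOM record, first model only, first
    alternate location where duplicates exist; coordinates in Angstrom.
    Node ids are ``chain:resseq`` and preserve file order.
    """
    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        structure = parser.get_structure("protein", str(path))
    try:
        model = next(structure.get_models())  # first model only
    except StopIteration:
        raise ValueError(f"{path}: no models found") from None
    coords, bfactors, ids = [], [], []
    for chain in model:
        for residue in chain:
            if "CA" not in residue:
                continue
            atom = residue["CA"]
            if atom.is_disordered():
                atom = sorted(atom.disordered_get_list(),
                              key=lambda a: a.get_altloc())[0]
            coords.append(atom.get_coord().astype(float))
            bfactors.append(float(atom.get_bfactor()))
            ids.append(f"{chain.id}:{residue.id[1]}")
    if not coords:
        raise ValueError(f"{path}: no C-alpha atoms found")
    return (
        PointCloud(coords=np.asarray(coords), ids=ids),
        np.asarray(bfactors),
    )


def read_point_cloud_csv(path: str | Path) -> PointCloud:
    """Point cloud from a CSV with header ``id,x,y,z,...``."""
    df = pd.read_csv(path)
    if "id" in df.columns:
        ids = df["id"].astype(str).tolist()
        coords = df.drop(columns=["id"]).to_numpy(dtype=float)
    else:
        ids = []
        coords = df.to_numpy(dtype=float)
    return PointCloud(coords=coords, ids=ids)


def write_point_cloud_csv(cloud: PointCloud, path: str | Path) -> None:
    cols = ["x", "y", "z"][: cloud.coords.shape[1]]
    if cloud.coords.shape[1] > 3:
        cols = [f"c{i}" for i in range(cloud.coords.shape[1])]
    df = pd.DataFrame(cloud.coords, columns=cols)
    df.insert(0, "id", cloud.ids)
    df.to_csv(path, index=False)


def read_signals_csv(
    path: str | Path, labels_path: str | Path | None = None
) -> SignalSet:
    """Signal set from a CSV with one row per channel (no header)."""
    signals = np.loadtxt(path, delimiter=",", ndmin=2)
    labels = None
    if labels_path is not None:
        labels = np.loadtxt(labels_path, delimiter=",", dtype=int, ndmin=1)
    return SignalSet(signals=signals, labels=labels)


def write_trajectory_csv(traj: TrajectoryEnsemble, path: str | Path) -> None:
    """Long-format CSV export: node, t, x, y, z."""
    N, _, T = traj.states.shape
    node = np.repeat(np.arange(N), T)
    t = np.tile(np.arange(T) * traj.h, N)
    flat = traj.states.transpose(0, 2, 1).reshape(N * T, 3)
    pd.DataFrame(
        {"node": node, "t": t, "x": flat[:, 0], "y": flat[:, 1],
         "z": flat[:, 2]}
    ).to_csv(path, index=False)
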