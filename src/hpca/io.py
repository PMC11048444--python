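"""HDF5 container and flat-file export for experiments and fitted models.

Layout of an experiment container::

    /spec                      JSON-serialised HierarchySpec (attribute)
    /subjects/<id>/data        V x N voxel-by-time matrix
    /subjects/<id>             attrs: cnr, sigma_s, sigma_n, tr_seconds
    /truth/maps                component x voxel group spatial maps
    /truth/timeseries/<id>     component x time per-subject series
    /compress/F_<id>, /compress/G, /compress/means_<id>, ...
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .compress import CompressionModel
from .simulate import GroundTruthSources, HierarchySpec, SubjectDataset

__all__ = [
    "save_experiment",
    "load_experiment",
    "save_compression",
    "load_compression",
    "export_npz",
    "write_newick",
]


def save_experiment(
    path: str | Path,
    spec: HierarchySpec,
    sources: GroundTruthSources,
    subjects: list[SubjectDataset],
) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["spec"] = spec.to_json()
        truth = f.create_group("truth")
        truth.create_dataset("maps", data=sources.spatial_maps)
        truth.create_dataset(
            "component_block",
            data=np.array(
                [(l, b, s, e) for (l, b, (s, e)) in sources.component_block],
                dtype=np.int64,
            ),
        )
        ts = truth.create_group("timeseries")
        grp = f.create_group("subjects")
        for s in subjects:
            g = grp.create_group(str(s.subject_id))
            g.create_dataset("data", data=s.data)
            g.attrs.update(
                cnr=s.cnr, sigma_s=s.sigma_s, sigma_n=s.sigma_n, tr_seconds=s.tr_seconds
            )
            if s.time_series is not None:
                ts.create_dataset(str(s.subject_id), data=s.time_series)


def load_experiment(path: str | Path):
    """Returns (spec, sources, subjects)."""
    with h5py.File(path, "r") as f:
        spec = HierarchySpec.from_json(f.attrs["spec"])
        blocks = [
            (int(l), int(b), (int(s), int(e)))
            for (l, b, s, e) in f["truth/component_block"][()]
        ]
        sources = GroundTruthSources(
            spatial_maps=f["truth/maps"][()], component_block=blocks
        )
        subjects = []
        for sid in sorted(f["subjects"], key=int):
            g = f["subjects"][sid]
            ts = f["truth/timeseries"].get(sid)
            subjects.append(
                SubjectDataset(
                    data=g["data"][()],
                    cnr=float(g.attrs["cnr"]),
                    sigma_s=float(g.attrs["sigma_s"]),
                    sigma_n=float(g.attrs["sigma_n"]),
                    tr_seconds=float(g.attrs["tr_seconds"]),
                    subject_id=int(sid),
                    time_series=ts[()] if ts is not None else None,
                )
            )
    return spec, sources, subjects


def save_compression(path: str | Path, model: CompressionModel, mode: str = "a") -> None:
    with h5py.File(path, mode) as f:
        if "compress" in f:
            del f["compress"]
        g = f.create_group("compress")
        g.create_dataset("G", data=model.group_basis)
        g.create_dataset("group_means", data=model.group_means)
        g.attrs.update(
            V=model.n_voxels,
            N=model.n_timepoints,
            C=model.n_subject_pcs,
            K=model.n_group_pcs,
            M=model.n_subjects,
        )
        for i, (F, mu) in enumerate(zip(model.subject_bases, model.subject_means)):
            g.create_dataset(f"F_{i}", data=F)
            g.create_dataset(f"means_{i}", data=mu)


def load_compression(path: str | Path) -> CompressionModel:
    with h5py.File(path, "r") as f:
        g = f["compress"]
        M = int(g.attrs["M"])
        return CompressionModel(
            subject_bases=[g[f"F_{i}"][()] for i in range(M)],
            subject_means=[g[f"means_{i}"][()] for i in range(M)],
            group_basis=g["G"][()],
            group_means=g["group_means"][()],
            n_voxels=int(g.attrs["V"]),
            n_timepoints=int(g.attrs["N"]),
            n_subject_pcs=int(g.attrs["C"]),
            n_group_pcs=int(g.attrs["K"]),
            n_subjects=M,
        )


def export_npz(path: str | Path, subjects: list[SubjectDataset], sources=None) -> None:
    """Flat NPZ export of the subject matrices (and truth maps if given)."""
    payload = {f"subject_{s.subject_id}": s.data for s in subjects}
    if sources is not None:
        payload["truth_maps"] = sources.spatial_maps
    np.savez_compressed(path, **payload)


def write_newick(path: str | Path, tree) -> None:
    Path(path).write_text(tree.to_newick() + "\n")
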