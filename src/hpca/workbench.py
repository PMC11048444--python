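"""Experiment orchestration: presets, end-to-end runs and NIfTI entry points.

``run_experiment`` executes simulate -> compress -> tree -> filter
(-> reconstruct -> evaluate) and writes a reproducible run directory whose
``summary.json`` is byte-identical across replays of the same configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluate as _evaluate
from . import io as _io
from .model import HierarchicalPCA
from .simulate import HierarchySpec, simulate_experiment

__all__ = ["RunConfig", "PRESETS", "preset_config", "run_experiment", "load_nifti_masked", "embed_map"]

logger = logging.getLogger("hpca")


@dataclass
class RunConfig:
    """Complete, replayable description of one experiment run."""

    name: str
    spec: HierarchySpec
    n_subjects: int = 100
    n_timepoints: int = 300
    tr: float = 2.0
    subject_pcs: int = 295
    group_pcs: int = 300
    gamma: float = 0.4
    alpha_fwe: float = 0.001
    orthogonalize: bool = True
    seed: int = 0
    reconstruct: bool = False
    evaluate_ica: bool = False
    save_dataset: bool = False
    out_dir: str = "runs"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["spec"] = json.loads(self.spec.to_json())
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        spec = d.pop("spec")
        if spec.get("dirichlet_alpha") is not None:
            spec["dirichlet_alpha"] = tuple(spec["dirichlet_alpha"])
        return cls(spec=HierarchySpec(**spec), **d)


def _preset_specs(seed: int) -> dict[str, HierarchySpec]:
    return {
        "5L2D": HierarchySpec(5, 2, 1024, "equal", seed=seed),
        "3L3D": HierarchySpec(3, 3, 1024, "equal", seed=seed),
        "3L3Ddirich": HierarchySpec(3, 3, 1024, "dirichlet", (3.0, 3.0, 3.0), seed=seed),
        "small": HierarchySpec(3, 2, 128, "equal", seed=seed),
    }


PRESETS = tuple(_preset_specs(0))


def preset_config(name: str, seed: int = 0, **overrides) -> RunConfig:
    """Named experiment presets with their standard parameters.

    ``5L2D``, ``3L3D`` and ``3L3Ddirich`` are the 100-subject, 1024-voxel,
    300-timepoint designs; ``small`` (V=128, M=10) is a fast configuration
    for smoke tests.
    """
    specs = _preset_specs(seed)
    if name not in specs:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(specs)}")
    base = dict(name=name, spec=specs[name], seed=seed)
    if name == "small":
        base.update(n_subjects=10, n_timepoints=150, subject_pcs=100, group_pcs=120)
    base.update(overrides)
    return RunConfig(**base)


def run_experiment(config: RunConfig) -> Path:
    """Execute all pipeline stages and persist results under a run directory.

    Returns the run directory.  Any stage failure raises a ``RuntimeError``
    naming the stage, after persisting the partial summary.
    """
    run_dir = Path(config.out_dir) / config.name
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    summary: dict = {"name": config.name, "seed": config.seed}
    timings: dict[str, float] = {}
    stage = "simulate"
    try:
        t0 = time.perf_counter()
        sources, subjects = simulate_experiment(
            config.spec,
            config.n_subjects,
            config.n_timepoints,
            config.tr,
            seed=config.seed,
        )
        summary["n_true_components"] = sources.n_components
        timings[stage] = time.perf_counter() - t0
        if config.save_dataset:
            _io.save_experiment(run_dir / "dataset.h5", config.spec, sources, subjects)

        stage = "fit"
        t0 = time.perf_counter()
        model = HierarchicalPCA(
            subjects,
            subject_pcs=config.subject_pcs,
            group_pcs=config.group_pcs,
            gamma=config.gamma,
            alpha_fwe=config.alpha_fwe,
        )
        res = model.fit()
        timings[stage] = time.perf_counter() - t0
        rep = res.report
        summary.update(
            base_level=rep.base_level,
            n_active=res.n_active,
            significant_levels=rep.significant_levels,
            unrelated_levels=rep.unrelated_levels,
            alpha_per_test=rep.alpha_per_test,
            n_levels=res.tree.n_levels,
        )
        res.level_table().to_csv(run_dir / "levels.csv", index=False)
        _io.write_newick(run_dir / "dendrogram.newick", res.tree)

        if config.reconstruct:
            stage = "reconstruct"
            t0 = time.perf_counter()
            maps = {}
            for level in rep.significant_levels:
                lm = res.reconstruct_level(level, orthogonalize=config.orthogonalize)
                maps[f"level_{level}"] = lm.group_map
            np.savez_compressed(run_dir / "group_maps.npz", **maps)
            timings[stage] = time.perf_counter() - t0

        if config.evaluate_ica:
            stage = "evaluate"
            t0 = time.perf_counter()
            # the ICA baseline gets its own reduction with K = model order
            from . import compress as _compress

            ica_cgd = _compress.compress_subjects(
                subjects, config.subject_pcs, sources.n_components
            )
            ica = _evaluate.run_ica_baseline(
                ica_cgd, sources.n_components, seed=config.seed
            )
            rows = []
            for i, s in enumerate(subjects):
                rows.append(
                    _evaluate.best_match(
                        sources.spatial_maps,
                        ica.maps,
                        method="ica",
                        subject=i,
                        domain="spatial",
                    )
                )
            import pandas as pd

            pd.concat(rows, ignore_index=True).to_csv(
                run_dir / "ica_matches.csv", index=False
            )
            timings[stage] = time.perf_counter() - t0
    except Exception as exc:  # persist partial state, then re-raise
        summary["failed_stage"] = stage
        (run_dir / "summary.json").write_text(
            json.dumps(summary, sort_keys=True, indent=1) + "\n"
        )
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    (run_dir / "summary.json").write_text(
        json.dumps(summary, sort_keys=True, indent=1) + "\n"
    )
    (run_dir / "run.log").write_text(
        "".join(f"{k}: {v:.2f} s\n" for k, v in timings.items())
    )
    logger.info("run %s complete: base level %s", config.name, summary["base_level"])
    return run_dir


def load_nifti_masked(volume_path: str | Path, mask_path: str | Path):
    """Flatten a 4-D NIfTI volume to voxel x time using a 3-D mask.

    Rows follow x-fastest (Fortran) linear order within the mask.  Returns
    ``(data, index)`` where ``index`` are the flat Fortran-order positions
    enabling exact re-embedding via :func:`embed_map`.
    """
    import nibabel as nib

    vol = nib.load(str(volume_path))
    msk = nib.load(str(mask_path))
    if vol.shape[:3] != msk.shape[:3] or not np.allclose(vol.affine, msk.affine):
        raise ValueError("volume and mask are not on the same grid")
    mask = np.asanyarray(msk.dataobj) > 0
    index = np.flatnonzero(mask.ravel(order="F"))
    if index.size == 0:
        raise ValueError("mask selects no voxels")
    data4d = np.asanyarray(vol.dataobj)
    if data4d.ndim != 4:
        raise ValueError("expected a 4-D volume")
    T = data4d.shape[3]
    flat = data4d.reshape(-1, T, order="F")
    return flat[index].astype(float), index


def embed_map(values: np.ndarray, mask_img) -> "object":
    """Re-embed a per-voxel vector into the mask's 3-D grid as a NIfTI image."""
    import nibabel as nib

    mask = np.asanyarray(mask_img.dataobj) > 0
    out = np.zeros(mask.size, dtype=float)
    out[np.flatnonzero(mask.ravel(order="F"))] = values
    vol = out.reshape(mask.shape, order="F")
    return nib.Nifti1Image(vol, mask_img.affine)
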