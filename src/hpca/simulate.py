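"""Multi-subject fMRI-like simulation with a nested block hierarchy.

Each experiment is defined by a recursive partition of ``V`` voxels: a root
block of all voxels is split into ``branching`` child blocks, each child is
split again, down to ``n_levels`` levels.  One latent network component is
attached to every block at every level, so a voxel at full depth carries one
component per ancestor level.  Per subject, noise-free data follow the linear
mixing model

    Z_nf = S D R

with spatial maps ``S`` (voxel x component), a diagonal amplitude matrix ``D``
and component time series ``R`` (component x time).  Component time courses
are Bernoulli(0.2) event trains convolved with a double-gamma HRF and
normalised to zero mean, unit peak-to-peak range.  Scanner noise is Rician:
``Z = Z_nf + sqrt(e1^2 + e2^2)`` with independent Gaussian ``e1, e2`` whose
standard deviation is set per subject from a contrast-to-noise ratio drawn
from U(0.65, 2).

Group spatial maps are unit-energy, spatially zero-mean block contrasts: a
block of ``B`` voxels gets weight ``1/sqrt(B)`` inside and a small negative
weight outside so each map sums to zero, then the map is rescaled to unit L2
norm.  Per-voxel amplitude therefore grows as the block shrinks, so small,
specialised networks are the most strongly correlated - the nested-block
structure seen in real functional connectivity.  See docs/methods.md for why
this construction (rather than flat 0/1 maps) is the one that produces the
intended redundancy structure across treelet levels.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .hrf import double_gamma_hrf

__all__ = [
    "HierarchySpec",
    "GroundTruthSources",
    "SubjectDataset",
    "count_components",
    "build_hierarchy_maps",
    "simulate_component_timeseries",
    "simulate_subject",
    "simulate_experiment",
    "group_correlation",
    "SimulationError",
    "InfeasibleSpecError",
]

#: Bernoulli event probability per TR for the neural event trains.
EVENT_RATE = 0.2
#: Standard deviation of the per-subject spatial-map perturbation.
MAP_NOISE_SD = 0.005
#: Mean and SD of the per-subject component amplitudes.
AMPLITUDE_MEAN, AMPLITUDE_SD = 1.0, 0.3
#: Range of the per-subject contrast-to-noise ratio.
CNR_LOW, CNR_HIGH = 0.65, 2.0


class SimulationError(RuntimeError):
    """Non-finite values produced during simulation."""


class InfeasibleSpecError(ValueError):
    """The hierarchy cannot be realised with the requested voxel count."""


def count_components(n_levels: int, branching: int) -> int:
    """Total number of network components in a full hierarchy.

    One component per block at every level: ``sum_{l=1..L} branching**l``.
    A binary five-level hierarchy has 2 + 4 + 8 + 16 + 32 = 62 components.
    """
    if n_levels < 1 or branching < 2:
        raise ValueError("need n_levels >= 1 and branching >= 2")
    return sum(branching**l for l in range(1, n_levels + 1))


@dataclass(frozen=True)
class HierarchySpec:
    """Declarative description of a nested block hierarchy."""

    n_levels: int
    branching: int
    n_voxels: int
    block_mode: str = "equal"
    dirichlet_alpha: tuple[float, ...] | None = None
    min_block: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.branching < 2:
            raise ValueError("branching must be >= 2")
        if self.block_mode not in ("equal", "dirichlet"):
            raise ValueError("block_mode must be 'equal' or 'dirichlet'")
        if self.min_block < 2:
            raise ValueError("min_block must be >= 2")
        if self.block_mode == "dirichlet":
            if self.dirichlet_alpha is None:
                raise ValueError("dirichlet mode requires dirichlet_alpha")
            object.__setattr__(
                self, "dirichlet_alpha", tuple(float(a) for a in self.dirichlet_alpha)
            )
            if len(self.dirichlet_alpha) != self.branching:
                raise ValueError("dirichlet_alpha must have length == branching")
            if any(a <= 0 for a in self.dirichlet_alpha):
                raise ValueError("dirichlet_alpha entries must be positive")
        if self.n_voxels < self.min_block * self.branching**self.n_levels:
            raise InfeasibleSpecError(
                f"{self.n_voxels} voxels cannot give every deepest block "
                f">= {self.min_block} voxels over "
                f"{self.branching ** self.n_levels} deepest blocks"
            )

    @property
    def n_components(self) -> int:
        return count_components(self.n_levels, self.branching)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_json(cls, payload: str) -> "HierarchySpec":
        d = json.loads(payload)
        if d.get("dirichlet_alpha") is not None:
            d["dirichlet_alpha"] = tuple(d["dirichlet_alpha"])
        return cls(**d)


@dataclass
class GroundTruthSources:
    """Ground-truth components of one simulated experiment.

    ``spatial_maps`` holds the group maps (component x voxel); each
    component's *support* (the voxels of its block) is recorded in
    ``component_block`` as ``(level, block_index, (start, stop))``.
    ``time_series`` and ``amplitudes`` are filled in per subject.
    """

    spatial_maps: np.ndarray
    component_block: list[tuple[int, int, tuple[int, int]]]
    amplitudes: np.ndarray | None = None
    time_series: np.ndarray | None = None

    @property
    def n_components(self) -> int:
        return self.spatial_maps.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.spatial_maps.shape[1]

    def supports(self) -> list[np.ndarray]:
        """Voxel index array for each component's block."""
        return [np.arange(s, e) for (_, _, (s, e)) in self.component_block]


@dataclass
class SubjectDataset:
    """One subject's voxel-by-time data plus its generative parameters."""

    data: np.ndarray
    cnr: float
    sigma_s: float
    sigma_n: float
    tr_seconds: float
    subject_id: int = 0
    noise_free: np.ndarray | None = field(default=None, repr=False)
    time_series: np.ndarray | None = field(default=None, repr=False)
    amplitudes: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]


def _split_sizes(n: int, spec: HierarchySpec, rng: np.random.Generator) -> list[int]:
    """Child block sizes for one branch point."""
    D = spec.branching
    if spec.block_mode == "equal":
        return [n // D + (1 if i < n % D else 0) for i in range(D)]
    # Dirichlet proportions -> largest-remainder apportionment; resample the
    # branch if any child would fall below min_block.
    for _ in range(1000):
        p = rng.dirichlet(spec.dirichlet_alpha)
        sizes = np.floor(p * n).astype(int)
        remainder = n - int(sizes.sum())
        order = np.argsort(-(p * n - sizes), kind="stable")
        for i in range(remainder):
            sizes[order[i % D]] += 1
        if (sizes >= spec.min_block).all():
            return [int(s) for s in sizes]
    raise InfeasibleSpecError(
        f"could not split a block of {n} voxels into {D} children of "
        f">= {spec.min_block} voxels"
    )


def build_hierarchy_maps(spec: HierarchySpec, rng=None) -> GroundTruthSources:
    """Construct the recursive block partition and group spatial maps.

    Returns a :class:`GroundTruthSources` whose ``spatial_maps`` rows are the
    unit-energy zero-mean block contrasts described in the module docstring.
    """
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    blocks = [(0, spec.n_voxels)]
    component_block: list[tuple[int, int, tuple[int, int]]] = []
    for level in range(1, spec.n_levels + 1):
        children: list[tuple[int, int]] = []
        for start, stop in blocks:
            sizes = _split_sizes(stop - start, spec, rng)
            c = start
            for size in sizes:
                if size < spec.min_block:
                    raise InfeasibleSpecError(
                        f"block of {size} voxels at level {level} is below "
                        f"min_block={spec.min_block}"
                    )
                children.append((c, c + size))
                c += size
        for idx, (s, e) in enumerate(children):
            component_block.append((level, idx, (s, e)))
        blocks = children

    V = spec.n_voxels
    S = np.zeros((len(component_block), V))
    for row, (_, _, (s, e)) in enumerate(component_block):
        S[row, s:e] = 1.0 / np.sqrt(e - s)
        S[row] -= S[row].mean()
        S[row] /= np.linalg.norm(S[row])
    return GroundTruthSources(spatial_maps=S, component_block=component_block)


def simulate_component_timeseries(
    n_components: int,
    n_timepoints: int,
    tr: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Event-driven BOLD-like component time courses.

    Each component's neural events are Bernoulli(0.2) per TR, convolved with
    the double-gamma HRF and normalised to zero mean and unit peak-to-peak
    range.  An all-zero event train (flat signal) cannot be normalised; such
    rows are resampled once and then raise :class:`SimulationError`.
    """
    if n_components < 1 or n_timepoints < 2 or tr <= 0:
        raise ValueError("counts must be positive and n_timepoints >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    kernel = double_gamma_hrf(tr)
    R = np.empty((n_components, n_timepoints))
    for c in range(n_components):
        for attempt in range(2):
            events = (rng.random(n_timepoints) < EVENT_RATE).astype(float)
            x = np.convolve(events, kernel)[:n_timepoints]
            ptp = x.max() - x.min()
            if ptp > 0:
                break
        else:
            raise SimulationError(f"degenerate all-zero event train for component {c}")
        x = x - x.mean()
        R[c] = x / ptp
    return R


def simulate_subject(
    sources: GroundTruthSources,
    spec: HierarchySpec,
    seed: int | np.random.Generator,
    n_timepoints: int = 300,
    tr: float = 2.0,
    subject_id: int = 0,
    map_noise_sd: float = MAP_NOISE_SD,
    amplitude_sd: float = AMPLITUDE_SD,
    cnr: float | None = None,
) -> SubjectDataset:
    """Simulate one subject from the shared group sources.

    Subject maps are the group maps plus elementwise N(0, map_noise_sd^2)
    perturbations; component time series and amplitudes are regenerated per
    subject; Rician scanner noise is added with sigma_n = sigma_s / CNR where
    sigma_s is the mean temporal SD of the noise-free data.
    """
    if sources.n_voxels != spec.n_voxels:
        raise ValueError("sources inconsistent with spec")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    S = sources.spatial_maps.T  # voxel x component
    Si = S + rng.normal(0.0, map_noise_sd, S.shape) if map_noise_sd > 0 else S.copy()
    d = rng.normal(AMPLITUDE_MEAN, amplitude_sd, S.shape[1])
    R = simulate_component_timeseries(S.shape[1], n_timepoints, tr, rng)
    Znf = (Si * d) @ R

    sigma_s = float(Znf.std(axis=1).mean())
    cnr = float(rng.uniform(CNR_LOW, CNR_HIGH)) if cnr is None else float(cnr)
    sigma_n = sigma_s / cnr
    if sigma_n > 0:
        e1 = rng.normal(0.0, sigma_n, Znf.shape)
        e2 = rng.normal(0.0, sigma_n, Znf.shape)
        Z = Znf + np.hypot(e1, e2)
    else:
        Z = Znf.copy()

    if not np.isfinite(Z).all():
        bad = np.argwhere(~np.isfinite(Z))[:5]
        raise SimulationError(f"non-finite simulated values at (voxel, t) {bad.tolist()}")
    return SubjectDataset(
        data=Z,
        noise_free=Znf,
        cnr=cnr,
        sigma_s=sigma_s,
        sigma_n=sigma_n,
        tr_seconds=tr,
        subject_id=subject_id,
        time_series=R,
        amplitudes=d,
    )


def simulate_experiment(
    spec: HierarchySpec,
    n_subjects: int,
    n_timepoints: int = 300,
    tr: float = 2.0,
    seed: int | None = None,
) -> tuple[GroundTruthSources, list[SubjectDataset]]:
    """Simulate a full multi-subject experiment.

    The hierarchy partition uses ``spec.seed`` (or ``seed`` when given), and
    each subject gets an independent child generator, so group structure is
    shared while subject dynamics are unique.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    root = np.random.default_rng(spec.seed if seed is None else seed)
    sources = build_hierarchy_maps(spec, rng=root)
    subject_rngs = root.spawn(n_subjects)
    subjects = [
        simulate_subject(
            sources, spec, subject_rngs[i], n_timepoints, tr, subject_id=i
        )
        for i in range(n_subjects)
    ]
    return sources, subjects


def group_correlation(subjects: list[SubjectDataset] | list[np.ndarray]) -> np.ndarray:
    """Subject-averaged voxel-by-voxel Pearson correlation matrix."""
    if len(subjects) == 0:
        raise ValueError("need at least one subject")
    mats = [s.data if isinstance(s, SubjectDataset) else np.asarray(s) for s in subjects]
    V = mats[0].shape[0]
    if any(m.shape[0] != V for m in mats):
        raise ValueError("all subjects must have the same number of voxels")
    acc = np.zeros((V, V))
    for i, Z in enumerate(mats):
        sd = Z.std(axis=1)
        if (sd == 0).any():
            voxel = int(np.flatnonzero(sd == 0)[0])
            raise ValueError(
                f"voxel {voxel} of subject {i} has zero variance; "
                "correlation undefined"
            )
        acc += np.corrcoef(Z)
    acc /= len(mats)
    np.fill_diagonal(acc, 1.0)
    return acc
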