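"""Artificial clinical data: perturb → simulate → sample → add noise.

Real clinical time-courses for single-fault signaling defects are not
available, so the study conditions are emulated: the model is run under a
single ground-truth perturbation, the designated outputs are sampled on a
regular grid (six points per hour by default), and each sampled value is
replaced by a draw from a Gaussian whose mean is the clean value and whose
standard deviation is a stated fraction of that value (20% by default).
Noise is independent across time points and outputs (white noise).

Negative draws are clamped at zero by default — concentrations cannot be
negative — and the choice is recorded on the dataset so the un-clamped
variant remains testable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace as _dc_replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .models import KineticModel, Perturbation, apply_perturbation
from .simulate import (SamplingSpec, Trajectory, read_trajectory, simulate,
                       write_trajectory)
from .similarity import trajectory_similarity

__all__ = ["ClinicalDataset", "add_noise", "generate_clinical",
           "select_representative", "thin", "write_clinical", "read_clinical"]

DEFAULT_NOISE_FRACTION = 0.2
DEFAULT_DENSITY = 6  # samples per hour


@dataclass(frozen=True)
class ClinicalDataset:
    """A noisy sampled time-course with its generation metadata."""

    trajectory: Trajectory
    noise_fraction: float
    seed: int | None
    truth: Perturbation | None
    source_model: str
    density_per_hour: int
    clamped: bool = True

    def __post_init__(self):
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")


def add_noise(traj: Trajectory, noise_fraction: float, seed: int | None, *,
              clamp: bool = True) -> Trajectory:
    """Signal-proportional Gaussian noise, seeded and reproducible.

    Each entry is independently replaced by a draw from
    Normal(mean = clean value, sd = noise_fraction * clean value); entries
    equal to zero keep sd = 0 and remain zero.  With ``clamp`` (default),
    negative draws are set to zero.
    """
    if noise_fraction < 0:
        raise ValueError(f"noise_fraction must be >= 0, got {noise_fraction}")
    if noise_fraction == 0:
        return traj
    rng = np.random.default_rng(seed)
    clean = traj.values
    noisy = clean + rng.standard_normal(clean.shape) * noise_fraction * clean
    if clamp:
        noisy = np.where(noisy < 0, 0.0, noisy)
    return Trajectory(times=traj.times, values=noisy,
                      output_names=traj.output_names)


def generate_clinical(model: KineticModel, truth: Perturbation,
                      noise_fraction: float = DEFAULT_NOISE_FRACTION,
                      spec: SamplingSpec | None = None,
                      seed: int | None = None, *,
                      clamp: bool = True) -> ClinicalDataset:
    """Simulate *model* under the ground-truth fault and add sampling noise."""
    if spec is None:
        spec = SamplingSpec(model.default_horizon_h, DEFAULT_DENSITY)
    clean = simulate(apply_perturbation(model, truth), spec)
    noisy = add_noise(clean, noise_fraction, seed, clamp=clamp)
    return ClinicalDataset(
        trajectory=noisy, noise_fraction=noise_fraction, seed=seed,
        truth=truth, source_model=model.name, density_per_hour=spec.density,
        clamped=clamp)


def select_representative(model: KineticModel, condition_kind: str,
                          fold_grid: Sequence[float],
                          spec: SamplingSpec | None = None,
                          sim_cache=None) -> Perturbation:
    """The candidate × fold whose noise-free profile differs most from normal.

    "Most different" is the lowest similarity S to the unperturbed profile
    (1 - S as the dissimilarity); ties break by candidate order then smaller
    fold.  The winner is the representative perturbation used to generate
    the clinical dataset for that abnormal condition.
    """
    from .faultscan import candidate_universe  # local import, no cycle at load

    folds = list(fold_grid)
    if not folds:
        raise ValueError("fold_grid must be nonempty")
    if spec is None:
        spec = SamplingSpec(model.default_horizon_h, DEFAULT_DENSITY)
    normal = simulate(model, spec)
    best: tuple[float, int, float, Perturbation] | None = None
    for ci, cand in enumerate(candidate_universe(model, condition_kind)):
        for fold in folds:
            p = Perturbation(condition_kind, cand, fold)
            if sim_cache is not None:
                traj = sim_cache.trajectory(p)
            else:
                traj = simulate(apply_perturbation(model, p), spec)
            s = trajectory_similarity(normal, traj)[0].S
            key = (s, ci, fold)
            if best is None or key < (best[0], best[1], best[2]):
                best = (s, ci, fold, p)
    assert best is not None
    return best[3]


def thin(dataset: ClinicalDataset, new_density: int) -> ClinicalDataset:
    """Restrict a dataset to a coarser divisor grid (t0 retained).

    The new density must divide the original one; no interpolation is ever
    performed.
    """
    old = dataset.density_per_hour
    if new_density < 1 or old % new_density != 0:
        raise ValueError(
            f"new density {new_density}/h must divide the original "
            f"{old}/h (no interpolation)")
    step = old // new_density
    if step == 1:
        return dataset
    traj = dataset.trajectory
    kept = Trajectory(times=traj.times[::step], values=traj.values[::step],
                      output_names=traj.output_names)
    return _dc_replace(dataset, trajectory=kept, density_per_hour=new_density)


# ---------------------------------------------------------------------------
# I/O: CSV (same dialect as Trajectory) plus a JSON metadata sidecar
# ---------------------------------------------------------------------------

def _sidecar_path(csv_path) -> Path:
    return Path(csv_path).with_suffix(".json")


def write_clinical(dataset: ClinicalDataset, csv_path) -> None:
    write_trajectory(dataset.trajectory, csv_path)
    meta = {
        "model": dataset.source_model,
        "truth": dataset.truth.to_dict() if dataset.truth else None,
        "noise_fraction": dataset.noise_fraction,
        "density_per_hour": dataset.density_per_hour,
        "seed": dataset.seed,
        "clamped": dataset.clamped,
    }
    with open(_sidecar_path(csv_path), "w") as fh:
        json.dump(meta, fh, indent=1)


def read_clinical(csv_path) -> ClinicalDataset:
    traj = read_trajectory(csv_path)
    side = _sidecar_path(csv_path)
    if side.exists():
        meta = json.loads(side.read_text())
    else:
        meta = {}
    truth = meta.get("truth")
    return ClinicalDataset(
        trajectory=traj,
        noise_fraction=meta.get("noise_fraction", 0.0),
        seed=meta.get("seed"),
        truth=Perturbation(**truth) if truth else None,
        source_model=meta.get("model", ""),
        density_per_hour=meta.get("density_per_hour",
                                  _infer_density(traj)),
        clamped=meta.get("clamped", True),
    )


def _infer_density(traj: Trajectory) -> int:
    dt = np.min(np.diff(traj.times))
    return int(round(1.0 / dt))
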