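"""The similarity score S between clinical and model-predicted profiles.

The sampled profiles of all measured outputs are concatenated into a single
column vector each (clinical and model), and

    S = shape_term * magnitude_term

where the shape term is the normalized inner product (cosine) of the two
stacked vectors and the magnitude term compares their means m_c and m_m:

    shape_term     = (y_c . y_m) / (||y_c|| ||y_m||)
    magnitude_term = 1 / ((m_c/m_m + m_m/m_c) / 2)
                   = 2 m_c m_m / (m_c^2 + m_m^2)

For nonnegative profiles S lies in [0, 1]; S = 1 exactly when the two
stacked profiles are equal.  Because outputs are concatenated raw, a
large-magnitude output dominates the combined S — per-output scores are
therefore reported alongside the combined one by the scanner.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import GridMismatchError, UndefinedSimilarityError
from .simulate import Trajectory

__all__ = ["StackedProfile", "SimilarityScore", "stack", "similarity",
           "trajectory_similarity"]


@dataclass(frozen=True)
class StackedProfile:
    """Profiles of several outputs concatenated in a fixed declared order."""

    values: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self):
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=float).ravel())

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SimilarityScore:
    """S and its two factors; ``S == shape_term * magnitude_term`` exactly."""

    S: float
    shape_term: float
    magnitude_term: float
    mean_clinical: float
    mean_model: float

    def __float__(self) -> float:
        return self.S


def stack(profiles: Mapping[str, np.ndarray] | Trajectory,
          order: Sequence[str]) -> StackedProfile:
    """Concatenate per-output profiles into one column vector.

    *profiles* is either a Trajectory or a mapping from output name to a
    1-D sample vector; all vectors must share the same grid length.  *order*
    must cover each declared output exactly once.
    """
    if isinstance(profiles, Trajectory):
        profiles = {o: profiles.column(o) for o in profiles.output_names}
    if sorted(order) != sorted(profiles):
        raise ValueError(f"order {list(order)} does not cover outputs "
                         f"{sorted(profiles)} exactly once")
    lengths = {name: len(np.asarray(profiles[name]).ravel()) for name in order}
    if len(set(lengths.values())) > 1:
        raise GridMismatchError(
            f"outputs sampled on different grids: {lengths}")
    vec = np.concatenate([np.asarray(profiles[name], dtype=float).ravel()
                          for name in order])
    return StackedProfile(values=vec, labels=tuple(order))


def similarity(clinical: StackedProfile | np.ndarray,
               model: StackedProfile | np.ndarray) -> SimilarityScore:
    """Similarity S between two stacked profiles (symmetric in its arguments).

    Raises :class:`UndefinedSimilarityError` for a zero-norm or
    nonpositive-mean input rather than silently returning 0; ranking callers
    map that error to S = 0 with a logged warning.
    """
    yc = clinical.values if isinstance(clinical, StackedProfile) \
        else np.asarray(clinical, dtype=float).ravel()
    ym = model.values if isinstance(model, StackedProfile) \
        else np.asarray(model, dtype=float).ravel()
    if yc.shape != ym.shape:
        raise GridMismatchError(
            f"stacked profiles differ in length: {len(yc)} vs {len(ym)}")
    nc, nm = np.linalg.norm(yc), np.linalg.norm(ym)
    mc, mm = float(np.mean(yc)), float(np.mean(ym))
    if nc == 0 or nm == 0:
        raise UndefinedSimilarityError(
            "similarity undefined for an all-zero profile")
    if mc <= 0 or mm <= 0:
        raise UndefinedSimilarityError(
            f"similarity undefined for nonpositive profile means "
            f"({mc:.3g}, {mm:.3g})")
    if np.array_equal(yc, ym):
        # identical profiles: both factors are exactly one
        return SimilarityScore(1.0, 1.0, 1.0, mc, mm)
    shape = float(yc @ ym / (nc * nm))
    mag = 2.0 * mc * mm / (mc * mc + mm * mm)
    return SimilarityScore(shape * mag, shape, mag, mc, mm)


def trajectory_similarity(clinical: Trajectory, model: Trajectory,
                          order: Sequence[str] | None = None
                          ) -> tuple[SimilarityScore, dict[str, float]]:
    """Combined and per-output S between two trajectories on the same grid.

    Returns ``(combined, per_output)`` where ``per_output`` maps each output
    name to the S computed from that output's profile alone.
    """
    if order is None:
        order = clinical.output_names
    if not clinical.same_grid(model):
        raise GridMismatchError(
            f"trajectories sampled on different grids "
            f"({len(clinical.times)} vs {len(model.times)} points)")
    combined = similarity(stack(clinical, order), stack(model, order))
    per_output = {}
    for o in order:
        try:
            per_output[o] = similarity(clinical.column(o), model.column(o)).S
        except UndefinedSimilarityError:
            per_output[o] = float("nan")
    return combined, per_output
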