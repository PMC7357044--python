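"""Variance-weighted goodness-of-fit between simulated and measured glucose.

The score is the root of a weighted sum of squared residuals between the
per-timepoint group mean glucose and the simulated glucose curve,

    epsilon(k) = sqrt( sum_i W_i (x_i - G_sim(t_i; k))^2 ),
    W_i = 1 / ( nu_i^2 * sum_j x_j^2 ),

where nu_i^2 is the between-animal sample variance at timepoint i.  A
large spread at a timepoint down-weights it: tightly clustered points are
the ones that must be hit.  Only glucose enters the score — insulin time
courses are not fitted.

Scores are comparable only *within* one dataset (the weights are built
from that dataset's means and variances); report utilities refuse to
aggregate scores across datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import InitialState, ModelParameters, PhysiologyRecord
from .simulate import DEFAULT_SETTINGS, SolverSettings, simulate

__all__ = ["OGTTDataset", "weights", "epsilon", "epsilon_from_curve"]


@dataclass(frozen=True)
class OGTTDataset:
    """Group-level OGTT summary: mean glucose and its variance per timepoint.

    ``variance`` is the between-animal sample variance (mg/dL)^2 at each
    timepoint; it must be strictly positive (a zero variance makes the
    fit weight undefined).  Timepoints are minutes after gavage, strictly
    increasing and positive.
    """

    group: str
    age: str
    timepoints: np.ndarray
    mean_glucose: np.ndarray
    variance: np.ndarray
    n_animals: Optional[int] = None
    variance_floored: bool = False

    def __post_init__(self) -> None:
        for name in ("timepoints", "mean_glucose", "variance"):
            object.__setattr__(
                self, name, np.asarray(getattr(self, name), dtype=float)
            )
        t, x, v = self.timepoints, self.mean_glucose, self.variance
        if not (t.shape == x.shape == v.shape) or t.ndim != 1 or t.size == 0:
            raise ValueError("timepoints, means and variances must be equal-length 1-D")
        if t[0] <= 0 or np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing and > 0")
        if np.any(v <= 0) or not np.all(np.isfinite(v)):
            raise ValueError(
                "variances must be strictly positive and finite "
                "(zero variance makes the weights undefined)"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("mean glucose values must be finite")
        if self.n_animals is not None and self.n_animals < 2:
            raise ValueError("n_animals must be >= 2 when given")

    @classmethod
    def from_points(
        cls,
        group: str,
        age: str,
        points,
        n_animals: Optional[int] = None,
        variance_floored: bool = False,
    ) -> "OGTTDataset":
        """Build from (time, mean, variance) triples in any order."""
        arr = sorted((float(t), float(x), float(v)) for t, x, v in points)
        t, x, v = zip(*arr)
        return cls(group, age, np.array(t), np.array(x), np.array(v),
                   n_animals=n_animals, variance_floored=variance_floored)

    @property
    def label(self) -> str:
        return f"{self.group}@{self.age}"


def weights(d: OGTTDataset) -> np.ndarray:
    """Per-timepoint fit weights W_i = 1 / (nu_i^2 * sum_j x_j^2)."""
    return 1.0 / (d.variance * np.sum(d.mean_glucose**2))


def epsilon_from_curve(d: OGTTDataset, glucose: np.ndarray) -> float:
    """Score a glucose curve already sampled at the dataset's timepoints."""
    glucose = np.asarray(glucose, dtype=float)
    if glucose.shape != d.timepoints.shape:
        raise ValueError("curve must be sampled at the dataset timepoints")
    r = d.mean_glucose - glucose
    return float(np.sqrt(np.sum(weights(d) * r * r)))


def epsilon(
    d: OGTTDataset,
    k: ModelParameters,
    s0: InitialState,
    phys: PhysiologyRecord,
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> float:
    """Goodness-of-fit of parameter set ``k`` against dataset ``d``.

    Zero iff the simulated glucose passes through every mean point.
    Propagates :class:`~ogttscan.simulate.IntegrationError` on solver
    failure (callers that scan parameter space score such sets +inf).
    """
    traj = simulate(k, s0, phys, grid=d.timepoints, settings=settings)
    return epsilon_from_curve(d, traj.G)
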