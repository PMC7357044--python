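"""One-parameter-at-a-time mechanistic hypothesis scanning.

The protocol: establish a reference (control) parameter set minimising
the weighted fit score on the control cohort, then — for a perturbed
cohort — refit exactly one parameter per mechanistic hypothesis while
freezing the other nine at their control values, and rank the hypotheses
by the resulting score.  The seven hypotheses map one-to-one onto model
parameters:

    H1.1  rCd    efficiency of insulin-dependent glucose withdrawal
    H1.2  p3     insulin action gain on the withdrawal rate
    H1.3  p2     decay rate of the withdrawal-rate variable
    H2    n      insulin degradation rate
    H3.1  gamma  slow-phase (glucose-driven) insulin release gain
    H3.2  p4     readily-releasable-pool release rate
    H3.3  h      glucose response threshold

A hypothesis whose refit cannot beat the control score is flagged
"no improvement" (rendered as "-" in reports).  Because the control
value always lies inside the search interval, a refit score can never
exceed the no-hypothesis score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import qmc

from .model import InitialState, ModelParameters, PhysiologyRecord
from .objective import OGTTDataset, epsilon
from .simulate import DEFAULT_SETTINGS, IntegrationError, SolverSettings

__all__ = [
    "HYPOTHESIS_PARAMETERS",
    "HYPOTHESIS_ORDER",
    "HypothesisSpec",
    "FitResult",
    "ScanReport",
    "FitError",
    "default_hypotheses",
    "default_bounds",
    "refit_one",
    "fit_control",
    "scan",
]

#: Fixed hypothesis-id -> parameter map.
HYPOTHESIS_PARAMETERS = {
    "H1.1": "rCd",
    "H1.2": "p3",
    "H1.3": "p2",
    "H2": "n",
    "H3.1": "gamma",
    "H3.2": "p4",
    "H3.3": "h",
}
HYPOTHESIS_ORDER = tuple(HYPOTHESIS_PARAMETERS)

_DESCRIPTIONS = {
    "H1.1": "withdrawal efficiency changes (rCd < 1: insulin resistance)",
    "H1.2": "insulin action on the withdrawal rate changes",
    "H1.3": "decay of the withdrawal rate changes",
    "H2": "insulin degradation rate changes",
    "H3.1": "slow-phase beta-cell response to glucose changes",
    "H3.2": "readily-releasable-pool release rate changes",
    "H3.3": "glucose response threshold changes",
}

#: Threshold-like parameters get a +/-50% interval instead of a decade
#: (a decade around a threshold near the state values leaves physiology).
_THRESHOLD_PARAMS = ("Gb", "h")

#: Score-equality tolerance for tie-breaking and improvement flags.
_EPS_TIE = 1e-9


class FitError(RuntimeError):
    """No successful model evaluation within the fitting budget."""


@dataclass(frozen=True)
class HypothesisSpec:
    """One mechanistic hypothesis: which parameter varies, and over what."""

    id: str
    parameter: str
    lo: float
    hi: float
    description: str = ""

    def __post_init__(self) -> None:
        expected = HYPOTHESIS_PARAMETERS.get(self.id)
        if expected is None:
            raise ValueError(
                f"unknown hypothesis id {self.id!r}; expected one of {HYPOTHESIS_ORDER}"
            )
        if self.parameter != expected:
            raise ValueError(
                f"hypothesis {self.id} varies {expected!r}, not {self.parameter!r}"
            )
        if not self.lo < self.hi:
            raise ValueError("search interval must satisfy lo < hi")


@dataclass(frozen=True)
class FitResult:
    """Outcome of one refit: fitted value, score and diagnostics."""

    hypothesis_id: str  # one of the H ids, or "no_hyp"
    parameter: Optional[str]
    fitted_value: Optional[float]
    epsilon: float
    parameters: ModelParameters
    n_evaluations: int = 0
    converged: bool = True
    improved: bool = False


def search_interval(parameter: str, control_value: float) -> tuple[float, float]:
    """Default search interval: a decade each way for rates and rCd,
    +/-50% for the threshold parameters."""
    if parameter in _THRESHOLD_PARAMS:
        return 0.5 * control_value, 1.5 * control_value
    if control_value <= 0:
        # a zero rate cannot anchor a multiplicative interval
        raise ValueError(
            f"cannot build a default interval around {parameter}={control_value}"
        )
    return control_value / 10.0, control_value * 10.0


def default_hypotheses(k_ctrl: ModelParameters) -> list[HypothesisSpec]:
    """All seven hypotheses with default intervals around ``k_ctrl``."""
    specs = []
    for hid, name in HYPOTHESIS_PARAMETERS.items():
        lo, hi = search_interval(name, getattr(k_ctrl, name))
        specs.append(HypothesisSpec(hid, name, lo, hi, _DESCRIPTIONS[hid]))
    return specs


def default_bounds(reference: ModelParameters) -> dict[str, tuple[float, float]]:
    """Per-parameter fitting box around a reference set (control fits).

    Rates span a decade each way; Gb and h span +/-50%; rCd is excluded
    (fixed at 1 for control fits).
    """
    bounds = {}
    for name in ("p1", "p2", "p3", "Ib", "n", "gamma", "p4", "Gb", "h"):
        v = getattr(reference, name)
        if name in _THRESHOLD_PARAMS:
            bounds[name] = (0.5 * v, 1.5 * v)
        else:
            bounds[name] = (v / 10.0, v * 10.0)
    return bounds


def _safe_epsilon(d, k, s0, phys, settings) -> float:
    try:
        return epsilon(d, k, s0, phys, settings)
    except IntegrationError:
        return math.inf


def refit_one(
    k_ctrl: ModelParameters,
    hyp: HypothesisSpec,
    d: OGTTDataset,
    s0: InitialState,
    phys: PhysiologyRecord,
    settings: SolverSettings = DEFAULT_SETTINGS,
    n_grid: int = 64,
) -> FitResult:
    """Bounded 1-D refit of the hypothesis parameter, others frozen.

    Deterministic: a coarse scan over the interval (log-spaced for
    positive intervals) brackets the best basin, then Brent refinement
    polishes it.  The control value itself is always a candidate, so the
    returned score never exceeds the no-hypothesis score.
    """
    ctrl_value = getattr(k_ctrl, hyp.parameter)
    if not (hyp.lo <= ctrl_value <= hyp.hi):
        raise ValueError(
            f"control value {ctrl_value} of {hyp.parameter} lies outside "
            f"[{hyp.lo}, {hyp.hi}]"
        )
    n_eval = 0

    def f(value: float) -> float:
        nonlocal n_eval
        n_eval += 1
        return _safe_epsilon(d, k_ctrl.replace(**{hyp.parameter: value}), s0, phys, settings)

    if hyp.lo > 0:
        grid = np.geomspace(hyp.lo, hyp.hi, n_grid)
    else:
        grid = np.linspace(hyp.lo, hyp.hi, n_grid)
    grid = np.unique(np.append(grid, ctrl_value))
    scores = np.array([f(v) for v in grid])
    order = np.argsort(scores, kind="stable")
    best_value = float(grid[order[0]])
    best_score = float(scores[order[0]])
    converged = True

    # polish the few best basins; the score can be near-flat or gently
    # multimodal along a single parameter, so one bracket is not enough
    for i in order[:3]:
        if not math.isfinite(scores[i]):
            continue
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid.size - 1)]
        if lo >= hi:
            continue
        res = minimize_scalar(
            f,
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": max(1e-12, 1e-10 * (hyp.hi - hyp.lo))},
        )
        converged = converged and bool(res.success)
        if res.fun < best_score:
            best_value, best_score = float(res.x), float(res.fun)

    eps_ctrl = f(ctrl_value)
    if eps_ctrl <= best_score:
        # optimizer found nothing better than the control value
        best_value, best_score = float(ctrl_value), float(eps_ctrl)
    improved = best_score < eps_ctrl - _EPS_TIE
    return FitResult(
        hypothesis_id=hyp.id,
        parameter=hyp.parameter,
        fitted_value=best_value,
        epsilon=best_score,
        parameters=k_ctrl.replace(**{hyp.parameter: best_value}),
        n_evaluations=n_eval,
        converged=converged,
        improved=improved,
    )


def fit_control(
    d: OGTTDataset,
    s0: InitialState,
    phys: PhysiologyRecord,
    bounds: Optional[dict[str, tuple[float, float]]] = None,
    reference: Optional[ModelParameters] = None,
    seed: int = 0,
    n_starts: int = 64,
    n_refine: int = 3,
    budget: int = 6000,
    settings: SolverSettings = DEFAULT_SETTINGS,
    return_details: bool = False,
):
    """Fit the nine free parameters to a control dataset (rCd fixed at 1).

    Latin-hypercube multi-start (log-scaled for rate-like parameters,
    linear for the thresholds) followed by local derivative-free
    refinement of the best starts.  Deterministic given ``seed``.  If a
    ``reference`` set is given (or ``bounds`` omitted, in which case the
    box is built around it), the reference is included as a candidate,
    so the returned score can never exceed the reference's score.
    """
    if bounds is None:
        if reference is None:
            raise ValueError("provide bounds or a reference parameter set")
        bounds = default_bounds(reference)
    names = list(bounds)
    log_scaled = [name not in _THRESHOLD_PARAMS for name in names]
    lo = np.array([bounds[n][0] for n in names], dtype=float)
    hi = np.array([bounds[n][1] for n in names], dtype=float)
    if np.any(lo >= hi) or np.any(lo <= 0):
        raise ValueError("bounds must satisfy 0 < lo < hi for every parameter")

    # transformed coordinates: log10 for rate-like parameters, linear otherwise
    t_lo = np.where(log_scaled, np.log10(lo), lo)
    t_hi = np.where(log_scaled, np.log10(hi), hi)

    n_eval = 0

    def build(z: np.ndarray) -> ModelParameters:
        vals = np.where(log_scaled, 10.0 ** np.asarray(z), z)
        return ModelParameters(**{**dict(zip(names, vals)), "rCd": 1.0})

    def f(z: np.ndarray) -> float:
        nonlocal n_eval
        if n_eval >= budget:
            return math.inf
        n_eval += 1
        try:
            return epsilon(d, build(z), s0, phys, settings)
        except (IntegrationError, ValueError):
            return math.inf

    sampler = qmc.LatinHypercube(d=len(names), seed=seed)
    starts = t_lo + sampler.random(n_starts) * (t_hi - t_lo)
    candidates = list(starts)
    if reference is not None:
        z_ref = np.array(
            [
                math.log10(getattr(reference, n)) if lg else getattr(reference, n)
                for n, lg in zip(names, log_scaled)
            ]
        )
        candidates.append(np.clip(z_ref, t_lo, t_hi))

    scored = [(f(z), i, z) for i, z in enumerate(candidates)]
    scored.sort(key=lambda t: (t[0], t[1]))
    if not math.isfinite(scored[0][0]):
        raise FitError("no parameter draw produced a successful simulation")

    best_score, _, best_z = scored[0]
    for score, _, z in scored[:n_refine]:
        if not math.isfinite(score) or n_eval >= budget:
            continue
        res = minimize(
            f,
            z,
            method="Powell",
            bounds=list(zip(t_lo, t_hi)),
            options={"maxfev": max(1, budget - n_eval), "xtol": 1e-8, "ftol": 1e-10},
        )
        if res.fun < best_score:
            best_score, best_z = float(res.fun), np.asarray(res.x)

    params = build(best_z)
    if reference is not None:
        # the transformed round trip perturbs the reference in the last
        # digits; honour the match-or-beat contract against the exact set
        eps_ref = _safe_epsilon(d, reference, s0, phys, settings)
        if eps_ref <= best_score:
            params, best_score = reference, eps_ref
    if not return_details:
        return params
    return params, FitResult(
        hypothesis_id="control",
        parameter=None,
        fitted_value=None,
        epsilon=float(best_score),
        parameters=params,
        n_evaluations=n_eval,
        converged=True,
    )


@dataclass(frozen=True)
class ScanReport:
    """Ranked outcome of a full hypothesis scan on one dataset."""

    dataset: str
    control_epsilon: float
    results: tuple[FitResult, ...]
    best: Optional[str] = field(default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "results", tuple(self.results))
        if self.best is None and self.results:
            object.__setattr__(self, "best", self.results[0].hypothesis_id)

    @staticmethod
    def merge(reports: Sequence["ScanReport"]) -> "ScanReport":
        """Combine scans *of the same dataset* (e.g. hypothesis subsets).

        Fit scores are dataset-specific — their weights are built from
        that dataset's means and variances — so merging or comparing
        scores across different datasets is meaningless and refused.
        """
        reports = list(reports)
        if not reports:
            raise ValueError("nothing to merge")
        labels = {r.dataset for r in reports}
        if len(labels) > 1:
            raise ValueError(
                "refusing to aggregate fit scores across datasets "
                f"({sorted(labels)}): the score is only comparable within one dataset"
            )
        results = [res for r in reports for res in r.results]
        return ScanReport(
            dataset=reports[0].dataset,
            control_epsilon=reports[0].control_epsilon,
            results=tuple(_rank(results)),
        )


def _rank(results: Sequence[FitResult]) -> list[FitResult]:
    """Ascending by score; ties (within 1e-9) broken by hypothesis order."""
    order = {hid: i for i, hid in enumerate(HYPOTHESIS_ORDER)}

    def key(r: FitResult):
        q = math.inf if math.isinf(r.epsilon) else round(r.epsilon / _EPS_TIE)
        return (q, order.get(r.hypothesis_id, len(order)))

    return sorted(results, key=key)


def scan(
    k_ctrl: ModelParameters,
    d: OGTTDataset,
    s0: InitialState,
    phys: PhysiologyRecord,
    hypotheses: Optional[Sequence[HypothesisSpec]] = None,
    settings: SolverSettings = DEFAULT_SETTINGS,
    n_grid: int = 64,
) -> ScanReport:
    """Refit every hypothesis against ``d`` and rank them by score.

    Per-hypothesis integration failures are scored +inf and do not abort
    the scan.  The report also carries the no-hypothesis (pure control)
    score for reference.
    """
    if hypotheses is None:
        hypotheses = default_hypotheses(k_ctrl)
    eps0 = _safe_epsilon(d, k_ctrl, s0, phys, settings)
    results = []
    for hyp in hypotheses:
        try:
            results.append(
                refit_one(k_ctrl, hyp, d, s0, phys, settings=settings, n_grid=n_grid)
            )
        except IntegrationError:
            results.append(
                FitResult(
                    hypothesis_id=hyp.id,
                    parameter=hyp.parameter,
                    fitted_value=None,
                    epsilon=math.inf,
                    parameters=k_ctrl,
                    converged=False,
                )
            )
    return ScanReport(dataset=d.label, control_epsilon=eps0, results=tuple(_rank(results)))
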