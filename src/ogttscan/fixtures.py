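"""Read-only registry of published rat OGTT constants.

Keys are post-natal day ("PND21", "PND26", "PND60") and exposure group
("control", "Cd1", "Cd2" — litters of dams with background, medium and
higher perinatal cadmium burden).  The registry carries, per age:
physiology (body mass, blood volume, the 2 mg/g gavage dose, and the
appearance-curve shape mu = 30 min, sigma = 35 min), the fasting initial
state, the reference (control) parameter set, the single-parameter
variants fitted to the exposed groups, cohort sizes, and the published
integer-rounded values of the dose-normalisation scale K.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

from .model import InitialState, ModelParameters, PhysiologyRecord

__all__ = [
    "AGES",
    "GROUPS",
    "get_physiology",
    "get_initial_state",
    "get_parameters",
    "cohort_size",
    "printed_K",
]

AGES = ("PND21", "PND26", "PND60")
GROUPS = ("control", "Cd1", "Cd2")


@lru_cache(maxsize=None)
def _load(name: str) -> dict:
    with resources.files(__package__).joinpath("data", name).open() as fh:
        return json.load(fh)


def _check_age(age: str) -> str:
    if age not in AGES:
        raise KeyError(f"unknown age {age!r}; expected one of {AGES}")
    return age


def get_physiology(age: str) -> PhysiologyRecord:
    """Physiology record for one age; K is derived at full precision."""
    return PhysiologyRecord(**_load(f"phys_{_check_age(age).lower()}.json"))


def get_initial_state(age: str) -> InitialState:
    """Fasting initial state determined for the control group at ``age``."""
    return InitialState(**_load(f"init_{_check_age(age).lower()}.json"))


def get_parameters(age: str, group: str = "control") -> ModelParameters:
    """Published parameter set for (age, group).

    Exposed-group sets equal the control set with the single
    best-hypothesis parameter replaced by its fitted value.
    """
    if group not in GROUPS:
        raise KeyError(f"unknown group {group!r}; expected one of {GROUPS}")
    return ModelParameters(
        **_load(f"params_{_check_age(age).lower()}_{group.lower()}.json")
    )


def cohort_size(age: str, group: str = "control") -> int:
    """Number of animals in the (group, age) cohort."""
    sizes = _load("cohort_sizes.json")
    if group not in sizes:
        raise KeyError(f"unknown group {group!r}; expected one of {GROUPS}")
    return int(sizes[group][_check_age(age)])


def printed_K(age: str) -> int:
    """Published integer-rounded dose-normalisation scale for ``age``."""
    return int(_load("printed_K.json")[_check_age(age)])
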