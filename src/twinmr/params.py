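"""Parameters with equality constraints via shared labels.

A structural model is a sparse collection of :class:`Parameter` objects.
Equality constraints are expressed by placing the *same* ``Parameter``
instance in several matrix cells; the label is the unit of identity, so a
model never contains two distinct objects with the same label.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field


class ConstraintError(ValueError):
    """Two parameters with one label disagree (value, bounds or free flag)."""


@dataclass
class Parameter:
    """A single (possibly shared) model parameter.

    Parameters
    ----------
    label : str
        Unique name; cells sharing a label share the value (equality
        constraint).
    value : float
        Current (or fixed) value.
    free : bool
        Whether the optimizer may move it.
    lower, upper : float
        Box bounds used by the optimizer and by profile-CI search.
    role : str
        One of ``loading``, ``regression``, ``correlation``, ``path``,
        ``variance``, ``mean``.  Only used to pick generic evaluation points
        for identification checks and to group output tables.
    """

    label: str
    value: float
    free: bool = True
    lower: float = -math.inf
    upper: float = math.inf
    role: str = "path"

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("parameter label must be non-empty")
        if not (self.lower <= self.value <= self.upper):
            raise ValueError(
                f"parameter {self.label}: value {self.value} outside "
                f"bounds [{self.lower}, {self.upper}]"
            )

    def set(self, value: float) -> None:
        if not self.free:
            raise ConstraintError(f"parameter {self.label} is fixed")
        self.value = float(value)


def fixed(label: str, value: float, role: str = "path") -> Parameter:
    """A parameter that never moves (identification constant)."""
    return Parameter(label, value, free=False, role=role)


def free(
    label: str,
    value: float,
    lower: float = -math.inf,
    upper: float = math.inf,
    role: str = "path",
) -> Parameter:
    return Parameter(label, value, free=True, lower=lower, upper=upper, role=role)


@dataclass
class ParameterSet:
    """Ordered registry enforcing one object per label."""

    _params: dict[str, Parameter] = field(default_factory=dict)

    def add(self, param: Parameter) -> Parameter:
        existing = self._params.get(param.label)
        if existing is None:
            self._params[param.label] = param
            return param
        if existing is not param:
            raise ConstraintError(
                f"label {param.label!r} bound to two distinct Parameter objects"
            )
        return existing

    def __getitem__(self, label: str) -> Parameter:
        return self._params[label]

    def __contains__(self, label: str) -> bool:
        return label in self._params

    def __iter__(self):
        return iter(self._params.values())

    def labels(self) -> list[str]:
        return list(self._params)

    def free_labels(self) -> list[str]:
        return [p.label for p in self._params.values() if p.free]
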