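"""Allometric conversions between fish length, weight and age.

Fish weight scales with body length as a power law, ``W = a * L**b``
(wet weight in grams, total length in centimetres).  Where a species
lacks measured coefficients, pooled defaults are used (``a = 0.01135``,
``b = 3.07``).  Three fixed empirical regressions fill in mean weight,
mean length and maximum age for species whose demographic parameters
were never measured directly; their coefficients are treated as
constants, not re-estimated.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "LengthWeightCoefficients",
    "DEFAULT_LW",
    "mean_weight_from_max_length",
    "mean_length_from_mean_weight",
    "max_age_from_max_length",
    "weight_from_length",
    "length_from_weight",
]

# Documentation constants: fit quality of the three fixed regressions
# (mean weight, mean length, max age).  Metadata only.
R_SQUARED = {"mean_weight": 0.74, "mean_length": 0.96, "max_age": 0.37}


@dataclass(frozen=True)
class LengthWeightCoefficients:
    """Coefficients of the weight-length power law ``W = a * L**b``.

    Defaults are the cross-species averages used whenever a species
    has no measured pair.
    """

    a: float = 0.01135
    b: float = 3.07

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValueError(
                f"length-weight coefficients must be positive, got a={self.a}, b={self.b}"
            )


DEFAULT_LW = LengthWeightCoefficients()


def _require_positive(value: float, name: str) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be positive, got {value!r}")


def mean_weight_from_max_length(max_length_cm: float) -> float:
    """Mean species weight (g) from maximum species length (cm).

    Fixed regression ``0.00654 * L**2.1675``.
    """
    _require_positive(max_length_cm, "max_length_cm")
    return 0.00654 * max_length_cm**2.1675


def mean_length_from_mean_weight(mean_weight_g: float) -> float:
    """Mean species length (cm) from mean species weight (g).

    Fixed regression ``4.7 * W**0.3184``.
    """
    _require_positive(mean_weight_g, "mean_weight_g")
    return 4.7 * mean_weight_g**0.3184


def max_age_from_max_length(max_length_cm: float) -> float:
    """Maximum species age (yr) from maximum species length (cm).

    Fixed regression ``1.333 * L**0.428``.
    """
    _require_positive(max_length_cm, "max_length_cm")
    return 1.333 * max_length_cm**0.428


def weight_from_length(
    length_cm: float, coeffs: LengthWeightCoefficients = DEFAULT_LW
) -> float:
    """Convert a length (cm) to wet weight (g) via ``W = a * L**b``."""
    _require_positive(length_cm, "length_cm")
    return coeffs.a * length_cm**coeffs.b


def length_from_weight(
    weight_g: float, coeffs: LengthWeightCoefficients = DEFAULT_LW
) -> float:
    """Convert a wet weight (g) to length (cm); exact inverse of
    :func:`weight_from_length` for the same coefficients."""
    _require_positive(weight_g, "weight_g")
    return (weight_g / coeffs.a) ** (1.0 / coeffs.b)
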