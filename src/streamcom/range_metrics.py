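"""Species range metrics: ubiquity, extent, tolerance, robustness.

Four complementary summaries of where and how often a species is
found:

* **Ubiquity** — percent of surveys within the species' known range in
  which it was actually caught: detectability inside the range.
* **Extent** — percent of conterminous-US HUC8 subbasins (of ~2200)
  the species occurs in: geographic range size.
* **Tolerance** — percent of randomly generated, covariance-matched
  streams whose occurrence model predicts presence: breadth of the
  environmental envelope, independent of geography.
* **Robustness** — the composite ``E**0.33 * T**0.33 * U**0.33``; high
  only when a species is widespread, environmentally flexible and
  easily found.

Random streams for Tolerance come from a multivariate normal with the
empirical covariate mean vector and covariance matrix, sampled via
Cholesky factorisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg

from .occurrence import COVARIATE_COLUMNS, OccurrenceModel, decision_threshold

__all__ = [
    "CONUS_HUC_TOTAL",
    "RangeMetrics",
    "ubiquity",
    "extent",
    "sample_covariates",
    "tolerance",
    "robustness",
]

#: Estimated number of HUC8 subbasins in the conterminous US.
CONUS_HUC_TOTAL = 2200

#: Exponent of each factor in the robustness composite (kept at the
#: published two-decimal value, not 1/3).
ROBUSTNESS_EXPONENT = 0.33


@dataclass(frozen=True)
class RangeMetrics:
    """The four range metrics for one species; tolerance and
    robustness are absent when the species has no occurrence model."""

    ubiquity: float
    extent: float
    tolerance: float | None = None
    robustness: float | None = None
    conus_huc_total: int = CONUS_HUC_TOTAL


def ubiquity(n_found: int, n_surveys_in_range: int) -> float:
    """Percent of in-range surveys where the species was caught."""
    if n_surveys_in_range <= 0:
        raise ValueError("n_surveys_in_range must be positive")
    if not 0 <= n_found <= n_surveys_in_range:
        raise ValueError(
            f"n_found ({n_found}) must lie in [0, {n_surveys_in_range}]"
        )
    return 100.0 * n_found / n_surveys_in_range


def extent(n_hucs: int, conus_huc_total: int = CONUS_HUC_TOTAL) -> float:
    """Percent of conterminous-US HUC8s the species occurs in."""
    if n_hucs < 0:
        raise ValueError("n_hucs must be non-negative")
    if conus_huc_total <= 0:
        raise ValueError("conus_huc_total must be positive")
    return 100.0 * n_hucs / conus_huc_total


def sample_covariates(
    covariance: np.ndarray,
    means: np.ndarray,
    n: int = 10_000,
    seed: int | None = None,
    clip_unit_interval: bool = True,
) -> pd.DataFrame:
    """Draw ``n`` random streams matching an empirical covariate
    covariance structure.

    Draws ``means + L z`` with ``L`` the lower Cholesky factor of the
    covariance matrix and ``z`` standard normal.  With
    ``clip_unit_interval`` (default) the bounded covariates IWI and
    BMMI are clipped to [0, 1] after sampling; pass ``False`` for raw
    Gaussian draws.
    """
    covariance = np.asarray(covariance, dtype=float)
    means = np.asarray(means, dtype=float)
    k = len(COVARIATE_COLUMNS)
    if covariance.shape != (k, k):
        raise ValueError(f"covariance must be {k}x{k}, got {covariance.shape}")
    if means.shape != (k,):
        raise ValueError(f"means must have length {k}, got {means.shape}")
    if not np.allclose(covariance, covariance.T):
        raise ValueError("covariance matrix must be symmetric")
    try:
        chol = scipy.linalg.cholesky(covariance, lower=True)
    except scipy.linalg.LinAlgError as err:
        raise ValueError(
            f"covariance matrix is not positive definite: Cholesky "
            f"factorization failed ({err})"
        ) from err

    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, k))
    draws = means + z @ chol.T
    frame = pd.DataFrame(draws, columns=COVARIATE_COLUMNS)
    if clip_unit_interval:
        frame["iwi"] = frame["iwi"].clip(0.0, 1.0)
        frame["bmmi"] = frame["bmmi"].clip(0.0, 1.0)
    return frame


def tolerance(
    model: OccurrenceModel,
    sampled_streams: pd.DataFrame,
    decision_threshold_value: str | float = 0.5,
) -> float:
    """Percent of sampled streams where the model predicts presence.

    The cutoff defaults to a fixed 0.5; pass 'mean' or 'robust' to use
    the species' own threshold rule instead — this choice materially
    changes the value and should be reported alongside it.
    """
    if len(sampled_streams) == 0:
        raise ValueError("sampled_streams must be non-empty")
    prob = model.predict_probability(sampled_streams)
    cutoff = decision_threshold(model.threshold_stats, decision_threshold_value)
    return 100.0 * float((prob >= cutoff).mean())


def robustness(
    extent_pct: float | None,
    tolerance_pct: float | None,
    ubiquity_pct: float | None,
) -> float | None:
    """Composite ``E**0.33 * T**0.33 * U**0.33``; ``None`` (not zero)
    when any component is missing."""
    components = (extent_pct, tolerance_pct, ubiquity_pct)
    if any(c is None for c in components):
        return None
    if any(c < 0 for c in components):  # type: ignore[operator]
        raise ValueError("range metric components must be non-negative")
    return float(
        np.prod([c**ROBUSTNESS_EXPONENT for c in components])
    )
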