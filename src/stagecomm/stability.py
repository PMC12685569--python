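"""Eigenvalue-based stability classification, analytic criteria and
Monte-Carlo stability ensembles.

A community is locally asymptotically stable when every eigenvalue of its
(structured) community matrix has negative real part.  Marginal eigenvalues
(real part within ``tol_zero`` of zero) are counted as *not* stable, matching
the strict "all real parts negative" rule.

The analytic layer implements the classical criteria: a large random community
is stable with probability approaching one when the scaled interaction
strength gamma = kappa(type, S, C) * sigma is below the self-regulation d
(circular law for the random type, elliptic law for typed interactions).  The
Monte-Carlo layer estimates the same transition by direct eigensolves of
generated ensembles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .assembly import (
    StructuredCommunityMatrix,
    StructuredConfig,
    assemble_k_stage,
    gamma_coefficient,
)
from .errors import ConfigurationError, NumericalError
from .random_community import (
    CommunityConfig,
    CommunityMatrix,
    InteractionType,
    build_community_matrix,
)

__all__ = [
    "TOL_ZERO",
    "StabilityResult",
    "EnsembleResult",
    "GridResult",
    "CriterionResult",
    "classify_stability",
    "may_criterion",
    "elliptic_criterion",
    "ensemble_stability",
    "ensemble_from_factory",
    "stability_grid",
    "grid_from_factory",
    "estimate_critical_gamma",
    "classify_structure_effect",
    "derive_seeds",
]

#: Stability tolerance: stable iff max real part < -TOL_ZERO.  Real parts in
#: [-TOL_ZERO, TOL_ZERO] are marginal and conservatively counted unstable.
TOL_ZERO = 1e-10


@dataclass(frozen=True)
class StabilityResult:
    spectrum: np.ndarray
    lambda_max_real: float
    stable: bool


@dataclass(frozen=True)
class CriterionResult:
    """Analytic stability prediction: stable iff gamma < d."""

    label: str
    gamma: float
    d: float

    @property
    def predicted_stable(self) -> bool:
        return self.gamma < self.d


@dataclass(frozen=True)
class EnsembleResult:
    n_reps: int
    proportion_stable: float
    lambda_max_real: np.ndarray
    seed: int


@dataclass(frozen=True)
class GridResult:
    """Proportion of stable communities over a (gamma2, gamma3) lattice.

    ``proportions[i, j]`` corresponds to ``(gamma2_values[i],
    gamma3_values[j])``.
    """

    gamma2_values: np.ndarray
    gamma3_values: np.ndarray
    proportions: np.ndarray
    n_reps: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        g2, g3 = np.meshgrid(self.gamma2_values, self.gamma3_values,
                             indexing="ij")
        return pd.DataFrame({
            "gamma2": g2.ravel(),
            "gamma3": g3.ravel(),
            "proportion_stable": self.proportions.ravel(),
        })


def _entries_of(matrix) -> tuple[np.ndarray, int]:
    """Extract the dense array and the structural-zero count of any of the
    accepted matrix representations."""
    if isinstance(matrix, StructuredCommunityMatrix):
        return matrix.entries, matrix.n_structural_zeros
    if isinstance(matrix, CommunityMatrix):
        return matrix.entries, 0
    a = np.asarray(matrix, dtype=float)
    return a, 0


def classify_stability(matrix, tol_zero: float = TOL_ZERO,
                       n_structural_zeros: int | None = None
                       ) -> StabilityResult:
    """Classify local asymptotic stability from the full spectrum.

    ``matrix`` may be a plain square array, a :class:`CommunityMatrix` or a
    :class:`StructuredCommunityMatrix`.  ``n_structural_zeros`` exact zero
    eigenvalues (introduced by stage-count padding) are discounted before the
    verdict; by default the count recorded on the structured matrix is used.
    """
    entries, default_zeros = _entries_of(matrix)
    if entries.ndim != 2 or entries.shape[0] != entries.shape[1]:
        raise ConfigurationError("stability requires a square matrix")
    if n_structural_zeros is None:
        n_structural_zeros = default_zeros
    spectrum = np.linalg.eigvals(entries)
    considered = spectrum
    if n_structural_zeros > 0:
        order = np.argsort(np.abs(spectrum))
        dropped = spectrum[order[:n_structural_zeros]]
        if np.any(np.abs(dropped) > 1e-8):
            raise NumericalError(
                "structural-zero exclusion would drop a nonzero eigenvalue")
        considered = spectrum[order[n_structural_zeros:]]
    lam = float(considered.real.max())
    return StabilityResult(spectrum=spectrum, lambda_max_real=lam,
                           stable=lam < -tol_zero)


def may_criterion(sigma: float, S: int, C: float, d: float = 1.0
                  ) -> CriterionResult:
    """Circular-law criterion: gamma = sigma * sqrt(S C) < d."""
    if sigma < 0 or d <= 0:
        raise ConfigurationError("need sigma >= 0 and d > 0")
    gamma = sigma * np.sqrt(S * C)
    return CriterionResult(label="may", gamma=float(gamma), d=d)


_ELLIPTIC_LABELS = {
    InteractionType.MUTUALISM: "mutualistic",
    InteractionType.COMPETITION: "competitive",
    InteractionType.PREDATION: "predator_prey",
}


def elliptic_criterion(interaction_type: InteractionType | str, sigma: float,
                       S: int, C: float, d: float = 1.0) -> CriterionResult:
    """Elliptic-law criterion for a typed community: gamma_type < d, with the
    type-specific coefficient of :func:`~stagecomm.assembly.gamma_coefficient`.
    """
    itype = InteractionType.coerce(interaction_type)
    if itype not in _ELLIPTIC_LABELS:
        raise ConfigurationError(
            f"elliptic criterion defined for {sorted(t.value for t in _ELLIPTIC_LABELS)}, "
            f"got {itype.value!r}")
    if sigma < 0 or d <= 0:
        raise ConfigurationError("need sigma >= 0 and d > 0")
    gamma = sigma * gamma_coefficient(itype, S, C)
    return CriterionResult(label=_ELLIPTIC_LABELS[itype], gamma=float(gamma), d=d)


def derive_seeds(seed: int, n: int) -> list[int]:
    """n independent 31-bit child seeds derived from one top-level seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] & 0x7FFFFFFF)
            for child in ss.spawn(n)]


def _build(config) -> CommunityMatrix | StructuredCommunityMatrix:
    if isinstance(config, StructuredConfig):
        return assemble_k_stage(config)
    if isinstance(config, CommunityConfig):
        return build_community_matrix(config)
    raise ConfigurationError(
        f"cannot build a matrix from {type(config).__name__}")


def ensemble_from_factory(factory: Callable[[int], object], n_reps: int,
                          seed: int, tol_zero: float = TOL_ZERO
                          ) -> EnsembleResult:
    """Monte-Carlo ensemble over matrices produced by ``factory(rep_seed)``.

    ``factory`` receives one derived 31-bit seed per replicate and returns
    any matrix representation accepted by :func:`classify_stability`.
    """
    if n_reps < 1:
        raise ConfigurationError("n_reps: must be >= 1")
    lams = np.empty(n_reps)
    n_stable = 0
    for k, rep_seed in enumerate(derive_seeds(seed, n_reps)):
        result = classify_stability(factory(rep_seed), tol_zero)
        lams[k] = result.lambda_max_real
        n_stable += result.stable
    return EnsembleResult(n_reps=n_reps,
                          proportion_stable=n_stable / n_reps,
                          lambda_max_real=lams, seed=seed)


def ensemble_stability(config, n_reps: int = 1000, seed: int = 0,
                       tol_zero: float = TOL_ZERO) -> EnsembleResult:
    """Proportion of stable communities among ``n_reps`` independent draws of
    ``config`` (a :class:`CommunityConfig` or :class:`StructuredConfig`).

    The default replicate count follows the ensemble size used for the phase
    diagrams (10^3); pass a smaller value for quick exploration.
    """
    if not isinstance(config, (StructuredConfig, CommunityConfig)):
        raise ConfigurationError(
            f"cannot build a matrix from {type(config).__name__}")
    return ensemble_from_factory(
        lambda s: _build(replace(config, seed=s)), n_reps, seed, tol_zero)


def grid_from_factory(
    factory: Callable[[float, float, int], object],
    gamma2_values: Sequence[float],
    gamma3_values: Sequence[float],
    n_reps: int,
    seed: int,
    tol_zero: float = TOL_ZERO,
) -> GridResult:
    """Stability grid over a (gamma2, gamma3) lattice for matrices produced
    by ``factory(gamma2, gamma3, rep_seed)``.

    Cell seeds are derived deterministically from ``seed`` and the cell index,
    so results are independent of evaluation order.
    """
    g2 = np.asarray(list(gamma2_values), dtype=float)
    g3 = np.asarray(list(gamma3_values), dtype=float)
    if g2.size == 0 or g3.size == 0:
        raise ConfigurationError("grid axes must be non-empty")
    cell_seeds = derive_seeds(seed, g2.size * g3.size)
    props = np.empty((g2.size, g3.size))
    for i, gamma2 in enumerate(g2):
        for j, gamma3 in enumerate(g3):
            cell_seed = cell_seeds[i * g3.size + j]
            res = ensemble_from_factory(
                lambda s, a=gamma2, b=gamma3: factory(a, b, s),
                n_reps, cell_seed, tol_zero)
            props[i, j] = res.proportion_stable
    return GridResult(gamma2_values=g2, gamma3_values=g3, proportions=props,
                      n_reps=n_reps, seed=seed)


def stability_grid(base_config: StructuredConfig,
                   gamma2_values: Sequence[float],
                   gamma3_values: Sequence[float],
                   n_reps: int = 1000, seed: int = 0,
                   tol_zero: float = TOL_ZERO) -> GridResult:
    """Proportion of stable structured communities over a (gamma2, gamma3)
    lattice, varying the two cross blocks of a K = 2 configuration."""

    def factory(gamma2: float, gamma3: float, rep_seed: int):
        cfg = base_config.with_cross_strengths(gamma2, gamma3)
        return assemble_k_stage(replace(cfg, seed=rep_seed))

    return grid_from_factory(factory, gamma2_values, gamma3_values,
                             n_reps, seed, tol_zero)


def estimate_critical_gamma(
    config_for_gamma: Callable[[float], object],
    gamma_values: Sequence[float],
    n_reps: int = 200,
    seed: int = 0,
    tol_zero: float = TOL_ZERO,
) -> float:
    """Locate the stability transition: the gamma at which the proportion of
    stable communities crosses 1/2, by a monotone scan over ``gamma_values``
    (ascending) with linear interpolation between the bracketing grid points.

    ``config_for_gamma`` maps a gamma value to a buildable config (or to a
    factory accepted by :func:`ensemble_from_factory` when callable).
    """
    gammas = np.asarray(list(gamma_values), dtype=float)
    if gammas.size < 2 or np.any(np.diff(gammas) <= 0):
        raise ConfigurationError(
            "gamma_values: need an ascending scan of at least two points")
    point_seeds = derive_seeds(seed, gammas.size)
    props = np.empty(gammas.size)
    for k, gamma in enumerate(gammas):
        cfg = config_for_gamma(float(gamma))
        if callable(cfg):
            res = ensemble_from_factory(cfg, n_reps, point_seeds[k], tol_zero)
        else:
            res = ensemble_stability(cfg, n_reps, point_seeds[k], tol_zero)
        props[k] = res.proportion_stable
    for k in range(gammas.size - 1):
        if props[k] >= 0.5 > props[k + 1]:
            span = props[k] - props[k + 1]
            frac = (props[k] - 0.5) / span
            return float(gammas[k] + frac * (gammas[k + 1] - gammas[k]))
    raise NumericalError(
        f"no 0.5-crossing of the stability proportion in the scanned range: "
        f"proportions {np.round(props, 3).tolist()} over gammas "
        f"{gammas.tolist()}")


def classify_structure_effect(structured, unstructured,
                              n_reps: int | None = None) -> str:
    """Compare stable regions of a structured and an unstructured model on a
    common parameter lattice.

    ``structured`` and ``unstructured`` are :class:`GridResult` objects or
    arrays of stability proportions (the unstructured one may be a scalar,
    broadcast over the lattice).  Returns ``"stabilising"`` when the
    structured stable region strictly gains lattice cells, ``"destabilising"``
    when it strictly loses cells, and ``"neutral"`` when the regions coincide
    within the Monte-Carlo tolerance ``2 / sqrt(n_reps)``.
    """
    if isinstance(structured, GridResult):
        if n_reps is None:
            n_reps = structured.n_reps
        structured = structured.proportions
    if isinstance(unstructured, GridResult):
        unstructured = unstructured.proportions
    structured = np.asarray(structured, dtype=float)
    unstructured = np.broadcast_to(
        np.asarray(unstructured, dtype=float), structured.shape)
    if n_reps is None:
        raise ConfigurationError("n_reps required for the tolerance window")
    tol = 2.0 / np.sqrt(n_reps)
    gained = (structured > 0.5) & (unstructured <= 0.5) \
        & (structured - unstructured > tol)
    lost = (unstructured > 0.5) & (structured <= 0.5) \
        & (unstructured - structured > tol)
    if gained.any() and lost.any():
        raise NumericalError(
            "mixed effect: the structured model both gains and loses stable "
            "regions on this lattice")
    if gained.any():
        return "stabilising"
    if lost.any():
        return "destabilising"
    return "neutral"
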