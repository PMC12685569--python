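"""Explicit stage-structured ODE systems and the change of variables.

This module is the ground-truth layer behind the random-matrix ensembles: it
works with concrete stage-structured dynamics

    dN_ik/dt = g_ik(N_11, ..., N_SK),

performs the change of variables to total densities N_i = sum_k N_ik and
stage fractions Z_ik = N_ik / N_i (k = 1..K-1), and computes the Jacobian of
the transformed system at a feasible equilibrium numerically.  That Jacobian
*is* a structured community matrix, so the block interpretation and the
stability verdicts of the random-matrix layer can be cross-checked against
explicit dynamics.

State layouts are stage-major throughout, matching the assembler: flat index
``k * S + i`` (0-based) addresses stage k of species i, and the transformed
state vector is ``[N_1..N_S, Z_11..Z_S1, ..., Z_1,K-1..Z_S,K-1]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .assembly import StructuredCommunityMatrix
from .errors import ConfigurationError, NumericalError

__all__ = [
    "StageODESystem",
    "AggregatedState",
    "EquilibriumPoint",
    "aggregate",
    "disaggregate",
    "transformed_rhs",
    "transformed_rhs_flat",
    "numerical_jacobian",
    "find_equilibrium",
    "stage_space_jacobian",
    "structured_matrix_from_system",
    "trajectory_equivalence_error",
    "lv_two_stage_system",
    "two_species_fixture",
]


@dataclass
class StageODESystem:
    """A community of S species with K stages and explicit growth rates.

    ``rhs`` maps a flat stage-major state (length S*K, nonnegative) to the
    per-stage growth rates g_ik in the same layout.  ``params`` records the
    named parameter values used to build the rhs, for manifests and symbolic
    cross-checks.
    """

    S: int
    K: int
    rhs: Callable[[np.ndarray], np.ndarray]
    params: dict = field(default_factory=dict)

    def rhs_matrix(self, stage_state: np.ndarray) -> np.ndarray:
        """Growth rates as an (S, K) array from an (S, K) state."""
        flat = np.asarray(stage_state, dtype=float).reshape(self.S, self.K)
        g = self.rhs(flat.ravel(order="F"))
        return np.asarray(g).reshape(self.S, self.K, order="F")


@dataclass(frozen=True)
class AggregatedState:
    """Totals N_i and stage fractions Z_ik (k = 1..K-1) of a community.

    The K-th fraction is implicit: Z_iK = 1 - sum_{k<K} Z_ik.
    """

    totals: np.ndarray          # (S,)
    fractions: np.ndarray       # (S, K-1)

    @property
    def S(self) -> int:
        return self.totals.shape[0]

    @property
    def K(self) -> int:
        return self.fractions.shape[1] + 1

    def to_vector(self) -> np.ndarray:
        """Flat stage-major vector [N; Z_.1; ...; Z_.,K-1]."""
        return np.concatenate([self.totals, self.fractions.ravel(order="F")])

    @classmethod
    def from_vector(cls, y: np.ndarray, S: int, K: int) -> "AggregatedState":
        y = np.asarray(y, dtype=float)
        if y.shape != (S * K,):
            raise ConfigurationError(f"state vector: expected length {S * K}")
        totals = y[:S].copy()
        fractions = y[S:].reshape(S, K - 1, order="F").copy()
        return cls(totals=totals, fractions=fractions)


@dataclass(frozen=True)
class EquilibriumPoint:
    """A feasible fixed point: strictly positive stage densities with a small
    rhs residual."""

    stage_densities: np.ndarray     # (S, K)
    residual_norm: float


def aggregate(stage_state: np.ndarray) -> AggregatedState:
    """Change of variables (S, K) stage densities -> totals and fractions."""
    N = np.asarray(stage_state, dtype=float)
    if N.ndim != 2:
        raise ConfigurationError("stage_state: expected an (S, K) array")
    if np.any(N < 0):
        raise ConfigurationError("stage_state: densities must be >= 0")
    totals = N.sum(axis=1)
    if np.any(totals <= 0):
        raise ConfigurationError(
            "aggregate undefined for species with zero total density")
    fractions = N[:, :-1] / totals[:, None]
    return AggregatedState(totals=totals, fractions=fractions)


def disaggregate(state: AggregatedState) -> np.ndarray:
    """Inverse change of variables -> (S, K) stage densities."""
    z_last = 1.0 - state.fractions.sum(axis=1)
    if np.any(state.fractions < -1e-12) or np.any(z_last < -1e-12):
        raise ConfigurationError(
            "fractions must lie in [0, 1] with a nonnegative complement")
    Z = np.column_stack([state.fractions, z_last])
    return state.totals[:, None] * Z


def transformed_rhs(system: StageODESystem, state: AggregatedState
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Growth rates of the transformed system.

    Returns ``(dN, dZ)`` with ``dN_i = sum_k g_ik`` and
    ``dZ_ik = (g_ik - Z_ik * sum_l g_il) / N_i`` for k = 1..K-1 -- the chain
    rule applied to the definition of totals and fractions.
    """
    if np.any(state.totals <= 0):
        raise ConfigurationError("transformed rhs undefined at zero totals")
    stage = disaggregate(state)
    g = system.rhs_matrix(stage)
    dN = g.sum(axis=1)
    dZ = (g[:, :-1] - state.fractions * dN[:, None]) / state.totals[:, None]
    return dN, dZ


def transformed_rhs_flat(system: StageODESystem
                         ) -> Callable[[np.ndarray], np.ndarray]:
    """The transformed rhs as a flat-vector function, for Jacobians and
    integrators."""

    def f(y: np.ndarray) -> np.ndarray:
        state = AggregatedState.from_vector(y, system.S, system.K)
        dN, dZ = transformed_rhs(system, state)
        return np.concatenate([dN, dZ.ravel(order="F")])

    return f


def numerical_jacobian(f: Callable[[np.ndarray], np.ndarray],
                       point: np.ndarray,
                       rel_step: float | None = None) -> np.ndarray:
    """Central finite-difference Jacobian of ``f`` at ``point``.

    Per-coordinate step ``h_i = rel_step * max(1, |x_i|)`` with the default
    ``rel_step = sqrt(machine epsilon)``.
    """
    x = np.asarray(point, dtype=float)
    if rel_step is None:
        rel_step = float(np.sqrt(np.finfo(float).eps))
    n = x.size
    f0 = np.asarray(f(x), dtype=float)
    if not np.all(np.isfinite(f0)):
        raise NumericalError("non-finite rhs evaluation at the base point")
    jac = np.empty((f0.size, n))
    for i in range(n):
        h = rel_step * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        fp = np.asarray(f(xp), dtype=float)
        fm = np.asarray(f(xm), dtype=float)
        if not (np.all(np.isfinite(fp)) and np.all(np.isfinite(fm))):
            raise NumericalError(
                f"non-finite rhs evaluation while differencing coordinate {i}")
        jac[:, i] = (fp - fm) / (2.0 * h)
    return jac


def find_equilibrium(system: StageODESystem, initial_guess: np.ndarray,
                     tol: float = 1e-12) -> EquilibriumPoint:
    """Root-solve the stage-space rhs from a guess in the positive orthant.

    Non-convergent solves and roots with any non-positive stage density
    (boundary equilibria are not feasible) raise :class:`NumericalError`.
    """
    guess = np.asarray(initial_guess, dtype=float).reshape(system.S, system.K)
    if np.any(guess <= 0):
        raise ConfigurationError("initial guess must be strictly positive")
    sol = root(system.rhs, guess.ravel(order="F"), method="hybr",
               options={"xtol": 1e-13})
    if not sol.success:
        raise NumericalError(f"equilibrium search failed: {sol.message}")
    densities = sol.x.reshape(system.S, system.K, order="F")
    residual = float(np.linalg.norm(system.rhs(sol.x)))
    if np.any(densities <= 1e-10):
        raise NumericalError(
            "root has non-positive stage densities: equilibrium infeasible")
    if residual > max(tol, 1e-9):
        raise NumericalError(f"residual {residual:.3e} above tolerance")
    return EquilibriumPoint(stage_densities=densities, residual_norm=residual)


def stage_space_jacobian(system: StageODESystem,
                         equilibrium: EquilibriumPoint) -> np.ndarray:
    """Jacobian of the raw SK-dimensional stage-space system at the
    equilibrium (no change of variables)."""
    x0 = equilibrium.stage_densities.ravel(order="F")
    return numerical_jacobian(system.rhs, x0)


def structured_matrix_from_system(system: StageODESystem,
                                  equilibrium: EquilibriumPoint
                                  ) -> StructuredCommunityMatrix:
    """Structured community matrix of an explicit system: the Jacobian of the
    transformed dynamics at the aggregated equilibrium.

    Its block (1, 1) is the traditional community matrix of the aggregated
    model.
    """
    if np.any(equilibrium.stage_densities <= 0):
        raise NumericalError("equilibrium must have strictly positive densities")
    agg = aggregate(equilibrium.stage_densities)
    jac = numerical_jacobian(transformed_rhs_flat(system), agg.to_vector())
    return StructuredCommunityMatrix(S=system.S, K=system.K, entries=jac,
                                     config=None)


def trajectory_equivalence_error(
    system: StageODESystem,
    initial_stage_state: np.ndarray,
    t_final: float = 100.0,
    n_samples: int = 50,
    rtol: float = 1e-9,
    atol: float = 1e-12,
) -> float:
    """Maximum relative discrepancy between (a) integrating the stage-space
    system and aggregating, and (b) integrating the transformed system, at
    ``n_samples`` common time points.

    The change of variables is a smooth bijection on the positive orthant, so
    for a correct transformation this is integrator error only.
    """
    x0 = np.asarray(initial_stage_state, dtype=float)
    t_eval = np.linspace(0.0, t_final, n_samples)
    raw = solve_ivp(lambda t, x: system.rhs(x), (0.0, t_final),
                    x0.ravel(order="F"), t_eval=t_eval, method="LSODA",
                    rtol=rtol, atol=atol)
    if not raw.success:
        raise NumericalError(f"stage-space integration failed: {raw.message}")
    y0 = aggregate(x0).to_vector()
    f = transformed_rhs_flat(system)
    trans = solve_ivp(lambda t, y: f(y), (0.0, t_final), y0,
                      t_eval=t_eval, method="LSODA", rtol=rtol, atol=atol)
    if not trans.success:
        raise NumericalError(f"transformed integration failed: {trans.message}")
    err = 0.0
    for k in range(t_eval.size):
        stage = raw.y[:, k].reshape(system.S, system.K, order="F")
        expected = aggregate(stage).to_vector()
        got = trans.y[:, k]
        err = max(err, float(np.max(np.abs(got - expected)
                                    / np.maximum(1e-9, np.abs(expected)))))
    return err


# ---------------------------------------------------------------------------
# Concrete generalised Lotka-Volterra stage model and the bundled fixture
# ---------------------------------------------------------------------------

def lv_two_stage_system(
    b: np.ndarray,
    m: np.ndarray,
    s: np.ndarray,
    r: np.ndarray,
    alpha: np.ndarray,
) -> StageODESystem:
    """Generalised Lotka-Volterra community with juvenile/adult structure.

    Stage 1 is the juvenile class J_i, stage 2 the adult class A_i:

        dJ_i/dt = b_i A_i - m_i J_i + J_i (r_i1 - s_i (J_i + A_i) + I_i1)
        dA_i/dt = m_i J_i         + A_i (r_i2 - s_i (J_i + A_i) + I_i2)

    with reproduction b_i, maturation m_i, logistic self-regulation s_i acting
    on the total density, intrinsic rates r_ik, and pairwise interaction
    pressure ``I_ik = sum_{j != i, l} alpha[i, k, j, l] N_jl`` whose
    stage-specificity is encoded in the (S, 2, S, 2) coefficient array.
    """
    b = np.asarray(b, dtype=float)
    m = np.asarray(m, dtype=float)
    s = np.asarray(s, dtype=float)
    r = np.asarray(r, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    S = b.shape[0]
    if r.shape != (S, 2) or alpha.shape != (S, 2, S, 2):
        raise ConfigurationError("parameter arrays have inconsistent shapes")
    if np.any(alpha[np.arange(S), :, np.arange(S), :] != 0):
        raise ConfigurationError("alpha: intraspecific entries must be zero "
                                 "(self-regulation is carried by s)")

    def rhs(x: np.ndarray) -> np.ndarray:
        N = np.asarray(x, dtype=float).reshape(S, 2, order="F")
        tot = N.sum(axis=1)
        inter = np.einsum("ikjl,jl->ik", alpha, N)
        percap = r - s[:, None] * tot[:, None] + inter
        g = N * percap
        g[:, 0] += b * N[:, 1] - m * N[:, 0]
        g[:, 1] += m * N[:, 0]
        return g.ravel(order="F")

    params = {"b": b, "m": m, "s": s, "r": r, "alpha": alpha}
    return StageODESystem(S=S, K=2, rhs=rhs, params=params)


#: Default target equilibrium of the bundled fixture (rows: species,
#: columns: juvenile, adult densities).
_FIXTURE_EQUILIBRIUM = np.array([[1.0, 0.8], [1.2, 0.6]])


def two_species_fixture(
    interaction: str = "adult_juvenile",
    a12: float = 0.08,
    a21: float = -0.06,
    target_equilibrium: np.ndarray | None = None,
) -> tuple[StageODESystem, EquilibriumPoint]:
    """Bundled 2-species, 2-stage verification model (synthetic, designed
    in-repo for oracle checks; its parameters are not taken from any dataset).

    The interaction placement is switchable:

    * ``"adult_adult"``     -- species j's adults act on species i's adults,
    * ``"adult_juvenile"``  -- species j's juveniles act on species i's adults
      (the cross-stage case),
    * ``"stage_symmetric"`` -- every stage of j acts identically on every
      stage of i (interactions depend on totals only, so the species-level
      entries of the fraction rows of the structured matrix cancel exactly),
    * ``"none"``            -- uncoupled species.

    The equilibrium is constructed by the target-equilibrium method: the
    stage densities are fixed first and the intrinsic rates ``r_ik`` solved
    from ``g_ik = 0``, so feasibility is guaranteed by construction.
    """
    N_star = _FIXTURE_EQUILIBRIUM if target_equilibrium is None \
        else np.asarray(target_equilibrium, dtype=float)
    if N_star.shape != (2, 2) or np.any(N_star <= 0):
        raise ConfigurationError(
            "target_equilibrium: expected strictly positive (2, 2) densities")
    b = np.array([0.5, 0.4])
    m = np.array([0.3, 0.35])
    s = np.array([1.0, 1.1])
    alpha = np.zeros((2, 2, 2, 2))
    placements = {
        "adult_adult": (1, 1),
        "adult_juvenile": (1, 0),
        "stage_symmetric": None,
        "none": None,
    }
    if interaction not in placements:
        raise ConfigurationError(
            f"interaction: unknown mode {interaction!r}; expected one of "
            f"{sorted(placements)}")
    if interaction == "stage_symmetric":
        alpha[0, :, 1, :] = a12
        alpha[1, :, 0, :] = a21
    elif interaction != "none":
        k, l = placements[interaction]
        alpha[0, k, 1, l] = a12
        alpha[1, k, 0, l] = a21

    # Target-equilibrium method: solve r from g = 0 at N_star.
    tot = N_star.sum(axis=1)
    inter = np.einsum("ikjl,jl->ik", alpha, N_star)
    transfer = np.column_stack([
        b * N_star[:, 1] - m * N_star[:, 0],
        m * N_star[:, 0],
    ])
    r = -transfer / N_star + s[:, None] * tot[:, None] - inter

    system = lv_two_stage_system(b, m, s, r, alpha)
    residual = float(np.linalg.norm(system.rhs(N_star.ravel(order="F"))))
    return system, EquilibriumPoint(stage_densities=N_star,
                                    residual_norm=residual)
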