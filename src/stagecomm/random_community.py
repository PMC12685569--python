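"""Random community-matrix ensembles for unstructured populations.

A community of S species near a feasible equilibrium is summarised by its
community matrix M (the Jacobian of the population dynamics): entry ``m[i, j]``
is the effect of a small change in the density of species j on the growth rate
of species i.  Instead of deriving M from an explicit model, the random-matrix
approach draws its entries from a distribution constrained only by

* the pairwise interaction probability (connectance) C,
* the self-regulation magnitude d (every diagonal entry is exactly ``-d``),
* the interaction type, which fixes the joint sign of each off-diagonal pair
  ``(m[i, j], m[j, i])``, and
* the scale sigma of the underlying normal distribution of coefficient
  magnitudes.

Conventions
-----------
``sigma`` is the *standard deviation* of the underlying normal distribution.
The classical stability criterion ``sigma * sqrt(S*C) < d`` only takes its
standard form under this reading, so it is adopted throughout even though
"variance" is sometimes used loosely for the same symbol in the literature.

For the ``random`` interaction type each off-diagonal entry is independently
nonzero with probability C (the classical construction); for all typed
interactions the unordered pair interacts or not jointly, and the two
coefficients are drawn together so the sign contract can be enforced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .errors import ConfigurationError

__all__ = [
    "InteractionType",
    "MagnitudeDistribution",
    "CommunityConfig",
    "CommunityMatrix",
    "draw_offdiagonal_pair",
    "fill_offdiagonal_pairs",
    "build_community_matrix",
    "may_matrix",
]


class InteractionType(str, Enum):
    """Joint sign contract of an off-diagonal coefficient pair.

    ``random``       -- any signs, entries independent.
    ``competition``  -- both negative (-/-).
    ``mutualism``    -- both positive (+/+).
    ``predation``    -- opposite signs (+/-), orientation random or supplied.
    ``commensalism`` -- one entry zero, the other positive (0/+).
    ``amensalism``   -- one entry zero, the other negative (0/-).
    """

    RANDOM = "random"
    COMPETITION = "competition"
    MUTUALISM = "mutualism"
    PREDATION = "predation"
    COMMENSALISM = "commensalism"
    AMENSALISM = "amensalism"

    @classmethod
    def coerce(cls, value: "InteractionType | str") -> "InteractionType":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ConfigurationError(
                f"unknown interaction type {value!r}; expected one of "
                f"{[t.value for t in cls]}"
            ) from None


@dataclass(frozen=True)
class MagnitudeDistribution:
    """Distribution of interaction-coefficient magnitudes.

    ``family`` is one of:

    * ``normal_signed``    -- signed draws from N(0, sigma^2); the natural
      choice for the ``random`` interaction type.
    * ``folded_normal``    -- |N(0, sigma^2)|; the standard choice for typed
      (signed) interactions.
    * ``truncated_normal`` -- N(0, sigma^2) truncated to [0, inf).  For a
      zero-mean normal this coincides in law with the folded normal; it is
      kept as a separate, scipy-backed sampling route for robustness checks.

    ``sigma`` is the standard deviation of the underlying normal; ``sigma=0``
    forces all magnitudes to zero.
    """

    family: str = "folded_normal"
    sigma: float = 0.1

    _FAMILIES = ("normal_signed", "folded_normal", "truncated_normal")

    def __post_init__(self) -> None:
        if self.family not in self._FAMILIES:
            raise ConfigurationError(
                f"distribution.family: unknown family {self.family!r}; "
                f"expected one of {self._FAMILIES}"
            )
        if self.sigma < 0:
            raise ConfigurationError("distribution.sigma: must be >= 0")

    def draw_magnitude(self, rng: np.random.Generator, size=None) -> np.ndarray:
        """Nonnegative magnitude draw(s)."""
        if self.sigma == 0:
            return np.zeros(() if size is None else size)
        if self.family == "truncated_normal":
            from scipy.stats import truncnorm

            return truncnorm.rvs(0.0, np.inf, loc=0.0, scale=self.sigma,
                                 size=size, random_state=rng)
        return np.abs(rng.normal(0.0, self.sigma, size))

    def draw_signed(self, rng: np.random.Generator, size=None) -> np.ndarray:
        """Signed draw(s): the raw normal for ``normal_signed``, otherwise a
        magnitude with an independent uniform random sign."""
        if self.sigma == 0:
            return np.zeros(() if size is None else size)
        if self.family == "normal_signed":
            return rng.normal(0.0, self.sigma, size)
        signs = np.where(rng.random(size) < 0.5, -1.0, 1.0)
        return signs * self.draw_magnitude(rng, size)


@dataclass(frozen=True)
class CommunityConfig:
    """Parameters of an unstructured random community.

    S
        number of species (>= 2),
    C
        pairwise interaction probability in [0, 1],
    d
        self-regulation magnitude (> 0); diagonal entries are ``-d``,
    interaction_type, distribution
        sign contract and magnitude law of the off-diagonal coefficients,
    seed
        integer seed; identical configs produce bit-identical matrices.
    """

    S: int
    C: float
    d: float = 1.0
    interaction_type: InteractionType = InteractionType.RANDOM
    distribution: MagnitudeDistribution = field(
        default_factory=MagnitudeDistribution)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "interaction_type", InteractionType.coerce(self.interaction_type))
        if self.S < 2:
            raise ConfigurationError(
                "S: need at least 2 species (a 1-species community is "
                "trivially governed by -d)")
        if not 0.0 <= self.C <= 1.0:
            raise ConfigurationError("C: must lie in [0, 1]")
        if self.d <= 0:
            raise ConfigurationError("d: self-regulation magnitude must be > 0")


@dataclass(frozen=True)
class CommunityMatrix:
    """An S x S community matrix together with its generating config."""

    entries: np.ndarray
    config: CommunityConfig

    @property
    def S(self) -> int:
        return self.entries.shape[0]

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(self.entries)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.entries, delimiter=",")


def draw_offdiagonal_pair(
    interaction_type: InteractionType | str,
    distribution: MagnitudeDistribution,
    rng: np.random.Generator,
    orientation: bool | None = None,
) -> tuple[float, float]:
    """Draw one off-diagonal coefficient pair ``(m[i, j], m[j, i])``.

    ``orientation`` resolves the asymmetric types.  For ``predation``,
    ``True`` means "i predates j" (``m[i, j] > 0``, ``m[j, i] < 0``); for
    ``commensalism``/``amensalism``, ``True`` puts the zero on ``m[i, j]``.
    When ``orientation`` is None it is drawn uniformly at random (one rng
    uniform is consumed *before* the magnitudes, so that supplying the
    orientation externally leaves the magnitude stream unchanged).
    """
    itype = InteractionType.coerce(interaction_type)
    if itype is InteractionType.RANDOM:
        return (float(distribution.draw_signed(rng)),
                float(distribution.draw_signed(rng)))
    if orientation is None:
        orientation = bool(rng.random() < 0.5)
    a = float(distribution.draw_magnitude(rng))
    b = float(distribution.draw_magnitude(rng))
    if itype is InteractionType.COMPETITION:
        return (-a, -b)
    if itype is InteractionType.MUTUALISM:
        return (a, b)
    if itype is InteractionType.PREDATION:
        return (a, -b) if orientation else (-a, b)
    if itype is InteractionType.COMMENSALISM:
        return (0.0, a) if orientation else (a, 0.0)
    if itype is InteractionType.AMENSALISM:
        return (0.0, -a) if orientation else (-a, 0.0)
    raise ConfigurationError(f"unknown interaction type {itype!r}")


def _draw_pairs(S: int, C: float, rng: np.random.Generator
                ) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli(C) interaction topology over unordered pairs i < j."""
    iu, ju = np.triu_indices(S, k=1)
    keep = rng.random(iu.shape[0]) < C
    return iu[keep], ju[keep]


def _as_pair_arrays(pairs) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, tuple) and len(pairs) == 2 and np.ndim(pairs[0]) == 1:
        iu, ju = np.asarray(pairs[0]), np.asarray(pairs[1])
    else:
        arr = np.asarray(list(pairs), dtype=int).reshape(-1, 2)
        iu, ju = arr[:, 0], arr[:, 1]
    if np.any(iu >= ju):
        raise ConfigurationError("pairs: expected unordered pairs with i < j")
    return iu, ju


def fill_offdiagonal_pairs(
    m: np.ndarray,
    iu: np.ndarray,
    ju: np.ndarray,
    interaction_type: InteractionType | str,
    distribution: MagnitudeDistribution,
    rng: np.random.Generator,
    orientations: np.ndarray | None = None,
) -> None:
    """Vectorised joint fill of the coefficient pairs ``(m[i, j], m[j, i])``
    for the unordered pairs ``(iu[k], ju[k])``, in place.

    Sign semantics per pair match :func:`draw_offdiagonal_pair`:
    ``orientations[k] = True`` means the lower-index member predates
    (``m[i, j] > 0``) for predation, and carries the zero entry for
    commensalism/amensalism.  When ``orientations`` is None, orientations are
    drawn first (one uniform per pair), then the magnitudes.
    """
    itype = InteractionType.coerce(interaction_type)
    n = iu.shape[0]
    if n == 0:
        return
    if itype is InteractionType.RANDOM:
        m[iu, ju] = distribution.draw_signed(rng, n)
        m[ju, iu] = distribution.draw_signed(rng, n)
        return
    if orientations is None:
        orientations = rng.random(n) < 0.5
    else:
        orientations = np.asarray(orientations, dtype=bool)
        if orientations.shape[0] != n:
            raise ConfigurationError(
                "orientations: length must match the number of pairs")
    if itype in (InteractionType.COMMENSALISM, InteractionType.AMENSALISM):
        a = distribution.draw_magnitude(rng, n)
        signed = a if itype is InteractionType.COMMENSALISM else -a
        m[iu, ju] = np.where(orientations, 0.0, signed)
        m[ju, iu] = np.where(orientations, signed, 0.0)
        return
    a = distribution.draw_magnitude(rng, n)
    b = distribution.draw_magnitude(rng, n)
    if itype is InteractionType.COMPETITION:
        m[iu, ju], m[ju, iu] = -a, -b
    elif itype is InteractionType.MUTUALISM:
        m[iu, ju], m[ju, iu] = a, b
    elif itype is InteractionType.PREDATION:
        m[iu, ju] = np.where(orientations, a, -a)
        m[ju, iu] = np.where(orientations, -b, b)
    else:  # pragma: no cover
        raise ConfigurationError(f"unknown interaction type {itype!r}")


def build_community_matrix(
    config: CommunityConfig,
    *,
    rng: np.random.Generator | None = None,
    pairs: Sequence[tuple[int, int]] | tuple[np.ndarray, np.ndarray] | None = None,
    orientations: np.ndarray | None = None,
) -> CommunityMatrix:
    """Build a random community matrix under ``config``.

    The diagonal is exactly ``-d``.  For the ``random`` type each ordered
    off-diagonal entry is independently present with probability C; for typed
    interactions presence is decided per unordered pair and the coefficient
    pair drawn jointly.

    The keyword arguments are hooks for the structured assembler: ``pairs``
    supplies a pre-drawn interaction topology (either ``(iu, ju)`` index
    arrays or a sequence of ``i < j`` index pairs), in which case *all* types
    -- including ``random`` -- are filled pairwise over exactly those pairs;
    ``orientations`` supplies per-pair predation orientations (boolean array
    aligned with ``pairs``); ``rng`` supplies an external stream (otherwise
    one is created from ``config.seed``).
    """
    S = config.S
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = np.zeros((S, S))
    np.fill_diagonal(m, -config.d)

    if pairs is None and config.interaction_type is InteractionType.RANDOM:
        mask = rng.random((S, S)) < config.C
        np.fill_diagonal(mask, False)
        values = config.distribution.draw_signed(rng, (S, S))
        m[mask] = values[mask]
        return CommunityMatrix(m, config)

    if pairs is None:
        iu, ju = _draw_pairs(S, config.C, rng)
    else:
        iu, ju = _as_pair_arrays(pairs)
    fill_offdiagonal_pairs(m, iu, ju, config.interaction_type,
                           config.distribution, rng, orientations)
    return CommunityMatrix(m, config)


def may_matrix(S: int, C: float, sigma: float, seed: int = 0) -> CommunityMatrix:
    """Member of the classical random ensemble: diagonal fixed to -1,
    off-diagonal entries N(0, sigma^2) present independently with
    probability C."""
    config = CommunityConfig(
        S=S, C=C, d=1.0,
        interaction_type=InteractionType.RANDOM,
        distribution=MagnitudeDistribution("normal_signed", sigma),
        seed=seed,
    )
    return build_community_matrix(config)
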