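"""Assembly of structured community matrices.

A community of S species, each with K life-cycle stages, is linearised (after
a change of variables to total densities N_i and stage fractions Z_ik) into an
SK x SK block Jacobian -- the *structured community matrix*.  Its top-left
S x S block is the traditional community matrix of the aggregated, unstructured
model; the remaining blocks carry the cross-stage interactions.  Here the
blocks are drawn from random-matrix ensembles, one
:class:`BlockSpec` per block of the K x K grid.

Layout is stage-major: flat index ``(k - 1) * S + i`` addresses stage block k
of species i (block row 1 holds the totals, block rows 2..K the fractions of
stages 1..K-1).

Scaled interaction strengths
----------------------------
Each block may be specified either by the raw normal scale ``sigma`` or by the
dimensionless strength ``gamma``, which is what the analytic criteria compare
against the self-regulation d.  ``gamma = kappa(type, S, C) * sigma`` with

* random:        ``kappa = sqrt(S C)``
* predator-prey: ``kappa = (pi - 2)/pi * sqrt(S C)``
* mutualism:     ``kappa = sqrt(2/pi) * C * (S - 1)``
* competition:   ``kappa = sqrt(S C (1 - 2C/pi)) * (pi + 2 - 4C)/(pi - 2C)
  + C * sqrt(2/pi)``

(the mutualistic and competitive coefficients follow the canonical elliptic-law
criteria for folded-normal coefficient pairs and are validated by simulation in
the test suite).

Cross-stage predation sign convention
-------------------------------------
One predation orientation is drawn per interacting species pair and shared by
every predation-type block: if i predates j, each such block gets
``+|draw|`` at (i, j) and ``-|draw|`` at (j, i).  Transpose-pair entries of the
full matrix across an upper/lower block pair, e.g. ``MS[i, S+j]`` and
``MS[S+j, i]``, then carry opposite signs, so every coupling loop between a
total density and a stage fraction is a negative feedback loop.  This is the
construction that makes cross-stage predation stabilising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .random_community import (
    CommunityConfig,
    CommunityMatrix,
    InteractionType,
    MagnitudeDistribution,
    _as_pair_arrays,
    _draw_pairs,
    build_community_matrix,
    fill_offdiagonal_pairs,
)

__all__ = [
    "BlockSpec",
    "StructuredConfig",
    "StructuredCommunityMatrix",
    "gamma_coefficient",
    "gamma_to_sigma",
    "sigma_to_gamma",
    "two_stage_config",
    "assemble_two_stage",
    "assemble_k_stage",
    "extract_unstructured",
]

_PI = math.pi


def gamma_coefficient(interaction_type: InteractionType | str,
                      S: int, C: float) -> float:
    """Coefficient kappa such that ``gamma = kappa * sigma`` for a block of
    the given interaction type in an (S, C) community."""
    itype = InteractionType.coerce(interaction_type)
    if S < 2:
        raise ConfigurationError("S: need at least 2 species")
    if not 0.0 <= C <= 1.0:
        raise ConfigurationError("C: must lie in [0, 1]")
    sc = math.sqrt(S * C)
    if itype is InteractionType.RANDOM:
        return sc
    if itype is InteractionType.PREDATION:
        return (_PI - 2.0) / _PI * sc
    if itype is InteractionType.MUTUALISM:
        return math.sqrt(2.0 / _PI) * C * (S - 1)
    if itype is InteractionType.COMPETITION:
        bulk = math.sqrt(S * C * (1.0 - 2.0 * C / _PI)) \
            * (_PI + 2.0 - 4.0 * C) / (_PI - 2.0 * C)
        return bulk + C * math.sqrt(2.0 / _PI)
    raise ConfigurationError(
        f"no scaled-strength coefficient defined for type {itype.value!r}")


def gamma_to_sigma(gamma: float, S: int, C: float,
                   interaction_type: InteractionType | str) -> float:
    """Raw normal scale sigma for which the block's scaled strength equals
    ``gamma``."""
    if gamma < 0:
        raise ConfigurationError("gamma: must be >= 0")
    if gamma == 0:
        return 0.0
    if C == 0:
        raise ConfigurationError(
            "gamma > 0 with C = 0 is undefined (no interacting pairs)")
    return gamma / gamma_coefficient(interaction_type, S, C)


def sigma_to_gamma(sigma: float, S: int, C: float,
                   interaction_type: InteractionType | str) -> float:
    if sigma < 0:
        raise ConfigurationError("sigma: must be >= 0")
    return sigma * gamma_coefficient(interaction_type, S, C)


@dataclass(frozen=True)
class BlockSpec:
    """Interaction type and strength of one block of the K x K grid.

    Exactly one of ``sigma`` (raw normal scale) or ``gamma`` (scaled strength)
    must be given; the other is derived from (S, C) at assembly time.
    ``family`` optionally overrides the magnitude-distribution family
    (default: ``normal_signed`` for random blocks, ``folded_normal`` for typed
    blocks).  The diagonal is not part of the spec: on-diagonal blocks of the
    grid get ``-d``, off-diagonal blocks zero.
    """

    row_block: int
    col_block: int
    interaction_type: InteractionType = InteractionType.RANDOM
    sigma: float | None = None
    gamma: float | None = None
    family: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "interaction_type", InteractionType.coerce(self.interaction_type))
        if self.row_block < 1 or self.col_block < 1:
            raise ConfigurationError("block indices are 1-based and >= 1")
        if (self.sigma is None) == (self.gamma is None):
            raise ConfigurationError(
                f"block ({self.row_block},{self.col_block}): give exactly one "
                "of sigma / gamma")
        value = self.sigma if self.sigma is not None else self.gamma
        if value < 0:
            raise ConfigurationError(
                f"block ({self.row_block},{self.col_block}): strength must be >= 0")

    def resolve_sigma(self, S: int, C: float) -> float:
        if self.sigma is not None:
            return self.sigma
        return gamma_to_sigma(self.gamma, S, C, self.interaction_type)

    def resolve_gamma(self, S: int, C: float) -> float:
        if self.gamma is not None:
            return self.gamma
        return sigma_to_gamma(self.sigma, S, C, self.interaction_type)

    def distribution(self, S: int, C: float) -> MagnitudeDistribution:
        family = self.family
        if family is None:
            family = ("normal_signed"
                      if self.interaction_type is InteractionType.RANDOM
                      else "folded_normal")
        return MagnitudeDistribution(family, self.resolve_sigma(S, C))


@dataclass(frozen=True)
class StructuredConfig:
    """Full specification of a random structured community.

    ``blocks`` maps 1-based grid positions ``(r, c)`` to :class:`BlockSpec`
    and must cover the complete K x K grid.  ``stage_counts`` optionally gives
    the number of stages of each species (1..K); rows and columns of
    non-existing stages are zeroed after assembly, each leaving a structural
    zero eigenvalue that stability classification can discount.  ``topology``
    optionally fixes which species pairs interact (sequence of ``i < j`` index
    pairs); otherwise a single Bernoulli(C) topology is drawn per community
    and shared by all blocks.
    """

    S: int
    K: int
    C: float
    d: float
    blocks: Mapping[tuple[int, int], BlockSpec]
    seed: int = 0
    stage_counts: tuple[int, ...] | None = None
    topology: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.S < 2:
            raise ConfigurationError("S: need at least 2 species")
        if self.K < 2:
            raise ConfigurationError("K: need at least 2 stages")
        if not 0.0 <= self.C <= 1.0:
            raise ConfigurationError("C: must lie in [0, 1]")
        if self.d <= 0:
            raise ConfigurationError("d: must be > 0")
        blocks = dict(self.blocks)
        expected = {(r, c) for r in range(1, self.K + 1)
                    for c in range(1, self.K + 1)}
        if set(blocks) != expected:
            missing = sorted(expected - set(blocks))
            extra = sorted(set(blocks) - expected)
            raise ConfigurationError(
                f"blocks: grid incomplete or inconsistent (missing {missing}, "
                f"unexpected {extra})")
        for key, spec in blocks.items():
            if (spec.row_block, spec.col_block) != key:
                raise ConfigurationError(
                    f"blocks[{key}]: spec addresses block "
                    f"({spec.row_block},{spec.col_block})")
        object.__setattr__(self, "blocks", blocks)
        if self.stage_counts is not None:
            counts = tuple(int(k) for k in self.stage_counts)
            if len(counts) != self.S:
                raise ConfigurationError("stage_counts: need one entry per species")
            if any(k < 1 or k > self.K for k in counts):
                raise ConfigurationError("stage_counts: entries must lie in 1..K")
            object.__setattr__(self, "stage_counts", counts)
        if self.topology is not None:
            topo = tuple((int(i), int(j)) for i, j in self.topology)
            for i, j in topo:
                if not (0 <= i < j < self.S):
                    raise ConfigurationError(
                        "topology: pairs must satisfy 0 <= i < j < S")
            if len(set(topo)) != len(topo):
                raise ConfigurationError("topology: duplicate pairs")
            object.__setattr__(self, "topology", topo)

    def block(self, r: int, c: int) -> BlockSpec:
        return self.blocks[(r, c)]

    def with_block(self, r: int, c: int, **changes) -> "StructuredConfig":
        """Copy of the config with one block spec replaced."""
        spec = self.blocks[(r, c)]
        if "gamma" in changes and "sigma" not in changes:
            changes.setdefault("sigma", None)
        if "sigma" in changes and "gamma" not in changes:
            changes.setdefault("gamma", None)
        blocks = dict(self.blocks)
        blocks[(r, c)] = replace(spec, **changes)
        return replace(self, blocks=blocks)

    def with_cross_strengths(self, gamma2: float, gamma3: float
                             ) -> "StructuredConfig":
        """K = 2 convenience: set the scaled strengths of the two cross
        blocks (1,2) and (2,1)."""
        if self.K != 2:
            raise ConfigurationError("with_cross_strengths requires K = 2")
        return (self.with_block(1, 2, gamma=gamma2)
                    .with_block(2, 1, gamma=gamma3))


@dataclass(frozen=True)
class StructuredCommunityMatrix:
    """An SK x SK structured community matrix with block accessors.

    ``block(1, 1)`` is the traditional community matrix of the aggregated
    model.  ``n_structural_zeros`` counts exact zero eigenvalues introduced by
    stage-count padding; stability classification discounts them.
    """

    S: int
    K: int
    entries: np.ndarray
    config: StructuredConfig | None = None
    n_structural_zeros: int = 0

    def __post_init__(self) -> None:
        n = self.S * self.K
        if self.entries.shape != (n, n):
            raise ConfigurationError(
                f"entries: expected shape {(n, n)}, got {self.entries.shape}")

    def block(self, r: int, c: int) -> np.ndarray:
        """S x S sub-matrix at 1-based grid position (r, c)."""
        if not (1 <= r <= self.K and 1 <= c <= self.K):
            raise ConfigurationError("block indices out of range")
        S = self.S
        return self.entries[(r - 1) * S:r * S, (c - 1) * S:c * S]

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(self.entries)

    def to_csv(self, path) -> None:
        np.savetxt(path, self.entries, delimiter=",")


def two_stage_config(
    S: int,
    C: float,
    d: float = 1.0,
    *,
    gamma1: float = 0.0,
    gamma2: float = 0.0,
    gamma3: float = 0.0,
    gamma4: float = 0.0,
    m1_type: InteractionType | str = InteractionType.RANDOM,
    cross_type: InteractionType | str = InteractionType.PREDATION,
    m4_type: InteractionType | str = InteractionType.RANDOM,
    family: str | None = None,
    seed: int = 0,
    stage_counts: Sequence[int] | None = None,
    topology: Sequence[tuple[int, int]] | None = None,
) -> StructuredConfig:
    """Two-stage (juvenile/adult) configuration in the gamma parametrization.

    ``gamma1`` scales the total-total block M1, ``gamma2``/``gamma3`` the
    cross blocks M2 = (1,2) and M3 = (2,1), ``gamma4`` the fraction-fraction
    block M4.  Defaults reproduce the cross-stage-predation setup: random M1
    and M4, predator-prey cross blocks, and no juvenile-juvenile interactions
    (``gamma4 = 0``).
    """
    blocks = {
        (1, 1): BlockSpec(1, 1, m1_type, gamma=gamma1, family=family),
        (1, 2): BlockSpec(1, 2, cross_type, gamma=gamma2, family=family),
        (2, 1): BlockSpec(2, 1, cross_type, gamma=gamma3, family=family),
        (2, 2): BlockSpec(2, 2, m4_type, gamma=gamma4, family=family),
    }
    return StructuredConfig(
        S=S, K=2, C=C, d=d, blocks=blocks, seed=seed,
        stage_counts=None if stage_counts is None else tuple(stage_counts),
        topology=None if topology is None else tuple(topology),
    )


def assemble_k_stage(config: StructuredConfig) -> StructuredCommunityMatrix:
    """Assemble the SK x SK structured community matrix.

    Randomness layout (documented so runs are reproducible and auditable):
    ``SeedSequence(config.seed)`` is spawned into ``2 + K*K`` child streams
    used, in order, for (1) the shared interaction topology, (2) the shared
    per-pair predation orientations, then (3...) one stream per block in
    row-major grid order.  Block (1, 1) is filled through
    :func:`~stagecomm.random_community.build_community_matrix` with its
    stream, topology and orientations, so it is bit-identical to the
    unstructured matrix built from the same inputs.
    """
    S, K = config.S, config.K
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(2 + K * K)
    rng_topology = np.random.default_rng(children[0])
    rng_orientation = np.random.default_rng(children[1])

    if config.topology is not None:
        iu, ju = _as_pair_arrays(config.topology)
    else:
        iu, ju = _draw_pairs(S, config.C, rng_topology)
    orientations = rng_orientation.random(iu.shape[0]) < 0.5

    entries = np.zeros((S * K, S * K))
    idx = 2
    for r in range(1, K + 1):
        for c in range(1, K + 1):
            spec = config.blocks[(r, c)]
            rng_block = np.random.default_rng(children[idx])
            idx += 1
            dist = spec.distribution(S, config.C)
            if r == c:
                block_cfg = CommunityConfig(
                    S=S, C=config.C, d=config.d,
                    interaction_type=spec.interaction_type,
                    distribution=dist, seed=0)
                block = build_community_matrix(
                    block_cfg, rng=rng_block, pairs=(iu, ju),
                    orientations=orientations).entries
            else:
                block = np.zeros((S, S))
                fill_offdiagonal_pairs(block, iu, ju, spec.interaction_type,
                                       dist, rng_block, orientations)
            entries[(r - 1) * S:r * S, (c - 1) * S:c * S] = block

    n_structural = 0
    if config.stage_counts is not None:
        for i, k_i in enumerate(config.stage_counts):
            for k in range(k_i + 1, K + 1):
                flat = (k - 1) * S + i
                entries[flat, :] = 0.0
                entries[:, flat] = 0.0
                n_structural += 1

    return StructuredCommunityMatrix(
        S=S, K=K, entries=entries, config=config,
        n_structural_zeros=n_structural)


def assemble_two_stage(config: StructuredConfig) -> StructuredCommunityMatrix:
    """Two-stage front end of :func:`assemble_k_stage` (requires K = 2)."""
    if config.K != 2:
        raise ConfigurationError("assemble_two_stage requires K = 2")
    return assemble_k_stage(config)


def extract_unstructured(ms: StructuredCommunityMatrix) -> CommunityMatrix:
    """Top-left S x S block of a structured matrix as a community matrix,
    for structured-vs-unstructured comparisons."""
    if ms.config is not None:
        spec = ms.config.blocks[(1, 1)]
        cfg = CommunityConfig(
            S=ms.S, C=ms.config.C, d=ms.config.d,
            interaction_type=spec.interaction_type,
            distribution=spec.distribution(ms.S, ms.config.C),
            seed=ms.config.seed)
    else:
        cfg = CommunityConfig(S=ms.S, C=1.0, d=1.0)
    return CommunityMatrix(ms.block(1, 1).copy(), cfg)
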