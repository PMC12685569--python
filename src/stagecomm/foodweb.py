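"""Empirical and synthetic food webs as interaction topologies.

A food web is a set of labelled species and directed predator -> prey links.
Webs constrain which species pairs interact and, for the cross-stage
predation block, which member of each pair is the predator — replacing the
Bernoulli topology and the random orientations of the purely random
ensembles.  Supported formats are a square 0/1 adjacency CSV
(row predates column) and a two-column predator TAB prey edge list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .assembly import (
    BlockSpec,
    StructuredCommunityMatrix,
    StructuredConfig,
    gamma_to_sigma,
)
from .errors import ConfigurationError
from .random_community import InteractionType, MagnitudeDistribution
from .stability import GridResult, derive_seeds, ensemble_from_factory, grid_from_factory

__all__ = [
    "FoodWeb",
    "WebStabilitySummary",
    "read_food_web",
    "write_food_web",
    "connectance",
    "random_food_web",
    "structure_from_web",
    "web_ensemble_summary",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoodWeb:
    """Directed predator -> prey link structure over labelled species."""

    species: tuple[str, ...]
    links: frozenset[tuple[str, str]]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(set(self.species)) != len(self.species):
            raise ConfigurationError("species labels must be unique")
        if len(self.species) == 0:
            raise ConfigurationError("empty web")
        known = set(self.species)
        for pred, prey in self.links:
            if pred not in known or prey not in known:
                raise ConfigurationError(
                    f"link ({pred!r}, {prey!r}) references unknown species")
            if pred == prey:
                raise ConfigurationError(
                    f"self-link on {pred!r}; drop self-links before construction")

    @property
    def S(self) -> int:
        return len(self.species)

    @property
    def L(self) -> int:
        return len(self.links)

    def index(self, label: str) -> int:
        return self.species.index(label)

    def link_indices(self) -> np.ndarray:
        """(L, 2) array of (predator, prey) species indices, sorted for
        reproducibility."""
        pos = {s: k for k, s in enumerate(self.species)}
        idx = sorted((pos[p], pos[q]) for p, q in self.links)
        return np.asarray(idx, dtype=int).reshape(-1, 2)

    def interacting_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """Unordered pairs (i < j) linked in either direction."""
        idx = self.link_indices()
        pairs = sorted({(min(i, j), max(i, j)) for i, j in idx})
        arr = np.asarray(pairs, dtype=int).reshape(-1, 2)
        return arr[:, 0], arr[:, 1]

    def adjacency(self) -> pd.DataFrame:
        """Square 0/1 adjacency, row predates column."""
        a = np.zeros((self.S, self.S), dtype=int)
        idx = self.link_indices()
        if idx.size:
            a[idx[:, 0], idx[:, 1]] = 1
        return pd.DataFrame(a, index=self.species, columns=self.species)

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.species)
        g.add_edges_from(self.links)
        return g


def connectance(web: FoodWeb) -> float:
    """Directed connectance C = L / (S (S - 1)), self-links excluded."""
    if web.S < 2:
        raise ConfigurationError("connectance needs at least 2 species")
    return web.L / (web.S * (web.S - 1))


def _drop_self_links(links: Iterable[tuple[str, str]], source: str
                     ) -> frozenset[tuple[str, str]]:
    links = list(links)
    kept = [(p, q) for p, q in links if p != q]
    n_dropped = len(links) - len(kept)
    if n_dropped:
        logger.warning("%s: dropped %d self-link(s) (cannibalism is folded "
                       "into self-regulation, not the web)", source, n_dropped)
    return frozenset(kept)


def read_food_web(path, format: str | None = None) -> FoodWeb:
    """Read a food web from ``adjacency-csv`` (square 0/1 matrix with label
    header row and column, row predates column) or ``edge-list-tsv``
    (one predator TAB prey pair per line, no header).

    The format is inferred from the file extension when not given.
    """
    path = Path(path)
    if format is None:
        format = {"csv": "adjacency-csv", "tsv": "edge-list-tsv"}.get(
            path.suffix.lstrip(".").lower())
        if format is None:
            raise ConfigurationError(
                f"cannot infer format from suffix {path.suffix!r}; pass "
                "'adjacency-csv' or 'edge-list-tsv'")
    if format == "adjacency-csv":
        frame = pd.read_csv(path, index_col=0)
        frame.index = frame.index.astype(str).str.strip()
        frame.columns = frame.columns.astype(str).str.strip()
        if frame.shape[0] != frame.shape[1]:
            raise ConfigurationError(
                f"{path}: adjacency must be square, got {frame.shape}")
        if list(frame.index) != list(frame.columns):
            raise ConfigurationError(
                f"{path}: adjacency row and column labels disagree")
        values = frame.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ConfigurationError(f"{path}: adjacency entries must be 0/1")
        species = tuple(frame.index)
        rows, cols = np.nonzero(values)
        links = ((species[r], species[c]) for r, c in zip(rows, cols))
        web = FoodWeb(species=species,
                      links=_drop_self_links(links, str(path)),
                      provenance=str(path))
    elif format == "edge-list-tsv":
        frame = pd.read_csv(path, sep="\t", header=None, dtype=str,
                            comment="#").dropna(how="all")
        if frame.shape[1] != 2:
            raise ConfigurationError(
                f"{path}: edge list must have exactly two columns "
                "(predator TAB prey)")
        frame = frame.apply(lambda col: col.str.strip())
        species: list[str] = []
        for label in pd.concat([frame[0], frame[1]]):
            if label not in species:
                species.append(label)
        links = ((p, q) for p, q in frame.itertuples(index=False))
        web = FoodWeb(species=tuple(species),
                      links=_drop_self_links(links, str(path)),
                      provenance=str(path))
    else:
        raise ConfigurationError(
            f"unknown food-web format {format!r}; expected 'adjacency-csv' "
            "or 'edge-list-tsv'")
    if web.S < 2:
        raise ConfigurationError(f"{path}: web has fewer than 2 species")
    return web


def write_food_web(web: FoodWeb, path, format: str | None = None) -> None:
    """Write a web in either supported format (inferred from the suffix)."""
    path = Path(path)
    if format is None:
        format = {"csv": "adjacency-csv", "tsv": "edge-list-tsv"}.get(
            path.suffix.lstrip(".").lower(), "adjacency-csv")
    if format == "adjacency-csv":
        web.adjacency().to_csv(path)
    elif format == "edge-list-tsv":
        idx = web.link_indices()
        with open(path, "w") as fh:
            for i, j in idx:
                fh.write(f"{web.species[i]}\t{web.species[j]}\n")
    else:
        raise ConfigurationError(f"unknown food-web format {format!r}")


def random_food_web(S: int, C: float, seed: int = 0) -> FoodWeb:
    """Synthetic web: each ordered non-self pair is a predator -> prey link
    independently with probability C (a directed Erdos-Renyi stand-in for
    empirical webs, so analyses run without any download)."""
    if S < 2:
        raise ConfigurationError("S: need at least 2 species")
    if not 0.0 <= C <= 1.0:
        raise ConfigurationError("C: must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    width = len(str(S))
    species = tuple(f"sp{k + 1:0{width}d}" for k in range(S))
    mask = rng.random((S, S)) < C
    np.fill_diagonal(mask, False)
    rows, cols = np.nonzero(mask)
    links = frozenset((species[r], species[c]) for r, c in zip(rows, cols))
    return FoodWeb(species=species, links=links,
                   provenance=f"synthetic(S={S}, C={C}, seed={seed})")


def pairwise_connectance(web: FoodWeb) -> float:
    """Probability that an off-diagonal *entry* of a web-constrained matrix
    is nonzero: the fraction of ordered pairs linked in either direction.

    Both coefficients of a species pair are filled whenever the pair is
    linked at all, so this -- not the directed connectance L / (S (S - 1)) --
    is the C under which the scaled strengths gamma keep their meaning as
    spectral radii.
    """
    iu, _ = web.interacting_pairs()
    return 2.0 * iu.size / (web.S * (web.S - 1))


def structure_from_web(
    web: FoodWeb,
    gamma1: float,
    gamma2: float,
    gamma3: float,
    d: float = 1.0,
    seed: int = 0,
    cross_mode: str = "predation",
) -> StructuredCommunityMatrix:
    """Two-stage structured community matrix constrained by a food web.

    Within-stage species interactions (block M1) are random-signed over the
    web's linked pairs; the cross blocks M2 and M3 carry cross-stage
    adult-juvenile predation with the orientation taken from the web's
    species-level link direction (predator row positive in both blocks, so
    every total-fraction feedback loop is negative -- the stabilising
    pairing).  Mutual links resolve to a single orientation, chosen uniformly
    at random.  Juvenile-juvenile interactions are omitted: M4 is ``-d I``.
    Only web-linked species pairs receive nonzero entries in any block.

    Each gamma is converted to its sigma using the web's own S and its
    *pairwise* connectance (:func:`pairwise_connectance`), so gamma values
    are comparable across webs and with the Bernoulli-topology ensembles.

    ``cross_mode`` selects the cross-block treatment: ``"predation"`` (both
    cross blocks predator-prey-paired, the default -- the only mapping under
    which cross-stage predation stabilises web-constrained communities),
    or ``"m2_random"`` / ``"m3_random"``, which replace the respective block
    by random-signed draws.
    """
    if web.L == 0:
        raise ConfigurationError("web has no links; nothing to parametrise")
    if cross_mode not in ("predation", "m2_random", "m3_random"):
        raise ConfigurationError(
            "cross_mode: expected 'predation', 'm2_random' or 'm3_random'")
    if d <= 0:
        raise ConfigurationError("d: must be > 0")
    S = web.S
    C = pairwise_connectance(web)
    m2_type = (InteractionType.RANDOM if cross_mode == "m2_random"
               else InteractionType.PREDATION)
    m3_type = (InteractionType.RANDOM if cross_mode == "m3_random"
               else InteractionType.PREDATION)
    sig1 = gamma_to_sigma(gamma1, S, C, InteractionType.RANDOM)
    sig2 = gamma_to_sigma(gamma2, S, C, m2_type)
    sig3 = gamma_to_sigma(gamma3, S, C, m3_type)

    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(c) for c in ss.spawn(4)]
    iu, ju = web.interacting_pairs()

    m1 = np.zeros((S, S))
    np.fill_diagonal(m1, -d)
    m1[iu, ju] = rngs[0].normal(0.0, sig1, iu.size)
    m1[ju, iu] = rngs[0].normal(0.0, sig1, iu.size)

    # One predation orientation per interacting pair from the link direction;
    # mutual links break the tie uniformly at random.
    links = set(map(tuple, web.link_indices()))
    oriented = []
    for i, j in zip(iu.tolist(), ju.tolist()):
        forward, backward = (i, j) in links, (j, i) in links
        if forward and backward:
            oriented.append((i, j) if rngs[3].random() < 0.5 else (j, i))
        elif forward:
            oriented.append((i, j))
        else:
            oriented.append((j, i))
    oriented = np.asarray(oriented, dtype=int).reshape(-1, 2)

    def predation_cross(sigma: float, rng: np.random.Generator) -> np.ndarray:
        block = np.zeros((S, S))
        n = oriented.shape[0]
        block[oriented[:, 0], oriented[:, 1]] = np.abs(rng.normal(0.0, sigma, n))
        block[oriented[:, 1], oriented[:, 0]] = -np.abs(rng.normal(0.0, sigma, n))
        return block

    def random_cross(sigma: float, rng: np.random.Generator) -> np.ndarray:
        block = np.zeros((S, S))
        block[iu, ju] = rng.normal(0.0, sigma, iu.size)
        block[ju, iu] = rng.normal(0.0, sigma, iu.size)
        return block

    m2 = (random_cross(sig2, rngs[1]) if m2_type is InteractionType.RANDOM
          else predation_cross(sig2, rngs[1]))
    m3 = (random_cross(sig3, rngs[2]) if m3_type is InteractionType.RANDOM
          else predation_cross(sig3, rngs[2]))

    m4 = np.zeros((S, S))
    np.fill_diagonal(m4, -d)

    entries = np.block([[m1, m2], [m3, m4]])
    config = StructuredConfig(
        S=S, K=2, C=C, d=d,
        blocks={
            (1, 1): BlockSpec(1, 1, InteractionType.RANDOM, gamma=gamma1),
            (1, 2): BlockSpec(1, 2, m2_type, gamma=gamma2),
            (2, 1): BlockSpec(2, 1, m3_type, gamma=gamma3),
            (2, 2): BlockSpec(2, 2, InteractionType.RANDOM, gamma=0.0),
        },
        seed=seed,
        topology=tuple(zip(iu.tolist(), ju.tolist())),
    )
    return StructuredCommunityMatrix(S=S, K=2, entries=entries, config=config)


@dataclass(frozen=True)
class WebStabilitySummary:
    """Cross-web stability summary on a shared (gamma2, gamma3) lattice."""

    webs: tuple[FoodWeb, ...]
    per_web: tuple[GridResult, ...]
    average: GridResult
    lambda_samples: dict          # {(gamma2, gamma3): {web label: ndarray}}
    gamma1: float
    d: float

    def metadata(self) -> pd.DataFrame:
        """Per-web table with name, S, L, C columns."""
        return pd.DataFrame({
            "name": [w.provenance or f"web{k}" for k, w in enumerate(self.webs)],
            "S": [w.S for w in self.webs],
            "L": [w.L for w in self.webs],
            "C": [connectance(w) for w in self.webs],
        })


def web_ensemble_summary(
    webs: Sequence[FoodWeb],
    gamma2_values: Sequence[float],
    gamma3_values: Sequence[float],
    n_reps: int = 100,
    gamma1: float = 1.2,
    d: float = 1.0,
    seed: int = 0,
    comparison_points: Sequence[tuple[float, float]] = ((0.0, 0.0), (0.5, 0.5)),
    cross_mode: str = "predation",
) -> WebStabilitySummary:
    """Per-web stability grids over a shared (gamma2, gamma3) lattice, their
    cross-web average, and samples of the leading eigenvalue's real part at
    designated comparison points."""
    if len(webs) == 0:
        raise ConfigurationError("need at least one web")
    web_seeds = derive_seeds(seed, len(webs))
    grids = []
    samples: dict = {tuple(pt): {} for pt in comparison_points}
    for web, web_seed in zip(webs, web_seeds):

        def factory(g2: float, g3: float, rep_seed: int, _web=web):
            return structure_from_web(_web, gamma1, g2, g3, d, rep_seed,
                                      cross_mode)

        grid = grid_from_factory(factory, gamma2_values, gamma3_values,
                                 n_reps, web_seed)
        grids.append(grid)
        for pt in comparison_points:
            res = ensemble_from_factory(
                lambda s, g2=pt[0], g3=pt[1], _web=web: structure_from_web(
                    _web, gamma1, g2, g3, d, s, cross_mode),
                n_reps, web_seed)
            samples[tuple(pt)][web.provenance or str(id(web))] = \
                res.lambda_max_real
    average = GridResult(
        gamma2_values=grids[0].gamma2_values,
        gamma3_values=grids[0].gamma3_values,
        proportions=np.mean([g.proportions for g in grids], axis=0),
        n_reps=n_reps, seed=seed)
    return WebStabilitySummary(
        webs=tuple(webs), per_web=tuple(grids), average=average,
        lambda_samples=samples, gamma1=gamma1, d=d)
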