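"""Fundamental and structural properties of a food web.

Four fundamental properties describe diversity and complexity: species
richness S, link richness L, link density L/S, and directed connectance
C = L/S^2.  Fourteen structural properties describe trophic organization:

``Top, Int, Bas``
    fractions of taxa with prey but no predators / both / no prey
    (self-links are ignored for this classification);
``Can, Herb, Omn, Loop``
    fractions of cannibals, of consumers whose (non-self) prey are all
    basal, of consumers whose prey span at least two shortest trophic
    levels, and of taxa inside directed cycles of length >= 2;
``LinkSD, GenSD, VulSD``
    sample standard deviations of total links, generality (prey counts)
    and vulnerability (predator counts), each normalized by L/S
    (total links by 2L/S);
``TL``
    mean short-weighted trophic level, the per-taxon average of the
    shortest-chain level and the prey-averaged level;
``MaxSim``
    mean over taxa of the maximum trophic similarity to any other taxon,
    where similarity is shared prey plus shared predators over the union
    of both;
``Path``
    mean shortest path length between connected pairs in the undirected
    projection;
``Clust``
    mean directed clustering coefficient over taxa with at least two
    undirected neighbors.

Webs in which some consumer has no feeding chain down to a basal taxon
("unrooted loops") have no defined trophic levels; TL and Omn are then
recorded as missing rather than aborting a collection run.
"""
from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass, field, fields
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import FoodWeb, adjacency_maps

FUNDAMENTAL_PROPERTIES = ("S", "L", "links_per_species", "C")
STRUCTURAL_PROPERTIES = (
    "Top", "Int", "Bas", "Can", "Herb", "Omn", "Loop",
    "LinkSD", "GenSD", "VulSD", "TL", "MaxSim", "Path", "Clust",
)
ALL_PROPERTIES = FUNDAMENTAL_PROPERTIES + STRUCTURAL_PROPERTIES


class UnrootedLoopError(ValueError):
    """Some consumer has no directed prey-chain to a basal taxon."""


@dataclass(frozen=True)
class TrophicLevels:
    """Per-taxon trophic levels under three conventions.

    ``short_weighted[t] == (shortest[t] + prey_averaged[t]) / 2``; basal
    taxa are 1 under all three.
    """

    shortest: dict[str, int]
    prey_averaged: dict[str, float]
    short_weighted: dict[str, float]


@dataclass
class PropertyRecord:
    """All 18 property values for one web; ``None`` marks a missing value."""

    web_id: str
    scale_label: str = "other"
    S: float | None = None
    L: float | None = None
    links_per_species: float | None = None
    C: float | None = None
    Top: float | None = None
    Int: float | None = None
    Bas: float | None = None
    Can: float | None = None
    Herb: float | None = None
    Omn: float | None = None
    Loop: float | None = None
    LinkSD: float | None = None
    GenSD: float | None = None
    VulSD: float | None = None
    TL: float | None = None
    MaxSim: float | None = None
    Path: float | None = None
    Clust: float | None = None
    errors: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name != "errors"}


def fundamental_props(web: FoodWeb) -> tuple[int, int, float, float]:
    """Return (S, L, L/S, C) with C = L/S^2 exactly."""
    if web.is_empty:
        raise ValueError("empty web")
    s, l = web.S, web.L
    return s, l, l / s, l / s**2


def _basal_set(prey: Mapping[str, set[str]]) -> set[str]:
    return {t for t, p in prey.items() if not (p - {t})}


def node_class_fractions(web: FoodWeb) -> tuple[float, float, float, float, float]:
    """Return (Top, Int, Bas, Can, Herb); self-links are ignored for the
    top/intermediate/basal classification."""
    if web.is_empty:
        raise ValueError("empty web")
    prey, pred = adjacency_maps(web)
    s = web.S
    basal = _basal_set(prey)
    top = sum(
        1 for t in web.taxa if t not in basal and not (pred[t] - {t})
    )
    bas = len(basal)
    intermediate = s - top - bas
    can = sum(1 for t in web.taxa if t in prey[t])
    herb = sum(
        1
        for t in web.taxa
        if (prey[t] - {t}) and (prey[t] - {t}) <= basal
    )
    return top / s, intermediate / s, bas / s, can / s, herb / s


def trophic_levels(web: FoodWeb) -> TrophicLevels:
    """Shortest, prey-averaged, and short-weighted trophic levels.

    Shortest level is 1 + length of the shortest prey-chain to a basal
    taxon.  Prey-averaged levels solve the linear system
    ``TL_i = 1 + mean over i's prey (self excluded) of TL_j`` with basal
    taxa fixed at 1.  Raises :class:`UnrootedLoopError` when a consumer
    has no chain to any basal taxon.
    """
    if web.is_empty:
        raise ValueError("empty web")
    prey, pred = adjacency_maps(web)
    basal = _basal_set(prey)
    if not basal:
        raise UnrootedLoopError(f"{web.web_id}: no basal taxa")
    # multi-source BFS upward from the basal set along resource->consumer
    shortest: dict[str, int] = {t: 1 for t in basal}
    queue = deque(basal)
    while queue:
        u = queue.popleft()
        for v in pred[u]:
            if v != u and v not in shortest:
                shortest[v] = shortest[u] + 1
                queue.append(v)
    unreached = set(web.taxa) - set(shortest)
    if unreached:
        raise UnrootedLoopError(
            f"{web.web_id}: {len(unreached)} taxa with no chain to a basal taxon"
        )
    taxa = sorted(web.taxa)
    index = {t: i for i, t in enumerate(taxa)}
    n = len(taxa)
    a = np.eye(n)
    b = np.ones(n)
    for t in taxa:
        i = index[t]
        diet = sorted(prey[t] - {t})
        if not diet:
            continue  # basal row: TL = 1
        w = 1.0 / len(diet)
        for j in diet:
            a[i, index[j]] -= w
    try:
        pa = np.linalg.solve(a, b)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - rooted webs solve
        raise UnrootedLoopError(f"{web.web_id}: singular trophic system") from exc
    prey_avg = {t: float(pa[index[t]]) for t in taxa}
    sw = {t: (shortest[t] + prey_avg[t]) / 2.0 for t in taxa}
    return TrophicLevels(shortest=shortest, prey_averaged=prey_avg, short_weighted=sw)


def omnivory_fraction(web: FoodWeb, levels: TrophicLevels) -> float:
    """Fraction of taxa whose (non-self) prey span >= 2 distinct shortest
    trophic levels."""
    prey, _ = adjacency_maps(web)
    omn = sum(
        1
        for t in web.taxa
        if len({levels.shortest[j] for j in prey[t] - {t}}) >= 2
    )
    return omn / web.S


def loop_fraction(web: FoodWeb) -> float:
    """Fraction of taxa in strongly connected components of size >= 2;
    cannibalism alone does not count as looping."""
    if web.is_empty:
        raise ValueError("empty web")
    g = nx.DiGraph()
    g.add_nodes_from(web.taxa)
    g.add_edges_from(web.links)
    in_loop = sum(len(c) for c in nx.strongly_connected_components(g) if len(c) >= 2)
    return in_loop / web.S


def degree_sds(
    web: FoodWeb, ddof: int = 1
) -> tuple[float | None, float | None, float | None]:
    """(LinkSD, GenSD, VulSD): standard deviations of normalized total
    links, generality, and vulnerability.

    A self-link contributes one to both generality and vulnerability.
    Missing when S < 2 or L = 0.  ``ddof=0`` gives the population SD.
    """
    if web.S < 2 or web.L == 0:
        return None, None, None
    prey, pred = adjacency_maps(web)
    taxa = sorted(web.taxa)
    g = np.array([len(prey[t]) for t in taxa], dtype=float)
    v = np.array([len(pred[t]) for t in taxa], dtype=float)
    ls = web.L / web.S
    gen_sd = float(np.std(g / ls, ddof=ddof))
    vul_sd = float(np.std(v / ls, ddof=ddof))
    link_sd = float(np.std((g + v) / (2 * ls), ddof=ddof))
    return link_sd, gen_sd, vul_sd


def max_similarity(web: FoodWeb) -> float | None:
    """Mean over taxa of the maximum pairwise trophic similarity,
    ``(shared prey + shared predators) / (union prey + union predators)``;
    a pair with empty unions scores 0.  Missing when S < 2."""
    if web.S < 2:
        return None
    prey, pred = adjacency_maps(web)
    taxa = sorted(web.taxa)
    n = len(taxa)
    best = [0.0] * n
    for i in range(n):
        for j in range(i + 1, n):
            ti, tj = taxa[i], taxa[j]
            denom = len(prey[ti] | prey[tj]) + len(pred[ti] | pred[tj])
            s = 0.0
            if denom:
                s = (len(prey[ti] & prey[tj]) + len(pred[ti] & pred[tj])) / denom
            if s > best[i]:
                best[i] = s
            if s > best[j]:
                best[j] = s
    return float(np.mean(best))


def path_and_clustering(web: FoodWeb) -> tuple[float | None, float | None]:
    """(Path, Clust) on the undirected projection.

    Path averages shortest path length over connected unordered pairs
    only.  Clust averages, over taxa with >= 2 undirected neighbors, the
    number of directed links among the neighbors (self-links excluded)
    divided by k(k-1).  Either is missing when undefined.
    """
    if web.S < 2:
        return None, None
    g = nx.Graph()
    g.add_nodes_from(web.taxa)
    g.add_edges_from((c, r) for c, r in web.links if c != r)
    total, pairs = 0, 0
    for comp in nx.connected_components(g):
        comp = list(comp)
        if len(comp) < 2:
            continue
        sub = g.subgraph(comp)
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
        pairs += len(comp) * (len(comp) - 1) // 2
    path = (total / 2) / pairs if pairs else None

    directed = {(c, r) for c, r in web.links if c != r}
    ccs = []
    for t in web.taxa:
        nb = set(g.neighbors(t)) - {t}
        k = len(nb)
        if k < 2:
            continue
        among = sum(1 for a, b in directed if a in nb and b in nb)
        ccs.append(among / (k * (k - 1)))
    clust = float(np.mean(ccs)) if ccs else None
    return path, clust


def structural_properties(
    web: FoodWeb, *, ddof: int = 1, web_id: str | None = None
) -> PropertyRecord:
    """Compose all fundamental and structural properties into one record.

    Properties that are undefined for the web (S < 2, unrooted loops,
    degenerate projections) are recorded as missing with an error note.
    """
    if web.is_empty:
        raise ValueError("empty web")
    errors: list[str] = []
    s, l, ls, c = fundamental_props(web)
    top, intermediate, bas, can, herb = node_class_fractions(web)
    rec = PropertyRecord(
        web_id=web_id or web.web_id,
        scale_label=web.scale_label,
        S=s, L=l, links_per_species=ls, C=c,
        Top=top, Int=intermediate, Bas=bas, Can=can, Herb=herb,
        Loop=loop_fraction(web),
    )
    try:
        levels = trophic_levels(web)
        rec.TL = float(np.mean(list(levels.short_weighted.values())))
        rec.Omn = omnivory_fraction(web, levels)
    except UnrootedLoopError as exc:
        errors.append(str(exc))
    rec.LinkSD, rec.GenSD, rec.VulSD = degree_sds(web, ddof=ddof)
    if rec.GenSD is None:
        errors.append("degree SDs undefined (S < 2 or no links)")
    rec.MaxSim = max_similarity(web)
    rec.Path, rec.Clust = path_and_clustering(web)
    if rec.Path is None:
        errors.append("no connected pair in undirected projection")
    if rec.Clust is None:
        errors.append("no taxon with >= 2 neighbors")
    rec.errors = tuple(errors)
    return rec


def records_to_frame(records) -> pd.DataFrame:
    """Stack property records into one DataFrame (one row per web)."""
    rows = [r.to_dict() for r in records]
    df = pd.DataFrame(rows)
    return df.astype({p: float for p in ALL_PROPERTIES if p in df.columns})
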