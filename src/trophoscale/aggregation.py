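"""Trophic-species aggregation.

Comparative food-web analysis works on *trophic species*: equivalence
classes of taxa that share exactly the same prey set and the same
predator set.  Collapsing them removes the inflation of richness that
comes from taxonomic resolution alone.  Equivalence is computed in a
single pass on the raw sets (including self-links, so a cannibal never
merges with an otherwise-identical non-cannibal); the operation is
idempotent because after merging no two nodes can share both sets.
"""
from __future__ import annotations

from dataclasses import dataclass

from .io_formats import FoodWeb, adjacency_maps


@dataclass(frozen=True)
class TrophicWeb:
    """An aggregated web plus the taxon -> trophic-species mapping."""

    web: FoodWeb
    membership: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.membership.values()) != set(self.web.taxa):
            raise ValueError("membership does not cover aggregated taxa")


def aggregate_trophic_species(web: FoodWeb) -> TrophicWeb:
    """Collapse taxa with identical (prey set, predator set) pairs.

    Each class becomes one node named after its lexicographically
    smallest member.  A link (X, Y) exists iff some member of X eats some
    member of Y; the class has a self-link iff some member eats a member
    of the same class.
    """
    if web.is_empty:
        raise ValueError("empty web")
    prey, pred = adjacency_maps(web)
    classes: dict[tuple[frozenset[str], frozenset[str]], list[str]] = {}
    for t in web.taxa:
        key = (frozenset(prey[t]), frozenset(pred[t]))
        classes.setdefault(key, []).append(t)
    membership: dict[str, str] = {}
    for members in classes.values():
        rep = min(members)
        for t in members:
            membership[t] = rep
    links = frozenset((membership[c], membership[r]) for c, r in web.links)
    agg = FoodWeb(
        web_id=web.web_id,
        taxa=frozenset(membership.values()),
        links=links,
        scale_label=web.scale_label,
        area_m2=web.area_m2,
    )
    return TrophicWeb(web=agg, membership=membership)


def aggregation_is_idempotent(web: FoodWeb) -> bool:
    """True iff aggregating twice equals aggregating once."""
    once = aggregate_trophic_species(web)
    twice = aggregate_trophic_species(once.web)
    same_web = (
        once.web.taxa == twice.web.taxa and once.web.links == twice.web.links
    )
    trivial = all(t == rep for t, rep in twice.membership.items())
    return same_web and trivial
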