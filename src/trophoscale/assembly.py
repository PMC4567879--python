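"""Assemble spatially localized food webs from a metaweb and species catalogs.

The metaweb records every known feeding link among the taxa of the study
region.  A local web for a sampling unit is built under the standard
co-occurrence assumption: if two taxa are linked anywhere, they are linked
wherever they co-occur.  The assembly sequence is fixed:

1. induce the metaweb subgraph on the taxa observed in the unit;
2. drop taxa left with no links to *other* taxa in that subgraph;
3. inject the ubiquitous basal resources (detrital and planktonic pools
   that every unit contains but surveys under-record) together with all
   their metaweb links to the retained taxa and among themselves.

Step 2 precedes step 3, so a taxon whose only links are to a ubiquitous
resource is dropped before the injection can rescue it.  Webs below a
trophic-species richness threshold are excluded from analysis because
structural null models are systematically unreliable for very small webs.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .aggregation import aggregate_trophic_species
from .io_formats import FoodWeb, SpeciesCatalog, WebCollection

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AssemblyConfig:
    """Rules applied while localizing the metaweb.

    ``ubiquitous_taxa`` must be a subset of the metaweb's taxa when
    assembly runs; ``min_trophic_species`` is the inclusive richness
    threshold used by :func:`filter_by_richness`.
    """

    ubiquitous_taxa: frozenset[str] = frozenset()
    min_trophic_species: int = 10
    iterate_drop: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "ubiquitous_taxa", frozenset(self.ubiquitous_taxa))
        if self.min_trophic_species < 1:
            raise ValueError("min_trophic_species must be >= 1")


def _drop_unlinked(taxa: set[str], links: set[tuple[str, str]], iterate: bool):
    """Remove taxa with no links to other taxa (self-links do not count)."""
    while True:
        linked = {t for c, r in links if c != r for t in (c, r)}
        keep = taxa & linked
        if keep == taxa:
            break
        taxa = keep
        links = {(c, r) for c, r in links if c in taxa and r in taxa}
        if not iterate:
            break
    return taxa, links


def extract_local_web(
    metaweb: FoodWeb, catalog: SpeciesCatalog, config: AssemblyConfig
) -> FoodWeb:
    """Build one local web: induce, drop unlinked, inject ubiquitous taxa.

    Catalog taxa absent from the metaweb are ignored with a logged
    warning.  The result carries the catalog's scale label and area; it
    may be empty.
    """
    if metaweb.is_empty:
        raise ValueError("empty metaweb")
    unmatched = catalog.taxa - metaweb.taxa
    if unmatched:
        logger.warning(
            "catalog %s: %d taxa not in metaweb: %s",
            catalog.sample_id,
            len(unmatched),
            ", ".join(sorted(unmatched)[:5]) + ("..." if len(unmatched) > 5 else ""),
        )
    present = set(catalog.taxa & metaweb.taxa)
    links = {(c, r) for c, r in metaweb.links if c in present and r in present}
    taxa, links = _drop_unlinked(present, links, config.iterate_drop)

    ubiq = set(config.ubiquitous_taxa)
    if ubiq - metaweb.taxa:
        raise ValueError("ubiquitous taxa not present in metaweb")
    if ubiq:
        taxa = taxa | ubiq
        links |= {(c, r) for c, r in metaweb.links if c in taxa and r in taxa
                  and (c in ubiq or r in ubiq)}
    return FoodWeb(
        web_id=catalog.sample_id,
        taxa=frozenset(taxa),
        links=frozenset(links),
        scale_label=catalog.scale_label,
        area_m2=catalog.area_m2,
    )


def assemble_collection(
    metaweb: FoodWeb,
    catalogs: Sequence[SpeciesCatalog],
    config: AssemblyConfig,
) -> WebCollection:
    """One local web per catalog, in catalog order, with a provenance manifest.

    Empty webs (all catalog taxa unmatched or unlinked, no ubiquitous
    injection) are retained but flagged in the manifest.
    """
    webs: list[FoodWeb] = []
    rows = []
    for cat in catalogs:
        web = extract_local_web(metaweb, cat, config)
        webs.append(web)
        rows.append(
            {
                "web_id": web.web_id,
                "scale_label": web.scale_label,
                "area_m2": web.area_m2,
                "n_taxa": web.S,
                "n_links": web.L,
                "n_catalog_taxa": len(cat.taxa),
                "n_unmatched": len(cat.taxa - metaweb.taxa),
                "empty": web.is_empty,
            }
        )
    return WebCollection(webs=webs, manifest=pd.DataFrame(rows))


def filter_by_richness(
    collection: WebCollection, min_trophic_species: int
) -> tuple[WebCollection, pd.DataFrame]:
    """Keep webs whose *trophic-species* richness is >= the threshold.

    Returns the filtered collection and a per-scale report of counts
    retained and excluded.  The threshold is evaluated on the aggregated
    (trophic-species) web, not the taxonomic one.
    """
    kept: list[FoodWeb] = []
    rows = []
    for web in collection.webs:
        if web.is_empty:
            trophic_s = 0
        else:
            trophic_s = aggregate_trophic_species(web).web.S
        retained = trophic_s >= min_trophic_species
        rows.append(
            {"web_id": web.web_id, "scale_label": web.scale_label,
             "trophic_S": trophic_s, "retained": retained}
        )
        if retained:
            kept.append(web)
    detail = pd.DataFrame(rows)
    report = (
        detail.groupby("scale_label")["retained"]
        .agg(retained="sum", total="count")
        .reset_index()
    )
    report["excluded"] = report["total"] - report["retained"]
    kept_ids = {w.web_id for w in kept}
    manifest = collection.manifest
    if len(manifest):
        manifest = manifest[manifest["web_id"].isin(kept_ids)].reset_index(drop=True)
    return WebCollection(webs=kept, manifest=manifest), report
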