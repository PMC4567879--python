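"""Plain-CSV input/output for food webs, species catalogs, and manifests.

A food web is stored as a directed edge list with a header row
``consumer,resource``; a row ``(c, r)`` means *c eats r*.  Taxa that carry
no links (possible before assembly filtering) are listed as rows with an
empty ``resource`` field so that edge-list round trips preserve them.
Species catalogs are long tables ``sample_id,scale_label,area_m2,taxon``.
All files are UTF-8 comma-separated text with headers; taxon ids are opaque
strings.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

#: Ordinal sampling scales, smallest to largest, plus a catch-all.
SCALE_LABELS = ("quadrat", "transect", "site", "locale", "archipelago", "other")

#: Ordering key for per-scale tables.
SCALE_ORDER = {label: i for i, label in enumerate(SCALE_LABELS)}


@dataclass(frozen=True)
class FoodWeb:
    """A directed feeding network.

    Links are ordered pairs ``(consumer, resource)``; a self-link
    ``(t, t)`` represents cannibalism.  ``taxa`` may include taxa without
    links.  An empty web (no taxa) is representable so that assembly can
    flag degenerate sampling units instead of crashing.
    """

    web_id: str
    taxa: frozenset[str]
    links: frozenset[tuple[str, str]]
    scale_label: str = "other"
    area_m2: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", frozenset(self.taxa))
        object.__setattr__(
            self, "links", frozenset((str(c), str(r)) for c, r in self.links)
        )
        for c, r in self.links:
            if c not in self.taxa or r not in self.taxa:
                raise ValueError(f"link endpoint not in taxa: {(c, r)!r}")
        if self.scale_label not in SCALE_LABELS:
            raise ValueError(f"unknown scale_label: {self.scale_label!r}")
        if self.area_m2 is not None and not self.area_m2 > 0:
            raise ValueError("area_m2 must be positive")

    @property
    def S(self) -> int:
        """Number of taxa (species richness)."""
        return len(self.taxa)

    @property
    def L(self) -> int:
        """Number of directed links (self-links count once)."""
        return len(self.links)

    @property
    def is_empty(self) -> bool:
        return len(self.taxa) == 0


@dataclass(frozen=True)
class SpeciesCatalog:
    """The set of taxa observed in one sampling unit at one spatial scale."""

    sample_id: str
    scale_label: str
    area_m2: float
    taxa: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", frozenset(self.taxa))
        if self.scale_label not in SCALE_LABELS:
            raise ValueError(f"unknown scale_label: {self.scale_label!r}")
        if not self.area_m2 > 0:
            raise ValueError("area_m2 must be positive")


@dataclass
class WebCollection:
    """An ordered set of food webs with per-web provenance."""

    webs: list[FoodWeb]
    manifest: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        ids = [w.web_id for w in self.webs]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate web_id in collection")

    def __len__(self) -> int:
        return len(self.webs)

    def __iter__(self):
        return iter(self.webs)

    def by_id(self, web_id: str) -> FoodWeb:
        for w in self.webs:
            if w.web_id == web_id:
                return w
        raise KeyError(web_id)


def adjacency_maps(
    web: FoodWeb,
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Return ``(prey, predators)`` maps over all taxa (self-links included)."""
    prey: dict[str, set[str]] = {t: set() for t in web.taxa}
    pred: dict[str, set[str]] = {t: set() for t in web.taxa}
    for c, r in web.links:
        prey[c].add(r)
        pred[r].add(c)
    return prey, pred


def read_web(
    path: str | Path,
    web_id: str | None = None,
    *,
    consumer_col: str = "consumer",
    resource_col: str = "resource",
    scale_label: str = "other",
    area_m2: float | None = None,
) -> FoodWeb:
    """Read a directed edge list; rows with an empty resource declare
    isolated taxa.  Duplicate rows collapse to one link."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    taxa: set[str] = set()
    links: set[tuple[str, str]] = set()
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None:
            raise ValueError(f"{path}: empty file")
        header = [h.strip() for h in header]
        try:
            ci = header.index(consumer_col)
            ri = header.index(resource_col)
        except ValueError as exc:
            raise ValueError(f"{path}: missing required columns") from exc
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not f.strip() for f in row):
                continue
            if len(row) != len(header):
                raise ValueError(f"{path}:{lineno}: wrong column count")
            c, r = row[ci].strip(), row[ri].strip()
            if c and r:
                taxa.update((c, r))
                links.add((c, r))
            elif c:
                taxa.add(c)  # isolated-taxon row
            else:
                raise ValueError(f"{path}:{lineno}: missing consumer field")
    if not taxa and not links:
        raise ValueError(f"{path}: empty web")
    return FoodWeb(
        web_id=web_id or path.stem,
        taxa=frozenset(taxa),
        links=frozenset(links),
        scale_label=scale_label,
        area_m2=area_m2,
    )


def write_web(web: FoodWeb, path: str | Path) -> Path:
    """Write a web as an edge list; isolated taxa get blank-resource rows.

    ``read_web(write_web(w))`` reproduces taxa and links exactly.
    """
    path = Path(path)
    linked = {t for link in web.links for t in link}
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["consumer", "resource"])
        for c, r in sorted(web.links):
            writer.writerow([c, r])
        for t in sorted(web.taxa - linked):
            writer.writerow([t, ""])
    return path


def read_catalogs(
    path: str | Path,
    *,
    sample_col: str = "sample_id",
    scale_col: str = "scale_label",
    area_col: str = "area_m2",
    taxon_col: str = "taxon",
) -> list[SpeciesCatalog]:
    """Read species catalogs from a long table, one catalog per sample_id.

    Catalogs are returned in order of first appearance; duplicate taxon
    rows within a sample are counted once.
    """
    df = pd.read_csv(path, dtype=str)
    for col in (sample_col, scale_col, area_col, taxon_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    catalogs: list[SpeciesCatalog] = []
    seen: dict[str, tuple[str, float, set[str]]] = {}
    order: list[str] = []
    for row in df.itertuples(index=False):
        sid = str(getattr(row, sample_col))
        scale = str(getattr(row, scale_col))
        area = float(getattr(row, area_col))
        taxon = str(getattr(row, taxon_col))
        if scale not in SCALE_LABELS:
            raise ValueError(f"unknown scale_label {scale!r} for sample {sid}")
        if not area > 0:
            raise ValueError(f"nonpositive area_m2 for sample {sid}")
        if sid not in seen:
            seen[sid] = (scale, area, set())
            order.append(sid)
        elif seen[sid][0] != scale or seen[sid][1] != area:
            raise ValueError(f"inconsistent scale/area within sample {sid}")
        seen[sid][2].add(taxon)
    for sid in order:
        scale, area, taxa = seen[sid]
        catalogs.append(
            SpeciesCatalog(
                sample_id=sid, scale_label=scale, area_m2=area, taxa=frozenset(taxa)
            )
        )
    return catalogs


def write_catalogs(catalogs: Sequence[SpeciesCatalog], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["sample_id", "scale_label", "area_m2", "taxon"])
        for cat in catalogs:
            for t in sorted(cat.taxa):
                writer.writerow([cat.sample_id, cat.scale_label, repr(cat.area_m2), t])
    return path


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    manifest.to_csv(path, index=False)
    return path


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
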