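"""Niche-model null ensembles and the model-error (ME) statistic.

The niche model places each of S species at a niche value n_i drawn
uniformly on [0, 1] and assigns it a contiguous feeding range of width
r_i = n_i * x_i, with x_i ~ Beta(1, beta) and beta = 1/(2C) - 1 so that
realized connectance is C in expectation.  The range center c_i is
uniform on [r_i/2, min(n_i, 1 - r_i/2)]; species i eats every j whose
n_j falls inside the range.  The species with the smallest niche value
gets r = 0, guaranteeing at least one basal species.  Candidate webs
containing isolated taxa, webs disconnected in the undirected
projection, or webs whose realized connectance misses the target by more
than a relative tolerance are rejected and redrawn.

An empirical web is compared against an ensemble of niche webs matched
to its S and C through the model error:

    ME = (median - value) / (q97.5 - median)   if value > median
    ME = (median - value) / (median - q2.5)    if value < median

so ME is 0 at the median, -1/+1 exactly at the 97.5th/2.5th ensemble
percentiles, and |ME| > 1 iff the empirical value falls outside the
central 95% of the modeled values.  Negative ME means the model
underestimates the property.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components
from scipy.sparse import csr_matrix

from .io_formats import FoodWeb
from .metrics import ALL_PROPERTIES, PropertyRecord, records_to_frame, structural_properties


def beta_shape_for_connectance(C: float) -> float:
    """Shape beta of the Beta(1, beta) range-width distribution giving an
    expected fraction 2C of the niche axis consumed per species."""
    if not 0 < C < 0.5:
        raise ValueError("C must lie in (0, 0.5)")
    if C > 0.45:
        warnings.warn("C near 0.5: beta -> 0 is degenerate", stacklevel=2)
    return 1.0 / (2.0 * C) - 1.0


def _draw_candidate(S: int, beta: float, rng: np.random.Generator):
    """One unvalidated niche web as (sorted niche values, adjacency matrix).

    Row i of the matrix is consumer i's diet.  Species are sorted by
    niche value so index 0 is the forced-basal smallest-niche species.
    """
    n = np.sort(rng.uniform(size=S))
    r = n * rng.beta(1.0, beta, size=S)
    r[0] = 0.0
    lo = r / 2.0
    hi = np.minimum(n, 1.0 - r / 2.0)
    c = rng.uniform(lo, hi)
    eats = (n[None, :] >= (c - r / 2.0)[:, None]) & (
        n[None, :] <= (c + r / 2.0)[:, None]
    )
    eats[0, :] = False  # zero-width range eats nothing
    return n, eats


def generate_niche_web(
    S: int,
    C: float,
    rng: np.random.Generator,
    *,
    c_tolerance: float = 0.05,
    max_tries: int = 10_000,
    require_connected: bool = True,
    web_id: str = "niche",
    scale_label: str = "other",
    label_prefix: str = "x",
) -> FoodWeb:
    """Draw an accepted niche-model web with exactly S taxa.

    Taxa are labeled ``x001, x002, ...`` in increasing niche order, so
    low labels sort to the base of the web.  Rejection resamples whole
    webs until none of the acceptance checks fails; the same seeded
    generator always yields the same web.
    """
    if S < 2:
        raise ValueError("S must be >= 2")
    if require_connected and S**2 * C * (1 + c_tolerance) < S - 1:
        raise ValueError(
            f"target C={C:.4f} admits fewer than S-1 links: no connected "
            f"web of {S} taxa exists at that connectance"
        )
    beta = beta_shape_for_connectance(C)
    width = max(3, len(str(S)))
    labels = [f"{label_prefix}{i + 1:0{width}d}" for i in range(S)]
    for attempt in range(max_tries):
        _, eats = _draw_candidate(S, beta, rng)
        l = int(eats.sum())
        realized = l / S**2
        if abs(realized - C) > c_tolerance * C:
            continue
        degree = eats.sum(axis=0) + eats.sum(axis=1)
        if (degree == 0).any():
            continue
        if require_connected:
            sym = eats | eats.T
            np.fill_diagonal(sym, False)
            n_comp, _ = connected_components(
                csr_matrix(sym), directed=False
            )
            if n_comp > 1:
                continue
        consumers, resources = np.nonzero(eats)
        links = frozenset(
            (labels[i], labels[j]) for i, j in zip(consumers, resources)
        )
        return FoodWeb(
            web_id=web_id,
            taxa=frozenset(labels),
            links=links,
            scale_label=scale_label,
        )
    raise RuntimeError(
        f"niche-model rejection budget exhausted after {max_tries} draws "
        f"(S={S}, C={C}, tolerance={c_tolerance})"
    )


@dataclass
class EnsembleSummary:
    """Per-property median and central 95% bounds of a niche ensemble."""

    S: int
    C: float
    n_webs: int
    stats: pd.DataFrame  # index: property; columns: median, q2_5, q97_5, n
    samples: pd.DataFrame | None = None

    @classmethod
    def from_samples(
        cls, samples: pd.DataFrame, *, S: int, C: float, keep_samples: bool = True
    ) -> "EnsembleSummary":
        rows = {}
        for prop in samples.columns:
            vals = samples[prop].dropna().to_numpy(dtype=float)
            if len(vals) == 0:
                rows[prop] = {"median": np.nan, "q2_5": np.nan,
                              "q97_5": np.nan, "n": 0}
                continue
            q2_5, med, q97_5 = np.percentile(vals, [2.5, 50.0, 97.5])
            rows[prop] = {"median": med, "q2_5": q2_5, "q97_5": q97_5,
                          "n": len(vals)}
        stats = pd.DataFrame.from_dict(rows, orient="index")
        return cls(S=S, C=C, n_webs=len(samples), stats=stats,
                   samples=samples if keep_samples else None)


def niche_ensemble(
    S: int,
    C: float,
    n_webs: int,
    rng: np.random.Generator,
    *,
    c_tolerance: float = 0.05,
    max_tries: int = 10_000,
    keep_samples: bool = True,
) -> EnsembleSummary:
    """Generate ``n_webs`` accepted niche webs matched to (S, C) and
    summarize the distribution of every structural property.

    Percentiles use linear interpolation; webs for which a property is
    missing are excluded from that property's summary (counts reported
    in the ``n`` column).
    """
    if n_webs < 1:
        raise ValueError("n_webs must be >= 1")
    records = []
    for i in range(n_webs):
        web = generate_niche_web(
            S, C, rng, c_tolerance=c_tolerance, max_tries=max_tries,
            web_id=f"niche{i:04d}",
        )
        records.append(structural_properties(web))
    samples = records_to_frame(records)[list(ALL_PROPERTIES)]
    return EnsembleSummary.from_samples(samples, S=S, C=C, keep_samples=keep_samples)


def model_error(
    empirical: PropertyRecord | Mapping[str, float | None],
    ensemble: EnsembleSummary,
) -> dict[str, float | None]:
    """Per-property model error of an empirical web against an ensemble.

    Missing empirical values yield missing MEs; a degenerate half-band
    (zero width) with a non-median value yields a signed infinity.
    """
    values = empirical.to_dict() if isinstance(empirical, PropertyRecord) else dict(empirical)
    me: dict[str, float | None] = {}
    for prop, row in ensemble.stats.iterrows():
        e = values.get(prop)
        m, lo, hi = row["median"], row["q2_5"], row["q97_5"]
        if e is None or (isinstance(e, float) and math.isnan(e)) or math.isnan(m):
            me[prop] = None
        elif e == m:
            me[prop] = 0.0
        elif e > m:
            half = hi - m
            me[prop] = (m - e) / half if half > 0 else -math.inf
        else:
            half = m - lo
            me[prop] = (m - e) / half if half > 0 else math.inf
    return me
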