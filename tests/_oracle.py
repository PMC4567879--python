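"""Brute-force reference implementations of every web property.

Deliberately naive and structured nothing like the package: pure-Python
loops over raw link sets, Warshall transitive closure for loops and
undirected distances, ``statistics.stdev`` for the degree SDs, and an
independently assembled dense linear solve for prey-averaged trophic
levels.  Only meant for webs with a handful of taxa.
"""
from __future__ import annotations

import statistics

import numpy as np


def _prey_pred(taxa, links):
    prey = {t: {r for c, r in links if c == t} for t in taxa}
    pred = {t: {c for c, r in links if r == t} for t in taxa}
    return prey, pred


def oracle_properties(taxa, links):
    """All 18 properties as a dict; ``None`` marks an undefined value."""
    taxa = sorted(taxa)
    links = set(links)
    s = len(taxa)
    l = len(links)
    out = {"S": s, "L": l, "links_per_species": l / s, "C": l / s**2}
    prey, pred = _prey_pred(taxa, links)

    basal = {t for t in taxa if not (prey[t] - {t})}
    top = {t for t in taxa if t not in basal and not (pred[t] - {t})}
    out["Top"] = len(top) / s
    out["Bas"] = len(basal) / s
    out["Int"] = (s - len(top) - len(basal)) / s
    out["Can"] = sum(1 for t in taxa if (t, t) in links) / s
    out["Herb"] = (
        sum(1 for t in taxa if prey[t] - {t} and (prey[t] - {t}) <= basal) / s
    )

    # shortest trophic level by repeated relaxation
    level = {t: 1 for t in basal}
    for _ in range(s):
        for t in taxa:
            if t in basal:
                continue
            known = [level[j] for j in prey[t] - {t} if j in level]
            if known:
                cand = 1 + min(known)
                if t not in level or cand < level[t]:
                    level[t] = cand
    if len(level) < s:
        out["TL"] = None
        out["Omn"] = None
    else:
        a = [[0.0] * s for _ in range(s)]
        b = [1.0] * s
        for i, t in enumerate(taxa):
            a[i][i] = 1.0
            diet = prey[t] - {t}
            for j in diet:
                a[i][taxa.index(j)] -= 1.0 / len(diet)
        pa = np.linalg.solve(np.array(a), np.array(b))
        swtl = [(level[t] + pa[i]) / 2 for i, t in enumerate(taxa)]
        out["TL"] = sum(swtl) / s
        out["Omn"] = (
            sum(
                1
                for t in taxa
                if len({level[j] for j in prey[t] - {t}}) >= 2
            )
            / s
        )

    # loops via Warshall transitive closure (self-links removed)
    reach = {t: {u: (t, u) in links and t != u for u in taxa} for t in taxa}
    for k in taxa:
        for i in taxa:
            for j in taxa:
                if reach[i][k] and reach[k][j]:
                    reach[i][j] = True
    out["Loop"] = (
        sum(1 for t in taxa if any(reach[t][u] and reach[u][t] for u in taxa if u != t))
        / s
    )

    if s < 2 or l == 0:
        out["LinkSD"] = out["GenSD"] = out["VulSD"] = None
    else:
        ls = l / s
        g = [len(prey[t]) for t in taxa]
        v = [len(pred[t]) for t in taxa]
        out["GenSD"] = statistics.stdev(x / ls for x in g)
        out["VulSD"] = statistics.stdev(x / ls for x in v)
        out["LinkSD"] = statistics.stdev((x + y) / (2 * ls) for x, y in zip(g, v))

    if s < 2:
        out["MaxSim"] = None
    else:
        maxima = []
        for t in taxa:
            best = 0.0
            for u in taxa:
                if u == t:
                    continue
                denom = len(prey[t] | prey[u]) + len(pred[t] | pred[u])
                sim = (
                    (len(prey[t] & prey[u]) + len(pred[t] & pred[u])) / denom
                    if denom
                    else 0.0
                )
                best = max(best, sim)
            maxima.append(best)
        out["MaxSim"] = sum(maxima) / s

    # undirected distances via Floyd-Warshall
    inf = float("inf")
    dist = {t: {u: (0 if t == u else inf) for u in taxa} for t in taxa}
    for c, r in links:
        if c != r:
            dist[c][r] = dist[r][c] = 1
    for k in taxa:
        for i in taxa:
            for j in taxa:
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    finite = [
        dist[taxa[i]][taxa[j]]
        for i in range(s)
        for j in range(i + 1, s)
        if dist[taxa[i]][taxa[j]] < inf
    ]
    out["Path"] = sum(finite) / len(finite) if finite else None

    ccs = []
    for t in taxa:
        nb = {u for u in taxa if u != t and (dist[t][u] == 1)}
        k = len(nb)
        if k < 2:
            continue
        among = sum(
            1 for c, r in links if c != r and c in nb and r in nb
        )
        ccs.append(among / (k * (k - 1)))
    out["Clust"] = sum(ccs) / len(ccs) if ccs else None
    return out


def random_web(seed, max_s=12):
    """A small random directed web (taxa list, link set) for oracle checks."""
    rng = np.random.default_rng(seed)
    s = int(rng.integers(2, max_s + 1))
    taxa = [f"t{i}" for i in range(s)]
    p = float(rng.uniform(0.1, 0.45))
    links = {
        (taxa[i], taxa[j])
        for i in range(s)
        for j in range(s)
        if (i != j and rng.random() < p)
        or (i == j and rng.random() < 0.1)
    }
    return taxa, links
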