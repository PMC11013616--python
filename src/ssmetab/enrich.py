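"""Metabolite-set over-representation analysis against a local catalog.

Each pathway is tested with the hypergeometric upper tail: drawing the query
of size n from a universe of N annotated metabolites, the probability of
seeing at least the observed overlap k with a pathway of size K is
``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``.  Pathways with p < 0.01
are flagged significant; a Benjamini-Hochberg FDR column is reported for
information but is not part of the flag.

The bundled catalog is a small KEGG-like set of ~30 pathways over the
synthetic metabolite library; identifiers are local names, not live database
accessions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .exceptions import ConfigurationError, DomainError


@dataclass
class PathwayCatalog:
    """Named metabolite sets plus the annotatable universe."""

    pathways: dict[str, frozenset[str]]
    universe: frozenset[str]

    def __post_init__(self) -> None:
        for name, members in self.pathways.items():
            if not members:
                raise ConfigurationError(f"empty pathway: {name}")
            if not members <= self.universe:
                raise ConfigurationError(f"pathway {name} has members outside the universe")


def load_gmt(lines, background: set[str] | None = None) -> PathwayCatalog:
    """Parse a GMT-like file: ``name<TAB>description<TAB>member...`` per line.

    ``background`` lists additional annotatable compounds that belong to the
    universe without being members of any pathway (the behaviour of services
    that annotate against their full compound collection).
    """
    pathways: dict[str, frozenset[str]] = {}
    for raw in lines:
        raw = raw.rstrip("\n")
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) < 3:
            raise ConfigurationError(f"malformed GMT line: {raw[:60]}")
        pathways[parts[0]] = frozenset(parts[2:])
    universe = frozenset().union(*pathways.values()) if pathways else frozenset()
    if background:
        universe |= frozenset(background)
    return PathwayCatalog(pathways=pathways, universe=universe)


def default_catalog() -> PathwayCatalog:
    """The bundled synthetic pathway catalog with its compound background."""
    data = resources.files("ssmetab.data")
    text = data.joinpath("pathways.gmt").read_text()
    background = {
        line.strip() for line in data.joinpath("background.txt").read_text().splitlines()
        if line.strip() and not line.startswith("#")
    }
    return load_gmt(text.splitlines(), background=background)


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """``P(X >= k)`` for ``X ~ Hypergeometric(N, K, n)``; k = 0 gives 1."""
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise DomainError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def ora(
    query: set[str],
    catalog: PathwayCatalog,
    p_threshold: float = 0.01,
    detected: set[str] | None = None,
) -> pd.DataFrame:
    """Over-representation of a biomarker set against every catalog pathway.

    The universe defaults to all metabolites the catalog annotates (the
    behaviour of annotating against a full compound background); pass
    ``detected`` to restrict both universe and pathways to the measured
    metabolites instead.  Query members outside the universe are dropped with
    a warning; an empty filtered query raises.
    """
    universe = catalog.universe if detected is None else catalog.universe & frozenset(detected)
    q = frozenset(query) & universe
    dropped = frozenset(query) - universe
    if dropped:
        warnings.warn(f"query members outside the universe dropped: {sorted(dropped)}")
    if not q:
        raise DomainError("query is empty after universe filtering")
    N, n = len(universe), len(q)
    rows = []
    for name, members in catalog.pathways.items():
        mem = members & universe
        if not mem:
            continue
        K = len(mem)
        k = len(q & mem)
        p = hypergeometric_tail(k, K, n, N)
        rows.append({"pathway": name, "overlap": k, "pathway_size": K,
                     "query_size": n, "universe_size": N, "p": p,
                     "members_hit": ";".join(sorted(q & mem))})
    out = pd.DataFrame(rows).sort_values(["p", "pathway"], kind="stable").reset_index(drop=True)
    out["significant"] = out["p"] < p_threshold
    # BH FDR, informational
    m = len(out)
    order = np.argsort(out["p"].to_numpy(), kind="stable")
    ranked = out["p"].to_numpy()[order] * m / np.arange(1, m + 1)
    fdr_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    fdr = np.empty(m)
    fdr[order] = np.minimum(fdr_sorted, 1.0)
    out["fdr"] = fdr
    return out
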