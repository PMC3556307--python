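"""Protein-domain enrichment of genes near UCR clusters.

For each cluster of UCRs, genes lying within a window (default 100 kb)
of any member UCR are collected, and each protein domain is tested for
overrepresentation among those nearby genes with an upper-tail
(cumulative) hypergeometric probability:

    P = sum_{i=d}^{min(D,g)} C(D,i) C(G-D, g-i) / C(G,g)

where G is the number of genes in the cluster's species pool, g the
number of nearby genes, D the pool genes carrying the domain, and d the
nearby genes carrying it.  A gene carrying a domain several times
counts once, keeping the urn model coherent (D <= G).

Raw p-values are the primary output (display filter: p < 0.05 and
d >= 3); Benjamini–Hochberg adjusted values are added as a convenience
column.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import pandas as pd
from scipy.stats import hypergeom

from .clustering import Cluster
from .ucr import UCR

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 100_000
DEFAULT_MIN_GENES = 10


@dataclasses.dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    species: str
    scaffold: str
    start0: int
    end0: int
    strand: str
    domains: frozenset[str]

    def __post_init__(self):
        if self.end0 <= self.start0:
            raise ValueError(f"gene {self.gene_id} has end <= start")


def interval_distance(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two half-open intervals; 0 when they overlap."""
    return max(0, b_start - a_end, a_start - b_end)


def find_nearby_genes(
    ucrs: Sequence[UCR],
    genes: Sequence[GeneRecord],
    window: int = DEFAULT_WINDOW,
) -> dict[str, list[str]]:
    """ucr_id -> gene_ids whose interval lies within `window` bp.

    Distance is the interval gap (overlap = 0) and the boundary is
    inclusive: a gene exactly `window` bp away counts as nearby.
    """
    by_loc: dict[tuple[str, str], list[GeneRecord]] = {}
    for g in genes:
        by_loc.setdefault((g.species, g.scaffold), []).append(g)
    out: dict[str, list[str]] = {}
    for u in ucrs:
        hits = []
        for g in by_loc.get((u.species, u.scaffold), []):
            if interval_distance(u.start0, u.end0, g.start0, g.end0) <= window:
                hits.append(g.gene_id)
        out[u.ucr_id] = sorted(hits)
    return out


def hypergeom_upper(G: int, g: int, D: int, d: int) -> float:
    """Upper-tail hypergeometric probability P(X >= d)."""
    if not (0 <= d <= min(D, g) and g <= G and D <= G):
        raise ValueError(f"invalid hypergeometric counts G={G} g={g} D={D} d={d}")
    if d == 0:
        return 1.0
    return float(hypergeom.sf(d - 1, G, D, g))


def cluster_domain_enrichment(
    clusters: Sequence[Cluster],
    ucrs_by_id: Mapping[str, UCR],
    genes: Sequence[GeneRecord],
    window: int = DEFAULT_WINDOW,
    min_genes: int = DEFAULT_MIN_GENES,
    p_threshold: float = 0.05,
    min_hits: int = 3,
) -> pd.DataFrame:
    """Domain-enrichment table over all clusters.

    Clusters with fewer than min_genes nearby genes are skipped (with a
    log entry).  The species pool of a cluster is every gene of every
    species represented among its members.
    """
    genes_by_species: dict[str, list[GeneRecord]] = {}
    for g in genes:
        genes_by_species.setdefault(g.species, []).append(g)

    rows = []
    for cluster in clusters:
        members = [ucrs_by_id[m] for m in cluster.member_ids]
        species = sorted({u.species for u in members})
        pool = [g for sp in species for g in genes_by_species.get(sp, [])]
        nearby_map = find_nearby_genes(members, pool, window)
        nearby_ids = sorted({gid for ids in nearby_map.values() for gid in ids})
        if len(nearby_ids) < min_genes:
            logger.info(
                "cluster %d skipped: %d nearby genes < %d",
                cluster.cluster_id, len(nearby_ids), min_genes,
            )
            continue
        pool_by_id = {g.gene_id: g for g in pool}
        nearby = [pool_by_id[i] for i in nearby_ids]
        domains = sorted({dom for g in pool for dom in g.domains})
        G, g_count = len(pool), len(nearby)
        for dom in domains:
            D = sum(1 for g in pool if dom in g.domains)
            d = sum(1 for g in nearby if dom in g.domains)
            p = hypergeom_upper(G, g_count, D, d)
            rows.append(
                {
                    "cluster_id": cluster.cluster_id,
                    "domain": dom,
                    "G": G,
                    "g": g_count,
                    "D": D,
                    "d": d,
                    "p_value": p,
                }
            )
    df = pd.DataFrame(
        rows, columns=["cluster_id", "domain", "G", "g", "D", "d", "p_value"]
    )
    if len(df):
        from statsmodels.stats.multitest import multipletests

        df["adjusted_p"] = multipletests(df["p_value"], method="fdr_bh")[1]
        df["flagged"] = (df["p_value"] < p_threshold) & (df["d"] >= min_hits)
        df = df.sort_values(["cluster_id", "p_value"], kind="stable").reset_index(
            drop=True
        )
    else:
        df["adjusted_p"] = []
        df["flagged"] = []
    return df
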