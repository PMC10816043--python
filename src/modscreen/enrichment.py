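"""Gene-set overrepresentation and cross-subgroup shared signatures.

Each subgroup's surviving gene list is tested for overrepresentation in
every set of a GMT collection with a one-sided Fisher exact test — the
hypergeometric tail P(X >= k) for drawing ``n`` query genes from a
background universe of ``N`` genes of which ``K`` lie in the set — followed
by Benjamini–Hochberg FDR adjustment across the collection.

The background universe defaults to all genes carrying at least one
annotated variant in the joined input; an explicit universe can be supplied
instead.  Query genes outside the universe are logged and dropped.

The cross-subgroup signature of one analysis comprises: genes present in
every subgroup's list; gene sets hit (>= 1 query gene) in every subgroup;
and the subset of those sets with Fisher p < alpha in every subgroup.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


class GeneSetError(ValueError):
    """Malformed gene-set input."""


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    members: frozenset[str]


@dataclass(frozen=True)
class GeneSetCollection:
    """An ordered GMT collection; member symbols uppercased for matching."""

    sets: tuple[GeneSet, ...]
    source_tag: str = ""

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentResult:
    """One gene set's overrepresentation outcome for one query list."""

    set_id: str
    name: str
    k: int  # query genes inside the set
    n: int  # query-list size (within the universe)
    K: int  # set size within the universe
    N: int  # universe size
    p: float  # one-sided Fisher exact / hypergeometric tail
    q: float  # BH-adjusted


@dataclass(frozen=True)
class SharedSignature:
    """What all subgroups of one analysis have in common."""

    shared_genes: tuple[str, ...]
    shared_sets: tuple[str, ...]
    significant_shared_sets: tuple[str, ...]
    alpha: float


def read_gmt(path: str | Path, source_tag: str = "") -> GeneSetCollection:
    """Parse a standard GMT file (set name, description, member symbols).

    Duplicate member symbols within a line are deduplicated; duplicate set
    names are an error; a line with fewer than three columns is an error
    reported with its line number.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GeneSetError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns"
                )
            set_id, description = fields[0].strip(), fields[1].strip()
            if set_id in seen:
                raise GeneSetError(f"{path}:{lineno}: duplicate set name {set_id!r}")
            seen.add(set_id)
            members = frozenset(
                g.strip().upper() for g in fields[2:] if g.strip()
            )
            if not members:
                raise GeneSetError(f"{path}:{lineno}: set {set_id!r} has no members")
            sets.append(GeneSet(set_id=set_id, name=description or set_id, members=members))
    return GeneSetCollection(sets=tuple(sets), source_tag=source_tag or path.name)


def fisher_overrep(
    query: Sequence[str],
    set_members: Sequence[str],
    background: Sequence[str],
    *,
    set_id: str = "",
    name: str = "",
) -> EnrichmentResult:
    """One-sided (greater) Fisher exact test of query/set overlap.

    Equals the hypergeometric tail P(X >= k) for the 2x2 table
    ``[k, n-k; K-k, N-K-n+k]``.  Query genes outside the background are
    logged and dropped; an empty background is an error.
    """
    universe = {g.upper() for g in background}
    if not universe:
        raise GeneSetError("empty background universe")
    q = {g.upper() for g in query}
    outside = q - universe
    if outside:
        logger.info("%d query genes outside the universe dropped: %s",
                    len(outside), sorted(outside)[:10])
    q &= universe
    members = {g.upper() for g in set_members} & universe

    N, n, K = len(universe), len(q), len(members)
    k = len(q & members)
    # hypergeom.sf(k-1, N, K, n) = P(X >= k)
    p = float(hypergeom.sf(k - 1, N, K, n))
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return EnrichmentResult(set_id=set_id, name=name or set_id,
                            k=k, n=n, K=K, N=N, p=p, q=p)


def adjust_fdr(pvalues: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up q-values, mapped back to input order."""
    if len(pvalues) == 0:
        return []
    arr = np.asarray(pvalues, dtype=float)
    if np.any((arr <= 0) | (arr > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, qvals, _, _ = multipletests(arr, method="fdr_bh")
    return [float(q) for q in qvals]


def enrich(
    query: Sequence[str],
    collection: GeneSetCollection,
    background: Sequence[str],
) -> list[EnrichmentResult]:
    """Test every set of a collection and FDR-adjust across the collection."""
    raw = [
        fisher_overrep(query, s.members, background, set_id=s.set_id, name=s.name)
        for s in collection
    ]
    qvals = adjust_fdr([r.p for r in raw])
    return [
        EnrichmentResult(
            set_id=r.set_id, name=r.name, k=r.k, n=r.n, K=r.K, N=r.N,
            p=r.p, q=max(qv, r.p),
        )
        for r, qv in zip(raw, qvals)
    ]


def intersect_subgroups(
    per_subgroup_genes: Mapping[str, Sequence[str]],
    per_subgroup_enrichment: Mapping[str, Sequence[EnrichmentResult]],
    alpha: float = 0.05,
) -> SharedSignature:
    """Cross-subgroup intersection of gene lists and gene-set hits.

    Requires at least two subgroups.  A set is *shared* when every subgroup
    has at least one query gene in it, and *significant shared* when its
    Fisher p is below ``alpha`` in every subgroup.
    """
    if len(per_subgroup_genes) < 2:
        raise ValueError("need at least two subgroups to intersect")

    gene_sets = [
        {g.upper() for g in genes} for genes in per_subgroup_genes.values()
    ]
    shared = set.intersection(*gene_sets)
    # stable order: first subgroup's list order
    first = next(iter(per_subgroup_genes.values()))
    ordered = [g.upper() for g in first if g.upper() in shared]
    seen = set(ordered)
    ordered += sorted(shared - seen)

    hit_ids: list[set[str]] = []
    sig_ids: list[set[str]] = []
    for results in per_subgroup_enrichment.values():
        hit_ids.append({r.set_id for r in results if r.k >= 1})
        sig_ids.append({r.set_id for r in results if r.k >= 1 and r.p < alpha})
    shared_sets = set.intersection(*hit_ids) if hit_ids else set()
    significant = set.intersection(*sig_ids) if sig_ids else set()
    significant &= shared_sets

    return SharedSignature(
        shared_genes=tuple(ordered),
        shared_sets=tuple(sorted(shared_sets)),
        significant_shared_sets=tuple(sorted(significant)),
        alpha=alpha,
    )
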