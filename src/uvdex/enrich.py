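"""Functional-annotation enrichment and fuzzy term clustering.

Given a called gene list and a gene-set collection (GMT), each annotation
term is tested for over-representation against the array universe with the
EASE-adjusted hypergeometric tail (the observed overlap is reduced by one
before taking P(X >= overlap - 1), a deliberately conservative score).
Qualifying terms (p below a cutoff, at least ``min_overlap`` list genes) are
then grouped by Cohen's kappa agreement between their binary membership
vectors over the gene list: terms with enough strong partners seed fuzzy
clusters, clusters sharing most members merge, and each surviving cluster is
scored as -log10 of the geometric mean of its member term p-values; a score
of at least 1.3 (geometric-mean p < 0.05) marks the cluster enriched.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, GmtParseError

ENRICHED_SCORE_CUTOFF = 1.3


@dataclass
class GeneSetCollection:
    """Annotation terms: term id -> (description, member gene set)."""

    terms: dict
    source: str = ""

    def __post_init__(self):
        for tid, (_, members) in self.terms.items():
            if not members:
                raise DataError(f"term {tid!r} has no members")

    def members(self, term_id: str) -> frozenset:
        return self.terms[term_id][1]

    def __len__(self):
        return len(self.terms)

    def __eq__(self, other):
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return self.terms == other.terms


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file: term <tab> description <tab> genes...

    Duplicate members within a term are deduplicated; a line with fewer than
    3 fields raises :class:`GmtParseError` naming the line number.
    """
    terms = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            tid, desc, *genes = fields
            if tid in terms:
                raise GmtParseError(f"{path}: line {lineno}: duplicate term {tid!r}")
            members = frozenset(g for g in genes if g)
            if not members:
                raise GmtParseError(f"{path}: line {lineno}: term has no members")
            terms[tid] = (desc, members)
    return GeneSetCollection(terms, source=str(path))


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for tid, (desc, members) in collection.terms.items():
            fh.write("\t".join([tid, desc, *sorted(members)]) + "\n")


@dataclass
class EnrichmentResult:
    term_id: str
    overlap: int
    term_size: int
    list_size: int
    universe_size: int
    ease_p: float
    fold_enrichment: float


def term_enrichment(
    gene_list,
    term_members,
    universe,
    min_overlap: int = 3,
    ease: bool = True,
    term_id: str = "",
) -> EnrichmentResult | None:
    """EASE (or plain) hypergeometric enrichment of one term.

    EASE p = P(X >= overlap - 1) -- the tail evaluated with the overlap
    reduced by one.  Terms with overlap below ``min_overlap`` are filtered
    (returns None).  Fold enrichment = (overlap/list)/(term/universe).
    """
    universe = set(universe)
    if not universe:
        raise DataError("empty universe")
    gene_list = set(gene_list) & universe
    members = set(term_members) & universe
    k = len(gene_list & members)
    if k < min_overlap:
        return None
    M, K, n = len(universe), len(members), len(gene_list)
    shift = 1 if ease else 0
    p = float(stats.hypergeom.sf(k - 1 - shift, M, K, n))
    p = min(1.0, max(p, np.nextafter(0, 1)))
    fold = (k / n) / (K / M) if n and K else 0.0
    return EnrichmentResult(term_id, k, K, n, M, p, fold)


def enrich_terms(
    gene_list,
    collection: GeneSetCollection,
    universe,
    min_overlap: int = 3,
    max_p: float | None = 0.05,
    ease: bool = True,
) -> pd.DataFrame:
    """Enrichment table over a collection, filtered to qualifying terms."""
    rows = []
    for tid, (_, members) in collection.terms.items():
        r = term_enrichment(gene_list, members, universe,
                            min_overlap=min_overlap, ease=ease, term_id=tid)
        if r is None:
            continue
        if max_p is not None and r.ease_p >= max_p:
            continue
        rows.append(
            (r.term_id, r.overlap, r.term_size, r.list_size,
             r.universe_size, r.ease_p, r.fold_enrichment)
        )
    df = pd.DataFrame(
        rows,
        columns=["term", "overlap", "term_size", "list_size",
                 "universe_size", "ease_p", "fold_enrichment"],
    )
    return df.sort_values(["ease_p", "term"], kind="stable").reset_index(drop=True)


def kappa_matrix(term_members: dict, gene_list) -> pd.DataFrame:
    """Cohen's kappa between all term pairs' membership vectors.

    Membership is binary over ``gene_list``.  kappa = (p_o - p_e)/(1 - p_e)
    with observed agreement p_o and margin-based chance agreement p_e; pairs
    with p_e = 1 (jointly degenerate margins) are flagged and set to 0; the
    diagonal is 1.
    """
    if len(term_members) < 2:
        raise DataError("kappa matrix needs at least 2 terms")
    genes = sorted(set(gene_list))
    G = len(genes)
    if G == 0:
        raise DataError("empty gene list")
    ids = list(term_members)
    M = np.array(
        [[g in term_members[t] for g in genes] for t in ids], dtype=float
    )
    r = M.sum(axis=1)
    both = M @ M.T
    p_o = (2 * both + G - r[:, None] - r[None, :]) / G
    p_e = (np.outer(r, r) + np.outer(G - r, G - r)) / G ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        K = (p_o - p_e) / (1.0 - p_e)
    degenerate = np.isclose(p_e, 1.0)
    if degenerate.any():
        warnings.warn("kappa undefined for degenerate term pairs; set to 0",
                      stacklevel=2)
        K[degenerate] = 0.0
    np.fill_diagonal(K, 1.0)
    return pd.DataFrame(K, index=ids, columns=ids)


@dataclass
class TermCluster:
    """A fuzzy cluster of annotation terms with its EASE enrichment score."""

    members: tuple
    ease_score: float = float("nan")

    @property
    def enriched(self) -> bool:
        return self.ease_score >= ENRICHED_SCORE_CUTOFF

    def __len__(self):
        return len(self.members)


def fuzzy_cluster_terms(
    K: pd.DataFrame,
    threshold: float = 0.3,
    min_membership: int = 4,
    merge_overlap: float = 0.5,
) -> list:
    """Seed-and-merge fuzzy clustering on a kappa similarity matrix.

    Every term with at least ``min_membership - 1`` partners above the kappa
    threshold seeds a group of itself plus those partners; groups sharing at
    least ``merge_overlap`` of their smaller group's members merge
    iteratively to a fixpoint; groups below ``min_membership`` are dropped.
    A term may appear in several clusters (fuzzy membership).
    """
    ids = list(K.index)
    A = K.to_numpy()
    if not np.allclose(A, A.T, atol=1e-9):
        raise DataError("kappa matrix must be symmetric")
    np.fill_diagonal(A, -np.inf)
    groups = []
    for i in range(len(ids)):
        partners = set(np.flatnonzero(A[i] > threshold))
        if len(partners) >= min_membership - 1:
            groups.append(frozenset(partners | {i}))
    groups = list(dict.fromkeys(groups))  # dedupe, keep order
    merged = True
    while merged:
        merged = False
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                ga, gb = groups[a], groups[b]
                if len(ga & gb) >= merge_overlap * min(len(ga), len(gb)):
                    groups[a] = ga | gb
                    del groups[b]
                    merged = True
                    break
            if merged:
                break
        groups = list(dict.fromkeys(groups))
    clusters = [
        TermCluster(tuple(sorted(ids[i] for i in g)))
        for g in groups
        if len(g) >= min_membership
    ]
    clusters.sort(key=lambda c: (-len(c.members), c.members))
    return clusters


def enrichment_score(p_values) -> float:
    """-log10 of the geometric mean of member term p-values."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise DataError("enrichment score needs at least one p-value")
    if ((p < 0) | (p > 1)).any():
        raise DataError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn("p = 0 clipped to smallest positive value", stacklevel=2)
        p = np.clip(p, np.nextafter(0, 1), 1.0)
    return float(-np.mean(np.log10(p)))


def cluster_enrichment(
    gene_list,
    collection: GeneSetCollection,
    universe,
    min_overlap: int = 3,
    max_p: float = 0.05,
    kappa_threshold: float = 0.3,
    min_membership: int = 4,
    ease: bool = True,
) -> list:
    """End-to-end DAVID-style annotation clustering of a gene list.

    Enrich every term, keep qualifying ones, cluster them by kappa agreement
    over the gene list, and score each cluster; returns TermClusters sorted
    by descending enrichment score.
    """
    table = enrich_terms(gene_list, collection, universe,
                         min_overlap=min_overlap, max_p=max_p, ease=ease)
    if len(table) < 2:
        return []
    keep = {t: collection.members(t) for t in table["term"]}
    K = kappa_matrix(keep, set(gene_list) & set(universe))
    clusters = fuzzy_cluster_terms(K, threshold=kappa_threshold,
                                   min_membership=min_membership)
    pmap = dict(zip(table["term"], table["ease_p"]))
    scored = [
        TermCluster(c.members, enrichment_score([pmap[t] for t in c.members]))
        for c in clusters
    ]
    scored.sort(key=lambda c: (-c.ease_score, c.members))
    return scored


def synthetic_annotation(
    gene_ids,
    signal_genes,
    rng,
    family_terms: int = 6,
    core_fraction: float = 0.5,
    term_extra_fraction: float = 0.15,
    n_background_terms: int = 40,
    background_size_range: tuple = (10, 50),
    family_label: str = "FAMILY",
) -> GeneSetCollection:
    """A synthetic GMT-style collection with one planted enriched family.

    Synthetic stand-in for a curated annotation database.  The family terms
    model redundant annotations of one biological process: all share a core
    of ``core_fraction`` of the signal genes and add ``term_extra_fraction``
    term-specific signal genes plus a few unrelated members, so over a list
    dominated by the signal genes the family terms agree strongly (kappa
    well above chance) without saturating the list.  Background terms are
    random draws from the universe.
    """
    gene_ids = list(gene_ids)
    signal = sorted(set(signal_genes))
    if not signal:
        raise DataError("signal_genes must be non-empty")
    terms = {}
    n_core = max(3, int(round(core_fraction * len(signal))))
    core = frozenset(rng.choice(signal, size=min(n_core, len(signal)),
                                replace=False))
    for i in range(family_terms):
        n_extra = max(1, int(round(term_extra_fraction * len(signal))))
        extra = rng.choice(signal, size=min(n_extra, len(signal)),
                           replace=False)
        padding = rng.choice(gene_ids, size=max(2, len(signal) // 10),
                             replace=False)
        terms[f"{family_label}_{i + 1}"] = (
            f"planted family term {i + 1}",
            core | frozenset(extra) | frozenset(padding),
        )
    lo, hi = background_size_range
    for i in range(n_background_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(gene_ids, size=size, replace=False)
        terms[f"BG_{i + 1}"] = (f"background term {i + 1}", frozenset(members))
    return GeneSetCollection(terms, source="synthetic")
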