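"""Local over-representation analysis over packaged gene sets.

A query gene list is tested against each pathway with the upper-tail
hypergeometric test (the probability of drawing at least the observed
number of pathway members in a random query of the same size from the
universe), with Benjamini–Hochberg q-values across pathways and a gene
ratio of 100·k/K (percentage of the pathway hit by the query). Only query
genes that belong to at least one pathway enter the calculation, and the
universe defaults to the union of all pathway genes.

This is a deliberately plain replacement for a web enrichment service:
just p, BH q, and gene ratio — no combined or composite scores. Kinase
names are mapped to gene symbols through a packaged alias table
(e.g. PKG1 → PRKG1); unmapped names are dropped with a warning count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "load_toy_pathways",
    "load_alias_table",
    "map_kinases_to_genes",
    "hypergeom_test",
    "bh_adjust",
    "run_ora",
]

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets plus the gene universe they are tested against."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self) -> None:
        self.sets = {name: {g.upper() for g in s} for name, s in self.sets.items()}
        self.universe = {g.upper() for g in self.universe}
        for name, s in self.sets.items():
            if not s:
                raise ValueError(f"gene set {name!r} is empty")
            extra = s - self.universe
            if extra:
                raise ValueError(f"gene set {name!r} has genes outside the universe: {sorted(extra)[:5]}")


def read_gmt(path, universe: set[str] | None = None) -> GeneSetCollection:
    """Read GMT (name, description, tab-separated symbols per line)."""
    sets: dict[str, set[str]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            sets[parts[0]] = {g for g in parts[2:] if g}
    if universe is None:
        universe = set().union(*sets.values()) if sets else set()
    return GeneSetCollection(sets=sets, universe=universe)


def load_toy_pathways() -> GeneSetCollection:
    """The packaged toy pathway collection (synthetic membership lists)."""
    with resources.as_file(resources.files("kinomeprofiler.data") / "toy_pathways.gmt") as p:
        return read_gmt(p)


def load_alias_table(path=None) -> dict[str, str]:
    """Kinase-name → gene-symbol alias map (packaged default)."""
    if path is None:
        with resources.as_file(
            resources.files("kinomeprofiler.data") / "kinase_gene_aliases.tsv"
        ) as p:
            df = pd.read_csv(p, sep="\t")
    else:
        df = pd.read_csv(path, sep="\t")
    return dict(zip(df["alias"].astype(str), df["gene_symbol"].astype(str)))


def map_kinases_to_genes(kinases: list[str], aliases: dict[str, str] | None = None) -> list[str]:
    """Translate kinase names to gene symbols, dropping unmapped names with a warning."""
    if aliases is None:
        aliases = load_alias_table()
    fold = {k.casefold(): v for k, v in aliases.items()}
    mapped, dropped = [], []
    for k in kinases:
        sym = fold.get(k.casefold())
        (mapped if sym else dropped).append(sym or k)
    if dropped:
        logger.warning("dropped %d kinase names without a gene alias: %s", len(dropped), dropped[:5])
    return mapped


def hypergeom_test(k: int, n: int, K: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X ≥ k), X ~ Hypergeom(N, K, n)."""
    if not (0 <= k <= min(n, K) and K <= N and n <= N and k >= max(0, n + K - N)):
        raise ValueError(f"inconsistent counts k={k}, n={n}, K={K}, N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in the input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_ora(
    query: list[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric ORA of ``query`` against every set in ``collection``.

    Returns a table sorted by p ascending with columns pathway, k, n, K, N,
    p, q, gene_ratio (100·k/K). Query symbols are upper-cased; symbols
    outside the universe are dropped with a warning count; only query genes
    belonging to at least one pathway enter n and k.
    """
    q = {g.upper() for g in query}
    dropped = q - collection.universe
    if dropped:
        logger.warning("dropped %d query symbols outside the universe", len(dropped))
    q &= collection.universe
    in_any = set().union(*collection.sets.values())
    q &= in_any
    if not q:
        raise ValueError("query is empty after universe/pathway filtering")
    N = len(collection.universe)
    n = len(q)
    rows = []
    for name, genes in collection.sets.items():
        K = len(genes)
        hits = q & genes
        k = len(hits)
        rows.append(
            (name, k, n, K, N, hypergeom_test(k, n, K, N), 100.0 * k / K,
             ";".join(sorted(hits)))
        )
    df = pd.DataFrame(
        rows, columns=["pathway", "k", "n", "K", "N", "p", "gene_ratio", "hit_genes"]
    )
    df["q"] = bh_adjust(df["p"].to_numpy())
    df = df[["pathway", "k", "n", "K", "N", "p", "q", "gene_ratio", "hit_genes"]]
    return df.sort_values("p", kind="stable").reset_index(drop=True)
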