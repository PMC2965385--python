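"""Gene-set enrichment on 2x2 tables and candidate-regulator screens.

Each (query, annotation) pair within a fixed gene universe yields the
table

    a = |query & annotation|    b = |query - annotation|
    c = |annotation - query|    d = |universe - query - annotation|

scored by Fisher's exact test (two-sided by default, so both
enrichments and depletions are reported) with the odds ratio
(a*d)/(b*c); a zero denominator maps to an infinite odds ratio and a
zero numerator (with a usable denominator) to zero.  Multiple testing is
controlled with Benjamini-Hochberg at a 10% false discovery rate by
default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    query_name: str
    set_name: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float

    @property
    def log2_odds_ratio(self) -> float:
        if self.odds_ratio == 0:
            return float("-inf")
        return float(np.log2(self.odds_ratio))

    def haldane_log2_odds_ratio(self) -> float:
        """log2 OR with a +0.5 continuity correction, finite for plotting."""
        a, b, c, d = (x + 0.5 for x in (self.a, self.b, self.c, self.d))
        return float(np.log2((a * d) / (b * c)))


def _odds_ratio(a: int, b: int, c: int, d: int) -> float:
    if b * c == 0:
        return float("inf")
    return (a * d) / (b * c)


def fisher_enrichment(
    query: set,
    annotation: set,
    universe: set,
    alternative: str = "two-sided",
    query_name: str = "query",
    set_name: str = "set",
) -> EnrichmentResult:
    """Fisher's exact test for overlap of two gene sets within a universe.

    Genes outside the universe are dropped from both sets with a
    warning.  ``alternative='greater'`` gives the enrichment-only test.
    """
    if not universe:
        raise ValueError("empty universe")
    query, annotation, universe = set(query), set(annotation), set(universe)
    stray = (query | annotation) - universe
    if stray:
        warnings.warn(
            f"{len(stray)} gene(s) outside the universe dropped from enrichment test",
            stacklevel=2,
        )
        query &= universe
        annotation &= universe
    a = len(query & annotation)
    b = len(query - annotation)
    c = len(annotation - query)
    d = len(universe) - a - b - c
    _, p = stats.fisher_exact([[a, b], [c, d]], alternative=alternative)
    return EnrichmentResult(
        query_name=query_name,
        set_name=set_name,
        a=a,
        b=b,
        c=c,
        d=d,
        odds_ratio=_odds_ratio(a, b, c, d),
        p=float(p),
    )


def bh_adjust(p_values, fdr: float = 0.10) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: q-values and rejection flags at ``fdr``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    reject, q, _, _ = multipletests(p, alpha=fdr, method="fdr_bh")
    return q, reject


def read_gene_sets(collections: dict) -> dict[str, set]:
    """Normalize a name -> iterable-of-genes mapping (duplicates collapsed)."""
    out = {}
    for name, members in collections.items():
        genes = {str(g) for g in members if str(g)}
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        out[name] = genes
    return out


def enrichment_grid(
    class_genes: dict[str, set],
    collections: dict[str, set],
    universe: set,
    alternative: str = "two-sided",
    fdr: float = 0.10,
) -> pd.DataFrame:
    """One Fisher test per (class, gene set), BH-adjusted over the grid.

    Returns a long-format frame ordered classes-outer / sets-inner, with
    2x2 counts, odds ratio, log2 OR (Haldane-corrected copy for
    heatmaps), p, q and the rejection flag.  Empty classes yield rows
    with undefined statistics flagged ``computed=False``.
    """
    if not class_genes or not collections:
        raise ValueError("classes and collections must be nonempty")
    rows = []
    for cls, genes in class_genes.items():
        for set_name, members in collections.items():
            if len(genes) == 0:
                rows.append(
                    {
                        "query_name": cls,
                        "set_name": set_name,
                        "a": 0, "b": 0, "c": 0, "d": 0,
                        "odds_ratio": np.nan,
                        "log2_or": np.nan,
                        "log2_or_haldane": np.nan,
                        "p": np.nan,
                        "computed": False,
                    }
                )
                continue
            r = fisher_enrichment(
                genes, members, universe,
                alternative=alternative, query_name=cls, set_name=set_name,
            )
            rows.append(
                {
                    "query_name": cls,
                    "set_name": set_name,
                    "a": r.a, "b": r.b, "c": r.c, "d": r.d,
                    "odds_ratio": r.odds_ratio,
                    "log2_or": r.log2_odds_ratio,
                    "log2_or_haldane": r.haldane_log2_odds_ratio(),
                    "p": r.p,
                    "computed": True,
                }
            )
    grid = pd.DataFrame(rows)
    computed = grid["computed"].to_numpy()
    q = np.full(len(grid), np.nan)
    flag = np.zeros(len(grid), dtype=bool)
    if computed.any():
        q[computed], flag[computed] = bh_adjust(grid.loc[computed, "p"], fdr=fdr)
    grid["q"] = q
    grid["significant"] = flag
    return grid


def grid_to_matrix(grid: pd.DataFrame, value: str = "log2_or_haldane") -> pd.DataFrame:
    """Pivot a long-format grid into a classes x sets heatmap matrix."""
    return grid.pivot(index="query_name", columns="set_name", values=value)


#: candidate-regulator presets: column requirements and filters
SCREEN_PRESETS = ("rbp", "mirna")


def screen_candidates(
    table: pd.DataFrame,
    preset: str,
    max_half_life: float = 150.0,
    min_peptides: int = 5,
    min_early_reads: float = 100.0,
) -> pd.DataFrame:
    """Filter a feature table down to candidate decay regulators.

    ``rbp``: RNA-binding proteins with dynamic expression - mRNA
    half-life strictly below ``max_half_life`` minutes AND at least
    ``min_peptides`` quantified peptides.

    ``mirna``: miRNAs with strong early-embryo expression - more than
    ``min_early_reads`` sequencing reads early AND a strict decrease in
    reads at later stages.
    """
    if preset == "rbp":
        required = ["half_life_min", "peptides"]
    elif preset == "mirna":
        required = ["early_reads", "late_reads"]
    else:
        raise ValueError(f"unknown preset {preset!r}; expected one of {SCREEN_PRESETS}")
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValueError(f"feature table lacks required columns: {missing}")
    if table.empty:
        return table.copy()
    if preset == "rbp":
        keep = (table["half_life_min"] < max_half_life) & (table["peptides"] >= min_peptides)
    else:
        keep = (table["early_reads"] > min_early_reads) & (
            table["late_reads"] < table["early_reads"]
        )
    return table.loc[keep.fillna(False)].copy()
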