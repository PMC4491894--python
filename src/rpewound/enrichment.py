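"""Directional gene-set enrichment and the fold + ANOVA candidate screen.

Disease gene lists carry a direction (up/down); they are matched only to
the DE set of the same direction, both restricted to the expressed-gene
universe, and over-representation is tested with a one-sided Fisher's
exact test (upper-tail hypergeometric). The screen used for curated
pathway/risk panels passes a gene when any time point shows a two-fold or
greater group difference with one-way ANOVA p <= 0.05 across the two
passage groups (n = 3 each).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


class EnrichmentError(ValueError):
    pass


@dataclass(frozen=True)
class GeneSet:
    name: str
    direction: str  # 'up', 'down' or 'none'
    members: tuple[str, ...]

    def __post_init__(self):
        if self.direction not in ("up", "down", "none"):
            raise EnrichmentError(f"bad direction {self.direction!r} for set {self.name}")
        deduped = tuple(dict.fromkeys(self.members))
        object.__setattr__(self, "members", deduped)

    def __len__(self) -> int:
        return len(self.members)


def restrict_to_universe(gene_set: GeneSet, universe) -> GeneSet:
    """Drop members outside the expressed-gene universe (after dedup)."""
    universe = set(universe)
    if not universe:
        raise EnrichmentError("empty gene universe")
    kept = tuple(m for m in gene_set.members if m in universe)
    return GeneSet(gene_set.name, gene_set.direction, kept)


def directional_overlap(disease_up: GeneSet, disease_down: GeneSet,
                        de_up: GeneSet, de_down: GeneSet) -> dict[str, set]:
    """Overlaps matched by direction only: up-with-up and down-with-down."""
    for s in (disease_up, disease_down, de_up, de_down):
        if s.direction == "none":
            raise EnrichmentError(f"gene set {s.name} lacks a direction tag")
    return {
        "up": set(disease_up.members) & set(de_up.members),
        "down": set(disease_down.members) & set(de_down.members),
    }


@dataclass
class EnrichmentResult:
    query: str
    target: str
    direction: str
    k: int           # overlap
    n_query: int
    n_target: int
    universe: int
    odds_ratio: float
    p_value: float

    def to_dict(self) -> dict:
        return {"query": self.query, "target": self.target,
                "direction": self.direction, "overlap": self.k,
                "n_query": self.n_query, "n_target": self.n_target,
                "universe": self.universe, "odds_ratio": self.odds_ratio,
                "p_value": self.p_value}


def fisher_enrichment(k: int, n_query: int, n_target: int, n_universe: int,
                      alternative: str = "greater",
                      query: str = "query", target: str = "target",
                      direction: str = "none") -> EnrichmentResult:
    """Fisher's exact test on the 2x2 overlap table.

    Cells: a = k (in both), b = n_query - k, c = n_target - k,
    d = N - n_query - n_target + k. One-sided p is the upper-tail
    hypergeometric probability P(X >= k); the odds ratio is the sample
    cross-product ratio with a Haldane 0.5 correction when any cell is zero.
    """
    a, b = k, n_query - k
    c, d = n_target - k, n_universe - n_query - n_target + k
    if min(a, b, c, d) < 0:
        raise EnrichmentError(
            f"inconsistent 2x2 table: k={k}, n_query={n_query}, "
            f"n_target={n_target}, N={n_universe}")
    if alternative == "greater":
        p = float(stats.hypergeom.sf(k - 1, n_universe, n_target, n_query))
    elif alternative == "two-sided":
        p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    else:
        raise EnrichmentError(f"unknown alternative: {alternative}")
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    else:
        a2, b2, c2, d2 = a, b, c, d
    odds = (a2 * d2) / (b2 * c2)
    return EnrichmentResult(query=query, target=target, direction=direction,
                            k=k, n_query=n_query, n_target=n_target,
                            universe=n_universe, odds_ratio=float(odds),
                            p_value=min(p, 1.0))


def enrich_directional(disease_sets: dict[str, GeneSet], de_up: GeneSet,
                       de_down: GeneSet, universe,
                       alternative: str = "greater") -> list[EnrichmentResult]:
    """Run direction-matched Fisher enrichment for every disease set.

    Every set (disease and DE) is first restricted to the universe; each
    disease set is tested against the DE set of the same direction.
    """
    universe = list(dict.fromkeys(universe))
    de = {"up": restrict_to_universe(de_up, universe),
          "down": restrict_to_universe(de_down, universe)}
    results = []
    for name, dset in disease_sets.items():
        if dset.direction not in de:
            raise EnrichmentError(f"disease set {name} lacks a direction tag")
        restricted = restrict_to_universe(dset, universe)
        target = de[dset.direction]
        k = len(set(restricted.members) & set(target.members))
        results.append(fisher_enrichment(
            k, len(restricted), len(target), len(universe),
            alternative=alternative, query=name, target=target.name,
            direction=dset.direction))
    return results


def one_way_anova_two_group(group1, group2) -> tuple[float, float]:
    """One-way ANOVA F and p for two groups (equals the squared pooled t)."""
    g1 = np.asarray(group1, float)
    g2 = np.asarray(group2, float)
    if len(g1) < 2 or len(g2) < 2:
        raise EnrichmentError("ANOVA needs at least two replicates per group")
    f, p = stats.f_oneway(g1, g2)
    return float(f), float(p)


def fold_anova_screen(expr: pd.DataFrame, sheet: pd.DataFrame,
                      gene_list=None, condition_col: str = "passage",
                      ref: str = "P0", alt: str = "P5", within: str = "day",
                      min_fold: float = 2.0, alpha: float = 0.05) -> pd.DataFrame:
    """Two-fold + ANOVA screen on linear-scale expression, per time point.

    For each gene and time point the linear group-mean ratio alt/ref and a
    one-way ANOVA on log2 values across the two groups are computed; a gene
    passes when some time point has |log2 ratio| >= log2(min_fold) and
    p <= alpha. The returned frame carries per-time log2 ratios and p-values
    plus the overall pass flag and the log2 ratio at the most significant
    passing time point.
    """
    if gene_list is not None:
        expr = expr.loc[pd.Index(gene_list)]
    if (expr.to_numpy(float) <= 0).any():
        raise EnrichmentError("screen requires positive linear expression values")
    days = sorted(sheet.loc[sheet[condition_col].isin([ref, alt]), within].unique())
    out = pd.DataFrame(index=expr.index)
    pass_any = np.zeros(len(expr), dtype=bool)
    for day in days:
        ids_ref = sheet.loc[(sheet[condition_col] == ref)
                            & (sheet[within] == day), "sample_id"].tolist()
        ids_alt = sheet.loc[(sheet[condition_col] == alt)
                            & (sheet[within] == day), "sample_id"].tolist()
        if len(ids_ref) < 2 or len(ids_alt) < 2:
            raise EnrichmentError(
                f"need >=2 replicates per group at {within}={day}")
        g_ref = expr[ids_ref].to_numpy(float)
        g_alt = expr[ids_alt].to_numpy(float)
        log2_ratio = np.log2(g_alt.mean(axis=1) / g_ref.mean(axis=1))
        f, p = stats.f_oneway(np.log2(g_alt), np.log2(g_ref), axis=1)
        out[f"log2_ratio_{within}{day}"] = log2_ratio
        out[f"anova_p_{within}{day}"] = p
        pass_any |= (np.abs(log2_ratio) >= np.log2(min_fold)) & (p <= alpha)
    out["passes"] = pass_any
    ratio_cols = [c for c in out.columns if c.startswith("log2_ratio_")]
    p_cols = [c for c in out.columns if c.startswith("anova_p_")]
    best = out[p_cols].to_numpy().argmin(axis=1)
    out["log2_ratio_best"] = out[ratio_cols].to_numpy()[np.arange(len(out)), best]
    return out
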