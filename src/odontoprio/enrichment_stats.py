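"""The statistical layer: permutation set enrichment with Benjamini-Hochberg
correction, exact Fisher 2x2 contingency analysis, and module-level
enrichment flag derivation.

Permutation enrichment draws uniform random gene subsets of the universe and
compares the observed query/target overlap against that null; empirical
p-values carry the +1 correction, so they are never exactly zero and bottom
out at 1/(n_perm + 1). The Fisher test is computed with exact integer
hypergeometric weights under the probability-ordering two-sided rule (the
convention of mainstream statistics tools).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentResult",
    "ContingencyResult",
    "permutation_set_enrichment",
    "bh_adjust",
    "fisher_2x2",
    "ModuleFlags",
    "ModuleEnrichment",
    "module_enrichment_flags",
]


@dataclass
class EnrichmentResult:
    """Outcome of one permutation set-enrichment test."""

    observed: int
    null_mean: float
    fold: float
    log2_fold: float
    p_empirical: float
    n_perm: int
    seed: int
    direction: str = "greater"  # tail tested: "greater" (enrichment) or "less"
    p_adjusted: float | None = None  # filled in across a test family by BH


def permutation_set_enrichment(
    query: set[str],
    target: set[str],
    universe: set[str],
    n_perm: int = 10_000,
    seed: int = 0,
    direction: str = "greater",
) -> EnrichmentResult:
    """Permutation enrichment of ``query`` within ``target`` over ``universe``.

    Draws ``n_perm`` uniform random subsets of the universe of size
    ``|query|`` and scores the overlap with ``target``; the empirical p is
    (1 + #{null >= observed}) / (1 + n_perm) for the ``greater`` tail (and
    symmetrically for ``less``). Fully reproducible from ``seed``.
    """
    if not universe:
        raise ValueError("universe is empty")
    if not query <= universe:
        raise ValueError("query is not a subset of the universe")
    if not target <= universe:
        raise ValueError("target is not a subset of the universe")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if direction not in ("greater", "less"):
        raise ValueError(f"unknown direction {direction!r}")

    uni = sorted(universe)
    n, k = len(uni), len(query)
    mask = np.fromiter((g in target for g in uni), dtype=bool, count=n)
    observed = len(query & target)

    rng = np.random.default_rng(seed)
    if k == 0:
        overlaps = np.zeros(n_perm, dtype=np.int64)
    else:
        overlaps = np.empty(n_perm, dtype=np.int64)
        # chunked uniform k-subset sampling: argpartition of random keys
        chunk = max(1, int(5e7) // max(n, 1))
        done = 0
        while done < n_perm:
            m = min(chunk, n_perm - done)
            keys = rng.random((m, n))
            idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
            overlaps[done : done + m] = mask[idx].sum(axis=1)
            done += m

    null_mean = float(overlaps.mean())
    if direction == "greater":
        exceed = int((overlaps >= observed).sum())
    else:
        exceed = int((overlaps <= observed).sum())
    p_emp = (1 + exceed) / (1 + n_perm)
    fold = observed / null_mean if null_mean > 0 else math.nan
    log2_fold = math.log2(fold) if null_mean > 0 and fold > 0 else math.nan
    return EnrichmentResult(
        observed=observed,
        null_mean=null_mean,
        fold=fold,
        log2_fold=log2_fold,
        p_empirical=p_emp,
        n_perm=n_perm,
        seed=seed,
        direction=direction,
    )


def bh_adjust(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return []
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("p-values must lie in [0, 1]")
    return list(multipletests(arr, method="fdr_bh")[1])


# ---------------------------------------------------------------------------
# Fisher exact 2x2
# ---------------------------------------------------------------------------


@dataclass
class ContingencyResult:
    """Exact analysis of a 2x2 table [[a, b], [c, d]].

    ``prop_ratio`` is the ratio of row proportions (a/(a+b)) / (c/(c+d)),
    the "fold increase" with the complement group as baseline.
    """

    table: tuple[tuple[int, int], tuple[int, int]]
    odds_ratio: float
    prop_ratio: float
    p_two_tailed: float


@lru_cache(maxsize=65536)
def _hypergeom_weights(r1: int, r2: int, c1: int) -> tuple[int, tuple[int, ...], int]:
    """Integer weights C(r1,k)*C(r2,c1-k) over the support; returns
    (k_min, weights, total) with total = C(r1+r2, c1)."""
    k_min = max(0, c1 - r2)
    k_max = min(r1, c1)
    weights = tuple(
        math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(k_min, k_max + 1)
    )
    return k_min, weights, math.comb(r1 + r2, c1)


def fisher_2x2(a: int, b: int, c: int, d: int) -> ContingencyResult:
    """Two-tailed Fisher exact test with exact integer arithmetic.

    The two-tailed p sums the hypergeometric probabilities of all tables
    (margins fixed) whose point probability does not exceed the observed
    table's; ties are exact, not tolerance-based.
    """
    for x in (a, b, c, d):
        if not isinstance(x, (int, np.integer)) or x < 0:
            raise ValueError("counts must be non-negative integers")
    if a + b == 0 or c + d == 0:
        raise ValueError("a row of the table is empty: proportions undefined")

    r1, r2, c1 = a + b, c + d, a + c
    k_min, weights, total = _hypergeom_weights(r1, r2, c1)
    w_obs = weights[a - k_min]
    matched = sum(w for w in weights if w <= w_obs)
    p = float(Fraction(matched, total))
    p = min(p, 1.0)

    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    p1 = a / (a + b)
    p2 = c / (c + d)
    if p2 == 0:
        prop_ratio = math.inf if p1 > 0 else math.nan
    else:
        prop_ratio = p1 / p2
    return ContingencyResult(
        table=((a, b), (c, d)),
        odds_ratio=odds,
        prop_ratio=prop_ratio,
        p_two_tailed=p,
    )


# ---------------------------------------------------------------------------
# module-level enrichment flags
# ---------------------------------------------------------------------------

_CATEGORIES = ("te_targets", "dental_ontology", "degs")


@dataclass(frozen=True)
class ModuleFlags:
    enr_te_targets: bool = False
    enr_dental_ontology: bool = False
    enr_degs: bool = False

    def n_true(self) -> int:
        return int(self.enr_te_targets) + int(self.enr_dental_ontology) + int(self.enr_degs)


@dataclass
class ModuleEnrichment:
    flags: dict[str, ModuleFlags]
    table: pd.DataFrame  # module, category, observed, expected, fold, log2_fold, p, padj, seed


def module_enrichment_flags(
    module_members: dict[str, set[str]],
    te_targets: set[str],
    dental_ontology_genes: set[str],
    deg_set: set[str],
    universe: set[str],
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
) -> ModuleEnrichment:
    """Per-module enrichment flags for three gene categories.

    Each (module, category) pair gets a permutation enrichment test; the flag
    is true iff fold > 1 and the BH-adjusted p across the whole module x
    category family is <= alpha. Category sets are intersected with the
    universe; an empty category yields a false flag, not an error.
    """
    for mod, members in module_members.items():
        if not members <= universe:
            raise ValueError(f"module {mod!r} has members outside the universe")
    categories = {
        "te_targets": te_targets & universe,
        "dental_ontology": dental_ontology_genes & universe,
        "degs": deg_set & universe,
    }
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(
        len(module_members) * len(_CATEGORIES)
    )]

    rows = []
    results: list[EnrichmentResult] = []
    i = 0
    for mod in sorted(module_members):
        for cat in _CATEGORIES:
            res = permutation_set_enrichment(
                query=module_members[mod],
                target=categories[cat],
                universe=universe,
                n_perm=n_perm,
                seed=child_seeds[i],
            )
            results.append(res)
            rows.append({"module": mod, "category": cat})
            i += 1

    padj = bh_adjust([r.p_empirical for r in results])
    flags: dict[str, ModuleFlags] = {}
    table_rows = []
    for (row, res, q) in zip(rows, results, padj):
        res.p_adjusted = q
        enriched = (not math.isnan(res.fold)) and res.fold > 1 and q <= alpha
        table_rows.append(
            {
                **row,
                "observed": res.observed,
                "expected": res.null_mean,
                "fold": res.fold,
                "log2_fold": res.log2_fold,
                "p": res.p_empirical,
                "padj": q,
                "seed": res.seed,
                "enriched": enriched,
            }
        )
    df = pd.DataFrame(table_rows)
    for mod in sorted(module_members):
        sub = df[df["module"] == mod].set_index("category")["enriched"]
        flags[mod] = ModuleFlags(
            enr_te_targets=bool(sub["te_targets"]),
            enr_dental_ontology=bool(sub["dental_ontology"]),
            enr_degs=bool(sub["degs"]),
        )
    return ModuleEnrichment(flags=flags, table=df)
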