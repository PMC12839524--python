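"""Fisher's-exact GO enrichment of DE transcripts and its cross-species comparison.

For each species, the universe is the set of annotated, tested transcripts; a
transcript is DE when its BH-adjusted p falls below the chosen threshold
(default 0.1). Each GO term gets a 2x2 table (DE/term membership), a two-sided
exact p defined by summing all tables with point probability at most the
observed one, and a conditional maximum-likelihood odds ratio of the
noncentral hypergeometric distribution — both matching the conventions of R's
``fisher.test``, which the two-sided-p definition ambiguity makes worth
stating. Enrichment similarity between species is the Pearson correlation of
odds ratios over shared terms.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _conditional_or

from .cross_species import correlation_distribution_test
from .io import GOAnnotation

__all__ = [
    "fisher_enrichment",
    "pairwise_enrichment_correlations",
]


def _fisher_cell(a: int, b: int, c: int, d: int):
    table = np.array([[a, b], [c, d]])
    p = stats.fisher_exact(table, alternative="two-sided").pvalue
    # conditional MLE is infinite when b or c is 0 and undefined on double margins
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return np.nan, p
    if b == 0 or c == 0:
        return np.inf, p
    if a == 0 or d == 0:
        return 0.0, p
    return float(_conditional_or(table, kind="conditional").statistic), p


def fisher_enrichment(
    de_transcripts: set,
    annotation: GOAnnotation,
    species_id: str,
    universe: set | None = None,
) -> pd.DataFrame:
    """Per-term enrichment of DE transcripts for one species.

    ``universe`` defaults to every annotated transcript of the species (a
    transcript with an empty term set still belongs to the universe). Terms
    absent from the universe are skipped. Columns: a, b, c, d (DE&term,
    DE&~term, ~DE&term, ~DE&~term), odds_ratio, p.
    """
    terms_by_tx = annotation.terms_for(species_id)
    if universe is not None:
        terms_by_tx = terms_by_tx[terms_by_tx.index.isin(universe)]
    txs = list(terms_by_tx.index)
    n_univ = len(txs)
    if n_univ == 0:
        raise ValueError(f"empty annotation universe for species {species_id!r}")
    is_de = np.array([tx in de_transcripts for tx in txs])
    n_de = int(is_de.sum())

    term_counts, term_de_counts = {}, {}
    for tx_terms, de_flag in zip(terms_by_tx, is_de):
        for term in tx_terms:
            term_counts[term] = term_counts.get(term, 0) + 1
            if de_flag:
                term_de_counts[term] = term_de_counts.get(term, 0) + 1

    rows = []
    for term in sorted(term_counts):
        a = term_de_counts.get(term, 0)
        c = term_counts[term] - a
        b = n_de - a
        d = n_univ - a - b - c
        orr, p = _fisher_cell(a, b, c, d)
        rows.append((term, a, b, c, d, orr, p))
    out = pd.DataFrame(
        rows, columns=["go_term", "a", "b", "c", "d", "odds_ratio", "p"]
    ).set_index("go_term")
    out.insert(0, "species_id", species_id)
    return out


def pairwise_enrichment_correlations(
    tables: dict, *, infinite_or: str = "exclude", min_shared: int = 3
) -> pd.DataFrame:
    """Pearson correlation of enrichment odds ratios for every species pair.

    Correlations are over GO terms present in both species. Infinite odds
    ratios are excluded by default; ``infinite_or='haldane'`` instead
    substitutes the Haldane–Anscombe-corrected sample odds ratio
    (a+.5)(d+.5)/((b+.5)(c+.5)) everywhere, which is finite by construction.
    """
    if infinite_or not in ("exclude", "haldane"):
        raise ValueError(f"unknown infinite-OR policy {infinite_or!r}")
    ors = {}
    for sp, tab in tables.items():
        if infinite_or == "haldane":
            vals = ((tab["a"] + 0.5) * (tab["d"] + 0.5)) / (
                (tab["b"] + 0.5) * (tab["c"] + 0.5)
            )
        else:
            vals = tab["odds_ratio"].replace([np.inf, -np.inf], np.nan)
        ors[sp] = vals
    mat = pd.DataFrame(ors)
    species = list(mat.columns)
    rows = []
    for a, b in itertools.combinations(species, 2):
        sub = mat[[a, b]].dropna()
        n = len(sub)
        if n < min_shared:
            rows.append((a, b, np.nan, n, np.nan, np.nan, "too_few_shared"))
            continue
        if sub[a].nunique() == 1 or sub[b].nunique() == 1:
            rows.append((a, b, np.nan, n, np.nan, np.nan, "constant"))
            continue
        r, p = stats.pearsonr(sub[a], sub[b])
        t = r * np.sqrt((n - 2) / max(1.0 - r**2, 1e-300))
        rows.append((a, b, r, n, t, p, "ok"))
    return pd.DataFrame(
        rows, columns=["species_a", "species_b", "r", "n_terms", "t", "p", "status"]
    )
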