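"""Cross-species effect-size decomposition and transcriptome-wide correlations.

Per orthogroup, an OLS model of summed normalized expression on
treatment + species + treatment:species yields Type-II F tests and eta-squared
effect sizes (SS_effect / SS_total), separating a shared treatment response
from species-specific (interaction) responses. Transcriptome-wide similarity
between species is measured by Pearson correlation of the per-orthogroup Wald
statistic vectors for every species pair, and the distribution of pairwise
correlations is tested against zero with a one-sample t-test (pairs treated as
independent observations, as is conventional in this design despite their
dependence).

Type-II sums of squares are obtained by model comparison (full vs drop-one),
which stays correct under mild imbalance; because every orthogroup shares the
same design, the projections are computed once and applied to the whole matrix.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .io import OrthogroupMap, SampleMetadata

__all__ = [
    "og_anova",
    "fit_og_anova",
    "effect_size_scatter",
    "pairwise_wald_correlations",
    "correlation_distribution_test",
    "copy_number_lfc_correlation",
]


def _design_matrices(meta: pd.DataFrame):
    """Design matrices for the four nested models sharing the factorial design."""
    treat = (meta["treatment"] == "alum").to_numpy(float)
    species = pd.Categorical(meta["species_id"])
    S = len(species.categories)
    n = len(meta)
    sp_dummies = np.zeros((n, S))
    sp_dummies[np.arange(n), species.codes] = 1.0
    ones = np.ones((n, 1))
    X_t = np.hstack([ones, treat[:, None]])
    X_s = sp_dummies
    X_ts = np.hstack([sp_dummies, treat[:, None]])
    X_full = np.hstack([sp_dummies * (1 - treat)[:, None], sp_dummies * treat[:, None]])
    return {"t": X_t, "s": X_s, "ts": X_ts, "full": X_full}, S


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Residual sums of squares of Y's columns after projection onto col(X)."""
    Q, _ = np.linalg.qr(X)
    proj = Q.T @ Y
    return (Y**2).sum(axis=0) - (proj**2).sum(axis=0)


def og_anova(
    values: pd.DataFrame, metadata: SampleMetadata, *, log1p: bool = False
) -> pd.DataFrame:
    """Type-II two-way ANOVA with eta-squared, one row per orthogroup.

    ``values`` is the orthogroup x sample summed normalized expression (the
    response is untransformed by default; ``log1p`` applies log(1+x) first).
    Requires both treatments within every species; a design with an empty
    species x treatment cell is rank deficient for the interaction and every
    row is flagged rather than silently refit.
    """
    meta = metadata.for_samples(values.columns)
    designs, S = _design_matrices(meta)
    N = len(meta)
    cells = meta.groupby(["species_id", "treatment"], observed=False).size()
    out_index = values.index.rename("orthogroup_id")
    cols = [
        "F_treatment", "p_treatment", "eta2_treatment",
        "F_species", "p_species", "eta2_species",
        "F_interaction", "p_interaction", "eta2_interaction",
        "df_resid", "status",
    ]
    if (cells == 0).any() or len(cells) < 2 * S:
        out = pd.DataFrame(np.nan, index=out_index, columns=cols[:-1])
        out["df_resid"] = N - 2 * S
        out["status"] = "rank_deficient"
        return out

    Y = values.to_numpy(float).T
    if log1p:
        Y = np.log1p(Y)
    rss = {name: _rss(X, Y) for name, X in designs.items()}
    ss_total = ((Y - Y.mean(axis=0)) ** 2).sum(axis=0)
    ss = {
        "treatment": rss["s"] - rss["ts"],
        "species": rss["t"] - rss["ts"],
        "interaction": rss["ts"] - rss["full"],
    }
    df = {"treatment": 1, "species": S - 1, "interaction": S - 1}
    df_resid = N - 2 * S
    ms_resid = rss["full"] / df_resid
    constant = ss_total <= 1e-12 * np.maximum(1.0, (Y**2).sum(axis=0))

    out = pd.DataFrame(index=out_index)
    for eff in ("treatment", "species", "interaction"):
        ss_eff = np.maximum(ss[eff], 0.0)  # guard tiny negative rounding
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss_eff / df[eff]) / ms_resid
            eta2 = np.where(ss_total > 0, ss_eff / ss_total, 0.0)
        F = np.where(constant, np.nan, F)
        out[f"F_{eff}"] = F
        out[f"p_{eff}"] = stats.f.sf(F, df[eff], df_resid)
        out[f"eta2_{eff}"] = eta2
    with np.errstate(divide="ignore", invalid="ignore"):
        out["eta2_residual"] = np.where(constant, 0.0, rss["full"] / ss_total)
    out["df_resid"] = df_resid
    out["status"] = np.where(constant, "constant", "ok")
    return out


def fit_og_anova(y: pd.Series, metadata: SampleMetadata, **kw) -> pd.Series:
    """Single-orthogroup convenience wrapper around :func:`og_anova`."""
    return og_anova(y.to_frame().T, metadata, **kw).iloc[0]


def effect_size_scatter(rows: pd.DataFrame, *, alpha_screen: float = 0.1) -> dict:
    """Summary of the treatment vs interaction effect-size comparison.

    Reports the fraction of orthogroups falling above the 1:1 line (treatment
    eta^2 exceeding interaction eta^2) and the fractions passing the raw-p
    screen for each effect.
    """
    ok = rows[rows["status"] == "ok"]
    n = len(ok)
    if n == 0:
        return {"n": 0}
    return {
        "n": n,
        "fraction_treatment_above_interaction": float(
            (ok["eta2_treatment"] > ok["eta2_interaction"]).mean()
        ),
        "fraction_treatment_significant": float(
            (ok["p_treatment"] < alpha_screen).mean()
        ),
        "fraction_species_significant": float((ok["p_species"] < alpha_screen).mean()),
        "fraction_interaction_significant": float(
            (ok["p_interaction"] < alpha_screen).mean()
        ),
        "median_eta2_treatment": float(ok["eta2_treatment"].median()),
        "median_eta2_interaction": float(ok["eta2_interaction"].median()),
    }


def _stat_matrix(de_tables: dict, column: str) -> pd.DataFrame:
    """Units x species matrix of a DE statistic, outer-joined on unit id."""
    series = {sp: tab[column] for sp, tab in de_tables.items()}
    return pd.DataFrame(series)


def pairwise_wald_correlations(
    de_tables: dict, *, column: str = "wald", min_shared: int = 3
) -> pd.DataFrame:
    """Pearson correlation of per-unit Wald vectors for every species pair.

    Pairwise-complete: each pair uses the units with finite statistics in both
    species; pairs with fewer than ``min_shared`` shared units are flagged NA.
    """
    mat = _stat_matrix(de_tables, column)
    species = list(mat.columns)
    if len(species) < 2:
        raise ValueError("need at least 2 species")
    rows = []
    for a, b in itertools.combinations(species, 2):
        sub = mat[[a, b]].dropna()
        sub = sub[np.isfinite(sub).all(axis=1)]
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
        rows, columns=["species_a", "species_b", "r", "n_units", "t", "p", "status"]
    )


def correlation_distribution_test(pairs: pd.DataFrame | np.ndarray):
    """One-sample two-sided t-test of the pairwise correlations against zero.

    Returns (mean r, t, p). Raises on fewer than 2 pairs or zero variance.
    """
    r = pairs["r"].to_numpy(float) if isinstance(pairs, pd.DataFrame) else np.asarray(
        pairs, float
    )
    r = r[np.isfinite(r)]
    if len(r) < 2:
        raise ValueError("need at least 2 pairwise correlations")
    if np.allclose(r.var(ddof=1), 0.0):
        raise ValueError("pairwise correlations have zero variance")
    t, p = stats.ttest_1samp(r, 0.0)
    return float(r.mean()), float(t), float(p)


def copy_number_lfc_correlation(de_tables: dict, og_map: OrthogroupMap) -> dict:
    """Pearson correlation of |lfc| with orthogroup copy number, pooled.

    Pairs each orthogroup's per-species |lfc| with that species' transcript
    copy number in the orthogroup, pooling over species. Constant copy number
    makes the correlation undefined (NA with reason).
    """
    cn = og_map.copy_numbers()
    xs, ys = [], []
    for sp, tab in de_tables.items():
        shared = tab.index.intersection(cn.index)
        lfc = tab.loc[shared, "lfc"].abs()
        copies = cn.loc[shared, sp]
        keep = np.isfinite(lfc) & (copies > 0)
        xs.append(copies[keep].to_numpy(float))
        ys.append(lfc[keep].to_numpy(float))
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if len(x) < 3:
        return {"r": np.nan, "t": np.nan, "p": np.nan, "n": len(x),
                "reason": "too_few_pairs"}
    if np.allclose(x.var(), 0.0) or np.allclose(y.var(), 0.0):
        return {"r": np.nan, "t": np.nan, "p": np.nan, "n": len(x),
                "reason": "constant_input"}
    r, p = stats.pearsonr(x, y)
    t = r * np.sqrt((len(x) - 2) / max(1.0 - r**2, 1e-300))
    return {"r": float(r), "t": float(t), "p": float(p), "n": int(len(x)),
            "reason": None}
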