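"""Unbalanced-design ANOVA: Type III sums of squares, Tukey-Kramer, CLD.

The engine fits fixed-effects linear models of a transformed germination
response on categorical factors (optionally with pairwise interactions)
under sum-to-zero (deviation) coding, and computes each term's marginal —
Type III — sum of squares as the residual-SS increase when that term's
columns are removed with every other term retained:

    SS_T = RSS(model without T) - RSS(full model)
    df_T = rank(X_full) - rank(X_without_T)
    F_T  = (SS_T / df_T) / (RSS_full / df_resid)

Type III SS are coding-dependent in singular designs, so the sum-to-zero
coding is part of the contract. Per-term R-squared is SS_T over the total
centred SS — the "proportion of variance explained" convention used
throughout the reporting tables. Empty cells are handled by dropping
all-zero interaction columns and letting the rank-revealing least-squares
fit absorb remaining collinearity, so an interaction's df reflects the
observed-cell rank rather than the nominal product of parent dfs.

Group mean comparisons use the Tukey-Kramer HSD (studentized range with the
harmonic pairwise-n correction, valid for unequal group sizes) and are
summarised as a compact letter display via insert-and-absorb.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist
from scipy.stats import studentized_range

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "OLSFit",
    "TukeyResult",
    "design_matrix",
    "fit_ols",
    "type3_anova",
    "run_table1",
    "run_table2",
    "tukey_letters",
    "STUDY_FACTORS",
]

# The eight study factors of the emulated design, in reporting order.
STUDY_FACTORS = (
    "order", "life_form", "seed_size_class", "dispersal_mode",
    "flowering_onset", "flowering_duration", "temperature", "habitat",
)


@dataclass(frozen=True)
class ModelSpec:
    """A fixed-effects model: response ~ factors (+ pairwise interactions)."""

    response: str
    factors: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...] = ()
    data_unit: str = "species_by_temperature"

    def __post_init__(self):
        if not self.factors:
            raise ValueError("at least one factor required")
        for a, b in self.interactions:
            if a not in self.factors or b not in self.factors:
                raise ValueError(f"interaction ({a},{b}) parents must be factors")


@dataclass(frozen=True)
class OLSFit:
    coef: np.ndarray
    rss: float
    rank: int
    df_resid: int
    n_obs: int


def _sum_to_zero(codes: np.ndarray, n_levels: int) -> np.ndarray:
    """Deviation coding: k-1 columns, last level coded -1 across all."""
    n = len(codes)
    X = np.zeros((n, n_levels - 1))
    for j in range(n_levels - 1):
        X[codes == j, j] = 1.0
    X[codes == n_levels - 1, :] = -1.0
    return X


def design_matrix(
    data: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, dict[str, slice]]:
    """Intercept + sum-to-zero main effects + product interaction columns.

    Unused factor levels are dropped per fit. All-zero columns (empty
    interaction cells) are removed with a warning; the term's df is
    recovered downstream from matrix rank, not column count.
    """
    blocks: list[np.ndarray] = [np.ones((len(data), 1))]
    term_cols: dict[str, slice] = {}
    main: dict[str, np.ndarray] = {}
    pos = 1
    for f_name in spec.factors:
        cat = pd.Categorical(data[f_name].astype(str))
        cat = cat.remove_unused_categories()
        k = len(cat.categories)
        if k < 2:
            raise ValueError(f"factor {f_name!r} has a single observed level")
        X = _sum_to_zero(cat.codes.astype(int), k)
        main[f_name] = X
        blocks.append(X)
        term_cols[f_name] = slice(pos, pos + X.shape[1])
        pos += X.shape[1]
    for a, b in spec.interactions:
        Xa, Xb = main[a], main[b]
        cols = [Xa[:, i] * Xb[:, j]
                for i in range(Xa.shape[1]) for j in range(Xb.shape[1])]
        X = np.column_stack(cols)
        nonzero = np.any(X != 0.0, axis=0)
        if not nonzero.all():
            logger.warning(
                "interaction %s:%s — dropped %d all-zero column(s) (empty cells)",
                a, b, int((~nonzero).sum()),
            )
            X = X[:, nonzero]
        blocks.append(X)
        term_cols[f"{a}:{b}"] = slice(pos, pos + X.shape[1])
        pos += X.shape[1]
    X = np.hstack(blocks)
    if spec.interactions:
        X, term_cols = _prune_dependent(X, term_cols)
    return X, term_cols


def _prune_dependent(
    X: np.ndarray, term_cols: dict[str, slice], tol: float = 1e-9
) -> tuple[np.ndarray, dict[str, slice]]:
    """Drop columns linearly dependent on earlier ones, in term order.

    With empty cells, product columns of an interaction can be exact linear
    combinations of the intercept and main-effect columns; keeping them
    would transfer the rank deficiency onto the main effects (their Type
    III df would collapse to 0). Pruning in order — intercept, mains,
    interactions — pins the deficiency on the interaction, whose achieved
    df then reflects the observed-cell rank.
    """
    norms = np.linalg.norm(X, axis=0)
    Q = np.empty_like(X)
    kept: list[int] = []
    r = 0
    for j in range(X.shape[1]):
        v = X[:, j].copy()
        if r:
            v -= Q[:, :r] @ (Q[:, :r].T @ v)
            v -= Q[:, :r] @ (Q[:, :r].T @ v)  # re-orthogonalise
        nv = np.linalg.norm(v)
        if nv > tol * max(norms[j], 1.0):
            Q[:, r] = v / nv
            r += 1
            kept.append(j)
    if len(kept) < X.shape[1]:
        logger.warning("dropped %d linearly dependent design column(s)",
                       X.shape[1] - len(kept))
        new_cols: dict[str, slice] = {}
        pos = 0
        kept_set = set(kept)
        for term, cols in term_cols.items():
            k = sum(1 for j in range(cols.start, cols.stop) if j in kept_set)
            new_cols[term] = slice(pos + 0, pos + k) if k else slice(pos, pos)
            pos += k
        # intercept occupies column 0 in every term layout
        X = X[:, kept]
        # recompute slices including the leading intercept column
        term_cols = {}
        pos = 1
        for term, cols in new_cols.items():
            width = cols.stop - cols.start
            term_cols[term] = slice(pos, pos + width)
            pos += width
    return X, term_cols


def fit_ols(X: np.ndarray, y: np.ndarray) -> OLSFit:
    """Rank-revealing least squares (SVD); residual df = n - rank(X)."""
    if X.size == 0 or X.shape[1] == 0:
        raise ValueError("empty design matrix")
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank == 0:
        raise ValueError("design matrix has rank 0")
    resid = y - X @ coef
    return OLSFit(coef=coef, rss=float(resid @ resid), rank=int(rank),
                  df_resid=len(y) - int(rank), n_obs=len(y))


def _model_frame(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    cols = [spec.response, *spec.factors]
    frame = data[cols].dropna(subset=[spec.response]).reset_index(drop=True)
    if len(frame) == 0:
        raise ValueError("no complete observations for this model")
    return frame


def type3_anova(data: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    """Type III ANOVA table: one row per term plus Model and Residual rows.

    Rows carry df, SS, F, P and R2 = SS / total centred SS. When the
    residual df is 0 the SS are still reported and F/P are NaN.
    """
    frame = _model_frame(data, spec)
    y = frame[spec.response].to_numpy(dtype=float)
    X, term_cols = design_matrix(frame, spec)
    full = fit_ols(X, y)
    if full.n_obs <= full.rank:
        logger.warning("saturated model: residual df = 0, F/P unavailable")
    ss_total = float(np.sum((y - y.mean()) ** 2))
    mse = full.rss / full.df_resid if full.df_resid > 0 else np.nan

    rows = []
    for term, cols in term_cols.items():
        keep = np.ones(X.shape[1], dtype=bool)
        keep[cols] = False
        sub = fit_ols(X[:, keep], y)
        ss = max(0.0, sub.rss - full.rss)
        df = full.rank - sub.rank
        if df > 0 and full.df_resid > 0:
            F = (ss / df) / mse
            P = float(f_dist.sf(F, df, full.df_resid))
        else:
            F, P = np.nan, np.nan
        rows.append({"source": term, "df": df, "SS": ss, "F": F, "P": P,
                     "R2": ss / ss_total if ss_total > 0 else np.nan})
    ss_model = max(0.0, ss_total - full.rss)
    df_model = full.rank - 1
    if df_model > 0 and full.df_resid > 0:
        F_model = (ss_model / df_model) / mse
        P_model = float(f_dist.sf(F_model, df_model, full.df_resid))
    else:
        F_model, P_model = np.nan, np.nan
    rows.append({"source": "Model", "df": df_model, "SS": ss_model,
                 "F": F_model, "P": P_model,
                 "R2": ss_model / ss_total if ss_total > 0 else np.nan})
    rows.append({"source": "Residual", "df": full.df_resid, "SS": full.rss,
                 "F": np.nan, "P": np.nan, "R2": np.nan})
    table = pd.DataFrame(rows)
    table.attrs["n_obs"] = full.n_obs
    table.attrs["ss_total"] = ss_total
    table.attrs["response"] = spec.response
    return table


def run_table1(
    data: pd.DataFrame,
    factors: tuple[str, ...] = STUDY_FACTORS,
    responses: tuple[str, ...] = ("GP_t", "GT_t"),
) -> pd.DataFrame:
    """One one-way ANOVA per factor and response; long-format battery table."""
    rows = []
    for response in responses:
        for f_name in factors:
            tab = type3_anova(data, ModelSpec(response=response,
                                              factors=(f_name,)))
            row = tab.loc[tab["source"] == f_name].iloc[0].to_dict()
            row["response"] = response
            rows.append(row)
    return pd.DataFrame(rows)[["response", "source", "df", "SS", "F", "P", "R2"]]


def run_table2(
    data: pd.DataFrame,
    pairs: tuple[tuple[str, str], ...],
    response: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-way ANOVAs A + B + A:B per pair; flags significant interactions."""
    rows = []
    for a, b in pairs:
        spec = ModelSpec(response=response, factors=(a, b),
                         interactions=((a, b),))
        tab = type3_anova(data, spec)
        for _, r in tab.iterrows():
            if r["source"] in ("Model", "Residual"):
                continue
            rows.append({
                "pair": f"{a}/{b}", "response": response, "source": r["source"],
                "df": r["df"], "SS": r["SS"], "F": r["F"], "P": r["P"],
                "R2": r["R2"],
                "significant_interaction": bool(
                    ":" in r["source"] and np.isfinite(r["P"]) and r["P"] < alpha
                ),
            })
    return pd.DataFrame(rows)


# ------------------------------------------------------- Tukey-Kramer + CLD

@dataclass
class TukeyResult:
    """Group means with SEs, Tukey-Kramer adjusted pairwise P, CLD letters."""

    groups: list[str]
    means: np.ndarray
    se: np.ndarray
    n: np.ndarray
    p_adjusted: pd.DataFrame
    letters: dict[str, str]
    excluded: list[str] = field(default_factory=list)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "group": self.groups, "mean": self.means, "se": self.se,
            "n": self.n, "letters": [self.letters[g] for g in self.groups],
        })


def _cld_insert_absorb(groups: list[str], distinct: set[tuple[str, str]]) -> dict[str, str]:
    """Compact letter display: groups share a letter iff not distinct.

    Insert-and-absorb: start from one all-inclusive letter column; for every
    significantly different pair found together in a column, duplicate the
    column, removing one group from each copy; drop columns that became
    subsets of another.
    """
    columns: list[set[str]] = [set(groups)]
    for a, b in sorted(distinct):
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            columns.extend([col - {a}, col - {b}])
        # absorb: drop strict-or-equal subsets (keep first of duplicates)
        kept: list[set[str]] = []
        for c in columns:
            if any(c <= other for other in kept) or not c:
                continue
            kept = [k for k in kept if not k <= c]
            kept.append(c)
        columns = kept
    # stable letter order: by best (first) group each column contains
    rank = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda c: min(rank[g] for g in c))
    alphabet = string.ascii_lowercase
    letters = {g: "" for g in groups}
    for i, col in enumerate(columns):
        ch = alphabet[i % 26] * (i // 26 + 1)
        for g in groups:
            if g in col:
                letters[g] += ch
    return letters


def tukey_letters(
    data: pd.DataFrame, factor: str, response: str, alpha: float = 0.05
) -> TukeyResult:
    """Tukey-Kramer all-pairs comparison with a compact letter display.

    Uses the pooled one-way MSE; the studentized-range statistic for a pair
    (i, j) is |m_i - m_j| / sqrt(MSE/2 * (1/n_i + 1/n_j)), referred to the
    range distribution with k groups and the pooled residual df. Groups are
    ordered by descending mean; singleton groups are excluded with a
    warning, since they carry no within-group variance.
    """
    frame = data[[factor, response]].dropna()
    counts = frame.groupby(factor, observed=True)[response].size()
    excluded = sorted(counts.index[counts < 2].astype(str))
    if excluded:
        logger.warning("tukey: excluding singleton group(s) %s", excluded)
        frame = frame[~frame[factor].astype(str).isin(excluded)]
    stats = frame.groupby(factor, observed=True)[response].agg(["mean", "size", "var"])
    if len(stats) < 2:
        raise ValueError("need >= 2 groups with >= 2 observations")
    stats = stats.sort_values("mean", ascending=False)
    groups = [str(g) for g in stats.index]
    k = len(groups)
    n = stats["size"].to_numpy()
    means = stats["mean"].to_numpy()
    df_resid = int(n.sum()) - k
    mse = float(((n - 1) * stats["var"].to_numpy()).sum() / df_resid)

    p = np.ones((k, k))
    distinct: set[tuple[str, str]] = set()
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(means[i] - means[j]) / np.sqrt(
                mse / 2.0 * (1.0 / n[i] + 1.0 / n[j])
            )
            pij = float(studentized_range.sf(q, k, df_resid))
            p[i, j] = p[j, i] = pij
            if pij < alpha:
                distinct.add(tuple(sorted((groups[i], groups[j]))))
    letters = _cld_insert_absorb(groups, distinct)
    return TukeyResult(
        groups=groups, means=means, se=np.sqrt(mse / n), n=n.astype(int),
        p_adjusted=pd.DataFrame(p, index=groups, columns=groups),
        letters=letters, excluded=excluded,
    )
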