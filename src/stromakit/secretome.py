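"""Secretome statistics: differential abundance and enrichment.

Protein abundance tables (normalised MS1 peak areas, proteins x samples)
are processed downstream of identification:

* total-intensity normalisation (each sample scaled so its column total
  equals the across-sample mean total),
* per-protein one-way ANOVA across groups with fold change as the ratio
  of group means (two-group ANOVA reduces to F = t^2),
* matrisome annotation (core matrisome / matrisome-associated /
  non-matrisome) with summary counts,
* a two-category chi-squared goodness-of-fit test for matrisome
  enrichment among significant proteins (df = 1, no continuity
  correction),
* hypergeometric gene-set over-representation with a >500-member set
  exclusion, Benjamini-Hochberg FDR, a q <= 0.05 keep-filter, and
  ordering by p ascending with ties broken by the k/K ratio descending.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic import GeneSetCollection

__all__ = [
    "MatrisomeSummary",
    "ChiSquareResult",
    "EnrichmentResult",
    "normalize_abundance",
    "differential_abundance",
    "annotate_matrisome",
    "chisq_matrisome_enrichment",
    "overrepresentation",
]

MATRISOME_DIVISIONS = ("core matrisome", "matrisome-associated", "non-matrisome")


@dataclass
class ChiSquareResult:
    """Two-category goodness-of-fit result (df = 1)."""

    observed: float
    expected: float
    chi2: float
    df: int
    p_value: float

    def __post_init__(self) -> None:
        if self.chi2 < 0 or not 0 <= self.p_value <= 1:
            raise ValueError("invalid chi-square result")


@dataclass
class MatrisomeSummary:
    """Counts and percentage of matrisome membership in a protein list."""

    n_total: int
    n_matrisome: int
    n_core: int
    n_associated: int
    percent_matrisome: float
    by_category: dict[str, int]


def _group_columns(table: pd.DataFrame, groups: dict[str, list[str]] | None):
    if groups is not None:
        return groups
    out: dict[str, list[str]] = {}
    for col in table.columns:
        g = str(col).split("_")[0]
        out.setdefault(g, []).append(col)
    if len(out) < 2:
        raise ValueError("could not infer >= 2 sample groups from column names")
    return out


def normalize_abundance(raw: pd.DataFrame) -> pd.DataFrame:
    """Scale each sample so its total equals the across-sample mean total.

    This is total-ion-intensity normalisation at the table level: the
    relative abundances within a sample are unchanged and every column
    ends up with the same total, so the operation is idempotent, and
    rescaling any single input sample changes its normalised profile only
    through the shared target factor (leaving all ratio statistics
    unchanged).
    """
    if (raw.to_numpy() < 0).any():
        raise ValueError("abundances must be non-negative")
    totals = raw.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"all-zero sample column(s): {bad}")
    return raw * (totals.mean() / totals)


def differential_abundance(
    table: pd.DataFrame,
    alpha: float = 0.05,
    groups: dict[str, list[str]] | None = None,
    ratio_groups: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Per-protein one-way ANOVA across sample groups with fold changes.

    Groups are inferred from column-name prefixes (``A_1`` -> group
    ``A``) unless given explicitly.  Fold change is the ratio of
    arithmetic group means (first/second of ``ratio_groups``, default the
    two inferred groups in sorted order), with a zero floor of the
    smallest positive table value / 10.  Proteins constant across all
    samples get p = 1 with a warning.  Returns a DataFrame indexed by
    protein with fold_change, log2_fold, p_value, significant.
    """
    grp = _group_columns(table, groups)
    names = sorted(grp) if ratio_groups is None else list(ratio_groups)
    if len(grp) < 2 or any(len(c) < 2 for c in grp.values()):
        raise ValueError("need >= 2 groups with >= 2 replicates each")
    ga, gb = names[0], names[1]
    vals = {g: table[cols].to_numpy(dtype=float) for g, cols in grp.items()}

    positive = table.to_numpy()
    positive = positive[positive > 0]
    eps = positive.min() / 10.0 if positive.size else 1e-12

    arrays = list(vals.values())
    n_const = 0
    pvals = np.empty(len(table))
    for i in range(len(table)):
        rows = [a[i] for a in arrays]
        flat = np.concatenate(rows)
        if np.ptp(flat) == 0:
            pvals[i] = 1.0
            n_const += 1
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            f, p = stats.f_oneway(*rows)
        pvals[i] = p if np.isfinite(p) else 1.0
    if n_const:
        warnings.warn(
            f"{n_const} protein(s) constant across all samples; p set to 1",
            stacklevel=2,
        )

    mean_a = np.maximum(vals[ga][:, :].mean(axis=1), eps)
    mean_b = np.maximum(vals[gb][:, :].mean(axis=1), eps)
    fold = mean_a / mean_b
    return pd.DataFrame(
        {
            "fold_change": fold,
            "log2_fold": np.log2(fold),
            "p_value": pvals,
            "significant": pvals < alpha,
        },
        index=table.index,
    )


def annotate_matrisome(
    proteins: list[str] | pd.Index,
    annotation: pd.DataFrame,
) -> tuple[pd.DataFrame, MatrisomeSummary]:
    """Tag proteins with matrisome division/category and summarise.

    ``annotation`` needs columns ``protein``, ``division`` (from the
    closed set core matrisome / matrisome-associated / non-matrisome) and
    optionally ``category``; proteins absent from the list are
    non-matrisome.  Conflicting duplicate entries raise.
    """
    ann = annotation.copy()
    required = {"protein", "division"}
    if not required.issubset(ann.columns):
        raise ValueError(f"annotation must have columns {sorted(required)}")
    bad = set(ann["division"]) - set(MATRISOME_DIVISIONS)
    if bad:
        raise ValueError(f"unknown matrisome division(s): {sorted(bad)}")
    dup = ann.groupby("protein")["division"].nunique()
    conflicts = list(dup.index[dup > 1])
    if conflicts:
        raise ValueError(f"conflicting annotations for: {conflicts}")
    ann = ann.drop_duplicates("protein").set_index("protein")

    proteins = list(proteins)
    division = [
        ann["division"].get(p, "non-matrisome") for p in proteins
    ]
    category = [
        (ann["category"].get(p, "") if "category" in ann.columns else "")
        for p in proteins
    ]
    out = pd.DataFrame(
        {"protein": proteins, "division": division, "category": category}
    ).set_index("protein")

    n_total = len(out)
    n_core = int((out["division"] == "core matrisome").sum())
    n_assoc = int((out["division"] == "matrisome-associated").sum())
    n_mat = n_core + n_assoc
    by_cat = (
        out.loc[out["division"] != "non-matrisome", "category"]
        .value_counts()
        .to_dict()
    )
    summary = MatrisomeSummary(
        n_total=n_total,
        n_matrisome=n_mat,
        n_core=n_core,
        n_associated=n_assoc,
        percent_matrisome=100.0 * n_mat / n_total if n_total else 0.0,
        by_category=by_cat,
    )
    return out, summary


def chisq_matrisome_enrichment(
    observed_k: int, n_significant: int, K_background: int, N_background: int
) -> ChiSquareResult:
    """Chi-squared test of matrisome enrichment among significant proteins.

    Under the null the significant list is a random draw from the
    background, so the expected matrisome count is
    ``n_significant * K_background / N_background``.  Pearson's
    two-category goodness-of-fit statistic (matrisome vs non-matrisome,
    df = 1, no continuity correction) is referred to the chi-squared
    distribution.  A warning is raised when the expected count is below 1
    (test validity).
    """
    if not 0 <= observed_k <= n_significant:
        raise ValueError("need 0 <= observed_k <= n_significant")
    if not 0 < K_background <= N_background:
        raise ValueError("need 0 < K_background <= N_background")
    expected = n_significant * K_background / N_background
    exp_other = n_significant - expected
    if expected < 1 or exp_other < 1:
        warnings.warn("expected count < 1; chi-square approximation is poor",
                      stacklevel=2)
    obs_other = n_significant - observed_k
    chi2 = (observed_k - expected) ** 2 / expected
    if exp_other > 0:
        chi2 += (obs_other - exp_other) ** 2 / exp_other
    p = float(stats.chi2.sf(chi2, df=1))
    return ChiSquareResult(
        observed=float(observed_k), expected=expected, chi2=float(chi2),
        df=1, p_value=p,
    )


@dataclass
class EnrichmentResult:
    """One gene set's over-representation result."""

    set_name: str
    k: int
    K: int
    k_over_K: float
    p_value: float
    q_value: float | None
    passed_filters: bool

    def __post_init__(self) -> None:
        if self.k > self.K:
            raise ValueError("overlap k cannot exceed set size K")


def overrepresentation(
    query: list[str] | set[str],
    universe: list[str] | set[str],
    collection: GeneSetCollection | dict[str, list[str]],
    q_max: float = 0.05,
    K_max: int = 500,
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query list against gene sets.

    For each set, K = |set ∩ universe| and k = |set ∩ query|; the
    upper-tail hypergeometric p is P(X >= k) drawing |query| from the
    universe.  Sets with K > ``K_max`` are excluded before testing
    (``passed_filters`` False, no p/q); BH q-values are computed over the
    tested sets and results with q > ``q_max`` are also flagged out.  The
    returned table contains every set; the ranked output is the
    ``passed_filters`` subset ordered by p ascending, ties broken by k/K
    descending.
    """
    query = set(query)
    universe = set(universe)
    if not query:
        raise ValueError("empty query")
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    sets = collection.sets if isinstance(collection, GeneSetCollection) else collection

    N, n = len(universe), len(query)
    rows = []
    for name, members in sets.items():
        inset = set(members) & universe
        K = len(inset)
        k = len(inset & query)
        tested = 0 < K <= K_max
        if tested:
            p = float(stats.hypergeom.sf(k - 1, N, K, n))
        else:
            p = np.nan
        rows.append(
            {"set_name": name, "k": k, "K": K,
             "k_over_K": k / K if K else 0.0, "p_value": p, "tested": tested}
        )
    df = pd.DataFrame(rows).set_index("set_name")
    df["q_value"] = np.nan
    tested_mask = df["tested"].to_numpy()
    if tested_mask.any():
        _, q, _, _ = multipletests(
            df.loc[tested_mask, "p_value"].to_numpy(), method="fdr_bh"
        )
        df.loc[tested_mask, "q_value"] = q
    df["passed_filters"] = tested_mask & (df["q_value"] <= q_max)
    df = df.sort_values(
        ["p_value", "k_over_K"], ascending=[True, False], na_position="last"
    )
    return df.drop(columns="tested")


def ranked_enrichment(df: pd.DataFrame) -> pd.DataFrame:
    """The filtered, ranked subset of an over-representation table."""
    return df[df["passed_filters"]]
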