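"""Gene-level enrichment of variant features among regulated genes.

Flags each gene for carrying (i) coding SNVs, (ii) UTR SNVs or
(iii) splice-site SNVs, then asks whether flagged genes are
over-represented among differentially expressed (fold-change tiers) or
alternatively spliced (significance tiers) genes, relative to the
unregulated baseline.  Tiers are cumulative — a gene above the highest
fold-change threshold is also counted in the lower tiers.  Each tier is
compared to the baseline in a 2x2 table with a two-sided Fisher exact
test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from strainvar.annotate import (
    CODING_CATEGORIES,
    SPLICE_CATEGORIES,
    UTR_CATEGORIES,
    Category,
    GeneLevelConsequence,
)
from strainvar.config import EnrichmentParams

FEATURES = ("coding", "utr", "splice")

_FEATURE_CATEGORIES: dict[str, set[Category]] = {
    "coding": CODING_CATEGORIES,
    "utr": UTR_CATEGORIES,
    "splice": SPLICE_CATEGORIES,
}


def build_feature_flags(
    gene_ids: list[str],
    consequences: list[GeneLevelConsequence],
) -> pd.DataFrame:
    """One row per gene with boolean coding/utr/splice flags.

    A flag is true iff at least one variant whose gene-level category
    falls in the corresponding category group overlaps the gene.
    """
    flags = pd.DataFrame(
        {
            "gene": list(gene_ids),
            "coding": False,
            "utr": False,
            "splice": False,
        }
    ).set_index("gene")
    for rec in consequences:
        if rec.gene_id not in flags.index:
            continue
        for feature, cats in _FEATURE_CATEGORIES.items():
            if rec.category in cats:
                flags.loc[rec.gene_id, feature] = True
    return flags.reset_index()


@dataclass
class EnrichmentResult:
    feature: str
    axis: str
    category: str
    n_genes: int
    n_flagged: int
    fraction: float
    baseline_fraction: float
    odds_ratio: float
    p_value: float


def _axis_categories(
    expr: pd.DataFrame, axis: str, params: EnrichmentParams
) -> list[tuple[str, pd.Series]]:
    """(label, boolean membership) per cumulative tier, baseline last."""
    if axis == "expression":
        fc = expr["fold_change"]
        tiers = [
            (f"FC>{t:g}", fc > t) for t in params.de_thresholds
        ]
        baseline = ("not-DE", fc <= min(params.de_thresholds))
    elif axis == "splicing":
        p = expr["splice_p"]
        tiers = [(f"p<{t:g}", p < t) for t in params.splice_thresholds]
        baseline = ("not-spliced", p >= max(params.splice_thresholds))
    else:
        raise ValueError(f"unknown axis {axis!r}")
    return [*tiers, baseline]


def enrichment_test(
    flags: pd.DataFrame,
    expression: pd.DataFrame,
    feature: str,
    axis: str = "expression",
    params: EnrichmentParams | None = None,
) -> list[EnrichmentResult]:
    """Per-tier flagged fractions plus Fisher exact tests vs baseline.

    Genes absent from the expression table are excluded entirely.
    An all-flagged tier against an unflagged baseline yields an
    unbounded (infinite) odds ratio.
    """
    params = params or EnrichmentParams()
    if feature not in FEATURES:
        raise ValueError(f"feature must be one of {FEATURES}")
    merged = expression.merge(flags, on="gene", how="inner")
    if axis == "splicing":
        merged = merged[merged["splice_p"].notna()]
    cats = _axis_categories(merged, axis, params)
    base_label, base_mask = cats[-1]
    flag = merged[feature].to_numpy(dtype=bool)
    base_flagged = int(flag[base_mask.to_numpy()].sum())
    base_n = int(base_mask.sum())
    if base_n == 0:
        raise ValueError("baseline category is empty")
    base_frac = base_flagged / base_n
    results: list[EnrichmentResult] = []
    for label, mask in cats:
        m = mask.to_numpy()
        n = int(m.sum())
        if n == 0:
            raise ValueError(f"category {label} is empty")
        k = int(flag[m].sum())
        if label == base_label:
            odds, p = 1.0, 1.0
        else:
            table = [
                [k, n - k],
                [base_flagged, base_n - base_flagged],
            ]
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            a, b = k, n - k
            c, d = base_flagged, base_n - base_flagged
            odds = float("inf") if b * c == 0 and a * d > 0 else (
                (a * d) / (b * c) if b * c else float("nan")
            )
        results.append(
            EnrichmentResult(
                feature=feature,
                axis=axis,
                category=label,
                n_genes=n,
                n_flagged=k,
                fraction=k / n,
                baseline_fraction=base_frac,
                odds_ratio=float(odds),
                p_value=float(p),
            )
        )
    return results


def enrichment_table(
    flags: pd.DataFrame,
    expression: pd.DataFrame,
    params: EnrichmentParams | None = None,
) -> pd.DataFrame:
    """All feature x axis x tier results as a tidy table."""
    rows = []
    for axis in ("expression", "splicing"):
        for feature in FEATURES:
            for r in enrichment_test(flags, expression, feature, axis, params):
                rows.append(vars(r))
    return pd.DataFrame(rows)


def plot_enrichment(table: pd.DataFrame, path: str) -> None:
    """Bar chart of flagged-gene fractions per tier, one panel per axis."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    axes_names = table["axis"].unique()
    fig, axs = plt.subplots(1, len(axes_names), figsize=(5 * len(axes_names), 4))
    if len(axes_names) == 1:
        axs = [axs]
    for ax, axis_name in zip(axs, axes_names):
        sub = table[table["axis"] == axis_name]
        cats = sub["category"].unique()
        width = 0.8 / len(FEATURES)
        for i, feature in enumerate(FEATURES):
            vals = [
                sub[(sub["category"] == c) & (sub["feature"] == feature)][
                    "fraction"
                ].iloc[0]
                for c in cats
            ]
            ax.bar(np.arange(len(cats)) + i * width, vals, width, label=feature)
        ax.set_xticks(np.arange(len(cats)) + 0.4 - width / 2)
        ax.set_xticklabels(cats, rotation=30, ha="right")
        ax.set_ylabel("fraction of genes with SNVs")
        ax.set_title(axis_name)
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
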