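"""Pathway-dependence classification of X-linked genes and group statistics.

Two perturbation read-outs are classified:

* SmcHD1 dependence — from the residual Xi allelic ratio of each gene in
  wild-type versus SmcHD1-knockout differentiated cells: genes silenced in
  WT are 'dependent' if they retain substantial Xi expression in the KO,
  'not' dependent if fully silenced in the KO, 'partial' in between;
  genes already expressed from Xi in the WT are escapees.
* SPEN SPOC dependence — from the day-6 silencing change (Dox - NoDox)
  in SPOC-mutant cells: genes that still silence strongly without a
  functional SPOC domain are SPOC-independent, genes with little residual
  silencing are SPOC-dependent.

Thresholds are configurable; defaults are recorded with every call.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .stats import fisher_exact, rank_sum_test

__all__ = [
    "DependencyConfig",
    "classify_smchd1",
    "classify_spoc",
    "classify_genes",
    "group_characteristics",
    "rank_sum_test",
    "fisher_exact",
]


@dataclass
class DependencyConfig:
    smchd1_escapee_min: float = 0.1   # WT Xi ratio above which a gene escapes
    smchd1_dep_min: float = 0.2       # KO Xi ratio at/above which: dependent
    smchd1_not_max: float = 0.05      # KO Xi ratio at/below which: not dependent
    spoc_indep_max_delta: float = -0.15  # day-6 delta at/below: SPOC-independent
    spoc_dep_min_delta: float = -0.05    # day-6 delta at/above: SPOC-dependent

    def __post_init__(self) -> None:
        if not self.smchd1_not_max < self.smchd1_dep_min:
            raise ValueError("require smchd1_not_max < smchd1_dep_min")
        if not self.spoc_indep_max_delta < self.spoc_dep_min_delta:
            raise ValueError("require spoc_indep_max_delta < spoc_dep_min_delta")


def classify_smchd1(wt_ratio, ko_ratio, cfg: DependencyConfig | None = None) -> str:
    """SmcHD1-dependence class from WT and KO Xi allelic ratios."""
    cfg = cfg or DependencyConfig()
    if wt_ratio is None or ko_ratio is None or not (
        np.isfinite(wt_ratio) and np.isfinite(ko_ratio)
    ):
        return "unassessed"
    if wt_ratio > cfg.smchd1_escapee_min:
        return "escapee"
    if ko_ratio >= cfg.smchd1_dep_min:
        return "dependent"
    if ko_ratio <= cfg.smchd1_not_max:
        return "not"
    return "partial"


def classify_spoc(delta_day6, cfg: DependencyConfig | None = None) -> str:
    """SPOC-dependence class from the day-6 Dox - NoDox allelic-ratio change
    in the SPOC-mutant line."""
    cfg = cfg or DependencyConfig()
    if delta_day6 is None or not np.isfinite(delta_day6):
        return "unclassified"
    if delta_day6 <= cfg.spoc_indep_max_delta:
        return "independent"
    if delta_day6 >= cfg.spoc_dep_min_delta:
        return "dependent"
    return "unclassified"


def classify_genes(
    wt_ratio: pd.Series | None = None,
    ko_ratio: pd.Series | None = None,
    spoc_delta: pd.Series | None = None,
    cfg: DependencyConfig | None = None,
) -> pd.DataFrame:
    """Per-gene dependence calls; records the thresholds used.

    Any subset of the three inputs may be given; classes for missing
    read-outs are 'unassessed'/'unclassified'. Index alignment is by
    gene_id.
    """
    cfg = cfg or DependencyConfig()
    frames = [s for s in (wt_ratio, ko_ratio, spoc_delta) if s is not None]
    if not frames:
        raise ValueError("at least one input series is required")
    index = frames[0].index
    for s in frames[1:]:
        index = index.union(s.index)

    def get(series, gene):
        if series is None or gene not in series.index:
            return np.nan
        return series[gene]

    rows = []
    for gene in index:
        rows.append(
            {
                "gene_id": gene,
                "smchd1_class": classify_smchd1(get(wt_ratio, gene), get(ko_ratio, gene), cfg),
                "spoc_class": classify_spoc(get(spoc_delta, gene), cfg),
            }
        )
    out = pd.DataFrame(rows).set_index("gene_id")
    for key, val in asdict(cfg).items():
        out.attrs[key] = val
    return out


def group_characteristics(
    groups: pd.Series,
    features: pd.DataFrame | pd.Series,
    alternative: str = "two-sided",
    adjust: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group medians and pairwise rank-sum tests for each feature.

    *groups* maps gene_id -> group label; *features* holds per-gene values
    (e.g. initial TPM, distance to the Xist locus). Returns
    ``(summary, tests)``. P-values are raw by default (``adjusted`` column
    flags this); pass ``adjust='bh'`` for Benjamini-Hochberg.
    """
    if isinstance(features, pd.Series):
        features = features.to_frame(features.name or "feature")
    groups = groups.dropna()
    labels = [g for g in pd.unique(groups) if not pd.isna(g)]
    if len(labels) < 2:
        raise ValueError("need at least two groups")

    summary_rows, test_rows = [], []
    for feat in features.columns:
        vals = features[feat]
        per_group = {
            g: vals[groups.index[groups == g]].dropna() for g in labels
        }
        for g in labels:
            summary_rows.append(
                {"feature": feat, "group": g, "n": len(per_group[g]),
                 "median": float(per_group[g].median()) if len(per_group[g]) else np.nan}
            )
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                if len(per_group[a]) == 0 or len(per_group[b]) == 0:
                    continue
                u, p = rank_sum_test(per_group[a], per_group[b], alternative)
                test_rows.append(
                    {"feature": feat, "group_a": a, "group_b": b,
                     "n_a": len(per_group[a]), "n_b": len(per_group[b]),
                     "statistic": u, "p_value": p}
                )
    tests = pd.DataFrame(test_rows)
    if adjust == "bh" and len(tests):
        p = tests["p_value"].to_numpy()
        order = np.argsort(p)
        ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(adj)
        out[order] = np.minimum(adj, 1.0)
        tests["p_adjusted"] = out
        tests["adjusted"] = "benjamini-hochberg"
    else:
        tests["adjusted"] = "none"
    return pd.DataFrame(summary_rows), tests
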