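"""Allelic expression quantification for X-inactivation time courses.

Counts arrive as a gene x sample matrix with three channels per sample:
``total`` (all fragments assigned to the gene), ``xi`` (fragments assigned
to the inducible/inactive-X allele) and ``xa`` (active-X allele). Fragments
without an informative SNP are neither xi nor xa, so xi + xa <= total.

The central quantity is the allelic ratio Xi/(Xi+Xa): 0.5 means biallelic
expression, 0 means a fully silenced Xi allele. Genes are admitted to
silencing analysis only if they carry enough allelically assignable
fragments across wild-type samples and are biallelic before Xist induction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AllelicCountMatrix",
    "FilterConfig",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "allelic_ratio",
    "filter_informative_genes",
    "ratio_table",
    "normalize_expression",
    "expression_tertiles",
    "xist_abundance",
    "delta_silencing",
    "tertile_assign",
]

SAMPLE_SHEET_COLUMNS = [
    "sample_id",
    "line",
    "condition",
    "day",
    "replicate",
    "cell_state",
    "wt_flag",
]

_CHANNELS = ("total", "xi", "xa")


@dataclass
class AllelicCountMatrix:
    """Gene x sample fragment counts split into total / Xi / Xa channels.

    All three frames share the same gene index and sample columns. The
    constructor validates non-negativity and the allelic-subset constraint
    xi + xa <= total.
    """

    total: pd.DataFrame
    xi: pd.DataFrame
    xa: pd.DataFrame

    def __post_init__(self) -> None:
        for name in ("xi", "xa"):
            frame = getattr(self, name)
            if not frame.index.equals(self.total.index) or not frame.columns.equals(
                self.total.columns
            ):
                raise ValueError(f"channel {name!r} is not aligned with 'total'")
        if self.total.index.has_duplicates:
            raise ValueError("duplicate gene identifiers")
        if self.total.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        for name in _CHANNELS:
            if (getattr(self, name).to_numpy() < 0).any():
                raise ValueError(f"negative counts in channel {name!r}")
        excess = (self.xi + self.xa) > self.total
        if excess.to_numpy().any():
            bad = self.total.index[excess.any(axis=1)].tolist()
            raise ValueError(f"xi + xa exceeds total for genes: {bad[:10]}")

    @property
    def genes(self) -> pd.Index:
        return self.total.index

    @property
    def samples(self) -> pd.Index:
        return self.total.columns

    @property
    def allelic(self) -> pd.DataFrame:
        """Allelically assigned fragments per gene x sample (xi + xa)."""
        return self.xi + self.xa

    def subset_genes(self, genes) -> "AllelicCountMatrix":
        return AllelicCountMatrix(
            self.total.loc[genes], self.xi.loc[genes], self.xa.loc[genes]
        )


@dataclass
class FilterConfig:
    """Gene-admission filters for silencing analysis.

    min_allelic_frags
        Minimum allelically assigned fragments (xi + xa) for a sample to
        count as covered.
    min_wt_sample_frac
        A gene is kept only if strictly more than this fraction of wild-type
        samples are covered (default >80%).
    baseline_low, baseline_high
        The baseline (uninduced mESC) allelic ratio must lie strictly inside
        this open interval; strongly monoallelic genes are likely artifacts
        of mis-annotated SNPs.
    baseline_mode
        "mean" averages per-sample baseline ratios (default); "pooled"
        computes one ratio from summed baseline counts.
    """

    min_allelic_frags: int = 10
    min_wt_sample_frac: float = 0.8
    baseline_low: float = 0.1
    baseline_high: float = 0.9
    baseline_mode: str = "mean"

    def __post_init__(self) -> None:
        if not 0.0 <= self.baseline_low < self.baseline_high <= 1.0:
            raise ValueError("require 0 <= baseline_low < baseline_high <= 1")
        if self.baseline_mode not in ("mean", "pooled"):
            raise ValueError("baseline_mode must be 'mean' or 'pooled'")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_counts(m: AllelicCountMatrix, path) -> None:
    """Write a wide TSV: gene_id plus '<sample>.total/.xi/.xa' columns."""
    out = pd.DataFrame(index=m.genes)
    for sid in m.samples:
        for ch in _CHANNELS:
            out[f"{sid}.{ch}"] = getattr(m, ch)[sid]
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def read_sample_sheet(path) -> pd.DataFrame:
    sheet = pd.read_csv(path)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    if sheet["sample_id"].duplicated().any():
        raise ValueError("duplicate sample_id in sample sheet")
    sheet = sheet.copy()
    sheet["wt_flag"] = sheet["wt_flag"].astype(bool)
    sheet["day"] = sheet["day"].astype(float)
    return sheet


def read_counts(matrix_path, samples_path=None):
    """Read a count matrix TSV (and optionally a sample sheet CSV).

    Returns the matrix alone, or ``(matrix, sheet)`` when *samples_path* is
    given; sheet samples are cross-checked against matrix columns and any
    mismatch is reported by name.
    """
    wide = pd.read_csv(matrix_path, sep="\t", index_col="gene_id")
    sids: list[str] = []
    for col in wide.columns:
        base, _, ch = col.rpartition(".")
        if ch not in _CHANNELS or not base:
            raise ValueError(f"unparseable count column {col!r}")
        if base not in sids:
            sids.append(base)
    frames = {}
    for ch in _CHANNELS:
        cols = [f"{s}.{ch}" for s in sids]
        absent = [c for c in cols if c not in wide.columns]
        if absent:
            raise ValueError(f"missing count columns: {absent}")
        frames[ch] = wide[cols].set_axis(sids, axis=1)
    m = AllelicCountMatrix(frames["total"], frames["xi"], frames["xa"])
    if samples_path is None:
        return m
    sheet = read_sample_sheet(samples_path)
    unknown = sorted(set(sheet["sample_id"]) - set(m.samples))
    if unknown:
        raise ValueError(f"samples in sheet absent from matrix: {unknown}")
    extra = sorted(set(m.samples) - set(sheet["sample_id"]))
    if extra:
        raise ValueError(f"matrix columns absent from sample sheet: {extra}")
    # keep matrix columns in sheet order
    order = sheet["sample_id"].tolist()
    m = AllelicCountMatrix(m.total[order], m.xi[order], m.xa[order])
    return m, sheet


# ---------------------------------------------------------------------------
# Ratios
# ---------------------------------------------------------------------------

def allelic_ratio(xi, xa):
    """Allelic ratio Xi/(Xi+Xa); NaN where no allelic fragments exist.

    Accepts scalars or aligned arrays/frames.
    """
    xi_arr = np.asarray(xi, dtype=float)
    xa_arr = np.asarray(xa, dtype=float)
    if (xi_arr < 0).any() or (xa_arr < 0).any():
        raise ValueError("allelic counts must be non-negative")
    denom = xi_arr + xa_arr
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom > 0, xi_arr / np.where(denom > 0, denom, 1.0), np.nan)
    if isinstance(xi, pd.DataFrame):
        return pd.DataFrame(out, index=xi.index, columns=xi.columns)
    if isinstance(xi, pd.Series):
        return pd.Series(out, index=xi.index)
    if np.isscalar(xi) and np.isscalar(xa):
        return float(out)
    return out


def sample_ratios(m: AllelicCountMatrix) -> pd.DataFrame:
    """Per-sample allelic ratio table (genes x samples)."""
    return allelic_ratio(m.xi, m.xa)


def baseline_samples_default(sheet: pd.DataFrame) -> list[str]:
    """Uninduced mESC baseline: NoDox, day 0, mESC state, wild type."""
    mask = (
        (sheet["condition"] == "nodox")
        & (sheet["day"] == 0)
        & (sheet["cell_state"] == "mESC")
        & sheet["wt_flag"]
    )
    return sheet.loc[mask, "sample_id"].tolist()


def filter_informative_genes(
    m: AllelicCountMatrix,
    sheet: pd.DataFrame,
    cfg: FilterConfig | None = None,
    baseline_samples: list[str] | None = None,
):
    """Apply coverage and biallelic-baseline filters.

    A gene is retained iff
      * xi + xa >= min_allelic_frags in strictly more than
        min_wt_sample_frac of wild-type samples, and
      * its baseline (uninduced mESC) allelic ratio lies strictly inside
        (baseline_low, baseline_high).

    Returns ``(retained_genes, reasons)`` where *reasons* is a per-gene
    Series with values 'ok', 'coverage', 'baseline' or 'coverage+baseline'.
    """
    cfg = cfg or FilterConfig()
    wt = sheet.loc[sheet["wt_flag"], "sample_id"].tolist()
    if not wt:
        raise ValueError("no wild-type samples in sheet")
    if baseline_samples is None:
        baseline_samples = baseline_samples_default(sheet)
    if not baseline_samples:
        raise ValueError("no baseline (uninduced mESC) samples identified")

    covered = (m.allelic[wt] >= cfg.min_allelic_frags).sum(axis=1)
    coverage_ok = covered > cfg.min_wt_sample_frac * len(wt)

    if cfg.baseline_mode == "pooled":
        base = allelic_ratio(
            m.xi[baseline_samples].sum(axis=1), m.xa[baseline_samples].sum(axis=1)
        )
    else:
        base = allelic_ratio(m.xi[baseline_samples], m.xa[baseline_samples]).mean(
            axis=1, skipna=True
        )
    baseline_ok = (base > cfg.baseline_low) & (base < cfg.baseline_high)
    baseline_ok &= base.notna()

    reasons = pd.Series("ok", index=m.genes, name="filter_reason")
    reasons[~coverage_ok & baseline_ok] = "coverage"
    reasons[coverage_ok & ~baseline_ok] = "baseline"
    reasons[~coverage_ok & ~baseline_ok] = "coverage+baseline"
    retained = m.genes[coverage_ok & baseline_ok]
    return retained, reasons


def ratio_table(
    m: AllelicCountMatrix, sheet: pd.DataFrame, average: bool = True
) -> pd.DataFrame:
    """Gene x condition-timepoint allelic-ratio table.

    Per-sample ratios are computed first; with *average* on, replicates of
    the same (line, condition, day) are combined by an unweighted mean with
    missing per-sample ratios omitted. Columns are a MultiIndex
    (line, condition, day) — or sample_id when *average* is off.
    """
    ratios = sample_ratios(m)
    if not average:
        return ratios
    meta = sheet.set_index("sample_id")
    keys = [(meta.at[s, "line"], meta.at[s, "condition"], meta.at[s, "day"]) for s in ratios.columns]
    grouped = ratios.T.groupby(pd.MultiIndex.from_tuples(keys, names=["line", "condition", "day"]))
    out = grouped.mean().T
    out.columns = pd.MultiIndex.from_tuples(out.columns, names=["line", "condition", "day"])
    return out


def delta_silencing(ratio_dox, ratio_nodox):
    """Signed silencing change, Dox - NoDox; missing inputs propagate NaN."""
    return ratio_dox - ratio_nodox


# ---------------------------------------------------------------------------
# Expression normalization
# ---------------------------------------------------------------------------

def normalize_expression(
    m: AllelicCountMatrix, genes: pd.DataFrame | None = None, mode: str = "rpm"
) -> pd.DataFrame:
    """RPM (a.k.a. CPM) or TPM normalization of the total-count channel.

    TPM requires a gene table with an ``exonic_length`` column (base pairs)
    indexed by gene_id.
    """
    counts = m.total.astype(float)
    depth = counts.sum(axis=0)
    if (depth <= 0).any():
        bad = depth.index[depth <= 0].tolist()
        raise ValueError(f"zero-depth samples: {bad}")
    if mode == "rpm":
        return counts * 1e6 / depth
    if mode == "tpm":
        if genes is None or "exonic_length" not in genes.columns:
            raise ValueError("TPM requires a gene table with exonic_length")
        length_kb = genes["exonic_length"].reindex(m.genes).astype(float) / 1e3
        if length_kb.isna().any() or (length_kb <= 0).any():
            raise ValueError("missing or non-positive exonic_length")
        rate = counts.div(length_kb, axis=0)
        return rate * 1e6 / rate.sum(axis=0)
    raise ValueError(f"unknown normalization mode {mode!r}")


def tertile_assign(values: pd.Series, labels=("low", "medium", "high")) -> pd.Series:
    """Rank-based split into three groups of near-equal size.

    Group sizes differ by at most one, with remainders assigned to the
    earliest groups (so the first label takes the extra member). Ties and
    NaN handling: ties broken by stable input order; NaN values receive a
    pandas NA label.
    """
    finite = values[np.isfinite(values.astype(float))]
    if len(finite) < 3:
        raise ValueError("need at least 3 finite values for tertiles")
    order = np.argsort(finite.to_numpy(), kind="stable")
    n = len(finite)
    base, rem = divmod(n, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    out = pd.Series(pd.NA, index=values.index, dtype="object", name="tertile")
    start = 0
    for label, size in zip(labels, sizes):
        idx = finite.index[order[start : start + size]]
        out[idx] = label
        start += size
    return out


def expression_tertiles(expr: pd.Series) -> pd.Series:
    """Classify genes into equal low/medium/high expression groups."""
    return tertile_assign(expr, labels=("low", "medium", "high"))


def xist_abundance(m: AllelicCountMatrix, xist_gene_id: str = "Xist") -> pd.Series:
    """Per-sample RPM of the Xist row (chromatin-associated transcript level)."""
    if xist_gene_id not in m.genes:
        raise KeyError(f"gene {xist_gene_id!r} not present in count matrix")
    return normalize_expression(m, mode="rpm").loc[xist_gene_id]
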