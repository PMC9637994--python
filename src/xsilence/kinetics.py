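"""Per-gene exponential silencing kinetics.

The silencing trajectory of each X-linked gene is modelled as

    y(t) = yf + y0 * exp(-t * k)

where y is the allelic ratio Xi/(Xi+Xa), t is days of Xist induction,
y0 + yf is the initial ratio, yf the final plateau and k the silencing
rate per day. yf is fixed at 0 for genes that inactivate completely and
is a free parameter only for escapees (mean allelic ratio > 0.1 in mature
differentiated samples). Fitting proceeds in two stages: a pooled fit over
all genes provides initial estimates, then each gene is fit individually
by bounded nonlinear least squares with seeded multistart.

The silencing half-time is the time at which the fitted curve reaches a
fraction F (default 0.5) of the initial ratio:

    t_half = -(1/k) * ln((F*(y0+yf) - yf) / y0)

undefined when k = 0, y0 = 0, or the half-point lies at/below the plateau
(F*(y0+yf) <= yf). In the yf = 0 limit this reduces to ln(2)/k.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .expression import sample_ratios, tertile_assign

__all__ = [
    "KineticsConfig",
    "SilencingFit",
    "pooled_fit_init",
    "flag_escapee",
    "fit_gene_trajectory",
    "silencing_halftime",
    "classify_halftime_tertiles",
    "cross_line_concordance",
    "fit_all",
]


@dataclass
class KineticsConfig:
    F: float = 0.5  # fraction of the initial ratio defining the half-point
    escapee_threshold: float = 0.1
    mature_day_min: float = 7.0
    k_max: float = 10.0
    tol: float = 1e-12
    max_iter: int = 2000
    n_starts: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.F < 1:
            raise ValueError("F must lie in (0, 1)")
        if self.k_max <= 0:
            raise ValueError("k_max must be positive")


@dataclass
class SilencingFit:
    gene_id: str
    y0: float
    yf: float
    k: float
    t_half: float  # NaN when undefined
    escapee: bool
    converged: bool
    sse: float
    n_points: int
    kinetic_class: str = "unclassified"


def _clean(t, y):
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(t) & np.isfinite(y)
    return t[keep], y[keep]


def pooled_fit_init(t, y, cfg: KineticsConfig | None = None):
    """Fit y = y0*exp(-k t) (yf fixed at 0) to pooled trajectory points.

    Returns ``(y0_init, k_init)`` used as the common starting point for
    per-gene fits. Requires at least three distinct timepoints.
    """
    cfg = cfg or KineticsConfig()
    t, y = _clean(t, y)
    if len(np.unique(t)) < 3:
        raise ValueError("pooled fit requires >= 3 distinct timepoints")

    def resid(p):
        return p[0] * np.exp(-p[1] * t) - y

    y_at_start = float(np.clip(np.mean(y[t == t.min()]), 1e-3, 1.0))
    sol = optimize.least_squares(
        resid,
        x0=[y_at_start, 0.5],
        bounds=([0.0, 0.0], [1.0, cfg.k_max]),
        xtol=cfg.tol,
        ftol=cfg.tol,
        gtol=cfg.tol,
        max_nfev=cfg.max_iter,
    )
    return float(sol.x[0]), float(sol.x[1])


def flag_escapee(mature_ratios, cfg: KineticsConfig | None = None) -> bool:
    """True iff the mean allelic ratio in mature samples strictly exceeds
    the escapee threshold (default 0.1)."""
    cfg = cfg or KineticsConfig()
    vals = np.asarray(mature_ratios, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("no mature samples with a defined allelic ratio")
    return bool(vals.mean() > cfg.escapee_threshold)


def _model(t, y0, yf, k):
    return yf + y0 * np.exp(-k * t)


def fit_gene_trajectory(
    t,
    y,
    escapee: bool,
    init=None,
    cfg: KineticsConfig | None = None,
    gene_id: str = "",
) -> SilencingFit:
    """Bounded nonlinear least-squares fit of one gene's trajectory.

    Non-escapees fit (y0, k) with yf = 0. Escapees fit (r0, phi, k) where
    y0 = r0*(1-phi), yf = r0*phi, which keeps y0 + yf <= 1 by construction.
    The best of ``n_starts`` seeded initializations (by SSE) is returned.
    """
    cfg = cfg or KineticsConfig()
    t, y = _clean(t, y)
    if len(t) < 3 or len(np.unique(t)) < 3:
        return SilencingFit(gene_id, math.nan, math.nan, math.nan, math.nan,
                            escapee, False, math.nan, len(t))
    if init is None:
        y0_init = float(np.clip(np.mean(y[t == t.min()]), 1e-3, 1.0))
        init = (y0_init, 0.5)
    y0_init, k_init = float(init[0]), float(init[1])
    k_init = min(max(k_init, 1e-3), cfg.k_max)
    rng = np.random.default_rng([cfg.seed, zlib.crc32(gene_id.encode())])

    if escapee:
        mature = y[t == t.max()]
        r0 = float(np.clip(y0_init if y0_init > 0 else 0.5, 1e-3, 1.0))
        phi0 = float(np.clip(np.mean(mature) / r0 if r0 > 0 else 0.2, 1e-3, 1 - 1e-3))

        def resid(p):
            return _model(t, p[0] * (1 - p[1]), p[0] * p[1], p[2]) - y

        base = np.array([r0, phi0, k_init])
        lo = np.array([0.0, 0.0, 0.0])
        hi = np.array([1.0, 1.0, cfg.k_max])
    else:

        def resid(p):
            return _model(t, p[0], 0.0, p[1]) - y

        base = np.array([np.clip(y0_init, 1e-3, 1.0), k_init])
        lo = np.array([0.0, 0.0])
        hi = np.array([1.0, cfg.k_max])

    best = None
    for s in range(cfg.n_starts):
        if s == 0:
            x0 = base
        else:
            jitter = rng.uniform(0.4, 1.8, size=base.shape)
            x0 = np.clip(base * jitter, lo + 1e-6, hi - 1e-6)
        sol = optimize.least_squares(
            resid, x0=x0, bounds=(lo, hi),
            xtol=cfg.tol, ftol=cfg.tol, gtol=cfg.tol, max_nfev=cfg.max_iter,
        )
        if best is None or sol.cost < best.cost:
            best = sol

    if escapee:
        r0_fit, phi_fit, k_fit = best.x
        y0_fit, yf_fit = r0_fit * (1 - phi_fit), r0_fit * phi_fit
    else:
        (y0_fit, k_fit), yf_fit = best.x, 0.0
    sse = float(2 * best.cost)
    t_half = silencing_halftime(y0_fit, yf_fit, k_fit, cfg)
    return SilencingFit(
        gene_id, float(y0_fit), float(yf_fit), float(k_fit), t_half,
        escapee, bool(best.success), sse, len(t),
    )


def silencing_halftime(y0: float, yf: float, k: float,
                       cfg: KineticsConfig | None = None) -> float:
    """Time at which the fitted curve reaches F*(y0+yf); NaN when undefined.

    Undefined when k = 0, y0 = 0, or the half-point lies at/below the
    plateau yf (the curve never gets there).
    """
    cfg = cfg or KineticsConfig()
    if k < 0:
        raise ValueError("silencing rate k must be non-negative")
    if k == 0 or y0 <= 0:
        return math.nan
    arg = (cfg.F * (y0 + yf) - yf) / y0
    if arg <= 0:
        return math.nan
    return -math.log(arg) / k


def classify_halftime_tertiles(t_half: pd.Series) -> pd.Series:
    """Rank-based fast/intermediate/slow classes of defined half-times.

    Group sizes differ by at most one (remainder to the fast group), ties
    break by stable input order, undefined half-times map to 'unclassified'.
    """
    defined = t_half[np.isfinite(t_half.astype(float))]
    if len(defined) < 3:
        raise ValueError("need >= 3 defined half-times to form classes")
    classes = tertile_assign(t_half, labels=("fast", "intermediate", "slow"))
    return classes.fillna("unclassified")


def cross_line_concordance(t_half_a: pd.Series, t_half_b: pd.Series) -> float:
    """Spearman rank correlation of half-times on shared, defined genes."""
    shared = t_half_a.index.intersection(t_half_b.index)
    a = t_half_a[shared].astype(float)
    b = t_half_b[shared].astype(float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError("need >= 3 shared genes with defined half-times")
    rho, _ = stats.spearmanr(a[ok], b[ok])
    return float(rho)


def fit_all(
    m_or_ratios,
    sheet: pd.DataFrame,
    cfg: KineticsConfig | None = None,
    line: str | None = None,
    genes=None,
) -> pd.DataFrame:
    """Fit silencing trajectories for every gene of one line's Dox samples.

    Accepts an AllelicCountMatrix or a per-sample ratio table (genes x
    samples). Escapee status is called from samples with
    day >= mature_day_min, then each gene is fit across all (day, ratio)
    points of induced samples. Returns one row per gene with fitted
    parameters, half-time, escapee flag, convergence and kinetic class.
    """
    cfg = cfg or KineticsConfig()
    ratios = m_or_ratios if isinstance(m_or_ratios, pd.DataFrame) else sample_ratios(m_or_ratios)
    if genes is not None:
        ratios = ratios.loc[genes]
    meta = sheet.set_index("sample_id").loc[ratios.columns]
    keep = meta["condition"] == "dox"
    if line is not None:
        keep &= meta["line"] == line
    dox = ratios.loc[:, keep.to_numpy()]
    days = meta.loc[keep, "day"].to_numpy(dtype=float)
    if dox.shape[1] == 0:
        raise ValueError("no induced (dox) samples selected")
    mature_cols = days >= cfg.mature_day_min
    if not mature_cols.any():
        raise ValueError("no mature samples at or beyond mature_day_min")

    t_pool = np.tile(days, len(dox))
    y_pool = dox.to_numpy(dtype=float).ravel()
    init = pooled_fit_init(t_pool, y_pool, cfg)

    fits = []
    for gene, row in dox.iterrows():
        y = row.to_numpy(dtype=float)
        mat = y[mature_cols]
        mat = mat[np.isfinite(mat)]
        escapee = bool(mat.mean() > cfg.escapee_threshold) if len(mat) else False
        fits.append(fit_gene_trajectory(days, y, escapee, init, cfg, gene_id=gene))

    table = pd.DataFrame([f.__dict__ for f in fits]).set_index("gene_id")
    defined = table["t_half"].astype(float)
    if np.isfinite(defined).sum() >= 3:
        table["kinetic_class"] = classify_halftime_tertiles(defined)
    return table
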