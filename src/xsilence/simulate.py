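"""Synthetic allelic ChrRNA-seq counts and calibrated ChIP window tracks.

The generator emulates the data structure of a doxycycline-inducible Xist
time course in differentiating XX mESCs: per-gene allelic ratios follow
r(t) = yf + y0*exp(-t*k), total fragment counts are overdispersed
(gamma-Poisson), only a SNP-dependent fraction of fragments is allelically
assignable, and Xi draws among allelic fragments are beta-binomial. Every
gene's true parameters are recorded in a truth table so downstream fits can
be scored against ground truth.

ChIP tracks are generated as per-window IP and input coverage for both
alleles plus spike-in/target read totals, with planted Xi enrichment and
optional mappability artifacts so calibration and blacklisting are
testable end to end.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .expression import SAMPLE_SHEET_COLUMNS, AllelicCountMatrix

__all__ = [
    "LineSpec",
    "SimulationDesign",
    "KINETIC_RATE_STRATA",
    "simulate_truth",
    "simulate_chrrna_counts",
    "expected_ratio_table",
    "simulate_chip_windows",
]

# Silencing-rate strata (per day), equivalent to half-times of roughly
# 0.3-0.8, 0.8-1.5 and 1.5-2.8 days. Chosen so wild-type silencing of
# non-escapees is largely complete by around day 7 of differentiation,
# with slow genes approaching their plateau last.
KINETIC_RATE_STRATA = {
    "fast": (0.9, 2.5),
    "intermediate": (0.45, 0.9),
    "slow": (0.25, 0.45),
}

# Plateau allelic ratios by pathway-dependence label, used for simulated
# knockout lines: dependent genes keep substantial Xi expression in the KO.
_DEPENDENCY_PLATEAU = {"dependent": 0.30, "partial": 0.15, "not": 0.02}

CHRX_REGION_LENGTH = 103_500_000


@dataclass(frozen=True)
class LineSpec:
    """A simulated cell line.

    k_multiplier scales every gene's silencing rate (0 models a line with
    no Xist-mediated silencing); yf_mode "dependency" overrides the plateau
    from the gene's dependency_true label, modelling a pathway knockout.
    """

    name: str
    k_multiplier: float = 1.0
    wt: bool = False
    yf_mode: str = "truth"  # or "dependency"


@dataclass
class SimulationDesign:
    """Time-course design for the ChrRNA-seq simulator."""

    timepoints: tuple = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0)
    replicates: int = 2
    lines: tuple = (LineSpec("WT", 1.0, wt=True),)
    nodox_timepoints: tuple | None = (0.0,)
    depth: float | None = None  # None: use per-gene mu_expr as-is
    nb_dispersion: float = 0.05
    bb_rho: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.timepoints) == 0:
            raise ValueError("need at least one timepoint")
        if any(t < 0 for t in self.timepoints):
            raise ValueError("timepoints must be non-negative")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.depth is not None and self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if not 0 <= self.bb_rho < 1:
            raise ValueError("bb_rho must be in [0, 1)")


def _apportion(n: int, fractions) -> list[int]:
    """Largest-remainder apportionment of n items over the given fractions."""
    fr = np.asarray(fractions, dtype=float)
    if (fr < 0).any() or (fr > 1).any():
        raise ValueError("class_mix fractions must lie in [0, 1]")
    if fr.sum() <= 0:
        raise ValueError("class_mix fractions must not all be zero")
    fr = fr / fr.sum()
    raw = fr * n
    counts = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - counts), kind="stable")[: n - counts.sum()]:
        counts[i] += 1
    return counts.tolist()


def simulate_truth(
    n_genes: int,
    design: SimulationDesign,
    class_mix=(1 / 3, 1 / 3, 1 / 3),
    escapee_frac: float = 0.06,
    mean_allelic_coverage: float = 100.0,
) -> pd.DataFrame:
    """Draw per-gene ground-truth silencing parameters.

    Genes are partitioned into fast/intermediate/slow rate strata according
    to *class_mix* (largest-remainder apportionment), a fraction
    *escapee_frac* receives a free plateau yf_true > 0.1, and expression
    levels are drawn so the mean allelic coverage per gene and sample is
    *mean_allelic_coverage* fragments. Deterministic given design.seed.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if not 0 <= escapee_frac <= 1:
        raise ValueError("escapee_frac must lie in [0, 1]")
    rng = np.random.default_rng([design.seed, 101])

    strata = list(KINETIC_RATE_STRATA)
    counts = _apportion(n_genes, class_mix)
    stratum = np.repeat(strata, counts)
    rng.shuffle(stratum)
    k_true = np.array(
        [rng.uniform(*KINETIC_RATE_STRATA[s]) for s in stratum], dtype=float
    )

    n_escape = int(round(escapee_frac * n_genes))
    escapee = np.zeros(n_genes, dtype=bool)
    escapee[rng.choice(n_genes, size=n_escape, replace=False)] = True

    r0 = np.clip(rng.normal(0.5, 0.03, n_genes), 0.35, 0.65)
    yf = np.zeros(n_genes)
    yf[escapee] = rng.uniform(0.15, np.minimum(0.35, r0[escapee] - 0.1))
    y0 = r0 - yf

    # Dependence labels correlate with kinetics: slowly silencing genes
    # tend to need SmcHD1, fast genes tend not to.
    probs = {
        "slow": (0.70, 0.25, 0.05),
        "intermediate": (0.15, 0.55, 0.30),
        "fast": (0.05, 0.25, 0.70),
    }
    dep = np.array(
        [
            rng.choice(["dependent", "partial", "not"], p=probs[s])
            for s in stratum
        ],
        dtype=object,
    )
    dep[escapee] = "escapee"

    snp_frac = rng.uniform(0.15, 0.45, n_genes)
    coverage = rng.lognormal(
        math.log(mean_allelic_coverage) - 0.5 * 0.4**2, 0.4, n_genes
    )
    coverage *= mean_allelic_coverage / coverage.mean()
    mu_expr = coverage / snp_frac

    width = len(str(n_genes))
    truth = pd.DataFrame(
        {
            "gene_id": [f"gene{i + 1:0{width}d}" for i in range(n_genes)],
            "chrom": "chrX",
            "tss_pos": np.sort(rng.integers(0, CHRX_REGION_LENGTH, n_genes)),
            "exonic_length": rng.integers(500, 10_000, n_genes),
            "mu_expr": mu_expr,
            "snp_frac": snp_frac,
            "y0_true": y0,
            "yf_true": yf,
            "k_true": k_true,
            "escapee_true": escapee,
            "kinetic_stratum": stratum,
            "dependency_true": dep,
        }
    ).set_index("gene_id")
    return truth


def _line_params(truth: pd.DataFrame, line: LineSpec):
    """Per-line (y0, yf) keeping the initial ratio y0+yf at its truth value."""
    r0 = truth["y0_true"].to_numpy() + truth["yf_true"].to_numpy()
    if line.yf_mode == "dependency":
        yf = np.array(
            [
                row.yf_true
                if row.dependency_true == "escapee"
                else _DEPENDENCY_PLATEAU[row.dependency_true]
                for row in truth.itertuples()
            ]
        )
        yf = np.minimum(yf, r0 - 0.01)
    elif line.yf_mode == "truth":
        yf = truth["yf_true"].to_numpy()
    else:
        raise ValueError(f"unknown yf_mode {line.yf_mode!r}")
    return r0 - yf, yf


def _expected_ratio(truth: pd.DataFrame, line: LineSpec, day: float, dox: bool):
    y0, yf = _line_params(truth, line)
    if not dox:
        r = y0 + yf
    else:
        k = truth["k_true"].to_numpy() * line.k_multiplier
        r = yf + y0 * np.exp(-day * k)
    if (r < 0).any() or (r > 1).any():
        raise ValueError("expected allelic ratio outside [0, 1]; reject design")
    return r


def _sample_plan(design: SimulationDesign):
    """Ordered list of (line, condition, day, replicate, sample_id) rows."""
    plan = []
    nodox = design.timepoints if design.nodox_timepoints is None else design.nodox_timepoints
    for line in design.lines:
        for cond, days in (("nodox", nodox), ("dox", design.timepoints)):
            for day in days:
                for rep in range(1, design.replicates + 1):
                    sid = f"{line.name}_{cond}_d{day:g}_r{rep}"
                    plan.append((line, cond, float(day), rep, sid))
    return plan


def expected_ratio_table(truth: pd.DataFrame, design: SimulationDesign):
    """Noise-free expected allelic ratios (genes x samples) and sample sheet.

    This is the infinite-depth, zero-dispersion limit of the simulator and
    serves as the oracle for identifiability tests.
    """
    plan = _sample_plan(design)
    data = {
        sid: _expected_ratio(truth, line, day, cond == "dox")
        for line, cond, day, _, sid in plan
    }
    ratios = pd.DataFrame(data, index=truth.index)
    return ratios, _sheet_from_plan(plan)


def _sheet_from_plan(plan) -> pd.DataFrame:
    rows = [
        {
            "sample_id": sid,
            "line": line.name,
            "condition": cond,
            "day": day,
            "replicate": rep,
            "cell_state": "mESC" if day <= 1 else "NPC",
            "wt_flag": line.wt,
        }
        for line, cond, day, rep, sid in plan
    ]
    return pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS)


def simulate_chrrna_counts(
    truth: pd.DataFrame,
    design: SimulationDesign,
    xist_row: bool = False,
):
    """Simulate an allelic count matrix for the given truth and design.

    Per gene and sample: total fragments ~ gamma-Poisson around mu_expr
    (optionally depth-rescaled), allelic fragments = binomial thinning by
    snp_frac, and Xi fragments ~ beta-binomial(n_allelic, r(t), bb_rho).
    Count conservation xi + xa + unassigned = total holds by construction.
    Returns ``(AllelicCountMatrix, sample_sheet)``.
    """
    rng = np.random.default_rng([design.seed, 202])
    plan = _sample_plan(design)
    n_genes = len(truth)

    mu = truth["mu_expr"].to_numpy(dtype=float)
    if design.depth is not None:
        mu = mu * design.depth / mu.sum()
    snp = truth["snp_frac"].to_numpy(dtype=float)

    total = np.empty((n_genes, len(plan)), dtype=np.int64)
    xi = np.empty_like(total)
    xa = np.empty_like(total)
    for j, (line, cond, day, _, _) in enumerate(plan):
        r = _expected_ratio(truth, line, day, cond == "dox")
        if design.nb_dispersion > 0:
            lam = rng.gamma(1.0 / design.nb_dispersion, mu * design.nb_dispersion)
        else:
            lam = mu
        tot = rng.poisson(lam)
        n_allelic = rng.binomial(tot, snp)
        if design.bb_rho > 0:
            conc = 1.0 / design.bb_rho - 1.0
            interior = (r > 0) & (r < 1)
            p = np.where(interior, r, r)
            p = p.astype(float).copy()
            p[interior] = rng.beta(r[interior] * conc, (1 - r[interior]) * conc)
        else:
            p = r
        xi_j = rng.binomial(n_allelic, p)
        total[:, j] = tot
        xi[:, j] = xi_j
        xa[:, j] = n_allelic - xi_j

    sids = [sid for *_, sid in plan]
    frames = {
        "total": pd.DataFrame(total, index=truth.index, columns=sids),
        "xi": pd.DataFrame(xi, index=truth.index, columns=sids),
        "xa": pd.DataFrame(xa, index=truth.index, columns=sids),
    }

    if xist_row:
        # Xist is expressed from the inducible Xi allele upon Dox addition
        # and ramps up over the first days of induction. Very few of its
        # fragments are allelically assignable here, keeping the row out of
        # gene-level silencing analysis while its RPM remains informative.
        row_tot, row_xi, row_xa = [], [], []
        for line, cond, day, _, _ in plan:
            if cond == "nodox":
                level = 40.0
            else:
                level = 40.0 + 6000.0 * (1 - math.exp(-1.2 * day))
            tot = int(rng.poisson(level))
            n_allelic = rng.binomial(tot, 0.02)
            p_xi = 0.5 if cond == "nodox" else 0.95
            xij = rng.binomial(n_allelic, p_xi)
            row_tot.append(tot)
            row_xi.append(xij)
            row_xa.append(n_allelic - xij)
        for ch, row in (("total", row_tot), ("xi", row_xi), ("xa", row_xa)):
            frames[ch].loc["Xist"] = row

    m = AllelicCountMatrix(frames["total"], frames["xi"], frames["xa"])
    return m, _sheet_from_plan(plan)


def gene_table(truth: pd.DataFrame, xist_locus: int = 50_000_000) -> pd.DataFrame:
    """Gene annotation derived from the truth table (BED-like, 0-based)."""
    tss = truth["tss_pos"].astype(int)
    length = truth["exonic_length"].astype(int)
    return pd.DataFrame(
        {
            "gene_id": truth.index,
            "chrom": truth["chrom"],
            "start": tss,
            "end": tss + length,
            "strand": "+",
            "tss_pos": tss,
            "exonic_length": length,
            "dist_to_xist": (tss - xist_locus).abs(),
        }
    ).set_index("gene_id")


# ---------------------------------------------------------------------------
# ChIP window tracks
# ---------------------------------------------------------------------------

def simulate_chip_windows(
    n_windows: int,
    planted_xi,
    planted_xa,
    artifact_windows=(),
    low_allelic_windows=(),
    replicates: int = 2,
    window_size: int = 250_000,
    base_input: float = 200.0,
    allelic_input_frac: float = 0.4,
    ip_scale: float = 2.0,
    spike_input_reads: int = 1_000_000,
    target_input_reads: int = 10_000_000,
    noise: str = "none",
    seed: int = 0,
):
    """Simulate calibrated allelic ChIP coverage over fixed-size windows.

    *planted_xi*/*planted_xa* give the true per-window IP/input enrichment
    on each allele. Artifact windows get 10x-inflated non-allelic input
    (poor mappability); low_allelic_windows get 20x-deflated allelic input.
    The IP sample is generated at *ip_scale* times the input's material,
    with spike-in reads scaled accordingly, so spike calibration exactly
    recovers the planted enrichment in the noise-free case.

    Returns ``(tracks, manifest)``: a dict of per-sample window DataFrames
    (chrom/start/end/total/xi/xa) and a read-count manifest DataFrame.
    """
    if n_windows < 1:
        raise ValueError("empty window set")
    e_xi = np.broadcast_to(np.asarray(planted_xi, dtype=float), (n_windows,)).copy()
    e_xa = np.broadcast_to(np.asarray(planted_xa, dtype=float), (n_windows,)).copy()
    artifact = np.asarray(sorted(artifact_windows), dtype=int)
    lowall = np.asarray(sorted(low_allelic_windows), dtype=int)
    for idx in (artifact, lowall):
        if len(idx) and (idx.min() < 0 or idx.max() >= n_windows):
            raise ValueError("artifact window index out of range")
    if noise not in ("none", "poisson"):
        raise ValueError("noise must be 'none' or 'poisson'")
    rng = np.random.default_rng([seed, 303])

    starts = np.arange(n_windows) * window_size
    ends = starts + window_size

    input_total = np.full(n_windows, base_input)
    input_total[artifact] *= 10.0
    input_allele = np.full(n_windows, base_input * allelic_input_frac / 2.0)
    input_allele_xi = input_allele.copy()
    input_allele_xa = input_allele.copy()
    input_allele_xi[lowall] /= 20.0
    input_allele_xa[lowall] /= 20.0

    ip_xi = ip_scale * input_allele_xi * e_xi
    ip_xa = ip_scale * input_allele_xa * e_xa
    ip_total = ip_scale * input_total * (e_xi + e_xa) / 2.0

    tracks: dict[str, pd.DataFrame] = {}
    manifest_rows = []
    for rep in range(1, replicates + 1):
        for role, tot, axi, axa, n_target, n_spike, pair in (
            (
                "input",
                input_total,
                input_allele_xi,
                input_allele_xa,
                target_input_reads,
                spike_input_reads,
                "",
            ),
            (
                "IP",
                ip_total,
                ip_xi,
                ip_xa,
                int(target_input_reads * ip_scale),
                int(spike_input_reads * ip_scale),
                f"input_r{rep}",
            ),
        ):
            sid = f"{role}_r{rep}"
            if noise == "poisson":
                tot = rng.poisson(tot).astype(float)
                axi = rng.poisson(axi).astype(float)
                axa = rng.poisson(axa).astype(float)
                tot = np.maximum(tot, axi + axa)
            tracks[sid] = pd.DataFrame(
                {
                    "chrom": "chrX",
                    "start": starts,
                    "end": ends,
                    "total": tot,
                    "xi": axi,
                    "xa": axa,
                }
            )
            manifest_rows.append(
                {
                    "sample_id": sid,
                    "role": role,
                    "antibody": "H2AK119ub1",
                    "n_target_reads": n_target,
                    "n_spike_reads": n_spike,
                    "input_id": pair,
                }
            )
    manifest = pd.DataFrame(manifest_rows)
    return tracks, manifest
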