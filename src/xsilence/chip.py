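"""Spike-calibrated allelic ChIP-seq window analysis.

The X chromosome's allelically analysable region is tiled into fixed-size
windows (default 250 kb over 103.5 Mb -> 414 windows). Per-sample window
coverage is depth-normalized, IP signal is scaled by a spike-in-derived
occupancy-ratio calibration factor, and per-allele enrichment E = IP/input
is computed per window. Differential (Xi - Xa) and ratio (Xi/Xa) summaries
are internally normalized and therefore robust to sample-to-sample
technical variability. Windows with aberrant non-allelic input (poor
mappability, median +/- k MAD outliers) or in the lowest tail of allelic
input signal are blacklisted from summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ChipConfig",
    "ChipSample",
    "WindowSet",
    "tile_windows",
    "calibration_factor",
    "window_enrichment",
    "blacklist_windows",
    "summarize_profiles",
    "read_bedgraph_windows",
]


@dataclass
class ChipConfig:
    window_size: int = 250_000
    mad_k: float = 2.5
    mad_scaled: bool = False          # apply the 1.4826 normal-consistency factor
    low_allelic_quantile: float = 0.05
    pseudocount: float = 1e-6         # guard for zero input, per-million units

    def __post_init__(self) -> None:
        if self.mad_k <= 0:
            raise ValueError("mad_k must be positive")
        if not 0 < self.low_allelic_quantile < 1:
            raise ValueError("low_allelic_quantile must lie in (0, 1)")


@dataclass
class WindowSet:
    chrom: str
    starts: np.ndarray
    ends: np.ndarray
    region_length: int

    def __len__(self) -> int:
        return len(self.starts)


@dataclass
class ChipSample:
    """One ChIP-seq sample: per-window signal plus calibration read counts."""

    sample_id: str
    role: str  # "IP" or "input"
    signal: pd.DataFrame  # columns: start, end, total, xi, xa
    n_target_reads: int
    n_spike_reads: int
    antibody: str = ""

    def __post_init__(self) -> None:
        if self.role not in ("IP", "input"):
            raise ValueError("role must be 'IP' or 'input'")
        if self.n_spike_reads <= 0 or self.n_target_reads <= 0:
            raise ValueError(
                f"sample {self.sample_id!r}: spike and target read counts must be positive"
            )
        for col in ("start", "end", "total", "xi", "xa"):
            if col not in self.signal.columns:
                raise ValueError(f"sample {self.sample_id!r}: missing column {col!r}")


def tile_windows(region_length: int, window_size: int = 250_000,
                 chrom: str = "chrX") -> WindowSet:
    """Contiguous half-open windows covering [0, region_length).

    The final window is truncated when region_length is not a multiple of
    window_size.
    """
    if region_length <= 0 or window_size <= 0:
        raise ValueError("region_length and window_size must be positive")
    n = math.ceil(region_length / window_size)
    starts = np.arange(n, dtype=np.int64) * window_size
    ends = np.minimum(starts + window_size, region_length)
    return WindowSet(chrom, starts, ends, region_length)


def calibration_factor(ip: ChipSample, input_: ChipSample) -> float:
    """Spike-in occupancy-ratio calibration factor for an IP/input pair.

    alpha = (spike_input / spike_IP) * (target_IP / target_input),
    applied multiplicatively to the IP's depth-normalized window signal.
    """
    return (input_.n_spike_reads / ip.n_spike_reads) * (
        ip.n_target_reads / input_.n_target_reads
    )


def _check_windows_match(ip: ChipSample, input_: ChipSample) -> None:
    if len(ip.signal) != len(input_.signal) or not (
        np.array_equal(ip.signal["start"].to_numpy(), input_.signal["start"].to_numpy())
        and np.array_equal(ip.signal["end"].to_numpy(), input_.signal["end"].to_numpy())
    ):
        raise ValueError("IP and input window sets do not match")


def window_enrichment(ip: ChipSample, input_: ChipSample,
                      cfg: ChipConfig | None = None) -> pd.DataFrame:
    """Calibrated per-window, per-allele IP/input enrichment.

    Window signal is first depth-normalized within each sample (per million
    target-genome reads) so that enrichment is invariant to uniform
    rescaling of either sample, then the IP side is multiplied by the
    spike-in calibration factor:

        E_a = alpha * (IP_a / N_IP) / (input_a / N_input)

    Returns a frame with E_xi, E_xa, the differential D = E_xi - E_xa, the
    ratio R = E_xi / E_xa (NaN where E_xa = 0) and a low_input flag for
    windows with zero allelic input on either allele.
    """
    cfg = cfg or ChipConfig()
    _check_windows_match(ip, input_)
    alpha = calibration_factor(ip, input_)

    out = ip.signal[["start", "end"]].copy()
    low = np.zeros(len(out), dtype=bool)
    for allele in ("xi", "xa"):
        ip_norm = ip.signal[allele].to_numpy(dtype=float) * 1e6 / ip.n_target_reads
        in_norm = input_.signal[allele].to_numpy(dtype=float) * 1e6 / input_.n_target_reads
        low |= in_norm <= 0
        denom = np.maximum(in_norm, cfg.pseudocount)
        out[f"E_{allele}"] = alpha * ip_norm / denom
    out["D"] = out["E_xi"] - out["E_xa"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = out["E_xi"] / out["E_xa"]
    out["R"] = ratio.where(out["E_xa"] > 0)
    out["low_input"] = low
    return out


def _lower_quantile(values: np.ndarray, q: float) -> float:
    """Type-1 (lower) empirical quantile: the ceil(q*n)-th order statistic."""
    srt = np.sort(values)
    idx = max(math.ceil(q * len(srt)), 1) - 1
    return float(srt[idx])


def blacklist_windows(input_nonallelic, input_allelic,
                      cfg: ChipConfig | None = None) -> pd.Series:
    """Per-window mask from input-signal rules.

    'poor_mappability': |signal - median| > mad_k * MAD of the non-allelic
    input (MAD unscaled by default). 'low_allelic': allelic input strictly
    below the low_allelic_quantile empirical quantile. Poor mappability
    takes precedence where both apply; everything else is 'ok'.
    """
    cfg = cfg or ChipConfig()
    na = np.asarray(input_nonallelic, dtype=float)
    al = np.asarray(input_allelic, dtype=float)
    if len(na) == 0 or len(al) != len(na):
        raise ValueError("tracks must be non-empty and of equal length")

    med = np.median(na)
    mad = np.median(np.abs(na - med))
    if cfg.mad_scaled:
        mad *= 1.4826
    poor = np.abs(na - med) > cfg.mad_k * mad

    thr = _lower_quantile(al, cfg.low_allelic_quantile)
    low = al < thr

    mask = np.where(poor, "poor_mappability", np.where(low, "low_allelic", "ok"))
    index = input_nonallelic.index if isinstance(input_nonallelic, pd.Series) else None
    return pd.Series(mask, index=index, name="mask")


def summarize_profiles(enrichments: list[pd.DataFrame],
                       mask: pd.Series | np.ndarray | None = None):
    """Replicate-averaged differential track and masked ratio distribution.

    Returns ``(mean_D, ratios, counts)``: the unweighted per-window mean of
    D across replicates, the per-window replicate-mean Xi/Xa ratios of
    unmasked windows, and a dict with masked/retained window counts.
    """
    if not enrichments:
        raise ValueError("no replicates given")
    first = enrichments[0]
    for e in enrichments[1:]:
        if len(e) != len(first) or not np.array_equal(
            e["start"].to_numpy(), first["start"].to_numpy()
        ):
            raise ValueError("replicate window sets do not match")
    mean_d = pd.concat([e["D"] for e in enrichments], axis=1).mean(axis=1)
    mean_r = pd.concat([e["R"] for e in enrichments], axis=1).mean(axis=1)
    if mask is None:
        keep = np.ones(len(first), dtype=bool)
    else:
        keep = np.asarray(mask) == "ok"
    ratios = mean_r.to_numpy()[keep]
    counts = {"n_windows": len(first), "n_masked": int((~keep).sum()),
              "n_retained": int(keep.sum())}
    return mean_d, ratios, counts


def read_bedgraph_windows(path, windows: WindowSet, chrom: str | None = None) -> np.ndarray:
    """Sum bedGraph coverage into windows, splitting intervals
    proportionally to their overlap with each window."""
    bg = pd.read_csv(path, sep="\t", header=None,
                     names=["chrom", "start", "end", "value"], comment="#")
    if chrom is None:
        chrom = windows.chrom
    bg = bg[bg["chrom"] == chrom]
    out = np.zeros(len(windows), dtype=float)
    size = windows.ends[0] - windows.starts[0] if len(windows) else 0
    for start, end, value in bg[["start", "end", "value"]].itertuples(index=False):
        start = max(int(start), 0)
        end = min(int(end), windows.region_length)
        if end <= start:
            continue
        first = int(start // size)
        last = int((end - 1) // size)
        for w in range(first, min(last, len(windows) - 1) + 1):
            ov = min(end, windows.ends[w]) - max(start, windows.starts[w])
            if ov > 0:
                out[w] += value * ov / (end - start)
    return out
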