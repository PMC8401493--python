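"""Reconstruction figures of merit and nonparametric method comparison.

Five figures of merit (FoM) quantify how a reconstructed lead ``xr`` matches
the original ``x`` (both in mV):

* RMS error (uV)      -- ``1000 * sqrt(mean((xr - x)**2))``
* cross-correlation % -- 100 x Pearson r with (N-1)-normalised deviations
* MAD (uV)            -- ``1000 * max|xr - x|`` over the whole segment
* SSD (mV^2)          -- ``sum((xr - x)**2)``
* SNR (dB)            -- ``10*log10(sum((x - mean(x))**2) / sum((x - xr)**2))``

SNR is reported signal-power-over-error-power, so larger is better; the
``error_over_signal`` flag flips the orientation for comparison with sources
that print the inverted ratio.

Method comparison uses the two-sided Wilcoxon rank-sum (Mann-Whitney) test:
exact enumeration with mid-rank ties for pooled sizes up to 20, normal
approximation with continuity and tie correction above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import EcgReconError, UndefinedMetricError

__all__ = [
    "FomReport",
    "rms_error",
    "cross_correlation",
    "mad",
    "ssd",
    "snr",
    "fom_report",
    "wilcoxon_rank_sum",
    "reports_to_frame",
    "format_p_value",
]

FOM_NAMES = ["rms_uv", "cc_pct", "mad_uv", "ssd_mv2", "snr_db"]


def _pair(x, xr) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float).ravel()
    xr = np.asarray(xr, dtype=float).ravel()
    if x.size != xr.size:
        raise EcgReconError(
            f"signal lengths differ: {x.size} vs {xr.size}"
        )
    if x.size < 1:
        raise EcgReconError("signals must contain at least one sample")
    return x, xr


def rms_error(x, xr) -> float:
    """Root-mean-square reconstruction error in microvolts."""
    x, xr = _pair(x, xr)
    return 1000.0 * float(np.sqrt(np.mean((xr - x) ** 2)))


def cross_correlation(x, xr) -> float:
    """Pearson cross-correlation in percent ((N-1)-normalised)."""
    x, xr = _pair(x, xr)
    if x.size < 2:
        raise EcgReconError("cross-correlation needs at least 2 samples")
    sx = x.std(ddof=1)
    sr = xr.std(ddof=1)
    if sx == 0 or sr == 0:
        raise UndefinedMetricError(
            "cross-correlation undefined for constant signals"
        )
    z = ((x - x.mean()) / sx) * ((xr - xr.mean()) / sr)
    return 100.0 * float(z.sum() / (x.size - 1))


def mad(x, xr) -> float:
    """Maximum amplitude distance in microvolts, over the whole segment."""
    x, xr = _pair(x, xr)
    return 1000.0 * float(np.max(np.abs(xr - x)))


def ssd(x, xr) -> float:
    """Sum of squared distances (accumulated error) in mV^2."""
    x, xr = _pair(x, xr)
    return float(np.sum((xr - x) ** 2))


def snr(x, xr, *, error_over_signal: bool = False) -> float:
    """Signal-to-noise ratio in dB, treating the residual as noise.

    Returns ``+inf`` for a perfect reconstruction (``-inf`` in the
    ``error_over_signal`` orientation).
    """
    x, xr = _pair(x, xr)
    sig = float(np.sum((x - x.mean()) ** 2))
    if sig == 0:
        raise UndefinedMetricError("SNR undefined for a constant signal")
    err = float(np.sum((x - xr) ** 2))
    if err == 0:
        return -math.inf if error_over_signal else math.inf
    ratio = err / sig if error_over_signal else sig / err
    return 10.0 * math.log10(ratio)


@dataclass(frozen=True)
class FomReport:
    """The five figures of merit for one (target lead, method) pair."""

    rms: float       # uV
    cc: float        # percent
    mad: float       # uV
    ssd: float       # mV^2
    snr: float       # dB
    lead_name: str = ""
    method_name: str = ""
    n_samples: int = 0


def fom_report(x, xr, lead_name: str = "",
               method_name: str = "") -> FomReport:
    """All five metrics computed on the same sample range."""
    x, xr = _pair(x, xr)
    return FomReport(
        rms=rms_error(x, xr),
        cc=cross_correlation(x, xr),
        mad=mad(x, xr),
        ssd=ssd(x, xr),
        snr=snr(x, xr),
        lead_name=lead_name,
        method_name=method_name,
        n_samples=x.size,
    )


def reports_to_frame(reports) -> pd.DataFrame:
    """Tidy table: one row per report, FoM columns in field order."""
    return pd.DataFrame([
        {"lead": r.lead_name, "method": r.method_name,
         "n_samples": r.n_samples, "rms_uv": r.rms, "cc_pct": r.cc,
         "mad_uv": r.mad, "ssd_mv2": r.ssd, "snr_db": r.snr}
        for r in reports
    ])


# --- Wilcoxon rank sum -----------------------------------------------------

def _midranks(values: np.ndarray) -> np.ndarray:
    return stats.rankdata(values, method="average")


def wilcoxon_rank_sum(a, b) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two value samples.

    Exact enumeration over all rank assignments (mid-ranks for ties) when
    ``len(a) + len(b) <= 20``; otherwise the normal approximation with
    continuity correction and tie-corrected variance.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise EcgReconError("both samples must contain at least one value")
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    n_a, n = a.size, pooled.size
    w_obs = float(ranks[:n_a].sum())
    mean_w = n_a * (n + 1) / 2.0

    if n <= 20:
        dev_obs = abs(w_obs - mean_w)
        hits = 0
        total = 0
        for comb in combinations(range(n), n_a):
            total += 1
            w = ranks[list(comb)].sum()
            if abs(w - mean_w) >= dev_obs - 1e-12:
                hits += 1
        return hits / total

    n_b = b.size
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts))
    var_w = n_a * n_b / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w == 0:
        return 1.0
    z = (abs(w_obs - mean_w) - 0.5) / math.sqrt(var_w)
    z = max(z, 0.0)
    return float(2.0 * stats.norm.sf(z))


def format_p_value(p: float, floor: float = 1e-16) -> str:
    """Human-readable p-value; values below the floor print as '<1e-16'."""
    return f"<{floor:g}" if p < floor else f"{p:.4g}"
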