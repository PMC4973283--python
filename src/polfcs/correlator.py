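"""Correlation estimators for two-channel binned photon traces.

``direct_correlate`` is the exact O(N*L) estimator evaluated at every integer
lag; it serves as the oracle for ``multitau_correlate``, which reproduces the
quasi-logarithmic lag grid of hardware correlators by re-binning the trace by
a coarsening factor p between stages.  Both use the symmetric normalization

    g(k) = <I1[t] I2[t+k]> / (<I1>_[0,N-k) <I2>_[k,N)) - 1,

with the channel means taken over the overlapping windows, which removes the
finite-trace bias of the naive estimator.  At lags representable without
coarsening the multi-tau values equal the direct estimator exactly; at
coarsened lags they equal the direct estimator applied to the re-binned
trace.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .model import CorrelationCurve, PolarizationConfig, get_config

__all__ = [
    "PhotonTrace",
    "direct_correlate",
    "multitau_correlate",
    "multitau_lag_grid",
    "average_curves",
]


@dataclass
class PhotonTrace:
    """Two-channel binned photon counts.

    ``counts_ch0``/``counts_ch1`` are non-negative integer counts per bin of
    width ``bin_width`` seconds; ``duration`` is the total trace length.
    """

    counts_ch0: np.ndarray
    counts_ch1: np.ndarray
    bin_width: float
    duration: Optional[float] = None
    config: Optional[PolarizationConfig] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        self.counts_ch0 = np.asarray(self.counts_ch0)
        self.counts_ch1 = np.asarray(self.counts_ch1)
        if self.counts_ch0.shape != self.counts_ch1.shape or self.counts_ch0.ndim != 1:
            raise ValueError("both channels must be 1-D arrays of equal length")
        if np.any(self.counts_ch0 < 0) or np.any(self.counts_ch1 < 0):
            raise ValueError("photon counts must be non-negative")
        if not self.bin_width > 0:
            raise ValueError("bin_width must be > 0")
        n = self.counts_ch0.size
        if self.duration is None:
            self.duration = n * self.bin_width
        elif abs(self.duration - n * self.bin_width) > self.bin_width:
            raise ValueError("duration inconsistent with n_bins * bin_width")
        if self.config is not None:
            self.config = get_config(self.config)

    def __len__(self) -> int:
        return self.counts_ch0.size

    # -- I/O ---------------------------------------------------------------
    def write(self, path) -> None:
        """Write the trace (.csv or .npz by extension) plus a JSON sidecar."""
        path = Path(path)
        if path.suffix == ".npz":
            np.savez_compressed(path, counts_ch0=self.counts_ch0, counts_ch1=self.counts_ch1)
        else:
            pd.DataFrame(
                {
                    "bin_index": np.arange(len(self)),
                    "counts_ch0": self.counts_ch0,
                    "counts_ch1": self.counts_ch1,
                }
            ).to_csv(path, index=False)
        meta = {
            "bin_width_s": self.bin_width,
            "duration_s": self.duration,
            "config_label": self.config.label if self.config else None,
            "seed": self.seed,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def read(cls, path) -> "PhotonTrace":
        path = Path(path)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        if path.suffix == ".npz":
            data = np.load(path)
            c0, c1 = data["counts_ch0"], data["counts_ch1"]
        else:
            df = pd.read_csv(path)
            c0, c1 = df["counts_ch0"].to_numpy(), df["counts_ch1"].to_numpy()
        return cls(
            counts_ch0=c0,
            counts_ch1=c1,
            bin_width=meta.get("bin_width_s", 1.0),
            duration=meta.get("duration_s"),
            config=meta.get("config_label"),
            seed=meta.get("seed"),
        )


def _normalized_xcorr(i1: np.ndarray, i2: np.ndarray, lags: np.ndarray) -> np.ndarray:
    """Symmetrically normalized cross-correlation at integer lags (>= 0)."""
    n = i1.size
    c1 = np.concatenate(([0.0], np.cumsum(i1, dtype=float)))
    c2 = np.concatenate(([0.0], np.cumsum(i2, dtype=float)))
    out = np.empty(lags.size)
    for j, k in enumerate(lags):
        m = n - k
        num = (i1[:m] @ i2[k:]) / m
        mean1 = c1[m] / m
        mean2 = (c2[n] - c2[k]) / m
        out[j] = num / (mean1 * mean2) - 1.0
    return out


def direct_correlate(trace: PhotonTrace, max_lag_bins: int) -> CorrelationCurve:
    """Exact normalized cross-correlation at every integer lag up to max_lag_bins.

    The zero-lag value is computed as well and stored on the returned curve's
    ``g_zero``; the curve itself starts at one bin of lag.
    """
    n = len(trace)
    if not 0 < max_lag_bins < n / 2:
        raise ValueError("max_lag_bins must be positive and < trace length / 2")
    i1 = trace.counts_ch0.astype(float)
    i2 = trace.counts_ch1.astype(float)
    if i1.mean() <= 0 or i2.mean() <= 0:
        raise ValueError("channel mean is zero; normalization undefined")
    lags = np.arange(0, max_lag_bins + 1)
    g = _normalized_xcorr(i1, i2, lags)
    return CorrelationCurve(
        lags=lags[1:] * trace.bin_width,
        values=g[1:],
        config=trace.config,
        g_zero=g[0],
    )


def _rebin(x: np.ndarray, p: int) -> np.ndarray:
    m = (x.size // p) * p
    return x[:m].reshape(-1, p).sum(axis=1)


def multitau_lag_grid(n_bins: int, m: int = 16, p: int = 2) -> list:
    """Lag schedule of the multi-tau scheme, as (stage, lags_in_raw_bins).

    Stage 0 covers lags 1..m at full resolution; stage j >= 1 covers lags
    (m//p+1..m) * p**j in the trace re-binned by p**j.  Stages stop when the
    re-binned trace is shorter than 2*m bins.
    """
    if m < p or m % p:
        raise ValueError("m must be a positive multiple of p")
    grid = [(0, np.arange(1, m + 1))]
    j = 1
    while (n_bins // p**j) >= 2 * m:
        grid.append((j, np.arange(m // p + 1, m + 1) * p**j))
        j += 1
    return grid


def multitau_correlate(trace: PhotonTrace, m: int = 16, p: int = 2,
                       max_lag: Optional[float] = None) -> CorrelationCurve:
    """Multi-tau cross-correlation on a quasi-logarithmic lag grid.

    Parameters
    ----------
    trace:
        Two-channel photon trace.
    m:
        Correlator points per stage (lags per coarsening level).
    p:
        Coarsening factor between stages.
    max_lag:
        Optional cap on the largest lag, in seconds.
    """
    n = len(trace)
    grid = multitau_lag_grid(n, m=m, p=p)
    if len(grid) < 2:
        raise ValueError("trace too short for at least two multi-tau stages")
    i1 = trace.counts_ch0.astype(float)
    i2 = trace.counts_ch1.astype(float)
    if i1.mean() <= 0 or i2.mean() <= 0:
        raise ValueError("channel mean is zero; normalization undefined")
    all_lags, all_vals = [], []
    g_zero = _normalized_xcorr(i1, i2, np.array([0]))[0]
    for stage, raw_lags in grid:
        f = p**stage
        if stage == 0:
            r1, r2 = i1, i2
        else:
            # re-bin from the raw trace so each stage matches the direct
            # estimator applied to the trace coarsened by p**stage exactly
            r1, r2 = _rebin(i1, f), _rebin(i2, f)
        vals = _normalized_xcorr(r1, r2, raw_lags // f)
        all_lags.append(raw_lags * trace.bin_width)
        all_vals.append(vals)
    lags = np.concatenate(all_lags)
    vals = np.concatenate(all_vals)
    if max_lag is not None:
        keep = lags <= max_lag
        lags, vals = lags[keep], vals[keep]
    return CorrelationCurve(lags=lags, values=vals, config=trace.config, g_zero=g_zero)


def average_curves(curves: Sequence[CorrelationCurve]) -> CorrelationCurve:
    """Pointwise mean of repeated curves, with per-lag sample SD as errors.

    All curves must share an identical lag grid and polarization
    configuration; the sample standard deviation uses ddof=1.
    """
    if len(curves) < 2:
        raise ValueError("need at least two curves to average")
    ref = curves[0]
    for c in curves[1:]:
        if len(c) != len(ref) or not np.array_equal(c.lags, ref.lags):
            raise ValueError("curves must share an identical lag grid")
        if (c.config is None) != (ref.config is None) or (
            c.config is not None and c.config.label != ref.config.label
        ):
            raise ValueError("curves must share the same polarization configuration")
    stack = np.vstack([c.values for c in curves])
    g_zeros = [c.g_zero for c in curves if c.g_zero is not None]
    return CorrelationCurve(
        lags=ref.lags.copy(),
        values=stack.mean(axis=0),
        errors=stack.std(axis=0, ddof=1),
        config=ref.config,
        n_repeats=len(curves),
        g_zero=float(np.mean(g_zeros)) if g_zeros else None,
    )
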