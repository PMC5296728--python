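"""Plug-in mutual-information estimation between input rate and mRNA output.

The input X is the instantaneous rate level at each sample time and the
output Y is the mRNA copy number at the same instant; pairs are pooled over
replicates and sample times after burn-in.  MI is the plug-in estimate

    MI = sum_xy P(x,y) * log2( P(x,y) / (P(x) P(y)) )

in bits (zero-probability cells contribute nothing).  Continuous AM levels
are quantile-binned; inputs with few distinct values (zero-noise square
waves, FM signals) are kept as discrete symbols.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError

__all__ = ["JointHistogram", "bin_input", "make_binner", "estimate_mi", "mi_from_joint"]


def bin_input(values, scheme: str = "auto", n_bins: int = 8):
    """Map input rate values to integer symbols.

    Schemes: ``discrete`` (one symbol per distinct value), ``quantile``
    (near-equal occupancy bins), ``fixed-width``, or ``auto`` (discrete when
    there are at most ``n_bins`` distinct values, quantile otherwise).
    Returns ``(symbols, edges)``; for the discrete scheme ``edges`` holds the
    sorted distinct values.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise InvalidParameterError("no input values to bin")
    if n_bins < 2:
        raise InvalidParameterError("n_bins must be >= 2")
    if scheme not in ("auto", "discrete", "quantile", "fixed-width"):
        raise InvalidParameterError(f"unknown binning scheme {scheme!r}")

    uniq = np.unique(values)
    if scheme == "discrete" or (scheme == "auto" and uniq.size <= n_bins):
        symbols = np.searchsorted(uniq, values)
        return symbols, uniq
    if scheme == "auto":
        scheme = "quantile"

    if scheme == "quantile":
        if uniq.size < n_bins:
            raise InvalidParameterError(
                f"quantile binning needs >= {n_bins} distinct values"
            )
        qs = np.linspace(0, 1, n_bins + 1)
        edges = np.unique(np.quantile(values, qs))
    else:  # fixed-width
        edges = np.linspace(values.min(), values.max(), n_bins + 1)
    # interior edges define the bins; clip so min/max fall in end bins
    symbols = np.clip(np.searchsorted(edges, values, side="right") - 1, 0, None)
    symbols = np.minimum(symbols, edges.size - 2)
    return symbols, edges


def make_binner(values, scheme: str = "auto", n_bins: int = 8):
    """Fit a binning on ``values`` and return ``(binner, edges)``.

    The returned callable maps any array of input levels onto the symbol
    alphabet fitted here, so pairs from several signal realizations share
    one alphabet.
    """
    values = np.asarray(values, dtype=float)
    uniq = np.unique(values)
    discrete = scheme == "discrete" or (scheme == "auto" and uniq.size <= n_bins)
    _, edges = bin_input(values, scheme=scheme, n_bins=n_bins)

    if discrete:

        def binner(v):
            return np.searchsorted(edges, np.asarray(v, dtype=float))

    else:

        def binner(v):
            s = np.searchsorted(edges, np.asarray(v, dtype=float), side="right") - 1
            return np.minimum(np.clip(s, 0, None), edges.size - 2)

    return binner, edges


@dataclass(frozen=True)
class JointHistogram:
    """Joint tally of (input symbol, output count) pairs."""

    counts: np.ndarray  # shape (n_input_symbols, n_output_values)
    input_values: np.ndarray  # representative value or bin index per row
    output_values: np.ndarray  # distinct mRNA counts per column

    @classmethod
    def from_pairs(cls, x_symbols, y_values) -> "JointHistogram":
        x = np.asarray(x_symbols)
        y = np.asarray(y_values)
        if x.size == 0 or x.shape != y.shape:
            raise InvalidParameterError("x and y must be equal-length, non-empty")
        xu, xi = np.unique(x, return_inverse=True)
        yu, yi = np.unique(y, return_inverse=True)
        counts = np.zeros((xu.size, yu.size), dtype=np.int64)
        np.add.at(counts, (xi, yi), 1)
        return cls(counts=counts, input_values=xu, output_values=yu)

    @property
    def n_samples(self) -> int:
        return int(self.counts.sum())

    def to_frame(self):
        import pandas as pd

        xs, ys = np.nonzero(self.counts)
        return pd.DataFrame(
            {
                "input_bin": self.input_values[xs],
                "output_count": self.output_values[ys],
                "count": self.counts[xs, ys],
            }
        )


def mi_from_joint(counts, miller_madow: bool = False) -> float:
    """Mutual information in bits from a joint count (or probability) table."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if counts.ndim != 2 or total <= 0 or np.any(counts < 0):
        raise InvalidParameterError("joint table must be 2-D, non-negative, non-empty")
    p = counts / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    mi = float(np.sum(p[mask] * np.log2(p[mask] / (px @ py)[mask])))
    if miller_madow:
        # Miller-Madow bias correction for plug-in entropies, in bits
        n = total
        kx = int(np.count_nonzero(px))
        ky = int(np.count_nonzero(py))
        kxy = int(np.count_nonzero(p))
        mi += (kx - 1 + ky - 1 - (kxy - 1)) / (2.0 * n * np.log(2.0))
    return max(mi, 0.0)


def estimate_mi(x_symbols, y_values, miller_madow: bool = False) -> float:
    """Plug-in MI (bits) between paired input symbols and output counts."""
    joint = JointHistogram.from_pairs(x_symbols, y_values)
    return mi_from_joint(joint.counts, miller_madow=miller_madow)
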