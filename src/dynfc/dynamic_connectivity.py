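"""Tapered sliding-window correlations among four network time series.

The four components are ordered (SN, LFPN, RFPN, DMN) throughout the
package. Each window is summarized both as a full 4x4 correlation matrix
and as a 6-vector of Fisher-z transformed unique off-diagonal entries in
the fixed pair order SN-LFPN, SN-RFPN, SN-DMN, LFPN-RFPN, LFPN-DMN,
RFPN-DMN.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Component order used for every (T, 4) time-series array.
NETWORKS: tuple[str, ...] = ("SN", "LFPN", "RFPN", "DMN")

#: Index pairs of the 6 unique off-diagonal entries, row-major upper triangle.
PAIRS: tuple[tuple[int, int], ...] = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))

PAIR_NAMES: tuple[str, ...] = tuple(f"{NETWORKS[i]}-{NETWORKS[j]}" for i, j in PAIRS)

#: Correlations are clipped to +/- this value before the Fisher transform so
#: degenerate windows yield large-but-finite z values instead of infinities.
Z_CLIP = 0.999999


class InputTooShortError(ValueError):
    """Time series shorter than the window length."""


class ZeroVarianceError(ValueError):
    """A component has (weighted) variance of zero within a window."""


@dataclass
class NetworkTimeSeries:
    """One subject's (T, 4) component time series.

    Parameters
    ----------
    data
        Array of shape (T, 4) with columns ordered as :data:`NETWORKS`.
    tr
        Repetition time in seconds (sampling interval of the rows).
    group
        Cohort label, e.g. ``"ADHD-Placebo"``.
    subject_id
        Stable identifier used in manifests and output tables.
    """

    data: np.ndarray
    tr: float
    group: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(NETWORKS):
            raise ValueError(
                f"expected (T, {len(NETWORKS)}) array, got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if self.tr <= 0:
            raise ValueError(f"tr must be positive, got {self.tr}")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class WindowSpec:
    """Exponentially tapered sliding-window parameters (in timepoints).

    ``length`` and ``step`` are counts of samples; ``theta`` is the decay
    constant of the taper. The default 20-sample window corresponds to 46 s
    at TR = 2.3 s, with theta = length / 3.
    """

    length: int = 20
    theta: float = 20 / 3
    step: int = 1

    def __post_init__(self) -> None:
        if self.length < 10:
            raise ValueError(f"window length must be >= 10, got {self.length}")
        if self.theta <= 0:
            raise ValueError(f"theta must be positive, got {self.theta}")
        if self.step < 1:
            raise ValueError(f"step must be >= 1, got {self.step}")

    def n_windows(self, n_timepoints: int) -> int:
        """Number of windows for a series of ``n_timepoints`` samples."""
        if n_timepoints < self.length:
            return 0
        return (n_timepoints - self.length) // self.step + 1


@dataclass
class WindowedCorrelations:
    """Per-window correlation structure for one subject.

    ``window_centers`` records, for each window, the index of the *last*
    sample in the window (trailing-edge / causal convention, matching the
    taper's emphasis on the most recent samples).
    """

    window_centers: np.ndarray
    corr: np.ndarray  # (W, 4, 4)
    z6: np.ndarray  # (W, 6) Fisher-z, pair order PAIR_NAMES
    spec: WindowSpec
    tr: float
    subject_id: str = ""
    group: str = ""

    @property
    def n_windows(self) -> int:
        return self.z6.shape[0]


def exponential_weights(spec: WindowSpec | tuple[int, float]) -> np.ndarray:
    """Normalized exponentially decaying taper.

    Weight for sample ``t`` (t = 0 .. L-1, t = L-1 most recent) is
    proportional to ``exp(-(L - 1 - t) / theta)``; weights are strictly
    positive, increasing in ``t``, and sum to one. Accepts a
    :class:`WindowSpec` or a raw ``(length, theta)`` pair (the latter
    bypasses the spec's minimum-length constraint, for direct evaluation
    of the taper formula).
    """
    if isinstance(spec, WindowSpec):
        length, theta = spec.length, spec.theta
    else:
        length, theta = int(spec[0]), float(spec[1])
        if length < 1 or theta <= 0:
            raise ValueError(f"invalid (length, theta) = ({length}, {theta})")
    t = np.arange(length, dtype=float)
    w = np.exp(-(length - 1 - t) / theta)
    return w / w.sum()


def fisher_z(cc):
    """Fisher z-transform ``0.5 * ln((1 + cc) / (1 - cc))``.

    Inputs are clipped to +/-``Z_CLIP`` first, so the result is always
    finite. Accepts scalars or arrays.
    """
    cc = np.clip(np.asarray(cc, dtype=float), -Z_CLIP, Z_CLIP)
    out = np.arctanh(cc)
    if out.ndim == 0:
        return float(out)
    return out


def weighted_pearson(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    """Weighted Pearson correlation of ``x`` and ``y`` under weights ``w``.

    ``w`` must be non-negative and sum to one. With uniform weights this
    reduces exactly to the plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    if not (x.shape == y.shape == w.shape):
        raise ValueError("x, y and w must have identical shapes")
    if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
        raise ValueError("weights must be non-negative and sum to 1")
    mx, my = w @ x, w @ y
    dx = x - mx
    dy = y - my
    vx = w @ (dx * dx)
    vy = w @ (dy * dy)
    # relative tolerance so exactly-constant series caught despite fp round-off
    tol_x = (1e-10 * max(1.0, abs(mx))) ** 2
    tol_y = (1e-10 * max(1.0, abs(my))) ** 2
    if vx <= tol_x or vy <= tol_y:
        raise ZeroVarianceError("zero weighted variance in correlation input")
    r = (w @ (dx * dy)) / np.sqrt(vx * vy)
    return float(np.clip(r, -1.0, 1.0))


def sliding_window_correlations(
    ts: NetworkTimeSeries, spec: WindowSpec | None = None
) -> WindowedCorrelations:
    """Compute tapered sliding-window correlation matrices for one subject.

    Raises
    ------
    InputTooShortError
        If the series has fewer samples than the window length.
    ZeroVarianceError
        If some component is constant within a window (the error names the
        offending window index).
    """
    if spec is None:
        spec = WindowSpec()
    T = ts.n_timepoints
    if T < spec.length:
        raise InputTooShortError(
            f"series of length {T} is shorter than window length {spec.length}"
        )
    w = exponential_weights(spec)
    starts = np.arange(0, T - spec.length + 1, spec.step)
    centers = starts + spec.length - 1

    # (n_positions, 4, L) view, then select the stepped starts
    view = np.lib.stride_tricks.sliding_window_view(ts.data, spec.length, axis=0)
    wins = view[starts]  # (W, 4, L)

    mean = wins @ w  # (W, 4)
    dev = wins - mean[:, :, None]
    cov = np.einsum("wil,wjl,l->wij", dev, dev, w)
    var = np.einsum("wii->wi", cov)
    tol = (1e-10 * np.maximum(1.0, np.abs(mean))) ** 2
    bad = np.nonzero(np.any(var <= tol, axis=1))[0]
    if bad.size:
        raise ZeroVarianceError(
            f"zero weighted variance in window(s) {bad.tolist()} "
            f"(subject {ts.subject_id or '<unnamed>'})"
        )
    sd = np.sqrt(var)
    corr = cov / (sd[:, :, None] * sd[:, None, :])
    corr = np.clip(corr, -1.0, 1.0)
    idx = np.arange(len(NETWORKS))
    corr[:, idx, idx] = 1.0

    rows = [corr[:, i, j] for i, j in PAIRS]
    z6 = fisher_z(np.stack(rows, axis=1))
    return WindowedCorrelations(
        window_centers=centers,
        corr=corr,
        z6=z6,
        spec=spec,
        tr=ts.tr,
        subject_id=ts.subject_id,
        group=ts.group,
    )
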