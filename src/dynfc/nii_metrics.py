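"""Network interaction index (NII) metrics.

NII per window = mean of the Fisher-z SN-LFPN and SN-RFPN couplings minus
the Fisher-z SN-DMN coupling. Subject summaries report the mean and
standard deviation of the time-varying NII (pooled over all windows by
default, or over per-state means), plus a static full-session NII.
Also includes the template-matching goodness-of-fit used to pick
components against a spatial template mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .dynamic_connectivity import (
    NetworkTimeSeries,
    WindowedCorrelations,
    fisher_z,
)

VARIABILITY_MODES = ("pooled", "state_level")


@dataclass
class NIISummary:
    """Mean/SD of a subject's time-varying NII plus per-state means."""

    nii_mean: float
    nii_sd: float  # NaN in state_level mode with a single state
    state_means: dict[int, float]
    mode: str
    n_windows: int


@dataclass
class SubjectMetrics:
    """Row of the per-subject metrics table."""

    subject_id: str
    group: str
    nii_mean: float
    nii_sd: float
    static_nii: float
    mean_dwell_s: float
    state_means: dict[int, float]


@dataclass
class TemplateMatch:
    component_id: int
    goodness_of_fit: float


def nii_window(z6: np.ndarray) -> np.ndarray | float:
    """NII from Fisher-z 6-vector(s): mean(z_SN-LFPN, z_SN-RFPN) - z_SN-DMN.

    Accepts a single 6-vector or an (W, 6) array; returns a scalar or a
    length-W array accordingly.
    """
    z6 = np.asarray(z6, dtype=float)
    if not np.all(np.isfinite(z6)):
        raise ValueError("non-finite Fisher-z input")
    out = 0.5 * (z6[..., 0] + z6[..., 1]) - z6[..., 2]
    return float(out) if out.ndim == 0 else out


def subject_nii_summary(
    nii: np.ndarray,
    labels: np.ndarray | None = None,
    mode: str = "pooled",
) -> NIISummary:
    """Summarize a subject's window NII series.

    ``pooled`` (default): mean and sample SD over all windows. ``state_level``:
    mean and sample SD over the per-state mean NIIs (NaN SD with one state,
    reported with a warning). Per-state means are always included when
    labels are given.
    """
    nii = np.asarray(nii, dtype=float)
    if nii.ndim != 1 or nii.size == 0:
        raise ValueError("nii must be a non-empty 1-D array")
    if mode not in VARIABILITY_MODES:
        raise ValueError(f"mode must be one of {VARIABILITY_MODES}, got {mode!r}")
    state_means: dict[int, float] = {}
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape != nii.shape:
            raise ValueError("labels must align one-to-one with windows")
        state_means = {
            int(s): float(nii[labels == s].mean()) for s in np.unique(labels)
        }

    if mode == "pooled":
        mean = float(nii.mean())
        sd = float(nii.std(ddof=1)) if nii.size > 1 else 0.0
    else:
        if labels is None:
            raise ValueError("state_level mode requires labels")
        vals = np.array(list(state_means.values()))
        mean = float(vals.mean())
        if vals.size < 2:
            warnings.warn(
                "state-level SD undefined with a single state; reporting NaN",
                stacklevel=2,
            )
            sd = float("nan")
        else:
            sd = float(vals.std(ddof=1))
    return NIISummary(
        nii_mean=mean,
        nii_sd=sd,
        state_means=state_means,
        mode=mode,
        n_windows=nii.size,
    )


def static_nii(ts: NetworkTimeSeries) -> float:
    """NII of the full-session (untapered) correlation matrix."""
    if ts.n_timepoints < 3:
        raise ValueError("need at least 3 timepoints")
    sd = ts.data.std(axis=0)
    if np.any(sd == 0):
        from .dynamic_connectivity import NETWORKS, ZeroVarianceError

        bad = [NETWORKS[i] for i in np.nonzero(sd == 0)[0]]
        raise ZeroVarianceError(f"zero-variance component(s): {bad}")
    c = np.corrcoef(ts.data.T)
    z = fisher_z(np.array([c[0, 1], c[0, 2], c[0, 3]]))
    return float(0.5 * (z[0] + z[1]) - z[2])


def subject_metrics(
    ts: NetworkTimeSeries,
    wc: WindowedCorrelations,
    labels: np.ndarray,
    mode: str = "pooled",
) -> SubjectMetrics:
    """Assemble one subject's metrics row from windows and state labels."""
    from .brain_states import dwell_times

    nii = nii_window(wc.z6)
    summary = subject_nii_summary(nii, labels, mode=mode)
    dwell = dwell_times(labels, tr=wc.tr, step=wc.spec.step)
    return SubjectMetrics(
        subject_id=ts.subject_id,
        group=ts.group,
        nii_mean=summary.nii_mean,
        nii_sd=summary.nii_sd,
        static_nii=static_nii(ts),
        mean_dwell_s=dwell.mean_dwell_seconds,
        state_means=summary.state_means,
    )


def template_goodness_of_fit(
    component_map: np.ndarray, template_mask: np.ndarray, component_id: int = 0
) -> TemplateMatch:
    """Mean value inside the template mask minus mean value outside it."""
    values = np.asarray(component_map, dtype=float)
    mask = np.asarray(template_mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError(
            f"map shape {values.shape} != mask shape {mask.shape}"
        )
    n_in = int(mask.sum())
    if n_in == 0 or n_in == mask.size:
        raise ValueError("template mask must contain both inside and outside voxels")
    gof = float(values[mask].mean() - values[~mask].mean())
    return TemplateMatch(component_id=component_id, goodness_of_fit=gof)


def select_component(
    maps: list[np.ndarray], template_mask: np.ndarray
) -> TemplateMatch:
    """Pick the component map with the greatest goodness-of-fit.

    Ties break deterministically toward the lowest component index.
    """
    if not maps:
        raise ValueError("no component maps given")
    matches = [
        template_goodness_of_fit(m, template_mask, component_id=i)
        for i, m in enumerate(maps)
    ]
    return max(matches, key=lambda t: (t.goodness_of_fit, -t.component_id))
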