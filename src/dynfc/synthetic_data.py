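"""Synthetic cohorts with known latent-state structure.

Each subject's four-component time series is generated from a hidden
Markov chain: a latent state sequence with a configurable self-transition
probability (which controls dwell time), and i.i.d. Gaussian emissions per
timepoint drawn from the active state's correlation-scale covariance plus
optional isotropic noise. Behavioral scores are generated as linear
functions of connectivity metrics plus Gaussian noise, so every downstream
stage has an analytically known ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dynamic_connectivity import NETWORKS, NetworkTimeSeries, fisher_z

_EIG_FLOOR = 1e-6

#: T-score range behavioral scales are clipped to.
T_SCORE_RANGE = (30.0, 100.0)


@dataclass(frozen=True)
class StateSpec:
    """One latent state: a correlation-scale covariance and its implied NII."""

    state_id: int
    covariance: np.ndarray  # (4, 4), symmetric PD, unit diagonal
    true_nii: float


def _nii_of_corr(c: np.ndarray) -> float:
    """NII implied by a 4x4 correlation matrix (components in NETWORKS order)."""
    z_lfpn = fisher_z(c[0, 1])
    z_rfpn = fisher_z(c[0, 2])
    z_dmn = fisher_z(c[0, 3])
    return float(0.5 * (z_lfpn + z_rfpn) - z_dmn)


def make_state_covariance(
    target_sn_fpn: float,
    target_sn_dmn: float,
    background: float = 0.0,
    state_id: int = 0,
) -> StateSpec:
    """Build a unit-diagonal state covariance with a known NII.

    SN couples to both FPN components at ``target_sn_fpn`` and to the DMN
    at ``target_sn_dmn``; all remaining pairs take ``background``. If the
    resulting matrix is indefinite it is repaired by flooring eigenvalues
    at 1e-6 and rescaling back to unit diagonal; ``true_nii`` is computed
    from the final (possibly repaired) entries.
    """
    for name, v in (
        ("target_sn_fpn", target_sn_fpn),
        ("target_sn_dmn", target_sn_dmn),
        ("background", background),
    ):
        if not -1.0 < v < 1.0:
            raise ValueError(f"{name} must be in (-1, 1), got {v}")

    c = np.eye(4)
    c[0, 1] = c[1, 0] = target_sn_fpn
    c[0, 2] = c[2, 0] = target_sn_fpn
    c[0, 3] = c[3, 0] = target_sn_dmn
    c[1, 2] = c[2, 1] = background
    c[1, 3] = c[3, 1] = background
    c[2, 3] = c[3, 2] = background

    eigval, eigvec = np.linalg.eigh(c)
    if eigval.min() < _EIG_FLOOR:
        floored = np.maximum(eigval, _EIG_FLOOR)
        c = eigvec @ np.diag(floored) @ eigvec.T
        d = np.sqrt(np.diag(c))
        c = c / np.outer(d, d)
        c = (c + c.T) / 2
        if np.linalg.eigvalsh(c).min() <= 0:
            raise ValueError(
                "state covariance not repairable to positive definite: "
                f"targets ({target_sn_fpn}, {target_sn_dmn}, {background})"
            )
    return StateSpec(state_id=state_id, covariance=c, true_nii=_nii_of_corr(c))


@dataclass(frozen=True)
class CohortSpec:
    """Generation recipe for one group of subjects.

    ``self_transition`` is the latent chain's probability of staying in the
    current state; remaining mass is spread uniformly over the other
    ``n_states - 1`` states, so the expected dwell time in timepoints is
    ``1 / (1 - self_transition)``.
    """

    group_name: str
    n_subjects: int
    states: tuple[StateSpec, ...]
    self_transition: float = 0.9
    n_timepoints: int = 200
    tr: float = 2.3
    emission_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.states:
            raise ValueError("at least one state is required")
        if len(self.states) > 1 and not 0.0 < self.self_transition < 1.0:
            raise ValueError(
                f"self_transition must be in (0, 1), got {self.self_transition}"
            )
        if self.n_timepoints < 50:
            raise ValueError("n_timepoints must be >= 50")
        if self.emission_noise_sd < 0:
            raise ValueError("emission_noise_sd must be >= 0")

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def transition_matrix(self) -> np.ndarray:
        k = self.n_states
        if k == 1:
            return np.ones((1, 1))
        p = np.full((k, k), (1.0 - self.self_transition) / (k - 1))
        np.fill_diagonal(p, self.self_transition)
        return p

    @property
    def expected_dwell_timepoints(self) -> float:
        if self.n_states == 1:
            return float("inf")
        return 1.0 / (1.0 - self.self_transition)


def simulate_subject(
    cohort: CohortSpec, subject_seed, subject_id: str = ""
) -> tuple[NetworkTimeSeries, np.ndarray]:
    """Draw one subject: a (T, 4) series and its latent state sequence.

    Deterministic under a fixed ``subject_seed`` (anything accepted by
    :func:`numpy.random.default_rng`). States are 0-based indices into
    ``cohort.states``.
    """
    rng = np.random.default_rng(subject_seed)
    T, k = cohort.n_timepoints, cohort.n_states

    if k == 1:
        states = np.zeros(T, dtype=int)
    else:
        p = cohort.transition_matrix
        states = np.empty(T, dtype=int)
        states[0] = rng.integers(k)
        u = rng.random(T - 1)
        cum = np.cumsum(p, axis=1)
        for t in range(1, T):
            states[t] = np.searchsorted(cum[states[t - 1]], u[t - 1], side="right")

    # total covariance = state covariance + isotropic emission noise
    chols = [
        np.linalg.cholesky(s.covariance + cohort.emission_noise_sd**2 * np.eye(4))
        for s in cohort.states
    ]
    z = rng.standard_normal((T, 4))
    data = np.empty((T, 4))
    for s in range(k):
        mask = states == s
        if mask.any():
            data[mask] = z[mask] @ chols[s].T

    ts = NetworkTimeSeries(
        data=data, tr=cohort.tr, group=cohort.group_name, subject_id=subject_id
    )
    return ts, states


def simulate_cohort(
    cohort: CohortSpec,
) -> tuple[list[NetworkTimeSeries], list[np.ndarray]]:
    """Draw all subjects of a cohort with hierarchically split seeds."""
    children = np.random.SeedSequence(cohort.seed).spawn(cohort.n_subjects)
    series, labels = [], []
    for i, child in enumerate(children):
        sid = f"{cohort.group_name}_{i + 1:03d}"
        ts, st = simulate_subject(cohort, child, subject_id=sid)
        series.append(ts)
        labels.append(st)
    return series, labels


@dataclass(frozen=True)
class BehaviorSpec:
    """Linear generators for behavioral scores from connectivity metrics.

    Composite CPT change is generated from NII variability; Conners-style
    inattention and hyperactivity T-scores from mean dwell time and NII
    variability. Age, FSIQ and mean framewise displacement are drawn from
    uniform ranges.
    """

    composite_intercept: float = 0.0
    composite_slope_nii_sd: float = 0.0
    composite_noise_sd: float = 1.0

    inattention_intercept: float = 60.0
    inattention_slope_dwell: float = 0.0
    inattention_slope_nii_sd: float = 0.0
    inattention_noise_sd: float = 5.0

    hyperactivity_intercept: float = 60.0
    hyperactivity_slope_dwell: float = 0.0
    hyperactivity_slope_nii_sd: float = 0.0
    hyperactivity_noise_sd: float = 5.0

    age_range: tuple[float, float] = (7.0, 15.0)
    fsiq_range: tuple[float, float] = (80.0, 120.0)
    fd_range: tuple[float, float] = (0.03, 0.12)

    def __post_init__(self) -> None:
        for name in ("composite_noise_sd", "inattention_noise_sd", "hyperactivity_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def simulate_behavior(
    metrics: pd.DataFrame, spec: BehaviorSpec, seed
) -> pd.DataFrame:
    """Generate a behavioral table aligned row-for-row with ``metrics``.

    ``metrics`` must provide ``nii_sd`` and ``mean_dwell_s`` columns.
    Conners-style scores are clipped to the T-score range [30, 100];
    composite change is left unclipped (it is a difference of
    standardized scores, not a normed scale).
    """
    required = {"nii_sd", "mean_dwell_s"}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table missing columns: {sorted(missing)}")
    rng = np.random.default_rng(seed)
    n = len(metrics)
    nii_sd = metrics["nii_sd"].to_numpy(dtype=float)
    dwell = metrics["mean_dwell_s"].to_numpy(dtype=float)

    composite = (
        spec.composite_intercept
        + spec.composite_slope_nii_sd * nii_sd
        + rng.normal(0.0, spec.composite_noise_sd, n)
    )
    inatt = (
        spec.inattention_intercept
        + spec.inattention_slope_dwell * dwell
        + spec.inattention_slope_nii_sd * nii_sd
        + rng.normal(0.0, spec.inattention_noise_sd, n)
    )
    hyper = (
        spec.hyperactivity_intercept
        + spec.hyperactivity_slope_dwell * dwell
        + spec.hyperactivity_slope_nii_sd * nii_sd
        + rng.normal(0.0, spec.hyperactivity_noise_sd, n)
    )
    lo, hi = T_SCORE_RANGE
    out = pd.DataFrame(
        {
            "composite_change": composite,
            "conners_inattention": np.clip(inatt, lo, hi),
            "conners_hyperactivity": np.clip(hyper, lo, hi),
            "age": rng.uniform(*spec.age_range, n),
            "fsiq": rng.uniform(*spec.fsiq_range, n),
            "mean_fd": rng.uniform(*spec.fd_range, n),
        }
    )
    if "subject_id" in metrics.columns:
        out.insert(0, "subject_id", metrics["subject_id"].to_numpy())
    return out


def write_cohort(
    outdir: str | Path,
    series: list[NetworkTimeSeries],
    labels: list[np.ndarray],
    cohort: CohortSpec,
    header_lines: tuple[str, ...] = (),
) -> Path:
    """Write per-subject TSVs, a manifest CSV and a ground-truth JSON.

    Returns the manifest path. Time-series files have one named column per
    component and one row per TR.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts in series:
        path = outdir / f"{ts.subject_id}.tsv"
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            pd.DataFrame(ts.data, columns=list(NETWORKS)).to_csv(
                fh, sep="\t", index=False
            )
        rows.append(
            {
                "subject_id": ts.subject_id,
                "group": ts.group,
                "tr": ts.tr,
                "path": path.name,
            }
        )
    manifest = outdir / f"manifest_{cohort.group_name}.csv"
    with open(manifest, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        pd.DataFrame(rows).to_csv(fh, index=False)

    truth = {
        "group": cohort.group_name,
        "seed": cohort.seed,
        "self_transition": cohort.self_transition,
        "n_states": cohort.n_states,
        "true_nii": {str(s.state_id): s.true_nii for s in cohort.states},
        "state_sequences": {
            ts.subject_id: st.tolist() for ts, st in zip(series, labels)
        },
    }
    with open(outdir / f"truth_{cohort.group_name}.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return manifest
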