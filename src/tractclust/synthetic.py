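"""Synthetic developmental cohorts with planted brain-type structure.

Generates the artifacts the subtyping pipeline consumes: participant x tract
FA profiles with age/gender confounds, behavioural scores shifted by latent
group, streamline-count connectomes with planted group-different edges, and
four-channel ROI time series whose mPFC-PCC coupling depends on marker-tract
FA at a group-specific slope.

The latent structure mirrors what the analysis assumes about real cohorts:
two balanced groups that differ only in the microstructure of a small set of
marker tracts (emulating the left/right cingulum), with everything else
shared.  All randomness flows from one seed through named sub-streams, so
adding one artifact never perturbs another.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_TRACT_NAMES = [
    "cingulum_L", "cingulum_R",
    "arcuate_L", "arcuate_R",
    "atr_L", "atr_R",
    "cst_L", "cst_R",
    "ifof_L", "ifof_R",
    "ilf_L", "ilf_R",
    "slf_L", "slf_R",
    "uncinate_L", "uncinate_R",
    "cingulum_hippocampal_L", "cingulum_hippocampal_R",
    "forceps_major", "forceps_minor",
]

DEFAULT_BEHAVIOUR_MEASURES = (
    "matrix_reasoning", "vocabulary", "digit_recall",
    "dot_matrix", "backward_digit_recall", "mr_x",
)


@dataclass
class BehaviourSpec:
    """Per-measure latent-group shift (in residual SD units) and noise SD."""

    measures: tuple[str, ...] = DEFAULT_BEHAVIOUR_MEASURES
    group_shift: float = 0.8
    noise_sd: float = 1.0


@dataclass
class ConnectomeSpec:
    """Streamline-count matrices with a few planted group-different edges.

    Edge-level baseline means are drawn lognormal so that a realistic share
    of connections fall under the >5-streamline absolute threshold and the
    60% consensus threshold; planted edges sit at ``planted_mean`` so the
    planted signal survives thresholding.  Counts are negative-binomial
    (overdispersed relative to Poisson, as tractography counts are).
    """

    n_rois: int = 45
    mean_log_mu: float = math.log(15.0)
    mean_log_sigma: float = 1.1
    dispersion: float = 8.0           # NB size parameter; smaller = more spread
    planted_edges: tuple[tuple[int, int], ...] = ((0, 1), (2, 3), (4, 5), (6, 7))
    planted_mean: float = 40.0
    group_factor: float = 0.5         # multiplies planted-edge means in group 2


@dataclass
class TimeseriesSpec:
    """Resting-state-like ROI signals with FA-dependent mPFC-PCC coupling."""

    n_volumes: int = 270
    tr: float = 2.0                   # seconds
    slopes: tuple[float, float] = (0.38, 0.0)   # partial-r slope per FA z, by group
    base_coupling: float = 0.3        # partial r at FA z = 0
    coupling_noise_sd: float = 0.1    # between-subject jitter (Fisher-z scale)
    tpj_coupling: float = 0.5
    ar_coef: float = 0.3


@dataclass
class CohortSpec:
    """Parameters of a two-group synthetic cohort."""

    n_participants: int = 80
    n_tracts: int = 20
    marker_tracts: tuple[int, ...] = (0, 1)
    group_effect: float = 1.2         # z-units (multiples of noise_sd) between groups
    age_range: tuple[float, float] = (6.0, 22.0)
    age_beta: float = 0.003           # FA per year
    age2_beta: float = -0.0001        # FA per (centered year)^2
    gender_beta: float = 0.005
    noise_sd: float = 0.04
    tract_names: tuple[str, ...] = tuple(DEFAULT_TRACT_NAMES)
    behaviour: BehaviourSpec = field(default_factory=BehaviourSpec)
    connectome: ConnectomeSpec = field(default_factory=ConnectomeSpec)
    timeseries: TimeseriesSpec = field(default_factory=TimeseriesSpec)
    cohort_id: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if self.n_participants <= 0 or self.n_tracts <= 0:
            raise ValueError("counts must be positive")
        for par in (self.group_effect, self.age_beta, self.age2_beta,
                    self.gender_beta, self.noise_sd):
            if not np.isfinite(par):
                raise ValueError("non-finite parameter in CohortSpec")
        mk = tuple(self.marker_tracts)
        if len(set(mk)) != len(mk) or any(t < 0 or t >= self.n_tracts for t in mk):
            raise ValueError("marker_tracts must be distinct indices < n_tracts")
        if len(self.tract_names) != self.n_tracts:
            names = list(self.tract_names)[: self.n_tracts]
            while len(names) < self.n_tracts:
                names.append(f"tract_{len(names) + 1}")
            self.tract_names = tuple(names)

    # named sub-streams: artifacts are independent given the master seed
    def rng(self, stream: str) -> np.random.Generator:
        streams = {"profiles": 1, "behaviour": 2, "connectomes": 3, "timeseries": 4}
        ss = np.random.SeedSequence(self.seed, spawn_key=(streams[stream],))
        return np.random.default_rng(ss)


def generate_cohort(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Draw one cohort: tract-profile table, behaviour table, truth labels.

    The profile per participant i in latent group g is

        FA_t = baseline_t + b1*age + b2*age_c^2 + b3*gender
               + 1[t in markers] * (+-group_effect*noise_sd/2) + eps,

    eps ~ N(0, noise_sd^2); groups are balanced; truth labels (1/2) are
    returned separately and never written into the tables.
    """
    rng = spec.rng("profiles")
    n = spec.n_participants
    groups = np.ones(n, dtype=int)
    groups[n // 2:] = 2
    groups = rng.permutation(groups)

    lo, hi = spec.age_range
    age = rng.uniform(lo, hi, size=n)
    age_c = age - age.mean()
    gender = rng.integers(0, 2, size=n)

    baseline = rng.uniform(0.35, 0.55, size=spec.n_tracts)
    fa = np.tile(baseline, (n, 1))
    fa += spec.age_beta * age[:, None]
    fa += spec.age2_beta * (age_c ** 2)[:, None]
    fa += spec.gender_beta * gender[:, None]
    shift = spec.group_effect * spec.noise_sd / 2.0
    sign = np.where(groups == 1, 1.0, -1.0)
    for t in spec.marker_tracts:
        fa[:, t] += sign * shift
    fa += rng.normal(0.0, spec.noise_sd, size=fa.shape)

    profiles = pd.DataFrame(fa, columns=list(spec.tract_names))
    profiles.insert(0, "gender", gender)
    profiles.insert(0, "age", age)
    profiles.insert(0, "cohort_id", spec.cohort_id)
    profiles.insert(0, "participant_id", [f"sub-{i:04d}" for i in range(n)])

    brng = spec.rng("behaviour")
    bspec = spec.behaviour
    bsign = np.where(groups == 1, 0.5, -0.5)
    scores = {
        m: bsign * bspec.group_shift * bspec.noise_sd
        + brng.normal(0.0, bspec.noise_sd, size=n)
        for m in bspec.measures
    }
    behaviour = pd.DataFrame(scores)
    behaviour.insert(0, "participant_id", profiles["participant_id"].to_numpy())

    return profiles, behaviour, groups


def generate_connectomes(spec: CohortSpec, group_truth: np.ndarray) -> np.ndarray:
    """Stack of symmetric nonnegative-integer count matrices, one per participant.

    Returns an array of shape (n_participants, n_rois, n_rois) with zero
    diagonals.  Planted edges have their expected count multiplied by
    ``group_factor`` for group 2.
    """
    cs = spec.connectome
    if cs.n_rois < 4:
        raise ValueError("n_rois must be >= 4")
    for i, j in cs.planted_edges:
        if not (0 <= i < cs.n_rois and 0 <= j < cs.n_rois) or i == j:
            raise ValueError(f"planted edge ({i},{j}) out of range")
    rng = spec.rng("connectomes")
    n = len(group_truth)
    r = cs.n_rois
    iu = np.triu_indices(r, k=1)
    n_edges = len(iu[0])

    edge_mu = rng.lognormal(cs.mean_log_mu, cs.mean_log_sigma, size=n_edges)
    planted_idx = []
    edge_lookup = {(a, b): k for k, (a, b) in enumerate(zip(*iu))}
    for i, j in cs.planted_edges:
        a, b = min(i, j), max(i, j)
        k = edge_lookup[(a, b)]
        edge_mu[k] = cs.planted_mean
        planted_idx.append(k)

    mu = np.tile(edge_mu, (n, 1))
    factor = np.where(np.asarray(group_truth) == 2, cs.group_factor, 1.0)
    for k in planted_idx:
        mu[:, k] = edge_mu[k] * factor

    # NB(mean mu, size k): p = k/(k+mu)
    k_disp = cs.dispersion
    p = k_disp / (k_disp + mu)
    counts = rng.negative_binomial(k_disp, p)

    stack = np.zeros((n, r, r), dtype=np.int64)
    stack[:, iu[0], iu[1]] = counts
    stack += stack.transpose(0, 2, 1)
    return stack


def generate_timeseries(
    spec: CohortSpec, fa_marker: np.ndarray, group_truth: np.ndarray
) -> dict[str, np.ndarray | float | list[str]]:
    """Four-channel ROI signals (mPFC, PCC, lTPJ, rTPJ) per participant.

    mPFC and PCC share a latent signal whose loading is set so that their
    partial correlation (given the TPJ channels) tracks

        r_i = clip(base + slope_g * fa_z_i + eta_i, -0.95, 0.95),

    with eta between-subject jitter (so the slope parameter IS the
    partial-correlation slope on standardized FA); the TPJ channels share a
    separate common signal.  All channels carry AR(1) noise with a common
    autocorrelation so band-pass filtering leaves the coupling unbiased.

    Returns dict with 'data' (n, 4, n_volumes), 'tr', 'channels'.
    """
    ts = spec.timeseries
    if ts.n_volumes < 50:
        raise ValueError("n_volumes must be >= 50")
    if ts.tr <= 0:
        raise ValueError("TR must be positive")
    rng = spec.rng("timeseries")
    fa_marker = np.asarray(fa_marker, dtype=float)
    fa_z = (fa_marker - fa_marker.mean()) / fa_marker.std(ddof=0)
    n = len(fa_z)
    slopes = np.where(np.asarray(group_truth) == 1, ts.slopes[0], ts.slopes[1])

    r_lin = ts.base_coupling + slopes * fa_z
    r_lin += rng.normal(0.0, ts.coupling_noise_sd, size=n)
    target_r = np.clip(r_lin, -0.95, 0.95)
    lam = np.sqrt(np.abs(target_r) / (1.0 - np.abs(target_r)))
    lam_signed = np.sign(target_r) * lam  # negative coupling flips one loading

    def ar1(shape):
        eps = rng.normal(size=shape)
        out = np.empty(shape)
        out[..., 0] = eps[..., 0]
        a = ts.ar_coef
        scale = math.sqrt(1.0 - a * a)
        for t in range(1, shape[-1]):
            out[..., t] = a * out[..., t - 1] + scale * eps[..., t]
        return out

    nt = ts.n_volumes
    shared = ar1((n, nt))
    tpj_shared = ar1((n, nt))
    noise = ar1((n, 4, nt))
    data = np.empty((n, 4, nt))
    data[:, 0] = lam[:, None] * shared + noise[:, 0]          # mPFC
    data[:, 1] = lam_signed[:, None] * shared + noise[:, 1]   # PCC
    data[:, 2] = ts.tpj_coupling * tpj_shared + noise[:, 2]   # lTPJ
    data[:, 3] = ts.tpj_coupling * tpj_shared + noise[:, 3]   # rTPJ
    return {"data": data, "tr": ts.tr, "channels": ["mPFC", "PCC", "lTPJ", "rTPJ"]}
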