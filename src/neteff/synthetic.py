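"""Synthetic inputs for the network-efficiency pipeline.

Everything the downstream stages consume can be generated here with known
ground truth: block-modular correlated time series (a stand-in for
gray-matter voxel BOLD), rigid-body motion traces with controllable
spikes, 2-back task session logs, and subject cohorts whose working-memory
d' follows the published per-cohort prediction equations

    d'_young = 3.6708 - 9.4607*E_local + 20.2928*E_global - 0.0034*RT
    d'_older = 9.2047 - 9.4607*E_local -  2.7517*E_global - 0.0034*RT

plus optional Gaussian noise.  All generators are bit-reproducible under a
fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import MOTION_COLUMNS, TimeSeriesMatrix, compute_fd

__all__ = [
    "CohortSpec",
    "ModularSeriesSpec",
    "NBackSessionSpec",
    "COHORT_EQUATIONS",
    "DEFAULT_COVARIATE_RANGES",
    "NBACK_ALPHABET",
    "generate_modular_timeseries",
    "generate_motion_trace",
    "generate_nback_session",
    "generate_subject_cohort",
]

#: Per-cohort d' prediction equations (age group 0 = young, 1 = old):
#: intercept plus slopes on task local efficiency, task global efficiency,
#: and mean correct response time (ms).
COHORT_EQUATIONS: dict[int, dict[str, float]] = {
    0: {"intercept": 3.6708, "e_local_task": -9.4607, "e_global_task": 20.2928, "mean_rt": -0.0034},
    1: {"intercept": 9.2047, "e_local_task": -9.4607, "e_global_task": -2.7517, "mean_rt": -0.0034},
}

#: Plausible covariate ranges: whole-brain efficiencies bracket the
#: observed group means, RT spans slow-but-plausible 2-back responding.
DEFAULT_COVARIATE_RANGES: dict[str, tuple[float, float]] = {
    "e_local_task": (0.35, 0.50),
    "e_global_task": (0.15, 0.35),
    "mean_rt": (400.0, 1500.0),
}

#: 20-consonant alphabet for letter 2-back stimuli (vowels excluded to
#: discourage phonological chunking; the task only needs identity matches).
NBACK_ALPHABET = "BCDFGHJKLMNPQRSTVWXZ"


@dataclass
class ModularSeriesSpec:
    """Parameters of a block-modular correlated time-series simulation.

    Each node's series is a weighted sum of one global latent signal, one
    block latent signal, and i.i.d. noise (a two-level factor model), with
    weights solved so the expected pairwise Pearson correlation is
    ``rho_within`` inside a block and ``rho_between`` across blocks.
    ``baseline``/``amplitude`` set a BOLD-like mean signal level and
    fluctuation scale; they do not affect correlations.
    """

    n_nodes: int
    n_blocks: int
    rho_within: float
    rho_between: float
    n_frames: int
    tr: float = 2.0
    seed: int = 0
    baseline: float = 1000.0
    amplitude: float = 2.0

    def __post_init__(self) -> None:
        if self.n_nodes < 1 or self.n_blocks < 1:
            raise ValueError("n_nodes and n_blocks must be >= 1")
        if self.n_blocks > self.n_nodes:
            raise ValueError("n_blocks cannot exceed n_nodes")
        if not (0.0 <= self.rho_between <= self.rho_within < 1.0):
            raise ValueError(
                "need 0 <= rho_between <= rho_within < 1, got "
                f"({self.rho_between}, {self.rho_within})"
            )
        if self.n_frames < 3:
            raise ValueError("n_frames must be >= 3")
        if self.tr <= 0:
            raise ValueError("tr must be positive")


@dataclass
class NBackSessionSpec:
    """Parameters of a synthetic 2-back session (default: 100 letters)."""

    n_trials: int = 100
    target_rate: float = 0.3
    hit_rate: float = 0.85
    fa_rate: float = 0.05
    rt_mean: float = 700.0
    rt_sd: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials < 3:
            raise ValueError("n_trials must be >= 3")
        for name in ("target_rate", "hit_rate", "fa_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.rt_mean <= 0:
            raise ValueError("rt_mean must be positive")
        if self.rt_sd < 0:
            raise ValueError("rt_sd must be non-negative")


@dataclass
class CohortSpec:
    """Parameters of a synthetic subject cohort.

    With ``noise_sd == 0`` covariates are laid out on a deterministic grid
    (no RNG) so a refit recovers the generating coefficients exactly; with
    ``noise_sd > 0`` covariates are drawn uniformly within
    ``covariate_ranges`` and Gaussian noise of that SD (d' units) is added
    to the equation-predicted d'.
    """

    n_young: int
    n_old: int
    noise_sd: float = 0.0
    covariate_ranges: dict[str, tuple[float, float]] = field(default=None)  # type: ignore[assignment]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_young < 1 or self.n_old < 1:
            raise ValueError("each cohort needs at least one subject")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.covariate_ranges is None:
            self.covariate_ranges = dict(DEFAULT_COVARIATE_RANGES)
        for name, (lo, hi) in self.covariate_ranges.items():
            if not lo < hi:
                raise ValueError(f"covariate {name}: need low < high, got ({lo}, {hi})")


def generate_modular_timeseries(spec: ModularSeriesSpec) -> TimeSeriesMatrix:
    """Simulate block-modular correlated series via a two-level factor model.

    ``x_i = a*g + b*f_block(i) + c*eps_i`` with ``a^2 = rho_between``,
    ``b^2 = rho_within - rho_between`` and ``c^2 = 1 - rho_within``, so
    every series has unit variance and expected correlations equal the
    requested within/between values exactly.
    """
    a2 = spec.rho_between
    b2 = spec.rho_within - spec.rho_between
    c2 = 1.0 - spec.rho_within
    if min(a2, b2, c2) < 0:  # unreachable given spec validation; kept as guard
        raise ValueError("infeasible (rho_between, rho_within) combination")
    a, b, c = math.sqrt(a2), math.sqrt(b2), math.sqrt(c2)

    rng = np.random.default_rng(spec.seed)
    membership = np.repeat(
        np.arange(spec.n_blocks),
        np.diff(np.linspace(0, spec.n_nodes, spec.n_blocks + 1).astype(int)),
    )
    global_sig = rng.standard_normal(spec.n_frames)
    block_sig = rng.standard_normal((spec.n_blocks, spec.n_frames))
    noise = rng.standard_normal((spec.n_nodes, spec.n_frames))
    latent = a * global_sig[None, :] + b * block_sig[membership] + c * noise
    values = spec.baseline + spec.amplitude * latent
    return TimeSeriesMatrix(values, tr=spec.tr, frame_ids=np.arange(spec.n_frames))


def generate_motion_trace(
    n_frames: int,
    spike_frames: tuple[int, ...] | list[int] = (),
    spike_fd: float = 1.0,
    seed: int = 0,
    rotation_radius: float = 50.0,
) -> pd.DataFrame:
    """Rigid-body motion table with baseline FD < 0.1 mm except at spikes.

    Each transition's FD target is drawn in [0.01, 0.08] mm (still-subject
    jitter) and distributed across the 6 parameters with random signs; at
    every index in ``spike_frames`` (frame terminating the transition,
    hence in ``[1, n_frames)``) the transition FD is set to ``spike_fd``.
    """
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if spike_fd < 0:
        raise ValueError("spike_fd must be non-negative")
    spikes = sorted(int(f) for f in spike_frames)
    for f in spikes:
        if not 1 <= f < n_frames:
            raise ValueError(f"spike frame {f} outside [1, {n_frames})")

    rng = np.random.default_rng(seed)
    fd_targets = rng.uniform(0.01, 0.08, size=n_frames - 1)
    for f in spikes:
        fd_targets[f - 1] = spike_fd
    # Split each transition's FD budget across the 6 parameters; rotation
    # shares are divided by the radius so the realized FD is exact.
    weights = rng.uniform(0.1, 1.0, size=(n_frames - 1, 6))
    weights /= weights.sum(axis=1, keepdims=True)
    signs = rng.choice([-1.0, 1.0], size=(n_frames - 1, 6))
    deltas = signs * weights * fd_targets[:, None]
    deltas[:, 3:] /= rotation_radius
    params = np.vstack([np.zeros(6), np.cumsum(deltas, axis=0)])
    table = pd.DataFrame(params, columns=list(MOTION_COLUMNS))
    # FD realized exactly as targeted (guard against arithmetic drift).
    assert np.allclose(compute_fd(table, rotation_radius), fd_targets)
    return table


def generate_nback_session(spec: NBackSessionSpec) -> pd.DataFrame:
    """Simulate one letter 2-back session as a trial-level log.

    The first two trials are never scoreable targets.  From trial 3 on,
    each trial is a 2-back match with probability ``target_rate`` (the
    letter from two back is repeated); otherwise a different letter is
    drawn.  Responses are Bernoulli: "match" with probability
    ``hit_rate`` on targets and ``fa_rate`` on non-targets, otherwise
    "nonmatch".  RTs on responded trials are log-normal with the requested
    mean and SD in ms.

    Returns a DataFrame with columns ``trial`` (1-based), ``letter``,
    ``is_target``, ``response``, ``rt_ms``.
    """
    rng = np.random.default_rng(spec.seed)
    alphabet = np.array(list(NBACK_ALPHABET))
    letters: list[str] = []
    is_target = np.zeros(spec.n_trials, dtype=bool)
    for i in range(spec.n_trials):
        if i < 2:
            letters.append(str(rng.choice(alphabet)))
            continue
        if rng.random() < spec.target_rate:
            is_target[i] = True
            letters.append(letters[i - 2])
        else:
            others = alphabet[alphabet != letters[i - 2]]
            letters.append(str(rng.choice(others)))

    respond_match = np.where(
        is_target,
        rng.random(spec.n_trials) < spec.hit_rate,
        rng.random(spec.n_trials) < spec.fa_rate,
    )
    response = np.where(respond_match, "match", "nonmatch")

    # log-normal parameterized by arithmetic mean/sd
    sigma2 = math.log(1.0 + (spec.rt_sd / spec.rt_mean) ** 2)
    mu = math.log(spec.rt_mean) - sigma2 / 2.0
    rt = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=spec.n_trials)

    return pd.DataFrame(
        {
            "trial": np.arange(1, spec.n_trials + 1),
            "letter": letters,
            "is_target": is_target,
            "response": response,
            "rt_ms": rt,
        }
    )


def _grid_covariates(n: int, ranges: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Deterministic covariate grid with full-rank quadratic/interaction design.

    Uses ``L = max(3, ceil(n**(1/3)))`` levels per covariate, cycled at
    different periods so squared terms and pairwise products are not
    collinear with the mains.
    """
    names = list(ranges)
    n_cov = len(names)
    level_count = max(3, math.ceil(n ** (1.0 / max(n_cov, 1))))
    levels = {
        name: np.linspace(lo, hi, level_count) for name, (lo, hi) in ranges.items()
    }
    cols: dict[str, np.ndarray] = {}
    j = np.arange(n)
    for k, name in enumerate(names):
        cols[name] = levels[name][(j // level_count**k) % level_count]
    return pd.DataFrame(cols)


def generate_subject_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Build a young+old subject table with d' set by the cohort equations.

    Returns one row per subject with columns ``subject_id``, ``age_group``
    (0 = young, 1 = old), the covariates in ``spec.covariate_ranges``,
    ``n_volumes_removed``, and ``dprime``.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for group, n in ((0, spec.n_young), (1, spec.n_old)):
        if spec.noise_sd == 0:
            cov = _grid_covariates(n, spec.covariate_ranges)
            nvol = (np.arange(n) // 2) % 4
            noise = np.zeros(n)
        else:
            cov = pd.DataFrame(
                {
                    name: rng.uniform(lo, hi, size=n)
                    for name, (lo, hi) in spec.covariate_ranges.items()
                }
            )
            nvol = rng.poisson(1.5, size=n)
            noise = rng.normal(0.0, spec.noise_sd, size=n)
        eq = COHORT_EQUATIONS[group]
        dprime = np.full(n, eq["intercept"], dtype=float)
        for name, slope in eq.items():
            if name == "intercept":
                continue
            if name not in cov.columns:
                raise ValueError(f"cohort equations need covariate {name!r}")
            dprime = dprime + slope * cov[name].to_numpy()
        df = cov.copy()
        df.insert(0, "age_group", group)
        df["n_volumes_removed"] = nvol
        df["dprime"] = dprime + noise
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.insert(0, "subject_id", [f"s{idx:03d}" for idx in range(len(out))])
    return out
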