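"""End-to-end orchestration: synthetic cohort -> networks -> model.

Two run modes:

* ``"cohort"`` — subject records (efficiencies, RT, d') come directly
  from the cohort generator, whose d' follows the published per-group
  prediction equations.  This is the mode used to check coefficient
  recovery.
* ``"full"`` — every subject gets simulated raw inputs (modular time
  series, motion trace with spikes, a 2-back session log) which are then
  pushed through the whole chain: band-pass filter -> nuisance
  regression -> FD/DVARS scrubbing -> correlation matrix ->
  density-matched thresholding -> efficiency -> behavioral scoring ->
  stepwise model.  Efficiency and behavior are independently simulated
  here, so this mode exercises plumbing, not the published effect.

Runs are reproducible: one seed fans out to per-subject seeds via
``numpy.random.SeedSequence`` and a manifest records the configuration
and library versions.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import statsmodels
import yaml

from . import behavior, connectivity, efficiency, modeling, preprocess, synthetic

__all__ = ["RunConfig", "ConfigError", "CohortRunResult", "run_subject", "run_cohort"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration."""


def _default_series() -> dict:
    # 159 frames at TR 2 s mirrors a ~5.3 min acquisition; 60 nodes keeps
    # whole-cohort efficiency tractable at desk scale.
    return {
        "n_nodes": 60,
        "n_blocks": 6,
        "rho_within": 0.6,
        "rho_between": 0.1,
        "n_frames": 159,
        "tr": 2.0,
    }


def _default_nback() -> dict:
    return {
        "n_trials": 100,
        "target_rate": 0.3,
        "rt_mean": 700.0,
        "rt_sd": 150.0,
        "hit_rate_range": (0.6, 0.95),
        "fa_rate_range": (0.02, 0.15),
    }


@dataclass
class RunConfig:
    """Configuration of a cohort run; defaults are the published settings.

    Density exponent ``s`` = 2.5, band 0.009-0.08 Hz, scrub thresholds
    FD 0.5 mm / DVARS 0.5%, cohort sizes 14 young / 15 old.
    """

    seed: int = 0
    mode: str = "cohort"
    n_young: int = 14
    n_old: int = 15
    noise_sd: float = 0.0
    s: float = 2.5
    low_hz: float = 0.009
    high_hz: float = 0.08
    fd_thresh: float = 0.5
    dvars_thresh: float = 0.5
    rotation_radius: float = 50.0
    spike_rate: float = 1.0
    spike_fd: float = 1.0
    series: dict = field(default_factory=_default_series)
    nback: dict = field(default_factory=_default_nback)
    include_rest: bool = False
    candidates: tuple = modeling.DEFAULT_CANDIDATE_COVARIATES
    outcome: str = "dprime"
    aicc: bool = False
    hierarchy: bool = False
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("cohort", "full"):
            raise ConfigError(f"mode must be 'cohort' or 'full', got {self.mode!r}")
        if self.s <= 0:
            raise ConfigError("density exponent s must be positive")
        if not 0 <= self.low_hz < self.high_hz:
            raise ConfigError("need 0 <= low_hz < high_hz")
        if self.fd_thresh <= 0 or self.dvars_thresh <= 0:
            raise ConfigError("scrub thresholds must be positive")
        if self.n_young < 0 or self.n_old < 0:
            raise ConfigError("cohort sizes must be non-negative")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        base = _default_series()
        base.update(self.series or {})
        self.series = base
        nb = _default_nback()
        nb.update(self.nback or {})
        for key in ("hit_rate_range", "fa_rate_range"):
            nb[key] = tuple(nb[key])
        self.nback = nb
        self.candidates = tuple(self.candidates)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        try:
            return cls(**d)
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["candidates"] = list(self.candidates)
        d["nback"] = {
            k: list(v) if isinstance(v, tuple) else v for k, v in self.nback.items()
        }
        return d


@dataclass
class CohortRunResult:
    """Outputs of one cohort run."""

    records: pd.DataFrame
    fit: modeling.ModelFit | None
    manifest: dict
    failures: list[dict] = field(default_factory=list)
    rest_fit: modeling.ModelFit | None = None
    efficiency_table: pd.DataFrame | None = None

    @property
    def exit_status(self) -> int:
        return 1 if self.failures else 0


def run_subject(
    ts: preprocess.TimeSeriesMatrix,
    motion: pd.DataFrame,
    trials: pd.DataFrame,
    config: RunConfig,
    age_group: int = 0,
    subject_id: str = "s000",
) -> tuple[dict, efficiency.EfficiencyResult, preprocess.ScrubReport]:
    """Run one subject's raw inputs through the whole per-subject chain."""
    if len(motion) != ts.n_frames:
        raise ValueError(
            f"subject {subject_id}: motion has {len(motion)} frames, "
            f"series has {ts.n_frames}"
        )
    raw_mean = float(np.mean(ts.values))
    filtered = preprocess.bandpass_filter(ts, config.low_hz, config.high_hz)
    global_signal = filtered.values.mean(axis=0)
    nuisance = np.column_stack(
        [global_signal, motion[list(preprocess.MOTION_COLUMNS)].to_numpy(dtype=float)]
    )
    regressed = preprocess.regress_nuisance(filtered, nuisance)
    clean, report = preprocess.scrub(
        regressed,
        motion,
        fd_thresh=config.fd_thresh,
        dvars_thresh=config.dvars_thresh,
        rotation_radius=config.rotation_radius,
        reference_mean=raw_mean,
    )
    logger.info(
        "subject %s: band %.3f-%.3f Hz, FD>%.2f mm / DVARS>%.2f%%, removed %d frames",
        subject_id, config.low_hz, config.high_hz,
        config.fd_thresh, config.dvars_thresh, report.n_removed,
    )
    corr = connectivity.correlation_matrix(clean)
    net = connectivity.threshold_to_density(corr, s=config.s)
    eff = efficiency.efficiency_result(net)
    beh = behavior.score_session(trials)
    record = {
        "subject_id": subject_id,
        "age_group": int(age_group),
        "e_local_task": eff.e_local,
        "e_global_task": eff.e_global,
        "mean_rt": beh["mean_rt"],
        "n_volumes_removed": report.n_removed,
        "dprime": beh["dprime"],
    }
    return record, eff, report


def _simulate_subject_inputs(config: RunConfig, seed: int, rng: np.random.Generator):
    series_spec = synthetic.ModularSeriesSpec(seed=seed, **config.series)
    n_frames = series_spec.n_frames
    ts = synthetic.generate_modular_timeseries(series_spec)
    n_spikes = min(int(rng.poisson(config.spike_rate)), n_frames - 1)
    spikes = sorted(
        int(f) for f in rng.choice(np.arange(1, n_frames), size=n_spikes, replace=False)
    )
    motion = synthetic.generate_motion_trace(
        n_frames,
        spike_frames=spikes,
        spike_fd=config.spike_fd,
        seed=seed,
        rotation_radius=config.rotation_radius,
    )
    nb = dict(config.nback)
    hit_lo, hit_hi = nb.pop("hit_rate_range")
    fa_lo, fa_hi = nb.pop("fa_rate_range")
    nback_spec = synthetic.NBackSessionSpec(
        hit_rate=float(rng.uniform(hit_lo, hit_hi)),
        fa_rate=float(rng.uniform(fa_lo, fa_hi)),
        seed=seed,
        **nb,
    )
    trials = synthetic.generate_nback_session(nback_spec)
    return ts, motion, trials


def _build_manifest(config: RunConfig) -> dict:
    from . import __version__

    return {
        "config": config.to_dict(),
        "versions": {
            "neteff": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }


def _fit_records(records: pd.DataFrame, config: RunConfig, candidates) -> modeling.ModelFit:
    usable = []
    for c in candidates:
        if records[c].std() == 0:
            logger.warning("dropping constant candidate column %r from the model", c)
        else:
            usable.append(c)
    if not usable:
        raise ConfigError("no non-constant candidate covariates to fit")
    # The search starts from the full candidate model, so it must be
    # estimable; for small cohorts shrink the candidate set (quadratics
    # first, then interactions) until n > p + 1.
    n = len(records)
    for interactions, quadratics in ((True, True), (True, False), (False, False)):
        X, _ = modeling.build_design(
            records, usable, interactions=interactions, quadratics=quadratics,
            drop_constant_derived=True,
        )
        if n > X.shape[1] + 1:
            if not (interactions and quadratics):
                logger.warning(
                    "cohort of %d subjects cannot estimate the full candidate "
                    "design; fitting with interactions=%s quadratics=%s",
                    n, interactions, quadratics,
                )
            return modeling.stepwise_select(
                records,
                candidates=usable,
                outcome=config.outcome,
                interactions=interactions,
                quadratics=quadratics,
                aicc=config.aicc,
                hierarchy=config.hierarchy,
                drop_constant_derived=True,
            )
    raise ConfigError(
        f"cohort of {n} subjects is too small for {len(usable)} candidate mains"
    )


def run_cohort(config: RunConfig) -> CohortRunResult:
    """Run a whole cohort and fit the stepwise model; optionally write outputs.

    Writes ``subjects.csv``, ``modelfit.json``, ``manifest.json`` (and in
    full mode ``efficiency.csv``) into ``config.output_dir`` when set.
    Failed subjects are logged and excluded; the run continues and
    ``exit_status`` reflects whether any subject failed.
    """
    if config.n_young < 1 or config.n_old < 1:
        raise ConfigError("cohort needs at least one subject per age group")
    manifest = _build_manifest(config)
    failures: list[dict] = []
    rest_fit = None
    eff_table = None

    if config.mode == "cohort":
        records = synthetic.generate_subject_cohort(
            synthetic.CohortSpec(
                n_young=config.n_young,
                n_old=config.n_old,
                noise_sd=config.noise_sd,
                seed=config.seed,
            )
        )
    else:
        n_total = config.n_young + config.n_old
        children = np.random.SeedSequence(config.seed).spawn(n_total)
        rows = []
        eff_rows = []
        for idx, child in enumerate(children):
            sid = f"s{idx:03d}"
            group = 0 if idx < config.n_young else 1
            seed = int(child.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
            rng = np.random.default_rng(child)
            try:
                ts, motion, trials = _simulate_subject_inputs(config, seed, rng)
                record, eff, _ = run_subject(
                    ts, motion, trials, config, age_group=group, subject_id=sid
                )
                if config.include_rest:
                    rest_spec = synthetic.ModularSeriesSpec(
                        seed=seed + 1, **config.series
                    )
                    rest_ts = synthetic.generate_modular_timeseries(rest_spec)
                    rest_corr = connectivity.correlation_matrix(
                        preprocess.bandpass_filter(rest_ts, config.low_hz, config.high_hz)
                    )
                    rest_eff = efficiency.efficiency_result(
                        connectivity.threshold_to_density(rest_corr, s=config.s)
                    )
                    record["e_local_rest"] = rest_eff.e_local
                    record["e_global_rest"] = rest_eff.e_global
                rows.append(record)
                eff_rows.append(
                    {"subject_id": sid, "e_local": eff.e_local, "e_global": eff.e_global}
                )
            except Exception as exc:  # noqa: BLE001 - partial-failure policy
                logger.error("subject %s failed: %s", sid, exc)
                failures.append({"subject_id": sid, "error": str(exc)})
        if not rows:
            raise ConfigError("every subject failed; nothing to fit")
        records = pd.DataFrame(rows)
        eff_table = pd.DataFrame(eff_rows)

    fit = _fit_records(records, config, config.candidates)
    if config.include_rest and "e_local_rest" in records.columns:
        rest_candidates = [
            c.replace("_task", "_rest") if c.endswith("_task") else c
            for c in config.candidates
        ]
        rest_fit = _fit_records(records, config, rest_candidates)

    result = CohortRunResult(
        records=records,
        fit=fit,
        manifest=manifest,
        failures=failures,
        rest_fit=rest_fit,
        efficiency_table=eff_table,
    )
    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        records.to_csv(out / "subjects.csv", index=False)
        fit.to_json(out / "modelfit.json")
        if rest_fit is not None:
            rest_fit.to_json(out / "modelfit_rest.json")
        if eff_table is not None:
            eff_table.to_csv(out / "efficiency.csv", index=False)
        manifest_path = out / "manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(
                {**manifest, "failures": failures, "exit_status": result.exit_status},
                fh,
                indent=1,
            )
        logger.info("wrote outputs to %s", out)
    return result
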