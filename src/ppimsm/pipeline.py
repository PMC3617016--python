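"""Configuration and end-to-end orchestration of the analysis stages.

Stages: simulate → featurize → cluster → build → validate → mfpt → pmf.
Each stage is a plain function usable from Python; the thin command-line
wrapper in :mod:`ppimsm.cli` maps them onto subcommands.

All physical times in the configuration (lags, dwell) are given in the
trajectory's time unit and must convert to whole frame counts exactly;
otherwise the run aborts naming the offending values — a different save
interval must never silently change the counting semantics.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import msm, pmf as pmfmod, synthetic
from .clustering import EuclideanMetric, assign, kcenter, write_clustering_tsv
from .errors import ConfigError, DataError
from .trajectory import FeatureTrajectory, read_feature_csv, write_feature_csv

__all__ = ["PipelineConfig", "PipelineResult", "PRESETS", "run_all", "stage_simulate"]


PRESETS: dict[str, dict] = {
    # Desk-scale analogue of the production analysis: 100 trajectories of
    # 10,000 frames at 1 ns from the calibrated two-state exchange, 50
    # microstates on the 1-D release coordinate, lag scan to a plateau,
    # final lag 5 ns, 2 macrostates, 100 bootstrap replicates.
    "two_state_release": dict(
        n_trajectories=100,
        n_frames=10_000,
        frame_interval=1.0,
        time_unit="ns",
        coords=["d1"],
        n_microstates=50,
        lag_scan=[1.0, 2.0, 5.0, 10.0, 20.0],
        final_lag=5.0,
        dwell_time=1.0,
        n_macrostates=2,
        n_bootstrap=100,
        weighting="msm",
        pmf_bins=50,
        seed=2013,
    ),
    # Small smoke-test preset for quick runs.
    "tiny": dict(
        n_trajectories=10,
        n_frames=2_000,
        frame_interval=1.0,
        time_unit="ns",
        coords=["d1"],
        n_microstates=20,
        lag_scan=[1.0, 2.0, 5.0],
        final_lag=5.0,
        dwell_time=1.0,
        n_macrostates=2,
        n_bootstrap=20,
        weighting="msm",
        pmf_bins=40,
        seed=7,
    ),
}


@dataclass
class PipelineConfig:
    preset: str = "two_state_release"
    n_trajectories: int = 100
    n_frames: int = 10_000
    frame_interval: float = 1.0
    time_unit: str = "ns"
    coords: list[str] = field(default_factory=lambda: ["d1"])
    n_microstates: int = 50
    lag_scan: list[float] = field(default_factory=lambda: [1.0, 2.0, 5.0, 10.0, 20.0])
    final_lag: float = 5.0
    dwell_time: float = 1.0
    n_macrostates: int | str = 2          # integer or "auto"
    n_bootstrap: int = 100
    weighting: str = "msm"
    pmf_bins: int = 50
    seed: int = 2013
    sliding: bool = True
    analysis_symmetrize: bool = True
    n_timescales: int = 5
    initial_cluster_index: int = 0
    cluster_stride: int = 1

    @classmethod
    def from_preset(cls, name: str, **overrides) -> "PipelineConfig":
        if name not in PRESETS:
            raise ConfigError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
        params = dict(PRESETS[name])
        params.update(overrides)
        return cls(preset=name, **params)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        preset = raw.pop("preset", None)
        if preset is not None:
            params = dict(PRESETS.get(preset) or {})
            if preset not in PRESETS:
                raise ConfigError(f"unknown preset {preset!r}")
            params.update(raw)
            params.update(overrides)
            return cls(preset=preset, **params)
        raw.update(overrides)
        known = {f for f in cls.__dataclass_fields__}
        for key in raw:
            if key not in known:
                raise ConfigError(f"unknown config field {key!r}")
        return cls(**raw)

    # -- derived quantities -------------------------------------------------

    def _frames(self, t: float, what: str) -> int:
        frames = t / self.frame_interval
        if abs(frames - round(frames)) > 1e-9 or round(frames) < 1:
            raise ConfigError(
                f"{what} {t} {self.time_unit} does not convert to a whole "
                f"positive frame count at frame_interval {self.frame_interval} "
                f"{self.time_unit}"
            )
        return int(round(frames))

    @property
    def final_lag_frames(self) -> int:
        return self._frames(self.final_lag, "final_lag")

    @property
    def dwell_frames(self) -> int:
        return self._frames(self.dwell_time, "dwell_time")

    @property
    def lag_scan_frames(self) -> list[int]:
        return [self._frames(t, "lag_scan entry") for t in self.lag_scan]

    def validate(self) -> None:
        if self.n_trajectories < 1 or self.n_frames < 2:
            raise ConfigError("need n_trajectories >= 1 and n_frames >= 2")
        if self.weighting not in ("uniform", "msm"):
            raise ConfigError(f"weighting must be uniform|msm, got {self.weighting!r}")
        if isinstance(self.n_macrostates, str) and self.n_macrostates != "auto":
            raise ConfigError("n_macrostates must be an integer or 'auto'")
        if self.n_microstates < 2:
            raise ConfigError("n_microstates must be >= 2")
        # force conversion errors early
        _ = self.final_lag_frames, self.dwell_frames, self.lag_scan_frames

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    truth: synthetic.SyntheticTruth | None
    clustering: object
    dtrajs: list[np.ndarray]
    timescales: msm.ImpliedTimescaleTable
    counts: msm.CountMatrix
    micro_model: msm.TransitionModel
    macro_model: msm.MacrostateModel
    boot: msm.BootstrapResult
    residence: msm.ResidenceValidation
    pmf: pmfmod.PMFGrid
    bound_macrostate: int
    released_macrostate: int


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> synthetic.JumpSimulation:
    """Generate the calibrated two-state data set for the configured sizes."""
    model = synthetic.ppi_release_preset()
    return synthetic.simulate_jump(
        model,
        n_frames=cfg.n_frames,
        frame_interval=cfg.frame_interval,
        n_trajectories=cfg.n_trajectories,
        seed=cfg.seed,
    )


def load_features(paths, time_unit="ns") -> list[FeatureTrajectory]:
    trajs = [read_feature_csv(p, time_unit) for p in paths]
    if not trajs:
        raise DataError("no input feature trajectories")
    dts = {t.frame_interval for t in trajs}
    if len(dts) > 1:
        raise DataError(f"inconsistent frame intervals across inputs: {sorted(dts)}")
    return trajs


def stage_cluster(cfg: PipelineConfig, features: list[FeatureTrajectory]):
    """K-center microstates on the configured coordinates; returns
    (clustering, discrete trajectories)."""
    X = np.vstack(
        [np.column_stack([t.column(c) for c in cfg.coords]) for t in features]
    )
    metric = EuclideanMetric()
    stride = max(1, cfg.cluster_stride)
    clustering = kcenter(
        X[::stride], cfg.n_microstates, metric, cfg.initial_cluster_index
    )
    labels = assign(X, clustering, metric)
    dtrajs, pos = [], 0
    for t in features:
        dtrajs.append(labels[pos : pos + t.n_frames])
        pos += t.n_frames
    return clustering, dtrajs


def _analysis_model(cfg, dtrajs, lag_frames):
    """Microstate model pair: raw-count model for π/MFPT, and (optionally)
    the symmetrized-count model used only for PCCA+ eigenvectors."""
    cm = msm.count_transitions(
        dtrajs, cfg.n_microstates, lag_frames, cfg.dwell_frames, cfg.sliding
    )
    erg = msm.largest_ergodic_subset(cm)
    model = msm.transition_matrix(erg, cfg.frame_interval, cfg.time_unit)
    if cfg.analysis_symmetrize:
        sym = msm.CountMatrix(
            0.5 * (erg.counts + erg.counts.T),
            erg.lag_frames, erg.dwell_frames, erg.sliding, erg.state_labels,
        )
        ana = msm.transition_matrix(sym, cfg.frame_interval, cfg.time_unit)
    else:
        ana = model
    return erg, model, ana


def stage_build(cfg: PipelineConfig, dtrajs):
    """Lag scan, final model, PCCA+ lumping."""
    table = msm.implied_timescales(
        dtrajs, cfg.n_microstates, cfg.lag_scan_frames, cfg.n_timescales,
        cfg.dwell_frames, cfg.sliding, cfg.frame_interval, cfg.time_unit,
    )
    lag = cfg.final_lag_frames
    if cfg.n_macrostates == "auto":
        m, _, _ = msm.choose_macrostate_count(table, lag)
    else:
        m = int(cfg.n_macrostates)
    erg, model, ana = _analysis_model(cfg, dtrajs, lag)
    chi = msm.pcca_plus(ana, m)
    macro = msm.lump(erg, model, chi, cfg.final_lag, cfg.time_unit)
    return table, erg, model, macro


def run_all(cfg: PipelineConfig, features=None, state_paths=None) -> PipelineResult:
    """Run every stage in memory and return the bundled results.

    With ``features=None`` the calibrated synthetic generator supplies the
    data (and its exact ground truth rides along in the result).
    """
    cfg.validate()
    truth = None
    if features is None:
        sim = stage_simulate(cfg)
        features, truth = sim.features, sim.truth
    clustering, dtrajs = stage_cluster(cfg, features)
    table, erg, micro_model, macro = stage_build(cfg, dtrajs)

    macro.mfpt = msm.mfpt(macro.macro_T, cfg.final_lag)
    crisp_full = np.full(cfg.n_microstates, -1)
    crisp_full[erg.state_labels] = macro.crisp
    boot = msm.bootstrap(
        dtrajs, cfg.n_microstates, crisp_full, cfg.final_lag_frames,
        cfg.dwell_frames, cfg.sliding, cfg.frame_interval, cfg.time_unit,
        n_replicates=cfg.n_bootstrap, seed=cfg.seed + 1_000_000,
    )
    macro.populations_sd = boot.populations_sd
    macro.mfpt_sd = boot.mfpt_sd

    residence = msm.validate_residence(
        macro.macro_T, macro.crisp, erg.state_labels, dtrajs,
        cfg.final_lag_frames, multiples=range(0, 11),
    )

    labels_concat = np.concatenate(dtrajs)
    grid = pmfmod.pmf_project(
        features, cfg.coords[:1], bins=cfg.pmf_bins, weighting=cfg.weighting,
        micro_labels=labels_concat, pi=micro_model.pi,
        pi_state_labels=micro_model.state_labels,
    )

    # identify the bound (low-coordinate) macrostate from the microstate
    # centers: the macrostate containing the lowest-coordinate center
    centers = np.array([np.atleast_1d(c)[0] for c in clustering.center_data])
    order = np.argsort(centers)
    bound = released = -1
    for micro in order:
        if crisp_full[micro] >= 0:
            bound = int(crisp_full[micro])
            break
    for micro in order[::-1]:
        if crisp_full[micro] >= 0:
            released = int(crisp_full[micro])
            break
    return PipelineResult(
        config=cfg, truth=truth, clustering=clustering, dtrajs=dtrajs,
        timescales=table, counts=erg, micro_model=micro_model, macro_model=macro,
        boot=boot, residence=residence, pmf=grid,
        bound_macrostate=bound, released_macrostate=released,
    )


# ---------------------------------------------------------------------------
# Artifact writing (all plain text, every numeric file names units and lag)
# ---------------------------------------------------------------------------

def write_artifacts(result: PipelineResult, outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    written: list[Path] = []

    def _open(name):
        p = outdir / name
        written.append(p)
        return open(p, "w")

    unit = cfg.time_unit
    lag_hdr = (
        f"lag_time={cfg.final_lag} {unit} lag_frames={cfg.final_lag_frames} "
        f"dwell_frames={cfg.dwell_frames} sliding={cfg.sliding}"
    )

    with _open("populations.tsv") as fh:
        fh.write(f"# macrostate equilibrium populations (fraction); {lag_hdr}\n")
        fh.write("macrostate\tpopulation\tbootstrap_sd\n")
        sd = result.macro_model.populations_sd
        for a, p in enumerate(result.macro_model.populations):
            fh.write(f"{a}\t{p!r}\t{(sd[a] if sd is not None else float('nan'))!r}\n")

    with _open("mfpt.tsv") as fh:
        fh.write(f"# mean first passage times in {unit}; {lag_hdr}\n")
        fh.write("from\tto\tmfpt\tbootstrap_sd\n")
        M, S = result.macro_model.mfpt, result.macro_model.mfpt_sd
        for i in range(result.macro_model.m):
            for j in range(result.macro_model.m):
                if i != j:
                    s = S[i, j] if S is not None else float("nan")
                    fh.write(f"{i}\t{j}\t{M[i, j]!r}\t{s!r}\n")

    labels = "\t".join(str(s) for s in result.counts.state_labels)
    with _open("count_matrix.tsv") as fh:
        fh.write(f"# transition counts (ergodic subset); {lag_hdr}\n")
        fh.write(f"# state_labels\t{labels}\n")
        for row in result.counts.counts:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")

    with _open("transition_matrix.tsv") as fh:
        fh.write(f"# row-stochastic transition matrix; {lag_hdr}\n")
        fh.write(f"# state_labels\t{labels}\n")
        for row in result.micro_model.T:
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")

    with _open("implied_timescales.tsv") as fh:
        fh.write(f"# implied timescales in {unit}; dwell_frames={cfg.dwell_frames}\n")
        fh.write("lag_" + unit + "\t" + "\t".join(
            f"tau_{k + 2}" for k in range(result.timescales.n_requested)) + "\n")
        for row, lag_t in enumerate(result.timescales.lags_time):
            vals = "\t".join(
                "undefined" if result.timescales.undefined[row, k]
                else repr(float(result.timescales.timescales[row, k]))
                for k in range(result.timescales.n_requested)
            )
            fh.write(f"{lag_t!r}\t{vals}\n")

    with _open("residence.csv") as fh:
        fh.write(f"# residence probability check; {lag_hdr}\n")
        fh.write("macrostate,n,predicted,observed\n")
        R = result.residence
        for A in range(R.predicted.shape[0]):
            for col, n in enumerate(R.multiples):
                obs = "" if R.undefined[A, col] else repr(float(R.observed[A, col]))
                fh.write(f"{A},{n},{R.predicted[A, col]!r},{obs}\n")

    ppath = outdir / "pmf.csv"
    pmfmod.write_pmf_csv(result.pmf, ppath, time_header=lag_hdr)
    written.append(ppath)

    with _open("run_log.json") as fh:
        json.dump(
            {
                "config_hash": cfg.config_hash(),
                "seed": cfg.seed,
                "config": asdict(cfg),
                "versions": _versions(),
                "bound_macrostate": result.bound_macrostate,
                "released_macrostate": result.released_macrostate,
                "bootstrap_excluded": result.boot.n_excluded,
            },
            fh, indent=1, sort_keys=True,
        )
    return written


def write_simulation(sim: synthetic.JumpSimulation, outdir) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for i, traj in enumerate(sim.features):
        p = outdir / f"traj_{i:04d}.csv"
        write_feature_csv(traj, p)
        written.append(p)
    tp = outdir / "truth.txt"
    synthetic.write_truth(sim.truth, tp)
    written.append(tp)
    return written


def _versions() -> dict:
    import importlib.metadata as im

    out = {}
    for pkg in ("ppimsm", "numpy", "scipy"):
        try:
            out[pkg] = im.version(pkg)
        except im.PackageNotFoundError:
            out[pkg] = "unknown"
    return out
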