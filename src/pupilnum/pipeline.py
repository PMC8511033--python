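"""End-to-end orchestration: stimuli -> simulated sessions -> preprocessing
-> pupil GLM -> psychophysics -> statistical report.

``run_full`` executes every stage into one run directory with a manifest
(file checksums), a structured log, and a full config echo, so each
intermediate file is readable by its consuming stage in isolation.  All
randomness derives from the master seed via numpy's seed-sequence spawning.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .preprocess import PreprocessConfig, preprocess_session
from .prf_glm import (
    PRFParams,
    average_epochs,
    build_design,
    difference_trace,
    fit_condition_betas,
    fit_prf,
    window_mean,
)
from .psychometrics import bias_index, fit_cumulative_gaussian
from .stimgen import GeometryConfig, convex_hull_area, generate_condition_set, ink_area
from .synth import ObserverSpec, SimConfig, make_session_design, simulate_2afc, simulate_session
from .stats_report import bcea, condition_matrix_from_frame, paired_t, rm_anova_2x2

logger = logging.getLogger(__name__)

PROBE_GRIDS = {"exp1": (8, 10, 12, 14, 16, 20, 22, 24), "exp2": tuple(range(5, 13))}
REFERENCE_N = 18


@dataclass(frozen=True)
class RunConfig:
    experiment: int = 1
    n_participants: int = 16
    sessions_per_condition: int = 1  # pupillometry sessions per (numerosity, polarity)
    trials_per_session: int = 60
    psych_sessions: int = 3
    psych_trials_per_session: int = 40
    observer_bias_connected: float = -30.0  # percent, generating illusion strength
    observer_sigma: float = 2.0  # dots
    seed: int = 0
    out_dir: str = "results/run"
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    preprocess: dict = field(default_factory=dict)  # PreprocessConfig overrides
    write_images: bool = False

    def __post_init__(self):
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.trials_per_session < 2 or self.psych_trials_per_session < 1:
            raise ValueError("trial counts too small")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _participant_sim_config(base: SimConfig, rng: np.random.Generator) -> SimConfig:
    """Per-participant ground truth: PRF and gains jittered around defaults."""
    prf = PRFParams(
        n=int(rng.integers(3, 6)),
        tau_ms=float(rng.uniform(180, 320)),
        delta_ms=float(rng.uniform(50, 150)),
    )
    gains = {k: v * float(rng.normal(1.0, 0.05)) for k, v in base.sustained_gains.items()}
    return replace(base, prf=prf, sustained_gains=gains)


def stage_stimuli(cfg: RunConfig, out: Path, rng: np.random.Generator) -> None:
    geom = GeometryConfig.for_experiment(cfg.experiment)
    stim_dir = out / "stimuli"
    stim_dir.mkdir(parents=True, exist_ok=True)
    seed = int(rng.integers(2**31))
    stimset = generate_condition_set(geom, rng_seed=seed)
    rows = []
    for (n, conn), stim in stimset.items():
        name = f"n{n}_{conn}"
        pio.write_stimulus(
            stim, stim_dir / f"{name}.json",
            extra={"seed": seed, "ink_deg2": ink_area(stim), "hull_deg2": convex_hull_area(stim)},
        )
        if cfg.write_images:
            from .stimgen import radial_fourier_amplitude, rasterize

            pio.write_stimulus_png(stim, geom, stim_dir / f"{name}.png")
            img, _ = rasterize(stim, geom)
            pio.write_spectrum(radial_fourier_amplitude(img, geom), stim_dir / f"{name}_spectrum.csv")
        rows.append({"numerosity": n, "connectedness": conn,
                     "ink_deg2": ink_area(stim), "hull_deg2": convex_hull_area(stim)})
    pd.DataFrame(rows).to_csv(stim_dir / "geometry_summary.csv", index=False)
    logger.info("stimuli: %d cells matched (seed %d)", len(stimset), seed)


def stage_simulate(cfg: RunConfig, out: Path, rng: np.random.Generator) -> None:
    raw = out / "raw"
    raw.mkdir(parents=True, exist_ok=True)
    base = SimConfig(**cfg.sim)
    truth_rows = []
    for p in range(cfg.n_participants):
        pcfg = _participant_sim_config(base, rng)
        truth_rows.append({"participant": p, "prf_n": pcfg.prf.n,
                           "prf_tau_ms": pcfg.prf.tau_ms, "prf_delta_ms": pcfg.prf.delta_ms})
        for numerosity in (18, 24):
            for polarity in ("white", "black"):
                for s in range(cfg.sessions_per_condition):
                    design = make_session_design(
                        n_trials=cfg.trials_per_session, numerosity=numerosity,
                        polarity=polarity, rng=rng,
                    )
                    trace, events = simulate_session(design, pcfg, rng, with_artifacts=True)
                    stem = f"p{p:02d}_n{numerosity}_{polarity}_s{s}"
                    pio.write_trace(trace, raw / f"{stem}_trace.csv")
                    pio.write_events(events, raw / f"{stem}_events.csv")
    pd.DataFrame(truth_rows).to_csv(raw / "ground_truth_prf.csv", index=False)
    logger.info("simulate: %d participants written", cfg.n_participants)


def stage_preprocess(cfg: RunConfig, out: Path) -> None:
    raw = out / "raw"
    epo = out / "epochs"
    epo.mkdir(parents=True, exist_ok=True)
    pcfg = PreprocessConfig(**cfg.preprocess)
    for trace_file in sorted(raw.glob("*_trace.csv")):
        stem = trace_file.name.replace("_trace.csv", "")
        trace = pio.read_trace(trace_file)
        events = pio.read_events(raw / f"{stem}_events.csv")
        epochs = preprocess_session(trace, events, pcfg)
        pio.write_epochs(epochs, epo / f"{stem}_epochs.csv")
    logger.info("preprocess: epochs written to %s", epo)


def _participant_epochs(out: Path, p: int) -> dict[tuple[int, str, str], list]:
    """Epochs per (numerosity, connectedness, polarity) cell for participant p."""
    cells: dict[tuple[int, str, str], list] = {}
    for f in sorted((out / "epochs").glob(f"p{p:02d}_*_epochs.csv")):
        for e in pio.read_epochs(f):
            key = (int(e.condition["numerosity"]), e.condition["connectedness"],
                   e.condition["polarity"])
            cells.setdefault(key, []).append(e)
    return cells


def stage_glm(cfg: RunConfig, out: Path) -> None:
    glm_dir = out / "glm"
    glm_dir.mkdir(parents=True, exist_ok=True)
    prf_rows, beta_rows, pol_rows, win_rows = [], [], [], []
    for p in range(cfg.n_participants):
        cells = _participant_epochs(out, p)
        if not cells:
            continue
        # net luminance response: dark minus light, per (numerosity, connectedness)
        diffs = {}
        polarity_avgs = {}
        for n in (18, 24):
            for conn in ("connected", "isolated"):
                dark = average_epochs(cells[(n, conn, "black")])
                light = average_epochs(cells[(n, conn, "white")])
                polarity_avgs[(n, conn, "black")] = dark
                polarity_avgs[(n, conn, "white")] = light
                diffs[(n, conn)] = difference_trace(dark, light)
        # grand-average difference trace -> participant PRF
        grand = diffs[(18, "connected")]
        pooled = np.nanmean(np.stack([d.pupil for d in diffs.values()]), axis=0)
        valid = np.logical_and.reduce([d.valid for d in diffs.values()])
        grand = replace(grand, pupil=pooled, valid=valid)
        prf, prf_fit = fit_prf(grand, seed=cfg.seed + p)
        prf_rows.append({"participant": p, "n": prf.n, "tau_ms": prf.tau_ms,
                         "delta_ms": prf.delta_ms, "r_squared": prf_fit.r_squared})
        t = grand.rel_time
        dt = float(np.median(np.diff(t)))
        _, X = build_design((0.0, 6.0), dt, prf, t_start=float(t[0]), t_end=float(t[-1]))
        for (n, conn), d in diffs.items():
            fit = fit_condition_betas(d, X)
            beta_rows.append({"participant": p, "numerosity": n, "connectedness": conn,
                              "beta_onset": fit.beta_onset, "beta_offset": fit.beta_offset,
                              "beta_sustained": fit.beta_sustained, "r_squared": fit.r_squared})
            win_rows.append({"participant": p, "numerosity": n, "connectedness": conn,
                             "window_mean_mm": window_mean(d)})
        for (n, conn, pol), avg in polarity_avgs.items():
            fit = fit_condition_betas(avg, X)
            pol_rows.append({"participant": p, "numerosity": n, "connectedness": conn,
                             "polarity": pol, "beta_onset": fit.beta_onset,
                             "beta_offset": fit.beta_offset,
                             "beta_sustained": fit.beta_sustained,
                             "r_squared": fit.r_squared})
    pd.DataFrame(prf_rows).to_csv(glm_dir / "prf_params.csv", index=False)
    pd.DataFrame(beta_rows).to_csv(glm_dir / "condition_betas.csv", index=False)
    pd.DataFrame(pol_rows).to_csv(glm_dir / "condition_betas_by_polarity.csv", index=False)
    pd.DataFrame(win_rows).to_csv(glm_dir / "window_means.csv", index=False)
    logger.info("glm: fitted %d participants", len(prf_rows))


def stage_psychophysics(cfg: RunConfig, out: Path, rng: np.random.Generator) -> None:
    psy = out / "psych"
    psy.mkdir(parents=True, exist_ok=True)
    exp = f"exp{cfg.experiment}"
    probes = PROBE_GRIDS[exp]
    trials_per_level = cfg.psych_sessions * cfg.psych_trials_per_session // len(probes)
    rows = []
    for p in range(cfg.n_participants):
        for conn, bias in (("connected", cfg.observer_bias_connected), ("isolated", 0.0)):
            true_pse = REFERENCE_N * (1 + bias / 100.0) * float(rng.normal(1.0, 0.03))
            obs = ObserverSpec(pse=true_pse, sigma=cfg.observer_sigma)
            table = simulate_2afc(obs, probes, trials_per_level, rng)
            table["participant"] = p
            table["connectedness"] = conn
            pio.write_responses(table, psy / f"p{p:02d}_{conn}_responses.csv")
            fit = fit_cumulative_gaussian(table)
            rows.append({"participant": p, "connectedness": conn, "true_pse": true_pse,
                         "pse": fit.pse, "sigma": fit.sigma,
                         "bias_percent": bias_index(fit.pse, REFERENCE_N)})
    pd.DataFrame(rows).to_csv(psy / "psychometric_fits.csv", index=False)
    logger.info("psychophysics: %d fits", len(rows))


def stage_report(cfg: RunConfig, out: Path) -> None:
    rep = out / "report"
    rep.mkdir(parents=True, exist_ok=True)
    win = pd.read_csv(out / "glm" / "window_means.csv")
    betas = pd.read_csv(out / "glm" / "condition_betas.csv")

    lines = ["# Pupillometry run report", ""]
    for name, df, col in (("window means (mm)", win, "window_mean_mm"),
                          ("sustained betas (mm)", betas, "beta_sustained")):
        cell_means = df.groupby(["numerosity", "connectedness"])[col].agg(["mean", "sem"])
        cell_means.to_csv(rep / f"{col}_cells.csv")
        lines += [f"## Condition means, {name}", cell_means.to_string(), ""]
        if df["participant"].nunique() >= 2:
            M = condition_matrix_from_frame(df, col)
            anova = rm_anova_2x2(M)
            pd.DataFrame([vars(e) for e in anova.values()]).to_csv(
                rep / f"{col}_anova.csv", index=False)
            lines += [f"## rm-ANOVA (numerosity x connectedness), {name}"]
            for key, eff in anova.items():
                lines.append(
                    f"- {key}: F({eff.df[0]},{eff.df[1]}) = {eff.F:.2f}, "
                    f"p = {eff.p:.4f}, partial eta^2 = {eff.partial_eta_sq:.2f}"
                )
            hi = df.query("numerosity == 24 and connectedness == 'isolated'").sort_values(
                "participant")[col].to_numpy()
            lo = df.query("numerosity == 18 and connectedness == 'connected'").sort_values(
                "participant")[col].to_numpy()
            t = paired_t(hi, lo)
            lines.append(
                f"- 24 isolated vs 18 connected: t({t['df']}) = {t['t']:.2f}, "
                f"p = {t['p']:.4f}, Cohen's d = {t['cohens_d']:.2f}"
            )
            lines.append("")

    # fixation-stability control: BCEA per participant x condition
    bcea_rows = []
    for p in range(cfg.n_participants):
        for f in sorted((out / "raw").glob(f"p{p:02d}_*_trace.csv")):
            stem = f.name.replace("_trace.csv", "")
            trace = pio.read_trace(f)
            events = pio.read_events(out / "raw" / f"{stem}_events.csv")
            for conn in ("connected", "isolated"):
                sel = np.zeros(len(trace.time), dtype=bool)
                for _, ev in events[events["connectedness"] == conn].iterrows():
                    sel |= (trace.time >= ev["onset_s"]) & (trace.time < ev["offset_s"])
                if sel.sum() >= 3:
                    bcea_rows.append({
                        "participant": p, "session": stem, "connectedness": conn,
                        "numerosity": int(events["numerosity"].iloc[0]),
                        "bcea_deg2": bcea(trace.gaze_x[sel], trace.gaze_y[sel]),
                    })
    bdf = pd.DataFrame(bcea_rows)
    bdf.to_csv(rep / "bcea.csv", index=False)
    if len(bdf):
        lines += ["## Fixation stability (BCEA, deg^2)",
                  bdf.groupby("connectedness")["bcea_deg2"].agg(["mean", "sem"]).to_string(), ""]

    psych_file = out / "psych" / "psychometric_fits.csv"
    if psych_file.exists():
        pf = pd.read_csv(psych_file)
        lines += ["## Psychophysics (bias index, %)",
                  pf.groupby("connectedness")["bias_percent"].agg(["mean", "sem"]).to_string(), ""]

    lines.append("Note: Bayes-factor analyses are not part of this report.")
    (rep / "report.md").write_text("\n".join(lines))
    logger.info("report written to %s", rep / "report.md")


def run_full(config: RunConfig) -> Path:
    """Run every stage into ``config.out_dir``; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("pupilnum")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    t_start = time.time()
    try:
        logger.info("config: %s", json.dumps(config.to_dict(), sort_keys=True))
        pio.dump_config_file(config.to_dict(), out / "config.yaml")
        master = np.random.SeedSequence(config.seed)
        seeds = master.spawn(3)
        stage_stimuli(config, out, np.random.default_rng(seeds[0]))
        stage_simulate(config, out, np.random.default_rng(seeds[1]))
        stage_preprocess(config, out)
        stage_glm(config, out)
        stage_psychophysics(config, out, np.random.default_rng(seeds[2]))
        stage_report(config, out)
    except Exception as exc:  # annotate the failing stage for the caller
        logger.error("run aborted: %s", exc)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()

    manifest = {
        str(f.relative_to(out)): _sha256(f)
        for f in sorted(out.rglob("*"))
        if f.is_file() and f.name not in ("manifest.json", "run.log")
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    logging.getLogger(__name__).info("run complete in %.1f s", time.time() - t_start)
    return out
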