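"""Study orchestration: simulate -> preprocess -> select -> erp -> stats.

``run_study`` drives the whole chain for a configured number of simulated
participants, reproducibly from a master seed (per-participant and
per-stage seeds are spawned deterministically).  ``recovery_experiment``
repeats scaled-down studies over a grid of true effect sizes and reports
detection rates and latency-recovery bias/RMSE.  The click CLI exposes the
stages as subcommands over a working directory of artifact files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from pathlib import Path

import click
import numpy as np
import pandas as pd
import yaml

from . import __version__, design, erp, preprocess, select, simulate, stats
from .brainvision import read_raw_binary, write_brainvision, write_raw_binary

logger = logging.getLogger("mmnkit")

REQUIRED_SECTIONS = ("design", "sim", "preprocess", "analysis", "stats")


class ConfigError(ValueError):
    pass


class StageError(RuntimeError):
    """A pipeline stage failed; carries stage name and participant id."""

    def __init__(self, stage: str, participant: str, original: Exception):
        super().__init__(f"stage {stage!r} failed for participant {participant!r}: {original}")
        self.stage = stage
        self.participant = participant
        self.original = original


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

def paper_profile() -> dict:
    """The full-size study configuration (design counts of the original
    paradigm; 57+2+4 channel montage; 24 participants)."""
    return {
        "design": {
            "counts": {"SD": 1332, "FD": 144, "TD": 144},
            "sep_range": [1, 8],
            "trial_duration_ms": 1200,
            "balanced": True,
            "block_size": 270,
        },
        "sim": {
            "montage": "standard",
            "srate": 1000.0,
        },
        "preprocess": {
            "band_hz": [0.5, 70.0],
            "notch_hz": [48.0, 52.0],
            "target_srate": 250.0,
            "ocular_method": "ica_auto",
            "eog_threshold": 0.7,
            "epoch_window_ms": [-100.0, 1000.0],
            "baseline_ms": [-100.0, 0.0],
            "reject_uv": 75.0,
        },
        "analysis": {"rois": "default", "halfwidth_ms": 24.0},
        "stats": {"alpha": 0.05},
        "study": {"n_participants": 24, "seed": 0},
    }


def test_profile() -> dict:
    """Scaled-down configuration for fast runs: 16 scalp channels, 400
    trials per condition, least-squares EOG regression for ocular cleanup."""
    cfg = paper_profile()
    cfg["design"]["counts"] = {"SD": 328, "FD": 36, "TD": 36}
    cfg["design"]["block_size"] = None
    cfg["sim"]["montage"] = "reduced"
    cfg["preprocess"]["ocular_method"] = "eog_regression"
    cfg["analysis"]["rois"] = "reduced"
    cfg["study"] = {"n_participants": 8, "seed": 0}
    return cfg


def recovery_profile() -> dict:
    """High-SNR variant of the test profile for parameter-recovery checks.

    Pink noise is scaled to 1 µV so the per-subject averaged difference
    wave (~31 trials) carries a ~10:1 peak signal-to-noise ratio: the
    regime in which latency recovery measures the correctness of the
    analysis chain rather than noise robustness.
    """
    cfg = test_profile()
    cfg["sim"]["pink_sd_uv"] = 1.0
    cfg["sim"]["eog_pink_sd_uv"] = 0.5
    return cfg


def validate_config(config: dict) -> dict:
    for section in REQUIRED_SECTIONS:
        if section not in config:
            raise ConfigError(f"configuration is missing required section {section!r}")
    config.setdefault("study", {"n_participants": 2, "seed": 0})
    return config


def load_config(path: str | Path) -> dict:
    with open(path) as f:
        return validate_config(yaml.safe_load(f))


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        yaml.safe_dump(config, sort_keys=True).encode()
    ).hexdigest()[:16]


def build_sim_config(config: dict, seed: int = 0) -> simulate.SimConfig:
    sim = dict(config["sim"])
    montage_name = sim.pop("montage", "standard")
    montage = (
        simulate.reduced_montage() if montage_name == "reduced" else simulate.standard_montage()
    )
    cfg = simulate.SimConfig(montage=montage, seed=seed)
    mmn_overrides = sim.pop("mmn", None)
    for key, val in sim.items():
        if not hasattr(cfg, key):
            raise ConfigError(f"unknown sim parameter {key!r}")
        setattr(cfg, key, val)
    if mmn_overrides:
        for row in mmn_overrides:
            cell = (row["phonprob"], row["sylstr"], row["role"])
            cur = cfg.mmn[cell]
            cfg.mmn[cell] = simulate.GaussianComponent(
                amplitude_uv=row.get("amplitude_uv", cur.amplitude_uv),
                latency_ms=row.get("latency_ms", cur.latency_ms),
                fwhm_ms=row.get("fwhm_ms", cur.fwhm_ms),
            )
    return cfg


def _rois(config: dict) -> dict[str, list[str]]:
    name = config["analysis"].get("rois", "default")
    if isinstance(name, dict):
        return name
    return erp.REDUCED_ROIS if name == "reduced" else erp.DEFAULT_ROIS


def _spawn_seeds(master_seed: int, n: int) -> list[int]:
    """Deterministic child seeds, each below 2**31."""
    ss = np.random.SeedSequence(master_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


# ---------------------------------------------------------------------------
# Per-participant processing
# ---------------------------------------------------------------------------

def preprocess_condition(
    raw, config: dict, seed: int = 0
) -> tuple[preprocess.Epochs, dict]:
    """filter -> downsample -> ocular removal -> epoch -> baseline/reject ->
    mastoid re-reference, returning cleaned epochs and QC counts."""
    pp = config["preprocess"]
    band = tuple(pp["band_hz"]) if pp.get("band_hz") else None
    notch = tuple(pp["notch_hz"]) if pp.get("notch_hz") else None
    raw = preprocess.filter_continuous(raw, band, notch)
    raw = preprocess.downsample(raw, pp.get("target_srate", 250.0))
    raw, oc_report = preprocess.remove_ocular_artifacts(
        raw, method=pp.get("ocular_method", "ica_auto"),
        threshold=pp.get("eog_threshold", 0.7), seed=seed,
    )
    ep = preprocess.epoch(raw, tuple(pp.get("epoch_window_ms", (-100.0, 1000.0))))
    ep = preprocess.baseline_and_reject(
        ep, tuple(pp.get("baseline_ms", (-100.0, 0.0))), pp.get("reject_uv", 75.0)
    )
    ep = preprocess.rereference_mastoids(ep)
    qc = {
        "n_trials": int(ep.n_trials),
        "n_kept": int(ep.metadata["kept"].sum()),
        "n_rejected_amplitude": int((ep.metadata["reason"] == "amplitude").sum()),
        "n_rejected_edge": int((ep.metadata["reason"] == "edge").sum()),
        "ocular_method": oc_report.method,
        "ocular_components": oc_report.n_components,
        "ocular_removed": oc_report.n_removed,
    }
    return ep, qc


def process_participant(
    participant: str, config: dict, seed: int, stimuli=None
) -> tuple[list[erp.MMNMeasure], dict]:
    """Run the full chain for one participant; returns MMN measures for all
    8 analysis cells plus QC counts."""
    stimuli = stimuli or design.default_stimuli()
    by_id = {s.id: s for s in stimuli}
    identity = design.build_identity_map(stimuli)
    rois = _rois(config)
    d = config["design"]
    seeds = _spawn_seeds(seed, 2 + 2 * len(stimuli))
    eq_seed, *stage_seeds = seeds[1:]

    epochs: dict[str, preprocess.Epochs] = {}
    selections: dict[str, pd.DataFrame] = {}
    qc: dict = {"participant": participant, "conditions": {}}
    for ci, stim in enumerate(stimuli):
        cond = stim.id
        stage = "design"
        try:
            seq = design.generate_condition_sequence(
                standard=stim,
                deviants=list(design.deviants_for(stim, stimuli).values()),
                counts=d.get("counts"),
                sep_range=tuple(d.get("sep_range", (1, 8))),
                trial_duration_ms=d.get("trial_duration_ms", 1200),
                seed=stage_seeds[2 * ci],
                balanced=d.get("balanced", True),
                block_size=d.get("block_size"),
            )
            stage = "simulate"
            t0 = time.perf_counter()
            simcfg = build_sim_config(config, seed=stage_seeds[2 * ci + 1])
            raw = simulate.simulate_subject(seq, simcfg, stimuli=stimuli)
            t1 = time.perf_counter()
            stage = "preprocess"
            ep, cond_qc = preprocess_condition(raw, config, seed=stage_seeds[2 * ci + 1])
            t2 = time.perf_counter()
            stage = "select"
            selections[cond] = select.select_analysis_trials(ep)
            epochs[cond] = ep
            cond_qc["t_simulate_s"] = round(t1 - t0, 3)
            cond_qc["t_preprocess_s"] = round(t2 - t1, 3)
            qc["conditions"][cond] = cond_qc
        except Exception as e:  # noqa: BLE001 - re-raised with context
            raise StageError(stage, participant, e) from e

    try:
        equalized, n_eq = select.equalize_counts(selections, seed=eq_seed)
    except Exception as e:
        raise StageError("equalize", participant, e) from e
    qc["n_equalized"] = int(n_eq)

    measures: list[erp.MMNMeasure] = []
    halfwidth = config["analysis"].get("halfwidth_ms", 24.0)
    for cond in sorted(epochs):
        for devtype in ("FD", "TD"):
            try:
                dev_stim = by_id[identity[(cond, devtype)]]
                offset = dev_stim.deviation_onset_ms(devtype)
                tab_c = equalized[equalized["condition"] == cond]
                dev_idx = tab_c.loc[
                    (tab_c["role"] == devtype) & tab_c["equalized"], "index"
                ].to_numpy()
                std_cond = dev_stim.id  # identical stimulus is standard there
                tab_m = equalized[equalized["condition"] == std_cond]
                std_idx = tab_m.loc[
                    (tab_m["role"] == "SD") & tab_m["equalized"], "index"
                ].to_numpy()
                labels_common = {
                    "stimulus": dev_stim.id,
                    "phonprob": dev_stim.phonprob,
                    "sylstr": dev_stim.sylstr,
                    "devtype": devtype,
                    "condition": cond,
                }
                dev_wave = erp.timelock_average(
                    epochs[cond], dev_idx, offset, {**labels_common, "role": devtype}
                )
                std_wave = erp.timelock_average(
                    epochs[std_cond], std_idx, offset, {**labels_common, "role": "SD"}
                )
                diff = erp.difference_wave(dev_wave, std_wave)
                lat, window_used, qc_flag = erp.detect_mmn_peak(
                    diff, devtype, rois=rois, halfwidth_ms=halfwidth
                )
                m = erp.mean_amplitudes(
                    std_wave, dev_wave, lat, halfwidth_ms=halfwidth, rois=rois,
                    window_used=window_used, qc_flag=qc_flag,
                )
                m.labels = {**labels_common, "subject": participant}
                measures.append(m)
            except Exception as e:
                raise StageError("erp", participant, e) from e
    return measures, qc


# ---------------------------------------------------------------------------
# Cell tables and study-level statistics
# ---------------------------------------------------------------------------

def build_cell_tables(measures_frame: pd.DataFrame) -> dict[str, dict[str, pd.DataFrame]]:
    """From the long measures table, build per-deviant-type amplitude
    (subject x phonprob x sylstr x cond x roi) and latency cell tables."""
    out: dict[str, dict[str, pd.DataFrame]] = {}
    roi_rows = measures_frame[measures_frame["site_kind"] == "roi"]
    for devtype, gd in roi_rows.groupby("devtype"):
        amp_rows = []
        for _, r in gd.iterrows():
            for cond_label, col in (("Standard", "amp_standard_uv"), ("Deviant", "amp_deviant_uv")):
                amp_rows.append(
                    {
                        "subject": r["subject"],
                        "phonprob": r["phonprob"],
                        "sylstr": r["sylstr"],
                        "cond": cond_label,
                        "roi": r["site"],
                        "value": r[col],
                    }
                )
        amp = pd.DataFrame(amp_rows)
        lat = (
            gd.drop_duplicates(subset=["subject", "phonprob", "sylstr"])[
                ["subject", "phonprob", "sylstr", "peak_latency_ms"]
            ]
            .rename(columns={"peak_latency_ms": "latency_ms"})
            .reset_index(drop=True)
        )
        out[devtype] = {"amplitude": amp, "latency": lat}
    return out


def run_statistics(cell_tables: dict, alpha: float = 0.05) -> dict:
    amp_effects = {}
    lat_effects = {}
    for devtype, tables in cell_tables.items():
        amp_effects[devtype] = stats.rm_anova_2k(
            tables["amplitude"], dv="value", subject="subject",
            factors=["phonprob", "sylstr", "cond", "roi"],
        )
        lat_effects[devtype] = stats.rm_anova_2x2_latency(tables["latency"])
    report = stats.hypothesis_report(amp_effects, lat_effects, alpha=alpha)
    return {"amplitude": amp_effects, "latency": lat_effects, "report": report}


def run_study(
    config: dict, outdir: str | Path | None = None, master_seed: int | None = None
) -> dict:
    """Run the full study; returns measures, cell tables, effects and the
    hypothesis report (and writes TSV/JSON artifacts when ``outdir``)."""
    config = validate_config(config)
    study = config["study"]
    seed = study.get("seed", 0) if master_seed is None else master_seed
    n_participants = study.get("n_participants", 2)
    pseeds = _spawn_seeds(seed, n_participants)
    header = {"config_hash": config_hash(config), "version": __version__, "seed": int(seed)}

    all_measures: list[erp.MMNMeasure] = []
    qc_all = []
    for pi in range(n_participants):
        pid = f"sub-{pi + 1:02d}"
        t0 = time.perf_counter()
        measures, qc = process_participant(pid, config, pseeds[pi])
        logger.info("participant %s done in %.1f s (equalized N=%s)",
                    pid, time.perf_counter() - t0, qc["n_equalized"])
        all_measures.extend(measures)
        qc_all.append(qc)

    frame = erp.measures_to_frame(all_measures)
    cell_tables = build_cell_tables(frame)
    results = run_statistics(cell_tables, alpha=config["stats"].get("alpha", 0.05))

    out = {
        "header": header,
        "measures": frame,
        "cell_tables": cell_tables,
        "effects": results,
        "report": results["report"],
        "qc": qc_all,
    }
    if outdir is not None:
        _write_artifacts(out, config, Path(outdir))
    return out


def _write_artifacts(out: dict, config: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    hdr = out["header"]
    banner = f"# mmnkit {hdr['version']} config={hdr['config_hash']} seed={hdr['seed']}\n"

    def _tsv(frame: pd.DataFrame, name: str) -> None:
        path = outdir / name
        with open(path, "w") as f:
            f.write(banner)
            frame.to_csv(f, sep="\t", index=False)

    _tsv(out["measures"], "measures.tsv")
    for devtype, tables in out["cell_tables"].items():
        _tsv(tables["amplitude"], f"cells_amplitude_{devtype}.tsv")
        _tsv(tables["latency"], f"cells_latency_{devtype}.tsv")
    eff_rows = []
    for measure in ("amplitude", "latency"):
        for devtype, effects in out["effects"][measure].items():
            df = stats.effects_to_frame(effects)
            df.insert(0, "measure", measure)
            df.insert(0, "deviant_type", devtype)
            eff_rows.append(df)
    _tsv(pd.concat(eff_rows, ignore_index=True), "effects.tsv")
    _tsv(out["report"], "hypothesis_report.tsv")
    (outdir / "qc.json").write_text(json.dumps({**hdr, "participants": out["qc"]}, indent=1))
    (outdir / "config.yaml").write_text(banner + yaml.safe_dump(config, sort_keys=True))
    (outdir / "report.json").write_text(
        json.dumps({**hdr, "hypotheses": out["report"].to_dict(orient="records")}, indent=1)
    )


# ---------------------------------------------------------------------------
# Recovery / calibration experiments
# ---------------------------------------------------------------------------

def recovery_experiment(
    config: dict | None = None,
    n_sims: int = 20,
    effect_grid: list[dict] | None = None,
    alpha: float = 0.05,
    base_seed: int = 0,
    deviant_type: str = "FD",
    target_effect: str = "phonprob",
) -> pd.DataFrame:
    """Parameter-recovery and detection-power experiment.

    For each grid point (a dict of ``sim`` overrides, e.g. formal-latency
    ground truth) run ``n_sims`` independent scaled-down studies and
    report, for the targeted latency effect: detection rate at Holm-
    adjusted alpha with the expected direction, plus bias and RMSE of the
    recovered per-study mean latency difference (first factor level minus
    second, HPP - LPP).
    """
    if n_sims < 1:
        raise ConfigError("n_sims must be >= 1")
    config = validate_config(dict(config or test_profile()))
    effect_grid = effect_grid or [{}]
    rows = []
    for gi, overrides in enumerate(effect_grid):
        cfg = json.loads(json.dumps(config))  # deep copy
        cfg["sim"] = {**cfg["sim"], **overrides}
        simcfg = build_sim_config(cfg, seed=0)
        truth = simulate.ground_truth_table(simcfg)
        t = truth[truth["deviant_type"] == deviant_type]
        if target_effect == "phonprob":
            true_diff = float(
                t[t["phonprob"] == "HPP"]["latency_ms"].mean()
                - t[t["phonprob"] == "LPP"]["latency_ms"].mean()
            )
        else:
            true_diff = float(
                t[t["sylstr"] == "SylStr1"]["latency_ms"].mean()
                - t[t["sylstr"] == "SylStr2"]["latency_ms"].mean()
            )
        seeds = _spawn_seeds(base_seed + 7919 * gi, n_sims)
        diffs, detected = [], []
        for seed in seeds:
            res = run_study(cfg, master_seed=seed)
            lat = res["cell_tables"][deviant_type]["latency"]
            if target_effect == "phonprob":
                d = float(
                    lat[lat["phonprob"] == "HPP"]["latency_ms"].mean()
                    - lat[lat["phonprob"] == "LPP"]["latency_ms"].mean()
                )
            else:
                d = float(
                    lat[lat["sylstr"] == "SylStr1"]["latency_ms"].mean()
                    - lat[lat["sylstr"] == "SylStr2"]["latency_ms"].mean()
                )
            rep = res["report"]
            row = rep[
                (rep["deviant_type"] == deviant_type)
                & (rep["measure"] == "latency")
                & (rep["effect"] == target_effect)
            ]
            sig = bool(row["significant"].iloc[0]) if len(row) else False
            direction_ok = (d < 0) == (true_diff < 0) if true_diff != 0 else True
            detected.append(sig and (direction_ok or true_diff == 0))
            diffs.append(d)
        diffs_arr = np.asarray(diffs)
        rows.append(
            {
                "grid_point": gi,
                "overrides": json.dumps(overrides),
                "true_diff_ms": true_diff,
                "n_sims": n_sims,
                "detection_rate": float(np.mean(detected)),
                "mean_recovered_ms": float(diffs_arr.mean()),
                "bias_ms": float(diffs_arr.mean() - true_diff),
                "rmse_ms": float(np.sqrt(((diffs_arr - true_diff) ** 2).mean())),
            }
        )
    return pd.DataFrame(rows)


def type1_calibration(
    n_subjects: int = 24,
    n_reps: int = 1000,
    factors: tuple[str, ...] = ("phonprob", "sylstr"),
    alpha: float = 0.05,
    seed: int = 0,
    sd: float = 1.0,
) -> pd.DataFrame:
    """Null calibration of the contrast-score ANOVA on Gaussian cell means:
    per-effect rejection rate at ``alpha`` over ``n_reps`` simulated null
    tables (should sit near ``alpha``)."""
    rng = np.random.default_rng(seed)
    k = len(factors)
    n_cells = 2**k
    # all +/-1 code vectors per effect, vectorized over reps
    from itertools import combinations, product

    cells = list(product([1.0, -1.0], repeat=k))
    effects = []
    for order in range(1, k + 1):
        for combo in combinations(range(k), order):
            codes = np.array([np.prod([c[fi] for fi in combo]) for c in cells])
            effects.append((" x ".join(factors[fi] for fi in combo), codes))
    data = rng.normal(0.0, sd, size=(n_reps, n_subjects, n_cells))
    from scipy import stats as spstats

    rows = []
    for name, codes in effects:
        scores = (data * codes).mean(axis=2)  # reps x subjects
        mean_s = scores.mean(axis=1)
        var_s = scores.var(axis=1, ddof=1)
        F = n_subjects * mean_s**2 / var_s
        p = spstats.f.sf(F, 1, n_subjects - 1)
        rows.append({"effect": name, "rejection_rate": float(np.mean(p < alpha)),
                     "n_reps": n_reps, "alpha": alpha})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

def _setup_logging(logfile: Path | None = None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


@click.group()
def cli() -> None:
    """mmnkit: multi-feature oddball MMN pipeline."""


def _load(config, profile):
    if config:
        return load_config(config)
    return test_profile() if profile == "test" else paper_profile()


_config_opts = [
    click.option("--config", type=click.Path(exists=True), default=None,
                 help="YAML config; defaults to a built-in profile."),
    click.option("--profile", type=click.Choice(["paper", "test"]), default="test"),
    click.option("--seed", type=int, default=0, help="master seed"),
]


def _with_opts(f):
    for opt in reversed(_config_opts):
        f = opt(f)
    return f


@cli.command("simulate")
@_with_opts
@click.option("--participant", type=int, default=1)
@click.option("--workdir", type=click.Path(), required=True)
@click.option("--fmt", type=click.Choice(["binary", "brainvision"]), default="binary")
def simulate_cmd(config, profile, seed, participant, workdir, fmt):
    """Generate sequences and raw EEG for one participant."""
    _setup_logging()
    cfg = _load(config, profile)
    stimuli = design.default_stimuli()
    pseed = _spawn_seeds(seed, participant)[participant - 1]
    seeds = _spawn_seeds(pseed, 2 + 2 * len(stimuli))
    stage_seeds = seeds[2:]
    subdir = Path(workdir) / f"sub-{participant:02d}"
    subdir.mkdir(parents=True, exist_ok=True)
    d = cfg["design"]
    for ci, stim in enumerate(stimuli):
        seq = design.generate_condition_sequence(
            standard=stim, deviants=list(design.deviants_for(stim, stimuli).values()),
            counts=d.get("counts"), sep_range=tuple(d.get("sep_range", (1, 8))),
            trial_duration_ms=d.get("trial_duration_ms", 1200),
            seed=stage_seeds[2 * ci], balanced=d.get("balanced", True),
            block_size=d.get("block_size"),
        )
        seq.to_tsv(subdir / f"events_{stim.id}.tsv")
        simcfg = build_sim_config(cfg, seed=stage_seeds[2 * ci + 1])
        raw = simulate.simulate_subject(seq, simcfg, stimuli=stimuli)
        base = subdir / f"raw_{stim.id}"
        if fmt == "brainvision":
            write_brainvision(raw, base)
        else:
            write_raw_binary(raw, base)
        logger.info("wrote %s (%d trials, %.0f s)", base, len(seq), raw.duration_s)


@cli.command("preprocess")
@_with_opts
@click.option("--participant", type=int, default=1)
@click.option("--workdir", type=click.Path(exists=True), required=True)
def preprocess_cmd(config, profile, seed, participant, workdir):
    """Filter/downsample/clean/epoch previously simulated raw files."""
    _setup_logging()
    cfg = _load(config, profile)
    subdir = Path(workdir) / f"sub-{participant:02d}"
    pseed = _spawn_seeds(seed, participant)[participant - 1]
    qc_all = {}
    for base in sorted(subdir.glob("raw_*.json")):
        cond = base.stem.replace("raw_", "")
        raw = read_raw_binary(base)
        ep, qc = preprocess_condition(raw, cfg, seed=pseed)
        ep.to_hdf5(subdir / f"epochs_{cond}.h5")
        qc_all[cond] = qc
        logger.info("preprocessed %s: %s", cond, qc)
    (subdir / "qc_preprocess.json").write_text(json.dumps(qc_all, indent=1))


@cli.command("select")
@_with_opts
@click.option("--participant", type=int, default=1)
@click.option("--workdir", type=click.Path(exists=True), required=True)
def select_cmd(config, profile, seed, participant, workdir):
    """Trial selection + cross-condition equalization for one participant."""
    _setup_logging()
    subdir = Path(workdir) / f"sub-{participant:02d}"
    pseed = _spawn_seeds(seed, participant)[participant - 1]
    eq_seed = _spawn_seeds(pseed, 2 + 8)[1]
    selections = {}
    for path in sorted(subdir.glob("epochs_*.h5")):
        cond = path.stem.replace("epochs_", "")
        selections[cond] = select.select_analysis_trials(preprocess.Epochs.from_hdf5(path))
    equalized, n_eq = select.equalize_counts(selections, seed=eq_seed)
    equalized.to_csv(subdir / "selection.tsv", sep="\t", index=False)
    logger.info("equalized N=%d", n_eq)


@cli.command("erp")
@_with_opts
@click.option("--participant", type=int, default=1)
@click.option("--workdir", type=click.Path(exists=True), required=True)
def erp_cmd(config, profile, seed, participant, workdir):
    """Difference waves, MMN peaks and amplitude measures for one participant."""
    _setup_logging()
    cfg = _load(config, profile)
    subdir = Path(workdir) / f"sub-{participant:02d}"
    pid = f"sub-{participant:02d}"
    stimuli = design.default_stimuli()
    by_id = {s.id: s for s in stimuli}
    identity = design.build_identity_map(stimuli)
    rois = _rois(cfg)
    halfwidth = cfg["analysis"].get("halfwidth_ms", 24.0)
    equalized = pd.read_csv(subdir / "selection.tsv", sep="\t")
    epochs = {
        p.stem.replace("epochs_", ""): preprocess.Epochs.from_hdf5(p)
        for p in sorted(subdir.glob("epochs_*.h5"))
    }
    measures = []
    for cond in sorted(epochs):
        for devtype in ("FD", "TD"):
            dev_stim = by_id[identity[(cond, devtype)]]
            offset = dev_stim.deviation_onset_ms(devtype)
            tab_c = equalized[equalized["condition"] == cond]
            dev_idx = tab_c.loc[(tab_c["role"] == devtype) & tab_c["equalized"], "index"].to_numpy()
            tab_m = equalized[equalized["condition"] == dev_stim.id]
            std_idx = tab_m.loc[(tab_m["role"] == "SD") & tab_m["equalized"], "index"].to_numpy()
            labels = {"stimulus": dev_stim.id, "phonprob": dev_stim.phonprob,
                      "sylstr": dev_stim.sylstr, "devtype": devtype, "condition": cond}
            dev_wave = erp.timelock_average(epochs[cond], dev_idx, offset, {**labels, "role": devtype})
            std_wave = erp.timelock_average(epochs[dev_stim.id], std_idx, offset, {**labels, "role": "SD"})
            diff = erp.difference_wave(dev_wave, std_wave)
            lat, window_used, qc_flag = erp.detect_mmn_peak(diff, devtype, rois=rois, halfwidth_ms=halfwidth)
            m = erp.mean_amplitudes(std_wave, dev_wave, lat, halfwidth_ms=halfwidth,
                                    rois=rois, window_used=window_used, qc_flag=qc_flag)
            m.labels = {**labels, "subject": pid}
            measures.append(m)
    frame = erp.measures_to_frame(measures)
    frame["subject"] = pid
    frame.to_csv(subdir / "measures.tsv", sep="\t", index=False)
    logger.info("wrote %s", subdir / "measures.tsv")


@cli.command("stats")
@_with_opts
@click.option("--workdir", type=click.Path(exists=True), required=True)
def stats_cmd(config, profile, seed, workdir):
    """Study-level ANOVAs + Holm-corrected hypothesis report from measures files."""
    _setup_logging()
    cfg = _load(config, profile)
    frames = [
        pd.read_csv(p, sep="\t") for p in sorted(Path(workdir).glob("sub-*/measures.tsv"))
    ]
    if not frames:
        raise click.ClickException("no sub-*/measures.tsv found under workdir")
    frame = pd.concat(frames, ignore_index=True)
    cell_tables = build_cell_tables(frame)
    results = run_statistics(cell_tables, alpha=cfg["stats"].get("alpha", 0.05))
    results["report"].to_csv(Path(workdir) / "hypothesis_report.tsv", sep="\t", index=False)
    click.echo(results["report"].to_string(index=False))


@cli.command("run-all")
@_with_opts
@click.option("--outdir", type=click.Path(), required=True)
def run_all_cmd(config, profile, seed, outdir):
    """Run the whole study end to end and write all artifacts."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir / "run.log")
    cfg = _load(config, profile)
    res = run_study(cfg, outdir=outdir, master_seed=seed)
    click.echo(res["report"].to_string(index=False))


@cli.command("recover")
@_with_opts
@click.option("--n-sims", type=int, default=20)
@click.option("--out", type=click.Path(), default=None)
def recover_cmd(config, profile, seed, n_sims, out):
    """Latency-recovery / detection-power experiment on the test profile."""
    _setup_logging()
    cfg = _load(config, profile)
    table = recovery_experiment(cfg, n_sims=n_sims, base_seed=seed)
    if out:
        table.to_csv(out, sep="\t", index=False)
    click.echo(table.to_string(index=False))
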