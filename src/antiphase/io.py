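"""Call-table I/O, run configuration, and the end-to-end pipeline driver.

Conventions used everywhere: times in seconds (float64), phases in radians
in [0, 2*pi), rates in Hz, 0-based sample indexing, half-open event
intervals [onset, offset).  Every pipeline run writes a JSON manifest with
the configuration hash and all seeds, so outputs are reproducible
byte-for-byte from the config alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import circstats, classify, detect, phase, ratemodels, simulate, stimgen

logger = logging.getLogger("antiphase")

REQUIRED_CALL_COLUMNS = ["onset_s", "offset_s"]


class CallTableError(ValueError):
    pass


def read_call_table(path, chunksize: int | None = None):
    """Read a call-event CSV, validating columns and onset ordering.

    With ``chunksize`` set, returns an iterator of validated DataFrame chunks
    so very large tables stream without full materialization.
    """
    if chunksize is not None:
        return _stream_call_table(path, chunksize)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:
        raise CallTableError(f"malformed call table {path}: {e}") from e
    _validate_call_table(df, path)
    return df


def _stream_call_table(path, chunksize):
    last_onset = -np.inf
    for i, chunk in enumerate(pd.read_csv(path, chunksize=chunksize)):
        _validate_call_table(chunk, path, check_monotone=False)
        onsets = chunk["onset_s"].to_numpy()
        if len(onsets) and (onsets[0] < last_onset or np.any(np.diff(onsets) < 0)):
            raise CallTableError(f"{path}: onsets not monotone in chunk {i}")
        if len(onsets):
            last_onset = onsets[-1]
        yield chunk


def _validate_call_table(df: pd.DataFrame, path, check_monotone: bool = True):
    missing = [c for c in REQUIRED_CALL_COLUMNS if c not in df.columns]
    if missing:
        raise CallTableError(f"{path}: missing required columns {missing}")
    bad = df.index[df["offset_s"] <= df["onset_s"]]
    if len(bad):
        # +2: header line plus 1-based numbering
        raise CallTableError(
            f"{path}: offset <= onset at line {int(bad[0]) + 2}"
        )
    if check_monotone:
        # onsets are monotone within a recording; tables concatenated across
        # conditions/rates are checked per group
        group_cols = [c for c in ("playback_condition", "modulation_rate_hz")
                      if c in df.columns]
        groups = df.groupby(group_cols, sort=False) if group_cols else [(None, df)]
        for _, grp in groups:
            onsets = grp["onset_s"].to_numpy()
            bad = np.flatnonzero(np.diff(onsets) < 0)
            if len(bad):
                line = int(grp.index[bad[0] + 1]) + 2
                raise CallTableError(
                    f"{path}: onsets not monotone at line {line}"
                )


def write_call_table(df: pd.DataFrame, path) -> None:
    _validate_call_table(df, path)
    df.to_csv(path, index=False)


@dataclass
class RunConfig:
    """Configuration of a synthetic end-to-end run."""

    out_dir: str = "antiphase_run"
    seed: int = 0
    sample_rate: float = 192_000.0
    masker_band_khz: tuple[float, float] = (10.0, 96.0)
    modulation_rates_hz: tuple[float, ...] = (8.0, 15.0)
    duration_s: float = 60.0
    modulation_depth: float = 1.0
    baseline_rate: float = 30.0
    phase_preference_mu: float = 3 * np.pi / 2
    phase_preference_kappa: float = 2.0
    suppression_factor: float = 0.6
    snr_db: float = 20.0
    n_boot: int = 200
    pretagged_events_csv: str | None = None  # skip audio stages, start here

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = RunConfig(**raw)
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_plain_dict(), fh, sort_keys=True)

    def as_plain_dict(self) -> dict:
        d = asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.as_plain_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full synthetic pipeline and write a results bundle.

    Stages (each logged, any failure aborts with a stage-named error):
    stimulus synthesis -> call-train simulation -> audio rendering ->
    detection -> envelope/phase tagging -> circular statistics + bootstrap ->
    count models -> timing-anchor classification.  With
    ``pretagged_events_csv`` set, the audio stages are skipped and the
    analysis starts from the tagged events.

    Returns a dict of output DataFrames; files land under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    manifest = {
        "config": config.as_plain_dict(),
        "config_hash": config.config_hash(),
        "stages": [],
    }

    def stage(name):
        logger.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        if config.pretagged_events_csv:
            stage("load_pretagged")
            tagged_all = read_call_table(config.pretagged_events_csv)
        else:
            tagged_parts = []
            for i, rate in enumerate(config.modulation_rates_hz):
                stage(f"stimgen_{rate:g}Hz")
                spec = stimgen.MaskerSpec(
                    carrier_band=config.masker_band_khz,
                    sample_rate=config.sample_rate,
                    duration=config.duration_s,
                    am_schedule=rate,
                    modulation_depth=config.modulation_depth,
                    rng_seed=config.seed + i,
                )
                masker, cycles = spec.render()
                stage(f"simulate_{rate:g}Hz")
                true_model = phase.phase_model_from_cycles(cycles)
                behav = simulate.BehaviorModel(
                    baseline_rate=config.baseline_rate,
                    phase_preference_mu=config.phase_preference_mu,
                    phase_preference_kappa=config.phase_preference_kappa,
                    suppression_factor=config.suppression_factor,
                    rng_seed=config.seed + 100 + i,
                )
                events = simulate.simulate_call_train(
                    behav, true_model, config.duration_s,
                    playback_condition="broadband",
                )
                events["modulation_rate_hz"] = rate
                stage(f"render_audio_{rate:g}Hz")
                audio = simulate.synth_call_audio(events, masker, config.snr_db)
                stage(f"detect_{rate:g}Hz")
                detected = detect.detect_calls(audio)
                stage(f"tag_{rate:g}Hz")
                env = phase.extract_envelope_steady(audio, rate)
                model = phase.phase_model_from_envelope(env, [rate])
                tagged = phase.tag_call_onsets(detected, model)
                tagged["modulation_rate_hz"] = rate
                tagged["playback_condition"] = "broadband"
                tagged_parts.append(tagged)
            tagged_all = pd.concat(tagged_parts, ignore_index=True)
        tagged_all.to_csv(out / "tagged_events.csv", index=False)
        results["tagged_events"] = tagged_all

        stage("circstats")
        stat_rows, boot_rows = [], []
        for rate, grp in tagged_all[tagged_all["tagged"] == True].groupby(  # noqa: E712
            "modulation_rate_hz"
        ):
            a = grp["onset_phase_rad"].to_numpy()
            summ = circstats.circ_summary(a)
            ray = circstats.rayleigh_test(a)
            fit = circstats.vm_mle(a)
            boots = circstats.bootstrap_vm(a, n_boot=config.n_boot,
                                           seed=config.seed + 1000)
            stat_rows.append(
                {
                    "modulation_rate_hz": rate,
                    "n": summ.n,
                    "mean_direction_rad": summ.mean_direction,
                    "mean_resultant": summ.mean_resultant,
                    "rayleigh_z": ray.statistic,
                    "rayleigh_p": ray.p_value,
                    "vm_mu": fit.mu,
                    "vm_kappa": fit.kappa,
                }
            )
            boot_rows.append(
                pd.DataFrame(
                    {
                        "modulation_rate_hz": rate,
                        "replicate": np.arange(config.n_boot),
                        "mu": boots.mu,
                        "kappa": boots.kappa,
                    }
                )
            )
        stats_df = pd.DataFrame(stat_rows)
        boots_df = pd.concat(boot_rows, ignore_index=True)
        stats_df.to_csv(out / "circular_stats.csv", index=False)
        boots_df.to_csv(out / "vm_bootstraps.csv", index=False)
        results["circular_stats"] = stats_df
        results["vm_bootstraps"] = boots_df

        stage("rate_models")
        spec = simulate.CountTableSpec(
            condition_irr={"silent": 1.0,
                           "broadband": config.suppression_factor,
                           "highfreq": 1.3}
        )
        counts = simulate.simulate_count_table(spec, seed=config.seed + 2000)
        fit = ratemodels.fit_nb(counts)
        anova = ratemodels.lr_anova(fit)
        means, contrasts = ratemodels.emmeans_contrasts(fit)
        counts.to_csv(out / "count_table.csv", index=False)
        fit.coef_table.to_csv(out / "nb_coefficients.csv", index=False)
        means.to_csv(out / "nb_marginal_means.csv", index=False)
        contrasts.to_csv(out / "nb_contrasts.csv", index=False)
        results["nb_fit"] = fit
        results["nb_anova"] = anova

        stage("timing_classifier")
        measures = classify.timing_measures(
            boots_df["mu"].to_numpy(), boots_df["modulation_rate_hz"].to_numpy()
        )
        reports = classify.run_anchor_analysis(measures, seed=config.seed)
        metric_rows = []
        for name, rep in reports.items():
            rep.confusion.to_csv(out / f"confusion_{name}.csv")
            rep.roc.to_csv(out / f"roc_{name}.csv", index=False)
            metric_rows.append(
                {
                    "model": name,
                    "accuracy": rep.accuracy,
                    "accuracy_lo": rep.accuracy_ci[0],
                    "accuracy_hi": rep.accuracy_ci[1],
                    "macro_f1": rep.macro_f1,
                    "macro_auc": rep.macro_auc,
                }
            )
        metrics_df = pd.DataFrame(metric_rows)
        metrics_df.to_csv(out / "classifier_metrics.csv", index=False)
        results["classifier_metrics"] = metrics_df
    except Exception as e:
        failed = manifest["stages"][-1] if manifest["stages"] else "setup"
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {e}") from e

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    results["manifest"] = manifest
    return results
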