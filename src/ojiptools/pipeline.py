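"""End-to-end orchestration: simulate inputs, run every analysis stage, report.

Separated from the CLI so the full pipeline is importable and testable
without going through the console entry point. All outputs are plain CSV;
a ``run.log`` records config, seed and per-stage row counts.
"""

from __future__ import annotations

import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import bands, io, jip, simulate, stats
from .config import PipelineConfig
from .errors import OJIPError, UsageError

__all__ = ["run_simulate", "run_analyze", "write_report"]

log = logging.getLogger("ojiptools")


def _setup_logging(out_dir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers = [h for h in log.handlers if not isinstance(h, logging.FileHandler)]
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)


def run_simulate(config: PipelineConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the bundled paper-like synthetic scenario to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    log.info("simulate: config=%s", asdict(config))
    base, effects = simulate.paper_like_scenario(
        noise_cv=config.noise_cv, trait_noise_cv=config.trait_noise_cv
    )
    transients, traits = simulate.simulate_experiment(
        base,
        effects,
        n_reps=config.n_reps,
        seed=config.seed,
        treatments=config.treatments,
    )
    paths = {
        "transients": out / "transients.csv",
        "physiology": out / "physiology.csv",
    }
    io.write_transients(transients, paths["transients"])
    io.write_group_table(traits, paths["physiology"])
    log.info("simulate: %d transients, %d trait rows", len(transients), len(traits))
    return paths


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                result = fn(*args, **kwargs)
            except OJIPError as exc:
                raise OJIPError(f"stage {name!r} failed: {exc}") from exc
            return result

        return run

    return wrap


def run_analyze(
    config: PipelineConfig,
    out_dir: str | Path,
    transients_csv: str | Path | None = None,
    physiology_csv: str | Path | None = None,
    plots: bool = False,
) -> dict[str, Path]:
    """Run every analysis stage on the given inputs and write the result CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    transients_csv = transients_csv or config.transients_csv
    physiology_csv = physiology_csv or config.physiology_csv
    if transients_csv is None or physiology_csv is None:
        raise UsageError("analyze needs transient and physiology input paths")

    transients = io.read_transients(transients_csv)
    physiology = io.read_group_table(physiology_csv)
    log.info("analyze: %d transients, %d trait rows", len(transients), len(physiology))
    treatments_present = {tr.treatment for tr in transients}
    if config.control not in treatments_present:
        raise UsageError(f"control {config.control!r} absent from transient data")

    outputs: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        outputs[name] = path
        log.info("stage %s: %d rows -> %s", name, len(df), path)

    # 1. landmarks
    landmarks_df = _stage("landmarks")(jip.landmark_table)(transients, t0=config.t0_us)
    emit("landmarks", landmarks_df)

    # 2. JIP parameters
    jip_table = _stage("jip_parameters")(jip.jip_parameter_table)(transients, t0=config.t0_us)
    emit("jip_parameters", jip_table.df)

    # 3. band curves (per variety: group-mean W and delta-W vs control)
    band_rows = []
    by_group: dict[tuple[str, str], list] = {}
    for tr in transients:
        by_group.setdefault(tr.group, []).append(tr)
    varieties = sorted({v for v, _ in by_group})
    mean_bands: dict[tuple[str, str, str], bands.NormalizedBand] = {}
    for phase in ("OJ", "OK", "OI"):
        for (variety, treatment), group in sorted(by_group.items()):
            reps = [
                bands.normalize_band(t, jip.extract_landmarks(t, t0=config.t0_us), phase)
                for t in group
            ]
            mb = bands.mean_band(reps)
            mean_bands[(phase, variety, treatment)] = mb
            band_rows.append(bands.band_frame(mb, variety, treatment))
        for variety in varieties:
            control = mean_bands[(phase, variety, config.control)]
            for treatment in sorted({t for _, t in by_group}):
                if treatment == config.control:
                    continue
                db = bands.delta_band(
                    mean_bands[(phase, variety, treatment)], control,
                    reference_group=config.control,
                )
                band_rows.append(bands.band_frame(db, variety, treatment))
    emit("band_curves", pd.concat(band_rows, ignore_index=True))

    # 4. OEC / QA-RC / K-band / W_OI tail per variety x treatment
    params_by_group = {
        key: [
            jip.compute_jip_parameters(jip.extract_landmarks(t, t0=config.t0_us))
            for t in group
        ]
        for key, group in by_group.items()
    }
    frac_rows = []
    for (variety, treatment), group in sorted(by_group.items()):
        control_params = params_by_group[(variety, config.control)]
        vk_mean, d_vk = bands.k_band_statistics(
            group, by_group[(variety, config.control)], t0=config.t0_us
        )
        frac_rows.append(
            {
                "variety": variety,
                "treatment": treatment,
                "oec_centers": bands.oec_centers(params_by_group[(variety, treatment)], control_params),
                "qa_rc": bands.qa_reducing_centers(
                    params_by_group[(variety, treatment)], control_params, mode=config.qa_rc_mode
                ),
                "VK_mean": vk_mean,
                "delta_VK": d_vk,
                "w_oi_tail_amplitude": bands.w_oi_tail_amplitude(
                    mean_bands[("OI", variety, treatment)]
                ),
            }
        )
    emit("oec_qa_rc", pd.DataFrame(frac_rows))

    # 5. relative JIP profiles
    profiles = _stage("relative_profile")(stats.relative_profile)(jip_table, config.control)
    emit("relative_profiles", profiles.df)

    # 6. combined trait table (physiology + JIP) for statistics
    combined = physiology.concat(jip_table)
    emit("traits_combined", combined.df)

    # 7. one-way ANOVA letters per variety and trait
    letter_rows = []
    for variety in combined.varieties():
        for trait in combined.traits():
            res = stats.one_way_anova_lsd(
                combined, trait, variety=variety, alpha=config.alpha
            )
            g = res.groups.rename(columns={"group": "treatment"})
            g.insert(0, "variety", variety)
            g.insert(1, "trait", trait)
            g["F"] = res.F
            g["p_anova"] = res.p
            letter_rows.append(g)
    emit("anova_letters", pd.concat(letter_rows, ignore_index=True))

    # 8. two-way ANOVA star table
    star_rows = []
    for trait in combined.traits():
        res = stats.two_way_anova(combined, trait)
        t = res.table[res.table["effect"] != "error"].copy()
        t.insert(0, "trait", trait)
        star_rows.append(t)
    emit("two_way_stars", pd.concat(star_rows, ignore_index=True))

    # 9. variability table
    pair = tuple(config.variety_pair) if len(config.variety_pair) == 2 else None
    var_rows = []
    for trait in combined.traits():
        res = stats.variability_from_table(combined, trait, variety_pair=pair)
        row = {"trait": trait, "delta_V": res.delta_V}
        row.update({f"V_{v}": val for v, val in res.V_per_variety.items()})
        var_rows.append(row)
    emit("variability", pd.DataFrame(var_rows))

    # 10. correlation matrix
    if config.correlation_pooling == "pooled":
        corr = stats.correlation_matrix(combined)
        emit("correlations", corr.to_long())
    else:
        frames = []
        for variety in combined.varieties():
            long = stats.correlation_matrix(combined, variety=variety).to_long()
            long.insert(0, "variety", variety)
            frames.append(long)
        emit("correlations", pd.concat(frames, ignore_index=True))

    if plots:
        from . import plots as _plots

        outputs.update(_plots.render_all(out, transients, mean_bands, config))
        log.info("plots written")
    return outputs


def write_report(out_dir: str | Path) -> Path:
    """Summarize an analyze run's CSVs into a small Markdown report."""
    out = Path(out_dir)
    lines = ["# OJIP pipeline report", ""]
    for name in (
        "landmarks", "jip_parameters", "band_curves", "oec_qa_rc", "relative_profiles",
        "traits_combined", "anova_letters", "two_way_stars", "variability", "correlations",
    ):
        path = out / f"{name}.csv"
        if not path.exists():
            raise UsageError(f"missing analysis output {path}; run analyze first")
        df = pd.read_csv(path)
        lines.append(f"## {name}\n\nrows: {len(df)}\n")
        if name in ("oec_qa_rc", "variability", "two_way_stars"):
            lines.append(df.to_string(index=False))
            lines.append("")
    report = out / "report.md"
    report.write_text("\n".join(lines))
    return report
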