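"""Reproducible pipeline runs: simulate → count → storm → analyze → report.

A run is driven by a :class:`RunConfig` (YAML round-trippable); every run
writes its resolved configuration next to its outputs together with a stage
log recording row counts and exclusions. Fixed seed ⇒ byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as psio
from .counting import count_participant
from .stats import (
    CohortModel,
    MorphologyThresholds,
    find_threshold,
    summarize_participant,
)
from .storm import process_table
from .synthetic import (
    AcquisitionParams,
    BlinkParams,
    CohortSpec,
    ParticipantData,
    simulate_cohort,
)

__all__ = ["RunConfig", "ConfigError", "StageError", "run_pipeline", "make_fixtures"]

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """The run configuration is invalid."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")


# default localization-table processing parameters of the storm stage
_STORM_DEFAULTS = {
    "trim": 200,
    "drift_bins": 10,
    "drift_bandwidth": 20.0,
    "merge_radius": 50.0,
    "merge_max_gap": 3,
    "density_radius": 50.0,
    "density_min_neighbors": 5,
    "render_px": 10.0,
    "min_locs": 10,
    "close_px": 3,
    "erode_px": 2,
    "correct_drift": True,
    # FoVs with fewer raw localizations are excluded (insufficient for drift)
    "min_table_locs": 500,
}

_THRESHOLD_DEFAULTS = {
    "area_um2": 0.03,
    "circularity": 0.4,
    "asyn_area_um2": 0.02,
    "rederive_thresholds": False,
    "alpha": 0.05,
}


@dataclass
class RunConfig:
    """Complete, serializable description of one pipeline run.

    ``acquisition``, ``blink`` and ``cohort`` override fields of
    :class:`AcquisitionParams`, :class:`BlinkParams` and :class:`CohortSpec`;
    ``storm`` overrides the localization-processing parameters; ``thresholds``
    holds the morphology cutoffs, the ``rederive_thresholds`` switch and the
    test level ``alpha``. The resolved (fully populated) config is written to
    the output directory of every run.
    """

    acquisition: dict = field(default_factory=dict)
    blink: dict = field(default_factory=dict)
    cohort: dict = field(default_factory=dict)
    storm: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    drift_per_frame: tuple[float, float] = (0.0125, 0.0)
    seed: int = 0
    out_dir: str = "run"

    # ------------------------------------------------------------------
    def resolved(self) -> "RunConfig":
        """Fill every omitted key with its default value."""
        try:
            acq = dataclasses.asdict(AcquisitionParams(**self.acquisition))
            blink = dataclasses.asdict(BlinkParams(**self.blink))
            cohort = dataclasses.asdict(CohortSpec(seed=self.seed, **{
                k: v for k, v in self.cohort.items() if k != "seed"}))
        except (TypeError, ValueError) as exc:
            raise ConfigError(str(exc)) from exc
        storm = dict(_STORM_DEFAULTS)
        unknown = set(self.storm) - set(storm)
        if unknown:
            raise ConfigError(f"unknown storm parameters: {sorted(unknown)}")
        storm.update(self.storm)
        thr = dict(_THRESHOLD_DEFAULTS)
        unknown = set(self.thresholds) - set(thr)
        if unknown:
            raise ConfigError(f"unknown threshold parameters: {sorted(unknown)}")
        thr.update(self.thresholds)
        return RunConfig(acq, blink, cohort, storm, thr,
                         tuple(self.drift_per_frame), int(self.seed), str(self.out_dir))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["drift_per_frame"] = list(self.drift_per_frame)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "drift_per_frame" in d:
            d["drift_per_frame"] = tuple(d["drift_per_frame"])
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def write(self, path: str | Path) -> Path:
        return psio.write_yaml(path, self.to_dict())

    @classmethod
    def read(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(psio.read_yaml(path))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: RunConfig):
    acq = AcquisitionParams(**cfg.acquisition)
    blink = BlinkParams(**cfg.blink)
    spec = CohortSpec(**cfg.cohort)
    bundles, truth = simulate_cohort(spec, acq, blink,
                                     drift_per_frame=cfg.drift_per_frame)
    logger.info("simulate: %d participants, %d truth rows", len(bundles), len(truth))
    return bundles, truth, acq


def _stage_count(bundles: list[ParticipantData]) -> pd.DataFrame:
    rows = []
    for p in bundles:
        for target, stacks in p.dl_stacks.items():
            per_fov, total = count_participant(stacks)
            rows.extend(
                {"participant": p.participant_id, "target": target,
                 "fov": i, "count": c}
                for i, c in enumerate(per_fov)
            )
            logger.info("count: %s/%s total %d over %d FoVs",
                        p.participant_id, target, total, len(per_fov))
    return pd.DataFrame(rows, columns=psio.COUNTS_COLUMNS)


def _stage_storm(bundles: list[ParticipantData], acq: AcquisitionParams,
                 storm_cfg: dict) -> pd.DataFrame:
    params = {k: v for k, v in storm_cfg.items() if k != "min_table_locs"}
    min_locs_tab = int(storm_cfg["min_table_locs"])
    rows = []
    for p in bundles:
        for target, tables in p.storm_tables.items():
            for fov, table in enumerate(tables):
                if len(table) < min_locs_tab:
                    logger.warning(
                        "storm: excluded %s/%s fov %d — %d localizations, "
                        "insufficient for drift correction (min %d)",
                        p.participant_id, target, fov, len(table), min_locs_tab)
                    continue
                morphs, _ = process_table(table, acq.n_frames_storm,
                                          acq.fov_side_nm, **params)
                rows.extend(
                    {"participant": p.participant_id, "target": target,
                     "fov": fov, "label": m.label, "area_um2": m.area,
                     "circularity": m.circularity, "n_locs": m.n_localizations}
                    for m in morphs
                )
                logger.info("storm: %s/%s fov %d — %d localizations → %d aggregates",
                            p.participant_id, target, fov, len(table), len(morphs))
    return pd.DataFrame(rows, columns=psio.MORPH_COLUMNS)


def _participant_groups(bundles: list[ParticipantData]) -> dict[str, str]:
    return {p.participant_id: p.group for p in bundles}


def analyze(counts: pd.DataFrame, morph: pd.DataFrame, groups: dict[str, str],
            thresholds_cfg: dict | None = None, disease_group: str = "PD"):
    """Analysis stage on counts + morphology tables.

    Returns ``(summaries, results, thresholds, threshold_results)`` where
    ``results`` is the fitted :class:`~pullstorm.stats.CohortResults`. With
    ``rederive_thresholds`` the area and circularity cutoffs are re-derived
    from the pooled Aβ aggregates by CDF subtraction before summarizing.
    """
    cfg = dict(_THRESHOLD_DEFAULTS)
    cfg.update(thresholds_cfg or {})
    thr = MorphologyThresholds(area_um2=cfg["area_um2"],
                               circularity=cfg["circularity"],
                               asyn_area_um2=cfg["asyn_area_um2"])
    abeta = morph[morph["target"] == "abeta"]
    threshold_results = {}
    if cfg["rederive_thresholds"]:
        is_pd = abeta["participant"].map(groups) == disease_group
        for feature, col in (("area", "area_um2"), ("circularity", "circularity")):
            res = find_threshold(abeta.loc[is_pd, col].to_numpy(),
                                 abeta.loc[~is_pd, col].to_numpy(), feature)
            threshold_results[feature] = res
        thr = MorphologyThresholds(
            area_um2=threshold_results["area"].threshold,
            circularity=threshold_results["circularity"].threshold,
            asyn_area_um2=cfg["asyn_area_um2"])
        logger.info("analyze: re-derived thresholds area=%.4g µm² circ=%.4g",
                    thr.area_um2, thr.circularity)

    totals = counts.groupby(["participant", "target"])["count"].sum()
    participants = []
    for pid in sorted(groups):
        n_asyn = int(totals.get((pid, "asyn"), 0))
        n_abeta = int(totals.get((pid, "abeta"), 0))
        pm = abeta[abeta["participant"] == pid]
        s = summarize_participant(pid, groups[pid], n_asyn, n_abeta, pm, thr)
        if not s.valid:
            logger.warning("analyze: excluded participant %s — zero Aβ count, "
                           "ratio undefined", pid)
        participants.append(s)

    summaries = pd.DataFrame([vars(p) for p in participants])
    model = CohortModel(summaries, disease_group=disease_group, alpha=cfg["alpha"])
    results = model.fit()
    logger.info("analyze: %d participants summarized, %d measures compared",
                len(summaries), len(results.comparisons))
    return summaries, results, thr, threshold_results


def _format_report(results, thr: MorphologyThresholds, seed: int) -> str:
    lines = [
        "Group comparison report",
        f"seed: {seed}",
        f"thresholds: area > {thr.area_um2:.4g} µm², circularity < "
        f"{thr.circularity:.4g} (αS area > {thr.asyn_area_um2:.4g} µm²)",
        "",
        results.summary().to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        "",
    ]
    return "\n".join(lines)


def _roc_long_table(results) -> pd.DataFrame:
    rows = []
    for m, r in results.rocs.items():
        for t, se, sp in zip(r.thresholds, r.sensitivity, r.specificity):
            rows.append({"measure": m, "threshold": t,
                         "sensitivity": se, "specificity": sp, "auc": r.auc})
    return pd.DataFrame(rows, columns=["measure", "threshold", "sensitivity",
                                       "specificity", "auc"])


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage and write the artifact set into ``config.out_dir``.

    Writes ``counts.csv``, ``morph.csv``, ``summaries.csv``,
    ``comparisons.txt``, ``roc.csv``, ``config.yaml`` (resolved) and
    ``pipeline.log``. Deterministic for a fixed seed. Stage failures raise
    :class:`StageError` naming the stage.
    """
    cfg = config.resolved()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("pullstorm")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        cfg.write(out / "config.yaml")

        def _run(stage, fn, *args):
            try:
                return fn(*args)
            except (ConfigError, StageError):
                raise
            except Exception as exc:
                raise StageError(stage, str(exc)) from exc

        bundles, truth, acq = _run("simulate", _stage_simulate, cfg)
        truth.to_csv(out / "truth.csv", index=False)

        counts = _run("count", _stage_count, bundles)
        psio.write_counts(out / "counts.csv", counts)
        logger.info("count: wrote %d rows", len(counts))

        morph = _run("storm", _stage_storm, bundles, acq, cfg.storm)
        psio.write_morphology(out / "morph.csv", morph)
        logger.info("storm: wrote %d rows", len(morph))

        groups = _participant_groups(bundles)
        summaries, results, thr, _ = _run(
            "analyze", analyze, counts, morph, groups, cfg.thresholds)
        summaries.to_csv(out / "summaries.csv", index=False)

        (out / "comparisons.txt").write_text(_format_report(results, thr, cfg.seed))
        _roc_long_table(results).to_csv(out / "roc.csv", index=False)
        logger.info("report: artifacts written to %s", out)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def fixture_config(seed: int = 7, out_dir: str = "fixture_run") -> RunConfig:
    """Small configuration exercising every stage in well under 30 s:
    2 participants × 2 STORM FoVs of 500 frames on a 97-pixel field."""
    return RunConfig(
        acquisition={"fov_side": 97, "n_frames_dl": 20, "n_frames_storm": 500,
                     "n_fov_dl": 2, "n_fov_storm": 2},
        cohort={"n_per_group": 1, "counts_rate": 8.0,
                "storm_aggregates_per_fov": 5.0},
        storm={"trim": 50, "min_table_locs": 200, "correct_drift": False},
        drift_per_frame=(0.0, 0.0),
        seed=seed,
        out_dir=out_dir,
    )


def make_fixtures(seed: int, out_dir: str | Path = "fixtures") -> Path:
    """Deterministic miniature dataset: 2 participants × 2 FoVs, 500 frames.

    Writes, per participant and target, the diffraction-limited stacks as
    multi-page TIFF, the localization streams as interchange CSV and a cohort
    manifest YAML. Regeneration with the same seed is bit-exact.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = fixture_config(seed).resolved()
    acq = AcquisitionParams(**cfg.acquisition)
    blink = BlinkParams(**cfg.blink)
    spec = CohortSpec(**cfg.cohort)
    bundles, truth = simulate_cohort(spec, acq, blink,
                                     drift_per_frame=cfg.drift_per_frame)
    manifest: dict = {"seed": int(seed), "pixel_size_nm": acq.pixel_size,
                      "n_frames_storm": acq.n_frames_storm, "participants": {}}
    for p in bundles:
        entry = {"group": p.group, "files": []}
        for target in p.dl_stacks:
            for i, stack in enumerate(p.dl_stacks[target]):
                f = f"{p.participant_id}_{target}_dl{i}.tif"
                psio.write_stack(out / f, stack, dtype="uint16")
                entry["files"].append(f)
            for i, table in enumerate(p.storm_tables[target]):
                f = f"{p.participant_id}_{target}_storm{i}.csv"
                psio.write_localizations(out / f, table)
                entry["files"].append(f)
        manifest["participants"][p.participant_id] = entry
    truth.to_csv(out / "truth.csv", index=False)
    psio.write_yaml(out / "manifest.yaml", manifest)
    logger.info("fixtures: %d participants written to %s", len(bundles), out)
    return out
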