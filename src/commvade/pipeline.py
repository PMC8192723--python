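"""End-to-end orchestration: simulate (or load) a study, then run
attribution, diversity, the taxa screen, and the gas analysis, writing every
artifact plus a checksummed manifest into an output directory."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import attribution as attr
from . import diversity as div
from . import gas_analysis as gas_mod
from . import taxa_screen as screen_mod
from .errors import CommvadeError, StageError
from .synthetic_community import SimConfig, SimulatedStudy, simulate_study
from .tables_io import (
    read_asv_table,
    read_gas,
    read_metadata,
    read_newick,
    write_asv_table,
    write_gas,
    write_metadata,
    write_newick_file,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "load_real_data"]


@dataclass
class RunConfig:
    sim: SimConfig = dataclasses.field(default_factory=SimConfig)
    n_permutations: int = 999
    permanova_seed: int = 0
    dunnett_mc: int = 100_000
    alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        sim = SimConfig(**data.pop("sim", {}))
        return cls(sim=sim, **data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_real_data(data_dir: str | Path) -> SimulatedStudy:
    """Load a user-supplied study bundle (no truth) from a directory with
    asv_table.tsv, metadata.tsv, tree.nwk, and gas.csv.

    The tree is loaded lazily by the diversity stage, so a missing tree
    fails there, not here."""
    data_dir = Path(data_dir)
    table = read_asv_table(data_dir / "asv_table.tsv")
    metadata = read_metadata(data_dir / "metadata.tsv")
    gas = read_gas(data_dir / "gas.csv")
    return SimulatedStudy(table, metadata, tree=None, gas=gas, truth=None, config=None)


def run_all(
    config: RunConfig,
    out_dir: str | Path,
    real_data: str | Path | None = None,
) -> dict:
    """Run every stage in study order; returns the run report dict.

    Any stage failure raises :class:`StageError` naming the stage, after
    writing a partial manifest of the artifacts produced so far.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    report: dict = {"config": dataclasses.asdict(config)}

    def emit(name: str) -> None:
        manifest[name] = _sha256(out / name)

    def fail(stage: str, exc: Exception) -> StageError:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
        return StageError(stage, str(exc))

    # --- stage: data ---
    try:
        if real_data is None:
            study = simulate_study(config.sim)
            study.truth.to_json(out / "truth.json")
            emit("truth.json")
        else:
            study = load_real_data(real_data)
        write_asv_table(study.table, out / "asv_table.tsv")
        write_metadata(study.metadata, out / "metadata.tsv")
        write_gas(study.gas, out / "gas.csv")
        for name in ("asv_table.tsv", "metadata.tsv", "gas.csv"):
            emit(name)
        if study.tree is not None:
            write_newick_file(study.tree, out / "tree.nwk")
            emit("tree.nwk")
        config.sim.to_yaml(out / "resolved_config.yaml")
        emit("resolved_config.yaml")
    except (CommvadeError, OSError) as exc:
        raise fail("data", exc) from exc
    logger.info("stage data: %d samples, %d ASVs", *study.table.shape)

    # --- stage: attribution ---
    try:
        origin_map = attr.attribute_origin(study.table, study.metadata)
        pd.DataFrame(
            {"asv_id": list(origin_map), "label": [v.value for v in origin_map.values()]}
        ).to_csv(out / "origins.tsv", sep="\t", index=False)
        emit("origins.tsv")
        metrics = attr.invasion_metrics_table(study.table, study.metadata, origin_map)
        metrics.to_csv(out / "invasion_metrics.tsv", sep="\t", index=False)
        emit("invasion_metrics.tsv")
        dose_tests = {}
        for response in ("invader_read_fraction", "invader_asv_fraction", "invader_asv_count"):
            r = attr.dose_effect_test(metrics, response)
            dose_tests[response] = {
                "F": r.F, "df_between": r.df_between, "df_within": r.df_within,
                "p": r.p, "group_means": r.group_means,
            }
        (out / "dose_tests.json").write_text(json.dumps(dose_tests, indent=1))
        emit("dose_tests.json")
        report["dose_tests"] = dose_tests
        if study.truth is not None:
            score = attr.score_against_truth(origin_map, study.truth)
            report["attribution_score"] = {
                "label_inversions": score.label_inversions,
                "detection_misattributions": score.detection_misattributions,
            }
    except (CommvadeError, OSError) as exc:
        raise fail("attribution", exc) from exc
    logger.info("stage attribution: %d ASVs labelled", len(origin_map))

    # --- stage: diversity ---
    try:
        if study.tree is None:
            tree = read_newick(Path(real_data) / "tree.nwk")
            write_newick_file(tree, out / "tree.nwk")
            emit("tree.nwk")
            study.tree = tree
        div.alpha_diversity_table(study.table).to_csv(
            out / "alpha_diversity.tsv", sep="\t", index=False
        )
        emit("alpha_diversity.tsv")
        groups = [study.metadata.treatment_of(s) for s in study.table.sample_ids]
        permanova_report = {}
        for metric, fname in (("unifrac-w", "unifrac_w.tsv"), ("unifrac-u", "unifrac_u.tsv")):
            dm = div.beta_diversity_matrix(study.table, study.tree, metric)
            dm.to_tsv(out / fname)
            emit(fname)
            res = div.permanova(
                dm, groups, config.n_permutations, config.permanova_seed
            )
            permanova_report[metric] = dataclasses.asdict(res)
            pw = div.pairwise_permanova(
                dm, groups, config.n_permutations, config.permanova_seed
            )
            pw_name = fname.replace(".tsv", "_pairwise.tsv")
            pw.to_csv(out / pw_name, sep="\t", index=False)
            emit(pw_name)
        (out / "permanova.json").write_text(json.dumps(permanova_report, indent=1))
        emit("permanova.json")
        report["permanova"] = permanova_report
    except (CommvadeError, OSError) as exc:
        raise fail("diversity", exc) from exc
    logger.info("stage diversity: done")

    # --- stage: screen ---
    try:
        hits = screen_mod.screen(study.table, study.metadata)
        hits.to_csv(out / "screen_hits.tsv", sep="\t", index=False)
        emit("screen_hits.tsv")
        report["screen"] = {
            "stage1": int(len(hits)),
            "stage2": int((hits["stage"] == 2).sum()) if len(hits) else 0,
        }
    except (CommvadeError, OSError) as exc:
        raise fail("screen", exc) from exc
    logger.info("stage screen: %d stage-1 hits", report["screen"]["stage1"])

    # --- stage: gas ---
    try:
        summary = gas_mod.summarize_gas(study.gas, study.metadata)
        summary.per_sample.to_csv(out / "gas_summary.tsv", sep="\t", index=False)
        emit("gas_summary.tsv")
        trend = gas_mod.dose_trend(summary)
        verdicts = {}
        for control in ("HP", "LP"):
            table = gas_mod.many_to_one(
                summary, control, config.alpha, config.dunnett_mc, config.permanova_seed
            )
            invaded = table[table["treatment"].isin(("D10", "D1", "D0.1", "D0.01"))]
            verdicts[control] = dict(
                zip(invaded["treatment"], invaded["significant"].astype(bool))
            )
            table.to_csv(out / f"dunnett_vs_{control}.tsv", sep="\t", index=False)
            emit(f"dunnett_vs_{control}.tsv")
        gas_report = {"trend": dataclasses.asdict(trend), "verdicts": verdicts}
        (out / "gas_tests.json").write_text(json.dumps(gas_report, indent=1))
        emit("gas_tests.json")
        report["gas"] = gas_report
    except (CommvadeError, OSError) as exc:
        raise fail("gas", exc) from exc
    logger.info("stage gas: done")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    (out / "run_report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
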