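"""End-to-end orchestration: simulate -> fit -> screen -> report."""

from __future__ import annotations

import dataclasses
import logging
from contextlib import contextmanager
from pathlib import Path

from . import io as kio
from .config import PipelineConfig
from .errors import KinscreenError
from .melt import fit_curves
from .screen import matrix_from_fit_table, screen_report
from .simulate import simulate_screen, wells_to_curves

logger = logging.getLogger(__name__)


@contextmanager
def _stage(name: str):
    try:
        yield
    except KinscreenError as exc:
        raise type(exc)(f"[stage {name}] {exc}") from exc


def run_pipeline(config: PipelineConfig, out_dir: Path) -> dict[str, Path]:
    """Deterministic simulated-screen run writing the five screen artifacts.

    Returns a name -> path mapping for: per-well fits, reported delta-Tm
    matrix, hit flags, per-kinase thresholds, the JSON report — plus the
    simulation's ground-truth table and a manifest carrying the config hash
    and seed (every TSV is also stamped with both).  Identical configs and
    seeds produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = config.stamp()
    paths = {
        "fits": out_dir / "fits.tsv",
        "dtm_matrix": out_dir / "dtm_matrix.tsv",
        "hits": out_dir / "hits.tsv",
        "thresholds": out_dir / "thresholds.tsv",
        "report": out_dir / "report.json",
        "ground_truth": out_dir / "ground_truth.tsv",
        "manifest": out_dir / "manifest.json",
    }

    with _stage("simulate"):
        scenario = dataclasses.replace(config.scenario, seed=config.seed)
        sim = simulate_screen(scenario)
        kio._write_text(
            paths["ground_truth"], sim.truth.to_csv(sep="\t", index=False, float_format="%.6f"), stamp
        )

    with _stage("fit"):
        logger.info("fitting %d wells", len(sim.wells))
        results = fit_curves(wells_to_curves(sim.wells, config.curve, seed=config.seed), config.fit)
        fit_table = kio.fits_to_table(results)
        kio.write_fit_table(fit_table, paths["fits"], stamp)

    with _stage("screen"):
        matrix = matrix_from_fit_table(fit_table, clamp=config.clamp, multiplier=config.multiplier)
        kio.write_dtm_matrix(matrix, paths["dtm_matrix"], stamp)
        kio.write_hits(matrix, paths["hits"], stamp)
        kio.write_thresholds(matrix, paths["thresholds"], stamp)

    with _stage("report"):
        report = screen_report(matrix)
        report["config_sha256"] = config.config_hash()
        report["seed"] = config.seed
        kio.write_report(report, paths["report"])
        kio.write_report(
            {
                "config_sha256": config.config_hash(),
                "seed": config.seed,
                "config": config.to_dict(),
                "artifacts": {k: p.name for k, p in paths.items() if k != "manifest"},
            },
            paths["manifest"],
        )
    return paths
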