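"""Batch orchestration: run the four-stage pipeline over directory pairs.

``run_batch`` mirrors the parameter-driven workflow of the original tool:
eight user-facing parameters plus backend selections, sequential per-sample
processing, a ``Results/`` folder with the quantitative CSVs and a
``Visualizations/`` folder with per-sample quality-control images. The fully
resolved configuration is serialized into the output directory before any
sample is processed so that every run is reproducible from its own echo.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import imaging
from .classify import process_sample
from .imaging import PipelineParams, PairPaths, SamplePair, load_pair
from .segment import get_instance_backend

__all__ = ["RunConfig", "BatchOutcome", "run_batch", "run_validation"]

logger = logging.getLogger("tunelquant")


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one batch run."""

    params: PipelineParams
    output_dir: Path
    profile: str = "primary"
    onl_backend: str = "classical"
    cell_backend: str = "fallback"
    save_visualizations: bool = True
    save_cell_records: bool = False
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self.params)
        d["nuclei_dir"] = str(d["nuclei_dir"])
        d["tunel_dir"] = str(d["tunel_dir"])
        return {
            "profile": self.profile,
            "onl_backend": self.onl_backend,
            "cell_backend": self.cell_backend,
            "output_dir": str(self.output_dir),
            "save_visualizations": self.save_visualizations,
            "params": d,
        }


@dataclass
class BatchOutcome:
    """Paths and per-sample outputs of a batch run."""

    results_csv: Path
    method_counts_csv: Path
    visualizations_dir: Path
    results: list
    failures: list[tuple[str, str]] = field(default_factory=list)

    @property
    def exit_code(self) -> int:
        return 3 if self.failures else 0


def run_batch(config: RunConfig) -> BatchOutcome:
    """Process every discovered pair under the given configuration.

    Samples are processed sequentially in sample_id order; a sample that
    cannot be read or processed is logged and skipped, partial results are
    preserved, and the outcome carries exit code 3.
    """
    params = config.params
    if params.nuclei_dir is None or params.tunel_dir is None:
        raise ValueError("config error: nuclei_dir and tunel_dir are required")
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(out_dir / "run.log")
    logger.addHandler(fh)

    (out_dir / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    backend = get_instance_backend(config.cell_backend)

    pairs = imaging.discover_pairs(params.nuclei_dir, params.tunel_dir)
    results, method_rows, failures = [], [], []
    for pp in pairs:
        try:
            sample = load_pair(pp, params.pixels_per_um)
            proc = process_sample(
                sample, params, cell_backend=backend, onl_backend=config.onl_backend
            )
        except Exception as exc:  # keep going; report at the end
            logger.error("sample %s failed: %s", pp.sample_id, exc)
            failures.append((pp.sample_id, str(exc)))
            continue
        results.append(proc.result)
        method_rows.append(
            {
                "sample_id": pp.sample_id,
                "combined": proc.result.tunel_count,
                "otsu_only": proc.otsu_only_count,
                "stardist_only": proc.stardist_only_count,
            }
        )
        if proc.result.tunel_count > proc.stardist_only_count:
            raise AssertionError(
                f"sample {pp.sample_id}: combined count exceeds instances-only count"
            )
        logger.info(
            "sample %s: TUNEL+=%d nuclei=%d ONL=%.1f um2 density=%.1f /mm2",
            pp.sample_id,
            proc.result.tunel_count,
            proc.result.nuclei_count,
            proc.result.onl_area_um2,
            proc.result.nuclei_density_per_mm2,
        )
        if config.save_visualizations:
            imaging.write_visualizations(sample, proc.intermediates, proc.records, out_dir)
        if config.save_cell_records:
            imaging.write_cell_records_csv(pp.sample_id, proc.records, out_dir)

    results_csv = imaging.write_results_csv(results, out_dir)
    import pandas as pd

    method_counts_csv = Path(out_dir) / "Results" / "method_counts.csv"
    pd.DataFrame(
        method_rows, columns=["sample_id", "combined", "otsu_only", "stardist_only"]
    ).to_csv(method_counts_csv, index=False)
    logger.removeHandler(fh)
    fh.close()
    return BatchOutcome(
        results_csv=results_csv,
        method_counts_csv=method_counts_csv,
        visualizations_dir=out_dir / "Visualizations",
        results=results,
        failures=failures,
    )


def run_validation(
    method_counts_csv: Path | str,
    manual_csv: Path | str,
    out_dir: Path | str,
    n_boot: int = 5000,
    seed: int = 0,
):
    """Compare pipeline and comparator counts against a manual reference.

    ``manual_csv`` needs columns ``sample_id`` and a count column (the first
    non-id numeric column is used). Writes ``agreement_report.csv`` and a
    forest plot; returns the report DataFrame.
    """
    import pandas as pd

    from .agreement import forest_plot, method_comparison

    manual_csv = Path(manual_csv)
    if not manual_csv.exists():
        raise FileNotFoundError(f"manual counts file not found: {manual_csv}")
    auto = pd.read_csv(method_counts_csv)
    manual = pd.read_csv(manual_csv)
    count_col = next(c for c in manual.columns if c != "sample_id")
    manual_map = dict(zip(manual["sample_id"].astype(str), manual[count_col]))
    methods = {
        name: dict(zip(auto["sample_id"].astype(str), auto[name]))
        for name in ("combined", "otsu_only", "stardist_only")
    }
    out_dir = Path(out_dir)
    df = method_comparison(
        manual_map,
        methods,
        n_boot=n_boot,
        seed=seed,
        out_csv=out_dir / "Results" / "agreement_report.csv",
    )
    forest_plot(df, out_dir / "Visualizations" / "agreement_forest.png")
    return df
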