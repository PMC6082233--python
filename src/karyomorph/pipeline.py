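"""End-to-end orchestration: measurements in, report bundle out.

``run_analysis`` reads a measurement table, and per population computes the
asymmetry summary, the consensus karyotype (with formula) and an idiogram,
plus a study-wide scatter table/plot.  All CSV/JSON artifacts are written
deterministically (fixed ordering, fixed float formatting), so re-running
on the same inputs reproduces them byte for byte.  ``run_simulation``
writes a synthetic measurement table from packaged (or user) templates that
``run_analysis`` can consume.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections import defaultdict
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import __version__
from .asymmetry import AsymmetrySummary, scatter_table, summarize_population
from .config import RunConfig
from .errors import ValidationError
from .karyotype import KaryotypeModel, build_idiogram, consensus_karyotype
from .measurements import MetaphasePlate, read_measurements, write_measurements
from .simulate import (
    VarietyTemplate,
    available_populations,
    packaged_template,
    simulate_population,
)

logger = logging.getLogger("karyomorph")


def group_by_population(
    plates: Sequence[MetaphasePlate],
) -> dict[str, list[MetaphasePlate]]:
    groups: dict[str, list[MetaphasePlate]] = defaultdict(list)
    for p in plates:
        groups[p.population_id].append(p)
    return dict(sorted(groups.items()))


def _karyotype_dict(model: KaryotypeModel) -> dict:
    return {
        "n_haploid": model.n_haploid,
        "diploid_number": model.diploid_number,
        "formula": model.formula,
        "pairs": [
            {
                "rank": p.rank,
                "mean_short_um": round(p.mean_short, 6),
                "mean_long_um": round(p.mean_long, 6),
                "mean_satellite_um": round(p.mean_satellite, 6),
                "satellite_arm": p.satellite_arm,
                "class": p.cls.label,
                "heteromorphic": p.heteromorphic,
            }
            for p in model.pairs
        ],
    }


def _summary_dict(s: AsymmetrySummary) -> dict:
    d = dataclasses.asdict(s)
    return {k: (round(v, 6) if isinstance(v, float) else v) for k, v in d.items()}


def _write_json(path: Path, obj: object) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")


def plot_scatter(table, path: Path) -> None:
    """M_CA (x) vs CV_CL (y) scatter; TCL encoded as point size."""
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    size = 12.0 * table["tcl_mean"] / table["tcl_mean"].max() * 10
    ax.scatter(table["m_ca_mean"], table["cv_cl_mean"], s=size, alpha=0.7,
               edgecolor="black")
    for _, row in table.iterrows():
        ax.annotate(row["population"], (row["m_ca_mean"], row["cv_cl_mean"]),
                    textcoords="offset points", xytext=(4, 4), fontsize=8)
    ax.set_xlabel("M$_{CA}$ (%)")
    ax.set_ylabel("CV$_{CL}$ (%)")
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)


def run_analysis(
    measurements: str | Path,
    config: RunConfig | None = None,
    output_dir: str | Path | None = None,
) -> dict:
    """Full analysis of a measurement file; returns the report dictionary.

    Writes, under the output directory: ``summary_<pop>.json``,
    ``karyotype_<pop>.json``, ``idiogram_<pop>.svg`` per population;
    ``summaries.csv``, ``scatter.csv``, ``scatter.svg`` and ``report.json``
    study-wide.
    """
    config = config or RunConfig()
    outdir = Path(output_dir) if output_dir is not None else Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    plates = read_measurements(measurements)
    if not plates:
        raise ValidationError(f"no plates found in {measurements}")
    groups = group_by_population(plates)
    logger.info("analyzing %d plates in %d populations", len(plates), len(groups))

    summaries: list[AsymmetrySummary] = []
    karyotypes: dict[str, KaryotypeModel] = {}
    for pop, pop_plates in groups.items():
        summary = summarize_population(pop_plates, config.satellite_in_length)
        model = consensus_karyotype(
            pop_plates,
            weight=config.pairing_weight,
            het_threshold=config.heteromorphism_threshold,
            thresholds=config.thresholds,
        )
        summaries.append(summary)
        karyotypes[pop] = model
        _write_json(outdir / f"summary_{pop}.json", _summary_dict(summary))
        _write_json(outdir / f"karyotype_{pop}.json", _karyotype_dict(model))
        (outdir / f"idiogram_{pop}.svg").write_text(
            build_idiogram(model).to_svg(), encoding="utf-8"
        )
        logger.info("population %s: 2n = %d, formula %s",
                    pop, model.diploid_number, model.formula)

    table = scatter_table(summaries)
    table.to_csv(outdir / "scatter.csv", index=False, float_format="%.6g")
    import pandas as pd

    pd.DataFrame([_summary_dict(s) for s in summaries]).to_csv(
        outdir / "summaries.csv", index=False, float_format="%.6g"
    )
    plot_scatter(table, outdir / "scatter.svg")

    report = {
        "version": __version__,
        "config": config.to_dict(),
        "n_plates": len(plates),
        "populations": {
            pop: {
                "summary": _summary_dict(s),
                "karyotype": _karyotype_dict(karyotypes[pop]),
            }
            for pop, s in zip(groups, summaries)
        },
        "distinct_formulas": sorted({m.formula for m in karyotypes.values()}),
    }
    _write_json(outdir / "report.json", report)
    return report


def run_simulation(
    template_ids: Sequence[str] | None,
    n_plates: int,
    seed: int,
    out: str | Path,
    templates: Mapping[str, VarietyTemplate] | None = None,
) -> Path:
    """Simulate populations and write one measurement CSV for ``run_analysis``.

    ``template_ids`` defaults to all packaged populations.  Each population
    gets an independent seed stream derived from ``(seed, position)``.
    """
    if templates is None:
        templates = {}
    ids = list(template_ids) if template_ids else available_populations()
    plates: list[MetaphasePlate] = []
    for k, tid in enumerate(ids):
        template = templates.get(tid)
        if template is None:
            try:
                template = packaged_template(tid)
            except KeyError as e:
                raise ValidationError(str(e)) from None
        import numpy as np

        pop_seed = int(np.random.SeedSequence((seed, k)).generate_state(1)[0])
        plates.extend(simulate_population(template, n_plates, pop_seed))
    out = Path(out)
    write_measurements(plates, out)
    logger.info("wrote %d plates (%d rows) to %s",
                len(plates), sum(len(p) for p in plates), out)
    return out
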