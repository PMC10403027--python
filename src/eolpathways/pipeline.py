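"""End-to-end pipeline stages: simulate, analyze, report.

Each stage reads and writes flat tables plus a provenance manifest
(seed, config digest, file digests), so a run is reproducible and
auditable from its outputs alone.
"""

from __future__ import annotations

import sys
import time
from pathlib import Path

import pandas as pd

from . import io
from .costing import CATEGORY_CODES
from .model import CarePathwayModel
from .simulate import generate_claims, generate_cohort, generate_pathways
from .states import SequenceSet


def _log(stage: str, message: str, t0: float) -> None:
    print(f"[{stage} +{time.perf_counter() - t0:6.1f}s] {message}", file=sys.stderr)


def run_simulate(config: io.PipelineConfig, out_dir) -> dict:
    """Generate cohort, sequences and claims tables into ``out_dir``."""
    t0 = time.perf_counter()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    cohort = generate_cohort(config.cohort)
    _log("simulate", f"cohort: {len(cohort)} patients", t0)
    files = [io.write_cohort(cohort, out_dir / "cohort.csv")]
    if len(cohort):
        sequences, truth = generate_pathways(cohort, config.archetypes)
        claims = generate_claims(cohort, sequences, config.costs)
        _log("simulate", f"claims: {len(claims)} records", t0)
        files.append(io.write_sequences(sequences, out_dir / "sequences.csv"))
        truth_frame = pd.DataFrame(
            {"patient_id": list(cohort["patient_id"]), "true_archetype": truth}
        )
    else:
        files.append(io.write_sequences(SequenceSet(), out_dir / "sequences.csv"))
        claims = pd.DataFrame(columns=["patient_id", "days_before_death",
                                       "category", "cost"])
        truth_frame = pd.DataFrame(columns=["patient_id", "true_archetype"])
    files.append(io.write_table(claims, out_dir / "claims.csv"))
    # ground truth is generator-only; analysis stages never read this file
    files.append(io.write_table(truth_frame, out_dir / "ground_truth.csv"))
    manifest = io.write_manifest(out_dir, "simulate", config, files)
    return {"manifest": manifest, "files": files}


def run_analyze(config: io.PipelineConfig, in_dir, out_dir) -> dict:
    """Run the sequence analysis and write every analysis product."""
    t0 = time.perf_counter()
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for name in ("cohort.csv", "sequences.csv", "claims.csv"):
        if not (in_dir / name).exists():
            raise FileNotFoundError(f"analyze: missing input {in_dir / name}")

    cohort = io.read_cohort(in_dir / "cohort.csv")
    sequences = io.read_sequences(in_dir / "sequences.csv")
    claims = io.read_table(in_dir / "claims.csv")
    if claims.empty:
        claims = claims.reindex(columns=["patient_id", "days_before_death",
                                         "category", "cost"])
    model = CarePathwayModel(sequences, cohort, claims,
                             cost_scheme=config.cost_scheme(),
                             ward_variant=config.ward_variant)
    res = model.fit(k=config.k, k_min=config.k_min, k_max=config.k_max,
                    k_default=config.k_default, sample_size=config.sample_size,
                    seed=io._derive_seed(config.seed, 3))
    _log("analyze", f"typology: k={res.k} over {len(res.sample)} sequences", t0)

    files = [
        io.write_dissimilarity(res.dissimilarity, out_dir / "dissimilarity.csv"),
        io.write_table(res.tree.to_frame(), out_dir / "tree.csv"),
        io.write_table(res.typology.to_frame(), out_dir / "typology.csv"),
        io.write_table(res.chronograms().to_frame(), out_dir / "chronogram.csv"),
        io.write_table(res.cluster_profile(), out_dir / "cluster_profile.csv"),
        io.write_table(res.cluster_costs().reset_index(), out_dir / "cluster_costs.csv"),
        io.write_table(res.cost_table().table.rename_axis("category").reset_index(),
                       out_dir / "cost_table_12m.csv"),
        io.write_table(
            res.cost_table(config.short_window).table.rename_axis("category").reset_index(),
            out_dir / "cost_table_3m.csv"),
        io.write_table(res.characteristics(), out_dir / "characteristics.csv"),
        io.write_table(res.palliative(), out_dir / "palliative.csv"),
        io.write_table(res.place_of_death().rename("proportion")
                       .rename_axis("place").reset_index(),
                       out_dir / "place_of_death.csv"),
    ]
    summary = pd.DataFrame([{
        "n_sequences": len(res.sample),
        "k": res.k,
        "window_share": res.window_share(config.short_window),
        "top_decile_count": res.top_decile().count,
        "top_decile_threshold": res.top_decile().threshold,
        "top_decile_share": res.top_decile().share,
    }])
    files.append(io.write_table(summary, out_dir / "analysis_summary.csv"))
    try:
        assoc = res.association()
        files.append(io.write_table(assoc.rename_axis("feature").reset_index(),
                                    out_dir / "association.csv"))
    except ValueError as exc:
        _log("analyze", f"association model skipped: {exc}", t0)
    _log("analyze", "all outputs written", t0)
    io.write_manifest(out_dir, "analyze", config, files)
    return {"results": res, "files": files}


def run_report(in_dir, out_dir) -> dict:
    """Render display tables (rounded euros / one-decimal percentages)."""
    t0 = time.perf_counter()
    in_dir, out_dir = Path(in_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    needed = ["typology.csv", "cost_table_12m.csv", "characteristics.csv",
              "cluster_costs.csv", "chronogram.csv"]
    for name in needed:
        if not (in_dir / name).exists():
            raise FileNotFoundError(f"report: missing analysis output {in_dir / name}")
    typology = io.read_table(in_dir / "typology.csv")
    if typology.empty:
        raise ValueError("report: typology is empty")

    files = []
    chars = io.read_table(in_dir / "characteristics.csv")
    chars["pct"] = chars["pct"].round(1)
    files.append(io.write_table(chars, out_dir / "table1_characteristics.csv"))

    for src, dst in (("cost_table_12m.csv", "table2a_service_costs_12m.csv"),
                     ("cost_table_3m.csv", "table2b_service_costs_3m.csv")):
        if not (in_dir / src).exists():
            continue
        t = io.read_table(in_dir / src).set_index("category")
        assert list(t.index) == CATEGORY_CODES + ["total"]
        for col in ("mean", "sd", "median", "iqr"):
            t[col] = t[col].round(0).astype(int)
        for col in ("pct_users", "pct_of_total"):
            t[col] = t[col].round(1)
        files.append(io.write_table(t.reset_index(), out_dir / dst))

    costs = io.read_table(in_dir / "cluster_costs.csv")
    for col in ("mean", "sd", "median", "iqr"):
        costs[col] = costs[col].round(0).astype(int)
    files.append(io.write_table(costs, out_dir / "table2c_cluster_costs.csv"))
    files.append(io.write_table(io.read_table(in_dir / "chronogram.csv"),
                                out_dir / "chronogram_plot_data.csv"))
    _log("report", "display tables rendered", t0)
    return {"files": files}
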