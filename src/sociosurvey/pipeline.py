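"""End-to-end study pipeline: simulate → ingest → score → analyze → report.

Every step is a thin composition of library operations, and the whole run
is deterministic for a fixed seed: artifacts written twice with the same
seed are byte-identical.  All outputs land under one user-chosen directory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .exports import export_gexf, export_graphml
from .instruments import load_bundled_instrument
from .networks import OneModeNetwork, build_one_mode, extract_ties
from .reports import group_report, individual_report
from .responses import ResponseSet, read_responses, score_all, scored_records_to_frame
from .sna import attach_metrics, group_summary
from .synthetic import (
    CohortSpec,
    StudyBundle,
    cohort_to_frame,
    responses_to_class_frames,
    simulate_study,
)

__all__ = ["PipelineResult", "run_pipeline", "write_simulated_study"]

#: How many individual reports a default pipeline run renders (the lowest
#: person ids, for determinism); pass ``report_persons`` to override.
DEFAULT_N_INDIVIDUAL_REPORTS = 5


@dataclass(frozen=True)
class PipelineResult:
    outdir: Path
    bundle: StudyBundle
    response_set: ResponseSet
    network: OneModeNetwork
    artifacts: tuple[str, ...]


def write_simulated_study(bundle: StudyBundle, outdir: str | Path) -> list[Path]:
    """Write the simulated study as the CSV dialects the ingestion layer
    reads: one roster file and one response file per classroom."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    roster_path = outdir / "roster.csv"
    cohort_to_frame(bundle.cohort).to_csv(roster_path, index=False)
    written.append(roster_path)
    for class_id, frame in responses_to_class_frames(bundle).items():
        p = outdir / f"responses_{class_id}.csv"
        frame.to_csv(p, index=False)
        written.append(p)
    return written


def run_pipeline(
    seed: int,
    outdir: str | Path,
    spec: CohortSpec | None = None,
    report_persons: list[str] | None = None,
    n_reports: int = DEFAULT_N_INDIVIDUAL_REPORTS,
) -> PipelineResult:
    """Run the full study pipeline and write all artifacts under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec or CohortSpec()
    audit = load_bundled_instrument("audit")
    bundle = simulate_study(spec, seed=seed, instruments=[audit])
    data_dir = outdir / "data"
    written = write_simulated_study(bundle, data_dir)

    # ingest the per-class CSVs back through the reading layer
    questionnaire = bundle.questionnaire
    response_files = sorted(p for p in data_dir.glob("responses_*.csv"))
    rs = read_responses(response_files, questionnaire)

    # score
    records = score_all(rs, questionnaire, missing_policy="omit")
    scores_frame = scored_records_to_frame(records)
    scores_path = outdir / "scores.csv"
    scores_frame.to_csv(scores_path, index=False)
    written.append(scores_path)

    # network with score-bearing node attributes
    template = questionnaire.template("friend")
    ties = extract_ties(rs, template, questionnaire)
    attributes = {
        rec.person_id: {
            "audit_total": rec.instrument_scores[0].total,
            "audit_band": rec.instrument_scores[0].band_label,
        }
        for rec in records
    }
    net = build_one_mode(ties, bundle.cohort.study_roster, attributes,
                         relation_label=template.relation_label, wave=rs.wave)

    # analyze
    table, partition = attach_metrics(net, seed=seed)
    centrality_path = outdir / "centrality.csv"
    centrality = table.table.copy()
    centrality["community"] = centrality["node"].map(partition.labels)
    centrality.to_csv(centrality_path, index=False, float_format="%.10g")
    written.append(centrality_path)
    summary = group_summary(net, score_attr="audit_total", seed=seed)
    summary_path = outdir / "group_summary.json"
    summary_path.write_text(json.dumps(summary.to_dict(), indent=1, sort_keys=True) + "\n",
                            encoding="utf-8")
    written.append(summary_path)

    # reports
    reports_dir = outdir / "reports"
    reports_dir.mkdir(exist_ok=True)
    persons = report_persons or [p.id for p in bundle.cohort.persons[:n_reports]]
    for pid in persons:
        doc = individual_report(pid, records, net, table, partition, instrument=audit)
        path = reports_dir / f"individual_{pid}.md"
        path.write_text(doc.render(), encoding="utf-8")
        written.append(path)
    score_columns = {"audit": scores_frame.set_index("person_id")["audit_total"].astype(float)}
    gdoc = group_report(net, summary, partition, score_columns=score_columns)
    gpath = reports_dir / "group.md"
    gpath.write_text(gdoc.render(), encoding="utf-8")
    written.append(gpath)

    # exports
    written.append(export_gexf(net, outdir / "network.gexf"))
    written.append(export_graphml(net, outdir / "network.graphml"))

    rel = tuple(sorted(str(Path(p).relative_to(outdir)) for p in written))
    (outdir / "manifest.json").write_text(
        json.dumps({"seed": seed, "artifacts": list(rel)}, indent=1) + "\n", encoding="utf-8"
    )
    return PipelineResult(outdir=outdir, bundle=bundle, response_set=rs, network=net,
                          artifacts=rel)
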