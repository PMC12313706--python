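"""Orchestrate the full comparative analysis over one or more genomes.

``run_comparative`` chains partitioning -> CDS assembly/filtering -> codon
usage -> diagnostics -> (optional) sliding-window diversity -> pairwise Ka/Ks
and returns a :class:`ComparativeReport` of pandas tables. Written output is
deterministic: stable sort orders and fixed float formatting (GC to 1 decimal,
pi to 4, ENC and rates to 4).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import __version__
from .codon_usage import assemble_cds, filter_cds, gene_cub_metrics, codon_counts, metrics_table, rscu
from .diagnostics import enc_gc3s_analysis, neutrality_regression, pr2_analysis
from .diversity import (
    AlignmentMatrix,
    column_to_position_map,
    diversity_summary,
    label_windows,
    sliding_windows,
)
from .io import PlastomeRecord, read_fasta, read_genbank
from .quadripartite import REGIONS, detect_inverted_repeats, junction_report, region_statistics
from .selection import kaks_scan


class PipelineError(RuntimeError):
    """A stage failure, naming the stage and the offending input."""


@dataclass
class ComparativeReport:
    genome_summary: pd.DataFrame
    junctions: pd.DataFrame
    cub_metrics: pd.DataFrame
    rscu: pd.DataFrame
    neutrality: pd.DataFrame
    enc_gc3s_summary: pd.DataFrame
    pr2_quadrants: pd.DataFrame
    pi_windows: pd.DataFrame | None
    kaks: pd.DataFrame
    provenance: dict = field(default_factory=dict)


def _stage(name: str, subject: str):
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed for {subject!r}: {exc}") from exc
            return False

    return _Ctx()


def run_comparative(
    genomes: Sequence[str | Path | PlastomeRecord],
    alignment_path: str | Path | None = None,
    config: dict | None = None,
    out_dir: str | Path | None = None,
) -> ComparativeReport:
    """Run every stage over >= 1 annotated genomes; no genome is silently
    dropped — any stage failure aborts, naming the stage and input."""
    cfg = {
        "min_ir_len": 1000,
        "min_cds_len": 300,
        "start_policy": "table11",
        "window": 600,
        "step": 200,
        "neutral_band": (0.95, 1.05),
        "pi_reference": None,
    }
    cfg.update(config or {})

    records: list[PlastomeRecord] = []
    for g in genomes:
        if isinstance(g, PlastomeRecord):
            records.append(g)
        else:
            with _stage("read_genbank", str(g)):
                records.extend(read_genbank(g))
    if not records:
        raise PipelineError("stage 'read_genbank' failed: no genomes supplied")
    records.sort(key=lambda r: r.identifier)

    summary_rows, junction_rows = [], []
    metrics_frames, rscu_rows, neutrality_rows = [], [], []
    enc_rows, pr2_rows = [], []
    filtered: dict[str, list] = {}

    for rec in records:
        with _stage("partition", rec.identifier):
            part = detect_inverted_repeats(rec.sequence, min_len=cfg["min_ir_len"])
            row = {
                "genome": rec.identifier,
                "organism": rec.organism,
                "length_bp": len(rec.sequence),
                "n_cds": len(rec.features_of_kind("CDS")),
            }
            if part is not None:
                lengths, gc = region_statistics(rec, part)
                row["ir_length_bp"] = part.ir_length
                for region in REGIONS:
                    row[f"{region.lower()}_len"] = lengths[region]
                    row[f"{region.lower()}_gc_pct"] = gc[region]
                for jr in junction_report(rec, part):
                    junction_rows.append(
                        {
                            "genome": rec.identifier,
                            "junction": jr.junction,
                            "gene": jr.gene_name,
                            "relation": jr.relation,
                            "overlap_bp": jr.overlap_bp,
                            "distance_bp": jr.distance_bp,
                        }
                    )
            summary_rows.append(row)

        with _stage("cds_filter", rec.identifier):
            result = filter_cds(
                assemble_cds(rec),
                min_len=cfg["min_cds_len"],
                start_policy=cfg["start_policy"],
            )
            filtered[rec.identifier] = result.retained
            summary_rows[-1]["n_cds_retained"] = len(result.retained)

        with _stage("codon_usage", rec.identifier):
            metrics = [gene_cub_metrics(c) for c in result.retained]
            frame = metrics_table(metrics)
            frame.insert(0, "genome", rec.identifier)
            metrics_frames.append(frame)
            pooled = codon_counts(result.retained, pool=True)
            for codon, value in sorted(rscu(pooled).rscu.items()):
                rscu_rows.append(
                    {"genome": rec.identifier, "codon": codon, "rscu": value}
                )

        with _stage("diagnostics", rec.identifier):
            _, enc_summary = enc_gc3s_analysis(metrics)
            enc_rows.append({"genome": rec.identifier, **enc_summary})
            _, quadrants = pr2_analysis(metrics)
            pr2_rows.append({"genome": rec.identifier, **quadrants})
            if len(metrics) >= 3:
                fit = neutrality_regression(metrics)
                neutrality_rows.append(
                    {
                        "genome": rec.identifier,
                        "slope": fit.slope,
                        "intercept": fit.intercept,
                        "pearson_r": fit.pearson_r,
                        "p_value": fit.p_value,
                        "n_genes": fit.n_genes,
                        "mutation_share_pct": fit.mutation_share,
                    }
                )

    pi_frame = None
    if alignment_path is not None:
        with _stage("diversity", str(alignment_path)):
            seqs = read_fasta(alignment_path)
            aln = AlignmentMatrix([s for s, _ in seqs], [q for _, q in seqs])
            windows = sliding_windows(aln, window=cfg["window"], step=cfg["step"])
            ref_label = cfg["pi_reference"] or aln.labels[0]
            ref = next((r for r in records if r.identifier == ref_label), None)
            if ref is not None:
                windows = label_windows(
                    windows, ref, column_to_position_map(aln, ref_label)
                )
            pi_frame = pd.DataFrame(
                [
                    {
                        "start": w.start,
                        "end": w.end,
                        "midpoint": w.midpoint,
                        "usable_sites": w.usable_sites,
                        "pi": w.pi,
                        "label": w.label or "",
                    }
                    for w in windows
                ]
            )

    kaks_rows = []
    ids = [r.identifier for r in records]
    for i, id_a in enumerate(ids):
        for id_b in ids[i + 1 :]:
            with _stage("kaks", f"{id_a} vs {id_b}"):
                for result, klass in kaks_scan(
                    filtered[id_a], filtered[id_b], neutral_band=cfg["neutral_band"]
                ):
                    kaks_rows.append(
                        {
                            "gene": result.gene_name,
                            "pair": f"{id_a}|{id_b}",
                            "N": result.N,
                            "S": result.S,
                            "Nd": result.Nd,
                            "Sd": result.Sd,
                            "Ka": result.Ka,
                            "Ks": result.Ks,
                            "omega": result.omega,
                            "class": klass,
                        }
                    )

    report = ComparativeReport(
        genome_summary=pd.DataFrame(summary_rows).sort_values("genome", ignore_index=True),
        junctions=pd.DataFrame(junction_rows),
        cub_metrics=(
            pd.concat(metrics_frames, ignore_index=True)
            .sort_values(["genome", "gene_name"], ignore_index=True)
            if metrics_frames
            else pd.DataFrame()
        ),
        rscu=pd.DataFrame(rscu_rows),
        neutrality=pd.DataFrame(neutrality_rows),
        enc_gc3s_summary=pd.DataFrame(enc_rows),
        pr2_quadrants=pd.DataFrame(pr2_rows),
        pi_windows=pi_frame,
        kaks=pd.DataFrame(kaks_rows).sort_values(["pair", "gene"], ignore_index=True)
        if kaks_rows
        else pd.DataFrame(),
        provenance={
            "tool": "plastocub",
            "version": __version__,
            "genomes": ids,
            "alignment": str(alignment_path) if alignment_path else None,
            "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in cfg.items()},
        },
    )
    if out_dir is not None:
        write_report(report, out_dir)
    return report


_FORMATS = {
    "pi": "{:.4f}", "Ka": "{:.4f}", "Ks": "{:.4f}", "omega": "{:.4f}",
    "enc": "{:.4f}", "rscu": "{:.4f}", "slope": "{:.4f}", "intercept": "{:.4f}",
    "pearson_r": "{:.4f}", "p_value": "{:.4g}", "mutation_share_pct": "{:.2f}",
    "N": "{:.2f}", "S": "{:.2f}", "Nd": "{:.2f}", "Sd": "{:.2f}",
}


def _format_frame(frame: pd.DataFrame) -> pd.DataFrame:
    out = frame.copy()
    for col in out.columns:
        if col.endswith("_gc_pct"):
            out[col] = out[col].map(lambda v: f"{v:.1f}")
        elif col in _FORMATS:
            fmt = _FORMATS[col]
            out[col] = out[col].map(lambda v: fmt.format(v))
        elif out[col].dtype.kind == "f":
            out[col] = out[col].map(lambda v: f"{v:.4f}")
    return out


def write_report(report: ComparativeReport, out_dir: str | Path) -> None:
    """TSV/JSON bundle with deterministic ordering and float formatting."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "genome_summary": report.genome_summary,
        "junctions": report.junctions,
        "cub_metrics": report.cub_metrics,
        "rscu": report.rscu,
        "neutrality": report.neutrality,
        "enc_gc3s_summary": report.enc_gc3s_summary,
        "pr2_quadrants": report.pr2_quadrants,
        "kaks": report.kaks,
    }
    if report.pi_windows is not None:
        tables["pi_windows"] = report.pi_windows
    for name, frame in tables.items():
        if frame is None or frame.empty:
            (out / f"{name}.tsv").write_text("")
            continue
        _format_frame(frame).to_csv(out / f"{name}.tsv", sep="\t", index=False)
    (out / "provenance.json").write_text(
        json.dumps(report.provenance, indent=2, sort_keys=True) + "\n"
    )
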