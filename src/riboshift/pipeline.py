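"""End-to-end pipeline: annotation -> quant -> diffexpr -> utrgroups -> uorf
-> enrichment, with tabular outputs, a machine-readable summary and a short
human-readable report.  Also houses the 2^-ddCt qPCR utility.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import annotation, diffexpr, enrichment, quant, uorf, utrgroups
from .annotation import TranscriptIndex, canonical_transcripts
from .io import read_alignments

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "ddct"]


class PipelineError(RuntimeError):
    pass


def ddct(
    ct_target_treat: float,
    ct_ref_treat: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference) under treatment minus the same
    difference under control; the result is 2 ** (-ddCt).
    """
    for v in (ct_target_treat, ct_ref_treat, ct_target_ctrl, ct_ref_ctrl):
        if not np.isfinite(v):
            raise ValueError("Ct values must be finite")
    dd = (ct_target_treat - ct_ref_treat) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-dd))


@dataclass
class PipelineConfig:
    """Paths, sample sheet and per-stage parameters for one pipeline run.

    The sample sheet maps each (sample_id, library) to an alignment file;
    conditions must include exactly one designated control.
    """

    annotation_path: str
    fasta_path: str | None
    sample_sheet: pd.DataFrame  # sample_id, condition, replicate, library, path
    control_condition: str
    treatment_condition: str
    gene_sets_path: str | None = None
    annotation_format: str | None = None
    psite_offsets: dict[int, int] = field(default_factory=dict)
    default_psite_offset: int = quant.DEFAULT_PSITE_OFFSET
    min_read_length: int = quant.DEFAULT_MIN_READ_LENGTH
    te_floor: float = 1.0
    log2fc_threshold: float = 1.0
    diff_pseudocount: float = 0.5
    shift_pseudocount: float = 1.0
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sheet = pd.DataFrame(raw.pop("samples"))
        offsets = {int(k): int(v) for k, v in raw.pop("psite_offsets", {}).items()}
        return cls(sample_sheet=sheet, psite_offsets=offsets, **raw)

    def validate(self) -> None:
        required = {"sample_id", "condition", "replicate", "library", "path"}
        missing = required - set(self.sample_sheet.columns)
        if missing:
            raise PipelineError(f"sample sheet missing columns: {sorted(missing)}")
        for p in self.sample_sheet["path"]:
            if not Path(p).exists():
                raise PipelineError(f"alignment file not found: {p}")
        conds = set(self.sample_sheet["condition"])
        for c in (self.control_condition, self.treatment_condition):
            if c not in conds:
                raise PipelineError(f"condition {c!r} absent from the sample sheet")
        if not Path(self.annotation_path).exists():
            raise PipelineError(f"annotation file not found: {self.annotation_path}")


def _condition_region_counts(
    reads_by_sample: Mapping[str, pd.DataFrame],
    sample_condition: Mapping[str, str],
    condition: str,
    txs: TranscriptIndex,
    cfg: PipelineConfig,
) -> pd.DataFrame:
    """RPF region counts summed over the replicates of one condition."""
    total = None
    for sample, df in reads_by_sample.items():
        if sample_condition[sample] != condition:
            continue
        rc = quant.region_counts(
            quant.filter_reads(df, cfg.min_read_length),
            txs,
            cfg.psite_offsets,
            cfg.default_psite_offset,
        ).set_index("transcript_id")
        total = rc if total is None else total + rc
    if total is None:
        raise PipelineError(f"no RPF samples for condition {condition!r}")
    return total.reset_index()


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage, writing tables, summary.json and report.txt.

    On stage failure a FAILED marker naming the stage is left in the
    output directory and the error re-raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "config"
    try:
        cfg.validate()

        stage = "annotation"
        models = annotation.read_annotation(cfg.annotation_path, cfg.annotation_format)
        if cfg.fasta_path:
            models = annotation.attach_sequences(models, cfg.fasta_path)
        canon = sorted(
            canonical_transcripts(models).values(), key=lambda m: m.gene_id
        )
        txs = TranscriptIndex(canon)

        stage = "quant"
        sheet = cfg.sample_sheet
        rpf_reads, rna_reads = {}, {}
        for _, row in sheet.iterrows():
            df = read_alignments(row["path"])
            (rpf_reads if row["library"] == "rpf" else rna_reads)[row["sample_id"]] = df
        sample_condition = dict(
            sheet.drop_duplicates("sample_id")[["sample_id", "condition"]].itertuples(
                index=False, name=None
            )
        )
        gq = quant.gene_quant(
            canon,
            rpf_reads,
            rna_reads,
            offsets=cfg.psite_offsets,
            default_offset=cfg.default_psite_offset,
            te_floor=cfg.te_floor,
            min_read_length=cfg.min_read_length,
        )
        gq.to_csv(outdir / "gene_quant.tsv", sep="\t", index=False)

        rc_ctrl = _condition_region_counts(
            rpf_reads, sample_condition, cfg.control_condition, txs, cfg
        )
        rc_treat = _condition_region_counts(
            rpf_reads, sample_condition, cfg.treatment_condition, txs, cfg
        )
        rc_ctrl.to_csv(outdir / "region_counts_control.tsv", sep="\t", index=False)
        rc_treat.to_csv(outdir / "region_counts_treatment.tsv", sep="\t", index=False)

        qc = {}
        all_rpf = pd.concat(list(rpf_reads.values()), ignore_index=True)
        all_rpf = quant.filter_reads(all_rpf, cfg.min_read_length)
        try:
            qc["region_pct"] = quant.region_distribution(
                all_rpf, txs, cfg.psite_offsets, cfg.default_psite_offset
            )
            frames = quant.frame_distribution(
                all_rpf, txs, cfg.psite_offsets, cfg.default_psite_offset
            )
            qc["frame_pct"] = {str(k): v for k, v in frames.items()}
        except quant.NoUsableReadsError:
            qc["region_pct"] = None
            qc["frame_pct"] = None

        stage = "diffexpr"
        calls = {}
        for level in diffexpr.LEVELS:
            c = diffexpr.classify(
                gq,
                sample_condition,
                level,
                cfg.control_condition,
                cfg.treatment_condition,
                theta=cfg.log2fc_threshold,
                floor=cfg.te_floor,
                pseudocount=cfg.diff_pseudocount,
            )
            c.to_csv(outdir / f"diffcalls_{level}.tsv", sep="\t", index=False)
            calls[level] = c

        stage = "utrgroups"
        idx_change = utrgroups.utr5_index_change(rc_ctrl, rc_treat)
        te_calls = calls["te"].set_index("gene_id")
        tx2gene = pd.Series(txs.gene_id, index=txs.ids)
        idx_change["gene_id"] = idx_change["transcript_id"].map(tx2gene)
        idx_change["te_class"] = idx_change["gene_id"].map(te_calls["class"])
        idx_change["delta_te"] = idx_change["gene_id"].map(te_calls["log2fc"])

        idx_ctrl = utrgroups.utr5_index(rc_ctrl)
        split = utrgroups.split_high_low(idx_ctrl)
        idx_change = idx_change.merge(
            split[["transcript_id", "group"]], on="transcript_id", how="left"
        )
        idx_change.to_csv(outdir / "utr5_index.tsv", sep="\t", index=False)

        anova_groups = {
            cls: idx_change.loc[idx_change["te_class"] == cls, "delta_utr5_index"]
            .dropna()
            .to_numpy()
            for cls in ("up", "unchanged", "down")
        }
        anova_groups = {k: v for k, v in anova_groups.items() if v.size >= 2}
        tests = {}
        if len(anova_groups) >= 2:
            res = utrgroups.compare_groups(anova_groups, test="anova")
            tests["delta_utr5_index_by_te_class_anova"] = dataclasses.asdict(res)
        dte_groups = {
            g: idx_change.loc[idx_change["group"] == g, "delta_te"].dropna().to_numpy()
            for g in ("high_UTR", "low_UTR")
        }
        if all(v.size >= 2 for v in dte_groups.values()):
            res = utrgroups.compare_groups(dte_groups, test="t_test")
            tests["delta_te_high_vs_low_utr_t_test"] = dataclasses.asdict(res)

        stage = "uorf"
        uorf_rows = []
        if cfg.fasta_path:
            for m in canon:
                if m.sequence is None or m.cds_start == 0:
                    continue
                for u in uorf.find_uorfs(m):
                    uorf_rows.append(
                        (
                            u.transcript_id,
                            u.uaug_pos,
                            -1 if u.stop_pos is None else u.stop_pos,
                            -1 if u.length is None else u.length,
                            u.overlaps_cds,
                            u.kozak,
                            u.cap_distance,
                        )
                    )
        uorf_df = pd.DataFrame(
            uorf_rows,
            columns=[
                "transcript_id", "uaug_pos", "stop_pos", "length",
                "overlaps_cds", "kozak", "cap_distance",
            ],
        )
        uorf_df.to_csv(outdir / "uorfs.tsv", sep="\t", index=False)
        shifts = uorf.shift_table(rc_ctrl, rc_treat, cfg.shift_pseudocount)
        shifts.to_csv(outdir / "shift_scores.tsv", sep="\t", index=False)

        stage = "enrichment"
        enrich_df = None
        if cfg.gene_sets_path:
            sets = enrichment.read_gmt(cfg.gene_sets_path)
            universe = (
                calls["te"].loc[calls["te"]["passed_floor"], "gene_id"].tolist()
            )
            up = calls["te"].loc[calls["te"]["class"] == "up", "gene_id"].tolist()
            down = calls["te"].loc[calls["te"]["class"] == "down", "gene_id"].tolist()
            frames = []
            for name, query in (("up", up), ("down", down)):
                if not query:
                    continue
                r = enrichment.ora(query, sets, universe)
                r.insert(0, "query", name)
                frames.append(r)
            if frames:
                enrich_df = pd.concat(frames, ignore_index=True)
                enrich_df.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

        stage = "summary"
        summary = {
            "n_transcripts": len(models),
            "n_genes": len(canon),
            "samples": sorted(sample_condition),
            "qc": qc,
            "diff_counts": {
                level: diffexpr.summary_counts(calls[level]) for level in calls
            },
            "utr_group_tests": tests,
            "n_utr5_index_transcripts": int(len(idx_change)),
            "n_uorfs": int(len(uorf_df)),
            "n_shift_scored": int(len(shifts)),
            "n_enriched_sets": 0 if enrich_df is None else int(len(enrich_df)),
            "seed": cfg.seed,
        }
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        _write_report(summary, outdir / "report.txt")
        return summary
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage={stage}\n{exc}\n")
        logger.error("pipeline failed at stage %s: %s", stage, exc)
        raise


def _write_report(summary: dict, path: Path) -> None:
    lines = [
        "riboshift pipeline report",
        "=========================",
        f"transcripts: {summary['n_transcripts']}  genes: {summary['n_genes']}",
        f"samples: {', '.join(summary['samples'])}",
        "",
    ]
    qc = summary["qc"]
    if qc.get("region_pct"):
        r = qc["region_pct"]
        lines.append(
            f"RPF region occupancy: 5'UTR {r['utr5']:.1f}%  CDS {r['cds']:.1f}%  "
            f"3'UTR {r['utr3']:.1f}%"
        )
    if qc.get("frame_pct"):
        f = qc["frame_pct"]
        lines.append(
            f"CDS P-site frames: 0 -> {f['0']:.1f}%  1 -> {f['1']:.1f}%  "
            f"2 -> {f['2']:.1f}%"
        )
    lines.append("")
    for level, counts in summary["diff_counts"].items():
        lines.append(
            f"{level}: up {counts['up']}, down {counts['down']}, "
            f"unchanged {counts['unchanged']}, not assessed {counts['not_assessed']}"
        )
    lines.append("")
    for name, t in summary["utr_group_tests"].items():
        lines.append(
            f"{name}: statistic={t['statistic']:.4g} p={t['pvalue']:.3g} "
            f"(groups {t['group_sizes']})"
        )
    lines.append("")
    lines.append(f"uORFs detected: {summary['n_uorfs']}")
    lines.append(f"transcripts with shift scores: {summary['n_shift_scored']}")
    path.write_text("\n".join(lines) + "\n")
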