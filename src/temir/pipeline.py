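"""End-to-end orchestration: classify -> scan -> phylo/gainloss -> alutest.

A single :class:`RunConfig` (loadable from YAML) names every input and holds
the analysis thresholds, whose defaults are the study parameters: 50%
precursor / 100% mature overlap, seed positions 2-8, 110-nt excision window,
+-5 bp junction flank, 1,000 bootstrap replicates.  Every stage writes a TSV
plus a JSON summary (counts, parameters, seed, input hashes); re-running
with unchanged inputs skips stages whose outputs are already up to date.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alu_recomb import link_table, run_alu_test
from .genome_io import (
    read_fasta,
    read_interval_table,
    read_newick,
    read_score_track,
)
from .paralog_scan import ScanConfig, scan_paralogs
from .phylo import (
    Alignment,
    bootstrap_support,
    dollo_gain_loss,
    nj_tree,
    k2p_matrix,
    p_distance,
    read_presence_table,
)
from .repeat_overlap import (
    classify_repeat_derived,
    distinct_loci,
    intersect_with_segdups,
    mean_conservation,
)

log = logging.getLogger("temir")

__all__ = ["RunConfig", "StageError", "run_pipeline", "classify_table"]


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    """Inputs, stage toggles and thresholds for a full run."""

    # inputs (paths; stages without their inputs are skipped unless toggled on)
    mirna: str | None = None
    repeats: str | None = None
    segdups: str | None = None
    conservation: str | None = None
    genome: str | None = None
    mature: str = "UUGGGACAUACUUAUGCUAAA"
    est: str | None = None
    exons: str | None = None
    alignment: str | None = None
    tree: str | None = None
    presence: str | None = None
    alus: str | None = None

    # stage toggles (None = auto: run when the inputs are present)
    stages: dict = field(default_factory=dict)

    # thresholds (defaults are the study parameters)
    precursor_overlap_pct: float = 50.0
    mature_overlap_pct: float = 100.0
    scan_window: int = 110
    junction_flank: int = 5
    bootstrap_reps: int = 1000
    distance_model: str = "p"
    internal_families: tuple[str, ...] = (
        "AluSp", "AluJo", "AluYc", "AluJr", "AluSx"
    )
    est_policy: str = "strict"
    ortholog_counts_as: str = "absent"
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "internal_families" in data:
            data["internal_families"] = tuple(data["internal_families"])
        return cls(**data)


def _hash_files(paths: list[str | Path]) -> str:
    h = hashlib.sha256()
    for p in paths:
        h.update(str(p).encode())
        h.update(Path(p).read_bytes())
    return h.hexdigest()


def _stage_fresh(summary_path: Path, outputs: list[Path], input_hash: str) -> bool:
    if not summary_path.exists() or not all(o.exists() for o in outputs):
        return False
    try:
        prev = json.loads(summary_path.read_text())
    except json.JSONDecodeError:
        return False
    return prev.get("input_hash") == input_hash


def classify_table(
    mirnas, repeats, segdups=None, track=None
) -> pd.DataFrame:
    """Table-1-style classification table for a set of miRNA loci."""
    rows = []
    for mirna in mirnas:
        rec = classify_repeat_derived(mirna, None, repeats)
        rows.append(
            {
                "coordinate": mirna.to_string(),
                "name": mirna.name,
                "repeats": ";".join(
                    f"{r.interval.to_string()}:{r.family}"
                    for r, _ in rec.contributors
                ),
                "families": ";".join(
                    sorted({r.family for r, _ in rec.contributors})
                ),
                "percent": float(rec.percent),
                "derived": bool(rec.derived_call),
                "mean_score": (
                    mean_conservation(mirna, track) if track is not None
                    else float("nan")
                ),
            }
        )
    df = pd.DataFrame(rows)
    if segdups is not None:
        in_sd = {
            (pre.chrom, pre.start, pre.end)
            for pre in distinct_loci(intersect_with_segdups(mirnas, segdups))
        }
        df["in_segdup"] = [
            (m.chrom, m.start, m.end) in in_sd for m in mirnas
        ]
    return df


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute the enabled stages in order and return the run report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "seed": cfg.rng_seed, "stages": {}}

    def want(stage: str, *inputs) -> bool:
        toggle = cfg.stages.get(stage)
        if toggle is False:
            return False
        have = all(p is not None for p in inputs)
        if toggle is True and not have:
            missing = [n for n, p in zip(["input"] * len(inputs), inputs) if p is None]
            raise StageError(stage, f"required input missing ({len(missing)})")
        return have

    def run_stage(stage: str, inputs: list, outputs: list[Path], fn) -> None:
        summary_path = outdir / f"{stage}.summary.json"
        input_hash = _hash_files(inputs)
        if _stage_fresh(summary_path, outputs, input_hash):
            log.info("stage %s up to date; skipping", stage)
            report["stages"][stage] = json.loads(summary_path.read_text())
            return
        try:
            counts = fn()
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, str(exc)) from exc
        summary = {
            "stage": stage,
            "counts": counts,
            "seed": cfg.rng_seed,
            "version": __version__,
            "input_hash": input_hash,
        }
        summary_path.write_text(json.dumps(summary, indent=1, sort_keys=True))
        report["stages"][stage] = summary
        log.info("stage %s: %s", stage, counts)

    # --- classify -----------------------------------------------------
    if want("classify", cfg.mirna, cfg.repeats):
        def do_classify() -> dict:
            mirnas = read_interval_table(cfg.mirna, kind="mirna")
            repeats = read_interval_table(cfg.repeats, kind="repeat")
            segdups = (
                read_interval_table(cfg.segdups, kind="segdup")
                if cfg.segdups else None
            )
            track = (
                read_score_track(cfg.conservation)
                if cfg.conservation else None
            )
            df = classify_table(mirnas, repeats, segdups, track)
            df.to_csv(outdir / "classify.tsv", sep="\t", index=False)
            counts = {
                "mirnas": len(mirnas),
                "derived": int(df["derived"].sum()),
            }
            if segdups is not None:
                counts["in_segdup_loci"] = int(
                    len(distinct_loci(intersect_with_segdups(mirnas, segdups)))
                )
            return counts

        inputs = [cfg.mirna, cfg.repeats]
        inputs += [p for p in (cfg.segdups, cfg.conservation) if p]
        run_stage("classify", inputs, [outdir / "classify.tsv"], do_classify)

    # --- scan ---------------------------------------------------------
    if want("scan", cfg.genome, cfg.repeats):
        def do_scan() -> dict:
            genome = read_fasta(cfg.genome)
            elements = read_interval_table(cfg.repeats, kind="repeat")
            ests = (
                read_interval_table(cfg.est, kind="est") if cfg.est else None
            )
            if ests is None and cfg.est_policy == "strict":
                raise StageError(
                    "scan", f"EST track required in strict mode ({cfg.est!r})"
                )
            exons = (
                read_interval_table(cfg.exons, kind="exon")
                if cfg.exons else None
            )
            scan_cfg = ScanConfig(window=cfg.scan_window,
                                  est_policy=cfg.est_policy)
            cands = scan_paralogs(
                genome, elements, cfg.mature, ests, exons, scan_cfg
            )
            pd.DataFrame(
                [
                    {
                        "coordinate": c.interval.to_string(),
                        "arm": c.arm,
                        "hairpin_ok": c.hairpin.accepted,
                        "hairpin_reasons": ",".join(c.hairpin.reasons),
                        "transcribed": c.transcribed,
                        "exonic": c.exonic,
                        "final_call": c.final_call,
                    }
                    for c in cands
                ]
            ).to_csv(outdir / "scan.tsv", sep="\t", index=False)
            return {
                "elements": len(elements),
                "candidates": len(cands),
                "final": sum(c.final_call for c in cands),
            }

        inputs = [cfg.genome, cfg.repeats]
        inputs += [p for p in (cfg.est, cfg.exons) if p]
        run_stage("scan", inputs, [outdir / "scan.tsv"], do_scan)

    # --- phylo --------------------------------------------------------
    if want("phylo", cfg.alignment):
        def do_phylo() -> dict:
            records = read_fasta(cfg.alignment)
            aln = Alignment(labels=[r.id for r in records],
                            rows=[r.seq for r in records])
            if cfg.bootstrap_reps > 0:
                boot = bootstrap_support(
                    aln, n_reps=cfg.bootstrap_reps, rng_seed=cfg.rng_seed
                )
                (outdir / "phylo.nwk").write_text(boot.annotated_newick())
                mean_support = (
                    sum(boot.support.values()) / len(boot.support)
                    if boot.support else 100.0
                )
                return {"taxa": len(aln.labels),
                        "mean_support": round(mean_support, 2)}
            dm = (p_distance(aln) if cfg.distance_model == "p"
                  else k2p_matrix(aln))
            tree = nj_tree(dm)
            (outdir / "phylo.nwk").write_text(
                tree.as_string(schema="newick", suppress_rooting=True)
            )
            return {"taxa": len(aln.labels)}

        run_stage("phylo", [cfg.alignment], [outdir / "phylo.nwk"], do_phylo)

    # --- gainloss -----------------------------------------------------
    if want("gainloss", cfg.tree, cfg.presence):
        def do_gainloss() -> dict:
            tree = read_newick(cfg.tree, rooted=True)
            pm = read_presence_table(
                cfg.presence, tree, ortholog_counts_as=cfg.ortholog_counts_as
            )
            rec = dollo_gain_loss(pm)
            rows = []
            for gene in pm.genes:
                gain = rec.gains[gene]
                rows.append(
                    {
                        "gene": gene,
                        "gain_branch": "+".join(gain) if gain else "",
                        "n_losses": len(rec.losses[gene]),
                        "loss_branches": ";".join(
                            "+".join(b) for b in rec.losses[gene]
                        ),
                    }
                )
            pd.DataFrame(rows).to_csv(
                outdir / "gainloss.tsv", sep="\t", index=False
            )
            return {"genes": len(pm.genes), "gains": rec.total_gains,
                    "losses": rec.total_losses}

        run_stage("gainloss", [cfg.tree, cfg.presence],
                  [outdir / "gainloss.tsv"], do_gainloss)

    # --- alutest ------------------------------------------------------
    if want("alutest", cfg.segdups, cfg.alus, cfg.genome):
        def do_alutest() -> dict:
            segdups = read_interval_table(cfg.segdups, kind="segdup")
            alus = [
                a for a in read_interval_table(cfg.alus, kind="repeat")
                if a.family.startswith("Alu")
            ]
            genome = read_fasta(cfg.genome)
            result = run_alu_test(
                segdups, alus, genome, cfg.internal_families
            )
            result.divergences.to_csv(
                outdir / "alutest.tsv", sep="\t", index=False
            )
            link_table(segdups).to_csv(
                outdir / "links.tsv", sep="\t", index=False
            )
            return {
                "pairs": len(segdups),
                "internal_H": round(result.internal.H, 4),
                "internal_df": result.internal.df,
                "internal_p": round(result.internal.p, 6),
                "combined_H": round(result.combined.H, 4),
                "combined_df": result.combined.df,
                "combined_p": round(result.combined.p, 6),
            }

        run_stage("alutest", [cfg.segdups, cfg.alus, cfg.genome],
                  [outdir / "alutest.tsv", outdir / "links.tsv"], do_alutest)

    (outdir / "report.json").write_text(
        json.dumps(report, indent=1, sort_keys=True)
    )
    return report
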