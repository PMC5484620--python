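"""End-to-end orchestration: simulate -> parse -> quantify -> call ->
annotate -> sequence stats -> enrichment, under one config and one seed.

Every output is a text table (TSV/BED/FASTA/SAM/JSON); the run manifest
records the seed, the parameters and a SHA-256 checksum of every output
file, so a repeated run with the same config and seed is byte-identical
and verifiably so.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import annotate_metagene as am
from . import enrichment as en
from . import expression as ex
from . import seqstats as ss
from . import sitecall as sc
from . import synthetic_data as syn
from .alignment_io import read_sam, write_sam
from .model import (
    CATEGORIES,
    UTR3,
    UTR5,
    TranscriptModel,
    load_transcripts,
    write_categories,
    write_fasta,
    write_region_gff,
    write_region_tsv,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One reproducible run: inputs (simulated or on disk) plus parameters."""

    outdir: str | Path = "larpclip_run"
    seed: int = 7
    condition: str = "both"  # mTOR_on | mTOR_off | both
    simulate: dict[str, Any] | None = field(default_factory=dict)
    # external-input mode (used when simulate is None)
    transcriptome: str | None = None
    regions: str | None = None
    parclip_sams: dict[str, str] = field(default_factory=dict)
    mrnaseq_sams: dict[str, list[str]] = field(default_factory=dict)
    go_annotation: str | None = None
    te_table: str | None = None
    supercategories: str | None = None
    caller: sc.CallerParams = field(default_factory=sc.CallerParams)
    n_bins: int = 100
    motif_run_k: int = 6
    site_extend: int = 15
    top_min_run: int = 4
    positional_window: int = 25

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "caller" in raw and isinstance(raw["caller"], dict):
            raw["caller"] = sc.CallerParams(**raw["caller"])
        return cls(**raw)

    def conditions(self) -> list[str]:
        if self.condition == "both":
            return list(syn.CONDITIONS)
        if self.condition not in syn.CONDITIONS:
            raise ValueError(f"condition must be one of {syn.CONDITIONS} or 'both'")
        return [self.condition]

    def validate(self) -> None:
        self.conditions()
        if self.simulate is None:
            for name in ("transcriptome", "regions"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ValueError(f"config path missing or absent: {name}={p}")
            for cond in self.conditions():
                if cond not in self.parclip_sams:
                    raise ValueError(f"no PAR-CLIP SAM configured for {cond}")
                if not Path(self.parclip_sams[cond]).exists():
                    raise ValueError(f"missing file: {self.parclip_sams[cond]}")
                for p in self.mrnaseq_sams.get(cond, []):
                    if not Path(p).exists():
                        raise ValueError(f"missing file: {p}")
        else:
            spec = self.sim_spec("mTOR_off")
            spec.validate()

    def sim_spec(self, condition: str) -> syn.SimulationSpec:
        over = dict(self.simulate or {})
        over.setdefault("seed", self.seed)
        over["condition"] = condition
        return syn.SimulationSpec(**over)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineError(RuntimeError):
    pass


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run every stage in order; returns in-memory results plus manifest.

    A stage failure aborts with the stage name; outputs written by earlier
    stages are preserved in the run directory.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logging.getLogger("larpclip").addHandler(handler)

    results: dict[str, Any] = {"outdir": outdir, "seed": config.seed}
    stage = "setup"
    try:
        # --- simulate / load inputs -----------------------------------
        stage = "simulate"
        conds = config.conditions()
        if config.simulate is not None:
            spec0 = config.sim_spec(conds[0])
            transcripts, truth = syn.generate_transcriptome(spec0)
            write_fasta(outdir / "transcripts.fa", transcripts)
            write_region_gff(outdir / "regions.gff", transcripts)
            write_region_tsv(outdir / "regions.tsv", transcripts)
            write_categories(outdir / "categories.tsv", transcripts)
            syn.write_truth_bed(outdir / "truth.bed", truth)
            syn.write_truth_tsv(outdir / "truth.tsv", truth)
            go_ann = syn.synthetic_go_annotation(transcripts, spec0)
            syn.write_go_annotation(outdir / "go_annotation.tsv", go_ann)
            te = syn.synthetic_te_table(transcripts, spec0)
            syn.write_te_table(outdir / "te_table.tsv", te)
            ref_lens = {t.transcript_id: t.length for t in transcripts}
            parclip_paths: dict[str, Path] = {}
            mrnaseq_paths: dict[str, list[Path]] = {}
            for cond in conds:
                spec = config.sim_spec(cond)
                recs = syn.simulate_parclip(transcripts, truth, spec)
                p = outdir / f"parclip_{cond}.sam"
                write_sam(p, recs, ref_lens)
                parclip_paths[cond] = p
                libs = syn.simulate_mrnaseq(transcripts, truth, spec)
                mrnaseq_paths[cond] = []
                for i, lib in enumerate(libs, start=1):
                    mp = outdir / f"mrnaseq_{cond}_rep{i}.sam"
                    write_sam(mp, lib, ref_lens)
                    mrnaseq_paths[cond].append(mp)
            results["truth"] = truth
        else:
            transcripts = load_transcripts(config.transcriptome, config.regions)
            parclip_paths = {c: Path(config.parclip_sams[c]) for c in conds}
            mrnaseq_paths = {
                c: [Path(p) for p in config.mrnaseq_sams.get(c, [])] for c in conds
            }
            go_ann = (
                en.read_annotation(config.go_annotation)
                if config.go_annotation
                else None
            )
            te = en.read_te_table(config.te_table) if config.te_table else None
        results["transcripts"] = transcripts
        refs = {t.transcript_id: t.seq for t in transcripts}
        lens = {t.transcript_id: t.length for t in transcripts}
        categories = {t.gene_id: t.category for t in transcripts}

        # --- quantify ---------------------------------------------------
        stage = "quantify"
        expression: dict[str, Any] = {}
        for cond in conds:
            if not mrnaseq_paths.get(cond):
                expression[cond] = None
                continue
            df = ex.expression_table(transcripts, mrnaseq_paths[cond])
            ex.write_expression_tsv(outdir / f"expression_{cond}.tsv", df)
            expression[cond] = df
        results["expression"] = expression

        # --- call sites -------------------------------------------------
        stage = "callsites"
        sites_by_cond: dict[str, list[sc.BindingSite]] = {}
        for cond in conds:
            reads = read_sam(parclip_paths[cond], refs, library_id=cond)
            total = sum(r.weight for r in reads)
            expr_map = (
                ex.rpkm_map(expression[cond]) if expression.get(cond) is not None else None
            )
            sites = sc.call_sites(
                sc.group_reads_by_transcript(reads),
                total,
                expr_map,
                config.caller,
                condition=cond,
                transcript_lengths=lens,
            )
            am.annotate_sites(sites, transcripts)
            sc.write_sites_bed(outdir / f"sites_{cond}.bed", sites)
            sc.write_sites_tsv(outdir / f"sites_{cond}.tsv", sites)
            sites_by_cond[cond] = sites
        results["sites"] = sites_by_cond

        # --- annotate / metagene -----------------------------------------
        stage = "annotate"
        all_sites = [s for cond in conds for s in sites_by_cond[cond]]
        coverage = am.region_coverage_table(all_sites, transcripts, categories)
        am.write_coverage_tsv(outdir / "region_coverage.tsv", coverage)
        results["coverage_table"] = coverage
        profiles = {}
        for cond in conds:
            for cat in CATEGORIES:
                prof = am.metagene_profile(
                    sites_by_cond[cond], transcripts, cat,
                    n_bins=config.n_bins, condition=cond,
                )
                am.write_profile_tsv(outdir / f"metagene_{cat}_{cond}.tsv", prof)
                profiles[(cat, cond)] = prof
        results["profiles"] = profiles

        # --- sequence statistics ----------------------------------------
        stage = "seqstats"
        tests: dict[str, ss.CompositionTest] = {}
        runs_summary: dict[str, tuple[float, int]] = {}
        for cond in conds:
            sites = sites_by_cond[cond]
            for scope in (UTR5, UTR3):
                try:
                    tests[f"bound_vs_unbound_{scope}_{cond}"] = (
                        ss.bound_vs_unbound_composition(sites, transcripts, scope)
                    )
                except ValueError as exc:
                    logger.info("composition test skipped (%s, %s): %s", scope, cond, exc)
            runs_summary[cond] = ss.summarize_runs(
                sites, transcripts, k=config.motif_run_k,
                extend=config.site_extend, region=UTR5,
            )
            ss.write_site_fasta(
                outdir / f"sites_utr5_ext_{cond}.fa", sites, transcripts,
                extend=config.site_extend, region=UTR5,
            )
        top_calls = ss.classify_top(transcripts, min_run=config.top_min_run)
        with open(outdir / "top_calls.tsv", "w") as fh:
            fh.write(f"# min_run={config.top_min_run} (cap C + pyrimidine run)\n")
            fh.write("transcript_id\tis_top\ttop_run_length\n")
            for c in top_calls:
                fh.write(f"{c.transcript_id}\t{c.is_top}\t{c.top_run_length}\n")
        top_ov = {
            cond: ss.top_overlap(sites_by_cond[cond], top_calls) for cond in conds
        }
        # positional profile: RP vs non-TR 5'UTRs
        rp_u5 = [t.region_seq(UTR5) for t in transcripts if t.category == "RP"]
        nt_u5 = [t.region_seq(UTR5) for t in transcripts if t.category == "non_TR"]
        positional = None
        if len(rp_u5) >= 2 and len(nt_u5) >= 2:
            try:
                positional = ss.positional_pyrimidine_profile(
                    rp_u5, nt_u5, window=config.positional_window
                )
                tests.update(
                    {
                        "positional_5p_RP_vs_nonTR": positional["five_prime"],
                        "positional_3p_RP_vs_nonTR": positional["three_prime"],
                    }
                )
            except ValueError as exc:
                logger.info("positional profile skipped: %s", exc)
        ss.write_test_tsv(
            outdir / "composition_tests.tsv",
            tests,
            header_note=f"seed={config.seed}",
        )
        results["tests"] = tests
        results["runs_summary"] = runs_summary
        results["top_overlap"] = top_ov
        results["top_calls"] = top_calls

        # --- enrichment --------------------------------------------------
        stage = "enrich"
        enrich_results = {}
        te_tabs = {}
        if go_ann:
            gene_of = {t.transcript_id: t.gene_id for t in transcripts}
            supercats = en.read_supercategories(config.supercategories)
            for cond in conds:
                if expression.get(cond) is not None:
                    dfx = expression[cond]
                    background = set(dfx.loc[dfx["expressed"], "gene_id"])
                else:
                    background = set(gene_of.values())
                bound = {
                    gene_of[s.transcript_id] for s in sites_by_cond[cond]
                } & background
                res = en.fisher_enrichment(bound, background, go_ann)
                en.group_supercategories(res, supercats)
                en.write_enrichment_tsv(outdir / f"enrichment_{cond}.tsv", res)
                enrich_results[cond] = res
                if te:
                    tab = en.te_cross_tab(te, bound)
                    tab.to_csv(
                        outdir / f"te_crosstab_{cond}.tsv", sep="\t",
                        index=False, float_format="%.6g",
                    )
                    te_tabs[cond] = tab
        results["enrichment"] = enrich_results
        results["te_crosstab"] = te_tabs

        # --- manifest -----------------------------------------------------
        stage = "manifest"
        handler.flush()
        files = sorted(
            p for p in outdir.iterdir()
            if p.is_file() and p.name not in {"manifest.json", "run.log"}
        )
        manifest = {
            "seed": config.seed,
            "condition": config.condition,
            "caller": dataclasses.asdict(config.caller),
            "outputs": {p.name: _sha256(p) for p in files},
            "concordance": {
                cond: {
                    f"{a}|{b}": [r, r2]
                    for (a, b), (r, r2) in df.attrs["concordance"].items()
                }
                for cond, df in expression.items()
                if df is not None
            },
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        results["manifest"] = manifest
    except Exception as exc:
        raise PipelineError(f"stage '{stage}' failed: {exc}") from exc
    finally:
        logging.getLogger("larpclip").removeHandler(handler)
        handler.close()
    return results
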