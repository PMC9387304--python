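"""End-to-end orchestration: simulate -> filter -> TMB/sharing ->
neoantigen -> signatures -> repertoire -> survival.

``run_pipeline`` writes every input in its documented external format,
reads it back through the io layer (so stage outputs are identical to
what the stage CLIs would produce on the same files), executes the
stages in dependency order, and emits a set of report tables plus a
:class:`RunManifest` with per-stage row counts and output checksums.
Partial failures stop downstream dependents only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import immune_expression as ie
from . import io_formats as io
from . import neoantigen as neo
from . import repertoire as rep
from . import survival as surv
from . import variant_filtering as vf
from .synthetic_cohort import CohortConfig, SyntheticCohort, evaluate_recovery, simulate_cohort

logger = logging.getLogger(__name__)

REPORT_TABLES = (
    "tmb_per_sample.tsv",
    "tmb_comparison.tsv",
    "pair_sharing.tsv",
    "binder_counts.tsv",
    "binder_comparison.tsv",
    "signature_scores.tsv",
    "signature_comparison.tsv",
    "repertoire_summary.tsv",
    "repertoire_comparison.tsv",
    "cox_forest.tsv",
)


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: dict[str, str] = field(default_factory=dict)  # stage -> ok/failed/skipped
    row_counts: dict[str, int] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    notes: dict[str, str] = field(default_factory=dict)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True) + "\n")


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_config(path: str | Path) -> CohortConfig:
    """Build a CohortConfig from a YAML file (flat keys; unknown keys error)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(CohortConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return CohortConfig(**raw)


def write_cohort_inputs(cohort: SyntheticCohort, outdir: Path) -> None:
    """Write every pipeline input in its documented external format."""
    inputs = outdir / "inputs"
    (inputs / "vcf").mkdir(parents=True, exist_ok=True)
    for sample, calls in sorted(cohort.matched_calls.items()):
        for caller in io.CALLERS:
            sub = [c for c in calls if c.caller == caller]
            io.write_caller_vcf(sub, inputs / "vcf" / f"{sample}.{caller}.vcf")
    for sample, calls in sorted(cohort.tumor_only_calls.items()):
        io.write_caller_vcf(calls, inputs / "vcf" / f"{sample}.mutect2.vcf")
    io.write_expression_matrix(cohort.counts, inputs / "counts.tsv")
    io.write_gmt(cohort.signatures, inputs / "signatures.gmt")
    io.write_clonotypes(cohort.clonotypes, inputs / "clonotypes.tsv")
    io.write_clinical(cohort.clinical, inputs / "clinical.csv")
    cohort.samples.to_csv(inputs / "samples.tsv", sep="\t", index=False)
    pd.Series(cohort.coding_reads, name="coding_reads").rename_axis("sample_id").to_csv(
        inputs / "qc_metrics.tsv", sep="\t"
    )


def run_pipeline(config: CohortConfig, outdir: str | Path) -> RunManifest:
    """Run the full analysis on a simulated cohort; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dataclasses.asdict(config), seed=config.seed)
    # caller_params dataclasses are not JSON-serializable as-is
    manifest.config["caller_params"] = {
        k: dataclasses.asdict(v) for k, v in config.caller_params.items()
    }

    cohort = simulate_cohort(config)
    write_cohort_inputs(cohort, outdir)
    manifest.stages["simulate"] = "ok"
    site_of = cohort.site_of

    # --- variant filtering (read back from the written VCFs) -------------
    consensus: dict[str, vf.ConsensusVariantSet] = {}
    try:
        vcf_dir = outdir / "inputs" / "vcf"
        for sample in sorted(cohort.matched_calls):
            calls = []
            for caller in io.CALLERS:
                calls.extend(
                    io.read_caller_calls(vcf_dir / f"{sample}.{caller}.vcf", caller, sample)
                )
            consensus[sample] = vf.filter_matched(calls)
        for sample in sorted(cohort.tumor_only_calls):
            calls = io.read_caller_calls(vcf_dir / f"{sample}.mutect2.vcf", "mutect2", sample)
            consensus[sample] = vf.filter_tumor_only(calls)
        pd.concat([c.to_frame() for c in consensus.values()]).to_csv(
            outdir / "consensus_variants.tsv", sep="\t", index=False
        )
        manifest.stages["filter"] = "ok"
        manifest.row_counts["consensus_variants"] = sum(len(c) for c in consensus.values())
    except Exception as exc:  # pragma: no cover - defensive
        logger.exception("variant filtering failed")
        manifest.stages["filter"] = f"failed: {exc}"

    # --- TMB and sharing ---------------------------------------------------
    if manifest.stages.get("filter") == "ok":
        tmb_rows = []
        for sample, cvs in sorted(consensus.items()):
            r = vf.compute_tmb(cvs, config.covered_mb)
            tmb_rows.append(
                {
                    "sample_id": sample,
                    "site": site_of[sample],
                    "n_variants": r.n_variants,
                    "covered_mb": r.covered_mb,
                    "tmb": r.tmb,
                }
            )
        tmb_df = pd.DataFrame(tmb_rows)
        tmb_df.to_csv(outdir / "tmb_per_sample.tsv", sep="\t", index=False)

        brm = tmb_df.loc[tmb_df["site"] == "brm", "tmb"].to_numpy()
        pri = tmb_df.loc[tmb_df["site"] == "primary", "tmb"].to_numpy()
        pd.DataFrame(
            [
                {
                    "median_tmb_brm": float(np.median(brm)),
                    "median_tmb_primary": float(np.median(pri)),
                    "n_brm": len(brm),
                    "n_primary": len(pri),
                    "wilcoxon_p": ie.wilcoxon_rank_sum(brm, pri),
                }
            ]
        ).to_csv(outdir / "tmb_comparison.tsv", sep="\t", index=False)

        share_rows = []
        by_patient = cohort.samples.groupby("patient_id")
        for pid, grp in by_patient:
            if len(grp) == 2:
                a, b = sorted(grp["sample_id"])
                if a in consensus and b in consensus:
                    s = vf.pair_sharing(consensus[b], consensus[a], patient_id=pid)
                    share_rows.append(dataclasses.asdict(s))
        pd.DataFrame(
            share_rows,
            columns=[
                "patient_id", "n_shared", "n_only_a", "n_only_b",
                "jaccard", "fraction_shared_of_a", "fraction_shared_of_b",
            ],
        ).to_csv(outdir / "pair_sharing.tsv", sep="\t", index=False)
        manifest.stages["tmb_sharing"] = "ok"
    else:
        manifest.stages["tmb_sharing"] = "skipped"

    # --- expression: QC, normalization, replicates ------------------------
    norm = None
    try:
        counts = io.read_expression_matrix(outdir / "inputs" / "counts.tsv")
        keep = ie.qc_filter_samples(cohort.coding_reads)
        counts = counts[[c for c in counts.columns if c in keep]]
        norm = ie.upper_quartile_normalize(counts)
        rep_map = {
            bio: [c for c in group if c in norm.samples]
            for bio, group in cohort.replicate_map.items()
        }
        rep_map = {b: g for b, g in rep_map.items() if g}
        norm = ie.average_technical_replicates(norm, rep_map)
        manifest.stages["expression"] = "ok"
        manifest.row_counts["expression_samples"] = len(norm.samples)
    except Exception as exc:
        logger.exception("expression stage failed")
        manifest.stages["expression"] = f"failed: {exc}"

    # --- neoantigen --------------------------------------------------------
    if manifest.stages.get("filter") == "ok":
        binder_results = []
        for sample, cvs in sorted(consensus.items()):
            confirmed = neo.rna_confirm_variants(cvs, cohort.rna_support.get(sample, {}))
            candidates: list[neo.PeptideCandidate] = []
            for key in sorted(confirmed.keys):
                ctx = cohort.variant_context.get(sample, {}).get(key)
                if ctx is None:
                    continue
                source_id = f"{key[0]}:{key[1]}:{key[2]}>{key[3]}"
                if ctx[0] == "snv":
                    _, protein, position, alt_aa = ctx
                    candidates.extend(
                        neo.enumerate_snv_peptides(
                            protein, position, alt_aa,
                            sample_id=sample, source_id=source_id,
                        )
                    )
                else:
                    _, cds, position, ref, alt = ctx
                    candidates.extend(
                        neo.enumerate_frameshift_peptides(
                            cds, (position, ref, alt),
                            sample_id=sample, source_id=source_id,
                        )
                    )
            if norm is not None and sample in norm.samples:
                expressed = neo.call_expressed_antigens(
                    norm.values[[sample]], cohort.antigen_classes, threshold=1.0
                )
                for gene, cls in sorted(
                    expressed.set_index("gene")["source_class"].items()
                ):
                    protein = _antigen_protein(gene)
                    candidates.extend(
                        neo.enumerate_self_peptides(
                            protein, lengths=(9,), sample_id=sample,
                            source_id=gene, source_class=cls,
                        )
                    )
            if not candidates:
                binder_results.append(neo.BinderCounts(sample_id=sample, counts={}))
                continue
            source_map = {c.peptide: c.source_class for c in candidates}
            preds = neo.predict_candidates(candidates, cohort.alleles[sample])
            binder_results.append(
                neo.classify_binders(preds, source_map, sample_id=sample)
            )
        binder_df = neo.binder_counts_frame(binder_results)
        binder_df["site"] = binder_df["sample_id"].map(site_of)
        binder_df.to_csv(outdir / "binder_counts.tsv", sep="\t", index=False)

        cmp_rows = []
        for cls in neo.SOURCE_CLASSES:
            sub = binder_df[binder_df["source_class"] == cls]
            a = sub.loc[sub["site"] == "brm", "n_positive"].to_numpy(dtype=float)
            b = sub.loc[sub["site"] == "primary", "n_positive"].to_numpy(dtype=float)
            if len(a) == 0 or len(b) == 0 or (a.sum() == 0 and b.sum() == 0):
                continue
            cmp_rows.append(
                {
                    "source_class": cls,
                    "median_brm": float(np.median(a)),
                    "median_primary": float(np.median(b)),
                    "wilcoxon_p": ie.wilcoxon_rank_sum(a, b),
                }
            )
        pd.DataFrame(
            cmp_rows, columns=["source_class", "median_brm", "median_primary", "wilcoxon_p"]
        ).to_csv(outdir / "binder_comparison.tsv", sep="\t", index=False)
        manifest.stages["neoantigen"] = "ok"
    else:
        manifest.stages["neoantigen"] = "skipped"

    # --- immune signatures -------------------------------------------------
    sig_results = None
    score_table = None
    if manifest.stages.get("expression") == "ok":
        signatures = io.read_gmt(outdir / "inputs" / "signatures.gmt")
        score_table = ie.score_signatures(norm, signatures)
        score_table.scores.rename_axis("signature").to_csv(
            outdir / "signature_scores.tsv", sep="\t"
        )
        labels = {s: ("A" if site_of.get(s) == "brm" else "B") for s in norm.samples}
        sig_results = ie.compare_signature_groups(score_table, labels)
        ie.comparison_frame(sig_results).to_csv(
            outdir / "signature_comparison.tsv", sep="\t", index=False
        )
        manifest.stages["signatures"] = "ok"
    else:
        manifest.stages["signatures"] = "skipped"

    # --- repertoire ---------------------------------------------------------
    try:
        clono = io.read_clonotypes(outdir / "inputs" / "clonotypes.tsv")
        summaries = rep.summarize_all(clono)
        rep.summary_frame(summaries).to_csv(
            outdir / "repertoire_summary.tsv", sep="\t", index=False
        )
        labels = {s: ("A" if site == "brm" else "B") for s, site in site_of.items()}
        rep_results = []
        for metric in ("total_reads", "entropy", "entropy_corrected"):
            rep_results.extend(rep.compare_repertoire_groups(summaries, labels, metric))
        rep.comparison_frame(rep_results).to_csv(
            outdir / "repertoire_comparison.tsv", sep="\t", index=False
        )
        manifest.stages["repertoire"] = "ok"
    except Exception as exc:
        logger.exception("repertoire stage failed")
        manifest.stages["repertoire"] = f"failed: {exc}"

    # --- survival ------------------------------------------------------------
    if manifest.stages.get("signatures") == "ok":
        clinical = io.read_clinical(outdir / "inputs" / "clinical.csv")
        sample_to_patient = dict(
            zip(cohort.samples["sample_id"], cohort.samples["patient_id"])
        )
        forest_frames = []
        for origin in surv.ORIGINS:
            forest = surv.signature_forest(
                clinical,
                score_table.scores,
                origin,
                sample_to_patient=sample_to_patient,
                penalizer=0.1,
            )
            forest_frames.append(forest)
        pd.concat(forest_frames, ignore_index=True).to_csv(
            outdir / "cox_forest.tsv", sep="\t", index=False
        )
        manifest.stages["survival"] = "ok"
    else:
        manifest.stages["survival"] = "skipped"

    # --- recovery report and manifest ---------------------------------------
    report = evaluate_recovery(
        {
            "seed": config.seed,
            "consensus": consensus,
            "signature_results": sig_results,
        },
        cohort.truth,
    )
    (outdir / "recovery_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )

    for name in REPORT_TABLES + ("recovery_report.json", "consensus_variants.tsv"):
        p = outdir / name
        if p.exists():
            manifest.outputs[name] = _checksum(p)
    manifest.write(outdir / "manifest.json")
    return manifest


def _antigen_protein(gene: str) -> str:
    """Deterministic 21-mer protein for an expressed antigen feature."""
    rng = np.random.default_rng(
        int(hashlib.sha256(gene.encode()).hexdigest()[:8], 16)
    )
    aas = list(io.AMINO_ACIDS)
    return "".join(rng.choice(aas, size=21))
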