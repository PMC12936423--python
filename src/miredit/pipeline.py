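"""Pipeline configuration and stage orchestration.

Stages: simulate → preprocess → align → detect-editing → de → associate →
retarget → qpcr.  Each stage writes a TSV (floats at 6 significant
digits) and logs its input/output record counts; a manifest JSON lists
every artifact with a sha256 checksum, so seeded reruns can be verified
byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import align as al
from . import clinical as cl
from . import editing as ed
from . import expression as ex
from . import preprocess as pp
from . import qpcr as qp
from . import retarget as rt
from . import simulate as sim

log = logging.getLogger("miredit")

__all__ = ["PipelineConfig", "validate_config", "run_pipeline"]


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    # simulation
    n_tumour: int = Field(default=60, ge=1)
    n_control: int = Field(default=48, ge=0)
    reads_per_sample: int = Field(default=4000, ge=100)
    n_genes: int = Field(default=400, ge=10)
    de_fraction: float = Field(default=0.08, ge=0.0, le=1.0)
    de_effect: float = Field(default=2.0, gt=0.0)
    per_base_error: float = Field(default=0.001, ge=0.0, le=0.05)
    # preprocessing
    adapter: str = sim.DEFAULT_ADAPTER
    adapter_max_mismatch_rate: float = Field(default=0.1, ge=0.0, le=0.5)
    min_mean_quality: float = Field(default=20.0, ge=0.0)
    min_insert_len: int = Field(default=16, ge=1)
    max_insert_len: int = Field(default=28, ge=1)
    # detection
    alpha: float = Field(default=0.05, gt=0.0, lt=1.0)
    p0_policy: Literal["quality", "fixed"] = "quality"
    p0_fixed: float = Field(default=0.001, gt=0.0, lt=1.0)
    min_rpm: float = Field(default=1.0, ge=0.0)
    # differential expression
    de_fdr_max: float = Field(default=0.05, gt=0.0, lt=1.0)
    de_lfc_min: float = Field(default=1.0, gt=0.0)
    # retargeting
    edited_mirna: str = "hsa-miR-200b-3p"
    edit_position: int = Field(default=5, ge=1)
    site_types: list[Literal["7mer-m8", "7mer-A1", "8mer"]] = ["7mer-m8", "8mer"]


class _UniqueKeyLoader(yaml.SafeLoader):
    pass


def _no_duplicates(loader, node, deep=False):
    seen = set()
    for key_node, _ in node.value:
        key = loader.construct_object(key_node, deep=deep)
        if key in seen:
            raise ValueError(f"duplicate configuration key: {key!r}")
        seen.add(key)
    return loader.construct_mapping(node, deep)


_UniqueKeyLoader.add_constructor(
    yaml.resolver.BaseResolver.DEFAULT_MAPPING_TAG, _no_duplicates
)


def validate_config(text: str) -> PipelineConfig:
    """Parse and range-check a YAML configuration; empty text yields all
    documented defaults."""
    raw = yaml.load(text, Loader=_UniqueKeyLoader) if text.strip() else {}
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ValueError("configuration must be a mapping")
    cfg = PipelineConfig(**raw)
    log.info("configuration: %s", cfg.model_dump())
    return cfg


def load_config(path: str | Path | None) -> PipelineConfig:
    if path is None:
        return PipelineConfig()
    return validate_config(Path(path).read_text())


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage on a freshly simulated bundle and return the
    manifest (also written to ``manifest.json``)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    log.info("stage simulate: seed=%d", config.seed)
    bundle = sim.simulate_bundle(
        outdir / "inputs",
        seed=config.seed,
        n_tumour=config.n_tumour,
        n_control=config.n_control,
        reads_per_sample=config.reads_per_sample,
        n_genes=config.n_genes,
        de_fraction=config.de_fraction,
        de_effect=config.de_effect,
        per_base_error=config.per_base_error,
    )
    artifacts["truth"] = bundle.truth_path

    if not Path(bundle.reference).exists():  # defensive; simulate just wrote it
        raise RuntimeError("stage align: reference FASTA missing")
    refs = al.load_reference(bundle.reference, al.load_blacklist(bundle.blacklist))
    refs_by_id = {r.id: r for r in refs}

    clin = cl.read_clinical(bundle.clinical)
    groups = dict(zip(clin["sample"], clin["group"]))

    per_sample_sites: dict[str, list[ed.EditSiteStat]] = {}
    n_reads_in = n_mapped = 0
    for sample, fastq in bundle.reads.items():
        collapsed = pp.process_fastq(
            fastq,
            config.adapter,
            config.adapter_max_mismatch_rate,
            min_mean_quality=config.min_mean_quality,
            min_len=config.min_insert_len,
            max_len=config.max_insert_len,
        )
        n_reads_in += sum(r.count for r in collapsed)
        assignments = al.map_sample(collapsed, refs)
        library = al.quantify(assignments, sample)
        n_mapped += int(library.total_mapped)
        per_sample_sites[sample] = ed.detect_sample(
            assignments,
            library,
            refs,
            alpha=config.alpha,
            p0_policy=config.p0_policy,
            p0_fixed=config.p0_fixed,
            min_rpm=config.min_rpm,
        )
    log.info(
        "stage preprocess+align: %d kept reads, %d uniquely mapped", n_reads_in, n_mapped
    )

    editing_table = ed.build_editing_table(per_sample_sites, groups)
    path = outdir / "editing_table.tsv"
    _write_tsv(editing_table, path)
    artifacts["editing_table"] = path
    log.info("stage detect-editing: %d called sites", len(editing_table))

    counts = pd.read_csv(bundle.counts, sep="\t", index_col=0)
    cgroups = pd.read_csv(
        Path(bundle.counts).parent / "counts_groups.tsv", sep="\t", index_col=0
    )["group"]
    cm = ex.CountMatrix(counts, cgroups)
    cm = ex.filter_low_counts(cm, mode="gene", require="any")
    logmat = ex.log_cpm(cm)
    de = ex.moderated_de(logmat, cm.groups)
    path = outdir / "de_table.tsv"
    _write_tsv(de, path)
    artifacts["de_table"] = path
    n_sig = int(((de.fdr <= config.de_fdr_max) & (de.log2fc.abs() >= config.de_lfc_min)).sum())
    log.info("stage de: %d features tested, %d significant", len(de), n_sig)

    # association of the edited site with outcome
    site_key = f"{config.edited_mirna}"
    lvl_rows = editing_table[
        (editing_table["mirna"] == config.edited_mirna)
        & (editing_table["position"] == config.edit_position)
    ]
    assoc: dict = {}
    if len(lvl_rows):
        sample_cols = [c for c in lvl_rows.columns if c in groups]
        levels = lvl_rows.iloc[0][sample_cols].astype(float)
        assoc = cl.associate(clin, levels)
    assoc_df = pd.DataFrame(
        [
            {"metric": k, "value": v}
            for k, v in assoc.items()
            if not isinstance(v, cl.KMCurve)
        ]
    )
    path = outdir / "association.tsv"
    _write_tsv(assoc_df, path)
    artifacts["association"] = path
    for label in ("km_high", "km_low"):
        if label in assoc:
            curve = assoc[label]
            kdf = pd.DataFrame(
                {"time": curve.times, "survival": curve.survival, "at_risk": curve.at_risk}
            )
            kpath = outdir / f"{label}.tsv"
            _write_tsv(kdf, kpath)
            artifacts[label] = kpath
    log.info("stage associate: %d metrics for %s:%d", len(assoc_df), site_key, config.edit_position)

    wt = refs_by_id[config.edited_mirna].sequence
    ctx_wt = rt.SeedContext(config.edited_mirna, wt)
    ctx_ed = rt.SeedContext(config.edited_mirna, wt, edit_position=config.edit_position)
    utrs = rt.load_utrs(bundle.utrs)
    site_counts = {
        g: (
            rt.count_binding_sites(u, ctx_wt, config.site_types),
            rt.count_binding_sites(u, ctx_ed, config.site_types),
        )
        for g, u in utrs.items()
    }
    predictions = rt.load_predictions(bundle.predicted_targets)
    candidates = rt.candidate_filter(
        de,
        site_counts,
        predictions,
        fdr_max=config.de_fdr_max,
        lfc_max=-config.de_lfc_min,
    )
    cand_df = pd.DataFrame(
        [
            {
                "gene": c.gene,
                "wt_sites": c.wt_sites,
                "ed_sites": c.ed_sites,
                "log2fc": c.log2fc,
                "fdr": c.fdr,
                "score": c.score,
                "passes": c.passes,
                "reasons": ";".join(c.reasons),
            }
            for c in candidates
        ]
    )
    path = outdir / "candidates.tsv"
    _write_tsv(cand_df, path)
    artifacts["candidates"] = path
    log.info("stage retarget: %d passing candidates", int(cand_df.passes.sum()))

    assays = qp.filter_efficiency(qp.read_qpcr(bundle.qpcr))
    by_id = {a.assay_id: a for a in assays}
    refs_q = [a for a in assays if a.role == "reference"]
    qrows = []
    if {"miR-200b-ED", "miR-200b-WT"} <= set(by_id) and refs_q:
        ratio = qp.ed_wt_ratio(
            by_id["miR-200b-ED"], by_id["miR-200b-WT"], refs_q, "siADAR1", "siNEG"
        )
        qrows.append({"readout": "ed_wt_ratio_siADAR1_vs_siNEG", "value": ratio})
    path = outdir / "qpcr_ratios.tsv"
    _write_tsv(pd.DataFrame(qrows), path)
    artifacts["qpcr_ratios"] = path

    manifest = {
        "seed": config.seed,
        "artifacts": {
            name: {"path": str(p.relative_to(outdir)), "sha256": _sha256(p)}
            for name, p in sorted(artifacts.items())
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
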