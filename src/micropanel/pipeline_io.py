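"""Shared file formats, run configuration, and the end-to-end pipeline.

Conventions: internal coordinates are 0-based half-open; every exported
TSV/VCF position is 1-based, with the conversion confined to this layer.
TSV is the canonical tabular dialect (UTF-8, tab-delimited, '#'-prefixed
header).  FASTQ is 4-line Phred+33, optionally gzipped.
"""

from __future__ import annotations

import gzip
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from . import mrd_monitor, stats_report, synthetic_data, umi_consensus, vaf_quant
from .panel_design import (
    FilterConfig,
    PanelConfig,
    PanelDesign,
    PanelTarget,
    SomaticVariant,
    build_pools,
    filter_variants,
    select_panel,
)

logger = logging.getLogger(__name__)

VARIANT_COLUMNS = [
    "patient_id", "chrom", "pos", "ref_allele", "alt_allele", "gene_symbol",
    "consequence_class", "tissue_vaf", "depth", "population_af",
    "mq0_fraction", "known_variant", "confidence",
]


class SchemaError(ValueError):
    """Raised when an input file does not match the expected schema."""


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq_pairs(
    path_r1: str | Path, path_r2: str | Path
) -> Iterator[tuple[tuple, tuple]]:
    """Lazily yield ((id, seq, qual), (id, seq, qual)) read pairs.

    Malformed records raise with the 1-based record index; mismatched pair
    counts raise at the point of truncation.
    """
    with _open_text(path_r1) as fh1, _open_text(path_r2) as fh2:
        it1 = FastqGeneralIterator(fh1)
        it2 = FastqGeneralIterator(fh2)
        idx = 0
        while True:
            idx += 1
            try:
                rec1 = next(it1, None)
            except ValueError as err:
                raise SchemaError(f"{path_r1}: malformed record {idx}: {err}")
            try:
                rec2 = next(it2, None)
            except ValueError as err:
                raise SchemaError(f"{path_r2}: malformed record {idx}: {err}")
            if rec1 is None and rec2 is None:
                return
            if rec1 is None or rec2 is None:
                short = path_r1 if rec1 is None else path_r2
                raise SchemaError(
                    f"{short}: ran out of reads at record {idx} "
                    "(mismatched pair counts)"
                )
            yield rec1, rec2


def write_fastq_pairs(
    read_pairs: list[tuple], path_r1: str | Path, path_r2: str | Path
) -> None:
    """Write (read_id, r1_seq, r1_qual, r2_seq, r2_qual) tuples as R1/R2."""
    with _open_text(path_r1, "wt") as f1, _open_text(path_r2, "wt") as f2:
        for rid, s1, q1, s2, q2 in read_pairs:
            f1.write(f"@{rid}/1\n{s1}\n+\n{q1}\n")
            f2.write(f"@{rid}/2\n{s2}\n+\n{q2}\n")


# ---------------------------------------------------------------------------
# variant tables (TSV and minimal VCF 4.2 subset)
# ---------------------------------------------------------------------------

def write_variant_table(variants: list[SomaticVariant], path: str | Path) -> None:
    rows = [
        {
            "patient_id": v.patient_id, "chrom": v.chrom, "pos": v.pos,
            "ref_allele": v.ref_allele, "alt_allele": v.alt_allele,
            "gene_symbol": v.gene_symbol,
            "consequence_class": v.consequence_class,
            "tissue_vaf": repr(v.tissue_vaf), "depth": v.depth,
            "population_af": repr(v.population_af),
            "mq0_fraction": repr(v.mq0_fraction),
            "known_variant": int(v.known_variant), "confidence": v.confidence,
        }
        for v in variants
    ]
    df = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(VARIANT_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def _variant_from_row(row: dict) -> SomaticVariant:
    pos = int(row["pos"])
    if pos < 1:
        raise SchemaError(f"pos must be 1-based and >= 1 (got {pos})")
    return SomaticVariant(
        patient_id=str(row["patient_id"]),
        chrom=str(row["chrom"]),
        pos=pos,
        ref_allele=str(row["ref_allele"]),
        alt_allele=str(row["alt_allele"]),
        gene_symbol=str(row["gene_symbol"]),
        consequence_class=str(row["consequence_class"]),
        tissue_vaf=float(row["tissue_vaf"]),
        depth=int(row["depth"]),
        population_af=float(row["population_af"]),
        mq0_fraction=float(row["mq0_fraction"]),
        known_variant=bool(int(row["known_variant"])),
        confidence=str(row["confidence"]),
    )


def read_variant_table(path: str | Path) -> list[SomaticVariant]:
    """Read somatic variants from TSV (canonical) or a minimal VCF subset."""
    path = Path(path)
    if path.suffix in (".vcf", ".bcf") or path.name.endswith(".vcf.gz"):
        return _read_variant_vcf(path)
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = set(VARIANT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    return [_variant_from_row(row) for row in df.to_dict("records")]


_VCF_INFO = [
    ("PATIENT", "String", "Patient identifier"),
    ("GENE", "String", "Gene symbol"),
    ("CSQ_CLASS", "String", "Consequence class"),
    ("TISSUE_VAF", "String", "Tumor tissue VAF"),
    ("DP_T", "Integer", "Tumor depth"),
    ("POP_AF", "String", "Population allele frequency"),
    ("MQ0_FRAC", "String", "Fraction of MQ0 reads"),
    ("KNOWN", "Integer", "Previously known variant (0/1)"),
    ("CONF", "String", "Caller confidence"),
]


def write_variant_vcf(variants: list[SomaticVariant], path: str | Path) -> None:
    """Write variants as a minimal VCF 4.2 with covariates in INFO.

    Fractions are carried as String INFO values so a TSV/VCF round trip is
    lossless.
    """
    header = pysam.VariantHeader()
    for chrom in sorted({v.chrom for v in variants}):
        header.contigs.add(chrom, length=250_000_000)
    for key, typ, desc in _VCF_INFO:
        header.info.add(key, 1, typ, desc)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
            rec = out.new_record(
                contig=v.chrom, start=v.pos - 1, stop=v.pos - 1 + len(v.ref_allele),
                alleles=(v.ref_allele, v.alt_allele),
            )
            rec.info["PATIENT"] = v.patient_id
            rec.info["GENE"] = v.gene_symbol
            rec.info["CSQ_CLASS"] = v.consequence_class
            rec.info["TISSUE_VAF"] = repr(v.tissue_vaf)
            rec.info["DP_T"] = v.depth
            rec.info["POP_AF"] = repr(v.population_af)
            rec.info["MQ0_FRAC"] = repr(v.mq0_fraction)
            rec.info["KNOWN"] = int(v.known_variant)
            rec.info["CONF"] = v.confidence
            out.write(rec)


def _read_variant_vcf(path: Path) -> list[SomaticVariant]:
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            out.append(
                SomaticVariant(
                    patient_id=str(info["PATIENT"]),
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                    gene_symbol=str(info["GENE"]),
                    consequence_class=str(info["CSQ_CLASS"]),
                    tissue_vaf=float(info["TISSUE_VAF"]),
                    depth=int(info["DP_T"]),
                    population_af=float(info["POP_AF"]),
                    mq0_fraction=float(info["MQ0_FRAC"]),
                    known_variant=bool(info["KNOWN"]),
                    confidence=str(info["CONF"]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# panel manifests, clinical tables, readcounts
# ---------------------------------------------------------------------------

MANIFEST_COLUMNS = [
    "patient_id", "amplicon_id", "chrom", "start", "end", "pos", "ref_allele",
    "alt_allele", "gene_symbol", "primer_pair_id", "pool_id", "amplicon_seq",
]


def write_panel_manifest(
    panels: list[PanelDesign],
    amplicon_seqs: dict[str, str],
    path: str | Path,
) -> None:
    """Panel manifest TSV; start/end exported 1-based inclusive."""
    rows = []
    for p in panels:
        for t in p.targets:
            v = t.variant
            rows.append(
                {
                    "patient_id": p.patient_id,
                    "amplicon_id": t.amplicon_id,
                    "chrom": v.chrom,
                    "start": t.amplicon_start + 1,
                    "end": t.amplicon_end,
                    "pos": v.pos,
                    "ref_allele": v.ref_allele,
                    "alt_allele": v.alt_allele,
                    "gene_symbol": v.gene_symbol,
                    "primer_pair_id": t.primer_pair_id,
                    "pool_id": p.pool_id if p.pool_id is not None else "",
                    "amplicon_seq": amplicon_seqs.get(t.amplicon_id, ""),
                }
            )
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(MANIFEST_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def write_clinical_table(truths: list[synthetic_data.TruthRecord], path) -> None:
    rows = [
        {
            "patient_id": t.patient_id,
            "pcr": int(t.pcr),
            "surgery_month": t.surgery_month,
            "clinical_relapse_month": (
                "" if t.clinical_relapse_month is None else t.clinical_relapse_month
            ),
            "last_followup_month": max(
                (m for _, m in t.occurred_draws()), default=0.0
            ),
        }
        for t in truths
    ]
    cols = list(rows[0].keys())
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(cols) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_clinical_table(path: str | Path) -> dict[str, dict]:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    out = {}
    for row in df.to_dict("records"):
        relapse = row.get("clinical_relapse_month")
        out[str(row["patient_id"])] = {
            "patient_id": str(row["patient_id"]),
            "pcr": bool(int(row["pcr"])),
            "surgery_month": float(row["surgery_month"]),
            "clinical_relapse_month": (
                None if pd.isna(relapse) or relapse == "" else float(relapse)
            ),
            "last_followup_month": float(row["last_followup_month"]),
        }
    return out


READCOUNT_COLUMNS = [
    "patient_id", "timepoint", "month", "chrom", "pos", "ref_allele",
    "alt_allele", "ref_count", "alt_count", "other_count", "no_call_count",
    "raw_coverage", "vaf", "probe_pass",
]


def write_readcounts_table(rows: list[dict], path: str | Path) -> None:
    """Long-format per-sample, per-locus readcount/VAF table."""
    df = pd.DataFrame(rows, columns=READCOUNT_COLUMNS)
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(READCOUNT_COLUMNS) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)


def read_readcounts_table(path: str | Path) -> list[dict]:
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lstrip("#") for c in df.columns]
    missing = set(READCOUNT_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    return df.to_dict("records")


def timelines_from_readcounts(
    rows: list[dict], clinical: dict[str, dict]
) -> list[vaf_quant.PatientTimeline]:
    """Rebuild per-patient timelines from a readcounts table."""
    by_patient: dict[str, list] = {}
    for r in rows:
        pid = str(r["patient_id"])
        if pid not in clinical:
            raise SchemaError(f"readcounts reference unknown patient {pid!r}")
        vaf = r["vaf"]
        vaf = None if (vaf == "" or pd.isna(vaf)) else float(vaf)
        m = vaf_quant.VafMeasurement(
            chrom=str(r["chrom"]), pos=int(r["pos"]),
            ref_allele=str(r["ref_allele"]), alt_allele=str(r["alt_allele"]),
            vaf=vaf,
            consensus_depth=int(r["ref_count"]) + int(r["alt_count"])
            + int(r["other_count"]) + int(r["no_call_count"]),
            raw_coverage=int(r["raw_coverage"]),
            probe_pass=bool(int(r["probe_pass"])),
        )
        by_patient.setdefault(pid, []).append(
            (pid, str(r["timepoint"]), float(r["month"]), m)
        )
    return [
        vaf_quant.assemble_timeline(meas, clinical[pid])
        for pid, meas in sorted(by_patient.items())
    ]


# ---------------------------------------------------------------------------
# run configuration and the pipeline
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Nested configuration for a full pipeline run."""

    cohort: synthetic_data.CohortConfig = field(
        default_factory=synthetic_data.CohortConfig
    )
    error_model: synthetic_data.ErrorModel = field(
        default_factory=synthetic_data.ErrorModel
    )
    filters: FilterConfig = field(default_factory=FilterConfig)
    panel: PanelConfig = field(default_factory=PanelConfig)
    consensus: umi_consensus.ConsensusFilterConfig = field(
        default_factory=umi_consensus.ConsensusFilterConfig
    )
    positivity: mrd_monitor.PositivityConfig = field(
        default_factory=mrd_monitor.PositivityConfig
    )
    read_simulation: str = "none"   # "none" (template counts) or "full"
    outdir: str = "micropanel_run"
    seed: int = 0
    log_level: str = "INFO"
    schema_version: int = 1

    def __post_init__(self) -> None:
        if self.read_simulation not in ("none", "full"):
            raise ValueError("read_simulation must be 'none' or 'full'")


def load_run_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "schema_version" not in raw:
        raise SchemaError("run config must carry schema_version")
    kwargs = dict(raw)
    if "cohort" in kwargs:
        c = dict(kwargs["cohort"])
        if "variant_count_law" in c:
            c["variant_count_law"] = synthetic_data.CountLaw(**c["variant_count_law"])
        if "lead_time_range" in c:
            c["lead_time_range"] = tuple(c["lead_time_range"])
        kwargs["cohort"] = synthetic_data.CohortConfig(**c)
    if "error_model" in kwargs:
        kwargs["error_model"] = synthetic_data.ErrorModel(**kwargs["error_model"])
    if "filters" in kwargs:
        kwargs["filters"] = FilterConfig(**kwargs["filters"])
    if "panel" in kwargs:
        kwargs["panel"] = PanelConfig(**kwargs["panel"])
    if "consensus" in kwargs:
        kwargs["consensus"] = umi_consensus.ConsensusFilterConfig(**kwargs["consensus"])
    if "positivity" in kwargs:
        kwargs["positivity"] = mrd_monitor.PositivityConfig(**kwargs["positivity"])
    return RunConfig(**kwargs)


def dump_run_config(
    config: RunConfig, path: str | Path, include_paths: bool = True
) -> None:
    d = asdict(config)
    if not include_paths:
        d.pop("outdir", None)  # keep the echo checksum path-independent
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _sample_rng(seed: int, *indices: int) -> np.random.Generator:
    return np.random.default_rng([seed] + list(indices))


def _quantify_sample_full(
    truth: synthetic_data.TruthRecord,
    panel: PanelDesign,
    amplicon_seqs: dict[str, str],
    label: str,
    config: RunConfig,
    rng: np.random.Generator,
) -> list[vaf_quant.LocusReadcount]:
    """Read-level path: simulate FASTQ-equivalent reads, collapse and count."""
    af = {
        t.amplicon_id: truth.true_locus_vaf(t.variant.locus, label)
        for t in panel.targets
    }
    read_pairs, _ = synthetic_data.simulate_amplicon_reads(
        panel, amplicon_seqs, af, config.error_model, rng,
        read_id_prefix=f"{truth.patient_id}:{label}",
    )
    anchors = {aid: seq[:20] for aid, seq in amplicon_seqs.items()}
    tagged = []
    raw_per_amp: dict[str, int] = {}
    for rid, s1, q1, s2, q2 in read_pairs:
        tr = umi_consensus.extract_umi(
            (rid, s1, q1), (rid, s2, q2), config.error_model.umi_length
        )
        if tr is None:
            continue
        amp = umi_consensus.assign_amplicon(tr, anchors)
        if amp is None:
            continue
        tagged.append(
            umi_consensus.TaggedRead(
                umi=tr.umi, sequence=tr.sequence, quality=tr.quality,
                read_id=tr.read_id, mate_remainder=tr.mate_remainder,
                amplicon_id=amp,
            )
        )
        raw_per_amp[amp] = raw_per_amp.get(amp, 0) + 1
    consensus = umi_consensus.collapse_reads(tagged, config.consensus)
    counts = []
    for t in panel.targets:
        rc = vaf_quant.count_alleles(
            consensus, t, patient_id=truth.patient_id, timepoint=label,
            raw_coverage=raw_per_amp.get(t.amplicon_id, 0),
        )
        counts.append(rc)
    return counts


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> design -> collapse/quantify -> monitor -> report.

    Returns a manifest dict of artifact paths and SHA-256 checksums; a fixed
    seed yields identical checksums.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cohort_cfg = config.cohort
    if config.seed and cohort_cfg.seed != config.seed:
        cohort_cfg = synthetic_data.CohortConfig(
            **{**asdict_cohort(cohort_cfg), "seed": config.seed}
        )

    truths = synthetic_data.simulate_cohort(cohort_cfg)
    logger.info("simulated %d patients", len(truths))

    all_variants = [v for t in truths for v in t.variant_profile]
    write_variant_table(all_variants, outdir / "variants.tsv")
    write_clinical_table(truths, outdir / "clinical.tsv")

    panels: dict[str, PanelDesign] = {}
    seqs: dict[str, str] = {}
    for idx, truth in enumerate(truths):
        passing = filter_variants(truth.variant_profile, config.filters)
        if not passing:
            logger.warning("patient %s: no variants pass filters", truth.patient_id)
            continue
        panel = select_panel(passing, config.panel)
        panels[truth.patient_id] = panel
        seqs.update(
            synthetic_data.attach_amplicon_sequences(
                panel, _sample_rng(cohort_cfg.seed, 1000 + idx)
            )
        )
    build_pools(list(panels.values()), config.panel)
    write_panel_manifest(list(panels.values()), seqs, outdir / "manifest.tsv")

    timelines = []
    rows = []
    for pidx, truth in enumerate(truths):
        clinical = {
            "patient_id": truth.patient_id,
            "pcr": truth.pcr,
            "surgery_month": truth.surgery_month,
            "clinical_relapse_month": truth.clinical_relapse_month,
            "last_followup_month": max(
                (m for _, m in truth.occurred_draws()), default=0.0
            ),
        }
        panel = panels.get(truth.patient_id)
        measurements = []
        if panel is not None:
            for tidx, (label, month) in enumerate(truth.occurred_draws()):
                rng = _sample_rng(cohort_cfg.seed, 2, pidx, tidx)
                if config.read_simulation == "full":
                    counts = _quantify_sample_full(
                        truth, panel, seqs, label, config, rng
                    )
                else:
                    counts = synthetic_data.simulate_locus_counts(
                        truth, panel, label, config.error_model, rng,
                        low_probe_prob=cohort_cfg.low_probe_prob,
                    )
                for rc in counts:
                    m = vaf_quant.compute_vaf(rc)
                    measurements.append((truth.patient_id, label, month, m))
                    rows.append(
                        {
                            "patient_id": truth.patient_id, "timepoint": label,
                            "month": month, "chrom": rc.chrom, "pos": rc.pos,
                            "ref_allele": rc.ref_allele,
                            "alt_allele": rc.alt_allele,
                            "ref_count": rc.ref_count, "alt_count": rc.alt_count,
                            "other_count": rc.other_count,
                            "no_call_count": rc.no_call_count,
                            "raw_coverage": rc.raw_coverage,
                            "vaf": "" if m.vaf is None else repr(m.vaf),
                            "probe_pass": int(m.probe_pass),
                        }
                    )
        if measurements:
            timelines.append(vaf_quant.assemble_timeline(measurements, clinical))

    if rows:
        write_readcounts_table(rows, outdir / "readcounts.tsv")

    summary = mrd_monitor.summarize_cohort(timelines, config.positivity)
    # patients with no panel or no occurred draws never reach a timeline;
    # they are insufficient-data by definition
    n_skipped = len(truths) - len(timelines)
    summary.category_counts["insufficient_data"] += n_skipped
    stats = stats_report.cohort_statistics(summary)
    report = stats_report.render_report(
        summary, stats, config_echo={"schema_version": config.schema_version},
        seed=cohort_cfg.seed,
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    with open(outdir / "report.md", "w") as fh:
        fh.write(stats_report.render_report_markdown(report))
    cat = pd.DataFrame(
        sorted(summary.category_counts.items()), columns=["category", "n"]
    )
    with open(outdir / "summary.tsv", "w") as fh:
        fh.write("#category\tn\n")
        cat.to_csv(fh, sep="\t", header=False, index=False)
    dump_run_config(config, outdir / "config_echo.yaml", include_paths=False)

    manifest = {
        "artifacts": {
            p.name: sha256_file(p)
            for p in sorted(outdir.iterdir())
            if p.is_file() and p.name != "checksums.json"
        }
    }
    with open(outdir / "checksums.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"outdir": str(outdir), "report": report, "checksums": manifest}


def asdict_cohort(cfg: synthetic_data.CohortConfig) -> dict:
    d = asdict(cfg)
    d["variant_count_law"] = synthetic_data.CountLaw(**d["variant_count_law"])
    d["lead_time_range"] = tuple(d["lead_time_range"])
    return d
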