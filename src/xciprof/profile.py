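"""Sample-level XCI state calling and the end-to-end pipeline.

A sample's X-inactivation state is summarized from three readouts:

* the fraction of informative X-linked genes (monoallelic or biallelic)
  that are biallelic,
* whether XIST is expressed (FPKM at or above the expression threshold),
* the X:A dosage ratio (reported, not used by the state rule).

The state rule mirrors the Class I/II/III nomenclature for female
pluripotent lines: a high biallelic fraction means two active X
chromosomes (class I, XaXa); a low fraction with XIST expressed is the
canonical post-XCI state (class II, XaXi XIST+); a low fraction without
XIST resembles the XIST-lost class III state (called "class III-like"
here, since distinguishing a stably inactive Xi from an eroded Xe needs
evidence this pipeline may lack); anything in between is partial XCI.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from .allele_counts import (
    count_alleles_at_sites,
    read_count_table,
    read_sites_vcf,
    write_count_table,
)
from .classify import (
    AllelicCall,
    ClassificationConfig,
    calls_to_bed,
    calls_to_frame,
    chromosome_status_map,
    classify_sample,
)
from .dosage import ExpressionMatrix, UndefinedRatioError, x_to_autosome_ratio

logger = logging.getLogger("xciprof")

REPORT_SCHEMA_VERSION = 1

XCI_STATE_NAMES = (
    "class_I_XaXa",
    "class_II_XaXi_XISTpos",
    "class_III_like_XaXi_XISTneg",
    "partial_XCI",
    "indeterminate",
)


class ConfigError(ValueError):
    """Raised when the pipeline config is missing or malformed."""


@dataclass(frozen=True)
class StateCallConfig:
    """Thresholds for mapping the biallelic fraction to an XCI state.

    Clean pre-XCI samples sit near fraction 1 and clean post-XCI samples
    near 0, so calls are insensitive to the exact placement of bi_high and
    bi_low; the band between them is reported as partial XCI.
    """

    bi_high: float = 0.7
    bi_low: float = 0.3
    xist_expression_threshold: float = 1.0  # FPKM; same convention as genes

    def __post_init__(self) -> None:
        if not 0 <= self.bi_low < self.bi_high <= 1:
            raise ValueError("need 0 <= bi_low < bi_high <= 1")


@dataclass
class SampleXCIProfile:
    """Per-sample XCI summary: tallies, dosage, XIST, and the called state."""

    sample_id: str
    n_monoallelic: int
    n_biallelic: int
    n_not_expressed: int
    n_no_call: int
    informative_fraction_biallelic: float | None
    x_to_a_ratio: float | None
    xist_fpkm: float | None
    xist_expressed: bool | None
    called_state: str = "indeterminate"


def call_xci_state(
    profile: SampleXCIProfile,
    config: StateCallConfig = StateCallConfig(),
) -> str:
    """Deterministic state call from the biallelic fraction and XIST flag."""
    frac = profile.informative_fraction_biallelic
    if frac is None:
        return "indeterminate"
    if frac >= config.bi_high:
        return "class_I_XaXa"
    if frac <= config.bi_low:
        if profile.xist_expressed:
            return "class_II_XaXi_XISTpos"
        return "class_III_like_XaXi_XISTneg"
    return "partial_XCI"


def build_sample_profile(
    calls: Sequence[AllelicCall],
    expression: ExpressionMatrix,
    sample: str,
    xist_gene_id: str = "XIST",
    state_config: StateCallConfig = StateCallConfig(),
    x_chrom: str = "chrX",
    autosome_chrom: str = "chr1",
) -> SampleXCIProfile:
    """Assemble the per-sample profile and call its XCI state.

    Only chrX calls enter the tallies. With zero informative genes the
    biallelic fraction is undefined and the state is indeterminate. A
    missing XIST row leaves the XIST fields undefined (with a warning);
    an undefined X:A ratio is reported as None.
    """
    x_calls = [c for c in calls if c.chrom == x_chrom]
    _, tally = chromosome_status_map(x_calls) if x_calls else (
        [], {s: 0 for s in ("monoallelic", "biallelic", "not_expressed", "no_call")}
    )
    n_mono, n_bi = tally["monoallelic"], tally["biallelic"]
    frac = n_bi / (n_bi + n_mono) if (n_bi + n_mono) > 0 else None

    if xist_gene_id in expression.values.index:
        xist_fpkm = float(expression.values.loc[xist_gene_id, sample])
        xist_expressed = xist_fpkm >= state_config.xist_expression_threshold
    else:
        logger.warning("XIST row %r absent from expression matrix", xist_gene_id)
        xist_fpkm, xist_expressed = None, None

    try:
        ratio = x_to_autosome_ratio(
            expression, sample, x_chrom=x_chrom, autosome_chrom=autosome_chrom
        )
    except (UndefinedRatioError, KeyError):
        ratio = None

    profile = SampleXCIProfile(
        sample_id=sample,
        n_monoallelic=n_mono,
        n_biallelic=n_bi,
        n_not_expressed=tally["not_expressed"],
        n_no_call=tally["no_call"],
        informative_fraction_biallelic=frac,
        x_to_a_ratio=ratio,
        xist_fpkm=xist_fpkm,
        xist_expressed=xist_expressed,
    )
    profile.called_state = call_xci_state(profile, state_config)
    return profile


# ---------------------------------------------------------------------------
# Pipeline orchestration


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs, loadable from YAML/JSON."""

    expression: str
    out_dir: str
    samples: list[str]
    counts: str | None = None  # per-sample counts TSV (sample_id column)
    bam: str | None = None  # alternative input: BAM + VCF sites
    vcf: str | None = None
    xist_gene_id: str = "XIST"
    x_chrom: str = "chrX"
    autosome_chrom: str = "chr1"
    min_base_quality: int = 20
    min_mapping_quality: int = 20
    classification: ClassificationConfig = field(default_factory=ClassificationConfig)
    state: StateCallConfig = field(default_factory=StateCallConfig)
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
        for key in ("expression", "out_dir", "samples"):
            if key not in raw:
                raise ConfigError(f"config missing required key: {key!r}")
        if "counts" not in raw and not ("bam" in raw and "vcf" in raw):
            raise ConfigError("config needs either 'counts' or both 'bam' and 'vcf'")
        cls_cfg = ClassificationConfig(**raw.pop("classification", {}))
        state_cfg = StateCallConfig(**raw.pop("state", {}))
        known = {f for f in cls.__dataclass_fields__} - {"classification", "state"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(classification=cls_cfg, state=state_cfg, **raw)


def _setup_logging(level: int = logging.INFO) -> None:
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)


def run_pipeline(config: "PipelineConfig | str | Path") -> dict[str, Any]:
    """Run count -> classify -> dosage -> profile and write the report bundle.

    Writes, per sample, a calls TSV, a BED status track and a JSON report,
    plus one combined summary TSV. Outputs are deterministic for a fixed
    config and seed. On any stage failure the partially written outputs are
    removed and the error is re-raised with the stage name.
    """
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_file(config)
    _setup_logging()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        stage = "load-expression"
        expression = ExpressionMatrix.from_tsv(config.expression)

        stage = "count"
        if config.counts is not None:
            all_records = read_count_table(config.counts)
        else:
            sites = read_sites_vcf(config.vcf)
            all_records = []
            for sample in config.samples:
                all_records.extend(
                    count_alleles_at_sites(
                        config.bam, sites,
                        min_base_quality=config.min_base_quality,
                        min_mapping_quality=config.min_mapping_quality,
                        sample_id=sample,
                    )
                )
            path = out_dir / "counts.tsv"
            write_count_table(all_records, path)
            written.append(path)

        summary_rows = []
        reports = {}
        for sample in config.samples:
            stage = f"classify[{sample}]"
            records = [r for r in all_records if r.sample_id == sample]
            sites = [r.site for r in records]
            calls = classify_sample(
                records, sites, expression, sample, config.classification
            )
            x_calls = [c for c in calls if c.chrom == config.x_chrom]

            stage = f"profile[{sample}]"
            profile = build_sample_profile(
                calls, expression, sample,
                xist_gene_id=config.xist_gene_id,
                state_config=config.state,
                x_chrom=config.x_chrom,
                autosome_chrom=config.autosome_chrom,
            )
            track, tally = chromosome_status_map(x_calls) if x_calls else ([], {})
            logger.info(
                "sample %s: state=%s fraction=%s thresholds=%s/%s",
                sample, profile.called_state,
                profile.informative_fraction_biallelic,
                config.state.bi_high, config.state.bi_low,
            )

            stage = f"write[{sample}]"
            calls_path = out_dir / f"{sample}.calls.tsv"
            calls_to_frame(calls).to_csv(calls_path, sep="\t", index=False)
            written.append(calls_path)
            bed_path = out_dir / f"{sample}.calls.bed"
            bed_path.write_text(calls_to_bed(calls, expression))
            written.append(bed_path)
            report = {
                "schema_version": REPORT_SCHEMA_VERSION,
                "profile": asdict(profile),
                "status_tally": tally,
                "status_track": [[float(c), s] for c, s in track],
                "thresholds": {
                    **asdict(config.classification),
                    **asdict(config.state),
                },
                "seed": config.seed,
                "note": (
                    "class_III_like marks XIST-negative monoallelic samples; "
                    "demonstrating erosion (Xe rather than Xi) needs additional "
                    "evidence."
                ),
            }
            report_path = out_dir / f"{sample}.report.json"
            report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
            written.append(report_path)
            reports[sample] = report
            summary_rows.append(
                {"sample_id": sample, **{k: v for k, v in asdict(profile).items()
                                         if k != "sample_id"}}
            )

        stage = "summary"
        summary_path = out_dir / "summary.tsv"
        pd.DataFrame(summary_rows).to_csv(summary_path, sep="\t", index=False)
        written.append(summary_path)
        return {"reports": reports, "summary": str(summary_path),
                "outputs": [str(p) for p in written]}
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
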