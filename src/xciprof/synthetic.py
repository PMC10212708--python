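"""Synthetic RNA-seq data under parameterized X-inactivation scenarios.

Generates the inputs the rest of the pipeline consumes — a gene/SNP panel
with ground-truth allelic labels, a per-gene FPKM expression column, per-SNP
ref/alt read counts, and tiny SAM/VCF fixtures — so every downstream stage
is testable without controlled-access sequencing data.

The generative model is deliberately minimal:

* gene baseline expression is log-normal(``fpkm_log_mean``, ``fpkm_log_sd``);
* a gene silenced by XCI keeps one expressed allele, so its total FPKM is
  multiplied by ``silenced_dosage_factor`` (default 0.5: no compensatory
  upregulation);
* per-SNP read depth is negative-binomial with mean proportional to
  ``mean_depth * fpkm / median(fpkm)``;
* reference-allele read counts are beta-binomial with intraclass
  correlation ``allelic_dispersion_rho``; the success probability is 0.5
  for biallelic genes and ``seq_error`` / ``1 - seq_error`` for
  monoallelic genes (the silenced haplotype leaks only via miscalls).

All draws are seeded; the same scenario and seed reproduce bitwise-identical
output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .allele_counts import AlleleCountRecord, SnpSite
from .dosage import ExpressionMatrix

CHROM_X = "chrX"
CHROM_1 = "chr1"
CHROM_X_LENGTH = 155_000_000
CHROM_1_LENGTH = 248_000_000
XIST_GENE_ID = "XIST"
XIST_START = 73_800_000  # near the real XIST locus on Xq13
FIXTURE_READ_LENGTH = 50

XCI_STATES = ("pre_xci", "post_xci", "partial_erosion")


class ScenarioError(ValueError):
    """Raised for an invalid simulation scenario."""


@dataclass
class XCIScenario:
    """Parameter bundle describing one simulated XCI condition.

    ``silenced_fraction`` is forced to 0 for ``pre_xci`` and to
    ``1 - escape_fraction`` for ``post_xci``; it is free only for
    ``partial_erosion``.
    """

    label: str = "scenario"
    xci_state: str = "pre_xci"
    n_x_genes: int = 200
    n_chr1_genes: int = 200
    silenced_fraction: float = 0.0
    escape_fraction: float = 0.0
    erosion_positional_bias: bool = False
    seq_error: float = 0.002
    mean_depth: float = 50.0
    depth_dispersion: float = 0.1
    allelic_dispersion_rho: float = 0.01
    fpkm_log_mean: float = 2.0
    fpkm_log_sd: float = 1.0
    silenced_dosage_factor: float = 0.5
    xist_fpkm: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.xci_state not in XCI_STATES:
            raise ScenarioError(f"unknown xci_state {self.xci_state!r}")
        if self.n_x_genes < 1 or self.n_chr1_genes < 1:
            raise ScenarioError("gene counts must be positive")
        for name in ("silenced_fraction", "escape_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ScenarioError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 <= self.seq_error <= 0.05:
            raise ScenarioError("seq_error must lie in [0, 0.05]")
        if self.mean_depth <= 0:
            raise ScenarioError("mean_depth must be positive")
        if self.depth_dispersion < 0:
            raise ScenarioError("depth_dispersion must be nonnegative")
        if not 0.0 <= self.allelic_dispersion_rho < 1.0:
            raise ScenarioError("allelic_dispersion_rho must lie in [0, 1)")
        if self.silenced_dosage_factor < 0 or self.xist_fpkm < 0:
            raise ScenarioError("dosage factor and XIST FPKM must be nonnegative")
        if self.xci_state == "pre_xci":
            self.silenced_fraction = 0.0
        elif self.xci_state == "post_xci":
            self.silenced_fraction = 1.0 - self.escape_fraction

    @classmethod
    def preset(cls, xci_state: str, seed: int = 0, **overrides) -> "XCIScenario":
        """Standard scenario for each XCI state.

        ``post_xci`` gets XIST coating (XIST+, class II-like); ``pre_xci``
        and ``partial_erosion`` are XIST-negative; erosion silences half the
        X genes with a distal-Xq positional bias.
        """
        defaults: dict = {"label": xci_state, "xci_state": xci_state, "seed": seed}
        if xci_state == "post_xci":
            defaults["xist_fpkm"] = 20.0
        elif xci_state == "partial_erosion":
            defaults.update(silenced_fraction=0.5, erosion_positional_bias=True)
        defaults.update(overrides)
        return cls(**defaults)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")
        return path


def _rng(scenario: XCIScenario, stream: int) -> np.random.Generator:
    # independent, reproducible stream per generator stage
    return np.random.default_rng([int(scenario.seed) % (2**31), stream])


def _place_genes(
    rng: np.random.Generator, n: int, chrom_length: int, prefix: str
) -> pd.DataFrame:
    lengths = rng.integers(10_000, 100_000, size=n)
    starts = np.sort(rng.integers(1, chrom_length - 200_000, size=n))
    rows = []
    prev_end = 0
    for i in range(n):
        start = max(int(starts[i]), prev_end + 1_000)
        end = start + int(lengths[i])
        if end >= chrom_length:  # clamp the tail of a crowded chromosome
            end = chrom_length - 1
            start = min(start, end - 1)
        rows.append((f"{prefix}{i + 1:04d}", start, end))
        prev_end = end
    return pd.DataFrame(rows, columns=["gene_id", "start", "end"])


def make_gene_and_snp_panel(
    scenario: XCIScenario,
) -> tuple[pd.DataFrame, list[SnpSite]]:
    """Lay out genes on chrX and chr1 and assign heterozygous SNP sites.

    Returns ``(gene_table, sites)``. The gene table has columns
    ``gene_id, chrom, start, end, truth_status`` where ``truth_status`` is
    the ground-truth allelic label (``monoallelic`` for silenced genes,
    ``biallelic`` otherwise). A dedicated XIST row is placed on chrX and
    carries no SNP sites. Each other X gene receives 1-3 sites inside its
    span; chr1 genes serve the dosage ratio only. When
    ``erosion_positional_bias`` is set, silenced labels are drawn with
    probability increasing linearly with chrX coordinate, concentrating
    silencing toward distal Xq.
    """
    rng = _rng(scenario, 0)
    x_genes = _place_genes(rng, scenario.n_x_genes, CHROM_X_LENGTH, "GX")
    x_genes["chrom"] = CHROM_X
    a_genes = _place_genes(rng, scenario.n_chr1_genes, CHROM_1_LENGTH, "GA")
    a_genes["chrom"] = CHROM_1

    n_silenced = int(round(scenario.silenced_fraction * scenario.n_x_genes))
    truth = np.array(["biallelic"] * scenario.n_x_genes, dtype=object)
    if n_silenced > 0:
        if scenario.erosion_positional_bias:
            # weight grows linearly with coordinate -> distal Xq enrichment
            weights = x_genes["start"].to_numpy(dtype=float)
            weights /= weights.sum()
            chosen = rng.choice(
                scenario.n_x_genes, size=n_silenced, replace=False, p=weights
            )
        else:
            chosen = rng.choice(scenario.n_x_genes, size=n_silenced, replace=False)
        truth[np.sort(chosen)] = "monoallelic"
    x_genes["truth_status"] = truth
    a_genes["truth_status"] = "biallelic"

    xist = pd.DataFrame(
        [
            {
                "gene_id": XIST_GENE_ID,
                "start": XIST_START,
                "end": XIST_START + 30_000,
                "chrom": CHROM_X,
                "truth_status": "biallelic",
            }
        ]
    )
    genes = pd.concat([x_genes, xist, a_genes], ignore_index=True)
    genes = genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    genes = genes[["gene_id", "chrom", "start", "end", "truth_status"]]

    bases = np.array(list("ACGT"))
    sites: list[SnpSite] = []
    for row in x_genes.itertuples(index=False):
        n_sites = int(rng.integers(1, 4))
        span = row.end - row.start
        offsets = np.sort(rng.choice(span, size=min(n_sites, span), replace=False))
        for off in offsets:
            ref, alt = rng.choice(4, size=2, replace=False)
            sites.append(
                SnpSite(
                    chrom=CHROM_X,
                    pos=int(row.start + off),
                    ref=str(bases[ref]),
                    alt=str(bases[alt]),
                    gene_id=row.gene_id,
                )
            )
    sites.sort(key=lambda s: (s.chrom, s.pos))
    return genes, sites


def simulate_expression(
    scenario: XCIScenario, gene_table: pd.DataFrame, sample_id: str = "sample"
) -> ExpressionMatrix:
    """Draw one FPKM column for the panel.

    Baseline FPKM is log-normal; genes labelled monoallelic lose one allele's
    worth of output (baseline times ``silenced_dosage_factor``); the XIST row
    is set to the scenario's ``xist_fpkm``.
    """
    rng = _rng(scenario, 1)
    n = len(gene_table)
    fpkm = rng.lognormal(scenario.fpkm_log_mean, scenario.fpkm_log_sd, size=n)
    silenced = (gene_table["truth_status"] == "monoallelic").to_numpy()
    fpkm = np.where(silenced, fpkm * scenario.silenced_dosage_factor, fpkm)
    fpkm = np.where(
        gene_table["gene_id"].to_numpy() == XIST_GENE_ID, scenario.xist_fpkm, fpkm
    )
    genes = gene_table.set_index("gene_id")[["chrom", "start", "end"]]
    values = pd.DataFrame({sample_id: fpkm}, index=gene_table["gene_id"])
    values.index.name = "gene_id"
    return ExpressionMatrix(genes=genes, values=values)


def _beta_binomial(
    rng: np.random.Generator, depth: int, p: float, rho: float
) -> int:
    if depth == 0:
        return 0
    if p <= 0.0:
        return 0
    if p >= 1.0:
        return depth
    if rho == 0.0:
        return int(rng.binomial(depth, p))
    a = p * (1.0 - rho) / rho
    b = (1.0 - p) * (1.0 - rho) / rho
    return int(rng.binomial(depth, rng.beta(a, b)))


def simulate_allele_counts(
    scenario: XCIScenario,
    gene_table: pd.DataFrame,
    sites: Sequence[SnpSite],
    expression: ExpressionMatrix,
    sample_id: str = "sample",
) -> list[AlleleCountRecord]:
    """Simulate per-SNP ref/alt read counts for one sample.

    Depth at a site is negative-binomial (Poisson when
    ``depth_dispersion`` is 0) with mean
    ``mean_depth * fpkm / median(fpkm over genes with sites)``. The
    reference-allele count is beta-binomial; a monoallelic gene expresses a
    single haplotype, so every one of its sites shares the same silenced
    direction (drawn once per gene, or once per sample for ``post_xci``
    where one chromosome is silenced genome-wide).
    """
    rng = _rng(scenario, 2)
    truth = gene_table.set_index("gene_id")["truth_status"]
    col = expression.values.columns[0]
    fpkm = expression.values[col]
    site_gene_ids = sorted({s.gene_id for s in sites})
    med = float(np.median(fpkm.loc[site_gene_ids])) if site_gene_ids else 1.0
    med = med if med > 0 else 1.0

    # silenced-haplotype direction: True -> reference allele silenced
    global_ref_silenced = bool(rng.random() < 0.5)
    gene_ref_silenced = {
        g: (global_ref_silenced if scenario.xci_state == "post_xci" else rng.random() < 0.5)
        for g in site_gene_ids
        if truth.get(g) == "monoallelic"
    }

    records: list[AlleleCountRecord] = []
    for site in sites:
        mean = scenario.mean_depth * float(fpkm.get(site.gene_id, 0.0)) / med
        if mean <= 0:
            depth = 0
        elif scenario.depth_dispersion == 0:
            depth = int(rng.poisson(mean))
        else:
            r = 1.0 / scenario.depth_dispersion
            depth = int(rng.negative_binomial(r, r / (r + mean)))
        if truth.get(site.gene_id) == "monoallelic":
            p = (
                scenario.seq_error
                if gene_ref_silenced[site.gene_id]
                else 1.0 - scenario.seq_error
            )
        else:
            p = 0.5
        n_ref = _beta_binomial(rng, depth, p, scenario.allelic_dispersion_rho)
        records.append(
            AlleleCountRecord(
                site=site, n_ref=n_ref, n_alt=depth - n_ref, n_other=0,
                sample_id=sample_id,
            )
        )
    return records


# ---------------------------------------------------------------------------
# SAM/VCF fixtures for testing the pileup counter


def write_fixture_sam_vcf(
    sites: Sequence[SnpSite],
    planted: Mapping[tuple[str, int], Sequence[str]],
    out_prefix: str | Path,
    mapping_quality: int = 60,
    base_quality: int = 40,
) -> tuple[Path, Path, list[AlleleCountRecord]]:
    """Emit a minimal single-end SAM and a VCF v4.2 for a set of SNP sites.

    ``planted`` maps ``(chrom, pos)`` to the list of read bases to plant at
    that position (one fixed-length ungapped read per base). Returns the SAM
    path, the VCF path, and the per-site truth table classifying each
    planted base as ref / alt / other.
    """
    contig_lengths = {CHROM_1: CHROM_1_LENGTH, CHROM_X: CHROM_X_LENGTH}
    total_reads = sum(len(v) for v in planted.values())
    if total_reads > 1000:
        raise ValueError("fixtures are capped at 1000 reads")
    for site in sites:
        if site.chrom not in contig_lengths:
            raise ValueError(f"unknown contig {site.chrom!r}")
        if not 1 <= site.pos <= contig_lengths[site.chrom]:
            raise ValueError(f"site {site.chrom}:{site.pos} outside contig")

    out_prefix = Path(out_prefix)
    sam_path = out_prefix.with_suffix(".sam")
    vcf_path = out_prefix.with_suffix(".vcf")

    half = FIXTURE_READ_LENGTH // 2
    qual = chr(base_quality + 33) * FIXTURE_READ_LENGTH
    alignments: list[tuple[str, int, str]] = []  # (chrom, start, line)
    truth: list[AlleleCountRecord] = []
    read_idx = 0
    for site in sites:
        bases = planted.get((site.chrom, site.pos), ())
        n_ref = n_alt = n_other = 0
        for base in bases:
            start = max(1, site.pos - half)
            offset = site.pos - start
            seq = list("A" * FIXTURE_READ_LENGTH)
            seq[offset] = base
            line = "\t".join(
                [
                    f"read{read_idx:05d}",
                    "0",
                    site.chrom,
                    str(start),
                    str(mapping_quality),
                    f"{FIXTURE_READ_LENGTH}M",
                    "*",
                    "0",
                    "0",
                    "".join(seq),
                    qual,
                ]
            )
            alignments.append((site.chrom, start, line))
            read_idx += 1
            if base == site.ref:
                n_ref += 1
            elif base == site.alt:
                n_alt += 1
            else:
                n_other += 1
        truth.append(
            AlleleCountRecord(
                site=site, n_ref=n_ref, n_alt=n_alt, n_other=n_other,
                sample_id="fixture",
            )
        )

    contig_order = {CHROM_1: 0, CHROM_X: 1}
    alignments.sort(key=lambda t: (contig_order[t[0]], t[1]))
    header = ["@HD\tVN:1.6\tSO:coordinate"]
    for chrom in (CHROM_1, CHROM_X):
        header.append(f"@SQ\tSN:{chrom}\tLN:{contig_lengths[chrom]}")
    sam_path.write_text("\n".join(header + [a[2] for a in alignments]) + "\n")

    vcf_lines = [
        "##fileformat=VCFv4.2",
        f"##contig=<ID={CHROM_1},length={CHROM_1_LENGTH}>",
        f"##contig=<ID={CHROM_X},length={CHROM_X_LENGTH}>",
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Owning gene">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO",
    ]
    for site in sorted(sites, key=lambda s: (contig_order[s.chrom], s.pos)):
        vcf_lines.append(
            f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t.\tPASS\t"
            f"GENE={site.gene_id}"
        )
    vcf_path.write_text("\n".join(vcf_lines) + "\n")
    return sam_path, vcf_path, truth


def write_gene_table(gene_table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    gene_table.to_csv(path, sep="\t", index=False)
    return path
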