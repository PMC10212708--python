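"""Gene-level allelic classification and the chromosome status map.

A gene's allelic status is called from its pooled reference-allele
frequency and its expression level:

* ``not_expressed`` when FPKM is below the expression threshold
  (1 FPKM by default) — this takes precedence over everything else;
* ``no_call`` when fewer than ``min_depth`` informative reads cover the
  gene's SNPs (or the frequency is undefined);
* ``biallelic`` when the reference-allele fraction lies in the biallelic
  band [0.25, 0.75] (boundaries inclusive), i.e. the minor-allele fraction
  is at least 25%;
* ``monoallelic`` otherwise (minor-allele fraction below 25%).

Counts from a gene's multiple SNPs are pooled by summation before one
gene-level frequency is computed, which weights sites by depth.

The module also provides a one-sided permutation test for the observation
that silenced genes cluster toward distal Xq: the statistic is the median
coordinate of monoallelic genes minus the median coordinate of biallelic
genes, with status labels permuted under the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .allele_counts import (
    AlleleCountRecord,
    SnpSite,
    UndefinedAlleleFrequencyError,
    reference_allele_frequency,
)
from .dosage import ExpressionMatrix

logger = logging.getLogger("xciprof")

STATUSES = ("monoallelic", "biallelic", "not_expressed", "no_call")

# Fig-style BED colors: monoallelic blue, biallelic red, not expressed grey
STATUS_COLORS = {
    "monoallelic": "0,0,255",
    "biallelic": "255,0,0",
    "not_expressed": "128,128,128",
    "no_call": "200,200,200",
}


@dataclass(frozen=True)
class ClassificationConfig:
    """Thresholds for allelic status calling."""

    expression_threshold: float = 1.0  # FPKM below which a gene is not expressed
    biallelic_low: float = 0.25
    biallelic_high: float = 0.75
    min_depth: int = 10  # informative reads required for a confident call

    def __post_init__(self) -> None:
        if not 0 <= self.biallelic_low < self.biallelic_high <= 1:
            raise ValueError("need 0 <= biallelic_low < biallelic_high <= 1")
        if self.min_depth < 0 or self.expression_threshold < 0:
            raise ValueError("thresholds must be nonnegative")


@dataclass
class AllelicCall:
    """Per-gene allelic status with its supporting statistics."""

    gene_id: str
    chrom: str
    midpoint_coord: float
    status: str
    ref_freq: float | None
    depth: int
    fpkm: float

    @property
    def minor_freq(self) -> float | None:
        if self.ref_freq is None:
            return None
        return min(self.ref_freq, 1.0 - self.ref_freq)


def aggregate_site_counts_to_gene(
    records: Sequence[AlleleCountRecord],
) -> pd.DataFrame:
    """Sum ref/alt counts over each gene's sites.

    Returns a frame indexed by gene_id with columns n_ref, n_alt, depth
    (depth = n_ref + n_alt, the informative reads). Genes with no records
    are absent. The pooled frequency n_ref/depth equals the depth-weighted
    mean of per-site frequencies.
    """
    rows = [
        (r.site.gene_id, r.n_ref, r.n_alt)
        for r in records
        if r.status == "ok"
    ]
    if not rows:
        return pd.DataFrame(columns=["n_ref", "n_alt", "depth"]).rename_axis("gene_id")
    df = pd.DataFrame(rows, columns=["gene_id", "n_ref", "n_alt"])
    agg = df.groupby("gene_id", sort=False).sum()
    agg["depth"] = agg["n_ref"] + agg["n_alt"]
    return agg


def classify_allelic_status(
    ref_freq: float | None,
    fpkm: float,
    depth: int,
    config: ClassificationConfig = ClassificationConfig(),
) -> str:
    """Call one gene's allelic status (see module docstring for the rules)."""
    if fpkm < 0:
        raise ValueError("fpkm must be nonnegative")
    if fpkm < config.expression_threshold:
        return "not_expressed"
    if ref_freq is None or depth < config.min_depth:
        return "no_call"
    if config.biallelic_low <= ref_freq <= config.biallelic_high:
        return "biallelic"
    return "monoallelic"


def classify_sample(
    records: Sequence[AlleleCountRecord],
    sites: Sequence[SnpSite],
    expression: ExpressionMatrix,
    sample: str,
    config: ClassificationConfig = ClassificationConfig(),
) -> list[AllelicCall]:
    """Produce one AllelicCall per gene having at least one SNP site.

    Calls are ordered by (chrom, midpoint coordinate). A gene present in
    the counts but missing from the expression table becomes a ``no_call``
    with a logged warning.
    """
    if sample not in expression.values.columns:
        raise KeyError(f"sample {sample!r} not in expression matrix")
    pooled = aggregate_site_counts_to_gene(records)
    gene_ids = sorted({s.gene_id for s in sites})
    calls = []
    for gene_id in gene_ids:
        if gene_id in pooled.index:
            n_ref = int(pooled.loc[gene_id, "n_ref"])
            depth = int(pooled.loc[gene_id, "depth"])
        else:
            n_ref, depth = 0, 0
        try:
            freq = reference_allele_frequency(n_ref, depth - n_ref)
        except UndefinedAlleleFrequencyError:
            freq = None
        if gene_id in expression.genes.index:
            meta = expression.genes.loc[gene_id]
            chrom = str(meta["chrom"])
            midpoint = (float(meta["start"]) + float(meta["end"])) / 2.0
            fpkm = float(expression.values.loc[gene_id, sample])
            status = classify_allelic_status(freq, fpkm, depth, config)
        else:
            logger.warning("gene %s has counts but no expression row; no_call", gene_id)
            site = next(s for s in sites if s.gene_id == gene_id)
            chrom, midpoint, fpkm = site.chrom, float(site.pos), 0.0
            status = "no_call"
        calls.append(
            AllelicCall(
                gene_id=gene_id, chrom=chrom, midpoint_coord=midpoint,
                status=status, ref_freq=freq, depth=depth, fpkm=fpkm,
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.midpoint_coord, c.gene_id))
    return calls


def chromosome_status_map(
    calls: Sequence[AllelicCall],
) -> tuple[list[tuple[float, str]], dict[str, int]]:
    """Ordered (coordinate, status) track plus a tally per status.

    All calls must lie on one chromosome; tallies sum to the number of
    calls.
    """
    chroms = {c.chrom for c in calls}
    if len(chroms) > 1:
        raise ValueError(f"calls span multiple chromosomes: {sorted(chroms)}")
    ordered = sorted(calls, key=lambda c: (c.midpoint_coord, c.gene_id))
    track = [(c.midpoint_coord, c.status) for c in ordered]
    tally = {s: 0 for s in STATUSES}
    for c in calls:
        tally[c.status] += 1
    return track, tally


def positional_bias_test(
    calls: Sequence[AllelicCall],
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Permutation test for distal clustering of monoallelic genes.

    Statistic: median midpoint coordinate of monoallelic genes minus the
    median midpoint coordinate of biallelic genes. Status labels are
    permuted ``n_perm`` times; the one-sided (toward larger coordinates)
    p-value uses the add-one correction, so p >= 1/(1+n_perm).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    mono = np.array([c.midpoint_coord for c in calls if c.status == "monoallelic"])
    bi = np.array([c.midpoint_coord for c in calls if c.status == "biallelic"])
    if len(mono) < 2 or len(bi) < 2:
        raise ValueError(
            f"need >= 2 monoallelic and >= 2 biallelic calls, "
            f"got {len(mono)} and {len(bi)}"
        )
    observed = float(np.median(mono) - np.median(bi))
    pooled = np.concatenate([mono, bi])
    n, k = len(pooled), len(mono)
    rng = np.random.default_rng(seed)
    # vectorized label permutations: random ranks pick k "monoallelic" slots
    order = np.argsort(rng.random((n_perm, n)), axis=1)
    perm_mono = np.median(pooled[order[:, :k]], axis=1)
    perm_bi = np.median(pooled[order[:, k:]], axis=1)
    exceed = int(np.sum(perm_mono - perm_bi >= observed))
    p = (1 + exceed) / (1 + n_perm)
    return observed, p


def calls_to_frame(calls: Sequence[AllelicCall]) -> pd.DataFrame:
    """Tabular view of calls for TSV output."""
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id, "chrom": c.chrom,
                "midpoint": c.midpoint_coord, "status": c.status,
                "ref_freq": c.ref_freq if c.ref_freq is not None else float("nan"),
                "minor_freq": c.minor_freq if c.minor_freq is not None else float("nan"),
                "depth": c.depth, "fpkm": c.fpkm,
            }
            for c in calls
        ]
    )


def calls_to_bed(calls: Sequence[AllelicCall], expression: ExpressionMatrix) -> str:
    """BED9 (0-based half-open) status track, color-coded per status."""
    lines = []
    for c in sorted(calls, key=lambda x: (x.chrom, x.midpoint_coord)):
        if c.gene_id in expression.genes.index:
            meta = expression.genes.loc[c.gene_id]
            start, end = int(meta["start"]) - 1, int(meta["end"])
        else:
            start, end = int(c.midpoint_coord) - 1, int(c.midpoint_coord)
        lines.append(
            "\t".join(
                [
                    c.chrom, str(max(start, 0)), str(end), f"{c.gene_id}:{c.status}",
                    "0", ".", str(max(start, 0)), str(end), STATUS_COLORS[c.status],
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
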