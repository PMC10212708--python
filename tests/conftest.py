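import numpy as np
import pandas as pd
import pytest

import xciprof as xp


@pytest.fixture
def small_scenario():
    return xp.XCIScenario.preset("partial_erosion", seed=11, n_x_genes=30,
                                 n_chr1_genes=20)


@pytest.fixture
def simulated_bundle(small_scenario):
    """Panel + expression + counts for one partial-erosion sample."""
    genes, sites = xp.make_gene_and_snp_panel(small_scenario)
    expr = xp.simulate_expression(small_scenario, genes, sample_id="S1")
    records = xp.simulate_allele_counts(small_scenario, genes, sites, expr,
                                        sample_id="S1")
    return genes, sites, expr, records


@pytest.fixture
def toy_matrix():
    """Two chrX and two chr1 genes, two samples, hand-set FPKM."""
    genes = pd.DataFrame(
        {
            "chrom": ["chrX", "chrX", "chr1", "chr1"],
            "start": [100, 2000, 100, 5000],
            "end": [1100, 3000, 1100, 6000],
        },
        index=pd.Index(["X1", "X2", "A1", "A2"], name="gene_id"),
    )
    values = pd.DataFrame(
        {"S1": [2.0, 3.0, 4.0, 6.0], "S2": [1.0, 9.0, 5.0, 5.0]},
        index=genes.index,
    )
    return xp.ExpressionMatrix(genes=genes, values=values)


def brute_force_sam_counts(sam_text, site, min_base_quality=20,
                           min_mapping_quality=20):
    """Independent pileup oracle: a per-read scan of the SAM text.

    Handles the fixture alignments (single-end, ungapped, all-M CIGAR) and
    applies the same exclusion rules as the counter.
    """
    n_ref = n_alt = n_other = 0
    for line in sam_text.splitlines():
        if not line or line.startswith("@"):
            continue
        f = line.split("\t")
        flag, chrom, pos, mapq, cigar, seq, qual = (
            int(f[1]), f[2], int(f[3]), int(f[4]), f[5], f[9], f[10])
        if flag & (0x4 | 0x100 | 0x400 | 0x800):
            continue
        if chrom != site.chrom or mapq < min_mapping_quality:
            continue
        assert cigar == f"{len(seq)}M", "oracle only handles ungapped reads"
        offset = site.pos - pos
        if not 0 <= offset < len(seq):
            continue
        if ord(qual[offset]) - 33 < min_base_quality:
            continue
        base = seq[offset].upper()
        if base == site.ref:
            n_ref += 1
        elif base == site.alt:
            n_alt += 1
        else:
            n_other += 1
    return n_ref, n_alt, n_other


def make_calls(coords, statuses, chrom="chrX"):
    return [
        xp.AllelicCall(gene_id=f"g{i}", chrom=chrom, midpoint_coord=float(c),
                       status=s, ref_freq=0.5, depth=100, fpkm=10.0)
        for i, (c, s) in enumerate(zip(coords, statuses))
    ]
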