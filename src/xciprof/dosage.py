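"""Expression-table filters, the X:autosome dosage ratio, DEG fold-change
selection, and the qPCR 2^-ddCt utility.

The X:A ratio — sum of chrX gene FPKM over sum of chr1 gene FPKM — is a
bulk readout of X dosage: it roughly doubles between one and two active X
chromosomes, so post-XCI samples sit near half the pre-XCI value.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd


class UndefinedRatioError(ValueError):
    """Autosomal denominator is empty or zero: the X:A ratio is undefined."""


@dataclass
class ExpressionMatrix:
    """Genes x samples FPKM values with gene coordinates.

    ``genes`` is indexed by gene_id with columns chrom/start/end; ``values``
    shares the index and has one nonnegative column per sample.
    """

    genes: pd.DataFrame
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.genes.index.has_duplicates:
            dups = self.genes.index[self.genes.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene_ids: {dups[:5]}")
        if not self.genes.index.equals(self.values.index):
            raise ValueError("genes and values must share one gene_id index")
        if self.genes["chrom"].isna().any():
            raise ValueError("every gene needs a chrom assignment")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("FPKM values must be nonnegative")

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def to_tsv(self, path: str | Path) -> Path:
        df = pd.concat([self.genes, self.values], axis=1)
        df.insert(0, "gene_id", df.index)
        path = Path(path)
        df.to_csv(path, sep="\t", index=False)
        return path

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str})
        required = ["gene_id", "chrom", "start", "end"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValueError(f"expression table missing columns: {missing}")
        df = df.set_index("gene_id")
        sample_cols = [c for c in df.columns if c not in ("chrom", "start", "end")]
        if not sample_cols:
            raise ValueError("expression table has no sample columns")
        return cls(genes=df[["chrom", "start", "end"]], values=df[sample_cols].astype(float))


@dataclass(frozen=True)
class QpcrRecord:
    """Ct values for the 2^-ddCt method: target and reference gene in a
    test and a control condition."""

    ct_target_test: float
    ct_reference_test: float
    ct_target_control: float
    ct_reference_control: float

    def __post_init__(self) -> None:
        for name in (
            "ct_target_test", "ct_reference_test",
            "ct_target_control", "ct_reference_control",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive, got {v}")


def filter_expressed_genes(
    matrix: ExpressionMatrix, threshold: float = 1.0
) -> ExpressionMatrix:
    """Keep genes reaching ``threshold`` FPKM in at least one sample."""
    keep = (matrix.values >= threshold).any(axis=1)
    return ExpressionMatrix(genes=matrix.genes.loc[keep].copy(),
                            values=matrix.values.loc[keep].copy())


def x_to_autosome_ratio(
    matrix: ExpressionMatrix,
    sample: str,
    x_chrom: str = "chrX",
    autosome_chrom: str = "chr1",
    expression_threshold: float = 1.0,
    apply_expressed_filter: bool = True,
    include_xist: bool = True,
    xist_gene_id: str = "XIST",
) -> float:
    """Sum of chrX FPKM over sum of chr1 FPKM for one sample.

    Computed on the expressed-gene-filtered matrix by default; genes on
    other chromosomes are ignored. XIST is part of the chrX sum unless
    ``include_xist`` is False.
    """
    if sample not in matrix.values.columns:
        raise KeyError(f"sample {sample!r} not in matrix")
    if apply_expressed_filter:
        matrix = filter_expressed_genes(matrix, expression_threshold)
    chrom = matrix.genes["chrom"]
    on_x = chrom == x_chrom
    if not include_xist:
        on_x &= matrix.genes.index != xist_gene_id
    on_a = chrom == autosome_chrom
    x_sum = float(matrix.values.loc[on_x, sample].sum())
    a_sum = float(matrix.values.loc[on_a, sample].sum())
    if on_a.sum() == 0 or a_sum == 0:
        raise UndefinedRatioError(f"no expressed {autosome_chrom} genes for {sample!r}")
    if on_x.sum() == 0:
        raise UndefinedRatioError(f"no expressed {x_chrom} genes for {sample!r}")
    return x_sum / a_sum


@dataclass
class DegResult:
    """DEG selection split by direction."""

    up_in_a: list[str]
    up_in_b: list[str]

    @property
    def selected(self) -> set[str]:
        return set(self.up_in_a) | set(self.up_in_b)


def deg_select(
    matrix: ExpressionMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    fold_threshold: float = 2.0,
    pvalues: "pd.Series | dict[str, float] | None" = None,
    p_threshold: float = 0.05,
    pseudocount: float = 0.01,
) -> DegResult:
    """Fold-change (and optional p-value) DEG selection.

    Fold change is ``(mean FPKM in A + eps) / (mean FPKM in B + eps)`` with a
    small pseudocount; a gene is selected when ``max(FC, 1/FC)`` reaches
    ``fold_threshold`` and, if p-values are supplied, its p-value is below
    ``p_threshold`` (the p criterion is skipped when p-values are absent,
    as in pure fold-change heatmap selections).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    if set(group_a) & set(group_b):
        raise ValueError("groups must be disjoint")
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    for s in list(group_a) + list(group_b):
        if s not in matrix.values.columns:
            raise KeyError(f"sample {s!r} not in matrix")
    if pvalues is not None and not isinstance(pvalues, pd.Series):
        pvalues = pd.Series(pvalues)

    mean_a = matrix.values[list(group_a)].mean(axis=1) + pseudocount
    mean_b = matrix.values[list(group_b)].mean(axis=1) + pseudocount
    fc = mean_a / mean_b
    up_in_a, up_in_b = [], []
    for gene in matrix.values.index:
        f = fc.loc[gene]
        if max(f, 1.0 / f) < fold_threshold:
            continue
        if pvalues is not None:
            if gene not in pvalues.index or pd.isna(pvalues.loc[gene]):
                raise ValueError(f"missing p-value for gene {gene!r}")
            if pvalues.loc[gene] >= p_threshold:
                continue
        (up_in_a if f > 1.0 else up_in_b).append(gene)
    return DegResult(up_in_a=up_in_a, up_in_b=up_in_b)


def ddct_relative_expression(record: QpcrRecord) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt_test = Ct(target, test) - Ct(reference, test); likewise for the
    control condition; the result is ``2 ** -(dCt_test - dCt_control)``.
    """
    dct_test = record.ct_target_test - record.ct_reference_test
    dct_control = record.ct_target_control - record.ct_reference_control
    return float(2.0 ** -(dct_test - dct_control))
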