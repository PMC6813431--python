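"""RPKM normalisation, expressed-gene calling, and differential expression.

Each species is analysed against its designated reference hair-cell type
(zebrafish HC; mouse IHC). Expression values are reads per kilobase of
exon model per million mapped reads (RPKM = count * 1e9 / (L * N)); genes
are called expressed at mean RPKM >= 0.10 with FDR-adjusted p <= 0.10, and
differentially expressed at |log2 fold change| crossing 1.0 with FDR <= 0.10
(up: log2FC >= 1.0; down: log2FC < -1.0 — the asymmetric bounds of the
published rule are preserved).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "rpkm",
    "counts_to_rpkm",
    "anova_pvalue",
    "test_gene",
    "benjamini_hochberg",
    "log2_fold_change",
    "call_de",
    "omnibus_fdr",
    "call_expressed",
    "differential_expression",
    "expression_summary",
]

RPKM_CUTOFF = 0.10
FDR_CUTOFF = 0.10
LFC_THRESHOLD = 1.0
PSEUDOCOUNT = 0.01


def rpkm(count, exonic_length_bp, total_mapped):
    """RPKM = count * 1e9 / (exonic_length_bp * total_mapped). Vectorised."""
    length = np.asarray(exonic_length_bp, dtype=float)
    total = np.asarray(total_mapped, dtype=float)
    if np.any(length <= 0):
        raise ValueError("exonic_length_bp must be > 0")
    if np.any(total <= 0):
        raise ValueError("total_mapped must be > 0")
    return np.asarray(count, dtype=float) * 1e9 / (length * total)


@dataclass
class ExpressionMatrix:
    """Genes x (cell type, replicate) expression values for one species.

    ``values`` has a gene-id index and a two-level (cell_type, replicate)
    column MultiIndex. ``value_kind`` is "counts" or "rpkm"; raw counts
    require per-column ``library_sizes`` (total mapped reads) and per-gene
    ``gene_lengths`` (exonic bp) for RPKM conversion.
    """

    species: str
    values: pd.DataFrame
    reference_type: str
    value_kind: str = "rpkm"
    library_sizes: pd.Series | None = None
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.value_kind not in ("counts", "rpkm"):
            raise ValueError(f"value_kind {self.value_kind!r} not in {{counts, rpkm}}")
        if self.values.columns.nlevels != 2:
            raise ValueError("values needs a (cell_type, replicate) column MultiIndex")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.reference_type not in self.cell_types:
            raise ValueError(
                f"reference_type {self.reference_type!r} not among cell types "
                f"{self.cell_types}"
            )
        if self.value_kind == "counts":
            if self.library_sizes is None:
                raise ValueError("library_sizes required when value_kind='counts'")
            if (self.library_sizes <= 0).any():
                raise ValueError("library_sizes must be > 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for ct in self.values.columns.get_level_values(0):
            seen.setdefault(ct, None)
        return list(seen)

    def replicates(self, cell_type: str) -> pd.DataFrame:
        if cell_type not in self.cell_types:
            raise KeyError(f"unknown cell type {cell_type!r} for species {self.species}")
        return self.values[cell_type]

    def to_rpkm(self) -> "ExpressionMatrix":
        """Convert counts to RPKM using gene lengths and library sizes."""
        if self.value_kind == "rpkm":
            return self
        if self.gene_lengths is None:
            raise ValueError("gene_lengths required to convert counts to RPKM")
        lengths = self.gene_lengths.reindex(self.values.index)
        if lengths.isna().any():
            missing = list(lengths[lengths.isna()].index[:5])
            raise ValueError(f"gene_lengths missing for genes {missing}")
        sizes = self.library_sizes.reindex(self.values.columns)
        vals = rpkm(self.values.values, lengths.values[:, None], sizes.values[None, :])
        return ExpressionMatrix(
            species=self.species,
            values=pd.DataFrame(vals, index=self.values.index, columns=self.values.columns),
            reference_type=self.reference_type,
            value_kind="rpkm",
            library_sizes=self.library_sizes,
            gene_lengths=self.gene_lengths,
        )

    def mean_rpkm(self, cell_type: str) -> pd.Series:
        """Arithmetic mean of replicate RPKM values for one cell type."""
        if self.value_kind != "rpkm":
            raise ValueError("mean_rpkm requires an RPKM matrix; call to_rpkm() first")
        return self.replicates(cell_type).mean(axis=1)


def counts_to_rpkm(matrix: ExpressionMatrix) -> ExpressionMatrix:
    return matrix.to_rpkm()


def anova_pvalue(*groups: Sequence[float], pseudocount: float = PSEUDOCOUNT) -> float:
    """One-way ANOVA p-value across replicate groups of log2(RPKM + pseudocount).

    Degenerate conventions: all groups constant with equal means -> p = 1;
    all groups constant with unequal means -> p = 0; equal group means with
    within-group variance -> p = 1 (F = 0).
    """
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs >= 2 replicates")
    logs = [np.log2(np.asarray(g, dtype=float) + pseudocount) for g in groups]
    within = sum(float(np.sum((x - x.mean()) ** 2)) for x in logs)
    means = [float(x.mean()) for x in logs]
    if within == 0.0:
        return 1.0 if len(set(means)) == 1 else 0.0
    if max(means) == min(means):
        return 1.0
    return float(stats.f_oneway(*logs).pvalue)


def test_gene(
    values_alt: Sequence[float],
    values_ref: Sequence[float],
    pseudocount: float = PSEUDOCOUNT,
) -> float:
    """Two-group per-gene test (one-way ANOVA, equivalent to a t-test)."""
    return anova_pvalue(values_alt, values_ref, pseudocount=pseudocount)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, input order preserved.

    q_(i) = min_{j >= i} (m * p_(j) / j), clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def log2_fold_change(mean_alt, mean_ref, pseudocount: float = PSEUDOCOUNT):
    """log2((mean_alt + pseudocount) / (mean_ref + pseudocount))."""
    return np.log2((np.asarray(mean_alt, dtype=float) + pseudocount)
                   / (np.asarray(mean_ref, dtype=float) + pseudocount))


def call_de(
    log2fc,
    fdr_q,
    log2fc_threshold: float = LFC_THRESHOLD,
    fdr_cutoff: float = FDR_CUTOFF,
):
    """DE call per gene: 'up' iff log2FC >= +threshold and q <= cutoff;
    'down' iff log2FC < -threshold and q <= cutoff; else 'unchanged'.

    The bounds are deliberately asymmetric (>= for up, strict < for down),
    matching the published rule verbatim.
    """
    lfc = np.asarray(log2fc, dtype=float)
    q = np.asarray(fdr_q, dtype=float)
    out = np.full(lfc.shape, "unchanged", dtype=object)
    sig = q <= fdr_cutoff
    out[sig & (lfc >= log2fc_threshold)] = "up"
    out[sig & (lfc < -log2fc_threshold)] = "down"
    if out.ndim == 0:
        return out.item()
    return out


def omnibus_fdr(matrix: ExpressionMatrix, pseudocount: float = PSEUDOCOUNT) -> pd.Series:
    """Per-gene BH q-value from a one-way ANOVA across all cell types.

    This is the gene-level FDR used alongside the RPKM cutoff in the
    expressed-gene call.
    """
    m = matrix.to_rpkm()
    groups = [m.replicates(ct).values for ct in m.cell_types]
    p = np.array([
        anova_pvalue(*[g[i] for g in groups], pseudocount=pseudocount)
        for i in range(len(m.gene_ids))
    ])
    return pd.Series(benjamini_hochberg(p), index=m.values.index, name="fdr_q")


def call_expressed(
    matrix: ExpressionMatrix,
    cell_type: str,
    fdr_q: pd.Series | None = None,
    rpkm_cutoff: float = RPKM_CUTOFF,
    fdr_cutoff: float = FDR_CUTOFF,
    use_fdr: bool = True,
) -> pd.Series:
    """Expressed iff mean replicate RPKM >= cutoff AND gene FDR <= cutoff.

    Both bounds inclusive. ``fdr_q`` defaults to the omnibus ANOVA q-values;
    ``use_fdr=False`` applies the RPKM cutoff alone.
    """
    m = matrix.to_rpkm()
    expressed = m.mean_rpkm(cell_type) >= rpkm_cutoff
    if use_fdr:
        if fdr_q is None:
            fdr_q = omnibus_fdr(m)
        expressed &= fdr_q.reindex(expressed.index) <= fdr_cutoff
    return expressed.rename(f"expressed.{cell_type}")


def differential_expression(
    matrix: ExpressionMatrix,
    pseudocount: float = PSEUDOCOUNT,
    log2fc_threshold: float = LFC_THRESHOLD,
    fdr_cutoff: float = FDR_CUTOFF,
    rpkm_cutoff: float = RPKM_CUTOFF,
) -> pd.DataFrame:
    """Per-gene DE table for every cell type against the species' reference.

    Returns one row per (gene, contrast): mean RPKM in both groups, log2 fold
    change, ANOVA p, BH q (adjusted within each contrast), the up/down/
    unchanged call, and expressed flags at the plain RPKM cutoff.
    """
    m = matrix.to_rpkm()
    ref = m.replicates(m.reference_type)
    mean_ref = ref.mean(axis=1)
    frames = []
    for ct in m.cell_types:
        if ct == m.reference_type:
            continue
        alt = m.replicates(ct)
        mean_alt = alt.mean(axis=1)
        p = np.array([
            anova_pvalue(alt.iloc[i].values, ref.iloc[i].values, pseudocount=pseudocount)
            for i in range(len(m.gene_ids))
        ])
        q = benjamini_hochberg(p)
        lfc = log2_fold_change(mean_alt.values, mean_ref.values, pseudocount)
        frames.append(pd.DataFrame({
            "gene_id": m.gene_ids,
            "contrast": f"{ct}_vs_{m.reference_type}",
            "cell_type": ct,
            "mean_ref": mean_ref.values,
            "mean_alt": mean_alt.values,
            "log2fc": lfc,
            "p_value": p,
            "fdr_q": q,
            "call": call_de(lfc, q, log2fc_threshold, fdr_cutoff),
            "expressed_alt": mean_alt.values >= rpkm_cutoff,
            "expressed_ref": mean_ref.values >= rpkm_cutoff,
        }))
    if not frames:
        raise ValueError("matrix has no non-reference cell types to contrast")
    return pd.concat(frames, ignore_index=True)


def expression_summary(
    matrix: ExpressionMatrix,
    rpkm_cutoff: float = RPKM_CUTOFF,
    fdr_cutoff: float = FDR_CUTOFF,
    use_fdr: bool = True,
) -> pd.DataFrame:
    """Per-gene mean RPKM and expressed flag for every cell type."""
    m = matrix.to_rpkm()
    fdr_q = omnibus_fdr(m) if use_fdr else None
    out = {}
    for ct in m.cell_types:
        out[f"mean_rpkm.{ct}"] = m.mean_rpkm(ct)
        out[f"expressed.{ct}"] = call_expressed(
            m, ct, fdr_q=fdr_q, rpkm_cutoff=rpkm_cutoff,
            fdr_cutoff=fdr_cutoff, use_fdr=use_fdr,
        )
    return pd.DataFrame(out)
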