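"""Two-group differential expression and seed-gene derivation.

Per-gene significance comes from a one-way two-group ANOVA (equivalently the
pooled-variance t-test; F = t^2) on the log2 matrix, followed by
Benjamini-Hochberg step-up FDR control. Fold change is computed on the log2
scale and reported as signed linear FC: for a log2 case-control difference d,
signed_fc = sign(d) * 2^|d|, so -4 means four-fold down in cases and
|signed_fc| is always >= 1. Genes passing |FC| > fc_cut and adjusted p <
q_cut (both strict) and also present on the copy-number-altered list become
the seed genes for network expansion.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from subnetmark.data_io import ExpressionMatrix, GeneList, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class DifferentialResult:
    """Per-gene differential expression table.

    ``table`` columns: mean_case, mean_control (log2), signed_fc (linear,
    sign = direction), p_value, adj_p, direction ("up"/"down"); index = gene
    symbols.
    """

    table: pd.DataFrame

    @property
    def genes(self) -> list[str]:
        return list(self.table.index)

    def to_tsv(self, path, fc_cut: float = 2.0, q_cut: float = 0.05) -> None:
        out = self.table.copy()
        out["selected"] = (np.abs(out["signed_fc"]) > fc_cut) & (out["adj_p"] < q_cut)
        out.to_csv(path, sep="\t", index_label="gene")


@dataclass
class SeedGeneSet:
    """Genes both differentially expressed and copy-number altered."""

    symbols: set[str]

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self):
        return iter(sorted(self.symbols))


def differential_expression(expr: ExpressionMatrix) -> DifferentialResult:
    """Two-group ANOVA p-value and signed linear fold change per gene.

    Requires class labels with at least two samples in each group. Genes with
    zero pooled within-group variance get p = 0 when the group means differ
    and p = 1 otherwise, with a warning (constant genes carry no sampling
    noise, so any mean difference is taken at face value).
    """
    if expr.class_labels is None:
        raise ValidationError("expression matrix has no class labels")
    case_ids = expr.samples_in_class("case")
    control_ids = expr.samples_in_class("control")
    n1, n2 = len(case_ids), len(control_ids)
    if n1 < 2 or n2 < 2:
        raise ValidationError(
            f"need >=2 samples per class, got case={n1}, control={n2}"
        )
    col = {s: j for j, s in enumerate(expr.sample_ids)}
    x = expr.values[:, [col[s] for s in case_ids]]
    y = expr.values[:, [col[s] for s in control_ids]]

    mean_case = x.mean(axis=1)
    mean_control = y.mean(axis=1)
    d = mean_case - mean_control

    ss1 = ((x - mean_case[:, None]) ** 2).sum(axis=1)
    ss2 = ((y - mean_control[:, None]) ** 2).sum(axis=1)
    df = n1 + n2 - 2
    pooled_var = (ss1 + ss2) / df

    p = np.ones(expr.n_genes)
    nz = pooled_var > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = d[nz] / np.sqrt(pooled_var[nz] * (1.0 / n1 + 1.0 / n2))
    # two-group one-way ANOVA: F = t^2 on (1, df) degrees of freedom
    p[nz] = stats.f.sf(t**2, 1, df)
    if (~nz).any():
        n_degenerate = int((~nz).sum())
        warnings.warn(
            f"{n_degenerate} genes with zero within-group variance; "
            "p set to 0 (means differ) or 1 (identical)"
        )
        p[~nz] = np.where(d[~nz] != 0, 0.0, 1.0)

    signed_fc = np.where(d == 0, 1.0, np.sign(d) * 2.0 ** np.abs(d))
    table = pd.DataFrame(
        {
            "mean_case": mean_case,
            "mean_control": mean_control,
            "signed_fc": signed_fc,
            "p_value": p,
            "adj_p": bh_adjust(p),
            "direction": np.where(d > 0, "up", "down"),
        },
        index=pd.Index(expr.gene_ids, name="gene"),
    )
    return DifferentialResult(table)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_p(i) = min over j with rank(j) >= rank(i) of p(j) * m / rank(j),
    capped at 1; the input order is preserved in the output.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    out = np.empty(m)
    out[order] = adjusted
    return out


def select_degs(
    results: DifferentialResult, fc_cut: float = 2.0, q_cut: float = 0.05
) -> GeneList:
    """Genes with |signed_fc| > fc_cut AND adj_p < q_cut (strict cutoffs)."""
    t = results.table
    mask = (np.abs(t["signed_fc"]) > fc_cut) & (t["adj_p"] < q_cut)
    symbols = list(t.index[mask])
    if not symbols:
        warnings.warn("no genes pass the DEG cutoffs")
    logger.info("selected %d DEGs of %d genes", len(symbols), len(t))
    return GeneList(symbols, source_tag="DEG")


def intersect_seeds(degs: GeneList, cna: GeneList) -> SeedGeneSet:
    """Venn intersection of the DEG list with the copy-number-altered list."""
    if len(degs) == 0 or len(cna) == 0:
        raise ValidationError("both gene lists must be non-empty")
    deg_set, cna_set = degs.as_set(), cna.as_set()
    shared = deg_set & cna_set
    logger.info(
        "seed intersection: DEG-only=%d, CNA-only=%d, shared=%d",
        len(deg_set - cna_set), len(cna_set - deg_set), len(shared),
    )
    if not shared:
        warnings.warn("DEG and CNA lists are disjoint; seed set is empty")
    return SeedGeneSet(shared)
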