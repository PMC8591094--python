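"""Per-sample subnetwork activity scores.

Expression is first standardized gene-wise across samples (z-transform,
sample standard deviation with n-1 denominator). A subnetwork's activity in
a sample is the mean z of its up-regulated members minus the mean z of its
down-regulated members; up/down membership is decided once, on training
data, by the sign of the case-control mean difference of every member gene.
Validation cohorts are z-scored within themselves (cross-platform scales
differ) while the training up/down assignments are frozen, so the marker
definition travels unchanged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from subnetmark.data_io import ExpressionMatrix, ValidationError
from subnetmark.diffexpr import DifferentialResult
from subnetmark.mcl import Subnetwork

logger = logging.getLogger(__name__)

#: Subnetworks with fewer than this fraction of scorable members are flagged.
MIN_COVERAGE = 0.5


@dataclass
class SubnetworkScoreMatrix:
    """Subnetworks x samples activity scores (rows indexed by subnetwork id)."""

    scores: pd.DataFrame  # index: subnetwork ids, columns: sample ids
    coverage: dict[int, float] | None = None  # fraction of members scorable

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.scores.to_numpy())):
            raise ValidationError("non-finite subnetwork scores")

    @property
    def subnetwork_ids(self) -> list[int]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    def to_tsv(self, path) -> None:
        self.scores.to_csv(path, sep="\t", index_label="subnetwork")


def zscore(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene row to mean 0 / sd 1 (n-1 denominator).

    Zero-variance rows are dropped with a warning — they carry no
    between-sample signal and would divide by zero.
    """
    if expr.n_samples < 2:
        raise ValidationError("z-transform needs at least 2 samples")
    values = expr.values
    mu = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    keep = sd[:, 0] > 0
    if not keep.all():
        warnings.warn(f"dropped {int((~keep).sum())} zero-variance genes in z-transform")
    z = (values[keep] - mu[keep]) / sd[keep]
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    return ExpressionMatrix(genes, list(expr.sample_ids), z, expr.class_labels)


def assign_directions(
    subnet: Subnetwork,
    de: DifferentialResult | None,
    expr: ExpressionMatrix,
) -> Subnetwork:
    """Fill the up/down partition from training-data group mean differences.

    Every member gene present in the training matrix is assigned by the sign
    of mean(case) - mean(control): positive -> up, negative -> down, exact
    tie -> neither. ``de`` is accepted for callers that already computed the
    differential table (its means are used when available); otherwise means
    come straight from the labelled matrix. Members missing from the matrix
    are excluded with a warning.
    """
    if expr.class_labels is None:
        raise ValidationError("training expression needs class labels")
    case_ids = expr.samples_in_class("case")
    control_ids = expr.samples_in_class("control")
    col = {s: j for j, s in enumerate(expr.sample_ids)}
    gene_row = {g: i for i, g in enumerate(expr.gene_ids)}

    up, down, missing = set(), set(), []
    for gene in sorted(subnet.members):
        if de is not None and gene in de.table.index:
            diff = de.table.at[gene, "mean_case"] - de.table.at[gene, "mean_control"]
        elif gene in gene_row:
            row = expr.values[gene_row[gene]]
            diff = (
                row[[col[s] for s in case_ids]].mean()
                - row[[col[s] for s in control_ids]].mean()
            )
        else:
            missing.append(gene)
            continue
        if diff > 0:
            up.add(gene)
        elif diff < 0:
            down.add(gene)
    if missing:
        warnings.warn(
            f"subnetwork {subnet.id}: {len(missing)} members absent from the "
            "expression matrix; excluded from scoring"
        )
    if not up and not down:
        raise ValidationError(f"subnetwork {subnet.id} has no scorable gene")
    return Subnetwork(
        id=subnet.id,
        members=set(subnet.members),
        seed_members=set(subnet.seed_members),
        up_set=up,
        down_set=down,
    )


def activity_scores(
    subnets: list[Subnetwork], zexpr: ExpressionMatrix
) -> SubnetworkScoreMatrix:
    """SS_i(sample) = mean z over up_set minus mean z over down_set.

    Genes missing from ``zexpr`` (e.g. a validation platform without them)
    are dropped from their sets; an empty up or down term contributes 0.
    Per-subnetwork coverage (scorable members / members) is reported, and a
    subnetwork below 50% coverage is flagged with a warning.
    """
    if not subnets:
        raise ValidationError("no subnetworks to score")
    gene_row = {g: i for i, g in enumerate(zexpr.gene_ids)}
    n_samples = zexpr.n_samples
    rows = np.zeros((len(subnets), n_samples))
    coverage: dict[int, float] = {}
    for k, sn in enumerate(subnets):
        up = [gene_row[g] for g in sn.up_set if g in gene_row]
        down = [gene_row[g] for g in sn.down_set if g in gene_row]
        directed = len(sn.up_set) + len(sn.down_set)
        coverage[sn.id] = (len(up) + len(down)) / directed if directed else 0.0
        if coverage[sn.id] < MIN_COVERAGE:
            warnings.warn(
                f"subnetwork {sn.id}: only {coverage[sn.id]:.0%} of directed "
                "members present in this matrix"
            )
        up_term = zexpr.values[up].mean(axis=0) if up else np.zeros(n_samples)
        down_term = zexpr.values[down].mean(axis=0) if down else np.zeros(n_samples)
        rows[k] = up_term - down_term
    scores = pd.DataFrame(
        rows,
        index=pd.Index([sn.id for sn in subnets], name="subnetwork"),
        columns=zexpr.sample_ids,
    )
    return SubnetworkScoreMatrix(scores, coverage=coverage)
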