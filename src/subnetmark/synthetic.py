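"""Seeded generators emulating every input the pipeline consumes.

The generators mirror the statistical structure of a two-class microarray
study with matched copy-number calls, an interaction database and a
survival cohort:

* ``gen_expression`` — log2 intensities, baseline Normal(7, 1) per gene,
  i.i.d. Normal(0, noise_sd) noise; a fraction of genes is shifted by
  +/- effect_log2 in cases (sign random, recorded as ground truth).
* ``gen_ppi`` — a planted-partition interaction graph (edge probability
  p_in within blocks, p_out between). True-DE genes are packed into the
  leading blocks so the planted "marker subnetworks" exist by construction,
  and the copy-number list is built from a fraction of the in-graph DE
  genes plus non-DE decoys, so the seed intersection lands inside the
  planted blocks.
* ``gen_survival`` — exponential event times with proportional hazards
  baseline_hazard * exp(survival_beta * standardized risk), independent
  Uniform(0, u) censoring with u solved to hit the requested censoring
  fraction in expectation, and independently drawn clinical covariates.

Everything is bitwise reproducible for a fixed ``rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from subnetmark.data_io import ClinicalTable, ExpressionMatrix, GeneList

__all__ = ["SyntheticSpec", "gen_expression", "gen_ppi", "gen_survival", "replace"]


@dataclass
class SyntheticSpec:
    """Study-design parameters for the generators (defaults = test conditions).

    Expression: ``n_genes`` genes, ``n_case``/``n_control`` samples,
    ``de_fraction`` of genes truly differential with log2 effect
    ``effect_log2`` and residual sd ``noise_sd``. Network: ``n_blocks``
    planted blocks of ``block_size`` nodes with edge probabilities ``p_in``
    / ``p_out``. ``seed_overlap_fraction`` of the in-graph DE genes enter
    the copy-number list. Survival: log hazard ratio ``survival_beta`` per
    sd of risk, exponential baseline ``baseline_hazard``, ``censor_rate``
    expected censoring fraction.
    """

    n_genes: int = 500
    n_case: int = 30
    n_control: int = 30
    de_fraction: float = 0.10
    effect_log2: float = 2.0
    noise_sd: float = 0.5
    n_blocks: int = 5
    block_size: int = 8
    p_in: float = 0.6
    p_out: float = 0.05
    seed_overlap_fraction: float = 0.5
    survival_beta: float = 1.0
    baseline_hazard: float = 0.02
    censor_rate: float = 0.2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.de_fraction < 1:
            raise ValueError("de_fraction must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not (0 <= self.p_out <= self.p_in <= 1):
            raise ValueError("need 0 <= p_out <= p_in <= 1 for planted structure")
        if self.n_blocks * self.block_size > self.n_genes:
            raise ValueError("n_blocks * block_size exceeds n_genes")
        if not 0 <= self.censor_rate < 1:
            raise ValueError("censor_rate must lie in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")


def gen_expression(
    spec: SyntheticSpec,
    sample_prefix: str = "",
    truth: dict[str, int] | None = None,
) -> tuple[ExpressionMatrix, dict[str, int]]:
    """Two-class log2 expression matrix plus ground-truth DE labels.

    Returns the matrix (class labels attached) and a map gene -> truth,
    where truth is +1 (up in cases), -1 (down) or 0 (null). Passing a
    ``truth`` map imposes the differential structure instead of sampling
    it — this is how an independent validation cohort shares the training
    cohort's true markers while drawing fresh baselines and noise.
    """
    rng = np.random.default_rng(spec.rng_seed)
    genes = [f"G{i:05d}" for i in range(1, spec.n_genes + 1)]
    cases = [f"{sample_prefix}T{i:03d}" for i in range(1, spec.n_case + 1)]
    controls = [f"{sample_prefix}N{i:03d}" for i in range(1, spec.n_control + 1)]

    if truth is None:
        n_de = int(round(spec.de_fraction * spec.n_genes))
        if n_de < 1:
            import warnings

            warnings.warn("de_fraction * n_genes < 1: no differential genes generated")
        de_idx = rng.choice(spec.n_genes, size=n_de, replace=False)
        signs = rng.choice([-1, 1], size=n_de)
        truth = {g: 0 for g in genes}
        for i, s in zip(de_idx, signs):
            truth[genes[i]] = int(s)
    else:
        if set(truth) != set(genes):
            raise ValueError("truth map must cover exactly the generated genes")
        truth = dict(truth)
    shift = np.array([truth[g] * spec.effect_log2 for g in genes])

    baseline = rng.normal(7.0, 1.0, size=spec.n_genes)
    n_samples = spec.n_case + spec.n_control
    values = baseline[:, None] + rng.normal(0, spec.noise_sd, (spec.n_genes, n_samples))
    values[:, : spec.n_case] += shift[:, None]

    labels = {s: "case" for s in cases} | {s: "control" for s in controls}
    return ExpressionMatrix(genes, cases + controls, values, labels), truth


def gen_ppi(
    spec: SyntheticSpec, de_labels: dict[str, int]
) -> tuple[list[tuple[str, str]], list[set[str]], GeneList]:
    """Planted-partition interaction graph, true blocks, and the CNA list.

    DE genes fill the leading blocks (so whole blocks are enriched for
    signal); remaining slots take null genes. The copy-number list holds
    ``seed_overlap_fraction`` of the in-graph DE genes plus an equal number
    of null decoys, half in-graph and half outside.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    de_genes = sorted(g for g, t in de_labels.items() if t != 0)
    null_genes = sorted(g for g, t in de_labels.items() if t == 0)
    n_nodes = spec.n_blocks * spec.block_size

    members = (de_genes + null_genes)[:n_nodes]
    blocks = [
        set(members[b * spec.block_size : (b + 1) * spec.block_size])
        for b in range(spec.n_blocks)
    ]

    node_block = np.repeat(np.arange(spec.n_blocks), spec.block_size)
    edges: list[tuple[str, str]] = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            p = spec.p_in if node_block[i] == node_block[j] else spec.p_out
            if rng.random() < p:
                a, b = members[i], members[j]
                edges.append((min(a, b), max(a, b)))
    edges.sort()

    de_in_graph = sorted(set(de_genes) & set(members))
    n_cna_de = int(round(spec.seed_overlap_fraction * len(de_in_graph)))
    cna_de = sorted(rng.choice(de_in_graph, size=n_cna_de, replace=False)) if n_cna_de else []
    null_in = sorted(set(null_genes) & set(members))
    null_out = sorted(set(null_genes) - set(members))
    n_half = max(n_cna_de // 2, 1)
    decoys = (
        list(rng.choice(null_in, size=min(n_half, len(null_in)), replace=False))
        + list(rng.choice(null_out, size=min(n_half, len(null_out)), replace=False))
    )
    cna = GeneList(sorted(set(cna_de) | set(decoys)), source_tag="CNA")
    return edges, blocks, cna


def gen_survival(risk: pd.Series, spec: SyntheticSpec) -> ClinicalTable:
    """Exponential proportional-hazards survival driven by a risk covariate.

    The per-sample hazard is baseline_hazard * exp(survival_beta * z(risk));
    censoring times are Uniform(0, u) with u solved so that the expected
    censoring fraction equals ``censor_rate`` (0 -> no censoring at all).
    Clinical covariates are drawn independently of survival: age >= 50 with
    probability 0.8, female 0.5, stage III-IV 0.45, lymphatic invasion 0.35.
    """
    values = np.asarray(risk, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("risk values must be finite")
    rng = np.random.default_rng(spec.rng_seed + 2)
    sd = values.std(ddof=1) if len(values) > 1 else 0.0
    z = (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)
    hazard = spec.baseline_hazard * np.exp(spec.survival_beta * z)
    event_time = rng.exponential(1.0 / hazard)

    if spec.censor_rate > 0:
        upper = _censor_horizon(hazard, spec.censor_rate)
        censor_time = rng.uniform(0, upper, size=len(values))
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time, event = event_time, np.ones(len(values), dtype=int)

    n = len(values)
    frame = pd.DataFrame(
        {
            "time": time,
            "event": event,
            "age_group": np.where(rng.random(n) < 0.8, ">=50", "<50"),
            "gender": np.where(rng.random(n) < 0.5, "female", "male"),
            "stage_group": np.where(rng.random(n) < 0.45, "III-IV", "I-II"),
            "lymphatic_invasion": np.where(rng.random(n) < 0.35, "yes", "no"),
        },
        index=pd.Index(risk.index, name="sample"),
    )
    return ClinicalTable(frame)


def _censor_horizon(hazard: np.ndarray, censor_rate: float) -> float:
    """Solve for the Uniform(0, u) horizon hitting the target censor fraction.

    A subject is censored when its event time exceeds its censoring time;
    with T ~ Exp(lambda) and C ~ U(0, u) that is P(T > C) = E[e^(-lambda C)]
    = (1 - e^(-lambda u)) / (lambda u), monotone decreasing in u. The mean
    over the cohort's hazards is bracketed and solved by Brent's method.
    """

    def expected_censoring(u: float) -> float:
        lu = hazard * u
        return float(np.mean((1.0 - np.exp(-lu)) / lu))

    scale = 1.0 / hazard.mean()
    lo, hi = 1e-6 * scale, 1e6 * scale
    return brentq(lambda u: expected_censoring(u) - censor_rate, lo, hi)
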