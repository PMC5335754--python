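"""Gamma-Gamma expression generation and per-gene differential testing.

The hierarchical Gamma-Gamma (GG) model draws a latent per-gene scale
β_g ~ Gamma(shape α0, scale ν) and observed expression y ~ Gamma(shape α,
scale β_g), so the gene mean is μ_g = α β_g and the marginal mean over genes
is α·α0·ν.  An equally expressed (EE) gene shares one β_g across both
phenotypes; a differentially expressed (DE) gene draws independent scales
for case and control, so its two condition means differ with probability 1.
Defaults follow the classical GG calibration α = 10, α0 = 0.9, ν = 0.5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class GGParams:
    """Gamma-Gamma simulation parameters.

    alpha : observation shape α (> 0)
    alpha0 : scale-prior shape α0 (> 0)
    nu : scale-prior scale ν (> 0); set ``nu_is_rate=True`` to read ν as a
        rate (scale 1/ν) instead
    n_case, n_control : samples per phenotype
    seed : RNG seed
    """

    alpha: float = 10.0
    alpha0: float = 0.9
    nu: float = 0.5
    n_case: int = 50
    n_control: int = 50
    nu_is_rate: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.alpha, self.alpha0, self.nu) <= 0:
            raise ValueError("alpha, alpha0 and nu must be positive")
        if self.n_case < 1 or self.n_control < 1:
            raise ValueError("need at least one sample per phenotype")

    @property
    def prior_scale(self) -> float:
        return 1.0 / self.nu if self.nu_is_rate else self.nu


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with phenotype labels.

    ``values`` is a DataFrame (rows = genes, columns = sample IDs);
    ``labels`` maps each sample ID to ``"case"`` or ``"control"``.
    """

    values: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if not self.values.columns.equals(self.labels.index):
            raise ValueError("labels index must match sample columns")

    @property
    def case(self) -> pd.DataFrame:
        return self.values.loc[:, self.labels == "case"]

    @property
    def control(self) -> pd.DataFrame:
        return self.values.loc[:, self.labels == "control"]

    def write(self, values_path, labels_path) -> None:
        self.values.rename_axis("gene").to_csv(values_path, sep="\t",
                                               float_format="%.10g")
        self.labels.rename_axis("sample").rename("phenotype").to_csv(
            labels_path, sep="\t")

    @classmethod
    def read(cls, values_path, labels_path) -> "ExpressionMatrix":
        values = pd.read_csv(values_path, sep="\t", index_col=0)
        labels = pd.read_csv(labels_path, sep="\t", index_col=0).iloc[:, 0]
        return cls(values, labels)


def gg_density(y, alpha: float, beta_g: float):
    """Gamma(shape α, scale β_g) density p(y|α, β_g) of the GG model.

    The distribution mean is μ_g = α β_g.  Accepts scalars or arrays;
    every y must be positive.
    """
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("y must be positive")
    out = stats.gamma.pdf(y, a=alpha, scale=beta_g)
    return float(out) if out.ndim == 0 else out


def generate_expression(genes: Sequence, states: pd.Series,
                        params: GGParams) -> ExpressionMatrix:
    """Simulate case/control expression for ``genes`` given binary states.

    EE genes (state 0) share one latent scale β_g between phenotypes; DE
    genes (state 1) get independent case and control scales from the same
    Gamma(α0, ν) prior.  Reproducible for a fixed seed; the per-gene draws
    do not depend on which other genes are present.
    """
    missing = [g for g in genes if g not in states.index]
    if missing:
        raise ValueError(f"states missing genes: {missing[:5]}")
    # Independent streams per block so e.g. changing n_case cannot perturb
    # the control draws.
    ss_beta, ss_case, ss_ctrl = np.random.SeedSequence(params.seed).spawn(3)
    n_genes = len(genes)
    nc, nn = params.n_case, params.n_control
    scale = params.prior_scale
    # Draw one scale per gene-condition; EE genes reuse the case scale.
    rng_beta = np.random.default_rng(ss_beta)
    beta_case = rng_beta.gamma(shape=params.alpha0, scale=scale, size=n_genes)
    beta_ctrl = rng_beta.gamma(shape=params.alpha0, scale=scale, size=n_genes)
    de = states.loc[list(genes)].to_numpy().astype(bool)
    beta_ctrl = np.where(de, beta_ctrl, beta_case)
    case = np.random.default_rng(ss_case).gamma(
        shape=params.alpha, scale=beta_case[:, None], size=(n_genes, nc))
    ctrl = np.random.default_rng(ss_ctrl).gamma(
        shape=params.alpha, scale=beta_ctrl[:, None], size=(n_genes, nn))
    samples = ([f"case_{i+1:03d}" for i in range(nc)]
               + [f"control_{i+1:03d}" for i in range(nn)])
    values = pd.DataFrame(np.hstack([case, ctrl]), index=list(genes),
                          columns=samples)
    labels = pd.Series(["case"] * nc + ["control"] * nn, index=samples,
                       name="phenotype")
    return ExpressionMatrix(values, labels)


_P_FLOOR = 1e-300


def differential_test(expr: ExpressionMatrix,
                      method: str = "welch") -> pd.DataFrame:
    """Per-gene two-sided case-vs-control test.

    ``method``: ``"welch"`` (default, unequal-variance t), ``"student"``
    (pooled-variance t) or ``"wilcoxon"`` (rank-sum; its t_statistic column
    holds the normalized U statistic).

    Returns a DataFrame indexed by gene with columns ``t_statistic``,
    ``p_value`` and ``z_score`` where z = Φ⁻¹(1 − p/2)·sign(t).  Genes with
    zero variance in both groups get p = 1, z = 0 (logged).
    """
    case = expr.case.to_numpy()
    ctrl = expr.control.to_numpy()
    if case.shape[1] < 2 or ctrl.shape[1] < 2:
        raise ValueError("need >= 2 samples per phenotype")
    with np.errstate(divide="ignore", invalid="ignore"):
        if method == "welch":
            t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=False)
        elif method == "student":
            t, p = stats.ttest_ind(case, ctrl, axis=1, equal_var=True)
        elif method == "wilcoxon":
            res = stats.mannwhitneyu(case, ctrl, axis=1,
                                     alternative="two-sided")
            n1, n2 = case.shape[1], ctrl.shape[1]
            t = (res.statistic - n1 * n2 / 2) / np.sqrt(
                n1 * n2 * (n1 + n2 + 1) / 12.0)
            p = res.pvalue
        else:
            raise ValueError(f"unknown test method {method!r}")
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(t) | ~np.isfinite(p)
    if degenerate.any():
        logger.warning("%d genes with zero variance in both groups: "
                       "p set to 1, z to 0", int(degenerate.sum()))
        t[degenerate] = 0.0
        p[degenerate] = 1.0
    p = np.clip(p, _P_FLOOR, 1.0)
    z = stats.norm.isf(p / 2.0) * np.sign(t)
    z[t == 0] = 0.0
    return pd.DataFrame(
        {"t_statistic": t, "p_value": p, "z_score": z},
        index=expr.values.index.rename("gene"))


def write_de_results(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", float_format="%.10g")


def read_de_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
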