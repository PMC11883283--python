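"""Self-contained differential expression for integer count matrices.

Implements the normalization and testing layer of the RNA-seq workflow:
trimmed-mean-of-M-values (TMM) scaling factors, a pooled method-of-moments
negative-binomial dispersion, and a per-gene conditional NB exact test.
The design is the study's: two genotypes (WT, MUT) x two conditions
(uninjured, regenerating) with replicate hearts per cell, contrasted as
regenerating vs uninjured within each genotype.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .stats_core import bh_adjust

__all__ = [
    "CountExperiment",
    "NormFactors",
    "tmm_factors",
    "common_dispersion",
    "nb_exact_test",
    "read_counts_tsv",
    "read_design_tsv",
]

GENOTYPES = ("WT", "MUT")
CONDITIONS = ("uninjured", "regenerating")


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    genotype: str
    condition: str
    replicate: int

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")


class CountExperiment:
    """Gene x sample integer count matrix with a genotype/condition design.

    Parameters
    ----------
    counts
        Non-negative integer array, shape (n_genes, n_samples).
    genes
        Unique gene identifiers, length n_genes.
    samples
        One :class:`SampleInfo` (or (id, genotype, condition, replicate)
        tuple) per column.
    """

    def __init__(self, counts, genes, samples) -> None:
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-D (genes x samples)")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if not np.all(counts == np.floor(counts)):
            raise ValueError("counts must be integers")
        self.counts = counts.astype(np.int64)
        self.genes = list(genes)
        if len(self.genes) != counts.shape[0]:
            raise ValueError("gene list length does not match counts rows")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("gene identifiers must be unique")
        self.samples = [
            s if isinstance(s, SampleInfo) else SampleInfo(*s) for s in samples
        ]
        if len(self.samples) != counts.shape[1]:
            raise ValueError("sample list length does not match counts columns")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample ids must be unique")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def columns(self, genotype: str | None = None, condition: str | None = None) -> list[int]:
        """Column indices matching a genotype and/or condition."""
        out = []
        for j, s in enumerate(self.samples):
            if genotype is not None and s.genotype != genotype:
                continue
            if condition is not None and s.condition != condition:
                continue
            out.append(j)
        return out

    def subset_samples(self, cols) -> "CountExperiment":
        cols = list(cols)
        return CountExperiment(
            self.counts[:, cols], self.genes, [self.samples[j] for j in cols]
        )


@dataclass(frozen=True)
class NormFactors:
    """Per-sample TMM scaling factors and library sizes.

    Factors are re-centred to geometric mean 1; effective library size of
    sample j is ``lib_sizes[j] * factors[j]``.
    """

    factors: np.ndarray
    lib_sizes: np.ndarray
    warnings: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "factors", np.asarray(self.factors, dtype=float))
        object.__setattr__(self, "lib_sizes", np.asarray(self.lib_sizes, dtype=float))
        if np.any(self.factors <= 0):
            raise ValueError("TMM factors must be positive")
        lg = np.mean(np.log(self.factors))
        if abs(lg) > 1e-8:
            raise ValueError("TMM factors must have geometric mean 1")

    @property
    def effective_sizes(self) -> np.ndarray:
        return self.factors * self.lib_sizes


def _tmm_pair(obs, obs_lib, ref, ref_lib, logratio_trim, abs_expr_trim):
    """TMM factor of one sample against the reference (log2 scale).

    Genes zero in either profile are dropped; the remaining M-values are
    doubly trimmed (by M rank and by A rank), and the surviving M-values
    are averaged with inverse asymptotic binomial-variance weights.
    Returns (log2_factor, n_kept).
    """
    keep = (obs > 0) & (ref > 0)
    if not np.any(keep):
        return 0.0, 0
    yo = obs[keep].astype(float)
    yr = ref[keep].astype(float)
    po = yo / obs_lib
    pr = yr / ref_lib
    m = np.log2(po / pr)
    a = 0.5 * np.log2(po * pr)
    w = (obs_lib - yo) / (obs_lib * yo) + (ref_lib - yr) / (ref_lib * yr)

    n = len(m)
    lo_m = np.floor(n * logratio_trim / 2.0) + 1.0
    hi_m = n + 1.0 - lo_m
    lo_a = np.floor(n * abs_expr_trim / 2.0) + 1.0
    hi_a = n + 1.0 - lo_a
    # average ranks so exactly tied values are kept or dropped together
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep2) or np.sum(w[keep2]) == 0.0:
        return 0.0, 0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    if not np.isfinite(f):
        return 0.0, 0
    return float(f), int(np.sum(keep2))


def _choose_reference(counts: np.ndarray, lib_sizes: np.ndarray) -> int:
    """Sample whose upper-quartile relative expression is closest to the mean."""
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = counts / lib_sizes
    uq = np.quantile(rel, 0.75, axis=0)
    return int(np.argmin(np.abs(uq - uq.mean())))


def tmm_factors(
    exp: CountExperiment,
    reference: str | None = None,
    logratio_trim: float = 0.30,
    abs_expr_trim: float = 0.05,
) -> NormFactors:
    """Trimmed-mean-of-M-values normalization factors.

    For each sample a scaling factor is computed against a reference
    sample: genes zero in either profile are dropped, the M-values
    (log2 relative-abundance ratios) are trimmed 30% (15% per tail) and
    the A-values (mean log2 abundance) 5% (2.5% per tail), and the
    remaining M-values are combined in a precision-weighted mean which is
    exponentiated. Factors are re-centred so their geometric mean is 1.

    Parameters
    ----------
    exp
        The count experiment (>= 2 samples).
    reference
        Sample id to normalize against; default picks the sample whose
        upper-quartile relative expression is closest to the mean upper
        quartile.
    """
    if exp.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = exp.library_sizes().astype(float)
    if np.any(lib == 0):
        raise ValueError("sample with zero library size")
    if reference is None:
        ref_j = _choose_reference(exp.counts, lib)
    else:
        ref_j = exp.sample_ids.index(reference)

    warnings: list[str] = []
    log2f = np.zeros(exp.n_samples)
    for j in range(exp.n_samples):
        if j == ref_j:
            continue
        f, kept = _tmm_pair(
            exp.counts[:, j], lib[j], exp.counts[:, ref_j], lib[ref_j],
            logratio_trim, abs_expr_trim,
        )
        if kept == 0:
            warnings.append(
                f"sample {exp.sample_ids[j]}: no genes survive trimming; factor 1"
            )
            f = 0.0
        log2f[j] = f
    factors = 2.0 ** (log2f - log2f.mean())
    return NormFactors(factors, lib, tuple(warnings))


def common_dispersion(exp: CountExperiment, groups: list[list[int]] | None = None,
                      factors: NormFactors | None = None) -> float:
    """Pooled NB dispersion by method of moments on normalized counts.

    With NB counts, var = mu + phi * mu^2, so each (gene, group) pair
    yields a moment estimate z = (s^2 - mu_hat) / mu_hat^2 of phi on
    counts rescaled to a common effective library size. The pooled
    estimate is the clipped mean of z over all pairs with mean >= 5
    (below that the per-gene moments are dominated by Poisson noise).
    Averaging per-gene z values bounds each gene's influence — a
    sum-based or median-based pooling is respectively dominated by the
    few largest genes or biased low by the skew of s^2 at 2-4
    replicates — which the exact test's null calibration depends on.
    Zero for Poisson data.

    Parameters
    ----------
    groups
        Partition of sample column indices into replicate groups; default
        is the (genotype, condition) cells of the design.
    """
    if groups is None:
        groups = [
            cols
            for g in GENOTYPES
            for c in CONDITIONS
            if (cols := exp.columns(g, c))
        ]
    groups = [list(g) for g in groups if len(g) >= 2]
    if not groups:
        raise ValueError("need at least one group with >= 2 replicates")
    if factors is None:
        factors = tmm_factors(exp)
    eff = factors.effective_sizes
    if np.all(exp.counts == 0):
        raise ValueError("all counts are zero")
    target = np.exp(np.mean(np.log(eff)))
    norm = exp.counts / eff * target  # counts rescaled to common library size

    zs = []
    fallback = []
    for cols in groups:
        sub = norm[:, cols]
        mu = sub.mean(axis=1)
        s2 = sub.var(axis=1, ddof=1)
        big = mu >= 5.0
        zs.append((s2[big] - mu[big]) / mu[big] ** 2)
        ok = mu > 0
        fallback.append((s2[ok] - mu[ok]) / mu[ok] ** 2)
    z = np.concatenate(zs)
    if z.size == 0:
        z = np.concatenate(fallback)  # only weakly expressed genes present
    if z.size == 0:
        raise ValueError("no gene with positive mean in any group")
    return max(0.0, float(z.mean()))


def _log_nb_conditional(t: int, r_a: float, r_b: float) -> np.ndarray:
    """Log conditional pmf of the group-A total z given overall total t.

    For summed NB counts with equal per-sample means and sizes r_a, r_b
    (size = n_group / phi), conditioning on the total removes the mean:
    P(z | t) ~ C(z + r_a - 1, z) * C(t - z + r_b - 1, t - z).
    Poisson (phi = 0) is the binomial limit.
    """
    z = np.arange(t + 1, dtype=float)
    if np.isinf(r_a):  # Poisson limit -> Binomial(t, n_a/(n_a+n_b)) handled upstream
        raise ValueError("use _log_binom_conditional for phi = 0")
    logp = (
        gammaln(z + r_a) - gammaln(z + 1.0) - gammaln(r_a)
        + gammaln(t - z + r_b) - gammaln(t - z + 1.0) - gammaln(r_b)
    )
    return logp - logsumexp(logp)


def _log_binom_conditional(t: int, frac_a: float) -> np.ndarray:
    z = np.arange(t + 1, dtype=float)
    logp = (
        gammaln(t + 1.0) - gammaln(z + 1.0) - gammaln(t - z + 1.0)
        + z * np.log(frac_a) + (t - z) * np.log1p(-frac_a)
    )
    return logp - logsumexp(logp)


def exact_test_pvalue(
    z_a: int, z_b: int, n_a: int, n_b: int, phi: float, midp: bool = False
) -> float:
    """Two-sided conditional NB exact p for group totals z_a vs z_b.

    The p-value is the total conditional probability of all group-A totals
    no more probable than the observed one, given the overall total and
    assuming equal per-sample means (the null) and common dispersion phi.
    With ``midp`` only half the probability of outcomes exactly as likely
    as the observed one is counted: the plain sum is conservative for a
    discrete statistic (it stochastically dominates uniform by about half
    the modal probability), while the mid-p variant is calibrated on
    average and is the right choice when the p-value distribution itself
    is the object of interest (e.g. FDR estimation across many genes).
    """
    t = z_a + z_b
    if t == 0:
        return 1.0
    if phi == 0.0:
        logp = _log_binom_conditional(t, n_a / (n_a + n_b))
    else:
        logp = _log_nb_conditional(t, n_a / phi, n_b / phi)
    obs = logp[z_a]
    keep = logp <= obs + 1e-10  # tolerate float ties
    p = np.exp(logsumexp(logp[keep]))
    if midp:
        tie = np.abs(logp - obs) <= 1e-10
        p -= 0.5 * np.exp(logsumexp(logp[tie]))
    return float(min(1.0, p))


def nb_exact_test(
    exp: CountExperiment,
    factors: NormFactors,
    phi: float,
    contrast: tuple[list[int], list[int]],
    prior_count: float = 0.5,
    midp: bool = False,
) -> pd.DataFrame:
    """Per-gene NB exact test between two replicate groups.

    Library sizes are pseudo-equalized to the geometric mean of the
    effective sizes, counts are summed within each contrast group, and a
    two-sided conditional exact p-value is computed per gene under a
    common-dispersion NB model. log2FC is log2 of the ratio of group mean
    CPM (group A over group B) with a ``prior_count`` offset (in CPM
    units, so fold-changes are invariant to pure depth changes) used only
    for the fold-change, never the test.

    Parameters
    ----------
    contrast
        (columns of group A, columns of group B); log2FC > 0 means higher
        in group A.
    midp
        Use the mid-p variant of the exact p-value (see
        :func:`exact_test_pvalue`); default is the plain conservative sum.

    Returns
    -------
    DataFrame indexed by gene with columns log2FC, p_value, adjusted_p,
    log2CPM. Genes with zero total count across the contrast are excluded.
    """
    cols_a, cols_b = [list(c) for c in contrast]
    if not cols_a or not cols_b:
        raise ValueError("both contrast groups must be non-empty")
    if phi < 0:
        raise ValueError("phi must be >= 0")
    eff = factors.effective_sizes
    target = np.exp(np.mean(np.log(eff[cols_a + cols_b])))
    scaled = exp.counts[:, cols_a + cols_b] / eff[cols_a + cols_b] * target
    n_a, n_b = len(cols_a), len(cols_b)
    sum_a = scaled[:, :n_a].sum(axis=1)
    sum_b = scaled[:, n_a:].sum(axis=1)

    keep = (sum_a + sum_b) > 0
    genes = [g for g, k in zip(exp.genes, keep) if k]
    za = np.rint(sum_a[keep]).astype(np.int64)
    zb = np.rint(sum_b[keep]).astype(np.int64)

    pvals = np.array(
        [exact_test_pvalue(a, b, n_a, n_b, phi, midp=midp) for a, b in zip(za, zb)]
    )
    cpm = exp.counts[:, cols_a + cols_b] / eff[cols_a + cols_b] * 1e6
    cpm_a = cpm[keep, :n_a].mean(axis=1)
    cpm_b = cpm[keep, n_a:].mean(axis=1)
    log2fc = np.log2(cpm_a + prior_count) - np.log2(cpm_b + prior_count)
    mean_cpm = (cpm_a * n_a + cpm_b * n_b) / (n_a + n_b)
    table = pd.DataFrame(
        {
            "log2FC": log2fc,
            "p_value": pvals,
            "adjusted_p": bh_adjust(pvals),
            "log2CPM": np.log2(mean_cpm + 1e-9),
        },
        index=pd.Index(genes, name="gene"),
    )
    return table


def regeneration_contrast(exp: CountExperiment, genotype: str) -> tuple[list[int], list[int]]:
    """(regenerating, uninjured) column groups for one genotype."""
    a = exp.columns(genotype, "regenerating")
    b = exp.columns(genotype, "uninjured")
    if not a or not b:
        raise ValueError(f"genotype {genotype!r} missing a condition group")
    return a, b


# ---------------------------------------------------------------------------
# I/O

def read_counts_tsv(path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a genes x samples TSV (header row of sample ids) -> (counts, genes, sample_ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), [str(g) for g in df.index], [str(c) for c in df.columns]


def read_design_tsv(path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "genotype", "condition", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"design table missing column(s): {sorted(missing)}")
    return [
        SampleInfo(str(r.sample_id), str(r.genotype), str(r.condition), int(r.replicate))
        for r in df.itertuples()
    ]


def load_count_experiment(counts_path, design_path) -> CountExperiment:
    counts, genes, sample_ids = read_counts_tsv(counts_path)
    design = {s.sample_id: s for s in read_design_tsv(design_path)}
    try:
        samples = [design[sid] for sid in sample_ids]
    except KeyError as e:
        raise ValueError(f"sample {e.args[0]!r} missing from design table") from None
    return CountExperiment(counts, genes, samples)


def write_de_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t")


def read_de_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")
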