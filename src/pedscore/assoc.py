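"""Efficient score-test scan over SNPs with LRT refinement of top hits.

Given the null-model fit (means and variance components estimated once,
without any SNP), each SNP enters the mean as a fixed effect and is tested
with the efficient score statistic

    U = Gᵀ P y,   V = Gᵀ P G,   S = Uᵀ V⁻¹ U  ~  χ²_df,

where P = Σ̂⁻¹ − Σ̂⁻¹A(AᵀΣ̂⁻¹A)⁻¹AᵀΣ̂⁻¹ is the null projection and G the
SNP design (one column per trait for the joint per-trait test, df = T; a
single shared column for df = 1).  Variance parameters are held at their
null estimates: in the Gaussian model the expected information between
mean and covariance parameters is block diagonal, so the efficient score
for the SNP effect needs no nuisance correction.  No per-SNP iteration is
required, which is what makes genome-wide pedigree scans cheap.

SNPs with the smallest score p-values (top 50 by default) are refitted by
full maximum likelihood and re-tested with the more accurate likelihood
ratio statistic, warm-started at the null optimum so the LRT is
nonnegative by construction.

Missing dosages are mean-imputed per SNP before testing and the imputed
count is reported.  The scan processes SNPs in fixed-width internal chunks
(zero-padded) so that results are bit-identical for any requested batch
size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from pedscore._errors import DataError, NumericalError
from pedscore.genio import GenotypeSource
from pedscore.vcfit import NullFit, StackedData, fit_null_ml

__all__ = [
    "SnpTest",
    "ScanResult",
    "score_test_snp",
    "lrt_snp",
    "scan",
    "write_results",
    "read_results",
]

GENOMEWIDE_SIGNIFICANCE = 5e-8  # conventional GWAS threshold for the plot line

# internal GEMM chunk width; fixed (and zero-padded) so statistics do not
# depend on the caller's batch size
_CHUNK = 64


@dataclass
class SnpTest:
    statistic: float
    df: int
    pvalue: float
    effect: np.ndarray        # one-step effect estimate(s) V⁻¹U
    n_imputed: int
    reason: str | None = None  # set when the SNP could not be tested


def _impute(g: np.ndarray):
    g = np.asarray(g, dtype=float).copy()
    miss = np.isnan(g)
    n_imp = int(miss.sum())
    if n_imp == g.size:
        return g, n_imp, "all dosages missing"
    if n_imp:
        g[miss] = g[~miss].mean()
    if np.var(g) <= 1e-12:
        return g, n_imp, "zero dosage variance (monomorphic)"
    return g, n_imp, None


def _snp_design(g: np.ndarray, mask: np.ndarray, effect: str) -> np.ndarray:
    """Stacked SNP design restricted to observed entries.

    Trait-major stacking: the column for trait t is e_t ⊗ g (per_trait) or
    the single column 1_T ⊗ g (shared).
    """
    T = mask.shape[0]
    if effect == "per_trait":
        G = np.kron(np.eye(T), g[:, None])
    elif effect == "shared":
        G = np.kron(np.ones((T, 1)), g[:, None])
    else:
        raise DataError(f"unknown effect mode {effect!r}")
    return G[mask.ravel()]


def score_test_snp(g: np.ndarray, fit: NullFit, effect: str = "per_trait") -> SnpTest:
    """Score-test one dosage vector (length n, NaN = missing) against the null."""
    gi, n_imp, reason = _impute(g)
    T = fit.data.T
    df = T if effect == "per_trait" else 1
    if reason is not None:
        return SnpTest(np.nan, df, np.nan, np.full(df, np.nan), n_imp, reason)
    G = _snp_design(gi, fit.data.mask, effect)
    U = G.T @ fit.Py
    V = G.T @ (fit.P @ G)
    try:
        Vinv_U = np.linalg.solve(V, U)
    except np.linalg.LinAlgError:
        return SnpTest(np.nan, df, np.nan, np.full(df, np.nan), n_imp,
                       "singular score information (SNP collinear with covariates)")
    if np.linalg.cond(V) > 1e12:
        return SnpTest(np.nan, df, np.nan, np.full(df, np.nan), n_imp,
                       "singular score information (SNP collinear with covariates)")
    stat = float(U @ Vinv_U)
    return SnpTest(stat, df, float(chi2.sf(stat, df)), Vinv_U, n_imp)


def lrt_snp(g: np.ndarray, fit: NullFit, effect: str = "per_trait"):
    """Likelihood-ratio test of one SNP: refit full ML with the SNP in the mean.

    The alternative fit is warm-started at the null variance estimates, so
    2(L_alt − L_null) ≥ 0 up to convergence tolerance (clipped at 0).
    Returns (statistic, pvalue, converged).
    """
    gi, _, reason = _impute(g)
    T = fit.data.T
    df = T if effect == "per_trait" else 1
    if reason is not None:
        return np.nan, np.nan, False
    G = _snp_design(gi, fit.data.mask, effect)
    data_alt = StackedData(fit.data.y, np.column_stack([fit.data.A, G]),
                           fit.data.mask, fit.data.n, fit.data.T)
    try:
        alt = fit_null_ml(fit.spec, data_alt, init_varcomp=fit.varcomp_hat)
    except NumericalError:
        return np.nan, np.nan, False
    stat = max(2.0 * (alt.loglik - fit.loglik), 0.0)
    return stat, float(chi2.sf(stat, df)), True


@dataclass
class ScanResult:
    """Per-SNP scan results as a tidy table.

    Columns: snp_id, chrom, bp, allele_effect, score_stat, df, pvalue,
    effect_1..effect_df (one-step estimates), n_imputed, reason,
    lrt_refined, lrt_stat, lrt_pvalue.
    """

    table: pd.DataFrame
    effect_mode: str = "per_trait"
    top_k: int = 50

    @property
    def n_tested(self) -> int:
        return int(self.table["pvalue"].notna().sum())


def _score_batch(D: np.ndarray, fit: NullFit, effect: str):
    """Score statistics for a block of imputed dosage columns (n × b).

    Vectorized over SNPs with matrix-matrix products on the per-trait
    blocks of P.  D must already be imputed (no NaN).
    """
    mask = fit.data.mask
    T, n = mask.shape
    df = T if effect == "per_trait" else 1
    b = D.shape[1]
    # positions of trait-t rows inside the stacked observed vector
    offsets = np.concatenate([[0], np.cumsum(mask.sum(axis=1))])
    rows = [np.arange(offsets[t], offsets[t + 1]) for t in range(T)]
    idx = [np.where(mask[t])[0] for t in range(T)]

    U = np.empty((T, b))
    Vblocks = np.empty((T, T, b))
    for t in range(T):
        Dt = D[idx[t]]
        U[t] = Dt.T @ fit.Py[rows[t]]
        for u in range(T):
            M = fit.P[np.ix_(rows[t], rows[u])] @ D[idx[u]]
            Vblocks[t, u] = np.einsum("is,is->s", Dt, M)
    if effect == "shared":
        U = U.sum(axis=0, keepdims=True)
        Vblocks = Vblocks.sum(axis=(0, 1))[None, None, :]
    stats = np.full(b, np.nan)
    pvals = np.full(b, np.nan)
    effects = np.full((b, df), np.nan)
    singular = np.zeros(b, dtype=bool)
    for s in range(b):
        V = Vblocks[:, :, s]
        try:
            ViU = np.linalg.solve(V, U[:, s])
        except np.linalg.LinAlgError:
            singular[s] = True
            continue
        if np.linalg.cond(V) > 1e12:
            singular[s] = True
            continue
        stats[s] = float(U[:, s] @ ViU)
        pvals[s] = float(chi2.sf(stats[s], df))
        effects[s] = ViU
    return stats, pvals, effects, singular


def scan(gs: GenotypeSource, fit: NullFit, top_k: int = 50,
         effect: str = "per_trait", batch_size: int = 512) -> ScanResult:
    """Score-test every SNP, then LRT-refit the top_k by score p-value.

    ``batch_size`` controls only how many SNPs are pulled per iteration;
    internally SNPs are processed in fixed zero-padded chunks so results
    are identical for any batch size.  Per-SNP failures (monomorphic,
    collinear) are recorded with a reason and never abort the scan.
    """
    if gs.n_individuals != fit.data.n:
        raise DataError("genotype source is not aligned to the fitted individuals")
    T = fit.data.T
    df = T if effect == "per_trait" else 1
    n = fit.data.n

    records = []
    for snps, block in gs.iter_batches(batch_size):
        b = block.shape[1]
        imputed = np.empty((n, b))
        n_imp = np.zeros(b, dtype=int)
        reason = np.array([None] * b, dtype=object)
        for s in range(b):
            imputed[:, s], n_imp[s], reason[s] = _impute(block[:, s])
            if reason[s] is not None:
                imputed[:, s] = 0.0  # placeholder column; result discarded
        stats = np.full(b, np.nan)
        pvals = np.full(b, np.nan)
        effs = np.full((b, df), np.nan)
        for start in range(0, b, _CHUNK):
            stop = min(start + _CHUNK, b)
            pad = np.zeros((n, _CHUNK))
            pad[:, : stop - start] = imputed[:, start:stop]
            st, pv, ef, sing = _score_batch(pad, fit, effect)
            w = slice(start, stop)
            k = stop - start
            stats[w], pvals[w], effs[w] = st[:k], pv[:k], ef[:k]
            for s in range(k):
                if sing[s] and reason[start + s] is None:
                    reason[start + s] = ("singular score information "
                                         "(SNP collinear with covariates)")
        for s in range(b):
            if reason[s] is not None:
                stats[s] = pvals[s] = np.nan
                effs[s] = np.nan
        part = snps.reset_index(drop=True).copy()
        part["score_stat"] = stats
        part["df"] = df
        part["pvalue"] = pvals
        for k in range(df):
            part[f"effect_{k + 1}"] = effs[:, k]
        part["n_imputed"] = n_imp
        part["reason"] = reason
        records.append(part)
    empty_cols = (["snp_id", "chrom", "bp", "allele_effect", "allele_other",
                   "score_stat", "df", "pvalue"]
                  + [f"effect_{k + 1}" for k in range(df)]
                  + ["n_imputed", "reason"])
    table = (pd.concat(records, ignore_index=True) if records
             else pd.DataFrame(columns=empty_cols))

    table["lrt_refined"] = False
    table["lrt_stat"] = np.nan
    table["lrt_pvalue"] = np.nan
    if top_k > 0 and len(table):
        # deterministic top-k: ties broken by (p-value, chrom, bp)
        order = table.loc[table["pvalue"].notna()] \
                     .sort_values(["pvalue", "chrom", "bp"], kind="mergesort")
        top = order.index[:top_k]
        dose_by_id = {sid: j for j, sid in enumerate(gs.snps["snp_id"])}
        for i in top:
            gvec = gs.dosages[:, dose_by_id[table.at[i, "snp_id"]]]
            stat, pv, ok = lrt_snp(gvec, fit, effect)
            table.at[i, "lrt_refined"] = True
            if ok:
                table.at[i, "lrt_stat"] = stat
                table.at[i, "lrt_pvalue"] = pv
    return ScanResult(table, effect_mode=effect, top_k=top_k)


def qq_data(res: ScanResult) -> pd.DataFrame:
    """Observed vs expected −log10 p for the QQ plot.

    Expected quantiles for m tested SNPs are −log10((i − 0.5)/m).
    """
    p = np.sort(res.table["pvalue"].dropna().to_numpy())
    m = len(p)
    i = np.arange(1, m + 1)
    return pd.DataFrame({
        "expected_neglog10p": -np.log10((i - 0.5) / m) if m else [],
        "observed_neglog10p": -np.log10(np.maximum(p, 1e-300)) if m else [],
    })


def write_results(res: ScanResult, prefix) -> dict:
    """Write `<prefix>.results.tsv` and `<prefix>.qq.tsv`; return their paths."""
    prefix = str(prefix)
    results_path = prefix + ".results.tsv"
    qq_path = prefix + ".qq.tsv"
    res.table.to_csv(results_path, sep="\t", index=False, float_format="%.17g")
    with open(qq_path, "w") as fh:
        fh.write(f"# genomewide_significance\t{GENOMEWIDE_SIGNIFICANCE:g}\n")
        qq_data(res).to_csv(fh, sep="\t", index=False, float_format="%.17g")
    return {"results": results_path, "qq": qq_path}


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
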