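"""MAF filtering, prediction metrics, and the replicate benchmark harness.

The harness reproduces the standard benchmark design: simulate a replicate,
filter SNPs by minor allele frequency computed on the *training* generation
only, fit every method on the identical training set, predict breeding values
for the candidate generation and score them against the simulated truth with
the Pearson correlation (accuracy) and the regression slope of TBV on GBV
(bias; 1.0 = unbiased).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import clone

from .io import GenotypeMatrix
from .popsim import SimScenario, generate_replicate

__all__ = ["EvalResult", "maf_filter", "accuracy", "bias_slope", "run_replicates"]


@dataclass
class EvalResult:
    """Per-replicate metric rows and their mean +/- s.e. summary."""

    replicates: pd.DataFrame
    summary: pd.DataFrame


def maf_filter(gm: GenotypeMatrix, threshold: float = 0.05):
    """Drop SNPs with minor allele frequency strictly below ``threshold``.

    Frequencies come from the allele counts of ``gm`` itself (training data by
    design).  Monomorphic SNPs are always dropped.  Returns the filtered
    matrix and the list of excluded SNP ids.
    """
    if not (0 <= threshold < 0.5):
        raise ValueError(f"threshold must be in [0, 0.5), got {threshold}")
    n = gm.n_individuals
    q = (gm.codes.astype(np.int64) + 1).sum(axis=0) / (2 * n)
    maf = np.minimum(q, 1.0 - q)
    keep = (maf >= threshold) & (q > 0) & (q < 1)
    if not keep.any():
        raise ValueError("no polymorphic SNPs left after MAF filtering")
    excluded = [sid for sid, k in zip(gm.snp_ids, keep) if not k]
    return gm.subset_snps(keep), excluded


def accuracy(gbv, tbv) -> float:
    """Pearson correlation between predicted and true breeding values.

    Returns NaN (reported as missing, never 0) if either vector is constant.
    """
    gbv = np.asarray(gbv, dtype=float)
    tbv = np.asarray(tbv, dtype=float)
    if gbv.shape != tbv.shape or gbv.size < 3:
        raise ValueError("gbv and tbv must have equal length >= 3")
    if np.ptp(gbv) == 0 or np.ptp(tbv) == 0:
        return float("nan")
    return float(np.corrcoef(gbv, tbv)[0, 1])


def bias_slope(tbv, gbv) -> float:
    """Regression coefficient of TBV on predicted GBV: cov(t, g)/var(g)."""
    gbv = np.asarray(gbv, dtype=float)
    tbv = np.asarray(tbv, dtype=float)
    if gbv.shape != tbv.shape or gbv.size < 3:
        raise ValueError("gbv and tbv must have equal length >= 3")
    var = np.var(gbv)
    if var == 0:
        return float("nan")
    return float(np.cov(tbv, gbv, bias=True)[0, 1] / var)


def _replicate_seed(master_seed: int, index: int) -> np.random.SeedSequence:
    """Per-replicate seed stream: methods compared within a replicate share
    the identical data set (paired design)."""
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(index,))


def run_replicates(scenario: SimScenario, methods, R: int, seed: int = 0,
                   maf_threshold: float = 0.05,
                   replicates=None, progress=None) -> EvalResult:
    """Benchmark a list of methods over ``R`` simulated replicates.

    Parameters
    ----------
    scenario : SimScenario
    methods : list of (label, estimator)
        Estimators are cloned per replicate; stochastic estimators get a
        per-replicate ``random_state`` derived from ``seed``.
    R : int
        Number of replicates (>= 1).
    seed : int
        Master seed; replicate ``i`` uses an independent derived stream.
    maf_threshold : float
        Training-set MAF cutoff applied before fitting; the surviving SNP set
        is applied unchanged to the candidates.
    replicates : iterable of SimReplicate, optional
        Pre-simulated replicates to reuse instead of simulating (must have
        length >= R).
    progress : callable, optional
        Called with a status string per (replicate, method).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    rows = []
    for i in range(R):
        ss = _replicate_seed(seed, i)
        rep = replicates[i] if replicates is not None else generate_replicate(scenario, ss)
        gm_train, pt = rep.training
        gm_cand, tbv = rep.candidates
        filtered, excluded = maf_filter(gm_train, maf_threshold)
        keep_ids = set(filtered.snp_ids)
        keep = np.array([sid in keep_ids for sid in gm_cand.snp_ids])
        cand = gm_cand.subset_snps(keep)
        covariates = pt.X[:, 1:] if pt.X.shape[1] > 1 else None
        for m, (label, est) in enumerate(methods):
            if progress is not None:
                progress(f"replicate {i + 1}/{R}: {label}")
            model = clone(est)
            if "random_state" in model.get_params():
                chain_seed = np.random.SeedSequence(
                    entropy=seed, spawn_key=(i, 1000 + m))
                model.set_params(random_state=chain_seed.generate_state(1)[0])
            model.fit(filtered.codes.astype(np.float64), pt.y, covariates=covariates)
            gbv = model.predict(cand.codes.astype(np.float64))
            params = model.get_params()
            rows.append({
                "replicate": i,
                "method": label,
                "p": params.get("p", 1.0),
                "nu": params.get("nu", np.nan),
                "s": params.get("s", np.nan),
                "accuracy": accuracy(gbv, tbv),
                "bias_slope": bias_slope(tbv, gbv),
                "iterations": getattr(model, "n_iter_",
                                      params.get("total_cycles", np.nan)),
                "converged": getattr(model, "converged_", True),
                "n_snps": filtered.n_snps,
                "realized_h2": rep.realized_h2,
            })
    replicates_df = pd.DataFrame(rows)
    grouped = replicates_df.groupby("method", sort=False)
    summary = grouped.agg(
        p=("p", "first"),
        nu=("nu", "first"),
        s=("s", "first"),
        mean_accuracy=("accuracy", "mean"),
        se_accuracy=("accuracy", lambda x: x.std(ddof=1) / np.sqrt(len(x))),
        mean_slope=("bias_slope", "mean"),
        se_slope=("bias_slope", lambda x: x.std(ddof=1) / np.sqrt(len(x))),
        n_replicates=("accuracy", "size"),
    ).reset_index()
    return EvalResult(replicates=replicates_df, summary=summary)
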