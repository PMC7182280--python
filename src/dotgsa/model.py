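"""Model/Results interface for gene-set association testing.

`GeneSetTest` bundles a vector of per-SNP summary statistics with the
correlation matrix of those statistics; `fit` runs the requested
combination tests and returns a `GeneSetTestResults` carrying the
statistics, p-values, the decorrelated vector, and the contributor
decomposition, with a printable `summary`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.iolib.table import SimpleTable

from .combine import (StatVector, acat_test, decorrelation_transform, dot_test,
                      minp_test, pvalues_to_z, rtp_decorrelated, tq_test)
from .genescan import read_sumstats
from .ld import CorrelationMatrix, read_ld_matrix

__all__ = ["GeneSetTest", "GeneSetTestResults"]


class GeneSetTest:
    """Gene-level association test battery on correlated summary statistics.

    Parameters
    ----------
    z : array-like or None
        Per-SNP association Z-scores.  Exactly one of ``z`` and ``p`` is
        required; P-values are converted to normal scores (two-sided, with
        optional ``signs``).
    corr : CorrelationMatrix or (L, L) array
        Correlation of the statistics (the LD matrix in the basic setting).
    p, signs, ids, weights : optional
        P-value input, effect directions, SNP identifiers, per-SNP weights.
    """

    def __init__(self, z=None, corr=None, p=None, signs=None, ids=None, weights=None):
        if corr is None:
            raise ValueError("a correlation matrix is required")
        if (z is None) == (p is None):
            raise ValueError("provide exactly one of z and p")
        if z is None:
            z = pvalues_to_z(np.asarray(p, dtype=float), signs).z
        self.corr = corr if isinstance(corr, CorrelationMatrix) else CorrelationMatrix(
            np.asarray(corr, dtype=float))
        if ids is None and self.corr.labels is not None:
            ids = list(self.corr.labels)
        self.data = StatVector(np.asarray(z, dtype=float), ids=ids, weights=weights)
        if len(self.data) != self.corr.n_snps:
            raise ValueError("statistic vector and correlation matrix disagree in size")

    @classmethod
    def from_files(cls, sumstats_path, ld_path) -> "GeneSetTest":
        """Build from a summary-statistics TSV and an LD matrix file,
        matching SNPs by identifier (intersection, LD-file order)."""
        df = read_sumstats(sumstats_path)
        R = read_ld_matrix(ld_path)
        if R.labels is None:
            if len(df) != R.n_snps:
                raise ValueError("unlabelled LD matrix size does not match sumstats")
            keep = df
            corr = R
        else:
            have = set(df["SNP"])
            labels = [lab for lab in R.labels if lab in have]
            corr = R.restrict(labels)
            keep = df.set_index("SNP").loc[labels].reset_index()
        if "Z" in keep.columns and keep["Z"].notna().all():
            return cls(z=keep["Z"].to_numpy(dtype=float), corr=corr, ids=list(keep["SNP"]))
        signs = keep["SIGN"].to_numpy(dtype=float) if "SIGN" in keep.columns else None
        return cls(p=keep["P"].to_numpy(dtype=float), signs=signs, corr=corr,
                   ids=list(keep["SNP"]))

    def fit(self, methods=("dot", "tq", "acat", "minp"), rtp_k=None,
            rtp_n_null=10**5, seed=None) -> "GeneSetTestResults":
        """Run the requested combination tests and collect the results."""
        transform = decorrelation_transform(self.corr)
        p_single = stats.chi2.sf(self.data.z**2, 1)
        results = {}
        for meth in methods:
            if meth == "dot":
                results["dot"] = dot_test(self.data, transform)
            elif meth == "tq":
                results["tq"] = tq_test(self.data, self.corr)
            elif meth == "acat":
                results["acat"] = acat_test(p_single)
            elif meth == "minp":
                results["minp"] = minp_test(p_single)
            elif meth == "rtp":
                k = rtp_k if rtp_k is not None else max(1, len(self.data) // 2)
                results["rtp"] = rtp_decorrelated(self.data, transform, k,
                                                  n_null=rtp_n_null, seed=seed)
            else:
                raise ValueError(f"unknown method {meth!r}")
        return GeneSetTestResults(self, transform, results)


class GeneSetTestResults:
    """Fitted results of a :class:`GeneSetTest`."""

    def __init__(self, model, transform, results):
        self.model = model
        self.transform = transform
        self.results = results
        self.decorrelated = transform.H @ model.data.z

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series({m: r.p_value for m, r in self.results.items()}, name="p_value")

    @property
    def statistics(self) -> pd.Series:
        return pd.Series({m: r.statistic for m, r in self.results.items()}, name="statistic")

    def top_contributors(self, n_components: int = 3, term_fraction: float = 0.25) -> pd.DataFrame:
        """Leading decorrelated components expanded into per-SNP terms h_j Z_j.

        Returns the same-sign terms at or above ``term_fraction`` of each
        component's largest |term|, ranked within component by |term|.
        """
        x = self.decorrelated
        ids = self.model.data.ids or [f"snp{i}" for i in range(x.size)]
        order = np.lexsort((np.arange(x.size), -(x**2)))
        rows = []
        for rank, i in enumerate(order[:n_components], start=1):
            terms = self.transform.H[i] * self.model.data.z
            cutoff = term_fraction * np.max(np.abs(terms))
            for j in np.argsort(-np.abs(terms)):
                if np.sign(terms[j]) == np.sign(x[i]) and np.abs(terms[j]) >= cutoff:
                    rows.append({"component_rank": rank, "component_value": x[i],
                                 "snp": ids[j], "term": terms[j]})
        return pd.DataFrame(rows)

    def summary(self) -> SimpleTable:
        """Summary table of statistics and p-values per method."""
        headers = ["method", "statistic", "p-value"]
        rows = [[m, f"{r.statistic:.4f}", f"{r.p_value:.3g}"]
                for m, r in self.results.items()]
        return SimpleTable(rows, headers,
                           title=f"Gene-set association ({len(self.model.data)} SNPs)")

    def __repr__(self):
        ps = ", ".join(f"{m}={r.p_value:.3g}" for m, r in self.results.items())
        return f"<GeneSetTestResults L={len(self.model.data)}: {ps}>"
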