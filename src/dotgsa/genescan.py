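"""Anchor-SNP gene-scan workflow on summary statistics.

Given per-SNP summary statistics and an LD matrix, a gene is represented
by the block of SNPs in LD with a previously reported "anchor" risk
variant.  The block is tested with the full battery of combination
methods, and the DOT decomposition is mined for the SNPs that drive the
signal: the top components X_i of the decorrelated vector are expanded
into their per-SNP terms h_j Z_j, and large same-sign terms name the
contributing variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .combine import (StatVector, TestResult, acat_test, decorrelation_transform,
                      dot_test, minp_test, pvalues_to_z, rtp_decorrelated, tq_test)
from .ld import CorrelationMatrix, read_ld_matrix

__all__ = [
    "read_sumstats",
    "GeneBlock",
    "ContributorRecord",
    "GeneReport",
    "anchor_block",
    "gene_test",
    "top_contributors",
    "scan",
    "write_gene_reports",
]


def read_sumstats(path) -> pd.DataFrame:
    """Read a summary-statistics TSV.

    Requires columns ``SNP`` and at least one of ``Z`` or ``P``; optional
    ``CHR``, ``POS``, ``SIGN``.  Unknown columns are preserved.
    """
    df = pd.read_csv(path, sep="\t")
    return validate_sumstats(df)


def validate_sumstats(df: pd.DataFrame) -> pd.DataFrame:
    if "SNP" not in df.columns:
        raise ValueError("summary statistics require an 'SNP' column")
    if "Z" not in df.columns and "P" not in df.columns:
        raise ValueError("summary statistics require a 'Z' or 'P' column")
    if df["SNP"].duplicated().any():
        dupes = df.loc[df["SNP"].duplicated(), "SNP"].tolist()
        raise ValueError(f"duplicate SNP ids: {dupes}")
    if "P" in df.columns:
        p = df["P"].to_numpy(dtype=float)
        if np.any((p <= 0) | (p > 1)):
            raise ValueError("P-values must lie in (0, 1]")
    if "Z" in df.columns and not np.all(np.isfinite(df["Z"].to_numpy(dtype=float))):
        raise ValueError("Z-scores must be finite")
    return df


@dataclass
class GeneBlock:
    """LD block around an anchor SNP."""

    anchor: str
    members: list[str]
    threshold: float

    def __post_init__(self):
        if self.anchor not in self.members:
            raise ValueError("anchor must be a member of its own block")

    @property
    def L(self) -> int:
        return len(self.members)


@dataclass
class ContributorRecord:
    """Per-SNP decomposition of one decorrelated component X_i = sum_j h_j Z_j."""

    rank: int                    # 1-based rank by X_i^2
    component_index: int         # index i in the decorrelated vector
    value: float                 # X_i
    terms: pd.DataFrame          # columns: snp, term (h_j Z_j), same_sign, selected

    @property
    def squared(self) -> float:
        return self.value**2


@dataclass
class GeneReport:
    """Gene-level results: per-method tests plus top-contributor records."""

    gene: str
    block: GeneBlock
    results: dict[str, TestResult]
    contributors: list[ContributorRecord] = field(default_factory=list)

    @property
    def L(self) -> int:
        return self.block.L

    def pvalues(self) -> dict[str, float]:
        return {m: r.p_value for m, r in self.results.items()}


def anchor_block(R: CorrelationMatrix, anchor: str, threshold: float = 0.25) -> GeneBlock:
    """SNPs whose |LD correlation| with the anchor is at least the threshold.

    The absolute value is used because the sign of an LD correlation flips
    with allele coding.
    """
    if R.labels is None:
        raise ValueError("LD matrix needs SNP labels for anchor-block selection")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if anchor not in R.labels:
        raise KeyError(f"anchor {anchor!r} not in LD matrix; available: {R.labels}")
    a = R.labels.index(anchor)
    keep = np.abs(R.values[a]) >= threshold
    keep[a] = True
    members = [lab for lab, k in zip(R.labels, keep) if k]
    return GeneBlock(anchor=anchor, members=members, threshold=threshold)


def _block_z(stats_df: pd.DataFrame, block: GeneBlock) -> StatVector:
    sub = stats_df.set_index("SNP").loc[block.members]
    if "Z" in sub.columns and sub["Z"].notna().all():
        z = sub["Z"].to_numpy(dtype=float)
        if "P" in sub.columns and sub["P"].notna().all():
            implied = stats.chi2.sf(z**2, 1)
            if np.max(np.abs(implied - sub["P"].to_numpy(dtype=float))) > 1e-6:
                warnings.warn("Z and P columns are inconsistent; using Z", RuntimeWarning)
    else:
        signs = sub["SIGN"].to_numpy(dtype=float) if "SIGN" in sub.columns else None
        z = pvalues_to_z(sub["P"].to_numpy(dtype=float), signs).z
    return StatVector(z, ids=list(block.members))


def gene_test(stats_df: pd.DataFrame, R: CorrelationMatrix, block: GeneBlock,
              methods=("dot", "tq", "acat", "minp"), rtp_k: int | None = None,
              rtp_n_null: int = 10**5, seed=None) -> GeneReport:
    """Run the combination tests on one anchor block.

    Z-scores take precedence where both Z and P are present (checked for
    consistency); otherwise P-values are converted to normal scores.
    """
    missing = [m for m in block.members if m not in set(stats_df["SNP"])]
    if missing:
        raise KeyError(f"block members missing from summary statistics: {missing}")
    sub_R = R.restrict(block.members)
    try:
        transform = decorrelation_transform(sub_R)
    except ValueError as exc:
        raise ValueError(
            f"block LD matrix for anchor {block.anchor!r} is not positive "
            "definite; check reference-panel quality or apply a PD repair"
        ) from exc
    sv = _block_z(stats_df, block)
    p_single = stats.chi2.sf(sv.z**2, 1)
    results: dict[str, TestResult] = {}
    for meth in methods:
        if meth == "dot":
            results["dot"] = dot_test(sv, transform)
        elif meth == "tq":
            results["tq"] = tq_test(sv, sub_R)
        elif meth == "acat":
            results["acat"] = acat_test(p_single)
        elif meth == "minp":
            results["minp"] = minp_test(p_single)
        elif meth == "rtp":
            k = rtp_k if rtp_k is not None else max(1, block.L // 2)
            results["rtp"] = rtp_decorrelated(sv, transform, k, n_null=rtp_n_null, seed=seed)
        else:
            raise ValueError(f"unknown method {meth!r}")
    return GeneReport(gene=block.anchor, block=block, results=results)


def top_contributors(stats_df: pd.DataFrame, R: CorrelationMatrix, block: GeneBlock,
                     n_components: int = 3, term_fraction: float = 0.25) -> list[ContributorRecord]:
    """Decompose the leading DOT components into per-SNP terms.

    Components are ranked by X_i^2 (ties broken by lower index).  Each
    X_i = sum_j h_j Z_j is expanded into its terms; terms sharing the sign
    of X_i with |h_j Z_j| at least ``term_fraction`` of the largest |term|
    are flagged ``selected`` — those SNPs are the reported contributors.
    """
    sub_R = R.restrict(block.members)
    transform = decorrelation_transform(sub_R)
    sv = _block_z(stats_df, block)
    x = transform.H @ sv.z
    order = np.lexsort((np.arange(x.size), -(x**2)))
    records = []
    for rank, i in enumerate(order[:n_components], start=1):
        terms = transform.H[i] * sv.z
        same_sign = np.sign(terms) == np.sign(x[i]) if x[i] != 0 else np.zeros_like(terms, bool)
        cutoff = term_fraction * np.max(np.abs(terms))
        selected = same_sign & (np.abs(terms) >= cutoff)
        df = pd.DataFrame({
            "snp": block.members, "term": terms,
            "same_sign": same_sign, "selected": selected,
        }).sort_values("term", key=np.abs, ascending=False, kind="stable").reset_index(drop=True)
        records.append(ContributorRecord(rank=rank, component_index=int(i),
                                         value=float(x[i]), terms=df))
    return records


def scan(sumstats_file, ld_file, genes_config) -> list[GeneReport]:
    """Run the gene-scan workflow over a collection of configured genes.

    ``genes_config`` is a list of dicts with keys ``label``, ``anchor``
    and optional ``threshold``, ``methods``, ``n_components``.  Per-gene
    failures are isolated: the failing gene is logged and skipped.
    """
    stats_df = read_sumstats(sumstats_file)
    R = read_ld_matrix(ld_file)
    reports = []
    for cfg in genes_config:
        label = cfg.get("label", cfg["anchor"])
        try:
            block = anchor_block(R, cfg["anchor"], cfg.get("threshold", 0.25))
            report = gene_test(stats_df, R, block,
                               methods=tuple(cfg.get("methods", ("dot", "tq", "acat", "minp"))))
            report.gene = label
            report.contributors = top_contributors(
                stats_df, R, block, n_components=cfg.get("n_components", 3))
            reports.append(report)
        except Exception as exc:        # noqa: BLE001 - per-gene isolation
            warnings.warn(f"gene {label!r} failed: {exc}", RuntimeWarning)
    return reports


def write_gene_reports(reports: list[GeneReport], out_prefix: str) -> None:
    """Write ``<prefix>.genes.tsv`` and ``<prefix>.contributors.tsv``."""
    gene_rows = []
    contrib_rows = []
    for rep in reports:
        row = {"gene": rep.gene, "anchor": rep.block.anchor, "L": rep.L}
        for meth, res in rep.results.items():
            row[f"p_{meth}"] = res.p_value
        gene_rows.append(row)
        for rec in rep.contributors:
            for _, t in rec.terms[rec.terms["selected"]].iterrows():
                contrib_rows.append({
                    "gene": rep.gene, "component_rank": rec.rank,
                    "component_value": rec.value, "snp": t["snp"], "term": t["term"],
                })
    pd.DataFrame(gene_rows).to_csv(f"{out_prefix}.genes.tsv", sep="\t", index=False)
    pd.DataFrame(contrib_rows).to_csv(f"{out_prefix}.contributors.tsv", sep="\t", index=False)
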