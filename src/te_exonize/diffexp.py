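"""Per-gene two-sample differential expression between two cell types,
with Benjamini-Hochberg FDR control, and its intersection with TE-derived
first-exon flags.

Gene expression is the sum of the gene's transcript FPKMs per replicate,
log2(FPKM+1)-transformed by default for variance stabilization, then
compared with a classical equal-variance Student's t-test (Welch
available). Genes are tested only when expressed (mean FPKM > 0 in at
least one group). Significance is q < alpha after BH adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .models import TranscriptRecord

TRANSFORMS = ("log2p1", "none")


@dataclass
class TTestResult:
    t: float
    p: float
    df: int


def t_test(
    x: Sequence[float], y: Sequence[float], equal_var: bool = True
) -> TTestResult:
    """Two-sample t-test; classical pooled-variance Student by default.

    Degenerate case: zero pooled variance with equal means is defined as
    t = 0, p = 1 (no evidence of difference); zero pooled variance with
    unequal means is an error — the test statistic is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 replicates")
    df = int(x.size + y.size - 2) if equal_var else None
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        if x.mean() == y.mean():
            return TTestResult(t=0.0, p=1.0, df=df if df is not None else 0)
        raise ValueError(
            "zero within-group variance with unequal means: t undefined"
        )
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    if not equal_var:
        # Welch-Satterthwaite df, for reporting
        vx, vy = x.var(ddof=1) / x.size, y.var(ddof=1) / y.size
        df = int(
            (vx + vy) ** 2
            / (vx**2 / (x.size - 1) + vy**2 / (y.size - 1))
        )
    return TTestResult(t=float(t), p=float(p), df=df)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), returned
    in input order: sort ascending, q_(i) = min_{j>=i} p_(j) * m / j,
    capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gene_expression_table(
    transcripts: Sequence[TranscriptRecord],
) -> pd.DataFrame:
    """Gene x sample matrix of expression: per replicate, the sum of the
    gene's transcript FPKMs."""
    rows = []
    for t in transcripts:
        for sample, value in t.fpkm.items():
            rows.append((t.gene_id, sample, value))
    if not rows:
        raise ValueError("no expression values on any transcript")
    df = pd.DataFrame(rows, columns=["gene_id", "sample", "fpkm"])
    return df.pivot_table(
        index="gene_id", columns="sample", values="fpkm", aggfunc="sum"
    ).fillna(0.0)


def run_diffexp(
    expr: pd.DataFrame,
    groups: Mapping[str, Sequence[str]],
    alpha: float = 0.05,
    transform: str = "log2p1",
    equal_var: bool = True,
) -> pd.DataFrame:
    """Test every expressed gene between two groups of samples.

    ``expr`` is a gene x sample matrix (raw FPKM scale); ``groups`` maps
    two group labels to their sample columns. Returns one row per tested
    gene: mean_a/mean_b (raw FPKM), t_stat, p, q, significant — sorted by
    gene_id.
    """
    if transform not in TRANSFORMS:
        raise ValueError(f"transform must be one of {TRANSFORMS}")
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    (label_a, samples_a), (label_b, samples_b) = groups.items()
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("each group needs >= 2 replicate samples")
    a_raw = expr[list(samples_a)].to_numpy(dtype=float)
    b_raw = expr[list(samples_b)].to_numpy(dtype=float)

    expressed = (a_raw.mean(axis=1) > 0) | (b_raw.mean(axis=1) > 0)
    genes = expr.index.to_numpy()[expressed]
    a_raw, b_raw = a_raw[expressed], b_raw[expressed]
    if genes.size == 0:
        raise ValueError("no expressed genes to test")

    if transform == "log2p1":
        a = np.log2(a_raw + 1.0)
        b = np.log2(b_raw + 1.0)
    else:
        a, b = a_raw, b_raw

    degenerate = (a.var(axis=1, ddof=1) == 0) & (b.var(axis=1, ddof=1) == 0)
    bad = degenerate & (a.mean(axis=1) != b.mean(axis=1))
    if np.any(bad):
        raise ValueError(
            "zero within-group variance with unequal means for genes: "
            f"{list(genes[bad][:5])}"
        )
    with np.errstate(invalid="ignore"):
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=equal_var)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)

    q = bh_fdr(p)
    out = pd.DataFrame(
        {
            "gene_id": genes,
            "mean_a": a_raw.mean(axis=1),
            "mean_b": b_raw.mean(axis=1),
            "t_stat": t,
            "p": p,
            "q": q,
            "significant": q < alpha,
        }
    )
    return out.sort_values("gene_id", ignore_index=True)


def de_te_first_exon_genes(
    results: pd.DataFrame,
    te_first_exon: Mapping[str, bool],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Genes both differentially expressed (q < alpha) and carrying a
    TE-derived first exon, sorted by q then gene_id."""
    missing = [g for g in results["gene_id"] if g not in te_first_exon]
    if missing:
        raise KeyError(f"missing te_first_exon flag for genes {missing[:5]}")
    flagged = results["gene_id"].map(te_first_exon).astype(bool)
    hits = results[(results["q"] < alpha) & flagged]
    return hits.sort_values(["q", "gene_id"], ignore_index=True)
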