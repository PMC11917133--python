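"""Gene-family and GO-term overrepresentation inside sweep-targeted OGDs.

One-tailed (greater) Fisher's exact tests on the 2x2 table

    a = target genes in the label        b = target genes not in the label
    c = other genes in the label         d = other genes not in the label

with Benjamini-Hochberg FDR control across GO terms.  Genes overlapping
several target regions count once (set semantics); the gene universe is
every annotated gene on the analyzed contigs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _stats
from statsmodels.stats.multitest import multipletests


@dataclass
class EnrichmentResult:
    label: str
    a: int
    b: int
    c: int
    d: int
    odds_ratio: float
    p: float
    q: float | None = None


def genes_in_regions(genes: pd.DataFrame, regions) -> set:
    """Gene ids whose half-open interval overlaps any region.

    ``regions`` is an iterable of (chrom, start, end).  A gene touching a
    region end-to-start (zero-length overlap) is excluded.
    """
    out: set = set()
    chroms = genes["chrom"].to_numpy()
    starts = genes["start"].to_numpy()
    ends = genes["end"].to_numpy()
    ids = genes["gene_id"].to_numpy()
    for chrom, rs, re in regions:
        hit = (chroms == chrom) & (starts < re) & (rs < ends)
        out.update(ids[hit])
    return out


def _fisher_greater(a: int, b: int, c: int, d: int):
    odds, p = _stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return float(odds), float(p)


def family_enrichment(genes: pd.DataFrame, target_set: set,
                      family: str) -> EnrichmentResult:
    """One-tailed Fisher test: is ``family`` overrepresented in the target?"""
    if len(genes) == 0:
        raise ValueError("empty gene universe")
    in_target = genes["gene_id"].isin(target_set).to_numpy()
    in_family = (genes["family"] == family).to_numpy()
    a = int((in_target & in_family).sum())
    b = int((in_target & ~in_family).sum())
    c = int((~in_target & in_family).sum())
    d = int((~in_target & ~in_family).sum())
    odds, p = _fisher_greater(a, b, c, d)
    return EnrichmentResult(family, a, b, c, d, odds, p)


def go_overrepresentation(genes: pd.DataFrame, target_set: set,
                          fdr_threshold: float = 0.1,
                          return_all: bool = False):
    """Per-GO-term Fisher tests with BH adjustment across tested terms.

    Only terms carried by at least one target gene are tested (untestable
    terms would merely inflate the BH denominator).  Returns the terms with
    q < ``fdr_threshold`` sorted by q, or every tested term when
    ``return_all``.
    """
    in_target = genes["gene_id"].isin(target_set).to_numpy()
    terms: set = set()
    for t, flag in zip(genes["go_terms"], in_target):
        if flag:
            terms.update(t)
    if not terms:
        return []
    results = []
    for term in sorted(terms):
        has = np.array([term in t for t in genes["go_terms"]])
        a = int((in_target & has).sum())
        b = int((in_target & ~has).sum())
        c = int((~in_target & has).sum())
        d = int((~in_target & ~has).sum())
        odds, p = _fisher_greater(a, b, c, d)
        results.append(EnrichmentResult(term, a, b, c, d, odds, p))
    pvals = np.array([r.p for r in results])
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    for r, q in zip(results, qvals):
        r.q = float(q)
    results.sort(key=lambda r: (r.q, r.p, r.label))
    if return_all:
        return results
    return [r for r in results if r.q < fdr_threshold]


def enrichment_table(results) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.label, r.a, r.b, r.c, r.d, r.odds_ratio, r.p, r.q) for r in results],
        columns=["label", "a", "b", "c", "d", "odds_ratio", "p", "q"],
    )
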