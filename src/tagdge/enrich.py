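"""Hypergeometric term enrichment of a screened gene set, Bonferroni-corrected.

For a background of ``N`` annotated genes of which ``n`` are in the screened
(differentially expressed) set, and a term annotating ``M`` background genes
of which ``m`` are screened, the enrichment p-value is the upper tail

    P = 1 - sum_{i=0}^{m-1} C(M, i) * C(N-M, n-i) / C(N, n)

i.e. one minus the hypergeometric CDF at m-1.  Terms containing at least one
screened gene are tested; raw p-values are Bonferroni-corrected over the
number of tested terms and a corrected p below ``alpha`` (default 0.05) flags
the term as enriched.
"""

from __future__ import annotations

import logging

import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


def hypergeom_enrich_p(N: int, n: int, M: int, m: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= m).

    N: annotated background genes; n: screened genes within N; M: background
    genes in the term; m: screened genes in the term.
    """
    if not 0 <= m:
        raise ValueError("m >= 0 violated")
    if m > n:
        raise ValueError("m <= n violated")
    if m > M:
        raise ValueError("m <= M violated")
    if M > N:
        raise ValueError("M <= N violated")
    if n > N:
        raise ValueError("n <= N violated")
    return float(hypergeom.sf(m - 1, N, M, n))


def enrich_terms(screened_genes, annotation: pd.DataFrame,
                 ontology: "str | None" = None,
                 alpha: float = 0.05,
                 bonferroni_all_terms: bool = False) -> pd.DataFrame:
    """Test every term containing at least one screened gene.

    ``annotation`` is a long table with columns gene, term, ontology.  The
    background N is the set of genes carrying at least one annotation (of the
    selected ontology), and the screened set is intersected with it first.
    With ``bonferroni_all_terms`` the Bonferroni divisor is the total number
    of terms rather than the number of tested (m >= 1) terms.

    Returns a table (term, ontology, N, n, M, m, p_value, p_bonferroni,
    enriched) sorted by corrected then raw p.
    """
    ann = annotation
    if ontology is not None:
        ann = ann[ann["ontology"] == ontology]
    background = set(ann["gene"])
    N = len(background)
    screened = set(screened_genes) & background
    n = len(screened)
    if n == 0:
        logger.warning("screened set does not intersect the annotated background")
        return pd.DataFrame(columns=["term", "ontology", "N", "n", "M", "m",
                                     "p_value", "p_bonferroni", "enriched"]
                            ).set_index("term")
    term_genes = ann.groupby("term")["gene"].agg(set)
    term_onto = ann.groupby("term")["ontology"].first()
    rows = []
    for term, genes in term_genes.items():
        m = len(genes & screened)
        if m < 1:
            continue
        M = len(genes)
        rows.append({"term": term, "ontology": term_onto[term],
                     "N": N, "n": n, "M": M, "m": m,
                     "p_value": hypergeom_enrich_p(N, n, M, m)})
    out = pd.DataFrame(rows)
    divisor = len(term_genes) if bonferroni_all_terms else len(out)
    out["p_bonferroni"] = (out["p_value"] * divisor).clip(upper=1.0)
    out["enriched"] = out["p_bonferroni"] < alpha
    return (out.sort_values(["p_bonferroni", "p_value", "term"])
               .set_index("term"))
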