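"""Gene-level crossing of differential methylation and differential expression.

Each gene is assigned a methylation direction from the significant peaks it
hosts (UP if only up-peaks, DOWN if only down-peaks, MIXED if both, NDE if
none) and an expression direction from the gene-level test, giving the
classic hyper/hypo x up/down quadrants plus MIXED and NDE margins.  Term
over-representation is a one-sided hypergeometric upper-tail test over
user-supplied term-to-gene maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .differential import DOWN, NDE, UP, bh_adjust

logger = logging.getLogger("merip_conjoint")

MIXED = "MIXED"

_METH_WORD = {UP: "hyper", DOWN: "hypo", MIXED: "mixed", NDE: "no-dmp"}
_EXPR_WORD = {UP: "up", DOWN: "down", NDE: "nde"}


@dataclass(frozen=True)
class ConjointRecord:
    gene_id: str
    meth_direction: str  # UP / DOWN / MIXED / NDE
    expr_direction: str  # UP / DOWN / NDE

    @property
    def quadrant(self) -> str:
        return f"{_METH_WORD[self.meth_direction]}-{_EXPR_WORD[self.expr_direction]}"


def gene_methylation_directions(
    peak_results: pd.DataFrame,
    peak_genes: Mapping[str, Optional[str]],
    alpha: float = 0.05,
) -> Dict[str, str]:
    """Collapse per-peak direction calls to one call per gene.

    Any gene hosting both significant UP and DOWN peaks is MIXED; genes with
    peaks but no significant one are NDE.
    """
    directions: Dict[str, set] = {}
    for peak_id, gene_id in peak_genes.items():
        if gene_id is None or peak_id not in peak_results.index:
            continue
        directions.setdefault(gene_id, set())
        call = peak_results.loc[peak_id, "direction"]
        if call in (UP, DOWN):
            directions[gene_id].add(call)
    out = {}
    for gene_id, calls in directions.items():
        if calls == {UP}:
            out[gene_id] = UP
        elif calls == {DOWN}:
            out[gene_id] = DOWN
        elif calls:
            out[gene_id] = MIXED
        else:
            out[gene_id] = NDE
    return out


def classify_conjoint(
    peak_results: pd.DataFrame,
    peak_genes: Mapping[str, Optional[str]],
    gene_results: pd.DataFrame,
    alpha: float = 0.05,
) -> Tuple[List[ConjointRecord], Dict[str, int]]:
    """Cross methylation and expression directions gene by gene.

    Returns one record per gene considered (genes hosting any assigned peak
    or present in the expression results) plus quadrant/overlap counts.
    Genes with peaks but absent from the expression table count as
    expression-NDE and are logged.
    """
    meth = gene_methylation_directions(peak_results, peak_genes, alpha=alpha)
    peak_hosting = {g for g in peak_genes.values() if g is not None}
    considered = sorted(peak_hosting | set(gene_results.index))
    missing_expr = peak_hosting - set(gene_results.index)
    if missing_expr:
        logger.warning(
            "%d gene(s) with peaks missing from expression table (treated NDE)",
            len(missing_expr),
        )
    records: List[ConjointRecord] = []
    for gene in considered:
        m = meth.get(gene, NDE)
        e = (
            gene_results.loc[gene, "direction"]
            if gene in gene_results.index
            else NDE
        )
        records.append(ConjointRecord(gene, m, e))

    counts: Dict[str, int] = {}
    for r in records:
        counts[r.quadrant] = counts.get(r.quadrant, 0) + 1
    sig_meth = {r.gene_id for r in records if r.meth_direction != NDE}
    sig_expr = {r.gene_id for r in records if r.expr_direction != NDE}
    counts.update(
        {
            "genes_considered": len(records),
            "dmp_only": len(sig_meth - sig_expr),
            "deg_only": len(sig_expr - sig_meth),
            "both": len(sig_meth & sig_expr),
            "dmp_genes": len(sig_meth),
            "deg_genes": len(sig_expr),
        }
    )
    return records, counts


def conjoint_frame(records: Sequence[ConjointRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "meth_direction": [r.meth_direction for r in records],
            "expr_direction": [r.expr_direction for r in records],
            "quadrant": [r.quadrant for r in records],
        }
    )


# ---------------------------------------------------------------------------
# Gene panels (writers / readers / erasers reporting)
# ---------------------------------------------------------------------------

def build_panel_report(
    panel: Sequence[Tuple[str, str, str]],
    comparison_calls: Mapping[str, Tuple[Mapping[str, str], Mapping[str, str]]],
    known_genes: Optional[Iterable[str]] = None,
) -> pd.DataFrame:
    """Per-panel-gene UP/DOWN/NDE calls across comparisons.

    ``panel`` rows are (gene_id, name, role); ``comparison_calls`` maps a
    comparison label to (gene->methylation direction, gene->expression
    direction) dictionaries.  Genes resolvable nowhere get an all-NDE row
    and a warning.
    """
    known = set(known_genes) if known_genes is not None else None
    rows = []
    for gene_id, name, role in panel:
        row: Dict[str, object] = {"gene_id": gene_id, "name": name, "role": role}
        seen = False
        for comp, (meth, expr) in comparison_calls.items():
            m = meth.get(gene_id, NDE)
            e = expr.get(gene_id, NDE)
            seen = seen or gene_id in meth or gene_id in expr
            row[f"{comp}_hcpeaks"] = m if m != MIXED else MIXED
            row[f"{comp}_DE_genes"] = e
        resolvable = seen or (known is not None and gene_id in known)
        if not resolvable:
            logger.warning("panel gene %s not resolvable; reported NDE", gene_id)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Term over-representation
# ---------------------------------------------------------------------------

@dataclass
class TermMap:
    """Term id -> (description, gene set), with an explicit gene universe."""

    terms: Dict[str, Tuple[str, FrozenSet[str]]]
    universe: FrozenSet[str]

    def __post_init__(self):
        if not self.universe:
            raise ValueError("term map universe is empty")
        for term_id, (_, genes) in self.terms.items():
            if not genes <= self.universe:
                raise ValueError(f"term {term_id!r} has genes outside the universe")


def read_term_map(path, universe: Optional[Iterable[str]] = None) -> TermMap:
    """Read a long-format TSV term map: term_id <TAB> description <TAB> gene_id.

    Without an explicit ``universe`` the union of all term genes is used.
    """
    df = pd.read_csv(path, sep="\t", header=0)
    df.columns = ["term_id", "description", "gene_id"]
    terms: Dict[str, Tuple[str, FrozenSet[str]]] = {}
    for term_id, sub in df.groupby("term_id", sort=True):
        terms[term_id] = (sub["description"].iloc[0], frozenset(sub["gene_id"]))
    uni = (
        frozenset(universe)
        if universe is not None
        else frozenset(df["gene_id"])
    )
    return TermMap(terms=terms, universe=uni)


def enrich_terms(
    gene_set: Iterable[str], term_map: TermMap, alpha: float = 0.05
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation per term.

    p = P(X >= x) with population N = |universe|, K = |term genes|,
    draws n = |gene_set| and overlap x; BH-adjusted across terms.
    """
    genes = frozenset(gene_set)
    if not genes <= term_map.universe:
        raise ValueError("gene set contains genes outside the universe")
    N, n = len(term_map.universe), len(genes)
    rows = []
    for term_id, (description, term_genes) in sorted(term_map.terms.items()):
        K = len(term_genes)
        x = len(genes & term_genes)
        p = float(stats.hypergeom.sf(x - 1, N, K, n))
        fold = (x / n) / (K / N) if (n > 0 and K > 0) else 0.0
        rows.append((term_id, description, x, K, n, N, fold, min(p, 1.0)))
    df = pd.DataFrame(
        rows,
        columns=[
            "term_id", "description", "overlap", "term_size",
            "query_size", "universe_size", "fold_enrichment", "pvalue",
        ],
    )
    df["fdr"] = bh_adjust(df["pvalue"].to_numpy()) if len(df) else []
    df["significant"] = df["fdr"] < alpha
    return df.sort_values(["pvalue", "term_id"], kind="mergesort").reset_index(
        drop=True
    )
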