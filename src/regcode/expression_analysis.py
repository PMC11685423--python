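"""Tissue-specific DEG sets, expression quintiles and the cross-inbred
homolog-conservation flow.

A gene is "tissue-specific" (up or down) when it is differentially
expressed in the stated direction in *every* pairwise comparison of that
tissue against each other tissue — intersection, not union, semantics.
Differential-expression fitting itself happens upstream; this module
consumes the resulting per-pair tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DE_COLUMNS = ("gene", "tissue_a", "tissue_b", "log2fc", "fdr")

CONSERVED = "conserved_DEG"
NOT_DEG = "homolog_not_DEG"
NO_HOMOLOG = "no_homolog"
STATUSES = (CONSERVED, NOT_DEG, NO_HOMOLOG)


def tissue_specific_sets(
    de: pd.DataFrame,
    tissue: str,
    direction: str = "up",
    fdr: float = 0.05,
    min_abs_log2fc: float = 0.0,
) -> set[str]:
    """Genes differential in ``direction`` in every pairing of ``tissue``
    against each other tissue.

    ``de`` columns: gene, tissue_a, tissue_b, log2fc (a over b), fdr.
    Each unordered pair may be stored in either orientation; the sign is
    flipped as needed. A tissue pairing absent from the table raises an
    error naming it.
    """
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    tissues = set(de["tissue_a"]) | set(de["tissue_b"])
    if tissue not in tissues:
        raise ValueError(f"tissue {tissue!r} not present in the DE table")
    others = sorted(tissues - {tissue})
    missing = []
    per_pair_sets = []
    for other in others:
        fwd = de[(de["tissue_a"] == tissue) & (de["tissue_b"] == other)]
        rev = de[(de["tissue_a"] == other) & (de["tissue_b"] == tissue)]
        if fwd.empty and rev.empty:
            missing.append((tissue, other))
            continue
        lfc = pd.concat([fwd["log2fc"], -rev["log2fc"]])
        q = pd.concat([fwd["fdr"], rev["fdr"]])
        genes = pd.concat([fwd["gene"], rev["gene"]])
        sig = q < fdr
        if direction == "up":
            sig &= lfc > min_abs_log2fc
        else:
            sig &= lfc < -min_abs_log2fc
        per_pair_sets.append(set(genes[sig]))
    if missing:
        raise ValueError(f"missing tissue pairings: {missing}")
    return set.intersection(*per_pair_sets) if per_pair_sets else set()


@dataclass
class ConservationFlow:
    """Per reference-DEG, per target-inbred conservation status.

    ``table`` is long format (gene, inbred, status); ``summary`` gives
    per-inbred percentages of the three exhaustive, exclusive statuses
    over all reference DEGs.
    """

    table: pd.DataFrame
    summary: pd.DataFrame

    def percent(self, inbred: str, status: str = CONSERVED) -> float:
        return float(self.summary.loc[inbred, status])


def homolog_flow(
    ref_degs: set[str],
    orthology: dict[str, dict[str, list[str]]],
    target_degs: dict[str, set[str]],
) -> ConservationFlow:
    """Track whether each reference DEG keeps differential expression in
    each target inbred through its homologs.

    ``orthology`` maps reference gene -> inbred -> homolog list; a gene
    missing from the map (or with an empty list) has no homolog in that
    inbred. A reference DEG is conserved in an inbred iff *any* listed
    homolog is in that inbred's DEG set.
    """
    rows = []
    for gene in sorted(ref_degs):
        per_inbred = orthology.get(gene, {})
        for inbred, degs in target_degs.items():
            homologs = per_inbred.get(inbred, [])
            if not homologs:
                status = NO_HOMOLOG
            elif any(h in degs for h in homologs):
                status = CONSERVED
            else:
                status = NOT_DEG
            rows.append({"gene": gene, "inbred": inbred, "status": status})
    table = pd.DataFrame(rows, columns=["gene", "inbred", "status"])
    n_ref = len(ref_degs)
    summary_rows = {}
    for inbred in target_degs:
        sub = table[table["inbred"] == inbred]["status"]
        summary_rows[inbred] = {
            s: (100.0 * (sub == s).sum() / n_ref if n_ref else np.nan) for s in STATUSES
        }
    summary = pd.DataFrame(summary_rows).T.reindex(columns=list(STATUSES))
    return ConservationFlow(table, summary)


def orthology_from_table(df: pd.DataFrame) -> dict[str, dict[str, list[str]]]:
    """Build the orthology map from a long TSV (ref_gene, inbred, homolog)."""
    out: dict[str, dict[str, list[str]]] = {}
    for r in df.itertuples(index=False):
        out.setdefault(str(r.ref_gene), {}).setdefault(str(r.inbred), []).append(
            str(r.homolog)
        )
    return out


def quintile_bins(
    expr: pd.DataFrame, tissue: str, min_rpkm: float = 0.0
) -> pd.Series:
    """Rank expressed genes (RPKM > min_rpkm) in one tissue into five
    near-equal bins, 1 = lowest expression, 5 = highest.

    Ties are broken by gene id so the split is deterministic;
    non-expressed genes are left out of the result.
    """
    col = expr[tissue]
    expressed = col[col > min_rpkm]
    if len(expressed) < 5:
        raise ValueError(f"need >= 5 expressed genes, got {len(expressed)}")
    order = expressed.sort_index().sort_values(kind="stable").index
    chunks = np.array_split(np.arange(len(order)), 5)
    q = pd.Series(0, index=order, dtype=int, name="quintile")
    for qi, idx in enumerate(chunks, start=1):
        q.iloc[idx] = qi
    return q
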