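"""Curation of resistance-gene homolog sets from homology-hit tables.

Two gene families are curated differently, reflecting how reliably each
can be told apart from its confounders:

* **Erm** (23S rRNA methyltransferase) hits keep everything at or above
  an identity threshold (default 35%), then drop hits recognizable as the
  closely related housekeeping dimethyltransferase KsgA by their genomic
  context: the ksgA gene sits in a neighborhood conserved across
  actinobacteria, flanked by IspE (4-diphosphocytidyl-2-C-methyl-D-
  erythritol kinase), a TatD-family deoxyribonuclease, and
  methionyl-tRNA synthetase.  A hit is excluded when at least two of the
  three marker products occur within a +/- ``window`` gene span.

* **ABC transporter ATPase** hits are filtered at a percent-positives
  threshold (default 40%) and then reduced to the single closest homolog
  per genome, "closest" operationalized as maximal bitscore (ties: higher
  percent identity, then lexicographic subject id).
"""

from __future__ import annotations

import logging

import pandas as pd

logger = logging.getLogger(__name__)

#: case-insensitive substring synonyms for the three conserved ksgA neighbors
KSGA_MARKER_SYNONYMS = (
    ("4-diphosphocytidyl-2-c-methyl-d-erythritol kinase", "ispe"),
    ("tatd",),
    ("methionyl-trna synthetase", "methionine--trna ligase", "metg"),
)

#: markers (of the three) that must match within the window to call a hit ksgA
KSGA_MIN_MARKERS = 2


def _matched_markers(products) -> int:
    """Count how many distinct marker groups occur among the given annotations."""
    lowered = [str(p).lower() for p in products]
    hits = 0
    for synonyms in KSGA_MARKER_SYNONYMS:
        if any(s in p for p in lowered for s in synonyms):
            hits += 1
    return hits


def is_ksga_context(
    genome: str, gene_id: str, neighborhoods: pd.DataFrame, window: int = 3
) -> bool | None:
    """Decide from genomic context whether a gene looks like ksgA.

    Returns True/False, or None when the gene is absent from the
    neighborhood table (context unknown).
    """
    genes = neighborhoods[neighborhoods["genome"] == genome]
    own = genes[genes["gene_id"] == gene_id]
    if own.empty:
        return None
    pos = int(own["position_index"].iloc[0])
    near = genes[
        (genes["position_index"] >= pos - window)
        & (genes["position_index"] <= pos + window)
        & (genes["position_index"] != pos)
    ]
    return _matched_markers(near["product"]) >= KSGA_MIN_MARKERS


def select_erm(
    hits: pd.DataFrame,
    neighborhoods: pd.DataFrame,
    min_identity: float = 35.0,
    window: int = 3,
) -> pd.DataFrame:
    """Erm selection: identity threshold plus ksgA genomic-context exclusion.

    Returns the retained hit rows with an added boolean ``context_known``
    column; hits missing from the neighborhood table are retained but
    flagged and logged.
    """
    kept = hits[hits["pct_identity"] >= min_identity].copy()
    flags, context_known = [], []
    for _, row in kept.iterrows():
        verdict = is_ksga_context(row["genome"], row["subject_id"], neighborhoods, window)
        if verdict is None:
            logger.warning(
                "context unknown for %s/%s; hit retained",
                row["genome"],
                row["subject_id"],
            )
            flags.append(False)
            context_known.append(False)
        else:
            flags.append(verdict)
            context_known.append(True)
    kept["context_known"] = context_known
    ksga_mask = pd.Series(flags, index=kept.index, dtype=bool)
    kept = kept[~ksga_mask]
    return kept.reset_index(drop=True)


def select_abc(hits: pd.DataFrame, min_positives: float = 40.0) -> pd.DataFrame:
    """ABC ATPase selection: best qualifying hit per genome.

    Keeps hits with percent positives >= threshold, then the maximal-
    bitscore hit per genome (ties broken by percent identity, then
    subject id).  Genomes with no qualifying hit are absent.
    """
    kept = hits[hits["pct_positives"] >= min_positives]
    if kept.empty:
        return kept.reset_index(drop=True)
    ordered = kept.sort_values(
        ["genome", "bitscore", "pct_identity", "subject_id"],
        ascending=[True, False, False, True],
        kind="mergesort",
    )
    # subject_id ascending makes the lexicographically smallest id win ties
    best = ordered.groupby("genome", sort=True).head(1)
    return best.reset_index(drop=True)


def subset_with_both(erm_selected: pd.DataFrame, abc_selected: pd.DataFrame) -> set:
    """Genomes carrying both curated resistance genes (the co-occurrence set)."""
    return set(erm_selected["genome"]) & set(abc_selected["genome"])
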